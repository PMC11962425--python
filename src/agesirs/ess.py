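"""Evolutionarily stable recovery rates under the infectivity-recovery trade-off.

Under slow aging the stationarity condition for the invasion number
decouples across age stages: the ESS recovery rate of stage ``i`` solves

    beta'(gamma_i) * (a_i + gamma_i + d_i + delta_i) = beta(gamma_i),

geometrically the point where a line through ``(-(a_i + d_i + delta_i), 0)``
is tangent to the trade-off curve.  Within-stage contact rates cancel from
this condition, so only the shape of ``beta(gamma)`` matters.  For the power
law ``beta = c * gamma**p`` (0 < p < 1) the root is ``gamma* = p m / (1-p)``
with ``m = a + d + delta``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from . import model, ngm
from .params import PopulationStructure, StrainTraits, TradeOff, TransmissionStructure

__all__ = [
    "ESSResult",
    "InvasionReport",
    "ess_residual",
    "solve_ess",
    "ess_power_law_closed_form",
    "tangency_check",
    "verify_ess_by_invasion",
]

#: default multiplicative probes applied per stage in invasion verification
DEFAULT_PROBE_FACTORS = (0.25, 0.5, 0.8, 0.9, 1.1, 1.25, 2.0, 4.0)


@dataclass
class ESSResult:
    gamma_star: np.ndarray
    beta_star: np.ndarray
    residuals: np.ndarray
    r0_at_ess: float
    tangency_slope: np.ndarray
    tangency_intercept: np.ndarray


@dataclass
class InvasionReport:
    """Outcome of probing an ESS candidate with mutant recovery rates."""

    q0_values: np.ndarray
    max_q0: float
    tolerance: float
    passed: bool
    subcritical_resident: bool


def ess_residual(gamma: float, a: float, d: float, delta: float, tradeoff: TradeOff) -> float:
    """Stationarity residual ``beta'(gamma)(a + gamma + d + delta) - beta(gamma)``.

    Roots are ESS candidates for a stage with aging rate ``a``, disease
    mortality ``d`` and background mortality ``delta``.  Within-stage
    contact scalars multiply both terms and therefore rescale the residual
    without moving its root.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    bp = float(tradeoff.beta_prime(gamma))
    b = float(tradeoff.beta(gamma))
    return bp * (a + gamma + d + delta) - b


def ess_power_law_closed_form(p: float, m) -> np.ndarray:
    """Closed-form ESS recovery rate ``gamma* = p m / (1 - p)`` for ``beta = c gamma**p``.

    ``m = a + d + delta`` is the stage's non-recovery removal rate.  Valid
    for ``0 < p < 1``; at ``p >= 1`` the trade-off is no longer concave and
    the optimum is unbounded.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("power-law exponent must satisfy 0 < p < 1 for an ESS")
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise ValueError("m = a + d + delta must be positive")
    return p * m / (1.0 - p)


def solve_ess(
    pop: PopulationStructure,
    disease_mortality,
    tradeoff: TradeOff,
    trans: Optional[TransmissionStructure] = None,
    bracket=(1e-6, 1e3),
    xtol: float = 1e-14,
) -> ESSResult:
    """Per-stage ESS recovery rates by bracketed root finding of the residual.

    Stages decouple under the slow-aging approximation, so each
    ``gamma_i*`` is found independently with Brent's method.  The bracket is
    scanned on a log grid first; the solver asserts exactly one sign change
    (multiple roots are reported as an error since the concavity-based
    uniqueness argument then fails).  ``r0_at_ess`` is evaluated with the
    supplied transmission structure, or unit contacts if none is given.
    """
    d = np.atleast_1d(np.asarray(disease_mortality, dtype=float))
    if d.size != pop.n:
        raise ValueError("disease_mortality must have one entry per stage")
    if tradeoff.form == "power_law" and not tradeoff.exponent < 1.0:
        raise ValueError(
            "power-law exponent p >= 1: the trade-off is not concave, the optimum "
            "is unbounded (a 'Darwinian demon') and no ESS exists"
        )
    tradeoff.check_concavity(lo=max(bracket[0], 1e-6), hi=min(bracket[1], 1e2))
    n = pop.n
    gamma_star = np.empty(n)
    residuals = np.empty(n)
    lo, hi = bracket
    grid = np.geomspace(lo, hi, 200)
    for i in range(n):
        a_i = pop.aging_rates[i]
        d_i = d[i]
        delta_i = pop.background_mortality[i]

        def f(g):
            return ess_residual(g, a_i, d_i, delta_i, tradeoff)

        vals = np.array([f(g) for g in grid])
        signs = np.sign(vals)
        changes = np.nonzero(signs[:-1] * signs[1:] < 0)[0]
        if changes.size == 0:
            raise ValueError(
                f"stage {i + 1}: no sign change of the ESS residual in "
                f"[{lo:g}, {hi:g}]; widen the bracket or check the trade-off"
            )
        if changes.size > 1:
            raise ValueError(
                f"stage {i + 1}: {changes.size} sign changes of the ESS residual in "
                f"the bracket; the root is not unique (non-concave trade-off?)"
            )
        k = changes[0]
        gamma_star[i] = brentq(f, grid[k], grid[k + 1], xtol=xtol, rtol=8.9e-16)
        residuals[i] = f(gamma_star[i])
    beta_star = np.asarray(tradeoff.beta(gamma_star), dtype=float)
    slope = np.asarray(tradeoff.beta_prime(gamma_star), dtype=float)
    m = pop.aging_rates + d + pop.background_mortality
    intercept = slope * m  # line value at gamma = 0, i.e. beta' * m
    if trans is None:
        trans = TransmissionStructure(
            mode="outer_product",
            susceptibility=np.ones(n),
            infectivity_weights=np.ones(n),
        )
    strain_star = StrainTraits(recovery=gamma_star, disease_mortality=d, tradeoff=tradeoff)
    r0_at_ess = ngm.r0(pop, strain_star, trans, method="eigen")
    return ESSResult(gamma_star=gamma_star, beta_star=beta_star, residuals=residuals,
                     r0_at_ess=r0_at_ess, tangency_slope=slope, tangency_intercept=intercept)


def tangency_check(
    gamma_star,
    a,
    d,
    delta,
    tradeoff: TradeOff,
    grid_size: int = 1000,
    span: float = 100.0,
):
    """Geometric reading of the stationarity condition, per stage.

    The line through ``(-(a + d + delta), 0)`` with slope ``beta'(gamma*)``
    touches the trade-off curve at ``gamma*`` and — for a concave trade-off —
    lies weakly above it everywhere.  Returns ``(slope, intercept, max_gap)``
    arrays where ``max_gap`` is the largest amount by which the curve rises
    above the line on a log grid (0 up to round-off for a concave
    trade-off; positive values flag a concavity violation).
    """
    gamma_star = np.atleast_1d(np.asarray(gamma_star, dtype=float))
    a = np.broadcast_to(np.asarray(a, dtype=float), gamma_star.shape)
    d = np.broadcast_to(np.asarray(d, dtype=float), gamma_star.shape)
    delta = np.broadcast_to(np.asarray(delta, dtype=float), gamma_star.shape)
    m = a + d + delta
    slope = np.asarray(tradeoff.beta_prime(gamma_star), dtype=float)
    intercept = slope * m
    max_gap = np.empty_like(gamma_star)
    for i, (g_star, s, m_i) in enumerate(zip(gamma_star, slope, m)):
        grid = np.geomspace(g_star / span, g_star * span, grid_size)
        line = s * (grid + m_i)
        curve = np.asarray(tradeoff.beta(grid), dtype=float)
        max_gap[i] = float(np.max(curve - line))
    return slope, intercept, max_gap


def verify_ess_by_invasion(
    ess: ESSResult,
    pop: PopulationStructure,
    trans: TransmissionStructure,
    tradeoff: TradeOff,
    disease_mortality=None,
    probe_factors: Sequence[float] = DEFAULT_PROBE_FACTORS,
    n_random: int = 50,
    random_scale: float = 0.3,
    seed: int = 0,
    tolerance: Optional[float] = None,
) -> InvasionReport:
    """Probe the ESS with mutant recovery rates and check no one invades.

    Each stage's ``gamma*`` is perturbed by the multiplicative
    ``probe_factors`` one stage at a time, plus ``n_random`` joint log-normal
    perturbations (fixed ``seed``).  The resident sits at its endemic
    equilibrium; the check passes when every probe's invasion number is at
    most ``1 + tolerance``.  The default tolerance is strict (1e-6) for a
    single stage — where the stationarity condition is exact — and scales
    with ``max_i a_i / (gamma_i + d_i)`` otherwise, reflecting the
    slow-aging approximation that decouples the stages.
    """
    n = pop.n
    d = (np.zeros(n) if disease_mortality is None
         else np.atleast_1d(np.asarray(disease_mortality, dtype=float)))
    resident = StrainTraits(recovery=ess.gamma_star, disease_mortality=d, tradeoff=tradeoff)
    if tolerance is None:
        if n == 1:
            tolerance = 1e-6
        else:
            ratio = float(np.max(pop.aging_rates / (ess.gamma_star + d)))
            tolerance = max(1e-6, 10.0 * ratio ** 2)
    eq = model.endemic_equilibrium(pop, resident, trans)
    if eq.subcritical:
        return InvasionReport(q0_values=np.array([]), max_q0=np.nan,
                              tolerance=tolerance, passed=False,
                              subcritical_resident=True)
    S_star = eq.state.S
    probes = []
    for i in range(n):
        for f in probe_factors:
            g = ess.gamma_star.copy()
            g[i] *= f
            probes.append(g)
    rng = np.random.default_rng(seed)
    for _ in range(n_random):
        probes.append(ess.gamma_star * np.exp(random_scale * rng.standard_normal(n)))
    q0 = np.array([
        ngm.invasion_number(S_star, pop, resident.with_recovery(g), trans)
        for g in probes
    ])
    max_q0 = float(q0.max())
    return InvasionReport(q0_values=q0, max_q0=max_q0, tolerance=tolerance,
                          passed=bool(max_q0 <= 1.0 + tolerance),
                          subcritical_resident=False)
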