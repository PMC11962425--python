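"""ODE right-hand sides and equilibria of the age-structured SIRS model.

Single-strain dynamics per age stage ``i`` (stage 1 receives all births,
which balance all deaths so the total population is constant):

    dS_i/dt = a_{i-1} S_{i-1} - (a_i + delta_i) S_i + omega R_i - S_i sum_j beta_ij I_j
    dI_i/dt = a_{i-1} I_{i-1} + S_i sum_j beta_ij I_j - (a_i + gamma_i + d_i + delta_i) I_i
    dR_i/dt = a_{i-1} R_{i-1} + gamma_i I_i - (a_i + delta_i + omega) R_i

with the stage-1 susceptible equation carrying the birth term
``sum_i [d_i I_i + delta_i (S_i + I_i + R_i)]`` instead of aging-in.  The
two-strain extension adds mutant pools ``I~, R~`` with total cross-immunity:
both recovered pools return to S, and the birth term also recycles
mutant-branch deaths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import ngm
from .params import PopulationStructure, StrainTraits, TransmissionStructure

__all__ = [
    "SystemState",
    "AggregateEquilibrium",
    "EquilibriumResult",
    "Trajectory",
    "single_strain_rhs",
    "two_strain_rhs",
    "integrate",
    "endemic_equilibrium",
    "aggregate_endemic",
]


@dataclass
class SystemState:
    """Per-stage compartment densities, optionally with mutant pools."""

    S: np.ndarray
    I: np.ndarray
    R: np.ndarray
    I_tilde: Optional[np.ndarray] = None
    R_tilde: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.S = np.atleast_1d(np.asarray(self.S, dtype=float))
        self.I = np.atleast_1d(np.asarray(self.I, dtype=float))
        self.R = np.atleast_1d(np.asarray(self.R, dtype=float))
        if not (self.S.shape == self.I.shape == self.R.shape):
            raise ValueError("S, I, R must have equal lengths")
        if (self.I_tilde is None) != (self.R_tilde is None):
            raise ValueError("mutant pools I_tilde and R_tilde must be given together")
        if self.I_tilde is not None:
            self.I_tilde = np.atleast_1d(np.asarray(self.I_tilde, dtype=float))
            self.R_tilde = np.atleast_1d(np.asarray(self.R_tilde, dtype=float))
            if self.I_tilde.shape != self.S.shape or self.R_tilde.shape != self.S.shape:
                raise ValueError("mutant pools must match the stage count")

    @property
    def n(self) -> int:
        return self.S.size

    @property
    def has_mutant(self) -> bool:
        return self.I_tilde is not None

    @property
    def total(self) -> float:
        t = float(self.S.sum() + self.I.sum() + self.R.sum())
        if self.has_mutant:
            t += float(self.I_tilde.sum() + self.R_tilde.sum())
        return t

    def to_vector(self) -> np.ndarray:
        parts = [self.S, self.I, self.R]
        if self.has_mutant:
            parts += [self.I_tilde, self.R_tilde]
        return np.concatenate(parts)

    @classmethod
    def from_vector(cls, y: np.ndarray, n: int, mutant: bool = False) -> "SystemState":
        y = np.asarray(y, dtype=float)
        k = 5 if mutant else 3
        if y.size != k * n:
            raise ValueError(f"state vector has length {y.size}, expected {k * n}")
        blocks = [y[i * n : (i + 1) * n] for i in range(k)]
        if mutant:
            return cls(S=blocks[0], I=blocks[1], R=blocks[2], I_tilde=blocks[3], R_tilde=blocks[4])
        return cls(S=blocks[0], I=blocks[1], R=blocks[2])


@dataclass
class AggregateEquilibrium:
    """Closed-form endemic equilibrium of the aggregate S, I, R totals.

    Valid in the low-CFR limit (d << delta); exact for n = 1 with d = 0.
    ``gamma_bar`` and ``delta_bar`` are averages weighted by the
    disease-free age structure.
    """

    S_star: float
    I_star: float
    R_star: float
    gamma_bar: float
    delta_bar: float
    r0: float
    supercritical: bool


def _aging_in(a: np.ndarray, v: np.ndarray) -> np.ndarray:
    out = np.zeros_like(v)
    out[1:] = a[:-1] * v[:-1]
    return out


def _rhs_single(y, n, a, delta, omega, gamma, d, beta):
    S, I, R = y[:n], y[n : 2 * n], y[2 * n :]
    lam = beta @ I
    births = float(delta @ (S + I + R) + d @ I)
    dS = _aging_in(a, S) - (a + delta) * S + omega * R - lam * S
    dS[0] += births
    dI = _aging_in(a, I) + lam * S - (a + gamma + d + delta) * I
    dR = _aging_in(a, R) + gamma * I - (a + delta + omega) * R
    return np.concatenate([dS, dI, dR])


def _rhs_two(y, n, a, delta, omega, gamma, d, beta, gamma_m, beta_m):
    S = y[:n]
    I = y[n : 2 * n]
    R = y[2 * n : 3 * n]
    It = y[3 * n : 4 * n]
    Rt = y[4 * n :]
    lam = beta @ I
    lam_m = beta_m @ It
    births = float(delta @ (S + I + R + It + Rt) + d @ (I + It))
    dS = _aging_in(a, S) - (a + delta) * S + omega * (R + Rt) - (lam + lam_m) * S
    dS[0] += births
    dI = _aging_in(a, I) + lam * S - (a + gamma + d + delta) * I
    dR = _aging_in(a, R) + gamma * I - (a + delta + omega) * R
    dIt = _aging_in(a, It) + lam_m * S - (a + gamma_m + d + delta) * It
    dRt = _aging_in(a, Rt) + gamma_m * It - (a + delta + omega) * Rt
    return np.concatenate([dS, dI, dR, dIt, dRt])


def single_strain_rhs(
    state: SystemState,
    pop: PopulationStructure,
    strain: StrainTraits,
    trans: TransmissionStructure,
) -> SystemState:
    """Time derivative of the single-strain system at ``state``."""
    if state.has_mutant:
        raise ValueError("single-strain RHS called on a state with mutant pools")
    if state.n != pop.n:
        raise ValueError("state and population dimensions differ")
    beta = trans.beta_matrix(strain)
    dy = _rhs_single(
        state.to_vector(), pop.n, pop.aging_rates, pop.background_mortality,
        pop.immunity_loss, strain.recovery, strain.disease_mortality, beta,
    )
    return SystemState.from_vector(dy, pop.n)


def two_strain_rhs(
    state: SystemState,
    pop: PopulationStructure,
    resident: StrainTraits,
    mutant: StrainTraits,
    trans_resident: TransmissionStructure,
    trans_mutant: Optional[TransmissionStructure] = None,
) -> SystemState:
    """Time derivative of the resident + mutant system at ``state``.

    Both strains share the host demography, disease mortality and immunity
    loss; they differ in recovery (and hence, through the trade-off, in
    infectivity).  ``trans_mutant`` defaults to the resident's contact
    structure.
    """
    if not state.has_mutant:
        raise ValueError("two-strain RHS needs a state with mutant pools")
    if state.n != pop.n:
        raise ValueError("state and population dimensions differ")
    if trans_mutant is None:
        trans_mutant = trans_resident
    beta = trans_resident.beta_matrix(resident)
    beta_m = trans_mutant.beta_matrix(mutant)
    dy = _rhs_two(
        state.to_vector(), pop.n, pop.aging_rates, pop.background_mortality,
        pop.immunity_loss, resident.recovery, resident.disease_mortality,
        beta, mutant.recovery, beta_m,
    )
    return SystemState.from_vector(dy, pop.n, mutant=True)


@dataclass
class Trajectory:
    """Time-ordered solution of an integration run."""

    t: np.ndarray
    y: np.ndarray  # shape (dim, len(t))
    n: int
    mutant: bool
    converged: bool

    @property
    def final_state(self) -> SystemState:
        return SystemState.from_vector(self.y[:, -1], self.n, mutant=self.mutant)

    def state_at(self, index: int) -> SystemState:
        return SystemState.from_vector(self.y[:, index], self.n, mutant=self.mutant)

    def as_frame(self) -> pd.DataFrame:
        names = compartment_names(self.n, self.mutant)
        frame = pd.DataFrame(self.y.T, columns=names)
        frame.insert(0, "t", self.t)
        return frame


def compartment_names(n: int, mutant: bool = False) -> list:
    names = [f"S{i}" for i in range(1, n + 1)]
    names += [f"I{i}" for i in range(1, n + 1)]
    names += [f"R{i}" for i in range(1, n + 1)]
    if mutant:
        names += [f"Itilde{i}" for i in range(1, n + 1)]
        names += [f"Rtilde{i}" for i in range(1, n + 1)]
    return names


_NEG_TOL = 1e-7


def integrate(
    initial: SystemState,
    pop: PopulationStructure,
    strain: StrainTraits,
    trans: TransmissionStructure,
    horizon: float,
    mutant: Optional[StrainTraits] = None,
    trans_mutant: Optional[TransmissionStructure] = None,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    equilibrium_tol: float = 1e-10,
    n_eval: Optional[int] = None,
    method: str = "LSODA",
) -> Trajectory:
    """Integrate the single- or two-strain system over ``[0, horizon]``.

    The two-strain RHS is selected automatically when ``initial`` carries
    mutant pools (``mutant`` traits are then required).  The returned
    trajectory is flagged converged when the RHS max-norm at the terminal
    state is below ``equilibrium_tol``.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if initial.n != pop.n:
        raise ValueError("initial state and population dimensions differ")
    if np.min(initial.to_vector()) < -_NEG_TOL:
        raise ValueError("initial state has negative entries")
    n = pop.n
    a, delta, omega = pop.aging_rates, pop.background_mortality, pop.immunity_loss
    beta = trans.beta_matrix(strain)
    if initial.has_mutant:
        if mutant is None:
            raise ValueError("two-strain initial state needs mutant traits")
        beta_m = (trans_mutant or trans).beta_matrix(mutant)

        def fun(t, y):
            return _rhs_two(y, n, a, delta, omega, strain.recovery,
                            strain.disease_mortality, beta, mutant.recovery, beta_m)
    else:

        def fun(t, y):
            return _rhs_single(y, n, a, delta, omega, strain.recovery,
                               strain.disease_mortality, beta)

    t_eval = np.linspace(0.0, horizon, n_eval) if n_eval else None
    sol = solve_ivp(fun, (0.0, horizon), initial.to_vector(), method=method,
                    rtol=rtol, atol=atol, t_eval=t_eval, dense_output=False)
    if not sol.success:
        raise RuntimeError(f"integrator failed: {sol.message}")
    y_end = sol.y[:, -1]
    worst = int(np.argmin(y_end))
    if y_end[worst] < -_NEG_TOL:
        names = compartment_names(n, initial.has_mutant)
        raise RuntimeError(
            f"integration produced negative density in {names[worst]}: {y_end[worst]:.3e}"
        )
    converged = float(np.max(np.abs(fun(sol.t[-1], y_end)))) < equilibrium_tol
    return Trajectory(t=sol.t, y=sol.y, n=n, mutant=initial.has_mutant, converged=converged)


@dataclass
class EquilibriumResult:
    """Endemic (or disease-free) equilibrium with its residual RHS norm."""

    state: SystemState
    residual: float
    converged: bool
    subcritical: bool
    elapsed: float


def _fd_jacobian(fun, y, eps=1e-8):
    m = y.size
    f0 = fun(y)
    J = np.empty((m, m))
    for k in range(m):
        h = eps * max(1.0, abs(y[k]))
        yk = y.copy()
        yk[k] += h
        J[:, k] = (fun(yk) - f0) / h
    return J


def _newton_polish(fun, y0, total, tol, max_iter=40):
    """Newton iteration on the RHS with the last equation replaced by conservation.

    The RHS conserves the total population identically, so its Jacobian has
    a left null vector and is singular; substituting ``sum(y) - total = 0``
    for one equation pins the equilibrium on the simplex.  Returns the
    refined state and residual, or None when the iteration leaves the
    admissible region.
    """
    y = y0.copy()
    res = float(np.max(np.abs(fun(y))))
    for _ in range(max_iter):
        if res < tol * 1e-2:
            break
        F = fun(y)
        F = F.copy()
        F[-1] = y.sum() - total
        J = _fd_jacobian(fun, y)
        J[-1, :] = 1.0
        try:
            step = np.linalg.solve(J, -F)
        except np.linalg.LinAlgError:
            return None
        t = 1.0
        improved = False
        while t >= 1e-4:
            y_new = y + t * step
            res_new = float(np.max(np.abs(fun(y_new))))
            if res_new < res:
                y, res = y_new, res_new
                improved = True
                break
            t /= 2.0
        if not improved:
            break
    if np.min(y) < -_NEG_TOL or res > tol:
        return None
    return y, res


def endemic_equilibrium(
    pop: PopulationStructure,
    strain: StrainTraits,
    trans: TransmissionStructure,
    total: float = 1.0,
    initial: Optional[SystemState] = None,
    tol: float = 1e-10,
    max_time: float = 1e6,
    rtol: float = 1e-9,
    atol: float = 1e-12,
    seed_fraction: float = 1e-3,
) -> EquilibriumResult:
    """Endemic equilibrium of the single-strain model.

    Requires R0 > 1 (otherwise the disease-free state is returned with the
    ``subcritical`` flag set).  The equilibrium is found by integrating from
    a seeded disease-free state (or the supplied ``initial`` guess, e.g. the
    previous equilibrium after a small trait change) in growing chunks until
    the RHS norm is small, then refined by a conservation-constrained Newton
    polish; the reported residual is the final RHS max-norm.
    """
    n = pop.n
    basic = ngm.r0(pop, strain, trans, method="eigen", total=total)
    dfe = ngm.disease_free_equilibrium(pop, total=total)
    if basic <= 1.0:
        state = SystemState(S=dfe.S_hat.copy(), I=np.zeros(n), R=np.zeros(n))
        return EquilibriumResult(state=state, residual=0.0, converged=True,
                                 subcritical=True, elapsed=0.0)
    a, delta, omega = pop.aging_rates, pop.background_mortality, pop.immunity_loss
    beta = trans.beta_matrix(strain)

    def fun(y):
        return _rhs_single(y, n, a, delta, omega, strain.recovery,
                           strain.disease_mortality, beta)

    if initial is not None:
        y = initial.to_vector().copy()
    else:
        seed = seed_fraction * dfe.S_hat
        y = np.concatenate([dfe.S_hat - seed, seed, np.zeros(n)])
    elapsed = 0.0
    chunk = 500.0
    polish_from = 1e-5
    while True:
        res = float(np.max(np.abs(fun(y))))
        if res < polish_from:
            polished = _newton_polish(fun, y, total, tol)
            if polished is not None:
                y_ref, res_ref = polished
                # reject spurious convergence to the (unstable) disease-free state
                if y_ref[n : 2 * n].sum() > 1e-10 * total:
                    state = SystemState.from_vector(y_ref, n)
                    return EquilibriumResult(state=state, residual=res_ref,
                                             converged=True, subcritical=False,
                                             elapsed=elapsed)
        if res < tol:
            state = SystemState.from_vector(y, n)
            return EquilibriumResult(state=state, residual=res, converged=True,
                                     subcritical=False, elapsed=elapsed)
        if elapsed >= max_time:
            state = SystemState.from_vector(y, n)
            return EquilibriumResult(state=state, residual=res, converged=False,
                                     subcritical=False, elapsed=elapsed)
        sol = solve_ivp(lambda t, yy: fun(yy), (0.0, chunk), y, method="LSODA",
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise RuntimeError(f"equilibrium integration failed: {sol.message}")
        y = sol.y[:, -1]
        elapsed += chunk
        chunk = min(chunk * 2.0, 2e5)


def aggregate_endemic(
    pop: PopulationStructure,
    strain: StrainTraits,
    trans: TransmissionStructure,
    total: float = 1.0,
) -> AggregateEquilibrium:
    """Closed-form endemic equilibrium of the aggregate compartments.

    In the low-CFR limit the aggregate totals settle at

        S* = 1/R0,
        I* = delta_bar (1 - 1/R0) / (gamma_bar + delta_bar
             - omega gamma_bar / (omega + delta_bar)),
        R* = gamma_bar I* / (omega + delta_bar),

    with gamma_bar, delta_bar averaged over the disease-free age structure.
    Exact for n = 1 with d = 0; an approximation otherwise.  Subcritical
    inputs (R0 <= 1) return the disease-free aggregates.
    """
    dfe = ngm.disease_free_equilibrium(pop, total=total)
    w = dfe.S_hat / dfe.S_hat.sum()
    gamma_bar = float(w @ strain.recovery)
    delta_bar = float(w @ pop.background_mortality)
    omega = pop.immunity_loss
    basic = ngm.r0(pop, strain, trans, method="eigen", total=total)
    if basic <= 1.0:
        return AggregateEquilibrium(S_star=total, I_star=0.0, R_star=0.0,
                                    gamma_bar=gamma_bar, delta_bar=delta_bar,
                                    r0=basic, supercritical=False)
    S_star = total / basic
    denom = gamma_bar + delta_bar - omega * gamma_bar / (omega + delta_bar)
    I_star = delta_bar * (total - total / basic) / denom
    R_star = gamma_bar * I_star / (omega + delta_bar)
    return AggregateEquilibrium(S_star=S_star, I_star=I_star, R_star=R_star,
                                gamma_bar=gamma_bar, delta_bar=delta_bar,
                                r0=basic, supercritical=True)
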