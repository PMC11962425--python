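"""Variant replacement: repeated mutant invasion of a resident strain.

Evolution proceeds as a chain of invasion attempts.  A mutant recovery-rate
vector is drawn from a multiplicative log-normal kernel around the resident,
its infectivity follows from the trade-off, and the attempt is settled
either by explicit two-strain ODE competition at the resident's endemic
equilibrium (``ode_competition``) or by the adaptive-dynamics surrogate
(``adaptive_dynamics``: the mutant fixes if and only if its invasion number
exceeds one).  On fixation the mutant becomes the new resident, its endemic
equilibrium is recomputed, and the chain continues.  Two sensitivity modes
break the model's simplifying assumptions: a random (non-rank-1) contact
matrix, and disease mortality far above background mortality.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import model, ngm
from .params import PopulationStructure, StrainTraits, TransmissionStructure

__all__ = [
    "MutationKernel",
    "CompetitionSettings",
    "CompetitionOutcome",
    "EvolutionRecord",
    "EvolutionTrajectory",
    "propose_mutant",
    "compete",
    "run_evolution",
    "sensitivity_random_contacts",
    "sensitivity_high_cfr",
]


@dataclass
class MutationKernel:
    """Multiplicative log-normal proposal kernel for mutant recovery rates.

    ``gamma~_i = gamma_i * exp(step_scale * z_i)`` with standard-normal
    ``z``; with ``per_stage=True`` only one randomly chosen stage is
    perturbed per proposal.  Multiplicative steps keep gamma positive and
    scale-free.
    """

    step_scale: float = 0.1
    per_stage: bool = False

    def __post_init__(self) -> None:
        if self.step_scale < 0:
            raise ValueError("step_scale must be nonnegative")


@dataclass
class CompetitionSettings:
    """Thresholds for the two-strain competition integration.

    ``seed_fraction`` of the total population is moved from the resident's
    infected pools to the mutant's (proportionally across stages) — small
    enough that the linearised mutant dynamics govern early growth.  The
    mutant fixes when its share of all infections exceeds
    ``fixation_threshold``, goes extinct when its pooled density falls below
    ``extinction_threshold`` (of total population), and the resident is
    retained on ``max_time`` timeout.
    """

    seed_fraction: float = 1e-6
    fixation_threshold: float = 0.99
    extinction_threshold: float = 1e-9
    max_time: float = 5e4
    rtol: float = 1e-8
    atol: float = 1e-12


@dataclass
class CompetitionOutcome:
    outcome: str  # "fixed" | "extinct" | "timeout"
    time: float
    mutant_share: float


@dataclass
class EvolutionRecord:
    attempt: int
    proposed_gamma: np.ndarray
    q0: float
    outcome: str
    resident_gamma: np.ndarray
    resident_r0: float


@dataclass
class EvolutionTrajectory:
    """Ordered record of invasion attempts and the resident they produced."""

    records: List[EvolutionRecord]
    mode: str
    seed: int
    kernel: MutationKernel
    initial_gamma: np.ndarray
    final_gamma: np.ndarray = field(default=None)
    final_r0: float = field(default=None)

    @property
    def fixations(self) -> List[EvolutionRecord]:
        return [r for r in self.records if r.outcome == "fixed"]

    def as_frame(self) -> pd.DataFrame:
        n = self.initial_gamma.size
        rows = []
        for r in self.records:
            row = {"attempt": r.attempt, "q0": r.q0, "outcome": r.outcome,
                   "resident_r0": r.resident_r0}
            for i in range(n):
                row[f"proposed_gamma{i + 1}"] = r.proposed_gamma[i]
            for i in range(n):
                row[f"resident_gamma{i + 1}"] = r.resident_gamma[i]
            rows.append(row)
        cols = (["attempt"]
                + [f"proposed_gamma{i + 1}" for i in range(n)]
                + ["q0", "outcome"]
                + [f"resident_gamma{i + 1}" for i in range(n)]
                + ["resident_r0"])
        return pd.DataFrame(rows, columns=cols)


def propose_mutant(gamma: np.ndarray, kernel: MutationKernel, rng: np.random.Generator) -> np.ndarray:
    """Draw a mutant recovery-rate vector around the resident's."""
    gamma = np.asarray(gamma, dtype=float)
    if np.any(gamma <= 0):
        raise ValueError("resident recovery rates must be positive")
    if kernel.per_stage:
        out = gamma.copy()
        i = int(rng.integers(gamma.size))
        out[i] = gamma[i] * np.exp(kernel.step_scale * rng.standard_normal())
        return out
    return gamma * np.exp(kernel.step_scale * rng.standard_normal(gamma.size))


def compete(
    resident: StrainTraits,
    mutant: StrainTraits,
    pop: PopulationStructure,
    trans: TransmissionStructure,
    settings: Optional[CompetitionSettings] = None,
    resident_eq: Optional[model.EquilibriumResult] = None,
    trans_mutant: Optional[TransmissionStructure] = None,
) -> CompetitionOutcome:
    """Integrate resident-vs-mutant competition from the resident's equilibrium."""
    settings = settings or CompetitionSettings()
    if resident_eq is None:
        resident_eq = model.endemic_equilibrium(pop, resident, trans)
    if resident_eq.subcritical:
        raise ValueError("resident is subcritical; it cannot host a competition")
    n = pop.n
    eq = resident_eq.state
    total = eq.total
    seed_mass = settings.seed_fraction * total
    I_res = eq.I * (1.0 - seed_mass / eq.I.sum())
    I_mut = eq.I * (seed_mass / eq.I.sum())
    y0 = np.concatenate([eq.S, I_res, eq.R, I_mut, np.zeros(n)])

    beta = trans.beta_matrix(resident)
    beta_m = (trans_mutant or trans).beta_matrix(mutant)
    a, delta, omega = pop.aging_rates, pop.background_mortality, pop.immunity_loss

    def fun(t, y):
        return model._rhs_two(y, n, a, delta, omega, resident.recovery,
                              resident.disease_mortality, beta,
                              mutant.recovery, beta_m)

    def share(y):
        tot_inf = y[n: 2 * n].sum() + y[3 * n: 4 * n].sum()
        return y[3 * n: 4 * n].sum() / tot_inf if tot_inf > 0 else 0.0

    def ev_fix(t, y):
        return share(y) - settings.fixation_threshold

    def ev_ext(t, y):
        return y[3 * n: 4 * n].sum() - settings.extinction_threshold * total

    ev_fix.terminal = True
    ev_fix.direction = 1.0
    ev_ext.terminal = True
    ev_ext.direction = -1.0

    sol = solve_ivp(fun, (0.0, settings.max_time), y0, method="LSODA",
                    rtol=settings.rtol, atol=settings.atol,
                    events=(ev_fix, ev_ext))
    if not sol.success:
        raise RuntimeError(f"competition integration failed: {sol.message}")
    y_end = sol.y[:, -1]
    t_end = float(sol.t[-1])
    if sol.t_events[0].size:
        return CompetitionOutcome("fixed", float(sol.t_events[0][0]), share(sol.y_events[0][0]))
    if sol.t_events[1].size:
        return CompetitionOutcome("extinct", float(sol.t_events[1][0]), share(sol.y_events[1][0]))
    return CompetitionOutcome("timeout", t_end, share(y_end))


def run_evolution(
    initial: StrainTraits,
    pop: PopulationStructure,
    trans: TransmissionStructure,
    kernel: Optional[MutationKernel] = None,
    n_attempts: int = 300,
    mode: str = "adaptive_dynamics",
    seed: int = 0,
    settings: Optional[CompetitionSettings] = None,
    trans_mutant_builder=None,
) -> EvolutionTrajectory:
    """Iterate invasion attempts, replacing the resident on fixation.

    ``adaptive_dynamics`` settles each attempt by the invasion number alone
    (fix iff Q0 > 1); ``ode_competition`` integrates the full two-strain
    system.  Identical seeds and configuration reproduce the trajectory
    bit-for-bit.
    """
    if mode not in ("adaptive_dynamics", "ode_competition"):
        raise ValueError(f"unknown evolution mode {mode!r}")
    if initial.tradeoff is None:
        raise ValueError("evolution needs a strain with a trade-off")
    kernel = kernel or MutationKernel()
    settings = settings or CompetitionSettings()
    rng = np.random.default_rng(seed)
    resident = initial
    eq = model.endemic_equilibrium(pop, resident, trans)
    if eq.subcritical:
        raise ValueError("initial strain is subcritical (R0 <= 1)")
    resident_r0 = ngm.r0(pop, resident, trans)
    records: List[EvolutionRecord] = []
    for attempt in range(n_attempts):
        g_tilde = propose_mutant(resident.recovery, kernel, rng)
        mutant = resident.with_recovery(g_tilde)
        q0 = ngm.invasion_number(eq.state.S, pop, mutant, trans)
        if mode == "adaptive_dynamics":
            outcome = "fixed" if q0 > 1.0 else "extinct"
        else:
            outcome = compete(resident, mutant, pop, trans, settings, resident_eq=eq).outcome
        if outcome == "fixed":
            resident = mutant
            eq = model.endemic_equilibrium(pop, resident, trans, initial=eq.state)
            if eq.subcritical or not eq.converged:
                raise RuntimeError("endemic equilibrium lost after fixation")
            resident_r0 = ngm.r0(pop, resident, trans)
        records.append(EvolutionRecord(
            attempt=attempt,
            proposed_gamma=g_tilde,
            q0=q0,
            outcome=outcome,
            resident_gamma=resident.recovery.copy(),
            resident_r0=resident_r0,
        ))
    return EvolutionTrajectory(records=records, mode=mode, seed=seed, kernel=kernel,
                               initial_gamma=initial.recovery.copy(),
                               final_gamma=resident.recovery.copy(),
                               final_r0=resident_r0)


def sensitivity_random_contacts(trans: TransmissionStructure, seed: int = 0) -> TransmissionStructure:
    """Break the outer-product assumption with a random contact matrix.

    Each contact element is multiplied by an independent Uniform(0, 1) draw,
    producing a generically full-rank structure; downstream R0/Q0 must then
    use the eigenvalue method (the trace shortcut is refused).
    """
    if not trans.is_outer_product:
        raise ValueError("sensitivity mode starts from an outer-product structure")
    rng = np.random.default_rng(seed)
    n = trans.n
    c = trans.contacts() * rng.uniform(size=(n, n))
    return TransmissionStructure(mode="general", contact_matrix=c)


def sensitivity_high_cfr(
    strain: StrainTraits,
    pop: PopulationStructure,
    multiplier: float = 1.0,
) -> StrainTraits:
    """Raise disease mortality far above background: d_i = 10 * delta_i * multiplier.

    Puts the model outside the low-CFR regime where the aggregate
    closed-form equilibrium holds; all equilibria must then come from
    integration.  The total population remains constant by construction
    (births balance all deaths), so no extinction pathway opens.
    """
    if multiplier < 1.0:
        raise ValueError("multiplier must be >= 1")
    d = 10.0 * pop.background_mortality * multiplier
    return StrainTraits(recovery=strain.recovery.copy(), disease_mortality=d,
                        tradeoff=strain.tradeoff)
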