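"""Next-generation matrices: disease-free equilibrium, R0 and the invasion number Q0.

For the age-structured SIRS model the linearised infected subsystem at a
given susceptible profile ``S`` reads ``dI/dt = (T + Sigma) I`` with
transmission matrix ``T_ij = beta_ij * S_i`` and a lower-bidiagonal
transition matrix ``Sigma`` (diagonal ``-mu_i`` with
``mu_i = a_i + delta_i + gamma_i + d_i``, subdiagonal ``a_i``).  The basic
reproduction number R0 is the spectral radius of the next-generation matrix
``K = -T Sigma^{-1}`` evaluated at the disease-free equilibrium; the
invasion number Q0 of a rare mutant is the same construction with the
mutant's traits and the resident's endemic susceptible profile ``S*``.

When the contact structure is an outer product, ``T`` has rank 1, so ``K``
has rank 1 and its spectral radius equals its trace — which expands into the
closed nested-sum formula implemented in :func:`reproduction_number_trace`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .params import PopulationStructure, StrainTraits, TransmissionStructure

__all__ = [
    "DFEVector",
    "NGMBundle",
    "disease_free_equilibrium",
    "transition_matrix",
    "transition_matrix_inverse",
    "ngm_bundle",
    "r0",
    "invasion_number",
    "q0_gradient",
]


@dataclass
class DFEVector:
    """Susceptible age profile at the disease-free equilibrium.

    ``alpha[i]`` (for stages i >= 2, stored from index 1) is the cumulative
    product ``prod_{k=2..i} a_{k-1} / (a_k + delta_k)`` so that
    ``S_hat_i = alpha_i * S_hat_1``; ``alpha[0] = 1`` by convention.
    """

    S_hat: np.ndarray
    alpha: np.ndarray

    @property
    def total(self) -> float:
        return float(self.S_hat.sum())


@dataclass
class NGMBundle:
    """Transmission/transition matrices and the resulting reproduction number."""

    T: np.ndarray
    Sigma: np.ndarray
    Sigma_inv: np.ndarray
    K: np.ndarray
    value: float
    method: str


def disease_free_equilibrium(pop: PopulationStructure, total: float = 1.0) -> DFEVector:
    """Susceptible densities with no infection present.

    With I = R = 0 the stage equations balance aging against background
    mortality, giving the recursion ``S_hat_i = alpha_i S_hat_1`` with
    ``alpha_i = prod_{k=2..i} a_{k-1}/(a_k + delta_k)``; the level is fixed
    by the total population.
    """
    a = pop.aging_rates
    delta = pop.background_mortality
    n = pop.n
    alpha = np.ones(n)
    for i in range(1, n):
        denom = a[i] + delta[i]
        if denom <= 0.0:
            raise ValueError(
                f"stage {i + 1}: a_i + delta_i must be positive to define the "
                "disease-free age profile (terminal stage needs delta_n > 0)"
            )
        alpha[i] = alpha[i - 1] * a[i - 1] / denom
    S1 = total / alpha.sum()
    return DFEVector(S_hat=alpha * S1, alpha=alpha)


def transition_matrix(pop: PopulationStructure, strain: StrainTraits) -> np.ndarray:
    """Lower-bidiagonal transition matrix Sigma of the infected subsystem."""
    mu = strain.removal_rates(pop)
    if np.any(mu <= 0):
        raise ValueError("all removal rates mu_i must be positive")
    Sigma = np.diag(-mu)
    n = pop.n
    if n > 1:
        Sigma[np.arange(1, n), np.arange(n - 1)] = pop.aging_rates[:-1]
    return Sigma

def transition_matrix_inverse(pop: PopulationStructure, strain: StrainTraits) -> np.ndarray:
    """Closed-form inverse of Sigma.

    ``(-Sigma^{-1})_{ji} = (a_i ... a_{j-1}) / (mu_i ... mu_j)`` for
    ``j >= i`` (zero above the diagonal): the expected time an individual
    entering the infected pool in stage ``i`` spends infected in stage ``j``.
    """
    mu = strain.removal_rates(pop)
    if np.any(mu <= 0):
        raise ValueError("all removal rates mu_i must be positive")
    a = pop.aging_rates
    n = pop.n
    inv = np.zeros((n, n))
    for i in range(n):
        acc = 1.0 / mu[i]
        inv[i, i] = -acc
        for j in range(i + 1, n):
            acc *= a[j - 1] / mu[j]
            inv[j, i] = -acc
    return inv


def ngm_bundle(
    susceptibles: np.ndarray,
    pop: PopulationStructure,
    strain: StrainTraits,
    trans: TransmissionStructure,
    method: str = "eigen",
) -> NGMBundle:
    """Assemble T, Sigma, Sigma^-1 and K = -T Sigma^-1 at a susceptible profile."""
    S = np.asarray(susceptibles, dtype=float)
    if S.shape != (pop.n,):
        raise ValueError("susceptible profile has wrong length")
    beta = trans.beta_matrix(strain)
    T = beta * S[:, None]
    Sigma = transition_matrix(pop, strain)
    Sigma_inv = transition_matrix_inverse(pop, strain)
    K = -T @ Sigma_inv
    value = _reproduction_number(S, pop, strain, trans, method)
    return NGMBundle(T=T, Sigma=Sigma, Sigma_inv=Sigma_inv, K=K, value=value, method=method)


def reproduction_number_trace(
    susceptibles: np.ndarray,
    pop: PopulationStructure,
    strain: StrainTraits,
    trans: TransmissionStructure,
) -> float:
    """Trace of the next-generation matrix via the closed nested-sum formula.

    ``R = sum_j sum_{i<=j} beta_ij S_i (prod_{k=i}^{j-1} a_k) /
    (prod_{k=i}^{j} mu_k)``.  Equals the spectral radius only for
    outer-product (rank-1) transmission; callers enforce that.
    """
    S = np.asarray(susceptibles, dtype=float)
    beta = trans.beta_matrix(strain)
    a = pop.aging_rates
    mu = strain.removal_rates(pop)
    if np.any(mu <= 0):
        raise ValueError("all removal rates mu_i must be positive")
    total = 0.0
    n = pop.n
    for j in range(n):
        prod = 1.0 / mu[j]
        total += beta[j, j] * S[j] * prod
        for i in range(j - 1, -1, -1):
            prod *= a[i] / mu[i]
            total += beta[i, j] * S[i] * prod
    return total


def _reproduction_number(S, pop, strain, trans, method: str) -> float:
    if method == "trace":
        if not trans.is_outer_product:
            raise ValueError(
                "trace method requires outer-product transmission: for a general "
                "contact matrix the NGM is not rank 1 and its trace is not the "
                "spectral radius; use method='eigen'"
            )
        return reproduction_number_trace(S, pop, strain, trans)
    if method == "eigen":
        beta = trans.beta_matrix(strain)
        T = beta * np.asarray(S, dtype=float)[:, None]
        K = -T @ transition_matrix_inverse(pop, strain)
        eigvals = np.linalg.eigvals(K)
        return float(np.max(eigvals.real))
    raise ValueError(f"unknown method {method!r}; use 'trace' or 'eigen'")


def r0(
    pop: PopulationStructure,
    strain: StrainTraits,
    trans: TransmissionStructure,
    method: str = "auto",
    total: float = 1.0,
) -> float:
    """Basic reproduction number at the disease-free equilibrium.

    ``method='trace'`` uses the rank-1 closed form (outer-product
    transmission only); ``'eigen'`` the dominant eigenvalue of the dense
    NGM; ``'auto'`` picks trace when available.
    """
    if method == "auto":
        method = "trace" if trans.is_outer_product else "eigen"
    dfe = disease_free_equilibrium(pop, total=total)
    return _reproduction_number(dfe.S_hat, pop, strain, trans, method)


def invasion_number(
    endemic_S: np.ndarray,
    pop: PopulationStructure,
    mutant: StrainTraits,
    trans: TransmissionStructure,
    method: str = "auto",
) -> float:
    """Invasion number Q0 of a rare mutant at the resident's endemic equilibrium.

    Same next-generation construction as R0, with the mutant's recovery
    rates entering both the transmission matrix (through the trade-off) and
    the removal rates, and the resident's endemic susceptible profile
    ``S*`` in place of the disease-free one.  Q0 < 1 means the mutant fails
    to invade; the resident is an ESS when Q0 < 1 for every mutant.
    """
    if method == "auto":
        method = "trace" if trans.is_outer_product else "eigen"
    return _reproduction_number(np.asarray(endemic_S, dtype=float), pop, mutant, trans, method)


def q0_gradient(
    resident: StrainTraits,
    pop: PopulationStructure,
    trans: TransmissionStructure,
    endemic_S: Optional[np.ndarray] = None,
    rel_step: float = 1e-5,
    method: str = "auto",
) -> np.ndarray:
    """Central-difference gradient of Q0 with respect to the mutant recovery rates.

    Evaluated at mutant = resident; at an evolutionarily stable resident the
    gradient vanishes (exactly for n = 1, to the slow-aging correction for
    n > 1).  ``endemic_S`` may be passed to avoid recomputing the resident's
    endemic equilibrium.
    """
    if resident.tradeoff is None:
        raise ValueError("q0_gradient needs a strain with a trade-off (beta depends on gamma)")
    if endemic_S is None:
        from .model import endemic_equilibrium  # deferred: model imports this module

        eq = endemic_equilibrium(pop, resident, trans)
        if eq.subcritical:
            raise ValueError("resident is subcritical (R0 <= 1); no endemic equilibrium")
        endemic_S = eq.state.S
    endemic_S = np.asarray(endemic_S, dtype=float)
    gamma = resident.recovery
    grad = np.empty(pop.n)
    for l in range(pop.n):
        h = rel_step * gamma[l]
        if h <= 0.0:
            raise ValueError("finite-difference step underflow")
        up = gamma.copy()
        dn = gamma.copy()
        up[l] += h
        dn[l] -= h
        q_up = invasion_number(endemic_S, pop, resident.with_recovery(up), trans, method)
        q_dn = invasion_number(endemic_S, pop, resident.with_recovery(dn), trans, method)
        grad[l] = (q_up - q_dn) / (2.0 * h)
    return grad
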