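"""Host demography, pathogen traits, and transmission structure.

The host population is split into ``n`` age stages.  Individuals age from
stage ``i`` into stage ``i+1`` at rate ``a_i``, die of background causes at
rate ``delta_i``, and recovered individuals lose immunity at the
age-invariant rate ``omega``.  A pathogen strain is characterised by
per-stage recovery rates ``gamma_i`` and disease-induced mortality ``d_i``;
its infectivity is generated from the recovery rate through a trade-off
function ``beta(gamma)``, so that acuter (shorter) infections transmit more
per unit time.  Transmission between stages is modulated by a contact
structure ``c_ij`` which by default factorises as an outer product
``c_ij = x_i * y_j``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np

__all__ = [
    "PopulationStructure",
    "StrainTraits",
    "TradeOff",
    "TransmissionStructure",
    "ConcavityWarning",
]


class ConcavityWarning(UserWarning):
    """Emitted when a trade-off fails the concavity check on the working grid."""


def _rate_vector(values, name: str, n: Optional[int] = None) -> np.ndarray:
    arr = np.atleast_1d(np.asarray(values, dtype=float))
    if arr.ndim != 1:
        raise ValueError(f"{name} must be a 1-d sequence of rates")
    if n is not None and arr.size != n:
        raise ValueError(f"{name} must have length {n}, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite entries")
    if np.any(arr < 0):
        raise ValueError(f"{name} must be nonnegative")
    return arr


@dataclass
class PopulationStructure:
    """Demography of an ``n``-stage host population.

    Parameters
    ----------
    aging_rates
        Per-time rates ``a_1 .. a_n``.  ``a_i`` moves individuals from stage
        ``i`` to stage ``i+1``; the terminal rate ``a_n`` must be 0 (the last
        stage is left only through death), otherwise the total population is
        not conserved under the birth accounting used here.
    background_mortality
        Per-time rates ``delta_1 .. delta_n``.
    immunity_loss
        Scalar per-time rate ``omega`` at which recovered individuals return
        to the susceptible pool (age-invariant).
    """

    aging_rates: np.ndarray
    background_mortality: np.ndarray
    immunity_loss: float

    def __post_init__(self) -> None:
        self.aging_rates = _rate_vector(self.aging_rates, "aging_rates")
        self.background_mortality = _rate_vector(
            self.background_mortality, "background_mortality", self.aging_rates.size
        )
        self.immunity_loss = float(self.immunity_loss)
        if self.immunity_loss < 0:
            raise ValueError("immunity_loss must be nonnegative")
        if self.aging_rates[-1] != 0.0:
            raise ValueError(
                "terminal aging rate a_n must be 0 (exit from the last stage is "
                "by death only; a_n > 0 breaks population conservation)"
            )

    @property
    def n(self) -> int:
        return self.aging_rates.size


@dataclass
class TradeOff:
    """Infectivity-recovery trade-off ``beta(gamma)``.

    ``beta`` must be positive and increasing for ``gamma > 0``; an
    evolutionarily stable strategy exists when ``beta`` is additionally
    concave (for the built-in power law ``beta = c * gamma**p`` this means
    ``0 < p < 1``).  A convex trade-off rewards unbounded acuteness and the
    optimum runs away (the "Darwinian demon").
    """

    form: str = "power_law"
    coefficient: float = 1.0
    exponent: float = 0.5
    func: Optional[Callable[[np.ndarray], np.ndarray]] = field(default=None, repr=False)
    deriv: Optional[Callable[[np.ndarray], np.ndarray]] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.form not in ("power_law", "custom"):
            raise ValueError(f"unknown trade-off form {self.form!r}")
        if self.form == "power_law":
            if not self.coefficient > 0:
                raise ValueError("power-law coefficient must be > 0")
            if not self.exponent > 0:
                raise ValueError("power-law exponent must be > 0")
        else:
            if self.func is None or self.deriv is None:
                raise ValueError("custom trade-off requires func and deriv")

    @classmethod
    def power_law(cls, coefficient: float = 1.0, exponent: float = 0.5) -> "TradeOff":
        """``beta(gamma) = coefficient * gamma**exponent``."""
        return cls(form="power_law", coefficient=coefficient, exponent=exponent)

    @classmethod
    def custom(cls, func: Callable, deriv: Callable) -> "TradeOff":
        """A user-supplied ``beta(gamma)`` with its first derivative."""
        return cls(form="custom", func=func, deriv=deriv)

    def beta(self, gamma):
        gamma = np.asarray(gamma, dtype=float)
        if self.form == "power_law":
            return self.coefficient * np.power(gamma, self.exponent)
        return self.func(gamma)

    def beta_prime(self, gamma):
        gamma = np.asarray(gamma, dtype=float)
        if self.form == "power_law":
            return self.coefficient * self.exponent * np.power(gamma, self.exponent - 1.0)
        return self.deriv(gamma)

    def check_concavity(self, lo: float = 1e-4, hi: float = 10.0, num: int = 256) -> bool:
        """Check ``beta'`` is non-increasing on a log grid; warn if not.

        Returns True when the check passes.  A violation does not raise: the
        ESS machinery may still be exercised, but its existence guarantee is
        void, hence the warning.
        """
        grid = np.geomspace(lo, hi, num)
        bp = np.asarray(self.beta_prime(grid), dtype=float)
        ok = bool(np.all(np.diff(bp) <= 1e-12 * np.maximum(1.0, np.abs(bp[:-1]))))
        if not ok:
            warnings.warn(
                "trade-off derivative increases on the working grid; beta(gamma) "
                "is not concave there and an ESS is not guaranteed to exist",
                ConcavityWarning,
                stacklevel=2,
            )
        return ok


@dataclass
class StrainTraits:
    """A pathogen phenotype: per-stage recovery and disease mortality.

    The strain's infectivity is not stored directly; it is generated from
    ``recovery`` through ``tradeoff`` when the transmission matrix is built.
    A strain with ``tradeoff=None`` is allowed for purely epidemiological
    computations where the contact structure already carries the absolute
    infection rates.
    """

    recovery: np.ndarray
    disease_mortality: np.ndarray
    tradeoff: Optional[TradeOff] = None

    def __post_init__(self) -> None:
        self.recovery = _rate_vector(self.recovery, "recovery")
        if np.any(self.recovery <= 0):
            raise ValueError("recovery rates must be strictly positive")
        self.disease_mortality = _rate_vector(
            self.disease_mortality, "disease_mortality", self.recovery.size
        )

    @property
    def n(self) -> int:
        return self.recovery.size

    def with_recovery(self, gamma) -> "StrainTraits":
        """A mutant sharing this strain's mortality and trade-off but with new gamma."""
        return StrainTraits(
            recovery=np.asarray(gamma, dtype=float).copy(),
            disease_mortality=self.disease_mortality.copy(),
            tradeoff=self.tradeoff,
        )

    def removal_rates(self, pop: PopulationStructure) -> np.ndarray:
        """mu_i = a_i + delta_i + gamma_i + d_i, the per-stage exit rates from I."""
        return (
            pop.aging_rates
            + pop.background_mortality
            + self.recovery
            + self.disease_mortality
        )


@dataclass
class TransmissionStructure:
    """Contact modulation composing the transmission matrix.

    ``beta_ij = c_ij * beta(gamma_j)`` is the rate at which an infected of
    stage ``j`` infects a susceptible of stage ``i``.  In ``outer_product``
    mode ``c_ij = x_i * y_j`` (susceptibility times infectivity weight),
    which makes the realised transmission matrix rank 1 and unlocks the
    trace formula for R0/Q0.  ``general`` mode takes an arbitrary
    nonnegative matrix ``c_ij``.
    """

    mode: str = "outer_product"
    susceptibility: Optional[np.ndarray] = None
    infectivity_weights: Optional[np.ndarray] = None
    contact_matrix: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.mode == "outer_product":
            if self.susceptibility is None or self.infectivity_weights is None:
                raise ValueError("outer_product mode requires susceptibility and infectivity_weights")
            self.susceptibility = _rate_vector(self.susceptibility, "susceptibility")
            self.infectivity_weights = _rate_vector(
                self.infectivity_weights, "infectivity_weights", self.susceptibility.size
            )
            self.contact_matrix = None
        elif self.mode == "general":
            mat = np.asarray(self.contact_matrix, dtype=float)
            if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
                raise ValueError("contact_matrix must be square")
            if not np.all(np.isfinite(mat)) or np.any(mat < 0):
                raise ValueError("contact_matrix must be nonnegative and finite")
            self.contact_matrix = mat
            self.susceptibility = None
            self.infectivity_weights = None
        else:
            raise ValueError(f"unknown transmission mode {self.mode!r}")

    @property
    def n(self) -> int:
        if self.mode == "outer_product":
            return self.susceptibility.size
        return self.contact_matrix.shape[0]

    @property
    def is_outer_product(self) -> bool:
        return self.mode == "outer_product"

    def contacts(self) -> np.ndarray:
        """The n x n contact-modulation matrix c_ij."""
        if self.mode == "outer_product":
            return np.outer(self.susceptibility, self.infectivity_weights)
        return self.contact_matrix.copy()

    def beta_matrix(self, strain: StrainTraits) -> np.ndarray:
        """Realised transmission matrix beta_ij = c_ij * beta(gamma_j).

        With ``strain.tradeoff is None`` the contacts are taken to already be
        the absolute rates beta_ij.
        """
        if strain.n != self.n:
            raise ValueError("strain and transmission structure dimensions differ")
        c = self.contacts()
        if strain.tradeoff is None:
            return c
        return c * np.asarray(strain.tradeoff.beta(strain.recovery), dtype=float)[None, :]

    def scaled(self, factor: float) -> "TransmissionStructure":
        """A copy with every contact rate multiplied by ``factor`` (> 0)."""
        if not factor > 0:
            raise ValueError("scaling factor must be positive")
        if self.mode == "outer_product":
            return TransmissionStructure(
                mode="outer_product",
                susceptibility=self.susceptibility * factor,
                infectivity_weights=self.infectivity_weights.copy(),
            )
        return TransmissionStructure(mode="general", contact_matrix=self.contact_matrix * factor)
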