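"""Scenario generation, validation and (de)serialisation.

A :class:`Scenario` bundles everything one model run needs — host
demography, resident strain, trade-off, transmission structure and solver
settings — and round-trips losslessly through a YAML file.  Built-in
templates produce the regimes the analysis targets: a scalar SIRS benchmark,
a three-stage human-like population with slow aging, an n-stage slow-aging
ladder, and the two assumption-breaking sensitivity variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import yaml

from .params import PopulationStructure, StrainTraits, TradeOff, TransmissionStructure

__all__ = ["Scenario", "SimulationSettings", "generate_scenario", "load_scenario",
           "save_scenario", "ScenarioError", "TEMPLATES"]

SCHEMA_VERSION = 1


class ScenarioError(ValueError):
    """Raised for malformed or invalid scenario files."""


@dataclass
class SimulationSettings:
    horizon: float = 1e6
    rtol: float = 1e-9
    atol: float = 1e-12
    equilibrium_tol: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ScenarioError("simulation.horizon must be positive")
        for name in ("rtol", "atol", "equilibrium_tol"):
            if getattr(self, name) <= 0:
                raise ScenarioError(f"simulation.{name} must be positive")


@dataclass
class Scenario:
    name: str
    population: PopulationStructure
    strain: StrainTraits
    tradeoff: TradeOff
    transmission: TransmissionStructure
    simulation: SimulationSettings = field(default_factory=SimulationSettings)
    description: str = ""

    def __post_init__(self) -> None:
        n = self.population.n
        if self.strain.n != n or self.transmission.n != n:
            raise ScenarioError("population, strain and transmission stage counts differ")
        if self.strain.tradeoff is None:
            self.strain.tradeoff = self.tradeoff

    @property
    def n(self) -> int:
        return self.population.n

    def to_dict(self) -> Dict:
        if self.tradeoff.form != "power_law":
            raise ScenarioError("only power-law trade-offs are serialisable")
        doc = {
            "schema_version": SCHEMA_VERSION,
            "name": self.name,
            "description": self.description,
            "population": {
                "stages": self.population.n,
                "aging_rates": self.population.aging_rates.tolist(),
                "background_mortality": self.population.background_mortality.tolist(),
                "immunity_loss": float(self.population.immunity_loss),
            },
            "strain": {
                "recovery": self.strain.recovery.tolist(),
                "disease_mortality": self.strain.disease_mortality.tolist(),
            },
            "tradeoff": {
                "form": "power_law",
                "coefficient": float(self.tradeoff.coefficient),
                "exponent": float(self.tradeoff.exponent),
            },
            "simulation": {
                "horizon": float(self.simulation.horizon),
                "rtol": float(self.simulation.rtol),
                "atol": float(self.simulation.atol),
                "equilibrium_tol": float(self.simulation.equilibrium_tol),
                "seed": int(self.simulation.seed),
            },
        }
        if self.transmission.is_outer_product:
            doc["transmission"] = {
                "mode": "outer_product",
                "susceptibility": self.transmission.susceptibility.tolist(),
                "infectivity_weights": self.transmission.infectivity_weights.tolist(),
            }
        else:
            doc["transmission"] = {
                "mode": "general",
                "contact_matrix": self.transmission.contact_matrix.tolist(),
            }
        return doc


_ALLOWED = {
    "": {"schema_version", "name", "description", "population", "strain",
         "tradeoff", "transmission", "simulation"},
    "population": {"stages", "aging_rates", "background_mortality", "immunity_loss"},
    "strain": {"recovery", "disease_mortality"},
    "tradeoff": {"form", "coefficient", "exponent"},
    "transmission": {"mode", "susceptibility", "infectivity_weights", "contact_matrix"},
    "simulation": {"horizon", "rtol", "atol", "equilibrium_tol", "seed"},
}


def _check_keys(mapping: Dict, section: str) -> None:
    if not isinstance(mapping, dict):
        raise ScenarioError(f"section '{section or 'top level'}' must be a mapping")
    unknown = set(mapping) - _ALLOWED[section]
    if unknown:
        where = section or "top level"
        raise ScenarioError(f"unknown key(s) {sorted(unknown)} in {where}")


def scenario_from_dict(doc: Dict) -> Scenario:
    _check_keys(doc, "")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ScenarioError(f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION})")
    for block in ("population", "strain", "transmission"):
        if block not in doc:
            raise ScenarioError(f"missing required block '{block}'")
    if "tradeoff" not in doc:
        raise ScenarioError(
            "missing 'tradeoff' block; add e.g.\n"
            "  tradeoff: {form: power_law, coefficient: 1.0, exponent: 0.5}"
        )
    for block in ("population", "strain", "tradeoff", "transmission"):
        _check_keys(doc[block], block)
    if "simulation" in doc:
        _check_keys(doc["simulation"], "simulation")
    p = doc["population"]
    try:
        pop = PopulationStructure(
            aging_rates=p["aging_rates"],
            background_mortality=p["background_mortality"],
            immunity_loss=p["immunity_loss"],
        )
    except (KeyError, ValueError) as exc:
        raise ScenarioError(f"population: {exc}") from exc
    if "stages" in p and int(p["stages"]) != pop.n:
        raise ScenarioError(f"population.stages = {p['stages']} but rate vectors have length {pop.n}")
    t = doc["tradeoff"]
    if t.get("form") != "power_law":
        raise ScenarioError("tradeoff.form must be 'power_law' in scenario files "
                            "(custom trade-offs are constructed in code)")
    try:
        tradeoff = TradeOff.power_law(coefficient=t.get("coefficient", 1.0),
                                      exponent=t.get("exponent", 0.5))
    except ValueError as exc:
        raise ScenarioError(f"tradeoff: {exc}") from exc
    s = doc["strain"]
    try:
        strain = StrainTraits(recovery=s["recovery"],
                              disease_mortality=s.get("disease_mortality",
                                                      np.zeros(pop.n)),
                              tradeoff=tradeoff)
    except (KeyError, ValueError) as exc:
        raise ScenarioError(f"strain: {exc}") from exc
    tr = doc["transmission"]
    try:
        if tr.get("mode", "outer_product") == "outer_product":
            trans = TransmissionStructure(
                mode="outer_product",
                susceptibility=tr["susceptibility"],
                infectivity_weights=tr["infectivity_weights"],
            )
        else:
            trans = TransmissionStructure(mode="general", contact_matrix=tr["contact_matrix"])
    except (KeyError, ValueError) as exc:
        raise ScenarioError(f"transmission: {exc}") from exc
    sim = doc.get("simulation", {})
    try:
        settings = SimulationSettings(**{k: v for k, v in sim.items()})
    except (TypeError, ScenarioError) as exc:
        raise ScenarioError(f"simulation: {exc}") from exc
    return Scenario(name=str(doc.get("name", "unnamed")), population=pop, strain=strain,
                    tradeoff=tradeoff, transmission=trans, simulation=settings,
                    description=str(doc.get("description", "")))


def load_scenario(path) -> Scenario:
    """Load and validate a YAML scenario file."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ScenarioError(f"{path}: cannot parse YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ScenarioError(f"{path}: scenario file must contain a mapping")
    try:
        return scenario_from_dict(doc)
    except ScenarioError as exc:
        raise ScenarioError(f"{path}: {exc}") from exc


def save_scenario(scenario: Scenario, path) -> None:
    """Write a scenario as YAML (round-trips through :func:`load_scenario`)."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(scenario.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# templates

def _single_stage(seed: int) -> Scenario:
    # scalar SIRS benchmark: beta(0.1) = 0.4, R0 = 0.4/0.11 ~ 3.64
    tradeoff = TradeOff.power_law(coefficient=0.4 / np.sqrt(0.1), exponent=0.5)
    return Scenario(
        name="single_stage",
        description="Scalar SIRS benchmark; supercritical, zero disease mortality.",
        population=PopulationStructure(aging_rates=[0.0], background_mortality=[0.01],
                                       immunity_loss=0.02),
        strain=StrainTraits(recovery=[0.1], disease_mortality=[0.0], tradeoff=tradeoff),
        tradeoff=tradeoff,
        transmission=TransmissionStructure(mode="outer_product", susceptibility=[1.0],
                                           infectivity_weights=[1.0]),
        simulation=SimulationSettings(seed=seed),
    )


def _three_stage_human(seed: int) -> Scenario:
    # young (0-20 y), adult (20-65 y), old stages; per-day rates; slow aging:
    # gamma + d exceeds 50 * a in every stage
    tradeoff = TradeOff.power_law(coefficient=2.0, exponent=0.5)
    pop = PopulationStructure(
        aging_rates=[1.0 / 7300.0, 1.0 / 16425.0, 0.0],
        background_mortality=[1e-5, 5e-5, 1.0 / 5475.0],
        immunity_loss=1.0 / 365.0,
    )
    # disease mortality rises steeply with age and dominates the aging rates,
    # keeping gamma + d >= 50 a everywhere along the evolutionary range
    # (including at the ESS, where gamma falls to the order of d + delta)
    strain = StrainTraits(recovery=[0.2, 0.15, 0.1],
                          disease_mortality=[5e-3, 1e-2, 2e-2],
                          tradeoff=tradeoff)
    trans = TransmissionStructure(mode="outer_product",
                                  susceptibility=[1.5, 1.0, 0.7],
                                  infectivity_weights=[1.2, 1.0, 0.8])
    return Scenario(
        name="three_stage_human",
        description=("Human-like three-stage population (young/adult/old) with "
                     "increasing background and disease mortality and slow aging."),
        population=pop, strain=strain, tradeoff=tradeoff, transmission=trans,
        simulation=SimulationSettings(seed=seed),
    )


def _slow_aging_n(seed: int, n: int = 5) -> Scenario:
    if n < 2:
        raise ScenarioError("slow_aging_n template needs n >= 2")
    tradeoff = TradeOff.power_law(coefficient=2.0, exponent=0.5)
    a = np.full(n, 1.0 / 5475.0)  # 15-year stages
    a[-1] = 0.0
    delta = np.geomspace(1e-5, 2e-4, n)
    delta[-1] = max(delta[-1], 1.0 / 7300.0)  # terminal stage exits by death
    gamma = np.linspace(0.2, 0.1, n)
    return Scenario(
        name=f"slow_aging_{n}",
        description=f"{n}-stage ladder with uniform slow aging ((gamma+d)/a >= 50).",
        population=PopulationStructure(aging_rates=a, background_mortality=delta,
                                       immunity_loss=1.0 / 365.0),
        strain=StrainTraits(recovery=gamma, disease_mortality=np.zeros(n),
                            tradeoff=tradeoff),
        tradeoff=tradeoff,
        transmission=TransmissionStructure(mode="outer_product",
                                           susceptibility=np.ones(n),
                                           infectivity_weights=np.ones(n)),
        simulation=SimulationSettings(seed=seed),
    )


def _high_cfr(seed: int) -> Scenario:
    from .evolution import sensitivity_high_cfr  # local: avoid import cycle at module load

    base = _three_stage_human(seed)
    strain = sensitivity_high_cfr(base.strain, base.population, multiplier=1.0)
    return Scenario(name="high_cfr",
                    description="Three-stage scenario with disease mortality 10x background.",
                    population=base.population, strain=strain, tradeoff=base.tradeoff,
                    transmission=base.transmission, simulation=base.simulation)


def _random_contacts(seed: int) -> Scenario:
    from .evolution import sensitivity_random_contacts

    base = _three_stage_human(seed)
    trans = sensitivity_random_contacts(base.transmission, seed=seed)
    return Scenario(name="random_contacts",
                    description=("Three-stage scenario with each contact element multiplied "
                                 "by a Uniform(0,1) draw (non-rank-1 transmission)."),
                    population=base.population, strain=base.strain, tradeoff=base.tradeoff,
                    transmission=trans, simulation=base.simulation)


TEMPLATES = {
    "single_stage": _single_stage,
    "three_stage_human": _three_stage_human,
    "slow_aging_n": _slow_aging_n,
    "high_cfr": _high_cfr,
    "random_contacts": _random_contacts,
}


def generate_scenario(template: str, overrides: Optional[Dict] = None, seed: int = 0,
                      **kwargs) -> Scenario:
    """Instantiate a named template, optionally overriding serialised fields.

    ``overrides`` is a nested mapping merged onto the template's dictionary
    form (so overriding e.g. ``{"strain": {"recovery": [0.2]}}`` re-runs the
    full validation).  Extra ``kwargs`` are template-specific (``n`` for
    ``slow_aging_n``).
    """
    if template not in TEMPLATES:
        raise ScenarioError(f"unknown template {template!r}; known: {sorted(TEMPLATES)}")
    scenario = TEMPLATES[template](seed, **kwargs)
    if overrides:
        doc = scenario.to_dict()
        for block, vals in overrides.items():
            if block not in _ALLOWED[""]:
                raise ScenarioError(f"unknown override block {block!r}")
            if isinstance(vals, dict):
                doc.setdefault(block, {}).update(vals)
            else:
                doc[block] = vals
        scenario = scenario_from_dict(doc)
    return scenario
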