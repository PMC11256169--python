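"""Domain types and scenario configuration.

The simulator is configured by a :class:`ScenarioConfig`, which bundles the
lattice geometry, the model clock, the nutrient fields, the resident species
table, the invader, the intervention schedule and the replicate/seed plan.
Configs serialize losslessly to plain dicts (and hence YAML/JSON), and the
species table can also be read from / written to CSV.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import pandas as pd
import yaml

MINUTES_PER_DAY = 1440.0


class ConfigurationError(ValueError):
    """Raised when a scenario or species description violates an invariant."""


@dataclass(frozen=True)
class Nutrient:
    """A diffusible nutrient field on the skin lattice.

    Parameters
    ----------
    name:
        Field identifier, referenced by ``SpeciesParams.carbon_sources``.
    diffusivity:
        Per-step smoothing coefficient in [0, 1]: each patch keeps
        ``1 - diffusivity`` of its amount and distributes the rest equally
        to its 8 toroidal neighbours.
    replenish_rate:
        Amount secreted per patch per timestep (skin secretion flux).
    initial_amount:
        Amount per patch at t = 0.
    """

    name: str
    diffusivity: float = 0.1
    replenish_rate: float = 0.0
    initial_amount: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.diffusivity <= 1.0:
            raise ConfigurationError(f"diffusivity must be in [0,1], got {self.diffusivity}")
        if self.replenish_rate < 0 or self.initial_amount < 0:
            raise ConfigurationError("nutrient rates/amounts must be non-negative")


@dataclass(frozen=True)
class SpeciesParams:
    """Kinetic and ecological parameters of one bacterial species.

    ``carbon_sources`` is an ordered tuple: when several usable nutrients are
    present on a patch, an agent fills its per-step uptake budget from them in
    this order of preference.

    ``mic`` is the local antibiotic concentration (in field units, where one
    unit is the nominal assay MIC that defines the dosing scale) at or above
    which the per-step kill rule applies; ``math.inf`` means resistant.

    ``growth_defect`` is the fractional burden d >= 0 of heterologous protein
    production: effective uptake is ``uptake_rate / (1 + d)``, so the
    effective doubling time is about ``(1 + d)`` times the nominal one.
    """

    name: str
    doubling_time: float  # minutes, under saturating nutrient
    carbon_sources: tuple[str, ...]
    uptake_rate: float  # nutrient units per timestep
    yield_coeff: float  # energy units per nutrient unit
    maintenance: float  # energy units per timestep
    division_threshold: float
    initial_energy: float
    mic: float = math.inf
    growth_defect: float = 0.0

    def __post_init__(self) -> None:
        if self.doubling_time <= 0:
            raise ConfigurationError("doubling_time must be > 0")
        if self.uptake_rate <= 0 or self.yield_coeff <= 0:
            raise ConfigurationError("uptake_rate and yield must be > 0")
        if self.maintenance < 0:
            raise ConfigurationError("maintenance must be >= 0")
        if not self.division_threshold > self.initial_energy > 0:
            raise ConfigurationError(
                "need division_threshold > initial_energy > 0, got "
                f"{self.division_threshold} / {self.initial_energy}"
            )
        if self.growth_defect < 0:
            raise ConfigurationError("growth_defect must be >= 0")
        if not self.carbon_sources:
            raise ConfigurationError("carbon_sources must be non-empty")

    @property
    def effective_uptake(self) -> float:
        return self.uptake_rate / (1.0 + self.growth_defect)

    def with_defect(self, d: float) -> "SpeciesParams":
        return replace(self, growth_defect=d)


@dataclass(frozen=True)
class ModelClock:
    """Conversion between timesteps, minutes and days.

    The default of one minute per timestep puts the invader introduction at
    timestep 4500 = 3.125 days (1440 steps per simulated day).
    """

    minutes_per_timestep: float = 1.0

    def __post_init__(self) -> None:
        if self.minutes_per_timestep <= 0:
            raise ConfigurationError("minutes_per_timestep must be > 0")

    @property
    def steps_per_day(self) -> float:
        return MINUTES_PER_DAY / self.minutes_per_timestep

    def steps_to_days(self, steps: float) -> float:
        return steps * self.minutes_per_timestep / MINUTES_PER_DAY

    def days_to_steps(self, days: float) -> int:
        return round(days * MINUTES_PER_DAY / self.minutes_per_timestep)


@dataclass(frozen=True)
class GridConfig:
    rows: int = 100
    cols: int = 100
    carrying_capacity: int = 10  # max agents per patch
    area_cm2: float = 1.0  # physical area represented by the whole lattice

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ConfigurationError("grid must have at least one patch")
        if self.carrying_capacity < 1:
            raise ConfigurationError("carrying_capacity must be >= 1")
        if self.area_cm2 <= 0:
            raise ConfigurationError("area_cm2 must be > 0")

    @property
    def n_patches(self) -> int:
        return self.rows * self.cols


@dataclass(frozen=True)
class DoseMap:
    """Conversion between physical doses and lattice field units.

    The antibiotic scale is pinned by one point: ``mg_per_cm2_per_1000mic``
    milligrams per cm^2 correspond to 1000x the nominal MIC; the mapping is
    linear through the origin. ``mol_to_field_units`` converts moles of a
    supplemented carbon source into nutrient field units.
    """

    mic_reference: float = 1.0  # nominal MIC in field units
    mg_per_cm2_per_1000mic: float = 10.0
    mol_to_field_units: float = 5.4e9

    def __post_init__(self) -> None:
        if min(self.mic_reference, self.mg_per_cm2_per_1000mic, self.mol_to_field_units) <= 0:
            raise ConfigurationError("DoseMap entries must all be positive")


VALID_INTERVENTION_KINDS = ("introduce_invader", "antibiotic", "carbon_supplement", "lb_bolus")


@dataclass(frozen=True)
class Intervention:
    """One scheduled perturbation.

    ``magnitude`` is in the kind's natural unit: cells for ``introduce_invader``,
    mg/cm^2 for ``antibiotic``, mol/cm^2 for ``carbon_supplement`` and raw
    nutrient field units for ``lb_bolus``.
    """

    kind: str
    at_timestep: int
    magnitude: float
    nutrient_name: str = "malate"  # only used by carbon_supplement

    def __post_init__(self) -> None:
        if self.kind not in VALID_INTERVENTION_KINDS:
            raise ConfigurationError(f"unknown intervention kind {self.kind!r}")
        if self.at_timestep < 0:
            raise ConfigurationError("at_timestep must be >= 0")
        if self.magnitude < 0:
            raise ConfigurationError("magnitude must be >= 0")


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of one simulation experiment."""

    grid: GridConfig
    clock: ModelClock
    nutrients: tuple[Nutrient, ...]
    residents: tuple[SpeciesParams, ...]
    n0: int  # initial agents per resident species (equal seeding)
    invader: SpeciesParams | None = None
    invader_n: int = 500
    invader_at: int = 4500
    interventions: tuple[Intervention, ...] = ()
    total_timesteps: int = 9000
    n_replicates: int = 3
    base_seed: int = 0
    p_kill: float = 0.1  # per-step death probability when local antibiotic >= mic
    antibiotic_decay: float = 0.0035  # first-order decay rate per timestep
    stagger_initial_energy: bool = True  # heterogeneous energies for seeded residents
    dosemap: DoseMap = field(default_factory=DoseMap)

    def __post_init__(self) -> None:
        if not self.residents:
            raise ConfigurationError("resident species list must be non-empty")
        if self.n0 < 0:
            raise ConfigurationError("n0 must be >= 0")
        names = [n.name for n in self.nutrients]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate nutrient names")
        all_species = list(self.residents) + ([self.invader] if self.invader else [])
        snames = [s.name for s in all_species]
        if len(set(snames)) != len(snames):
            raise ConfigurationError("duplicate species names")
        for sp in all_species:
            missing = set(sp.carbon_sources) - set(names)
            if missing:
                raise ConfigurationError(f"{sp.name} uses unknown nutrients {sorted(missing)}")
        if self.invader is not None and self.total_timesteps <= self.invader_at:
            raise ConfigurationError("total_timesteps must exceed the introduction timestep")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        total0 = self.n0 * len(self.residents)
        if total0 > self.grid.n_patches * self.grid.carrying_capacity:
            raise ConfigurationError("initial agents exceed total grid capacity")
        if not 0.0 <= self.p_kill <= 1.0:
            raise ConfigurationError("p_kill must be in [0,1]")
        if self.antibiotic_decay < 0:
            raise ConfigurationError("antibiotic_decay must be >= 0")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        for sp in ["residents"]:
            for s in d[sp]:
                s["carbon_sources"] = list(s["carbon_sources"])
                if math.isinf(s["mic"]):
                    s["mic"] = "inf"
        if d["invader"] is not None:
            d["invader"]["carbon_sources"] = list(d["invader"]["carbon_sources"])
            if math.isinf(d["invader"]["mic"]):
                d["invader"]["mic"] = "inf"
        d["nutrients"] = list(d["nutrients"])
        d["interventions"] = list(d["interventions"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        def _species(s: dict) -> SpeciesParams:
            s = dict(s)
            s["carbon_sources"] = tuple(s["carbon_sources"])
            if s.get("mic") == "inf":
                s["mic"] = math.inf
            return SpeciesParams(**s)

        return cls(
            grid=GridConfig(**d["grid"]),
            clock=ModelClock(**d["clock"]),
            nutrients=tuple(Nutrient(**n) for n in d["nutrients"]),
            residents=tuple(_species(s) for s in d["residents"]),
            n0=d["n0"],
            invader=_species(d["invader"]) if d.get("invader") else None,
            invader_n=d.get("invader_n", 500),
            invader_at=d.get("invader_at", 4500),
            interventions=tuple(Intervention(**i) for i in d.get("interventions", [])),
            total_timesteps=d.get("total_timesteps", 9000),
            n_replicates=d.get("n_replicates", 3),
            base_seed=d.get("base_seed", 0),
            p_kill=d.get("p_kill", 0.1),
            antibiotic_decay=d.get("antibiotic_decay", 0.0035),
            stagger_initial_energy=d.get("stagger_initial_energy", True),
            dosemap=DoseMap(**d.get("dosemap", {})),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        """Stable hash identifying the scenario (for output provenance)."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @property
    def all_species(self) -> tuple[SpeciesParams, ...]:
        if self.invader is not None:
            return self.residents + (self.invader,)
        return self.residents


def species_table_to_csv(species: Sequence[SpeciesParams]) -> pd.DataFrame:
    """Species table in the tabular exchange format (one row per species)."""
    rows = []
    for s in species:
        rows.append(
            {
                "name": s.name,
                "doubling_time_min": s.doubling_time,
                "carbon_sources": ";".join(s.carbon_sources),
                "uptake_rate": s.uptake_rate,
                "yield": s.yield_coeff,
                "maintenance": s.maintenance,
                "division_threshold": s.division_threshold,
                "initial_energy": s.initial_energy,
                "mic": s.mic,
                "growth_defect": s.growth_defect,
            }
        )
    return pd.DataFrame(rows)


def species_table_from_csv(df: pd.DataFrame) -> tuple[SpeciesParams, ...]:
    out = []
    for _, r in df.iterrows():
        out.append(
            SpeciesParams(
                name=str(r["name"]),
                doubling_time=float(r["doubling_time_min"]),
                carbon_sources=tuple(str(r["carbon_sources"]).split(";")),
                uptake_rate=float(r["uptake_rate"]),
                yield_coeff=float(r["yield"]),
                maintenance=float(r["maintenance"]),
                division_threshold=float(r["division_threshold"]),
                initial_energy=float(r["initial_energy"]),
                mic=float(r["mic"]),
                growth_defect=float(r.get("growth_defect", 0.0)),
            )
        )
    return tuple(out)
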