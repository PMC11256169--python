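"""Shipped default parameterization of the skin community.

The resident community is three populations representative of common skin
microbiome constituents -- Corynebacteria-, Staphylococci- and
Acinetobacter-like species -- plus an engineered *B. subtilis*-like invader.
Each resident has a preferred skin nutrient of its own (lipids, peptides and
free amino acids respectively; skin secretions supply all three), on top of a
small shared carbon pool every species can use. Malate is usable only by the
invader, which additionally scavenges the peptide pool of the abundant
Staphylococci-like population. Steady-state relative abundances are then set
by the replenishment-flux ratios of the preferred nutrients; the shipped
fluxes are calibrated (see ``scripts/calibrate_defaults.py``) so that equal
seeding relaxes to the characteristic skin composition (~83% / 15% / 2%).

The invader is parameterized as a fast-growing, high-uptake, high-maintenance
species: in the nutrient-scarce steady state its maintenance outruns what it
can scavenge and it starves away in about half a day, while on freed or
supplemented resources it outgrows every resident. Antibiotic sensitivity is
a per-species effective kill threshold in field units (1 unit = the nominal
assay MIC defining the mg/cm^2 dose scale); effective in-situ tolerances far
exceed the nominal MIC, which is what lets sub-1000x doses perturb the
community only transiently.
"""

from __future__ import annotations

import math

from .config import (
    DoseMap,
    GridConfig,
    ModelClock,
    Nutrient,
    ScenarioConfig,
    SpeciesParams,
)
from .core import calibrate_division_time

CLOCK = ModelClock(minutes_per_timestep=1.0)
GRID = GridConfig(rows=100, cols=100, carrying_capacity=10, area_cm2=1.0)

# Replenishment fluxes (units/patch/step). The exclusive-niche fluxes are in
# the steady-state abundance ratio 84:15:1; skin_carbon is the shared pool.
NUTRIENTS = (
    Nutrient("malate", diffusivity=0.1, replenish_rate=0.0, initial_amount=0.0),
    Nutrient("lipids", diffusivity=0.1, replenish_rate=0.4788, initial_amount=0.27),
    Nutrient("peptides", diffusivity=0.1, replenish_rate=0.0855, initial_amount=0.51),
    Nutrient("amino_acids", diffusivity=0.1, replenish_rate=0.012, initial_amount=0.2),
    Nutrient("skin_carbon", diffusivity=0.1, replenish_rate=0.04, initial_amount=0.02),
)


def _species(name, doubling_time, sources, uptake, yld, maint, mic, defect=0.0):
    base = SpeciesParams(
        name=name,
        doubling_time=doubling_time,
        carbon_sources=tuple(sources),
        uptake_rate=uptake,
        yield_coeff=yld,
        maintenance=maint,
        division_threshold=2.0,  # placeholder, replaced by calibration
        initial_energy=1.0,
        mic=mic,
        growth_defect=defect,
    )
    return calibrate_division_time(base, CLOCK)


CORYNEBACTERIA = _species(
    "corynebacteria", 60.0, ("lipids", "skin_carbon"), uptake=2.0, yld=1.0, maint=0.5, mic=900.0
)
STAPHYLOCOCCI = _species(
    "staphylococci", 80.0, ("peptides", "skin_carbon"), uptake=2.0, yld=1.0, maint=0.5, mic=700.0
)
ACINETOBACTER = _species(
    "acinetobacter", 120.0, ("amino_acids", "skin_carbon"), uptake=2.0, yld=1.0, maint=0.5, mic=870.0
)
BSUBTILIS = _species(
    "bsubtilis",
    40.0,
    ("malate", "peptides", "skin_carbon"),
    uptake=22.0,
    yld=1.0,
    maint=1.5,
    mic=math.inf,
)

RESIDENTS = (CORYNEBACTERIA, STAPHYLOCOCCI, ACINETOBACTER)

#: 10 mg/cm^2 of antibiotic corresponds to 1000x the nominal MIC; the malate
#: conversion is calibrated so the highest dose in the sweep (0.37 mmol/cm^2)
#: feeds the invader for roughly an extra half day before running out.
DOSEMAP = DoseMap(mic_reference=1.0, mg_per_cm2_per_1000mic=10.0, mol_to_field_units=2.8e8)

P_KILL = 0.1
ANTIBIOTIC_DECAY = 0.0035  # per-step first-order rate; half-life ~3.3 h

N0 = 500
INVADER_N = 500
INVADER_AT = 4500  # = 3.125 days at one minute per step
TOTAL_TIMESTEPS = 9000
N_REPLICATES = 3


def baseline_config(**overrides) -> ScenarioConfig:
    """The default scenario: three residents seeded equally, invader at 4500."""
    kwargs = dict(
        grid=GRID,
        clock=CLOCK,
        nutrients=NUTRIENTS,
        residents=RESIDENTS,
        n0=N0,
        invader=BSUBTILIS,
        invader_n=INVADER_N,
        invader_at=INVADER_AT,
        interventions=(),
        total_timesteps=TOTAL_TIMESTEPS,
        n_replicates=N_REPLICATES,
        base_seed=0,
        p_kill=P_KILL,
        antibiotic_decay=ANTIBIOTIC_DECAY,
        dosemap=DOSEMAP,
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)
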