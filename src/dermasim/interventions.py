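"""Perturbations applied to a running simulation.

Four interventions are modelled, all applied (by default) at the moment the
engineered invader is introduced: the introduction itself, a topical
antibiotic dosed in mg/cm^2 and converted to multiples of the nominal MIC, a
supplemental carbon source (malate) dosed in mol/cm^2 that only the invader
can metabolize, and a bolus of non-specific nutrients (LB) added to the
shared carbon pool that every species can use.
"""

from __future__ import annotations

import numpy as np

from .config import DoseMap, Intervention, ScenarioConfig, SpeciesParams
from .core import SimulationState

__all__ = [
    "introduce_invader",
    "dose_to_mic_multiple",
    "apply_antibiotic",
    "apply_carbon_supplement",
    "apply_lb_bolus",
    "apply_intervention",
]


def introduce_invader(
    state: SimulationState, species_name: str, n_cells: int, at_timestep: int | None = None
) -> SimulationState:
    """Add ``n_cells`` invader agents at uniformly random patches.

    Each arrives with its species' seeding energy. ``at_timestep``, when
    given, must equal the state's current timestep (the schedule is the
    caller's job; this guards against misuse).
    """
    if at_timestep is not None and at_timestep != state.timestep:
        raise ValueError(
            f"introduction scheduled for t={at_timestep} but state is at t={state.timestep}"
        )
    si = state.species_index(species_name)  # KeyError for unknown species
    state.seed_uniform(si, n_cells)
    return state


def dose_to_mic_multiple(dose_mg_per_cm2: float, dosemap: DoseMap) -> float:
    """Linear map from a topical dose to a multiple of the nominal MIC.

    Pinned by the single calibration point ``mg_per_cm2_per_1000mic`` mg/cm^2
    <-> 1000x MIC (default: 10 mg/cm^2).
    """
    if dose_mg_per_cm2 < 0:
        raise ValueError("antibiotic dose must be >= 0")
    return dose_mg_per_cm2 * 1000.0 / dosemap.mg_per_cm2_per_1000mic


def apply_antibiotic(
    state: SimulationState, dose_mg_per_cm2: float, dosemap: DoseMap
) -> SimulationState:
    """Apply a spatially uniform antibiotic dose.

    The field is set to ``mic_multiple * mic_reference`` everywhere and
    subsequently decays first-order per the core update. A zero dose leaves
    the field untouched (and the trajectory identical to baseline)."""
    multiple = dose_to_mic_multiple(dose_mg_per_cm2, dosemap)
    if multiple > 0:
        state.grid.antibiotic[:] = multiple * dosemap.mic_reference
    return state


def apply_carbon_supplement(
    state: SimulationState,
    amount_mol_per_cm2: float,
    nutrient_name: str,
    dosemap: DoseMap,
) -> SimulationState:
    """Distribute a carbon-source bolus equally across all patches.

    ``amount_mol_per_cm2 * area_cm2 * mol_to_field_units`` field units are
    split evenly over the lattice into the named nutrient field.
    """
    if amount_mol_per_cm2 < 0:
        raise ValueError("supplement amount must be >= 0")
    total_units = amount_mol_per_cm2 * state.grid.area_cm2 * dosemap.mol_to_field_units
    state.grid.fields[nutrient_name] += total_units / state.grid.n_patches
    return state


def apply_lb_bolus(state: SimulationState, amount: float) -> SimulationState:
    """Add non-specific nutrients (an LB bolus) to the shared carbon pool.

    The amount is in raw field units, spread uniformly over the lattice into
    ``skin_carbon``, which every species can consume.
    """
    if amount < 0:
        raise ValueError("bolus amount must be >= 0")
    state.grid.fields["skin_carbon"] += amount / state.grid.n_patches
    return state


def apply_intervention(
    state: SimulationState, iv: Intervention, config: ScenarioConfig
) -> SimulationState:
    """Dispatch one scheduled intervention (used by the experiment runner)."""
    if iv.kind == "introduce_invader":
        if config.invader is None:
            raise ValueError("scenario has no invader species")
        return introduce_invader(state, config.invader.name, int(iv.magnitude), iv.at_timestep)
    if iv.kind == "antibiotic":
        return apply_antibiotic(state, iv.magnitude, config.dosemap)
    if iv.kind == "carbon_supplement":
        return apply_carbon_supplement(state, iv.magnitude, iv.nutrient_name, config.dosemap)
    if iv.kind == "lb_bolus":
        return apply_lb_bolus(state, iv.magnitude)
    raise ValueError(f"unknown intervention kind {iv.kind!r}")
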