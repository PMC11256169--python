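"""Scenario presets, replicate execution and summary statistics.

`run_scenario` executes ``n_replicates`` independent trajectories (replicate
``r`` is seeded with ``base_seed + r``) and returns a
:class:`PopulationTimeSeries` with per-species counts at every timestep.
From it the two reported statistics are computed: pre-introduction
steady-state community fractions, and the invader's survival time after
introduction with right-censoring at the post-introduction horizon.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import defaults
from .config import Intervention, ScenarioConfig
from .core import advance, init_environment
from .interventions import apply_intervention, introduce_invader

__all__ = [
    "PopulationTimeSeries",
    "SurvivalResult",
    "run_scenario",
    "run_replicate",
    "survival_time",
    "steady_state_fractions",
    "replicate_summary",
    "preset",
    "PRESET_NAMES",
]

#: post-introduction horizon (days) at which survival is right-censored
DEFAULT_HORIZON_DAYS = 3.0


@dataclass
class PopulationTimeSeries:
    """Per-species population counts for every replicate of a scenario.

    ``counts`` has shape ``(n_replicates, n_recorded_steps, n_species)`` with
    row ``t`` holding the counts at timestep ``t`` (so a full run has
    ``total_timesteps + 1`` rows). Runs stopped early (only ever after the
    invader's extinction) have fewer rows; ``total_timesteps`` always records
    the configured horizon.
    """

    counts: np.ndarray
    species: tuple[str, ...]
    steps_per_day: float
    introduced_at: int | None
    total_timesteps: int
    seeds: tuple[int, ...]
    config_hash: str

    @property
    def n_replicates(self) -> int:
        return self.counts.shape[0]

    @property
    def days(self) -> np.ndarray:
        return np.arange(self.counts.shape[1]) / self.steps_per_day

    def species_counts(self, name: str) -> np.ndarray:
        return self.counts[:, :, self.species.index(name)]

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table: replicate, timestep, day, species, count."""
        reps, steps, nsp = self.counts.shape
        rep = np.repeat(np.arange(1, reps + 1), steps * nsp)
        t = np.tile(np.repeat(np.arange(steps), nsp), reps)
        sp = np.tile(np.array(self.species), steps * reps)
        return pd.DataFrame(
            {
                "replicate": rep,
                "timestep": t,
                "day": t / self.steps_per_day,
                "species": sp,
                "count": self.counts.reshape(-1),
            }
        )

    def to_csv(self) -> str:
        buf = io.StringIO()
        self.to_tidy().to_csv(buf, index=False, float_format="%.6f")
        return buf.getvalue()


@dataclass(frozen=True)
class SurvivalResult:
    """Invader survival after introduction, right-censored at the horizon."""

    survival_days: float
    censored: bool

    def __post_init__(self):
        if self.survival_days < 0:
            raise ValueError("survival_days must be >= 0")


def run_replicate(
    config: ScenarioConfig, seed: int, stop_after_invader_extinct: bool = False
) -> np.ndarray:
    """One trajectory; returns counts of shape (n_steps_recorded, n_species).

    With ``stop_after_invader_extinct`` the run ends once the invader has
    been introduced and has died out (used for survival-only sweeps).
    """
    state = init_environment(config, seed)
    n_species = len(config.all_species)
    inv_idx = len(config.residents) if config.invader is not None else None
    rows = [state.counts()]
    for t in range(config.total_timesteps):
        # interventions fire at the *start* of their timestep, so counts at
        # the introduction step already include the inoculum
        if config.invader is not None and state.timestep == config.invader_at:
            introduce_invader(state, config.invader.name, config.invader_n, config.invader_at)
            rows[-1] = state.counts()
        for iv in config.interventions:
            if iv.at_timestep == state.timestep:
                apply_intervention(state, iv, config)
                rows[-1] = state.counts()
        advance(state)
        rows.append(state.counts())
        if (
            stop_after_invader_extinct
            and inv_idx is not None
            and state.timestep > config.invader_at
            and rows[-1][inv_idx] == 0
        ):
            break
    return np.asarray(rows)


def run_scenario(
    config: ScenarioConfig, stop_after_invader_extinct: bool = False
) -> PopulationTimeSeries:
    """Run all replicates of a scenario (replicate r uses seed base_seed + r)."""
    seeds = tuple(config.base_seed + r for r in range(1, config.n_replicates + 1))
    runs = [run_replicate(config, s, stop_after_invader_extinct) for s in seeds]
    n = max(r.shape[0] for r in runs)
    counts = np.zeros((len(runs), n, runs[0].shape[1]), dtype=np.int64)
    for i, r in enumerate(runs):
        counts[i, : r.shape[0]] = r
        counts[i, r.shape[0] :] = r[-1]  # only ever pads past invader extinction
    return PopulationTimeSeries(
        counts=counts,
        species=tuple(s.name for s in config.all_species),
        steps_per_day=config.clock.steps_per_day,
        introduced_at=config.invader_at if config.invader is not None else None,
        total_timesteps=config.total_timesteps,
        seeds=seeds,
        config_hash=config.config_hash(),
    )


def survival_time(
    ts: PopulationTimeSeries,
    invader_name: str,
    horizon_days: float = DEFAULT_HORIZON_DAYS,
) -> list[SurvivalResult]:
    """Per-replicate invader survival time in days.

    Survival is the time from introduction to the first post-introduction
    timestep with zero invaders. A population still alive ``horizon_days``
    after introduction is right-censored at the horizon: long-term survivors
    are reported as 3 days because the observation window ends there.
    """
    if ts.introduced_at is None:
        raise ValueError("scenario has no invader")
    intro = ts.introduced_at
    horizon_steps = round(horizon_days * ts.steps_per_day)
    inv = ts.species_counts(invader_name)
    out = []
    for r in range(ts.n_replicates):
        window = inv[r, intro : min(intro + horizon_steps, inv.shape[1] - 1) + 1]
        zeros = np.flatnonzero(window == 0)
        if zeros.size:
            out.append(SurvivalResult(zeros[0] / ts.steps_per_day, censored=False))
        else:
            out.append(SurvivalResult(horizon_days, censored=True))
    return out


def steady_state_fractions(
    ts: PopulationTimeSeries, window_days: float = 1.0
) -> dict[str, tuple[float, float]]:
    """Community composition over the trailing window before introduction.

    Per replicate, each species' mean count over the last ``window_days``
    before the introduction timestep (or before the end of the run when there
    is no invader), normalized to sum to one; returns the across-replicate
    mean and standard deviation of each fraction.
    """
    end = ts.introduced_at if ts.introduced_at is not None else ts.counts.shape[1] - 1
    start = max(0, end - round(window_days * ts.steps_per_day))
    window = ts.counts[:, start:end, :].mean(axis=1)  # (reps, species)
    totals = window.sum(axis=1, keepdims=True)
    frac = np.divide(window, totals, out=np.zeros_like(window, dtype=float), where=totals > 0)
    return {
        sp: (float(frac[:, i].mean()), float(frac[:, i].std(ddof=1)) if ts.n_replicates > 1 else 0.0)
        for i, sp in enumerate(ts.species)
    }


def replicate_summary(values) -> tuple[float, float]:
    """Mean and (sample) standard deviation across replicates."""
    v = np.asarray(values, dtype=float)
    return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0


# ---------------------------------------------------------------------------
# presets

ANTIBIOTIC_DOSES = (0.0, 4.0, 8.0, 10.0)  # mg/cm^2
MALATE_DOSES = (0.0, 37e-9, 3.7e-6, 0.37e-3)  # mol/cm^2
GROWTH_DEFECTS = (0.1, 0.25, 0.5, 1.0)
DEFAULT_LB_UNITS = 2.0e5

PRESET_NAMES = (
    ["baseline", "lb_bolus"]
    + [f"antibiotic:{d:g}" for d in ANTIBIOTIC_DOSES]
    + [f"malate:{d:g}" for d in MALATE_DOSES]
    + [f"growth_defect:{d:g}" for d in GROWTH_DEFECTS]
)


def preset(name: str, base_seed: int = 0) -> ScenarioConfig:
    """Named scenario presets.

    ``baseline``; ``antibiotic:{0,4,8,10}`` (mg/cm^2);
    ``malate:{0,3.7e-08,3.7e-06,0.00037}`` (mol/cm^2);
    ``growth_defect:{0.1,0.25,0.5,1.0}``; ``lb_bolus``. All interventions are
    applied concurrently with the invader's introduction.
    """
    if name == "baseline":
        return defaults.baseline_config(base_seed=base_seed)
    if name == "lb_bolus":
        iv = Intervention("lb_bolus", defaults.INVADER_AT, DEFAULT_LB_UNITS)
        return defaults.baseline_config(base_seed=base_seed, interventions=(iv,))
    if ":" in name:
        kind, _, val = name.partition(":")
        try:
            x = float(val)
        except ValueError:
            raise ValueError(f"bad preset value in {name!r}") from None
        if kind == "antibiotic":
            iv = Intervention("antibiotic", defaults.INVADER_AT, x)
            return defaults.baseline_config(base_seed=base_seed, interventions=(iv,))
        if kind == "malate":
            iv = Intervention("carbon_supplement", defaults.INVADER_AT, x, nutrient_name="malate")
            return defaults.baseline_config(base_seed=base_seed, interventions=(iv,))
        if kind == "growth_defect":
            return defaults.baseline_config(
                base_seed=base_seed, invader=defaults.BSUBTILIS.with_defect(x)
            )
    raise ValueError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
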