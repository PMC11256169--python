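"""Lattice agent-based model core.

The model descends from NetLogo-style gut community simulators: bacteria are
discrete agents on a toroidal patch lattice carrying an energy store. Each
timestep an agent, in randomized order, (1) consumes nutrient from its patch
(up to its uptake budget, filled from its usable carbon sources in preference
order), (2) pays a maintenance cost, (3) dies if its energy is exhausted,
(4) dies with probability ``p_kill`` if the local antibiotic concentration is
at or above its MIC, (5) divides into two half-energy daughters when its
energy reaches the division threshold and there is patch capacity, and
(6) random-walks to a neighbouring patch when local food is scarce. Nutrient
fields are replenished (skin secretion), smoothed by 8-neighbour diffusion,
and depleted by consumption; the antibiotic field decays first-order. There
is no advective flow.

The implementation is vectorized over agents. Within a timestep the six rules
run as synchronous phases, but the two contended resources -- nutrient on a
patch and free capacity slots for division -- are allocated to agents
*sequentially in the shuffled order*, i.e. exactly the first-come semantics
of a per-agent loop. On a single patch with a single agent the engine is
step-for-step identical to a closed-form energy ledger, which the test suite
checks.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .config import (
    ConfigurationError,
    GridConfig,
    ModelClock,
    Nutrient,
    ScenarioConfig,
    SpeciesParams,
)

__all__ = [
    "EnvironmentGrid",
    "SimulationState",
    "init_environment",
    "replenish_and_diffuse",
    "advance",
    "calibrate_division_time",
    "steps_to_divide",
]


class CalibrationError(ValueError):
    """Raised when a species' energy budget cannot realise its doubling time."""


def steps_to_divide(species: SpeciesParams) -> int:
    """Timesteps from seeding to first division under saturating nutrient.

    Closed form of the energy ledger: each step the agent gains
    ``yield * effective_uptake - maintenance`` energy, starting from
    ``initial_energy`` and dividing at ``division_threshold``.
    """
    net = species.yield_coeff * species.effective_uptake - species.maintenance
    if net <= 0:
        raise CalibrationError(
            f"{species.name}: maintenance >= yield*uptake, agent can never divide"
        )
    return math.ceil((species.division_threshold - species.initial_energy) / net)


def calibrate_division_time(
    species: SpeciesParams, clock: ModelClock | None = None
) -> SpeciesParams:
    """Anchor the emergent division interval to the species' doubling time.

    Solves for ``division_threshold`` and ``initial_energy`` (threshold = 2 x
    initial energy, so daughters restart exactly at the seeding energy) such
    that under saturating nutrient the agent divides after
    ``round(doubling_time / minutes_per_timestep)`` steps. A growth defect d
    rescales effective uptake by 1/(1+d), so the realised doubling time is
    about (1+d) times the nominal one.
    """
    clock = clock or ModelClock()
    n = max(1, round(species.doubling_time / clock.minutes_per_timestep))
    net = species.yield_coeff * species.uptake_rate - species.maintenance
    if net <= 0:
        raise CalibrationError(
            f"{species.name}: maintenance {species.maintenance} >= "
            f"yield*uptake {species.yield_coeff * species.uptake_rate}"
        )
    threshold = 2.0 * n * net
    return replace(species, division_threshold=threshold, initial_energy=threshold / 2.0)


class EnvironmentGrid:
    """Toroidal patch lattice holding nutrient and antibiotic fields."""

    def __init__(self, config: GridConfig, nutrients: tuple[Nutrient, ...]):
        self.rows = config.rows
        self.cols = config.cols
        self.area_cm2 = config.area_cm2
        self.carrying_capacity = config.carrying_capacity
        self.nutrients = nutrients
        self.n_patches = config.n_patches
        self.fields: dict[str, np.ndarray] = {
            n.name: np.full(self.n_patches, float(n.initial_amount)) for n in nutrients
        }
        self.antibiotic = np.zeros(self.n_patches)
        self._neighbors = self._build_neighbors()

    def _build_neighbors(self) -> np.ndarray:
        """(n_patches, 8) flat indices of the Moore neighbourhood on the torus."""
        r = np.arange(self.n_patches) // self.cols
        c = np.arange(self.n_patches) % self.cols
        offs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
        nb = np.empty((self.n_patches, 8), dtype=np.int64)
        for k, (dr, dc) in enumerate(offs):
            nb[:, k] = ((r + dr) % self.rows) * self.cols + (c + dc) % self.cols
        return nb

    @property
    def neighbors(self) -> np.ndarray:
        return self._neighbors

    def field_total(self, name: str) -> float:
        return float(self.fields[name].sum())

    def diffuse_field(self, name: str, diffusivity: float) -> None:
        """Each patch keeps (1-D) of its amount, distributing D equally to its
        8 toroidal neighbours. Conserves total mass exactly (up to roundoff)."""
        if diffusivity == 0.0:
            return
        f = self.fields[name]
        nb_sum = f[self._neighbors].sum(axis=1)
        self.fields[name] = (1.0 - diffusivity) * f + (diffusivity / 8.0) * nb_sum


class SimulationState:
    """Full mutable state of one replicate: grid, agents, clock and RNG.

    Agents are stored structure-of-arrays: ``species_id`` (index into
    ``species``), ``patch`` (flat lattice index) and ``energy``. A single
    seeded :class:`numpy.random.Generator` drives every stochastic choice, so
    an identical config + seed reproduces the trajectory bit for bit.
    """

    def __init__(
        self,
        grid: EnvironmentGrid,
        clock: ModelClock,
        species: tuple[SpeciesParams, ...],
        seed: int,
        p_kill: float = 0.1,
        antibiotic_decay: float = 0.0035,
    ):
        self.grid = grid
        self.clock = clock
        self.species = species
        self.p_kill = float(p_kill)
        self.antibiotic_decay = float(antibiotic_decay)
        self.rng = np.random.default_rng(seed)
        self.seed = seed
        self.timestep = 0

        self.species_id = np.empty(0, dtype=np.int64)
        self.patch = np.empty(0, dtype=np.int64)
        self.energy = np.empty(0, dtype=np.float64)

        # per-species lookup arrays for the vectorized update
        self._u_eff = np.array([s.effective_uptake for s in species])
        self._yield = np.array([s.yield_coeff for s in species])
        self._maint = np.array([s.maintenance for s in species])
        self._thresh = np.array([s.division_threshold for s in species])
        self._e0 = np.array([s.initial_energy for s in species])
        self._mic = np.array([s.mic for s in species])
        self._forage = 0.1 * self._u_eff  # move when local usable nutrient < 10% of uptake
        field_names = [n.name for n in grid.nutrients]
        self._field_order = field_names
        self._src_mask = np.zeros((len(species), len(field_names)), dtype=bool)
        # preference: an agent fills its budget walking its carbon_sources order;
        # because all shipped source lists are compatible with one global field
        # order we realise preference by ordering the global passes
        pref_rank = {}
        for si, s in enumerate(species):
            for rank, src in enumerate(s.carbon_sources):
                self._src_mask[si, field_names.index(src)] = True
                pref_rank.setdefault(src, rank)
        self._pass_order = sorted(range(len(field_names)), key=lambda fi: pref_rank.get(field_names[fi], 99))

        # per-step diagnostics for mass-balance accounting
        self.last_replenished: dict[str, float] = {n: 0.0 for n in field_names}
        self.last_consumed: dict[str, float] = {n: 0.0 for n in field_names}

    # -- convenience -------------------------------------------------------

    @property
    def n_agents(self) -> int:
        return self.species_id.size

    def counts(self) -> np.ndarray:
        return np.bincount(self.species_id, minlength=len(self.species))

    def species_index(self, name: str) -> int:
        for i, s in enumerate(self.species):
            if s.name == name:
                return i
        raise KeyError(f"unknown species {name!r}")

    def patch_occupancy(self) -> np.ndarray:
        return np.bincount(self.patch, minlength=self.grid.n_patches)

    def add_agents(self, species_idx: int, patches: np.ndarray, energy: float) -> None:
        n = len(patches)
        self.species_id = np.concatenate([self.species_id, np.full(n, species_idx, dtype=np.int64)])
        self.patch = np.concatenate([self.patch, patches.astype(np.int64)])
        self.energy = np.concatenate([self.energy, np.full(n, float(energy))])

    def seed_uniform(self, species_idx: int, n: int, stagger_energy: bool = False) -> None:
        """Place ``n`` fresh agents at uniformly random patches, respecting the
        patch carrying capacity (overfull draws are re-drawn onto free patches).

        With ``stagger_energy`` the agents' energies are drawn uniformly from
        [0.5, 1.5] x initial_energy (mean unchanged): an established wild
        population is heterogeneous in cell state, and seeding identical
        energies produces artificial synchronized starvation waves. A fresh
        inoculum (the introduced invader) is seeded without staggering.
        """
        if n == 0:
            return
        patches = self.rng.integers(0, self.grid.n_patches, size=n)
        e0 = self.species[species_idx].initial_energy
        self.add_agents(species_idx, patches, e0)
        if stagger_energy:
            self.energy[-n:] = e0 * self.rng.uniform(0.5, 1.5, size=n)
        cap = self.grid.carrying_capacity
        occ = self.patch_occupancy()
        while (occ > cap).any():
            over = np.flatnonzero(occ > cap)
            for p in over:
                idx = np.flatnonzero(self.patch == p)
                excess = idx[cap:]
                room = np.flatnonzero(occ < cap)
                dest = self.rng.choice(room, size=len(excess), replace=True)
                self.patch[excess] = dest
                occ = self.patch_occupancy()


def init_environment(config: ScenarioConfig, seed: int | None = None) -> SimulationState:
    """Build the initial state: equal numbers of each resident species at
    uniformly random patches, nutrient fields at their initial amounts, no
    antibiotic, timestep zero."""
    total0 = config.n0 * len(config.residents)
    if total0 > config.grid.n_patches * config.grid.carrying_capacity:
        raise ConfigurationError("initial agents exceed total grid capacity")
    grid = EnvironmentGrid(config.grid, config.nutrients)
    state = SimulationState(
        grid,
        config.clock,
        config.all_species,
        seed=config.base_seed if seed is None else seed,
        p_kill=config.p_kill,
        antibiotic_decay=config.antibiotic_decay,
    )
    for si, _ in enumerate(config.residents):
        state.seed_uniform(si, config.n0, stagger_energy=config.stagger_initial_energy)
    return state


def replenish_and_diffuse(state: SimulationState) -> SimulationState:
    """Secrete nutrients, smooth all fields, decay the antibiotic.

    Replenishment adds ``replenish_rate`` to every patch; diffusion then
    redistributes without changing totals; the antibiotic field decays by
    ``exp(-lambda)`` per step.
    """
    grid = state.grid
    for nut in grid.nutrients:
        if nut.replenish_rate:
            grid.fields[nut.name] += nut.replenish_rate
        state.last_replenished[nut.name] = nut.replenish_rate * grid.n_patches
        grid.diffuse_field(nut.name, nut.diffusivity)
    if state.antibiotic_decay:
        grid.antibiotic *= math.exp(-state.antibiotic_decay)
    return state


def _segment_starts(sorted_keys: np.ndarray) -> np.ndarray:
    """Indices where a new key begins in a sorted key array."""
    if sorted_keys.size == 0:
        return np.empty(0, dtype=np.int64)
    mask = np.empty(sorted_keys.size, dtype=bool)
    mask[0] = True
    np.not_equal(sorted_keys[1:], sorted_keys[:-1], out=mask[1:])
    return np.flatnonzero(mask)


def _ranked_grant(patches: np.ndarray, order: np.ndarray, slots: np.ndarray) -> np.ndarray:
    """First-come allocation of per-patch slots.

    ``patches[i]`` requests one slot on that patch; requests are served in
    increasing ``order`` (the shuffled agent rank). Returns a boolean grant
    mask. ``slots`` is the free-slot count per patch (may be negative).
    """
    if patches.size == 0:
        return np.zeros(0, dtype=bool)
    # fast path: no patch is oversubscribed, so everyone is granted
    requests = np.bincount(patches, minlength=slots.size)
    if np.all(requests <= np.maximum(slots, 0)):
        return np.ones(patches.size, dtype=bool)
    idx = np.lexsort((order, patches))
    ps = patches[idx]
    starts = _segment_starts(ps)
    seg_id = np.zeros(ps.size, dtype=np.int64)
    seg_id[starts] = 1
    seg_id = np.cumsum(seg_id) - 1
    rank = np.arange(ps.size) - starts[seg_id]
    grant_sorted = rank < np.maximum(slots[ps], 0)
    grant = np.zeros(patches.size, dtype=bool)
    grant[idx] = grant_sorted
    return grant


def _agent_phase(state: SimulationState) -> None:
    n = state.n_agents
    grid = state.grid
    rng = state.rng
    for f in state._field_order:
        state.last_consumed[f] = 0.0
    if n == 0:
        return

    sid = state.species_id
    patch = state.patch
    order = rng.permutation(n)

    # ---- consumption: sequential first-come allocation within each patch ----
    idx = np.lexsort((order, patch))  # agents sorted by (patch, shuffled rank)
    ps = patch[idx]
    starts = _segment_starts(ps)
    seg_patch = ps[starts]
    seg_id = np.zeros(ps.size, dtype=np.int64)
    seg_id[starts] = 1
    seg_id = np.cumsum(seg_id) - 1

    remaining = state._u_eff[sid].copy()  # uptake budget left, nutrient units
    eaten = np.zeros(n)
    for fi in state._pass_order:
        fname = state._field_order[fi]
        field = grid.fields[fname]
        elig = state._src_mask[sid, fi]
        if not elig.any():
            continue
        demand = np.where(elig, remaining, 0.0)
        ds = demand[idx]
        cs = np.cumsum(ds)
        base = (cs[starts] - ds[starts])[seg_id]
        before = cs - ds - base  # demand ahead of me on my patch
        avail = field[seg_patch][seg_id]
        take_sorted = np.clip(avail - before, 0.0, ds)
        consumed_per_patch = np.add.reduceat(take_sorted, starts)
        field[seg_patch] = np.maximum(field[seg_patch] - consumed_per_patch, 0.0)
        take = np.zeros(n)
        take[idx] = take_sorted
        remaining -= take
        eaten += take
        state.last_consumed[fname] = float(take_sorted.sum())

    # ---- energy ledger, starvation, antibiotic kill ----
    energy = state.energy
    energy += state._yield[sid] * eaten - state._maint[sid]
    starved = energy <= 0.0
    exposed = grid.antibiotic[patch] >= state._mic[sid]
    killed = exposed & (rng.random(n) < state.p_kill)
    keep = ~(starved | killed)

    sid = sid[keep]
    patch = patch[keep]
    energy = energy[keep]
    order = order[keep]

    cap = grid.carrying_capacity
    occ = np.bincount(patch, minlength=grid.n_patches)
    slots = cap - occ

    # ---- division: two half-energy daughters if there is room ----
    div = np.flatnonzero(energy >= state._thresh[sid])
    off_sid = np.empty(0, dtype=np.int64)
    off_patch = np.empty(0, dtype=np.int64)
    off_energy = np.empty(0)
    if div.size:
        grant_here = _ranked_grant(patch[div], order[div], slots)
        placed = div[grant_here]
        placed_patch = patch[placed]
        # daughters placed off-patch when the parent patch is full: one attempt
        # at a random neighbour with room, otherwise division is deferred
        spill = div[~grant_here]
        if spill.size:
            slots2 = slots - np.bincount(placed_patch, minlength=grid.n_patches)
            prop = grid.neighbors[patch[spill], rng.integers(0, 8, size=spill.size)]
            grant_nb = _ranked_grant(prop, order[spill], slots2)
            placed = np.concatenate([placed, spill[grant_nb]])
            placed_patch = np.concatenate([placed_patch, prop[grant_nb]])
        if placed.size:
            energy[placed] *= 0.5
            off_sid = sid[placed]
            off_patch = placed_patch
            off_energy = energy[placed].copy()
            occ = occ + np.bincount(off_patch, minlength=grid.n_patches)
            slots = cap - occ

    # ---- foraging movement when local usable nutrient is scarce ----
    usable = np.zeros(sid.size)
    for fi, fname in enumerate(state._field_order):
        m = state._src_mask[sid, fi]
        if m.any():
            usable[m] += grid.fields[fname][patch[m]]
    movers = np.flatnonzero(usable < state._forage[sid])
    if movers.size:
        target = grid.neighbors[patch[movers], rng.integers(0, 8, size=movers.size)]
        # conservative capacity check: arrivals ranked against current free
        # slots (departures within the same step do not free slots)
        grant_mv = _ranked_grant(target, order[movers], slots)
        patch[movers[grant_mv]] = target[grant_mv]

    state.species_id = np.concatenate([sid, off_sid])
    state.patch = np.concatenate([patch, off_patch])
    state.energy = np.concatenate([energy, off_energy])


def advance(state: SimulationState) -> SimulationState:
    """Advance the model by exactly one timestep."""
    replenish_and_diffuse(state)
    _agent_phase(state)
    state.timestep += 1
    return state
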