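# Methods

## Model overview

`dermasim` simulates bacterial population dynamics on skin with a lattice
agent-based model in the NetLogo gut-community tradition: discrete bacteria
carrying an energy store live on a toroidal grid of patches, eat diffusible
nutrient fields, pay a maintenance cost, divide when their energy reaches a
threshold, starve when it runs out, and random-walk toward food. Population
structure is emergent; nothing imposes the community composition directly.
There is no advective flow (skin, unlike the gut lumen, does not wash cells
through), no pH/temperature physics, no horizontal gene transfer and no
plasmid-loss subpopulation.

### Update loop

Each timestep (1 minute by default):

1. **Replenish** — every nutrient field gains `replenish_rate` per patch
   (skin secretion).
2. **Diffuse** — each field keeps `1 − D` of a patch's amount and splits `D`
   equally over the 8 toroidal neighbours; total mass is conserved exactly.
3. **Antibiotic decay** — the antibiotic field decays by `exp(−λ)` per step.
4. **Agents** (in a freshly shuffled order):
   consume up to `uptake/(1+growth_defect)` nutrient units from the patch,
   filling the budget from the species' carbon sources in preference order
   and gaining `yield` energy per unit; pay `maintenance`; die at energy ≤ 0;
   die with probability `p_kill` if the local antibiotic concentration ≥ the
   species' MIC; divide into two half-energy daughters when energy ≥ the
   division threshold and patch occupancy allows (daughters spill to a random
   neighbour with room, else division is deferred); move to a random
   neighbour when local usable nutrient is below 10 % of the uptake budget.

The implementation is vectorized; within a timestep the rules run as
synchronous phases, but the two contended resources — nutrient on a patch
and free division slots — are allocated to agents sequentially in the
shuffled order, which is exactly the first-come semantics of a per-agent
loop. On a 1×1 grid with one agent the engine is step-for-step identical to
a closed-form energy ledger (tested). A movement target is granted only if
the destination has free capacity, counted conservatively (same-step
departures do not free slots), so patch occupancy never exceeds the carrying
capacity.

One seeded `numpy.random.Generator` per replicate drives every stochastic
choice; identical config + seed reproduces trajectories bit for bit.
Replicate *r* of a scenario uses seed `base_seed + r`.

### Division-time calibration

`calibrate_division_time` fixes the emergent division interval to a species'
stated doubling time: with net energy gain `g = yield·uptake − maintenance`
per saturated step, it sets `division_threshold = 2·n·g` and
`initial_energy = threshold/2` where `n = round(doubling_time / Δt)`, so the
first division occurs after exactly `n` steps and daughters restart at the
seeding energy. A growth defect `d` divides the uptake budget by `1 + d`,
lengthening the effective doubling time by about `(1+d)×` and leaving the
energy scheme otherwise untouched. Infeasible budgets
(`maintenance ≥ yield·uptake`) raise a calibration error.

## The shipped community

Five nutrient fields and four species. Each resident holds a preferred
nutrient of its own — lipids (Corynebacteria-like), peptides
(Staphylococci-like), free amino acids (Acinetobacter-like) — plus a small
shared `skin_carbon` pool usable by everyone. `malate` is consumable only by
the *B. subtilis*-like invader, which also scavenges the peptide pool and
the shared pool. Under this structure each resident's steady state is
pinned by its niche's replenishment flux (`N* ≈ flux·yield/maintenance`
plus its per-capita share of the shared pool), so steady-state fractions
equal the flux ratios and the community is *stably* coexisting — it
recovers from perturbations rather than drifting toward competitive
exclusion. The shipped fluxes (0.4788 : 0.0855 : 0.012 units/patch/step,
+ 0.04 shared) were calibrated with `scripts/calibrate_defaults.py` so that
equal seeding of 500 agents each relaxes, within about 1.5 simulated days,
to roughly 83 % / 15 % / 2 % and stays there; the search varied the
amino-acid flux, the shared flux, the initial field inventories and the
doubling times that set relaxation speed.

Resident kinetics are identical (uptake 2, yield 1, maintenance 0.5 per
step) except for doubling times (60 / 80 / 120 min), so competition for the
shared pool is per-capita neutral and does not distort the fractions.
Resident seeding energies are staggered uniformly over [0.5, 1.5] × the
seeding energy (mean unchanged): a wild community is heterogeneous in cell
state, and identical energies produce artificial synchronized starvation
waves with slowly damped community oscillations. The invader inoculum — a
fresh culture — is seeded at exactly its seeding energy.

### The invader

The engineered invader is parameterized as a fast grower with an expensive
metabolism: doubling time 40 min, uptake budget 22, maintenance 1.5, diet
(malate, peptides, shared carbon). Its break-even intake (1.5 units/step)
is several times what peptide scavenging yields while the dense
Staphylococci-like population keeps that pool grazed down, so after
introduction the invader runs an energy deficit and starves away in about
half a day — its seeding reserve (820 energy units) divided by the net
deficit. Because the niche it scavenges belongs to an *abundant* resident,
500 hungry invaders remove only a modest share of that resident's flux:
the community is dented, not destabilized. This is the mechanism behind
three observed behaviours:

* **Baseline:** extinction at ~0.5 d, residents dip briefly and return to
  their pre-introduction steady state (tested to within 10 %).
* **Antibiotic at 1000× MIC:** the residents crash; the most sensitive
  species (the Staphylococci-like population, whose niche the invader can
  use) goes extinct, permanently freeing its peptide flux, which sustains
  the resistant invader well past the 3-day censoring horizon while the
  other residents recover.
* **Malate supplementation:** a finite exclusive meal raises invader energy
  stores; survival extends with dose from ~0.5 d to ~1 d at 0.37 mmol/cm²,
  ending when the bolus is consumed and the reserve drains.

### Antibiotic model

Application sets a spatially uniform field in units of the nominal assay MIC
(the `DoseMap` pins 10 mg/cm² = 1000× nominal MIC; the mapping is linear
through the origin, an assumption the model makes explicit). The field
decays first-order with λ = 0.0035 min⁻¹ (half-life ≈ 3.3 h — a topical
compound cleared within hours). The kill rule is a threshold: while local
concentration ≥ a species' MIC, the agent dies with probability
`p_kill = 0.1` per step. Under exponential decay the expected survivor
fraction is `(MIC/C₀)^(−ln(1−p_kill)/λ)`, a steep power law; the shipped
per-species *effective* thresholds (900, 700, 870 nominal-MIC units for the
Corynebacteria-, Staphylococci- and Acinetobacter-like species; ∞ for the
plasmid-bearing invader) are calibrated so that a 10 mg/cm² dose
exterminates only the most sensitive species while the others recover, and
an 8 mg/cm² dose perturbs without extinction. Effective
in-situ tolerances far above the nominal assay MIC encode the usual gap
between in-vitro MIC and in-vivo efficacy; with thresholds near the nominal
MIC every tested dose would annihilate the whole community, which is not
what the modelled system does.

### Interventions

All interventions default to the invader's introduction timestep (4500 =
3.125 days; 1 timestep = 1 minute, forced by that equivalence). The malate
conversion (`mol_to_field_units = 2.8×10⁸` units/mol) was calibrated so the
0.37 mmol/cm² dose extends survival to about one day; the sweep doses
(0 / 37 nmol / 3.7 µmol / 0.37 mmol per cm²) then span negligible →
dominant. The LB bolus adds its amount, uniformly, to the shared
`skin_carbon` pool that every species (invader included) consumes; the
default bolus (2×10⁵ units) produces a slight survival increase, most of it
captured by the abundant residents.

## Reported statistics

* **Steady-state fractions** — per replicate, mean counts over the trailing
  simulated day before introduction, normalized to sum to 1; mean ± SD
  across replicates. The window precedes the plateau-then-introduction
  structure of the baseline run.
* **Survival time** — time from introduction to the first timestep with zero
  invaders, in days; right-censored at a 3-day post-introduction horizon
  (long-term survivors are reported as 3 d because the simulation ends).
  Extinction is literal `count == 0`; agents are discrete.
* **Replicate summaries** — mean and sample SD (ddof = 1).

## Fluorescence-curve statistics

* **Background subtraction:** the control group's per-timepoint mean is
  subtracted from every treatment sample; negatives are kept.
* **Production stop:** derivative by central differences
  `(y[i+1]−y[i−1])/(t[i+1]−t[i−1])` (one-sided at the endpoints; only
  interior points are scanned for the call); production stops at the first
  timepoint with a negative derivative; monotone curves report "not
  reached".
* **Rate constant:** per sample, the OLS slope of log₁₀(value) vs
  log₁₀(time) over strictly positive pairs (rows with fewer than two usable
  points are excluded and reported); the statistic is the mean slope. The
  fit range starting at the first positive pair and the log base are
  documented choices; the slope is base-invariant.
* **Doubling time:** the mid-exponential window is the contiguous run of
  points whose log-absorbance lies between 20 % and 80 % of the observed
  log-range — an explicit stand-in for manual phase selection — fitted as
  `y = y₀·2^(t/Td)`.

### Synthetic plate-reader generator

Treatment wells follow `plateau·(1 − e^(−rt))` until the programmed stop
time, then decline linearly (photobleaching/degradation); background wells
sit at a constant offset; Gaussian noise is added everywhere, reproducibly
per seed. The generator emulates the *shape* of plate-reader data — rising
signal, plateau/decline, background group, replicate noise — not instrument
artifacts (gain changes, evaporation drift, well-position effects) or
biological variability between skin samples, so recovery tests certify the
statistics' correctness, not their robustness to every laboratory nuisance.

## Problem sizes and numerical choices

Default lattice 100×100 patches ≙ 1 cm² (doses are per cm²; the torus
avoids edge artifacts), carrying capacity 10 agents/patch, ~12 000 resident
agents at steady state, 9 000 steps = 6.25 days per replicate, 3 replicates
per scenario. Seed-ensemble tests (growth-defect robustness, dose
monotonicity) run on a 40×40 lattice with introduction at t = 2000: per-patch
fluxes are unchanged, so populations scale with area while per-capita
rates — and therefore survival times — do not; the community settles well
before the earlier introduction. Nutrient mass balance holds to 1e−9
relative per step (tested); consumption ties within a patch resolve
first-come in the shuffled order; division with a full parent patch tries
one random neighbour, then defers.

## Known limitations

* Steady-state composition is built in through niche fluxes; the model
  explains *maintenance and invasion resistance* of the community, not its
  assembly from first principles.
* The antibiotic's effective thresholds and clearance rate are calibrated
  jointly; only their combination is identified by the behaviours above.
* The invader's long-term colonization under high-dose antibiotic rides on
  extinction of the resident whose niche it scavenges; in replicates where
  a handful of that resident's agents survive the dose, recolonization can
  evict the invader early.
* Survival at high malate doses is governed by the last surviving agent and
  is therefore noisier than mean-population statistics.
* No plasmid loss: the resistant invader never reverts, so long-term
  survival under antibiotic may be overestimated.
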