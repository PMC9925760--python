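# Methods

This note documents the model equations, the numerical choices, the
synthetic-data generators and their defaults, and the known limitations of
`bloomweb`. Everything stated here is computed by the package's tests or by
`scripts/acceptance.py`; nothing is quoted from external runs.

## 1. Mass balance

The static snapshot solves, for every living group *i*,

    B_i · PB_i · EE_i = Σ_j B_j · QB_j · DC_ji + Y_i + BA_i

for exactly one unknown per group chosen from {B, EE} (`solve_balance`).
Groups with biomass unknown form a linear system (their predators may also
be unknown); ecotrophic efficiencies then follow directly. EE outside
[0, 1] raises `UnbalancedWebError` — there is no automatic re-balancing;
the synthetic generator re-draws instead. Baseline other mortality is
M0base = PB·(1 − EE) (yr⁻¹).

Detritus is a non-living pool with no balance equation. Its dynamic budget
receives all other-mortality deaths, the unassimilated fraction of
consumption (default 0.2, the conventional assimilation complement), and
red-tide kills; it loses detritivory. The residual at baseline is closed by
a constant export flux (or import, if detritivory exceeds supply) fixed
once from the snapshot, so the balanced state is an exact equilibrium of
the dynamic model. This closure is this package's choice; only the pool
itself and the 0.2 egestion fraction are conventional.

## 2. Trophic dynamics

Foraging-arena consumption per predator–prey link:

    Q_ji = a_ji · v_ji · B_i · B_j / (2·v_ji + a_ji · B_j)

where the exchange rate v_ji = vmult_j · Q0_ji / B0_i is parameterised by a
per-predator vulnerability multiplier vmult (default 2, floored at 1.01;
vmult→1 is donor control, large vmult approaches mass action a·B_i·B_j/2),
and the search rate a_ji is set from the snapshot so Q equals the baseline
flow Q0 = B_j·QB_j·DC_ji at baseline biomasses and capacity 1. Habitat
capacity multiplies the search rate (a smaller arena). Growth efficiency
GE = PB/QB is held at its baseline value.

Producers grow as PB·B·f(chl)·capacity·g(B) with f the chlorophyll anomaly
relative to its cell-wise time mean, clipped to [0.1, 10] (f = 1 at
baseline), and g(B) = (1+ν)/(1+ν·B/B0) a self-limitation factor with ν = 3,
i.e. a maximum per-capita production of 4·PB as the stock is grazed down.
g(B0) = 1, so the baseline is untouched. Without g, sustained chlorophyll
anomalies below ≈0.6 have no producer equilibrium at all (production and
losses are both linear in B) and high-turnover producers collapse; ν = 3
tolerates anomalies down to f = 0.25.

Fishing is effort-based: catchability q_{f,i} = Y_{f,i}/B0_i per fleet, so
baseline effort 1 per cell reproduces the snapshot catch.

**Integration.** Months are divided into 4 equal sub-steps (dt = 1/48 yr).
Gains are explicit; losses — all proportional to the group's own biomass —
are applied semi-implicitly (Patankar form):

    B⁺ = (B + G·dt) / (1 + (L/B)·dt)

This cannot undershoot zero however stiff the loss rate (producer loss
rates exceed 100 yr⁻¹, far beyond the explicit-Euler step limit at this
dt), and a balanced state (G = L) is reproduced exactly, which is why the
fixed-point drift in the tests is at machine precision rather than at an
integration tolerance. The realised loss over a sub-step is L·(B⁺/B)·dt,
and reported catch is scaled identically, so the per-group budget
ΔB = gains − realised losses closes to rounding. The scheme and sub-step
count are this package's choices; they are deliberately shared between the
single-cell model and every cell of the spatial model so that a one-cell
grid reproduces the single-cell trajectory.

## 3. Spatial model

Per-timestep (monthly) order of operations, fixed and relied on by the
tests: (1) update drivers and habitat capacity (fishing effort comes from
the previous step, initialised uniform), (2) apply red-tide mortality and
record losses, (3) trophic-dynamics sub-steps, (4) movement, (5) effort
reallocation for the next step.

**Habitat capacity** is the product of per-group environmental responses
(logistic in the driver, normalised to 1 at the driver's domain-and-time
mean so a uniform baseline has capacity exactly 1) times, under a sublethal
scenario, the foraging response to bloom concentration; floored at 1e-4.
The default assignment is trait-based: bottom temperature for demersal,
reef-associated and benthic groups, surface temperature for pelagic groups.

**Movement** is donor-controlled flux on the 4-neighbour lattice with
no-flux (reflecting) land/edge boundaries:

    flux(s→n) = min( D·dt/(4L) · (ρ0 + (1 − cap_s)) · cap_n , 0.95/4 ) · B_s

with D the group's dispersal rate (km·yr⁻¹; 300 for mobile pelagic groups,
30 for demersal/reef-associated, 3 for benthic, planktonic and producer
pools), L the cell width, ρ0 = 0.1 a baseline mixing share, (1 − cap_s)
the emigration boost from degraded habitat, and cap_n the attraction of the
receiving cell. The per-edge cap keeps total outflow below 95 % regardless
of neighbour count and makes uniform fields exactly invariant. Mass is
conserved identically (fluxes are moved, not approximated). The strength
of capacity-driven emigration and the ρ0 baseline are this package's
choices; with ρ0 = 0 all movement would vanish at baseline capacity and
dispersal would be uncalibratable.

**Effort** per fleet is allocated proportional to
max(0, Σ_i price_i·B_{s,i} − cost_s), normalised so each fleet's total
effort equals the number of water cells (uniform effort 1 at baseline);
an unprofitable fleet spreads uniformly. Default prices are 1 for landed
groups, default costs 0.

**Spin-up** (default 24 months) runs with bloom forcing off while domain
totals are relaxed multiplicatively toward the snapshot totals with a
6-month time constant; recording starts after spin-up. **Stability**: a
run is flagged (and truncated) if any group's domain total leaves
[1e-4, 100]× baseline or turns non-finite; flagged runs are excluded from
indicator aggregation but always recorded in the manifest.

## 4. Red-tide responses

Lethal: A(x) = 1/(1 + (x/c)^(−b)), the proportion of biomass killed in a
cell-month; A(0) = 0, A(c) = 1/2, clipped to 1 − 1e-12. Annualised rate
Â = −ln(1 − A)·12 and multiplier M0mult = Â/M0base, composed additively
(effective other mortality M0base·(1 + M0mult), so M0mult = 0 recovers the
baseline; a replacement composition would make a zero bloom lethal). In
the spatial engine the kill is applied as the discrete monthly removal
loss = A·B, routed to detritus — the exact monthly equivalent of the rate
form, since exp(−Â/12) = 1 − A identically; applying both would kill
twice. For a group with EE = 1 (M0base = 0) the rate Â stands in for the
multiplier directly.

The 20-curve mortality library uses 5 inflections log-spaced over
10^4.5–10^6.5 cells·L⁻¹ and 4 slope scalars (1, 2, 4, 8), both
config-overridable: the inflections span concentrations at which harmful
effects are plausible, the slopes give visibly distinct steepness on a
log-x axis.

Sublethal: each mortality inflection c spawns foraging curves at 25/50/75 %
of c. The curve family is the decreasing log-logistic
φ(x) = 1/(1 + (x/x0)^k) — value exactly 1 at x = 0 (required for the
zero-forcing identity: with no bloom, every scenario must reproduce the
baseline bitwise) and 1/2 at its inflection — with the exponent
k = 4·x0·5e-5 chosen so the linear-x slope at the inflection equals the
slope multiplier −5·10⁻⁵ (L·cell⁻¹)⁻¹ for every curve. An exp-logistic
translation family with that slope was rejected because it cannot reach 1
at zero concentration for the lower inflections.

Scenario grid: 20 mortality-only + 60 paired configurations, × 2 target
sets (all consumer groups, or one focal harvested group) = 160 scenarios
with stable ids S001–S160 (all-consumer block first).

## 5. Calibration

The gridded model is calibrated to the single-cell trajectory (not to
data): a twin of the well-mixed model is the reference, which isolates the
spatial parameters. Score: total |pbias| = Σ_i |100·Σ_t(sim−ref)/Σ_t ref|
over groups. The reference and candidate series are the **monthly**
domain-mean biomass per group; at desk scale (2–4 simulated years) an
annual series is 2–4 points per group and the search is unidentifiable.
A lognormal log-likelihood (σ = 0.3, diagnostic only) is logged alongside.

One-at-a-time sensitivity perturbs each parameter ×2 and ×0.5 and ranks by
the induced |Δ total pbias| (unstable runs flagged, worst rank). The
fitting loop sweeps the ranked parameters over shared log-spaced candidate
grids — vulnerability multipliers in [1.01, 1e4], dispersal multipliers in
[0.1, 10], 20 values each — accepting only strict improvements (ties break
toward the incumbent in log space), and stops at the first iteration with
no accepted change. Acceptance-on-improvement makes the pbias trajectory
non-increasing by construction.

**Limitation.** Coordinate descent on a scalar aggregate can stall in
compensated local minima when parameters interact strongly or when
vulnerabilities sit in the near-saturated (mass-action) regime where the
response surface is flat. The twin experiment in the test suite draws its
true values from the candidate grids, so an exact zero-pbias optimum
exists and recovery is verifiable; with off-grid truths the fitted values
are only grid-resolution approximations, and for some randomly drawn webs
the final pbias plateaus above 1 % of its unfitted value.

## 6. Synthetic data

The generators define the study conditions; all are pure functions of
their seeds.

*Food webs* (`gen_foodweb`, default 10 groups/2 fleets): one detritus
pool, ≥1 producer, consumers in up to three trophic tiers with
tier-decreasing QB (≈15/8/4 yr⁻¹), growth efficiencies U(0.15, 0.3),
harvest fractions U(0.05, 0.15) of production on upper-tier groups, and
ecotrophic-efficiency targets U(0.55, 0.9). Biomasses are set top-down
from the EE targets so the web balances by construction; draws whose
implied biomasses or rates leave plausible ranges are rejected (bounded
retries, then `InfeasibleFoodWebError`). Traits are assigned by trophic
level plus a pelagic/demersal coin flip; dispersal follows the
300-30-3 convention by trait.

*Drivers* (`gen_drivers`): SST/SBT/SSS/chlorophyll as a 12-month sinusoid
plus smooth spatial gradients plus seeded smoothed noise; depth increases
with shoreline distance; depth and rugosity static.

*Blooms* (`gen_blooms`): concentration = background (default 10³
cells·L⁻¹, a parameter, not an asserted field value) plus Gaussian spatial
kernels anchored at near-shore cells, modulated by a within-year temporal
envelope centred in Aug–Nov. Non-severe years draw amplitudes
10⁴–8·10⁴ cells·L⁻¹ (kernel sd 1–2 cells, 1.5–2.5 months); severe years
draw 2·10⁶–8·10⁶ (sd 1.8–3.0 cells, 2.5–4 months). These widths keep
severe blooms coastal with offshore refuges on the default 12–15-cell
grids — kernels much wider than ~3 cells cover the whole desk-scale
domain, every consumer is exposed, and sensitive scenarios collapse
(which the stability screen then flags honestly).

*Surveys* (`gen_surveys`): station value = cell biomass of the sampled
groups × exp(N(0, σ²) − σ²/2), mean-corrected so survey means are
unbiased estimates of model biomass (σ = 0.3 default).

What the generators do **not** emulate: real bathymetry or hydrodynamics,
kriged bloom maps, multi-species survey catchability, age structure
(juvenile flags exist and are honoured by the metrics, but the default
generator emits none), recruitment dynamics, or inter-annual driver
trends. Passing tests therefore demonstrate internal consistency of the
method chain under controlled conditions, not predictive skill on a real
shelf.

## 7. Metrics

Annual indicators: B_T and B_har are annual means of the spatial-mean
biomass summed over (non-juvenile; harvested for B_har) groups; B_loss
sums the spatial-mean monthly kill over the year; C_T sums spatial-mean
catch over months, fleets and groups. The per-group mortality index is
Σ(loss over the year's cell-months) / (annual mean of the domain-total
biomass). Screening accepts runs whose focal-year loss rate lies within
μ ± 2σ (defaults 0.77 ± 0.12, config) **and** whose RMSE against the
observed index is within 10 % of the ensemble minimum; RMSE is computed on
log-scale, mean-centred series, since survey indices are relative and
carry no common unit. Before/after–inside/outside comparisons report mean,
SE over cells and percent change with the before/outside stratum as the
denominator (missing when zero).

## 8. Problem sizes and reproducibility

Default desk configuration: 15×15 grid (5-km cells), 10 groups, 2 fleets,
4 simulated years plus 24 months spin-up; the test suite uses 5×5–15×15
grids and 6–10 groups, and the acceptance script mirrors those sizes.
All randomness flows through `numpy.random.default_rng` seeds; pipeline
stages draw child seeds from the master seed via `SeedSequence.spawn`, so
a config determines every output byte up to floating-point platform
variation. Serial and process-parallel ensemble execution are bitwise
identical because each run is a pure function of (inputs, scenario).
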