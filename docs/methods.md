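# Methods

## Scope and data model

`gutflux` starts where metagenome processing ends: its inputs are species
relative-abundance tables (samples × MSPs, rows summing to 1), per-species
genome-scale metabolic models (GEMs) in a small JSON dialect, a diet file
(metabolite → maximal uptake rate), and optionally a plasma metabolite table.
Model reconstruction, gap-filling, read QC, and normalization are out of
scope; tables are assumed normalized on arrival.

Metabolite identity is by string id in one namespace shared across models.
This is a deliberate design constraint: diet application, reaction-presence
profiling, and community merging all compare or join metabolites across
models, which is only well-defined when the models derive from a common
reference namespace. Exchange reactions carry exactly one metabolite with
coefficient −1; negative flux is uptake, positive is secretion.

## Flux balance analysis

FBA solves max c·v s.t. S·v = 0, l ≤ v ≤ u with the HiGHS solvers via
`scipy.optimize.linprog`. Defaults: secretion cap 1000 mmol/gDW/h, solver
feasibility/optimality tolerance 1e−9, exchange-classification threshold
eps = 1e−6 — conventional constraint-based-modeling values. Only the
objective value and steady state are guaranteed; the flux vector is one
optimal vertex and need not be unique, so tests assert objectives, never
full flux vectors.

Diet application sets each exchange's lower bound to −(uptake limit), or 0
for metabolites absent from the diet; secretion stays open. Diets are
supersets of any one model's exchanges: unmatched entries are logged, not
errors. The anaerobic flag closes oxygen uptake and takes precedence over an
oxygen entry in the diet table, a precedence we fixed because "anaerobic"
and "diet" can otherwise contradict each other. The shipped synthetic
high-fibre omnivore diet (glucose 10, fructose 8, sucrose 5, starch 5,
glutamate 2, tryptophan 1, tartrate 1 mmol/gDW/h, oxygen listed but closed)
is a documented stand-in: real diet compositions are user inputs.

In group-average flux tables a model lacking an exchange contributes flux 0
rather than being dropped, keeping group means comparable across the full
metabolite panel; averaging over carriers only is available behind
`carriers_only=True`. Clipping fluxes at ±1 is a display concern and is
never applied to computed values.

## Differential statistics

The Wilcoxon rank-sum test uses the exact permutation null when the pooled
sample size is ≤ 20 and tie-free, otherwise the normal approximation with
tie and continuity corrections (exactness where it is cheap, the standard
approximation elsewhere). Constant features are assigned p = 1 directly: a
feature with zero range carries no rank information. BH adjustment is the
usual step-up, order-equivariant and capped at 1.

Species selection is two-step: FDR < 0.01 *and* exactly one group median
equal to 0 with the other strictly positive ("a real positive number" is
read as > 0; the median is the standard middle-order statistic). Enrichment
direction is the strict mean comparison; exact ties are labelled
control-enriched and are flagged, a tie-break we had to fix by fiat. Fold
change is log2((mean_case + ε)/(mean_control + ε)) with ε = half the
smallest nonzero table value.

## Reactobiome

Reaction abundance is the matrix product of abundance (samples × species)
and binary reaction presence (species × reactions). Presence is binary by
construction — per-model reaction copy number is not multiplied in. Species
without models contribute nothing and are logged (in real data only a
minority of gut species have models). Per-disease reaction tests use the
machinery above with FDR computed within disease; cross-disease reactions
are those significant in every disease, optionally filtered for a
disease-enriched direction everywhere and for a presence-fraction gap > 0.2
between disease- and control-enriched models. KO mapping is the union of
reaction annotations; because it is ambiguous whether KO significance should
be re-tested at the KO level, a KO-abundance matrix (sum of member-reaction
abundances) is provided for re-testing behind `ko_abundance`, with the plain
union as the default reading.

## Community models

A sample's community is its top-N species by abundance (default N = 10, a
computational-cost compromise, configurable) among those with models, ties
broken lexicographically, weights renormalized to 1. The merge relabels each
species' metabolites into a private compartment `c_i`, converts each
single-metabolite exchange into a species↔lumen transport with unchanged
bounds, and adds per lumen metabolite one diet-uptake reaction (d → u,
capped by the diet) and one output reaction (u → f, capped at 1000). Species
biomass reactions gain a species-biomass product consumed by the community
biomass reaction at the weight coefficients, so lumen-side mass balance
*forces* v_bio,i = wᵢ·v_community — abundance becomes a binding equality
constraint while keeping a single objective. A proportional-bound variant
(v_bio,i ≤ wᵢ·v_max, total biomass maximized) exists behind
`coupling="bound"` for sensitivity checks and is provably a relaxation.
Diet limits act on the d → u totals only; species-internal bounds are left
unscaled, since abundance-scaling intracellular capacity has no clear
biological reading at this granularity.

Degenerate cases are rejected early: duplicate species ids, weight sums off
by more than 1e−6, and no modelable species all raise before any LP is
built. An N = 1 community collapses exactly to single-model FBA, which the
tests assert to 1e−6 on every generated model.

## Association analysis

Each (reaction, metabolite) pair is fitted as
metabolite ~ intercept + log(RA + c) + age + sex + BMI by OLS, with c half
the smallest nonzero abundance (abundances are heavily right-skewed). The
fits are vectorized through the Frisch-Waugh-Lovell identity — residualize
both sides against the covariates once, then per-pair slope and t statistic
— which the tests verify against full `statsmodels` OLS fits. This is a
transparent fixed-effects simplification of mixed-effects association
tooling: samples are treated cross-sectionally and no random effects are
fitted; longitudinal modeling of repeated visits is explicitly out of scope.
Missing covariates are median-imputed; constant predictors are skipped and
logged. BH runs across all pairs.

The BMI comparison is a per-reaction Wilcoxon between BMI > 30 and BMI < 30
at raw α = 0.05 (no multiplicity correction, deliberately mirroring the
screening character of the comparison). Samples at exactly BMI = 30 go to
the lower stratum and are counted in the result's `at_cut` attribute —
excluding them, as a strict reading of "> 30 vs < 30" would demand, is not
workable for real data.

## Synthetic data: what it emulates, and what it does not

The generator produces the statistical structure the pipeline assumes:

* **Toy GEMs** follow a template — sugar uptake, one catabolic route to
  pyruvate, biomass consuming pyruvate + glutamate — plus optional sucrose /
  starch hydrolysis and indole modules, accessory dead-end reactions for
  reaction-content diversity, and a five-reaction tartrate-like marker
  subsystem annotated to two KOs. Fermentation by-products are obligate
  route products, so disease-designated species necessarily secrete acetate
  (or propionate) and consume extra glutamate while control-designated
  species secrete butyrate; this is how group-level flux contrasts are
  planted. Marker presence probabilities are (1 ± gap)/2 for
  disease-designated vs other species, so the expected presence-fraction gap
  equals `marker_presence_gap` (default 0.9). Every emitted model must pass
  an FBA growth check under the shipped diet or generation aborts.
* **Abundance tables** draw log-normal species baselines (σ = 1.5) with
  per-sample log-normal noise (σ = 0.7), renormalized per sample. Planted
  species (default 10 of 40, half disease- half control-enriched, equal low
  baselines so group totals stay balanced) are multiplied by `effect_size`
  (8) in their enriched group and zeroed with probability
  `zero_inflation_prob` (0.7) in the other — making the two-step median
  rule satisfiable and, conversely, making false selections structurally
  impossible for never-zero null species. Default cohort size is 60 + 60,
  one cohort per disease; BMI is drawn with the disease-specific group means
  of the emulated study populations (obese cases ≈ 33.5 kg/m²).
* **Metabolomes** plant `association_effect` (1.5) × standardized log
  reaction abundance on marker reactions (cycled), signs alternating, plus
  small age/sex/BMI terms and Gaussian noise (σ = 1); the remaining ~490
  metabolites are covariate structure + noise.

Everything is a deterministic function of (config, seed), and the truth
manifest lists every planted species, marker carrier, and association pair.

What passing tests on these data do **not** show: real cohorts have
compositional dependence, sequencing noise, covariate confounding, and
model-quality heterogeneity far beyond the generator's; curated GEMs have
thousands of reactions, cofactor coupling, and alternate optima the toy
template avoids. Recovery rates here certify the pipeline's correctness and
calibration, not expected power on real data. One observed and expected
consequence of the planted compositional shift plus correlated tests: at
FDR 0.01 across all pairs, an occasional null metabolite can ride a lucky
noise draw into significance with several mutually correlated reactions —
the acceptance check therefore bounds the *number of null metabolites*
implicated (≤ 1% of the null panel) rather than pretending the pair-level
false-discovery proportion is zero.

## Numerical and reproducibility choices

Steady state is asserted at |S·v| ≤ 1e−6; objective determinism at 1e−9
for fixed inputs (HiGHS is deterministic). All randomness flows from
`numpy.random.default_rng` seeded via `SeedSequence([seed, stream])` with
fixed per-component stream ids, so cohorts, models, and metabolomes are
independently reproducible. Pipeline outputs are written with sorted keys
and fixed float formatting; re-running an identical config reproduces
byte-identical files (checksums recorded in the manifest). The default
problem sizes (40 species, ~50 reactions/model, 3 × 120 samples, 32
community models, 500 metabolites) keep a full run around a few seconds on
one CPU.

## Known limitations

* Single-objective FBA only: no flux variability, parsimonious FBA,
  thermodynamic constraints, or dynamic simulation.
* Community modeling is plain weighted-biomass FBA; no multi-objective or
  game-theoretic community formulations, and N = 10 truncates real
  community diversity.
* Association analysis is cross-sectional fixed-effects OLS; repeated-visit
  correlation is ignored.
* Differential abundance is rank-based on relative abundances; no
  compositional transforms (CLR) or count models.
* The published per-cohort vs per-disease T2D case counts of the emulated
  studies disagree (164 vs 271); the cohort-summary module reproduces both
  as printed and reconciles nothing.
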