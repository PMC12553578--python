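# Methods

`obsbias` quantifies trait-linked sampling bias in community-science
occurrence datasets of the kind exported from iNaturalist through GBIF:
one row per observation event, aggregated to per-species counts and
joined to an EltonTraits-style trait table. This note describes each
statistical component, the synthetic data the package tests itself
against, and the numerical choices a user may want to audit.

## Data model and ingest rules

An occurrence record carries a scientific name, taxon rank, order, an
event timestamp, and optionally a biogeographic realm. Cleaning follows
the conventions of global mammal analyses of such data:

* **Subspecies roll-up.** Names are reduced to the first two word tokens
  (genus + epithet), case-folded; subspecies thereby merge into their
  parent species. The rule is idempotent. Hybrid names (a `×` or a
  standalone `x` token) and mononomials cannot be reduced to a binomial
  and are dropped, with a count.
* **Domestic exclusion.** Observations of domestic species are removed
  against a configurable list of binomials. The shipped default
  (`obsbias/data/domestic_mammals.txt`) holds 13 common domestic mammals
  and is explicitly a stand-in — swap in your own list for serious use.
* **Timestamps.** The clock hour is read verbatim from the local time
  string (no timezone conversion — community platforms record local
  clock time, and diel windows are defined on the local clock).
  Date-only records are kept for all count analyses and excluded, with a
  count, from the activity-alignment stage.
* **Accounting.** Every run asserts
  `raw = domestic-excluded + invalid-dropped + retained`.
* **Multi-membership.** A species may hold several trophic guilds,
  habitat strata and realms. Realm totals credit a species' full count
  to every realm it occupies, so realm totals may exceed the grand total;
  this is surfaced rather than apportioned, since any apportionment rule
  would be arbitrary without per-record coordinates.

Species present in the occurrence data but missing from the trait table
keep a profile with empty trait fields, so their observations still count
in totals (mirroring the "no trophic information" category of real trait
joins).

## Benford conformity of per-species counts

If per-species counts behaved like effort-neutral abundances spanning
several orders of magnitude, their leading digits would follow Benford's
Law, `P(d) = log10(1 + 1/d)`. The default test uses the first two digits
(bins 10–99, 89 degrees of freedom), the convention for samples in the
thousands; first-digit (bins 1–9) is available. Reported statistics:

* `chi2 = n * Σ_d (p̂_d − p_d)² / p_d` with a χ²(df) tail p-value;
* MAD, the mean absolute deviation of bin proportions, classified with
  Nigrini's conformity bands (two-digit: ≤0.0012 close, ≤0.0018
  acceptable, ≤0.0022 marginal, else nonconforming; one-digit:
  0.006/0.012/0.015);
* the distortion factor: each value is collapsed onto [10, 100) by
  powers of ten; DF = 100·(mean − EM)/EM with EM = 90/ln 10 ≈ 39.0865.
  Negative DF means an excess of small leading digits.

Numerical choices: digit extraction truncates after rounding the
collapsed mantissa at 12 significant decimal digits, so binary-float
artifacts (1.9 → 18.999…) do not shift a digit bin. No bin pooling is
done for sparse expected counts; a warning is attached when any expected
bin count falls below 5, and when n is below the bin count.

## Order-level representation

With `S_i` species in order `i` and `O_i` observations, the
richness-proportional expectation is `E_i = (ΣO)·S_i/(ΣS)`. Orders are
classed over/underrepresented by strict inequality against `E_i`
("proportional" only at exact equality); standardized residuals
`(O−E)/√E` are reported so users can impose a significance gate instead.
The global fit is the goodness-of-fit χ² with `#orders − 1` df, and the
richness–observations association is Spearman's rank correlation (average
ranks for ties, p from the t approximation on n−2 df, matching the common
statistical-software default; `S = Σd²` is reported for tie-free data).

## Diel activity alignment

Trait databases flag species as diurnal/nocturnal/crepuscular; the eight
flag combinations map onto eight categorical patterns (cathemeral =
day + night but not twilight; flexible = all periods; unknown = none).
Observations fall into diel periods — diurnal 6:00–18:00, nocturnal
18:00–6:00, crepuscular 5:00–7:00 ∪ 17:00–19:00 — which as written
overlap at 5–7 h and 17–19 h. Two policies are implemented:

* `crepuscular_priority` (default): twilight hours count as crepuscular
  only, so the three periods partition the 24-h clock (diurnal [7,17),
  crepuscular [5,7)∪[17,19), nocturnal [19,5)); each observation gets
  exactly one period.
* `overlapping`: literal windows; an observation may belong to two
  periods.

All interval bounds are half-open so every instant maps deterministically.
An observation is *aligned* when a period it falls in belongs to the
species' declared pattern; combined patterns align on any declared
period; flexible aligns always; for cathemeral species a crepuscular-
window hit vetoes alignment (under either policy). Per-pattern alignment
proportions are summarized by a binomial GLM of aligned/not-aligned on
pattern, treatment-coded against a configurable reference (default
`cathemeral`, the alphabetically first level); quasi-complete separation
(a level at 0% or 100%, which the flexible pattern produces by
construction) is flagged on the result rather than raised.

## Phylogenetic body-mass contrast

Body mass is compared between diurnal and non-diurnal species twice:

* **Welch's t-test**, the unequal-variance two-sample contrast with
  Welch–Satterthwaite degrees of freedom — ignores phylogeny.
* **Simulation-based phylogenetic ANOVA.** The observed one-way ANOVA F
  is referred to a null distribution obtained by simulating the trait
  under Brownian motion on the phylogeny (group labels fixed), with rate
  σ² set to its maximum-likelihood estimate from the observed data
  (GLS root state; `σ̂² = (x−μ̂1)ᵀC⁻¹(x−μ̂1)/n`, C the shared-path
  matrix). The p-value is `(1 + #{F_sim ≥ F_obs})/(nsim + 1)`, which can
  never be exactly zero and differs from a plain proportion by at most
  `1/(nsim+1)`. Simulations are vectorized through one Cholesky factor
  of σ²C; a diagonal jitter of 1e-12·max(C) is applied only if zero-
  length structure makes C numerically semidefinite. Default nsim is
  1000. On a star tree the null collapses to iid Gaussian, so the
  simulation p agrees with the parametric F-test p — the calibration the
  test suite checks.
* **Grafen branch lengths** for trees supplied without lengths: node
  height `(d−1)/(N−1)` (d descendant tips, N total tips; tips 0, root 1),
  optionally raised to a power ρ, edge length = height difference.
  Heights are monotone along root-to-tip paths, so lengths are ≥0.

The response defaults to log body mass (mass spans ~8 orders of
magnitude; on the raw scale a handful of megafauna dominate every sum of
squares); the raw scale is available. Tips missing from either the tree
or the trait table are dropped with a reconciliation count. Taxonomy
reconciliation against external services is out of scope — trees enter
as Newick.

## Trait mixed model

The per-species observation count (raw scale) is regressed on:
IUCN category (treatment-coded, reference CR), trophic guild (reference
carnivore), habitat stratum (reference aerial), the three activity flags
as separate binaries, and natural logs of estimated population, body
mass, total species biomass, and range area — with random intercepts for
taxonomic order and for Nearctic occurrence (a two-level factor, kept as
a random effect for fidelity to the modelling convention it mirrors; its
fragility is surfaced through the singularity flag rather than avoided).
Estimation is REML via statsmodels `MixedLM` with two crossed variance
components.

Choices a user should know:

* **Multi-label resolution.** The design needs one category per factor;
  multi-label species resolve by a documented precedence (trophic:
  herbivore > insectivore > omnivore > carnivore; strata: marine >
  aerial > arboreal > scansorial > ground), configurable. Species with
  no trophic information become a `not_assigned` level; species with no
  stratum information are dropped (counted).
* **Inference.** CIs and p-values use a Wald t distribution on residual
  df (n − p_fixed). This is an approximation: for effects informed by
  few grouping-factor levels it is anti-conservative relative to
  Satterthwaite df. The coverage simulation below quantifies the
  practical consequence under the generator's conditions (≈95%
  nominal coverage of the body-mass slope).
* **Diagnostics.** Nakagawa R²: marginal = var(Xβ̂)/(var(Xβ̂)+Σσ²_re+σ²);
  conditional adds Σσ²_re to the numerator. Adjusted ICC =
  Σσ²_re/(Σσ²_re+σ²). RMSE is the root mean square of conditional
  residuals (random effects subtracted). VIF regresses each fixed-design
  column on the others (intercept included); dummy columns of a factor
  with a rare reference level inflate mechanically — read factor VIFs
  jointly. AIC is computed from the REML log-likelihood with one
  parameter per fixed effect, variance component and scale.
* **Singularity.** A variance component whose sd is below 1% of the
  residual sd is flagged singular: the optimizer does not snap exactly
  to the boundary, so a literal zero test would never fire.
* **Standardization.** `standardize=True` z-scores the response and the
  numeric covariates; slope t statistics and p-values are invariant to
  this rescaling (property-tested).

## Synthetic data: what it emulates and what it does not

The generator draws a community with: skewed order richness (Zipf-like
shares, every order non-empty); all eight activity-flag combinations;
lognormal body mass (ln-scale mean 7, sd 2.5 — median ≈1.1 kg),
population and range area; total biomass only loosely coupled to
mass × population (partial log-scale regression plus sd-2.2 noise) so the
four log covariates stay far from collinear, matching the low-VIF regime
the analysis assumes; realms with a configurable Nearctic probability;
IUCN categories at plausible global frequencies.

Counts come from one of four regimes:

* `lognormal_mixture` (default): three ln-scale components (means
  4.5/7.0/9.5, sd 1.5, weights 0.30/0.40/0.30), ceil'd to integers.
  This is the Benford-conformant regime: counts span >4 orders of
  magnitude and keep the sub-10 integer mass near 2% (single-digit
  integers collapse onto two-digit bins 10,20,…,90 and otherwise
  dominate the MAD).
* `lognormal`: a single component, for small, fast communities.
* `truncated`: mixture counts capped (default 99) — the saturated,
  biased regime a digit test must flag.
* `linear`: raw-scale counts `intercept + Σβx + b_order + b_nearctic + ε`,
  rounded, floored at 1 — used for mixed-model recovery experiments,
  whose effect sizes live on the raw count scale (default intercept 8000
  keeps the floor inactive at noise sd 2500).

Observation hours mix a truncated-normal observer-effort density (peak
13:00, sd 3 h, the daytime bias of volunteer recording) with probability
`effort_weight` (default 0.8) and a uniform draw over the species' own
literal activity windows otherwise. Dates are uniform over one year.
Everything derives from numpy's seeded PCG64 generator: one config + seed
is bit-reproducible.

Not emulated: spatial coordinates, observer identity and
pseudoreplication, identification error, seasonal phenology, and any
correlation between traits and detectability beyond what `trait_effects`
injects. Passing tests therefore demonstrate that the *estimators* do
what they claim under known structure — not that real community-science
data satisfy that structure.

## Problem sizes used in the self-checks

The test suite and `scripts/acceptance.py` use deliberately desk-scale
sizes: 5000 species for digit-conformity regimes (20 seeds in the test
suite), a 400-species community for the end-to-end pipeline, 32-tip
trees with 999–2000 simulations for phylANOVA calibration (200 replicates
for the type-I check), and 2000-species fits for mixed-model coverage
(200 seeds in the suite, 50 in the acceptance script). These sizes give
Monte-Carlo error comfortably inside the asserted tolerances.

## Known limitations

* Residual-df Wald inference (above) instead of Satterthwaite.
* The two-digit MAD conformity bands are a convention, not a test with a
  sampling distribution; at very large n even trivial deviations become
  "nonconforming" by χ² while MAD stays small, and vice versa at small n.
* The alignment GLM treats observations as independent; repeated
  observations of one species (or one animal) are not modelled.
* `phyl_anova` supports only the Brownian-motion null (no OU or lambda
  transforms) and no post-hoc pairwise contrasts.
* Realm assignment must arrive as a column; no coordinate-to-realm
  spatial join is performed.
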