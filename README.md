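# obsbias

Diagnostics for trait-linked sampling bias in community-science
occurrence data.

Community (citizen) science platforms such as iNaturalist now contribute
more biodiversity records than research institutions, but what gets
recorded is shaped by the observers as much as by the fauna: large,
charismatic, wide-ranging, day-active species are photographed far more
often than small, nocturnal, range-restricted ones. Before such data can
inform macroecology or conservation, that bias has to be measured.
`obsbias` packages the standard battery of bias diagnostics for a
Darwin-Core-style occurrence export joined to a species trait table:

* **Benford conformity** of per-species observation counts — leading
  digits of effort-neutral multi-scale counts should follow
  P(d) = log10(1 + 1/d); χ², mean absolute deviation (Nigrini bands) and
  the distortion factor quantify departure.
* **Order-level representation** — observed observations per taxonomic
  order against the richness-proportional expectation
  E_i = (ΣO)·S_i/(ΣS), with goodness-of-fit χ², over/under
  classification, and the Spearman rank correlation of richness with
  observations.
* **Diel activity alignment** — each observation's clock hour is
  classified into diurnal (6–18 h), nocturnal (18–6 h) or crepuscular
  (5–7, 17–19 h) periods and scored against the species' declared
  activity pattern; per-pattern alignment proportions are summarized by
  a logistic regression.
* **Phylogenetically controlled body-mass contrast** — Welch's t-test
  plus a simulation-based phylogenetic ANOVA (Brownian-motion null on
  the tree, Grafen branch lengths when none are supplied).
* **Trait mixed model** — per-species counts regressed on IUCN status,
  trophic guild, habitat stratum, activity flags and log population /
  body mass / biomass / range area, with random intercepts for order and
  Nearctic occurrence (REML), reporting Wald-t coefficient tables,
  Nakagawa marginal/conditional R², ICC, RMSE, VIF and a singularity
  flag.
* **Synthetic data generator** — seeded communities with known ground
  truth (heavy-tailed counts, multi-label traits, daytime-biased
  observation hours, log-linear or linear trait effects with order
  intercepts), so every stage is testable without any download.

See `docs/methods.md` for the statistical details and design choices.

## Worked example

Simulate a 300-species community whose observation hours are 80% driven
by a 13:00 ± 3 h observer-effort peak, ingest it, and run the
diagnostics (all commands are also available as library functions):

```bash
cat > sim.yaml <<EOF
n_species: 300
n_orders: 12
count_model: lognormal
lognormal_mu: 2.5
lognormal_sigma: 1.2
effort_weight: 0.8
subspecies_frac: 0.05
EOF
obsbias simulate --seed 4 --config sim.yaml --out sim
obsbias ingest --occurrences sim/occurrences.csv --traits sim/traits.csv --out ing
obsbias benford --profiles ing/species_profiles.csv --digits 2
```

The Benford report for this small, single-lognormal community:

```
chi2 511.2  df 89  mad 0.0087  distortion -11.86  conformity nonconforming  n 300
```

Counts here span too few orders of magnitude for digit conformity
(MAD 0.0087 is far above the two-digit "marginal" band at 0.0022, and
the negative distortion factor signals an excess of small leading
digits) — the expected verdict for a truncated-range count distribution.

```bash
obsbias represent --profiles ing/species_profiles.csv --out rep.csv
# gof chi2=4072.9 df=11 p=0; spearman rho=0.740 p=0.00589
```

Species-rich orders receive more observations (ρ = 0.74), yet the
per-order totals still deviate strongly from richness-proportional
expectations (χ² = 4072.9 on 11 df) — some orders are over-, others
underobserved.

```bash
obsbias align --occurrences sim/occurrences.csv --traits sim/traits.csv --policy priority
```

Per-pattern alignment proportions (share of observations falling in the
species' declared activity period):

```
diurnal               0.870      nocturnal              0.191
diurnal_crepuscular   0.978      nocturnal_crepuscular  0.306
cathemeral            0.886      crepuscular            0.298
flexible              1.000
```

Exactly the signature of daytime-biased effort the generator was told to
produce: day-active patterns align at 87–100%, night- and
twilight-active ones at 19–31%.

```bash
obsbias model --profiles ing/species_profiles.csv
# n=300 AIC=3028.8 R2m=0.037 R2c=0.506 ICC=0.487 RMSE=38.7 sigma=40.91 singular=False
```

With no trait effects injected, fixed effects explain little
(marginal R² = 0.04) while the order random intercept absorbs the
between-order count spread (ICC = 0.49).

A single YAML drives the whole pipeline at once
(`obsbias run-all --config run.yaml`), writing `report.json`,
`species_profiles.csv` and `model_coefficients.csv`; reports are
byte-identical across reruns with the same inputs and seed.

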