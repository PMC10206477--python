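# Methods

This note documents the models and procedures `frugnet` implements, the
choices made where the methodology was genuinely open, and what the
synthetic-data experiments do and do not establish.

## Survey standardization

Both survey channels undercount true visitation deterministically: a camera
frames a fraction of the plant (0.60 / 0.40 / 0.20 for cover < 20 m²,
20–40 m², > 40 m²; the class bounds are closed for the middle class, so
cover = 20 and 40 map to 0.40) and records for part of the study; a seed
trap samples `sampled_area / canopy_area` of the drop zone for part of the
study. Counts are divided by both fractions to give whole-plant,
whole-study estimates. Numbers are kept at full precision internally and
rounded only for display (the textbook example prints 4/0.6 as 6.7).

Open choices:

* **Merge rule.** The two standardized channels are summed cell-wise. Both
  are unbiased estimates of whole-plant visitation from disjoint detection
  processes, and the sum conserves channel totals exactly
  (`F_merged = F_cam + F_scat`); a cell-wise mean is available
  (`merge_visit_matrices(..., how="mean")`).
* **Unidentified barcoding samples** (7.4 % at the reference identification
  rate) are dropped without reweighting, since failures carry no species
  information; inflating identified counts by `1/id_success` is possible in
  principle but off by default because it would also inflate sampling noise.
* The trap **area fraction is capped at 1** (a trap cannot oversample its
  canopy).

## Bipartite modularity

Barber's weighted modularity is maximized by a label-propagation local
search in the LPAwb+ family: plants start in singleton modules, species
greedily adopt the best plant-side module, and both sides are repeatedly
relabeled (seeded shuffle order, ties to the lowest module index) until no
single move raises Q; then module-pair merges are attempted and relabeling
resumes. The returned Q is a local maximum under single relabels and pair
merges, and the recorded Q trajectory is non-decreasing. Merges that leave
Q exactly unchanged are also applied — they collapse structureless
fragments (an all-equal matrix ends in one module) without affecting Q.
The multi-restart wrapper (`dirt_lpawb_plus`, default 20 restarts) varies
the initial module count from 2 up to `min(n_plants, n_species) + 1`;
restart 0 reproduces the single run, so one restart is exactly
`lpawb_plus`. Defaults follow standard practice: 1000 steps, tolerance
1e-10. On exhaustive enumeration of all joint partitions of random
matrices up to 4×4, the heuristic attains the global optimum in ≳ 95 % of
instances and never exceeds it (it cannot; the oracle bound is the check
that the heuristic's Q computation is consistent with the definition).

**Null model.** Significance uses a connectance-preserving ensemble in the
style of marginal-probability null models: cell probabilities ∝ kᵢdⱼ,
single interactions placed sequentially (first pairing uncovered rows with
uncovered columns so every node keeps at least one link) until the observed
link count L is reached, then the remaining weight distributed
multinomially over occupied cells. Every replicate conserves L and the
integer grand total; marginal totals are free. Because the null allocates
discrete interactions, the observed matrix is rounded to integers for null
generation with occupied cells floored at 1; the observed Q itself is
maximized on the unrounded matrix. Both a normal-approximation p (from the
z-score, as is conventional) and an empirical rank p with the +1 correction
are reported.

**Node roles.** `c = 1 − Σₜ (κᵢₜ/kᵢ)²` and z standardizes a node's
within-own-module interaction against same-side nodes of its module
(population s.d.). Roles default to weighted κ (strengths); binary link
counts are available. One-node modules have zero spread; their z is set to
0 with a warning rather than NaN. Node "centrality" for the contribution
regressions defaults to strength (row/column sums), the only centrality
that is unambiguous on a weighted bipartite graph without further choices.

## Module composition

Pearson's χ² of independence (no continuity correction; df = (r−1)(c−1))
on the module × stand plant counts, delegated to `scipy.stats`. Cellwise
over-/under-representation uses Haberman adjusted standardized residuals,
`r = (O−E)/√(E(1−row/N)(1−col/N))`, flagged at |r| > 1.96; the χ² test
asserts only global association, the residuals localize it. On the
reference counts the statistic is 22.12 (df 4), whose exact upper-tail p is
1.9e-4 (reported at full precision).

## Trait discrimination

VIF pruning iteratively removes the variable with the largest
`1/(1−R²)` until all fall below 3 — with three stands the between-stand
space is two-dimensional, so any three strongly stand-structured traits
are necessarily mutually predictable, and the threshold limits how much of
that redundancy enters the LDA. Forward selection minimizes Wilks'
Λ = det(W)/det(T) with the partial-F entry test
`F = (Λₚ/Λₚ₊₁ − 1)(n−g−p)/(g−1)`; the entry threshold defaults to p ≤ 0.2
(the customary default of greedy Wilks selection routines). The LDA uses
class-proportional priors and reports resubstitution accuracy —
deliberately, since the quantity of interest is descriptive separation of
the observed modules, not out-of-sample prediction; leave-one-out accuracy
is available (`loo=True`). The pulp-chemistry variant is the same code run
on the complete-case nutrition subset (no imputation).

## Seed rain

The estimator is multiplicative and exactly linear in each factor; a zero
anywhere (e.g. zero viability) annihilates the cell. Species totals get
nonparametric bootstrap standard errors (plants resampled with replacement,
1000 draws, seeded). The contribution regression uses per-plant totals as
the response — log(x+1)-transformed, the +1 guarding plants with zero
estimated viable seeds — and as predictors the dominant disperser's visits
on their own, remaining visits pooled by functional group (bird groups
separate, mammal groups merged), and the two reproductive traits. AICc is
the Gaussian form `n log(RSS/n) + 2k + 2k(k+1)/(n−k−1)` with k counting
the intercept, slopes and residual variance; subsets are enumerated
exhaustively (≤ 12 predictors). LMG relative importance is computed
exactly by the subset-weighted formula (and, as a cross-check, by direct
averaging over all orderings); shares are nonnegative and sum to the full
model's R². Group comparisons use one-way ANOVA plus Tukey–Kramer
contrasts whose p-values come from the studentized-range distribution
(N−k df), verified against published q-tables. Within-stand z-scores use
the sample s.d. (n−1); an all-equal stand yields z = 0 with a warning.

## The synthetic generator

The generator emulates the reference study design; its defaults are the
design constants where published (3 × 35 plants, 434 days, camera coverage
60/40/20 %, 82 ± 27 recorded days, 0.56 ± 0.1 m² traps active 415 ± 8
days, 48 % of camera records being true foraging, 92.6 % identification
success, ~5 seeds/cone, 32 ± 14 % viability) and field-realistic choices
elsewhere:

* **Latent visits** are negative binomial (size 3 — moderate ecological
  overdispersion; `inf` gives the Poisson limit) around
  `stand intensity × attractiveness`. Default intensities are the reference
  survey's per-stand visit estimates divided by plant number and by two
  (each survey channel estimates the same latent process and merging sums
  them, so the merged network reproduces the reference scale of ~110,000
  visits).
* **Attractiveness** is log-linear in globally standardized log crop size
  (coefficient 0.9) and cone diameter (0.25), mean-one within stand — more
  fecund, larger-coned plants draw proportionally more visits, the same
  traits the discriminant analysis is meant to detect.
* **Stand gradients.** Cone and cover traits increase toward the
  colonization front; neighbourhood density and fecundity follow the
  stand-level gradient. The three planted discriminators (neighbourhood
  density, neighbourhood fecundity, cone diameter) separate the gradient
  extremes by ~2–3 within-stand s.d. — strong but below the collinearity
  ceiling imposed by the VIF threshold — while all other traits drift by
  ≤ 1 s.d. Crop size is lognormal with CV 0.3/0.5/1.0 (MAR/OJI/COL): front
  pioneers range from stunted colonists to huge open-grown producers, which
  concentrates the front's seed rain in a few super-producers. This
  heterogeneity gradient is the generator's planted mechanism for the
  front-vs-mature contribution-inequality contrast.
* **Planted modules.** Species carry a module affinity; a plant's
  ground-truth module is the affinity whose species dominate expected
  visitation in its stand. `StudyConfig.strong_modular()` concentrates each
  module's species on one stand (2 % leakage), giving a known three-module
  partition for recovery experiments.

What the generator does **not** emulate: within-season phenology, spatial
frugivore movement (visits are independent across plants given intensities),
correlated detection failures, multi-year demography, and trait–trait
correlations beyond those induced by the stand structure. Passing the
recovery tests therefore shows the *pipeline* is correct and powerful under
the stated design, not that any particular field system will yield the same
effect sizes.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed and is bit-reproducible;
the pipeline derives per-stage seeds from one base seed. The validation
experiments use 105-plant studies with 20 pipeline replicates for recovery
statistics, 50 random matrices for the exhaustive modularity oracle, 30–100
null replicates for significance, and 2000 response redraws for the
regression-coverage check — sizes at which every Monte-Carlo criterion has
comfortable margins while the whole suite runs in well under a minute per
experiment.

## Known limitations

* LPAwb+ is a local search; on larger networks the restart count, not the
  step limit, is the lever that matters.
* The null ensemble requires every node to have at least one interaction;
  the pipeline therefore drops never-detected plants or species from the
  network (with a warning) before modularity.
* Exact LMG and all-subsets AICc are exponential in the predictor count
  (capped at 10 and 12 respectively) — ample for functional-group designs.
* AICc selects a minimum-criterion model among the candidates it is given;
  with many pure-noise candidate supersets it retains extra predictors at
  the usual information-criterion rates. The candidate list should encode
  the hypotheses, not the power set, when exact-subset recovery matters.
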