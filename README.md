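# frugnet

Individual-based analysis of plant–frugivore interaction networks along a
range-expansion gradient.

`frugnet` is a Python library for ecologists studying seed dispersal at the
resolution of *individual plants*. It was built around the study design of a
juniper (*Juniperus phoenicea* subsp. *turbinata*) range expansion: three
1-ha stands from a mature forest (MAR) through an intermediate stand (OJI)
to the colonization front (COL), 35 focal plants per stand, and a 434-day
study in which plant–frugivore interactions were sampled by rotating camera
traps and by seed traps whose scats were identified by DNA barcoding. The
library covers the full analysis chain:

1. **Survey standardization** — cameras frame only 60/40/20 % of a
   small/medium/large plant's surface and record only part of the study;
   seed traps sample ~0.56 m² beneath the canopy. Raw counts are scaled to
   whole-plant, whole-study visit estimates
   (`count / area fraction / time fraction`) and the two channels, now in
   the same units, are merged cell-wise into one weighted adjacency matrix
   `A` (plants × species).
2. **Modularity** — Barber's weighted bipartite modularity

   `Q = (1/F) Σᵢⱼ [Aᵢⱼ − kᵢ dⱼ / F] δ(gᵢ, gⱼ)`

   (with `F` the grand total, `kᵢ`, `dⱼ` the plant and species strengths and
   `g` the joint module assignment) is maximized by weighted label
   propagation (LPAwb+-style, steps = 1000, tolerance = 1e-10) with a
   multi-restart wrapper. Significance comes from a connectance-preserving
   null ensemble (cell probabilities ∝ kᵢdⱼ, link count and integer total
   conserved, marginals free; default 100 nulls, z-score → p). Node roles
   report among-module connectivity `c` and within-module degree `z`.
3. **Module composition** — Pearson's χ² of independence on the
   module × stand contingency table, with Haberman adjusted residuals to
   flag over-/under-represented cells.
4. **Trait discrimination** — VIF pruning (threshold 3), forward selection
   by the Wilks' Λ criterion, and linear discriminant analysis with
   resubstitution accuracy.
5. **Seed rain** — viable seeds dispersed per plant and frugivore:

   `seeds = visits × feeding rate × seeds/cone × % undamaged × viability`,

   followed by species shares (bootstrap s.e.), OLS of log contributions on
   functional-group visits and reproductive traits, AICc model selection,
   exact LMG relative-importance decomposition, ANOVA with Tukey–Kramer
   contrasts between modules/stands, within-stand z-scores and ranked
   cumulative-contribution curves.

A first-class synthetic-data generator (`frugnet.synthesize`) emulates the
study design end to end — stand-structured traits, negative-binomial latent
visits, binomial survey thinning, a non-foraging behaviour load on camera
records (~52 %) and 92.6 % barcoding identification success — with planted
module structure, so every stage can be validated against known truth.

## Worked example

The package's numerical core can be checked by hand. Five red-fox visits
(feeding rate 7.4 cones/visit, 97 % of ingested seeds passing intact) to a
plant bearing 5.22 seeds/cone with 21 % seed viability disperse

```
5 × 7.4 × 5.22 × 0.97 × 0.21 = 39.3 viable seeds
```

and four camera records of a blackbird on a small plant recorded during
20 % of the study scale to `4 / 0.60 = 6.7` whole-plant and
`6.7 / 0.20 = 33.3` whole-study visits. Both are one call each:

```python
>>> from frugnet.worked_examples import seed_rain_worked_example, camera_worked_example
>>> round(seed_rain_worked_example(), 1)
39.3
>>> camera_worked_example()
(6.666666666666667, 33.33333333333333)
```

Running the whole pipeline on a synthetic study with planted three-module
structure (`python examples/07_full_pipeline.py`) prints

```
modularity: Q = 0.543, null z = 184.2, p = 0.0e+00
stand x module: X2 = 210.0, df = 4, p = 2.7e-44
LDA accuracy: 95.2%
```

meaning the planted modules are recovered, they are far stronger than any
connectance-matched random expectation, module membership tracks the stand
gradient, and the planted trait differences classify plants back to their
modules well above the 1/3 chance level. The `examples/` directory holds
one short script per capability; each prints the numbers it computes and a
line on what they mean.

## Command line

```bash
frugnet simulate --seed 1 --out study/        # write the four raw CSVs
frugnet run --data-dir study/ --out results/  # full analysis
frugnet verify-reference                      # desk-checkable reference numbers
```

## Input schemas

Four CSVs (UTF-8, `.` decimal, comma separator):

| file | required columns |
|---|---|
| `plants.csv` | `plant_id` (unique), `stand`, `cover` (m², > 0), `seeds_per_cone` (1–10), `seed_viability` (0–1), plus any traits used in the LDA |
| `species.csv` | `species_id` (unique), `functional_group`, `feeding_rate` (> 0), `undamaged_fraction` (0–1) |
| `camera_records.csv` | `plant_id`, `species_id`, `n_records` (≥ 0), `recorded_days` (0 < d ≤ study), `coverage_fraction` (0–1]; optional `behaviour` |
| `scat_records.csv` | `plant_id`, `species_id` (or `UNIDENTIFIED`), `n_samples` (≥ 0), `sampled_area` (> 0), `canopy_area` (> 0), `active_days` (0 < d ≤ study) |

Extra columns are preserved but ignored; all schema violations are reported
together with row numbers.
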