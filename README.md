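# wolfrecol

Statistical pipeline for documenting a wolf (*Canis lupus*) recolonization
from heterogeneous monitoring data: opportunistic occurrence records,
camera-trap detections and scat contents. It is aimed at wildlife ecologists
who need the standard chain of analyses — record filtering, grid-based
occupancy classification, diel-activity overlap, diet composition and
information-theoretic habitat modeling — as tested, scriptable functions
rather than one-off spreadsheets.

## What it computes

**Occurrence filtering.** Records carry SCALP reliability codes (C1 hard
evidence, C2 expert-confirmed, C3 unconfirmed); C3 is removed. Independence
filters keep one record per area per day, and thin camera detections so that
consecutive retained events of a species at a site are separated by more than
30 minutes. Pup records cluster into unique reproduction events by
single-linkage with a 20 km planar threshold within each year.

**Grid occupancy.** On a 10 × 10 km grid, a cell-year *qualifies* with ≥ 1 C1
or ≥ 2 C2 records. Over a period of *L* years a cell is **Permanent** with
⌈L/2⌉ qualifying years (3 of 5) or a reproduction event in the last three
years, **Sporadic** with any lesser C1/C2 presence, **Absent** otherwise.
Between periods the net increase is 100 (c₂ − c₁)/c₁ per status.

**Activity overlap.** Detection times map to the circle (hours × 2π/24).
Activity densities are von Mises kernel estimates
f̂(θ) = n⁻¹ Σᵢ vM(θ; tᵢ, κ) with a plug-in concentration that grows as
n^(2/5). Overlap between species 1 and 2 is the coefficient of overlapping
Δ = ∫ min(f₁, f₂), estimated by

Δ̂₄ = ½ [ n₁⁻¹ Σᵢ min{1, f̂₂(x₁ᵢ)/f̂₁(x₁ᵢ)} + n₂⁻¹ Σⱼ min{1, f̂₁(x₂ⱼ)/f̂₂(x₂ⱼ)} ]

with a direct trapezoidal integration of min(f̂₁, f̂₂) as oracle, and
classified low (< 0.50), moderate (0.50–0.75) or high (> 0.75). The Relative
Abundance Index is 100 × detections / trap-nights.

**Diet.** Frequency of occurrence of an item or category is the percentage
of scats containing it, with 95% bootstrap percentile intervals over
resampled scats (1000 replicates). Diversity is the Brillouin index
HB = (ln N! − Σᵢ ln nᵢ!)/N; its accumulation curve, averaged over random scat
orderings, yields the minimum sample size at which the incremental change
stays below 1%.

**Model selection.** Permanent (1) vs Sporadic (0) cells are modeled by
binomial GLMs over every subset of the collinearity-screened covariates
(Pearson |r| ≤ 0.7). Models are ranked by AICc = AIC + 2k(k+1)/(n−k−1), with
Akaike weights ωᵢ = exp(−Δᵢ/2)/Σⱼ exp(−Δⱼ/2), and coefficients are averaged
over the competitor set (Δ < 2).

No field data ship with the package; `wolfrecol.simulate` generates all
inputs with the statistical structure the analyses assume (covariate-linked
occupancy with yearly growth, von Mises activity mixtures, multinomial scat
contents), under one master seed.

## Worked example

Run the numbered analysis scripts in order (or `wolfrecol all --seed 1` for
the same chain through the CLI):

```sh
python analysis/01_simulate.py --seed 1
python analysis/02_filter_occurrences.py
python analysis/03_occupancy.py
python analysis/04_activity_overlap.py
python analysis/05_diet.py --seed 1
python analysis/06_model_selection.py
```

With seed 1 the chain prints, among other output:

```
162 raw records -> 156 C1/C2 -> 156 independent events (96% retained)
2015-2019: 1 Permanent + 12 Sporadic = 13 occupied cells (of 45)
2020-2024: 13 Permanent + 24 Sporadic = 37 occupied cells (of 45)
net increase: occupied +185%, Permanent +1200%
...
Site 1    red fox  287  289  delta4 0.930  class high
Site 1      human  287  285  delta4 0.275  class low
...
  livestock: FO 40.0% [29.3, 50.7] (n=30)
Brillouin index at N=75: 2.168; minimum sample size (change < 1%): 32
...
collinearity screen dropped ['forest_area']; 5 covariates -> 32 candidate models
```

Reading this: the simulated recolonization roughly triples occupied cells
between the five-year periods; the wolf-like and fox-like series are both
nocturnal, hence high overlap, while overlap with the diurnal human series is
low; livestock is the leading diet category with its bootstrap interval; and
the redundant total-forest-area covariate is screened out before the 32-model
AICc ranking, exactly as a field analyst would drop it.

Stage outputs (CSV, GeoJSON, JSON summary) land under `results/`.

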