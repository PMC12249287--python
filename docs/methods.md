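# Methods

This note documents the statistical procedures implemented in `wolfrecol`,
the assumptions behind them, the defaults and why they were chosen, and what
the synthetic data can and cannot demonstrate.

## Data model and filters

An occurrence record is a dated, georeferenced wolf sign with a SCALP
reliability code (C1 hard evidence, C2 expert-confirmed, C3 unconfirmed), a
source, an area identifier and an optional pup-evidence flag. Coordinates
are planar metres in a projected CRS; all distances are Euclidean. The CRS
label is configuration metadata — no geodesy is performed, so inputs must be
projected sensibly (UTM-style) beforehand.

C3 records are removed before any analysis: they are unvalidated and would
bias maps toward reporting effort. Two independence filters follow.

*Daily rule.* One record per (area, calendar day). The retained record is
the earliest by timestamp, ties broken by smallest record id. Any rule that
keeps exactly one record per group gives the same occupancy statistics; the
tie-break only pins down which row survives, for reproducibility.

*Camera rule.* Within each (site, species), sorted by time, the first
detection is kept and others are discarded while within the 30-minute window
of a reference event. Two references are implemented: `rolling` (default) —
the last *retained* detection, so each kept event opens a fresh window — and
`previous` — the immediately preceding detection, so an unbroken burst
extends the window indefinitely. The rolling rule matches common camera-trap
practice; the burst rule is stricter and available as a config switch. A gap
strictly greater than the window makes a detection independent. Grouping is
at the monitoring-site level, not per camera, because clustered cameras
would otherwise multiply-count one pass of an animal.

*Reproduction events.* Pup records within one calendar year are clustered by
single linkage, linking pairs strictly closer than 20 km; each cluster is a
unique reproduction. "Simultaneous" is interpreted as the calendar year —
the natural resolution for an annual breeding cycle — and the count of
events in a year is the maximum number of distinct reproductions. The 20 km
spacing is a conservative pack-separation distance for a flat, homogeneous
landscape. Clustering uses a union-find over the pairwise distance matrix,
keeping the strict-inequality link rule exact.

## Grid occupancy

Cells are half-open squares [min, min+size) tiling the extent, 10 km by
default, with the origin snapped to the cell-size lattice so grids can align
with national reference grids (configurable to start at the extent corner
instead). Snapping can add one row or column relative to tiling from the
extent corner itself; every point still maps to exactly one cell. Cell
assignment corrects floating-point rounding at cell edges so half-open
membership is exact.

For a period of L consecutive years, a cell-year *qualifies* with ≥ 1 C1 or
≥ 2 C2 records, and has *presence* with any C1/C2 record. The cell is

* **Permanent** — qualifying years ≥ ⌈L/2⌉ (3 for five-year periods), or a
  reproduction event in the cell in the last three calendar years of the
  period;
* **Sporadic** — not Permanent, presence in ≥ 1 year;
* **Absent** — no presence at all.

One ambiguity deserves note: a cell with presence in half the years or more
but never meeting the per-year evidence bar (say, a single C2 in each of
four years) is neither clearly Permanent nor literally "presence in less
than half the period". It is classified Sporadic — the conservative choice,
since the Permanent bar is explicitly about evidence strength per year — and
logged when it occurs.

Net increases between the first and last period are 100 (c_last −
c_first)/c_first per status and for total occupied; a zero baseline yields
NaN with a warning rather than an arbitrary number.

## Activity patterns and overlap

Detection clock times are mapped to angles (hours × 2π/24) with no solar
anchoring: sunrise/sunset vary little over a short Mediterranean monitoring
window relative to kernel bandwidths.

The activity density is a von Mises kernel estimate. Two concentrations play
different roles:

* `fit_vonmises_kappa` — the maximum-likelihood concentration of a von Mises
  fit, solving A(κ) = R̄ with A = I₁/I₀ via Brent's method on exponentially
  scaled Bessel functions. Degenerate samples (R̄ → 1) are capped at a
  configurable κ_max (default 500) with a warning; balanced samples give 0.
* `kde_kappa` — the kernel concentration actually used for densities: the
  AMISE-optimal plug-in rule κ_bw = [3 n κ̂² I₂(2κ̂) / (4√π I₀(κ̂)²)]^(2/5)
  evaluated at the ML estimate. It grows as n^(2/5), so the estimator is
  consistent; a fixed concentration would leave the density biased at any
  sample size and the ratio-based overlap estimator and the direct integral
  would then disagree persistently. A user `adjust` multiplier (default 1,
  the usual choice for the large-sample overlap estimator) scales it;
  near-uniform samples are floored at κ = 0.01.

Densities are evaluated on a closed [0, 2π] grid (default 512 points;
trapezoidal integral equals 1 to 1e-6 for any reachable bandwidth; the
kernel is computed as exp(κ(cosΔ−1))/(2π·I₀ᵉ(κ)), overflow-safe).

Overlap uses the large-sample density-ratio estimator Δ̂₄ (clamped to [0,1],
densities floored at ε = 1e-12 before ratios) and carries a direct numerical
oracle: the trapezoidal integral of min(f̂₁, f̂₂) on a 4096-point grid. The
two are distinct estimates of the same coefficient; they agree as n grows
but differ at finite n by the kernel bias — worst for strongly bimodal
patterns, shrinking roughly as n^(−2/5). The test suite checks agreement
within 0.05 at 500 detections per series, the order of what multi-month
camera-trap monitoring actually produces for common species; at 200–300
detections the worst bimodal pairings can still differ by ~0.05–0.06, which
users comparing the two estimators on small samples should expect. Samples
of 75 or fewer trigger a warning, as the ratio estimator is recommended for
large samples only.

Overlap classes use fixed cutoffs on Δ: low < 0.50, 0.50 ≤ moderate ≤ 0.75,
high > 0.75. The cited classification's "percentile" phrasing is read as
these fixed thresholds, which is the reading consistent with the labels
attached to published coefficients (0.512 moderate, 0.808 high).

RAI is 100 × detections / trap-nights, rounded to 2 decimals.

## Diet

Scats arrive long-format (scat, date, item) with a taxonomy mapping each
item to one of five fixed categories (livestock, wild prey, pet, fruit,
other); unknown items raise an error naming them. Seasons follow the
astronomically anchored ranges (spring from 20 March, summer from 21 June,
fall from 22 September, winter from 21 December), half-open so each boundary
date belongs to the season it starts — the source ranges list overlapping
endpoints, so an ownership convention is required.

FO of a unit is 100 × (scats containing it)/N, counting a scat once per
category however many items of that category it holds. Uncertainty is a
bootstrap percentile interval (default B = 1000, 95%) over resampling whole
scats — the scat, not the item, is the sampling unit. Seeded generators make
intervals reproducible.

The Brillouin index is computed via log-gamma. The accumulation curve pools
scats one at a time, recording HB and its absolute relative change; since
collection order is arbitrary, the curve is averaged over random orderings
(default 100, seeded; collection-date order available). The minimum sample
size is the smallest k at which the averaged change drops below 1% *and
remains below* for all larger k; requiring persistence avoids a spuriously
early first crossing, and the curve is flagged undefined when HB is
identically zero (single-item diets) or never stabilizes.

## Occupancy model selection

The response is Permanent (1) vs Sporadic (0); Absent cells carry no
covariate signal about settlement quality and are excluded. Covariates are
first screened for collinearity: iteratively, from the worst pair with
Pearson |r| > 0.7, the member with the larger mean |r| against all remaining
covariates (the more redundant hub) is dropped, ties alphabetically;
constant covariates are dropped first. Fits are binomial GLMs with logit
link through statsmodels' IRLS. Separation is flagged by non-convergence,
any |β| > 50, or fitted probabilities reaching the observed labels to within
1e-3; flagged fits are excluded from ranking with a warning.

All 2^p subsets (including intercept-only) are fitted — refused above p = 20.
Ranking is by AICc (AICc = AIC + 2k(k+1)/(n−k−1); an error when n ≤ k+1),
which matters at occupancy-study sizes (tens of cells); AIC is reported
alongside. Akaike weights are normalized over all candidates, and
coefficients are averaged over the competitor set (Δ < 2) with weights
renormalized there. Full averaging (absent terms contribute 0, shrinking
effects toward zero) is the default; conditional averaging is a flag.

## Synthetic data

The generator produces every pipeline input under one master seed, fanned
out to named child streams (covariates, occurrences, activity, scats,
status) via `SeedSequence.spawn`, so each generator is independently
reproducible.

Defaults emulate the monitored system's magnitudes, chosen once from its
published dimensions: a 50 × 90 km extent (45 cells, the size of a coastal
peninsula of ~4000 km²), two five-year periods, three camera sites with
732/480/190 trap-nights, 75 scats collected June–December. Covariates are
uniform within field-realistic ranges (road density 1.3–5.9 km/km², 7–40
forest patches, 0–36 ovicaprine farms); total forested area is derived from
forest percentage and patch count, making it the redundant hub the
collinearity screen must remove. Occurrence intensity per cell-year is
Poisson with mean `base_rate × growth^(year−first) × p`, where p is a
logistic score on standardized covariates (default slopes: forest patches
1.2, forest percentage 0.4, protected area 0.3) — base_rate 0.15 and growth
1.35/year give an ongoing recolonization with roughly a dozen occupied cells
in the first period and about three times as many in the second. SCALP codes
are multinomial (85/8/7% C1/C2/C3); pup records go to the highest-scoring
cells in the later years. Activity times come from von Mises mixtures
(nocturnal 22h/4h, crepuscular 6h/19h, diurnal 13h, cathemeral presets);
scat contents are drawn per scat (1–3 distinct items) from configurable item
probabilities shaped like a livestock-heavy, low-wild-ungulate diet.

What the synthetic data do *not* emulate: spatial autocorrelation between
neighbouring cells, detection bias toward roads and trails, seasonal
activity shifts, observer effort varying over years, and misidentified
scats. Tests passing on these data therefore demonstrate that the
*computations* are correct under the assumed statistical structure, not that
the assumptions hold in any particular field system.

## Numerical choices

* Strict inequalities where rules say "within": camera gaps must exceed the
  window; reproduction links require distance < threshold.
* KDE: closed evaluation grid including both 0 and 2π; scaled Bessel
  functions throughout; density floor 1e-12 in overlap ratios.
* Brent root-finding bracket for A(κ) = R̄: [1e-12, κ_max].
* GLM convergence is statsmodels' IRLS default; AICc errors out rather than
  extrapolating when n − k − 1 ≤ 0.
* Bootstrap intervals are plain percentile (2.5/97.5); no BCa correction,
  matching standard practice for FO intervals.
* All tabular outputs are sorted deterministically; reruns with one seed are
  byte-identical.

## Known limitations

* Grid origin and projection are configuration; occupancy maps are only
  comparable across runs sharing both.
* Δ̂₄ on samples under ~100 detections is noisy and the package only warns;
  bootstrap intervals for Δ are not implemented.
* The diet module treats items as presence/absence; no biomass conversion,
  and predation cannot be distinguished from scavenging.
* Model averaging reports coefficients only; unconditional standard errors
  for averaged coefficients are not computed.
* Residual diagnostics for the GLMs (dispersion, spatial autocorrelation)
  are out of scope and should be run separately before interpreting effects.
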