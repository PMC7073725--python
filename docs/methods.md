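# Methods

This note documents the models behind `aromix`, the defaults and why, what
the synthetic generators do and do not emulate, and the numerical choices
that a maintainer would want written down.

## Quantification

Internal-standard calibration regresses the peak-area ratio
`y = area(analyte)/area(IS)` on the concentration ratio
`x = conc(analyte)/conc(IS)` by ordinary least squares
(`scipy.stats.linregress`).  A fit needs at least three distinct
concentration levels; routine standard series carry six.  Inversion maps a
measured area ratio back through the line and rescales by the
internal-standard concentration in the vial (default 400 µg/L in the
examples) and an optional dilution factor (default 1 — sample dilution is
configuration, not a hard-coded constant).  A back-calculated value below
zero is physically meaningless but diagnostically useful, so it is
returned with a `below_range` flag rather than clamped.  Replicates are
aggregated as mean and `RSD = 100·sd/mean` with the ddof = 1 standard
deviation.  A flat response fits slope 0 with `R² = 0`; such a curve is
representable but refuses inversion.  The internal standard is treated as
an opaque labelled channel: nothing depends on its identity, only on its
concentration.

## Screening

`OAV = C/T` with concentration and threshold in the same units; the
screening cascade keeps compounds with `FD ≥ fd_min` (default 16) and
`OAV ≥ oav_min` (default 1).  Three conventions matter for reproducing
printed tables:

* Display rounding is half-up to the nearest integer, with values below 1
  printed `<1`; the raw float is kept internally and used by all filters
  (so a compound at OAV 1.17 passes the ≥ 1 filter while printing `1`).
* A compound with no literature threshold has no OAV and can never pass
  the OAV filter — it is excluded from OAV-based counts, not treated as 0
  or infinity.
* FD factors reported as ranges (e.g. `128-256`, a between-dilutions
  call) are stored as ranges and filtered by their lower bound.

Literature thresholds are often determined in a slightly different matrix
(e.g. 46% ethanol/water against 53% samples); the mismatch is recorded as
`threshold_source` metadata and deliberately not corrected — no validated
matrix-correction model exists for these systems.

## Triangle and omission tests

A triangle (or general m-AFC) test is analysed with the exact one-sided
upper-tail binomial probability of at least the attained number of correct
answers under chance rate `1/m`.  Panel batteries here are small (≤ 60
presentations), so exactness costs nothing and removes approximation
error; no normal approximation or continuity correction is used.  Star
labels follow the conventional bands (`***` p < 0.001, `**` p < 0.01, `*`
p < 0.05, `=` otherwise).  Published omission tables sometimes print only
star labels; `p_from_stars` maps a label to a representative value strictly
inside its band so that downstream filters behave as the labels dictate —
these representatives carry band information only, never precision.

## Psychometric fitting

Detection data are per-level 3-AFC counts.  The model is the logistic
`P(x) = 1/(1 + e^{−(x−c)/D})` of log₁₀ concentration (log base 10
throughout; `c` is the threshold where P = 0.5, `D` the gradient).
Estimation maximises the binomial likelihood of the guessing-folded curve
`p_correct = 1/m + (1 − 1/m)·P(x)` at the trial level, which is equivalent
to fitting the chance-corrected proportions but remains well-defined when
an observed proportion is 0 or 1.  Optimisation is Nelder–Mead on
`(c, log D)` (the log-parameterisation keeps `D > 0` without constraints)
with tight tolerances (`xatol 1e-9`); the start point interpolates the
first 0.5-crossing of the corrected proportions.  The likelihood accepts
fractional counts so that noiseless expected-count designs invert exactly.
Fits require ≥ 3 levels with the corrected proportions crossing 0.5 inside
the tested range; all-ceiling or all-chance data raise a non-identifiable
error rather than returning a runaway threshold.  Sub-chance corrected
proportions are kept as (slightly negative) computed values so that
averaging stays unbiased.

## Feller's additive model and classification

For a binary mixture diluted along a *total concentration* axis with fixed
component mass fractions `(wA, wB)` (components mixed at their ratio in the
original sample), independence predicts
`P(AB)(C) = P_A(log₁₀ wA·C) + P_B(log₁₀ wB·C) − P_A·P_B`.  The predicted
threshold is the P = 0.5 root, found by bracketed Brent root-finding on
the monotone curve.  The comparison statistic is the observed fitted
detection probability at the predicted threshold — exactly 0.5 under
independent additivity.  Its null distribution is estimated by a seeded
bootstrap: trials are resampled within each concentration level, the curve
refitted, and the statistic recomputed; the two-sided p-value uses tail
fractions with a `+1/(B+1)` finite-sample correction.  The bootstrap
refits use a vectorised Fisher-scoring Newton iteration across all
replicates (verified against the reference optimiser to ~1e-8 in both
parameters), keeping the default `B = 2000` interactive.  Classification:
significant excess detection (observed threshold below prediction) is
synergy, significant deficit suppression, otherwise independent-additive;
`alpha` defaults to 0.05.  The underlying statistical test for published
mixture p-values is generally unstated in the literature; this bootstrap
is the package's own declared choice.

Two numerical caveats are documented because tests rely on them: the
Feller combination of two logistics is not itself a logistic, so feeding
the prediction's own expected counts back through the logistic fitter
reproduces the predicted threshold only to ~1%; and the classification
accuracy simulations (100 replicates per interaction mode) run the
bootstrap at `B = 400`, a study-size choice — power at threshold factors
0.5 and 2 with 60 trials/level is limited by the panel, not by B.

## The X-statistic

`X = ΣOAVᵢ / OAV_mix`, where `OAVᵢ = Cᵢ/Tᵢ` at the tested mixture
composition and `OAV_mix = (ΣCᵢ)/T_m` with `T_m` the measured mixture
threshold.  X = 1 is additivity, X < 1 synergy, X > 1 antagonism.  Because
panel thresholds are noisy, classification uses a configurable
`additive_band` (default ±0.2) around 1; the band is reported with every
classification.  When both the X analysis and the Feller detection test
exist for a mixture, `combine_classifications` lets the significance-based
Feller call override the X heuristic (default on): a mixture with X = 0.59
but a non-significant Feller departure is reported additive.  Published
`ΣOAVᵢ` columns can differ from the sum of their printed components by
≤ 0.01 from rounding; X is therefore computed from the printed sums when
reproducing tables, and at full precision from raw inputs otherwise,
rounding only at display (2 decimals).

## Vector model

Mixture intensity is the resultant of two component vectors,
`OI_ab² = OI_a² + OI_b² + 2·cosα·OI_a·OI_b`.  In the equal-intensity
design (`OI_a = OI_b`, the standard protocol) the half-angle identity
gives `OI_ab = (OI_a + OI_b)·cos(α/2)`, so `cos(α/2)` is estimated as the
least-squares slope through the origin, `Σxy/Σx²` — the model has no
intercept, and an unconstrained line is available behind a flag purely as
a drift diagnostic.  Intensities are panel means on the 1-butanol odour
intensity referencing scale (12 aqueous levels doubling from 10 ppm to
20,480 ppm) and are treated as continuous.  `cos_half_alpha_point` checks
the equal-intensity assumption (5% relative tolerance) and raises a
design-violation error otherwise.

## Synthetic data

The generators emulate the study designs the analysis expects:

* **Panels** — 20 assessors × 3 presentations per level (60 trials/level),
  six levels spanning the true threshold, 3-AFC; responses are binomial
  draws from the guessing-folded logistic.  Panellists are exchangeable by
  default; a heterogeneity mode draws per-panellist thresholds
  `c_i ~ Normal(c, σ_c)`, which visibly flattens the group curve.
* **Mixtures** — independent mode draws detection from the Feller
  combination of the two component curves; factor mode shifts that curve
  so the linear threshold is multiplied by `f` (f < 1 synergy, f > 1
  suppression).  The true threshold is available analytically, enabling
  classification-accuracy studies.
* **Calibration** — six-gradient series with lognormal (multiplicative,
  mean-1) area noise at a given CV (default studies use 5%).
* **Intensity ratings** — equal-intensity pairs with additive Gaussian
  rating noise (sd 0.3 in the recovery studies, a realistic scatter for
  panel means on a 12-level category scale), truncated at zero.

What the generators do **not** emulate: chromatographic peak shape or
retention drift, panellist learning/fatigue and session effects,
correlation between repeated presentations to the same assessor, and
matrix effects on thresholds.  Passing recovery tests therefore show the
estimators are correct and well-calibrated under the stated sampling
models, not that real panels satisfy those models.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| `fd_min` | 16 | FD screening cut-off (dilution steps of 1:2 from 1:1024 series) |
| `oav_min` | 1 | concentration at/above threshold |
| `omission_p_max` | 0.001 | key-ester omission significance |
| `m` | 3 | choices per forced-choice trial (triangle / 3-AFC) |
| `feller alpha` | 0.05 | two-sided classification boundary |
| `n_boot` | 2000 | bootstrap replicates per classification |
| `x_additive_band` | 0.2 | half-width of the X "additive" band around 1 |
| IS concentration | 400 µg/L | internal-standard level in the examples |
| dilution factor | 1 | sample dilution, configuration not constant |

## Known limitations

* Binary mixtures only; no ternary or dose-addition models.
* Thresholds are taken as given; no matrix correction or structure-based
  threshold prediction.
* The pipeline starts at peak areas / FD factors: no peak detection,
  deconvolution or spectral matching.
* The omission battery's published star labels are band information only;
  reconstructed p-values inside a band cannot distinguish, say, 0.03 from
  0.045.
* Group-level fits are the default; per-individual fitting is supported
  through the same API (one dataset per assessor) but no hierarchical
  model is provided.
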