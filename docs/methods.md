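# Methods

This note documents the models and procedures implemented in `rbcflow`,
the parameter choices that matter, and what the synthetic benchmarks do
and do not demonstrate.

## Deformability profile

A specimen is summarised from its per-cell elongation ratios
(ER = major/minor axis, ER ≥ 1 by convention; the caller must sort axes).
MER is the empirical median (midpoint of the central order statistics for
even n), AER the arithmetic mean. Sub-population percentages are direct
counts under a threshold scheme with cut-points 1.1 / 1.3 / 2.5.

Published descriptions of these bands differ in boundary handling: the
parameter definitions use strict bands (ER < 1.1; 1.1 < ER < 1.3) while
the cumulative-curve protocol reads them as ER ≤ 1.1 and ER ≤ 1.3. We
default to **disjoint half-open bins** — UDFC [1, 1.1), LDFC [1.1, 1.3),
MID [1.3, 2.5), HDFC [2.5, ∞) — because only a partition makes the four
percentages sum to 100 exactly, which is asserted to 1e-9. A
`cumulative` convention (upper edges closed: UDFC [1, 1.1],
LDFC (1.1, 1.3]) is available; for continuous data the boundaries carry
zero mass and the two conventions coincide. The unnamed 1.3 ≤ ER < 2.5
band is reported as `pct_mid` so the partition is explicit.

Distribution curves use a default bin width of 0.05, fine enough to
resolve the 1.1/1.3 thresholds; the median read off the cumulative curve
agrees with the raw-sample MER within one bin width. The raw-sample
median is canonical; the curve read-off is provided because analyzers
historically derived parameters graphically.

The protocol targets of 10,000–15,000 pooled cells over 25–35 fields are
treated as advisory: falling outside them warns but never fails, since
they describe measurement practice, not validity conditions.

## Image analysis

Cells are bright ellipses on a dark background (an `invert` flag handles
the opposite dialect). Detection is a global Otsu threshold followed by
8-connected component labeling; touching-cell splitting (watershed) is
deliberately out of scope — the generator controls overlap instead, which
keeps the detection stage simple and its oracle exact. Components
touching the border, outside 20–200 µm² projected area, or with ER > 6
are flagged with a reason and excluded from profiling rather than
silently dropped.

Axes come from the second-order central moments of the component mask:
with λ₁ ≥ λ₂ the eigenvalues of the coordinate covariance, the full axis
lengths are 4√λᵢ (exact for an ideal filled ellipse), the orientation is
the major-axis angle from the +x axis. Coordinates are x-right, y-down,
pixel centers at integer positions, 0-based — fixed so a brute-force
covariance oracle can be written independently. Single-pixel and
collinear masks raise a degenerate-shape error and are QC-flagged by the
caller.

Moment estimates on a rasterized mask carry lattice-quantization error
that shrinks with resolution and is worst for masks centered exactly on a
pixel. At the default rendering resolution (0.15 µm/px, giving minor
axes ≳ 20 px for normal cell areas) the per-cell ER error on noise-free
fields stays well under 3% (measured max ≈ 1.3% over 10,000 cells), with
recall and precision of 100% on non-overlapping fields.

## Synthetic ER populations

No within-sample ER distribution family is established in the
literature, so the generator defines one with the features the analysis
assumes: support on [1, ∞), a small spike of rigid cells at ER ≈ 1, and
a right-skewed deformable bulk:

    ER = 1 + X,  X ~ w·|N(0, σ_r)| + (1−w)·LogNormal(ln s̃, σ_t)

with `rigid_fraction` w, `rigid_spread` σ_r (default 0.03), lognormal
median `tail_scale` s̃ and shape `tail_shape` σ_t (default 0.65). The
lognormal tail is a deliberate choice: measured units combine a *low*
undeformable fraction (%UDFC ≈ 1) with a *heavy* high-deformability tail
(%HDFC ≈ 6) at MER ≈ 1.55, and within this mixture form a gamma tail
cannot reach that corner — any gamma shape putting ≤ 1.1% of mass below
ER 1.1 at that median puts ≲ 1.6% above ER 2.5. The lognormal hits all
three targets exactly.

**Calibration** maps profile targets (MER, %UDFC, optionally %HDFC) to
mixture parameters through the exact mixture CDF: the two lognormal
quantile equations are linear in (ln s̃, σ_t) given the spike weight, and
the weight follows from the %UDFC equation; a short fixed-point iteration
closes the loop (deterministic, verified to reproduce the analytic median
within 1e-3). With no %HDFC target the shape stays at its default and
%HDFC emerges. Rigid-dominated targets (%UDFC ≥ 50) instead solve the
spike spread for the median. Infeasible target combinations raise a
calibration error rather than approximating.

**Cohorts.** Unit-to-unit variability is modeled on MER and %UDFC only
(per-unit targets drawn from truncated normals at the cohort's printed
mean ± SD; MER floored at 1.05), with %LDFC/%HDFC emerging from the
calibrated shape — constraining all four correlated parameters per unit
would over-determine the mixture. Defaults encode the two studied
cohorts: donor units (MER 1.52 ± 0.11, %UDFC 3.18 ± 3.83, n = 156) and
cord-blood samples (MER 1.61 ± 0.07, %UDFC 2.21 ± 1.06, n = 78).

**Field rendering.** Square fields of 0.1 mm²; each cell is a filled
ellipse whose projected area is drawn from N(55, 8²) µm² (an undeformed
disc of ≈ 8 µm diameter; area preserved under elongation), axis ratio
equal to its ER, major axis along the flow (image x) with 5° Gaussian
angular jitter. Placement is rejection sampling against a one-pixel-
dilated occupancy mask, so distinct cells can never merge under
8-connectivity; overcrowded fields raise a placement error. Optional
Gaussian blur and additive noise; pixel size defaults to 0.15 µm/px
(high-magnification imaging), chosen so moment-estimator quantization is
far inside the recovery tolerance.

What the rendered benchmark does *not* emulate: uneven illumination,
touching or partially attached cells, debris, focus drift, and camera
noise statistics. Passing recovery tests therefore demonstrates
correctness of the measurement chain, not robustness to all real imaging
artifacts.

## Population statistics

Group comparisons operate on unit-level parameter values with a
pooled-variance Student t-test by default (Welch behind a flag), matching
the study's stated analysis; each group is screened with Shapiro–Wilk and
a warning is raised when a group looks non-normal with n < 30 (above
that, the t-test is robust to the violation). No multiple-testing
correction is applied across the five parameters by default (raw
per-parameter p-values are the convention); a Bonferroni flag exists.

Unit ranking against a recipient compares MERs with a tolerance for
"at least equal". The tolerance is nowhere quantified in the source
analysis; 0.01 MER units — roughly the measurement repeatability of a
10,000-cell median — is the declared convention. Selection returns all
strictly higher units, else all equal-within-tolerance units, else the
maximal-MER unit with a warning. %UDFC (lower is better) is an optional
secondary sort key.

## Proteomics predictor

Ln(LFQ) protein levels enter single-predictor fits (R = |Pearson r|,
two-sided correlation p) and the combined two-predictor least squares
(R = √R², p from the overall F-test). The printed form of the combined
predictor has no intercept, but without one R is not a Pearson-type
quantity, and the single-predictor correlations imply centering — so the
intercept is included by default and the no-intercept variant sits
behind a flag. The response is MER by default, AER supported; output
metadata names which was used. Non-positive LFQ intensities are treated
as missing (the label-free convention), never log-imputed; affected
units are excluded from fits using that protein, with a warning.

The generator draws Ln(LFQ) predictors independently per protein
(means ≈ 20–24, SDs 0.5–0.8, typical label-free scales) and builds the
response as a·[protein] + b·[HBB] + intercept + noise with defaults
a = 0.05 (structural-protein loss lowers deformability), b = −0.04
(membrane-bound hemoglobin stiffens the cell), and noise_sd = 0.034,
sized so the population multiple correlation is ≈ 0.77 — the magnitude
reported for the best protein/HBB pair. Non-causal panel proteins are
inert covariates; real membrane proteomes are correlated across
proteins, so panel-wide correlation structure is *not* emulated.

## Numerical conventions

- All generators take explicit seeds (numpy `default_rng`); identical
  seeds give byte-identical outputs, and the pipeline writes its seed and
  a hash of the scientific configuration into every report.
- Calibration verifies itself (analytic median within 1e-3 of target)
  and fails loudly otherwise.
- Degenerate inputs raise typed errors (`rbcflow.errors`) rather than
  returning NaN: empty samples, ER < 1, constant samples for normality,
  zero-variance predictors, misconfigured fixed thresholds.
- Benchmark problem sizes: the imaging benchmark uses 25 fields × 400
  cells; cohort detectability uses 200 replicates at 1,000 cells per unit
  and null calibration 500 replicates at 500 cells per unit — the median
  of ≥ 500 draws adds ≈ 0.01–0.02 sampling noise, negligible against the
  0.07–0.11 between-unit spread, so these sizes preserve the operating
  characteristics being measured.

## Known limitations

- ER is taken as measured; no shear-stress physics or membrane mechanics
  links the 3.0 Pa operating point to elongation.
- Touching/overlapping cells are excluded by construction, not resolved.
- Cohort presets encode outcomes (printed means and SDs), not donor
  biology; they support power/calibration studies, not inference about
  new cohorts.
- The proteomics model is linear with Gaussian noise and independent
  predictors; it cannot validate coefficient values against the original
  study, which does not print them.
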