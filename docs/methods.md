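# Methods

## Scan geometry and units

All en-face products live on the 512 x 512 grid spanned by (B-scan index,
A-scan index). The depth axis has 1024 pixels over a 1.4 mm imaging depth,
so one depth pixel is `1400/1024 ≈ 1.3672 μm`; thickness is measured along
the A-scan (axial) direction as the distance between adjacent boundary
surfaces, the standard OCT convention. No curvature flattening or
perpendicular-to-surface correction is applied.

The optic-disc centre defaults to the midpoint of the bottom edge of the
en-face grid — the scan protocol places the volume directly above the disc
and horizontally centred on it — and is configurable everywhere it enters
(generator, radial profiles).

## Orientation convention

Right-eye (OD) maps are the reference frame. Left-eye (OS) maps are
mirrored left-right once, after which the left half of any standardized
map is temporal retina and the right half nasal. `standardize_orientation`
is an involution on the flip and idempotent on the state flag: calling it
on an already-standardized map logs a warning and changes nothing (a
`force` flag exists to apply the raw flip in tests).

## Block aggregation and the quality filter

The 512 x 512 map is centre-cropped by one pixel per edge to 510 x 510 —
the crop is needed so the nine aggregation blocks are equal 170 x 170
tiles; which pixels to shed is not otherwise determined, and the symmetric
choice is the least arbitrary. Blocks are numbered 1..9 row-major from the
top-left of the standardized map; the temporal column is blocks {1, 4, 7}
and the nasal column {3, 6, 9}.

Per-pixel validity screening is a conjunction of ordered rules. The
default battery — non-negativity, per-layer physiological bounds, and a
robust standard-score cut at 6 using median/MAD (scaled by 1.4826) — is a
synthetic stand-in for the image-quality, boundary-consistency and
value-distribution screening applied to real segmentations, whose exact
criteria are not reproducible. Default bounds are `[0, 3x]` the packaged
age-matched layer mean: generous enough never to clip plausible tissue,
tight enough to catch gross segmentation failures; both the bounds and the
z threshold are parameters.

A block is retained iff `valid / 28,900 ≥ 0.90`, inclusive at the
boundary; dropped blocks carry NaN means. Whole-area means are computed
over the valid positions of the *uncropped* 512 x 512 grid (whole-area and
block reporting are separate modes) and refuse to answer when under 50% of
positions are valid (configurable).

## Normative databases

A cell is `(mean, SD, n)` with the n−1 sample SD (the estimator is not
otherwise pinned down). Cells are built per eye and for both eyes pooled
(`eye="combined"`), treating eyes as independent samples — consistent with
the published per-age Ns, which equal the sum of the per-eye counts.
Cells with n < 2 are omitted and logged. The packaged tables (wild-type
and 3xTg-AD whole-area means per layer and age, plus cohort weights) are
checksummed CSVs loaded via `load_packaged`; a per-block reference can be
supplied externally through `load_block_table`, which validates the
schema but ships empty.

Normality is checked with a one-sample Kolmogorov-Smirnov test against a
Normal with the sample's own mean and SD. Estimating the parameters from
the same sample makes the plain KS p conservative (the Lilliefors
effect); plain KS is nevertheless the default because it is the named
procedure, with `method="lilliefors"` and fixed-parameter variants
available. The fixed-parameter form is exact and is what the calibration
test exercises (rejection 5% ± 2.5% at α = 0.05 over 1,000 samples).

## Group and longitudinal statistics

Significance tiers 5%, 1%, 0.1% are strict (`p < 0.05` etc.; `p = 0.05`
is ns). Welch is the default two-sample variant — the safer choice when
variances differ, and identical to the pooled test in the balanced
equal-variance limit — with Student's pooled version available for
sensitivity checks. Summary-statistic inputs `(mean, SD, n)` are accepted
and give bit-identical results to raw samples, which is what allows
testing against printed tables.

The nasal-temporal asymmetry test is operationalized as a paired contrast:
per eye, the mean of the retained nasal-column blocks minus the mean of
the retained temporal-column blocks, then a paired two-sided t-test across
eyes. This is one reasonable construction of a finding whose original test
is not specified; the null simulation in the test suite confirms its size.

RANOVA is the one-within-factor decomposition computed directly from the
subjects x ages matrix: `F = MS_time / MS_subject×time` with `(k−1)` and
`(k−1)(n−1)` degrees of freedom, complete cases only (incomplete rows are
a contract violation upstream of the computation, removed by
`select_complete_cases`). The uncorrected p is primary; the
Greenhouse-Geisser epsilon (eigenvalues of the double-centred column
covariance, clamped to `[1/(k−1), 1]`) and adjusted p are reported
alongside. The implementation is cross-checked against an established
repeated-measures ANOVA implementation in the test suite. Degenerate
inputs are rejected rather than scored: fewer than three subjects, or a
zero within-subject error term (e.g. a single subject duplicated). A
table with zero time variance returns `F = 0, p = 1` even when the error
term is also zero. Tukey HSD uses the studentized-range tail at k = 4
with the RANOVA error term; no further multiplicity correction is applied
across layers, blocks or ages.

## Deviation scoring

"More extreme than the observed thickness" is read as two-sided tail
mass: `p = 2(1 − Φ(|z|))`, the only reading consistent with `p = 1.00`
exactly at the reference mean. p is kept at full precision internally and
shown to two decimals in renderings. Colour intensity is linear in
`1 − p` (taken from the stated colour semantics; linear in `|z|` would be
the alternative), blue below / red above the mean, neutral gray for
blocks the quality filter excluded. The reference defaults to the
eyes-combined cells; per-eye references are selectable.

## The synthetic generator

Per layer, thickness at (r, c) is
`base + g_nt·x(c) + g_d·d(r,c) + ε`, `ε ~ N(0, σ²)` i.i.d. per position,
clamped at zero (physical non-negativity; clamping cannot reorder the
surfaces, which are running depth sums of the clamped thicknesses below a
flat inner limiting membrane at depth 200 px). `x(c)` is the centred
nasal-temporal coordinate (±0.5 at the edges, mirrored for OS, mean
exactly zero so the gradient never shifts the map mean); `d` is distance
to the disc centre normalised by the map width.

Defaults: noise σ = 2 μm per position (the order of the instrument's 3 μm
axial resolution), nasal-temporal slope +1 μm per map width and disc
slope −2 μm per unit normalised distance — both nominal magnitudes of the
right sign, as no quantitative gradient values are published — and
per-layer bases equal to the packaged one-month wild-type means. Noise is
applied to thickness rather than to the interface depths; that is simpler
and sufficient for testing statistics that only consume thickness.

`sample_cohort` draws one mean per layer per eye from
`Normal(cell.mean, scale·cell.SD)` and compensates the base for the mean
disc-distance term, so the expected whole-area mean of a generated layer
equals its draw exactly. The eight layer cells and the TRT cell cannot
all be honoured simultaneously (the printed TRT is not the printed layer
sum, because block/value selection runs per layer), so the sampler has
two modes: `anchor="layers"` (default) reproduces each layer's own cell
and lets TRT be the sum; `anchor="TRT"` additionally draws a TRT value
and rescales the layer draws proportionally to sum to it, reproducing the
TRT cell at the cost of a ~1% relative bias on individual layers.

What the generator does *not* emulate: OCT speckle and intensity data,
segmentation-network error modes, within-retina spatial autocorrelation
of noise, eye-to-eye correlation within an animal, or longitudinal
within-subject correlation across ages. Tests passing on synthetic
cohorts therefore validate the *analysis machinery* (geometry, filtering,
estimators, calibration of the statistics), not the biological claims
about real retinas.

## Problem sizes and numerics

The test suite and the reproduction script use full 512 x 512 grids
wherever the geometry matters (block filters, cohort recoveries at the
published 103/84/104-eye sizes) and 24-64 pixel grids for purely
structural properties, keeping the default suite fast while exercising
the real shapes. Type-I-error calibrations run 500-1,000 replicates with
a ±2-2.5 percentage-point acceptance band around α = 5% (about three
binomial SDs). Grouped-mean and telescoping identities are asserted at
1e-9 relative tolerance (floating-point associativity, not method error).
Seeds are fixed in tests; the reproduction script derives all its seeds
from `--seed`.

## Known limitations

- The per-block supplementary reference values are not packaged; block
  deviation maps against published references require loading them via
  `load_block_table`.
- Real-cohort quantities that depend on the unreleased images (per-block
  removal percentages, complete-case counts) are out of reach; the QC
  report reproduces the *format*, not the numbers.
- RANOVA assumes sphericity for its primary p; only the
  Greenhouse-Geisser adjustment is offered (no mixed-effects
  alternative).
- The weight-table p-values are packaged as printed but are not
  recomputable (the per-group n behind them is not stated); they are
  validated qualitatively (all non-significant) only.
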