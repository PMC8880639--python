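# Methods

`lastkit` turns a scanned paper form of the alternating-series drawing task
(an examinee continues a chain of connected open rectangles and triangles,
drawn without lifting the pencil) into a quantitative per-subject record.
This note documents the models, the parameter choices that matter, and what
the synthetic test bed does and does not establish.

## From scan to signal form

A 600-dpi grayscale scan is almost entirely white paper, so the intensity
histogram has a dominant high-intensity lobe. The binarization threshold is
placed at the low-intensity *foot* of that lobe: walking down from the
smoothed histogram's mode (above intensity 128) until counts fall below
0.1% of the peak, minus a 3-gray-level safety margin. Walking by strict
monotonicity alone is not robust: additive scanner noise clips at 255 and
creates a secondary spike there, with a dip between the spike and the true
background mode that a monotone walk mistakes for the foot.

The thresholded ink mask is cleaned by a morphological opening with a disk
of radius `round(dpi/600)` pixels and thinned to a one-pixel, 8-connected,
topology-preserving skeleton (the Lam–Lee–Suen thinning family). The
skeleton is collapsed left-to-right into the **signal form**: for every
column in the ink extent, the height of the *uppermost* skeleton pixel, in
up-positive page coordinates. The upper envelope is the only choice
consistent with the amplitude-based recognition rule (a rectangle is a
plateau near maximum amplitude); columns the pen never crossed are linearly
interpolated and flagged so features can skip them.

## Baseline estimation (sparsity-assisted)

The writing line wanders slowly across a page. The signal form is modelled
as `y = x + f + w`: sparse positive peaks `x` (the characters), a low-pass
baseline `f`, and noise `w`, recovered by minimizing

    F(x) = 1/2 ||H(y-x)||^2 + lam0 * sum theta_eps(x_n; r)
                             + lam1 * sum phi([D1 x]_n)
                             + lam2 * sum phi([D2 x]_n)

with `H = B A^{-1}` the banded high-pass complement of a zero-phase
recursive low-pass filter of order `d` and cut-off `fc`, `D1`/`D2` the
first/second difference operators, `theta_eps` the smoothed asymmetric
penalty (negative peaks cost `r` times more than positive ones) and `phi` a
smoothed absolute value. The minimizer is found by
majorization–minimization; each iteration solves one banded linear system.
The returned baseline is `f = L(y - x̂)` and the aligned signal is
`raw - f` exactly (conservation holds element-wise by construction).

Parameter choices, with reasons:

- **Shift.** The signal is first shifted so its first sample is zero. On a
  real trace the first ink column contains the *base* of the first rising
  stroke, so this anchors the writing line near zero — the state the valley
  detection below assumes.
- **`lam0 = 1/std(y)`, `lam1 = lam2 = 2*lam0`**, data-driven weights;
  standard deviation with denominator N.
- **Asymmetry `r`** is the inverse variance of the amplitude-normalized
  signal (typically 8–20). Computed on raw pixel units it would be ~1e-3,
  i.e. no asymmetry at all, and the baseline would not hug the valley
  floor; the normalized-units reading restores the canonical behaviour of
  the method (baselines track the floor under positive peaks).
- **`fc = 2e-3` cycles/sample, `d = 1`.** The cut-off must pass
  writing-line wander (periods of a page width, thousands of pixels) while
  attenuating character-scale content (period ≈ 300 px at the default
  geometry, i.e. 3.3e-3 cycles/sample). Much lower cut-offs make the banded
  filter numerically near-singular and the solver unable to move within-page
  drift into the baseline. Both `fc` and `d` are exposed in `BeadsParams`
  and the `[beads]` config table.
- **Adaptation loop.** If the estimated baseline tops the signal's own
  maximum — an unambiguously pathological fit — one of `lam1`/`lam2` is
  doubled (`lam1` first, alternating) and the solve repeated, up to 10
  times; exhaustion returns the last result with a warning flag rather than
  failing the scan.
- **Numerics.** `eps = 1e-6` smoothing, 30 iterations, solver keeps the
  best-objective iterate. Near the optimum the eps-clamped majorizer can
  limit-cycle at the 0.1% level; growth is treated as divergence only when
  the solver never improved on its starting objective.

## Character separation

Between two characters the pen returns to the writing line, so the aligned
signal shows a run of samples near zero. A separating column is the
midpoint of each maximal run of samples below `valley_frac = 0.10` of the
robust maximum (95th percentile) that contains a local minimum; cuts closer
than 0.3 of the median cut spacing are merged (several shallow dips inside
one connector are one transition). Midpoint placement keeps the cut centred
even when residual drift tilts the connector, which keeps the per-class
width ratios unbiased.

Vertical strips of half-width equal to the stroke-width estimate (median
skeleton-to-boundary distance, min 1 px) are erased around each cut; the
remaining 8-connected components are the characters. Fragments smaller than
5% of the median component area are merged into the component with maximal
column overlap (skew fragments) or dropped (isolated specks). Segmentations
are scored against expert masks per character: greedy highest-Jaccard
matching, a match accepted above Jaccard 0.70, summarised as
`2TP/(2TP+FP+FN)` in percent.

## Shape recognition

Per scan, *model* characters are selected by cheap geometric rules, applied
in order (first match wins): (a) the minimum enclosing triangle area share
`T/(R+T) < 0.55` makes a triangle model; (b) the smaller of the two
enclosures, if its share of `R+T` is below the same threshold, assigns its
class; (c) a near-horizontal stroke longer than 0.25 of the character width
(a line-parameter search within ±5° of horizontal) makes a rectangle model;
(d) in the normalized signal, more than 66% of samples above 0.8 amplitude
makes a rectangle model, fewer than 33% a triangle model. Rule (b) is a
symmetric reconstruction around the one fully stated rule (a); as
implemented it accepts any character with a non-degenerate enclosure pair,
so on clean scans most characters become models and the enclosure geometry
effectively decides their class — the warping-based matcher below then
mainly serves characters whose geometry is degenerate.

Minimum enclosing rectangles are computed by rotating calipers over the
convex hull. Minimum enclosing triangles exploit the optimality conditions
(each side's midpoint touches the hull; at least one side flush with a hull
edge): candidates are every pair of flush edges with the third side either
flush or tangent at a hull vertex placed at the side's midpoint, checked
for containment. Both are exact and validated against brute-force oracles.

A class with no selected models receives three artificial unit-amplitude
templates: perfect rectangle plus two isosceles trapezoids (top 0.5 and 0.7
of base), or perfect triangle plus two mirrored right triangles (apex at
0.25 and 0.75 of width). All model signals are normalized to [0, 1] and
resampled to the scan's median character width.

Non-model characters are classified by constrained dynamic time warping:
squared local cost, steps (i-1,j), (i,j-1), (i-1,j-1), matched boundaries,
and a slope-scaled band `|i*(m/n) - j| <= 0.05 * max(n, m)`; an infeasible
band falls back to the unconstrained path (logged). The nearest model's
class wins; ties break toward rectangle.

## Features and the NW coefficient

Per character: bounding-box width/height before and after *straightening*
(rotation by the orientation of the ellipse with identical second central
moments; isotropic characters rotate by zero); ink-pixel area; convex hull
area; equivalent-ellipse axis lengths and orientation; signal polyline arc
length `sum sqrt(1 + dy^2)` skipping interpolated samples; the amplitude
plateau occupancy; and the constrained-DTW distance from the perfect
artificial template of the character's class. All spatial features are also
divided by the corresponding feature of the examiner's first character of
the same class (`*_n` variants), making series from different examiners
comparable.

Per series: median (MED) and interquartile range (IQR, Q3−Q1 with
linear-interpolation quantiles) of every feature per class (IQR needs at
least two characters, else flagged missing); the per-class width ratio
(sum of class bounding-box widths over the examinee extent, in percent;
50% is the ideal balanced value); and the **NW coefficient** — the
sequence-correctness score. The recognized examinee sequence `E` is aligned
against the ideal alternation `G` of the same length, continuing the
examiner's pattern, with the Needleman–Wunsch scoring matrix (match reward
m=1, mismatch and gap penalties 0) normalized as
`NW = max(H_EG)/max(H_GG) * 100`. With these defaults NW equals the
longest-common-subsequence ratio: 100% for a perfect series, 5/6 ≈ 83% for
one substitution in six.

## Group statistics and classification

Features are compared across PD, PSP and control with the Kruskal–Wallis
rank test (tie-corrected) at α = 0.05; only features that reject receive
Dunn's pairwise mean-rank z-tests (no multiplicity correction by default,
Holm optional). The classifier reduces the three-class problem to three
one-vs-one Gaussian-kernel SVMs combined by error-correcting output codes;
prediction decodes the vote vector to the class with the nearest codeword
(Hamming distance, zeros excluded), ties to the larger training class.
Features are median-imputed and standardized with training-fold statistics.
The kernel coefficient defaults to the conventional medium-Gaussian preset
γ = 1/n on standardized features (`gamma_mode="medium"`); γ = n
(`gamma_mode="paper"`) is available but near-degenerate in n standardized
dimensions. Cross-validation is stratified k-fold with a mandatory seed;
the significance-based feature selection is refitted inside each training
fold by default (non-nested selection is an option).

## Synthetic test bed

The generator draws the series analytically — open rectangles (sides
leaning inward 4°, as hand-drawn "verticals" do) and triangles joined by
short baseline connectors — then applies per-character size jitter, skew,
multiplicative size decay (micrographia), perseveration substitutions
(probability `p` per character of repeating the previous shape), a slow
sinusoidal drift of the writing line, rasterization at pencil stroke width,
Gaussian scanner noise and salt speckle. Default geometry: 120 × 100 px
characters (~5 mm at 600 dpi), 30 px connectors, stroke width 3 px, drift
20 px over an 8000 px period, noise SD 4 gray levels. Ground truth (masks,
labels, envelope) is exact by construction; the first five characters are
the examiner's and use the mean geometry.

Group presets express the motivating phenotypes: PD — smaller characters
(90 × 70 px), tighter jitter, 3% per-character size decay; PSP — frequent
perseveration (p = 0.30) and larger skew/jitter; control — near-clean
execution. These are caricatures for pipeline validation, not simulations
of clinical distributions: passing tests show the pipeline recovers known
structure under controlled distortions, not that clinical accuracy figures
would be reproduced. Real pencil texture, hesitations, retracing,
corrections and paper artifacts are not modelled.

## Problem sizes and limitations

The default validation scale — ten noise-free scans for end-to-end checks,
35 subjects per group for the classifier sanity check, 10^5 random pairs
for the sequence-score equivalence — keeps a full run in a few minutes on
one core while leaving the statistical conclusions comfortably clear of
their thresholds.

Known limitations: characters that physically overlap are separated only by
strip-cutting at signal valleys; multi-line series and page de-skewing are
out of scope; no kinematic (velocity/pressure) information exists in a
static scan; and rule (b) of model selection is a reconstruction whose
original definition was not available — its threshold semantics are
configurable.
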