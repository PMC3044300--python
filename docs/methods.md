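# Methods

## The problem

Hydrogen–deuterium exchange mass spectrometry (HDX-MS) probes protein
structure dynamics: backbone amide hydrogens exchange with solvent
deuterium at rates governed by solvent protection, so a peptide's mass
drift over incubation time reports on the flexibility of the region it
covers. In a differential experiment the same protein is measured *apo*
and ligand-bound; a region that takes up less deuterium when the ligand is
present has been stabilized by binding, and one that takes up more has
been destabilized. Because uptake is strongly time-dependent and
saturating, deciding whether two uptake curves differ *significantly*
requires statistics that remove the shared time trend — the core of this
package.

## From peaks to percent deuteration

Inputs are pre-extracted peak lists: one row per isotopic peak with
peptide id, state, charge, exchange time, replicate, m/z and intensity.
No peak picking, smoothing or envelope deconvolution is performed; the
package starts where instrument export ends.

The centroid of a cluster is the intensity-weighted mean m/z,

    c = sum(mz_i * I_i) / sum(I_i),

computed on the m/z scale. All compared records of a peptide must share
one charge state; conversion to neutral mass is deliberately not done, so
"m/z response" analyses read directly in Thomson.

Percent deuterium incorporation anchors the partially deuterated centroid
P between a nondeuterated control N and a fully deuterated control F:

    %D = 100 * (c_P - c_N) / (c_F - c_N).

Controls are identified by the reserved state labels `nondeut` and
`fulldeut`. When no fully deuterated control was measured, a theoretical
anchor is synthesized:

    c_F = c_N + n_exchangeable * 1.00628 * recovery * buffer_d / charge,

where 1.00628 Da is the deuterium–protium mass difference, `recovery` is
the fraction of label surviving back-exchange during workup (default
0.70) and `buffer_d` the deuterium content of the labeling buffer
(default 0.80); both are user-settable. A *measured* fully deuterated
control already embodies back-exchange, so no further correction is
applied to it — the corrections act only through the theoretical anchor.
This keeps both anchors physically meaningful in either mode; whether to
correct the anchor or to rescale %D multiplicatively is a genuinely open
design point, and the anchor interpretation was chosen because it leaves
the 0%/100% calibration exact for measured controls.

Percent-D values slightly outside [0, 100] arise from noise and are
preserved unclamped (clamping would bias downstream statistics);
excursions beyond ±5 points are logged.

Very early timepoints show too little exchange to be informative; the
`min_time_s` filter (conventionally 600 s = ten minutes) drops them before
analysis.

## Differential statistics

Two methods are run per peptide, on either the centroid m/z or %D
response.

**Paired t-test over timepoints.** Replicates are averaged within each
state × timepoint; the per-timepoint differences d_t = mean_b(t) −
mean_a(t) remove the shared time trend, and a one-sample t-test of d
against zero gives the estimate (mean difference), a t-based CI and a
two-sided p-value with df = (#timepoints − 1). Degenerate inputs never
crash: all-zero differences give p = 1 with a zero-width CI; a nonzero
constant difference is reported with p = 0 and a warning.

**Time × group linear model (ANCOVA).** All observations enter an OLS fit

    Y = b0 + bT*X_time + bG*X_group + bTG*X_time*X_group,

with X_group = 0 for state_a and 1 for state_b (so positive effects mean
the second state exchanges more) and X_time either raw seconds or log10
seconds. An intercept is included — without it the reference group would
be forced through Y = 0 at t = 0, nonsensical for m/z responses. The group
effect is the contrast

    L = bG + bTG * t*,

evaluated by default at the mean of the (transformed) fitted times; t* can
be fixed by the user (extrapolation beyond the fitted range warns). With
the interaction off, L reduces to bG. Its variance is c'Σc from the
coefficient covariance, with t-based CI and p-value on the residual df.

**Why both, and when they agree.** On a balanced complete design (same
timepoints and replicate counts in both states) the contrast at mean time
is algebraically identical to the paired-t estimate; the test suite checks
this identity to 1e-8. The regression is more powerful because it pools
all replicates into one residual variance (df = n − p rather than
#timepoints − 1), at the price of assuming the response is linear in the
time covariate. p-values are two-sided and kept at full precision; display
helpers floor them at 1e-16.

**Multiplicity.** Adjustment is off by default; Benjamini–Hochberg FDR is
available and is applied within each method family across peptides.

**A real limitation worth knowing.** The paired t treats any across-time
variation of the true difference as noise. When the difference grows with
time (as kinetic effects do early in the exchange), its spread inflates
sd(d) and caps the attainable significance regardless of effect size, and
the CI over-covers a time-averaged estimand. The regression with
interaction models that trend instead of absorbing it. Consequently: for
strongly time-varying differences prefer the regression, or sample a
window where the difference is near-constant.

The log10 time option exists because uptake saturates; on a log axis a
saturating curve is closer to linear over wide time ranges. It requires
strictly positive times (`min_time_s > 0`).

## Synthetic data generator

The generator exists so every pipeline stage is testable with known ground
truth and no external data. Each peptide's deuterated fraction follows
first-order kinetics d(t) = d_max·(1 − e^(−k t)); ligand binding is
modeled as a rate change (rate_b = ratio × rate_a). An isotopic envelope
is the convolution of a natural-isotope profile with a
binomial(n_exchangeable, d(t)) deuterium distribution, on a grid with
1.0033/z (¹³C) and 1.00628/z (D−H) spacings. The expected centroid shift
is exactly n_exchangeable·d(t)·1.00628/z, which anchors all ground truth.
Noise is multiplicative log-normal on intensities and additive Gaussian on
m/z; references (`nondeut` at d = 0, `fulldeut` at d = d_max) are measured
once with the same noise model. Identical spec + seed gives byte-identical
files.

Deliberately non-physical simplifications: the natural-isotope profile is
a geometric decay (ratio 0.5), not an averagine model; no chromatographic
effects, no overlapping envelopes, no EX1 bimodality, no peak truncation.
Passing tests therefore certify the arithmetic and the statistical
calibration under clean, well-separated envelopes — not robustness to
envelope overlap or detector artifacts in real spectra.

### Default study conditions

One choice of conditions is used throughout the simulation experiments:

| parameter | default | rationale |
|---|---|---|
| timepoints | 600, 1200, 1800, 2400 s | past the ten-minute cutoff, equally spaced |
| replicates | 3 | typical technical replication |
| rate_a | 5e-5 /s | slow-exchange regime: uptake is nearly linear over the window (lack-of-fit ±0.04 %D), the regime the linear time model presumes |
| d_max | 0.85 | incomplete exchangeability at plateau |
| n_exchangeable | 8 | mid-size peptide |
| intensity noise | 8% (log-normal sigma 0.08) | routine MS repeatability; yields ~0.4 %D replicate scatter |
| m/z jitter | 0.002 Th | sub-ppm-level mass stability |

Within these conditions the Monte-Carlo experiments use: 2000 null
replicates for type-I error, 1000 replicates (rate ratio 1.02) for CI
coverage, 2000 replicates per effect size over ratios (1.01, 1.02, 1.05,
1.1) for the power curve, and 50 datasets for the balanced-design
identity. The coverage experiment's estimand is the true difference
averaged over analyzed timepoints — the quantity both estimators target on
balanced designs — and uses a small effect because a steeply time-varying
difference triggers the paired-t over-coverage described above.

## Numerical and I/O choices

- Peak-list files are written at full round-trip precision (shortest
  representation) and parsed with a round-trip float parser, so
  write → parse is lossless and closely spaced jittered peaks can never
  collapse into duplicate rows through formatting. Result and uptake
  tables serialize with 8–10 significant digits.
- The parser validates eagerly with row numbers: nonpositive m/z, negative
  intensity, duplicate (group, m/z) rows, unknown or missing columns.
- Dataset assembly drops peptides missing either state (warning), takes
  the timepoint intersection by default, or errors under `strict` pairing;
  it is idempotent.
- A numerically exact regression fit (residual variance below a relative
  threshold of ~1e-20) is treated like the zero-variance paired case
  rather than dividing rounding error by rounding error.
- Rank-deficient designs raise a dedicated error naming the collinear
  term; per-peptide statistical failures are logged and skipped, never
  aborting a batch.
- Missing percent-D serializes as an empty field, never 0.

## Known limitations

- No envelope deconvolution: overlapping peptides must be resolved
  upstream.
- No kinetic (rate-constant) modeling, EX1/EX2 classification, or
  equivalence testing; the methods answer "is there a difference?", not
  "what is the exchange rate?".
- The m/z response mode requires a single shared charge state per peptide.
- The paired t's p-value floor under strongly time-varying differences
  (discussed above).
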