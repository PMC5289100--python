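# Methods

## Stimulus model

Every pixel of a noise-letter stimulus is generated by

    I(x, y) = I · [1 + n·N(x,y) + l·L(x,y) + m·n·M(x,y)·N(x,y)]

where `I` is the mean luminance (normalized, default 1.0, so all pixels lie
in [0, 2I]), `N` is a binary ±1 check-noise carrier, `L` and `M` are the
square-wave luminance- and contrast-modulation supports of the letter, `n`
is the carrier contrast (default 0.2), `l` the luminance amplitude (LM
letters, `m = 0`) and `m` the contrast amplitude (CM letters, `l = 0`).
Validity requires `|l| + n(1+|m|) ≤ 1`, which keeps every pixel in gamut.

**Square-wave convention.** `L` and `M` take the values 1 on letter ink and
0 on background (a `bipolar_modulation` option switches to −1/+1 without any
claim that this matches any particular apparatus). The unipolar convention
makes the background statistically identical for LM and CM stimuli
(carrier-only, Michelson contrast `n`), and inside a CM letter the carrier
contrast is `n(1+m)`. With `m = 0` a CM stimulus degenerates to pure noise.

**Modulation depths.** Acuity is manipulated through letter *size* at fixed
modulation, so `l` and `m` are free parameters; the defaults `l = 0.3`,
`m = 1.0` are clearly suprathreshold at `n = 0.2` while staying in gamut.

**Letterforms.** H, O, T, V are drawn on canonical square 5×5 stroke grids
(stroke width exactly one fifth of letter size, in the Sloan tradition);
each stroke cell expands to 3×3 noise checks by nearest-neighbour
replication, so a letter spans 15×15 checks. The grids are fixture data in
`stimulus.py`, documented cell by cell.

**Dynamics.** Noise is refreshed independently on every frame (default
60 Hz, configurable); per-frame seeds are spawned from one root seed, so a
movie is bit-reproducible. The `check_mean_luminance` report verifies the
defining property of CM stimuli — ensemble mean luminance equal to `I` both
inside and outside the letter — using checks × frames as the independent
statistical units (pixels within a check are perfectly correlated).

**Letter placement.** The letter is centred in a noise field whose side
defaults to twice the letter side. Images are kept in linear normalized
luminance; an optional 8-bit quantizer (256 levels on [0, 2I]) is applied
only when exporting PNGs. Display gamma, hardware calibration and real-time
presentation are out of scope.

## Viewing geometry

The minimum angle of resolution (MAR) of a letter is the visual angle of one
stroke: `atan(stroke_size / distance)`, with `logMAR = log10(MAR in
arcmin)`. One noise check occupies an integer number of 0.47 mm screen
pixels, so at a fixed distance only a discrete ladder of letter sizes is
achievable; `logmar_to_size` returns the achievable level nearest the
request, breaking exact ties toward the larger letter (conservative against
floor effects). The exact `atan` is used; at 4.5–9 m it differs from the
small-angle approximation only beyond the 6th decimal. The 9 m mirror path
of the LM condition is treated as a plain 9 m distance.

At these distances the achievable ladder is coarse: at 9 m the two smallest
letters sit at −0.269 and +0.032 logMAR, a 0.30 logMAR gap, and at 4.5 m the
gap between neighbouring sizes near threshold is ≈ 0.18 logMAR — far coarser
than the 0.125 logMAR staircase step. How the original apparatus realised
0.125 logMAR steps on its pixel grid is not documented, so pixel
quantization of staircase levels is **optional** here (`quantize_levels`,
default off): by default the staircase presents its nominal continuous
levels, which makes threshold recovery unbiased to a few hundredths of a
logMAR. With quantization on, presentation snaps to the nearest achievable
size, reversal levels are logged at the achieved values, and recovered
thresholds inherit a bias of up to roughly half the local grid gap;
observers whose true threshold falls below the one-pixel floor are censored
at the floor (their run ends at the trial cap with no reversals and is
flagged as not converged).

## Staircase

2-down/1-up: two consecutive correct responses lower the level by
0.125 logMAR, any error raises it by the same step, and the consecutive
counter resets after every step. The rule equilibrates where p(correct)
satisfies p² = ½, i.e. p = √0.5 ≈ 70.7 % (for an n-down/1-up rule,
p = 0.5^(1/n); the generalized counters are implemented). A reversal is a
level change opposite in direction to the previous change and is logged at
the level from which the change departs — symmetric for up and down steps,
the standard convention in the transformed up-down literature. Whether the
starting plateau contributes a "direction" before the first step is not
inferable from any description of such procedures; here the first step sets
the direction and can therefore never itself be a reversal.

A run ends at 8 reversals (or a 200-trial safety cap, flagged not
converged); the threshold is the arithmetic mean of the last 6 reversal
levels, and 4 runs are averaged into a session threshold (mean ± SE).
Letters are drawn uniformly with replacement; repeats are allowed. Start
levels default to 0.2 logMAR (LM) and 0.8 logMAR (CM), comfortably above the
corresponding group thresholds.

Monte-Carlo behaviour under the default observer (Weibull slope 0.08, see
below): runs take a median of ~24 trials, and the mean of many estimates
sits ~0.02 logMAR below the generating 70.7 % point — the well-known small
negative bias of short mean-of-reversals tracks started above threshold —
comfortably inside the ±0.03 logMAR recovery tolerance used in the tests.

`convergence_probe` measures the equilibrium percent-correct empirically:
it runs the update rule without reversal stopping for many trials (default
50,000, 500-trial burn-in) against a stationary observer whose 70.7 % point
lies on the level ladder, and reports the observed proportion correct at the
most-visited level. This is an observed frequency, not a read-off of the
observer model: had the track equilibrated one step away, the measured value
would be far from 70.7 %.

## Simulated observers

**Psychometric observer.** p(correct at x) = g + (1 − g − λ)·F(z), with
g = ¼ (4AFC), lapse λ = 0.01, F a Weibull in logMAR,
F(z) = 1 − exp(−ln2 · 10^z), z = (x − α)/β + z₀, and z₀ chosen so that
p(α) = √0.5 *exactly*. Anchoring at the staircase convergence point makes
staircase estimates directly comparable to the generating α. The slope
β = 0.08 logMAR gives psychometric functions of realistic steepness for
letter acuity (the function rises from near-chance to near-perfect over
roughly 0.25 logMAR).

**Template observer.** An image-domain demonstration observer: it
correlates a (zero-meaned) feature map of the stimulus with the four letter
supports and answers with the argmax (ties broken H < O < T < V; optional
Gaussian internal noise on the decision variables). With the linear
`pixel_correlation` rule the feature map is the luminance image itself —
sufficient for LM letters, but at chance on CM letters in expectation,
because a CM letter's expected luminance is everywhere equal to the
background's. With the `rectified_contrast_correlation` rule the map is
|luminance − I|, a local-contrast image on which CM letters are plainly
visible. This is the filter–rectify–filter logic of second-order vision
reduced to its minimal computational statement, and it is what the
conservation tests exercise; it is not a model of human letter recognition.

## Cohort generator

The synthetic cohort emulates the study design: groups `older` and
`younger`, 5 participants each, conditions LM/CM × monocular/binocular,
4 runs per condition. Per participant × condition a true threshold is drawn
Normal(cell mean, between-subject sd); each run jitters the observer's α by
Normal(0, run_sd) before the staircase. Defaults:

* cell means: the study's group condition means (logMAR) — older LM
  −0.12/−0.15, older CM 0.44/0.39, younger LM −0.18/−0.24, younger CM
  0.34/0.20 (monocular/binocular);
* between-subject sd: reconstructed per cell as SE·√5 from the reported
  group standard errors (0.02–0.07 logMAR);
* run_sd = 0.05 logMAR, a conventional within-session variability (no
  published value exists);
* neutral-density scenario: an 85N6 filter transmitting 19 % is modelled as
  a threshold shift of `nd_coefficient · log10(1/transmission)` logMAR with
  default coefficient 0, i.e. no effect of retinal illuminance — the
  interpretation supported by the original control experiment — rather than
  as image attenuation. `simulate_nd_control` re-tests the same simulated
  participants (identical true thresholds, fresh staircase randomness)
  with and without the filter, and `paired_nd_test` runs the paired
  comparison.

All randomness derives from one seed through per-(participant, condition,
run, session) spawn keys: cohorts are bit-reproducible and insensitive to
iteration order. Individual participant thresholds were never published, so
the between-subject and run-level variability are conventions; passing
recovery tests shows the estimation chain is unbiased under the assumed
Gaussian heterogeneity and stationary observers, not that real observers
behave this way (no learning, fatigue, lapses beyond the fixed rate, or
criterion drift are modelled).

## Analysis

Binocular summation ratio = monocular MAR ÷ binocular MAR =
10^(logMAR_mono − logMAR_bino); values > 1 mean binocular viewing improves
acuity. Ratios are computed per participant and then averaged (mean ± SE
per group × stimulus type) — the aggregation a per-participant table
implies. Because 10^d is convex, the mean of per-participant ratios exceeds
the ratio implied by group mean logMARs on heterogeneous data (Jensen); a
published mean ratio can therefore legitimately differ from the ratio of the
published group means, and both aggregations are provided
(`summation_table` and `summation_ratio` on cell means). Fold-differences
between groups are 10^(Δ logMAR), reported alongside the raw difference.

The mixed-design ANOVA (one between-subject factor, one within-subject
factor) is delegated to `pingouin.mixed_anova` behind the `mixed_anova`
surface, with balance checked first (no imputation); with two within levels
no sphericity correction is needed. The test suite validates it against a
hand-written textbook sums-of-squares decomposition. Reproducing any
particular published F statistic requires the per-participant data, which
exist only in external deposits; the package validates the computation, not
those numbers. Rounding for reported tables is half-up to 2 decimals.

## Problem sizes in tests

The test suite uses 2,000 staircase replicates per recovery point, 20
replicate cohorts for cell-mean recovery, 50,000 trials for the equilibrium
probe, 500-frame movies for luminance conservation and 1,000 trials for
template-observer accuracy — sizes at which Monte-Carlo standard errors are
several times smaller than the tolerances being asserted, while the whole
suite runs in well under a minute.
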