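# Methods

This note documents the models, conventions and numerical choices behind
the package; it is the reference for anyone asking *why* a default is what
it is, and what passing tests do and do not establish.

## Stimulus synthesis

Vowels are synthesized source-filter style. The voiced source is a unit
click train starting at sample 0 with period `round(fs / F0)` samples
(period rounding to the nearest sample keeps synthesis deterministic);
the whispered source is zero-mean unit-variance Gaussian noise from a
seeded generator. Four two-pole resonators act in parallel, one per
formant: poles at radius `exp(−π·BW/fs)` and angle `2π·F/fs`, with a
scalar numerator normalizing each resonator to unity gain at its center
frequency, and the four outputs summed with equal weights. This is the
minimal "appropriate numerator" choice that places the stated formant
peaks without imposing any additional spectral tilt; no source-spectrum
(glottal roll-off) compensation is applied, and none is claimed.

Tokens are 250 ms, ramped with 5 ms raised-cosine ramps whose endpoints
are exactly zero, and presented as two identical tokens separated by a
250 ms silent gap (0.75 s total). Level is purely digital: 70 dB maps to
an RMS of 0.05 full-scale, so a stated difference of x dB is reproduced
exactly as a factor `10^(x/20)` in RMS; absolute SPL is not calibratable
in software. Default sample rate is 48 kHz (configurable); analysis does
not depend on the hardware rate.

## Synthetic data generator

The generator is the package's stand-in for recordings: it produces the
statistical structure the analyses assume, with parameters that *are* the
study conditions rather than free dials.

**Trials.** A session varies one orthogonal feature (default: five F0
values 149–459 Hz) against two vowels, with balanced condition counts
before correction trials. Outcomes are Bernoulli with a configurable
p(correct); each error on a test trial is followed by one flagged
correction trial with the same stimulus; whispered probe trials occur at
a configurable rate (must lie in [0, 0.2]) and any response on them is
rewarded. Response times are right-skewed (0.5 s + lognormal, median
≈ 1.4 s) so the 1 s response-floor exclusion used by the matched analysis
has bite. Trial counts per condition default to ~10–20 per cell —
sufficient for the decoder's 5-trial floor and the population decoder's
8-per-vowel floor — and are configurable because the source experiments
only state those minima.

**Rates.** A unit's rate is
`max(0, baseline + Σ_f gain_f(value)·kernel_f(t) + choice/accuracy terms)`.
Kernels are half-cosine bumps (unit peak, two parameters: latency and
duration) — smooth, compactly supported, and sufficient to encode
feature-specific timing. Choice and accuracy terms use the same bump with
their own latencies (default 300 ms, when the behavioral signal
plausibly arises). Engagement suppression multiplies the evoked (not
baseline) rate by `engagement_scale` during stimulus presentation
[0, 1] s, matching suppression during but not before the sound; a
per-kernel `passive_latency_shift` lets the generator emulate delayed
feature information in passive listening. Spikes are drawn on
[−0.5, 1.5] s by thinning a homogeneous process at an analytic rate
bound (baseline + summed positive gains), which is exact for this rate
model. Each unit draws from its own stream spawned from the top-level
seed, so units are conditionally independent given the trial and adding
units never perturbs existing ones.

What the generator does **not** emulate: correlated noise across units,
non-Poisson spiking statistics (refractoriness, bursting), rate
adaptation across trials, and drift. Passing tests therefore show that
the analysis chain is correct and calibrated under its own assumptions —
not that real cortical data satisfy those assumptions.

## Single-unit decoder

Responses are spike counts in half-open bins tiling a half-open window
`[start, start + duration)`; bin width defaults to 10 ms (the grid's
duration quantum), with a single-bin count mode available. For each test
trial the template of its own class excludes that trial (leave-one-out);
other classes use all their trials. Distances are Euclidean on count
vectors (mean templates in counts/bin — rates would differ only by a
constant factor). Equidistant templates are resolved by a seeded uniform
draw; tied trials are processed in ascending trial order, one draw each,
which is the contract the brute-force equivalence tests rely on. Squared
distances are compared with a 1e-9 relative tolerance so exact rational
ties are not split by float rounding.

The window grid spans starts −0.5 to 1 s and durations 10–500 ms. The
default start step is 0.05 s, giving 31 × 50 = 1550 windows (the stated
window count); a 0.1 s step (800 windows) is also supported because the
two stated grid parameters are mutually inconsistent and both variants
are defensible. Windows apply to continuous trial time, so spikes in the
inter-token gap are included. Best cell: maximum performance, ties broken
by earliest start then shortest duration. Classes may be unbalanced above
the 5-trial floor; percent correct is the raw fraction over test trials
(the matched module handles balancing where it matters).

Sound-responsiveness is a paired sign-rank test of per-trial counts in
[0, 0.3) s versus [−0.3, 0) s at p < 0.05; all-zero difference vectors
are classified not responsive.

## Significance

The null for a unit's optimized performance shuffles the decoded labels
across trials and repeats the full procedure *including window
optimization* (default 100 shuffles; fewer than 10 is refused). This
matters: maximizing over 30–1550 windows inflates null performance well
above nominal chance, so an unoptimized null would be anti-conservative.
The null is summarized by a Gaussian fit (mean, unbiased sd) and
p = upper-tail probability of the observed performance, clamped to
[1e-10, 1]; the fit buys resolution below 1/n_shuffles at the cost of
assuming approximate normality of the null (empirically the null of
grid-maxima is mildly right-skewed, which makes the test slightly
conservative — the measured type-I rate on null units runs a little
under the nominal 0.05). A null sd of exactly 0 returns p = 1 unless the
observed value exceeds the degenerate null value. "Informative" is a
strict p < alpha with alpha = 0.05, with no correction across units —
reported raw to match the source analysis, recorded here rather than
endorsed.

The dual-feature permutation shuffles unit identity of one flag set
(10^4 iterations) and counts units informative about both features. The
default p is ties-inclusive (fraction of permuted counts ≥ observed):
the strictly-above variant returns p = 0 in the degenerate case where
every permutation reproduces the observed count, which would be absurd;
ties-inclusive is conservative and available alongside `ties="strict"`.
The permutation null is exactly hypergeometric, which the tests verify.

## Timing and engagement

The timing statistic is the best window's center (start + duration/2);
start-time and duration variants are available as columns, not separate
pipelines. Paired contrasts (same units, two features or two states) use
the sign-rank test and report the median paired difference; unpaired
contrasts use the rank-sum test and the difference of medians — the sign
convention is first-group-minus-second. Three or more groups use
Kruskal–Wallis; post-hoc pairwise comparisons use Tukey–Kramer on mean
ranks (studentized range on `SE = sqrt(N(N+1)/12 (1/ni + 1/nj))`,
infinite df), implemented here because no installed routine offers the
rank-based multcompare step directly. Firing-rate time courses use 100 ms
bins at 50 ms steps; baseline normalization defaults to the *ratio*
to the mean rate in the 450 ms before onset ("relative to" read as
division), with a difference mode behind a flag; zero-baseline units are
flagged NaN and excluded by callers.

## Matched datasets

Outcome is a deterministic function of vowel and choice in a two-choice
task, so only 4 of the 8 vowel × choice × outcome combinations can occur.
The matched set balances these 4 feasible cells at N = the post-exclusion
minimum cell count (N ≥ 5 enforced, limiting cell named in the error),
which balances all three marginals and fixes behavioral percent correct
at exactly 50%. Exclusions: whispered trials, levels at or below the
floor (60 dB default, 70 for stricter subjects), corrections,
no-responses, and responses within 1 s of first-token onset — the
second-token anchor (adds 0.5 s) is available behind a flag because the
two plausible anchors differ in the source descriptions. Error-trial
decoding uses fixed templates built from all correct trials; a unit with
no error trials raises an explicit signal rather than returning a
vacuous result.

## Population decoding

Within a (default 100 ms, single-bin count) window, each unit's LOCV
distances yield an estimate and weight `w = 1 − d_min/Σd_j`, bounded in
[1 − 1/n, 1]; all-zero distance vectors take the lower bound with a
seeded estimate. Weights are summed per class across members; argmax
(seeded tie-break) is the population estimate. Units need ≥ 8 trials per
vowel; correct and error trials are both included. Populations are drawn
from the pool of best single-unit vowel decoders on correct trials (up to
74 units); for size k, 100 combinations are sampled without replacement,
enumerated exhaustively when fewer exist (at k = pool size there is
exactly one). Roving 100 ms windows at 50 ms steps give the performance
time course; peak time is the center of the first maximum. Between-
dimension timing differences are tested by permuting the dimension labels
of population peak times (10^4 iterations, two-sided).

## Behavior metrics

Constancy: per-value percent correct with binomial tests against 50%,
plus a logistic regression of correctness on the orthogonal feature
value; constancy is declared when the feature coefficient is
non-significant (p ≥ 0.05). Generalization: performance over the first
L = 1, 2, … trials from first exposure, tested one-sided above chance
against a permutation null (10^4 iterations; randomized required
responses) at p < 0.001, or the exact binomial tail in analytic mode —
for an error-free record the smallest significant L is 10, since 0.5^10
is the first power below 0.001. A sliding-window variant is provided
behind a flag. Long-term reference performance resamples contiguous
windows from the whole record. Single units are those with strictly less
than 1% of inter-spike intervals below 1 ms.

## Problem sizes and the acceptance script

`scripts/acceptance.py` recomputes five quantities from scratch at desk
scale: chance calibration of the shuffled-label decoder (one untuned
15 Hz unit, 100 trials, fixed 0–250 ms window, 200 shuffles; two- and
five-class labels), the type-I rate of the permutation framework (200
untuned units, 20 trials per class, a reduced 30-window grid, 100
shuffles each, alpha = 0.05), the ceiling of the population decoder (74
units with moderate vowel tuning — gains chosen so mean single-unit
decoding sits in the 65–75% band — 20 trials per vowel, 0–100 ms
window, best sampled combination at maximum size), and the exact 50%
behavioral performance of a matched set built from a 72%-correct
synthetic subject. The reduced grid and these cohort sizes were chosen
as the smallest problems at which the calibration properties are
measurable with useful precision; all randomness descends from the
single `--seed` argument.

## Known limitations

- The Gaussian null fit is an approximation to a skewed maximum
  distribution; it is mildly conservative and exact calibration at
  alpha = 0.05 should not be expected to the third decimal.
- LOCV mean-template decoding has a small below-chance bias under the
  null (excluding the test trial shifts its own-class template away);
  at the default trial counts the bias is well under one percentage
  point, and it is reported, not corrected.
- The generator's independence and Poisson assumptions make population
  decoding saturate faster than correlated real populations would.
- No family-wise correction across units or features anywhere, by
  design fidelity to the source analysis.
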