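# Methods

`dnmp-decode` re-implements, end to end, a pseudo-simultaneous population
decoding analysis of medial prefrontal cortex (mPFC) ensembles recorded while
rats perform a T-maze delayed non-match to position (DNMP) task. Because the
original tetrode recordings are not publicly deposited, the package pairs the
analysis with a synthetic-study generator that emulates the statistical
structure the analysis assumes; every claim the test suite makes is therefore a
claim about recovery of *planted* structure, not about the biology itself.

## The task and its synthetic emulation

A DNMP trial has two stem traversals: a forced **sample** run (one goal arm
blocked), a 20 s delay, then a free **choice** run rewarded only at the arm
opposite the sample. Trials are separated by a 40 s inter-trial interval.
Sessions hold 18 trials (a longer run is truncated to its first 18, the
emulated inclusion rule); forced-turn sequences are balanced 9 L / 9 R with no
more than three consecutive same-direction turns. The generator constructs
sequences by sequential random choice under an exact completability rule, so
every draw satisfies both constraints (uniformity over valid sequences is not
claimed, matching the pseudo-random hand-sequencing it emulates).

**Position.** The stem (127 × 9 cm) is tracked at 30 Hz. x advances at a
constant running speed (default 30 cm/s — a placeholder exposed in config,
since the emulated conditions do not pin a speed distribution), and the lateral coordinate y
follows a logistic divergence toward the chosen arm — amplitude 3 cm, onset at
80% of the stem, slope 0.3 cm⁻¹ — plus 1 cm s.d. Gaussian tracking noise,
anchored to y = 0 at stem entry. Sign convention: y > 0 toward the right goal
arm. Real trajectories diverge smoothly and stay near the midline until
late stem; the logistic form is a modelling convenience with that shape, and
amplitude/onset/slope are all configurable.

**Spiking.** Each unit has a baseline rate drawn lognormally with
μ = ln 1.86 and σ = 0.4806 — the two parameters are pinned jointly by the
emulated rate-histogram conditions (median 1.86 Hz; 56% of units below
2 Hz).
Units fire Poisson background spikes at baseline throughout the session
(traversals, delay and ITI alike), so the *session-averaged rate*
(total spikes / session duration) estimates the baseline; this is what the
2 Hz high/low split consumes. Within a stem bin on a traversal, the count is
Poisson(baseline × gain(phase, trajectory, bin) × occupancy). Spike times
within a bin are uniform (each spike attaches to a random tracking sample of
its bin, jittered within half a sample period), sufficient for bin-level rate
recomputation; no finer spike-timing structure is claimed or emulated.

**Planted modulations.** A modulation spec selects a fraction of units
(optionally restricted to a true rate class) and multiplies their rate by a
gain in chosen bins/phase/trajectory. The study-analog defaults plant (a) a 2×
trajectory gain at the T-junction bin on sample runs in 40% of all units and
(b) a 2× prospective trajectory gain at the second stem bin on choice runs in
40% of *high-rate* units — the locus is fully configurable because the
corresponding empirical effects are findings, not assumptions. Behavioural
errors occur with probability 0.1 per trial (choice repeats the sample arm);
error flags are redrawn until each session retains ≥ 15 correct trials and ≥ 6
correct trials per trajectory so that every session supports the decoding
problems defined below.

**What the generator does not emulate:** bursting and refractoriness,
rate drift within sessions, correlated noise across units, goal-arm/return-arm
kinematics, LFP. Passing tests therefore demonstrate correctness of the
*analysis machinery* under the stated statistical structure, not robustness to
real-data pathologies.

## Binning and rates

The stem is partitioned into seven equal-width bins; bin 7 is the T-junction.
Boundary samples belong to the downstream bin and the far stem end to bin 7.
Per traversal, occupancy is (samples in bin)/30 Hz; spikes map to the tracking
sample nearest in time (tracking is coarser than spiking; no interpolation);
rate = count/occupancy. Traversals with a zero-occupancy bin are flagged and
excluded rather than imputed. Lateral position and speed (central-difference,
unsmoothed; a boxcar is available but off) are binned identically. The
session-stability screen correlates per-cluster mean waveform peak amplitudes
between the first and last 10 minutes (Pearson r across clusters).

## Pseudo-simultaneous permutation-style decoding

For a binary problem (task phase ±1, trajectory within a phase, or a
phase × trajectory pair that co-occurs on correct trials), only correct trials
enter. Per unit — independently, from its own session — n trials per class are
drawn without replacement (n = 15 for pooled task phase, 6 otherwise: the
smallest correct-trial counts across sessions), forming a class-balanced
2n × M matrix for one stem bin. A linear soft-margin SVM (hinge loss, C = 1,
bias term, no internal standardization; libsvm via scikit-learn) is scored by
leave-one-out cross-validation; a decision value of exactly zero predicts +1.
The draw repeats `n_iterations` times; chance is the distribution of LOOCV
accuracies over `n_shuffles` uniform label permutations of the *final*
iteration's matrix (a per-iteration-null variant exists behind a flag).
Significance is z = (mean accuracy − null mean)/null s.d. with two-tailed
normal p; per-bin permutation-style tests are not multiplicity-corrected (they
are planned comparisons against a single chance reference), while the classic
fixed-trial variant (each unit's first k eligible trials, one LOOCV) applies
Bonferroni α/7 across bins. The significant-iteration fraction counts
iterations with two-tailed p < 0.05 *above* the null mean. Optional per-unit
[0,1] min–max scaling (constant columns → 0) is provided as the
scale-sensitivity control.

**Small-sample chance bias.** Leave-one-out on a class-balanced matrix makes
the held-out trial's class the training minority, so label-shuffled accuracy
centres *below* 50% when rows are few relative to units: measured ≈ 47% for
12 × 10 matrices, ≈ 49% for 30 × 100, but ≈ 41–43% for the 12-row × 100-unit
matrices the trajectory problems produce. The bias affects true-label and
shuffled accuracies identically, so the z-test remains calibrated — on
no-signal cohorts the per-bin two-tailed rejection rate stays below nominal
(the method is conservative by construction). Interpretations should use the z against the shuffled reference, never
the raw distance from 50%.

**Fidelity profiles.** The full profile is 1000 iterations / 1000 shuffles
(and 5000 subsets per ensemble size); the test profile — used by the test
suite and the acceptance script — is 100/100 (and 200 subsets), which leaves
the expected z unchanged and only widens its Monte-Carlo error. Problem sizes
in the suite (100–240 unit cohorts) were chosen as the package's standard
desk-scale conditions.

## Ensemble scaling and forecasting

The neuron-adding curve draws, per ensemble size, random unit subsets
(independent across sizes, one fresh pseudo-population draw per subset) and
records mean/s.d. LOOCV accuracy. Sizes and accuracies (%) are transformed
decibel-style, v′ = 10·log₁₀ v (base 10; the slope is then interpretable
per decade of ensemble size), an OLS line y′ = a + b·x′ is fit (SSE and adjusted R²
reported in transformed space), and predictions map back through
min(100, 10^((a + b·10·log₁₀N)/10)) — a power law accuracy = 10^(a/10)·N^b
capped at 100 only beyond the data. The minimal significant ensemble size is
the smallest size whose (mean or predicted) accuracy clears the full
population's shuffled distribution (two-tailed p < α above the null mean) —
that null is the only one the procedure constructs.

Two numerical caveats govern extrapolation, and the scaling tests are designed
around them: near the 50% chance floor and the 100% ceiling the true curve
departs from any power law, so fits should use sizes above the floor region
and horizons below saturation; and the forecast inherits the Monte-Carlo error
of the fitted means amplified by extrapolation leverage, so the subset depth
is chosen to make the forecast standard error (~0.6 accuracy points at 1200
subsets/size) small against the 2-point agreement tolerance used in the
scaling-recovery check.

## Behavioural and single-unit statistics

Behavioural measures use the session as the unit of observation (class × bin
fixed-effects two-way ANOVA with interaction; Type II sums of squares, which
coincide with the classical decomposition on balanced designs); follow-up
paired t-tests per bin carry a Bonferroni-corrected α (0.05/7 ≈ 0.0071 across
stem bins; 0.025 for two designated bins) and pooled-s.d. Cohen's d. A unit is
"trajectory-modulated" when its trial-level two-way ANOVA (trajectory × bin)
shows a trajectory main effect or interaction at α = 0.05; follow-ups at the
designated bins (default 2 and 7) use α = 0.025. Because a unit's left and
right trials have no natural pairing, the i-th correct left trial is paired
with the i-th correct right trial (truncated to the common count).
Rate-constant units are untestable and excluded from denominators; group
proportions are reported per rate class, with empty classes undefined rather
than zero. At the emulated firing-rate regime (~1 spike per bin), the
single-bin 2× gain is detected in only ~30–50% of units — a power property of
the trial counts, documented here because the suite asserts detection above
the (separately verified, ≤ 10%) type-I rate rather than near-certain
detection; near-certain detection (> 0.9) holds at gain 3 in ≥ 4 Hz units.

## Determinism and orchestration

One master seed drives everything: per-stage and per-bin generators are
spawned from `numpy.random.SeedSequence`, so a bin's decoding result is
identical whether or not other bins are computed, and pipeline reruns
reproduce every table byte for byte. The pipeline (`simulate → bin → decode →
scale → stats`) writes CSV tables, a `summary.json` of headline quantities,
and a manifest (seed, config hash, stage runtimes); `scripts/acceptance.py`
recomputes the package's headline quantities from scratch at the test-fidelity
profile. Configs are strict YAML (unknown keys rejected) mirroring frozen
dataclasses.

## Known limitations

Pseudo-simultaneous pooling removes trial-to-trial co-fluctuations between
units recorded in different sessions, so decoding accuracies are best read as
an upper bound relative to truly simultaneous ensembles. The LOOCV chance
bias above makes raw accuracies incomparable across matrix shapes. The
power-law forecast is a descriptive extrapolation: it has no mechanism for
saturation and must not be read beyond the regime where the log-linear fit is
tight. The generator's independence assumptions (Poisson counts, independent
units, i.i.d. tracking noise) are idealizations chosen to make every planted
effect exactly recoverable in expectation.
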