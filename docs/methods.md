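# Methods

## Stimulus spaces

Directions live on a 16-point grid (multiples of 22.5°, degrees in all I/O,
radians internally). The streaming set contains 16 gratings (100% contrast),
plaids at dOri ∈ {22.5, 45, 67.5, 90, 112.5, 135, 157.5}° × 16 pattern
directions, and one blank — 129 conditions, with a counting window of 1/3 s
matching the 3 Hz update of streaming sequences. The classic set contains 16
gratings and 16 directions of dOri = 135° plaids (50% contrast per
component) plus a blank, presented for 1 s with 5 repetitions by default.
Streaming presentations are treated as independent trials. A plaid's
component directions are pattern ± dOri/2; on this grid they land on the
half-step 11.25° lattice.

## Synthetic data

**Ideal cells.** The underlying direction tuning bump is a peak-normalised
von Mises, `f(θ) = exp(κ(cos θ − 1))`, with concentration κ (default 3,
giving a half-width at half-height near 40°; κ is a user parameter because
the idealisation fixes no analytic form). A pattern cell's plaid grid
repeats `f` at every dOri; a component cell's rows average the two bumps at
±dOri/2. Every row is rescaled to a constant row sum over the 16 directions
(a discrete stand-in for constant area under the direction curve), so the
only dOri dependence is the one the component geometry forces.

**V1 presets.** Two deterministic mean-V1 profiles serve as the model's
front end. Both are component-dominated (V-shaped, κ = 3) with a smooth
dOri gain `0.65 + 0.35·cos(dOri)` that suppresses wide-angle plaids
(cross-orientation suppression increasing with dOri), centred at 0° and
normalised to a unit maximum grating response. The `"middle"` preset adds
`0.35 · exp(−((dOri−90)/45)²) · exp(4(cos θ − 1))` to the plaid rows: a
boost confined to the pattern ridge at intermediate dOri values, emulating
the transient enhancement of V1 pattern responses seen mid-development. The
amplitudes were chosen so the young preset classifies strongly as component
while the boost stays small relative to the V arms.

**Trial generation.** Spike counts are Poisson with mean
`(model rate + baseline) × window`; blanks carry baseline only. Everything
is deterministic given a seed. Ground-truth populations draw parameters
uniformly within `DEFAULT_PARAM_RANGES` (K_E, K_I ∈ [0.5, 3], I ∈ [0.2, 1.5],
T_PSS ∈ [0.5, 2.5], Resp_max ∈ [5, 30] Hz) — comfortably inside the fitting
bounds, spanning sharp-to-broad integration and moderate-to-strong
null-direction inhibition at plausible peak rates; preferred directions are
drawn from the grid and baseline defaults to 0 Hz so recovery tests probe
the stimulus-driven model alone.

**Latency emulation.** Streaming extraction at the wrong latency mixes the
counting window with the neighbouring (random) stimulus. The emulator
attenuates each condition's expected rate toward the sequence-mean rate by
the non-overlap fraction `|Δlatency|/window`, and generates counts by
inverse-CDF sampling from one shared uniform draw per trial so that
extractions at different latencies are strongly correlated — as re-binnings
of a single recorded spike train are. The latency estimator scans a grid
(default 0–150 ms in 10 ms steps) and returns the latency maximising the
between-condition variance of mean responses, ties broken toward the
smallest value. What these passing tests show is that the estimator finds
the generating latency under this attenuation model; real streaming data
add adaptation and sequence correlations the emulator does not contain.

## Response extraction and screens

Classic-paradigm responses are baseline-corrected by subtracting the blank
rate (the stand-in for the pre-stimulus rate); corrected rates may be
negative and are kept as-is for ANOVA screens but rectified at 0 before any
ratio-based index (DSI, OSI, relative plaid responses), which require
nonnegative rates. Streaming rates are raw counts/window — the 2 Hz and
1.5 Hz screen thresholds refer to raw rates. DSI = 1 − R(null)/R(pref) and
OSI = 1 − R(orth)/R(pref) use exact grid points (null = pref + 180°,
orthogonals = pref ± 90°) and gratings only. Screens use one-way
fixed-effects ANOVAs on per-trial rates; streaming inclusion requires the
dOri = 90 plaid ANOVA at p < 0.01, best grating > 2 Hz, best dOri = 90
plaid > 1.5 Hz, OSI > 0.6 and DSI > 0.7 (strict inequalities).

## Pattern/component classification

The dOri curve g (direction-average per dOri) and two direction tuning
curves — the pattern curve (gratings and plaids entered at their pattern
direction) and the component curve (each plaid entered at both component
directions, gratings at their own; accumulated on the 32-point half-step
lattice where all component directions land) — combine into 2D predictions:
each prediction row is the relevant direction curve rescaled so its
direction mean equals g(dOri). Both predictions therefore share the data's
dOri marginal, allowing peak height to vary with dOri while the direction
structure distinguishes pattern from component. The combination rule is a
design choice (the construction is conventionally inherited from earlier
work without an explicit normalisation); the ideal-cell limits — noise-free
pattern/component profiles classify as pattern/component in both paradigms —
pin it down and are tested.

Partial correlations use the standard first-order formula and are verified
against a residual-regression oracle to 1e−10. Degenerate inputs: collinear
predictions raise; a data vector identical to one prediction (noise-free
profiles) yields a pairwise correlation of exactly 1, so the data-side
pairwise correlations are nudged to ±(1 − 1e−15) and the end-to-end scorer
clips partial correlations to |r| ≤ 1 − 1e−9 before the Z transform, mapping
exact matches to a large finite Z (≈150 at N = 112). `fisher_z` itself keeps
the strict |r| < 1 contract. Classification uses the one-sided p = 0.1
normal critical value, 1.28: pattern iff Z_P − Z_C > 1.28 when Z_C ≥ 0, or
Z_P > 1.28 when Z_C < 0; component by the mirrored rule; the pattern index
floors negative Z values at 0 before subtracting. The streaming correlations
use the 7 × 16 plaid grid only (N = 112); gratings enter only through the
tuning curves.

## The two-stage pathway model

**V1 stage.** The mean profile (centred, unit grating max) is symmetrised —
entries equidistant from the preferred direction are averaged per row —
replicated to 16 channels by circular shifts, and made perfectly direction
selective by opponency: each channel's output is
`max(0, P − P(o)·O)` with O the opposite channel's response and P(o) the
channel's own null-grating response. This forces an exactly zero response to
each channel's anti-preferred grating (tested as an invariant).

**PSS stage.** Channel responses are combined with
`w(d) = exp(K_E(cos d − 1)) − I·exp(K_I(cos(d − 180°) − 1))` relative to the
neuron's preferred direction. Both von Mises components are peak-normalised,
so I is directly the inhibitory/excitatory peak ratio and I = 0 disables
inhibition. Negative concentrations (allowed by the bounds) give inverted or
broad components. W_exc and W_inh are the discrete sums of the two
components over the 16 channel directions; W_inh is exactly linear in I.
The linear drive is rectified at 0 and normalised by its maximum over the
stimulus set before the exponent: `rate = Resp_max · L̂^T_PSS`, making
T_PSS shape-only and Resp_max the peak rate, consistent with its
(0.8, 1.2) × empirical-max bounds. Zero drive maps to zero rate for every
T_PSS (including T_PSS = 0, by convention); blanks are zero.

**Fitting.** The Poisson log-likelihood sums `k ln λ − λ − ln k!` over every
trial, with λ floored at 1e−6 spikes/window to stay finite. Per-condition
sufficient statistics (count sums) make each evaluation O(conditions).
Bounds: K_E, K_I ∈ [−5, 6], I ∈ [0, 2], T_PSS ∈ [0, 3], Resp_max within
(0.8, 1.2) × the empirical maximum mean rate. Optimisation is bounded dual
annealing, 3 independent restarts of at most 5000 evaluations each, seeded
deterministically; the best restart is kept. The preferred direction is not
fitted: it is estimated as the circular vector average of the grating tuning
curve snapped to the grid — at 10 repetitions the plain argmax regularly
lands one grid step off on the tuning plateau, which severely corrupts fits,
while the vector average is consistent for the symmetric model tuning.
Fit quality is the Pearson correlation between mean empirical and model
rates across non-blank conditions; fits below 0.5 are conventionally
removed.

**Identifiability.** The likelihood constrains only the *shape* of the net
weight function (the drive is max-normalised), and a difference of two
broadened von Mises components can reproduce nearly the same shape at a much
smaller amplitude. The likelihood surface therefore has a near-flat ridge
along which the component decomposition — and with it W_inh and W_exc —
varies several-fold while their ratio is roughly preserved. At 10
repetitions per condition this is the dominant error source for per-neuron
W_inh: refining the optimum from the true parameters walks to the same
displaced solution for a few log-likelihood units, and the scatter shrinks
markedly at 100 repetitions. T_PSS and the overall response shape (hence
the pattern index and its sign) are well identified. Population-level
comparisons of W_inh remain meaningful; per-neuron point estimates should be
treated as noisy.

## Population perturbation experiments

Manipulations apply one common additive change to every neuron (an increment
of I for inhibition, a decrement of K_E for excitation), clipped per neuron
at the parameter bounds and found by bisection so the population-mean W_inh
(or W_exc) hits the target within 1e−6 relative tolerance; K_I is never
adjusted. A common shift is the simplest rule consistent with "increase the
inhibition parameter", and it is isolated so per-neuron or multiplicative
alternatives are pluggable. The V1 swap replaces the shared bank and keeps
all PSS parameters. Population summaries are computed on noise-free model
responses (normalised by mean grating response, aligned to 0°, averaged);
pattern indices of model neurons are therefore systematically larger in
magnitude than trial-based ones, a convention kept deliberately. A
manipulated neuron whose plaid responses are entirely suppressed cannot be
scored and contributes NaN to the index distribution (the median ignores
it), mirroring a failed responsiveness screen.

## Statistics

Welch's t uses unpooled variances with
`d′ = |mean₁ − mean₂| / sqrt((s₁² + s₂²)/2)` (an explicit convention; d′ has
no single standard formula). The resampling median test draws 1000 resamples
of the smaller group's size, with replacement, from the larger group; the
null distribution is resample median minus the larger group's median, and
the p-value is the two-sided exceedance of the observed median difference
with a +1/(n+1) continuity correction (two-sided is the conservative default
and a flag exposes the one-sided variant). Its type-I error runs slightly
above nominal (≈7–9% at α = 0.05 for 15 vs 60 samples) because subsampling
the larger group underestimates the median's sampling variability for the
smaller group — a property of the procedure itself, reported as measured.
Two-way ANOVA uses Type II sums of squares (group sizes are unbalanced in
the intended use). Rank-sum comparisons delegate to scipy under the same
result container.

## Problem sizes and limitations

Default test-scale sizes: 50 neurons × 10 repetitions for parameter
recovery, 100 model neurons for population experiments, 2000/500 null
simulations for calibration — sizes at which every reported quantity is
stable to reruns at different seeds except per-neuron W_inh (see
Identifiability). The synthetic generator emulates direction-tuned Poisson
spiking with exact condition structure; it omits adaptation, correlated
variability, eye movements, recording artefacts and cell-to-cell
heterogeneity in tuning width, so passing tests demonstrate the pipeline's
correctness on its stated model, not performance on recorded data.
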