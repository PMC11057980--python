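# Methods

## Model family

Reactive balance is modelled as delayed linear feedback of the center-of-mass
(CoM) "balance error" — displacement *d* (cm), velocity *v* (cm/s) and
acceleration *a* (cm/s²) relative to the base of support — onto a measured
neurophysiological output. Every variant evaluates one half-wave rectifier
around the full pre-rectification sum (a single `max(0, ·)`, modelling net
excitatory drive to the motor pool or the envelope-like cortical trace):

| variant | output | loops | free parameters |
|---|---|---|---|
| mSRM | EMG envelope | kinematics @ λ_bs | 3 gains + λ_bs = 4 |
| hSRM-kin | EMG envelope | + kinematics @ λ_c | 8 (6 with accel-only loop 2) |
| hSRM-N1 / hSRM-β | EMG envelope | + measured Cz or β @ δ_c | 6 |
| cSRM-N1 / cSRM-β | Cz or β trace | kinematics @ τ_c | 4 (2 accel-only) |

λ_bs is the subcortical loop delay, λ_c ≥ λ_bs the transcortical loop delay,
τ_c the afferent delay to cortex, and δ_c = λ_c − τ_c the efferent delay
applied to a measured cortical predictor. Parameter counts count every
freely optimized quantity once.

Sign conventions. The N1 is a negative-going potential; the cSRM-N1
reconstruction is computed on the negated trace (so rectification is
meaningful) and reported with polarity −1. Kinematic gains are constrained
non-negative for the agonist in a backward translation; cortical-signal
gains (k_N1, k_β) are sign-free, since a negative potential must be allowed
to drive positive muscle activity through a negative gain.

All signals live on a common analysis grid — 1000 Hz on the −400…+1400 ms
EMG epoch, time zero at perturbation onset — with linear-interpolation
resampling. Delays are continuous parameters: fractional-sample shifts use
linear interpolation, and samples that would need pre-epoch history take
the first epoch value (quiet-stance assumption; constant extension avoids
spurious edge transients).

## Parameter identification

The objective over the fit window (default 0–1300 ms, i.e. 1301 samples at
1 kHz, configurable) is

J(k, λ) = μ_s ∫ e² dt + μ_m max|e| + μ_k kᵀk,

with e the reconstruction error, the integral a trapezoidal sum with dt in
seconds, and the gain penalty regularising inactive channels. The weight
ratio 1 : 1 : 10⁻⁶ is interpreted on the **sample-sum** scale — i.e. the
squared-error term is Σe² over window samples, implemented as μ_s = fs =
1000 on the seconds-scale integral. Applied literally to a time integral in
seconds, "1 : 1" would make the squared term ~1000× smaller than the
max-error term; the objective then degenerates into a minimax problem with a
near-flat valley along the collinear displacement/velocity gain direction,
in which the squared error varies several-fold at sub-percent cost
differences — gains become poorly determined and any SSR-based downstream
statistic turns into optimizer-path noise. On the sample-sum scale the two
error terms have comparable magnitude and the fit is well-posed. (The
`srm_objective` function itself keeps the seconds-scale API; only the
default fitting weights encode this interpretation, and both are
configurable.)

The optimizer (deterministic given the configuration, and never returning a
point worse than its start):

1. **Seeding.** The loop delay is scanned on a coarse grid (λ_bs: 60–180 ms,
   τ_c: 40–140 ms, λ_c: 120–350 ms, δ_c: 0–250 ms, 10 ms steps); at each
   grid point non-negative least squares on the delayed predictors gives
   candidate gains, ranked by the smooth squared-error part.
2. **Variable-projection anchor.** The model is linear in the gains for a
   fixed delay, so the smooth part is profiled exactly: an inner
   (non-negative) least-squares solve per delay, a dense 1 ms outer scan and
   a bounded golden refinement. This canonical, path-independent candidate
   guards against trust-region stalls on the delay axis.
3. **Smooth refinement.** Trust-region least squares with Jacobian-adaptive
   scaling (gains are O(10⁻³)–O(10⁻¹), delays O(10²)), alternated with a
   bounded scalar minimisation along each delay axis — fractional-sample
   interpolation puts a kink at every sample boundary, which can otherwise
   collapse the trust region 1–2 ms short of the optimum, leaving a large
   error spike at the acceleration transient.
4. **Polish and selection.** A quasi-Newton (L-BFGS-B) pass on unit-scaled
   parameters minimises the full objective including the nonsmooth max-error
   term; among all candidates whose cost lies within 5% of the best found,
   the one with the smallest squared error is reported (ties in this band
   reflect the residual flatness of the max term, and the squared-error
   corner is the solution every downstream SSR-based statistic assumes).
   Tolerances follow the protocol (step 10⁻⁹, objective 10⁻⁷, ≤10⁵
   evaluations). Bounds: kinematic gains [0, 100], signal gains [−100, 100],
   delays at their scan spans.

Double-loop variants are fitted in stages: (1) the short-latency loop alone;
(2) the long-latency loop against the signed stage-1 residual (the kinematic
second loop keeps its own rectifier there; a cortical-signal term is fitted
linearly, as it enters the model inside the single outer rectifier and its
gain is sign-free); (3) joint refinement from the concatenated estimates
within ±10% gain and ±10 ms delay boxes. Because rectification of the summed
loops breaks exact superposition, the separate residual fits are only an
initial decomposition: before stage 3 the estimates are refined by
block-coordinate descent on the exact joint objective (loop-2 block, then
loop-1 block, repeated until the joint cost stops improving). Without this
step the stage-1 fit absorbs part of the second burst and the ±10% box
cannot recover the generating parameters; with it, noiseless recovery is
exact to optimizer precision. The final selection additionally considers the
nested candidate — the single-loop solution with a silent second loop — so a
second loop is reported only when it actually improves on the nested fit.
Near-zero stage estimates receive a ±10⁻⁶ absolute floor on their refinement
box (otherwise degenerate); an absent second loop is reported with near-zero
gains and flagged.

## Goodness of fit and model selection

R² is the coefficient of determination of an intercept-including OLS
regression of observed on reconstruction (equal to the squared centered
Pearson correlation, hence affine-invariant in the reconstruction and equal
to 1 for perfect anti-correlation — a documented property of this
definition). VAF is 100 × the squared *uncentered* correlation,
scale-invariant but offset-sensitive. Degenerate inputs (zero variance /
all-zero) report NaN rather than a value.

AIC = N·log(SSR/N) + 2·P with natural log, N the fit-window sample count
and P the free-parameter count; SSR = 0 returns −∞ with a warning. For
comparison, AIC is computed per fit (participant × magnitude) and summed
across the identical trial set per variant; the lowest total wins, and a
preference is declared only when the margin over the runner-up is ≥ 2.

## Synthetic data generator

The generator emulates the study conditions, not arbitrary data:

- **Platform profiles.** Trapezoidal-velocity backward translations — the
  only two-phase profile matching a (displacement, peak velocity, peak
  acceleration) triplet simultaneously — evaluated analytically per sample,
  so the printed magnitudes (small 7.7 cm / 16.0 cm/s / 0.23 g; medium
  13.8 / 29.0 / 0.415; large 20.15 / 40.5 / 0.59, the midpoints of the
  height-adjusted ranges) are reproduced exactly. g = 981 cm/s². Backward
  is the negative direction; magnitudes are absolute values.
- **CoM plant.** A stabilised linear second-order plant
  x″ = −K·x − B·x′ − a_platform (platform frame), K = 20 s⁻², B = 6 s⁻¹,
  integrated from rest by exact zero-order-hold discretisation.
  Participants in the protocol do not fall, so the plant must return the
  balance error toward zero; the acceleration keeps a sharp onset-locked
  transient, which is what makes the loop delays identifiable.
- **Responses.** EMG (normalized envelope domain), Cz (μV, polarity −1) and
  β (dB, polarity +1) traces are produced by the forward models at drawn
  ground truth (λ_bs ∈ [90, 120] ms, λ_c ∈ [180, 280] ms, τ_c ∈ [60, 100]
  ms; gains log-uniform over ranges putting the small-perturbation envelope
  peak at O(0.5)), plus Gaussian noise with sd(t) = σ₀·ref + σ_prop·|clean|
  (σ₀ = 0.01, σ_prop = 0.05 by default; ref = 1 for normalized EMG, the
  trace peak otherwise). EMG noise is clipped at zero; noise lives in the
  envelope domain because that is what the models are fitted to. The
  second-loop gain scales with magnitude (×0.6 / 1.0 / 1.4), emulating the
  growth of the second burst with balance challenge. The default design is
  17 participants × 3 magnitudes × 8 trials, with every seed derived from
  one base seed.

What the generator does **not** emulate: raw (carrier-band) EMG except for
filter-chain tests, realistic EEG spectra, inter-trial kinematic
variability, stepping responses, or antagonist muscles. Passing recovery
tests therefore demonstrate the estimator's correctness under the model's
own assumptions — identifiability on real recordings additionally depends
on how well those assumptions hold.

## Signal conditioning

- **EMG.** 35 Hz high-pass, mean subtraction, half-wave rectification,
  40 Hz low-pass; both filters 6th-order Butterworth applied
  forward-backward (zero phase lag). Envelopes are normalized to a maximum
  of 1 across all trials within each participant × side group, and
  summarised as trapezoidal integrals over 75–200 / 200–300 / 300–500 ms.
- **CoM velocity.** Savitzky-Golay smoothing-derivative, 3rd order. The
  nominal 48-sample window has no centre sample; the implementation uses 49
  (configurable) and takes the derivative from the SG convolution itself,
  which reproduces polynomial derivatives up to order 3 exactly on interior
  samples.
- **CoM acceleration.** Horizontal ground-reaction force over body mass,
  minus platform acceleration (platform-relative, cm/s²).
- **N1.** Minimum of the Cz epoch in 100–200 ms minus the mean of the
  −400…−100 ms baseline; latency at that minimum, earliest sample on ties.
- **ERSP / β.** Complex Morlet transform with a Gaussian envelope truncated
  to the 256 ms analysis window, cycles rising linearly from 3 at 6 Hz to
  23 at 50 Hz; only time points where the full window fits are kept (no
  zero-padding). Power is expressed in dB and referenced per frequency to
  the mean baseline dB (equivalently, divided by the geometric-mean baseline
  power), so the baseline mean is 0 dB by construction; dividing by the
  arithmetic-mean power before taking dB would bias single-trial baselines
  by ≈ −2.5 dB (Jensen's inequality on log power). β power averages the
  ERSP across 13–30 Hz and is summarised as bin means (dB) over
  50–150 / 150–250 / 250–500 ms.

## Validation design and known limitations

Validation is property-based: brute-force oracles for every forward model
and metric; parameter recovery on self-generated data; model-selection
recovery (summed AIC prefers the generating architecture, and does **not**
prefer the richer model on single-loop data, where its 2·ΔP penalty
dominates); and byte-level determinism of the full pipeline. Recovery
experiments fit the 8-trial condition average — the unit the objective is
defined on in the protocol.

Limitations worth knowing:

- **AIC over-selects a delay-bearing extra loop on noise-dominated
  residuals.** When the data contain no second loop, the fitted long-latency
  loop still captures, in effect, the best of the ~10–20 effectively
  independent delay positions in its scan range — an expected AIC gain of
  roughly 2·ln(dictionary size) ≈ 5–9 units per fit, systematically above
  the 2·ΔP = 4 penalty (burst-concentrated noise inflates it further, since
  AIC assumes homogeneous noise). Summed-AIC comparison therefore prefers
  the hierarchical model on a substantial fraction of purely single-loop
  synthetic datasets. This does not arise for comparisons that add *linear*
  parameters (the accel-only vs full-kinematics comparisons), where the
  capture is ~χ²(ΔP) < 2·ΔP, nor in the regime where the residual is
  dominated by model misfit rather than noise (R² ≈ 0.6–0.85 on real
  recordings), which dilutes noise capture below the penalty. Detection of
  a genuinely present second loop is unambiguous (margins of ~10⁴ AIC
  units on synthetic data).
- Local optimization with grid seeding carries no global-optimality
  guarantee; multimodality in the delay is handled by the grid and the
  variable-projection scan, not proved away.
- No uncertainty quantification on parameters (no bootstrap/Bayes), and no
  cross-validation — model comparison is AIC only, as in the protocol.
- The EEG feature chain starts from a clean epoch; artifact rejection,
  re-referencing and channel handling are out of scope.
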