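# Methods

## The model

A long heart-rate record is reduced to an unmarked point process (the R-peak
times), from which RR intervals and instantaneous rate samples
`y_i = 60 / RR_i` (bpm) are derived. The marginal distribution of the `y_i`
is modelled as a univariate finite Gaussian mixture

    p(y) = Σ_k π_k N(y; μ_k, σ_k²),   Σ_k π_k = 1,  0 < π_k ≤ 1.

The mixture is a model of the *amplitude* distribution only; it deliberately
ignores temporal ordering. Multimodality of that distribution arises from
regime structure in the record (different autonomic states dominating at
different times), which is exactly what the component decomposition is meant
to expose. Components with weight above a threshold (default 0.05) are
reported as *dominant*; the recurring empirical finding is three dominant
components, interpreted against the three major rate-shaping inputs
(sinoatrial pacemaker, sympathetic and parasympathetic branches).

Heart rate is positive while Gaussians have full support. The fitted
mixtures place negligible mass below zero for physiological data, so no
truncation is applied; generative sampling warns if more than 0.1% of draws
are non-positive, and series constructors clip at the positive floor.

## Greedy EM

Fitting maximizes the log-likelihood `L = Σ_i log p(y_i)` (always evaluated
by log-sum-exp). Rather than fixing K and restarting EM from random
configurations, the mixture is grown one component at a time:

1. **Start** with the optimal one-component mixture: sample mean and biased
   sample variance (the closed-form MLE).
2. **Candidate insertion.** For each existing component, 10 candidate means
   are drawn from the data with probability proportional to that component's
   responsibilities; each mean is tried at two starting variances (one half
   and one eighth of the parent's). Every candidate `(α, μ, σ²)` — with
   mixing weight initialized at `2/(K+2)` — is refined by *partial EM* (at
   most 50 iterations) that updates only the candidate against the frozen
   current mixture `(1−α)·f_K + α·φ`. The candidate with the highest embedded
   log-likelihood wins. Two starting scales matter in practice: with a single
   large starting variance the partial EM occasionally collapses every
   candidate back onto its parent and a clearly profitable insertion is
   missed.
3. **Full refit.** The accepted (K+1)-component mixture is refined by
   standard EM (tolerance 1e-8 relative, at most 200 iterations). EM's
   monotonicity is asserted in the tests, not assumed.
4. **Stopping.** Growth stops when (a) no candidate improves the likelihood,
   (b) K reaches `k_max` (default 15, not reached in practice), or (c) the
   stage's log-likelihood gain fails the model-selection criterion. The
   default criterion is a **BIC margin**: an insertion must gain more than
   `1.5·log N` log-likelihood units (the BIC cost of three extra
   parameters). A pure likelihood threshold (`criterion="loglik"`, relative
   tolerance 1e-5) is also available, but overfits measurably: on data drawn
   from a true three-component mixture the candidate search keeps finding
   spurious splits worth a few log-likelihood units each, and those splits
   drain weight from the genuine components. Genuine structure is two to
   three orders of magnitude above the BIC margin, so the criterion costs
   nothing in sensitivity.

Degenerate inputs: data whose total spread is at numerical-noise level
(ptp ≤ 1e-9 relative) return the single-component fit immediately — splitting
float rounding artifacts into "clusters" is meaningless. During EM a variance
floor of 1e-4 × var(data) prevents likelihood singularities; a collapsing
component is reset to the global mean/variance and the event logged. Output
components are sorted by decreasing weight, ties broken by ascending mean, so
results are deterministic given the seed; all stochastic steps (candidate
draws, sampling, simulators) take explicit seeds.

The `HeartRateMixture` → `HeartRateMixtureResults` wrapper reports
approximate standard errors from single-Gaussian asymptotics at effective
sample sizes `N_k = N·π_k` (`se(μ_k) = σ_k/√N_k`, `se(σ_k²) = σ_k²√(2/N_k)`,
`se(π_k) = √(π_k(1−π_k)/N)`). They ignore component overlap and are meant as
reporting scale, not formal inference.

## Spectral analysis

Beat-aligned series are irregular, so the PSD route is: cubic-spline
resampling onto a uniform grid (default 4 Hz — comfortably above the Nyquist
need of the 0.40 Hz HF band edge), then Welch's averaged periodogram (Hann
window, 50% overlap, per-segment linear detrending, one-sided density
normalization). The zero-frequency bin is dropped: it carries no variance
after detrending and the slope fit needs `f > 0`. The density normalization
is contractually tied to Parseval: the integrated PSD of white noise matches
the signal variance within 5% at N = 2¹⁴ (tested).

Band powers integrate the density by the trapezoidal rule with linear
interpolation at band edges; defaults are the standard short-term HRV bands
VLF 0.003–0.04 Hz, LF 0.04–0.15 Hz, HF 0.15–0.40 Hz (the physiological
anchors: vagal modulation reaches up through the HF band, sympathetic
modulation acts below ~0.15 Hz). The LF/HF ratio is reported as undefined
(`None`) when HF power vanishes rather than as infinity. The log–log slope β
is an ordinary least-squares line on `(log₁₀ f, log₁₀ P)` over a configurable
range (default 0.003–0.1 Hz), exact on noiseless power laws; zero-power bins
are excluded with a logged count and at least five usable points are
required. A Lomb–Scargle periodogram is included for irregular series but is
not used by any default pipeline — it is not a consistent PSD estimator.

When spectra are averaged across subjects, power is averaged linearly (not
log-transformed) before any slope fit.

## Simulators

Both simulators exist to answer one question: does a physiologically
plausible beat generator, driven by exactly three inputs, reproduce the
three-dominant-component decomposition? Their defaults are therefore
calibrated to that target, and the calibration reasoning is recorded here.

**IPFM.** The modulating signal `v(t) = r₀·(1 + m(t))` with

    m(t) = a_s sin(2π f_s t) + a_p sin(2π f_p t) + ξ(t)

is integrated (trapezoidal rule, fixed step ≤ 1/(50·f_p), default 0.01 s); a
beat fires whenever the integral crosses a multiple of the threshold R, the
crossing time refined by linear interpolation within the step. Defaults:
r₀ = 1.1 Hz (≈66 bpm), R = 1, f_s = 0.1 Hz, f_p = 0.25 Hz, a_s = 0.25,
a_p = 0.05, noise sd 0.07.

The noise ξ(t) is an Ornstein–Uhlenbeck process (correlation time 3 s,
exact discretization), not per-step white noise. This is a physical, not
cosmetic, choice: the integrator averages the input over a whole beat
(~0.9 s), so white noise at the integration step contributes essentially
nothing to rate variability, leaving the sharp arcsine-shaped marginal of
the bare oscillators — which a BIC-guided mixture fit resolves into five or
more narrow components. Autonomic fluctuations are band-limited on the scale
of seconds; with the OU term the per-beat rate distribution is the oscillator
structure smoothed by a genuine Gaussian, and the fitted decomposition
becomes the slow oscillator's two turning-point lobes plus a centre component
— stably three. The dominant sympathetic amplitude (a_s ≫ a_p) encodes the
same fact in amplitude: the slow swing carries the bulk of rate variability.

Analytic anchors kept exact: constant input with R = 1, r₀ = 1 Hz produces
intervals of exactly 1 s (to integrator precision ≪ 1e-6), and the zero-noise
beat count equals the integrated input divided by R to ±1.

**Switching model.** Each of three inputs (sinoatrial, parasympathetic,
sympathetic) follows

    dI_j/dt = −g_j (I_j − P_j(t)) + η_j ,

where `P_j(t)` is a random step function: levels drawn uniformly within a
per-input range, dwell times exponential (memoryless — the simplest reading
of "random step-like"). The interbeat interval relaxes toward the τ-weighted
combination `Σ_j w_j I_j` with the mean feedback rate, and one interval is
emitted per beat at the beat's onset. All updates use the exact exponential
solution per grid step (preferred levels zero-order-held on the grid, OU
noise by its exact discretization, the RR forcing by matched-exponential
convolution terms), so the zero-noise trajectory agrees with a fine-step
Runge–Kutta solve to integrator precision rather than to first order in dt.

Defaults: weights (0.5, 0.3, 0.2), g = 2 s⁻¹, mean dwell 3 s, noise sd 0.06,
preferred ranges 0.60–1.20 s (sinoatrial), 0.80–1.30 s (parasympathetic,
lengthening intervals), 0.45–0.75 s (sympathetic, shortening them);
dt = 0.05 s, intervals clamped to the physiological window (0.2, 4.0) s with
an error above 5% clamping. Switching on the seconds scale follows the
stochastic-feedback tradition this model family comes from, and matters
statistically: a 2-hour record then contains thousands of level episodes, so
the rate marginal is close to its asymptotic shape — a central bulk with two
shoulders spanning roughly 55–100 bpm — instead of a lumpy handful of
regimes whose fitted component count would fluctuate from seed to seed.

A structural note: because the interval is a weighted *sum* of three
independent unimodal inputs, its marginal is smooth and cannot be literally
trimodal; the three-component result on this simulator is about how the
mixture decomposes the bulk-plus-shoulders shape, not about three visible
histogram peaks. This mirrors the real-data situation, where the component
count comes from the fit, not from counting histogram bumps by eye.

**Cohorts.** Per-subject parameters are jittered multiplicatively
(lognormal, sd given by `jitter`, mean-one correction applied) around the
base configuration; per-subject seeds derive deterministically from the
master seed and subject index. With `jitter=0` all subjects share parameters
but not realizations.

## What the synthetic data do and do not show

The simulators emulate: multimodal/structured bpm marginals produced by a
small number of physiological inputs, LF/HF-band oscillatory content (IPFM),
and regime switching (switching model). They do not emulate: circadian
sleep/wake structure of true 24-hour recordings, respiratory coupling,
ectopy/artifacts, or the long-range-correlated 1/f^β background of real HRV
(i.i.d. generative sampling from a fitted mixture reproduces the amplitude
distribution, never the spectrum — a flat spectrum is expected from such
resampling, and the package makes no contrary claim). Passing the synthetic
battery therefore validates the estimator chain, not any clinical claim
about real recordings.

## Pipeline conventions

Per-subject analysis fits the mixture on the native per-beat bpm values (no
prior resampling — the marginal is what is being modelled, and uniform
resampling would re-weight time, not beats), then computes the spectrum on
the resampled series. Cohort aggregation aligns components by weight rank
(rank 1 = heaviest), reports cross-subject means with standard errors of the
mean, and correlates rank-1..3 component variances with VLF/LF/HF band
powers across subjects — Pearson and Spearman both reported, with unadjusted
and Holm-adjusted p-values; only subjects with at least three dominant
components enter the correlation, and exclusions are logged. Correlations on
degenerate (zero-variance) columns are reported as NaN rather than raised.

## Problem sizes used in validation

The validation battery uses ten 2-hour records per simulator (≈8000 beats
each), twenty recovery replicates at 10⁴ samples, fifty randomized
monotonicity datasets of a few hundred points, and spectral checks at 2¹³–2¹⁴
samples. These sizes put every Monte-Carlo tolerance (3 standard errors,
8-of-10 and 18-of-20 frequency bounds) in a regime where the checks are
sharp, while a full run of the suite plus the acceptance script stays in the
minutes range on a single core.

## Known limitations

- The greedy candidate schedule is one faithful instantiation of the greedy
  EM family; other candidate constructions can land in different local
  optima on near-degenerate data.
- The approximate standard errors understate uncertainty for strongly
  overlapping components.
- The switching model's combination rule (relaxation toward a τ-weighted sum
  of inputs) is one defensible reading of the model family it abstracts;
  competing nonlinear combination rules would change the marginal's shape.
- Band-power estimates inherit the usual Welch bias/variance trade-off; with
  the 4096-sample default segments the VLF band retains few independent
  frequency bins in short records.
- Real 24-hour recordings were not available; nothing here quantifies how
  the method behaves on genuine Holter data.
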