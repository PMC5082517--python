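# Methods

This note records the models, parameter choices and numerical decisions
behind `ictomark`, and what the synthetic benchmark does and does not
establish.

## Preprocessing

Segments are band-passed 0.5–70 Hz (Butterworth, order 4) with a 48–52 Hz
band-stop against power-line interference.  All filters run
forward-backward (`sosfiltfilt`), i.e. zero-phase with effective order 8:
phase estimates feed the connectivity stage, so filter phase distortion is
not acceptable.  Filter edge transients are handled downstream by
discarding 5% of samples at each end before any phase statistic.

Power spectra use Welch's method with 2 s Hann windows and 50% overlap
(0.5 Hz resolution).  Every channel's spectrum is divided by one constant
— the mean over channels of the frequency-integrated power — so the
normalized spectrum is invariant to global amplitude scale (skull
thickness, electrode impedance) while between-channel ratios are
preserved.

Narrow bands are alpha = 8–13 Hz and low-alpha = 6–9 Hz.  The functional
network and the model's channel variances are both computed on the
low-alpha-filtered segment; using one band for both keeps the model
internally consistent (the network's phase lags and the variances describe
the same oscillatory component).  Whether variances should instead come
from broadband data is genuinely open; the low-alpha choice is this
package's convention.

## Functional-network inference

The phase-locking factor between channels a, b over T samples is
`PLF = |Σ_t exp(i(φ_a − φ_b))| / T`; its circular mean angle is the lag.
Phases are analytic-signal (Hilbert) phases of the narrowband signal.

Significance: for each surrogate realization, each channel's phase series
is circularly shifted by an offset drawn uniformly from [1 s, T − 1 s];
shifting preserves each channel's marginal dynamics while destroying
inter-channel alignment.  With 99 surrogates the per-pair threshold is the
95th order statistic, giving an exact 5/100 exceedance probability under
exchangeability.  Thresholds are per-pair by default; a pooled global
threshold is available (`per_pair=False`).  Measured on independent
two-channel null segments the false-edge rate is ≈ 6% at the 5% level —
the small excess comes from the wrap discontinuity a circular shift
introduces into a non-circular phase series.  Pairs sharing a channel are
correlated, so whole-montage false-edge counts fluctuate more than a
binomial count would.

Edges additionally require the lag to lie in (ε, π − ε) with ε = 0.1 rad:
a single cortical source seen by two electrodes (volume conduction)
produces strong locking at exactly zero (or π) lag, and the generator's
mixing option confirms that a dominant common source is rejected by this
guard.  The mean degree of the resulting binary graph is the network
biomarker (higher in the patient group).

## Dynamic network model

Each channel is modelled as a large Kuramoto population with Lorentzian
frequency spread of half-width Δ and internal coupling k; the
Ott–Antonsen ansatz reduces each population to one complex order
parameter, giving per node i

    dz_i/dt = (iω₀ − Δ) z_i + (H_i − conj(H_i) z_i²)/2,
    H_i     = k_i z_i + g Σ_j A_ji exp(i lag_ji) z_j.

The reduction preserves the operative mechanism — a critical internal
coupling k_c = 2Δ beyond which a node synchronizes, with closed-form
isolated-node steady state |z*| = √(1 − 2Δ/k) — while remaining cheap and
analytically checkable (the integrator is validated against that closed
form to 1e-3).

Defaults: Δ = 0.5 (so k_c = 1), ω₀ = 2π·7.5 rad/s (low-alpha centre),
θ_sync = 0.8, dt = 1 ms, burn-in 5 s and scoring horizon 30 s for
single-subject fits.  Integration is fixed-step Heun with a
renormalization guard at |z| = 1; an optional additive complex white-noise
term gives a stochastic mode (default off — the default model is fully
deterministic and bit-reproducible given the seed, which sets initial
phases only).  Initial conditions are |z| = 0.1 with node-indexed random
phases, so batched and single-node runs coincide exactly.

Local coupling is tied to data as k_i = K·σ²_i with σ²_i the low-alpha
channel variance and K a free scale optimized by the classifier over a
log-spaced grid spanning 0.1·k_c/max σ² to 10·k_c/mean σ² (20 points by
default) — from "every node far subcritical" to "typical node an order of
magnitude supercritical".

**Seizure likelihood.**  S_m clamps node m's coupling at k_drive = 2·k_c,
integrates past burn-in, and averages, over the *other* nodes and sampled
times (every 10 ms), the indicator |z_j| > θ_sync.  The clamped node is
excluded because the quantity of interest is emergent spread; including it
(`include_driven=True`) merely adds a near-constant offset.  Driving via a
coupling-strength increase (rather than a state perturbation) matches the
mechanism the biomarker is meant to probe.

**Global gain g.**  g is the one network-level free parameter.  It is set
by a calibration rule, not by fiat: scan a gain grid on a reference
(control) cohort at K = k_c/mean σ² and keep the smallest g whose
cohort-mean S lands in 0.1–0.3.  On the package's default synthetic
control cohort this gives g = 0.1 (mean S = 0.127).  Small gains matter
qualitatively: large g makes recruitment all-or-none (S collapses to
{0, 1} and carries little per-subject information), while the calibrated
gain leaves recruitment graded.

**Cohort-scale horizons.**  For whole-cohort grid evaluation the pipeline
integrates 2 s burn-in + 8 s scoring at dt = 1 ms with an 8-point K grid.
The deterministic model reaches its attractor within ~1/Δ = 2 s, so the
shorter horizon changes S negligibly (halving dt moves S by < 0.01) while
keeping a 40-subject × 8-K × 19-channel evaluation to roughly a minute.

## Dual-threshold classification

For a biomarker with known polarity, th1 is the cut with maximal
sensitivity under zero training false positives, th2 the cut with maximal
specificity under zero training false negatives.  Cuts sit at the midpoint
of the gap between the two order statistics realizing each optimum; if no
value lies beyond the constraint boundary the cut is placed half a median
gap outside the data range.  Exact control/patient ties at a boundary are
resolved strictly — the 100% requirement wins and the cut moves past the
tied value.  A subject beyond both cuts is "IGE", below both "normal",
otherwise "uncertain"; sensitivity/specificity count only unequivocal
outcomes.

Leave-one-out evaluation re-optimizes everything per fold.  For the model
biomarker, the scored channel and K are chosen per fold and per objective
from the precomputed (subject, channel, K) table; ties on the training
objective are broken by the widest class-separation margin (then lowest
channel/K index), which is deterministic and transfers better than an
arbitrary grid-order pick.  Both objectives may select different
(channel, K), in which case the test subject is judged against th1 with
objective-1 values and th2 with objective-2 values.

## Biomarker comparison

Three-way outcomes are scored 2 (correct) / 1 (uncertain) / 0
(misclassified) — any strictly monotone coding yields the same ranks — and
compared with the Friedman test using mid-ranks and the standard tie
correction, computed separately for the patient and control cohorts (never
pooled).  An all-tied matrix leaves the statistic undefined and raises
explicitly.  A seeded within-row permutation variant is provided for small
cohorts; the χ² reference is the default.  On heavily tied 30-subject
ordinal data the χ² approximation holds its nominal 5% level to within
about ±2 percentage points.

## Synthetic data: what it emulates, and what it does not

Each synthetic channel is an alpha-band phase oscillator (Kuramoto sine
coupling with fixed pairwise lags, phase diffusion 2 rad/√s, 0.1 Hz
intrinsic-frequency spread) plus 1/f background noise, rescaled exactly to
a per-channel target variance.  Defaults: 19-channel 10–20 montage, 256 Hz,
20 s.  Because the source *is* a coupled phase-oscillator system, the
generator provides exact ground truth for the quantities the pipeline
estimates (which pairs couple, at what lag and strength).

Cohorts draw per-subject parameters around a base: alpha peak ~ N(10.5,
1.0²) Hz for controls, coupling graphs Bernoulli with lognormal-jittered
density (baseline 0.12, σ = 0.5), lognormal channel-variance jitter
(σ = 0.5).  The patient arm shifts the alpha peak by −1.2 Hz, multiplies
coupling density by 1.25 and variance by 1.8.  These effect sizes were
chosen to reproduce the qualitative clinical picture — each single
feature overlaps heavily between arms (the comparator biomarkers sit near
chance at the individual level), while their conjunction through the
model biomarker remains discriminative — with the group difference carried
mainly by variance-driven local coupling.

Not emulated: volume conduction is off by default (an instantaneous mixing
matrix can be enabled to exercise the zero-lag guard); no eye-blink/EMG
artifacts, no re-referencing effects, no biophysical head model, no
nonstationarity beyond phase diffusion.  Consequently, passing tests show
that the pipeline recovers the structures it is designed to measure under
its own generative assumptions — they do not certify performance on
clinical EEG, where artifact content, reference choices and broadband
coupling all intervene.

## Numerical details and degenerate inputs

* Surrogate thresholds need `alpha_level·(n_surrogates+1) ≥ 1`
  (≥ 19 surrogates at the 5% level); fewer raise.
* Constant channels have no phase and raise; broadband input to the phase
  stage warns.
* All-zero recordings make spectrum normalization undefined and raise.
* `k_drive ≤ k_c` is a configuration error (the drive must cross the
  synchrony threshold).
* `t_sim` must cover at least 10 intrinsic periods.
* EDF output rounds each channel's symmetric physical range up to 5
  significant digits so the header re-parses exactly; round-trip error is
  bounded by one 16-bit quantization step.

## Known limitations

* The surrogate null is mildly anticonservative (≈ 6% at the 5% level, see
  above); per-pair thresholds are not corrected across the 171 pairs of a
  19-channel montage, matching the group-level origin of the method.
* S is a deterministic functional of the inferred graph; subjects whose
  networks percolate from most channels saturate near S = 1, compressing
  the biomarker's upper range.
* The leave-one-out (channel, K) search optimizes extreme-value training
  objectives on ~40 subjects and will overfit on small cohorts; the
  uncertain band absorbs much of that variance by design.
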