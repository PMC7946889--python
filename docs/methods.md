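# Methods

`lamicsd` implements a complete analysis chain for laminar
extracellular recordings from sensory cortex — multi-trial local field
potentials (LFP) from a linear probe spanning the cortical depth — and a
synthetic-recording generator that provides ground truth for every stage.
This note documents the estimators, their parameters and numerical
conventions, what the generator does and does not emulate, and the design
choices made where the procedure was genuinely open.

## Current-source density

The one-dimensional CSD is the discrete second spatial derivative of the
field potential θ along the depth coordinate z,

    CSD(z) ≈ [θ(z + nΔz) − 2 θ(z) + θ(z − nΔz)] / (nΔz)²,

with Δz the contact spacing (0.05 mm by default) and n the differentiation
grid (default 1). Before differencing, depth profiles are smoothed with a
Hamming-weighted average over 7 channels (a 300 µm spatial kernel),
weights normalized to unit sum so constant and affine profiles pass
unchanged. Both smoothing and differencing extend the profile by 4 virtual
channels per end using the straight line through the outermost two
contacts — the minimal linear boundary rule; it reproduces affine profiles
exactly and gives every physical channel a CSD value. Sinks
(transmembrane influx) are negative.

`grid_n = 1` on the smoothed LFP is the default because the smoothing
already sets the effective spatial scale; both are arguments.

## Columnar measures

From single-trial CSD of the *unsmoothed* LFP (smoothing would leak charge
across the column boundary and bias the residue):

* `AVREC(t) = Σᵢ |CSDᵢ(t)| / n` — overall columnar current-flow magnitude;
* `RelResCSD(t) = Σᵢ CSDᵢ(t) / Σᵢ |CSDᵢ(t)|` — the signed residue of
  sinks and sources, defined as 0 when no current flows. Values away from
  zero indicate unbalanced currents, attributed to synaptic input relayed
  laterally into the recording cylinder.

Layer-resolved quantities use the smoothed CSD: RMS per channel over the
200 ms stimulus window, then averaged across the layer's channels (never
RMS of the channel-averaged trace, which cancels antiphase channels).

Layer assignment is configuration, not inference. The default 32-channel
map assigns I/II → channels 1–6, III/IV → 8–13, Vb → 15–20, VI → 23–28
(0-based, half-open spans), leaving the pial contact, the layer
transitions and white matter unassigned — as an experimenter marking
layers from the sink pattern would. The gaps also matter quantitatively:
with directly adjacent spans the 300 µm smoothing kernel mixes a
noticeable fraction of each layer's signal into its neighbor's trace,
which biases every per-layer measure downstream. The map is overridable
per dataset (YAML).

## Onset latency and electrode stability

Sink onset latency per layer is the first post-stimulus time at which the
trial- and layer-averaged CSD falls below baseline mean − 2 SD
continuously for more than 5 ms — the same sustained-threshold criterion
used for response detection (one shared implementation; the choice to
reuse it for latencies is a documented convention). Electrode stability
across conditions is assessed by reducing each condition to a depth
profile (per-channel mean over the first 50 ms after onset, averaged over
trials) and Pearson-correlating the two profiles at integer channel shifts
within ±5 channels (±250 µm); per-layer amplitude changes leave the peak
at (or within one channel of) zero lag, whereas electrode drift moves it.

## Frequency tuning

The best frequency (BF) is the tone maximizing granular (III/IV) layer
RMS, ties broken toward the lower frequency. Tuning curves are binned by
octave distance d = round(log₂(f/BF)) into five bins (−3–4, −1–2, BF,
+1–2, +3–4 octaves); |d| > 4 is excluded. The response bandwidth (Q40dB,
responses measured at 40 dB above threshold) counts the stimulus
frequencies whose trial-averaged trace passes the 2 SD / >5 ms criterion,
times the octave spacing of the grid; contiguity around BF is not required
(the readings coincide for unimodal tuning). Detection is restricted to
the stimulus period (onset to +250 ms): late spontaneous excursions are
not tone-evoked responses. The baseline is the final 100 ms before onset.
The layer-symmetry index LSI = (I/II − Vb)/(I/II + Vb) on layer RMS is
positive for supragranular dominance, antisymmetric and bounded in
[−1, 1]; it is undefined (NaN) when both inputs vanish.

## Spontaneous columnar events

Events are peaks of the single-trial AVREC exceeding
median + 3 SD, with at least 150 ms between peaks (closer peaks merge,
keeping the larger; `scipy.signal.find_peaks` provides exactly this
semantics). Event duration is the width of the supra-threshold excursion
containing the peak — the package's definition, stated here because none
is standard. When a recording is cut into 6 s traces the threshold
statistics are taken over the whole recording ("the whole spontaneous
trace") and passed to the per-trace detector; a per-cut threshold is
scale-free and detects spurious peaks on event-free cuts. The SD window
is configurable; whole-trace is the default reading.

Spontaneous metrics are RMS over each full 6 s trace: per-layer CSD RMS,
AVREC RMS and RelResCSD RMS.

## Multitaper spectra

Spectra use K = 5 orthonormal Slepian (DPSS) tapers on 600 ms epochs with
time–bandwidth product NW = 3 and no padding: frequency spacing
1/0.6 s ≈ 1.667 Hz, concentration half-bandwidth W = 5 Hz, retained grid
1–100 Hz, each spectrum normalized to unit sum over the retained grid.
The *evoked* estimator averages complex spectra across trials within each
taper before squaring (only phase-locked energy survives; by the triangle
inequality it never exceeds the total-power estimate bin-wise), then
averages power across tapers. The *spontaneous* estimator averages power
per trial and taper (induced plus evoked energy). Epochs are demeaned;
the evoked epoch starts at stimulus onset (200 ms tone + 400 ms).

The group comparison computes, per frequency bin, a paired t across
matched subjects on the normalized power (t on pre − post, so negative t
means more power after treatment), with Benjamini–Hochberg control at
Q = 0.1 across the 60 retained bins of a layer. An option to treat
subject × taper as samples exists but is off by default — it inflates the
effective n.

When reading BH output, note what FDR control promises: with a handful of
true rejections present, the step-up threshold rises and isolated false
bins elsewhere appear with substantial probability *by design*. A
band-limited effect is therefore read at the estimator's resolution: a
run of at least 3 adjacent significant bins (the 5 Hz half-bandwidth);
sub-resolution singletons are the permitted false discoveries.

## Conditional Granger causality

Layer traces (layer-averaged CSD per trial) are compared under a vector
autoregression of order p: the full model regresses each target on the
past of all k series; the reduced model for source j omits j while
keeping the remaining k − 2 series as conditioning variables. The causal
estimate is F[i, j] = ln(var ε′ᵢ / var εᵢ) ≥ 0 (negative finite-sample
values are clipped to 0 and flagged).

Estimation follows the autocovariance route: the full model is fitted by
solving the Yule–Walker equations of the pooled empirical autocovariance
(the LWR / multivariate Durbin estimate — solved directly as the small
block-Toeplitz system; trials are demeaned individually and never
regressed across their boundaries; the biased per-trial normalization
keeps the sequence positive definite). This fit is moment-matching: its
implied autocovariance (companion-form discrete Lyapunov equation,
extended by the Yule–Walker recursion) reproduces the empirical sequence
up to lag p exactly. Reduced models are solved from the implied
sub-autocovariance at the same order p — the reduced autoregression of
the defining equations; a `reduced_order` argument can deepen the lag
window to absorb the moving-average structure of the marginalized
process. One reduced solve per excluded source yields the residual
variances of all its targets, so k solves cover all k(k−1) edges.

Order selection minimizes AIC(p) = ln det Σ̂_ML + 2pk²/N over 1..max_order
(default 20, i.e. 10 ms of history at 2 kHz), comparing all candidates on
the identical sample. Preprocessing takes the first temporal derivative
per trial and runs augmented Dickey–Fuller checks per series
(statsmodels, fixed lag depth 10); series still failing at α = 0.05 are
flagged, not rejected. Traces that are stationary by construction (the
generator's VAR realizations) are analyzed without differencing —
over-differencing plants a moving-average unit root and the resulting
misspecification biases are structure-dependent, which contaminates
null-edge comparisons.

A direct route — both models refitted by pooled OLS — is kept as an
independent cross-check. The two routes estimate the same quantity but
differ in finite samples by trial-windowing terms of order p over the
trial length (≈0.3–1 % relative at 10 × 600 samples); they agree to
better than 0.1 % on long realizations, and the identity reduction (no
series removed) is exact to machine precision.

The group comparison takes a paired t on ln F per edge across subjects
(clipped zeros excluded pairwise; fewer than 3 usable pairs flags the
edge untestable), BH-corrected at Q = 0.05 over the 12 off-diagonal edges
of the four-layer network, with the signed direction of change reported.
The critical BH cut-off is data-dependent and reported per run.

## Shared statistics

`bh_correct` implements the step-up rule exactly: p-values ranked
ascending, critical values (i/m)·Q, rejection of every rank up to the
largest i with p(i) ≤ (i/m)·Q; the critical p is the largest rejected
p-value. `paired_t` is the standard paired Student t with df = n − 1 and
two-sided p; zero-variance differences are flagged rather than silently
propagated.

## Synthetic laminar recordings

The generator is phenomenological — no compartmental or volume-conductor
forward model — but it is constructed so that the *pipeline*, not the
generator, recovers every pattern:

* **Evoked trials.** Each layer contributes a charge-balanced spatial
  kernel (Gaussian sink flanked by source lobes inside the layer's span,
  normalized to unit mean absolute amplitude, summing to ~0) times a
  gamma-shaped temporal transient (≈5 ms rise, ≈30 ms decay, peaking
  16 ms after the layer's onset latency), scaled by layer gain ×
  Gaussian-in-octaves tuning around the best frequency. Latencies default
  to III/IV ≈ Vb ≈ 20 ms, I/II 32 ms, VI 35 ms — the feedforward
  ordering. Default grid: 32 channels at 50 µm, 2 kHz, 200 ms tones at
  40 dB above threshold inside 800 ms trials (onset at 200 ms), 8 tones at
  one-octave spacing from 250 Hz to 32 kHz.
* **Broadband ripple.** Each temporal kernel carries a deterministic
  broadband component (low-passed at 120 Hz, decaying envelope, ~0.6 of
  the transient peak, an independent realization per layer and animal).
  It stands for the phase-locked fine structure of real evoked responses
  and keeps the evoked spectrum signal-dominated over the whole 1–100 Hz
  grid, which in turn makes normalized spectra invariant under pure gain
  changes — without it, every noise-floor bin's normalized share moves
  deterministically whenever a gain changes, and the paired comparison
  flags bins all over the grid.
* **Lateral input.** A spatially unbalanced (all-sink) kernel centered on
  the granular/Va depth injects the cross-columnar contribution that
  drives RelResCSD away from zero, with its own (broader-scalable)
  octave tuning.
* **Ongoing activity and noise.** Slow charge-balanced background per
  layer (Butterworth-filtered Gaussian noise, 14 Hz cutoff — steep, so
  its power stays clear of the 25–36 Hz analysis band), a fast unbalanced
  lateral background (120 Hz, the RelRes noise floor; fast so it cannot
  fake sustained threshold crossings), and white measurement noise. The
  default levels (0.3 / 0.15 / 0.03 in kernel units) were chosen together
  so that (i) evoked spectra stay signal-dominated at every retained bin,
  (ii) the RelRes bandwidth criterion passes near the best frequency
  before and across most of the grid after the lateral input broadens,
  and (iii) event detection on spontaneous data reaches recall and
  precision ≥ 0.95.
* **Emission.** The designed CSD (plus noise) is double-integrated along
  depth to the emitted LFP, constructed so the discrete second difference
  returns the design exactly at interior channels; an option emits the
  designed CSD directly for unit tests.
* **Spontaneous data.** Event onsets are Poisson arrivals on the usable
  window of each 6 s trace, thinned with a 150 ms dead time (the later
  event of a close pair is dropped); the retained count has an exact
  delayed-renewal expectation, implemented for the rate-bias test. Each
  event is a translaminar kernel sequence led by layer Vb (III/IV +15 ms,
  VI +25 ms, I/II +30 ms, amplitudes 1.0/0.8/0.5/0.6 × the event
  amplitude) plus a small unbalanced lateral component. Default rate
  1.0 events/s.
* **Layer-trace networks.** Stationary VAR(2) realizations with a known
  coupling tensor (burn-in discarded). The preset network carries exactly
  three cross-layer edges — Vb→III/IV (strong), I/II→VI and VI→Vb (weak)
  — so every other ordered pair is conditionally independent in both
  conditions. This sparsity is deliberate: conditional GC responds to the
  whole network, and editing edges in a dense ground truth changes F on
  unedited edges, which no network comparison should be blamed for.

**The enzyme-effect preset** (`hyase_effect`) maps a pre-condition
parameter set to its post-condition twin: supragranular gain ×1.2
(deliberately weak relative to the between-animal spread — in the source
population this effect does not reach significance), Vb gain ×0.55 (the
consistent effect), III/IV and VI unchanged in the mean; lateral input
×1.6 and twice as broad; a phase-locked 30 Hz oscillation (Gaussian
envelope, σ = 120 ms, centered 300 ms post-onset, amplitude 0.06) added to
layer Vb so the evoked spectrum gains a 25–36 Hz band; spontaneous events
×0.6 in rate, ×0.65 in amplitude, ×0.6 in duration, with more lateral
spread; and the coupling rewired — I/II→VI and VI→Vb strengthened to
0.4, Vb→III/IV weakened to 0.15. Layer gains are calibrated so the
measured population LSI sits near +0.2 before and above +0.4 after
treatment.

**Cohorts.** `pipeline.make_cohort` draws matched (pre, post) parameter
pairs per animal: multiplicative gain and lateral jitter, ±3 ms latency
spread, per-animal kernel peak time, per-animal ripple realizations and a
per-animal oscillation phase (phase-locked within an animal, random
across animals), plus log-normal spread on every enzyme-effect factor.
Per-recording "state" jitter on the noise and background levels models
the hours between the two sessions. This heterogeneity is not decoration:
identical kernels across animals make every tiny deterministic mixture
change (interference between layer kernels, normalization shifts)
perfectly consistent across the cohort, and a paired t detects it however
small it is. Real between-animal variability is what keeps real analyses
honest, and the generator must supply it for the same reason.

### What the generator does not emulate

Electrode drift, non-Gaussian artifacts, line noise, spike leakage,
cortical state transitions, adaptation across trials, tonotopic
heterogeneity under the probe, and any biophysical relationship between
the enzyme and the kernel parameters. Passing tests on this surface show
that the estimators recover what they claim from data with the assumed
structure — not that the biological effects themselves are real, nor that
the pipeline is robust to artifacts it never sees.

## Problem sizes

The bundled study-scale checks use 9 subjects per cohort, 8 tones × 6
trials per condition for evoked measures, 36 s of spontaneous data and
15 × 800-sample layer-trace realizations per condition, with 20 cohort
replicates for the majority-vote comparisons; estimator cross-checks use
10 trials × 600 samples (and 2 × 10⁵ samples for asymptotic agreement).
These sizes are the package's chosen desk-scale study conditions.

## Known limitations

* The second-difference estimator is the classical one; no inverse-CSD
  (iCSD/kCSD) variants.
* The reduced-model order defaults to the full order p; the marginalized
  process is VARMA and a deeper `reduced_order` reduces the resulting
  (small) bias at extra variance.
* The Yule–Walker and OLS routes differ by O(p/T) in finite samples;
  sub-0.1 % agreement needs long trials.
* BH control is marginal per family (layer); no across-layer hierarchy.
* Time-domain GC only; no spectral or state-space variants.
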