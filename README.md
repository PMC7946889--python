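# lamicsd

Laminar current-source-density analysis for multi-trial extracellular
recordings from sensory cortex, with a synthetic-recording generator that
provides ground truth for every stage.

Given trials × channels × time local field potentials from a linear probe
spanning the cortical depth (32 contacts at 50 µm, 2 kHz by default), the
package computes:

* **CSD** — the second spatial derivative
  `CSD(z) ≈ [θ(z+nΔz) − 2θ(z) + θ(z−nΔz)] / (nΔz)²` after 7-channel
  Hamming smoothing with linear boundary extrapolation (sinks negative);
* **columnar measures** — `AVREC(t) = Σ|CSDᵢ|/n` (overall current flow)
  and `RelResCSD(t) = ΣCSDᵢ / Σ|CSDᵢ|` (sink/source imbalance, a proxy
  for lateral corticocortical input), from unsmoothed single-trial CSD;
* **layer metrics** — per-layer RMS over the stimulus window, sink onset
  latencies (2 SD / >5 ms sustained-threshold criterion), and the
  electrode-stability cross-correlogram of pre/post depth profiles;
* **frequency tuning** — best frequency (argmax granular RMS),
  octave-binned tuning curves, Q40dB response bandwidth, and the
  layer-symmetry index `LSI = (I/II − Vb)/(I/II + Vb)`;
* **spontaneous events** — AVREC peak detection at median + 3 SD with
  150 ms separation, event rates and spontaneous RMS metrics;
* **multitaper spectra** — 5 DPSS tapers, 600 ms epochs, NW = 3, no
  padding, 1–100 Hz, unit-sum normalized; evoked (complex trial average
  before squaring) and total-power estimators, compared across subjects
  per bin by paired t with Benjamini–Hochberg control (Q = 0.1);
* **conditional Granger causality** — per subject, a 4 × 4 matrix
  `F[i,j] = ln(var ε′ᵢ / var εᵢ)` between layer CSD traces from
  Yule–Walker-fitted VAR models via the implied autocovariance sequence,
  with AIC order selection, ADF stationarity checks, and an edge-wise
  paired-t / BH (Q = 0.05) comparison between conditions.

The synthetic generator (`lamicsd.synth`) emits recordings with the
statistical structure these estimators assume — feedforward evoked CSD
kernels, Gaussian-in-octaves tuning, condition-dependent layer gains and a
beta-band oscillation, translaminar spontaneous events led by layer Vb,
and layer traces with known directed VAR coupling — by designing the CSD
and double-integrating it to the emitted LFP, so the analysis pipeline is
what recovers the pattern. `lamicsd.synth.hyase_effect` maps any
pre-condition parameter set to its enzyme-treated twin (infragranular
weakening, moderate supragranular increase, broader lateral input, beta
oscillation, rarer/shorter events, three rewired network edges).
See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
from lamicsd import synth
from lamicsd.pipeline import analyze_evoked

params = synth.preset("pre")                      # untreated cortex
rec = synth.generate_evoked(params, n_trials_per_freq=6, seed=1)
ev = analyze_evoked(rec)
print(f"best frequency : {ev.bf_hz:.0f} Hz")
print(f"LSI at BF      : {ev.lsi_bf:.3f}")
print(f"Vb layer RMS   : {ev.layer_rms_bf['Vb']:.3f}")
print(f"RelRes Q40dB   : {ev.q40_relres_oct:.1f} octaves")
```

prints

```
best frequency : 2000 Hz
LSI at BF      : 0.234
Vb layer RMS   : 0.142
RelRes Q40dB   : 4.0 octaves
```

The best frequency is recovered at the generator's ground truth (2 kHz);
the LSI near +0.2 says supragranular current flow moderately leads
infragranular layer Vb in the untreated column; the RelRes bandwidth of
4 octaves means lateral input is detectable only near the best frequency.
Running the same analysis on `synth.preset("post")` data yields an LSI
of 0.375, a Vb RMS of 0.133 and a Q40dB of 8.0 octaves — the columnar
fingerprint of matrix removal: activity shifted toward upper layers and
laterally relayed input spread across the whole stimulus grid.

`lamicsd.pipeline.fingerprint(n_subjects=9, seed=...)` runs the full
matched-cohort comparison (evoked metrics, spectra, spontaneous events,
networks, electrode stability) and `fingerprint_checks` summarizes every
predicted direction of the effect.

## Command line

```
lamicsd simulate --preset paper-pre --seed 1 --n-trials 6 --out rec.h5
lamicsd csd      --rec rec.h5 --out-prefix out/run
lamicsd tuning   --rec rec.h5 --out-prefix out/run
lamicsd sce      --rec spont.h5 --out-prefix out/run
lamicsd spectral --rec rec.h5 --out-prefix out/run
lamicsd gc       --rec rec.h5 --out-prefix out/run
```

Recordings are HDF5 (`lfp` dataset + `fs`, `dz`, `condition`,
`stim_onset` attributes, per-trial `stim_freq`); all derived tables are
CSV; layer maps are YAML.

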