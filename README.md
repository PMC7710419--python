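# eegnet

Peri-ictal scalp-EEG analysis: how does brain activity differ in the minutes
immediately **before** and **after** an epileptic seizure, and does the
functional network degrade across consecutive seizures?

`eegnet` is a tested, reproducible pipeline for clinicians and
neuroscientists working with 16-channel 10-20 scalp recordings (256 Hz, EDF).
From annotated seizure onsets/offsets it extracts 10 min pre/post windows
and computes, per frequency band (delta, theta, alpha, beta, low gamma):

* **Band power** — Welch PSD (2 s Hann windows, 50% overlap on 6 s epochs),
  integrated per band;
* **Fuzzy entropy** — the sample-entropy variant with similarity kernel
  exp(−(d/r)^n): FuzzyEn = ln φ^m − ln φ^(m+1), a monotone index of signal
  complexity;
* **Functional networks** — magnitude-squared coherence
  C(f) = |S_xy(f)|² / (S_xx(f)·S_yy(f)) between all channel pairs, averaged
  over band bins;
* **Graph metrics** — characteristic path length
  CPL = (1/n) Σ_i Σ_{j≠i} d_ij/(n−1) on reciprocal-weight shortest paths,
  and the weighted clustering coefficient
  CC = (1/n) Σ_i T_i / denom_i with triangle intensity
  T_i = Σ_{j,h} (w_ij w_ih w_jh)^{1/3}, in both a strength-denominator and
  the conventional degree-denominator variant;
* **Paired statistics** — channel-, edge- and metric-level paired t-tests
  with Benjamini–Hochberg FDR, plus the Pearson correlation between network
  metrics and seizure number across temporally ordered segments
  (1-pre, 1-post, 2-pre, …).

Because clinical peri-ictal recordings are rarely shareable, the package
includes a first-class **synthetic EEG generator** with closed-form planted
ground truth — per-band power, pairwise coherence via shared-source mixing,
complexity via the noise-to-oscillation ratio, >80 µV artifacts, and
monotone pre/post network degradation — so every stage of the pipeline is
validated end-to-end by parameter recovery.

## Worked example

Plant a 2× post-seizure delta-power increase, run the chain, and test it:

```python
import numpy as np
from eegnet import (SyntheticConfig, PrePostEffect, generate_recording,
                    preprocess, welch_psd, band_power, epoch_band_power,
                    channel_tests, coherence_matrix, BAND_BY_NAME,
                    characteristic_path_length, clustering_coefficient)

cfg = SyntheticConfig(duration=120.0,
                      effect=PrePostEffect(delta_power_ratio=2.0), seed=7)
esets = {s: preprocess(generate_recording(cfg, s)) for s in ("pre", "post")}

for s, es in esets.items():
    bp = band_power(welch_psd(es))
    print(s, "delta power Fp1 = %.2f uV^2" % bp.band("delta")[0])

pre  = np.log10(epoch_band_power(esets["pre"])[:, :, 0])   # per-epoch delta
post = np.log10(epoch_band_power(esets["post"])[:, :, 0])
res = channel_tests(pre, post, esets["pre"].channel_labels,
                    alpha=0.05, use_fdr=True)
print("significant channels:", list(res.loc[res.significant, "feature_id"]))

cm = coherence_matrix(esets["pre"], BAND_BY_NAME["delta"])
print("CPL = %.3f" % characteristic_path_length(cm),
      "CC(standard) = %.4f" % clustering_coefficient(cm, "standard"))
```

Output:

```
pre delta power Fp1 = 16.16 uV^2
post delta power Fp1 = 30.72 uV^2
significant channels: ['Fp1', 'Fp2', 'F3', 'F4', 'F7', 'F8', 'C3', 'C4',
                       'P3', 'P4', 'O1', 'O2', 'T3', 'T4', 'T5', 'T6']
CPL = 67.272 CC(standard) = 0.0140
```

The planted effect roughly doubles delta power (16.2 → 30.7 µV²; the common
average reference redistributes a little of it), and with the ratio planted
on every channel, every channel is flagged at FDR 0.05.  The uncoupled
network's coherence sits near the small-sample bias floor, hence the long
characteristic path length and near-zero clustering.

The same analysis runs from the shell on EDF or synthetic input:

```bash
eegnet synth --out data/ --seed 1            # EDF + ground-truth sidecar
eegnet run   --config run.yaml --seed 1      # full pipeline, CSV/JSON out
eegnet metrics --matrix coh.csv --variant standard
```

## Layout

```
src/eegnet/
  recording.py     Recording/EpochSet containers, EDF + annotation I/O
  synthetic.py     ground-truth generator (coupling, effects, artifacts)
  preprocess.py    reref -> 1-45 Hz band-pass -> 6 s epochs -> +-80 uV reject
  spectral.py      Welch PSD, band definitions, band power
  entropy.py       fuzzy entropy (vectorised)
  connectivity.py  pooled + per-epoch coherence matrices
  netmetrics.py    CPL, clustering (both variants), thresholding utilities
  stats.py         paired tests, BH-FDR, seizure-number trend
  pipeline.py      end-to-end runs, config, manifest
  validation.py    planted-truth recovery experiments
  reference.py     naive double/triple-loop reference implementations
```
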