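# cofluct

Analysis of co-fluctuations between the global fMRI signal, EEG power, and
autonomic physiological signals: feature extraction from raw recordings,
PCA / complex-PCA spatiotemporal modeling of voxel time series, lagged
cross-correlation and Gaussian-process impulse-response deconvolution,
multi-set canonical correlation with subject-block permutation inference,
event-related averaging, and multi-echo T2*/S0 decay modeling — together
with a synthetic-data generator that produces coupled fMRI / physio / EEG
sessions with a known latent arousal process, so every stage is testable
without any external recordings.

## Modules

| module | what it does |
| --- | --- |
| `cofluct.synthetic` | coupled synthetic sessions (latent arousal, traveling-wave fMRI, pulsatile PPG, respiration, SC/pupil, EEG, multi-echo volumes, event onsets) with full ground truth |
| `cofluct.physio` | PPG peak detection (two-moving-average scheme), heart rate / pulse amplitude (monotone-cubic), respiratory volume (Hilbert), tonic skin conductance, Morlet wavelet power, alpha envelope, 5-SD clip + resample + 0.01–0.1 Hz standardization |
| `cofluct.globalcomp` | BOLD preprocessing (smoothing, zero-phase bandpass), first principal component, first complex principal component with phase-delay map, phase-binned temporal reconstruction |
| `cofluct.coupling` | lagged cross-correlation curves on a ±30 s spline grid, group averaging, MAP deconvolution of impulse responses under a squared-exponential GP prior |
| `cofluct.mcca` | distributed-lag natural-spline predictor sets (0–10 s, 3 splines), sum-of-correlations multi-set CCA (generalized eigenproblem), subject-block permutation test |
| `cofluct.events` | trial filtering (30 s minimum gap, response requirement), peri-event averaging, cluster-bootstrap SEs, baseline-dB EEG power maps |
| `cofluct.multiecho` | volume-wise log-linear monoexponential T2*/S0 fits, cardiac-cycle Fourier regressors per slice, max-R² selection |
| `cofluct.pipeline` / `cofluct.cli` | config-driven orchestration and the `cofluct` command-line interface |

## CLI

```sh
cofluct run-all --seed 1 --outdir out/            # full synthetic pipeline
cofluct simulate --seed 1 --outdir out/           # synthetic session only
cofluct cpca --seed 1 --outdir out/               # simulate + PCA/CPCA
cofluct run-all --config my_config.yaml           # everything from a config
```

A config file mirrors `cofluct.pipeline.PipelineConfig`:

```yaml
outdir: out
seed: 3
n_subjects: 4
synthetic:
  duration_s: 600.0
  n_voxels: 500
mcca_n_perm: 199
```

Outputs per subject: 4D NIfTI BOLD + per-echo volumes, mask, BIDS-style
physio `.tsv.gz` + JSON sidecar, events TSV, ground-truth JSON, feature
TSVs, PC1/CPC1 maps and scores, phase-movie NIfTI, cross-correlation and
impulse-response TSVs, T2*/S0 NIfTI series, and an MCCA summary JSON.

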