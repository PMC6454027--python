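# wavemeg

Linking multilevel Haar-wavelet descriptors of visual stimuli to
time-resolved MEG decoding — a tested re-implementation of the full
analysis chain, exercised end-to-end on synthetic data with known ground
truth.

**Who it is for.** Researchers in computational neuroimaging who want a
reproducible, unit-tested version of this analysis style: multivariate
pattern analysis (MVPA) decoding over time, representational similarity
analysis (RSA) against image-computable model RDMs, and nonparametric
latency statistics — or who want the synthetic-data machinery to
validate such pipelines.

## The analysis

1. **Wavelet descriptors.** Each grayscale stimulus is decomposed with a
   5-level separable 2D Haar transform. Per level j this yields an
   approximation band A_j and horizontal / vertical / diagonal detail
   bands H_j, V_j, D_j (each half the previous resolution; a 175×175
   image gives sides 88/44/22/11/6). Flattening A, H, V, D and the
   concatenation ALL = [H|V|D] per level gives 25 descriptor vectors
   W1…W25 per stimulus.
2. **Decoding RDMs.** For every condition pair (i, j) and timepoint t, a
   linear SVM is trained on pseudo-trials (averages of `group_size`
   randomly partitioned raw trials, K = 4 groups) with
   leave-one-pseudo-trial-per-class-out cross-validation, repeated 100
   times with fresh partitions. The mean accuracy fills cell (i, j) of
   the decoding RDM at t — one symmetric, diagonal-undefined
   condition × condition matrix per timepoint.
3. **Model RDMs and RSA.** Descriptor RDMs are 1 − Pearson r between
   descriptor vectors. Each model RDM is compared with each subject's
   decoding RDM at every timepoint by Spearman correlation over the
   upper triangle, giving per-descriptor time-courses ρ(t).
4. **Statistics.** Significant timepoints come from a two-sided
   sign-permutation test (1,000 flips) with cluster-size correction
   (cluster-defining threshold 0.05, corrected α = 0.05). Peak and onset
   latencies are estimated by bootstrapping the subject sample 1,000
   times (mean ± SEM, percentile 95% CI), with optional 5% outlier
   trimming and a 150 ms latency cutoff; significant-timepoint counts
   are summed per detail orientation (the oblique-effect comparison:
   cardinal H/V versus diagonal D).

A synthetic-data module generates stimuli with controllable oriented
edge energy and MEG-like epochs whose condition geometry follows any
target RDM exactly in rank order, localized in time by a compact
Gaussian envelope — so every stage above can be checked against injected
ground truth. See `docs/methods.md` for the models and numerical
choices.

## Worked example

```python
import numpy as np
import wavemeg as wm

# 1. stimuli with controlled oriented-edge content, and their descriptors
rng = np.random.default_rng(0)
profiles = [wm.OrientationProfile(*rng.uniform(0.2, 1.0, 3)) for _ in range(10)]
images = wm.generate_stimuli(10, 64, profiles, seed=1)
descriptors = wm.build_descriptors(images, levels=5)
print(f"{len(descriptors[0])} descriptors per stimulus; "
      f"W5 (level-1 ALL) has {len(descriptors[0][4].vector)} coefficients")

# 2. synthetic epochs whose geometry follows the W5 descriptor RDM,
#    peaking 120 ms after stimulus onset
target = np.nan_to_num(wm.model_rdms(descriptors)["W5"])
truth = wm.GroundTruth(model_rdm=target, signal_peak_ms=120.0,
                       signal_width_ms=60.0, noise_sd=0.8, seed=2)
epochs = wm.generate_epochs(truth, n_subjects=8, n_conditions=10, n_trials=24,
                            n_channels=48, window_ms=(-100.0, 300.0), step_ms=5.0)

# 3. preprocess, decode, correlate, test
clean = wm.preprocess_pipeline(epochs, remove_blinks=False)
series = wm.decoding_rdm_series(clean, K=4, group_size=6, n_reps=10, seed=3)
rho = wm.rsa_timecourse(series, target)
mask = wm.significance_mask(rho, n_perm=1000, rng=np.random.default_rng(4))
peak = wm.bootstrap_latency(rho, series.times, (0.0, 300.0), 1000, "peak",
                            rng=np.random.default_rng(5))
print(f"grand-average rho peaks at {rho.mean(0).max():.2f}")
print(f"significant timepoints: {mask.count()}")
print(f"peak latency: {peak.point:.0f} ms, bootstrap {peak.mean:.1f} ± {peak.sem:.1f} ms, "
      f"95% CI ({peak.ci95[0]:.0f}, {peak.ci95[1]:.0f}) ms")
```

Output (≈ 45 s on one core):

```
25 descriptors per stimulus; W5 (level-1 ALL) has 3072 coefficients
grand-average rho peaks at 0.41
significant timepoints: 19
peak latency: 125 ms, bootstrap 125.1 ± 4.7 ms, 95% CI (115, 140) ms
```

The injected geometry peaked at 120 ms; the pipeline recovers a clear
representational trace (ρ ≈ 0.4), a significant cluster around it, and a
bootstrap peak latency of 125 ± 5 ms — one time-step off the ground
truth at the 5 ms resolution used here.

## Command line

The same stages run as a pipeline with file artifacts (PNG stimuli, HDF5
epochs/RDMs, CSV time-courses, JSON stat reports):

```sh
wavemeg simulate      # synthetic stimuli + epochs with ground truth
wavemeg descriptors   # 25 wavelet descriptors per stimulus
wavemeg preprocess    # baseline, rejection, 30 Hz low-pass, blink PCA
wavemeg decode        # per-timepoint pairwise SVM decoding RDMs
wavemeg rsa           # 25 Spearman time-courses
wavemeg stats         # cluster-corrected masks, latencies, counts
wavemeg report        # summary plots
```

`wavemeg all` runs the chain; `--config pipeline.toml` overlays a TOML
file on the defaults (which equal the published analysis parameters
wherever one is printed), and every stage writes a manifest with the
config hash and seed. Re-running a stage with identical config and
inputs reproduces its numeric outputs exactly.

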