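# mionpipe

Simulation and analysis of block-design monkey fMRI experiments that map
**object novelty** (novel vs. familiar, "NF") and **object value** (good vs.
bad, "GB") coding with the MION contrast agent. The package is aimed at
methods work: every stage of the analysis chain runs on synthetic data with
known ground truth, so estimator behavior (bias, familywise error control,
graph recovery, model selection) can be measured directly.

## What it implements

* **Synthetic data** (`mionpipe.synth`): 16-block base/probe runs (30 s
  blocks, TR 2.5 s, 192 volumes) with pseudorandomized probe types
  ([good,bad] or [novel,familiar] × [left,right hemifield]), sign-inverted
  gamma-variate MION hemodynamics, planted per-network percent-signal
  effects, spatially autocorrelated noise at a target temporal SNR, and
  resting-state series drawn from a known sparse precision matrix.
* **GLM** (`mionpipe.glm`): percent-change conversion, per-run design
  matrices (4 condition boxcars, 17 nuisance regressors — 12 motion terms
  unconvolved, reward/blinks/eye traces MION-convolved — plus 4th-order
  Legendre drift), OLS betas/t-maps, GB/NF/visual contrasts.
* **Cluster correction** (`mionpipe.cluster`): Monte-Carlo cluster-extent
  thresholds for noise with the mixed spatial autocorrelation
  ACF(r) = a·exp(−r²/2b²) + (1−a)·exp(−r/c), and their application to stat
  maps (face-adjacency clustering, NN = 1).
* **Connectivity graphs** (`mionpipe.netgraph`): confound regression and
  FFT bandpass (0.01–0.1 Hz), the order-independent **PC-stable** skeleton
  with Fisher-z partial-correlation tests, net-correlation edge weights,
  spectral partitioning (normalized Laplacian + k-means, k = 4), and
  seed-correlation maps against network centroids.
* **Joint coding** (`mionpipe.joint`): per-region averages over the top-10
  visually active voxels (selection orthogonal to value/novelty/hemifield
  coding), bivariate-Gaussian joint null with 68%/95% iso-probability
  contours, and per-network NF/GB canonical time-course correlations.
* **Bilinear DCM** (`mionpipe.dcm`): the neural state equation
  ż = (A + Σⱼ uⱼBⱼ) z + Cu over 4 nodes ([temporal, prefrontal] ×
  [left, right]) and 8 condition inputs, a balloon hemodynamic stage with
  volume-weighted, sign-inverted readout y = −ε(v−1), MAP inversion with a
  Laplace model evidence, and fixed-effects selection over the 3 × 3 grid
  of input/self-modulation architectures.
* **Pipeline and power** (`mionpipe.pipeline`, CLI `mionpipe`): end-to-end
  orchestration with provenance, and the scan-power formula
  N_run = (8/TRnum)·(erfc⁻¹(p)/(tSNR·eff·5))².

## Worked example

```python
import mionpipe as mp

# how many runs does the block design need to see a 0.1% effect?
n = mp.required_runs(mp.PowerParams(p=1e-3, tsnr=25, eff=0.001,
                                    mion_factor=5, tr_per_run=192))
print(f"{n:.1f}")          # -> 14.4

# simulate a run with a planted 0.1% value effect and recover it
truth = mp.make_ground_truth(shape=(8, 4, 2), n_networks=2,
                             regions_per_network=2, gb_effect=0.1)
kernel = mp.mion_irf()
design = mp.make_design("GB", seed=2)
run = mp.simulate_task_run(design, truth, seed=2, kernel=kernel, noise=False)
X = mp.build_design_matrix(run.events, run.nuisance, kernel, "GB", design)
fit = mp.fit_glm(run, X)
gb = mp.contrast_map(fit, mp.ContrastSpec.gb())
net = truth.network_labels().ravel()
print(round(gb.effect[net == 1].mean(), 6))   # -> 0.1  (percent signal)
print(round(gb.effect[net == 2].mean(), 6))   # -> -0.0  (no planted effect)
```

The printed `14.4` is the minimum run count the power formula assigns to
detecting a 0.1% signal change at voxelwise P = 1e-3 with temporal SNR 25
and the 5× MION sensitivity factor over a full 192-volume run; the `0.1`
is the GLM's exact recovery (in percent-change units) of the planted
good-vs-bad contrast in the coding network, and `0.0` the absence of an
effect where none was planted.

An end-to-end run (simulate → GLM → cluster correction → graph → joint
coding) with the default planted 4-network ground truth:

```bash
mionpipe run-all --seed 3 --out-dir out/
```

writes contrast and label volumes (NIfTI), the connectivity edge list and
GraphML graph, the network partition, region scatter tables and a summary
JSON whose `partition_ari_vs_truth` field reports the adjusted Rand index
of the recovered partition against the planted networks (1.0 at the
default settings).

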