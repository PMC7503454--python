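# Methods

This note documents the models, estimators and numerical choices behind
`mionpipe`, what the synthetic-data generator does and does not emulate,
and the problem sizes the test suite uses.

## Scan design and the power formula

A run is 16 alternating base/probe blocks of 30 s at TR 2.5 s — 192
volumes, of which the first 3 are discarded as a magnetization transient.
Probe blocks carry one of four conditions per scan type
([good, bad] × [left, right] in value scans, [novel, familiar] ×
[left, right] in novelty scans). Each run holds two cycles of four probe
blocks; within a cycle every condition appears exactly once, the order a
seeded permutation. The balance invariant is enforced per cycle: a strict
sliding-window reading (every four *consecutive* probe blocks balanced)
would force both cycles to share one permutation and contradict
independently randomized cycles, so the per-cycle reading is used.

The run-count calculator evaluates

    N_run = (8 / TRnum) · (erfc⁻¹(p) / (tSNR · eff · 5))²

exactly, via `scipy.special.erfcinv`. `TRnum` is an explicit argument: at
the full 192 volumes the formula gives 14.4 runs for eff = 0.1%,
tSNR = 25, p = 1e-3, while at the 189 usable volumes it gives 14.7. Both
readings are exposed rather than silently reconciled, because the two
stated inputs (189 usable volumes; a printed result of 14.4) are mutually
inconsistent by one rounding step.

## MION hemodynamics

MION tracks cerebral blood volume, so activation *decreases* the measured
signal. The impulse response is a gamma-variate kernel with configurable
peak delay (default 10 s, shape 3), sign-inverted and normalized so a
sustained unit boxcar asymptotes to −1; an optional delayed positive lobe
(`undershoot_ratio`, default 0) is provided but off, since MION responses
are slow and monophasic. The kernel family is a package choice — only the
sign convention is externally fixed — and is therefore configurable.

## Synthetic task runs

Voxel signal is `baseline · (1 + pct/100)` where `pct` sums, per network,
the condition boxcars scaled by planted percent effects and convolved with
the MION kernel, plus 17 nuisance contributions with known loadings
(motion enters unconvolved, event nuisances convolved — mirroring the
design-matrix convention exactly, so noise-free recovery is exact to
machine precision). `pct` is centered over time before scaling: planted
effects are thereby defined in percent-change-from-the-temporal-mean
units, the same units the GLM estimates; without centering, the voxel mean
would absorb a fraction of the effect and "exact recovery" would be off by
O(effect²). Noise is white in time and spatially correlated with the
mixed Gaussian/exponential ACF (shared with the cluster module), scaled so
the empirical temporal SNR matches the target (default 25).

Defaults plant 0.1% GB and NF effects and a 0.2% probe-vs-base (visual)
effect on a 24×24×16 grid of 24 slab regions in 4 networks (GB-only,
NF-only, joint, silent). What the generator does **not** emulate: motion
and distortion artifacts, slice timing, physiological (cardiac/
respiratory) structure, temporal autocorrelation of noise, and
inter-subject variability. Passing tests therefore certify estimator
logic under the stated noise model, not robustness to real-scanner
artifacts.

## GLM

Ordinary least squares per voxel on percent-change data, without
prewhitening (an AR option is out of scope; the noise generator is white
in time). Columns: 4 condition regressors (MION-convolved boxcars sampled
at TR), 17 nuisance regressors, and Legendre drift terms of order 0–4
evaluated over run time — drift as in-model columns is algebraically
identical to a separate detrending pass for OLS. The first three rows and
all rows of censored blocks are dropped (189 rows at defaults). Reward
and blink nuisances are onset impulses convolved with the kernel; the eye
"interaction" trace is the horizontal×vertical product. Voxels with
non-positive temporal mean are masked out of the percent-change
conversion. The visual (probe-vs-base) beta comes from a separate
single-regressor fit and is invariant to condition and hemifield labels,
which is what licenses using it to select voxels without biasing GB/NF
comparisons. Contrast t statistics use w'(X'X)⁻¹w σ̂² with the fit's
residual dof.

## Cluster-extent correction

Null fields are synthesized by multiplying the FFT of white noise by the
square root of the power spectrum of the target ACF evaluated on the
periodic (minimum-image) distance grid; negative spectral estimates are
clipped to zero and the spectrum renormalized so the field variance is
exactly 1. Sample means of single fields wander (the DC mode carries real
variance under long-range correlation); this is correct for a stationary
field and left as is. Per iteration the field is thresholded two-sided at
`p_voxel`, clusters are labeled with the configured neighbor rule
(default NN = 1, faces only) inside the mask, and the maximum cluster size
recorded. The minimum cluster size is where the survival curve of maxima
crosses `alpha_fwe`, linearly interpolated between integers — hence
possibly fractional, e.g. 4.7 — and rounded *up* at application time.
Published monkey thresholds are not reproducible here because the
whole-brain mask geometry is not available; the package instead verifies
self-consistent familywise control on its own masks. ACF parameters are
inputs (both published parameter sets ship as constants); residual-based
ACF estimation is out of scope.

## Functional connectivity

Resting segments are confound-regressed (white-matter/ventricle
analogues, with intercept) and bandpassed by zeroing FFT bins strictly
outside 0.01–0.1 Hz, then row-centered. The PC-stable skeleton freezes
neighbor sets per depth (order independence), tests conditional
independence with the Fisher-z statistic √(n−|S|−3)·atanh(ρ̂) against a
two-sided normal at `ci_alpha`, and removes an edge on the first
nonsignificant test. No effective-sample-size correction is applied for
bandpass-induced autocorrelation; the nominal n makes the tests
anticonservative, which matters for edge density but not for the
package's recovery guarantees (verified empirically at n = 4000). Edge
weight is the signed partial correlation of smallest magnitude seen for
the pair over all its tests — for surviving edges every test was
significant, so this coincides with "smallest significant"; a
`significant_only` flag switches readings explicitly. Conditioning-set
size is unbounded (limited only by neighbor counts). Clustering uses
|weight| affinities (partial correlations can be negative; affinities
must not be), the symmetric normalized Laplacian, row-normalized
embedding on the k lowest eigenvectors, and seeded k-means++ with 50
restarts; k is fixed at 4 by configuration, with no model selection over
k. Components are clustered separately; only the largest is partitioned
(ties broken toward the smallest node id; an edgeless graph degenerates
to a single node with a warning).

## Joint coding summaries

The joint GB/NF null is a bivariate Gaussian fit over all gray-matter
voxels regardless of significance; iso-probability contours at 68%/95%
are Mahalanobis ellipses (χ²₂ quantiles), with a KDE contour mode behind
a flag for robustness checks. Per-region scatter points average the
`n_top = 10` most visually active voxels, ranked only on the visual beta
with stable index tie-breaks, so the selection is provably invariant to
GB/NF values. NF/GB time-course correlation first canonicalizes block
order — volumes of each block type averaged in block-relative time and
concatenated as [base, high-left, high-right, low-left, low-right],
"high" meaning good or novel — because runs have different pseudorandom
orders; correlation is Pearson between the run-averaged canonical NF and
GB courses per voxel. Canonicalization leaves a small carryover residual
(slow hemodynamics leak across block boundaries), so identical planted
dynamics give r = 1 exactly only when the compared runs share a block
order, and r ≳ 0.999 otherwise.

## Bilinear DCM

Neural dynamics ż = (A + Σ uⱼBⱼ)z + Cu over k = 4 nodes ([temporal,
prefrontal] × hemisphere) and m = 8 inputs (condition × hemifield). All
nine candidate models share the A mask — self-connections plus reciprocal
temporal↔prefrontal within each hemisphere — and A is common to the GB
and NF segments. Input schemes place contralateral stimulus drive on the
temporal nodes, the prefrontal nodes, or both; self-modulation schemes
put no, good/novel, or all-condition inputs on the B diagonals. Good and
novel inputs modulate the forward and backward connections of the
hemisphere *contralateral to the stimulated hemifield* (the driven
pathway): modulation of the undriven hemisphere's connections is
unidentifiable under contralateral input — its nodes are quiescent during
those blocks — and simulations confirm such parameters simply return
their prior. Bad/familiar inputs modulate self-connections only (in the
all-condition scheme), matching the scheme's name.

Self-connections are parameterized −exp(θ) (prior mean 0.5 s⁻¹ decay);
other free entries have zero-mean Gaussian shrinkage priors with variance
0.25. The hemodynamic stage is the standard balloon model (vasodilatory
signal, flow, volume, deoxyhemoglobin; κ = 0.65, γ = 0.41, τ = 0.98,
α = 0.32, E₀ = 0.34, fixed) and the readout is the volume-weighted,
sign-inverted y = −ε(v−1) with ε = exp(θ_ε) free (prior ε = 1), since
MION tracks blood volume. Integration is fixed-step RK4 at TR/16 with
input patterns precompiled per block (the empirical convergence order is
4, verified over step halvings; at the default step the residual
discretization error is a few 1e-6 relative). A smooth hinge on the
largest real eigenvalue part of every modulated connectivity matrix keeps
the optimizer inside the stable region, and a divergence guard caps
blown-up trajectories.

Inversion is MAP (multi-start L-BFGS with a forward-difference gradient,
JIT-compiled) with the observation-noise variance profiled at its ML
value, followed by a Laplace evidence using a Gauss-Newton Hessian
(J'J/σ̂² plus the prior precision) — a deliberate simplification of
variational EM that preserves the model-comparison semantics (data fit
minus parameter-volume penalty). Fixed-effects selection takes the
softmax of log evidences, ties broken toward fewer parameters; fits whose
optimizer never produced a finite objective are flagged and excluded.
Edge summaries report A + B per condition, averaged across left/right
presentations after contra/ipsi relabeling.

## Problem sizes used by the tests

The statistical suite runs at desk scale by choice: GLM coverage pools 19
runs × 100 replicates on an 8×4×2 grid; PC-stable is checked against a
brute-force all-subsets oracle on 50 five-node models at n = 2000,
α = 0.01, with population edge partial correlations ≥ 0.18; network
recovery uses the default 24-region/4-network precision at n = 4000 over
20 seeds; familywise calibration uses 10 000 Monte-Carlo iterations and
500 fresh 24³ nulls per ACF set; DCM recovery/selection uses 20
replicates of one GB plus one NF single-cycle segment (192 volumes, 4
nodes) at SNR 5 with single-start, 40-iteration inversions for the grid.
The pipeline's own defaults (2 cycles, 10 000 iterations, 8 restarts)
are larger; the tests choose the smallest sizes at which the checked
properties are stable.

## Known limitations

* OLS without prewhitening; no AR noise in the generator either.
* The joint null's Gaussian model understates tail mass for heavy-tailed
  beta distributions; the KDE mode exists for that check.
* PC-stable p-values ignore bandpass-induced autocorrelation (see above).
* The DCM evidence is a Laplace/Gauss-Newton approximation; absolute
  evidence values are not comparable with SPM's variational free energy,
  only relative rankings within the grid are used.
* Cluster-threshold values depend on mask geometry; published per-animal
  thresholds cannot be reproduced without the original masks.
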