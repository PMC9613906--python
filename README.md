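# scenescale

Analysis pipeline for how a 15-step **object-to-scene continuum** — views
ranging from a close-up single object (condition 1) to a full-room scene
(condition 15) — is encoded by populations of fMRI voxels. The package
takes condition × voxel response matrices (GLM beta weights) and asks two
linked questions:

1. **What do single voxels look like?** Split-half-reliable voxels are
   characterized by their preferred condition and by Gaussian peak fits,
   and grouped by *response profile clustering*: k-means on zero-mean,
   unit-length 15-condition profiles with correlation distance
   `d(x, y) = 1 − Pearson(x, y)`, with stability quantified by voxel-pair
   co-assignment between independent solutions (Dice and d′).
2. **What does the population code look like?** Condition patterns are
   compared via a 15 × 15 representational dissimilarity matrix
   (RDM, `1 − Pearson`), embedded with classical (Torgerson) MDS, and
   summarized by the PCA eigenspectrum of the condition × voxel matrix.
   Two idealized coding schemes are simulated and tested against the data
   RDMs: **opponent ramp coding** (two pools with linear tuning of opposite
   sign — an exactly one-dimensional code) and **Gaussian multi-channel
   coding** (each voxel a Gaussian channel peaked at a random condition).

Because group-level beta matrices from the original experiment are not
redistributable, the package ships a synthetic-data generator
(`scenescale.synth`) that emulates the study's structure — 12 participants
× 2 stimulus-split halves × 15 conditions × V voxels, with voxels drawn
from planted tuning families plus i.i.d. Gaussian noise — so every stage of
the pipeline is testable end to end, including recovery of known ground
truth.

## The statistics at the core

* **Split-half reliability**: per voxel, Pearson r between the
  group-average 15-condition profiles of the two stimulus halves; voxels
  with r > 0.3 are selected.
* **Co-assignment stability**: for two clusterings of the same voxels,
  over all unordered voxel pairs, `Hit` pairs are co-clustered in both,
  `Miss` in the first only, `FA` in the second only;
  `Dice = 2·Hit / (2·Hit + FA + Miss)` and
  `d′ = Φ⁻¹(hit rate) − Φ⁻¹(FA rate)` (rates clamped to
  `[1/(2P), 1 − 1/(2P)]` to stay finite).
* **Variance Ratio Criterion** (Calinski–Harabasz):
  `VRC = [B/(k−1)] / [W/(n−k)]`, used with mean pairwise centroid
  similarity to pick k over a 2..20 scan.
* **Model comparison**: Spearman correlation between the vectorized lower
  triangles (105 entries) of each subject's RDM and each model RDM,
  Fisher-z transformed, contrasted with a paired t-test.

## Worked example

The analysis is organized as numbered drivers over the library:

```bash
python analysis/01_simulate_dataset.py --seed 0   # 12×2×15×400 synthetic betas
python analysis/02_select_voxels.py               # split-half reliability, r > 0.3
python analysis/03_tuning_maps.py                 # preference map + Gaussian fits
python analysis/04_cluster_profiles.py --seed 0   # RPC with k-scan 2..20
python analysis/05_stability.py --seed 0          # stimulus- & participant-split
python analysis/06_geometry.py                    # RDM, MDS, eigenspectrum
python analysis/07_model_comparison.py --seed 0   # ramp vs Gaussian models
```

With seed 0 the run prints, among others:

```
selected 351/400 voxels (87.8%) at r > 0.3
stimulus-split stability at k=4: Dice = 0.81, d' = 2.37
PC1 explains 51.7% of variance, PC2 30.9%
ramp         PC1 =  100.0%   mean rho vs subjects = 0.796
gaussian     PC1 =   27.8%   mean rho vs subjects = 0.632
gaussian_2   PC1 =   79.0%   mean rho vs subjects = 0.807
paired t (ramp vs gaussian): t(11) = 8.91, p = 2.3e-06
directional recovery: ramp model preferred in 100% of 100 opponent-ramp cohorts
```

Reading: most planted voxels replicate across stimulus halves and survive
selection; the k = 4 clustering is highly stable across halves; the
population code is low-dimensional; and the subject RDMs (generated here
from opponent-ramp tuning) are matched far better by the opponent-ramp
model — whose centered activation matrix is rank 1, hence PC1 = 100% —
than by the narrow Gaussian channel model, while a wide Gaussian model
(σ = 5, here `gaussian_2`) becomes nearly indistinguishable from the ramp
model. Tables land in `results/`, figures in `scratch/figures/`.

## Layout

```
src/scenescale/     synth, select, tuning, rpc, geometry, simcompare
analysis/           numbered narrative drivers (see worked example)
tests/              pytest suite (unit, property and end-to-end checks)
scripts/            acceptance.py
docs/methods.md     models, parameters, numerical choices, limitations
```
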