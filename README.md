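# manifold-gw

Alignment of two spatial-omics slices measured in **arbitrary, different
modalities** — transcriptomics to metabolomics, imaging panels to
sequencing, and so on — by learning the intrinsic Riemannian geometry each
modality induces on the shared tissue space and matching those geometries
with Gromov-Wasserstein optimal transport.  There is no hyperparameter
weighting "spatial" against "feature" similarity: all comparisons happen
through learned distances on the common spatial base.

Intended users: computational biologists integrating spatial multi-omics
slices (Visium/Xenium/Stereo-seq/MALDI-MSI/AFADESI-MSI and similar) and
methods researchers who need a transparent, dependency-light reference
implementation with executable invariance guarantees.

## The method

Given two slices `(s_i, X_i)` and `(t_j, Z_j)` with coordinates in a shared
Euclidean space `E` and features in modality spaces `M`, `N`:

1. fit a smooth neural field per slice (SiLU MLP),
   `θ ← argmin (1/2n) Σ_i ‖φ_θ(s_i) − X_i‖²`, likewise `ψ_η` for the second;
2. evaluate the space-modality Jacobians and pull-back metrics
   `g_M(s_i) = J_φ(s_i)ᵀ J_φ(s_i)`, `g_N(t_j) = J_ψ(t_j)ᵀ J_ψ(t_j)`;
3. approximate Riemannian geodesic distances `d_M`, `d_N` on arc-length
   weighted k-NN graphs (weights
   `w_ii′ = ½√(Δᵀg_i Δ) + ½√(Δᵀg_i′ Δ)`, all-pairs shortest paths);
4. solve the pull-back Gromov-Wasserstein problem

   ```
   P* = argmin_{P ∈ Π(a,b)}  Σ_{ii′jj′} (d_M(s_i,s_i′)² − d_N(t_j,t_j′)²)²  P_ij P_i′j′
   ```

The coupling `P*` transfers labels and features across modalities by
barycentric projection.  The construction provably (and, here, testably)
reduces to plain spatial GW when the fields are identities, is invariant to
rigid motions of either slice, and is invariant to global feature-space
similarities `λ·U·(·) + b` (objective scales by `λ⁴`).

An optional pre-processing step selects the alignment-informative feature
subsets with ridge-regularized CCA across spatially paired samples,
removing modality-specific "marginal" features before metric learning.

## Worked example

```python
import numpy as np
from mgw import (MgwConfig, SyntheticSpec, make_pair, migration,
                 ami_transfer, run_mgw)
from scipy.spatial.distance import cdist

# paired slices: shared 2-D latent, two distinct nonlinear modality maps,
# 10 shared + 5 modality-specific features, noise sd 0.05, n = 1024
dsA, dsB, truth = make_pair(SyntheticSpec(seed=1641411168, n_label_clusters=5))

cfg = MgwConfig(seed=1454127163)
cfg.features.cca.enabled = True          # drop the modality-specific block
res = run_mgw(dsA, dsB, cfg)

P = res.coupling.P
near = cdist(dsA.coords, dsB.coords) <= 2 / 31 + 1e-9   # 2 grid cells
print("mass near ground truth:", round(float(P[near].sum()), 3))
print("migration % of extent :", round(migration(P, dsA.coords, dsB.coords), 2))
print("label-transfer AMI    :", round(ami_transfer(P, dsA.labels, dsB.labels), 3))
```

```
mass near ground truth: 0.989
migration % of extent : 0.68
label-transfer AMI    : 0.972
```

`0.989` of the coupling mass lands within two grid cells of the true
correspondence although the two slices share no feature space; the average
spot migrates 0.68% of the slide extent after rigid registration, and
cluster labels transferred through `P` agree with the truth at AMI 0.97.

The same pipeline is available from the shell:

```bash
mgw simulate --n-points 1024 --seed 1 --out sim/
mgw align sim/coords_A.csv sim/coords_B.csv \
    --features-a sim/features_A.csv --features-b sim/features_B.csv \
    --config cfg.yaml --out result/
mgw evaluate --coupling result/coupling.npz \
    --coords-a sim/coords_A.csv --coords-b sim/coords_B.csv
mgw selftest            # P1/P2/P3 invariance suite on analytic fields
```

Real data enter through `read_dataset` (h5ad with coordinates in
`obsm["spatial"]`, CSV coordinate/feature pairs, or MatrixMarket features).

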