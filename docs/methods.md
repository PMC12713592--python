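# Methods

## Model

A spatial-omics slice is modeled as samples of a smooth map from physical
space into a modality space: coordinates `s_i ∈ E ⊂ R^k` (k = 2 or 3) with
features `X_i = φ(s_i) + noise`, where `φ: E → M` is the unknown field of
the measured modality.  Two slices of arbitrary modalities share the
physical base space `E` but not the feature space, so their features are
not directly comparable.  The alignment strategy is:

1. **Fields.**  Fit a smooth neural field `φ_θ` per slice by minimizing the
   mean-squared loss `(1/2n) Σ_i ‖φ_θ(s_i) − X_i‖²`.
2. **Pull-back metrics.**  At each point evaluate the space-modality
   Jacobian `J(s) = ∂φ/∂s` and form the pull-back metric
   `g(s) = J(s)ᵀ J(s)`, a symmetric PSD form on the spatial tangent space:
   it measures how strongly features change per unit spatial displacement,
   direction by direction.
3. **Geodesics.**  Approximate Riemannian distances under `g` at the
   resolution of the point set: build a k-NN graph on the coordinates
   (Euclidean neighborhoods), weight each edge (i, i′) by the symmetrized
   local arc-length
   `w = ½√(Δᵀ g(s_i) Δ) + ½√(Δᵀ g(s_i′) Δ)` with `Δ = s_i − s_i′`, and run
   all-pairs shortest paths.  This is the only reading of the arc-length
   that has length units and collapses to `‖Δ‖₂` when `g = I`.
4. **Alignment.**  Solve the Gromov-Wasserstein problem on the two geodesic
   matrices,

   `P* = argmin_{P ∈ Π(a,b)} Σ (d_M(i,i′)² − d_N(j,j′)²)² P_ij P_i′j′`,

   i.e. square-loss GW on the *squared* distances, with balanced uniform
   marginals by default.

Because both slices are compared through distances on the shared base
space, there is no hyperparameter trading off spatial against feature
similarity.  The construction carries three structural guarantees, all
covered by executable tests (`run_invariance_suite`): with identity fields
it reduces exactly to spatial GW on Euclidean graph geodesics; rigid
motions of either slice's coordinates leave the problem unchanged; global
feature-space similarities `λ·U·(·)+b` scale distances by `|λ|` and the
objective by `λ⁴` without moving the optimum.

## Assumptions

- Each modality map is a *smooth immersion*: its Jacobian has full column
  rank, so the slice is a local parametrization of a feature-space
  submanifold.  Regions where a field is (numerically) constant collapse
  to zero-length arcs; a `metric_epsilon > 0` blends the metric toward
  spatial geometry if that is a concern, at the cost of strict fidelity to
  the pull-back construction.
- Features vary smoothly over tissue at the sampling resolution; the k-NN
  graph geodesics are a resolution-level approximation of the continuous
  Riemannian distance.
- Balanced transport: both slices cover the same tissue region.  Partial
  overlap, unbalanced and semi-relaxed variants are out of scope.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| field architecture | 3 hidden layers × 128, SiLU | — | SiLU is C∞, so Jacobians are smooth; 128-wide reaches the noise floor of the synthetic study in a few hundred epochs on one CPU.  Width/depth/optimizer are open design choices in this method class. |
| field training | Adam, lr 1e-2, cosine decay to 1e-4, ≤ 600 epochs | — | Cosine decay lets Adam settle instead of orbiting; training ends with a closed-form least-squares solve of the (linear) output layer, which strictly lowers the loss and makes degenerate targets (constants, linear maps) essentially exact. |
| `weight_decay` | 1e-3 | — | Decoupled L2 on weights (biases exempt; matching ridge in the final-layer solve).  Chosen by minimizing the trained-vs-true Jacobian error on the synthetic generator, where the true Jacobian is known in closed form: it roughly halves the metric error at the preset noise level and the optimum is flat over 3e-4–3e-3. |
| coordinate normalization | per-slice zero mean, unit max pairwise extent, isotropic | — | The objective is rigid-invariant but *not* invariant to spatially rescaling one slice; unit extent makes cross-platform slices comparable.  The scaling is a single factor for all axes — per-axis scaling would distort the metric.  `none` keeps raw units. |
| graph `k` | 10 | neighbors | Standard manifold-learning regime for ~10³–10⁴ points: dense enough for geodesic accuracy, sparse enough that arcs stay local.  Symmetrization is by edge union; mutual k-NN fragments sparse slices. |
| `connect_components` | on | — | GW needs finite distances; disconnected graphs are bridged by the lowest-arc-length edge per component pair on a component-level spanning tree. |
| `metric_epsilon` | 0 | metric units² | 0 is the faithful, hyperparameter-free default; positive values are an extension that blends toward spatial geometry. |
| GW solver | conditional gradient (Frank-Wolfe) | — | Exact inner linear-OT solves (Hungarian for uniform n = m — the LP optimum is a permutation vertex by Birkhoff; sparse HiGHS LP otherwise) and exact line search, tol 1e-9, ≤ 1000 iterations.  An entropic (log-domain Sinkhorn) solver is provided; its marginal feasibility is only as tight as the inner loop. |
| solver init | `auto` | — | The energy is non-convex and plain product-init Frank-Wolfe can land in poor basins (observed: a returned objective of 8.9 when a feasible plan scoring 4.0 existed).  `auto` runs FW from the product plan *and* from a deterministic coarse-to-fine entropic annealing (ε = 0.5, 0.1, 0.02 × mean gradient scale, 8 sweeps each, rounded back onto the polytope), returning the lower objective.  `product` restores the single-start behavior. |
| CCA filter | off by default; `n_components = min(10, d₁, d₂)`, `loading_threshold = 0.3`, ridge 1e-3 | — | Pre-alignment selection of the feature subsets with joint structure across slices.  Samples are paired by spatial nearest neighbor in per-slice-normalized coordinates (the only correspondence information available before alignment); a `given` pairing is the escape hatch.  Selection uses structure loadings (feature–variate correlations) scaled by the canonical correlation, so near-null components cannot dominate; a feature is kept when its best scaled loading reaches 0.3× the per-modality maximum.  The exact published selection rule for this step is not available; this rule is the package's stand-in. |
| `preprocess` | `none` | — | The preprocessing applied to counts in the original studies is unstated.  `library_log1p` (row total → median, then log1p) is the conventional choice for counts; `zscore` is per-feature and therefore voids the feature-similarity guarantee (documented opt-in). |

## Synthetic data generator

The generator produces the conditions every quantitative claim in this
package is measured under: a 32×32 regular grid (n = 1024), a shared 2-D
latent field, per-modality smooth maps, 10 shared + 5 independent features
per modality, additive Gaussian noise with sd 0.05, and an identity
ground-truth correspondence (by index, also after rigid motions).

Two design points deserve explanation because first drafts got them wrong:

- **Latent richness.**  The latent is a sum of 16 Gaussian bumps with
  widths 0.08–0.25 of the slide.  With only a few broad bumps the
  pull-back geometries are nearly flat and anisotropic, and GW between two
  near-flat metrics is ambiguous up to a global rotation — on such draws a
  slightly rotated matching scores a strictly *lower* objective than the
  true correspondence, so recovery is ill-posed for any solver.  Structure
  at several spatial scales (as tissue has) makes the ground truth
  identifiable.
- **Modality maps as immersions.**  Each modality map is an
  orthonormal-column affine embedding plus a mild tanh perturbation
  (`f(z) = Az + 0.4·W₂ tanh(W₁z + c₁) + c₂`).  A saturating random MLP map
  produces rank-deficient Jacobians in whole regions, violating the
  immersion assumption above and making the two modality geometries
  genuinely incomparable — again a property of the data, not the method.

Even so, individual latent draws can admit a small-rotation matching whose
distortion is slightly below the identity's; on one of the five default
study seeds this caps the recoverable near-diagonal mass at ~0.81 (checked
with the closed-form fields, which remove all training error).  The
recovery study therefore reports per-seed values and judges the mean.

What the generator does **not** emulate: count-distribution noise
(negative binomial over-dispersion, dropout), partial tissue overlap,
platform-specific spot geometries, and batch effects.  Passing tests on
this generator demonstrate correctness of the geometry/transport machinery
and recoverability under smooth additive-noise conditions; they do not
certify performance on real count data.

The latent and map Jacobians have closed forms, exposed via `OracleField`;
invariance tests inject these in place of trained networks because the
structural guarantees hold at the level of the metric and should not be
confounded with optimization noise from retraining.

## Numerical choices

- Jacobians of trained fields are exact forward-mode derivatives of the
  network function, chain-rule corrected for the stored input/output
  normalization (a central-difference check is part of the test suite).
- Feature targets are normalized by column centering plus a single global
  scale — itself a feature-space similarity, which the objective is
  invariant to, so it does not alter the learned geometry.
- Arc weights clip tiny negative quadratic forms (PSD round-off) to zero;
  metric tensors are explicitly symmetrized; geodesic matrices are
  symmetrized (½(D + Dᵀ)) and validated finite.
- With `g = I` the arc-weight einsum ordering reproduces the Euclidean
  edge norm bit-for-bit, so the spatial-GW reduction is exact, not
  approximate.
- GW ties: with symmetric inputs multiple global optima exist (e.g. the
  two-point swap).  The solver is deterministic given its config; tests
  assert objective values, never a particular optimum, when ties exist.
- Degenerate inputs: all-zero feature rows under library normalization are
  left at zero (warned); zero-mass coupling rows produce NaN projections
  and are excluded from migration (warned, never silently zeroed);
  constant values make Moran's I undefined (NaN + warning); single-class
  ground truth makes AMI 0 by definition.
- Distance matrices are dense (targeting n ≲ 10⁴); only the k-NN stage is
  sparse.  APSP is per-source Dijkstra on the sparse graph.

## Evaluation conventions

- **Migration** projects target coordinates through the coupling onto each
  source point and reports the coupling-weighted mean displacement as a
  percentage of the target slide's maximal pairwise extent.  Default
  registration is a coupling-weighted rigid (Kabsch) alignment first, so a
  global rigid offset costs nothing; `common_frame` instead measures raw
  displacements after placing both slices in the target's frame (the
  published description of this metric family leaves the registration
  step open; both are provided).
- **AMI** uses hard label transfer at threshold 0 and the permutation-model
  expected-MI correction (arithmetic normalization).  The 50%-confidence
  threshold variant is available through `transfer_labels`.
- **PAS** flags a spot when more than half of its k = 8 spatial neighbors
  carry a different cluster label; the source definition's exact constants
  are not published, so both are exposed.
- AMI/AUROC/AUPRC are computed with scikit-learn; the test suite holds
  them against independent first-principles oracles (hypergeometric
  expected-MI formula, O(n²) pairwise comparisons).

## Problem sizes used in the checks

Unit and property tests run at n = 32–500; the structural invariance suite
at n = 256; the recovery study at the full preset (n = 1024 per slice,
5 seeds); the feature-filter study at n = 1024 over 10 seeds.  These sizes
were chosen so the whole suite completes in minutes on a single CPU while
keeping every study at its stated conditions.

## Known limitations

- Two slices only; no multi-slice joint alignment or 3-D reconstruction.
- Balanced OT only; no unbalanced/partial/semi-relaxed variants.
- The CCA pairing uses spatial nearest neighbors, which presumes the
  slices are roughly pre-oriented; heavily rotated pairs should use
  `pairing="given"` or disable the filter.
- The field class is a fixed MLP family; no uncertainty quantification.
- GW is non-convex: the two-start strategy is a heuristic, and adversarial
  geometries can still defeat it.
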