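# Methods

This note records the models, the parameter choices, and the limits of what
the test suite demonstrates. It is written for a maintainer deciding whether
a number produced by `rsnet` can be trusted, and why each default is what it
is.

## The analysis model

The pipeline treats each resting-state subnetwork as a voxel-level graph.
For one subject and one subnetwork with node time series
x_i(t), the connectivity matrix is the pairwise Pearson correlation
r_ij; binarizing at sparsity s keeps the round(s·n(n−1)/2) largest
correlations as edges of an undirected simple graph. Sparsity, not a raw
correlation cutoff, is the thresholding variable so that all subjects'
graphs have the same edge budget; topology is swept over
s = 0.05 … 0.40 in steps of 0.01 and each metric is reduced to its
trapezoidal area under the curve (AUC), the scalar entering group tests.

Ten global properties are computed per graph. C_p is the mean triangle
clustering coefficient; L_p the mean shortest-path length; E_global the
mean inverse shortest-path length over all pairs; E_local the mean, over
nodes, of E_global of the subgraph induced by each node's neighbors;
assortativity r is Newman's degree-mixing coefficient (Pearson correlation
of degrees across edge endpoints); hierarchy β is the negative slope of
log C on log k over nodes with k ≥ 2 and C > 0; synchronization S is
θ₂/θ_N of the combinatorial Laplacian D − A. The normalized quantities
γ = C_p/⟨C_p⟩_null, λ = L_p/⟨L_p⟩_null and σ = γ/λ use the mean of 100
degree-preserving surrogates produced by double-edge swaps (default
100·|E| swap attempts per surrogate; degree sequences are conserved
exactly, connectivity of the surrogates is not enforced).

Statistics follow a screening design: one two-sample pooled t-test per
network × metric on AUC values at uncorrected α = 0.05 (Bonferroni and
Benjamini–Hochberg are available but off by default, matching the original
screening convention), baseline tables by pooled t from summary statistics
and Yates-corrected χ² (Fisher's exact as the small-count fallback), the
pre/post outcome by between-group one-way F at each timepoint (for two
groups F = t²) plus within-group repeated-measures F from raw paired scores
(for two timepoints, the squared paired t), and metric–clinical association
by Pearson correlation of AUC with the post-minus-pre score gain.

## Numerical choices

- **Edge ranking** uses the signed correlation: negative correlations are
  never selected before positive ones (absolute-value ranking is a config
  option). Ties break by lexicographic node-pair order, which makes edge
  sets nested across increasing sparsity and the sweep deterministic.
- **Edge count** is round-half-up of s·n(n−1)/2.
- **Disconnected graphs**: L_p averages over reachable pairs only, keeping
  λ defined at low sparsity; the alternative L_p = 1/E_global is a config
  option. Unreachable pairs contribute 0 to efficiencies.
- **Undefined metrics** are NaN with a warning — assortativity on
  degree-regular graphs, hierarchy with fewer than two eligible nodes of
  distinct degree, synchronization of edgeless graphs, γ/λ/σ when the
  surrogates have no triangles (common below s ≈ 0.1 on small graphs).
  NaN grid points are excluded pairwise from AUCs, and AUC itself requires
  at least two defined points.
- **Mean clustering is not monotone in sparsity.** Although edge sets are
  nested, C_p can decrease when a new edge inflates a node's degree
  denominator faster than its triangle count; the suite therefore tests
  nestedness and density monotonicity, not metric monotonicity.
- **ICA**: Infomax with a logistic nonlinearity and natural-gradient ascent
  (learning rate 0.005, tolerance 1e−6, up to 1000 iterations, restart with
  halved step on divergence) on the whitened group subspace; FastICA is the
  faster config alternative. Group reduction uses exact SVD rather than an
  iterative expectation–maximization scheme — identical subspace at desk
  scale, simpler. Stability clustering is average-linkage agglomerative on
  1 − |spatial correlation| with as many clusters as components; the
  stability index is mean within-cluster minus mean between-cluster
  similarity (a single run degenerately yields 1).
- **Template matching** assigns components to the seven labels greedily by
  best absolute spatial correlation, one-to-one, with a match floor of 0.3;
  anything unmatched is a hard error, never a silent partial result. Node
  sets are voxels with |z| ≥ 2 in the assigned group map (the map threshold
  is a free parameter of such analyses; 2.0 is surfaced in config).

## The synthetic cohort

The generator emulates the study design the statistics assume: two arms of
20 subjects (40 analyzed), 200 volumes at TR = 3 s, and seven embedded
networks. Its purpose is effect-recovery testing, so every piece of
structure is known:

- **Spatial maps** are isotropic Gaussian blobs (σ = 0.11·min(grid) voxels,
  peak-normalized) at fixed fractional centers on an 18×18×18 default grid
  (a desk-scale stand-in for a full 3 mm standard-space grid; the test
  profile uses 14³). Right-lesion subjects are generated mirrored so that
  the preprocessing flip restores canonical positions — the same logic that
  justifies flipping real images into a common orientation.
- **Time courses** are moving-average-smoothed Gaussian noise (window
  3 TRs, re-standardized), a minimal stand-in for hemodynamic
  autocorrelation. Voxel noise is i.i.d. N(0, σ²) with σ = 0.5 by default;
  neither amplitude is empirically constrained, so both are config.
- **Clustering effect** (target VN): every subject's VN carries 30
  additional amplitude-weighted random coupling courses of total strength
  β = 3.0, which makes its thresholded graph strongly clustered relative to
  degree-matched surrogates (γ ≈ 1.8 at mid-sweep). The intervention arm
  multiplies β by 0.45, so its edge ranking is closer to noise-driven and
  γ drops (≈ 1.35). The shift is multiplicative because the group
  difference of interest is a *relative* loss of clustered organization.
- **Assortativity effect** (target DAN): the network's supporting voxels
  split by map amplitude into two modules; each module puts a variance
  fraction w of its signal on a module-wide course. w is the per-subject
  latent: 0.1 ± 0.12 in controls, 0.7 ± 0.12 in the intervention arm
  (clipped to [0, 0.95]). Module segregation concentrates edges between
  like-degree nodes, raising r from ≈ 0.36 to ≈ 0.49.
- **Clinical scores**: pre-intervention scores are N(20.8, 11²) clipped to
  the 0–66 scale; gains are mean 1.65 (control) / 9.1 (intervention) with
  SD 4.5, constructed as r·z(latent) + √(1−r²)·ε so the population
  correlation with the per-subject coupling latent is exactly the requested
  value (0.5 by default). Clipping at the scale bounds attenuates the
  realized correlation; the generator warns when more than 1% of scores
  clip.

What passing tests therefore show: the pipeline detects group differences
and clinical correlations of the injected kind at realistic sample sizes,
with type-I error near nominal on null cohorts. What they do not show:
robustness to scanner artifacts, head motion, hemodynamic convolution,
lesion-distorted anatomy, inter-subject spatial variability beyond the
mirrored-orientation case, or non-Gaussian noise — none of which the
generator emulates.

## Problem sizes and profiles

Full-fidelity defaults (40 subjects × 200 volumes, 40 components × 100 ICA
repetitions, 36 sparsities × 100 surrogates) are the design parameters of
the emulated study and are what `RunConfig()` encodes. The shipped test
profile (`RunConfig.test_profile()`: 4 + 4 subjects, 120 volumes, 14³ grid,
10 components, 5 ICA runs, node pooling factor 2, sparsity step 0.05, 10
surrogates with 10·|E| swap attempts) was chosen as the smallest
configuration at which all seven subnetworks are still recovered and every
stage is exercised end-to-end. Simulation-based calibration tests
(type-I, power, effect direction) use the ground-truth node sets directly
rather than re-running ICA, since component estimation is tested
separately; they run at n = 20–200 per arm with a coarsened sweep and
reduced surrogate counts.

## Known limitations

- The within-group repeated-measures F is only available from raw paired
  scores; printed summary tables cannot recover it (the pre–post
  correlation is unreported in such tables), and the package refuses to
  guess.
- Graph metrics are binary and global; weighted, nodal and edge-level
  statistics (network-based statistic, rich club, modularity) are out of
  scope.
- Pearson correlation is fixed as the connectivity estimator; partial
  correlation and covariate regression are not implemented.
- The Infomax implementation targets super-Gaussian (sparse, blob-like)
  spatial sources; sub-Gaussian sources would need the extended variant.
- Surrogate connectivity is not enforced, so λ can exceed 1 noticeably on
  strongly clustered graphs whose surrogates fragment.
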