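# Methods

## The analysis

`scnkit` implements a structural covariance network (SCN) analysis of
ROI-level cortical thickness for a two-condition crossover cohort. The
pipeline is:

1. **Covariance matrix.** For each condition, the Pearson correlation of
   mean cortical thickness is computed for every pair of the 68
   Desikan–Killiany cortical ROIs across subjects. Two-sided p-values use
   the exact t transform `t = r·sqrt((n−2)/(1−r²))` on `n−2` degrees of
   freedom (standard for Pearson r; a permutation p would be equally
   defensible but is far more expensive inside the permutation engine).
2. **Binarization.** The 2278 upper-triangle p-values are submitted to the
   Benjamini–Hochberg step-up procedure at rate `q = 0.05`; an edge exists
   iff its pair is BH-significant *and* its correlation is positive.
   Negative correlations are filtered *after* BH: they are part of the
   hypothesis pool but can never become edges. Filtering before BH would
   shrink the pool and shift the step-up threshold; keeping the pool fixed
   makes the edge threshold independent of the sign pattern.
3. **Graph metrics.** On the binary network: mean clustering coefficient C,
   characteristic path length L, global efficiency, local efficiency, and
   per-ROI degree, nodal efficiency and betweenness (normalized by
   `(n−1)(n−2)/2`, so values lie in [0, 1]; raw values are also reported).
   Small-worldness is assessed against 100 degree-preserving
   (Maslov–Sneppen) random references: `γ = C/⟨C_rand⟩`,
   `λ = L/⟨L_rand⟩`, `σ = γ/λ` (the mean, not median, over references —
   the conventional estimator). Each reference is produced by `10·|E|`
   double-edge-swap proposals, rejecting swaps that would create
   self-loops or multi-edges; the attempt budget is a standard mixing
   heuristic and is recorded in output metadata. Graphs with no
   swappable edge pair (e.g. complete graphs) return references equal to
   the input, flagged.
4. **Inference.** Conditions are compared with a paired label-permutation
   test: each permutation independently swaps every subject's two
   condition rows with probability 1/2 and re-runs the *entire* pipeline
   (correlation, BH thresholding, metrics) on both permuted conditions.
   The edge threshold is recomputed inside every permutation because it is
   data-dependent; freezing it would understate the null variance. With
   the add-one estimator `p = (1 + #{null ≥ obs})/(P + 1)` a p-value is
   never exactly zero; one-sided p-values in both directions and the
   two-sided p (doubled smaller tail, capped at 1) are all reported, with
   two-sided decisions as the headline. Nodal metrics are corrected across
   the 68 ROIs by BH at `q = 0.05`, on the two-sided p (headline) and on
   each one-sided p (reported alongside, for directional claims).
   Reference-network seeds inside permutations derive deterministically
   from (master seed, permutation index), so full results — null
   distributions included — are reproducible bit for bit.

### Conventions for disconnected graphs

FDR-thresholded covariance networks are frequently disconnected, so:

* L averages each node's mean distance to *reachable* partners over nodes
  with at least one reachable partner; an edgeless graph has no defined L
  and is signalled as undefined (NaN inside the permutation engine).
* Efficiencies use the Latora–Marchiori convention `1/∞ = 0` and are
  always defined.
* Nodes with degree < 2 have clustering 0 and local efficiency 0.
* λ is the ratio of path lengths, γ of clustering coefficients; if the
  random references have zero mean clustering the small-world ratios are
  undefined and omitted rather than reported as infinities.

## The synthetic cohort generator

No human data ships with the package; every analysis runs on a synthetic
cohort with *known* covariance structure so the pipeline can be calibrated
and its power measured against ground truth.

For subject `s` under condition `c`,

    x_sc = μ_c + L_c (√ρ · z_s + √(1−ρ) · e_sc),  Σ_c = L_c L_cᵀ,

with a shared latent subject effect `z_s` giving cross-condition
correlation ≈ ρ per ROI — the within-subject dependence that the paired
permutation exploits. Defaults:

| parameter | default | rationale |
|---|---|---|
| cohort | 43 young + 37 old subjects, 2 conditions | the crossover design under study |
| baseline thickness | 2.5 mm ± 0.25 mm SD | physiologically plausible cortical values; irrelevant to correlation-based downstream stages |
| subject reliability ρ | 0.9 | scan–rescan ICC of FreeSurfer ROI thickness is ≈0.8–0.95; thickness is a stable trait over weeks |
| covariance modules | frontal/parietal/temporal/occipital at r = 0.55; paralimbic (incl. insula) at r = 0.15 | association cortex shows strong, reliable thickness covariance; limbic/paralimbic ROIs (entorhinal, temporal pole) have lower measurement reliability and weaker covariance |

Condition effects are expressed as mean shifts (regional thinning, mm) and
within-module correlation increments applied on the correlation scale. Any
correlation pushed above 0.999 is a hard configuration error, not a silent
clip — clipping would distort recovery simulations. Module index sets must
be disjoint; every condition target is checked for positive
semi-definiteness (smallest eigenvalue ≥ −1e−10) at construction.

What the generator does **not** emulate: vertex-level surfaces, spatial
smoothness, scanner noise, age-dependent covariance differences, or the
empirically observed long-tailed degree distribution of real SCNs. Passing
tests therefore demonstrate correctness and calibration of the *method*,
not properties of any real cohort.

### Why the power-study geometry looks the way it does

A binarized covariance network can only express a correlation change that
**crosses the FDR edge threshold** (r* ≈ 0.31 at n = 80, q = 0.05). Pilot
simulations showed that placing every module near r* drowns both the
observed differences and the permutation null in binary edge-flip noise.
The recovery study therefore injects Δr = +0.30 on the weak paralimbic
module (0.15 → 0.45, crossing r*), while the association modules sit
stably above threshold. With 500 permutations, BH across 68 ROIs can only
flag an ROI whose observed difference exceeds *all* 500 null draws, and at
least three such ROIs are needed (the add-one minimum p of 1/501 exceeds
the rank-1 BH threshold 0.05/68); occasional coherent pseudo-module
appearances in permutations — a swap imbalance shifts the mixture
correlation of the boosted module near r* — make per-cohort full recovery
intrinsically bimodal: a cohort tends to recover either most of the
injected module or none of it. The recovery acceptance therefore asserts
detection rates for the global metrics and a mean recovered-hub count for
the nodal metric, rather than full per-cohort hub recovery. All detection
thresholds were frozen from a pilot run (recorded with its own seed)
before the confirmatory simulations.

Two further properties of nodal inference on binarized networks are worth
knowing. First, under the pure null the nodal BH correction is extremely
conservative (simulated nodal false-flag rate ≈ 0), because flagging any
ROI requires several ROIs to beat *all* permutation draws simultaneously.
Second, a localized covariance effect legitimately spills over: once the
injected module is connected, a single chance bridge edge to the rest of
the network raises the nodal efficiency of *every* bridged node, so
BH-flagged ROIs outside the injected module are genuine indirect
consequences of the effect, not false positives.

## Numerical choices

* Correlations are clipped to [−1, 1] before the t transform; |r| = 1 maps
  to p = 0.
* The permutation hot path recomputes the correlation/BH/adjacency step in
  a vectorized routine working on the upper triangle only; a test pins its
  exact equivalence to the reference route (`correlation_matrix` +
  `threshold_fdr`, which go through scipy.stats and statsmodels).
* All-pairs distances use breadth-first search (scipy.sparse.csgraph for
  the full graph, a boolean matrix-iteration BFS for the small
  neighbour subgraphs of local efficiency); betweenness uses the Brandes
  algorithm (networkx).
* Demo problem sizes: the bundled demo config runs 1,000 permutations with
  the non-reference global metrics (C, L, E_global, E_local) in the
  permutation null and reports γ/λ/σ for the observed networks against 100
  references. Re-running the reference ensemble inside every permutation
  is supported (per-permutation derived seeds) and unit-tested, and can be
  requested by listing `gamma`/`lambda`/`sigma` under `metrics.global`.
* Every output file is stamped with the SHA-256 hash (first 16 hex digits)
  of its configuration; the run manifest records seed, thresholds and
  library versions. Identical config + seed reproduces all outputs byte
  for byte.

## Known limitations

* Binarization discards edge weights; correlation changes that do not
  cross the edge threshold are invisible by construction (this is a
  property of the method, demonstrated directly by the pilot).
* The t-transform p-values assume approximately Gaussian thickness across
  subjects; heavy-tailed morphometry would make the edge threshold
  miscalibrated (the permutation test itself remains exact either way).
* Group-stratified analysis reuses the same machinery per group and
  requires ≥ 4 subjects per group; small groups yield very unstable
  covariance estimates.
* The paired permutation test assumes within-subject exchangeability of
  condition labels under the null; order or session effects that differ
  between conditions would violate it.
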