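# scnkit

Structural covariance network (SCN) analysis of ROI cortical thickness.

Brain regions whose morphology co-varies across individuals form networks:
nodes are atlas regions, edges are significant across-subject correlations
of a morphometric measure — here, mean cortical thickness over the 68
Desikan–Killiany regions. `scnkit` builds these networks per condition of
a two-condition crossover study (e.g. one night of restricted sleep vs.
normal sleep), characterizes their topology, and tests condition
differences with a paired permutation scheme. It is aimed at neuroimaging
researchers who already have ROI thickness tables (e.g. exported from
FreeSurfer) and want a reproducible, fully seeded network comparison.

## Method in brief

Per condition, the ROI×ROI Pearson correlation matrix `r` is computed
across subjects, with p-values from `t = r√((n−2)/(1−r²))` on `n−2` df.
Edges are pairs that survive Benjamini–Hochberg FDR at `q < 0.05` over the
2278 region pairs and have `r > 0`. On the resulting binary graph:

* clustering coefficient **C**, characteristic path length **L**;
* small-worldness against 100 degree-preserving (Maslov–Sneppen rewired)
  random networks: **γ** = C/⟨C_rand⟩, **λ** = L/⟨L_rand⟩, **σ** = γ/λ
  (σ > 1 indicates small-world organization);
* global and local efficiency **E_global**, **E_local**;
* per-ROI degree, nodal efficiency and betweenness.

Conditions are compared with a paired label-permutation test: each
permutation randomly swaps every subject's two condition rows and re-runs
the entire pipeline (correlation → FDR threshold → metrics), giving a null
distribution of metric differences; `p = (1 + #{null ≥ obs})/(P + 1)`.
Nodal metrics are FDR-corrected across the 68 ROIs.

A synthetic cohort generator (multivariate normal thickness with
configurable covariance modules, condition-specific regional thinning and
covariance increments, and a latent subject effect matching the crossover
design) provides ground-truth data for calibration and power analysis; no
imaging data is required. See `docs/methods.md` for models, conventions
and design rationale.

## Worked example

Run the bundled demo — an 80-subject synthetic crossover cohort in which
the paralimbic module (bilateral insula, parahippocampal, entorhinal,
temporal pole, transverse temporal) gains +0.30 within-module correlation
under the restricted condition:

```sh
scnkit run-all -c configs/demo.yaml -o demo_run
cat demo_run/summary.txt
```

```
Paired permutation test (1000 permutations, n=80 subjects)

metric                restricted        full        diff  p(2-sided)
clustering                0.7080      0.5585      0.1495      0.0020
path_length               1.0463      1.2311     -0.1848      0.4755
global_efficiency         0.0933      0.0857      0.0076      0.5395
local_efficiency          0.7143      0.5617      0.1525      0.0040

nodal degree: 3 ROI(s) significant after BH q=0.05: lh_parahippocampal, lh_superiorfrontal, lh_temporalpole
```

Reading this: the restricted-condition network is more densely clustered
(C 0.71 vs 0.56) — the injected covariance increase pushes the paralimbic
pair correlations across the FDR edge threshold, creating new edges — and
the permutation test flags the clustering (p = 0.002) and local-efficiency
(p = 0.004) increases. Path length and global efficiency differences are
within null variability, as expected for an effect confined to one module. The output directory
also contains the per-condition correlation/p-value matrices, binary
networks, full metric JSON (including γ/λ/σ against 100 degree-matched
references), the permutation report with per-ROI p-values and BH
decisions, and a manifest recording the config hash, seed and thresholds;
re-running the same config and seed reproduces every file byte for byte.

Other subcommands: `simulate`, `build-network`, `metrics`, `permute`, and
`demographics` (pooled two-sample t from printed group summaries,
chi-square on 2×2 counts), e.g.

```sh
scnkit demographics --t-summary anxiety:43,2.79,2.45:37,1.46,1.46 \
                    --chi2 gender:21,22,20,17
```

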