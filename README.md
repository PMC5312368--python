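# nmrpath

Serum ¹H-NMR metabolomics of staged disease progression, from bucketed
spectra to altered metabolic pathways.

`nmrpath` implements the full inference chain used in NMR studies of staged
gastric carcinogenesis (five groups: controls `CON` and the stages `GS`,
`LGD`, `HGD`, `GC`):

1. **Preprocessing** — zero the residual-water region (δ 5.7–4.6), align
   spectra segment-wise against a median reference, normalize each spectrum
   to a constant total integral of 100.
2. **SRV clustering** (statistical recoupling of variables) — merge
   consecutive 0.001-ppm buckets whose across-sample Pearson correlation
   stays above a threshold (default 0.8) into peak-coherent clusters of at
   least one singlet width (0.01 ppm); clusters become the variables for
   everything downstream.
3. **Chemometrics** — PCA, two-class PLS-DA with response permutation
   validation, and OPLS-DA with one orthogonal component. Differential
   variables are selected by the double rule VIP > 1 **and**
   |r| > r\*(α), where r is the correlation of a variable with the first
   predictive score tp1 and

   r\*(α) = √( t² / (t² + df) ),  df = n₁ + n₂ − 2,

   with t the two-tailed Student-t quantile. At the study's group sizes
   this gives r\* = 0.389 / 0.372 (α = 0.01) and 0.301 / 0.288 (α = 0.05).
4. **R-STOCSY / OR-STOCSY** — the cluster autocorrelation matrix
   C = X′X / (NS − 1) on the autoscaled cluster matrix (NS spectra × NV
   clusters); for a stage-vs-control contrast an orthogonal filter first
   removes the dominant class-orthogonal variation. Pairs with |r| ≥ 0.9
   are significant correlations: *intra*-metabolite pairs aid assignment,
   *inter*-metabolite pairs feed the network stage.
5. **Network reconstruction** — KGML-style pathway XML files are merged
   into one bipartite metabolite–enzyme "biograph"; the perturbed network
   of a stage is the union of all shortest paths between its correlated
   metabolite pairs, which pulls in NMR-invisible intermediates and the
   connecting enzymes.
6. **Pathway impact** — each pathway is projected to its metabolite graph
   (metabolites adjacent iff they share an enzyme); impact is the summed
   betweenness centrality of the hit metabolites over the pathway total,
   significant at impact ≥ 0.3, with a hypergeometric enrichment p
   alongside.

A first-class synthetic-data module generates group-structured spectra
(Lorentzian multiplets, log-normal concentrations, latent-factor
correlations, peak jitter, noise) and toy pathway files with known ground
truth, so every stage is testable without any download.

## Worked example

Run the whole pipeline on the default synthetic design (group sizes
32/11/15/15/11, δ 9.00–0.00 at 0.001 ppm):

```python
from nmrpath.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=7, outdir="out", synthetic={}, n_perm=50)
report = run_pipeline(cfg)
print(report["n_clusters"], report["coverage_fraction"])
for stage, r in report["stages"].items():
    print(stage, r["pls_r2y"], r["pls_q2"], r["rpt_valid"],
          r["n_differential"], r["n_edges_intra"], r["n_edges_inter"])
```

prints

```
35 0.639781
GS 0.7515 0.4458 True 11 6 0
LGD 0.8973 0.7961 True 10 6 2
HGD 0.9149 0.8637 True 11 6 2
GC 0.9642 0.9249 True 9 6 0
```

Read: SRV found 35 clusters capturing ~64% of the total signal (the rest
is unassigned background and noise, by design). Each stage-vs-control
PLS-DA is validated by its permutation test (`True`), and discrimination
strengthens monotonically along the stage sequence (Q² rising from 0.45 in
early gastritis to 0.92 in carcinoma) — the planted effects grow with
stage. OPLS-DA flags ~10 differential cluster variables per contrast;
OR-STOCSY at |r| ≥ 0.9 finds 6 intra-metabolite correlations per stage
(multiplet clusters of the same metabolite) and, in the middle stages, 2
inter-metabolite edges from a planted latent factor, which seed the
perturbed-network and pathway-impact stages. Per-stage artifacts
(differential tables, edge lists, GraphML networks, pathway tables) are
written under `out/`.

The same run is available from the shell:

```sh
nmrpath run-all --config config.yaml --seed 7 --outdir out
```

with subcommands `simulate`, `preprocess`, `srv`, `models`, `stocsy`,
`network`, `pathways` and `make-fixtures` for stage-by-stage use.

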