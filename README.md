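# gipni

Sample-specific **g**ene **i**nteraction **p**erturbation **n**etwork
analysis and a linear prognostic **i**ndex built on it, for squamous
tumor transcriptomics.

Static differential expression treats each gene in isolation. In
normal tissue, interacting gene pairs keep a stable relative ordering;
in tumors that coordination breaks down. `gipni` quantifies this per
sample: expression values are converted to within-sample ranks, and for
every edge (i, j) of a background interaction network the rank
difference

```
d_s(i, j) = rank_s(i) - rank_s(j)
```

is compared with the reference difference `d_ref(i, j)` obtained by
ordering genes by their mean expression in normal reference tissue.
The deviation

```
p_s(i, j) = d_s(i, j) - d_ref(i, j)
```

is the perturbation of edge (i, j) in sample s. Stacked over edges and
samples this gives the **edge perturbation matrix**, the central object
of the pipeline. Everything downstream consumes it:

- **Sample scores** — `log2(mean_e |p_s(e)| + 1)`, the per-sample
  network perturbation burden (tumors score higher than normals).
- **Differential edges** — rank-sum tests of `|p|` tumor vs normal
  with Benjamini–Hochberg control; their endpoint genes form the
  candidate gene pool.
- **Perturbation subtypes** — Monti consensus clustering (PAM on
  1 − Spearman distance over edges, CDF delta-area selection of k).
- **Survival index** — per-gene univariate Cox screening with Fisher
  meta-p combination across cohorts, a feature-selector × learner
  benchmark (stepwise Cox, lasso/ridge/elastic-net Cox, random survival
  forest, boosting, supervised components, survival SVM, PLS-Cox)
  ranked by Harrell's C-index, and a final linear index
  `score_s = Σ_g β_g · z_g(s)` with log-rank-optimal cutpoint
  stratification and time-dependent AUC evaluation.
- **ssGSEA** — single-sample gene-set enrichment (rank-weighted ECDF
  difference, α = 0.25) for pathway and immune-infiltration association
  with the index.

A synthetic-data module (`gipni.datagen`) generates cohorts with the
statistical structure the method assumes — a stable normal gene
ordering, planted rank-coordination disruption with molecular
subtypes, survival driven by perturbation burden, and a toy
single-cell experiment — so the entire pipeline is testable without
any downloads. The package ships the published 11-gene signature list
(`gipni.survival.packaged_signature_genes()`).

## Worked example

```python
from gipni import datagen, io, perturbation, subtypes
from scipy import stats

cfg = datagen.SimulationConfig()            # 200 genes, 600 edges, 2 cohorts
net = datagen.make_toy_network(cfg.n_genes, cfg.n_edges, cfg.seed)
cohorts, surv, truth = datagen.simulate_bulk(cfg, net)

epm = perturbation.perturbation_matrix(cohorts[1], cohorts[0], net)
score = perturbation.sample_perturbation_score(epm)
t = score[epm.samples_of_class("tumor")]
n = score[epm.samples_of_class("normal")]
print(t.mean() - n.mean())                  # 0.2217
print(stats.mannwhitneyu(t, n).pvalue)      # 1.0e-14

res = subtypes.consensus_cluster(epm.subset_samples(epm.samples_of_class("tumor")))
print(res.optimal_k)                        # 3
```

Tumor samples carry a mean perturbation score 0.22 log2 units above
the matched normals (rank-sum p ≈ 1e-14): the planted coordination
loss is detected. Consensus clustering recovers the three planted
molecular subtypes. On the survival side, a Cox signature refit on one
simulated cohort carries a C-index of 0.86 into the held-out cohort,
with 1/3/5-year time-dependent AUCs of 0.92/0.93/0.94.

The same steps are exposed on the command line:

```bash
gipni simulate --outdir sim/
gipni perturb --expr sim/expr_COHORT1.tsv --meta sim/meta_COHORT1.tsv \
      --normals sim/expr_REF.tsv --network sim/network.tsv --out epm.tsv
gipni subtype --epm epm.tsv --out subtypes.tsv
```

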