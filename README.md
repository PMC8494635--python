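# cerebstat

Statistics for regionally resolved single-nucleus RNA-seq atlases — built
around the questions a lobule-resolved cerebellar atlas has to answer:

* **Sampling power** — how many nuclei must be profiled so that every rare
  cell type is captured often enough to cluster?  Modelling the count of one
  type with prevalence *p* among *n* nuclei as X ~ Binomial(*n*, *p*), the
  probability that all *m* independent rare types are each seen at least *k*
  times is `[P(X ≥ k)]^m`, evaluated with the exact binomial tail.
* **Spatially variable genes** — for each gene, the log index of dispersion
  of per-region expression, `logVMR = ln(Var_j(x_j) / Mean_j(x_j))`, is
  tested against a Gaussian null centred on the mode of the logVMR
  distribution (located by kernel density estimation) with a standard
  deviation from the below-mode half-sample reflected across the mode —
  robust to the right tail of genuinely spatial genes.  Upper-tail p-values
  are Benjamini–Hochberg adjusted.
* **Regional composition of clusters** — with `n_ij` nuclei of cluster *i*
  in lobule *j* and `N_j` the lobule totals of the cluster's coarse cell
  type, expected counts `E_ij = N_i · N_j / Σ_j N_j` feed a Pearson
  chi-squared test on *k*−1 degrees of freedom, and lobule enrichment
  `LE_ij = (n_ij / Σ_j n_ij) / (N_j / Σ_j N_j)` quantifies where the
  cluster concentrates.  Replicate consistency correlates LE vectors
  between two per-region replicate sets; clusters with FDR < 0.001,
  max LE > 2 and replicate r > 0.85 are labeled spatially significant.
* **Continuity metric m** — are two clusters discrete states or ends of a
  continuum?  Cells are ordered along a trajectory (external pseudotime or
  the first principal axis), each differentially expressed gene is fit with
  a logistic `y = a + (d−a)/(1+exp(−b(x−x0)))` against normalized rank
  `x = rank/N`, and the maximum slope normalized for cell number and
  dynamic range is `m = b/4`.  Small m means graded variation, large m a
  step-like switch; pairs are compared through the ECDF of log10(m).

A synthetic-data module generates count matrices and annotations with the
structure each stage assumes (marker-gene clusters with configurable lobule
compositions, logistic-activation trajectories, Poisson-background region
summaries with a spatial subset), so the whole pipeline runs and is tested
without any download.

## Worked example

```python
import numpy as np
from cerebstat.power import PowerParams, detection_probability, min_nuclei_for_power
from cerebstat.simulate import AtlasSimConfig, ClusterSpec, simulate_atlas
from cerebstat.composition import analyze_composition

print(detection_probability(PowerParams(n=611034, p=0.0015, k=70, m_types=10)))
print(min_nuclei_for_power(0.9, p=0.0015, k=70, m_types=10))

comp = np.full(16, 0.7 / 15); comp[0] = 0.3      # 30% of cells in lobule 1
cfg = AtlasSimConfig(n_genes=60, clusters=[
    ClusterSpec("granule_enr", "granule", 2000, tuple(comp)),
    ClusterSpec("granule_uni", "granule", 8000, tuple(np.full(16, 1 / 16))),
], seed=1)
expr, ann = simulate_atlas(cfg)
results, le = analyze_composition(ann)
print(results[["chi2", "df", "q", "max_le", "replicate_r", "labeled"]].round(3))
```

prints

```
1.0
60486
                chi2  df    q  max_le  replicate_r  labeled
cluster
granule_enr  635.121  15  0.0   2.584        0.966     True
granule_uni  158.780  15  0.0   1.084        0.966    False
```

At 611,034 nuclei, ten rare types of prevalence 0.15% are each captured at
least 70 times with probability ≈ 1 (the threshold 90% is already reached
at 60,486 nuclei).  In the simulated atlas, the cluster built with 30% of
its cells in one lobule is labeled spatially significant (max LE 2.6,
replicate r 0.97), while the uniform cluster — though its chi-squared test
is powered enough to reject at n = 8,000 — shows no enrichment (max LE 1.1)
and is not labeled.

## Command line

```sh
cerebstat power --n 611034 --prevalence 0.0015 --threshold 70 --types 10
cerebstat simulate atlas --config clusters.yaml --seed 1 --outdir sim/
cerebstat composition --annotations sim/annotations.tsv --out composition.tsv
cerebstat spatial-genes --matrix sim/matrix.mtx --genes sim/genes.tsv \
    --cells sim/cells.tsv --annotations sim/annotations.tsv --out spatial.tsv
cerebstat continuity --matrix ... --annotations ... --group-a A --group-b B \
    --out continuity.tsv
cerebstat run --config pipeline.yaml          # full pipeline
```

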