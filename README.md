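# raretax

Abundant and rare soil bacterial sub-communities respond differently to
agricultural management: the handful of dominant OTUs (operational
taxonomic units) that carry most 16S reads tend to assemble
stochastically, while the long tail of rare OTUs is often shaped by
environmental selection and carries most of the community's diversity.
`raretax` is a toolkit for making that contrast quantitative from three
inputs — an OTU count table (samples × OTUs), a rooted phylogeny with
branch lengths, and per-sample metadata (group label plus soil
covariates). It is written for microbial ecologists who want the whole
chain — abundance partitioning, diversity, null-model assembly
inference, co-occurrence networks, environment association — as plain,
tested Python functions rather than a patchwork of platforms, and it
ships a synthetic-data generator so the entire chain runs (and is
benchmarked) with no external download.

## What it computes

* **Abundance classes** — an OTU is *abundant* when its mean relative
  abundance across samples is ≥ 0.1 %, *rare* below 0.01 %, *moderate*
  between; per-sample local flags (> 0.1 % within a sample) are
  reported alongside. Downstream analyses run on the whole, abundant,
  and rare fractions.
* **Alpha diversity** — observed richness, bias-corrected Chao1,
  Shannon *H* (natural log), Simpson concentration Σp², Pielou *J*,
  Good's coverage; low-count OTU filtering (total < 2) and rarefaction
  without replacement.
* **Beta diversity** — Bray–Curtis distances, non-metric
  multidimensional scaling (Kruskal stress-1), Wilcoxon rank-sum group
  contrasts with Benjamini–Hochberg FDR.
* **Assembly processes** — NTI and betaNTI against a tip-shuffle null:
  `betaNTI = (betaMNTD_obs − mean_null) / sd_null`, with |betaNTI| > 2
  read as deterministic assembly (below −2 homogeneous selection,
  above +2 variable selection) and |betaNTI| < 2 as stochastic.
* **Co-occurrence networks** — pairwise Spearman correlations, edges at
  |ρ| ≥ 0.6 and BH-adjusted p ≤ 0.01; topology (degree, density,
  clustering, geodesic distance, diameter, Louvain modularity),
  degree-preserving rewired baselines (mean ± sd), and Zi–Pi node roles
  (module hubs, connectors, network hubs at the 2.5 / 0.62 cutoffs).
* **Environment association** — Mantel tests of community distance
  against each soil covariate per fraction × group (with FDR stars),
  and RDA on Hellinger-transformed counts with selection-aware
  permutation forward selection.

The model details, defaults, and known limits are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate a study in which each sample experiences its own environmental
optimum (variable selection), then ask whether the null-model inference
recovers it:

```python
from raretax import (SimulationConfig, simulate_dataset, classify_taxa,
                     partition_summary, cophenetic_distances, beta_nti,
                     summarize_assembly)
from raretax.assembly import within_group_pairs

data = simulate_dataset(SimulationConfig(
    n_otus=200, n_samples_per_group=10, depth=20000,
    assembly_mode="variable_filtering", seed=1))

classes = classify_taxa(data.table)
print(partition_summary(data.table, classes).round(3))

coph = cophenetic_distances(data.tree)
pairs = within_group_pairs(data.table, data.metadata.group)
bnti = beta_nti(data.table, coph, n_null=999, seed=1, sample_pairs=pairs)
print(summarize_assembly(bnti, data.metadata.group).round(2))
```

```
          n_otus  otu_fraction  mean_read_fraction
label
abundant      52         0.260               0.981
moderate      45         0.225               0.017
rare         103         0.515               0.002

       n_pairs  median_beta_nti  frac_deterministic  frac_homogeneous_selection  frac_variable_selection
group
M           44             3.42                0.68                         0.0                     0.68
R           45             2.63                0.62                         0.0                     0.62
```

The median betaNTI above +2 in both groups and the ~65 % of sample
pairs called deterministic (all on the variable-selection side) recover
the planted regime; a neutral simulation at the same scale yields
medians inside (−2, 2) with under 10 % deterministic calls. The
partition table reads: 26 % of OTUs are abundant at this small pool
size yet carry 98.1 % of reads, while the 51.5 % of OTUs that are rare
carry 0.2 %.

The same chain is available from the shell:

```bash
raretax run --outdir out/ --mode variable_filtering --seed 1
raretax simulate --n-otus 300 --samples-per-group 15 --outdir sim/
raretax partition --otu-table sim/otu_table.tsv --out classes.tsv
```

`raretax run` writes the full report bundle (classes, alpha table,
NMDS coordinates, betaNTI pairs and per-fraction summaries, per-fraction
network bundles with node roles and random baselines, the Mantel table,
an RDA summary, and a `manifest.json` recording every threshold and
seed); re-running the same config reproduces every file byte-for-byte.

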