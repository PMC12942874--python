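# mdagkit

Comparative analysis of microbial community metabolism through **metabolic
DAGs (m-DAGs)** — for microbiome researchers who have per-sample KEGG-Ortholog
(KO) annotations and want to compare the *structure* of the metabolic
capacity those annotations encode, not just pathway abundances.

## The method

Each sample's KO repertoire is mapped (KO → EC → reaction) to a reaction set
and turned into a **reaction graph** *G_R*: one node per oriented reaction
(reversible reactions contribute a forward and a backward node, the latter
labelled `…rev`), and an arc *R → R′* iff some compound produced by *R* is
consumed by *R′*. Contracting each strongly connected component of *G_R*
gives its condensation, the **m-DAG**; each component is a **metabolic
building block (MBB)**, an emergent functional module. A single-reaction MBB
is *essential* if deleting it disconnects the m-DAG further.

Samples are compared with the **Munkres similarity**, a two-level
maximum-weight bipartite matching: reactions are matched within MBB pairs
(similarity = matched score / size of the larger MBB), then MBBs are matched
across the two m-DAGs (similarity = matched weight / number of MBBs in the
larger m-DAG). The **Munkres dissimilarity** is *d* = 1 − sim². On the
resulting matrix the toolkit provides:

* per-sample topological descriptors (size, connectivity, diameter, average
  path length, edge density, essential-MBB proportion) and a
  PCA + Mahalanobis + chi-square outlier screen with FDR correction;
* complete-linkage hierarchical clustering with elbow and silhouette curves,
  classical (Torgerson) MDS embedding, and per-clade **approximately
  unbiased (AU)** support from multiscale bootstrap
  (*z(r) = v√r + c/√r*, AU = 1 − Φ(v − c));
* **core / pan metabolism** (intersection / union of reaction sets) per
  cluster, metadata group, individual or cohort, with m-DAG summaries;
* **sparse PLS-DA** (ncomp = 2, keepX = (50, 30)) on MBB completeness
  features, selecting discriminant MBBs at ≥ 95% of the maximal absolute
  loading per component, rolled up to pathway-level reaction counts.

A fully seeded synthetic generator produces a toy reaction universe and an
age-structured cohort (infant-like, adult-like, and bimodal elderly
repertoire modes with repeated samples per individual), so the entire
pipeline runs and is tested end-to-end without any external data. See
`docs/methods.md` for the models, parameter defaults and design choices.

## Worked example

```python
import mdagkit as mk
from mdagkit.synthetic import generate_universe, generate_cohort

synth = generate_universe(seed=1)            # ~300-reaction toy universe
cohort = generate_cohort(synth, seed=1)      # 3 groups x 10 individuals x 4 samples

# KO repertoires -> reaction sets -> m-DAGs
reactions = {s: set(mk.map_kos_to_reactions(synth.universe, kos))
             for s, kos in cohort.sample_kos().items()}
mdags = {s: mk.condense_to_mdag(mk.build_reaction_graph(synth.universe, r, sample_id=s))
         for s, r in reactions.items()}

# pairwise Munkres dissimilarity and clustering
d = mk.dissimilarity_matrix(mdags)
tree = mk.hierarchical_cluster(d)
sel = mk.choose_k(tree, d)
print("recommended k:", sel.recommended_k)
print("mean silhouette at k=3:", round(sel.silhouette[sel.ks.index(3)], 3))

labels = tree.cut(sel.recommended_k)
print("cluster sizes:", labels.value_counts().sort_index().to_dict())

# AU support for the three cluster clades
coords, _ = mk.embed_mds(d, dims=len(d) - 1)
au = mk.au_bootstrap(coords, replicates=1000, seed=1, leaf_ids=d.sample_ids)
for lab in sorted(labels.unique()):
    leaves = frozenset(labels.index[labels == lab])
    print(f"cluster {lab}: n={len(leaves)}, AU={au.au_for(leaves):.2f}")

# core/pan summary for the whole cohort
summary, _, _ = mk.group_mdag_summary(synth.universe, {"cohort": reactions})
print(summary[["kind", "n_reactions", "n_mbbs", "n_essential", "prop_essential"]]
      .to_string(index=False))
```

Output:

```
recommended k: 3
mean silhouette at k=3: 0.648
cluster sizes: {1: 56, 2: 40, 3: 24}
cluster 1: n=56, AU=1.00
cluster 2: n=40, AU=1.00
cluster 3: n=24, AU=1.00
kind  n_reactions  n_mbbs  n_essential  prop_essential
core           88      40            3          0.0750
 pan          251     105            3          0.0286
```

Both k-selection criteria point at the three planted repertoire modes
(adults plus adult-like elderly; infant-like elderly; infants), each with
unit bootstrap support. The cohort core (reactions every sample carries)
retains 88 of the 251 pan reactions, and its m-DAG has a higher proportion
of essential single-reaction MBBs than the pan m-DAG — removing modules from
a smaller network disconnects it more easily.

## Command line

```bash
mdagkit simulate --outdir demo --seed 1           # universe + cohort TSVs
mdagkit run-all --universe demo/universe \
    --ko-table demo/ko_table.tsv --metadata demo/metadata.tsv \
    --outdir demo/run --seed 1
```

Stage subcommands (`build`, `topology`, `compare`, `cluster`, `corepan`,
`discriminate`) write the same deterministic tables as a full run; every run
directory contains a `manifest.json` with the effective configuration, its
hash and all stage outputs. A YAML file covering every `PipelineConfig`
field can replace the flags (`--config`).

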