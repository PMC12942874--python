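# Methods

`mdagkit` analyses the metabolic capacity of microbial communities through
directed-graph representations of their reaction repertoires. This note
records the models and procedures implemented, the parameters that matter,
the design choices made where the design was genuinely open, and what the
synthetic data generator does and does not emulate.

## From KO repertoires to reaction graphs

Input is a per-sample table of KEGG Orthologs (KOs). Each KO maps to its
enzyme (EC) numbers and each EC to the reactions it catalyses; the union over
a sample's KOs is its reaction set. KOs without reaction links are skipped
with a warning by default (`strict` mode raises), since metagenome
annotations routinely contain them. Stoichiometry is ignored throughout:
substrates and products are sets, which is all the arc rule below consumes.

The **reaction graph** (RG) has one node per oriented reaction — a forward
node per reaction plus a backward node (label suffix `rev`) per reversible
reaction, with substrate and product sets swapped — and an arc `R → R'`
exactly when some compound produced by `R` is consumed by `R'`.

Two consequences of reading the rule verbatim are handled explicitly:

* the forward and backward orientations of a reversible reaction always form
  a 2-cycle (each consumes what the other produces). The default
  `strict` arc policy keeps this; a `no-self-pair` policy suppresses arcs
  between the two orientations of one reaction for sensitivity analysis.
* a reaction that produces a compound it also consumes would get a self-arc;
  self-arcs are never created (the rule is stated for a pair of reactions,
  and self-arcs are invisible to the condensation anyway).

No compounds are excluded from arc mediation by default; an exclusion list
(e.g. for currency metabolites) is available in the configuration.

## m-DAGs, MBBs and essential nodes

Contracting each strongly connected component (SCC) of the RG to one node
yields its condensation, the **metabolic DAG (m-DAG)**; each SCC is a
**metabolic building block (MBB)**. Condensation preserves the number of
(weakly) connected components. MBB identity is a content hash of the sorted
member labels, so the same reaction module receives the same id in every
sample — this is what makes cohort-wide feature matrices and core/pan
comparisons possible.

A single-reaction MBB is **essential** when deleting it (with incident arcs)
increases the number of weak components of the m-DAG. This is equivalent to
being an articulation point of the undirected m-DAG, which is how it is
computed (linear time); the test suite checks the equivalence against
exhaustive single-node deletion. "Connected components" of these directed
graphs are always weak components: isolated-node and component-size counts
are only meaningful in the undirected sense.

### Topological descriptors

Per sample: counts of reactions, enzymes, compounds, MBBs (single- and
multi-reaction), weak components, largest-component size, isolated MBBs; and
on the largest component: diameter and average path length (arcs treated as
undirected — in a DAG most ordered pairs are unreachable; path lengths
average over unordered pairs), mean total degree, and edge density with the
directed convention `arcs / (n (n − 1))`. Degenerate cases (empty m-DAG,
single-node component) report zeros and a `diameter_defined = False` flag.

### Multivariate outlier screen

Descriptors are standardized, constant columns dropped, and the samples
projected onto the smallest principal subspace holding ≥ 95% of the variance
(configurable). Because principal axes are uncorrelated, the squared
Mahalanobis distance is the sum of squared scores over component variances;
p-values come from the upper tail of a chi-square with the subspace dimension
as degrees of freedom, corrected by Benjamini–Hochberg, flagging at adjusted
p < 0.05. The screen reports; it never excludes. Exclusion is a second,
explicit pass (`exclude_samples` in the pipeline configuration), after which
the dissimilarity matrix is recomputed. An extreme-dissimilarity ranking
(median pairwise dissimilarity per sample) is reported alongside for the
same purpose, with no automatic cutoff.

## Munkres similarity of m-DAGs

Two-step maximum-weight bipartite matching (Hungarian/Munkres algorithm,
solved by `scipy.optimize.linear_sum_assignment` on negated weights):

1. **MBB level** — a complete bipartite graph between the member reactions
   of two MBBs, edges weighted by a reaction similarity score; similarity is
   the matched weight divided by the size of the larger MBB.
2. **m-DAG level** — a complete bipartite graph between the MBBs of two
   m-DAGs, weighted by the step-1 similarities; similarity is the matched
   weight divided by the MBB count of the larger m-DAG.

The reaction score is pluggable. The default is the **identity score**
(1 iff same reaction id and orientation): no graded reaction similarity
table is bundled, so the declared default reproduces set-overlap semantics,
under which step 1 reduces to `|intersection| / max sizes`. That closed form
drives a fast whole-matrix path; the matching route remains the reference
and the two are cross-checked in tests. Empty m-DAGs get similarity 1
against empty and 0 against non-empty, by convention.

The dissimilarity is `d = 1 − sim²` (default), with plain `1 − sim`
available as a configuration switch. Step 2 matches MBB contents only; arc
structure does not enter the comparison.

## Clustering, k selection and AU support

Agglomerative clustering with complete linkage runs directly on the
dissimilarity matrix. For each candidate k (default 2–8) the tree is cut and
two curves reported: the within-cluster dispersion
`W(k) = Σ_clusters Σ_{i<j∈c} d_ij² / |c|` (elbow curve, advisory — there is
no canonical W for a non-Euclidean dissimilarity, so this form is a declared
choice) and the mean silhouette computed directly from the dissimilarities
(singleton clusters score 0). The silhouette argmax is the recommendation;
identical samples make the silhouette undefined and the recommendation
abstains with a warning.

For bootstrap support the dissimilarities are first embedded by classical
(Torgerson) multidimensional scaling: double-center `−D²/2`,
eigendecompose, keep the top positive eigenvalues (negative eigenvalues are
truncated and counted). Embedded points are reclustered (complete linkage,
Euclidean) under multiscale bootstrap: at each scale
`r ∈ {0.5, 0.6, …, 1.4}` (10 scales), 1000 replicates of size `round(r·n)`
are drawn with replacement — resampling *samples*, since the input is an
embedded distance, not a feature matrix. A reference clade is recovered by a
replicate when its restriction to the replicate's distinct leaves appears as
a clade of the replicate tree (restrictions with < 2 leaves are vacuously
consistent); this is the natural adaptation of clade matching to
observation resampling, where a replicate rarely contains every leaf. Per
clade, the bootstrap probabilities `BP_r` are transformed to
`z_r = Φ⁻¹(1 − BP_r)` and the model `z(r) = v√r + c/√r` is fitted by
weighted least squares (weights `B·φ(z)²/(BP(1−BP))`) over scales with
`0 < BP_r < 1`; the approximately-unbiased support is `AU = 1 − Φ(v − c)`.
Clades recovered in all or almost all replicates leave fewer than two
informative scales; their AU falls back to the plain proportion at the scale
nearest 1.0 and is flagged `degenerate` (a clade recovered always therefore
gets AU = 1 exactly). Never-observed clades get AU = 0 with a flag. The
stringent support threshold reported by the pipeline is AU ≥ 0.9685. All
resampling is seeded and reproducible.

## Core and pan metabolism

For any grouping of samples (clusters, metadata groups, individuals, the
whole cohort) the core is the intersection and the pan the union of member
reaction sets — defined on reaction ids, before orientation. Core and pan
graphs are rebuilt from those sets with the same arc policy as the samples
and summarized with the same counts; the proportion of essential MBBs is
reported to 4 decimals. Optionally each member sample is scored against its
group's core and pan m-DAGs with the Munkres similarity.

## Sparse PLS-DA on MBB completeness features

Features are defined against the pan m-DAG of the retained cohort: for pan
MBB `M` and sample `s`, `value = |members(M) ∩ oriented(s)| / |members(M)|`
∈ [0, 1]. Completeness fractions are the declared default encoding (binary
presence would discard partial-module information; abundance weighting is
out of scope), and zero-variance columns are dropped with a warning.

Per pairwise cluster comparison a two-component sparse PLS-DA is fitted
(ncomp = 2, keepX = (50, 30) by default): X column-standardized, Y a
centered one-hot encoding; per component the loading starts at the dominant
singular direction of the cross-covariance `XᵀY` and alternates hard
top-keepX selection, renormalization and cross-covariance updates to
convergence (tol 1e-6, ≤ 500 iterations), after which X and Y are deflated
by regression on the component scores. With keepX covering all features the
sparse step is inactive and the component equals the exact dominant singular
direction, giving dense PLS-DA to machine precision. Exact ties at the
selection boundary are broken by a seeded infinitesimal jitter; component
sign is fixed by making the strongest loading positive. The model is used
descriptively: no cross-validation, tuning or classification-error
estimation.

Discriminant MBBs are the kept variables whose |loading| reaches 95% of the
component maximum (the loading weight on the standardized scale is the
contribution metric); the loading sign assigns each to the group whose score
centroid lies on the same side of the component. Selected MBBs are expanded
to member reactions (orientation collapsed) and counted per pathway
annotation — one count per pathway a reaction belongs to, distinct reactions
only, with an `unannotated` bucket.

## Synthetic universe and cohort

The generator exists so every stage runs and is testable without downloads.

**Universe.** Reactions come in modules: directed cycles of 2–4 reactions on
private compounds (each condenses to exactly one multi-reaction MBB) and
singletons (reversible with probability 0.15, giving a forward/backward
2-cycle MBB under the strict policy). Sparse linker substrates let later
modules consume products of earlier ones — reproducing the one large
component + many small components + isolated nodes shape of real m-DAGs —
but only on irreversible target reactions and only forward in module order,
so no cross-module cycles arise and every module's MBB content is known by
construction. KO → EC → reaction links are one-to-one; pathways label
contiguous module blocks. Default target size: 300 reactions (~140 modules),
large enough to allocate all cohort blocks with margin while keeping the
120-sample pairwise analysis around half a minute on one CPU. Two hand-check
universes (`F1`, a 4-reaction cycle-plus-isolate fixture; `F2`, a 3-reaction
path) are available as named presets.

**Cohort.** Three repertoire modes are planted over the module pool
(40 shared core modules; three signature blocks of 12 cycle modules each,
dealt round-robin from the largest cycles so the blocks have matched size
profiles; a nested accessory pool of 30):

| mode | who | signature | accessory share |
|------|-----|-----------|-----------------|
| `EI` | infants | own block | 25 of 30 (largest repertoire) |
| `MIX` | infant-like elderly | own block | 16 of 30 |
| `AA` | adults and adult-like elderly | own block | 8 of 30 (most compact) |

Each elderly *individual* is drawn once from `MIX` (probability
`mixture_weight`, default 0.5) or `AA`, so elderly bimodality lives at the
individual level; with weight 0 only two modes remain in the cohort.
Individual repertoires apply Bernoulli membership flips over the accessory
pool (inter-individual jitter: adults 0.10, elderly 0.06, infants 0.02 —
adults are the most variable group, infants the most homogeneous); repeated
samples apply iid KO dropout (presence → absence only: the analysis is
presence-driven; abundances are emitted but unused) at rates 0.05 / 0.04 /
0.01 for adults / elderly / infants. The shared core block is exempt from
dropout — core functions are assumed always detected, otherwise a
120-sample strict intersection would be empty, which no real cohort shows.
Planted truth (mode per individual and sample, signature reactions and
their MBB member sets) is written alongside the tables.

Defaults (3 groups × 10 individuals × 4 samples = 120 samples) give
cleanly separated modes: silhouette selects k = 3, clusters match planted
modes (ARI 1.0 on the seeds exercised in tests), intra-individual
dissimilarity stays below inter-individual within every group, and the
planted signature MBBs dominate the sparse PLS-DA selections.

**What the generator does not emulate:** taxonomic composition, read-level
noise, abundance structure, KO co-occurrence driven by genome linkage,
shared enzymes across reactions (EC promiscuity), and annotation biases.
Passing tests on this cohort demonstrates that the pipeline recovers known
structure of the kind the analysis assumes — not that real cohorts contain
such structure.

## Numerical and determinism notes

* All node, arc and id iterations are in sorted order; identical inputs and
  configuration give byte-identical output tables, so re-running any single
  pipeline stage reproduces downstream files exactly.
* The rectangular assignment problems are solved exactly (Jonker–Volgenant
  via SciPy), not greedily; assignment optima are invariant to input order,
  which is property-tested.
* Classical MDS uses a symmetric eigendecomposition with an
  eigenvalue tolerance of `n · eps · max(|λ|, 1)`; requested dimensions are
  clipped to n − 1 with a warning.
* The outlier screen falls back gracefully: constant descriptor columns are
  dropped, a rank-deficient covariance loses its null directions with a
  warning, and a descriptor matrix with no usable columns yields zero
  distances and no flags.
* Silhouettes of singleton clusters are 0; trees whose tied merge heights
  make an exact k-cut infeasible are skipped in the k scan.

## Known limitations

* The identity reaction score makes the m-DAG similarity a set-overlap
  statistic at both matching levels; a graded score table is supported but
  none is shipped.
* The AU fit extrapolates from ten scales in [0.5, 1.4]; strongly supported
  clades bypass the fit entirely (see above), so AU values very close to 1
  carry no fitted standard error.
* Core/pan analysis treats reaction presence as binary; partial module
  presence only enters through the sPLS-DA completeness features.
* The pipeline holds all per-sample graphs in memory; cohorts of a few
  hundred samples with universes of a few thousand reactions are
  comfortable, but nothing is streamed.
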