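"""End-to-end pipeline: KO tables → graphs → topology → dissimilarity →
clustering → core/pan → discriminant MBBs, with stable on-disk outputs.

Every stage writes TSV tables (graphs additionally as GraphML/edge lists,
trees as Newick) under the run directory, plus a manifest recording the
effective configuration, a config hash and the stage outputs.  The pipeline
is deterministic given the configuration, so re-running any stage reproduces
byte-identical downstream tables.

Outlier handling is two-pass: the topology screen and the
extreme-dissimilarity ranking (median pairwise dissimilarity per sample) are
always reported; samples are excluded only when named in
``exclude_samples``, after which the dissimilarity matrix and all downstream
stages use the retained samples.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import clustering, corepan, discriminant, graphs, similarity, topology, universe as universe_io

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "Pipeline", "run_pipeline", "STAGES"]

STAGES = (
    "build",
    "topology",
    "compare",
    "cluster",
    "corepan",
    "discriminate",
)


@dataclass
class PipelineConfig:
    universe_path: str
    ko_table: str
    metadata: str
    outdir: str
    universe_format: str | None = None
    arc_policy: str = "strict"
    exclude_compounds: tuple[str, ...] = ()
    strict_kos: bool = False
    dissimilarity_transform: str = "one_minus_sim_squared"
    linkage: str = "complete"
    k_min: int = 2
    k_max: int = 8
    n_clusters: int | None = None  # override silhouette recommendation
    mds_dims: int | None = None  # None: all positive eigenvalues
    bootstrap_scales: tuple[float, ...] = clustering.DEFAULT_SCALES
    bootstrap_replicates: int = 1000
    au_threshold: float = clustering.STRINGENT_AU_THRESHOLD
    outlier_variance_kept: float = 0.95
    outlier_alpha: float = 0.05
    splsda_ncomp: int = 2
    splsda_keepx: tuple[int, ...] = (50, 30)
    splsda_threshold: float = 0.95
    exclude_samples: tuple[str, ...] = ()
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in (self.universe_path, self.ko_table, self.metadata):
            if not Path(p).exists():
                raise FileNotFoundError(f"input not found: {p}")
        if self.arc_policy not in graphs.ARC_POLICIES:
            raise ValueError(f"unknown arc policy {self.arc_policy!r}")
        if self.dissimilarity_transform not in similarity.DISSIMILARITY_TRANSFORMS:
            raise ValueError(
                f"unknown dissimilarity transform {self.dissimilarity_transform!r}"
            )
        if len(self.splsda_keepx) != self.splsda_ncomp:
            raise ValueError("splsda_keepx length must equal splsda_ncomp")
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


class Pipeline:
    """Stage runner with in-memory caching; all stages are deterministic."""

    def __init__(self, config: PipelineConfig) -> None:
        config.validate()
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self._cache: dict[str, object] = {}
        self.outputs: dict[str, list[str]] = {}

    # -- cached intermediates ------------------------------------------------
    def _record(self, stage: str, *paths: Path) -> None:
        self.outputs.setdefault(stage, []).extend(
            str(p.relative_to(self.outdir)) for p in paths
        )

    @property
    def universe(self):
        if "universe" not in self._cache:
            self._cache["universe"] = universe_io.load_universe(
                self.config.universe_path, self.config.universe_format
            )
        return self._cache["universe"]

    @property
    def metadata(self) -> pd.DataFrame:
        if "metadata" not in self._cache:
            self._cache["metadata"] = universe_io.read_metadata(self.config.metadata)
        return self._cache["metadata"]

    @property
    def sample_reactions(self) -> dict[str, set[str]]:
        if "sample_reactions" not in self._cache:
            kos = universe_io.read_ko_table(self.config.ko_table)
            self._cache["sample_reactions"] = {
                sid: set(
                    universe_io.map_kos_to_reactions(
                        self.universe, sorted(klist), strict=self.config.strict_kos
                    )
                )
                for sid, klist in sorted(kos.items())
            }
        return self._cache["sample_reactions"]

    def _graph_pair(self, sid: str):
        rg = graphs.build_reaction_graph(
            self.universe,
            self.sample_reactions[sid],
            policy=self.config.arc_policy,
            exclude_compounds=self.config.exclude_compounds,
            sample_id=sid,
        )
        return rg, graphs.condense_to_mdag(rg)

    @property
    def mdags(self) -> dict[str, graphs.MDag]:
        if "mdags" not in self._cache:
            pairs = {sid: self._graph_pair(sid) for sid in sorted(self.sample_reactions)}
            self._cache["rgs"] = {sid: rg for sid, (rg, _) in pairs.items()}
            self._cache["mdags"] = {sid: md for sid, (_, md) in pairs.items()}
        return self._cache["mdags"]

    @property
    def retained(self) -> list[str]:
        excluded = set(self.config.exclude_samples)
        return [s for s in sorted(self.sample_reactions) if s not in excluded]

    @property
    def dissimilarity(self) -> similarity.DissimilarityMatrix:
        if "dissimilarity" not in self._cache:
            mdags = self.mdags
            self._cache["dissimilarity"] = similarity.dissimilarity_matrix(
                [(sid, mdags[sid]) for sid in self.retained],
                transform=self.config.dissimilarity_transform,
            )
        return self._cache["dissimilarity"]

    @property
    def cluster_labels(self) -> pd.Series:
        if "cluster_labels" not in self._cache:
            self.stage_cluster()
        return self._cache["cluster_labels"]

    # -- stages ---------------------------------------------------------------
    def stage_build(self) -> None:
        gdir = self.outdir / "graphs"
        gdir.mkdir(exist_ok=True)
        written = []
        mdags = self.mdags
        for sid in sorted(self.sample_reactions):
            rg, mdag = self._cache["rgs"][sid], mdags[sid]
            written.extend(graphs.export_graph_tsv(rg, gdir / f"{sid}.rg"))
            written.extend(graphs.export_mdag_tsv(mdag, gdir / f"{sid}.mdag"))
            written.append(graphs.export_graphml(mdag, gdir / f"{sid}.mdag.graphml"))
        self._record("build", *written)

    def stage_topology(self) -> None:
        reports = [
            topology.summarize_topology(self.mdags[sid], self._cache["rgs"][sid], self.universe)
            for sid in sorted(self.mdags)
        ]
        table = topology.topology_table(reports)
        tpath = self.outdir / "topology.tsv"
        table.to_csv(tpath, sep="\t")
        feats = table.drop(columns=["diameter_defined"]).astype(float)
        outliers = topology.detect_multivariate_outliers(
            feats,
            variance_kept=self.config.outlier_variance_kept,
            alpha=self.config.outlier_alpha,
        )
        opath = self.outdir / "outliers.tsv"
        outliers.to_csv(opath, sep="\t")
        self._cache["topology_table"] = table
        self._record("topology", tpath, opath)

    def stage_compare(self) -> None:
        d = self.dissimilarity
        dpath = d.write_tsv(self.outdir / "dissimilarity.tsv")
        lpath = self.outdir / "dissimilarity_long.tsv"
        d.to_long().to_csv(lpath, sep="\t", index=False)
        rpath = self.outdir / "dissimilarity_ranking.tsv"
        d.median_per_sample().rename("median_dissimilarity").to_csv(rpath, sep="\t")
        self._record("compare", dpath, lpath, rpath)

    def stage_cluster(self) -> None:
        cfg = self.config
        d = self.dissimilarity
        tree = clustering.hierarchical_cluster(d, linkage=cfg.linkage)
        (self.outdir / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
        sel = clustering.choose_k(tree, d, range(cfg.k_min, cfg.k_max + 1))
        sel.as_frame().to_csv(self.outdir / "k_selection.tsv", sep="\t")
        k = cfg.n_clusters or sel.recommended_k
        if k is None:
            raise RuntimeError("no cluster number recommended and none configured")
        assignment = clustering.cluster_assignment(tree, d, k)
        assignment.to_csv(self.outdir / "clusters.tsv", sep="\t")

        coords, mds = clustering.embed_mds(
            d, dims=cfg.mds_dims or (len(d) - 1)
        )
        pd.DataFrame(
            coords,
            index=d.sample_ids,
            columns=[f"dim{i + 1}" for i in range(coords.shape[1])],
        ).to_csv(self.outdir / "mds_coordinates.tsv", sep="\t")
        au = clustering.au_bootstrap(
            coords,
            linkage=cfg.linkage,
            scales=cfg.bootstrap_scales,
            replicates=cfg.bootstrap_replicates,
            seed=cfg.seed,
            leaf_ids=d.sample_ids,
        )
        au_table = au.table.copy()
        au_table["leaves"] = au_table["leaves"].map(lambda t: ",".join(t))
        au_table["stringent_support"] = au_table["au"] >= cfg.au_threshold
        au_table.to_csv(self.outdir / "au_support.tsv", sep="\t", index=False)

        self._cache["tree"] = tree
        self._cache["k_selection"] = sel
        self._cache["cluster_labels"] = assignment["cluster"]
        self._cache["au"] = au
        self._record(
            "cluster",
            self.outdir / "dendrogram.nwk",
            self.outdir / "k_selection.tsv",
            self.outdir / "clusters.tsv",
            self.outdir / "mds_coordinates.tsv",
            self.outdir / "au_support.tsv",
        )

    def _groupings(self) -> dict[str, dict[str, dict[str, set[str]]]]:
        """Cluster-based and metadata-group-based sample groupings."""
        labels = self.cluster_labels
        meta = self.metadata
        reactions = self.sample_reactions
        by_cluster: dict[str, dict[str, set[str]]] = {}
        for sid, lab in labels.items():
            by_cluster.setdefault(f"cluster{lab}", {})[sid] = reactions[sid]
        by_group: dict[str, dict[str, set[str]]] = {}
        for sid in self.retained:
            grp = str(meta.loc[sid, "group"]) if sid in meta.index else "unknown"
            by_group.setdefault(grp, {})[sid] = reactions[sid]
        cohort = {"cohort": {sid: reactions[sid] for sid in self.retained}}
        return {"cluster": by_cluster, "metadata": by_group, "cohort": cohort}

    def stage_corepan(self) -> None:
        frames = []
        sims = []
        for basis, groups in self._groupings().items():
            summary, sim, _ = corepan.group_mdag_summary(
                self.universe,
                groups,
                policy=self.config.arc_policy,
                sample_similarity=True,
            )
            summary.insert(0, "basis", basis)
            frames.append(summary)
            sim.insert(0, "basis", basis)
            sims.append(sim)
        spath = self.outdir / "corepan_summary.tsv"
        pd.concat(frames, ignore_index=True).to_csv(spath, sep="\t", index=False)
        ppath = self.outdir / "corepan_sample_similarity.tsv"
        pd.concat(sims, ignore_index=True).to_csv(ppath, sep="\t", index=False)
        self._record("corepan", spath, ppath)

    def stage_discriminate(self) -> None:
        cfg = self.config
        labels = self.cluster_labels
        reactions = self.sample_reactions
        pan = corepan.pan_reactions([reactions[s] for s in self.retained])
        pan_rg = graphs.build_reaction_graph(
            self.universe, pan, policy=cfg.arc_policy, sample_id="cohort_pan"
        )
        pan_mdag = graphs.condense_to_mdag(pan_rg)
        oriented = {
            sid: graphs.oriented_labels(self.universe, reactions[sid])
            for sid in self.retained
        }
        X = discriminant.build_mbb_features(oriented, pan_mdag)
        X.to_csv(self.outdir / "mbb_features.tsv", sep="\t")

        selections = []
        for a, b in itertools.combinations(sorted(labels.unique()), 2):
            keep = labels[labels.isin([a, b])].index
            model = discriminant.SparsePLSDA(
                n_components=cfg.splsda_ncomp,
                keep_x=cfg.splsda_keepx,
                random_state=cfg.seed,
            ).fit(X.loc[keep], labels.loc[keep].to_numpy())
            sel = discriminant.select_discriminants(model, cfg.splsda_threshold)
            sel.insert(0, "comparison", f"cluster{a}_vs_cluster{b}")
            sel["group"] = sel["group"].map(lambda g: f"cluster{g}")
            selections.append(sel)
        selected = pd.concat(selections, ignore_index=True)
        sel_path = self.outdir / "discriminant_mbbs.tsv"
        selected.to_csv(sel_path, sep="\t", index=False)

        members = {mid: mbb.members for mid, mbb in pan_mdag.mbbs.items()}
        rollup = discriminant.pathway_rollup(selected, members, self.universe)
        roll_path = self.outdir / "pathway_rollup.tsv"
        rollup.to_csv(roll_path, sep="\t", index=False)
        self._cache["selected"] = selected
        self._record(
            "discriminate", self.outdir / "mbb_features.tsv", sel_path, roll_path
        )

    # -- driver ----------------------------------------------------------------
    def run(self, stages: tuple[str, ...] = STAGES) -> Path:
        for stage in stages:
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r}")
            logger.info("running stage %s", stage)
            getattr(self, f"stage_{stage}")()
        manifest = {
            "config": asdict(self.config),
            "config_hash": self.config.digest(),
            "universe_version": self.universe.version,
            "n_samples": len(self.sample_reactions),
            "n_retained": len(self.retained),
            "stages": list(stages),
            "outputs": self.outputs,
        }
        (self.outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=str) + "\n"
        )
        return self.outdir


def run_pipeline(config: PipelineConfig, stages: tuple[str, ...] = STAGES) -> Path:
    """Run the configured stages in order and return the run directory."""
    return Pipeline(config).run(stages)
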