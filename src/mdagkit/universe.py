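"""Reaction-universe knowledge base and KO → reaction mapping.

The universe emulates the content of a KEGG-style reaction knowledge base:
compounds, reactions (substrate/product sets, reversibility, EC numbers,
pathway annotations) and KEGG-Ortholog (KO) records linking orthologs to EC
numbers.  Stoichiometry and compound multiplicity are deliberately ignored:
all downstream graph construction is set-based (a reaction either produces a
compound or it does not).

Two equivalent on-disk dialects are supported:

* a TSV bundle — ``compounds.tsv``, ``reactions.tsv``, ``ko2ec.tsv`` and
  ``reaction2pathway.tsv`` in one directory, tab-separated with a header row,
  set-valued fields comma-joined;
* a single JSON file with keys ``version``, ``compounds``, ``reactions``,
  ``kos`` and ``pathway_names``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Compound",
    "ReactionSpec",
    "KoMapping",
    "ReactionUniverse",
    "UniverseValidationError",
    "load_universe",
    "write_universe",
    "map_kos_to_reactions",
    "read_ko_table",
    "read_metadata",
]


class UniverseValidationError(ValueError):
    """Raised when a universe violates referential integrity."""


@dataclass(frozen=True)
class Compound:
    id: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise UniverseValidationError("compound id must be non-empty")


@dataclass(frozen=True)
class ReactionSpec:
    """One reaction: substrate/product compound sets, reversibility,
    catalysing EC numbers and pathway memberships.

    ``substrates & products`` may be non-empty (a reaction can regenerate a
    compound it consumes); downstream arc construction excludes the resulting
    self-arcs.
    """

    id: str
    substrates: frozenset[str]
    products: frozenset[str]
    reversible: bool = False
    enzymes: frozenset[str] = frozenset()
    pathways: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.id:
            raise UniverseValidationError("reaction id must be non-empty")
        if not self.substrates or not self.products:
            raise UniverseValidationError(
                f"reaction {self.id!r}: substrates and products must be non-empty"
            )


@dataclass(frozen=True)
class KoMapping:
    ko: str
    enzymes: frozenset[str] = frozenset()


@dataclass
class ReactionUniverse:
    """Validated, deterministically ordered reaction knowledge base."""

    compounds: dict[str, Compound] = field(default_factory=dict)
    reactions: dict[str, ReactionSpec] = field(default_factory=dict)
    kos: dict[str, KoMapping] = field(default_factory=dict)
    pathway_names: dict[str, str] = field(default_factory=dict)
    version: str = "0"

    def __post_init__(self) -> None:
        self.validate()
        # canonical sorted iteration order
        self.compounds = dict(sorted(self.compounds.items()))
        self.reactions = dict(sorted(self.reactions.items()))
        self.kos = dict(sorted(self.kos.items()))
        self.pathway_names = dict(sorted(self.pathway_names.items()))
        self._ec_to_reactions: dict[str, tuple[str, ...]] | None = None

    def validate(self) -> None:
        for rid, rxn in self.reactions.items():
            if rid != rxn.id:
                raise UniverseValidationError(f"reaction key {rid!r} != id {rxn.id!r}")
            for cid in rxn.substrates | rxn.products:
                if cid not in self.compounds:
                    raise UniverseValidationError(
                        f"reaction {rid!r} references unknown compound {cid!r}"
                    )

    @property
    def ec_to_reactions(self) -> Mapping[str, tuple[str, ...]]:
        """EC number -> sorted tuple of reaction ids it catalyses."""
        if self._ec_to_reactions is None:
            idx: dict[str, list[str]] = {}
            for rid, rxn in self.reactions.items():
                for ec in rxn.enzymes:
                    idx.setdefault(ec, []).append(rid)
            self._ec_to_reactions = {ec: tuple(sorted(v)) for ec, v in idx.items()}
        return self._ec_to_reactions

    def reactions_for_kos(self, kos: Iterable[str], strict: bool = False) -> list[str]:
        return map_kos_to_reactions(self, kos, strict=strict)

    # -- summary counts used by topology / core-pan reports ----------------
    def enzymes_of(self, reaction_ids: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for rid in reaction_ids:
            out |= self.reactions[rid].enzymes
        return out

    def compounds_of(self, reaction_ids: Iterable[str]) -> set[str]:
        out: set[str] = set()
        for rid in reaction_ids:
            rxn = self.reactions[rid]
            out |= rxn.substrates | rxn.products
        return out

    def pathways_of(self, reaction_id: str) -> frozenset[str]:
        return self.reactions[reaction_id].pathways


def map_kos_to_reactions(
    universe: ReactionUniverse, kos: Iterable[str], strict: bool = False
) -> list[str]:
    """Map KO identifiers to the union of reactions their enzymes catalyse.

    Unknown KOs raise in strict mode and are warned-and-skipped otherwise
    (metagenome annotations routinely contain KOs without reaction links).
    Returns a sorted list for deterministic downstream iteration.
    """
    out: set[str] = set()
    ec_index = universe.ec_to_reactions
    for ko in kos:
        mapping = universe.kos.get(ko)
        if mapping is None:
            if strict:
                raise KeyError(f"unknown KO {ko!r}")
            warnings.warn(f"unknown KO {ko!r} skipped", stacklevel=2)
            continue
        for ec in mapping.enzymes:
            out.update(ec_index.get(ec, ()))
    return sorted(out)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_TSV_FILES = ("compounds.tsv", "reactions.tsv", "ko2ec.tsv", "reaction2pathway.tsv")


def _split_set(cell: object) -> frozenset[str]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return frozenset()
    s = str(cell).strip()
    if not s:
        return frozenset()
    return frozenset(x.strip() for x in s.split(",") if x.strip())


def load_universe(path: str | Path, format: str | None = None) -> ReactionUniverse:
    """Load a universe from a TSV bundle directory or a single JSON file.

    ``format`` may be ``"tsv-bundle"`` or ``"json"``; when omitted it is
    inferred from the path (directory → bundle, ``.json`` file → JSON).
    """
    path = Path(path)
    if format is None:
        format = "tsv-bundle" if path.is_dir() else "json"
    if format == "tsv-bundle":
        return _load_tsv_bundle(path)
    if format == "json":
        return _load_json(path)
    raise ValueError(f"unknown universe format {format!r}")


def _load_tsv_bundle(root: Path) -> ReactionUniverse:
    if not root.is_dir():
        raise FileNotFoundError(f"universe bundle directory not found: {root}")
    for name in _TSV_FILES:
        if not (root / name).exists():
            raise FileNotFoundError(f"universe bundle missing {name} in {root}")

    comp_df = pd.read_csv(root / "compounds.tsv", sep="\t", dtype=str).fillna("")
    rxn_df = pd.read_csv(root / "reactions.tsv", sep="\t", dtype=str).fillna("")
    ko_df = pd.read_csv(root / "ko2ec.tsv", sep="\t", dtype=str).fillna("")
    pw_df = pd.read_csv(root / "reaction2pathway.tsv", sep="\t", dtype=str).fillna("")

    compounds: dict[str, Compound] = {}
    for row in comp_df.itertuples(index=False):
        if row.compound_id in compounds:
            raise UniverseValidationError(f"duplicate compound id {row.compound_id!r}")
        compounds[row.compound_id] = Compound(row.compound_id, getattr(row, "name", ""))

    rxn_pathways: dict[str, set[str]] = {}
    pathway_names: dict[str, str] = {}
    for row in pw_df.itertuples(index=False):
        rxn_pathways.setdefault(row.reaction_id, set()).add(row.pathway_id)
        if getattr(row, "pathway_name", ""):
            pathway_names[row.pathway_id] = row.pathway_name

    reactions: dict[str, ReactionSpec] = {}
    for row in rxn_df.itertuples(index=False):
        if row.reaction_id in reactions:
            raise UniverseValidationError(f"duplicate reaction id {row.reaction_id!r}")
        reactions[row.reaction_id] = ReactionSpec(
            id=row.reaction_id,
            substrates=_split_set(row.substrates),
            products=_split_set(row.products),
            reversible=str(row.reversible).strip().lower() in ("1", "true", "yes"),
            enzymes=_split_set(row.enzymes),
            pathways=frozenset(rxn_pathways.get(row.reaction_id, ())),
        )

    kos: dict[str, KoMapping] = {}
    for row in ko_df.itertuples(index=False):
        if row.ko_id in kos:
            raise UniverseValidationError(f"duplicate KO id {row.ko_id!r}")
        kos[row.ko_id] = KoMapping(row.ko_id, _split_set(row.ec_ids))

    version = "0"
    vfile = root / "VERSION"
    if vfile.exists():
        version = vfile.read_text().strip()
    return ReactionUniverse(compounds, reactions, kos, pathway_names, version)


def _load_json(path: Path) -> ReactionUniverse:
    if not path.exists():
        raise FileNotFoundError(f"universe file not found: {path}")
    data = json.loads(path.read_text())
    compounds = {
        c["id"]: Compound(c["id"], c.get("name", "")) for c in data.get("compounds", [])
    }
    if len(compounds) != len(data.get("compounds", [])):
        raise UniverseValidationError("duplicate compound ids in JSON universe")
    reactions = {}
    for r in data.get("reactions", []):
        if r["id"] in reactions:
            raise UniverseValidationError(f"duplicate reaction id {r['id']!r}")
        reactions[r["id"]] = ReactionSpec(
            id=r["id"],
            substrates=frozenset(r["substrates"]),
            products=frozenset(r["products"]),
            reversible=bool(r.get("reversible", False)),
            enzymes=frozenset(r.get("enzymes", ())),
            pathways=frozenset(r.get("pathways", ())),
        )
    kos = {}
    for k in data.get("kos", []):
        if k["ko"] in kos:
            raise UniverseValidationError(f"duplicate KO id {k['ko']!r}")
        kos[k["ko"]] = KoMapping(k["ko"], frozenset(k.get("enzymes", ())))
    return ReactionUniverse(
        compounds,
        reactions,
        kos,
        dict(data.get("pathway_names", {})),
        str(data.get("version", "0")),
    )


def write_universe(
    universe: ReactionUniverse, path: str | Path, format: str = "tsv-bundle"
) -> Path:
    """Write in canonical (sorted) form; ``load_universe`` round-trips it."""
    path = Path(path)
    if format == "json":
        payload = {
            "version": universe.version,
            "compounds": [
                {"id": c.id, "name": c.name} for c in universe.compounds.values()
            ],
            "reactions": [
                {
                    "id": r.id,
                    "substrates": sorted(r.substrates),
                    "products": sorted(r.products),
                    "reversible": r.reversible,
                    "enzymes": sorted(r.enzymes),
                    "pathways": sorted(r.pathways),
                }
                for r in universe.reactions.values()
            ],
            "kos": [
                {"ko": k.ko, "enzymes": sorted(k.enzymes)}
                for k in universe.kos.values()
            ],
            "pathway_names": universe.pathway_names,
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
        return path
    if format != "tsv-bundle":
        raise ValueError(f"unknown universe format {format!r}")

    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [{"compound_id": c.id, "name": c.name} for c in universe.compounds.values()],
        columns=["compound_id", "name"],
    ).to_csv(path / "compounds.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "reaction_id": r.id,
                "substrates": ",".join(sorted(r.substrates)),
                "products": ",".join(sorted(r.products)),
                "reversible": int(r.reversible),
                "enzymes": ",".join(sorted(r.enzymes)),
            }
            for r in universe.reactions.values()
        ],
        columns=["reaction_id", "substrates", "products", "reversible", "enzymes"],
    ).to_csv(path / "reactions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"ko_id": k.ko, "ec_ids": ",".join(sorted(k.enzymes))}
            for k in universe.kos.values()
        ],
        columns=["ko_id", "ec_ids"],
    ).to_csv(path / "ko2ec.tsv", sep="\t", index=False)
    pw_rows = []
    for r in universe.reactions.values():
        for pw in sorted(r.pathways):
            pw_rows.append(
                {
                    "reaction_id": r.id,
                    "pathway_id": pw,
                    "pathway_name": universe.pathway_names.get(pw, ""),
                }
            )
    pd.DataFrame(
        pw_rows, columns=["reaction_id", "pathway_id", "pathway_name"]
    ).to_csv(path / "reaction2pathway.tsv", sep="\t", index=False)
    (path / "VERSION").write_text(universe.version + "\n")
    return path


# ---------------------------------------------------------------------------
# Sample tables
# ---------------------------------------------------------------------------


def read_ko_table(path: str | Path) -> dict[str, set[str]]:
    """Read a long-form KO table (sample_id, ko_id[, abundance]) into
    ``sample -> set of KO ids``. Abundances are carried on disk but presence
    drives the analysis."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "ko_id": str})
    if not {"sample_id", "ko_id"} <= set(df.columns):
        raise ValueError("KO table needs columns sample_id and ko_id")
    out: dict[str, set[str]] = {}
    for sid, group in df.groupby("sample_id", sort=True):
        out[str(sid)] = set(group["ko_id"].astype(str))
    return out


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (sample_id, individual_id, group, timepoint)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "individual_id", "group"}
    if not required <= set(df.columns):
        raise ValueError(f"metadata needs columns {sorted(required)}")
    return df.set_index("sample_id", drop=False)
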