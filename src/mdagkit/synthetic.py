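"""Synthetic reaction universe and age-structured KO cohort.

The generator provides everything the pipeline needs without any external
download: a toy reaction universe with known modular structure, and a cohort
of per-sample KO repertoires with planted group structure.

Universe
--------
Reactions are organized in *modules*: directed cycles of 2–4 reactions over
private compounds (each condenses to one multi-reaction MBB) and single
reactions (optionally reversible; under the strict arc policy a reversible
reaction forms a forward/backward 2-cycle MBB).  Sparse "linker" substrates
connect later modules to products of earlier ones, giving the realistic
one-giant-component shape without creating cross-module cycles, so the MBB
content of every module is known by construction.  KO → EC → reaction links
are one-to-one; pathway labels are assigned to contiguous module blocks.

Cohort
------
Three repertoire modes are planted:

* ``EI`` (infant-like): largest repertoire — core modules, the infant
  signature block and the largest accessory share; low dropout and jitter.
* ``AA`` (adult-like): compact — core, adult signature block, smallest
  accessory share; highest dropout and jitter (adults are the most variable).
* ``MIX``: the infant-like elderly mode — infant-sized accessory share with
  its own signature block.

Adults are always ``AA`` and infants always ``EI``; each *elderly
individual* is drawn once from ``MIX`` (infant-like, probability
``mixture_weight``) or ``AA`` (adult-like), so elderly bimodality lives at
the individual level.  With ``mixture_weight = 0`` every elderly individual
is adult-like and only two modes remain.  Individual repertoires apply
Bernoulli membership flips over the accessory pool (inter-individual
jitter); repeated samples of an individual apply iid KO dropout
(intra-individual noise, presence → absence only).  The planted truth
(mode per individual/sample, signature reactions and their MBB member sets)
is emitted for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .graphs import REV_SUFFIX
from .universe import Compound, KoMapping, ReactionSpec, ReactionUniverse

__all__ = [
    "UniverseConfig",
    "GroupConfig",
    "CohortConfig",
    "Module",
    "SyntheticUniverse",
    "CohortData",
    "generate_universe",
    "generate_cohort",
    "fixture_universe",
]

MODES = ("AA", "MIX", "EI")


@dataclass(frozen=True)
class Module:
    """One universe module; a module's reactions form exactly one known MBB
    (plus the rev orientation for reversible singletons)."""

    index: int
    reactions: tuple[str, ...]
    kos: tuple[str, ...]
    pathway: str
    kind: str  # "cycle" | "single" | "single_rev"

    def mbb_members(self) -> frozenset[str]:
        if self.kind == "single_rev":
            (r,) = self.reactions
            return frozenset([r, r + REV_SUFFIX])
        return frozenset(self.reactions)


@dataclass
class SyntheticUniverse:
    universe: ReactionUniverse
    modules: list[Module]

    def module_kos(self, indices) -> set[str]:
        out: set[str] = set()
        for i in indices:
            out |= set(self.modules[i].kos)
        return out


@dataclass(frozen=True)
class UniverseConfig:
    """Universe size and shape.

    n_reactions is a target: modules are added until it is reached.
    ``cycle_fraction`` of modules are reaction cycles (sizes 2..max_cycle_size),
    the rest single reactions, of which ``reversible_fraction`` are
    reversible.  ``linker_rate`` is the probability that a module consumes one
    product of an earlier module (irreversible target reactions only, keeping
    cross-module structure acyclic).
    """

    n_reactions: int = 300
    cycle_fraction: float = 0.5
    max_cycle_size: int = 4
    reversible_fraction: float = 0.15
    n_pathways: int = 12
    linker_rate: float = 0.3

    def __post_init__(self) -> None:
        for name in ("cycle_fraction", "reversible_fraction", "linker_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_reactions < 1 or self.n_pathways < 1 or self.max_cycle_size < 2:
            raise ValueError("infeasible universe sizes")


def generate_universe(
    config: UniverseConfig | None = None, seed: int = 0
) -> SyntheticUniverse:
    """Generate the modular toy universe; same seed → identical output."""
    config = config or UniverseConfig()
    rng = np.random.default_rng(seed)

    compounds: dict[str, Compound] = {}
    reactions: dict[str, ReactionSpec] = {}
    kos: dict[str, KoMapping] = {}
    modules: list[Module] = []
    module_products: list[list[str]] = []  # linker-eligible products per module

    c_counter = 0
    r_counter = 0

    def new_compound() -> str:
        nonlocal c_counter
        c_counter += 1
        cid = f"C{c_counter:05d}"
        compounds[cid] = Compound(cid)
        return cid

    total = 0
    m_idx = 0
    while total < config.n_reactions:
        is_cycle = rng.random() < config.cycle_fraction
        size = int(rng.integers(2, config.max_cycle_size + 1)) if is_cycle else 1
        cpds = [new_compound() for _ in range(size if is_cycle else 2)]
        specs: list[dict] = []
        if is_cycle:
            kind = "cycle"
            for i in range(size):
                specs.append(
                    {
                        "substrates": {cpds[i]},
                        "products": {cpds[(i + 1) % size]},
                        "reversible": False,
                    }
                )
        else:
            reversible = rng.random() < config.reversible_fraction
            kind = "single_rev" if reversible else "single"
            specs.append(
                {
                    "substrates": {cpds[0]},
                    "products": {cpds[1]},
                    "reversible": reversible,
                }
            )
        # linker: this module consumes one upstream product (irreversible
        # targets only so no cross-module cycle can arise)
        if modules and rng.random() < config.linker_rate and kind != "single_rev":
            src = int(rng.integers(0, len(modules)))
            choices = module_products[src]
            specs[0]["substrates"] = set(specs[0]["substrates"]) | {
                choices[int(rng.integers(0, len(choices)))]
            }

        rids, kids = [], []
        for s in specs:
            r_counter += 1
            rid = f"R{r_counter:05d}"
            ko = f"K{r_counter:05d}"
            ec = f"9.9.{m_idx + 1}.{len(rids) + 1}"
            reactions[rid] = ReactionSpec(
                id=rid,
                substrates=frozenset(s["substrates"]),
                products=frozenset(s["products"]),
                reversible=s["reversible"],
                enzymes=frozenset([ec]),
            )
            kos[ko] = KoMapping(ko, frozenset([ec]))
            rids.append(rid)
            kids.append(ko)
        modules.append(Module(m_idx, tuple(rids), tuple(kids), "", kind))
        module_products.append(
            sorted({p for s in specs for p in s["products"]})
        )
        total += len(rids)
        m_idx += 1

    # contiguous pathway blocks over modules
    n_modules = len(modules)
    block = max(1, int(np.ceil(n_modules / config.n_pathways)))
    pathway_names: dict[str, str] = {}
    final_modules: list[Module] = []
    rxn_with_pw: dict[str, ReactionSpec] = {}
    for mod in modules:
        pw_idx = mod.index // block + 1
        pw = f"map{pw_idx:04d}"
        pathway_names[pw] = f"Synthetic pathway {pw_idx}"
        final_modules.append(
            Module(mod.index, mod.reactions, mod.kos, pw, mod.kind)
        )
        for rid in mod.reactions:
            r = reactions[rid]
            rxn_with_pw[rid] = ReactionSpec(
                r.id, r.substrates, r.products, r.reversible, r.enzymes,
                frozenset([pw]),
            )

    universe = ReactionUniverse(
        compounds, rxn_with_pw, kos, pathway_names, version=f"synthetic-seed{seed}"
    )
    return SyntheticUniverse(universe, final_modules)


# ---------------------------------------------------------------------------
# hand-check fixture universes
# ---------------------------------------------------------------------------


def fixture_universe(preset: str) -> ReactionUniverse:
    """Named hand-check universes.

    ``F1``: compounds A–E; R1: A→B, R2: B↔C (reversible), R3: C→A, R4: D→E;
    KOs K1..K4 each mapping one-to-one through EC1..EC4.  The full reaction
    graph has 5 nodes and 5 arcs and condenses to 2 MBBs.

    ``F2``: a 3-reaction irreversible path P1: A→B, P2: B→C, P3: C→D whose
    condensation is the identity (3 singleton MBBs, P1→P2→P3).
    """
    if preset == "F1":
        compounds = {c: Compound(c) for c in "ABCDE"}
        rxns = {
            "R1": ReactionSpec("R1", frozenset("A"), frozenset("B"), False,
                               frozenset(["EC1"]), frozenset(["pwA"])),
            "R2": ReactionSpec("R2", frozenset("B"), frozenset("C"), True,
                               frozenset(["EC2"]), frozenset(["pwA", "pwB"])),
            "R3": ReactionSpec("R3", frozenset("C"), frozenset("A"), False,
                               frozenset(["EC3"]), frozenset()),
            "R4": ReactionSpec("R4", frozenset("D"), frozenset("E"), False,
                               frozenset(["EC4"]), frozenset(["pwC"])),
        }
        kos = {f"K{i}": KoMapping(f"K{i}", frozenset([f"EC{i}"])) for i in range(1, 5)}
        names = {"pwA": "Pathway A", "pwB": "Pathway B", "pwC": "Pathway C"}
        return ReactionUniverse(compounds, rxns, kos, names, version="F1")
    if preset == "F2":
        compounds = {c: Compound(c) for c in "ABCD"}
        rxns = {
            "P1": ReactionSpec("P1", frozenset("A"), frozenset("B"), False,
                               frozenset(["ECP1"])),
            "P2": ReactionSpec("P2", frozenset("B"), frozenset("C"), False,
                               frozenset(["ECP2"])),
            "P3": ReactionSpec("P3", frozenset("C"), frozenset("D"), False,
                               frozenset(["ECP3"])),
        }
        kos = {f"KP{i}": KoMapping(f"KP{i}", frozenset([f"ECP{i}"])) for i in (1, 2, 3)}
        return ReactionUniverse(compounds, rxns, kos, {}, version="F2")
    raise KeyError(f"unknown preset {preset!r}")


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupConfig:
    """One cohort group.

    ``mode`` is "AA", "EI" or "mixture"; mixture draws each individual's mode
    once: MIX (infant-like elderly) with probability ``mixture_weight``, AA
    otherwise.  ``jitter`` is the individual-level accessory membership flip
    rate; ``dropout`` the per-sample KO dropout rate.
    """

    name: str
    mode: str
    n_individuals: int = 10
    samples_per_individual: int = 4
    dropout: float = 0.02
    jitter: float = 0.05
    mixture_weight: float = 0.5

    def __post_init__(self) -> None:
        for f in ("dropout", "jitter", "mixture_weight"):
            v = getattr(self, f)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f} must be in [0, 1], got {v}")
        if self.n_individuals < 1 or self.samples_per_individual < 1:
            raise ValueError("sizes must be positive")
        if self.mode not in ("AA", "EI", "MIX", "mixture"):
            raise ValueError(f"unknown mode {self.mode!r}")


def default_groups() -> tuple[GroupConfig, ...]:
    return (
        GroupConfig("adult", mode="AA", dropout=0.05, jitter=0.10),
        GroupConfig("elderly", mode="mixture", dropout=0.04, jitter=0.06,
                    mixture_weight=0.5),
        GroupConfig("infant", mode="EI", dropout=0.01, jitter=0.02),
    )


@dataclass(frozen=True)
class CohortConfig:
    """Cohort design: module-block allocation plus per-group settings.

    The first ``n_core_modules`` universe modules are shared by every sample.
    Signature blocks of ``n_signature_modules`` per mode (AA, MIX, EI) are
    drawn from the remaining *cycle* modules — the planted discriminative
    building blocks are multi-reaction functional modules, whose completeness
    features are far less noisy under KO dropout than single reactions.  The
    next ``n_accessory_modules`` remaining modules form a nested accessory
    pool of which each mode takes the first ``accessory_take[mode]``.
    """

    groups: tuple[GroupConfig, ...] = field(default_factory=default_groups)
    n_core_modules: int = 40
    n_signature_modules: int = 12
    n_accessory_modules: int = 30
    accessory_take: tuple[tuple[str, int], ...] = (("AA", 8), ("MIX", 16), ("EI", 25))

    def required_modules(self) -> int:
        return (
            self.n_core_modules
            + 3 * self.n_signature_modules
            + self.n_accessory_modules
        )


@dataclass
class CohortData:
    ko_table: pd.DataFrame  # long form: sample_id, ko_id, abundance
    metadata: pd.DataFrame  # sample_id, individual_id, group, timepoint
    truth: dict

    def sample_kos(self) -> dict[str, set[str]]:
        return {
            str(sid): set(g["ko_id"])
            for sid, g in self.ko_table.groupby("sample_id", sort=True)
        }

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "ko_table": outdir / "ko_table.tsv",
            "metadata": outdir / "metadata.tsv",
            "truth": outdir / "truth.json",
        }
        self.ko_table.to_csv(paths["ko_table"], sep="\t", index=False)
        self.metadata.to_csv(paths["metadata"], sep="\t", index=False)
        paths["truth"].write_text(json.dumps(self.truth, indent=1, sort_keys=True))
        return paths


def generate_cohort(
    synth: SyntheticUniverse, config: CohortConfig | None = None, seed: int = 0
) -> CohortData:
    """Sample the cohort KO table, metadata and planted truth."""
    config = config or CohortConfig()
    rng = np.random.default_rng(seed)

    nc, ns, na = (
        config.n_core_modules,
        config.n_signature_modules,
        config.n_accessory_modules,
    )
    if len(synth.modules) < nc:
        raise ValueError(
            f"universe has {len(synth.modules)} modules; need {nc} core modules"
        )
    core_idx = list(range(nc))
    # largest cycles first: planted blocks should be sizeable functional
    # modules whose completeness features are stable under KO dropout
    cycle_pool = sorted(
        (i for i in range(nc, len(synth.modules))
         if synth.modules[i].kind == "cycle"),
        key=lambda i: (-len(synth.modules[i].reactions), i),
    )
    if len(cycle_pool) < 3 * ns:
        raise ValueError(
            f"universe has {len(cycle_pool)} non-core cycle modules; "
            f"signature blocks need {3 * ns}"
        )
    # round-robin deal so the three blocks have matched size profiles
    sig_idx = {
        "AA": cycle_pool[0: 3 * ns: 3],
        "MIX": cycle_pool[1: 3 * ns: 3],
        "EI": cycle_pool[2: 3 * ns: 3],
    }
    taken = set(core_idx) | set(cycle_pool[: 3 * ns])
    remaining = [i for i in range(len(synth.modules)) if i not in taken]
    if len(remaining) < na:
        raise ValueError(
            f"universe has {len(remaining)} modules left for the accessory "
            f"pool; need {na}"
        )
    acc_idx = remaining[:na]
    take = dict(config.accessory_take)

    def mode_modules(mode: str) -> set[int]:
        return set(core_idx) | set(sig_idx[mode]) | set(acc_idx[: take[mode]])

    rows = []
    meta_rows = []
    individual_modes: dict[str, str] = {}
    sample_modes: dict[str, str] = {}
    for g in config.groups:
        prefix = g.name[0].upper()
        for i in range(g.n_individuals):
            ind = f"{prefix}{i + 1:02d}"
            if g.mode == "mixture":
                mode = "MIX" if rng.random() < g.mixture_weight else "AA"
            else:
                mode = g.mode
            individual_modes[ind] = mode
            # individual repertoire: mode base +/- accessory jitter flips
            mods = mode_modules(mode)
            for a in acc_idx:
                if rng.random() < g.jitter:
                    mods ^= {a}
            # the shared core block is present in every sample; dropout is
            # intra-individual noise on the variable repertoire only
            core_kos = sorted(synth.module_kos(core_idx))
            var_kos = sorted(synth.module_kos(sorted(mods - set(core_idx))))
            if (1.0 - g.dropout) * len(var_kos) < 1.0:
                raise ValueError(
                    f"dropout {g.dropout} leaves individual {ind} with an "
                    "expected variable repertoire below one KO"
                )
            for t in range(g.samples_per_individual):
                sid = f"{ind}T{t + 1}"
                sample_modes[sid] = mode
                keep = rng.random(len(var_kos)) >= g.dropout
                kos = core_kos + [k for k, kk in zip(var_kos, keep) if kk]
                kos.sort()
                abund = rng.lognormal(mean=0.0, sigma=1.0, size=len(kos))
                rows.extend(
                    {"sample_id": sid, "ko_id": k, "abundance": round(float(a), 4)}
                    for k, a in zip(kos, abund)
                )
                meta_rows.append(
                    {
                        "sample_id": sid,
                        "individual_id": ind,
                        "group": g.name,
                        "timepoint": f"T{t + 1}",
                    }
                )

    signature = {
        mode: {
            "reactions": sorted(
                r for i in sig_idx[mode] for r in synth.modules[i].reactions
            ),
            "kos": sorted(k for i in sig_idx[mode] for k in synth.modules[i].kos),
            "mbb_members": sorted(
                sorted(synth.modules[i].mbb_members()) for i in sig_idx[mode]
            ),
        }
        for mode in MODES
    }
    truth = {
        "individual_modes": individual_modes,
        "sample_modes": sample_modes,
        "signature": signature,
        "modes_present": sorted(set(individual_modes.values())),
        "core_modules": core_idx,
        "accessory_modules": acc_idx,
        "seed": seed,
    }
    ko_table = pd.DataFrame(rows, columns=["sample_id", "ko_id", "abundance"])
    metadata = pd.DataFrame(
        meta_rows, columns=["sample_id", "individual_id", "group", "timepoint"]
    )
    return CohortData(ko_table, metadata, truth)
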