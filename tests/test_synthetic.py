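import numpy as np
import pytest

import mdagkit as mk
from mdagkit.synthetic import (
    CohortConfig,
    GroupConfig,
    UniverseConfig,
    generate_cohort,
    generate_universe,
)


class TestUniverseGeneration:
    def test_same_seed_identical_output(self, tmp_path):
        a = generate_universe(seed=42)
        b = generate_universe(seed=42)
        pa = mk.write_universe(a.universe, tmp_path / "a.json", format="json")
        pb = mk.write_universe(b.universe, tmp_path / "b.json", format="json")
        assert pa.read_text() == pb.read_text()

    def test_reaches_target_size(self):
        synth = generate_universe(UniverseConfig(n_reactions=120), seed=0)
        assert len(synth.universe.reactions) >= 120

    def test_modules_condense_to_single_mbbs(self):
        synth = generate_universe(seed=3)
        rg = mk.build_reaction_graph(
            synth.universe, synth.universe.reactions.keys()
        )
        mdag = mk.condense_to_mdag(rg)
        member_sets = set(mdag.member_sets)
        for mod in synth.modules:
            assert mod.mbb_members() in member_sets

    def test_reversible_fraction_zero_means_no_rev_nodes(self):
        synth = generate_universe(
            UniverseConfig(n_reactions=60, reversible_fraction=0.0), seed=1
        )
        rg = mk.build_reaction_graph(synth.universe, synth.universe.reactions)
        assert all(not n.endswith("rev") for n in rg.nodes)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            UniverseConfig(n_reactions=0)
        with pytest.raises(ValueError):
            UniverseConfig(cycle_fraction=1.5)


class TestCohortGeneration:
    def test_same_seed_identical_tables(self):
        synth = generate_universe(seed=2)
        a = generate_cohort(synth, seed=7)
        b = generate_cohort(synth, seed=7)
        assert a.ko_table.equals(b.ko_table)
        assert a.metadata.equals(b.metadata)
        assert a.truth == b.truth

    def test_default_design_shape(self, synthetic_run):
        cohort = synthetic_run["cohort"]
        meta = cohort.metadata
        assert meta["individual_id"].nunique() == 30
        assert len(meta) == 120
        assert set(meta["group"]) == {"adult", "elderly", "infant"}

    def test_infant_mode_repertoires_exceed_adult_mode(self, synthetic_run):
        cohort = synthetic_run["cohort"]
        reactions = synthetic_run["sample_reactions"]
        modes = cohort.truth["sample_modes"]
        ei = [len(reactions[s]) for s, m in modes.items() if m == "EI"]
        aa = [len(reactions[s]) for s, m in modes.items() if m == "AA"]
        assert min(ei) > max(aa)

    def test_mixture_weight_extremes(self):
        synth = generate_universe(seed=4)
        only_adult_like = CohortConfig(
            groups=(
                GroupConfig("adult", mode="AA"),
                GroupConfig("elderly", mode="mixture", mixture_weight=0.0),
                GroupConfig("infant", mode="EI"),
            )
        )
        cohort = generate_cohort(synth, only_adult_like, seed=4)
        elderly = cohort.metadata[cohort.metadata["group"] == "elderly"]
        assert all(
            cohort.truth["individual_modes"][i] == "AA"
            for i in elderly["individual_id"].unique()
        )
        assert cohort.truth["modes_present"] == ["AA", "EI"]

    def test_noiseless_groups_have_identical_samples(self):
        synth = generate_universe(seed=5)
        cfg = CohortConfig(
            groups=(
                GroupConfig("adult", mode="AA", n_individuals=3,
                            dropout=0.0, jitter=0.0),
                GroupConfig("infant", mode="EI", n_individuals=3,
                            dropout=0.0, jitter=0.0),
            )
        )
        cohort = generate_cohort(synth, cfg, seed=5)
        kos = cohort.sample_kos()
        meta = cohort.metadata.set_index("sample_id")
        for g, part in meta.groupby("group"):
            sets = [frozenset(kos[s]) for s in part.index]
            assert len(set(sets)) == 1

    def test_excessive_dropout_rejected(self):
        synth = generate_universe(seed=6)
        cfg = CohortConfig(
            groups=(GroupConfig("adult", mode="AA", dropout=0.999),
                    GroupConfig("infant", mode="EI"))
        )
        with pytest.raises(ValueError, match="dropout"):
            generate_cohort(synth, cfg, seed=6)

    def test_small_universe_rejected(self):
        synth = generate_universe(UniverseConfig(n_reactions=40), seed=0)
        with pytest.raises(ValueError):
            generate_cohort(synth, seed=0)

    def test_truth_signature_mbbs_exist_in_pan_mdag(self, synthetic_run):
        from mdagkit.graphs import MBB

        cohort = synthetic_run["cohort"]
        synth = synthetic_run["synth"]
        reactions = synthetic_run["sample_reactions"]
        pan = mk.pan_reactions(list(reactions.values()))
        pan_mdag = mk.condense_to_mdag(mk.build_reaction_graph(synth.universe, pan))
        for mode in ("AA", "MIX", "EI"):
            for members in cohort.truth["signature"][mode]["mbb_members"]:
                assert MBB.from_members(frozenset(members)).id in pan_mdag.mbbs

    def test_intra_individual_below_inter_individual_dissimilarity(self, synthetic_run):
        d = synthetic_run["dissimilarity"].to_dataframe()
        meta = synthetic_run["cohort"].metadata.set_index("sample_id")
        for g, part in meta.groupby("group"):
            ids = list(part.index)
            intra, inter = [], []
            for i, a in enumerate(ids):
                for b in ids[i + 1:]:
                    same = part.loc[a, "individual_id"] == part.loc[b, "individual_id"]
                    (intra if same else inter).append(d.loc[a, b])
            assert np.mean(intra) < np.mean(inter)

    def test_write_outputs_consumable_by_io_layer(self, tmp_path, synthetic_run):
        cohort = synthetic_run["cohort"]
        paths = cohort.write(tmp_path)
        table = mk.read_ko_table(paths["ko_table"])
        meta = mk.read_metadata(paths["metadata"])
        assert set(table) == set(meta.index)
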