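"""Synthetic-repertoire generation: clone sizes, trees, context-dependent
sequence evolution and mutability tables."""

import numpy as np
import pytest

from bcrphylo.codon_space import CODON_SPACE, MOTIFS, RegionMask, seq_to_codon_indices
from bcrphylo.phylo_likelihood import Repertoire
from bcrphylo.simulate import (
    MutabilityTable,
    SimConfig,
    default_sim_params,
    draw_clone_sizes,
    evolve_hlp19_full_context,
    evolve_s5f,
    generate_repertoire_fixture,
    make_vregion_mask,
    motif_mean_mutability,
    random_coalescent_tree,
    subsample_repertoire,
)
from bcrphylo.substitution_models import ModelParams
from bcrphylo.trees import LineageTree

STOPS = {"TAA", "TAG", "TGA"}


def has_stop(seq):
    return any(seq[3 * i:3 * i + 3] in STOPS for i in range(len(seq) // 3))


class TestCloneSizes:
    def test_fixed_law_gives_constant_sizes(self, rng):
        assert set(draw_clone_sizes(50, ("fixed", 6), rng)) == {6}

    def test_power_law_default_is_dominated_by_singletons(self, rng):
        sizes = draw_clone_sizes(5000, ("power_law", 3.95), rng)
        frac = float(np.mean(sizes == 1))
        assert 0.88 <= frac <= 0.96
        # and nearly all clones stay small
        assert float(np.mean(sizes < 5)) > 0.98


class TestTreesAndMasks:
    def test_coalescent_tree_rescaled_to_requested_length(self, rng):
        tree = random_coalescent_tree(6, rng, [f"t{i}" for i in range(6)], 0.3)
        assert tree.tree_length() == pytest.approx(0.3)
        assert sorted(tree.tip_labels()) == [f"t{i}" for i in range(6)]
        assert tree.root.label == "GERMLINE"

    def test_singleton_tree_is_single_branch(self, rng):
        tree = random_coalescent_tree(1, rng, ["only"], 0.3)
        assert tree.tree_length() == pytest.approx(0.3)
        assert tree.tip_labels() == ["only"]

    def test_vregion_mask_fractions(self):
        mask = make_vregion_mask(100, 0.25)
        labels = list(mask.labels)
        assert labels.count("CDR") == 25
        assert labels.count("IGNORED") == 5
        assert len(mask) == 100


class TestHlp19Evolver:
    def test_zero_length_tree_returns_germline(self):
        germ = "AAACCCGGG"
        tree = LineageTree.from_newick("((a:0,b:0):0)GERMLINE;")
        tips = evolve_hlp19_full_context(germ, tree, default_sim_params(), seed=1)
        assert tips == {"a": germ, "b": germ}

    def test_determinism_and_seed_sensitivity(self, rng):
        germ = "".join(CODON_SPACE.codons[i] for i in rng.integers(0, 61, 40))
        tree = LineageTree.from_newick("((a:0.1,b:0.1):0.05)GERMLINE;")
        t1 = evolve_hlp19_full_context(germ, tree, default_sim_params(), seed=7)
        t2 = evolve_hlp19_full_context(germ, tree, default_sim_params(), seed=7)
        t3 = evolve_hlp19_full_context(germ, tree, default_sim_params(), seed=8)
        assert t1 == t2
        assert t1 != t3

    def test_neutral_substitution_count_tracks_branch_length(self, rng):
        # h=0, kappa=1, omega=1: expected substitutions per codon equal the
        # branch length (short branch, so multiple hits are negligible)
        params = ModelParams(kappa=1, omega_fwr=1, omega_cdr=1)
        t = 0.05
        n_codons, reps = 200, 60
        tree = LineageTree.from_newick(f"(tip:{t})GERMLINE;")
        total = 0
        for r in range(reps):
            germ = "".join(CODON_SPACE.codons[i] for i in rng.integers(0, 61, n_codons))
            tips = evolve_hlp19_full_context(germ, tree, params, seed=int(r))
            total += sum(a != b for a, b in zip(tips["tip"], germ))
        expected = t * n_codons * reps
        # 3 SE Poisson band, small downward allowance for multiple hits
        assert abs(total - expected) < 3 * np.sqrt(expected) + 0.02 * expected

    def test_hot_spot_sites_mutate_about_seven_times_faster(self):
        # GTA codons carry a deterministic GYW target at their G, GAT
        # codons carry a motif-free G; with h_GYW=6 the hot G should see
        # ~7x the substitutions of the neutral G
        params = ModelParams(kappa=1, omega_fwr=1, omega_cdr=1,
                             h={"WRC": 0, "GYW": 6.0, "WA": 0, "TW": 0, "SYC": 0, "GRS": 0})
        germ = "GTAGAT" * 25
        hot = [i for i in range(0, len(germ), 6)]
        neutral = [i + 3 for i in hot]
        tree = LineageTree.from_newick("(tip:0.06)GERMLINE;")
        ch, cn = 0, 0
        for r in range(200):
            tips = evolve_hlp19_full_context(germ, tree, params, seed=1000 + r)
            s = tips["tip"]
            ch += sum(s[i] != germ[i] for i in hot)
            cn += sum(s[i] != germ[i] for i in neutral)
        assert cn > 50  # enough events to compare
        ratio = ch / cn
        assert 5.0 < ratio < 9.5

    def test_no_stop_codons_ever(self, small_repertoire):
        for lin in small_repertoire.lineages:
            assert not has_stop(lin.germline)
            for s in lin.sequences.values():
                assert not has_stop(s)

    def test_divergence_monotone_in_branch_scale(self, rng):
        germ = "".join(CODON_SPACE.codons[i] for i in rng.integers(0, 61, 80))
        divs = []
        for scale in (0.05, 0.2, 0.6):
            tree = LineageTree.from_newick(f"(tip:{scale})GERMLINE;")
            d = 0
            for r in range(25):
                tips = evolve_hlp19_full_context(germ, tree, default_sim_params(),
                                                 seed=200 + r)
                d += sum(a != b for a, b in zip(tips["tip"], germ))
            divs.append(d)
        assert divs[0] < divs[1] < divs[2]


class TestMutabilityTables:
    def test_synthetic_table_reproduces_hot_cold_ranking(self):
        table = MutabilityTable.synthetic()
        means = {m: motif_mean_mutability(table, MOTIFS[m]) for m in MOTIFS}
        assert means["GYW"] > means["WRC"] >= means["WA"] > means["TW"]
        assert means["TW"] > means["SYC"]
        assert abs(means["SYC"] - means["GRS"]) < 0.05 * means["TW"]

    def test_unit_scores_give_unit_motif_mean(self):
        # every matching pentamer scores 1.0, so the motif mean is 1.0
        table = MutabilityTable.uniform()
        motif = MOTIFS["TW"]
        assert motif_mean_mutability(table, motif) == pytest.approx(1.0)

    def test_tsv_round_trip(self, tmp_path):
        table = MutabilityTable.synthetic()
        path = tmp_path / "table.tsv"
        table.to_tsv(path)
        back = MutabilityTable.from_tsv(path)
        for fm in ("GTAAA", "TACGT", "AAAAA"):
            assert back.lookup(fm) == pytest.approx(table.lookup(fm))

    def test_missing_fivemer_falls_back_to_matching_average(self):
        table = MutabilityTable({"AATAA": 2.0, "CATAA": 4.0}, {})
        assert table.lookup("NATAA") == pytest.approx(3.0)

    def test_motif_without_matching_pentamers_rejected(self):
        from bcrphylo.codon_space import MotifSpec

        impossible = MotifSpec("X", "AAAAAA", 2)  # longer than a 5-mer window
        with pytest.raises(ValueError):
            motif_mean_mutability(MutabilityTable.uniform(), impossible)


class TestS5fEvolver:
    def test_uniform_table_reduces_to_context_free_divergence(self, rng):
        germ = "".join(CODON_SPACE.codons[i] for i in rng.integers(0, 61, 100))
        tree = LineageTree.from_newick("(tip:0.08)GERMLINE;")
        table = MutabilityTable.uniform()
        d = 0
        for r in range(40):
            tips = evolve_s5f(germ, tree, table, seed=300 + r)
            assert not has_stop(tips["tip"])
            d += sum(a != b for a, b in zip(tips["tip"], germ))
        expected = 0.08 * 100 * 40
        assert abs(d - expected) < 3 * np.sqrt(expected) + 0.05 * expected

    def test_hot_fivemers_accumulate_more_changes(self):
        table = MutabilityTable.synthetic()
        germ = "GTAGAT" * 20
        hot = list(range(0, len(germ), 6))
        neutral = [i + 3 for i in hot]
        tree = LineageTree.from_newick("(tip:0.2)GERMLINE;")
        ch = cn = 0
        for r in range(250):
            s = evolve_s5f(germ, tree, table, seed=400 + r)["tip"]
            ch += sum(s[i] != germ[i] for i in hot)
            cn += sum(s[i] != germ[i] for i in neutral)
        assert cn > 60
        assert 4.0 < ch / cn < 10.5

    def test_deterministic_given_seed(self):
        germ = "AAACCCGGGTTTACT"
        tree = LineageTree.from_newick("(tip:0.3)GERMLINE;")
        table = MutabilityTable.synthetic()
        assert evolve_s5f(germ, tree, table, seed=5) == evolve_s5f(germ, tree, table, seed=5)


class TestFixtures:
    def test_fixture_determinism_same_seed_identical_files(self, tmp_path):
        cfg = dict(n_lineages=4, clone_size_law=("fixed", 3), n_codons=30)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_repertoire_fixture(SimConfig(seed=5, **cfg), out_dir=str(d1))
        generate_repertoire_fixture(SimConfig(seed=5, **cfg), out_dir=str(d2))
        for name in ("repertoire.airr.tsv", "trees.tsv", "mask.tsv", "manifest.json"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_fixed_singleton_config_gives_single_tip_lineages(self):
        rep = generate_repertoire_fixture(
            SimConfig(n_lineages=5, clone_size_law=("fixed", 1), n_codons=20, seed=3))
        assert all(len(lin.sequences) == 1 for lin in rep.lineages)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimConfig(n_lineages=0).validate()
        with pytest.raises(ValueError):
            SimConfig(cdr_fraction=1.5).validate()
        with pytest.raises(ValueError):
            SimConfig(generator="bogus").validate()


class TestSubsampling:
    def _rep(self):
        cfg = SimConfig(n_lineages=12, clone_size_law=("fixed", 4), n_codons=20, seed=9)
        return generate_repertoire_fixture(cfg)

    def test_depth_at_total_is_identity(self):
        rep = self._rep()
        total = sum(len(l.sequences) for l in rep.lineages)
        out = subsample_repertoire(rep, total, seed=0)
        assert sum(len(l.sequences) for l in out.lineages) == total

    def test_exact_depth_retained(self):
        rep = self._rep()
        out = subsample_repertoire(rep, 30, seed=0)
        kept = sum(len(l.sequences) for l in out.lineages
                   if l.n_unique_sequences() >= 1)
        # all retained lineages came from the nonsingleton pool
        assert sum(len(l.sequences) for l in out.lineages) <= 30
        assert all(l.n_unique_sequences() >= 2 for l in out.lineages)
        assert kept > 0

    def test_different_seeds_differ_but_same_size(self):
        rep = self._rep()
        o1 = subsample_repertoire(rep, 30, seed=1)
        o2 = subsample_repertoire(rep, 30, seed=2)
        n1 = sorted(sid for l in o1.lineages for sid in l.sequences)
        n2 = sorted(sid for l in o2.lineages for sid in l.sequences)
        assert n1 != n2
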