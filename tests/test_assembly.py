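import numpy as np
import pandas as pd
import pytest

from ecoassembly.io import CommunityTable, PairwiseMatrix, PhyloTree
from ecoassembly.assembly import (
    ProcessThresholds,
    beta_mntd,
    bnti,
    classify_pair,
    classify_processes,
    fit_ncm,
    ncm_predicted_frequency,
    pnst,
    raup_crick_bray,
)
from ecoassembly.synthetic import SyntheticScenario, simulate_neutral, simulate_tree


def _ct(rows, taxa):
    rows = np.asarray(rows, dtype=float)
    return CommunityTable(rows, [f"s{i}" for i in range(rows.shape[0])], taxa)


class TestBetaMntd:
    def test_disjoint_communities(self, three_leaf_tree):
        t = _ct([[1, 0, 0], [0, 0, 1]], ["A", "B", "C"])
        m = beta_mntd(t, three_leaf_tree.cophenetic(["A", "B", "C"]))
        assert m.values[0, 1] == pytest.approx(4.0)

    def test_partially_shared(self, three_leaf_tree):
        t = _ct([[0.5, 0.5, 0], [1, 0, 0]], ["A", "B", "C"])
        m = beta_mntd(t, three_leaf_tree.cophenetic(["A", "B", "C"]))
        assert m.values[0, 1] == pytest.approx(0.5)

    def test_identical_communities(self, three_leaf_tree):
        t = _ct([[2, 1, 3], [2, 1, 3]], ["A", "B", "C"])
        m = beta_mntd(t, three_leaf_tree.cophenetic(["A", "B", "C"]))
        assert m.values[0, 1] == pytest.approx(0.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        tree = simulate_tree(10, seed=1)
        taxa = sorted(tree.leaf_labels)
        counts = rng.integers(0, 8, size=(6, 10)).astype(float)
        counts[:, 0] += 1
        table = _ct(counts, taxa)
        d = tree.cophenetic(taxa).values
        got = beta_mntd(table, tree.cophenetic(taxa)).values

        rel = counts / counts.sum(axis=1, keepdims=True)
        for k in range(6):
            for l in range(6):
                if k == l:
                    continue
                pk = np.flatnonzero(counts[k] > 0)
                pl = np.flatnonzero(counts[l] > 0)
                term1 = sum(rel[k, i] * min(d[i, j] for j in pl) for i in pk)
                term2 = sum(rel[l, j] * min(d[i, j] for i in pk) for j in pl)
                assert got[k, l] == pytest.approx(0.5 * (term1 + term2),
                                                  abs=1e-12)


class TestBnti:
    def test_star_phylogeny_degenerate_null(self):
        # equal tip distances: every shuffle leaves betaMNTD unchanged
        star = PhyloTree.from_newick("(A:1,B:1,C:1,D:1);")
        t = _ct([[1, 1, 0, 0], [0, 0, 1, 1]], ["A", "B", "C", "D"])
        z = bnti(t, star, n_null=19, seed=0)
        assert np.isnan(z.values[0, 1])

    def test_taxon_relabeling_invariance(self):
        tree = simulate_tree(12, seed=2)
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 6, size=(5, 12)).astype(float) + (
            rng.random((5, 12)) < 0.3)
        counts[:, 0] += 1
        taxa = sorted(tree.leaf_labels)
        t1 = _ct(counts, taxa)
        # permute table columns; same taxa set, same canonical order inside
        perm = rng.permutation(12)
        t2 = CommunityTable(counts[:, perm], t1.sample_ids,
                            [taxa[i] for i in perm])
        t2 = t2.select_taxa(taxa)
        z1 = bnti(t1, tree, n_null=49, seed=5)
        z2 = bnti(t2, tree, n_null=49, seed=5)
        np.testing.assert_allclose(z1.values, z2.values, atol=1e-10)

    def test_neutral_data_centered(self):
        scen = SyntheticScenario(n_taxa=80, reads_per_sample=500,
                                 migration_rate=0.2, seed=6)
        table = simulate_neutral(scen, n_samples=10)
        tree = simulate_tree(80, seed=6)
        z = bnti(table, tree, n_null=99, seed=7)
        vals = z.condensed()
        assert np.abs(np.nanmean(vals)) < 1.0


class TestRaupCrick:
    def test_bounds_and_symmetry(self):
        scen = SyntheticScenario(n_taxa=40, reads_per_sample=200, seed=8)
        table = simulate_neutral(scen, n_samples=8)
        rc = raup_crick_bray(table, n_null=49, seed=9)
        assert np.abs(rc.values).max() <= 1.0 + 1e-12
        np.testing.assert_allclose(rc.values, rc.values.T, atol=1e-12)

    def test_extreme_ranks(self):
        # two disjoint single-taxon samples against a pool where co-occurrence
        # is forced: observed BC (=1) is never exceeded -> RC = +1
        counts = np.array([[50, 0, 1, 1], [0, 50, 1, 1.],
                           [25, 25, 1, 1], [25, 25, 1, 1]])
        table = _ct(counts, list("abcd"))
        rc = raup_crick_bray(table, n_null=99, seed=10)
        assert rc.values[0, 1] > 0.9  # far more dissimilar than the null

    def test_rc_mean_decreases_with_migration(self):
        # dispersal limitation (low m) -> positive RC; homogenization -> negative
        means = []
        for m in (0.05, 0.3, 1.0):
            scen = SyntheticScenario(n_taxa=60, reads_per_sample=500,
                                     migration_rate=m, seed=11)
            t = simulate_neutral(scen, n_samples=10)
            rc = raup_crick_bray(t, n_null=99, seed=12)
            means.append(rc.condensed().mean())
        assert means[0] > means[1] > means[2]

    def test_requires_integer_counts(self):
        with pytest.raises(ValueError, match="integer"):
            raup_crick_bray(_ct([[0.5, 1.5], [1, 1]], ["a", "b"]))


class TestClassification:
    @pytest.mark.parametrize("b,rc,expected", [
        (-3.0, 0.99, "homogeneous_selection"),   # selection takes precedence
        (3.0, -0.99, "variable_selection"),
        (0.5, -0.99, "homogenizing_dispersal"),
        (-1.0, 0.97, "dispersal_limitation"),
        (1.0, 0.2, "drift"),
    ])
    def test_rule_table(self, b, rc, expected):
        assert classify_pair(b, rc, ProcessThresholds()) == expected

    def test_fractions_sum_to_100(self):
        rng = np.random.default_rng(13)
        n = 8
        labels = [f"s{i}" for i in range(n)]
        z = rng.normal(scale=2.5, size=(n, n))
        z = (z + z.T) / 2
        np.fill_diagonal(z, 0)
        r = np.clip(rng.normal(scale=0.8, size=(n, n)), -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 0)
        cls = classify_processes(PairwiseMatrix(z, labels),
                                 PairwiseMatrix(r, labels),
                                 groups={s: "g" for s in labels})
        assert cls.fractions.loc["pooled"].sum() == pytest.approx(100.0)
        assert cls.fractions.loc["g"].sum() == pytest.approx(100.0)

    def test_undefined_pairs_counted(self):
        labels = ["a", "b", "c"]
        z = np.zeros((3, 3))
        z[0, 1] = z[1, 0] = np.nan
        r = np.zeros((3, 3))
        cls = classify_processes(PairwiseMatrix(z, labels),
                                 PairwiseMatrix(r, labels))
        assert cls.n_undefined == 1
        assert len(cls.pair_labels) == 2


class TestNcm:
    def test_predicted_frequency_monotone_in_p(self):
        p = np.linspace(1e-4, 0.2, 100)
        f = ncm_predicted_frequency(p, N=1000, m=0.1, detection_limit=1e-3)
        assert np.all(np.diff(f) >= -1e-12)
        assert f[-1] > 0.99

    def test_abundant_taxa_reach_frequency_one(self):
        f = ncm_predicted_frequency(np.array([0.3]), N=5000, m=0.5,
                                    detection_limit=1 / 5000)
        assert f[0] == pytest.approx(1.0, abs=1e-6)

    def test_recovery_with_count_calibrated_detection(self):
        # with d = ln(2)/N (the 50%-detection abundance for N-read sampling)
        # the fitted m recovers the generating value within 20%
        scen = SyntheticScenario(n_taxa=300, reads_per_sample=1000,
                                 migration_rate=0.1, seed=42)
        table = simulate_neutral(scen, n_samples=50)
        fit = fit_ncm(table, detection_limit=np.log(2) / 1000)
        assert 0.08 <= fit.m <= 0.12
        assert fit.r_squared > 0.6
        assert set(fit.taxa["band"]) <= {"above", "within", "below"}

    def test_needs_enough_taxa(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_ncm(_ct([[5, 5], [4, 6]], ["a", "b"]))


class TestPnst:
    def test_bounded_and_deterministic(self):
        scen = SyntheticScenario(n_taxa=40, reads_per_sample=300,
                                 migration_rate=0.2, seed=14)
        table = simulate_neutral(scen, n_samples=8)
        tree = simulate_tree(40, seed=14)
        groups = {s: ("x" if i < 4 else "y")
                  for i, s in enumerate(table.sample_ids)}
        r1 = pnst(table, tree, groups, n_null=29, seed=15)
        r2 = pnst(table, tree, groups, n_null=29, seed=15)
        assert ((r1.pairwise["pnst"] >= 0) & (r1.pairwise["pnst"] <= 1)).all()
        pd.testing.assert_frame_equal(r1.pairwise, r2.pairwise)

    def test_small_group_rejected(self):
        scen = SyntheticScenario(n_taxa=20, seed=16)
        table = simulate_neutral(scen, n_samples=4)
        tree = simulate_tree(20, seed=16)
        groups = {s: ("x" if i < 2 else "y")
                  for i, s in enumerate(table.sample_ids)}
        with pytest.raises(ValueError, match="fewer than 3"):
            pnst(table, tree, groups, n_null=9, seed=0)
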