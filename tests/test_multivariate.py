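import numpy as np
import pandas as pd
import pytest

from ecoassembly.io import CommunityTable
from ecoassembly.diversity import beta_distance
from ecoassembly.multivariate import (
    bh_adjust,
    correlation_table,
    dbrda,
    lmg_importance,
    significance_stars,
    vif_screen,
    _pcoa_coords,
)


def _env(n, k, seed=0, names=None):
    rng = np.random.default_rng(seed)
    names = names or [f"v{i}" for i in range(k)]
    return pd.DataFrame(rng.normal(size=(n, k)), columns=names,
                        index=[f"s{i}" for i in range(n)])


class TestVif:
    def test_orthogonal_predictors(self):
        x = pd.DataFrame({"a": [1, -1, 1, -1, 1, -1.],
                          "b": [1, 1, -1, -1, 1, -1.]})
        x["b"] -= x["b"].mean()  # keep them uncorrelated enough
        retained, vifs = vif_screen(_env(40, 3, seed=1))
        assert set(retained) == {"v0", "v1", "v2"}
        assert all(v < 2 for v in vifs.values())

    def test_two_correlated_closed_form(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=4000)
        b = 0.8 * a + np.sqrt(1 - 0.64) * rng.normal(size=4000)
        env = pd.DataFrame({"a": a, "b": b})
        _, vifs = vif_screen(env)
        expected = 1 / (1 - np.corrcoef(a, b)[0, 1] ** 2)
        assert vifs["a"] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(1 / (1 - 0.64), rel=0.05)

    def test_duplicated_column_removed(self):
        env = _env(30, 2, seed=4)
        env["dup"] = env["v0"]
        retained, _ = vif_screen(env)
        assert len(retained) == 2
        assert "v1" in retained


class TestDbrda:
    def test_projection_identity(self):
        scen_counts = np.random.default_rng(5).integers(0, 50, (15, 40))
        table = CommunityTable(scen_counts.astype(float),
                               [f"s{i}" for i in range(15)],
                               [f"t{i}" for i in range(40)])
        bc = beta_distance(table, "bray_curtis")
        coords, eig, _ = _pcoa_coords(bc)
        env = pd.DataFrame({"ax1": coords[:, 0]}, index=bc.labels)
        res = dbrda(bc, env, n_perm=0, seed=0)
        assert res.constrained_proportion == pytest.approx(
            eig[0] / eig.sum(), abs=1e-6)

    def test_affine_invariance(self):
        counts = np.random.default_rng(6).integers(0, 30, (12, 25)).astype(float)
        table = CommunityTable(counts, [f"s{i}" for i in range(12)],
                               [f"t{i}" for i in range(25)])
        bc = beta_distance(table, "bray_curtis")
        env = _env(12, 2, seed=7)
        env.index = bc.labels
        p0 = dbrda(bc, env, n_perm=0, seed=0).constrained_proportion
        env2 = env.copy()
        env2["v0"] = 5.0 * env2["v0"] - 3.0
        p1 = dbrda(bc, env2, n_perm=0, seed=0).constrained_proportion
        assert p0 == pytest.approx(p1, abs=1e-10)

    def test_one_level_condition_only(self):
        counts = np.random.default_rng(8).integers(0, 30, (8, 10)).astype(float)
        table = CommunityTable(counts, [f"s{i}" for i in range(8)],
                               [f"t{i}" for i in range(10)])
        bc = beta_distance(table, "bray_curtis")
        env = pd.DataFrame(index=bc.labels)
        res = dbrda(bc, env, condition=pd.Series("all", index=bc.labels),
                    n_perm=0, seed=0)
        assert res.constrained_proportion == 0.0

    def test_too_many_constraints(self):
        counts = np.random.default_rng(9).integers(0, 9, (5, 8)).astype(float) + 1
        table = CommunityTable(counts, [f"s{i}" for i in range(5)],
                               [f"t{i}" for i in range(8)])
        bc = beta_distance(table, "bray_curtis")
        with pytest.raises(ValueError, match="more constraints"):
            dbrda(bc, _env(5, 5, seed=1, names=list("abcde")).set_index(
                pd.Index(bc.labels)), n_perm=0, seed=0)


class TestCorrelationTable:
    def test_perfect_monotone(self):
        x = pd.DataFrame({"a": np.arange(10.0)})
        y = pd.DataFrame({"b": np.arange(10.0) ** 3})
        out = correlation_table(x, y)
        assert out["coefficient"].iloc[0] == pytest.approx(1.0)
        assert out["stars"].iloc[0] == "****"

    def test_bh_hand_example(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.01, 0.02, 0.04])),
                                   [0.03, 0.03, 0.04])

    def test_star_thresholds(self):
        assert significance_stars(0.03) == "*"
        assert significance_stars(0.007) == "**"
        assert significance_stars(0.003) == "***"
        assert significance_stars(0.0005) == "****"
        assert significance_stars(0.2) == ""

    def test_constant_variable_null_record(self):
        x = pd.DataFrame({"a": np.arange(8.0)})
        y = pd.DataFrame({"b": np.ones(8)})
        out = correlation_table(x, y)
        assert np.isnan(out["coefficient"].iloc[0])

    def test_spearman_monotone_invariance(self):
        rng = np.random.default_rng(10)
        a = rng.normal(size=30)
        b = rng.normal(size=30)
        x = pd.DataFrame({"a": a})
        r1 = correlation_table(x, pd.DataFrame({"b": b}))["coefficient"].iloc[0]
        r2 = correlation_table(x, pd.DataFrame({"b": np.exp(b)}))[
            "coefficient"].iloc[0]
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestLmg:
    def test_single_predictor_is_simple_r2(self):
        rng = np.random.default_rng(11)
        x = _env(50, 1, seed=11)
        y = pd.Series(2 * x["v0"] + rng.normal(size=50), name="y")
        dec = lmg_importance(y, x)
        assert dec.shares["v0"] == pytest.approx(dec.full_model_r2, abs=1e-12)

    def test_orthogonal_shares_are_marginal_r2(self):
        n = 400
        a = np.tile([1.0, -1.0], n // 2)
        b = np.repeat([1.0, -1.0], n // 2)
        rng = np.random.default_rng(12)
        y = pd.Series(a + 0.5 * b + 0.1 * rng.normal(size=n), name="y")
        x = pd.DataFrame({"a": a, "b": b})
        dec = lmg_importance(y, x)
        r2a = np.corrcoef(a, y)[0, 1] ** 2
        r2b = np.corrcoef(b, y)[0, 1] ** 2
        assert dec.shares["a"] == pytest.approx(r2a, abs=1e-10)
        assert dec.shares["b"] == pytest.approx(r2b, abs=1e-10)

    def test_shares_sum_to_full_r2(self):
        rng = np.random.default_rng(13)
        x = _env(60, 5, seed=13)
        y = pd.Series(x.to_numpy() @ rng.normal(size=5)
                      + rng.normal(size=60), name="y")
        dec = lmg_importance(y, x)
        assert sum(dec.shares.values()) == pytest.approx(dec.full_model_r2,
                                                         abs=1e-10)

    def test_singular_design_rejected(self):
        x = _env(30, 2, seed=14)
        x["dup"] = x["v0"]
        with pytest.raises(ValueError, match="singular"):
            lmg_importance(pd.Series(np.arange(30.0)), x)
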