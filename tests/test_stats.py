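"""Statistical workflow: gating, factorial tests, correlations, permutation
statistics (with exhaustive brute-force oracles) and constrained ordination."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from ntracer.stats import (
    cca,
    correlation_matrix,
    mantel,
    normality_gate,
    pcoa,
    permanova,
    simper,
    two_way_anova,
)


def random_distance(rng, n, dim=3):
    return squareform(pdist(rng.normal(size=(n, dim))))


class TestNormalityGate:
    def test_normal_sample_routes_parametric(self, rng):
        x = rng.normal(size=50)
        gate = normality_gate(x)
        # oracle: the library Shapiro-Wilk on the pinned sample
        assert gate.p_value == pytest.approx(sps.shapiro(x)[1])
        assert gate.route == ("parametric" if gate.p_value >= 0.05 else "rank")
        assert gate.route == "parametric"  # pinned seed

    def test_heavy_lognormal_routes_rank(self, rng):
        x = np.exp(rng.normal(size=60) * 3)
        assert normality_gate(x).route == "rank"

    def test_constant_vector_routes_rank_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert normality_gate([2.0, 2.0, 2.0, 2.0]).route == "rank"

    def test_tiny_sample_routes_rank_with_warning(self):
        with pytest.warns(UserWarning):
            assert normality_gate([1.0, 2.0]).route == "rank"


def make_design(rng, shift_a=0.0, n_per_cell=6, lognormal=False):
    rows = []
    for i, a in enumerate(["WW", "FL", "MC"]):
        for b in ["NO3", "NH4", "UREA", "GLU"]:
            y = rng.normal(size=n_per_cell) + (shift_a * i)
            if lognormal:
                y = np.exp(y)
            for v in y:
                rows.append({"y": v, "group": a, "form": b})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_detects_planted_group_effect(self, rng):
        df = make_design(rng, shift_a=3.0)
        res = two_way_anova(df, "y", "group", "form")
        assert res.effects.loc["group", "p_value"] < 0.05
        assert res.effects.loc["form", "p_value"] > 0.05

    def test_rank_route_on_skewed_data(self, rng):
        df = make_design(rng, shift_a=3.0, lognormal=True)
        res = two_way_anova(df, "y", "group", "form")
        assert res.route == "rank"
        assert res.effects.loc["group", "p_value"] < 0.05

    def test_rank_statistic_invariant_to_monotone_transform(self, rng):
        df = make_design(rng, shift_a=1.0)
        a = two_way_anova(df, "y", "group", "form", route="rank")
        df2 = df.assign(y=np.exp(df["y"]))
        b = two_way_anova(df2, "y", "group", "form", route="rank")
        assert a.effects["statistic"].values == pytest.approx(b.effects["statistic"].values)

    def test_constant_response_rejected(self):
        df = pd.DataFrame({"y": [1.0] * 8, "a": ["x", "y"] * 4, "b": ["u", "u", "v", "v"] * 2})
        with pytest.raises(ValueError, match="no variance"):
            two_way_anova(df, "y", "a", "b")

    def test_tukey_reported_per_factor(self, rng):
        df = make_design(rng, shift_a=2.0)
        res = two_way_anova(df, "y", "group", "form")
        assert set(res.tukey) == {"group", "form"}


class TestCorrelationMatrix:
    def test_self_correlation_unity_and_antithetic(self, rng):
        x = rng.random(30)
        df = pd.DataFrame({"x": x, "negx": -x, "z": rng.random(30)})
        out = correlation_matrix(df)
        assert out["rho"].loc["x", "x"] == 1.0
        assert out["rho"].loc["x", "negx"] == pytest.approx(-1.0)
        assert out["stars"].loc["x", "negx"] == "***"

    def test_spearman_invariant_to_ln_transform(self, rng):
        x = np.exp(rng.normal(size=40) * 2)
        y = x * np.exp(rng.normal(size=40) * 0.2)
        df = pd.DataFrame({"x": x, "y": y})
        with_t = correlation_matrix(df, transform=True)
        without = correlation_matrix(df, transform=False)
        assert with_t["rho"].loc["x", "y"] == pytest.approx(without["rho"].loc["x", "y"])
        assert any(with_t["transformed"].values())

    def test_constant_variable_dropped(self, rng):
        df = pd.DataFrame({"x": rng.random(20), "c": np.ones(20)})
        with pytest.warns(UserWarning, match="constant"):
            out = correlation_matrix(df)
        assert "c" not in out["rho"].columns


def mantel_oracle(a, b):
    """Exhaustive Mantel p by direct enumeration, Spearman via rank + corrcoef."""
    n = a.shape[0]
    iu = np.triu_indices(n, k=1)

    def spear(x, y):
        return np.corrcoef(sps.rankdata(x), sps.rankdata(y))[0, 1]

    obs = spear(a[iu], b[iu])
    hits = total = 0
    for p in itertools.permutations(range(n)):
        bp = b[np.ix_(p, p)]
        if spear(a[iu], bp[iu]) >= obs - 1e-12:
            hits += 1
        total += 1
    return obs, hits / total


class TestMantel:
    def test_identical_matrices_maximal_statistic(self, rng):
        d = random_distance(rng, 5)
        res = mantel(d, d)
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_independent_matrices_nonsignificant(self, rng):
        a = random_distance(rng, 7)
        b = random_distance(rng, 7)
        res = mantel(a, b)
        assert res.p_value > 0.05

    @pytest.mark.parametrize("n", [4, 5])
    def test_exhaustive_matches_brute_force(self, rng, n):
        a = random_distance(rng, n)
        b = random_distance(rng, n)
        res = mantel(a, b)
        obs, p = mantel_oracle(a, b)
        assert res.exhaustive
        assert res.statistic == pytest.approx(obs, rel=1e-9)
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            mantel(random_distance(rng, 4), random_distance(rng, 5))


def permanova_oracle_f(d, labels):
    """Pseudo-F via scikit-bio (independent implementation)."""
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.distance import permanova as sk_permanova

    res = sk_permanova(DistanceMatrix(d), list(labels), permutations=0)
    return float(res["test statistic"])


class TestPermanova:
    def test_statistic_matches_skbio(self, rng):
        pytest.importorskip("skbio")
        d = random_distance(rng, 10)
        labels = ["a"] * 5 + ["b"] * 5
        res = permanova(d, labels, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(permanova_oracle_f(d, labels), rel=1e-9)

    def test_exhaustive_p_matches_brute_force(self, rng):
        pytest.importorskip("skbio")
        d = random_distance(rng, 6)
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        res = permanova(d, labels, n_perm=999)
        assert res.exhaustive
        obs = permanova_oracle_f(d, labels)
        hits = total = 0
        for p in itertools.permutations(range(6)):
            if permanova_oracle_f(d, labels[list(p)]) >= obs - 1e-12:
                hits += 1
            total += 1
        assert res.p_value == pytest.approx(hits / total, abs=1e-12)

    def test_separated_clouds_significant(self, rng):
        x = np.vstack([rng.normal(0, 1, (8, 3)), rng.normal(6, 1, (8, 3))])
        d = squareform(pdist(x))
        res = permanova(d, ["a"] * 8 + ["b"] * 8, n_perm=999, seed=1)
        assert res.p_value <= 0.01
        assert res.extras["r_squared"] > 0.5

    def test_singleton_group_excluded(self, rng):
        d = random_distance(rng, 5)
        with pytest.warns(UserWarning, match="singleton"):
            res = permanova(d, ["a", "a", "b", "b", "c"], n_perm=99, seed=0)
        assert res.extras["n_groups"] == 2

    def test_single_group_rejected(self, rng):
        d = random_distance(rng, 4)
        with pytest.raises(ValueError):
            permanova(d, ["a"] * 4, n_perm=99)

    def test_seed_reproducible(self, rng):
        d = random_distance(rng, 12)
        labels = ["a"] * 6 + ["b"] * 6
        p1 = permanova(d, labels, n_perm=199, seed=7).p_value
        p2 = permanova(d, labels, n_perm=199, seed=7).p_value
        assert p1 == p2


class TestSimper:
    def test_single_differing_taxon_contributes_all(self):
        ab = pd.DataFrame(
            {"s1": [0.5, 0.5], "s2": [0.5, 0.5], "s3": [0.9, 0.1], "s4": [0.9, 0.1]},
            index=["mic", "cyb"],
        )
        out = simper(ab, ["g1", "g1", "g2", "g2"])
        assert out["contribution_pct"].sum() == pytest.approx(100.0)
        # both taxa move by the same |0.4| so each carries 50% here; instead make
        # a table where only one taxon differs:
        ab2 = pd.DataFrame(
            {"s1": [0.5, 0.5, 0.0], "s2": [0.3, 0.5, 0.2]}, index=["a", "b", "c"]
        )
        out2 = simper(ab2, ["g1", "g2"])
        assert out2.loc[out2["taxon"] == "b", "contribution_pct"].iloc[0] == pytest.approx(0.0)

    def test_hand_computed_two_by_two(self):
        # samples (1, 0) and (0, 1): BC = 1, split equally between the taxa
        ab = pd.DataFrame({"s1": [1.0, 0.0], "s2": [0.0, 1.0]}, index=["a", "b"])
        out = simper(ab, ["g1", "g2"])
        assert out["mean_dissimilarity"].iloc[0] == pytest.approx(1.0)
        assert sorted(out["contribution_pct"]) == pytest.approx([50.0, 50.0])

    def test_contributions_sum_to_mean_dissimilarity(self, community_fixture):
        table, _ = community_fixture
        out = simper(table.abundance, table.metadata["fraction"])
        total = out.groupby("pair")["contribution"].sum()
        mean_bc = out.groupby("pair")["mean_dissimilarity"].first()
        assert np.allclose(total, mean_bc)
        assert np.allclose(out.groupby("pair")["contribution_pct"].sum(), 100.0)

    def test_invariant_to_sample_order(self, rng):
        ab = pd.DataFrame(rng.random((4, 6)), index=list("wxyz"),
                          columns=[f"s{i}" for i in range(6)])
        labels = ["g1", "g2"] * 3
        perm = rng.permutation(6)
        out1 = simper(ab, labels).set_index("taxon")["contribution"]
        out2 = simper(ab.iloc[:, perm], [labels[i] for i in perm]).set_index("taxon")[
            "contribution"
        ]
        assert np.allclose(out1.sort_index(), out2.sort_index())


class TestCCA:
    def test_separating_constraint_carries_inertia(self, rng):
        n = 8
        block = np.repeat([1.0, 0.0], 4)
        Y = pd.DataFrame(rng.random((n, 5)) * 0.05)
        Y.iloc[:4, 0] += 2.0
        Y.iloc[4:, 1] += 2.0
        X = pd.DataFrame({"split": block, "noise": rng.random(n) * 1e-3})
        res = cca(Y, X)
        assert res.proportion_explained[0] > 0.9

    def test_axis_proportions_normalized_and_sorted(self, rng):
        Y = pd.DataFrame(rng.random((10, 6)))
        X = pd.DataFrame(rng.random((10, 3)), columns=["a", "b", "c"])
        res = cca(Y, X)
        assert res.proportion_explained.sum() == pytest.approx(1.0)
        assert (np.diff(res.proportion_explained) <= 1e-12).all()
        assert res.constrained_inertia <= res.total_inertia + 1e-12

    def test_zero_constraints_rejected(self, rng):
        Y = pd.DataFrame(rng.random((6, 4)))
        X = pd.DataFrame({"z": np.zeros(6)})
        with pytest.raises(ValueError):
            cca(Y, X)

    def test_collinear_constraint_dropped(self, rng):
        Y = pd.DataFrame(rng.random((8, 5)))
        a = rng.random(8)
        X = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.random(8)})
        with pytest.warns(UserWarning, match="collinear"):
            res = cca(Y, X)
        assert len(res.dropped_constraints) == 1


def test_pcoa_recovers_planted_separation(rng):
    x = np.vstack([rng.normal(0, 0.3, (5, 4)), rng.normal(4, 0.3, (5, 4))])
    d = squareform(pdist(x))
    coords = pcoa(pd.DataFrame(d))
    axis1 = coords["PCo1"].to_numpy()
    assert (axis1[:5].mean() < axis1[5:].mean()) or (axis1[:5].mean() > axis1[5:].mean())
    gap = abs(axis1[:5].mean() - axis1[5:].mean())
    spread = axis1[:5].std() + axis1[5:].std()
    assert gap > 3 * spread
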