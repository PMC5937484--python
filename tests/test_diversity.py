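"""Diversity statistics: rarefaction, Shannon, Bray-Curtis, Mantel,
PERMANOVA, non-metric MDS, Venn partitions, category summaries."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr
from skbio.stats.distance import DistanceMatrix

from motupipe import (DesignTable, bray_curtis, category_summary, mantel,
                      nmmds, permanova, permanova_oneway, rarefied_richness,
                      shannon, venn_partition)
from motupipe.diversity import DiversityError
from motupipe.motu import MOTUTable
from motupipe.taxassign import Assignment


def table_from(counts, samples):
    df = pd.DataFrame.from_dict(counts, orient="index", columns=samples)
    df.index.name = "motu_id"
    return MOTUTable(df, {m: "A" * 10 for m in counts})


class TestRarefaction:
    def test_depth_equals_total_gives_observed_richness(self):
        assert rarefied_richness([10, 5, 1], depth=16) == pytest.approx(3.0)

    def test_depth_one_gives_one(self):
        assert rarefied_richness([7, 3, 2], depth=1) == pytest.approx(1.0)

    def test_fifty_fifty_depth_two(self):
        # 2 - 2*C(50,2)/C(100,2) = 2 - 2*1225/4950 = 1.505050...
        expected = 2 - 2 * (1225 / 4950)
        assert rarefied_richness([50, 50], depth=2) == pytest.approx(expected)

    def test_depth_above_total_raises(self):
        with pytest.raises(DiversityError):
            rarefied_richness([5, 5], depth=11)

    def test_closed_form_matches_resampling(self, rng):
        """Hypergeometric expectation within 3 SE of the resampling mean."""
        counts = rng.integers(0, 400, size=40)
        counts[0] += 1200  # ensure depth attainable
        depth = 1000
        closed = rarefied_richness(counts, depth)
        n_res = 300
        vals = [rarefied_richness(counts, depth, mode="resample",
                                  n_resample=1, seed=s) for s in range(n_res)]
        mean, se = np.mean(vals), np.std(vals) / math.sqrt(n_res)
        assert abs(closed - mean) <= 3 * se


class TestShannon:
    def test_uniform_is_log_s(self):
        assert shannon([7, 7, 7, 7]) == pytest.approx(math.log(4))

    def test_single_motu_zero(self):
        assert shannon([42]) == 0.0

    def test_hand_example(self):
        # -(0.25 ln 0.25 * 2 + 0.5 ln 0.5) = 1.03972...
        assert shannon([1, 1, 2]) == pytest.approx(1.0397207708399179)

    def test_all_zero_raises(self):
        with pytest.raises(DiversityError):
            shannon([0, 0])

    def test_base_two(self):
        assert shannon([1, 1], base=2) == pytest.approx(1.0)


class TestBrayCurtis:
    def test_identical_columns_zero(self):
        t = table_from({"m1": [5, 5], "m2": [3, 3]}, ["a", "b"])
        dm = bray_curtis(t)
        assert dm["a", "b"] == pytest.approx(0.0)

    def test_disjoint_motus_one(self):
        t = table_from({"m1": [5, 0], "m2": [0, 3]}, ["a", "b"])
        dm = bray_curtis(t)
        assert dm["a", "b"] == pytest.approx(1.0)

    def test_mixed_case_elementwise_oracle(self):
        t = table_from({"m1": [4, 1], "m2": [0, 3], "m3": [12, 4]}, ["a", "b"])
        dm = bray_curtis(t)
        # independent elementwise computation of the transform and BC
        xa = (np.array([4, 0, 12]) / 16) ** 0.25
        xb = (np.array([1, 3, 4]) / 8) ** 0.25
        expected = np.abs(xa - xb).sum() / (xa + xb).sum()
        assert dm["a", "b"] == pytest.approx(expected)

    def test_scale_invariance(self, rng):
        counts = rng.integers(0, 50, size=(6, 4))
        t1 = table_from({f"m{i}": list(counts[i]) for i in range(6)},
                        ["a", "b", "c", "d"])
        scaled = counts.copy()
        scaled[:, 2] *= 13  # multiply one sample's counts by a constant
        t2 = table_from({f"m{i}": list(scaled[i]) for i in range(6)},
                        ["a", "b", "c", "d"])
        np.testing.assert_allclose(bray_curtis(t1).data, bray_curtis(t2).data,
                                   atol=1e-12)

    def test_range_and_symmetry(self, rng):
        counts = rng.integers(0, 100, size=(8, 5)) + 1
        t = table_from({f"m{i}": list(counts[i]) for i in range(8)},
                       [f"s{j}" for j in range(5)])
        d = bray_curtis(t).data
        assert (d >= 0).all() and (d <= 1).all()
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0)


class TestMantel:
    def _random_dm(self, rng, n=10):
        x = rng.standard_normal((n, 3))
        return DistanceMatrix(squareform(pdist(x)),
                              ids=[f"s{i}" for i in range(n)])

    def test_self_correlation_is_one(self, rng):
        d = self._random_dm(rng)
        r, p = mantel(d, d, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)
        assert p >= 1 / 100

    def test_affine_transform_r_one(self, rng):
        d = self._random_dm(rng)
        d2 = DistanceMatrix(2.5 * d.data, ids=d.ids)
        r, _ = mantel(d, d2, n_perm=99, seed=0)
        assert r == pytest.approx(1.0)

    def test_r_matches_skbio(self, rng):
        from skbio.stats.distance import mantel as skbio_mantel
        d1, d2 = self._random_dm(rng), self._random_dm(rng)
        r_ours, _ = mantel(d1, d2, n_perm=10, seed=0)
        r_ref, _, _ = skbio_mantel(d1, d2, permutations=10)
        assert r_ours == pytest.approx(float(r_ref))

    def test_p_value_floor(self, rng):
        d = self._random_dm(rng, n=12)
        _, p = mantel(d, d, n_perm=199, seed=1)
        assert p >= 1 / 200


def hand_oneway_f(d, labels):
    """Independent pseudo-F: SS_total and within-group SS from first
    principles."""
    n = len(labels)
    d2 = d ** 2
    ss_total = sum(d2[i, j] for i in range(n) for j in range(i + 1, n)) / n
    groups = sorted(set(labels))
    ss_w = 0.0
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        ss_w += sum(d2[i, j] for i in idx for j in idx if i < j) / len(idx)
    ss_a = ss_total - ss_w
    a = len(groups)
    return (ss_a / (a - 1)) / (ss_w / (n - a))


class TestPermanovaOneway:
    def test_four_point_toy_matches_hand_computation(self):
        d = np.array([[0, 1, 4, 4.2],
                      [1, 0, 4.1, 4.3],
                      [4, 4.1, 0, 1.2],
                      [4.2, 4.3, 1.2, 0]])
        labels = ["g1", "g1", "g2", "g2"]
        f_obs, _ = permanova_oneway(d, labels, n_perm=10, seed=0)
        assert f_obs == pytest.approx(hand_oneway_f(d, labels))

    def test_f_matches_skbio(self, rng):
        from skbio.stats.distance import permanova as skbio_permanova
        x = rng.standard_normal((12, 3))
        d = DistanceMatrix(squareform(pdist(x)), ids=[f"s{i}" for i in range(12)])
        labels = ["a"] * 6 + ["b"] * 6
        f_ours, _ = permanova_oneway(d, labels, n_perm=10, seed=0)
        res = skbio_permanova(d, grouping=labels, permutations=10)
        assert f_ours == pytest.approx(float(res["test statistic"]))

    def test_fully_separated_groups_minimum_p(self, rng):
        a = rng.standard_normal((6, 2))
        b = rng.standard_normal((6, 2)) + 100.0
        x = np.vstack([a, b])
        d = squareform(pdist(x))
        _, p = permanova_oneway(d, ["a"] * 6 + ["b"] * 6, n_perm=199, seed=0)
        assert p == pytest.approx(1 / 200)


class TestPermanovaNested:
    def _design(self, n_comm=4, n_frac=3, n_rep=2):
        rows = {}
        for c in range(n_comm):
            site = "Atl" if c < n_comm // 2 else "Med"
            for f in "ABC"[:n_frac]:
                for r in range(n_rep):
                    rows[f"c{c}_{f}_r{r}"] = {
                        "site": site, "community": f"comm{c}",
                        "fraction": f, "replicate": str(r)}
        return DesignTable(pd.DataFrame.from_dict(rows, orient="index"))

    def test_table_shape_and_partition(self, rng):
        design = self._design()
        ids = list(design.frame.index)
        x = rng.standard_normal((len(ids), 4))
        dm = DistanceMatrix(squareform(pdist(x)), ids=ids)
        res = permanova(dm, design, n_perm=49, seed=0)
        assert list(res.term) == ["site", "fraction", "site_x_fraction",
                                  "community(site)", "sample(community)",
                                  "residual"]
        n = len(ids)
        assert res.df.sum() == n - 1
        d2 = dm.data ** 2
        iu = np.triu_indices(n, k=1)
        assert res.SS.sum() == pytest.approx(d2[iu].sum() / n)

    def test_fraction_effect_detected(self, rng):
        design = self._design()
        ids = list(design.frame.index)
        shift = {"A": 0.0, "B": 0.0, "C": 8.0}
        x = rng.standard_normal((len(ids), 2))
        for i, sid in enumerate(ids):
            x[i, 0] += shift[design.frame.loc[sid, "fraction"]]
        dm = DistanceMatrix(squareform(pdist(x)), ids=ids)
        res = permanova(dm, design, n_perm=199, seed=0).set_index("term")
        assert res.loc["fraction", "p_value"] <= 0.02

    def test_community_nesting_validated(self):
        frame = pd.DataFrame({
            "site": ["a", "b"], "community": ["c1", "c1"],
            "fraction": ["A", "A"], "replicate": ["1", "1"]},
            index=["s1", "s2"])
        with pytest.raises(DiversityError):
            DesignTable(frame)


class TestNMDS:
    def _dm(self, x):
        return DistanceMatrix(squareform(pdist(np.asarray(x, float))),
                              ids=[f"s{i}" for i in range(len(x))])

    def test_collinear_points_near_zero_stress(self):
        x = [[i, 0.0] for i in range(8)]
        res = nmmds(self._dm(x), k=2, seed=0)
        assert res.stress <= 1e-6

    def test_rank_recovery_on_metric_cloud(self, rng):
        x = rng.standard_normal((20, 2))
        dm = self._dm(x)
        res = nmmds(dm, k=2, seed=0)
        iu = np.triu_indices(20, k=1)
        rec = squareform(pdist(res.coords.to_numpy()))
        rho = spearmanr(dm.data[iu], rec[iu]).statistic
        assert rho >= 0.99

    def test_degenerate_all_equal_flagged(self):
        d = np.ones((5, 5)) - np.eye(5)
        res = nmmds(DistanceMatrix(d, ids=list("abcde")), seed=0)
        assert res.degenerate

    def test_too_few_points_raises(self):
        with pytest.raises(DiversityError):
            nmmds(DistanceMatrix(np.zeros((2, 2)), ids=["a", "b"]), k=2)


class TestVenn:
    def _design(self):
        rows = {}
        for f in "ABC":
            rows[f"x_{f}"] = {"site": "Atl", "community": "c", "fraction": f,
                              "replicate": "1"}
        return DesignTable(pd.DataFrame.from_dict(rows, orient="index"))

    def test_region_classification(self):
        t = table_from({"all3": [1, 1, 1], "bc": [0, 2, 3], "onlyA": [4, 0, 0]},
                       ["x_A", "x_B", "x_C"])
        venn = venn_partition(t, self._design())["Atl"].set_index("region")
        assert venn.loc["ABC", "n_motus"] == 1
        assert venn.loc["BC", "n_motus"] == 1   # only in the two smaller fractions
        assert venn.loc["A", "n_motus"] == 1
        assert venn.pct.sum() == pytest.approx(100.0)

    def test_matches_pattern_enumeration_oracle(self, rng):
        samples = ["x_A", "x_B", "x_C"]
        counts = {f"m{i}": list(rng.integers(0, 3, 3)) for i in range(40)}
        counts["m0"] = [1, 0, 0]  # ensure at least one detected MOTU
        t = table_from(counts, samples)
        venn = venn_partition(t, self._design())["Atl"].set_index("region")
        oracle = {r: 0 for r in ("A", "B", "C", "AB", "AC", "BC", "ABC")}
        for m, row in counts.items():
            pat = "".join(f for f, v in zip("ABC", row) if v > 0)
            if pat:
                oracle[pat] += 1
        for region, n in oracle.items():
            assert venn.loc[region, "n_motus"] == n


class TestCategorySummary:
    def test_single_category_hundred_percent(self, toy_tree):
        t = table_from({"m1": [10], "m2": [30]}, ["x_A"])
        design = pd.DataFrame({"site": ["Atl"], "community": ["c"],
                               "fraction": ["A"], "replicate": ["1"]},
                              index=["x_A"])
        assigns = {"m1": Assignment("m1", 1.0, "r", 11, "species", "a"),
                   "m2": Assignment("m2", 1.0, "r", 12, "species", "b")}
        cat_map = {5: "meiofaunal metazoa"}  # the Annelida phylum node
        df = category_summary(t, assigns, cat_map, toy_tree, design)
        row = df[(df.category == "meiofaunal metazoa")].iloc[0]
        assert row.pct_reads == pytest.approx(100.0)
        assert row.pct_motus == pytest.approx(100.0)

    def test_unassigned_and_percentages_sum(self, toy_tree):
        t = table_from({"m1": [10], "m2": [30], "m3": [60]}, ["x_A"])
        design = pd.DataFrame({"site": ["Atl"], "community": ["c"],
                               "fraction": ["A"], "replicate": ["1"]},
                              index=["x_A"])
        assigns = {"m1": Assignment("m1", 1.0, "r", 11, "species", "a"),
                   "m2": Assignment("m2", 0.6, "r", 2, "superkingdom", "euk")}
        cat_map = {5: "meiofaunal metazoa"}
        df = category_summary(t, assigns, cat_map, toy_tree, design)
        assert df.pct_reads.sum() == pytest.approx(100.0)
        assert df.pct_motus.sum() == pytest.approx(100.0)
        un = df[df.category == "unassigned"].iloc[0]
        assert un.reads == 90  # m2 above phylum + m3 unassigned
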