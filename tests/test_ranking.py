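"""Physiological formulas, DTC tables, clustering and rank concordance."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from cottonfvfm.ranking import (
    cluster_dtc,
    dendrogram_newick,
    dtc_table,
    fvfm,
    rank_and_compare,
    water_content,
)


class TestFvfm:
    @pytest.mark.parametrize(
        "Fo,Fm,expected", [(0.3, 1.5, 0.8), (1.5, 1.5, 0.0), (0.0, 2.0, 1.0)]
    )
    def test_forced_arithmetic(self, Fo, Fm, expected):
        assert fvfm(Fo, Fm) == pytest.approx(expected)

    def test_guards(self):
        with pytest.raises(ValueError):
            fvfm(0.5, 0.0)
        with pytest.raises(ValueError):
            fvfm(2.0, 1.0)


class TestWaterContent:
    @pytest.mark.parametrize(
        "fresh,dry,expected", [(10, 2, 80.0), (5, 5, 0.0), (4, 3, 25.0)]
    )
    def test_forced_arithmetic(self, fresh, dry, expected):
        assert water_content(fresh, dry) == pytest.approx(expected)

    def test_guards(self):
        with pytest.raises(ValueError):
            water_content(2, 3)
        with pytest.raises(ValueError):
            water_content(0, 0)


def _records(values: dict[tuple[int, str], list[float]], stage="flowering"):
    rows = []
    for (g, trt), vals in values.items():
        for i, v in enumerate(vals):
            rows.append(
                {"genotype_id": g, "treatment": trt, "stage": stage,
                 "replicate": i + 1, "fvfm": v}
            )
    return pd.DataFrame(rows)


class TestDtcTable:
    def test_simple_ratio(self):
        df = _records({(1, "CK"): [0.80], (1, "DS"): [0.76]})
        out = dtc_table(df)
        assert out.loc[0, "dtc"] == pytest.approx(0.95)

    def test_equal_arms_give_unit_dtc(self):
        df = _records({(g, t): [0.8, 0.81] for g in (1, 2) for t in ("CK", "DS")})
        out = dtc_table(df)
        np.testing.assert_allclose(out["dtc"], 1.0)

    def test_matches_hand_grouped_oracle(self):
        rng = np.random.default_rng(6)
        values = {
            (g, t): list(rng.uniform(0.6, 0.85, 3)) for g in (1, 2, 3) for t in ("CK", "DS")
        }
        out = dtc_table(_records(values))
        for i, g in enumerate((1, 2, 3)):
            ck = np.mean(values[(g, "CK")])
            ds = np.mean(values[(g, "DS")])
            assert out.loc[i, "mean_fvfm_ck"] == pytest.approx(ck)
            assert out.loc[i, "dtc"] == pytest.approx(ds / ck)
            assert out.loc[i, "n_ck"] == 3 and out.loc[i, "n_ds"] == 3

    def test_missing_arm_error_lists_genotypes(self):
        df = _records({(1, "CK"): [0.8], (1, "DS"): [0.76], (2, "CK"): [0.8]})
        with pytest.raises(ValueError, match=r"\[2\]"):
            dtc_table(df)

    def test_scale_invariance(self):
        base = {(1, "CK"): [0.8, 0.82], (1, "DS"): [0.7, 0.72],
                (2, "CK"): [0.81], (2, "DS"): [0.79]}
        scaled = {k: ([2 * v for v in vals] if k[0] == 1 else vals) for k, vals in base.items()}
        a = dtc_table(_records(base))
        b = dtc_table(_records(scaled))
        np.testing.assert_allclose(a["dtc"], b["dtc"])

    def test_stage_filter(self):
        df = pd.concat([
            _records({(1, "CK"): [0.8], (1, "DS"): [0.4]}, stage="boll_setting"),
            _records({(1, "CK"): [0.8], (1, "DS"): [0.8]}, stage="flowering"),
        ])
        out = dtc_table(df, stage="flowering")
        assert out.loc[0, "dtc"] == pytest.approx(1.0)


def two_cluster_oracle(values):
    """Exhaustive minimal within-cluster sum of squares over 2-partitions."""
    best, best_cost = None, np.inf
    idx = range(len(values))
    for r in range(1, len(values)):
        for subset in itertools.combinations(idx, r):
            a = np.array([values[i] for i in subset])
            b = np.array([values[i] for i in idx if i not in subset])
            cost = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
            if cost < best_cost:
                best, best_cost = set(subset), cost
    return best


class TestClustering:
    def test_two_group_separation_matches_exhaustive_oracle(self):
        table = pd.DataFrame(
            {"genotype_id": [1, 2, 3, 4], "dtc": [0.99, 0.98, 0.60, 0.61]}
        )
        res = cluster_dtc(table, k=2)
        labels = res.labels
        oracle = two_cluster_oracle([0.99, 0.98, 0.60, 0.61])
        cluster_of = {g: labels[g] for g in (1, 2, 3, 4)}
        group_a = {g for g in (1, 2, 3, 4) if cluster_of[g] == cluster_of[1]}
        assert group_a == {i + 1 for i in oracle} or group_a == {1, 2, 3, 4} - {i + 1 for i in oracle}
        assert group_a == {1, 2}

    def test_identical_values_single_chain(self):
        table = pd.DataFrame({"genotype_id": [1, 2, 3], "dtc": [0.9, 0.9, 0.9]})
        res = cluster_dtc(table, k=2)
        assert set(res.labels) <= {1, 2}
        assert np.all(np.diff(res.merge_tree[:, 2]) >= -1e-12)

    def test_permutation_gives_same_partition(self):
        rng = np.random.default_rng(2)
        dtc = rng.uniform(0.7, 1.0, 8)
        t1 = pd.DataFrame({"genotype_id": np.arange(1, 9), "dtc": dtc})
        perm = rng.permutation(8)
        t2 = t1.iloc[perm].reset_index(drop=True)
        r1 = cluster_dtc(t1, k=3)
        r2 = cluster_dtc(t2, k=3)
        # identical partitions up to relabeling
        def partition(res):
            groups = {}
            for g, c in res.labels.items():
                groups.setdefault(c, set()).add(g)
            return sorted(map(frozenset, groups.values()), key=lambda s: min(s))
        assert partition(r1) == partition(r2)
        assert r1.ranking == r2.ranking

    def test_ranking_descending_with_id_ties(self):
        table = pd.DataFrame({"genotype_id": [3, 1, 2], "dtc": [0.9, 0.95, 0.9]})
        res = cluster_dtc(table, k=2)
        assert res.ranking == [1, 2, 3]

    def test_single_genotype_rejected(self):
        with pytest.raises(ValueError):
            cluster_dtc(pd.DataFrame({"genotype_id": [1], "dtc": [0.9]}), k=1)

    def test_newick_export_contains_all_leaves(self):
        table = pd.DataFrame({"genotype_id": [1, 2, 3, 4], "dtc": [0.99, 0.98, 0.60, 0.61]})
        res = cluster_dtc(table, k=2)
        nwk = dendrogram_newick(res, table)
        assert nwk.endswith(";")
        for g in (1, 2, 3, 4):
            assert str(g) in nwk


class TestConcordance:
    def _table(self, dtc_by_genotype):
        return pd.DataFrame(
            {"genotype_id": list(dtc_by_genotype), "dtc": list(dtc_by_genotype.values())}
        )

    def test_identical_tables(self):
        t = self._table({1: 0.9, 2: 0.95, 3: 0.85, 4: 0.8})
        rep = rank_and_compare(t, t, k=2)
        assert rep.overlap == 2 and rep.spearman_rho == pytest.approx(1.0)

    def test_reversed_ranking(self):
        m = self._table({1: 0.9, 2: 0.8, 3: 0.7})
        p = self._table({1: 0.7, 2: 0.8, 3: 0.9})
        assert rank_and_compare(m, p, k=1).spearman_rho == pytest.approx(-1.0)

    def test_adjacent_swap_closed_form(self):
        # measured ranks (1,2,3,4), predicted (2,1,3,4):
        # rho = 1 - 6*sum(d^2)/(n(n^2-1)) = 1 - 12/60 = 0.8
        m = self._table({1: 0.95, 2: 0.90, 3: 0.85, 4: 0.80})
        p = self._table({1: 0.90, 2: 0.95, 3: 0.85, 4: 0.80})
        rep = rank_and_compare(m, p, k=2)
        assert rep.overlap == 2
        assert rep.spearman_rho == pytest.approx(1 - 6 * 2 / (4 * 15))

    def test_mismatched_genotype_sets_rejected(self):
        m = self._table({1: 0.9, 2: 0.8})
        p = self._table({1: 0.9, 3: 0.8})
        with pytest.raises(ValueError, match="different genotype sets"):
            rank_and_compare(m, p, k=1)

    def test_spearman_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(4)
        m = self._table({g: v for g, v in enumerate(rng.uniform(0.7, 1, 12), start=1)})
        p = self._table({g: v for g, v in enumerate(rng.uniform(0.7, 1, 12), start=1)})
        rep = rank_and_compare(m, p, k=5)
        assert rep.spearman_rho == pytest.approx(
            spearmanr(m["dtc"], p["dtc"]).statistic
        )
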