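import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pnec
from pnec.repertoire import (
    COUNTS_POSITIVE,
    DetectionPolicy,
    TPM_OVER_5,
    compare_datasets,
    enumerate_combinations,
    fisher_exact_two_tailed,
    gene_prevalence,
    repertoire_stats,
    set_union_summary,
)

from conftest import make_detection, make_matrix


def fisher_oracle(a, b, c, d):
    """Exact-rational two-sided Fisher p by full table enumeration.

    Table weights C(c1, k)·C(n−c1, r1−k) are exact integers sharing the
    denominator C(n, r1); tables with weight ≤ the observed weight are
    summed in integer arithmetic.
    """
    n = a + b + c + d
    r1, c1 = a + b, a + c
    k_lo, k_hi = max(0, r1 - (n - c1)), min(r1, c1)
    weights = {k: math.comb(c1, k) * math.comb(n - c1, r1 - k) for k in range(k_lo, k_hi + 1)}
    obs = weights[a]
    total = sum(w for w in weights.values() if w <= obs)
    return float(Fraction(total, math.comb(n, r1)))


class TestDetection:
    def test_counts_policy_boundary(self):
        d = pnec.call_detection(make_matrix([[1, 0]]), _panel(["g0"]))
        assert d.calls.loc["g0"].tolist() == [True, False]

    def test_tpm_threshold_is_strict(self):
        # one gene at exactly 5 per million of the cell's library
        counts = np.array([[5, 6], [999995, 999994]])
        m = make_matrix(counts, genes=["g", "bg"])
        d = pnec.call_detection(m, _panel(["g"]), TPM_OVER_5)
        assert d.calls.loc["g"].tolist() == [False, True]

    def test_missing_panel_gene_warns_and_is_never_detected(self):
        m = make_matrix([[1, 1]])
        with pytest.warns(UserWarning, match="absent"):
            d = pnec.call_detection(m, _panel(["g0", "ghost"]))
        assert not d.calls.loc["ghost"].any()
        prev = gene_prevalence(d)
        assert prev.loc["ghost", "fraction"] == 0.0

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError, match="statistic"):
            DetectionPolicy("reads", 0)

    def test_threshold_monotonicity(self, mouse_run):
        m = mouse_run["pnec"]
        panel = mouse_run["spec"].panel
        prev_combo = []
        for thr in (0.0, 5.0, 50.0, 500.0):
            d = pnec.call_detection(m, panel, DetectionPolicy("cpm", thr))
            prev_combo.append(
                (
                    gene_prevalence(d)["fraction"].to_numpy(),
                    d.per_cell_counts().to_numpy(),
                    enumerate_combinations(d).n_combinations,
                )
            )
        for (p1, c1, n1), (p2, c2, n2) in zip(prev_combo, prev_combo[1:]):
            assert (p2 <= p1 + 1e-12).all()
            assert (c2 <= c1).all()
            assert n2 <= n1


def _panel(genes):
    from pnec.io import GenePanel

    return GenePanel.from_genes(genes)


class TestPrevalence:
    def test_fraction_arithmetic(self):
        calls = np.zeros((1, 176), dtype=bool)
        calls[0, :167] = True
        d = make_detection(calls)
        assert gene_prevalence(d).loc["g0", "fraction"] == pytest.approx(167 / 176)

    def test_mean_over_detecting_cells_only(self):
        m = pnec.normalize_lncpm(make_matrix([[10, 0], [90, 100]], genes=["g", "bg"]))
        d = pnec.call_detection(m, _panel(["g"]))
        prev = gene_prevalence(d, m)
        assert prev.loc["g", "mean_lncpm"] == pytest.approx(m.lncpm.loc["g"].iloc[0])

    def test_undetected_gene_mean_missing(self):
        m = pnec.normalize_lncpm(make_matrix([[0, 0], [10, 10]], genes=["g", "bg"]))
        d = pnec.call_detection(m, _panel(["g"]))
        prev = gene_prevalence(d, m)
        assert prev.loc["g", "fraction"] == 0.0
        assert np.isnan(prev.loc["g", "mean_lncpm"])

    def test_prevalence_sum_equals_mean_per_cell_count(self, mouse_run):
        d = mouse_run["detection"]
        total_prev = gene_prevalence(d)["fraction"].sum()
        assert total_prev == pytest.approx(d.per_cell_counts().mean(), abs=1e-9)


class TestCombinations:
    def test_single_pattern(self):
        combos = enumerate_combinations(make_detection(np.ones((3, 5), dtype=bool)))
        assert combos.n_combinations == 1
        assert combos.table.iloc[0]["n_cells"] == 5

    def test_hand_enumeration(self):
        # cells: {A}, {A}, {A,B}, {}
        calls = np.array([[1, 1, 1, 0], [0, 0, 1, 0]], dtype=bool)
        combos = enumerate_combinations(make_detection(calls, genes=["A", "B"]))
        assert combos.n_combinations == 3
        assert combos.table["n_cells"].tolist() == [2, 1, 1]
        assert combos.table["n_cells"].sum() == 4
        assert combos.table["is_empty"].sum() == 1

    def test_duplicating_a_cell_preserves_combination_count(self, mouse_run):
        d = mouse_run["detection"]
        base = enumerate_combinations(d).n_combinations
        dup = d.calls.copy()
        dup["dup_cell"] = dup.iloc[:, 0]
        d2 = make_detection(dup.to_numpy(), genes=list(dup.index), cells=list(dup.columns))
        assert enumerate_combinations(d2).n_combinations == base

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**30))
    def test_bounds_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        g, c = rng.integers(1, 6), rng.integers(1, 8)
        d = make_detection(rng.random((g, c)) < rng.random())
        combos = enumerate_combinations(d)
        assert combos.n_combinations <= min(c, 2**g)
        assert combos.table["n_cells"].sum() == c


class TestRepertoireStats:
    def test_hand_arithmetic(self):
        calls = np.zeros((4, 3), dtype=bool)
        calls[:2, 0] = True  # 2
        calls[:2, 1] = True  # 2
        calls[:4, 2] = True  # 4
        s = repertoire_stats(make_detection(calls))
        assert s.mean == pytest.approx(8 / 3)
        assert s.median == 2 and s.mode == 2
        assert (s.min, s.max) == (2, 4)
        assert s.sd == pytest.approx(np.std([2, 2, 4], ddof=1))

    def test_single_cell_sd_missing(self):
        s = repertoire_stats(make_detection(np.ones((2, 1), dtype=bool)))
        assert s.sd is None

    def test_mode_tie_takes_smallest(self):
        calls = np.zeros((3, 4), dtype=bool)
        calls[:1, 0] = True
        calls[:1, 1] = True
        calls[:3, 2] = True
        calls[:3, 3] = True
        s = repertoire_stats(make_detection(calls))
        assert s.mode == 1

    def test_empty_rejected(self):
        d = make_detection(np.zeros((2, 2), dtype=bool))
        with pytest.raises(ValueError):
            repertoire_stats(d, drop_empty=True)


class TestFisher:
    def test_hand_enumerated_table(self):
        assert fisher_exact_two_tailed(3, 1, 1, 3) == pytest.approx(34 / 70, abs=1e-12)

    def test_identical_proportions(self):
        assert fisher_exact_two_tailed(5, 5, 5, 5) == 1.0

    def test_perfect_separation(self):
        assert fisher_exact_two_tailed(10, 0, 0, 10) == pytest.approx(
            2 / math.comb(20, 10), rel=1e-9
        )

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_tailed(-1, 2, 3, 4)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 15)] * 4))
    def test_matches_rational_oracle(self, table):
        a, b, c, d = table
        if a + b + c + d == 0:
            return
        assert fisher_exact_two_tailed(a, b, c, d) == pytest.approx(
            fisher_oracle(a, b, c, d), abs=1e-9, rel=1e-9
        )

    def test_matches_scipy_reference(self):
        import scipy.stats

        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 25, 4)
            if a + b + c + d == 0:
                continue
            ours = fisher_exact_two_tailed(a, b, c, d)
            ref = scipy.stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-6)


class TestCompareDatasets:
    def _prev(self, pairs):
        return pd.DataFrame(
            {"n_detected": [p[0] for p in pairs.values()],
             "n_cells": [p[1] for p in pairs.values()]},
            index=list(pairs),
        )

    def test_identical_prevalences_give_p_one(self):
        a = self._prev({"g1": (30, 100), "g2": (50, 100)})
        table, _ = compare_datasets(a, a)
        assert (table["p"] == 1.0).all()

    def test_discordant_gene_flagged(self):
        a = self._prev({"g": (60, 176)})
        b = self._prev({"g": (67, 100)})
        table, _ = compare_datasets(a, b)
        assert table.loc["g", "p"] == pytest.approx(fisher_oracle(60, 116, 67, 33), rel=1e-9)
        assert table.loc["g", "p"] < 0.05

    def test_concordant_gene_not_flagged(self):
        a = self._prev({"g": (167, 176)})
        b = self._prev({"g": (94, 100)})
        table, _ = compare_datasets(a, b)
        assert table.loc["g", "p"] == pytest.approx(fisher_oracle(167, 9, 94, 6), rel=1e-9)
        assert table.loc["g", "p"] > 0.5

    def test_set_summary(self):
        a = self._prev({"g1": (5, 10), "g2": (0, 10)})
        b = self._prev({"g2": (3, 12), "g3": (2, 12)})
        _, summary = compare_datasets(a, b)
        assert summary["detected_a"] == {"g1"}
        assert summary["union"] == {"g1", "g2", "g3"}
        assert summary["intersection"] == set()


class TestSetUnion:
    def test_in_catalog_percentage(self):
        a = {f"g{i}" for i in range(31)}
        b = {f"g{i}" for i in range(1, 31)} | {f"h{i}" for i in range(12)}
        res = set_union_summary(a, b, catalog_size=91)
        assert res.size == 43
        assert res.percent == 47

    def test_idempotent(self):
        a = {"x", "y"}
        res = set_union_summary(a, a)
        assert res.union == a and res.percent is None

    def test_disjoint(self):
        res = set_union_summary({"a"}, {"b", "c"})
        assert res.size == 3

    def test_bad_catalog(self):
        with pytest.raises(ValueError):
            set_union_summary({"a"}, {"b"}, catalog_size=0)
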