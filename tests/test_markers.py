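import itertools
import math

import numpy as np
import pandas as pd
import pytest

import pnec
from pnec.markers import marker_score, rank_sum_markers

from conftest import make_matrix


def _two_group_matrix(values_in, values_out, extra_rows=()):
    """One focal gene (first row) split across two cell types."""
    rows = [list(values_in) + list(values_out)]
    for r in extra_rows:
        rows.append(list(r))
    # background gene keeps library sizes positive
    rows.append([1000] * (len(values_in) + len(values_out)))
    types = ["A"] * len(values_in) + ["B"] * len(values_out)
    m = make_matrix(np.array(rows), cell_type=types)
    return pnec.normalize_lncpm(m)


def _exact_permutation_p(x, y):
    """Exhaustive two-sided rank-sum p: proportion of group assignments with
    a rank sum at least as extreme as observed (oracle)."""
    pooled = np.concatenate([x, y])
    ranks = pd.Series(pooled).rank().to_numpy()
    n = len(x)
    obs = ranks[:n].sum()
    mean = ranks.sum() * n / len(pooled)
    stats = [
        abs(sum(ranks[list(idx)]) - mean)
        for idx in itertools.combinations(range(len(pooled)), n)
    ]
    return np.mean(np.array(stats) >= abs(obs - mean) - 1e-12)


class TestRankSum:
    def test_identical_gene_flagged_untestable(self):
        m = _two_group_matrix([5, 5, 5], [5, 5, 5])
        res = rank_sum_markers(m, "A")
        assert res.loc["g0", "p"] == 1.0
        assert res.loc["g0", "untestable"]

    def test_extreme_separation_matches_exact_permutation(self):
        x, y = [10, 9, 8, 7, 6], [5, 4, 3, 2, 1]
        m = _two_group_matrix(x, y)
        res = rank_sum_markers(m, "A")
        # lncpm is a monotone per-cell transform but here library sizes are
        # dominated by the background gene, so ranks are preserved
        oracle = _exact_permutation_p(np.array(x, float), np.array(y, float))
        assert res.loc["g0", "p"] == pytest.approx(oracle, rel=1e-6)

    def test_constant_zero_gene(self):
        m = _two_group_matrix([0, 0, 0], [0, 0, 0])
        res = rank_sum_markers(m, "A")
        assert res.loc["g0", "p"] == 1.0 and res.loc["g0", "untestable"]

    @pytest.mark.parametrize("n1,n2,seed", [(3, 3, 0), (4, 5, 1), (6, 6, 2), (5, 6, 3)])
    def test_agrees_with_exhaustive_permutation_small_groups(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        pooled = rng.choice(np.arange(1, 500), size=n1 + n2, replace=False)
        x, y = np.sort(pooled[:n1])[::-1], pooled[n1:]  # tie-free counts
        m = _two_group_matrix(x, y)
        lnc = m.lncpm.loc["g0"]
        xs = lnc.iloc[:n1].to_numpy()
        ys = lnc.iloc[n1:].to_numpy()
        res = rank_sum_markers(m, "A")
        oracle = _exact_permutation_p(xs, ys)
        assert res.loc["g0", "p"] == pytest.approx(oracle, rel=0.05)

    def test_adjusted_p_never_below_raw(self, mouse_run):
        res = rank_sum_markers(mouse_run["matrix"], "PNEC", correction="bh")
        assert (res["p_adj"] >= res["p"] - 1e-15).all()

    def test_small_group_rejected(self):
        m = _two_group_matrix([1], [2, 3])
        with pytest.raises(ValueError, match="2 cells"):
            rank_sum_markers(m, "A")


class TestMarkerScore:
    def _matrix(self):
        # gene A: sensitive and specific; gene B: sensitive but unspecific
        rng = np.random.default_rng(0)
        n_in, n_out = 100, 200
        a = np.concatenate([(rng.random(n_in) < 0.95) * 500, (rng.random(n_out) < 0.01) * 5])
        b = np.concatenate([(rng.random(n_in) < 0.95) * 300, (rng.random(n_out) < 0.15) * 300])
        bg = np.full(n_in + n_out, 2000)
        types = ["NE"] * n_in + ["other"] * n_out
        m = make_matrix(np.array([a, b, bg]), genes=["A", "B", "bg"], cell_type=types)
        return pnec.normalize_lncpm(m)

    def test_filter_selects_sensitive_specific_gene_only(self):
        res = marker_score(self._matrix(), "NE")
        assert "A" in res.index and "B" not in res.index

    def test_absent_from_comparison_scores_by_eps_guard(self):
        vals = np.zeros((2, 6), dtype=int)
        vals[0] = [100, 120, 90, 0, 0, 0]
        vals[1] = [900, 880, 910, 1000, 1000, 1000]
        m = pnec.normalize_lncpm(
            make_matrix(vals, genes=["A", "bg"], cell_type=["NE"] * 3 + ["other"] * 3)
        )
        res = marker_score(m, "NE", eps=0.01)
        mean_cpm_in = np.expm1(m.lncpm.loc["A"].iloc[:3]).mean()
        assert res.loc["A", "score"] == pytest.approx(math.log(mean_cpm_in + 1) / 0.01)
        assert res.index[0] == "A"

    def test_identical_means_score_one(self):
        vals = np.array([[100] * 6, [900] * 6])
        m = pnec.normalize_lncpm(
            make_matrix(vals, genes=["A", "bg"], cell_type=["NE"] * 3 + ["other"] * 3)
        )
        res = marker_score(m, "NE", sens_min=0.5, spec_max=1.01)
        assert res.loc["A", "score"] == pytest.approx(1.0, abs=1e-12)

    def test_eps_must_be_positive(self):
        with pytest.raises(ValueError, match="eps"):
            marker_score(self._matrix(), "NE", eps=0.0)

    def test_no_passing_gene_is_empty_not_error(self):
        res = marker_score(self._matrix(), "NE", sens_min=0.999, spec_max=1e-9)
        assert len(res) == 0

    def test_scores_invariant_under_cell_permutation(self):
        m = self._matrix()
        rng = np.random.default_rng(1)
        perm = rng.permutation(m.n_cells)
        m2 = pnec.ExpressionMatrix(
            counts=m.counts.iloc[:, perm],
            cell_meta=m.cell_meta.iloc[perm],
            lncpm=m.lncpm.iloc[:, perm],
        )
        r1 = marker_score(m, "NE", sens_min=0, spec_max=1.01)
        r2 = marker_score(m2, "NE", sens_min=0, spec_max=1.01)
        pd.testing.assert_series_equal(r1["score"], r2["score"].reindex(r1.index))

    def test_filter_monotonicity(self, mouse_run):
        m = mouse_run["matrix"]
        base = set(marker_score(m, "PNEC", sens_min=0.5, spec_max=0.10).index)
        stricter_sens = set(marker_score(m, "PNEC", sens_min=0.8, spec_max=0.10).index)
        stricter_spec = set(marker_score(m, "PNEC", sens_min=0.5, spec_max=0.03).index)
        assert stricter_sens <= base
        assert stricter_spec <= base

    def test_cell_types_specificity_mode(self, mouse_run):
        m = mouse_run["matrix"]
        res = marker_score(m, "PNEC", spec_mode="cell_types", sens_min=0.85, spec_max=0.3)
        # packaged marker genes are near-absent in every other type
        assert {"Resp18", "Pcsk1"} <= set(res.index)

    def test_packaged_markers_recovered(self, mouse_run):
        res = marker_score(mouse_run["matrix"], "PNEC")
        assert {"Resp18", "Pcsk1"} <= set(res.index)
        assert "Scgb1a1" not in res.index
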