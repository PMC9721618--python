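"""Marker-gene detection: rank-sum differential expression and the
sensitivity / specificity / ratio-of-logs marker ranking.

The ranking statistic is the ratio of the natural logs of the average
expression of a gene in the target population versus the comparison
population, with average expression computed on the CPM scale and logged
afterwards: ``score = ln(mean CPM_in + 1) / max(ln(mean CPM_out + 1), eps)``.
Candidate markers are first filtered for sensitivity (detected in more than
``sens_min`` of target cells) and specificity (detected in fewer than
``spec_max`` of comparison cells, or optionally of comparison cell *types*).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

_CORRECTIONS = {"bonferroni": "bonferroni", "bh": "fdr_bh", "fdr_bh": "fdr_bh"}


def _split_groups(m, target_type, comparison_types):
    in_cells = m.cells_of_type(target_type)
    if len(in_cells) == 0:
        raise ValueError(f"target cell type {target_type!r} not present in metadata")
    if comparison_types is None:
        out_cells = m.cells.difference(in_cells)
    else:
        out_cells = m.cells_of_type(*comparison_types)
    return in_cells, out_cells


def rank_sum_markers(
    m,
    target_type: str,
    comparison_types=None,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum test per gene, target vs comparison cells.

    Uses the exact null distribution for small tie-free groups and the
    tie-corrected normal approximation otherwise (scipy's ``method="auto"``).
    Genes constant across both groups are flagged ``untestable`` with p = 1.
    The correction (default Bonferroni, option ``"bh"``) is applied across
    all genes; ``p_adj`` is clipped at 1 so it is never below ``p``.
    """
    if m.lncpm is None:
        raise ValueError("lncpm layer required; run normalize_lncpm first")
    if correction not in _CORRECTIONS:
        raise ValueError(f"unknown correction {correction!r}")
    in_cells, out_cells = _split_groups(m, target_type, comparison_types)
    if len(in_cells) < 2 or len(out_cells) < 2:
        raise ValueError("each group needs at least 2 cells for the rank-sum test")
    x = m.lncpm.loc[:, in_cells].to_numpy()
    y = m.lncpm.loc[:, out_cells].to_numpy()
    pvals = np.ones(m.n_genes)
    untestable = np.zeros(m.n_genes, dtype=bool)
    for i in range(m.n_genes):
        xi, yi = x[i], y[i]
        if np.ptp(np.concatenate([xi, yi])) == 0:
            untestable[i] = True
            continue
        _, p = scipy.stats.mannwhitneyu(xi, yi, alternative="two-sided", method="auto")
        pvals[i] = min(p, 1.0)
    p_adj = multipletests(pvals, method=_CORRECTIONS[correction])[1]
    p_adj = np.maximum(p_adj, pvals)
    return pd.DataFrame(
        {"p": pvals, "p_adj": p_adj, "untestable": untestable}, index=m.genes
    )


def marker_score(
    m,
    target_type: str,
    comparison_types=None,
    sens_min: float = 0.85,
    spec_max: float = 0.05,
    eps: float = 0.01,
    mean_mode: str = "cpm",
    spec_mode: str = "cells",
    type_prevalence_min: float = 0.05,
) -> pd.DataFrame:
    """Rank candidate markers of ``target_type`` by the ratio-of-logs score.

    Parameters
    ----------
    sens_min, spec_max
        Keep genes detected (count > 0) in more than ``sens_min`` of target
        cells and, under ``spec_mode="cells"``, in fewer than ``spec_max`` of
        comparison cells. Under ``spec_mode="cell_types"`` the specificity
        denominator is comparison cell *types*: the fraction of types in
        which the gene's detection prevalence exceeds ``type_prevalence_min``.
    eps
        Floor for the denominator log, guarding division by zero when the
        gene is absent from the comparison group. Must be positive.
    mean_mode
        ``"cpm"`` (default): ln(mean CPM + 1) per group. ``"logs"``: mean of
        per-cell ln(CPM+1) values instead.

    Returns a DataFrame of passing genes sorted by descending score, with
    columns frac_in, frac_out, mean_ln_in, mean_ln_out, score.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    if mean_mode not in ("cpm", "logs"):
        raise ValueError(f"unknown mean_mode {mean_mode!r}")
    if spec_mode not in ("cells", "cell_types"):
        raise ValueError(f"unknown spec_mode {spec_mode!r}")
    if m.lncpm is None:
        raise ValueError("lncpm layer required; run normalize_lncpm first")
    in_cells, out_cells = _split_groups(m, target_type, comparison_types)
    if len(out_cells) == 0:
        raise ValueError("comparison group is empty")

    detected = m.counts > 0
    frac_in = detected.loc[:, in_cells].mean(axis=1)
    if spec_mode == "cells":
        frac_out = detected.loc[:, out_cells].mean(axis=1)
    else:
        types = m.cell_meta.loc[out_cells, "cell_type"]
        per_type = (
            detected.loc[:, out_cells]
            .T.groupby(types)
            .mean()
            .T
        )
        frac_out = (per_type > type_prevalence_min).mean(axis=1)

    cpm = np.expm1(m.lncpm)
    if mean_mode == "cpm":
        mean_ln_in = np.log1p(cpm.loc[:, in_cells].mean(axis=1))
        mean_ln_out = np.log1p(cpm.loc[:, out_cells].mean(axis=1))
    else:
        mean_ln_in = m.lncpm.loc[:, in_cells].mean(axis=1)
        mean_ln_out = m.lncpm.loc[:, out_cells].mean(axis=1)
    score = mean_ln_in / np.maximum(mean_ln_out, eps)

    table = pd.DataFrame(
        {
            "frac_in": frac_in,
            "frac_out": frac_out,
            "mean_ln_in": mean_ln_in,
            "mean_ln_out": mean_ln_out,
            "score": score,
        },
        index=m.genes,
    )
    passing = table[(table["frac_in"] > sens_min) & (table["frac_out"] < spec_max)]
    return passing.sort_values("score", ascending=False)
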