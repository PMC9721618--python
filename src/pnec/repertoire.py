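"""Panel detection calls, prevalence, combination enumeration, repertoire
statistics, and cross-dataset Fisher comparisons.

The central object is the :class:`DetectionMatrix`: boolean detection calls
for every (panel gene, cell) pair under an explicit detection policy. The
default policy for plate-based (Smart-seq2-style) count matrices is a strict
``counts > 0``; a ``tpm > 5`` preset mirrors the convention used for
microfluidic validation datasets. Everything downstream — per-gene
prevalence, the per-cell expressed-gene sets ("combinations"), repertoire
summary statistics and the incidence data fed to the saturation module — is
derived from these boolean calls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix, GenePanel

_STATISTICS = ("counts", "cpm", "tpm")


@dataclass(frozen=True)
class DetectionPolicy:
    """Detection rule: ``statistic(gene, cell) > threshold`` (strict).

    ``statistic`` is ``counts``, ``cpm`` or ``tpm``. For the full-length
    count matrices this package operates on, ``cpm`` and ``tpm`` are both
    per-million scalings of counts (no transcript-length information is
    available at this stage).
    """

    statistic: str = "counts"
    threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.statistic not in _STATISTICS:
            raise ValueError(f"unknown statistic {self.statistic!r}; use one of {_STATISTICS}")
        if self.threshold < 0:
            raise ValueError("threshold must be >= 0")


#: strict counts > 0, the default for plate-based SS2-style matrices
COUNTS_POSITIVE = DetectionPolicy("counts", 0.0)
#: tpm > 5, the convention used for the microfluidic validation dataset
TPM_OVER_5 = DetectionPolicy("tpm", 5.0)


@dataclass
class DetectionMatrix:
    """Boolean calls (panel genes × cells) plus the policy that produced them."""

    calls: pd.DataFrame  # bool, panel genes × cells
    panel: GenePanel
    cell_meta: pd.DataFrame
    policy: DetectionPolicy
    missing_genes: list = field(default_factory=list)

    @property
    def genes(self) -> pd.Index:
        return self.calls.index

    @property
    def cells(self) -> pd.Index:
        return self.calls.columns

    @property
    def n_cells(self) -> int:
        return self.calls.shape[1]

    def per_cell_sets(self) -> pd.Series:
        """frozenset of detected panel genes for each cell."""
        arr = self.calls.to_numpy()
        genes = self.genes.to_numpy()
        return pd.Series(
            [frozenset(genes[arr[:, j]]) for j in range(arr.shape[1])],
            index=self.cells,
        )

    def per_cell_counts(self) -> pd.Series:
        return self.calls.sum(axis=0)

    def subset_cells(self, cells) -> "DetectionMatrix":
        cells = pd.Index(cells)
        return DetectionMatrix(
            calls=self.calls.loc[:, cells],
            panel=self.panel,
            cell_meta=self.cell_meta.loc[cells],
            policy=self.policy,
            missing_genes=list(self.missing_genes),
        )


def call_detection(
    m: ExpressionMatrix, panel: GenePanel, policy: DetectionPolicy = COUNTS_POSITIVE
) -> DetectionMatrix:
    """Apply the detection policy to every (panel gene, cell).

    Panel genes absent from the matrix are retained with all-False calls and
    reported via a warning (and ``missing_genes``).
    """
    if policy.statistic == "counts":
        values = m.counts
    else:  # cpm / tpm: per-million scaling of counts
        values = m.cpm()
    present = panel.genes.intersection(m.genes)
    missing = panel.genes.difference(m.genes).tolist()
    if missing:
        warnings.warn(
            f"{len(missing)} panel gene(s) absent from matrix, treated as never "
            f"detected: {missing[:5]}",
            stacklevel=2,
        )
    calls = pd.DataFrame(False, index=panel.genes, columns=m.cells)
    calls.loc[present] = values.loc[present] > policy.threshold
    return DetectionMatrix(
        calls=calls,
        panel=panel,
        cell_meta=m.cell_meta,
        policy=policy,
        missing_genes=missing,
    )


def gene_prevalence(d: DetectionMatrix, m: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Per-gene detection fraction and mean ln(CPM+1) among detecting cells.

    The mean is reported as NaN for genes detected in no cell. Passing the
    source :class:`ExpressionMatrix` (with its lncpm layer) is required for
    the means; without it only fractions are returned.
    """
    n = d.n_cells
    n_detected = d.calls.sum(axis=1)
    out = pd.DataFrame(
        {"n_detected": n_detected, "n_cells": n, "fraction": n_detected / n}
    )
    if m is not None:
        if m.lncpm is None:
            raise ValueError("lncpm layer required for expression means")
        means = np.full(len(d.genes), np.nan)
        for i, g in enumerate(d.genes):
            mask = d.calls.loc[g]
            if mask.any() and g in m.genes:
                means[i] = m.lncpm.loc[g, mask[mask].index].mean()
        out["mean_lncpm"] = means
    return out


@dataclass
class CombinationTable:
    """Distinct per-cell expressed-gene sets with multiplicities."""

    table: pd.DataFrame  # columns: genes (tuple), n_cells, n_genes, is_empty
    per_cell: pd.Series  # cell id -> frozenset

    @property
    def n_combinations(self) -> int:
        return len(self.table)


def enumerate_combinations(d: DetectionMatrix) -> CombinationTable:
    """Enumerate distinct expressed-gene sets across cells.

    Ordered by descending cell count, then lexicographically by gene set.
    Cells detecting no panel gene form their own combination, flagged
    ``is_empty``.
    """
    per_cell = d.per_cell_sets()
    counts: dict = {}
    for s in per_cell:
        counts[s] = counts.get(s, 0) + 1
    rows = [
        {
            "genes": tuple(sorted(s)),
            "n_cells": c,
            "n_genes": len(s),
            "is_empty": len(s) == 0,
        }
        for s, c in counts.items()
    ]
    rows.sort(key=lambda r: (-r["n_cells"], r["genes"]))
    table = pd.DataFrame(rows, columns=["genes", "n_cells", "n_genes", "is_empty"])
    return CombinationTable(table=table, per_cell=per_cell)


@dataclass
class RepertoireSummary:
    """Summary of the per-cell expressed-gene counts."""

    n_cells: int
    mean: float
    sd: float | None  # sample SD (n-1); None for a single cell
    median: float
    mode: int  # ties broken by smallest attained count
    min: int
    max: int
    n_combinations: int

    def as_dict(self) -> dict:
        return {
            "n_cells": self.n_cells,
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "mode": self.mode,
            "min": self.min,
            "max": self.max,
            "n_combinations": self.n_combinations,
        }


def repertoire_stats(d: DetectionMatrix, drop_empty: bool = False) -> RepertoireSummary:
    """Mean ± SD, median, mode and range of genes expressed per cell.

    ``drop_empty`` restricts the summary to cells expressing at least one
    panel gene. SD uses the n−1 denominator; mode ties go to the smallest
    attained count.
    """
    counts = d.per_cell_counts()
    if drop_empty:
        counts = counts[counts > 0]
    if len(counts) == 0:
        raise ValueError("no cells to summarize")
    values = counts.to_numpy()
    uniq, freq = np.unique(values, return_counts=True)
    mode = int(uniq[np.argmax(freq)])  # np.argmax takes the first (smallest) tie
    combos = enumerate_combinations(
        d if not drop_empty else d.subset_cells(counts.index)
    )
    return RepertoireSummary(
        n_cells=len(values),
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)) if len(values) > 1 else None,
        median=float(np.median(values)),
        mode=mode,
        min=int(values.min()),
        max=int(values.max()),
        n_combinations=combos.n_combinations,
    )


# ---------------------------------------------------------------------------
# Fisher's exact test and cross-dataset comparison
# ---------------------------------------------------------------------------

_TIE_SLACK = 1e-7  # relative slack when comparing table probabilities


def fisher_exact_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2×2 table [[a, b], [c, d]].

    Conditional on the margins, sums the hypergeometric probabilities of all
    tables whose point probability is ≤ that of the observed table (with
    relative slack 1e-7 for floating-point ties) — the convention of the
    standard statistical suites.
    """
    cells = (a, b, c, d)
    for v in cells:
        if v < 0 or v != int(v):
            raise ValueError(f"table entries must be non-negative integers, got {cells}")
    a, b, c, d = (int(v) for v in cells)
    n = a + b + c + d
    if n == 0:
        raise ValueError("at least one margin must be positive")
    r1 = a + b  # row 1 margin
    c1 = a + c  # column 1 margin
    rv = scipy.stats.hypergeom(n, c1, r1)
    k_lo = max(0, r1 - (n - c1))
    k_hi = min(r1, c1)
    ks = np.arange(k_lo, k_hi + 1)
    pmf = rv.pmf(ks)
    p_obs = rv.pmf(a)
    include = pmf <= p_obs * (1 + _TIE_SLACK)
    if include.all():  # observed table is (tied with) the mode: p is exactly 1
        return 1.0
    return min(float(pmf[include].sum()), 1.0)


def compare_datasets(
    prev_a: pd.DataFrame,
    prev_b: pd.DataFrame,
    correction: str = "bonferroni",
) -> tuple[pd.DataFrame, dict]:
    """Per-gene Fisher comparison of detection prevalence in two datasets.

    ``prev_a`` / ``prev_b`` are prevalence tables as returned by
    :func:`gene_prevalence` (columns ``n_detected`` and ``n_cells``,
    indexed by gene). The shared gene universe is the union of the two
    indexes; a gene absent from one table contributes 0 detections against
    that dataset's cell count. Genes with no denominator in either dataset
    are excluded with a warning.

    Returns the per-gene table (detected/total in each dataset, p, p_adj)
    and a set summary (genes detected in A, in B, union, intersection).
    """
    method = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(correction)
    if method is None:
        raise ValueError(f"unknown correction {correction!r}")
    n_a = int(prev_a["n_cells"].max()) if len(prev_a) else 0
    n_b = int(prev_b["n_cells"].max()) if len(prev_b) else 0
    universe = prev_a.index.union(prev_b.index)
    rows = []
    for g in universe:
        da = int(prev_a.loc[g, "n_detected"]) if g in prev_a.index else 0
        ta = int(prev_a.loc[g, "n_cells"]) if g in prev_a.index else n_a
        db = int(prev_b.loc[g, "n_detected"]) if g in prev_b.index else 0
        tb = int(prev_b.loc[g, "n_cells"]) if g in prev_b.index else n_b
        if ta == 0 and tb == 0:
            warnings.warn(f"gene {g!r} has no denominator in either dataset; excluded")
            continue
        p = fisher_exact_two_tailed(da, ta - da, db, tb - db)
        rows.append(
            {"gene": g, "det_a": da, "n_a": ta, "det_b": db, "n_b": tb, "p": p}
        )
    table = pd.DataFrame(rows).set_index("gene")
    table["p_adj"] = np.maximum(
        multipletests(table["p"].to_numpy(), method=method)[1], table["p"].to_numpy()
    )
    set_a = set(table.index[table["det_a"] > 0])
    set_b = set(table.index[table["det_b"] > 0])
    summary = {
        "detected_a": set_a,
        "detected_b": set_b,
        "union": set_a | set_b,
        "intersection": set_a & set_b,
    }
    return table, summary


@dataclass
class UnionSummary:
    union: set
    size: int
    percent: int | None  # round(100 * size / catalog_size), None without catalog


def set_union_summary(
    set_a: Iterable[str], set_b: Iterable[str], catalog_size: int | None = None
) -> UnionSummary:
    """Union of two detected-gene sets, with percent-of-catalog if given.

    The percent is rounded to the nearest integer, matching how such
    fractions are conventionally reported.
    """
    union = set(set_a) | set(set_b)
    percent = None
    if catalog_size is not None:
        if catalog_size <= 0:
            raise ValueError("catalog_size must be positive")
        percent = int(round(100 * len(union) / catalog_size))
    return UnionSummary(union=union, size=len(union), percent=percent)
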