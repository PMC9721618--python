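"""Neuroendocrine-tumor analyses: bulk quantile normalization, the composite
tumor expression profile, panel coverage, and nearest-normal-cell matching.

A carcinoid is expected to amplify the expression program of the single
normal neuroendocrine cell it arose from. The composite profile collects
the panel genes detected in more than ``frac_min`` of the profiled tumor
cells (plus any explicitly hand-included genes); matching then finds the
normal reference cell whose expressed-gene set is most similar to that
composite, by Jaccard similarity over binary panel profiles (default) or
cosine similarity over the same binary vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .repertoire import DetectionMatrix


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a genes × samples matrix.

    Each sample's values are replaced by the rank-wise mean of the sorted
    columns; tied values receive the mean of the reference distribution at
    the tied ranks (average-rank convention). After normalization every
    sample has the same value multiset, and within-sample ranks are
    preserved.
    """
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    if not np.isfinite(values.to_numpy()).all():
        raise ValueError("matrix contains non-finite values")
    n = values.shape[0]
    reference = np.sort(values.to_numpy(), axis=0).mean(axis=1)
    ranks = values.rank(axis=0, method="average")
    out = pd.DataFrame(
        np.interp(ranks.to_numpy(), np.arange(1, n + 1), reference),
        index=values.index,
        columns=values.columns,
    )
    return out


def filter_samples(meta: pd.DataFrame, column: str, labels: Iterable[str]) -> pd.Index:
    """Sample ids whose histopathology label is one of ``labels``."""
    labels = set(labels)
    return meta.index[meta[column].isin(labels)]


@dataclass
class CompositeProfile:
    """Gene set expressed above the prevalence cutoff across tumor cells."""

    genes: set
    frac_min: float
    manual: set = field(default_factory=set)  # hand-included, below cutoff

    @property
    def all_genes(self) -> set:
        return self.genes | self.manual


def composite_profile(
    tumor: DetectionMatrix, frac_min: float = 0.15, include: Iterable[str] = ()
) -> CompositeProfile:
    """Genes detected in strictly more than ``frac_min`` of the tumor cells.

    ``include`` adds genes regardless of prevalence (the documented manual
    include list); they are flagged separately in ``manual``.
    """
    if not (0 <= frac_min < 1):
        raise ValueError("frac_min must lie in [0, 1)")
    if tumor.n_cells < 1:
        raise ValueError("tumor detection matrix has no cells")
    prevalence = tumor.calls.mean(axis=1)
    genes = set(prevalence.index[prevalence > frac_min])
    manual = set(include) - genes
    return CompositeProfile(genes=genes, frac_min=frac_min, manual=manual)


def panel_coverage(detected: Iterable[str], reference: Iterable[str]) -> tuple[int, float]:
    """How much of a reference gene set the detected set covers.

    Returns ``(n_detected_in_reference, fraction)`` with
    fraction = |detected ∩ reference| / |reference|.
    """
    reference = set(reference)
    if not reference:
        raise ValueError("reference gene set is empty")
    hit = set(detected) & reference
    return len(hit), len(hit) / len(reference)


@dataclass
class MatchResult:
    """Similarity of every reference cell to a composite profile."""

    scores: pd.Series
    best: str
    metric: str
    tie: bool
    uninformative: bool  # all scores zero


def _jaccard(a: set, b: set) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def _cosine_binary(a: set, b: set) -> float:
    if not a or not b:
        return 0.0
    return len(a & b) / np.sqrt(len(a) * len(b))


_METRICS = {"jaccard": _jaccard, "cosine": _cosine_binary}


def match_to_reference(
    profile: CompositeProfile | set,
    reference_cells: Mapping[str, set],
    metric: str = "jaccard",
) -> MatchResult:
    """Find the reference cell whose expressed-gene set best matches the
    tumor composite profile.

    Ties are broken by reference-cell order and flagged; an all-zero score
    vector is flagged uninformative. An empty profile against an empty cell
    scores 0 with a warning.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    if not reference_cells:
        raise ValueError("need at least one reference cell")
    pset = profile.all_genes if isinstance(profile, CompositeProfile) else set(profile)
    fn = _METRICS[metric]
    ids = list(reference_cells)
    if not pset and any(not reference_cells[c] for c in ids):
        warnings.warn("empty profile compared against empty cell; score defined as 0")
    scores = pd.Series([fn(pset, set(reference_cells[c])) for c in ids], index=ids)
    best = scores.idxmax()  # first maximum in reference order
    max_score = scores.max()
    tie = int((scores == max_score).sum()) > 1
    return MatchResult(
        scores=scores,
        best=best,
        metric=metric,
        tie=tie,
        uninformative=bool(max_score == 0),
    )
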