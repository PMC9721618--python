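"""Per-cell isoform classification from splice-junction read counts.

The motivating case is the Calca/CALCA gene, whose transcripts are
alternatively spliced into mRNAs encoding either CGRP or calcitonin. The
two products are distinguished by which exon junction the reads support:
exon3→exon4 is diagnostic for calcitonin, exon3→exon5 for CGRP. Given a
table of junction-supporting read counts per cell, each cell is classified
as expressing one isoform exclusively, both, or neither (given a minimum
read support). Junction extraction from alignments belongs to standard
upstream tools; this module owns only the classification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass
class JunctionTable:
    """Junction read counts per cell plus the isoform-diagnostic junctions.

    ``counts``: cells × junctions, non-negative integers.
    ``isoforms``: isoform name → set of diagnostic junction names; the
    diagnostic sets must be pairwise disjoint.
    ``junctions``: optional definitions (name, donor_end, acceptor_start) in
    0-based half-open genomic coordinates.
    """

    counts: pd.DataFrame
    isoforms: dict
    junctions: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("junction counts must be non-negative")
        names = list(self.isoforms)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                shared = set(self.isoforms[a]) & set(self.isoforms[b])
                if shared:
                    raise ValueError(
                        f"diagnostic junctions shared between {a!r} and {b!r}: {shared}"
                    )
        for iso, juncs in self.isoforms.items():
            missing = set(juncs) - set(self.counts.columns)
            if missing:
                raise ValueError(f"isoform {iso!r} references unknown junctions {missing}")

    @property
    def cells(self) -> pd.Index:
        return self.counts.index


#: default mouse Calca diagnostic junctions (exon3→exon4 = calcitonin,
#: exon3→exon5 = CGRP), encoded as data
CALCA_ISOFORMS = {"CGRP": {"e3-e5"}, "calcitonin": {"e3-e4"}}


def load_junction_table(counts_path, isoforms_path=None) -> JunctionTable:
    """Read a junction TSV (cell_id, junction_name, count) and isoform JSON."""
    long = pd.read_csv(counts_path, sep="\t")
    for col in ("cell_id", "junction_name", "count"):
        if col not in long.columns:
            raise ValueError(f"junction TSV lacks required column {col!r}")
    counts = (
        long.pivot_table(
            index="cell_id", columns="junction_name", values="count", fill_value=0
        )
        .astype(int)
    )
    if isoforms_path is None:
        isoforms = {k: set(v) for k, v in CALCA_ISOFORMS.items()}
    else:
        with open(isoforms_path) as fh:
            isoforms = {k: set(v) for k, v in json.load(fh).items()}
    return JunctionTable(counts=counts, isoforms=isoforms)


def classify_isoforms(jt: JunctionTable, min_reads: int = 1) -> pd.DataFrame:
    """Classify each cell's isoform usage from diagnostic-junction counts.

    For the two defined isoforms (iso1, iso2 in definition order), sums the
    diagnostic-junction reads per isoform and assigns a category:
    ``<iso1>_only`` iff the iso1 sum ≥ min_reads and the iso2 sum < min_reads
    (symmetrically for iso2), ``both`` iff both pass, ``undetected``
    otherwise. ``f`` is the iso1 fraction iso1/(iso1+iso2), NaN when both
    sums are zero.
    """
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    names = list(jt.isoforms)
    if len(names) != 2:
        raise ValueError(f"exactly two isoforms required, got {len(names)}")
    iso1, iso2 = names
    s1 = jt.counts[sorted(jt.isoforms[iso1])].sum(axis=1)
    s2 = jt.counts[sorted(jt.isoforms[iso2])].sum(axis=1)
    has1, has2 = s1 >= min_reads, s2 >= min_reads
    category = np.select(
        [has1 & has2, has1 & ~has2, ~has1 & has2],
        ["both", f"{iso1}_only", f"{iso2}_only"],
        default="undetected",
    )
    total = s1 + s2
    with np.errstate(invalid="ignore"):
        f = np.where(total > 0, s1 / total.replace(0, np.nan), np.nan)
    return pd.DataFrame(
        {f"{iso1}_count": s1, f"{iso2}_count": s2, "category": category, "f": f},
        index=jt.cells,
    )


def isoform_summary(calls: pd.DataFrame, min_reads: int = 1) -> dict:
    """Category fractions and per-isoform expressing fractions.

    Fractions are over cells with at least one detected isoform; cells with
    no diagnostic reads are reported separately (``n_undetected``). Raises
    when every cell is undetected.
    """
    detected = calls[calls["category"] != "undetected"]
    n_undetected = int((calls["category"] == "undetected").sum())
    if len(detected) == 0:
        raise ValueError("no cell has a detected isoform")
    count_cols = [c for c in calls.columns if c.endswith("_count")]
    iso_names = [c[: -len("_count")] for c in count_cols]
    n = len(detected)
    category_fractions = {
        cat: float((detected["category"] == cat).sum()) / n
        for cat in [f"{iso_names[0]}_only", f"{iso_names[1]}_only", "both"]
    }
    expressing_fractions = {
        iso: float((detected[f"{iso}_count"] >= min_reads).sum()) / n
        for iso in iso_names
    }
    return {
        "n_cells": n,
        "n_undetected": n_undetected,
        "category_fractions": category_fractions,
        "expressing_fractions": expressing_fractions,
    }
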