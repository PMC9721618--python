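"""Matrices, annotation tables, and the ln(CPM+1) normalization.

The package's in-memory container for single-cell expression data is
:class:`ExpressionMatrix`: a genes × cells integer count matrix plus per-cell
metadata, with an optional ``lncpm`` layer holding ln(counts-per-million + 1).
All downstream stages (marker scoring, detection calls, target mapping) read
from this container.

On disk, matrices are MatrixMarket coordinate triplets (1-based indices) with
sidecar ``genes.tsv`` / ``barcodes.tsv`` files, or dense CSV with genes as
rows; cell metadata is a TSV with columns ``cell_id``, ``cell_type``,
``dataset`` (plus optional extras such as ``group``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class DimensionError(ValueError):
    """Matrix / gene-list / cell-list / metadata dimensions disagree."""


REQUIRED_META_COLUMNS = ("cell_type",)


@dataclass
class ExpressionMatrix:
    """Genes × cells count matrix with per-cell metadata.

    Parameters
    ----------
    counts
        Non-negative integer counts, index = gene identifiers,
        columns = cell identifiers.
    cell_meta
        One row per cell (index = cell identifier); must contain a
        ``cell_type`` column and usually a ``dataset`` column.
    lncpm
        Optional ln(CPM+1) layer with the same shape as ``counts``.
        Produced by :func:`normalize_lncpm`; never filled in by readers.
    """

    counts: pd.DataFrame
    cell_meta: pd.DataFrame
    lncpm: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene identifiers: {dups[:5]}")
        if self.counts.columns.has_duplicates:
            dups = self.counts.columns[self.counts.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate cell identifiers: {dups[:5]}")
        values = self.counts.to_numpy()
        if np.any(values < 0) or not np.allclose(values, np.round(values)):
            bad = np.argwhere((values < 0) | ~np.isclose(values, np.round(values)))
            g, c = bad[0]
            raise ValueError(
                "counts must be non-negative integers; offending entry at "
                f"gene={self.counts.index[g]!r}, cell={self.counts.columns[c]!r} "
                f"(value {values[g, c]!r})"
            )
        missing = self.counts.columns.difference(self.cell_meta.index)
        if len(missing):
            raise DimensionError(
                f"cell metadata does not cover all cells; missing {list(missing[:5])}"
            )
        for col in REQUIRED_META_COLUMNS:
            if col not in self.cell_meta.columns:
                raise ValueError(f"cell metadata lacks required column {col!r}")
        if self.cell_meta["cell_type"].isna().any():
            raise ValueError("every cell must carry a cell_type label")
        # align metadata row order to the matrix column order
        self.cell_meta = self.cell_meta.loc[self.counts.columns]
        if self.lncpm is not None:
            if self.lncpm.shape != self.counts.shape:
                raise DimensionError("lncpm layer shape differs from counts")

    # -- basic introspection ------------------------------------------------
    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def cells(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def subset_cells(self, cells: Sequence[str]) -> "ExpressionMatrix":
        cells = pd.Index(cells)
        return ExpressionMatrix(
            counts=self.counts.loc[:, cells],
            cell_meta=self.cell_meta.loc[cells],
            lncpm=None if self.lncpm is None else self.lncpm.loc[:, cells],
        )

    def cells_of_type(self, *cell_types: str) -> pd.Index:
        mask = self.cell_meta["cell_type"].isin(cell_types)
        return self.cell_meta.index[mask]

    def cpm(self) -> pd.DataFrame:
        """Counts-per-million layer (no pseudocount, no log)."""
        totals = self.counts.sum(axis=0)
        if (totals == 0).any():
            zero = totals.index[totals == 0].tolist()
            raise ValueError(f"cells with zero total count: {zero[:10]}")
        return self.counts / totals * 1e6

    def to_anndata(self):
        """Export as an :class:`anndata.AnnData` (cells × genes)."""
        import anndata

        adata = anndata.AnnData(
            X=self.counts.to_numpy(dtype=float).T,
            obs=self.cell_meta.copy(),
            var=pd.DataFrame(index=self.genes),
        )
        if self.lncpm is not None:
            adata.layers["lncpm"] = self.lncpm.to_numpy().T
        return adata


@dataclass
class GenePanel:
    """A curated gene catalog: peptidergic genes, sensory genes, etc.

    ``table`` is indexed by gene identifier with at least a ``category``
    column and a boolean ``hormone`` column; extra columns from the source
    CSV are preserved untouched.
    """

    name: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene in panel {self.name!r}: {dups[:5]}")
        if "category" in self.table.columns:
            cats = self.table["category"].astype(str)
            if (cats.str.len() == 0).any():
                raise ValueError("panel categories must be non-empty strings")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_genes(
        cls, genes: Iterable[str], name: str = "panel", category: str = "peptidergic"
    ) -> "GenePanel":
        genes = list(genes)
        table = pd.DataFrame(
            {"category": category, "hormone": False}, index=pd.Index(genes, name="gene")
        )
        return cls(name=name, table=table)


@dataclass(frozen=True)
class LRRecord:
    """One ligand → peptide → receptor-unit triple."""

    ligand: str
    peptide: str
    receptor_unit: frozenset

    def __post_init__(self) -> None:
        if not self.receptor_unit:
            raise ValueError(
                f"empty receptor unit for ligand {self.ligand!r} / peptide {self.peptide!r}"
            )


@dataclass
class LigandReceptorMap:
    """Curated map from signal genes to the genes encoding their receptors.

    A ligand gene may encode several peptides (e.g. Calca → CGRP and
    calcitonin) and a peptide may have several alternative receptor units;
    multi-subunit receptors are a set of gene identifiers.
    """

    records: list = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            key = (rec.ligand, rec.peptide, rec.receptor_unit)
            if key in seen:
                raise ValueError(f"duplicate ligand-receptor record: {key}")
            seen.add(key)

    @property
    def ligands(self) -> list:
        out = []
        for rec in self.records:
            if rec.ligand not in out:
                out.append(rec.ligand)
        return out

    @property
    def receptor_genes(self) -> list:
        out: list = []
        for rec in self.records:
            for g in sorted(rec.receptor_unit):
                if g not in out:
                    out.append(g)
        return out

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _read_cell_meta(meta_path) -> pd.DataFrame:
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "cell_id" not in meta.columns:
        raise ValueError(f"metadata file {meta_path} lacks a 'cell_id' column")
    return meta.set_index("cell_id")


def load_count_matrix(
    matrix_path,
    meta_path,
    genes_path=None,
    cells_path=None,
    orientation: str = "genes-by-cells",
) -> ExpressionMatrix:
    """Load an MTX triplet (+ genes.tsv / barcodes.tsv) or dense CSV matrix.

    ``orientation`` declares the on-disk layout ("genes-by-cells" or
    "cells-by-genes"); the in-memory matrix is always genes × cells. The
    returned matrix carries no ``lncpm`` layer; call :func:`normalize_lncpm`.
    """
    if orientation not in ("genes-by-cells", "cells-by-genes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if genes_path is None or cells_path is None:
            raise ValueError("MTX input requires genes_path and cells_path")
        mat = scipy.io.mmread(str(matrix_path))
        genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str)
        cells = pd.read_csv(cells_path, sep="\t", header=None)[0].astype(str)
        dense = np.asarray(scipy.sparse.coo_matrix(mat).todense())
        if orientation == "cells-by-genes":
            dense = dense.T
        if dense.shape[0] != len(genes):
            raise DimensionError(
                f"gene axis mismatch: matrix has {dense.shape[0]} rows, "
                f"gene list has {len(genes)} entries"
            )
        if dense.shape[1] != len(cells):
            raise DimensionError(
                f"cell axis mismatch: matrix has {dense.shape[1]} columns, "
                f"cell list has {len(cells)} entries"
            )
        counts = pd.DataFrame(dense, index=genes, columns=cells)
    else:
        counts = pd.read_csv(matrix_path, index_col=0)
        counts.index = counts.index.astype(str)
        counts.columns = counts.columns.astype(str)
        if orientation == "cells-by-genes":
            counts = counts.T
    meta = _read_cell_meta(meta_path)
    missing = counts.columns.difference(meta.index)
    if len(missing):
        raise DimensionError(
            f"metadata does not cover all cells; missing {list(missing[:5])}"
        )
    return ExpressionMatrix(counts=counts, cell_meta=meta.loc[counts.columns])


def write_count_matrix(m: ExpressionMatrix, outdir, stem: str = "matrix") -> dict:
    """Write MTX + genes.tsv + barcodes.tsv + metadata TSV; return the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / f"{stem}.mtx",
        "genes": outdir / f"{stem}.genes.tsv",
        "cells": outdir / f"{stem}.barcodes.tsv",
        "meta": outdir / f"{stem}.meta.tsv",
    }
    sparse = scipy.sparse.coo_matrix(m.counts.to_numpy())
    scipy.io.mmwrite(str(paths["matrix"]), sparse, field="integer")
    pd.Series(m.genes).to_csv(paths["genes"], sep="\t", header=False, index=False)
    pd.Series(m.cells).to_csv(paths["cells"], sep="\t", header=False, index=False)
    m.cell_meta.rename_axis("cell_id").reset_index().to_csv(
        paths["meta"], sep="\t", index=False
    )
    return paths


def normalize_lncpm(
    m: ExpressionMatrix, exclude: Iterable[str] = ()
) -> ExpressionMatrix:
    """Attach the ln(CPM+1) layer: counts scaled per million, log1p'd.

    ``exclude`` lists genes (reporters, spike-ins) removed from each cell's
    library-size denominator; their own lncpm values are still reported
    against that denominator. Cells whose (post-exclusion) total is zero are
    rejected with a :class:`ValueError` listing the offending cell ids.
    """
    exclude = set(exclude)
    keep = ~m.genes.isin(exclude)
    totals = m.counts.loc[keep].sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValueError(f"cells with zero total count: {zero[:20]}")
    lncpm = np.log1p(m.counts / totals * 1e6)
    return ExpressionMatrix(counts=m.counts, cell_meta=m.cell_meta, lncpm=lncpm)


def load_gene_panel(path, name: str | None = None) -> GenePanel:
    """Read a panel CSV with required headers ``gene``, ``category``, ``hormone``."""
    df = pd.read_csv(path)
    for col in ("gene", "category", "hormone"):
        if col not in df.columns:
            raise ValueError(f"panel CSV {path} lacks required header {col!r}")
    df["hormone"] = df["hormone"].astype(bool)
    table = df.set_index("gene")
    return GenePanel(name=name or Path(path).stem, table=table)


def write_gene_panel(panel: GenePanel, path) -> None:
    panel.table.rename_axis("gene").reset_index().to_csv(path, index=False)


def load_ligand_receptor_map(path) -> LigandReceptorMap:
    """Read an L-R CSV with headers ``ligand,peptide,receptor_unit``.

    Multi-subunit receptor units are '+'-joined gene lists.
    """
    df = pd.read_csv(path)
    for col in ("ligand", "peptide", "receptor_unit"):
        if col not in df.columns:
            raise ValueError(f"ligand-receptor CSV {path} lacks required header {col!r}")
    records = []
    for _, row in df.iterrows():
        raw = "" if pd.isna(row["receptor_unit"]) else str(row["receptor_unit"])
        unit = frozenset(g.strip() for g in raw.split("+") if g.strip())
        records.append(
            LRRecord(
                ligand=str(row["ligand"]).strip(),
                peptide=str(row["peptide"]).strip(),
                receptor_unit=unit,
            )
        )
    return LigandReceptorMap(records=records)


def write_ligand_receptor_map(lr: LigandReceptorMap, path) -> None:
    rows = [
        {
            "ligand": rec.ligand,
            "peptide": rec.peptide,
            "receptor_unit": "+".join(sorted(rec.receptor_unit)),
        }
        for rec in lr.records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
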