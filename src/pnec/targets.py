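"""Ligand → receptor target calling against a reference cell atlas.

For every receptor gene in a ligand-receptor map, compute the fraction of
cells of each atlas cell type detecting it (and the mean ln(CPM+1) among
detecting cells). A receptor *unit* (possibly multi-subunit) is expressed in
a cell type when its member genes pass the prevalence threshold (all of
them under the default ``unit_rule="all"``); a cell type is a target of a
ligand when any receptor unit of any of its peptides is expressed there.
Ligands with known receptors but no called cell type are flagged orphans —
candidate endocrine signals that may enter the circulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, LigandReceptorMap
from .repertoire import DetectionPolicy, COUNTS_POSITIVE


@dataclass
class TargetCallMatrix:
    """Receptor expression profile and (once completed) the target calls."""

    lr: LigandReceptorMap
    fractions: pd.DataFrame  # receptor gene × cell type detection fraction
    means: pd.DataFrame  # receptor gene × cell type mean lncpm among detecting
    missing_receptors: list = field(default_factory=list)
    # filled in by call_targets:
    frac_min: float | None = None
    unit_rule: str | None = None
    unit_expressed: pd.DataFrame | None = None  # (ligand,peptide,unit) × cell type
    ligand_targets: pd.DataFrame | None = None  # ligand × cell type bool
    signal_counts: pd.Series | None = None  # per cell type
    orphans: set = field(default_factory=set)
    no_known_receptor: set = field(default_factory=set)

    @property
    def cell_types(self) -> pd.Index:
        return self.fractions.columns

    def long_table(self) -> pd.DataFrame:
        """Long-format (ligand, peptide, receptor_unit, cell_type, ...) table."""
        rows = []
        called = self.unit_expressed
        for rec in self.lr.records:
            unit_key = "+".join(sorted(rec.receptor_unit))
            for ct in self.cell_types:
                genes = sorted(rec.receptor_unit)
                frac = float(self.fractions.loc[genes, ct].min())
                vals = self.means.loc[genes, ct].to_numpy()
                mean = float(np.nanmean(vals)) if not np.isnan(vals).all() else float("nan")
                row = {
                    "ligand": rec.ligand,
                    "peptide": rec.peptide,
                    "receptor_unit": unit_key,
                    "cell_type": ct,
                    "fraction": frac,
                    "mean_lncpm": mean,
                }
                if called is not None:
                    row["called"] = bool(
                        called.loc[(rec.ligand, rec.peptide, unit_key), ct]
                    )
                rows.append(row)
        return pd.DataFrame(rows)


def receptor_profile(
    atlas: ExpressionMatrix,
    lr: LigandReceptorMap,
    policy: DetectionPolicy = COUNTS_POSITIVE,
) -> TargetCallMatrix:
    """Per (receptor gene, cell type) detection fraction and expression mean.

    Receptor genes absent from the atlas get fraction 0 everywhere (with a
    warning). Cell types with zero cells cannot occur in a validated
    :class:`ExpressionMatrix`; empty *labels* are simply absent.
    """
    genes = lr.receptor_genes
    present = [g for g in genes if g in atlas.genes]
    missing = [g for g in genes if g not in atlas.genes]
    if missing:
        warnings.warn(
            f"{len(missing)} receptor gene(s) absent from atlas: {missing[:5]}",
            stacklevel=2,
        )
    if policy.statistic == "counts":
        values = atlas.counts
    else:
        values = atlas.cpm()
    detected = pd.DataFrame(False, index=pd.Index(genes), columns=atlas.cells)
    detected.loc[present] = values.loc[present] > policy.threshold
    types = atlas.cell_meta["cell_type"]
    fractions = detected.T.groupby(types).mean().T
    if atlas.lncpm is None:
        means = pd.DataFrame(np.nan, index=fractions.index, columns=fractions.columns)
    else:
        means = pd.DataFrame(np.nan, index=fractions.index, columns=fractions.columns)
        for g in present:
            mask = detected.loc[g]
            if mask.any():
                expr = atlas.lncpm.loc[g, mask[mask].index]
                means.loc[g] = expr.groupby(types[mask[mask].index]).mean()
    return TargetCallMatrix(lr=lr, fractions=fractions, means=means, missing_receptors=missing)


def call_targets(
    profile: TargetCallMatrix,
    frac_min: float = 0.10,
    unit_rule: str = "all",
    count_by: str = "ligand",
    ligands_without_receptors=(),
) -> TargetCallMatrix:
    """Complete the target calls on a receptor profile.

    A receptor unit is expressed in a cell type iff every member gene
    (``unit_rule="all"``) or at least one (``"any"``) has detection fraction
    ≥ ``frac_min`` (inclusive). Per-cell-type signal counts count distinct
    ligands with at least one expressed unit by default
    (``count_by="ligand"``); ``count_by="receptor_gene"`` counts distinct
    receptor genes passing the threshold instead. ``ligands_without_receptors``
    are carried through flagged separately from orphans.
    """
    if not (0 < frac_min <= 1):
        raise ValueError("frac_min must lie in (0, 1]")
    if unit_rule not in ("all", "any"):
        raise ValueError(f"unknown unit_rule {unit_rule!r}")
    if count_by not in ("ligand", "receptor_gene"):
        raise ValueError(f"unknown count_by {count_by!r}")

    cts = profile.cell_types
    unit_index = []
    unit_rows = []
    for rec in profile.lr.records:
        genes = sorted(rec.receptor_unit)
        passing = profile.fractions.loc[genes] >= frac_min
        expressed = passing.all(axis=0) if unit_rule == "all" else passing.any(axis=0)
        unit_index.append((rec.ligand, rec.peptide, "+".join(genes)))
        unit_rows.append(expressed)
    unit_expressed = pd.DataFrame(
        unit_rows,
        index=pd.MultiIndex.from_tuples(
            unit_index, names=["ligand", "peptide", "receptor_unit"]
        ),
        columns=cts,
    )
    ligand_targets = unit_expressed.groupby(level="ligand", sort=False).any()

    if count_by == "ligand":
        signal_counts = ligand_targets.sum(axis=0)
    else:
        gene_pass = (profile.fractions >= frac_min).loc[
            [g for g in profile.lr.receptor_genes if g in profile.fractions.index]
        ]
        signal_counts = gene_pass.sum(axis=0)

    orphans = set(ligand_targets.index[~ligand_targets.any(axis=1)])
    return TargetCallMatrix(
        lr=profile.lr,
        fractions=profile.fractions,
        means=profile.means,
        missing_receptors=list(profile.missing_receptors),
        frac_min=frac_min,
        unit_rule=unit_rule,
        unit_expressed=unit_expressed,
        ligand_targets=ligand_targets,
        signal_counts=signal_counts,
        orphans=orphans,
        no_known_receptor=set(ligands_without_receptors),
    )
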