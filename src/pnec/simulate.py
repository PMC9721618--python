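"""Synthetic data with the statistical structure the pipeline assumes.

The generative model is a zero-inflated log-normal: gene g is *detected* in
a cell of type t with probability p[g, t] (technical dropout and true
absence are not distinguished); detected genes draw a relative expression
mass from a log-normal(mu_g, sigma_g); each cell draws a library size from
a log-normal and integer counts are Poisson around the cell's scaled
expression masses. Detection and magnitude are independent — the simplest
structure matching the two quantities the analyses report (the percent of
cells detecting a gene, and the mean expression among detecting cells).

The packaged "mouse-PNEC-like" and "human-PNEC-like" specifications place
the peptidergic panel genes on a prevalence spectrum anchored to published
per-gene detection percentages for pulmonary neuroendocrine cells
(e.g. Calca 95%, Pcsk1n 62%, Cartpt 34%, Igf2 72%; human POMC 57%,
CARTPT 4%), with the remaining probabilities chosen so the expected
per-cell panel count is ≈7.2 (mouse) and ≈12.2 (human). Genes are
statistically independent; real gene-gene correlation structure is not
emulated.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GenePanel, LigandReceptorMap, LRRecord
from .isoforms import CALCA_ISOFORMS, JunctionTable
from .repertoire import DetectionMatrix


@dataclass
class SimulationSpec:
    """Full parameterization of the cell simulator.

    ``detection_p`` is genes × cell types; ``log_mean`` / ``log_sd`` are the
    per-gene log-normal parameters of expression mass among detecting cells;
    library sizes are log-normal with the given parameters. ``seed`` is
    mandatory: every generator draws from ``numpy.random.default_rng`` keyed
    on it (or an explicit override).
    """

    n_cells: Mapping[str, int]
    detection_p: pd.DataFrame
    log_mean: pd.Series
    log_sd: pd.Series
    seed: int
    libsize_log_mean: float = float(np.log(5e5))
    libsize_log_sd: float = 0.3
    panel: GenePanel | None = None
    dataset: str = "sim"
    poisson_counts: bool = True  # False: deterministic rounding (noise-free mode)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        p = self.detection_p.to_numpy()
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("detection probabilities must lie in [0, 1]")
        if np.any(self.log_sd.to_numpy() < 0):
            raise ValueError("log_sd must be >= 0")
        for ct in self.n_cells:
            if ct not in self.detection_p.columns:
                raise ValueError(f"cell type {ct!r} missing from detection_p columns")
        self.log_mean = self.log_mean.reindex(self.detection_p.index)
        self.log_sd = self.log_sd.reindex(self.detection_p.index)
        if self.log_mean.isna().any() or self.log_sd.isna().any():
            raise ValueError("log_mean/log_sd must cover every gene in detection_p")

    @property
    def genes(self) -> pd.Index:
        return self.detection_p.index


def simulate_cells(spec: SimulationSpec, seed: int | None = None) -> ExpressionMatrix:
    """Draw a genes × cells count matrix from the zero-inflated log-normal."""
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    genes = spec.genes
    mu = spec.log_mean.to_numpy()[:, None]
    sigma = spec.log_sd.to_numpy()[:, None]
    blocks, ids, types = [], [], []
    for ct, n in spec.n_cells.items():
        p = spec.detection_p[ct].to_numpy()[:, None]
        detected = rng.random((len(genes), n)) < p
        mass = np.exp(mu + sigma * rng.standard_normal((len(genes), n))) * detected
        lib = rng.lognormal(spec.libsize_log_mean, spec.libsize_log_sd, size=n)
        totals = mass.sum(axis=0)
        rates = np.zeros_like(mass)
        nonzero = totals > 0
        rates[:, nonzero] = mass[:, nonzero] / totals[nonzero] * lib[nonzero]
        blocks.append(rng.poisson(rates) if spec.poisson_counts else np.round(rates).astype(int))
        ids.extend(f"{ct}_{i:04d}" for i in range(n))
        types.extend([ct] * n)
    counts = pd.DataFrame(
        np.concatenate(blocks, axis=1), index=genes, columns=pd.Index(ids)
    )
    meta = pd.DataFrame(
        {"cell_type": types, "dataset": spec.dataset}, index=counts.columns
    )
    return ExpressionMatrix(counts=counts, cell_meta=meta)


# ---------------------------------------------------------------------------
# Two-dataset design
# ---------------------------------------------------------------------------

def design_gene_sets(
    catalog: Sequence[str], n_a: int, n_b: int, n_overlap: int
) -> tuple[list, list]:
    """Split a gene catalog into two expressed sets with a designed overlap.

    Returns (genes_a, genes_b) with |A| = n_a, |B| = n_b, |A∩B| = n_overlap.
    """
    if n_overlap > min(n_a, n_b):
        raise ValueError("overlap cannot exceed either set size")
    if n_a + n_b - n_overlap > len(catalog):
        raise ValueError("catalog too small for the requested design")
    catalog = list(catalog)
    genes_a = catalog[:n_a]
    shared = catalog[n_a - n_overlap : n_a]
    genes_b = shared + catalog[n_a : n_a + (n_b - n_overlap)]
    return genes_a, genes_b


def simulate_two_datasets(
    spec: SimulationSpec,
    genes_a: Iterable[str],
    genes_b: Iterable[str],
    n_cells_a: int = 176,
    n_cells_b: int = 92,
    cell_type: str = "PNEC",
    min_p: float = 0.25,
    p_overrides_a: Mapping[str, float] | None = None,
    p_overrides_b: Mapping[str, float] | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Two datasets whose expressed panel-gene sets are designed.

    Dataset A expresses exactly the panel genes in ``genes_a`` (others get
    detection probability 0), and likewise B. Designed genes have their
    detection probability floored at ``min_p`` so that, at the default cell
    numbers, every designed gene is detected and downstream set-union
    summaries recover the designed union. Per-gene probability overrides
    allow planting prevalence differences between the datasets.
    """
    genes_a, genes_b = set(genes_a), set(genes_b)
    panel_genes = set(spec.panel.genes) if spec.panel is not None else set(spec.genes)
    unknown = (genes_a | genes_b) - set(spec.genes)
    if unknown:
        raise ValueError(f"designed genes absent from spec: {sorted(unknown)[:5]}")

    def build(gene_set, overrides, n, tag, sub):
        p = spec.detection_p.copy()
        for g in panel_genes:
            for ct in p.columns:
                if g not in gene_set:
                    p.loc[g, ct] = 0.0
                else:
                    p.loc[g, ct] = max(p.loc[g, ct], min_p)
        for g, v in (overrides or {}).items():
            p.loc[g, :] = v
        return replace(
            spec,
            n_cells={cell_type: n},
            detection_p=p,
            dataset=tag,
            seed=spec.seed + sub,
        )

    spec_a = build(genes_a, p_overrides_a, n_cells_a, "A", 1)
    spec_b = build(genes_b, p_overrides_b, n_cells_b, "B", 2)
    return simulate_cells(spec_a), simulate_cells(spec_b)


# ---------------------------------------------------------------------------
# Junctions, atlas, tumor
# ---------------------------------------------------------------------------

def simulate_junctions(
    weights: Sequence[float],
    seed: int,
    mean_depth: float = 25.0,
    isoforms: Mapping[str, set] | None = None,
    cell_ids: Sequence[str] | None = None,
) -> JunctionTable:
    """Junction counts from per-cell isoform mixture weights.

    ``weights[i]`` is the fraction of cell i's junction reads supporting the
    first isoform (CGRP by default); counts are Poisson with total mean
    ``mean_depth`` split by the weight.
    """
    weights = np.asarray(weights, dtype=float)
    if np.any(weights < 0) or np.any(weights > 1):
        raise ValueError("mixture weights must lie in [0, 1]")
    isoforms = {k: set(v) for k, v in (isoforms or CALCA_ISOFORMS).items()}
    names = list(isoforms)
    if len(names) != 2:
        raise ValueError("exactly two isoforms expected")
    (j1,) = (sorted(isoforms[names[0]])[0],)
    (j2,) = (sorted(isoforms[names[1]])[0],)
    rng = np.random.default_rng(seed)
    c1 = rng.poisson(mean_depth * weights)
    c2 = rng.poisson(mean_depth * (1 - weights))
    if cell_ids is None:
        cell_ids = [f"cell_{i:03d}" for i in range(len(weights))]
    counts = pd.DataFrame({j1: c1, j2: c2}, index=pd.Index(cell_ids, name="cell_id"))
    return JunctionTable(counts=counts, isoforms=isoforms)


def simulate_atlas(
    design: pd.DataFrame,
    n_cells: Mapping[str, int],
    seed: int,
    n_background: int = 40,
) -> ExpressionMatrix:
    """Reference atlas with designed receptor-expression fractions.

    ``design`` is receptor genes × cell types of detection probabilities.
    Background housekeeping genes (always detected in every type) supply a
    realistic library so CPM values are sensible.
    """
    bg_genes = [f"Hk{i:02d}" for i in range(n_background)]
    genes = list(design.index) + bg_genes
    p = pd.DataFrame(0.0, index=genes, columns=design.columns)
    p.loc[design.index] = design
    p.loc[bg_genes] = 1.0
    log_mean = pd.Series(1.0, index=pd.Index(genes))
    log_mean.loc[bg_genes] = 3.0
    spec = SimulationSpec(
        n_cells=dict(n_cells),
        detection_p=p,
        log_mean=log_mean,
        log_sd=pd.Series(0.5, index=p.index),
        seed=seed,
        dataset="atlas",
    )
    return simulate_cells(spec)


def simulate_tumor(
    spec: SimulationSpec,
    reference: DetectionMatrix,
    seed_cell: str,
    n_tumor_cells: int = 330,
    flip_rate: float = 0.05,
    seed: int | None = None,
) -> ExpressionMatrix:
    """Tumor cells that amplify one reference cell's panel profile.

    Each tumor cell copies the seed cell's binary panel profile with
    per-gene flip probability ``flip_rate``; expression magnitudes and
    counts are then drawn as in :func:`simulate_cells`. Non-panel genes in
    the spec keep their usual detection probabilities (first cell type's
    column).
    """
    if seed_cell not in reference.cells:
        raise ValueError(f"seed cell {seed_cell!r} not present in reference")
    profile = reference.calls[seed_cell]
    base_ct = next(iter(spec.n_cells))
    p = spec.detection_p[base_ct].copy()
    p.loc[profile.index] = np.where(profile.to_numpy(), 1 - flip_rate, flip_rate)
    tumor_spec = replace(
        spec,
        n_cells={"tumor": n_tumor_cells},
        detection_p=p.to_frame(name="tumor"),
        dataset="tumor",
        seed=spec.seed if seed is None else seed,
    )
    return simulate_cells(tumor_spec, seed=seed)


# ---------------------------------------------------------------------------
# Packaged specifications
# ---------------------------------------------------------------------------

#: Per-gene detection probabilities for the mouse peptidergic panel
#: (43 genes). Anchored values follow published per-gene percentages; the
#: rest form a realistic prevalence spectrum whose sum (the expected
#: per-cell panel count) is ~7.2.
MOUSE_PNEC_PREVALENCE: dict = {
    "Calca": 0.95, "Scg5": 0.88, "Chga": 0.80, "Chgb": 0.70, "Igf2": 0.72,
    "Pcsk1n": 0.62, "Scg2": 0.62, "Scg3": 0.55, "Cartpt": 0.34, "Ucn2": 0.13,
    "Vgf": 0.10, "Iapp": 0.07, "Calcb": 0.05, "Dbi": 0.05, "Adm": 0.04,
    "Pomc": 0.04, "Edn1": 0.03, "Agt": 0.02, "Nmb": 0.02, "Adcyap1": 0.02,
    "Igf1": 0.02, "Lhb": 0.02, "Inha": 0.02, "Inhba": 0.02, "Inhbb": 0.02,
    "Oxt": 0.02, "Crh": 0.02, "Nppa": 0.02, "Nppb": 0.02, "Nppc": 0.02,
    "Npb": 0.02, "Npff": 0.02, "Npw": 0.02, "Pnoc": 0.02, "Prok2": 0.02,
    "Gal": 0.02, "Gnrh1": 0.02, "Hcrt": 0.02, "Agrp": 0.02, "Thpo": 0.02,
    "Uts2": 0.02, "Ghrl": 0.02, "Edn3": 0.02,
}

#: Genes of the mouse panel whose orthologs are absent from the human panel.
MOUSE_SPECIFIC: tuple = (
    "Igf2", "Ucn2", "Iapp", "Dbi", "Nppb", "Nppc", "Npb", "Npff", "Pnoc",
    "Prok2", "Gnrh1", "Hcrt", "Agrp", "Thpo", "Uts2", "Oxt", "Lhb",
)

#: Human peptidergic panel (40 genes): the 26 shared with mouse plus 14
#: human-specific hormone genes. Expected per-cell count ~12.2.
HUMAN_PNEC_PREVALENCE: dict = {
    # shared with mouse (26)
    "CALCA": 0.98, "GRP": 0.93, "CHGA": 0.95, "CHGB": 0.82, "SCG2": 0.80,
    "SCG3": 0.75, "SCG5": 0.95, "PCSK1N": 0.70, "VGF": 0.50, "POMC": 0.57,
    "CARTPT": 0.04, "AGT": 0.22, "NMB": 0.20, "ADCYAP1": 0.20, "IGF1": 0.10,
    "INHA": 0.15, "INHBA": 0.25, "INHBB": 0.30, "ADM": 0.25, "CRH": 0.10,
    "GAL": 0.10, "CALCB": 0.20, "GHRL": 0.10, "EDN1": 0.18, "EDN3": 0.10,
    "NPW": 0.07, "NPPA": 0.10,
    # human-specific (14; GRP counted above is shared-by-name but treated
    # as human-panel member, so specifics below complete the 40)
    "EPO": 0.15, "REN": 0.10, "TRH": 0.10, "PRLH": 0.10, "GNRH2": 0.08,
    "UCN": 0.10, "SST": 0.15, "CGA": 0.30, "AMH": 0.08, "CCK": 0.15,
    "UTS2B": 0.10, "KNG1": 0.10, "NPS": 0.05,
}

#: marker genes with high prevalence in PNECs and near-absence elsewhere
MOUSE_MARKERS: dict = {
    "Resp18": 0.97, "Pcsk1": 0.94, "Sez6l2": 0.90, "Ascl1": 0.88, "Syp": 0.92,
}

_OTHER_TYPE_GENES: dict = {
    "club": {"Scgb1a1": 0.95, "Scgb3a2": 0.9},
    "ciliated": {"Foxj1": 0.95, "Ccdc153": 0.85},
    "basal": {"Krt5": 0.9, "Trp63": 0.8},
    "immune": {"Ptprc": 0.98, "Cd52": 0.9},
}


def _assemble_spec(
    panel_p: Mapping[str, float],
    n_cells: Mapping[str, int],
    seed: int,
    markers: Mapping[str, float] | None = None,
    other_type_genes: Mapping[str, Mapping[str, float]] | None = None,
    baseline_p: float = 0.01,
    n_background: int = 40,
    panel_name: str = "peptidergic",
) -> SimulationSpec:
    markers = markers or {}
    other_type_genes = other_type_genes or {}
    bg_genes = [f"Hk{i:02d}" for i in range(n_background)]
    genes = (
        list(panel_p)
        + [g for g in markers if g not in panel_p]
        + [g for og in other_type_genes.values() for g in og]
        + bg_genes
    )
    cell_types = list(n_cells)
    p = pd.DataFrame(baseline_p, index=pd.Index(genes), columns=cell_types)
    target = cell_types[0]
    for g, v in panel_p.items():
        p.loc[g, :] = min(baseline_p, v)  # panel genes near-absent elsewhere
        p.loc[g, target] = v
    for g, v in markers.items():
        p.loc[g, :] = baseline_p
        p.loc[g, target] = v
    for ct, og in other_type_genes.items():
        if ct in p.columns:
            for g, v in og.items():
                p.loc[g, ct] = v
    p.loc[bg_genes, :] = 1.0
    log_mean = pd.Series(1.0, index=p.index)
    log_mean.loc[bg_genes] = 3.0
    log_sd = pd.Series(0.6, index=p.index)
    log_sd.loc[bg_genes] = 0.3
    panel = GenePanel.from_genes(panel_p, name=panel_name)
    return SimulationSpec(
        n_cells=dict(n_cells),
        detection_p=p,
        log_mean=log_mean,
        log_sd=log_sd,
        seed=seed,
        panel=panel,
    )


def mouse_pnec_like_spec(
    n_pnec: int = 176,
    n_other: Mapping[str, int] | None = None,
    seed: int = 0,
) -> SimulationSpec:
    """Packaged mouse-like specification: 43-gene peptidergic panel on the
    published prevalence spectrum, PNEC markers, and four comparison cell
    types."""
    n_other = dict(
        n_other if n_other is not None else {"club": 120, "ciliated": 80, "basal": 60, "immune": 100}
    )
    n_cells = {"PNEC": n_pnec, **n_other}
    return _assemble_spec(
        MOUSE_PNEC_PREVALENCE,
        n_cells,
        seed=seed,
        markers=MOUSE_MARKERS,
        other_type_genes=_OTHER_TYPE_GENES,
        panel_name="mouse_peptidergic",
    )


def human_pnec_like_spec(n_pnec: int = 55, seed: int = 0) -> SimulationSpec:
    """Packaged human-like specification: 40-gene peptidergic panel."""
    return _assemble_spec(
        HUMAN_PNEC_PREVALENCE,
        {"PNEC": n_pnec},
        seed=seed,
        panel_name="human_peptidergic",
    )


def richness_test_assemblage(
    n_genes: int = 40, seed: int = 0, p_min: float = 0.007, p_max: float = 0.6
) -> pd.Series:
    """Detection-probability vector for richness-recovery studies.

    Probabilities are drawn log-uniformly on [p_min, p_max]. The default
    lower bound is calibrated so that, at ~176 sampling units, the expected
    fraction of genes with incidence Y_i ≥ 2 is ≈0.90: the rarest genes are
    usually seen as singletons or missed, so observed richness falls short
    of the truth and extrapolation has work to do.
    """
    rng = np.random.default_rng(seed)
    p = np.exp(rng.uniform(np.log(p_min), np.log(p_max), size=n_genes))
    genes = [f"g{i:02d}" for i in range(n_genes)]
    return pd.Series(p, index=pd.Index(genes))


def mouse_peptidergic_catalog(n_total: int = 91) -> list:
    """The full annotated mouse peptidergic catalog (panel denominator).

    The 43 expressed panel genes plus synthetic never-expressed members
    ("NpXX") padding the catalog to its annotated size; the catalog size is
    the denominator for percent-of-catalog summaries.
    """
    expressed = list(MOUSE_PNEC_PREVALENCE)
    if n_total < len(expressed):
        raise ValueError("catalog cannot be smaller than the expressed panel")
    extras = [f"Np{i:02d}" for i in range(n_total - len(expressed))]
    return expressed + extras


def shared_human_mouse_genes() -> tuple[list, list]:
    """(human panel genes, subset shared with the mouse panel by ortholog).

    Orthology here is by case-insensitive symbol against the mouse panel,
    excluding the mouse-specific genes; this reproduces the 26-of-40 overlap
    structure of the packaged panels.
    """
    mouse = {g.upper() for g in MOUSE_PNEC_PREVALENCE} - {
        g.upper() for g in MOUSE_SPECIFIC
    }
    human = list(HUMAN_PNEC_PREVALENCE)
    shared = [g for g in human if g in mouse]
    return human, shared


def builtin_lr_map(species: str = "mouse") -> tuple[LigandReceptorMap, list]:
    """Packaged ligand → receptor map and the ligands with no known receptor.

    A small, structurally faithful map: single-gene receptor units, one
    multi-subunit unit (CGRP receptor = Calcrl + Ramp1), ligands with
    several peptides (Calca) and several receptor units (Edn1), and ligands
    whose receptor is real but unexpressed in lung (Calcr, Mc2r) so orphan
    calls have something to find.
    """
    recs = [
        ("Calca", "CGRP", {"Calcrl", "Ramp1"}),
        ("Calca", "Calcitonin", {"Calcr"}),
        ("Adm", "Adrenomedullin", {"Calcrl", "Ramp2"}),
        ("Agt", "AngiotensinII", {"Agtr1a"}),
        ("Pomc", "ACTH", {"Mc2r"}),
        ("Pomc", "beta-endorphin", {"Oprm1"}),
        ("Nmb", "NeuromedinB", {"Nmbr"}),
        ("Edn1", "Endothelin1", {"Ednra"}),
        ("Edn1", "Endothelin1", {"Ednrb"}),
        ("Igf1", "IGF1", {"Igf1r"}),
        ("Gal", "Galanin", {"Galr1"}),
        ("Crh", "CRH", {"Crhr1"}),
    ]
    no_receptor = ["Cartpt", "Pcsk1n", "Chga", "Scg5"]
    if species == "human":
        recs = [(l.upper(), p, {g.upper() for g in u}) for l, p, u in recs]
        no_receptor = [g.upper() for g in no_receptor]
    lr = LigandReceptorMap(
        records=[LRRecord(l, p, frozenset(u)) for l, p, u in recs]
    )
    return lr, no_receptor


def builtin_atlas_design() -> pd.DataFrame:
    """Receptor-expression design mimicking a lung atlas plus the two
    NEB-innervating sensory-neuron types, which receive the most signals."""
    receptors = [
        "Calcrl", "Ramp1", "Ramp2", "Calcr", "Agtr1a", "Mc2r", "Oprm1",
        "Nmbr", "Ednra", "Ednrb", "Igf1r", "Galr1", "Crhr1",
    ]
    cell_types = ["PSN4", "PSN7", "club", "goblet", "basal", "pericyte", "immune"]
    d = pd.DataFrame(0.01, index=pd.Index(receptors), columns=cell_types)
    # sensory neurons express most receptors
    for g in ["Calcrl", "Ramp1", "Ramp2", "Agtr1a", "Oprm1", "Nmbr", "Igf1r",
              "Galr1", "Crhr1", "Ednra"]:
        d.loc[g, ["PSN4", "PSN7"]] = [0.5, 0.6]
    # scattered epithelial / stromal / immune targets
    d.loc["Calcrl", ["goblet", "immune"]] = [0.3, 0.25]
    d.loc["Ramp1", ["goblet", "immune"]] = [0.3, 0.25]
    d.loc["Agtr1a", "pericyte"] = 0.4
    d.loc["Ednra", "pericyte"] = 0.5
    d.loc["Ednrb", "pericyte"] = 0.35
    d.loc["Igf1r", "basal"] = 0.2
    # receptors with no lung expression anywhere: Calcr, Mc2r stay at 0
    d.loc[["Calcr", "Mc2r"], :] = 0.0
    return d
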