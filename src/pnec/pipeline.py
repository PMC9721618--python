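"""End-to-end run orchestration: plain files plus a manifest.

A run executes the requested stages in dependency order
(simulate → normalize → markers → repertoire → saturate → targets →
isoforms → carcinoid), each stage reading its inputs from the output
directory, so any single stage can be re-run from cached upstream
artifacts and reproduce the full-run outputs. Every tabular output starts
with a comment line carrying the configuration hash and seed; the manifest
echoes the configuration verbatim.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import carcinoid as carcinoid_mod
from . import io as io_mod
from . import isoforms as isoforms_mod
from . import markers as markers_mod
from . import repertoire as repertoire_mod
from . import saturation as saturation_mod
from . import simulate as simulate_mod
from . import targets as targets_mod

log = logging.getLogger("pnec")

STAGES = (
    "simulate",
    "normalize",
    "markers",
    "repertoire",
    "saturate",
    "targets",
    "isoforms",
    "carcinoid",
)


@dataclass
class RunConfig:
    """Validated run configuration."""

    outdir: Path
    seed: int = 0
    stages: list = field(default_factory=lambda: list(STAGES))
    n_pnec: int = 176
    n_boot: int = 200
    detection_threshold: float = 0.0
    detection_statistic: str = "counts"
    frac_min: float = 0.10
    min_reads: int = 1
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.outdir = Path(self.outdir)
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stage(s): {unknown}; valid stages: {list(STAGES)}")
        repertoire_mod.DetectionPolicy(self.detection_statistic, self.detection_threshold)
        if not (0 < self.frac_min <= 1):
            raise ValueError("frac_min must lie in (0, 1]")
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "outdir" not in raw:
            raise ValueError("config must set 'outdir'")
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        return cls(**known, raw=raw)  # type: ignore[arg-type]

    def config_hash(self) -> str:
        payload = {
            k: getattr(self, k)
            for k in (
                "seed", "stages", "n_pnec", "n_boot", "detection_threshold",
                "detection_statistic", "frac_min", "min_reads",
            )
        }
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def policy(self) -> repertoire_mod.DetectionPolicy:
        return repertoire_mod.DetectionPolicy(
            self.detection_statistic, self.detection_threshold
        )


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig, index=True) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config={config.config_hash()} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=index)


def _write_json(obj, path: Path, config: RunConfig) -> None:
    payload = {"config": config.config_hash(), "seed": config.seed, "result": obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


def _load_matrix(config: RunConfig) -> io_mod.ExpressionMatrix:
    outdir = config.outdir
    matrix = outdir / "matrix.mtx"
    if not matrix.exists():
        raise FileNotFoundError(
            "no simulated matrix in output directory; run the 'simulate' stage first"
        )
    return io_mod.load_count_matrix(
        matrix,
        genes_path=outdir / "matrix.genes.tsv",
        cells_path=outdir / "matrix.barcodes.tsv",
        meta_path=outdir / "matrix.meta.tsv",
    )


def _panel(config: RunConfig) -> io_mod.GenePanel:
    path = config.outdir / "panel.csv"
    if not path.exists():
        raise FileNotFoundError(
            "no panel in output directory; run the 'simulate' stage first"
        )
    return io_mod.load_gene_panel(path)


def _detection(config: RunConfig):
    m = io_mod.normalize_lncpm(_load_matrix(config))
    pnec = m.subset_cells(m.cells_of_type("PNEC"))
    d = repertoire_mod.call_detection(pnec, _panel(config), config.policy())
    return m, pnec, d


# -- stage implementations --------------------------------------------------

def _stage_simulate(config: RunConfig) -> None:
    spec = simulate_mod.mouse_pnec_like_spec(n_pnec=config.n_pnec, seed=config.seed)
    m = simulate_mod.simulate_cells(spec)
    io_mod.write_count_matrix(m, config.outdir, stem="matrix")
    io_mod.write_gene_panel(spec.panel, config.outdir / "panel.csv")


def _stage_normalize(config: RunConfig) -> None:
    m = io_mod.normalize_lncpm(_load_matrix(config))
    _write_tsv(m.lncpm.round(6), config.outdir / "lncpm.tsv", config)


def _stage_markers(config: RunConfig) -> None:
    m = io_mod.normalize_lncpm(_load_matrix(config))
    score = markers_mod.marker_score(m, "PNEC")
    pvals = markers_mod.rank_sum_markers(m, "PNEC")
    table = score.join(pvals, how="left")
    _write_tsv(table, config.outdir / "markers.tsv", config)


def _stage_repertoire(config: RunConfig) -> None:
    m, pnec, d = _detection(config)
    prev = repertoire_mod.gene_prevalence(d, pnec)
    _write_tsv(prev, config.outdir / "prevalence.tsv", config)
    combos = repertoire_mod.enumerate_combinations(d)
    combo_table = combos.table.copy()
    combo_table["genes"] = combo_table["genes"].map(";".join)
    _write_tsv(combo_table, config.outdir / "combinations.tsv", config, index=False)
    stats = repertoire_mod.repertoire_stats(d)
    _write_json(stats.as_dict(), config.outdir / "repertoire_summary.json", config)


def _stage_saturate(config: RunConfig) -> None:
    _, _, d = _detection(config)
    T = d.n_cells
    grid = sorted(set(np.linspace(1, 2 * T, 30, dtype=int)) | {T})
    curve = saturation_mod.bootstrap_curve(
        d, grid, n_boot=config.n_boot, seed=config.seed
    )
    _write_tsv(curve.table, config.outdir / "rarefaction.tsv", config, index=False)
    _write_json(
        {
            "S_obs": curve.S_obs,
            "chao2": curve.chao2,
            "q0_hat": curve.q0_hat,
            "T": curve.T,
            "n_boot": curve.n_boot,
        },
        config.outdir / "saturation.json",
        config,
    )


def _stage_targets(config: RunConfig) -> None:
    lr, no_receptor = simulate_mod.builtin_lr_map()
    atlas = simulate_mod.simulate_atlas(
        simulate_mod.builtin_atlas_design(),
        n_cells={ct: 150 for ct in simulate_mod.builtin_atlas_design().columns},
        seed=config.seed + 7,
    )
    atlas = io_mod.normalize_lncpm(atlas)
    profile = targets_mod.receptor_profile(atlas, lr, config.policy())
    calls = targets_mod.call_targets(
        profile, frac_min=config.frac_min, ligands_without_receptors=no_receptor
    )
    _write_tsv(calls.long_table(), config.outdir / "targets.tsv", config, index=False)
    _write_tsv(
        calls.signal_counts.rename("n_signals").to_frame(),
        config.outdir / "target_counts.tsv",
        config,
    )
    _write_json(
        {
            "orphans": sorted(calls.orphans),
            "no_known_receptor": sorted(calls.no_known_receptor),
        },
        config.outdir / "orphans.json",
        config,
    )


def _stage_isoforms(config: RunConfig) -> None:
    rng = np.random.default_rng(config.seed + 11)
    n = 20
    weights = np.concatenate([
        np.ones(4), np.zeros(2), rng.uniform(0.2, 0.8, n - 6)
    ])
    jt = simulate_mod.simulate_junctions(weights, seed=config.seed + 12)
    calls = isoforms_mod.classify_isoforms(jt, min_reads=config.min_reads)
    _write_tsv(calls, config.outdir / "isoform_calls.tsv", config)
    _write_json(
        isoforms_mod.isoform_summary(calls, min_reads=config.min_reads),
        config.outdir / "isoform_summary.json",
        config,
    )


def _stage_carcinoid(config: RunConfig) -> None:
    spec = simulate_mod.human_pnec_like_spec(seed=config.seed + 21)
    ref = simulate_mod.simulate_cells(spec)
    ref_det = repertoire_mod.call_detection(ref, spec.panel, config.policy())
    seed_cell = ref_det.cells[0]
    tumor = simulate_mod.simulate_tumor(
        spec, ref_det, seed_cell, n_tumor_cells=150, seed=config.seed + 22
    )
    tumor_det = repertoire_mod.call_detection(tumor, spec.panel, config.policy())
    profile = carcinoid_mod.composite_profile(tumor_det, frac_min=0.15)
    match = carcinoid_mod.match_to_reference(
        profile, ref_det.per_cell_sets().map(set).to_dict()
    )
    n_hit, frac = carcinoid_mod.panel_coverage(profile.all_genes, set(spec.panel.genes))
    _write_json(
        {
            "seed_cell": seed_cell,
            "best_match": match.best,
            "best_score": float(match.scores.max()),
            "tie": match.tie,
            "profile_size": len(profile.all_genes),
            "panel_coverage": {"n": n_hit, "fraction": frac},
        },
        config.outdir / "carcinoid_match.json",
        config,
    )


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "normalize": _stage_normalize,
    "markers": _stage_markers,
    "repertoire": _stage_repertoire,
    "saturate": _stage_saturate,
    "targets": _stage_targets,
    "isoforms": _stage_isoforms,
    "carcinoid": _stage_carcinoid,
}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    config.outdir.mkdir(parents=True, exist_ok=True)
    ordered = [s for s in STAGES if s in config.stages]
    timings = {}
    for stage in ordered:
        t0 = time.perf_counter()
        log.info("stage %s: starting", stage)
        _STAGE_FUNCS[stage](config)
        timings[stage] = round(time.perf_counter() - t0, 3)
        log.info("stage %s: done in %.2fs", stage, timings[stage])
    manifest = {
        "config": config.raw or {"outdir": str(config.outdir), "seed": config.seed},
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": ordered,
        "timings_s": timings,
    }
    with open(config.outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
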