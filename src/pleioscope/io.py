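"""Tabular file formats, pipeline configuration and orchestration.

All tables are TSV with a header row, UTF-8, '.' decimal, ``NA`` for
missing. Marker positions are centimorgans on a per-chromosome scale
starting at 0. ``run_pipeline`` ties the stages together into one
reproducible run directory with a checksummed manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allele_split as asp
from . import cellcycle as cc
from . import network as net
from . import partition as cp
from . import preprocess as pp
from . import qtl
from .errors import ValidationError
from .simulate import (
    CELL_TYPES,
    QtlEffect,
    SimConfig,
    SimTruth,
    simulate_cells,
    simulate_cross,
    simulate_dose_series,
    simulate_ma_panel,
)

__all__ = [
    "read_cell_table",
    "write_cell_table",
    "read_genotypes",
    "write_genotypes",
    "read_marker_map",
    "write_marker_map",
    "PipelineConfig",
    "run_pipeline",
    "make_fixture",
]

_REQUIRED = ("strain", "replicate", "cell_type")
_META = {"cell_id", "strain", "replicate", "cell_type", "condition", "dose",
         "true_pseudotime", "pseudotime", "bin"}


def read_cell_table(path) -> pd.DataFrame:
    """Read and validate a cell-level trait table (TSV)."""
    table = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in _REQUIRED:
        if col not in table.columns:
            raise ValidationError(f"cell table missing required column {col!r}")
    bad = set(table["cell_type"].dropna().unique()) - set(CELL_TYPES)
    if bad:
        raise ValidationError(
            f"unknown cell_type values {sorted(bad)}; expected {CELL_TYPES}")
    for col in table.columns:
        if col in _META or col == "condition":
            continue
        if not pd.api.types.is_numeric_dtype(table[col]):
            coerced = pd.to_numeric(table[col], errors="coerce")
            bad_rows = table.index[coerced.isna() & table[col].notna()]
            if len(bad_rows):
                raise ValidationError(
                    f"non-numeric value for trait {col!r} at row {bad_rows[0] + 2}")
            table[col] = coerced
    if "cell_id" not in table.columns:
        table.insert(0, "cell_id", np.arange(len(table)))
    return table


def write_cell_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_genotypes(path) -> pd.DataFrame:
    g = pd.read_csv(path, sep="\t", index_col=0)
    g.index.name = "strain"
    return g.astype(np.int8)


def write_genotypes(genotypes: pd.DataFrame, path) -> None:
    genotypes.to_csv(path, sep="\t")


def read_marker_map(path) -> pd.DataFrame:
    mm = pd.read_csv(path, sep="\t")
    for col in ("marker", "chromosome", "position_cM"):
        if col not in mm.columns:
            raise ValidationError(f"marker map missing column {col!r}")
    return mm


def write_marker_map(marker_map: pd.DataFrame, path) -> None:
    marker_map.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# pipeline configuration
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """All stage parameters in one place; echoed verbatim into the run log.

    Every stage derives its random seed from ``seed`` via a fixed offset, so
    one master seed reproduces the whole run.
    """

    cell_table: str = ""
    genotypes: str = ""
    marker_map: str = ""
    control_strains: tuple[str, str] | None = None
    # stage toggles
    run_preprocess: bool = True
    run_scan: bool = True
    run_partition: bool = True
    run_network: bool = True
    run_cellcycle: bool = True
    run_split: bool = True
    # parameters (one home for every threshold)
    trait_missing_max: float = 0.10
    outlier_sd: float = 5.0
    scan_alpha: float = 0.05
    scan_n_perm: int = 1000
    scan_step_cM: float = 0.0
    qtl_gap_cM: float = 5.0
    qtl_dense_gap_cM: float = 2.0
    qtl_span_warning_cM: float = 17.0
    partition_alpha: float = 0.01
    rw_threshold: float = 0.2
    network_n_perm: int = 100
    n_bins: int = 16
    pseudotime_k: int = 30
    pseudotime_anchor: dict | None = None
    split_n_boot: int = 200
    ma_outlier_sd: float = 4.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        cfg = cls(**payload)
        if cfg.control_strains is not None:
            cfg.control_strains = tuple(cfg.control_strains)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the configured stages in order, writing a checksummed manifest.

    Stage order: preprocess -> scan -> partition -> network -> cellcycle ->
    allele split. A stage failure is recorded in the manifest and later
    stages that depend on it are skipped.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "files": {}}

    def save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
        manifest["files"][name] = _sha256(path)

    table = read_cell_table(config.cell_table)
    genotypes = read_genotypes(config.genotypes) if config.genotypes else None
    marker_map = read_marker_map(config.marker_map) if config.marker_map else None

    hits = clusters = partitions = None
    try:
        if config.run_preprocess:
            table, report = pp.preprocess_pipeline(
                table, control_strains=config.control_strains,
                trait_missing_max=config.trait_missing_max,
                outlier_sd=config.outlier_sd)
            save(table, "cells_preprocessed.tsv")
            (out / "preprocess_log.json").write_text(json.dumps(dict(
                boxcox_lambda=report.boxcox_lambda,
                heritability=report.heritability,
                cells_dropped=report.cells_dropped,
                traits_dropped=report.traits_dropped,
                log=report.log), indent=1))
            manifest["files"]["preprocess_log.json"] = _sha256(out / "preprocess_log.json")
            manifest["stages"]["preprocess"] = "ok"
    except Exception as exc:  # noqa: BLE001 - recorded, run continues
        manifest["stages"]["preprocess"] = f"failed: {exc}"

    if config.run_scan and genotypes is not None and marker_map is not None:
        try:
            phenos = qtl.strain_phenotypes(table)
            hits = qtl.scan_all(
                phenos, genotypes, marker_map,
                n_perm=config.scan_n_perm, alpha=config.scan_alpha,
                seed=config.seed + 1, step_cM=config.scan_step_cM)
            save(hits, "qtl_hits.tsv")
            clusters = qtl.cluster_qtl(hits, gap_cM=config.qtl_gap_cM,
                                       span_warning_cM=config.qtl_span_warning_cM)
            save(clusters, "qtl_clusters.tsv")
            manifest["stages"]["scan"] = "ok"
        except Exception as exc:  # noqa: BLE001
            manifest["stages"]["scan"] = f"failed: {exc}"

    if config.run_partition:
        try:
            partitions = cp.partition_all(table, alpha=config.partition_alpha)
            save(partitions, "partitions.tsv")
            null = cp.pseudo_strain_null(table, seed=config.seed + 2,
                                         alpha=config.partition_alpha,
                                         m=partitions.attrs.get("m"))
            save(null, "partitions_pseudostrain_null.tsv")
            manifest["stages"]["partition"] = "ok"
        except Exception as exc:  # noqa: BLE001
            manifest["stages"]["partition"] = f"failed: {exc}"

    if config.run_network and partitions is not None and clusters is not None:
        try:
            calls = net.classify_pairs(partitions, clusters,
                                       rw_threshold=config.rw_threshold)
            save(calls, "pleiotropy_calls.tsv")
            summary = net.enrichment_summary(calls, rw_threshold=config.rw_threshold)
            (out / "enrichment.json").write_text(json.dumps(summary, indent=1))
            manifest["files"]["enrichment.json"] = _sha256(out / "enrichment.json")
            wcc_rows = []
            for ct in sorted(set(partitions["cell_type"])):
                traits, W = net.rw_matrix(partitions, ct)
                res = net.network_permutation_null(
                    W, n_perm=config.network_n_perm, seed=config.seed + 3)
                for t, w in zip(traits, res.observed):
                    wcc_rows.append(dict(cell_type=ct, trait=t, wcc=w,
                                         null_mean=res.null.mean()))
            save(pd.DataFrame(wcc_rows), "network_wcc.tsv")
            manifest["stages"]["network"] = "ok"
        except Exception as exc:  # noqa: BLE001
            manifest["stages"]["network"] = f"failed: {exc}"

    if config.run_cellcycle:
        try:
            frames = []
            for ct in sorted(table["cell_type"].unique()):
                anchor = config.pseudotime_anchor
                if anchor is None:
                    first_trait = next(c for c in table.columns
                                       if c not in _META
                                       and table.loc[table.cell_type == ct, c].notna().all())
                    anchor = {first_trait: "min"}
                pt = cc.infer_pseudotime(table, ct, anchor, k=config.pseudotime_k)
                binned = cc.bin_cells(table[table["cell_type"] == ct], pt,
                                      n_bins=config.n_bins)
                series = cc.per_bin_partition(binned, n_bins=config.n_bins,
                                              alpha=config.partition_alpha)
                frames.append(series)
            save(pd.concat(frames, ignore_index=True), "bin_series.tsv")
            manifest["stages"]["cellcycle"] = "ok"
        except Exception as exc:  # noqa: BLE001
            manifest["stages"]["cellcycle"] = f"failed: {exc}"

    if (config.run_split and clusters is not None and genotypes is not None
            and len(clusters)):
        try:
            res = asp.allele_split_analysis(
                table, genotypes, clusters, hits, marker_map,
                n_boot=config.split_n_boot, seed=config.seed + 4,
                alpha=config.partition_alpha)
            save(res, "allele_splits.tsv")
            manifest["stages"]["split"] = "ok"
        except Exception as exc:  # noqa: BLE001
            manifest["stages"]["split"] = f"failed: {exc}"

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


# --------------------------------------------------------------------------
# bundled miniature fixtures
# --------------------------------------------------------------------------

def make_fixture(name: str, out_dir, seed: int = 20260101):
    """Deterministic miniature datasets for demos and CI.

    ``cross-demo``: 60 strains x 30 markers x 200 cells x 12 traits with one
    QTL of each mechanism. ``ma-demo``: 20 MA lines (2 altered) x 300 cells.
    ``dose-demo``: 3 doses with growing correlation shifts, paired controls.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if name == "cross-demo":
        base = np.eye(4)
        base[2, 3] = base[3, 2] = 0.5
        config = SimConfig(
            n_strains=60, n_markers=30, n_chromosomes=5, chrom_length_cM=100.0,
            n_traits_per_celltype=(4, 4, 4), cells_per_strain=200,
            n_replicates=3, strain_var=0.05, plate_effect_sd=0.1, seed=seed,
            base_within_corr={ct: base for ct in CELL_TYPES},
            qtl_spec=[
                QtlEffect("m3", "vertical", ("l001", "l002"), beta=0.2,
                          loadings=(1.0, 1.0)),
                QtlEffect("m9", "direct_horizontal", ("l003", "l004"), beta=0.3),
                QtlEffect("m15", "corr_modifying", ("s003", "s004"),
                          rho0=0.1, delta=0.6),
            ],
            cellcycle_spec={"u001": ("monotone", 1.0), "s001": ("monotone", 1.0),
                            "l001": ("bump", 0.5)},
        )
        genotypes, marker_map = simulate_cross(config)
        cells, truth = simulate_cells(genotypes, config)
        write_genotypes(genotypes, out / "genotypes.tsv")
        write_marker_map(marker_map, out / "marker_map.tsv")
        write_cell_table(cells, out / "cells.tsv")
        truth.to_json(out / "truth.json")
        return genotypes, marker_map, cells, truth
    if name == "ma-demo":
        config = SimConfig(
            n_strains=20, n_traits_per_celltype=(0, 0, 4), cells_per_strain=300,
            n_replicates=1, strain_var=0.0, plate_effect_sd=0.0, seed=seed,
        )
        cells, truth = simulate_ma_panel(config, n_lines=20, n_altered=2,
                                         delta=0.6)
        write_cell_table(cells, out / "cells.tsv")
        truth.to_json(out / "truth.json")
        return cells, truth
    if name == "dose-demo":
        config = SimConfig(
            n_strains=15, n_traits_per_celltype=(0, 0, 4), cells_per_strain=200,
            n_replicates=1, strain_var=0.05, plate_effect_sd=0.0, seed=seed,
        )
        cells, truth = simulate_dose_series(
            config, doses=[8.5, 25.0, 100.0],
            corr_shift_per_dose={("l001", "l002"): [0.05, 0.15, 0.3]})
        write_cell_table(cells, out / "cells.tsv")
        truth.to_json(out / "truth.json")
        return cells, truth
    raise ValidationError(f"unknown fixture {name!r}")
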