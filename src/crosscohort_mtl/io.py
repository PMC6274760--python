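"""Reading and writing cohorts, configs, reports and run manifests.

Expression matrices travel as tab-delimited text (rows = gene symbols,
header = sample IDs, mirroring GEO series-matrix conventions), metadata as
CSV, experiment configuration as YAML and result tables as tidy long-format
CSV.  Every randomized pipeline stage records its seed in a run manifest so
a run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .data import META_COLUMNS, CohortDataset

logger = logging.getLogger("crosscohort_mtl")

#: columns of the tidy long-format report CSV
REPORT_COLUMNS = ("algorithm", "subset", "replicate", "metric", "value")


def setup_logging(log_path: str | Path | None = None, level: int = logging.INFO) -> None:
    """Attach a timestamped stream (and optionally file) handler."""
    fmt = logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    logger.setLevel(level)
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        sh = logging.StreamHandler()
        sh.setFormatter(fmt)
        logger.addHandler(sh)
    if log_path is not None:
        fh = logging.FileHandler(log_path)
        fh.setFormatter(fmt)
        logger.addHandler(fh)


def read_cohort(expr_path: str | Path, meta_path: str | Path,
                cohort_id: str | None = None) -> CohortDataset:
    """Load one cohort from a TSV expression matrix and a CSV metadata table.

    The expression file has a header row of sample IDs and a first column of
    gene symbols; metadata must provide ``sample_id, diagnosis, sex, age,
    pmi, ph``.  Expression columns are reordered to metadata row order.
    Duplicate gene symbols and sample-ID mismatches raise ``ValueError``.
    """
    expr_path, meta_path = Path(expr_path), Path(meta_path)
    expr = pd.read_csv(expr_path, sep="\t", index_col=0)
    try:
        expr = expr.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{expr_path}: non-numeric expression cells ({exc})")
    meta = pd.read_csv(meta_path, dtype={"sample_id": str})
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"{meta_path}: metadata missing columns {missing}")
    expr.columns = expr.columns.astype(str)
    cid = cohort_id if cohort_id is not None else expr_path.stem.replace("_expr", "")
    return CohortDataset(cid, expr, meta)


def write_cohort(cohort: CohortDataset, out_dir: str | Path) -> tuple[Path, Path]:
    """Write one cohort as ``<id>_expr.tsv`` + ``<id>_meta.csv``; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    expr_path = out_dir / f"{cohort.cohort_id}_expr.tsv"
    meta_path = out_dir / f"{cohort.cohort_id}_meta.csv"
    expr = cohort.expr.copy()
    expr.index.name = "gene"
    expr.to_csv(expr_path, sep="\t", float_format="%.12g")
    cohort.meta.to_csv(meta_path, index=False)
    return expr_path, meta_path


def write_report(report: pd.DataFrame, path: str | Path) -> Path:
    """Write a result table as tidy long-format CSV.

    Accepts either an already-long table with columns
    ``(algorithm, subset, replicate, metric, value)`` or any table holding
    those columns plus extras (extras are kept).  An empty report produces a
    header-only file.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if report.empty and not set(REPORT_COLUMNS) <= set(report.columns):
        report = pd.DataFrame(columns=list(REPORT_COLUMNS))
    missing = [c for c in REPORT_COLUMNS if c not in report.columns]
    if missing:
        raise ValueError(f"report missing required columns {missing}")
    ordered = [c for c in REPORT_COLUMNS] + [
        c for c in report.columns if c not in REPORT_COLUMNS
    ]
    report.loc[:, ordered].to_csv(path, index=False, float_format="%.12g")
    return path


def read_report(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_config(path: str | Path) -> dict:
    """Load an experiment configuration from YAML."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    return cfg


@dataclass
class ExperimentConfig:
    """Validated experiment settings shared by evaluation and robustness runs."""

    algorithms: list[str]
    grids: dict[str, dict] = field(default_factory=dict)
    n_folds: int = 5
    n_repetitions: int = 10
    n_bootstrap: int = 100
    rng_seed: int = 0
    subset_sizes: list[int] = field(default_factory=lambda: [2, 3, 4, 5])

    def __post_init__(self) -> None:
        if not self.algorithms:
            raise ValueError("algorithm list is empty")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        for alg, grid in self.grids.items():
            if isinstance(grid, dict):
                if any(len(v) == 0 for v in grid.values()):
                    raise ValueError(f"empty hyperparameter grid for {alg}")
            elif len(grid) == 0:
                raise ValueError(f"empty hyperparameter grid for {alg}")

    @classmethod
    def from_dict(cls, cfg: dict) -> "ExperimentConfig":
        known = {f for f in cls.__dataclass_fields__}
        return cls(**{k: v for k, v in cfg.items() if k in known})


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(out_dir: str | Path, config: dict, seeds: dict,
                   stage_timings: dict | None = None,
                   paths: dict | None = None) -> Path:
    """Write the run manifest (config hash, seeds, package version, timings)."""
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package_version": __version__,
        "written_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": config,
        "config_hash": config_hash(config),
        "seeds": seeds,
        "stage_timings_s": stage_timings or {},
        "paths": {k: str(v) for k, v in (paths or {}).items()},
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path
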