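"""Readers, writers and the pipeline runner.

Block tables travel as comma-separated UTF-8 CSV with a mandatory header;
spatial weights as plain-text GAL adjacency lists.  Every JSON artifact the
pipeline writes embeds the package version, a hash of the run configuration
and the master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .likelihoods import FAMILIES, ModelSpec, fit, predict_expected_counts
from .synthetic_data import SimulationConfig, SpatialWeights, simulate_dataset
from .validation import compare_models

logger = logging.getLogger("blockcount")

REQUIRED_COLUMNS = ("block_id", "y", "n_tests", "x1", "x2", "x3")
OPTIONAL_COLUMNS = ("row", "col", "gamma_true", "gamma_zero_true")


class BlockTableError(ValueError):
    """Malformed block table."""


def _fail(row, column, message):
    raise BlockTableError(f"row {row}, column {column!r}: {message}")


def validate_block_table(df: pd.DataFrame) -> pd.DataFrame:
    """Type-check and validate a block table, returning a typed copy.

    Counts must be non-negative integers, offsets integers >= 1 (the log
    offset in the link function is undefined at zero), covariates finite,
    block ids unique.  Errors name the offending row and column.
    """
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise BlockTableError(f"missing required column {col!r}")
    out = df.copy().reset_index(drop=True)
    dup = out["block_id"].duplicated()
    if dup.any():
        _fail(int(np.argmax(dup.to_numpy())), "block_id", "duplicated block id")
    for col, minimum in (("y", 0), ("n_tests", 1)):
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = vals.isna() | (vals != np.round(vals))
        if bad.any():
            _fail(int(np.argmax(bad.to_numpy())), col, "not an integer")
        if (vals < minimum).any():
            _fail(
                int(np.argmax((vals < minimum).to_numpy())),
                col,
                f"must be >= {minimum}"
                + (" (offset enters the model as ln N)" if col == "n_tests" else ""),
            )
        out[col] = vals.astype(int)
    for col in ("x1", "x2", "x3"):
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = ~np.isfinite(vals.to_numpy(dtype=float))
        if bad.any():
            _fail(int(np.argmax(bad)), col, "not a finite number")
        out[col] = vals.astype(float)
    out["block_id"] = out["block_id"].astype(str)
    logger.info(
        "block table: %d blocks, %.1f%% zero counts",
        len(out),
        100.0 * float(np.mean(out["y"] == 0)),
    )
    return out


def read_block_table(path) -> pd.DataFrame:
    """Read and validate a block table CSV."""
    df = pd.read_csv(path)
    return validate_block_table(df)


def write_block_table(df: pd.DataFrame, path):
    cols = [c for c in REQUIRED_COLUMNS if c in df.columns] + [
        c for c in OPTIONAL_COLUMNS if c in df.columns
    ]
    df.to_csv(path, columns=cols, index=False)


# ---------------------------------------------------------------------------
# GAL weights
# ---------------------------------------------------------------------------


def write_weights_gal(weights: SpatialWeights, path, name="blocks"):
    """Write adjacency in GAL format: header then id/degree + neighbour lines."""
    lines = [f"0 {weights.n} {name} block_id"]
    for i in weights.ids:
        nbrs = weights.neighbours.get(i, [])
        lines.append(f"{i} {len(nbrs)}")
        lines.append(" ".join(str(j) for j in nbrs))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_weights_gal(path, ids: Optional[Sequence] = None) -> SpatialWeights:
    """Read GAL adjacency; if ``ids`` is given, align and verify coverage.

    Ids present in the file but absent from ``ids`` (or vice versa) are an
    error naming the id.  Asymmetric adjacency is rejected.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln.rstrip("\n") for ln in text.splitlines()]
    if not lines:
        raise ValueError("empty GAL file")
    header = lines[0].split()
    if len(header) < 2:
        raise ValueError("malformed GAL header")
    n = int(header[1])
    nbrs = {}
    order = []
    pos = 1
    for _ in range(n):
        if pos >= len(lines):
            raise ValueError("truncated GAL file")
        head = lines[pos].split()
        if len(head) != 2:
            raise ValueError(f"malformed GAL record at line {pos + 1}")
        bid, deg = head[0], int(head[1])
        neigh = lines[pos + 1].split() if deg > 0 else []
        if deg > 0:
            pos += 2
        else:
            # degree-0 rows may or may not carry an (empty) neighbour line
            pos += 2 if pos + 1 < len(lines) and lines[pos + 1].strip() == "" else 1
        if len(neigh) != deg:
            raise ValueError(f"degree mismatch for id {bid!r}")
        order.append(bid)
        nbrs[bid] = neigh
    weights = SpatialWeights(ids=order, neighbours=nbrs)  # validates symmetry
    if ids is not None:
        ids = [str(i) for i in ids]
        missing = set(ids) - set(order)
        if missing:
            raise ValueError(f"table id {sorted(missing)[0]!r} absent from GAL file")
        extra = set(order) - set(ids)
        if extra:
            raise ValueError(f"GAL id {sorted(extra)[0]!r} absent from the table")
        weights = weights.subset(ids)
    return weights


# ---------------------------------------------------------------------------
# configuration and pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (simulate -> fit -> validate)."""

    out_dir: str = "blockcount_run"
    data: Optional[str] = None
    weights: Optional[str] = None
    simulate: Optional[dict] = None
    families: Sequence[str] = FAMILIES
    random_effects: bool = True
    quadrature_points: int = 7
    jackknife: Optional[str] = None
    max_category: int = 5
    moran: bool = True
    seed: int = 0
    verbose: bool = False

    def __post_init__(self):
        for fam in self.families:
            if fam not in FAMILIES:
                raise ValueError(f"unknown family {fam!r}")
        if self.data is not None and not Path(self.data).exists():
            raise FileNotFoundError(self.data)
        if self.weights is not None and not Path(self.weights).exists():
            raise FileNotFoundError(self.weights)


def load_run_config(path) -> RunConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def load_simulation_config(path) -> SimulationConfig:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    return simulation_config_from_dict(raw)


def simulation_config_from_dict(raw: dict) -> SimulationConfig:
    cfg = SimulationConfig(**raw)
    return cfg


def simulation_config_to_dict(cfg: SimulationConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["grid_shape"] = list(cfg.grid_shape)
    d["covariate_means"] = list(cfg.covariate_means)
    d["covariate_sds"] = list(cfg.covariate_sds)
    d["covariate_corr"] = [list(r) for r in np.asarray(cfg.covariate_corr)]
    return d


def _config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _provenance(config_dict, seed):
    return {
        "package_version": __version__,
        "config_hash": _config_hash(config_dict),
        "seed": seed,
    }


def write_json(obj, path, provenance=None):
    payload = dict(obj)
    if provenance:
        payload["provenance"] = provenance
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return str(o)
    Path(path).write_text(
        json.dumps(payload, indent=2, default=_default, allow_nan=True) + "\n",
        encoding="utf-8",
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run simulate -> fit -> validate, writing artifacts under ``out_dir``.

    Returns a dict of artifact paths.  Deterministic under the master seed
    for every stochastic stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_dict = dataclasses.asdict(config)
    prov = _provenance(cfg_dict, config.seed)
    artifacts = {}

    if config.data is None:
        sim_overrides = dict(config.simulate or {})
        sim_overrides.setdefault("seed", config.seed)
        sim_cfg = simulation_config_from_dict(sim_overrides)
        logger.info("simulating %d blocks (family=%s)", sim_cfg.n_blocks, sim_cfg.family)
        table, weights = simulate_dataset(sim_cfg)
        data_path = out_dir / "data.csv"
        gal_path = out_dir / "data.gal"
        write_block_table(table, data_path)
        write_weights_gal(weights, gal_path)
        artifacts["data"] = str(data_path)
        artifacts["weights"] = str(gal_path)
        table = validate_block_table(table)
    else:
        table = read_block_table(config.data)
        artifacts["data"] = config.data
        weights = None
        if config.weights is not None:
            weights = read_weights_gal(config.weights, ids=table["block_id"])
            artifacts["weights"] = config.weights
    if config.moran and weights is None:
        raise ValueError(
            "Moran's I requested but no weights available: pass a GAL file "
            "or let the pipeline simulate one"
        )

    report = compare_models(
        table,
        families=config.families,
        random_effects=config.random_effects,
        weights=weights if config.moran else None,
        jackknife_mode=config.jackknife,
        seed=config.seed,
        max_category=config.max_category,
        spec_kwargs={"quadrature_points": config.quadrature_points},
    )
    for fam, res in report.fits.items():
        path = out_dir / f"fit_{fam}.json"
        write_json(res.to_dict(), path, provenance=prov)
        artifacts[f"fit_{fam}"] = str(path)
    report_path = out_dir / "report.json"
    write_json(report.to_dict(), report_path, provenance=prov)
    artifacts["report"] = str(report_path)
    for fam, fc in report.frequency_tables.items():
        path = out_dir / f"frequencies_{fam}.csv"
        fc.table.to_csv(path, index=False)
        artifacts[f"frequencies_{fam}"] = str(path)
    logger.info("pipeline complete; AIC winner: %s", report.best_family)
    return artifacts
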