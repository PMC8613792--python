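"""Tabular readers/writers and run configuration."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import InputError
from .matrix import ScoreMatrix
from .ordination import DEFAULT_SEED, OrdinationConfig, OrdinationResult
from .parsing import parse_number

logger = logging.getLogger("rapbeef")

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Whole-pipeline configuration; one seed fans out to every stream."""

    seed: int = DEFAULT_SEED
    n_anchor_pairs: int = 1
    n_restarts: int = 4
    mds_max_iter: int = 1000
    mds_tolerance: float = 1e-9
    stress_formula: str = "sstress"
    mc_reps: int = 25
    mc_noise: str = "uniform"
    mc_half_width: float = 0.25
    w_stop_threshold: float = 0.5
    locale: str = "point"
    output_dir: str = "."

    def ordination(self) -> OrdinationConfig:
        return OrdinationConfig(
            n_anchor_pairs=self.n_anchor_pairs,
            n_restarts=self.n_restarts,
            mds_max_iter=self.mds_max_iter,
            mds_tolerance=self.mds_tolerance,
            seed=self.seed,
            stress_formula=self.stress_formula,
        )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls().to_dict())
        if unknown:
            raise InputError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


def read_scores(path: str | Path, dimensions: dict[str, str] | None = None) -> ScoreMatrix:
    """Read a scores.csv (header of attribute ids, one row per entity).

    Cells must be integers 1-6; offending cells are reported by entity and
    column. ``dimensions`` optionally labels each attribute's dimension
    (defaults to the packaged indicator battery when ids match, else
    "multi").
    """
    frame = pd.read_csv(path, index_col=0)
    if frame.empty and frame.columns.empty:
        raise InputError(f"{path}: no score columns found")
    bad = []
    for e in frame.index:
        for c in frame.columns:
            v = frame.at[e, c]
            if pd.isna(v) or float(v) != int(float(v)) or not 1 <= float(v) <= 6:
                bad.append((str(e), str(c), v))
    if bad:
        raise InputError(f"{path}: invalid score cell(s): {bad}")
    if dimensions is None:
        from .indicators import load_definitions

        defs = load_definitions()
        if all(c in defs for c in frame.columns):
            dimensions = {c: defs[c].dimension for c in frame.columns}
    return ScoreMatrix.from_scores(frame.astype(float), dimensions=dimensions)


def read_values(path: str | Path, locale: str = "point") -> pd.DataFrame:
    """Read a values.csv of raw indicator values under a decimal locale."""
    frame = pd.read_csv(path, index_col=0, dtype=str)
    return frame.map(lambda v: parse_number(v, locale))


def read_ratings(path: str | Path) -> pd.DataFrame:
    """Read a Delphi ratings.csv (rows = raters, columns = items)."""
    frame = pd.read_csv(path, index_col=0)
    return frame.astype(int)


def write_report(results: dict, path: str | Path, config: RunConfig | None = None) -> None:
    """Write the versioned JSON report; ``results`` maps section name to a
    dict-like payload (ordination/leverage/Monte Carlo/Delphi outputs)."""
    if not results:
        raise InputError("no results to report")
    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "package_version": __version__,
    }
    if config is not None:
        payload["config"] = config.to_dict()
        payload["config_digest"] = config.digest()
        payload["seed"] = config.seed
    payload["results"] = results
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
    logger.info("wrote report %s (schema v%d)", path, REPORT_SCHEMA_VERSION)


def write_kite_csv(results: dict[str, OrdinationResult], path: str | Path) -> None:
    """Export (entity, dimension, index) rows for external kite plotting."""
    rows = [
        {"entity": e, "dimension": dim, "index": float(res.index[e])}
        for dim, res in results.items()
        for e in res.index.index
    ]
    if not rows:
        raise InputError("no ordination results to export")
    pd.DataFrame(rows).to_csv(path, index=False)
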