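"""CSV/TSV/JSON readers and writers plus run-metadata capture.

The CSV boundary uses the printed units of the source tables (LMDR in %, MMR
per 100,000 live births, obesity in % adults); no unit conversion happens on
read beyond sanity checks. Below-detection cells written as ``<value`` are
parsed to 0 so the log-transform floor rule handles them, with a
machine-readable warning recorded.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .stats import ALL_COLUMNS, DEVELOPMENT_CLASS, NATION, NUMERIC_COLUMNS

_PERCENT_COLUMNS = (
    "lmdr_1990",
    "obesity_1990",
    "obesity_2016",
    "insufficient_physical_activity",
)
_BELOW_DETECTION = re.compile(r"^\s*<\s*([0-9.eE+-]+)\s*$")


@dataclass
class RunMetadata:
    """Provenance sidecar attached to every output artifact."""

    version: str = __version__
    seed: "int | None" = None
    config_hash: "str | None" = None
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )
    input_checksums: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def add_input(self, path: "str | Path") -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.input_checksums[str(path)] = digest

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "created": self.created,
            "input_checksums": self.input_checksums,
            "warnings": self.warnings,
            **self.extra,
        }

    def write(self, path: "str | Path") -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def config_hash(config: dict) -> str:
    """Stable sha256 of a JSON-serializable configuration mapping."""
    canonical = json.dumps(config, sort_keys=True, default=_jsonable)
    return hashlib.sha256(canonical.encode()).hexdigest()


def read_country_csv(path: "str | Path") -> pd.DataFrame:
    """Read a country table CSV into the canonical schema.

    Headers are matched case-insensitively. Malformed numeric cells become
    missing (with the row recorded); ``<value`` cells are below-detection
    markers parsed to 0 for the downstream log-floor rule. Percent columns
    outside [0, 100] and negative MMRs are set missing with a warning. All
    warnings are machine-readable in ``result.attrs["warnings"]``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if raw.empty and raw.columns.size == 0:
        raise ValueError(f"{path}: empty file, no header row")
    warnings: list = []

    rename = {}
    known = {c.lower(): c for c in ALL_COLUMNS}
    for col in raw.columns:
        key = col.strip().lower()
        if key in known:
            rename[col] = known[key]
        else:
            warnings.append({"kind": "unknown_column", "column": col})
    raw = raw.rename(columns=rename)
    if NATION not in raw.columns:
        if len(raw.columns) == 1 and ";" in raw.columns[0]:
            raise ValueError(f"{path}: header looks ';'-delimited; expected comma-delimited CSV")
        raise ValueError(f"{path}: required column 'nation' not found in header")
    missing_cols = [c for c in NUMERIC_COLUMNS if c not in raw.columns]
    for col in missing_cols:
        warnings.append({"kind": "missing_column", "column": col})

    table = pd.DataFrame({NATION: raw[NATION].astype(str).str.strip()})
    if table[NATION].duplicated().any():
        dupes = table[NATION][table[NATION].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate nation labels {dupes}")

    for col in NUMERIC_COLUMNS:
        if col not in raw.columns:
            table[col] = np.nan
            continue
        parsed = np.full(len(raw), np.nan)
        for i, cell in enumerate(raw[col]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            text = str(cell).strip()
            if text == "" or text.lower() in ("na", "nan", "none"):
                continue
            m = _BELOW_DETECTION.match(text)
            if m:
                parsed[i] = 0.0  # handled by the log-transform floor rule
                warnings.append(
                    {"kind": "below_detection", "column": col, "row": i, "limit": float(m.group(1))}
                )
                continue
            try:
                parsed[i] = float(text)
            except ValueError:
                warnings.append({"kind": "malformed_numeric", "column": col, "row": i, "value": text})
        table[col] = parsed

    for col in _PERCENT_COLUMNS:
        bad = table[col].notna() & ((table[col] < 0) | (table[col] > 100))
        if bad.any():
            warnings.append(
                {"kind": "percent_out_of_range", "column": col, "rows": list(np.where(bad)[0])}
            )
            table.loc[bad, col] = np.nan
    bad_mmr = table["mmr_1990"].notna() & (table["mmr_1990"] < 0)
    if bad_mmr.any():
        warnings.append({"kind": "negative_mmr", "rows": list(np.where(bad_mmr)[0])})
        table.loc[bad_mmr, "mmr_1990"] = np.nan

    if DEVELOPMENT_CLASS in raw.columns:
        table[DEVELOPMENT_CLASS] = raw[DEVELOPMENT_CLASS].astype(str).str.strip().str.lower()
        table.loc[table[DEVELOPMENT_CLASS].isin(("", "nan", "na", "none")), DEVELOPMENT_CLASS] = None
    else:
        table[DEVELOPMENT_CLASS] = None
        warnings.append({"kind": "missing_column", "column": DEVELOPMENT_CLASS})

    table.attrs["warnings"] = warnings
    table.attrs["source"] = str(path)
    return table


def write_country_csv(table: pd.DataFrame, path: "str | Path") -> None:
    """Write a country table in the canonical column order."""
    cols = [c for c in ALL_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False)


def write_trajectory(result, out_dir: "str | Path", metadata: "RunMetadata | None" = None):
    """Write a TrajectoryResult as TSVs plus a JSON metadata sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    traj_path = out_dir / "trajectory.tsv"
    adult_path = out_dir / "adult_prevalence.tsv"
    result.generations.to_csv(traj_path, sep="\t", index=False)
    result.adult.to_csv(adult_path, sep="\t", index=False)
    meta = metadata or RunMetadata()
    meta.extra.setdefault("run", {}).update(result.metadata)
    meta.write(out_dir / "metadata.json")
    return traj_path, adult_path
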