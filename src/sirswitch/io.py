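"""Tabular I/O dialects and run manifests.

All tabular data are tab-separated text with '#'-prefixed comment lines;
reports are JSON.  Readers validate records and report offending data-row
numbers (1-based, comments and header excluded).
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .survival import HISTORIES, PlateCounts

__all__ = [
    "read_counts_tsv", "write_counts_tsv",
    "read_colors_tsv", "write_colors_tsv",
    "write_trajectory_tsv", "write_json", "write_manifest", "config_hash",
]

COUNTS_COLUMNS = ["concentration_uM", "history", "N_YPD", "d_YPD",
                  "N_FOA", "d_FOA"]
COLORS_COLUMNS = ["plate_id", "concentration_uM", "colony_id", "R", "G", "B"]


class TableFormatError(ValueError):
    """Malformed tabular input."""


def _read_tsv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: header mismatch, missing columns {missing}")
    return df[list(columns)]


def read_counts_tsv(path: str | Path) -> list[PlateCounts]:
    """Read a plate-counts table; validates every row."""
    df = _read_tsv(path, COUNTS_COLUMNS)
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            if float(row.N_YPD) != int(row.N_YPD) or \
                    float(row.N_FOA) != int(row.N_FOA):
                raise ValueError("colony counts must be integers")
            out.append(PlateCounts(
                concentration=float(row.concentration_uM),
                history=str(row.history),
                N_YPD=int(row.N_YPD), d_YPD=float(row.d_YPD),
                N_FOA=int(row.N_FOA), d_FOA=float(row.d_FOA)))
        except (ValueError, TypeError) as exc:
            raise TableFormatError(f"{path}: data row {i}: {exc}") from exc
    return out


def write_counts_tsv(counts: Sequence[PlateCounts] | pd.DataFrame,
                     path: str | Path, comments: Sequence[str] = ()) -> None:
    if isinstance(counts, pd.DataFrame):
        df = counts[COUNTS_COLUMNS]
    else:
        df = pd.DataFrame([{
            "concentration_uM": pc.concentration, "history": pc.history,
            "N_YPD": pc.N_YPD, "d_YPD": pc.d_YPD,
            "N_FOA": pc.N_FOA, "d_FOA": pc.d_FOA} for pc in counts])
    _write_tsv(df, path, comments)


def read_colors_tsv(path: str | Path) -> pd.DataFrame:
    """Read a per-colony RGB table grouped by plate; validates rows."""
    df = _read_tsv(path, COLORS_COLUMNS)
    for i, row in enumerate(df.itertuples(index=False), start=1):
        for ch in ("R", "G", "B"):
            v = float(getattr(row, ch))
            if not np.isfinite(v) or v < 0:
                raise TableFormatError(
                    f"{path}: data row {i}: channel {ch} must be finite "
                    f"and non-negative, got {v}")
        if float(row.concentration_uM) < 0:
            raise TableFormatError(
                f"{path}: data row {i}: negative concentration")
    return df


def write_colors_tsv(df: pd.DataFrame, path: str | Path,
                     comments: Sequence[str] = ()) -> None:
    _write_tsv(df[COLORS_COLUMNS], path, comments)


def _write_tsv(df: pd.DataFrame, path: str | Path,
               comments: Sequence[str]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        df.to_csv(fh, sep="\t", index=False)


def write_trajectory_tsv(traj, path: str | Path,
                         metadata: dict | None = None) -> None:
    """Write a trajectory as TSV (time, occupancy, n_S, free_sir) with
    run metadata in '#' comment lines."""
    meta = {"seed": traj.seed, "n_events": traj.n_events,
            "window": list(traj.window),
            "conservation_ok": traj.conservation_ok}
    if metadata:
        meta.update(metadata)
    df = pd.DataFrame({"time": traj.times, "occupancy": traj.occupancy,
                       "n_S": traj.n_S, "free_sir": traj.free_sir})
    _write_tsv(df, path, [f"{k}={v}" for k, v in meta.items()])


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        return super().default(o)


def write_json(obj: dict, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, cls=_NumpyEncoder)
        fh.write("\n")


def config_hash(config_dict: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config_dict, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_manifest(out_dir: str | Path, *, command: str, seed: int,
                   config_dict: dict) -> Path:
    """Write the reproducibility manifest for a CLI invocation."""
    import sirswitch
    manifest = {
        "command": command,
        "seed": seed,
        "config_hash": config_hash(config_dict),
        "config": config_dict,
        "versions": {
            "sirswitch": sirswitch.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
        },
    }
    path = Path(out_dir) / "manifest.json"
    write_json(manifest, path)
    return path
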