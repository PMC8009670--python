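"""Reading and writing trace bundles and feature tables.

Two on-disk dialects are supported for trace bundles:

``csv_sidecar``
    A directory holding one CSV per sweep (columns ``time_s, command,
    response``) plus a single JSON sidecar ``<cell_id>.json`` with the
    cell metadata and the per-sweep mode/rate/protocol.  Inspectable with
    any text editor.

``hdf5_container``
    A single ``.h5`` file with one group per sweep and metadata stored as
    attributes.  Preferred for multi-sweep cells.

Feature tables are plain CSV with the canonical 21-feature schema defined
in :mod:`picquant.pipeline`; missing values are written as empty fields.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import h5py
import numpy as np
import pandas as pd

from .types import (
    CellRecord,
    TraceSweep,
    protocol_from_dict,
    protocol_to_dict,
)

__all__ = [
    "read_trace_bundle",
    "write_trace_bundle",
    "read_feature_table",
    "write_feature_table",
    "FormatError",
    "SchemaError",
]

log = logging.getLogger("picquant.io")

DIALECTS = ("csv_sidecar", "hdf5_container")

_TRACE_COLUMNS = ["time_s", "command", "response"]


class FormatError(ValueError):
    """A bundle on disk does not follow the expected layout."""


class SchemaError(ValueError):
    """A feature table does not follow the canonical schema."""


_REQUIRED_META = ("cell_id", "animal_id", "genotype", "age_days")


# ---------------------------------------------------------------------------
# trace bundles
# ---------------------------------------------------------------------------

def write_trace_bundle(cell: CellRecord, path, dialect: str = "csv_sidecar") -> Path:
    """Write ``cell`` to ``path`` and return the path of the sidecar/container.

    ``path`` is a directory for ``csv_sidecar`` and an ``.h5`` file path
    for ``hdf5_container``.  The representation round-trips losslessly
    through :func:`read_trace_bundle`.
    """
    path = Path(path)
    if dialect == "csv_sidecar":
        return _write_csv_sidecar(cell, path)
    if dialect == "hdf5_container":
        return _write_hdf5(cell, path)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def read_trace_bundle(path, dialect: Optional[str] = None) -> CellRecord:
    """Read a trace bundle written by :func:`write_trace_bundle`.

    ``path`` may be the sidecar JSON, the bundle directory, or the HDF5
    container.  The dialect is inferred from the layout when not given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        if path.suffix in (".h5", ".hdf5"):
            dialect = "hdf5_container"
        else:
            dialect = "csv_sidecar"
    if dialect == "csv_sidecar":
        return _read_csv_sidecar(path)
    if dialect == "hdf5_container":
        return _read_hdf5(path)
    raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


def _meta_from_sidecar(meta: dict, where: str) -> dict:
    missing = [k for k in _REQUIRED_META if k not in meta]
    if missing:
        raise FormatError(f"{where}: missing metadata field(s): {', '.join(missing)}")
    return {k: meta[k] for k in _REQUIRED_META}


def _write_csv_sidecar(cell: CellRecord, directory: Path) -> Path:
    directory.mkdir(parents=True, exist_ok=True)
    sweep_entries = []
    for i, sweep in enumerate(cell.sweeps):
        fname = f"{cell.cell_id}_sweep{i:02d}.csv"
        df = pd.DataFrame(
            {
                "time_s": sweep.time,
                "command": sweep.command,
                "response": sweep.response,
            }
        )
        # float64 round-trip-exact representation
        df.to_csv(directory / fname, index=False, float_format="%.17g")
        sweep_entries.append(
            {
                "file": fname,
                "mode": sweep.mode,
                "sampling_rate_hz": sweep.sampling_rate,
                "protocol": protocol_to_dict(sweep.protocol),
            }
        )
    sidecar = {
        "cell_id": cell.cell_id,
        "animal_id": cell.animal_id,
        "genotype": cell.genotype,
        "age_days": cell.age_days,
        "rmp": cell.rmp,
        "sweeps": sweep_entries,
    }
    if cell.truth is not None:
        with open(directory / f"{cell.cell_id}.truth.json", "w") as fh:
            json.dump(cell.truth, fh, indent=1, sort_keys=True, default=float)
    sidecar_path = directory / f"{cell.cell_id}.json"
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    log.debug("wrote csv_sidecar bundle", extra={"cell_id": cell.cell_id})
    return sidecar_path


def _read_trace_csv(csv_path: Path) -> pd.DataFrame:
    df = pd.read_csv(csv_path, float_precision="round_trip")
    missing = [c for c in _TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{csv_path}: missing column(s) {missing}")
    if df[_TRACE_COLUMNS].isna().any().any():
        raise FormatError(
            f"{csv_path}: columns have unequal lengths or missing samples"
        )
    return df


def _read_csv_sidecar(path: Path) -> CellRecord:
    if path.is_dir():
        sidecars = [
            p for p in sorted(path.glob("*.json")) if not p.name.endswith(".truth.json")
        ]
        if len(sidecars) != 1:
            raise FormatError(
                f"{path}: expected exactly one sidecar JSON, found {len(sidecars)}"
            )
        path = sidecars[0]
    with open(path) as fh:
        meta = json.load(fh)
    directory = path.parent
    core = _meta_from_sidecar(meta, str(path))
    if "sweeps" in meta:
        entries = meta["sweeps"]
    else:
        # flat single-sweep sidecar: mode/rate at top level, one CSV next to it
        for key in ("mode",):
            if key not in meta:
                raise FormatError(f"{path}: missing metadata field(s): {key}")
        csvs = sorted(directory.glob("*.csv"))
        if len(csvs) != 1:
            raise FormatError(
                f"{path}: flat sidecar requires exactly one CSV in the directory"
            )
        entries = [
            {
                "file": csvs[0].name,
                "mode": meta["mode"],
                "sampling_rate_hz": meta.get("sampling_rate_hz"),
                "protocol": meta.get("protocol"),
            }
        ]
    sweeps = []
    for entry in entries:
        df = _read_trace_csv(directory / entry["file"])
        rate = entry.get("sampling_rate_hz")
        if rate is None:
            rate = 1.0 / float(np.median(np.diff(df["time_s"].to_numpy())))
        sweeps.append(
            TraceSweep(
                time=df["time_s"].to_numpy(),
                command=df["command"].to_numpy(),
                response=df["response"].to_numpy(),
                mode=entry["mode"],
                sampling_rate=float(rate),
                protocol=protocol_from_dict(entry.get("protocol")),
            )
        )
    truth = None
    truth_path = directory / f"{core['cell_id']}.truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            truth = json.load(fh)
    return CellRecord(sweeps=sweeps, rmp=meta.get("rmp"), truth=truth, **core)


def _write_hdf5(cell: CellRecord, path: Path) -> Path:
    if path.suffix not in (".h5", ".hdf5"):
        path = path.with_suffix(".h5")
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.attrs["cell_id"] = cell.cell_id
        f.attrs["animal_id"] = cell.animal_id
        f.attrs["genotype"] = cell.genotype
        f.attrs["age_days"] = cell.age_days
        if cell.rmp is not None:
            f.attrs["rmp"] = cell.rmp
        if cell.truth is not None:
            f.attrs["truth_json"] = json.dumps(cell.truth, sort_keys=True, default=float)
        for i, sweep in enumerate(cell.sweeps):
            g = f.create_group(f"sweep_{i:03d}")
            g.create_dataset("time", data=sweep.time)
            g.create_dataset("command", data=sweep.command)
            g.create_dataset("response", data=sweep.response)
            g.attrs["mode"] = sweep.mode
            g.attrs["sampling_rate_hz"] = sweep.sampling_rate
            proto = protocol_to_dict(sweep.protocol)
            if proto is not None:
                g.attrs["protocol_json"] = json.dumps(proto, sort_keys=True)
    log.debug("wrote hdf5 bundle", extra={"cell_id": cell.cell_id})
    return path


def _read_hdf5(path: Path) -> CellRecord:
    with h5py.File(path, "r") as f:
        missing = [k for k in _REQUIRED_META if k not in f.attrs]
        if missing:
            raise FormatError(
                f"{path}: missing metadata field(s): {', '.join(missing)}"
            )
        sweeps = []
        for name in sorted(k for k in f.keys() if k.startswith("sweep_")):
            g = f[name]
            proto = None
            if "protocol_json" in g.attrs:
                proto = protocol_from_dict(json.loads(g.attrs["protocol_json"]))
            sweeps.append(
                TraceSweep(
                    time=g["time"][()],
                    command=g["command"][()],
                    response=g["response"][()],
                    mode=str(g.attrs["mode"]),
                    sampling_rate=float(g.attrs["sampling_rate_hz"]),
                    protocol=proto,
                )
            )
        truth = None
        if "truth_json" in f.attrs:
            truth = json.loads(f.attrs["truth_json"])
        return CellRecord(
            cell_id=str(f.attrs["cell_id"]),
            animal_id=str(f.attrs["animal_id"]),
            genotype=str(f.attrs["genotype"]),
            age_days=int(f.attrs["age_days"]),
            sweeps=sweeps,
            rmp=float(f.attrs["rmp"]) if "rmp" in f.attrs else None,
            truth=truth,
        )


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def write_feature_table(table: pd.DataFrame, path) -> Path:
    """Write a canonical feature table as CSV (empty field = missing)."""
    from .pipeline import FEATURE_COLUMNS, META_COLUMNS, OPTIONAL_COLUMNS

    allowed = set(META_COLUMNS) | set(FEATURE_COLUMNS) | set(OPTIONAL_COLUMNS)
    unknown = [c for c in table.columns if c not in allowed]
    if unknown:
        raise SchemaError(f"unknown feature-table column(s): {unknown}")
    missing = [c for c in META_COLUMNS + FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"feature table is missing column(s): {missing}")
    ordered = META_COLUMNS + FEATURE_COLUMNS + [
        c for c in OPTIONAL_COLUMNS if c in table.columns
    ]
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table[ordered].to_csv(path, index=False, float_format="%.17g", na_rep="")
    return path


def read_feature_table(path) -> pd.DataFrame:
    """Read a feature table CSV written by :func:`write_feature_table`."""
    from .pipeline import FEATURE_COLUMNS, META_COLUMNS

    df = pd.read_csv(Path(path), float_precision="round_trip")
    missing = [c for c in META_COLUMNS + FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"feature table is missing column(s): {missing}")
    return df
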