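"""File formats: spectra-matrix text files and YAML configurations.

The spectra file is delimiter-separated UTF-8 text with '.' decimals: any
number of ``#``-prefixed provenance lines, one header line
(``spectrum_id,day,session,replicate`` followed by the wavenumber axis),
then one row per spectrum.  Values round-trip to 1e-12 relative; metadata
round-trip exactly.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import PreprocessParams
from .simulate import BandKinetic, SimulationConfig
from .spectra import META_COLUMNS, SpectraSet

__all__ = [
    "read_spectra",
    "write_spectra",
    "config_to_dict",
    "config_from_dict",
    "read_config",
    "write_config",
    "config_hash",
]

_FLOAT_FMT = "%.12g"


def write_spectra(spectra: SpectraSet, path, provenance: dict | None = None) -> None:
    """Write a SpectraSet to a delimiter-separated text file."""
    path = Path(path)
    lines = ["# phytoraman spectra v1"]
    for key, value in (provenance or {}).items():
        lines.append(f"# {key}={value}")
    header = ",".join(
        list(META_COLUMNS) + [_FLOAT_FMT % w for w in spectra.axis]
    )
    lines.append(header)
    for i in range(spectra.n_spectra):
        row = spectra.meta.iloc[i]
        cells = [
            str(row["spectrum_id"]),
            str(int(row["day"])),
            str(int(row["session"])),
            str(int(row["replicate"])),
        ]
        cells += [_FLOAT_FMT % v for v in spectra.matrix[i]]
        lines.append(",".join(cells))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_spectra(path) -> SpectraSet:
    """Read a spectra-matrix text file; malformed rows are reported by line number."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    header = None
    header_line_no = 0
    data_rows: list[tuple[int, list[str]]] = []
    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = line.split(",")
        if header is None:
            header = cells
            header_line_no = line_no
        else:
            data_rows.append((line_no, cells))
    if header is None:
        raise ValueError(f"{path}: no header line found")
    if list(header[:4]) != list(META_COLUMNS):
        raise ValueError(
            f"{path}:{header_line_no}: header must start with {list(META_COLUMNS)}"
        )
    try:
        axis = np.array([float(c) for c in header[4:]])
    except ValueError as err:
        raise ValueError(f"{path}:{header_line_no}: non-numeric wavenumber: {err}") from err
    if axis.size == 0:
        raise ValueError(f"{path}:{header_line_no}: header carries no wavenumbers")
    if not data_rows:
        raise ValueError(f"{path}: no spectra rows")
    n_cols = 4 + axis.size
    matrix = np.empty((len(data_rows), axis.size))
    meta_records = []
    for k, (line_no, cells) in enumerate(data_rows):
        if len(cells) != n_cols:
            raise ValueError(
                f"{path}:{line_no}: expected {n_cols} cells, found {len(cells)}"
            )
        try:
            meta_records.append(
                {
                    "spectrum_id": cells[0],
                    "day": int(cells[1]),
                    "session": int(cells[2]),
                    "replicate": int(cells[3]),
                }
            )
            matrix[k] = [float(c) for c in cells[4:]]
        except ValueError as err:
            raise ValueError(f"{path}:{line_no}: malformed cell: {err}") from err
        if meta_records[-1]["day"] < 0:
            raise ValueError(f"{path}:{line_no}: negative day index")
    meta = pd.DataFrame.from_records(meta_records)
    if meta["spectrum_id"].duplicated().any():
        dup = meta.loc[meta["spectrum_id"].duplicated(), "spectrum_id"].iloc[0]
        raise ValueError(f"{path}: duplicate spectrum id {dup!r}")
    return SpectraSet(axis=axis, matrix=matrix, meta=meta)


# ---------------------------------------------------------------------------
# configuration serialisation
# ---------------------------------------------------------------------------

def config_to_dict(config: SimulationConfig) -> dict:
    out = dataclasses.asdict(config)
    out["bands"] = [
        {
            "label": b.label,
            "center": b.center,
            "width": b.width,
            "shape": b.shape,
            "amplitude_by_day": [float(a) for a in b.amplitude_by_day],
        }
        for b in config.bands
    ]
    out["baseline_coeffs"] = [float(c) for c in config.baseline_coeffs]
    return out


def config_from_dict(data: dict) -> SimulationConfig:
    data = dict(data)
    data["bands"] = [BandKinetic(**b) for b in data.get("bands", [])]
    if data.get("baseline_coeffs") is not None:
        data["baseline_coeffs"] = tuple(data["baseline_coeffs"])
    return SimulationConfig(**data)


def write_config(config: SimulationConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config_to_dict(config), sort_keys=False), encoding="utf-8"
    )


def read_config(path) -> SimulationConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    return config_from_dict(data)


def params_to_dict(params: PreprocessParams) -> dict:
    out = dataclasses.asdict(params)
    out["ranges"] = [list(r) for r in params.ranges]
    return out


def params_from_dict(data: dict) -> PreprocessParams:
    data = dict(data)
    if "ranges" in data:
        data["ranges"] = tuple(tuple(r) for r in data["ranges"])
    return PreprocessParams(**data)


def config_hash(data: dict) -> str:
    """Stable short hash of a configuration dict, for provenance headers."""
    blob = json.dumps(data, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
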