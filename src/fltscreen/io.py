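"""Readers and writers for the plate-text formats.

All formats are plain delimited text:

* plate map CSV — header ``well,row,col,role,compound_id,conc_uM``;
* waveform matrix — tab-separated, first row ``well`` + bin-midpoint times
  (ns, strictly increasing), then one row of counts per well;
* spectra CSV — tidy ``well,band,intensity``;
* fit CSV — ``well,tau_ns,tau_stderr,amplitude,baseline,chi2,converged,n_bins_used``.

Readers validate and report the offending line on malformed input; every
writer/reader pair round-trips exactly on valid data.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import List, Union

import numpy as np
import pandas as pd

from .decay import PlateWaveforms
from .layout import ROLES, PlateLayout, Well, parse_well_label

__all__ = [
    "read_plate_map",
    "write_plate_map",
    "read_waveforms",
    "write_waveforms",
    "read_spectra",
    "write_spectra",
    "read_fits",
    "write_fits",
]

PathLike = Union[str, Path]

_MAP_HEADER = ["well", "row", "col", "role", "compound_id", "conc_uM"]


def write_plate_map(layout: PlateLayout, path: PathLike) -> None:
    """Write a layout as the plate-map CSV."""
    df = layout.to_frame()
    df.to_csv(path, index=False)


def read_plate_map(path: PathLike) -> PlateLayout:
    """Read and validate a plate-map CSV; errors carry the line number."""
    path = Path(path)
    wells: List[Well] = []
    seen = set()
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file; expected header {','.join(_MAP_HEADER)}")
        if [h.strip() for h in header] != _MAP_HEADER:
            raise ValueError(
                f"{path}:1: bad header {header!r}; expected {','.join(_MAP_HEADER)}"
            )
        for lineno, rec in enumerate(reader, start=2):
            if not rec or all(not f.strip() for f in rec):
                continue
            if len(rec) != len(_MAP_HEADER):
                raise ValueError(f"{path}:{lineno}: expected {len(_MAP_HEADER)} fields, got {len(rec)}")
            label, row_s, col_s, role, compound_id, conc_s = (f.strip() for f in rec)
            try:
                row, col = int(row_s), int(col_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer row/col {row_s!r},{col_s!r}")
            try:
                lr, lc = parse_well_label(label)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}")
            if (lr, lc) != (row, col):
                raise ValueError(
                    f"{path}:{lineno}: well label {label!r} disagrees with row/col ({row},{col})"
                )
            if role not in ROLES:
                raise ValueError(
                    f"{path}:{lineno}: unknown role {role!r}; expected one of {ROLES}"
                )
            if (row, col) in seen:
                raise ValueError(f"{path}:{lineno}: duplicate well {label}")
            seen.add((row, col))
            wells.append(
                Well(
                    row=row,
                    col=col,
                    role=role,
                    compound_id=compound_id or None,
                    conc_uM=float(conc_s) if conc_s else None,
                )
            )
    return PlateLayout.from_frame(
        pd.DataFrame(
            {
                "row": [w.row for w in wells],
                "col": [w.col for w in wells],
                "role": [w.role for w in wells],
                "compound_id": [w.compound_id for w in wells],
                "conc_uM": [w.conc_uM for w in wells],
            }
        )
    )


def write_waveforms(plate: PlateWaveforms, path: PathLike) -> None:
    """Write a plate's waveforms as the tab-separated matrix format."""
    path = Path(path)
    with path.open("w") as fh:
        # %.17g round-trips IEEE doubles exactly
        fh.write("well\t" + "\t".join(f"{float(t):.17g}" for t in plate.times) + "\n")
        for well, row in zip(plate.wells, plate.counts):
            fh.write(well + "\t" + "\t".join(f"{float(c):.17g}" for c in row) + "\n")


def read_waveforms(path: PathLike) -> PlateWaveforms:
    """Read the waveform matrix; validates the time header and row shapes."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline()
        if not header.strip():
            raise ValueError(
                f"{path}: empty file; expected header 'well<TAB>t0<TAB>t1...' with bin times"
            )
        parts = header.rstrip("\n").split("\t")
        if parts[0] != "well" or len(parts) < 2:
            raise ValueError(f"{path}:1: expected header starting with 'well' then bin times")
        try:
            times = np.array([float(p) for p in parts[1:]])
        except ValueError:
            raise ValueError(f"{path}:1: non-numeric bin time in header")
        if np.any(np.diff(times) <= 0):
            raise ValueError(f"{path}:1: bin times must be strictly increasing")
        wells: List[str] = []
        rows: List[np.ndarray] = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != times.size + 1:
                raise ValueError(
                    f"{path}:{lineno}: ragged row; expected {times.size} counts, "
                    f"got {len(fields) - 1}"
                )
            try:
                counts = np.array([float(f) for f in fields[1:]])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric count")
            if np.any(counts < 0):
                raise ValueError(f"{path}:{lineno}: negative count")
            wells.append(fields[0])
            rows.append(counts)
    if not rows:
        raise ValueError(f"{path}: no waveform rows")
    return PlateWaveforms(times=times, counts=np.vstack(rows), wells=wells)


def write_spectra(spectra: pd.DataFrame, path: PathLike) -> None:
    spectra.to_csv(path, index=False)


def read_spectra(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"well", "band", "intensity"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: spectra CSV missing columns {sorted(missing)}")
    return df


def write_fits(fits: pd.DataFrame, path: PathLike) -> None:
    fits.to_csv(path, index=False)


def read_fits(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"well", "tau_ns", "converged"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: fit CSV missing columns {sorted(missing)}")
    df["converged"] = df["converged"].astype(bool)
    return df
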