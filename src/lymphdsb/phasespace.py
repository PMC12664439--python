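"""Phase-space records and their bookkeeping.

A phase space is the list of particle states (name, kinetic energy,
position, direction, statistical weight, event id) recorded on the
surface of each cell sphere during the macroscopic vial simulation.
The cells are cold sources — decays inside them are forbidden — so the
recorded particles are purely external irradiation.  To drive the
single-cell microscopic simulation, each cell's phase space is
translated to the cell's own origin, all cells are merged into one
*total phase space*, and anti-neutrinos (which deposit nothing) are
stripped to cut the file size.

Records are held in a :class:`pandas.DataFrame` with the columns of
:data:`COLUMNS`; files are HDF5 (one ``/phasespace`` group with one
1-D dataset per column, metadata in root attributes) or plain CSV with
``#`` metadata lines.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .geometry import CellPlacement

__all__ = [
    "COLUMNS",
    "ANTINEUTRINO_NAMES",
    "PhaseSpace",
    "SchemaError",
    "translate_to_cell_origin",
    "merge_phase_spaces",
    "strip_antineutrinos",
    "read_phase_space",
    "write_phase_space",
]

COLUMNS = (
    "name", "ekin_MeV", "x_um", "y_um", "z_um",
    "dx", "dy", "dz", "weight", "event_id", "cell_id",
)

#: generator-dependent spellings of the electron anti-neutrino
ANTINEUTRINO_NAMES = frozenset(
    {"anti_nu_e", "nu_e_bar", "nu_e-bar", "anti-nu_e", "antinu_e"}
)

_FRAMES = ("vial", "cell-local")


class SchemaError(ValueError):
    """A phase-space file is missing required columns or datasets."""


@dataclass(frozen=True)
class PhaseSpace:
    """An ordered collection of particle records plus run metadata."""

    records: pd.DataFrame
    radionuclide: str = "unknown"
    nt: int = 1
    frame: str = "vial"

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.records.columns]
        if missing:
            raise SchemaError(f"phase space missing columns: {missing}")
        if self.frame not in _FRAMES:
            raise ValueError(f"frame must be one of {_FRAMES}, got {self.frame!r}")
        if self.nt < 1:
            raise ValueError("nt (nuclear transformations) must be >= 1")
        df = self.records
        if len(df):
            if (df["ekin_MeV"].to_numpy() < 0).any():
                raise ValueError("kinetic energies must be non-negative")
            if (df["weight"].to_numpy() <= 0).any():
                raise ValueError("weights must be strictly positive")
            norms = np.linalg.norm(df[["dx", "dy", "dz"]].to_numpy(), axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ValueError("directions must be unit vectors (|1 - norm| <= 1e-6)")

    def __len__(self) -> int:
        return len(self.records)


def translate_to_cell_origin(
    ps: PhaseSpace, placement: CellPlacement
) -> PhaseSpace:
    """Shift each record's position by minus its cell's center.

    After translation every record lives in the cell-local frame with
    the cell center at the origin (records sit on the 3.75 um cell
    surface).  Directions are untouched.  Translating an already
    cell-local phase space is an error, as is a record whose cell_id
    is not in the placement.
    """
    if ps.frame != "vial":
        raise ValueError("phase space is already cell-local")
    df = ps.records.copy()
    cell_ids = df["cell_id"].to_numpy(dtype=int)
    unknown = np.setdiff1d(np.unique(cell_ids), np.arange(placement.n_cells))
    if unknown.size:
        raise KeyError(f"unknown cell_id {unknown[0]}")
    centers = placement.centers[cell_ids]
    df[["x_um", "y_um", "z_um"]] = df[["x_um", "y_um", "z_um"]].to_numpy() - centers
    return replace(ps, records=df, frame="cell-local")


def merge_phase_spaces(spaces: list[PhaseSpace]) -> PhaseSpace:
    """Sum per-cell phase spaces into the total phase space.

    All inputs must be cell-local and share the radionuclide and nt.
    Particles that crossed several cells appear once per crossing —
    each crossing is an independent source particle for the
    single-cell simulation.  Ordering is stable: input order, then
    record order.
    """
    if not spaces:
        raise ValueError("cannot merge an empty list of phase spaces")
    first = spaces[0]
    for ps in spaces:
        if ps.frame != "cell-local":
            raise ValueError("all phase spaces must be cell-local before merging")
        if ps.radionuclide != first.radionuclide:
            raise ValueError(
                f"mixed radionuclides: {first.radionuclide!r} vs {ps.radionuclide!r}"
            )
        if ps.nt != first.nt:
            raise ValueError("mixed nt among phase spaces")
    merged = pd.concat([ps.records for ps in spaces], ignore_index=True)
    return replace(first, records=merged)


def strip_antineutrinos(ps: PhaseSpace) -> PhaseSpace:
    """Drop anti-neutrino records (case-insensitive name match)."""
    names = ps.records["name"].astype(str).str.lower()
    keep = ~names.isin(ANTINEUTRINO_NAMES)
    return replace(ps, records=ps.records[keep].reset_index(drop=True))


def write_phase_space(
    ps: PhaseSpace, path: str | Path, format: str | None = None
) -> None:
    """Write to HDF5 (default) or CSV; metadata is persisted."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix == ".csv" else "hdf5")
    if fmt == "hdf5":
        with h5py.File(path, "w") as fh:
            grp = fh.create_group("phasespace")
            for col in COLUMNS:
                data = ps.records[col].to_numpy()
                if col == "name":
                    grp.create_dataset(
                        col, data=data.astype(object), dtype=h5py.string_dtype()
                    )
                else:
                    grp.create_dataset(col, data=data)
            fh.attrs["radionuclide"] = ps.radionuclide
            fh.attrs["nt"] = ps.nt
            fh.attrs["frame"] = ps.frame
    elif fmt == "csv":
        with path.open("w") as fh:
            fh.write(
                f"# radionuclide={ps.radionuclide} nt={ps.nt} frame={ps.frame}\n"
            )
            ps.records.to_csv(fh, index=False, columns=list(COLUMNS))
    else:
        raise ValueError(f"format must be 'hdf5' or 'csv', got {fmt!r}")


def read_phase_space(path: str | Path, format: str | None = None) -> PhaseSpace:
    """Read a phase space written by :func:`write_phase_space`.

    Raises :class:`SchemaError` listing any missing columns/datasets.
    """
    path = Path(path)
    fmt = format or ("csv" if path.suffix == ".csv" else "hdf5")
    if fmt == "hdf5":
        with h5py.File(path, "r") as fh:
            if "phasespace" not in fh:
                raise SchemaError(f"{path}: missing group 'phasespace'")
            grp = fh["phasespace"]
            missing = [c for c in COLUMNS if c not in grp]
            if missing:
                raise SchemaError(f"{path}: missing datasets: {missing}")
            data = {}
            for col in COLUMNS:
                arr = grp[col][()]
                if col == "name":
                    arr = np.array([v.decode() if isinstance(v, bytes) else str(v)
                                    for v in arr], dtype=object)
                data[col] = arr
            meta = dict(fh.attrs)
        df = pd.DataFrame(data)
        df["event_id"] = df["event_id"].astype(int)
        df["cell_id"] = df["cell_id"].astype(int)
        return PhaseSpace(
            df,
            radionuclide=str(meta.get("radionuclide", "unknown")),
            nt=int(meta.get("nt", 1)),
            frame=str(meta.get("frame", "vial")),
        )
    if fmt == "csv":
        meta = {"radionuclide": "unknown", "nt": "1", "frame": "vial"}
        with path.open() as fh:
            first = fh.readline()
            if first.startswith("#"):
                for token in first[1:].split():
                    key, _, val = token.partition("=")
                    if key in meta:
                        meta[key] = val
                df = pd.read_csv(fh)
            else:
                fh.seek(0)
                df = pd.read_csv(fh)
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing columns: {missing}")
        return PhaseSpace(
            df[list(COLUMNS)],
            radionuclide=meta["radionuclide"],
            nt=int(float(meta["nt"])),
            frame=meta["frame"],
        )
    raise ValueError(f"format must be 'hdf5' or 'csv', got {fmt!r}")
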