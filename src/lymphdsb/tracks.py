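"""Synthetic energy-deposition tracks through the spherical nucleus.

Stands in for a track-structure physics engine so the damage scorer is
testable at desk scale.  A primary particle enters the 3.1 um-radius
nucleus at a surface point and travels along a straight chord (alpha
paths at MeV energies are nearly straight; multiple scattering is a
documented fidelity limit).  Energy-deposition points are laid down as
a 1-D Poisson process along the chord:

* alphas: the deposition linear density follows a user-editable
  two-column LET table (MeV -> keV/um); each deposition energy is
  lognormal (median 60 eV).  The density is LET divided by the mean
  deposition energy, so the expected energy per unit path matches the
  table.  Alpha kinetic energies of interest span 0.01-8.36 MeV.
* electrons: sparse depositions at a fixed low linear density
  (order 0.1-1 per um) — low-LET plumbing for mixed exposures.

The default alpha LET table is a placeholder with the right order of
magnitude for alpha particles in liquid water (Bragg-peak region near
0.7 MeV); it is not a calibrated stopping-power dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "TrackModel",
    "NucleusExposure",
    "default_alpha_model",
    "default_electron_model",
    "chord_length",
    "generate_alpha_track",
    "generate_electron_track",
    "generate_nucleus_exposure",
    "write_depositions",
    "read_depositions",
]

DEPOSITION_COLUMNS = ("x_nm", "y_nm", "z_nm", "edep_eV", "track_id", "particle")

#: placeholder LET table for alphas in water, MeV -> keV/um
DEFAULT_ALPHA_LET_TABLE = np.array(
    [
        [0.01, 60.0],
        [0.1, 130.0],
        [0.5, 220.0],
        [0.7, 230.0],
        [1.0, 215.0],
        [2.0, 165.0],
        [4.0, 115.0],
        [6.0, 92.0],
        [8.36, 75.0],
    ]
)


@dataclass(frozen=True)
class TrackModel:
    """How one particle species deposits energy along its chord.

    Either ``let_table_MeV_keV_per_um`` (density = LET / mean
    deposition energy, interpolated in kinetic energy) or a fixed
    ``linear_density_per_um`` must be given.  Deposition energies are
    i.i.d. lognormal with the given median (eV) and log-space sigma.
    """

    particle_name: str
    kinetic_energy_range_MeV: tuple[float, float]
    let_table_MeV_keV_per_um: np.ndarray | None = None
    linear_density_per_um: float | None = None
    edep_median_eV: float = 60.0
    edep_sigma: float = 1.0

    def __post_init__(self) -> None:
        lo, hi = self.kinetic_energy_range_MeV
        if not 0 < lo < hi:
            raise ValueError("kinetic energy range must satisfy 0 < lo < hi")
        if (self.let_table_MeV_keV_per_um is None) == (
            self.linear_density_per_um is None
        ):
            raise ValueError("give exactly one of LET table or fixed density")
        if self.linear_density_per_um is not None and self.linear_density_per_um < 0:
            raise ValueError("linear density must be non-negative")
        if self.edep_median_eV <= 0 or self.edep_sigma < 0:
            raise ValueError("deposition energy sampler parameters invalid")
        if self.let_table_MeV_keV_per_um is not None:
            tab = np.asarray(self.let_table_MeV_keV_per_um, dtype=float)
            if tab.ndim != 2 or tab.shape[1] != 2 or (tab <= 0).any():
                raise ValueError("LET table must be a positive (k, 2) array")
            object.__setattr__(self, "let_table_MeV_keV_per_um", tab)

    @property
    def mean_edep_eV(self) -> float:
        """Mean of the lognormal deposition-energy distribution."""
        return self.edep_median_eV * float(np.exp(self.edep_sigma**2 / 2))

    def density_per_um(self, kinetic_energy_MeV: float) -> float:
        """Expected depositions per um of path at this kinetic energy."""
        if self.linear_density_per_um is not None:
            return self.linear_density_per_um
        tab = self.let_table_MeV_keV_per_um
        let_keV_um = float(np.interp(kinetic_energy_MeV, tab[:, 0], tab[:, 1]))
        return let_keV_um * 1e3 / self.mean_edep_eV

    def check_energy(self, kinetic_energy_MeV: float) -> None:
        lo, hi = self.kinetic_energy_range_MeV
        if not lo <= kinetic_energy_MeV <= hi:
            raise ValueError(
                f"kinetic energy {kinetic_energy_MeV} MeV outside model range "
                f"[{lo}, {hi}] MeV for {self.particle_name}"
            )


def default_alpha_model() -> TrackModel:
    """High-LET alpha model over 0.01-8.36 MeV (placeholder LET table)."""
    return TrackModel(
        particle_name="alpha",
        kinetic_energy_range_MeV=(0.01, 8.36),
        let_table_MeV_keV_per_um=DEFAULT_ALPHA_LET_TABLE,
    )


def default_electron_model() -> TrackModel:
    """Sparse low-LET electron model (fixed 0.5 depositions/um)."""
    return TrackModel(
        particle_name="e-",
        kinetic_energy_range_MeV=(1e-3, 10.0),
        linear_density_per_um=0.5,
    )


def chord_length(
    entry_um: np.ndarray,
    direction: np.ndarray,
    nucleus_radius_um: float = 3.1,
    atol_um: float = 1e-6,
) -> float:
    """Length of a straight ray's intersection with the nucleus sphere.

    ``entry_um`` must lie on the sphere surface (within ``atol_um``).
    For a surface point e with |e| = R and unit direction d, the exit
    parameter solves |e + t d| = R, so the chord is t = -2 (e . d);
    tangent rays give 0 and outward rays give 0 with a warning.
    """
    entry = np.asarray(entry_um, dtype=float)
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    r = float(np.linalg.norm(entry))
    if abs(r - nucleus_radius_um) > atol_um:
        raise ValueError(
            f"entry point at |p| = {r:.6f} um is not on the sphere surface "
            f"(radius {nucleus_radius_um} um)"
        )
    dot = float(entry @ d)
    if dot > 0:
        warnings.warn("direction points outward; chord length is 0", stacklevel=2)
        return 0.0
    return max(0.0, min(-2.0 * dot, 2.0 * nucleus_radius_um))


def _poisson_depositions(
    entry_um: np.ndarray,
    direction: np.ndarray,
    chord_um: float,
    density_per_um: float,
    model: TrackModel,
    rng: np.random.Generator,
    track_id: int,
    nucleus_radius_um: float,
) -> pd.DataFrame:
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    n = rng.poisson(density_per_um * chord_um) if chord_um > 0 else 0
    t_um = rng.uniform(0.0, chord_um, size=n) if n else np.empty(0)
    pos_nm = (np.asarray(entry_um) + t_um[:, None] * d) * 1e3
    edep = model.edep_median_eV * np.exp(rng.normal(0.0, model.edep_sigma, size=n))
    norms = np.linalg.norm(pos_nm, axis=1)
    r_nm = nucleus_radius_um * 1e3
    assert np.all(norms <= r_nm * (1 + 1e-9)), "deposition escaped the nucleus"
    np.minimum(norms, r_nm, out=norms)  # clip boundary round-off
    return pd.DataFrame(
        {
            "x_nm": pos_nm[:, 0],
            "y_nm": pos_nm[:, 1],
            "z_nm": pos_nm[:, 2],
            "edep_eV": edep,
            "track_id": np.full(n, track_id, dtype=int),
            "particle": np.full(n, model.particle_name, dtype=object),
        }
    )


def generate_alpha_track(
    entry_um: np.ndarray,
    direction: np.ndarray,
    kinetic_energy_MeV: float,
    model: TrackModel | None = None,
    seed: int | np.random.SeedSequence = 0,
    nucleus_radius_um: float = 3.1,
    track_id: int = 0,
) -> tuple[pd.DataFrame, float]:
    """One straight alpha track; returns (depositions, chord length in um)."""
    model = model or default_alpha_model()
    model.check_energy(kinetic_energy_MeV)
    rng = np.random.default_rng(seed)
    chord = chord_length(entry_um, direction, nucleus_radius_um)
    density = model.density_per_um(kinetic_energy_MeV)
    df = _poisson_depositions(
        entry_um, direction, chord, density, model, rng, track_id, nucleus_radius_um
    )
    return df, chord


def generate_electron_track(
    entry_um: np.ndarray,
    direction: np.ndarray,
    kinetic_energy_MeV: float,
    model: TrackModel | None = None,
    seed: int | np.random.SeedSequence = 0,
    nucleus_radius_um: float = 3.1,
    track_id: int = 0,
) -> pd.DataFrame:
    """One sparse electron track (no track-length bookkeeping)."""
    model = model or default_electron_model()
    model.check_energy(kinetic_energy_MeV)
    rng = np.random.default_rng(seed)
    chord = chord_length(entry_um, direction, nucleus_radius_um)
    density = model.density_per_um(kinetic_energy_MeV)
    return _poisson_depositions(
        entry_um, direction, chord, density, model, rng, track_id, nucleus_radius_um
    )


@dataclass(frozen=True)
class NucleusExposure:
    """Depositions of many primaries, grouped by ``track_id``.

    ``tracks`` carries one row per primary: track_id, particle,
    kinetic energy, and the chord (= alpha track length inside the
    nucleus for alphas).
    """

    depositions: pd.DataFrame
    tracks: pd.DataFrame
    nucleus_radius_um: float = 3.1
    seed: int | None = None


def generate_nucleus_exposure(
    n_primaries: int,
    mixture: list[tuple[TrackModel, float]],
    nucleus_radius_um: float = 3.1,
    seed: int = 0,
) -> NucleusExposure:
    """Expose the nucleus to ``n_primaries`` particles from a mixture.

    Entry points are uniform on the sphere surface; inward directions
    are cosine-weighted (a surface element of an isotropically
    irradiated sphere sees a cosine-law flux).  Kinetic energies are
    drawn uniformly over each model's range.  Per-track RNG streams are
    split from the master seed and the track index, so exposures are
    reproducible and insensitive to generation order.
    """
    if not mixture:
        raise ValueError("mixture must contain at least one track model")
    weights = np.array([w for _, w in mixture], dtype=float)
    if weights.min() < 0 or abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("mixture weights must be non-negative and sum to 1")
    models = [m for m, _ in mixture]

    rng = np.random.default_rng(np.random.SeedSequence((seed, 1, 0)))
    choices = rng.choice(len(models), size=n_primaries, p=weights)

    dep_frames: list[pd.DataFrame] = []
    meta_rows = []
    for i in range(n_primaries):
        model = models[choices[i]]
        sub = np.random.default_rng(np.random.SeedSequence((seed, 0, i)))
        # uniform point on the sphere surface
        v = sub.normal(size=3)
        v /= np.linalg.norm(v)
        entry = nucleus_radius_um * v
        # cosine-weighted inward direction: normal + uniform unit vector
        inward = -v
        while True:
            s = sub.normal(size=3)
            s /= np.linalg.norm(s)
            d = inward + s
            norm = np.linalg.norm(d)
            if norm > 1e-9:
                d /= norm
                break
        lo, hi = model.kinetic_energy_range_MeV
        ekin = sub.uniform(lo, hi)
        chord = chord_length(entry, d, nucleus_radius_um)
        density = model.density_per_um(ekin)
        df = _poisson_depositions(
            entry, d, chord, density, model, sub, i, nucleus_radius_um
        )
        dep_frames.append(df)
        meta_rows.append(
            {
                "track_id": i,
                "particle": model.particle_name,
                "ekin_MeV": ekin,
                "chord_um": chord,
            }
        )
    if dep_frames:
        depositions = pd.concat(dep_frames, ignore_index=True)
    else:
        depositions = pd.DataFrame(
            {c: pd.Series(dtype=(object if c == "particle" else
                                 int if c == "track_id" else float))
             for c in DEPOSITION_COLUMNS}
        )
    tracks = pd.DataFrame(
        meta_rows, columns=["track_id", "particle", "ekin_MeV", "chord_um"]
    )
    return NucleusExposure(depositions, tracks, nucleus_radius_um, seed)


def write_depositions(exposure: NucleusExposure, path: str | Path) -> None:
    """HDF5 layout mirroring the phase-space files."""
    with h5py.File(Path(path), "w") as fh:
        grp = fh.create_group("depositions")
        for col in DEPOSITION_COLUMNS:
            data = exposure.depositions[col].to_numpy()
            if col == "particle":
                grp.create_dataset(
                    col, data=data.astype(object), dtype=h5py.string_dtype()
                )
            else:
                grp.create_dataset(col, data=data)
        tgrp = fh.create_group("tracks")
        for col in ("track_id", "particle", "ekin_MeV", "chord_um"):
            data = exposure.tracks[col].to_numpy()
            if col == "particle":
                tgrp.create_dataset(
                    col, data=data.astype(object), dtype=h5py.string_dtype()
                )
            else:
                tgrp.create_dataset(col, data=data)
        fh.attrs["nucleus_radius_um"] = exposure.nucleus_radius_um
        if exposure.seed is not None:
            fh.attrs["seed"] = exposure.seed


def read_depositions(path: str | Path) -> NucleusExposure:
    with h5py.File(Path(path), "r") as fh:
        if "depositions" not in fh or "tracks" not in fh:
            raise ValueError(f"{path}: missing 'depositions'/'tracks' groups")

        def load(grp, cols):
            data = {}
            for col in cols:
                arr = grp[col][()]
                if col == "particle":
                    arr = np.array(
                        [v.decode() if isinstance(v, bytes) else str(v) for v in arr],
                        dtype=object,
                    )
                data[col] = arr
            return pd.DataFrame(data)

        dep = load(fh["depositions"], DEPOSITION_COLUMNS)
        tracks = load(fh["tracks"], ("track_id", "particle", "ekin_MeV", "chord_um"))
        radius = float(fh.attrs.get("nucleus_radius_um", 3.1))
        seed = int(fh.attrs["seed"]) if "seed" in fh.attrs else None
    dep["track_id"] = dep["track_id"].astype(int)
    tracks["track_id"] = tracks["track_id"].astype(int)
    return NucleusExposure(dep, tracks, radius, seed)
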