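"""Vial and cell geometry for internal ex vivo blood irradiation.

The irradiation volume is an 8 mL cylindrical vial of water-equivalent
medium.  Lymphocytes are modelled as non-overlapping spheres of 3.75 um
radius (125 cells/mL, i.e. 1000 cells in the vial), each with a
concentric spherical nucleus of 3.1 um radius.  This module places the
cells by rejection sampling, persists their coordinates as a plain-text
table, and derives the geometric constants the damage model consumes:

* the DNA "sensitive volume" fraction of the nucleus (``SPointsProb``),
  either from the cylindrical B-DNA geometry (radius 1.1 nm, rise
  0.34 nm/bp, 6.4e9 bp) or from the genome mass and DNA mass density;
* nucleus volume, mass and geometric cross section.

Coordinates are right-handed Cartesian in micrometres, origin at the
midpoint of the cylinder axis, axis along z.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "VialGeometry",
    "CellPlacement",
    "GeometryConstants",
    "PackingError",
    "PlacementFileError",
    "place_cells",
    "write_placement",
    "read_placement",
    "sensitive_fraction_geometric",
    "sensitive_fraction_molecular",
    "dna_cylinder_volume_um3",
    "dna_length_m",
    "nucleus_metrics",
    "round_half_up_percent",
]

#: density of water, kg/m^3 — the nucleus is modelled as liquid water
WATER_DENSITY_KG_M3 = 1000.0


class PackingError(RuntimeError):
    """Random sphere packing did not converge."""


class PlacementFileError(ValueError):
    """Malformed or inconsistent placement file."""


@dataclass(frozen=True)
class VialGeometry:
    """Cylindrical blood vial.

    The nominal vial holds 8 mL (radius 7.2 mm, height 49.12 mm of
    water-equivalent medium).
    """

    radius_mm: float
    height_mm: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.height_mm <= 0:
            raise ValueError("vial radius and height must be positive")

    @property
    def volume_mL(self) -> float:
        """Volume in mL (1 mL = 1000 mm^3)."""
        return math.pi * self.radius_mm**2 * self.height_mm / 1000.0

    @property
    def radius_um(self) -> float:
        return self.radius_mm * 1000.0

    @property
    def height_um(self) -> float:
        return self.height_mm * 1000.0

    @classmethod
    def default_8ml(cls) -> "VialGeometry":
        return cls(radius_mm=7.2, height_mm=49.12)

    def check_volume(self, nominal_mL: float, rtol: float = 0.01) -> None:
        """Assert the derived volume matches a nominal label within ``rtol``."""
        if not math.isclose(self.volume_mL, nominal_mL, rel_tol=rtol):
            raise ValueError(
                f"vial volume {self.volume_mL:.4f} mL inconsistent with "
                f"nominal {nominal_mL} mL (tolerance {rtol:.0%})"
            )


@dataclass(frozen=True)
class CellPlacement:
    """Centers of non-overlapping spherical cells inside a vial (um)."""

    centers: np.ndarray  # (n, 3) um, vial frame
    cell_radius_um: float = 3.75
    nucleus_radius_um: float = 3.1
    seed: int | None = None

    def __post_init__(self) -> None:
        centers = np.asarray(self.centers, dtype=float)
        if centers.ndim != 2 or centers.shape[1] != 3:
            raise ValueError("centers must be an (n, 3) array")
        object.__setattr__(self, "centers", centers)
        if not 0 < self.nucleus_radius_um < self.cell_radius_um:
            raise ValueError("need 0 < nucleus_radius < cell_radius")

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    def min_pair_distance(self) -> float:
        """Smallest pairwise center distance (inf for < 2 cells)."""
        if self.n_cells < 2:
            return math.inf
        d, _ = cKDTree(self.centers).query(self.centers, k=2)
        return float(d[:, 1].min())

    def validate(self, vial: VialGeometry) -> None:
        """Check wall margins and non-overlap against ``vial``."""
        r = self.cell_radius_um
        radial = np.hypot(self.centers[:, 0], self.centers[:, 1])
        if np.any(radial > vial.radius_um - r + 1e-9):
            raise PlacementFileError("cell center violates cylinder wall margin")
        if np.any(np.abs(self.centers[:, 2]) > vial.height_um / 2 - r + 1e-9):
            raise PlacementFileError("cell center violates end-cap margin")
        if self.min_pair_distance() < 2 * r - 1e-9:
            raise PlacementFileError("overlapping cells in placement")

    def center_of(self, cell_id: int) -> np.ndarray:
        if not 0 <= cell_id < self.n_cells:
            raise KeyError(f"unknown cell_id {cell_id}")
        return self.centers[cell_id]


def place_cells(
    n: int,
    vial: VialGeometry,
    cell_radius_um: float = 3.75,
    seed: int = 0,
    max_attempts: int = 1_000_000,
    nucleus_radius_um: float = 3.1,
) -> CellPlacement:
    """Randomly place ``n`` non-overlapping spheres inside the vial.

    Candidates are drawn uniformly over the margin-shrunk cylinder
    (so the wall constraint holds by construction) and rejected on
    overlap with already-accepted cells.  At the nominal occupancy
    (1000 cells of 3.75 um radius in 8 mL, packing fraction ~3e-8)
    rejections are vanishingly rare.

    Deterministic for a fixed ``seed``.  Raises :class:`PackingError`
    after ``max_attempts`` rejected candidates for any single cell.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if cell_radius_um >= vial.radius_um:
        raise ValueError("cell radius must be smaller than the vial radius")
    r_max = vial.radius_um - cell_radius_um
    z_max = vial.height_um / 2 - cell_radius_um
    if r_max < 0 or z_max < 0:
        raise PackingError("vial too small to hold a single cell")

    rng = np.random.default_rng(seed)
    centers = np.empty((n, 3))
    min_sq = (2 * cell_radius_um) ** 2
    for i in range(n):
        for attempt in range(max_attempts):
            radial = r_max * math.sqrt(rng.random())
            theta = 2 * math.pi * rng.random()
            cand = np.array(
                [radial * math.cos(theta), radial * math.sin(theta),
                 z_max * (2 * rng.random() - 1)]
            )
            if i == 0:
                break
            d2 = np.einsum("ij,ij->i", centers[:i] - cand, centers[:i] - cand)
            if d2.min() >= min_sq:
                break
        else:
            raise PackingError(
                f"packing failed: {max_attempts} attempts exhausted placing "
                f"cell {i} of {n}"
            )
        centers[i] = cand
    return CellPlacement(centers, cell_radius_um, nucleus_radius_um, seed)


def write_placement(placement: CellPlacement, path: str | Path) -> None:
    """Write a placement as plain text: ``cell_id,x_um,y_um,z_um`` rows.

    Radii and seed are kept in comment lines so the round trip is the
    identity to full double precision.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(
            f"# cell_radius_um={placement.cell_radius_um!r} "
            f"nucleus_radius_um={placement.nucleus_radius_um!r} "
            f"seed={placement.seed!r}\n"
        )
        fh.write("cell_id,x_um,y_um,z_um\n")
        for i, (x, y, z) in enumerate(placement.centers):
            fh.write(f"{i},{float(x)!r},{float(y)!r},{float(z)!r}\n")


def read_placement(
    path: str | Path, vial: VialGeometry | None = None
) -> CellPlacement:
    """Read a placement file; optionally validate against ``vial``.

    Raises :class:`PlacementFileError` naming the offending line for a
    malformed file, or on invariant violations when ``vial`` is given.
    """
    path = Path(path)
    meta = {"cell_radius_um": 3.75, "nucleus_radius_um": 3.1, "seed": None}
    rows: list[tuple[float, float, float]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for token in line[1:].split():
                    if "=" in token:
                        key, _, val = token.partition("=")
                        if key in meta:
                            meta[key] = None if val == "None" else float(val)
                continue
            if line.startswith("cell_id"):
                continue
            parts = line.split(",")
            if len(parts) != 4:
                raise PlacementFileError(
                    f"{path}:{lineno}: expected 4 comma-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                rows.append((float(parts[1]), float(parts[2]), float(parts[3])))
            except ValueError as exc:
                raise PlacementFileError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        raise PlacementFileError(f"{path}: no cells")
    seed = meta["seed"]
    placement = CellPlacement(
        np.array(rows),
        cell_radius_um=float(meta["cell_radius_um"]),
        nucleus_radius_um=float(meta["nucleus_radius_um"]),
        seed=None if seed is None else int(seed),
    )
    if vial is not None:
        placement.validate(vial)
    return placement


# ---------------------------------------------------------------------------
# Geometric constants of the damage model


@dataclass(frozen=True)
class GeometryConstants:
    """Constants entering the sensitive-volume fraction.

    ``bp_length_nm``
        axial rise of B-DNA per base pair (0.34 nm/bp).
    ``dna_radius_nm``
        radius of the DNA double-helix cylinder (1.1 nm).
    ``n_bp``
        diploid human genome size in base pairs (6.4e9 bp).
    ``genome_mass_pg``
        diploid genome mass (6.41 pg, male).
    ``dna_density_g_per_mL``
        DNA mass density (1.7 g/mL).
    ``world_radius_um``
        bounding sphere of the single-cell simulation world; exceeds
        the 3.75 um cell radius by 0.01 um to leave room for source
        positioning on the cell surface.
    """

    bp_length_nm: float = 0.34
    dna_radius_nm: float = 1.1
    n_bp: float = 6.4e9
    genome_mass_pg: float = 6.41
    dna_density_g_per_mL: float = 1.7
    world_radius_um: float = 3.76
    cell_radius_um: float = 3.75
    nucleus_radius_um: float = 3.1

    def __post_init__(self) -> None:
        for name in (
            "bp_length_nm", "dna_radius_nm", "n_bp", "genome_mass_pg",
            "dna_density_g_per_mL", "world_radius_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.world_radius_um <= self.cell_radius_um:
            raise ValueError("world radius must exceed the cell radius")


def dna_length_m(bp_length_nm: float = 0.34, n_bp: float = 6.4e9) -> float:
    """Total contour length of the genome in metres (~2.2 m)."""
    return bp_length_nm * 1e-9 * n_bp


def dna_cylinder_volume_um3(
    dna_radius_nm: float = 1.1,
    bp_length_nm: float = 0.34,
    n_bp: float = 6.4e9,
) -> float:
    """Volume of the genome modelled as one long cylinder (~8.3 um^3)."""
    if dna_radius_nm <= 0 or bp_length_nm <= 0 or n_bp < 0:
        raise ValueError("inputs must be positive (n_bp may be zero)")
    r_um = dna_radius_nm * 1e-3
    length_um = bp_length_nm * 1e-3 * n_bp
    return math.pi * r_um**2 * length_um


def sensitive_fraction_geometric(
    dna_radius_nm: float = 1.1,
    bp_length_nm: float = 0.34,
    n_bp: float = 6.4e9,
    nucleus_radius_um: float = 3.1,
) -> float:
    """DNA volume fraction of the nucleus from the cylindrical DNA model.

    Ratio of the DNA-cylinder volume (pi r^2 * rise * n_bp) to the
    spherical nucleus volume.  With the defaults this is ~0.066,
    reported in the field as the 7% ``SPointsProb``.
    """
    if dna_radius_nm <= 0 or bp_length_nm <= 0 or nucleus_radius_um <= 0:
        raise ValueError("all lengths must be strictly positive")
    if n_bp < 0:
        raise ValueError("n_bp must be non-negative")
    dna_vol = dna_cylinder_volume_um3(dna_radius_nm, bp_length_nm, n_bp)
    nucleus_vol = 4.0 / 3.0 * math.pi * nucleus_radius_um**3
    return dna_vol / nucleus_vol


def sensitive_fraction_molecular(
    genome_mass_pg: float = 6.41,
    dna_density_g_per_mL: float = 1.7,
    nucleus_volume_um3: float | None = None,
    nucleus_radius_um: float = 3.1,
) -> float:
    """DNA volume fraction from genome mass and DNA mass density.

    Mass in pg over density in g/mL gives the DNA volume directly in
    um^3 (1 g/mL = 1 pg/um^3).  With the defaults the volume is
    ~3.8 um^3 and the fraction ~0.03 (the molecular 3% figure).
    """
    if genome_mass_pg < 0:
        raise ValueError("genome mass must be non-negative")
    if dna_density_g_per_mL <= 0:
        raise ValueError("DNA density must be strictly positive")
    if nucleus_volume_um3 is None:
        nucleus_volume_um3 = 4.0 / 3.0 * math.pi * nucleus_radius_um**3
    if nucleus_volume_um3 <= 0:
        raise ValueError("nucleus volume must be strictly positive")
    return (genome_mass_pg / dna_density_g_per_mL) / nucleus_volume_um3


def nucleus_metrics(
    nucleus_radius_um: float = 3.1,
    density_kg_per_m3: float = WATER_DENSITY_KG_M3,
) -> dict[str, float]:
    """Volume (um^3), mass (kg) and geometric cross section (um^2).

    The nucleus is a water sphere: volume (4/3) pi r^3, mass
    volume * density, cross section pi r^2 (~124.8 um^3, ~1.25e-13 kg
    and ~30.2 um^2 at r = 3.1 um).
    """
    if nucleus_radius_um <= 0:
        raise ValueError("nucleus radius must be strictly positive")
    if density_kg_per_m3 <= 0:
        raise ValueError("density must be strictly positive")
    volume_um3 = 4.0 / 3.0 * math.pi * nucleus_radius_um**3
    mass_kg = volume_um3 * 1e-18 * density_kg_per_m3  # 1 um^3 = 1e-18 m^3
    cross_section_um2 = math.pi * nucleus_radius_um**2
    return {
        "volume_um3": volume_um3,
        "mass_kg": mass_kg,
        "cross_section_um2": cross_section_um2,
    }


def round_half_up_percent(fraction: float) -> int:
    """Round a fraction to an integer percent, halves away from zero.

    Mirrors how volume fractions are conventionally quoted (0.066 -> 7,
    0.030 -> 3); the unrounded fraction is always available alongside.
    """
    return int(math.floor(fraction * 100.0 + 0.5))
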