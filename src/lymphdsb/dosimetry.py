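"""Dose bookkeeping for 1 h of internal ex vivo blood irradiation.

Converts per-event energy tallies into the quantities reported for
blood-irradiation experiments:

* mean energy deposited in the lymphocyte nuclei per nuclear
  transformation (keV/nt) with its history-by-history standard error;
* the activity corresponding to a number of simulated decays, via
  N1h, the number of decays one Bq undergoes during the 1 h
  irradiation (the decay integral (1 - e^{-lambda t})/lambda, which
  approaches 3600 for long-lived nuclides);
* absorbed dose to whole blood from the blood dose coefficient
  d_Blood (an external input, mGy.mL/MBq for the 8 mL vial);
* the lymphocyte-nucleus dose coefficient d_Lymph on the same
  convention (D = A[MBq] * d / V[mL]), directly comparable to d_Blood;
* DSB per cell per mGy, and the standard deviation over independent
  seed replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "KEV_TO_J",
    "RunTally",
    "NuclideContext",
    "DoseResult",
    "mean_deposited_energy",
    "deposited_energy_uncertainty",
    "transformations_per_hour",
    "activity_from_events",
    "blood_dose",
    "lymph_dose_coefficient",
    "dsb_per_cell_per_mGy",
    "seed_replicate_sd",
]

KEV_TO_J = 1.602176634e-16
SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class RunTally:
    """Per-primary-event energy sums over all scored nuclei.

    ``per_event_energy_keV`` must include zero-deposit events
    explicitly (or be shorter than nt, in which case the missing
    events are implicitly zero).
    """

    per_event_energy_keV: np.ndarray
    nt: int
    n_cells: int = 1000

    def __post_init__(self) -> None:
        e = np.asarray(self.per_event_energy_keV, dtype=float)
        if (e < 0).any():
            raise ValueError("per-event energies must be non-negative")
        if self.nt < len(e):
            raise ValueError("nt must cover every listed event")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        object.__setattr__(self, "per_event_energy_keV", e)

    def padded(self) -> np.ndarray:
        """Event energies with implicit zero-deposit events appended."""
        e = self.per_event_energy_keV
        if len(e) == self.nt:
            return e
        return np.concatenate([e, np.zeros(self.nt - len(e))])


@dataclass(frozen=True)
class NuclideContext:
    """Radionuclide metadata for the dose chain.

    ``d_blood_mGy_mL_per_MBq`` is the whole-blood absorbed dose
    coefficient for the 8 mL vial — an external input from macroscopic
    transport, not something this package computes.
    """

    name: str
    half_life_h: float
    d_blood_mGy_mL_per_MBq: float
    blood_volume_mL: float = 8.0
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValueError("half-life must be positive")
        if self.blood_volume_mL <= 0:
            raise ValueError("blood volume must be positive")

    @property
    def n1h(self) -> float:
        if self.decay_corrected:
            return transformations_per_hour(self.half_life_h)
        return SECONDS_PER_HOUR


@dataclass(frozen=True)
class DoseResult:
    """Outputs of the dose chain for one run."""

    e_dep_lymph_keV_per_nt: float
    e_dep_uncertainty_keV_per_nt: float
    activity_MBq: float
    d_blood_dose_mGy: float
    d_lymph_mGy_mL_per_MBq: float
    dsb_per_cell_per_mGy: float
    dsb_per_cell_per_mGy_sd: float | None = None


def mean_deposited_energy(tally: RunTally) -> float:
    """Sum of per-event energies over (N_cells * nt), in keV/nt."""
    if tally.nt == 0:
        raise ValueError("nt must be >= 1")
    return float(tally.per_event_energy_keV.sum()) / (tally.n_cells * tally.nt)


def deposited_energy_uncertainty(tally: RunTally) -> float:
    """History-by-history standard error of the mean, keV/nt.

    (1/N_cells) * sqrt[(mean(E^2) - mean(E)^2) / (N - 1)] with N = nt,
    zero-deposit events counted as E = 0.
    """
    n = tally.nt
    if n < 2:
        raise ValueError("need at least 2 events for an uncertainty")
    # implicit zero-deposit events contribute nothing to the sums
    e = tally.per_event_energy_keV
    mean_sq = float((e**2).sum()) / n
    sq_mean = (float(e.sum()) / n) ** 2
    var = max(mean_sq - sq_mean, 0.0) / (n - 1)
    return math.sqrt(var) / tally.n_cells


def transformations_per_hour(half_life_h: float) -> float:
    """Decays during 1 h per Bq of initial activity.

    The decay integral N1h = (1 - e^{-lambda * 3600 s}) / lambda with
    lambda = ln2 / half-life; bounded by 3600 and approaching it for
    long-lived nuclides.
    """
    if half_life_h <= 0:
        raise ValueError("half-life must be positive")
    lam_per_s = math.log(2.0) / (half_life_h * SECONDS_PER_HOUR)
    return -math.expm1(-lam_per_s * SECONDS_PER_HOUR) / lam_per_s


def activity_from_events(nt: float, n1h: float) -> float:
    """Activity (MBq) whose 1 h irradiation yields ``nt`` decays."""
    if n1h <= 0:
        raise ValueError("N1h must be positive")
    return nt / (n1h * 1e6)


def blood_dose(
    activity_MBq: float, d_blood_mGy_mL_per_MBq: float, volume_mL: float = 8.0
) -> float:
    """Absorbed dose to whole blood, mGy: A * d_Blood / V."""
    if volume_mL <= 0:
        raise ValueError("volume must be positive")
    return activity_MBq * d_blood_mGy_mL_per_MBq / volume_mL


def lymph_dose_coefficient(
    e_per_nt_keV: float,
    nucleus_mass_kg: float,
    n1h: float,
    volume_mL: float = 8.0,
) -> float:
    """Nucleus dose coefficient d_Lymph, mGy.mL/MBq.

    Defined on the same convention as d_Blood, i.e. so that
    D_nucleus[mGy] = A[MBq] * d_Lymph / V[mL]: the dose per decay
    (E/m) times the decays per Bq.h (N1h), scaled to MBq and mGy and
    multiplied by the vial volume.
    """
    if nucleus_mass_kg <= 0:
        raise ValueError("nucleus mass must be positive")
    gray_per_nt = e_per_nt_keV * KEV_TO_J / nucleus_mass_kg
    return gray_per_nt * n1h * 1e6 * 1e3 * volume_mL


def dsb_per_cell_per_mGy(
    total_dsb: float, n_cells: int, d_blood_dose_mGy: float
) -> float:
    """DSB yield normalized per cell and per mGy of blood dose."""
    if d_blood_dose_mGy <= 0:
        raise ValueError("blood dose must be positive")
    return total_dsb / (n_cells * d_blood_dose_mGy)


def seed_replicate_sd(values: Sequence[float]) -> float:
    """Sample standard deviation (n-1) over independent-seed runs."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 replicates")
    return float(v.std(ddof=1))
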