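"""Alpha-track counting and linear DSB density.

Microscopy counts an alpha track only if it is long enough to show at
least three adjacent damage foci in a row (resolution 250-300 nm, so
the shortest countable track is 0.75-0.9 um) and dense enough in DSBs.
The detectability thresholds are therefore: track length strictly
greater than 0.75 um AND strictly more than 7 DSBs.  Track counts are
normalized per 100 cells and per mGy; the linear DSB density is the
ratio of total DSBs to total alpha track length (a ratio of sums, not
a mean of per-track ratios).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .damage import TrackDamageSummary

__all__ = [
    "AlphaThresholds",
    "apply_track_thresholds",
    "alpha_tracks_per_100cells_per_mGy",
    "linear_dsb_density",
]


@dataclass(frozen=True)
class AlphaThresholds:
    """Experiment-based detectability thresholds (strict comparisons)."""

    min_length_um: float = 0.75
    min_dsb: int = 7

    def __post_init__(self) -> None:
        if self.min_length_um < 0 or self.min_dsb < 0:
            raise ValueError("thresholds must be non-negative")


def apply_track_thresholds(
    summaries: Sequence[TrackDamageSummary],
    thresholds: AlphaThresholds | None = None,
) -> list[TrackDamageSummary]:
    """Keep tracks with length > min_length AND n_DSB > min_dsb.

    Both comparisons are strict: a track of exactly 0.75 um or exactly
    7 DSBs is excluded.  Every summary must carry an alpha track
    length.
    """
    th = thresholds or AlphaThresholds()
    for s in summaries:
        if s.alpha_track_length_um is None:
            raise ValueError(
                f"track {s.track_id} has no alpha track length; "
                "thresholds apply to alpha tracks only"
            )
    return [
        s
        for s in summaries
        if s.alpha_track_length_um > th.min_length_um and s.n_dsb > th.min_dsb
    ]


def alpha_tracks_per_100cells_per_mGy(
    n_tracks: int, n_cells: int, d_blood_dose_mGy: float
) -> float:
    """Alpha tracks per 100 cells per mGy of blood dose."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if d_blood_dose_mGy <= 0:
        raise ValueError("blood dose must be positive")
    return 100.0 * n_tracks / (n_cells * d_blood_dose_mGy)


def linear_dsb_density(summaries: Iterable[TrackDamageSummary]) -> float:
    """Total DSBs over total alpha track length, DSB/um.

    Zero DSBs over a positive length is 0; zero total length is an
    error.
    """
    total_dsb = 0
    total_length = 0.0
    for s in summaries:
        if s.alpha_track_length_um is None:
            raise ValueError(f"track {s.track_id} has no alpha track length")
        total_dsb += s.n_dsb
        total_length += s.alpha_track_length_um
    if total_length <= 0:
        raise ValueError("total alpha track length is zero")
    return total_dsb / total_length
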