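"""Strand-break sampling, DBSCAN clustering and SSB/DSB classification.

The scorer follows the clustering approach used for unstructured-DNA
damage models: the DNA is not modelled explicitly but as a "sensitive"
fraction of the nucleus volume (``SPointsProb``, default 7%).  Each
energy-deposition point is accepted as a single-strand break (SSB)
with probability

    SPointsProb * ramp(E),   ramp(E) = clip((E - EMin)/(EMax - EMin), 0, 1)

with EMin = 5 eV and EMax = 37.5 eV: depositions below 5 eV never
damage, those at or above 37.5 eV always damage if they fall in the
sensitive volume.  Accepted breaks get a random strand label (0/1,
fair coin by default).

Breaks of one primary track are then clustered with DBSCAN using
MinPts = 2 and a neighborhood radius of 10 base pairs (~3.4 nm,
strictly "less than").  With MinPts = 2 the DBSCAN clusters are exactly
the connected components of the eps-proximity graph and the noise
points are isolated breaks.  Classification:

* isolated break               -> SSB
* cluster, one strand only     -> complex SSB
* cluster, both strands        -> DSB
  (size 2 -> simple DSB; size >= 3 -> complex DSB)

Clustering never crosses track boundaries: damage is scored per
primary particle, as in per-event tallies of track-structure codes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.cluster import DBSCAN

from .tracks import NucleusExposure

__all__ = [
    "DamageParameters",
    "BreakCluster",
    "TrackDamageSummary",
    "damage_probability",
    "sample_breaks",
    "cluster_breaks",
    "classify_clusters",
    "score_track",
    "score_exposure",
    "brute_force_cluster",
    "summaries_to_frame",
    "frame_to_summaries",
]

BREAK_COLUMNS = ("x_nm", "y_nm", "z_nm", "strand", "track_id")


@dataclass(frozen=True)
class DamageParameters:
    """Constants of the strand-break model.

    eps is the DSB pairing distance: 10 bp at 0.34 nm/bp = 3.4 nm.
    """

    s_points_prob: float = 0.07
    e_min_damage_eV: float = 5.0
    e_max_damage_eV: float = 37.5
    eps_nm: float = 3.4
    min_pts: int = 2
    strand_prob: float = 0.5
    bp_length_nm: float = 0.34

    def __post_init__(self) -> None:
        if not 0.0 <= self.s_points_prob <= 1.0:
            raise ValueError("s_points_prob must be in [0, 1]")
        if not self.e_min_damage_eV < self.e_max_damage_eV:
            raise ValueError("need e_min_damage < e_max_damage")
        if self.eps_nm <= 0:
            raise ValueError("eps must be positive")
        if self.min_pts < 2:
            raise ValueError("min_pts must be >= 2")
        if not 0.0 <= self.strand_prob <= 1.0:
            raise ValueError("strand_prob must be in [0, 1]")


@dataclass(frozen=True)
class BreakCluster:
    """A DBSCAN cluster of strand breaks (size >= 2)."""

    members: pd.DataFrame
    size: int
    strands_present: frozenset
    max_span_nm: float


@dataclass(frozen=True)
class TrackDamageSummary:
    """Per-primary-particle damage tallies."""

    track_id: int
    particle_name: str
    n_ssb: int
    n_complex_ssb: int
    n_dsb: int
    n_simple_dsb: int
    n_complex_dsb: int
    cluster_size_histogram: dict[int, int]
    n_breaks: int
    deposited_energy_eV: float
    alpha_track_length_um: float | None = None

    def __post_init__(self) -> None:
        if self.n_dsb != self.n_simple_dsb + self.n_complex_dsb:
            raise ValueError("n_dsb must equal n_simple_dsb + n_complex_dsb")
        clustered = sum(s * c for s, c in self.cluster_size_histogram.items())
        if clustered + self.n_ssb != self.n_breaks:
            raise ValueError("cluster sizes + isolated breaks != total breaks")


def damage_probability(
    energy_eV: float | np.ndarray, params: DamageParameters | None = None
) -> float | np.ndarray:
    """Clamped linear damage ramp in the deposited energy."""
    p = params or DamageParameters()
    e = np.asarray(energy_eV, dtype=float)
    ramp = (e - p.e_min_damage_eV) / (p.e_max_damage_eV - p.e_min_damage_eV)
    out = np.clip(ramp, 0.0, 1.0)
    return float(out) if np.isscalar(energy_eV) else out


def sample_breaks(
    depositions: pd.DataFrame,
    params: DamageParameters | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> pd.DataFrame:
    """Accept depositions as strand breaks.

    A single Bernoulli draw per deposition with probability
    ``SPointsProb * ramp(E)`` (statistically identical to drawing the
    sensitive-volume and damage decisions separately).  The uniform
    stream is drawn for every deposition regardless of acceptance, so
    runs with different SPointsProb on the same seed are coupled:
    raising SPointsProb can only add breaks.
    """
    p = params or DamageParameters()
    rng = np.random.default_rng(seed)
    n = len(depositions)
    u = rng.random(n)
    strands = (rng.random(n) < p.strand_prob).astype(int)
    prob = p.s_points_prob * damage_probability(
        depositions["edep_eV"].to_numpy(), p
    )
    accept = u < prob
    out = pd.DataFrame(
        {
            "x_nm": depositions["x_nm"].to_numpy()[accept],
            "y_nm": depositions["y_nm"].to_numpy()[accept],
            "z_nm": depositions["z_nm"].to_numpy()[accept],
            "strand": strands[accept],
            "track_id": depositions["track_id"].to_numpy()[accept]
            if "track_id" in depositions
            else np.zeros(int(accept.sum()), dtype=int),
        }
    )
    return out.reset_index(drop=True)


def _cluster_sort_key(members: pd.DataFrame) -> tuple:
    pos = members[["x_nm", "y_nm", "z_nm"]].to_numpy()
    return tuple(pos.min(axis=0))


def cluster_breaks(
    breaks: pd.DataFrame, params: DamageParameters | None = None
) -> tuple[list[BreakCluster], pd.DataFrame]:
    """DBSCAN the breaks; returns (clusters, isolated breaks).

    The pairing inequality is strict (two breaks exactly eps apart do
    not join), realized by running DBSCAN at the largest double below
    eps.  Cluster identity is the partition, not the discovery order;
    the returned list is sorted by minimum member coordinates.
    """
    p = params or DamageParameters()
    empty = breaks.iloc[0:0]
    if len(breaks) == 0:
        return [], empty
    X = breaks[["x_nm", "y_nm", "z_nm"]].to_numpy()
    # d < eps  <=>  d <= nextafter(eps, 0) in double precision
    labels = DBSCAN(eps=np.nextafter(p.eps_nm, 0.0), min_samples=p.min_pts).fit(
        X
    ).labels_
    clusters = []
    for label in np.unique(labels):
        if label < 0:
            continue
        members = breaks[labels == label]
        pos = members[["x_nm", "y_nm", "z_nm"]].to_numpy()
        span = float(pdist(pos).max()) if len(pos) > 1 else 0.0
        clusters.append(
            BreakCluster(
                members=members.reset_index(drop=True),
                size=len(members),
                strands_present=frozenset(members["strand"].tolist()),
                max_span_nm=span,
            )
        )
    clusters.sort(key=lambda c: _cluster_sort_key(c.members))
    isolated = breaks[labels < 0].reset_index(drop=True)
    return clusters, isolated


def classify_clusters(
    clusters: list[BreakCluster], isolated: pd.DataFrame
) -> dict:
    """SSB / complex SSB / simple and complex DSB tallies.

    * isolated break: SSB
    * cluster with one strand represented: complex SSB (>= 2 breaks on
      the same strand)
    * cluster with both strands: DSB — simple at size 2, complex at
      size >= 3 (at least one break on the opposite strand)
    """
    n_ssb = len(isolated)
    n_complex_ssb = n_simple_dsb = n_complex_dsb = 0
    hist: dict[int, int] = {}
    for cluster in clusters:
        if cluster.size < 2:
            raise ValueError("internal inconsistency: cluster of size < 2")
        hist[cluster.size] = hist.get(cluster.size, 0) + 1
        if len(cluster.strands_present) == 1:
            n_complex_ssb += 1
        elif cluster.size == 2:
            n_simple_dsb += 1
        else:
            n_complex_dsb += 1
    return {
        "n_ssb": n_ssb,
        "n_complex_ssb": n_complex_ssb,
        "n_dsb": n_simple_dsb + n_complex_dsb,
        "n_simple_dsb": n_simple_dsb,
        "n_complex_dsb": n_complex_dsb,
        "cluster_size_histogram": hist,
    }


def score_track(
    depositions: pd.DataFrame,
    params: DamageParameters | None = None,
    seed: int | np.random.SeedSequence = 0,
    particle_name: str | None = None,
    alpha_track_length_um: float | None = None,
) -> TrackDamageSummary:
    """Sample, cluster and classify the depositions of one primary."""
    p = params or DamageParameters()
    track_ids = depositions["track_id"].unique() if len(depositions) else []
    if len(track_ids) > 1:
        raise ValueError(f"mixed track_ids in one track: {sorted(track_ids)}")
    track_id = int(track_ids[0]) if len(track_ids) else -1
    if particle_name is None:
        particle_name = (
            str(depositions["particle"].iloc[0])
            if "particle" in depositions and len(depositions)
            else "unknown"
        )
    breaks = sample_breaks(depositions, p, seed)
    clusters, isolated = cluster_breaks(breaks, p)
    counts = classify_clusters(clusters, isolated)
    return TrackDamageSummary(
        track_id=track_id,
        particle_name=particle_name,
        n_breaks=len(breaks),
        deposited_energy_eV=float(depositions["edep_eV"].sum())
        if len(depositions)
        else 0.0,
        alpha_track_length_um=alpha_track_length_um,
        **counts,
    )


def score_exposure(
    exposure: NucleusExposure,
    params: DamageParameters | None = None,
    seed: int = 0,
) -> list[TrackDamageSummary]:
    """Score every primary of an exposure; one summary per track.

    Clustering is confined to each track's own breaks.  Per-track
    random streams are split from ``(seed, track_id)``, so scores do
    not depend on iteration order.
    """
    p = params or DamageParameters()
    grouped = dict(tuple(exposure.depositions.groupby("track_id")))
    summaries = []
    for row in exposure.tracks.itertuples(index=False):
        dep = grouped.get(row.track_id)
        if dep is None:
            dep = exposure.depositions.iloc[0:0].copy()
            dep["track_id"] = dep["track_id"].astype(int)
        length = float(row.chord_um) if row.particle == "alpha" else None
        summary = score_track(
            dep,
            p,
            seed=np.random.SeedSequence((seed, 2, int(row.track_id))),
            particle_name=str(row.particle),
            alpha_track_length_um=length,
        )
        if summary.track_id < 0:  # empty deposition list keeps track identity
            summary = TrackDamageSummary(
                **{**summary.__dict__, "track_id": int(row.track_id)}
            )
        summaries.append(summary)
    return summaries


def brute_force_cluster(
    breaks: pd.DataFrame, eps_nm: float
) -> tuple[list[np.ndarray], np.ndarray]:
    """Independent O(n^2) clustering oracle.

    Transitive closure of the strict pairwise distance-< eps relation
    by exhaustive scan and union-find.  Returns (clusters as index
    arrays into ``breaks``, isolated indices); intended for <= 5000
    points.
    """
    n = len(breaks)
    if n > 5000:
        raise ValueError("brute-force oracle limited to 5000 breaks")
    if n == 0:
        return [], np.array([], dtype=int)
    pos = breaks[["x_nm", "y_nm", "z_nm"]].to_numpy()
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        d2 = np.einsum("ij,ij->i", pos[i + 1:] - pos[i], pos[i + 1:] - pos[i])
        for j in np.nonzero(d2 < eps_nm**2)[0]:
            ra, rb = find(i), find(int(i + 1 + j))
            if ra != rb:
                parent[rb] = ra
    roots: dict[int, list[int]] = {}
    for i in range(n):
        roots.setdefault(find(i), []).append(i)
    clusters = [np.array(v) for v in roots.values() if len(v) >= 2]
    isolated = np.array(
        sorted(i for v in roots.values() if len(v) == 1 for i in v), dtype=int
    )
    return clusters, isolated


def summaries_to_frame(summaries: Iterable[TrackDamageSummary]) -> pd.DataFrame:
    """One row per track; the histogram is serialized as 'size:count;...'."""
    rows = []
    for s in summaries:
        hist = ";".join(
            f"{k}:{v}" for k, v in sorted(s.cluster_size_histogram.items())
        )
        rows.append(
            {
                "track_id": s.track_id,
                "particle": s.particle_name,
                "n_ssb": s.n_ssb,
                "n_complex_ssb": s.n_complex_ssb,
                "n_dsb": s.n_dsb,
                "n_simple_dsb": s.n_simple_dsb,
                "n_complex_dsb": s.n_complex_dsb,
                "n_breaks": s.n_breaks,
                "deposited_energy_eV": s.deposited_energy_eV,
                "alpha_track_length_um": (
                    np.nan
                    if s.alpha_track_length_um is None
                    else s.alpha_track_length_um
                ),
                "cluster_size_histogram": hist,
            }
        )
    return pd.DataFrame(rows)


def frame_to_summaries(df: pd.DataFrame) -> list[TrackDamageSummary]:
    out = []
    for row in df.itertuples(index=False):
        hist = {}
        raw = getattr(row, "cluster_size_histogram", "")
        if isinstance(raw, str) and raw:
            for item in raw.split(";"):
                k, _, v = item.partition(":")
                hist[int(k)] = int(v)
        length = row.alpha_track_length_um
        out.append(
            TrackDamageSummary(
                track_id=int(row.track_id),
                particle_name=str(row.particle),
                n_ssb=int(row.n_ssb),
                n_complex_ssb=int(row.n_complex_ssb),
                n_dsb=int(row.n_dsb),
                n_simple_dsb=int(row.n_simple_dsb),
                n_complex_dsb=int(row.n_complex_dsb),
                cluster_size_histogram=hist,
                n_breaks=int(row.n_breaks),
                deposited_energy_eV=float(row.deposited_energy_eV),
                alpha_track_length_um=None if pd.isna(length) else float(length),
            )
        )
    return out
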