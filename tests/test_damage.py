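import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import make_breaks, make_depositions
from lymphdsb.damage import (
    DamageParameters,
    TrackDamageSummary,
    brute_force_cluster,
    classify_clusters,
    cluster_breaks,
    damage_probability,
    frame_to_summaries,
    sample_breaks,
    score_exposure,
    score_track,
    summaries_to_frame,
)
from lymphdsb.tracks import NucleusExposure


class TestDamageProbability:
    @pytest.mark.parametrize(
        "energy,expected",
        [(0.0, 0.0), (5.0, 0.0), (21.25, 0.5), (37.5, 1.0), (100.0, 1.0)],
    )
    def test_ramp(self, energy, expected):
        assert damage_probability(energy) == pytest.approx(expected)

    def test_monotone_nondecreasing(self):
        e = np.linspace(0, 60, 500)
        p = damage_probability(e)
        assert (np.diff(p) >= 0).all()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            DamageParameters(e_min_damage_eV=40.0, e_max_damage_eV=37.5)
        with pytest.raises(ValueError):
            DamageParameters(s_points_prob=1.5)
        with pytest.raises(ValueError):
            DamageParameters(min_pts=1)


class TestSampleBreaks:
    def test_low_energy_depositions_never_break(self):
        dep = make_depositions(np.zeros((100, 3)), np.full(100, 5.0))
        assert len(sample_breaks(dep, seed=1)) == 0

    def test_zero_sensitive_fraction_never_breaks(self):
        dep = make_depositions(np.zeros((100, 3)), np.full(100, 100.0))
        params = DamageParameters(s_points_prob=0.0)
        assert len(sample_breaks(dep, params, seed=1)) == 0

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(0)
        dep = make_depositions(rng.normal(size=(500, 3)), rng.uniform(5, 60, 500))
        a = sample_breaks(dep, seed=7)
        b = sample_breaks(dep, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_raising_spointsprob_only_adds_breaks(self):
        # coupled uniform stream: acceptance is monotone in SPointsProb
        rng = np.random.default_rng(1)
        dep = make_depositions(rng.normal(size=(2000, 3)), rng.uniform(0, 60, 2000))
        for seed in range(10):
            lo = len(sample_breaks(dep, DamageParameters(s_points_prob=0.05), seed))
            hi = len(sample_breaks(dep, DamageParameters(s_points_prob=0.20), seed))
            assert hi >= lo

    def test_strand_labels_are_binary(self):
        rng = np.random.default_rng(2)
        dep = make_depositions(rng.normal(size=(300, 3)), np.full(300, 50.0))
        breaks = sample_breaks(dep, DamageParameters(s_points_prob=1.0), seed=3)
        assert set(breaks["strand"]) <= {0, 1}
        assert len(breaks) == 300  # certain acceptance above EMax


class TestClusterBreaks:
    def test_pair_within_eps_clusters(self):
        b = make_breaks([[0, 0, 0], [3.0, 0, 0]], [0, 1])
        clusters, isolated = cluster_breaks(b)
        assert len(clusters) == 1 and clusters[0].size == 2
        assert len(isolated) == 0

    def test_pair_beyond_eps_isolated(self):
        b = make_breaks([[0, 0, 0], [3.5, 0, 0]], [0, 1])
        clusters, isolated = cluster_breaks(b)
        assert clusters == [] and len(isolated) == 2

    def test_exact_eps_distance_does_not_join(self):
        b = make_breaks([[0, 0, 0], [3.4, 0, 0]], [0, 1])
        clusters, isolated = cluster_breaks(b)
        assert clusters == [] and len(isolated) == 2

    def test_chain_is_transitively_connected(self):
        # A-B and B-C within eps, A-C at 6.0 nm: one cluster of 3
        b = make_breaks([[0, 0, 0], [3.0, 0, 0], [6.0, 0, 0]], [0, 1, 0])
        clusters, isolated = cluster_breaks(b)
        assert len(clusters) == 1 and clusters[0].size == 3
        assert clusters[0].max_span_nm == pytest.approx(6.0)
        assert len(isolated) == 0

    def test_partition_is_input_order_independent(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 30, size=(60, 3))
        b = make_breaks(pos, rng.integers(0, 2, 60))
        shuffled = b.sample(frac=1.0, random_state=5).reset_index(drop=True)

        def partition(frame):
            clusters, isolated = cluster_breaks(frame)
            key = lambda df: frozenset(
                map(tuple, df[["x_nm", "y_nm", "z_nm"]].to_numpy())
            )
            return (
                {key(c.members) for c in clusters},
                key(isolated) if len(isolated) else frozenset(),
            )

        assert partition(b) == partition(shuffled)

    def test_empty_input(self):
        clusters, isolated = cluster_breaks(make_breaks(np.empty((0, 3)), []))
        assert clusters == [] and len(isolated) == 0


class TestBruteForceOracle:
    def test_all_identical_points_one_cluster(self):
        b = make_breaks(np.zeros((7, 3)), np.zeros(7))
        clusters, isolated = brute_force_cluster(b, 3.4)
        assert len(clusters) == 1 and len(clusters[0]) == 7
        assert isolated.size == 0

    def test_empty(self):
        clusters, isolated = brute_force_cluster(
            make_breaks(np.empty((0, 3)), []), 3.4
        )
        assert clusters == [] and isolated.size == 0

    def test_matches_dbscan_on_random_fixture(self):
        rng = np.random.default_rng(11)
        pos = rng.uniform(0, 40, size=(300, 3))
        b = make_breaks(pos, rng.integers(0, 2, 300))
        clusters, isolated = cluster_breaks(b)
        bf_clusters, bf_isolated = brute_force_cluster(b, 3.4)
        ours = {
            frozenset(map(tuple, c.members[["x_nm", "y_nm", "z_nm"]].to_numpy()))
            for c in clusters
        }
        theirs = {
            frozenset(map(tuple, pos[idx])) for idx in bf_clusters
        }
        assert ours == theirs
        assert len(isolated) == bf_isolated.size

    def test_size_guard(self):
        b = make_breaks(np.zeros((5001, 3)), np.zeros(5001))
        with pytest.raises(ValueError, match="5000"):
            brute_force_cluster(b, 3.4)


class TestClassification:
    def run(self, positions, strands):
        clusters, isolated = cluster_breaks(make_breaks(positions, strands))
        return classify_clusters(clusters, isolated)

    def test_opposite_strand_pair_is_simple_dsb(self):
        c = self.run([[0, 0, 0], [1, 0, 0]], [0, 1])
        assert c["n_simple_dsb"] == 1 and c["n_dsb"] == 1
        assert c["n_complex_ssb"] == 0 and c["n_ssb"] == 0

    def test_same_strand_pair_is_complex_ssb(self):
        c = self.run([[0, 0, 0], [1, 0, 0]], [0, 0])
        assert c["n_complex_ssb"] == 1 and c["n_dsb"] == 0

    def test_three_breaks_both_strands_is_complex_dsb(self):
        c = self.run([[0, 0, 0], [1, 0, 0], [2, 0, 0]], [0, 0, 1])
        assert c["n_complex_dsb"] == 1 and c["n_dsb"] == 1
        assert c["n_simple_dsb"] == 0

    def test_isolated_break_is_ssb(self):
        c = self.run([[0, 0, 0], [100, 0, 0]], [0, 1])
        assert c["n_ssb"] == 2 and c["n_dsb"] == 0

    def test_histogram_and_conservation(self):
        rng = np.random.default_rng(6)
        pos = rng.uniform(0, 25, size=(80, 3))
        b = make_breaks(pos, rng.integers(0, 2, 80))
        clusters, isolated = cluster_breaks(b)
        c = classify_clusters(clusters, isolated)
        clustered = sum(s * n for s, n in c["cluster_size_histogram"].items())
        assert clustered + c["n_ssb"] == len(b)
        assert c["n_dsb"] == c["n_simple_dsb"] + c["n_complex_dsb"]

    def test_undersized_cluster_is_internal_error(self):
        from lymphdsb.damage import BreakCluster

        bad = BreakCluster(
            members=make_breaks([[0, 0, 0]], [0]),
            size=1,
            strands_present=frozenset({0}),
            max_span_nm=0.0,
        )
        with pytest.raises(ValueError, match="size < 2"):
            classify_clusters([bad], make_breaks(np.empty((0, 3)), []))


class TestScoreTrack:
    def test_empty_depositions_all_zero(self):
        dep = make_depositions(np.empty((0, 3)), [])
        s = score_track(dep, seed=0)
        assert s.n_breaks == 0 and s.n_dsb == 0 and s.deposited_energy_eV == 0.0

    def test_single_deposit_cannot_form_dsb(self):
        dep = make_depositions([[0, 0, 0]], [1e6])
        for seed in range(20):
            s = score_track(dep, seed=seed)
            assert s.n_breaks <= 1 and s.n_dsb == 0

    def test_deterministic_summary(self):
        rng = np.random.default_rng(9)
        dep = make_depositions(rng.uniform(0, 20, (50, 3)), rng.uniform(5, 60, 50))
        a = score_track(dep, seed=4)
        b = score_track(dep, seed=4)
        assert a == b

    def test_mixed_track_ids_rejected(self):
        dep = pd.concat(
            [
                make_depositions([[0, 0, 0]], [50.0], track_id=0),
                make_depositions([[1, 0, 0]], [50.0], track_id=1),
            ],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="mixed track_ids"):
            score_track(dep, seed=0)

    def test_strand_prob_one_never_yields_dsb(self):
        rng = np.random.default_rng(10)
        dep = make_depositions(rng.uniform(0, 5, (200, 3)), np.full(200, 100.0))
        params = DamageParameters(strand_prob=1.0, s_points_prob=1.0)
        s = score_track(dep, params, seed=1)
        assert s.n_breaks == 200
        assert s.n_dsb == 0 and s.n_complex_ssb > 0


class TestScoreExposure:
    def make_exposure(self, dep_frames, particles=None):
        dep = pd.concat(dep_frames, ignore_index=True)
        ids = sorted(dep["track_id"].unique())
        particles = particles or ["e-"] * len(ids)
        tracks = pd.DataFrame(
            {
                "track_id": ids,
                "particle": particles,
                "ekin_MeV": [1.0] * len(ids),
                "chord_um": [6.2] * len(ids),
            }
        )
        return NucleusExposure(dep, tracks)

    def test_clustering_never_crosses_tracks(self):
        # two certain breaks 1 nm apart but on different primaries
        exp = self.make_exposure(
            [
                make_depositions([[0, 0, 0]], [1e6], track_id=0),
                make_depositions([[1, 0, 0]], [1e6], track_id=1),
            ]
        )
        params = DamageParameters(s_points_prob=1.0)
        summaries = score_exposure(exp, params, seed=0)
        assert sum(s.n_dsb for s in summaries) == 0
        assert sum(s.n_ssb for s in summaries) == 2

    def test_one_summary_per_track_and_additivity(self):
        rng = np.random.default_rng(12)
        frames = [
            make_depositions(
                rng.uniform(0, 10, (30, 3)), rng.uniform(5, 60, 30), track_id=i
            )
            for i in range(5)
        ]
        exp = self.make_exposure(frames)
        summaries = score_exposure(exp, seed=3)
        assert len(summaries) == 5
        assert [s.track_id for s in summaries] == list(range(5))
        total = sum(s.n_dsb for s in summaries)
        assert total == sum(s.n_simple_dsb + s.n_complex_dsb for s in summaries)

    def test_alpha_tracks_carry_length(self):
        exp = self.make_exposure(
            [make_depositions([[0, 0, 0]], [50.0], track_id=0, particle="alpha")],
            particles=["alpha"],
        )
        (s,) = score_exposure(exp, seed=0)
        assert s.alpha_track_length_um == pytest.approx(6.2)


class TestRigidMotionInvariance:
    @given(
        shift=st.tuples(*[st.floats(-50, 50) for _ in range(3)]),
        angle=st.floats(0, 2 * np.pi),
        seed=st.integers(0, 50),
    )
    def test_counts_invariant_under_translation_rotation(self, shift, angle, seed):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 20, size=(40, 3))
        strands = rng.integers(0, 2, 40)
        c, a = np.cos(angle), np.sin(angle)
        rot = np.array([[c, -a, 0], [a, c, 0], [0, 0, 1]])
        moved = pos @ rot.T + np.asarray(shift)
        before = classify_clusters(*cluster_breaks(make_breaks(pos, strands)))
        after = classify_clusters(*cluster_breaks(make_breaks(moved, strands)))
        for key in ("n_ssb", "n_complex_ssb", "n_dsb", "n_simple_dsb",
                    "n_complex_dsb"):
            assert before[key] == after[key]


class TestSummaryFrame:
    def test_round_trip(self):
        s = TrackDamageSummary(
            track_id=3,
            particle_name="alpha",
            n_ssb=2,
            n_complex_ssb=1,
            n_dsb=2,
            n_simple_dsb=1,
            n_complex_dsb=1,
            cluster_size_histogram={2: 2, 3: 1},
            n_breaks=9,
            deposited_energy_eV=1234.5,
            alpha_track_length_um=4.2,
        )
        (back,) = frame_to_summaries(summaries_to_frame([s]))
        assert back == s

    def test_inconsistent_summary_rejected(self):
        with pytest.raises(ValueError):
            TrackDamageSummary(
                track_id=0, particle_name="e-", n_ssb=0, n_complex_ssb=0,
                n_dsb=1, n_simple_dsb=0, n_complex_dsb=0,
                cluster_size_histogram={}, n_breaks=0, deposited_energy_eV=0.0,
            )
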