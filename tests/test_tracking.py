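"""Linking, gap repair, sub-track fusion and speed estimation."""

import numpy as np
import pytest
from conftest import nucleus_frame

import epibolykit as ek
from epibolykit.records import Track


def greedy_oracle(pa, pb, max_dist):
    """Independent brute-force enumeration of the sorted-greedy rule."""
    edges = sorted(
        (np.linalg.norm(pa[i] - pb[j]), i, j)
        for i in range(len(pa))
        for j in range(len(pb))
        if np.linalg.norm(pa[i] - pb[j]) <= max_dist
    )
    used_a, used_b, out = set(), set(), []
    for _, i, j in edges:
        if i not in used_a and j not in used_b:
            used_a.add(i)
            used_b.add(j)
            out.append((i, j))
    return out


class TestLinkFrames:
    def test_close_pair_matched(self):
        a = nucleus_frame(np.array([[0.0, 0.0, 0.0]]))
        b = nucleus_frame(np.array([[2.0, 0.0, 0.0]]), frame=1)
        assert ek.link_frames(a, b, 10.0) == [(0, 0)]

    def test_distant_pair_unmatched(self):
        a = nucleus_frame(np.array([[0.0, 0.0, 0.0]]))
        b = nucleus_frame(np.array([[15.0, 0.0, 0.0]]), frame=1)
        assert ek.link_frames(a, b, 10.0) == []

    def test_empty_frames_allowed(self):
        empty = nucleus_frame(np.zeros((0, 3)))
        assert ek.link_frames(empty, empty, 5.0) == []

    def test_matches_brute_force_greedy_oracle(self, rng):
        pa = rng.uniform(0, 30, (20, 3))
        pb = pa + rng.normal(0, 2.0, (20, 3))
        got = sorted(
            ek.link_frames(nucleus_frame(pa), nucleus_frame(pb, frame=1), 6.0)
        )
        assert got == sorted(greedy_oracle(pa, pb, 6.0))

    def test_recovers_ground_truth_when_spacing_exceeds_displacement(self, control_truth):
        # inter-nucleus spacing >= 3x per-step displacement by construction
        df = control_truth.nuclei
        f0 = df[df["frame"] == 0].reset_index(drop=True)
        f1 = df[df["frame"] == 1].reset_index(drop=True)
        assignment = ek.link_frames(f0, f1, 4.0)
        assert len(assignment) == len(f0)
        for i, j in assignment:
            assert f0.loc[i, "track_id"] == f1.loc[j, "track_id"]


def straight_track(tid, frames, start=(0.0, 0.0, 0.0), step=(1.0, 0.0, 0.0)):
    frames = np.asarray(frames)
    pos = np.asarray(start) + np.outer(frames - frames[0], np.asarray(step))
    return Track(track_id=tid, frames=frames, positions=pos)


class TestGapRepair:
    def test_deleted_internal_frame_recovered_at_midpoint(self, rng):
        """Delete one internal detection and recover the original track."""
        full = straight_track(0, np.arange(10))
        a = Track(0, np.arange(5), full.positions[:5])
        b = Track(1, np.arange(6, 10), full.positions[6:])
        params = ek.TrackingParams(gap_link_distance=8.0)
        repaired = ek.repair_single_frame_gaps([a, b], params)
        assert len(repaired) == 1
        t = repaired[0]
        assert list(t.frames) == list(range(10))
        i5 = list(t.frames).index(5)
        assert t.flags[i5] == "interpolated"
        # midpoint of frames 4 and 6 = true frame-5 position (within half a step)
        assert np.linalg.norm(t.positions[i5] - full.positions[5]) <= 0.5

    def test_no_gaps_is_identity(self):
        t = straight_track(0, np.arange(8))
        out = ek.repair_single_frame_gaps([t], ek.TrackingParams())
        assert len(out) == 1
        assert np.array_equal(out[0].positions, t.positions)

    def test_endpoints_too_far_stay_separate(self):
        a = straight_track(0, np.arange(5))
        b = straight_track(1, np.arange(6, 10), start=(100.0, 0, 0))
        out = ek.repair_single_frame_gaps([a, b], ek.TrackingParams(gap_link_distance=8.0))
        assert len(out) == 2


class TestFuseSubtracks:
    def test_abutting_halves_fuse_into_one(self):
        full = straight_track(0, np.arange(10))
        a = Track(0, np.arange(5), full.positions[:5])
        b = Track(1, np.arange(5, 10), full.positions[5:])
        fused = ek.fuse_subtracks([a, b], ek.TrackingParams(fuse_start_end_distance=8.0))
        assert len(fused) == 1
        assert fused[0].provenance == [0, 1]
        assert not fused[0].has_gaps()

    def test_single_track_maps_to_itself(self):
        t = straight_track(3, np.arange(6))
        fused = ek.fuse_subtracks([t], ek.TrackingParams())
        assert len(fused) == 1
        assert fused[0].track_id == 3

    def test_three_way_chain_fuses(self):
        full = straight_track(0, np.arange(12))
        parts = [
            Track(0, np.arange(0, 4), full.positions[0:4]),
            Track(1, np.arange(4, 8), full.positions[4:8]),
            Track(2, np.arange(8, 12), full.positions[8:12]),
        ]
        fused = ek.fuse_subtracks(parts, ek.TrackingParams(fuse_start_end_distance=8.0))
        assert len(fused) == 1
        assert fused[0].provenance == [0, 1, 2]
        assert list(fused[0].frames) == list(range(12))


class TestEndToEndRecovery:
    def test_dropout_corrupted_tracks_recovered(self, control_truth):
        """>= 95% of ground-truth tracks come back as single tracks with
        zero cross-track links after repair and fusion (5% dropouts)."""
        df = control_truth.nuclei
        rng = np.random.default_rng(123)
        obs = ek.apply_dropout(df, 0.05, rng)
        params = ek.TrackingParams(
            max_link_distance=4.0, gap_link_distance=6.0, fuse_start_end_distance=6.0
        )
        tracks = ek.track_nuclei(obs, params)
        key = {
            (int(row.frame), float(row.x_um), float(row.y_um), float(row.z_um)): row.track_id
            for row in obs.itertuples()
        }
        hits = {}
        for t in tracks:
            true_ids = {
                key[(int(t.frames[i]), float(t.positions[i][0]),
                     float(t.positions[i][1]), float(t.positions[i][2]))]
                for i in range(len(t))
                if t.flags[i] == "observed"
            }
            assert len(true_ids) == 1, "cross-track link detected"
            tid = true_ids.pop()
            hits.setdefault(tid, 0)
            hits[tid] += 1
        n_true = df["track_id"].nunique()
        singles = sum(1 for v in hits.values() if v == 1)
        assert singles / n_true >= 0.95

    def test_tracks_gap_free_after_pipeline(self, control_truth):
        rng = np.random.default_rng(5)
        obs = ek.apply_dropout(control_truth.nuclei, 0.05, rng)
        tracks = ek.track_nuclei(obs, ek.TrackingParams(max_link_distance=4.0))
        assert all(not t.has_gaps() for t in tracks)


class TestSpeed:
    def test_constant_velocity(self):
        t = straight_track(0, np.arange(11))  # 1 µm per frame
        assert ek.estimate_mean_speed([t], window=10, frame_interval=2.0) == pytest.approx(0.5)

    def test_stationary_tracks_give_zero(self):
        t = Track(0, np.arange(11), np.tile([3.0, 4.0, 5.0], (11, 1)))
        assert ek.estimate_mean_speed([t], window=10, frame_interval=1.0) == 0.0

    def test_short_track_rejected(self):
        t = straight_track(0, np.arange(5))
        with pytest.raises(ValueError, match="shorter"):
            ek.estimate_mean_speed([t], window=10, frame_interval=1.0)

    def test_recovers_configured_speed_within_3_se(self):
        rng = np.random.default_rng(17)
        v, jitter = 1.0, 0.1
        tracks = ek.constant_speed_tracks(
            10, 100, speed=v, frame_interval=2.0, speed_jitter_sd=jitter,
            heading_sd=0.2, rng=rng,
        )
        est = ek.estimate_mean_speed(tracks, window=100, frame_interval=2.0)
        n_steps = 10 * 100
        se = jitter / np.sqrt(n_steps)
        assert abs(est - v) <= 3 * se

    def test_rotation_invariance(self, rng):
        tracks = ek.constant_speed_tracks(5, 30, speed=1.0, rng=rng)
        # random rotation via QR decomposition
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        rotated = [
            Track(t.track_id, t.frames, t.positions @ q.T) for t in tracks
        ]
        v0 = ek.estimate_mean_speed(tracks, window=30, frame_interval=1.0)
        v1 = ek.estimate_mean_speed(rotated, window=30, frame_interval=1.0)
        assert v0 == pytest.approx(v1, rel=1e-12)

    def test_interpolated_steps_excluded_by_default(self):
        pos = np.outer(np.arange(11), [1.0, 0, 0])
        flags = ["observed"] * 11
        flags[5] = "interpolated"
        pos[5] = [100.0, 0, 0]  # absurd interpolated point must not count
        t = Track(0, np.arange(11), pos, flags=flags)
        v = ek.estimate_mean_speed([t], window=10, frame_interval=1.0)
        assert v == pytest.approx(1.0)
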