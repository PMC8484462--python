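"""Linking, motion features, windows, and exclusion rules."""

import numpy as np
import pandas as pd
import pytest

import killscope as ks
from killscope.track import LinkParams, apply_exclusions, build_tracks, link, motion_features, windows, windows_meta


def frame_df(points, frame_index=0, area=1000.0):
    return pd.DataFrame(
        {
            "frame_index": frame_index,
            "region_id": np.arange(1, len(points) + 1),
            "x_coord": [p[0] for p in points],
            "y_coord": [p[1] for p in points],
            "area": area,
        }
    )


class TestLink:
    def test_identical_frames_identity_assignment(self):
        pts = [(10, 10), (50, 80), (200, 30)]
        a = frame_df(pts, 0)
        b = frame_df(pts, 1)
        assert link(a, b, LinkParams(), 0.5) == [(0, 0), (1, 1), (2, 2)]

    def test_empty_frames_yield_empty_assignment(self):
        a = frame_df([])
        b = frame_df([(1, 1)])
        assert link(a, b, LinkParams(), 0.5) == []
        assert link(b, a, LinkParams(), 0.5) == []

    def test_gate_blocks_distant_matches(self):
        a = frame_df([(0, 0)])
        b = frame_df([(100, 100)])
        assert link(a, b, LinkParams(max_disp_um=5), 0.5) == []

    def test_contested_pair_minimizes_total_displacement(self):
        """Two cells both within gate of both candidates: the assignment
        matching each to its near partner (total 2 px) beats the swap
        (total 18 px), as brute-force enumeration confirms."""
        a = frame_df([(0.0, 0.0), (10.0, 0.0)])
        b = frame_df([(1.0, 0.0), (9.0, 0.0)])
        params = LinkParams(max_disp_um=20.0)
        got = link(a, b, params, 1.0)
        costs = {
            ((0, 0), (1, 1)): 1 + 1,
            ((0, 1), (1, 0)): 9 + 9,
        }
        best = min(costs, key=costs.get)
        assert tuple(got) == best

    def test_assignment_is_one_to_one(self):
        rng = np.random.default_rng(0)
        a = frame_df(rng.uniform(0, 100, size=(20, 2)))
        b = frame_df(rng.uniform(0, 100, size=(25, 2)))
        pairs = link(a, b, LinkParams(max_disp_um=30), 1.0)
        ia = [p[0] for p in pairs]
        ib = [p[1] for p in pairs]
        assert len(ia) == len(set(ia)) and len(ib) == len(set(ib))


class TestMotionFeatures:
    def make_track(self, coords, areas=None):
        n = len(coords)
        return pd.DataFrame(
            {
                "track_id": 0,
                "frame_index": np.arange(n),
                "x_coord": [c[0] for c in coords],
                "y_coord": [c[1] for c in coords],
                "area": areas if areas is not None else [1000.0] * n,
            }
        )

    def test_stationary_cell_zero_distances(self):
        df = motion_features(self.make_track([(5, 5)] * 4), 0.5)
        assert (df["distance"].iloc[1:] == 0).all()
        assert (df["relative_distance"].iloc[1:] == 0).all()
        assert np.isnan(df["distance"].iloc[0])

    def test_per_step_displacements_not_cumulative(self):
        df = motion_features(self.make_track([(0, 0), (3, 0), (3, 4)]), 1.0)
        assert list(df["distance"].iloc[1:]) == [3.0, 4.0]

    def test_relative_distance_halves_when_area_doubles(self):
        d1 = motion_features(self.make_track([(0, 0), (2, 0)], [500, 500]), 1.0)
        d2 = motion_features(self.make_track([(0, 0), (2, 0)], [500, 1000]), 1.0)
        assert d2["relative_distance"].iloc[1] == d1["relative_distance"].iloc[1] / 2


class TestWindows:
    def make_tracks(self, lengths, gap_track=None):
        rows = []
        for tid, L in enumerate(lengths):
            fr = list(range(L))
            if gap_track == tid:
                fr = [f if f < L // 2 else f + 1 for f in fr]
            for f in fr:
                rows.append({"track_id": tid, "frame_index": f, "x_coord": 0.0,
                             "y_coord": 0.0, "area": 1.0})
        return pd.DataFrame(rows)

    @pytest.mark.parametrize("L,expected", [(3, 1), (10, 8), (2, 0)])
    def test_track_length_window_count(self, L, expected):
        wl = windows(self.make_tracks([L]))
        assert wl["window_id"].nunique() if len(wl) else 0 == expected

    def test_window_count_conservation(self):
        lengths = [3, 5, 2, 8, 1]
        wl = windows(self.make_tracks(lengths))
        assert wl["window_id"].nunique() == sum(max(0, L - 2) for L in lengths)

    def test_no_window_spans_a_gap(self):
        wl = windows(self.make_tracks([8], gap_track=0))
        for _, sub in wl.groupby("window_id"):
            f = sub.sort_values("slot")["frame_index"].to_numpy()
            assert f[2] - f[0] == 2


class TestExclusions:
    def make_track_df(self, tid, biomass, cluster=False, t0=0):
        n = len(biomass)
        return pd.DataFrame(
            {
                "track_id": tid,
                "frame_index": np.arange(t0, t0 + n),
                "timestamp_min": 15.0 * np.arange(t0, t0 + n),
                "biomass_pg": biomass,
                "cluster_flag": cluster,
            }
        )

    def test_growing_retained_flat_and_shrinking_excluded(self):
        df = pd.concat(
            [
                self.make_track_df(0, [100, 101, 102, 90, 80]),   # grows pre-co-culture
                self.make_track_df(1, [100, 100, 100, 110, 120]),  # flat (strict rule)
                self.make_track_df(2, [100, 99, 98, 97, 96]),      # shrinks
            ],
            ignore_index=True,
        )
        kept, report = apply_exclusions(df, coculture_start_frame=3)
        assert sorted(kept["track_id"].unique()) == [0]
        assert report["no_growth"] == 2

    def test_cluster_flag_excludes_track(self):
        df = pd.concat(
            [
                self.make_track_df(0, [100, 101, 102, 103]),
                self.make_track_df(1, [100, 101, 102, 103], cluster=True),
            ],
            ignore_index=True,
        )
        kept, report = apply_exclusions(df, coculture_start_frame=3)
        assert sorted(kept["track_id"].unique()) == [0]
        assert report["cluster"] == 1

    def test_no_precoculture_frames_skips_growth_rule(self, caplog):
        df = self.make_track_df(0, [100, 99, 98])
        kept, _ = apply_exclusions(df, coculture_start_frame=0)
        assert list(kept["track_id"].unique()) == [0]

    def test_track_born_after_coculture_excluded(self):
        df = self.make_track_df(0, [100, 101, 102], t0=5)
        kept, report = apply_exclusions(df, coculture_start_frame=3)
        assert len(kept) == 0 and report["no_growth"] == 1

    def test_merged_two_cell_region_is_cluster_flagged(self):
        """A frame where two rendered cells merge into one region produces a
        region ~2x the median area; build_tracks must flag it."""
        frames = []
        for f in range(3):
            img = np.zeros((300, 300))
            # five separated normal cells
            for i, cx in enumerate([40, 100, 160, 220, 270]):
                patch, org = ks.render_cell(300.0, (cx, 50 + 40 * i), (6.0, 5.0))
                img[org[0]:org[0] + patch.shape[0], org[1]:org[1] + patch.shape[1]] += patch
            # one merged pair
            for cx in (58, 82):
                patch, org = ks.render_cell(300.0, (cx, 250), (6.0, 5.0))
                img[org[0]:org[0] + patch.shape[0], org[1]:org[1] + patch.shape[1]] += patch
            frames.append(ks.PhaseImage(img, 0.5, frame_index=f, timestamp_min=15.0 * f))
        feats = ks.features_table(frames)
        tracks = build_tracks(feats, LinkParams(), 0.5)
        assert tracks["cluster_flag"].any()
        flagged = tracks[tracks["cluster_flag"]]
        # the merged object is the largest region in each frame
        assert flagged["area"].min() > tracks[~tracks["cluster_flag"]]["area"].max()
        kept, report = apply_exclusions(
            tracks.assign(biomass_pg=1.0), coculture_start_frame=0
        )
        assert report["cluster"] >= 1
        assert not kept["cluster_flag"].any() if len(kept) else True


class TestTrackingFidelity:
    def test_noise_free_scene_perfect_tracking(self, clean_config):
        """Well-separated, slow cells: every ground-truth cell is recovered
        by exactly one full-length track (recall and precision 1.0) with no
        identity switches."""
        cfg = clean_config(n_tumor_cells=10, image_height_px=460, image_width_px=460)
        images, gt = ks.generate_scene(cfg)
        feats = ks.features_table(images)
        tracks = build_tracks(feats, LinkParams(), cfg.pixel_size_um)
        tracks = motion_features(tracks, cfg.pixel_size_um)
        assert tracks["track_id"].nunique() == cfg.n_tumor_cells
        labels = ks.label_tracks(tracks, gt, cfg.pixel_size_um)
        assert set(labels["gt_cell_id"]) == set(range(cfg.n_tumor_cells))
        for _, sub in tracks.groupby("track_id"):
            assert len(sub) == cfg.n_frames  # full length, no fragmentation
        # no region in two tracks at one frame
        assert not tracks.duplicated(["frame_index", "region_id"]).any()
        wl = windows(tracks)
        assert wl["window_id"].nunique() == cfg.n_tumor_cells * (cfg.n_frames - 2)
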