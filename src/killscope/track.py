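"""Frame-to-frame linking, track assembly, motion features and exclusions.

Regions are linked across consecutive frames by mutual nearest neighbour
within a displacement gate, with a minimum-total-displacement (Hungarian)
assignment resolving contested leftovers.  Tracks are gap-free runs of
linked regions; every run of three consecutive frames becomes one
classification window.  Two exclusion rules mirror standard practice in
killing-assay analysis: regions flagged as clusters (area far above the
running median single-cell area, e.g. two touching cells segmented as one)
are dropped, and tumor cells that were not accumulating biomass before the
attackers were added are dropped, since their later death cannot be
attributed to attack.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LinkParams:
    """max_disp_um: per-frame displacement gate; cluster_area_factor:
    multiple of the running median single-cell area above which a region is
    flagged as a (multi-cell) cluster."""

    max_disp_um: float = 5.0
    cluster_area_factor: float = 1.8

    def __post_init__(self) -> None:
        if not self.max_disp_um > 0:
            raise ValueError("max_disp_um must be positive")


@dataclass
class CellTrack:
    """A labeled per-cell feature sequence (rows ordered by frame_index)."""

    track_id: int
    frames: pd.DataFrame
    label: str = "unlabeled"

    def __len__(self) -> int:
        return len(self.frames)


# ---------------------------------------------------------------------------
# Linking
# ---------------------------------------------------------------------------

def link(
    regions_t: pd.DataFrame,
    regions_t1: pd.DataFrame,
    params: LinkParams,
    pixel_size_um: float,
) -> list[tuple[int, int]]:
    """Assign regions of frame t to regions of frame t+1.

    Mutual-nearest-neighbour pairs within ``max_disp_um`` are accepted
    first; remaining candidates are resolved by a minimum-total-displacement
    assignment restricted to the gate.  Returns positional index pairs
    ``(i_t, i_t1)``; unmatched regions simply end or start tracks.
    """
    if len(regions_t) == 0 or len(regions_t1) == 0:
        return []
    pa = regions_t[["x_coord", "y_coord"]].to_numpy(dtype=float) * pixel_size_um
    pb = regions_t1[["x_coord", "y_coord"]].to_numpy(dtype=float) * pixel_size_um
    dist = cdist(pa, pb)
    allowed = dist <= params.max_disp_um

    pairs: list[tuple[int, int]] = []
    used_a: set[int] = set()
    used_b: set[int] = set()

    masked = np.where(allowed, dist, np.inf)
    nearest_b = masked.argmin(axis=1)
    nearest_a = masked.argmin(axis=0)
    for ia in range(len(pa)):
        ib = nearest_b[ia]
        if np.isfinite(masked[ia, ib]) and nearest_a[ib] == ia:
            pairs.append((ia, int(ib)))
            used_a.add(ia)
            used_b.add(int(ib))

    rem_a = [i for i in range(len(pa)) if i not in used_a and allowed[i].any()]
    rem_b = [j for j in range(len(pb)) if j not in used_b]
    rem_b = [j for j in rem_b if allowed[rem_a, j].any()] if rem_a else []
    if rem_a and rem_b:
        sub = dist[np.ix_(rem_a, rem_b)].copy()
        big = params.max_disp_um * 1e6
        sub[~allowed[np.ix_(rem_a, rem_b)]] = big
        ri, ci = linear_sum_assignment(sub)
        for r, c in zip(ri, ci):
            if sub[r, c] < big:
                pairs.append((rem_a[r], rem_b[c]))
    return sorted(pairs)


def build_tracks(
    features: pd.DataFrame,
    params: LinkParams,
    pixel_size_um: float,
) -> pd.DataFrame:
    """Link a multi-frame feature table into tracks.

    ``features`` is the concatenated per-frame table from
    :func:`killscope.imagefeat.features_table`.  Returns a copy with
    ``track_id`` (assigned in order of first appearance: frame, then
    row-major region order) and ``cluster_flag`` columns.  Links are only
    attempted between frames whose indices differ by exactly 1; a missing
    frame therefore terminates all tracks (no gap closing).
    """
    df = features.sort_values(["frame_index", "region_id"], kind="stable").reset_index(
        drop=True
    )
    df["track_id"] = -1
    frames = sorted(df["frame_index"].unique())
    next_id = 0
    prev_rows: pd.DataFrame | None = None
    prev_tracks: dict[int, int] = {}  # positional index in prev frame -> track_id
    prev_frame = None

    for f in frames:
        cur = df[df["frame_index"] == f]
        cur_positions = list(cur.index)
        assigned: dict[int, int] = {}
        if prev_rows is not None and prev_frame is not None and f == prev_frame + 1:
            for ia, ib in link(prev_rows, cur, params, pixel_size_um):
                assigned[ib] = prev_tracks[ia]
        new_tracks: dict[int, int] = {}
        for pos, row_idx in enumerate(cur_positions):
            if pos in assigned:
                tid = assigned[pos]
            else:
                tid = next_id
                next_id += 1
            df.at[row_idx, "track_id"] = tid
            new_tracks[pos] = tid
        prev_rows, prev_tracks, prev_frame = cur, new_tracks, f

    # running-median cluster flag (median of all region areas seen up to and
    # including each frame; robust because single cells dominate the counts)
    df["cluster_flag"] = False
    seen: list[float] = []
    for f in frames:
        idx = df.index[df["frame_index"] == f]
        seen.extend(df.loc[idx, "area"].tolist())
        med = float(np.median(seen))
        df.loc[idx, "cluster_flag"] = df.loc[idx, "area"] > params.cluster_area_factor * med
    return df


# ---------------------------------------------------------------------------
# Motion features
# ---------------------------------------------------------------------------

def motion_features(tracks: pd.DataFrame, pixel_size_um: float) -> pd.DataFrame:
    """Fill per-frame displacement features along each track.

    ``distance`` is the Euclidean centroid displacement (micrometres) from
    the previous frame of the same track (NaN at the first frame);
    ``relative_distance`` is ``distance / area``.
    """
    df = tracks.sort_values(["track_id", "frame_index"], kind="stable").copy()
    dx = df.groupby("track_id")["x_coord"].diff()
    dy = df.groupby("track_id")["y_coord"].diff()
    df["distance"] = np.hypot(dx, dy) * pixel_size_um
    df["relative_distance"] = df["distance"] / df["area"]
    return df


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------

def windows(tracks: pd.DataFrame, width: int = 3) -> pd.DataFrame:
    """Cut every track into all runs of ``width`` consecutive frames.

    A track of length L (gap-free) yields L - width + 1 windows; windows
    never span a frame gap.  Returns a long-format table: one row per
    (window, slot) with columns ``window_id``, ``track_id``, ``slot``
    (0-based within the window), ``start_frame``, ``end_frame`` plus every
    input column.
    """
    out = []
    window_id = 0
    for tid, sub in tracks.groupby("track_id"):
        sub = sub.sort_values("frame_index")
        fidx = sub["frame_index"].to_numpy()
        for s in range(len(sub) - width + 1):
            if fidx[s + width - 1] - fidx[s] != width - 1:
                continue  # gap inside the candidate window
            block = sub.iloc[s : s + width].copy()
            block["window_id"] = window_id
            block["slot"] = np.arange(width)
            block["start_frame"] = fidx[s]
            block["end_frame"] = fidx[s + width - 1]
            out.append(block)
            window_id += 1
    if not out:
        cols = list(tracks.columns) + ["window_id", "slot", "start_frame", "end_frame"]
        return pd.DataFrame(columns=cols)
    return pd.concat(out, ignore_index=True)


def windows_meta(windows_long: pd.DataFrame) -> pd.DataFrame:
    """One row per window: window_id, track_id, start_frame, end_frame."""
    if len(windows_long) == 0:
        return pd.DataFrame(columns=["window_id", "track_id", "start_frame", "end_frame"])
    meta = (
        windows_long.groupby("window_id")
        .agg(
            track_id=("track_id", "first"),
            start_frame=("start_frame", "first"),
            end_frame=("end_frame", "first"),
        )
        .reset_index()
    )
    return meta


# ---------------------------------------------------------------------------
# Exclusions
# ---------------------------------------------------------------------------

def apply_exclusions(
    tracks: pd.DataFrame,
    coculture_start_frame: int,
    params: LinkParams | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Drop cluster-contaminated tracks and non-growing tumor cells.

    A track is excluded when (a) any of its regions carries
    ``cluster_flag`` (two or more cells segmented as one), or (b) the
    ordinary-least-squares slope of its biomass versus time over the frames
    before ``coculture_start_frame`` is not strictly positive — including
    tracks with fewer than two pre-co-culture frames, whose growth cannot
    be verified.  When ``coculture_start_frame`` is 0 the growth test is
    skipped entirely (with a warning), since no pre-co-culture data exist.
    Cells that keep growing after co-culture begins are retained (they are
    the assay's potential false positives).

    Returns the retained rows and a report dict with per-rule counts.
    """
    report = {"n_tracks": tracks["track_id"].nunique(), "cluster": 0, "no_growth": 0}
    keep_ids = []
    skip_growth = coculture_start_frame <= 0
    if skip_growth:
        logger.warning("no pre-co-culture frames: growth exclusion skipped")
    for tid, sub in tracks.groupby("track_id"):
        if sub["cluster_flag"].any():
            report["cluster"] += 1
            continue
        if not skip_growth:
            pre = sub[sub["frame_index"] < coculture_start_frame]
            if len(pre) < 2:
                report["no_growth"] += 1
                continue
            t = pre["timestamp_min"].to_numpy(dtype=float)
            m = pre["biomass_pg"].to_numpy(dtype=float)
            # cov/var form: exactly zero for constant biomass (strict rule)
            slope = float(((t - t.mean()) * (m - m.mean())).sum() / ((t - t.mean()) ** 2).sum())
            if not slope > 0:
                report["no_growth"] += 1
                continue
        keep_ids.append(tid)
    report["retained"] = len(keep_ids)
    return tracks[tracks["track_id"].isin(keep_ids)].copy(), report
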