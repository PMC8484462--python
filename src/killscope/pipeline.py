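"""End-to-end orchestration: scenes -> features -> tracks -> windows ->
inputs -> selection -> training, plus the streaming watch mode.

The batch path (:func:`run_pipeline`) generates synthetic scenes, extracts
and tracks features, assembles labeled three-frame windows, selects the
top-k features, and sweeps classifier families over feature subsets,
writing every intermediate artifact as CSV.  The streaming path
(:class:`StreamingTracker`, :func:`watch`) processes one frame at a time —
as a microscope would deliver them — and classifies each cell as soon as
its third frame arrives; it mirrors the batch logic exactly, so stream and
batch outputs agree on identical inputs.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, imagefeat, inputs, select, synth, track

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Scene -> labeled windows
# ---------------------------------------------------------------------------

def scene_windows(
    config: synth.SceneConfig,
    seg: imagefeat.SegmentationParams | None = None,
    linkp: track.LinkParams | None = None,
    exclusions: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run one synthetic scene through segmentation, tracking and windowing.

    Returns ``(windows_long, meta)`` where meta has one row per window with
    its ground-truth label (alive / killed / unlabeled).
    """
    linkp = linkp or track.LinkParams()
    images, gt = synth.generate_scene(config)
    feats = imagefeat.features_table(images, seg, config.alpha)
    tr = track.build_tracks(feats, linkp, config.pixel_size_um)
    tr = track.motion_features(tr, config.pixel_size_um)
    if exclusions:
        tr, _ = track.apply_exclusions(tr, config.coculture_start_frame, linkp)
    wl = track.windows(tr)
    meta = track.windows_meta(wl)
    if len(meta) == 0:
        meta["label"] = pd.Series(dtype=object)
        return wl, meta
    tl = synth.label_tracks(tr, gt, config.pixel_size_um)
    meta = meta.merge(
        tl[["track_id", "label", "kill_onset_frame"]].rename(
            columns={"label": "track_label"}
        ),
        on="track_id",
        how="left",
    )
    meta["label"] = synth.label_windows(meta, tl).to_numpy()
    return wl, meta


def build_window_pool(
    base_config: synth.SceneConfig,
    n_killed: int,
    n_alive: int,
    seg: imagefeat.SegmentationParams | None = None,
    linkp: track.LinkParams | None = None,
    one_alive_per_track: bool = True,
    max_scenes: int = 400,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accumulate labeled windows over scenes until both pools are filled.

    Scenes are generated with seeds ``base_config.seed, seed+1, ...``.
    Killed-class windows are the signature windows of killed tracks (the
    window starting at the kill onset, one per track).  Alive-class windows
    come from alive tracks only, restricted to co-culture frames; with
    ``one_alive_per_track`` a single seeded choice per track is kept, so
    every pooled window belongs to a distinct track and balanced
    track-disjoint splits are trivial.  Raises ``RuntimeError`` if
    ``max_scenes`` scenes cannot fill the pools.
    """
    got_killed = 0
    got_alive = 0
    wl_parts: list[pd.DataFrame] = []
    meta_parts: list[pd.DataFrame] = []
    wid_offset = 0
    tid_offset = 0
    for s in range(max_scenes):
        cfg = dataclasses.replace(base_config, seed=base_config.seed + s)
        wl, meta = scene_windows(cfg, seg, linkp)
        if len(meta) == 0:
            continue
        rng = np.random.default_rng([base_config.seed, s])
        keep_ids: list[int] = []
        labels: dict[int, str] = {}
        for tid, sub in meta.groupby("track_id"):
            tlab = sub["track_label"].iloc[0]
            if tlab == "killed" and got_killed < n_killed:
                onset = int(sub["kill_onset_frame"].iloc[0])
                hit = sub[(sub["start_frame"] == onset) & (sub["label"] == "killed")]
                if len(hit):
                    wid = int(hit["window_id"].iloc[0])
                    keep_ids.append(wid)
                    labels[wid] = "killed"
                    got_killed += 1
            elif tlab == "alive" and got_alive < n_alive:
                elig = sub[
                    (sub["label"] == "alive")
                    & (sub["start_frame"] >= cfg.coculture_start_frame)
                ]
                if len(elig) == 0:
                    continue
                if one_alive_per_track:
                    picks = [int(elig["window_id"].iloc[rng.integers(len(elig))])]
                else:
                    picks = [int(w) for w in elig["window_id"]]
                    picks = picks[: n_alive - got_alive]
                for wid in picks:
                    keep_ids.append(wid)
                    labels[wid] = "alive"
                    got_alive += 1
        if keep_ids:
            sel_meta = meta[meta["window_id"].isin(keep_ids)].copy()
            sel_wl = wl[wl["window_id"].isin(keep_ids)].copy()
            sel_meta["label"] = sel_meta["window_id"].map(labels)
            sel_wl["window_id"] += wid_offset
            sel_meta["window_id"] += wid_offset
            sel_wl["track_id"] += tid_offset
            sel_meta["track_id"] += tid_offset
            wid_offset = int(sel_wl["window_id"].max()) + 1
            tid_offset = int(sel_wl["track_id"].max()) + 1
            wl_parts.append(sel_wl)
            meta_parts.append(sel_meta)
        if got_killed >= n_killed and got_alive >= n_alive:
            break
    else:
        raise RuntimeError(
            f"could not fill window pools within {max_scenes} scenes "
            f"(killed {got_killed}/{n_killed}, alive {got_alive}/{n_alive})"
        )
    return pd.concat(wl_parts, ignore_index=True), pd.concat(meta_parts, ignore_index=True)


def pool_inputs(
    windows_long: pd.DataFrame,
    meta: pd.DataFrame,
    feature_names: list[str],
    input_type: str,
    denominator: str = "preceding",
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Transform a window pool into one input table plus aligned labels.

    Returns (table, labels, meta) restricted to windows that survived the
    transformation (zero-denominator or non-finite windows are dropped).
    """
    table, _ = inputs.make_inputs_table(windows_long, input_type, feature_names, denominator)
    meta_ok = meta[meta["window_id"].isin(table.index)].copy()
    labels = meta_ok.set_index("window_id")["label"].reindex(table.index)
    return table, labels, meta_ok


# ---------------------------------------------------------------------------
# Batch pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs, with demo-scale defaults.

    ``k`` features are selected from the ranked, pruned list (the sweep
    trains 2^k - 1 subsets per family and input type, so the demo default
    keeps k modest; the headline configuration uses k = 10).
    """

    scene: synth.SceneConfig = field(default_factory=synth.SceneConfig)
    seg: imagefeat.SegmentationParams = field(default_factory=imagefeat.SegmentationParams)
    link: track.LinkParams = field(default_factory=track.LinkParams)
    split: classify.SplitPlan = field(
        default_factory=lambda: classify.SplitPlan(
            n_train_per_class=40, n_validation_sets=2, n_val_per_class=15
        )
    )
    families: tuple[str, ...] = classify.FAMILIES
    input_types: tuple[str, ...] = inputs.INPUT_TYPES
    k: int = 5
    corr_threshold: float = 0.95
    denominator: str = "preceding"
    feature_names: list[str] | None = None  # None -> rank and prune
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "scene" in d:
            d["scene"] = synth.SceneConfig.from_dict(d["scene"])
        if "seg" in d:
            d["seg"] = imagefeat.SegmentationParams(**d["seg"])
        if "link" in d:
            d["link"] = track.LinkParams(**d["link"])
        if "split" in d:
            d["split"] = classify.SplitPlan(**d["split"])
        for key in ("families", "input_types"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute simulate -> features -> track -> select -> inputs -> train.

    Writes ``windows.csv``, ``windows_meta.csv``, ``ranking.csv``,
    ``correlation.csv``, ``top_features.txt``, ``inputs_<type>.csv``,
    ``sweep_results.csv``, ``summary.csv``, ``roc_top.csv`` and
    ``model_top.bin`` under ``out_dir``.  Existing ``windows.csv`` /
    ``windows_meta.csv`` are reused, so a deleted downstream artifact can be
    regenerated without re-simulating; all randomness flows from the config
    seeds, so a full re-run reproduces identical payloads.  Returns a dict
    of the in-memory artifacts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    plan = config.split
    need = plan.n_train_per_class + plan.n_validation_sets * plan.n_val_per_class

    wpath, mpath = out / "windows.csv", out / "windows_meta.csv"
    if wpath.exists() and mpath.exists():
        logger.info("stage simulate: reusing %s", wpath)
        wl = pd.read_csv(wpath)
        meta = pd.read_csv(mpath)
    else:
        logger.info("stage simulate: generating scenes")
        wl, meta = build_window_pool(
            config.scene, n_killed=need, n_alive=need, seg=config.seg, linkp=config.link
        )
        wl.to_csv(wpath, index=False)
        meta.to_csv(mpath, index=False)

    splits = classify.make_splits(meta, plan)

    # --- feature selection on training absolutes (newest frame) ---------
    if config.feature_names is None:
        logger.info("stage select: ranking features")
        sel_feats = [f for f in imagefeat.FEATURE_NAMES if f not in ("x_coord", "y_coord")]
        a1, labels_a1, _ = pool_inputs(wl, meta, sel_feats, "A1", config.denominator)
        tr_idx = [i for i in splits["train"] if i in a1.index]
        table_tr = a1.loc[tr_idx]
        table_tr.columns = sel_feats
        ranking = select.univariate_rank(
            table_tr, labels_a1.loc[tr_idx], seed=config.seed
        )
        corr = select.correlation_matrix(table_tr)
        top = select.prune(ranking, corr, config.corr_threshold, config.k)
        ranking.auc_table.to_csv(out / "ranking.csv")
        corr.to_csv(out / "correlation.csv")
    else:
        top = list(config.feature_names)
    (out / "top_features.txt").write_text("\n".join(top) + "\n")

    # --- inputs + sweep ---------------------------------------------------
    all_results: list[classify.SweepResult] = []
    for itype in config.input_types:
        table, labels, meta_ok = pool_inputs(wl, meta, top, itype, config.denominator)
        table.to_csv(out / f"inputs_{itype}.csv")
        ok = set(table.index)
        sub_splits = {
            "train": [i for i in splits["train"] if i in ok],
            "validation": [[i for i in v if i in ok] for v in splits["validation"]],
        }
        for fam in config.families:
            logger.info("stage train: %s / %s", fam, itype)
            all_results.extend(
                classify.sweep(
                    table, labels, top, itype, fam, sub_splits, seed=config.seed
                )
            )
    summary, top_result = classify.compare_inputs(all_results)
    classify.sweep_to_frame(all_results).to_csv(out / "sweep_results.csv", index=False)
    summary.to_csv(out / "summary.csv", index=False)

    # --- refit + persist the top configuration ---------------------------
    table, labels, _ = pool_inputs(
        wl, meta, top, top_result.input_type, config.denominator
    )
    cols = classify.subset_columns(table.columns, top_result.feature_subset)
    tr_idx = [i for i in splits["train"] if i in table.index]
    model = classify.train(
        classify.ClassifierSpec(family=top_result.family, seed=config.seed),
        table.loc[tr_idx, cols],
        labels.loc[tr_idx],
    )
    roc_pts, _ = classify.roc_auc(model.scores(table.loc[tr_idx, cols]), labels.loc[tr_idx])
    pd.DataFrame(roc_pts, columns=["fpr", "tpr"]).to_csv(out / "roc_top.csv", index=False)
    model.save(out / "model_top.bin")

    return {
        "windows": wl,
        "meta": meta,
        "top_features": top,
        "results": all_results,
        "summary": summary,
        "top_result": top_result,
        "model": model,
        "splits": splits,
    }


# ---------------------------------------------------------------------------
# Streaming (watch) mode
# ---------------------------------------------------------------------------

class StreamingTracker:
    """Incremental version of the batch tracking path.

    Frames are consumed one at a time; track ids, cluster flags and motion
    features follow exactly the batch rules (same linking, same running
    median), so feeding a scene frame-by-frame yields the same windows as
    the batch pipeline.
    """

    def __init__(self, linkp: track.LinkParams, pixel_size_um: float):
        self.linkp = linkp
        self.pixel_size_um = pixel_size_um
        self.next_id = 0
        self.prev: pd.DataFrame | None = None
        self.prev_frame_index: int | None = None
        self.prev_tracks: dict[int, int] = {}
        self.areas_seen: list[float] = []
        self.history: dict[int, list[pd.Series]] = {}

    def add_frame(self, frame_df: pd.DataFrame) -> pd.DataFrame:
        """Ingest one frame's feature table; returns it with track columns.

        Raises ``ValueError`` if the frame index does not increase.
        """
        if len(frame_df) == 0:
            self.prev, self.prev_tracks = None, {}
            return frame_df.assign(track_id=[], cluster_flag=[], distance=[], relative_distance=[])
        f = int(frame_df["frame_index"].iloc[0])
        if self.prev_frame_index is not None and f <= self.prev_frame_index:
            raise ValueError("out-of-order frame index")
        cur = frame_df.sort_values("region_id", kind="stable").reset_index(drop=True)
        assigned: dict[int, int] = {}
        if (
            self.prev is not None
            and self.prev_frame_index is not None
            and f == self.prev_frame_index + 1
        ):
            for ia, ib in track.link(self.prev, cur, self.linkp, self.pixel_size_um):
                assigned[ib] = self.prev_tracks[ia]

        tids, dists = [], []
        new_tracks: dict[int, int] = {}
        for pos in range(len(cur)):
            if pos in assigned:
                tid = assigned[pos]
                last = self.history[tid][-1]
                d = float(
                    np.hypot(
                        cur.at[pos, "x_coord"] - last["x_coord"],
                        cur.at[pos, "y_coord"] - last["y_coord"],
                    )
                    * self.pixel_size_um
                )
            else:
                tid = self.next_id
                self.next_id += 1
                d = float("nan")
            tids.append(tid)
            dists.append(d)
            new_tracks[pos] = tid
        cur["track_id"] = tids
        cur["distance"] = dists
        cur["relative_distance"] = cur["distance"] / cur["area"]

        self.areas_seen.extend(cur["area"].tolist())
        med = float(np.median(self.areas_seen))
        cur["cluster_flag"] = cur["area"] > self.linkp.cluster_area_factor * med

        for pos in range(len(cur)):
            self.history.setdefault(int(cur.at[pos, "track_id"]), []).append(cur.iloc[pos])
        self.prev, self.prev_tracks, self.prev_frame_index = cur, new_tracks, f
        return cur

    def current_windows(self, width: int = 3) -> list[pd.DataFrame]:
        """Windows ending at the newest frame (one per eligible track)."""
        if self.prev is None or self.prev_frame_index is None:
            return []
        out = []
        for tid in self.prev["track_id"]:
            rows = self.history.get(int(tid), [])
            if len(rows) < width:
                continue
            tail = pd.DataFrame(rows[-width:])
            fidx = tail["frame_index"].to_numpy()
            if fidx[-1] - fidx[0] == width - 1 and fidx[-1] == self.prev_frame_index:
                tail = tail.reset_index(drop=True)
                tail["slot"] = np.arange(width)
                tail["window_id"] = -1
                out.append(tail)
        return out


def watch(
    directory: str | Path,
    model: classify.FittedModel,
    feature_names: list[str],
    input_type: str = "P2",
    pixel_size_um: float = 0.5,
    seg: imagefeat.SegmentationParams | None = None,
    linkp: track.LinkParams | None = None,
    alpha: float = imagefeat.DEFAULT_ALPHA,
    frame_interval_min: float = 15.0,
    denominator: str = "preceding",
    follow: bool = False,
    poll_interval_s: float = 0.5,
    idle_timeout_s: float = 10.0,
    pattern: str = "scene_t*.tif",
) -> pd.DataFrame:
    """Classify cells as their third frame arrives in a watched directory.

    Each newly discovered frame (by filename index) is segmented, tracks
    are extended, and every track with three consecutive frames ending at
    the new frame is transformed to ``input_type`` and scored by the frozen
    model.  With ``follow=False`` the files currently present are processed
    in index order and the function returns; with ``follow=True`` it keeps
    polling until no new frame arrives for ``idle_timeout_s``.  Returns a
    record table (frame_index, track_id, score, label, latency_s).
    """
    import tifffile

    directory = Path(directory)
    linkp = linkp or track.LinkParams()
    tracker = StreamingTracker(linkp, pixel_size_um)
    records: list[dict] = []
    processed: set[int] = set()
    last_new = time.monotonic()

    def pending() -> list[tuple[int, Path]]:
        found = []
        for p in sorted(directory.glob(pattern)):
            digits = "".join(ch for ch in p.stem if ch.isdigit())
            if digits and int(digits) not in processed:
                found.append((int(digits), p))
        return sorted(found)

    while True:
        batch = pending()
        for idx, path in batch:
            t0 = time.monotonic()
            try:
                opd = tifffile.imread(path).astype(float)
            except Exception as exc:  # unreadable frame: skip with warning
                logger.warning("skipping unreadable frame %s: %s", path.name, exc)
                processed.add(idx)
                continue
            img = imagefeat.PhaseImage(
                opd_nm=opd,
                pixel_size_um=pixel_size_um,
                frame_index=idx,
                timestamp_min=idx * frame_interval_min,
            )
            frame_df = imagefeat.frame_table(img, seg, alpha)
            tracker.add_frame(frame_df)
            for win in tracker.current_windows():
                try:
                    iv = inputs.make_input(win, input_type, feature_names, denominator)
                except (ZeroDivisionError, ValueError):
                    continue
                score = float(model.scores(iv.values.reshape(1, -1))[0])
                records.append(
                    {
                        "frame_index": idx,
                        "track_id": int(win["track_id"].iloc[0]),
                        "score": score,
                        "label": "killed" if score >= model.default_threshold else "alive",
                        "latency_s": time.monotonic() - t0,
                    }
                )
            processed.add(idx)
            last_new = time.monotonic()
            logger.info(
                "watch: frame %d, %d regions, %.2fs", idx, len(frame_df),
                time.monotonic() - t0,
            )
        if not follow:
            if not pending():
                break
        else:
            if time.monotonic() - last_new > idle_timeout_s:
                break
            time.sleep(poll_interval_s)
    return pd.DataFrame(
        records, columns=["frame_index", "track_id", "score", "label", "latency_s"]
    )
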