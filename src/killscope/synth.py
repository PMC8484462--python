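"""Synthetic quantitative-phase time-lapse scenes with ground truth.

Emulates a co-culture killing assay as seen by a quantitative phase
microscope: adherent tumor cells that accumulate dry mass exponentially,
small fast-moving attacker (T) cells added after a pre-co-culture growth
phase, and killing events with the canonical phase-imaging death signature —
the projected area of the dying cell shrinks while its mean dry-mass density
rises (mass is conserved during the contraction), and after a short delay
the cell lyses and loses a large fraction of its mass.

Cells are rendered as elliptical super-Gaussian phase blobs (order 2,
clipped at 1% of peak so the boundary is crisp) whose integrated optical
path difference is scaled to the prescribed dry mass exactly; the rendering
is therefore the inverse of :func:`killscope.imagefeat.measure_biomass` up
to discretization.  Every random choice flows from ``SceneConfig.seed``, so
identical configs reproduce bit-identical scenes.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .imagefeat import DEFAULT_ALPHA, PhaseImage

_CLIP_LOG = math.log(100.0)  # profile falls to 1% of peak at the footprint edge


@dataclass(frozen=True)
class KillParams:
    """Death-signature parameters.

    ``shrink_rate_per_h``: exponential area-contraction rate after kill
    onset.  ``density_gain_per_h``: rate of mean-density increase; when equal
    to the shrink rate, mass is conserved during contraction (the default).
    ``lysis_delay_frames``: frames between onset and lysis.
    ``lysis_loss_fraction``: fraction of dry mass lost at lysis.
    """

    shrink_rate_per_h: float = 0.4
    density_gain_per_h: float = 0.4
    lysis_delay_frames: int = 2
    lysis_loss_fraction: float = 0.5


@dataclass(frozen=True)
class SceneConfig:
    """Scene geometry, population and dynamics.

    Defaults emulate a 20x phase setup: 0.5 um pixels, a frame every 15
    minutes, tumor cells of 150-400 pg at ~1.0-1.4 pg/um^2 mean density
    (peak optical path difference a few hundred nanometres), attackers at a
    2:1 ratio added at ``coculture_start_frame``, and ~4%/h tumor biomass
    growth.  ``motility_sigma_um`` is the per-frame random-walk step for
    (tumor, attacker) cells — attackers are an order of magnitude faster.
    """

    image_height_px: int = 480
    image_width_px: int = 480
    pixel_size_um: float = 0.5
    frame_interval_min: float = 15.0
    n_frames: int = 10
    n_tumor_cells: int = 16
    attacker_ratio: float = 2.0
    kill_fraction: float = 0.5
    growth_rate_per_h: float = 0.04
    kill_params: KillParams = field(default_factory=KillParams)
    motility_sigma_um: tuple[float, float] = (0.3, 3.0)
    noise_sd_nm: float = 2.0
    seed: int = 0
    coculture_start_frame: int = 3
    mass_range_pg: tuple[float, float] = (150.0, 400.0)
    density_range_pg_per_um2: tuple[float, float] = (1.0, 1.4)
    attacker_mass_range_pg: tuple[float, float] = (20.0, 35.0)
    attacker_density_pg_per_um2: float = 2.5
    max_aspect_ratio: float = 1.8
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3 (a window needs three frames)")
        if not 0.0 <= self.kill_fraction <= 1.0:
            raise ValueError("kill_fraction must lie in [0, 1]")
        for name in ("growth_rate_per_h", "noise_sd_nm", "attacker_ratio"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and non-negative")
        if self.n_tumor_cells < 1:
            raise ValueError("n_tumor_cells must be >= 1")
        if not 0 <= self.coculture_start_frame < self.n_frames:
            raise ValueError("coculture_start_frame must lie within the series")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        if "kill_params" in d and isinstance(d["kill_params"], dict):
            d["kill_params"] = KillParams(**d["kill_params"])
        for key in ("motility_sigma_um", "mass_range_pg", "density_range_pg_per_um2",
                    "attacker_mass_range_pg"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class GroundTruth:
    """True per-cell state of a scene.

    ``cells``: one row per tumor cell (cell_id, fate in {alive, killed},
    kill_onset_frame, -1 for alive cells).  ``frames``: one row per tumor
    cell per frame with the true centroid (pixels), footprint area (px^2)
    and dry mass (pg).  Attacker cells are rendered but carry no ground
    truth; they exist to stress segmentation and tracking.
    """

    cells: pd.DataFrame
    frames: pd.DataFrame

    def fate_of(self, cell_id: int) -> str:
        return str(self.cells.set_index("cell_id").loc[cell_id, "fate"])

    def onset_of(self, cell_id: int) -> int:
        return int(self.cells.set_index("cell_id").loc[cell_id, "kill_onset_frame"])


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_cell(
    mass_pg: float,
    center_xy_px: tuple[float, float],
    axes_um: tuple[float, float],
    angle_deg: float = 0.0,
    alpha: float = DEFAULT_ALPHA,
    pixel_size_um: float = 0.5,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Render one cell as an OPD patch (nanometres).

    The profile is a rotated elliptical super-Gaussian of order 2,
    ``exp(-ln(100) * rho**4)`` with ``rho`` the normalized elliptical
    radius, set to zero beyond ``rho > 1`` so the footprint is exactly the
    ellipse with semi-axes ``axes_um``.  The patch is scaled so that
    ``sum(patch) * pixel_area / alpha`` equals ``mass_pg`` exactly.

    Returns ``(patch_nm, (row0, col0))`` — the patch and its top-left pixel
    index in the frame the center coordinates refer to.
    """
    if not mass_pg > 0:
        raise ValueError("mass_pg must be positive")
    a_um, b_um = axes_um
    if not (a_um > 0 and b_um > 0):
        raise ValueError("axes must be positive")

    a = a_um / pixel_size_um
    b = b_um / pixel_size_um
    cx, cy = center_xy_px
    radius = int(math.ceil(max(a, b))) + 2
    r0 = int(math.floor(cy)) - radius
    c0 = int(math.floor(cx)) - radius
    n = 2 * radius + 1
    rows = np.arange(r0, r0 + n, dtype=float)[:, None] - cy
    cols = np.arange(c0, c0 + n, dtype=float)[None, :] - cx

    th = math.radians(angle_deg)
    # y-up convention: image rows grow downward
    xr = cols * math.cos(th) - rows * math.sin(th)
    yr = -(cols * math.sin(th) + rows * math.cos(th))
    rho2 = (xr / a) ** 2 + (yr / b) ** 2
    profile = np.exp(-_CLIP_LOG * rho2**2)
    profile[rho2 > 1.0] = 0.0

    total = profile.sum()
    if total <= 0:
        raise ValueError("cell footprint smaller than one pixel")
    # scale so integrated OPD converts back to mass_pg exactly
    scale = mass_pg * alpha / (pixel_size_um**2 * 1e-6) / total
    return profile * scale, (r0, c0)


def _add_patch(frame: np.ndarray, patch: np.ndarray, origin: tuple[int, int]) -> None:
    r0, c0 = origin
    h, w = frame.shape
    pr0, pc0 = max(0, -r0), max(0, -c0)
    fr0, fc0 = max(0, r0), max(0, c0)
    fr1 = min(h, r0 + patch.shape[0])
    fc1 = min(w, c0 + patch.shape[1])
    if fr1 > fr0 and fc1 > fc0:
        frame[fr0:fr1, fc0:fc1] += patch[pr0 : pr0 + fr1 - fr0, pc0 : pc0 + fc1 - fc0]


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------

def _place_cells(
    rng: np.random.Generator,
    radii_px: np.ndarray,
    height: int,
    width: int,
) -> np.ndarray:
    """Rejection-sample non-overlapping initial centers (x, y in px)."""
    n = len(radii_px)
    centers = np.zeros((n, 2))
    max_attempts = 400 * n
    attempts = 0
    for i in range(n):
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    "scene over-crowded: cannot place cells without seed overlap"
                )
            m = radii_px[i] + 4
            x = rng.uniform(m, width - m)
            y = rng.uniform(m, height - m)
            ok = True
            for j in range(i):
                d = math.hypot(x - centers[j, 0], y - centers[j, 1])
                if d < 1.25 * (radii_px[i] + radii_px[j]) + 6:
                    ok = False
                    break
            if ok:
                centers[i] = (x, y)
                break
    return centers


def generate_scene(config: SceneConfig) -> tuple[list[PhaseImage], GroundTruth]:
    """Generate a full scene: phase maps for every frame plus ground truth.

    Fates are assigned deterministically: after a seeded shuffle, the first
    ``round(kill_fraction * n_tumor_cells)`` cells are fated to be killed,
    so class counts are exact.  Kill onset frames are drawn uniformly in
    ``[coculture_start_frame, n_frames - 3]`` so that a full three-frame
    window covers the signature.  Attackers appear at
    ``coculture_start_frame`` and perform a fast random walk.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_tumor_cells
    nf = config.n_frames
    dt_h = config.frame_interval_min / 60.0
    px = config.pixel_size_um
    kp = config.kill_params

    # --- fates ---------------------------------------------------------
    n_killed = int(round(config.kill_fraction * n))
    order = rng.permutation(n)
    killed_ids = set(int(i) for i in order[:n_killed])

    onset_high = max(config.coculture_start_frame, nf - 3)
    onsets = {
        i: int(rng.integers(config.coculture_start_frame, onset_high + 1))
        for i in sorted(killed_ids)
    }

    # --- per-cell static draws ------------------------------------------
    mass0 = rng.uniform(*config.mass_range_pg, size=n)
    dens0 = rng.uniform(*config.density_range_pg_per_um2, size=n)
    aspect = rng.uniform(1.0, config.max_aspect_ratio, size=n)
    angles = rng.uniform(-90.0, 90.0, size=n)

    area0_um2 = mass0 / dens0
    radii_px = np.sqrt(area0_um2 * aspect / math.pi) / px  # major semi-axis
    centers0 = _place_cells(rng, radii_px, config.image_height_px, config.image_width_px)

    sig_t = config.motility_sigma_um[0] / px
    steps = rng.normal(0.0, sig_t, size=(nf - 1, n, 2))
    positions = np.concatenate([centers0[None], centers0[None] + np.cumsum(steps, axis=0)])

    # --- mass / area trajectories ---------------------------------------
    mass = np.zeros((nf, n))
    area_um2 = np.zeros((nf, n))
    g = config.growth_rate_per_h
    for i in range(n):
        onset = onsets.get(i, nf + 1)
        for f in range(nf):
            if f < onset:
                m = mass0[i] * math.exp(g * f * dt_h)
                a = m / dens0[i]
            elif f < onset + kp.lysis_delay_frames:
                k = f - onset + 1
                m_base = mass0[i] * math.exp(g * (onset - 1) * dt_h)
                a_base = m_base / dens0[i]
                a = a_base * math.exp(-kp.shrink_rate_per_h * k * dt_h)
                m = m_base * math.exp((kp.density_gain_per_h - kp.shrink_rate_per_h) * k * dt_h)
            else:
                kpre = kp.lysis_delay_frames
                m_base = mass0[i] * math.exp(g * (onset - 1) * dt_h)
                a_base = m_base / dens0[i]
                if kpre > 0:
                    a = a_base * math.exp(-kp.shrink_rate_per_h * kpre * dt_h)
                    m = m_base * math.exp(
                        (kp.density_gain_per_h - kp.shrink_rate_per_h) * kpre * dt_h
                    )
                else:
                    a, m = a_base, m_base
                m *= 1.0 - kp.lysis_loss_fraction
            mass[f, i] = m
            area_um2[f, i] = a

    # --- attackers -------------------------------------------------------
    n_att = int(round(config.attacker_ratio * n))
    att_mass = rng.uniform(*config.attacker_mass_range_pg, size=n_att)
    att_area = att_mass / config.attacker_density_pg_per_um2
    att_r_px = np.sqrt(att_area / math.pi) / px
    att_pos0 = np.column_stack(
        [
            rng.uniform(6, config.image_width_px - 6, size=n_att),
            rng.uniform(6, config.image_height_px - 6, size=n_att),
        ]
    )
    sig_a = config.motility_sigma_um[1] / px
    n_att_frames = nf - config.coculture_start_frame
    if n_att_frames > 0 and n_att > 0:
        att_steps = rng.normal(0.0, sig_a, size=(max(0, n_att_frames - 1), n_att, 2))
        att_pos = np.concatenate(
            [att_pos0[None], att_pos0[None] + np.cumsum(att_steps, axis=0)]
        )
    else:
        att_pos = np.zeros((0, n_att, 2))

    # --- render ----------------------------------------------------------
    images: list[PhaseImage] = []
    for f in range(nf):
        frame = np.zeros((config.image_height_px, config.image_width_px), dtype=float)
        for i in range(n):
            a_semi = math.sqrt(area_um2[f, i] * aspect[i] / math.pi)
            b_semi = math.sqrt(area_um2[f, i] / (math.pi * aspect[i]))
            patch, origin = render_cell(
                mass[f, i],
                tuple(positions[f, i]),
                (a_semi, b_semi),
                angles[i],
                config.alpha,
                px,
            )
            _add_patch(frame, patch, origin)
        if f >= config.coculture_start_frame and n_att > 0:
            fa = f - config.coculture_start_frame
            for j in range(n_att):
                r_um = math.sqrt(att_area[j] / math.pi)
                patch, origin = render_cell(
                    att_mass[j],
                    tuple(att_pos[fa, j]),
                    (r_um, r_um),
                    0.0,
                    config.alpha,
                    px,
                )
                _add_patch(frame, patch, origin)
        if config.noise_sd_nm > 0:
            frame += rng.normal(0.0, config.noise_sd_nm, size=frame.shape)
        images.append(
            PhaseImage(
                opd_nm=frame.astype(np.float32).astype(float),
                pixel_size_um=px,
                frame_index=f,
                timestamp_min=f * config.frame_interval_min,
            )
        )

    # --- ground truth ----------------------------------------------------
    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "fate": ["killed" if i in killed_ids else "alive" for i in range(n)],
            "kill_onset_frame": [onsets.get(i, -1) for i in range(n)],
        }
    )
    rows = []
    for f in range(nf):
        for i in range(n):
            rows.append(
                {
                    "cell_id": i,
                    "frame": f,
                    "x_px": positions[f, i, 0],
                    "y_px": positions[f, i, 1],
                    "area_px": area_um2[f, i] / px**2,
                    "mass_pg": mass[f, i],
                }
            )
    return images, GroundTruth(cells=cells, frames=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Ground-truth matching / labeling
# ---------------------------------------------------------------------------

def label_tracks(
    tracks: pd.DataFrame,
    gt: GroundTruth,
    pixel_size_um: float,
    max_match_dist_um: float = 6.0,
) -> pd.DataFrame:
    """Match detected tracks to ground-truth tumor cells by centroid distance.

    A track is assigned to the ground-truth cell minimizing the mean
    centroid distance over the frames they share, provided that mean is
    below ``max_match_dist_um``; otherwise it stays unlabeled (attacker
    debris, merged regions).  Returns one row per track: track_id, label in
    {alive, killed, unlabeled}, gt_cell_id (-1 if unmatched),
    kill_onset_frame (-1 if not killed).
    """
    fates = gt.cells.set_index("cell_id")["fate"]
    onsets = gt.cells.set_index("cell_id")["kill_onset_frame"]

    pairs = tracks[["track_id", "frame_index", "x_coord", "y_coord"]].merge(
        gt.frames.rename(columns={"frame": "frame_index"}),
        on="frame_index",
        how="inner",
    )
    pairs["dist_um"] = (
        np.hypot(pairs["x_coord"] - pairs["x_px"], pairs["y_coord"] - pairs["y_px"])
        * pixel_size_um
    )
    mean_dist = (
        pairs.groupby(["track_id", "cell_id"])["dist_um"].mean().reset_index()
    )

    out = []
    for track_id in tracks["track_id"].unique():
        cand = mean_dist[mean_dist["track_id"] == track_id]
        if len(cand):
            row = cand.loc[cand["dist_um"].idxmin()]
            best_cell, best_dist = int(row["cell_id"]), float(row["dist_um"])
        else:
            best_cell, best_dist = -1, np.inf
        if best_cell >= 0 and best_dist <= max_match_dist_um:
            out.append(
                {
                    "track_id": track_id,
                    "label": str(fates.loc[best_cell]),
                    "gt_cell_id": best_cell,
                    "kill_onset_frame": int(onsets.loc[best_cell]),
                    "match_dist_um": best_dist,
                }
            )
        else:
            out.append(
                {
                    "track_id": track_id,
                    "label": "unlabeled",
                    "gt_cell_id": -1,
                    "kill_onset_frame": -1,
                    "match_dist_um": best_dist,
                }
            )
    return pd.DataFrame(out)


def label_windows(windows_meta: pd.DataFrame, track_labels: pd.DataFrame) -> pd.Series:
    """Assign alive/killed/unlabeled to three-frame windows.

    Windows of alive tracks are alive.  Windows of killed tracks are killed
    when they start at or after the kill onset (the death signature is
    underway for all three frames), alive when they end before onset, and
    unlabeled when they straddle the onset (ambiguous mixtures are not used
    for training or evaluation).
    """
    tl = track_labels.set_index("track_id")
    labels = []
    for _, row in windows_meta.iterrows():
        tid = row["track_id"]
        if tid not in tl.index:
            labels.append("unlabeled")
            continue
        lab = tl.loc[tid, "label"]
        if lab == "alive":
            labels.append("alive")
        elif lab == "killed":
            onset = int(tl.loc[tid, "kill_onset_frame"])
            if row["start_frame"] >= onset:
                labels.append("killed")
            elif row["end_frame"] < onset:
                labels.append("alive")
            else:
                labels.append("unlabeled")
        else:
            labels.append("unlabeled")
    return pd.Series(labels, index=windows_meta.index, name="label")


# ---------------------------------------------------------------------------
# Scene I/O
# ---------------------------------------------------------------------------

def write_scene(
    images: Sequence[PhaseImage],
    gt: GroundTruth,
    config: SceneConfig,
    out_dir: str | Path,
) -> None:
    """Write a scene as numbered float32 TIFFs + ground_truth.csv + config.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for img in images:
        tifffile.imwrite(
            out / f"scene_t{img.frame_index:04d}.tif",
            img.opd_nm.astype(np.float32),
        )
    merged = gt.frames.merge(gt.cells, on="cell_id")
    merged.to_csv(out / "ground_truth.csv", index=False)
    (out / "scene_config.json").write_text(config.to_json())
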