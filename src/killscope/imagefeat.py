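"""Segmentation and per-cell feature extraction from quantitative phase maps.

A quantitative phase microscope reports, per pixel, the optical path
difference (OPD) that light accumulates through the specimen.  Because the
refractive-index excess of cellular material is proportional to its dry-mass
concentration (specific refractive increment ``alpha`` ~ 1.8e-4 m^3/kg),
integrating OPD over a segmented cell converts directly to dry biomass in
picograms.  This module segments cells from an OPD map and computes a
21-component feature vector per cell: optical features (OPD extrema and
mean), biophysical features (area, biomass, motion placeholders, centroid)
and morphological features (regionprops-style shape descriptors).

Motion features (``distance``, ``relative_distance``) depend on two
consecutive frames and are filled in by :mod:`killscope.track`; here they are
emitted as NaN.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage import measure, morphology
from skimage.filters import apply_hysteresis_threshold

#: Default specific refractive increment, m^3/kg.
DEFAULT_ALPHA = 1.8e-4

#: Canonical feature order (optical, biophysical, morphological).
FEATURE_NAMES = [
    "max_intensity",
    "min_intensity",
    "mean_phase_shift",
    "area",
    "biomass_pg",
    "distance",
    "relative_distance",
    "x_coord",
    "y_coord",
    "convex_area",
    "eccentricity",
    "equivalent_diameter",
    "extent",
    "filled_area",
    "major_axis",
    "minor_axis",
    "orientation",
    "perimeter",
    "perimeter2",
    "shape_factor",
    "solidity",
]

#: Default top-ten discriminative feature set (may be re-derived by
#: :mod:`killscope.select` on any labeled table).
TOP10_FEATURES = [
    "max_intensity",
    "mean_phase_shift",
    "area",
    "distance",
    "relative_distance",
    "eccentricity",
    "equivalent_diameter",
    "major_axis",
    "perimeter",
    "shape_factor",
]


@dataclass(frozen=True)
class PhaseImage:
    """One time point's OPD map with pixel geometry.

    Parameters
    ----------
    opd_nm
        2-D array of optical path difference per pixel, in nanometres.
    pixel_size_um
        Lateral pixel size in micrometres.
    frame_index
        Zero-based acquisition index.
    timestamp_min
        Acquisition time in minutes from the start of the series.
    """

    opd_nm: np.ndarray
    pixel_size_um: float
    frame_index: int = 0
    timestamp_min: float = 0.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.opd_nm, dtype=float)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("opd_nm must be a non-empty 2-D array")
        if not np.all(np.isfinite(arr)):
            raise ValueError("opd_nm contains non-finite values")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "opd_nm", arr)


@dataclass(frozen=True)
class SegmentationParams:
    """Parameters of the local-threshold + edge-detection segmentation.

    ``local_window_px`` and ``local_offset_nm`` control the adaptive mean
    threshold (a pixel is foreground when it exceeds its local mean by the
    offset).  ``edge_sigma_px`` is the Gaussian scale of the gradient used
    for edge detection; edge hysteresis thresholds default to
    ``local_offset_nm / edge_sigma_px`` (high) and half that (low), i.e. an
    edge must climb the threshold offset within about one smoothing scale.
    """

    local_window_px: int = 31
    local_offset_nm: float = 8.0
    edge_sigma_px: float = 1.5
    min_area_px: int = 250
    fill_holes: bool = True
    edge_low_nm_per_px: float | None = None
    edge_high_nm_per_px: float | None = None

    def __post_init__(self) -> None:
        if self.local_window_px < 3 or self.local_window_px % 2 == 0:
            raise ValueError("local_window_px must be odd and >= 3")
        if self.min_area_px < 1:
            raise ValueError("min_area_px must be >= 1")

    @property
    def edge_high(self) -> float:
        if self.edge_high_nm_per_px is not None:
            return self.edge_high_nm_per_px
        return self.local_offset_nm / self.edge_sigma_px

    @property
    def edge_low(self) -> float:
        if self.edge_low_nm_per_px is not None:
            return self.edge_low_nm_per_px
        return 0.5 * self.edge_high


@dataclass
class FeatureVector:
    """Per-cell feature values, one field per quantified feature.

    Intensities are OPD in nanometres; ``area`` and other geometric features
    are in pixel units (``area_um2`` is provided alongside in exported
    tables); ``biomass_pg`` is dry mass in picograms; ``distance`` is the
    centroid displacement from the previous frame in micrometres and
    ``relative_distance`` is ``distance / area`` — both NaN until a track
    provides the preceding frame.
    """

    max_intensity: float
    min_intensity: float
    mean_phase_shift: float
    area: float
    biomass_pg: float
    distance: float
    relative_distance: float
    x_coord: float
    y_coord: float
    convex_area: float
    eccentricity: float
    equivalent_diameter: float
    extent: float
    filled_area: float
    major_axis: float
    minor_axis: float
    orientation: float
    perimeter: float
    perimeter2: float
    shape_factor: float
    solidity: float

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass
class CellRegion:
    """One segmented cell at one time point.

    ``mask`` is the boolean mask of the region within the bounding-box
    ``bbox = (min_row, min_col, max_row, max_col)`` (half-open, as in
    scikit-image).
    """

    region_id: int
    frame_index: int
    bbox: tuple[int, int, int, int]
    mask: np.ndarray
    features: FeatureVector | None = None

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment(
    image: PhaseImage, params: SegmentationParams | None = None
) -> tuple[np.ndarray, list[CellRegion]]:
    """Segment cells from background.

    The foreground mask is the union of (a) an adaptive mean threshold —
    pixels exceeding their ``local_window_px`` neighbourhood mean by
    ``local_offset_nm`` — and (b) a hysteresis threshold on the Gaussian
    gradient magnitude of the OPD map.  Holes are filled (optional), objects
    below ``min_area_px`` removed, and the result labeled with
    4-connectivity.

    Returns the integer label map (0 = background) and one
    :class:`CellRegion` per labeled object, ordered by label (row-major
    first-pixel order).  A uniform image yields zero regions.
    """
    params = params or SegmentationParams()
    opd = image.opd_nm

    local_mean = ndimage.uniform_filter(opd, size=params.local_window_px, mode="nearest")
    mask = opd > local_mean + params.local_offset_nm

    grad = ndimage.gaussian_gradient_magnitude(opd, sigma=params.edge_sigma_px)
    edges = apply_hysteresis_threshold(grad, params.edge_low, params.edge_high)
    mask |= edges

    if params.fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    mask = morphology.remove_small_objects(mask, max_size=params.min_area_px - 1)

    labels, _ = ndimage.label(mask, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))
    regions = []
    for rp in measure.regionprops(labels):
        regions.append(
            CellRegion(
                region_id=int(rp.label),
                frame_index=image.frame_index,
                bbox=tuple(int(v) for v in rp.bbox),
                mask=rp.image.copy(),
            )
        )
    return labels, regions


# ---------------------------------------------------------------------------
# Biomass
# ---------------------------------------------------------------------------

def measure_biomass(
    region: CellRegion, image: PhaseImage, alpha: float = DEFAULT_ALPHA
) -> float:
    """Dry biomass of a segmented region in picograms.

    mass = (sum of OPD over the mask) * pixel_area / alpha, i.e.

        pg = sum(OPD_nm) * pixel_size_um**2 * 1e-6 / alpha

    (1 nm * 1 um^2 = 1e-21 m^3; dividing by alpha [m^3/kg] gives kg;
    1 kg = 1e15 pg).
    """
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    r0, c0, r1, c1 = region.bbox
    patch = image.opd_nm[r0:r1, c0:c1]
    if patch.shape != region.mask.shape:
        raise ValueError("region bounding box exceeds image bounds")
    total_nm = float(patch[region.mask].sum())
    return total_nm * image.pixel_size_um**2 * 1e-6 / alpha


# ---------------------------------------------------------------------------
# Shape / intensity features
# ---------------------------------------------------------------------------

def _orientation_deg(mask: np.ndarray) -> float:
    """Major-axis angle from the x-axis, counter-clockwise positive, degrees.

    Computed from the central second moments of the mask with the image row
    direction negated so that the result follows the mathematical (y-up)
    convention used in the source tables. Range [-90, 90].
    """
    rows, cols = np.nonzero(mask)
    x = cols - cols.mean()
    y = -(rows - rows.mean())  # y-up
    mxx = float((x * x).mean())
    myy = float((y * y).mean())
    mxy = float((x * y).mean())
    if mxx == myy and mxy == 0.0:
        return 0.0
    theta = 0.5 * math.atan2(2.0 * mxy, mxx - myy)
    deg = math.degrees(theta)
    if deg > 90.0:
        deg -= 180.0
    elif deg < -90.0:
        deg += 180.0
    return deg


def extract_features(
    region: CellRegion,
    image: PhaseImage,
    alpha: float = DEFAULT_ALPHA,
    shape_factor_literal: bool = False,
) -> FeatureVector:
    """Compute the full feature vector for one segmented region.

    ``shape_factor`` defaults to the dimensionless circularity 4*pi*A/P**2
    (1 for a circle); ``shape_factor_literal=True`` switches to 4*pi*A/P.
    ``perimeter`` is the Crofton-formula boundary length (nearly unbiased on
    rasterized smooth shapes, so circularity of a digital circle is ~1) and
    ``perimeter2`` the polygonal chain length (a second edge weighting of
    the same boundary, biased high by ~5% on curved boundaries).
    Degenerate regions (single pixel / zero-length axes) use the convention
    eccentricity = 0, orientation = 0.
    """
    r0, c0, r1, c1 = region.bbox
    patch = image.opd_nm[r0:r1, c0:c1]
    labeled = region.mask.astype(np.uint8)
    rp = measure.regionprops(labeled, intensity_image=patch)[0]

    vals = patch[region.mask]
    area = float(rp.area)
    perim = float(rp.perimeter_crofton)
    perim2 = float(rp.perimeter)
    major = float(rp.axis_major_length)
    minor = float(rp.axis_minor_length)
    ecc = float(rp.eccentricity) if major > 0 else 0.0

    if perim > 0:
        shape_factor = 4.0 * math.pi * area / (perim if shape_factor_literal else perim**2)
    else:
        shape_factor = 0.0

    cy, cx = rp.centroid  # row, col within the patch
    return FeatureVector(
        max_intensity=float(vals.max()),
        min_intensity=float(vals.min()),
        mean_phase_shift=float(vals.mean()),
        area=area,
        biomass_pg=measure_biomass(region, image, alpha),
        distance=float("nan"),
        relative_distance=float("nan"),
        x_coord=float(cx + c0),
        y_coord=float(cy + r0),
        convex_area=float(rp.area_convex),
        eccentricity=ecc,
        equivalent_diameter=math.sqrt(4.0 * area / math.pi),
        extent=float(rp.extent),
        filled_area=float(rp.area_filled),
        major_axis=major,
        minor_axis=minor,
        orientation=_orientation_deg(region.mask),
        perimeter=perim,
        perimeter2=perim2,
        shape_factor=shape_factor,
        solidity=float(rp.solidity),
    )


# ---------------------------------------------------------------------------
# Frame-level convenience and I/O
# ---------------------------------------------------------------------------

def frame_table(
    image: PhaseImage,
    params: SegmentationParams | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Segment one frame and return a feature table (one row per region).

    Columns: ``frame_index``, ``region_id``, every :data:`FEATURE_NAMES`
    entry, plus ``area_um2`` and ``timestamp_min``.
    """
    _, regions = segment(image, params)
    rows = []
    for reg in regions:
        fv = extract_features(reg, image, alpha=alpha)
        reg.features = fv
        row = {"frame_index": image.frame_index, "region_id": reg.region_id}
        row.update(fv.as_dict())
        row["area_um2"] = fv.area * image.pixel_size_um**2
        row["timestamp_min"] = image.timestamp_min
        rows.append(row)
    cols = ["frame_index", "region_id", *FEATURE_NAMES, "area_um2", "timestamp_min"]
    return pd.DataFrame(rows, columns=cols)


def features_table(
    images: Sequence[PhaseImage],
    params: SegmentationParams | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Concatenated :func:`frame_table` over a whole image sequence."""
    tables = [frame_table(img, params, alpha) for img in images]
    if not tables:
        raise ValueError("empty image sequence")
    return pd.concat(tables, ignore_index=True)


def read_phase_tiffs(
    directory: str | Path,
    pixel_size_um: float,
    frame_interval_min: float = 15.0,
    pattern: str = "scene_t*.tif",
) -> list[PhaseImage]:
    """Load a directory of numbered float TIFF phase maps as PhaseImages.

    Frames are ordered by the numeric index embedded in the filename
    (``scene_t0003.tif`` -> 3); timestamps are ``index * frame_interval_min``.
    """
    directory = Path(directory)
    paths = sorted(directory.glob(pattern))
    if not paths:
        raise FileNotFoundError(f"no files matching {pattern!r} in {directory}")
    images = []
    for path in paths:
        digits = "".join(ch for ch in path.stem if ch.isdigit())
        idx = int(digits) if digits else len(images)
        opd = tifffile.imread(path).astype(float)
        images.append(
            PhaseImage(
                opd_nm=opd,
                pixel_size_um=pixel_size_um,
                frame_index=idx,
                timestamp_min=idx * frame_interval_min,
            )
        )
    images.sort(key=lambda im: im.frame_index)
    return images
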