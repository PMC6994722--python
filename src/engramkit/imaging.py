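"""Per-slice image processing: projection, ROI clearing, particle detection,
nucleus confirmation and dual-channel colocalization.

The stage mirrors a standard Fiji workflow for counting labeled neurons in
tissue sections: per-plane background subtraction, maximum projection of
the z-stack, clearing everything outside the granule-cell-layer ROI,
thresholding, and keeping connected components larger than a minimum
particle size (default 50 pixels, strict).  Signals are confirmed as cells
by requiring overlap with a Hoechst nucleus, and dual-labeled cells are
those detected in both fluorescence channels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.transform import resize

logger = logging.getLogger(__name__)


@dataclass
class DetectionParams:
    """Thresholding / filtering constants of the detection stage.

    ``threshold_mode`` is ``"otsu"`` (computed over positive pixels of the
    cleared projection) or ``"fixed"`` (requires ``threshold_value``).
    ``min_particle_size`` is a strict lower bound on component pixel area.
    ``colocalization_min_fraction`` is the fraction of the *smaller*
    footprint that the pixel intersection must cover for two particles to
    count as the same cell.
    """

    threshold_mode: str = "otsu"
    threshold_value: float | None = None
    min_particle_size: int = 50
    background_radius: float | None = 50.0
    colocalization_min_fraction: float = 0.5
    require_plane_support: bool = False

    def __post_init__(self) -> None:
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode == "fixed" and self.threshold_value is None:
            raise ValueError("fixed threshold mode requires threshold_value")
        if self.min_particle_size < 1:
            raise ValueError("min_particle_size must be >= 1")
        if not (0.0 < self.colocalization_min_fraction <= 1.0):
            raise ValueError("colocalization_min_fraction must be in (0, 1]")


@dataclass
class Detection:
    """One supra-threshold particle accepted as a positive signal."""

    id: int
    channel: str
    centroid: tuple[float, float]  # (row, col), 0-based
    pixel_area: int
    mean_intensity: float
    coords: np.ndarray  # (n_pixels, 2) int row/col footprint
    region: str | None = None


def subtract_background(image: np.ndarray, radius: float | None) -> np.ndarray:
    """Rolling-ball-style background subtraction via grey opening.

    The background is estimated as a morphological opening with a disk
    footprint of the given radius, computed on a downsampled copy for large
    radii and resampled back (the standard speed trick for rolling-ball
    subtraction).  ``radius=None`` disables subtraction.
    """
    img = np.asarray(image, dtype=np.float64)
    if radius is None:
        return img.copy()
    if radius <= 0:
        raise ValueError("background_radius must be positive or None")
    factor = max(1, int(radius // 8))
    if factor > 1:
        small_shape = (max(1, img.shape[0] // factor),
                       max(1, img.shape[1] // factor))
        small = resize(img, small_shape, order=1, anti_aliasing=True,
                       preserve_range=True)
        r_small = max(1, int(round(radius / factor)))
        bg_small = ndimage.grey_opening(small, footprint=disk(r_small))
        background = resize(bg_small, img.shape, order=1,
                            preserve_range=True)
    else:
        background = ndimage.grey_opening(img, footprint=disk(int(radius)))
    out = img - np.minimum(background, img)
    return out


def project_stack(
    stack: np.ndarray, background_radius: float | None = 50.0
) -> np.ndarray:
    """Background-subtract each plane, then take the per-pixel maximum."""
    arr = np.asarray(stack, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[0] < 1:
        raise ValueError("stack must contain at least one 2-D plane")
    planes = [subtract_background(p, background_radius) for p in arr]
    out = np.maximum.reduce(planes)
    return np.maximum(out, 0.0)


def clear_outside_roi(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Zero every pixel outside the ROI mask, leaving the inside unchanged."""
    img = np.asarray(image)
    m = np.asarray(mask).astype(bool)
    if img.shape != m.shape:
        raise ValueError(
            f"mask shape {m.shape} does not match image shape {img.shape}"
        )
    return np.where(m, img, 0)


def _resolve_threshold(image: np.ndarray, params: DetectionParams) -> float:
    if params.threshold_mode == "fixed":
        return float(params.threshold_value)
    pos = image[image > 0]
    if pos.size == 0 or np.all(pos == pos.flat[0]):
        return float("inf")  # nothing to separate: no detections
    return float(threshold_otsu(pos))


def detect_particles(
    image: np.ndarray,
    params: DetectionParams,
    channel: str = "",
    stack: np.ndarray | None = None,
) -> list[Detection]:
    """Threshold the cleared projection and keep large connected particles.

    Components use 8-connectivity and must have pixel area strictly greater
    than ``params.min_particle_size``.  If ``require_plane_support`` is set
    and the originating z-stack is supplied, a particle must additionally
    be supra-threshold in at least one individual plane (the single-frame
    review rule for ambiguous projected signals).
    """
    img = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    thr = _resolve_threshold(img, params)
    binary = img > thr
    if not binary.any():
        return []
    labeled = sk_label(binary, connectivity=2)
    dets: list[Detection] = []
    for prop in regionprops(labeled, intensity_image=img):
        if prop.area <= params.min_particle_size:
            continue
        coords = prop.coords
        if params.require_plane_support and stack is not None:
            planes = np.asarray(stack, dtype=np.float64)
            sub = planes[:, coords[:, 0], coords[:, 1]]
            if not (sub > thr).any():
                logger.info("dropping particle without single-plane support")
                continue
        dets.append(Detection(
            id=len(dets),
            channel=channel,
            centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
            pixel_area=int(prop.area),
            mean_intensity=float(prop.intensity_mean),
            coords=coords,
        ))
    return dets


def _footprint_label_map(
    dets: list[Detection], shape: tuple[int, int]
) -> np.ndarray:
    """Label image with det index + 1 at each footprint pixel."""
    lab = np.zeros(shape, dtype=np.int32)
    for i, d in enumerate(dets):
        lab[d.coords[:, 0], d.coords[:, 1]] = i + 1
    return lab


def _intersections(
    dets_a: list[Detection], dets_b: list[Detection], shape: tuple[int, int]
) -> dict[tuple[int, int], int]:
    """Pixel-intersection sizes for every overlapping (a, b) index pair."""
    if not dets_a or not dets_b:
        return {}
    lab_b = _footprint_label_map(dets_b, shape)
    inter: dict[tuple[int, int], int] = {}
    for i, d in enumerate(dets_a):
        hits = lab_b[d.coords[:, 0], d.coords[:, 1]]
        hits = hits[hits > 0]
        if hits.size:
            for j, cnt in zip(*np.unique(hits, return_counts=True)):
                inter[(i, int(j) - 1)] = int(cnt)
    return inter


def _image_shape(dets: list[Detection]) -> tuple[int, int]:
    mx = np.max([d.coords.max(axis=0) for d in dets], axis=0)
    return int(mx[0]) + 1, int(mx[1]) + 1


def confirm_nuclei(
    dets: list[Detection],
    hoechst_dets: list[Detection],
    params: DetectionParams | None = None,
) -> list[Detection]:
    """Keep only detections supported by a Hoechst nucleus.

    A detection is confirmed when its footprint intersection with some
    single nucleus covers at least ``colocalization_min_fraction`` of the
    smaller of the two footprints.
    """
    params = params or DetectionParams()
    if not dets or not hoechst_dets:
        return []
    shape = _image_shape(dets + hoechst_dets)
    inter = _intersections(dets, hoechst_dets, shape)
    frac = params.colocalization_min_fraction
    confirmed_idx = set()
    for (i, j), cnt in inter.items():
        smaller = min(dets[i].pixel_area, hoechst_dets[j].pixel_area)
        if cnt >= frac * smaller:
            confirmed_idx.add(i)
    dropped = len(dets) - len(confirmed_idx)
    if dropped:
        logger.info("confirm_nuclei: dropped %d unsupported signal(s)", dropped)
    return [d for i, d in enumerate(dets) if i in confirmed_idx]


def colocalize(
    dets_a: list[Detection],
    dets_b: list[Detection],
    params: DetectionParams | None = None,
) -> list[tuple[Detection, Detection]]:
    """One-to-one matching of particles detected in both channels.

    A pair overlaps when the footprint intersection covers at least
    ``colocalization_min_fraction`` of the smaller footprint; candidate
    pairs are resolved greedily by descending intersection size with a
    deterministic (a-index, b-index) tie-break.
    """
    params = params or DetectionParams()
    if not dets_a or not dets_b:
        return []
    shape = _image_shape(dets_a + dets_b)
    inter = _intersections(dets_a, dets_b, shape)
    frac = params.colocalization_min_fraction
    candidates = [
        (cnt, i, j)
        for (i, j), cnt in inter.items()
        if cnt >= frac * min(dets_a[i].pixel_area, dets_b[j].pixel_area)
    ]
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[Detection, Detection]] = []
    for cnt, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((dets_a[i], dets_b[j]))
    return pairs


def detections_frame(dets: list[Detection]):
    """Tidy per-detection table (no footprints) for CSV export."""
    import pandas as pd

    return pd.DataFrame([
        dict(id=d.id, channel=d.channel, row=d.centroid[0], col=d.centroid[1],
             pixel_area=d.pixel_area, mean_intensity=d.mean_intensity,
             region=d.region)
        for d in dets
    ])
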