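"""From detections to per-slice, per-region counts.

Total granule-cell numbers (Hoechst+) are not counted exhaustively in
tissue; instead a linear calibration from ROI area to manually counted
cells is fitted once per staining/sectioning condition and used to
estimate the denominator of the population fractions.  A calibration is
only accepted as valid when built from at least 15 ROIs with R^2 > 0.80.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .imaging import Detection

logger = logging.getLogger(__name__)

MIN_CALIBRATION_ROIS = 15
MIN_CALIBRATION_R2 = 0.80


@dataclass(frozen=True)
class AreaCountModel:
    """Fitted linear ROI-area -> cell-count calibration."""

    slope: float  # cells per pixel^2
    intercept: float  # cells
    r_squared: float
    n_rois: int
    valid: bool
    provenance: str = ""


@dataclass(frozen=True)
class SliceCounts:
    """Census of one slice/region: the symbols of the four rate formulas."""

    region: str
    hoechst: int
    gfp: int
    fos: int
    overlap: int

    def __post_init__(self) -> None:
        if not (0 <= self.overlap <= min(self.gfp, self.fos)):
            raise ValueError(
                f"overlap={self.overlap} outside [0, min(gfp={self.gfp}, "
                f"fos={self.fos})]"
            )
        if self.gfp > self.hoechst or self.fos > self.hoechst:
            raise ValueError(
                "single-channel count exceeds the Hoechst+ total "
                f"(hoechst={self.hoechst}, gfp={self.gfp}, fos={self.fos})"
            )


def fit_area_count_model(
    pairs: pd.DataFrame | list[tuple[float, float]],
    provenance: str = "",
) -> AreaCountModel:
    """Ordinary least-squares line through (ROI area, cell count) pairs.

    Models built from fewer than 15 ROIs or with R^2 <= 0.80 are returned
    flagged ``valid=False`` with a warning, never silently.
    """
    if isinstance(pairs, pd.DataFrame):
        areas = pairs["area"].to_numpy(dtype=float)
        counts = pairs["count"].to_numpy(dtype=float)
    else:
        arr = np.asarray(pairs, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("pairs must be (area, count) tuples")
        areas, counts = arr[:, 0], arr[:, 1]
    if areas.size < 2:
        raise ValueError("need at least 2 (area, count) pairs")
    if np.any(areas <= 0):
        raise ValueError("ROI areas must be positive")
    if np.allclose(areas, areas[0]):
        raise ValueError("all ROI areas identical: slope is unidentifiable")
    fit = stats.linregress(areas, counts)
    r2 = float(fit.rvalue**2)
    valid = areas.size >= MIN_CALIBRATION_ROIS and r2 > MIN_CALIBRATION_R2
    if not valid:
        warnings.warn(
            f"area-count calibration flagged invalid (n_rois={areas.size}, "
            f"R^2={r2:.3f}); needs >= {MIN_CALIBRATION_ROIS} ROIs and "
            f"R^2 > {MIN_CALIBRATION_R2}",
            stacklevel=2,
        )
    return AreaCountModel(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=r2,
        n_rois=int(areas.size),
        valid=valid,
        provenance=provenance,
    )


class AreaCountRegressor:
    """sklearn-style wrapper around the area->count calibration.

    ``fit(X, y)`` with ``X`` of shape (n, 1) ROI areas and ``y`` manual
    counts; exposes ``slope_``, ``intercept_``, ``r_squared_``, ``n_rois_``
    and ``valid_`` after fitting, and ``predict(X)`` returns rounded
    integer estimates.
    """

    def __init__(self, provenance: str = ""):
        self.provenance = provenance

    def get_params(self, deep: bool = True) -> dict:
        return {"provenance": self.provenance}

    def set_params(self, **params) -> "AreaCountRegressor":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y) -> "AreaCountRegressor":
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if X.ndim != 2 or X.shape[1] != 1:
            raise ValueError("X must be a single column of ROI areas")
        model = fit_area_count_model(
            list(zip(X[:, 0], np.asarray(y, dtype=float))),
            provenance=self.provenance,
        )
        self.model_ = model
        self.slope_ = model.slope
        self.intercept_ = model.intercept
        self.r_squared_ = model.r_squared
        self.n_rois_ = model.n_rois
        self.valid_ = model.valid
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise RuntimeError("regressor is not fitted")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        return np.rint(self.slope_ * X[:, 0] + self.intercept_).astype(int)


def estimate_total_cells(
    roi_area: float,
    model: AreaCountModel,
    floor_count: int | None = None,
    allow_invalid: bool = False,
) -> int:
    """Estimate Hoechst+ cells in an ROI from its area via the calibration.

    The estimate is floored at the number of directly detected nuclei when
    given.  Using a calibration flagged invalid requires ``allow_invalid``.
    """
    if not model.valid and not allow_invalid:
        raise ValueError(
            "area-count calibration is flagged invalid "
            f"(n_rois={model.n_rois}, R^2={model.r_squared:.3f}); "
            "pass allow_invalid=True to override"
        )
    est = model.slope * float(roi_area) + model.intercept
    if floor_count is not None:
        est = max(est, float(floor_count))
    if est < 0:
        raise ValueError(
            f"negative cell estimate ({est:.1f}) and no floor provided"
        )
    return int(round(est))


def split_total_by_area(total: int, areas: dict[str, float]) -> dict[str, int]:
    """Allocate a whole-ROI estimate to blades proportionally to blade area.

    Largest-remainder rounding keeps the blade counts summing exactly to
    the total, preserving the upper + lower = total invariant.
    """
    area_sum = sum(areas.values())
    if area_sum <= 0:
        raise ValueError("blade areas must sum to a positive value")
    keys = sorted(areas)
    raw = {k: total * areas[k] / area_sum for k in keys}
    base = {k: int(np.floor(raw[k])) for k in keys}
    short = total - sum(base.values())
    for k in sorted(keys, key=lambda k: raw[k] - base[k], reverse=True)[:short]:
        base[k] += 1
    return base


def _assign_region(
    det: Detection, region_labels: np.ndarray,
    nearest_label: np.ndarray | None,
) -> str:
    r, c = (int(round(det.centroid[0])), int(round(det.centroid[1])))
    r = np.clip(r, 0, region_labels.shape[0] - 1)
    c = np.clip(c, 0, region_labels.shape[1] - 1)
    lab = region_labels[r, c]
    if lab == 0 and nearest_label is not None:
        lab = nearest_label[r, c]
        logger.info(
            "detection at (%.0f, %.0f) outside both blades; assigned to "
            "nearest blade", det.centroid[0], det.centroid[1],
        )
    return {1: "lower", 2: "upper"}.get(int(lab), "lower")


def tabulate_slice(
    gfp_dets: list[Detection],
    fos_dets: list[Detection],
    pairs: list[tuple[Detection, Detection]],
    hoechst_estimate: int | dict[str, int],
    region_labels: np.ndarray,
) -> dict[str, SliceCounts]:
    """Blade-resolved census of one slice.

    Detections are assigned to the upper/lower blade by the label under
    their centroid (nearest blade for centroids in neither, logged); a
    colocalized pair counts toward the blade of its GFP member.
    ``hoechst_estimate`` is either per-blade ``{"upper": ..., "lower": ...}``
    or a whole-ROI total, split proportionally to blade pixel areas.

    Returns ``{"upper": SliceCounts, "lower": ..., "total": ...}``.
    """
    labels = np.asarray(region_labels)
    if isinstance(hoechst_estimate, dict):
        hoechst = {k: int(hoechst_estimate[k]) for k in ("upper", "lower")}
    else:
        areas = {
            "upper": float(np.sum(labels == 2)),
            "lower": float(np.sum(labels == 1)),
        }
        hoechst = split_total_by_area(int(hoechst_estimate), areas)

    nearest = None
    if labels.size and (labels == 0).any() and (labels > 0).any():
        _, idx = ndimage.distance_transform_edt(
            labels == 0, return_indices=True
        )
        nearest = labels[idx[0], idx[1]]

    counts = {r: {"gfp": 0, "fos": 0, "overlap": 0} for r in ("upper", "lower")}
    for d in gfp_dets:
        counts[_assign_region(d, labels, nearest)]["gfp"] += 1
    for d in fos_dets:
        counts[_assign_region(d, labels, nearest)]["fos"] += 1
    for g, _f in pairs:
        counts[_assign_region(g, labels, nearest)]["overlap"] += 1

    out: dict[str, SliceCounts] = {}
    for region in ("upper", "lower"):
        c = counts[region]
        h = max(hoechst[region], c["gfp"], c["fos"])  # estimate can undershoot
        if h > hoechst[region]:
            logger.info(
                "%s blade: Hoechst estimate %d below channel count; floored "
                "to %d", region, hoechst[region], h,
            )
        out[region] = SliceCounts(
            region=region, hoechst=h, gfp=c["gfp"], fos=c["fos"],
            overlap=min(c["overlap"], c["gfp"], c["fos"]),
        )
    out["total"] = SliceCounts(
        region="total",
        hoechst=out["upper"].hoechst + out["lower"].hoechst,
        gfp=out["upper"].gfp + out["lower"].gfp,
        fos=out["upper"].fos + out["lower"].fos,
        overlap=out["upper"].overlap + out["lower"].overlap,
    )
    return out


def counts_frame(
    per_region: dict[str, SliceCounts],
    *,
    group: str = "",
    batch: str = "",
    animal: str = "",
    slice_id: str = "",
) -> pd.DataFrame:
    """One tidy row per region, in the generator's count-table schema."""
    rows = [
        dict(group=group, batch=batch, animal=animal, slice=slice_id,
             region=c.region, hoechst=c.hoechst, gfp=c.gfp, fos=c.fos,
             overlap=c.overlap)
        for c in per_region.values()
    ]
    return pd.DataFrame(rows)
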