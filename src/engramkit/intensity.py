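"""Per-cell signal-intensity analyses for cultured neurons.

Two analyses operate on background-subtracted single-cell measurements:

* channel correlation — each neuron's integrated intensity
  (pixel area x mean intensity) is normalized to the set mean per channel
  and the two channels are correlated (Pearson);
* thresholded group comparison — cells above an expression threshold in a
  marker channel (e.g. an HA epitope tag) form the positive group, a
  random 10-15 sub-threshold cells per slice form the negative group, and
  the target-channel mean intensity of each group is averaged per slice,
  then per animal, then normalized to the animal's negative-group mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .imaging import Detection
from .inference import TestResult, pearson_test

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntensityRecord:
    """One cell's photometry in one channel."""

    cell_id: int
    channel: str
    pixel_area: int
    mean_intensity: float
    integrated_intensity: float
    normalized_intensity: float | None = None


def integrated_intensity(det: Detection, image: np.ndarray) -> IntensityRecord:
    """Area x mean intensity over the detection footprint.

    The image must already be background-subtracted; the footprint must lie
    inside it and be non-empty.
    """
    img = np.asarray(image, dtype=np.float64)
    if det.coords.size == 0:
        raise ValueError("empty detection footprint")
    if (det.coords[:, 0].max() >= img.shape[0]
            or det.coords[:, 1].max() >= img.shape[1]):
        raise ValueError("detection footprint outside image")
    vals = img[det.coords[:, 0], det.coords[:, 1]]
    mean = float(vals.mean())
    area = int(det.coords.shape[0])
    return IntensityRecord(
        cell_id=det.id,
        channel=det.channel,
        pixel_area=area,
        mean_intensity=mean,
        integrated_intensity=area * mean,
    )


def normalize_set(records: list[IntensityRecord]) -> list[IntensityRecord]:
    """Divide integrated intensities by the per-channel set mean.

    After normalization the mean of ``normalized_intensity`` within each
    channel is 1 by construction.
    """
    if not records:
        raise ValueError("need at least one record")
    out: list[IntensityRecord] = []
    by_channel: dict[str, list[IntensityRecord]] = {}
    for r in records:
        by_channel.setdefault(r.channel, []).append(r)
    normed: dict[int, IntensityRecord] = {}
    for ch, recs in by_channel.items():
        mean = float(np.mean([r.integrated_intensity for r in recs]))
        if mean <= 0:
            raise ValueError(f"channel {ch!r}: mean integrated intensity is 0")
        for r in recs:
            normed[id(r)] = replace(
                r, normalized_intensity=r.integrated_intensity / mean
            )
    return [normed[id(r)] for r in records]


def correlate_channels(
    records_a: list[IntensityRecord],
    records_b: list[IntensityRecord],
) -> TestResult:
    """Pearson correlation of normalized integrated intensities, paired by cell."""
    a = {r.cell_id: r for r in records_a}
    b = {r.cell_id: r for r in records_b}
    common = sorted(set(a) & set(b))
    if len(common) < 3:
        raise ValueError("need at least 3 cells present in both channels")

    def value(r: IntensityRecord) -> float:
        return (r.normalized_intensity
                if r.normalized_intensity is not None
                else r.integrated_intensity)

    xs = [value(a[c]) for c in common]
    ys = [value(b[c]) for c in common]
    return pearson_test(xs, ys)


def compare_ha_groups(
    cells: pd.DataFrame,
    threshold: float,
    k_negative_range: tuple[int, int] = (10, 15),
    seed: int = 0,
    *,
    marker_col: str = "ha",
    target_col: str = "target",
) -> pd.DataFrame:
    """Marker-positive vs. marker-negative target intensity, per animal.

    ``cells`` has one row per cell with columns ``animal, slice`` plus the
    marker-channel and target-channel mean intensities.  Per slice, cells
    with marker intensity above ``threshold`` form the positive group and a
    seeded uniform sample of k sub-threshold cells (k drawn from
    ``k_negative_range``) forms the negative group; slices with fewer than
    ``k_negative_range[0]`` sub-threshold cells are skipped with a log
    entry.  Per-slice group means of the target intensity are averaged per
    animal and divided by the animal's negative-group mean, so the negative
    group normalizes to 1.

    Returns one row per animal: ``ha_pos, ha_neg, ha_pos_norm, ha_neg_norm``.
    """
    k_lo, k_hi = k_negative_range
    if k_lo < 1 or k_hi < k_lo:
        raise ValueError("invalid k_negative_range")
    rng = np.random.default_rng(seed)
    slice_rows = []
    for (animal, slc), sub in cells.groupby(["animal", "slice"], sort=True):
        pos = sub[sub[marker_col] > threshold]
        neg_pool = sub[sub[marker_col] <= threshold]
        if pos.empty:
            logger.info("slice %s/%s: no marker-positive cells; skipped",
                        animal, slc)
            continue
        if len(neg_pool) < k_lo:
            logger.info(
                "slice %s/%s: only %d sub-threshold cells (< %d); skipped",
                animal, slc, len(neg_pool), k_lo,
            )
            continue
        k = int(rng.integers(k_lo, min(k_hi, len(neg_pool)) + 1))
        neg = neg_pool.sample(n=k, random_state=rng)
        slice_rows.append(dict(
            animal=animal, slice=slc,
            ha_pos=float(pos[target_col].mean()),
            ha_neg=float(neg[target_col].mean()),
        ))
    if not slice_rows:
        raise ValueError("no usable slices after selection rules")
    per_slice = pd.DataFrame(slice_rows)
    per_animal = per_slice.groupby("animal", as_index=False)[
        ["ha_pos", "ha_neg"]
    ].mean()
    per_animal["ha_pos_norm"] = per_animal["ha_pos"] / per_animal["ha_neg"]
    per_animal["ha_neg_norm"] = 1.0
    return per_animal
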