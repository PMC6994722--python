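"""The four ensemble-reactivation statistics and their aggregation.

Given a slice census (Hoechst+, GFP+, Fos+, GFP+Fos+ counts), four
quantities describe how strongly the learning-tagged ensemble is re-engaged
at recall:

* observed overlap  = (GFP+Fos+) / Hoechst+ x 100
* chance overlap    = GFP+/Hoechst+ x Fos+/Hoechst+ x 100
  (the overlap expected were the two labels independent)
* reactivation rate = (GFP+Fos+) / GFP+ x 100
* similarity index  = (GFP+Fos+) / (GFP+ + Fos+ - GFP+Fos+) x 100
  (the Jaccard index of the two labeled populations)

Slices are quantified individually, averaged per animal, and optionally
normalized to the control-group mean within an experimental batch to
absorb batch-to-batch differences in viral delivery and staining.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .census import SliceCounts

logger = logging.getLogger(__name__)

RATE_COLUMNS = [
    "observed_overlap", "chance_overlap", "obs_over_chance",
    "reactivation_rate", "similarity_index", "gfp_rate", "fos_rate",
]


@dataclass(frozen=True)
class EngramRates:
    """The ensemble statistics of one slice (or one animal, after averaging).

    All rate fields are percentages in [0, 100]; ``obs_over_chance`` is a
    dimensionless ratio.  Undefined statistics (e.g. the reactivation rate
    of a slice with no GFP+ cells) are NaN.
    """

    observed_overlap: float
    chance_overlap: float
    obs_over_chance: float
    reactivation_rate: float
    similarity_index: float
    gfp_rate: float
    fos_rate: float


def observed_overlap(c: SliceCounts) -> float:
    """(GFP+Fos+) / Hoechst+ x 100."""
    if c.hoechst <= 0:
        raise ValueError("observed overlap undefined: Hoechst+ count is 0")
    return 100.0 * c.overlap / c.hoechst


def chance_overlap(c: SliceCounts) -> float:
    """GFP+/Hoechst+ x Fos+/Hoechst+ x 100 — the independence expectation."""
    if c.hoechst <= 0:
        raise ValueError("chance overlap undefined: Hoechst+ count is 0")
    return 100.0 * (c.gfp / c.hoechst) * (c.fos / c.hoechst)


def reactivation_rate(c: SliceCounts) -> float:
    """(GFP+Fos+) / GFP+ x 100; NaN (with a log entry) when GFP+ = 0."""
    if c.gfp <= 0:
        logger.info("reactivation rate undefined (GFP+ = 0); slice excluded")
        return float("nan")
    return 100.0 * c.overlap / c.gfp


def similarity_index(c: SliceCounts) -> float:
    """Jaccard index of the GFP+ and Fos+ populations x 100.

    NaN (with a log entry) when both populations are empty.
    """
    denom = c.gfp + c.fos - c.overlap
    if denom <= 0:
        logger.info("similarity index undefined (both sets empty); excluded")
        return float("nan")
    return 100.0 * c.overlap / denom


def compute_rates(c: SliceCounts) -> EngramRates:
    """All engram statistics of one slice census."""
    obs = observed_overlap(c)
    cha = chance_overlap(c)
    return EngramRates(
        observed_overlap=obs,
        chance_overlap=cha,
        obs_over_chance=obs / cha if cha > 0 else float("nan"),
        reactivation_rate=reactivation_rate(c),
        similarity_index=similarity_index(c),
        gfp_rate=100.0 * c.gfp / c.hoechst,
        fos_rate=100.0 * c.fos / c.hoechst,
    )


def rates_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-slice rates for a tidy count table (generator/census schema).

    Appends the rate columns to the identifying columns; rows where a
    statistic is undefined carry NaN there and stay in the table so that
    per-animal averaging can skip them.
    """
    required = {"hoechst", "gfp", "fos", "overlap"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"count table lacks columns: {sorted(missing)}")
    out = counts.copy()
    h = out["hoechst"].to_numpy(dtype=float)
    g = out["gfp"].to_numpy(dtype=float)
    f = out["fos"].to_numpy(dtype=float)
    o = out["overlap"].to_numpy(dtype=float)
    if np.any(h <= 0):
        raise ValueError("count table has rows with Hoechst+ = 0")
    obs = 100.0 * o / h
    cha = 100.0 * (g / h) * (f / h)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["observed_overlap"] = obs
        out["chance_overlap"] = cha
        out["obs_over_chance"] = np.where(cha > 0, obs / cha, np.nan)
        out["reactivation_rate"] = np.where(g > 0, 100.0 * o / g, np.nan)
        denom = g + f - o
        out["similarity_index"] = np.where(denom > 0, 100.0 * o / denom, np.nan)
        out["gfp_rate"] = 100.0 * g / h
        out["fos_rate"] = 100.0 * f / h
    n_undef = int(out["reactivation_rate"].isna().sum())
    if n_undef:
        logger.info("rates_table: %d slice/region row(s) with GFP+ = 0", n_undef)
    return out


def aggregate_animal(
    rates: pd.DataFrame | list[EngramRates],
    by: tuple[str, ...] = ("group", "batch", "animal", "region"),
) -> pd.DataFrame | EngramRates:
    """Per-animal arithmetic mean of each statistic over its slices.

    Undefined (NaN) slice values are skipped per statistic; an animal with
    no defined slice for a statistic propagates NaN.  Accepts either a
    tidy per-slice frame (grouped by ``by``) or a plain list of
    :class:`EngramRates` for one animal.
    """
    if isinstance(rates, list):
        if not rates:
            raise ValueError("need at least one slice")
        arr = {
            f.name: np.nanmean([getattr(r, f.name) for r in rates])
            if not np.all(np.isnan([getattr(r, f.name) for r in rates]))
            else float("nan")
            for f in fields(EngramRates)
        }
        return EngramRates(**arr)
    keys = [k for k in by if k in rates.columns]
    return (
        rates.groupby(keys, sort=True, as_index=False)[RATE_COLUMNS]
        .mean()  # pandas mean skips NaN per column
    )


def normalize_to_control(
    animals: pd.DataFrame,
    value_cols: list[str] | None = None,
    *,
    group_col: str = "group",
    control_group: str = "control",
    batch_col: str = "batch",
) -> pd.DataFrame:
    """Express each animal's rate as fold change over its batch's controls.

    Within every batch the named columns are divided by the mean over the
    control-group animals of that batch, so controls average to 1 within
    batch.  A batch without control animals is an error.
    """
    value_cols = value_cols or [c for c in RATE_COLUMNS if c in animals.columns]
    out = animals.copy()
    for batch, sub in animals.groupby(batch_col):
        ctrl = sub[sub[group_col] == control_group]
        if ctrl.empty:
            raise ValueError(f"batch {batch!r} has no {control_group!r} animals")
        for col in value_cols:
            denom = ctrl[col].mean()
            if not np.isfinite(denom) or denom == 0:
                raise ValueError(
                    f"batch {batch!r}: control mean of {col} is {denom}; "
                    "cannot normalize"
                )
            idx = sub.index
            out.loc[idx, col + "_norm"] = animals.loc[idx, col] / denom
    return out
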