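"""TIFF / CSV round-tripping for image bundles and count tables."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import COUNT_COLUMNS, ImageBundle


def write_bundle(bundle: ImageBundle, directory: str | Path,
                 prefix: str = "slice") -> dict[str, Path]:
    """Write one channel per multi-page TIFF plus the region label mask.

    Masks use the 0 = outside / 1 = lower blade / 2 = upper blade
    convention as 8-bit label TIFF.  Returns the written paths by name.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for ch, stack in bundle.channels.items():
        p = d / f"{prefix}_{ch}.tif"
        tifffile.imwrite(p, np.asarray(stack, dtype=np.float32))
        paths[ch] = p
    mask_path = d / f"{prefix}_regions.tif"
    tifffile.imwrite(mask_path, bundle.region_labels.astype(np.uint8))
    paths["regions"] = mask_path
    return paths


def read_bundle(channel_paths: dict[str, str | Path],
                regions_path: str | Path) -> ImageBundle:
    """Load an :class:`ImageBundle` from per-channel TIFFs and a label mask."""
    channels = {}
    for ch, p in channel_paths.items():
        arr = tifffile.imread(p)
        if arr.ndim == 2:
            arr = arr[None]
        channels[ch] = arr.astype(np.float32)
    labels = tifffile.imread(regions_path).astype(np.uint8)
    return ImageBundle(channels=channels, region_labels=labels)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a tidy count table, validating the schema."""
    df = pd.read_csv(path)
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table lacks columns: {sorted(missing)}")
    return df


def write_counts(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
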