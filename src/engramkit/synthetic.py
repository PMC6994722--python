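"""Synthetic dentate-gyrus cohorts with known ground truth.

The generator emulates the labeling design of an engram-reactivation
experiment: a sparse learning-tagged ensemble (GFP channel, ~5% of granule
cells), a recall-activated population (Fos channel) and a nuclear
counterstain (Hoechst), in a two-bladed band-shaped granule-cell layer.
Labeling is per-cell independent Bernoulli — the minimal generative model
consistent with the product-of-marginals chance-overlap formula — with the
conditional reactivation probability ``rho = P(Fos+ | GFP+)`` the single
dial for above-chance overlap.  ``rho = p_fos`` reproduces independence.

All randomness flows from one explicit integer seed through
``numpy.random.SeedSequence`` spawning, so identical seeds give
bit-identical tables and images.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

REGIONS = ("upper", "lower")
COUNT_COLUMNS = [
    "group", "batch", "animal", "slice", "region",
    "hoechst", "gfp", "fos", "overlap",
]


@dataclass(frozen=True)
class EnsembleGroundTruth:
    """Population parameters of one simulated condition.

    Parameters
    ----------
    n_cells : int
        Granule cells per region (both blades together).
    p_gfp : float
        Fraction of cells tagged during learning (GFP+).
    p_fos : float
        Marginal fraction activated at recall (Fos+).
    rho : float
        Conditional reactivation probability ``P(Fos+ | GFP+)``; the
        population reactivation rate is ``100 * rho``.
    region_split : float
        Fraction of cells in the upper blade.
    """

    n_cells: int = 2000
    p_gfp: float = 0.05
    p_fos: float = 0.05
    rho: float = 0.30
    region_split: float = 0.5

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1 (empty region)")
        for name in ("p_gfp", "p_fos", "rho", "region_split"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.rho * self.p_gfp > self.p_fos + 1e-12:
            raise ValueError(
                "infeasible truth: rho*p_gfp "
                f"({self.rho * self.p_gfp:.4g}) exceeds p_fos ({self.p_fos:.4g})"
            )
        if self.p_gfp < 1.0:
            q = self.fos_given_not_gfp
            if not (0.0 <= q <= 1.0 + 1e-12):
                raise ValueError(
                    "infeasible truth: P(Fos+|GFP-) = "
                    f"(p_fos - rho*p_gfp)/(1 - p_gfp) = {q:.4g} outside [0, 1]"
                )

    @property
    def fos_given_not_gfp(self) -> float:
        """``P(Fos+ | GFP-)`` implied by the marginal and conditional."""
        if self.p_gfp >= 1.0:
            return 0.0
        return (self.p_fos - self.rho * self.p_gfp) / (1.0 - self.p_gfp)


def _clip_rho(rho: float, truth: EnsembleGroundTruth) -> float:
    """Clip a jittered rho into the feasible interval of the marginals."""
    lo = 0.0
    hi = 1.0
    if truth.p_gfp > 0:
        hi = min(hi, truth.p_fos / truth.p_gfp)
        lo = max(lo, (truth.p_fos - (1.0 - truth.p_gfp)) / truth.p_gfp)
    return float(np.clip(rho, lo, hi))


def _sample_region_counts(
    n: int, truth: EnsembleGroundTruth, rho: float, rng: np.random.Generator
) -> tuple[int, int, int]:
    """Draw (gfp, fos, overlap) for ``n`` cells labeled independently."""
    gfp = int(rng.binomial(n, truth.p_gfp))
    overlap = int(rng.binomial(gfp, rho))
    q = truth.fos_given_not_gfp if rho == truth.rho else _q_for(truth, rho)
    fos = overlap + int(rng.binomial(n - gfp, q))
    return gfp, fos, overlap


def _q_for(truth: EnsembleGroundTruth, rho: float) -> float:
    if truth.p_gfp >= 1.0:
        return 0.0
    return float(np.clip(
        (truth.p_fos - rho * truth.p_gfp) / (1.0 - truth.p_gfp), 0.0, 1.0
    ))


def make_count_table(
    truth: EnsembleGroundTruth,
    n_animals_per_group: int,
    n_slices_per_animal: int,
    seed: int,
    *,
    group: str = "control",
    batch: str = "b1",
    between_animal_sd: float = 0.0,
    within_animal_sd: float = 0.0,
) -> pd.DataFrame:
    """Simulate a hierarchical count table (animal -> slice -> region).

    Each slice carries rows for the upper blade, lower blade and their sum
    (region ``total``), in the same tidy schema the image pipeline emits:
    columns ``group, batch, animal, slice, region, hoechst, gfp, fos,
    overlap``.  ``between_animal_sd`` / ``within_animal_sd`` optionally
    jitter rho per animal / per slice (Gaussian, clipped to the feasible
    range), defaulting to no jitter.
    """
    if n_animals_per_group < 1 or n_slices_per_animal < 1:
        raise ValueError("need at least 1 animal and 1 slice")
    root = np.random.SeedSequence(seed)
    rows: list[dict] = []
    for a_idx, a_seq in enumerate(root.spawn(n_animals_per_group), start=1):
        rng = np.random.default_rng(a_seq)
        animal = f"{group}_a{a_idx}"
        rho_animal = _clip_rho(
            truth.rho + rng.normal(0.0, between_animal_sd)
            if between_animal_sd > 0 else truth.rho,
            truth,
        )
        for s_idx in range(1, n_slices_per_animal + 1):
            rho_slice = _clip_rho(
                rho_animal + rng.normal(0.0, within_animal_sd)
                if within_animal_sd > 0 else rho_animal,
                truth,
            )
            n_upper = int(rng.binomial(truth.n_cells, truth.region_split))
            per_region = {}
            for region, n_reg in (("upper", n_upper),
                                  ("lower", truth.n_cells - n_upper)):
                gfp, fos, overlap = _sample_region_counts(
                    n_reg, truth, rho_slice, rng
                )
                per_region[region] = (n_reg, gfp, fos, overlap)
                rows.append(dict(
                    group=group, batch=batch, animal=animal,
                    slice=f"s{s_idx}", region=region,
                    hoechst=n_reg, gfp=gfp, fos=fos, overlap=overlap,
                ))
            tot = tuple(sum(v[i] for v in per_region.values()) for i in range(4))
            rows.append(dict(
                group=group, batch=batch, animal=animal,
                slice=f"s{s_idx}", region="total",
                hoechst=tot[0], gfp=tot[1], fos=tot[2], overlap=tot[3],
            ))
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RenderParams:
    """Geometry and photometry of a rendered slice.

    Nuclei are isotropic Gaussian-profile blobs (sd ``nucleus_radius``
    pixels, truncated at 3 sd); at the default radius the half-peak
    footprint is ~70 pixels, safely above the 50-pixel particle filter.
    ``n_z`` planes are spaced ``z_step`` micrometres apart and each nucleus
    spreads over z with sd ``z_sigma_um``.
    """

    image_shape: tuple[int, int] = (768, 768)
    n_z: int = 3
    z_step: float = 2.0  # micrometres between consecutive planes
    nucleus_radius: float = 4.0  # Gaussian sd, pixels
    z_sigma_um: float = 2.0
    peak_intensity: dict = field(default_factory=lambda: {
        "hoechst": 200.0, "gfp": 200.0, "fos": 200.0,
    })
    background_level: float = 20.0
    noise_sd: float = 5.0
    # min center distance in units of nucleus_radius; at 4.0 the intensity
    # saddle between two neighbours stays well below the Otsu threshold, so
    # nuclei resolve as separate connected components
    min_spacing_factor: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_z < 1:
            raise ValueError("need at least one z-plane")
        if self.nucleus_radius <= 0:
            raise ValueError("nucleus_radius must be positive")
        # half-peak footprint must clear the particle-size filter
        area = np.pi * (self.nucleus_radius * np.sqrt(2 * np.log(2))) ** 2
        if area <= 50:
            raise ValueError(
                f"nucleus half-peak area {area:.0f} px does not exceed the "
                "50-pixel particle filter; increase nucleus_radius"
            )


@dataclass
class ImageBundle:
    """One rendered slice: per-channel z-stacks plus region label mask.

    ``region_labels`` uses 0 = outside ROI, 1 = lower blade, 2 = upper
    blade, the same convention the detection stage reads.
    """

    channels: dict[str, np.ndarray]  # channel -> (n_z, H, W) float32
    region_labels: np.ndarray  # (H, W) uint8

    def mask(self, region: str) -> np.ndarray:
        if region == "total":
            return self.region_labels > 0
        if region == "upper":
            return self.region_labels == 2
        if region == "lower":
            return self.region_labels == 1
        raise ValueError(f"unknown region {region!r}")


def blade_label_mask(shape: tuple[int, int]) -> np.ndarray:
    """Two parallel curved bands emulating the DG blades.

    The centerlines are shallow parabolas; band half-thickness is 9% of the
    image height.  Returns a uint8 label image (0/1/2).
    """
    h, w = shape
    x = np.arange(w)
    bow = 0.10 * h * ((2.0 * x / max(w - 1, 1) - 1.0) ** 2 - 0.5)
    c_upper = 0.32 * h + bow
    c_lower = 0.68 * h + bow
    half = 0.09 * h
    rowgrid = np.arange(h)[:, None]
    labels = np.zeros(shape, dtype=np.uint8)
    labels[np.abs(rowgrid - c_lower[None, :]) <= half] = 1
    labels[np.abs(rowgrid - c_upper[None, :]) <= half] = 2
    return labels


def _place_nuclei(
    labels: np.ndarray,
    n_upper: int,
    n_lower: int,
    min_dist: float,
    rng: np.random.Generator,
    margin: float = 0.0,
    max_tries_per_cell: int = 400,
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping centers inside each blade band.

    ``margin`` erodes the placement region so that a nucleus footprint
    never straddles the ROI boundary (where clearing would clip it).
    """
    if margin > 0:
        from scipy import ndimage

        placement = np.zeros_like(labels)
        for lab in (1, 2):
            eroded = ndimage.binary_erosion(
                labels == lab, iterations=int(np.ceil(margin)),
                border_value=0,
            )
            placement[eroded] = lab
        labels = placement
    cell = max(min_dist, 1.0)
    buckets: dict[tuple[int, int], list[tuple[float, float]]] = {}

    def ok(y: float, x: float) -> bool:
        by, bx = int(y // cell), int(x // cell)
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                for (py, px) in buckets.get((by + dy, bx + dx), ()):
                    if (py - y) ** 2 + (px - x) ** 2 < min_dist**2:
                        return False
        return True

    coords_r, regions = [], []
    for region_label, n_req, name in ((2, n_upper, "upper"), (1, n_lower, "lower")):
        ys, xs = np.nonzero(labels == region_label)
        if n_req > 0 and ys.size == 0:
            raise RuntimeError(f"blade mask for {name} region is empty")
        for _ in range(n_req):
            for _try in range(max_tries_per_cell):
                k = int(rng.integers(ys.size))
                y = ys[k] + rng.uniform(-0.5, 0.5)
                x = xs[k] + rng.uniform(-0.5, 0.5)
                if ok(y, x):
                    buckets.setdefault(
                        (int(y // cell), int(x // cell)), []
                    ).append((y, x))
                    coords_r.append((y, x))
                    regions.append(name)
                    break
            else:
                raise RuntimeError(
                    f"could not place {n_req} nuclei in the {name} blade at "
                    f"min spacing {min_dist:.1f}px; density too high"
                )
    return np.asarray(coords_r, dtype=float), np.asarray(regions, dtype=object)


def render_slice(
    truth: EnsembleGroundTruth,
    rp: RenderParams,
) -> tuple[ImageBundle, pd.DataFrame]:
    """Render one slice and return the bundle plus a per-cell truth table.

    The truth table has columns ``cell, y, x, z, region, gfp, fos``; the
    Hoechst channel contains every nucleus, the GFP/Fos channels contain
    blobs only at nuclei carrying the corresponding label.
    """
    rng = np.random.default_rng(rp.seed)
    labels = blade_label_mask(rp.image_shape)
    n_upper = int(rng.binomial(truth.n_cells, truth.region_split))
    n_lower = truth.n_cells - n_upper
    min_dist = rp.min_spacing_factor * rp.nucleus_radius
    # keep centers 1.5 sd clear of the ROI boundary: intensity beyond
    # 1.5 sd is < 33% of peak, below any sensible threshold, so clearing
    # outside the ROI never clips a supra-threshold footprint
    coords, regions = _place_nuclei(
        labels, n_upper, n_lower, min_dist, rng,
        margin=1.5 * rp.nucleus_radius,
    )

    n = coords.shape[0]
    gfp = rng.random(n) < truth.p_gfp
    q = truth.fos_given_not_gfp
    u = rng.random(n)
    fos = np.where(gfp, u < truth.rho, u < q)

    zc = rng.uniform(0.0, max(rp.n_z - 1, 0) + 1e-9, size=n) if rp.n_z > 1 \
        else np.zeros(n)
    truth_table = pd.DataFrame({
        "cell": np.arange(n),
        "y": coords[:, 0], "x": coords[:, 1], "z": zc,
        "region": regions, "gfp": gfp, "fos": fos,
    })

    z_sigma_planes = rp.z_sigma_um / rp.z_step
    channels: dict[str, np.ndarray] = {}
    member = {"hoechst": np.ones(n, dtype=bool), "gfp": gfp, "fos": fos}
    for ch, sel in member.items():
        stack = np.zeros((rp.n_z,) + tuple(rp.image_shape), dtype=np.float64)
        peak = float(rp.peak_intensity[ch])
        _render_blobs(stack, coords[sel], zc[sel], peak,
                      rp.nucleus_radius, z_sigma_planes)
        stack += rp.background_level
        if rp.noise_sd > 0:
            stack += rng.normal(0.0, rp.noise_sd, size=stack.shape)
        np.maximum(stack, 0.0, out=stack)
        channels[ch] = stack.astype(np.float32)
    return ImageBundle(channels=channels, region_labels=labels), truth_table


def _render_blobs(
    stack: np.ndarray,
    coords: np.ndarray,
    zc: np.ndarray,
    peak: float,
    sigma: float,
    z_sigma_planes: float,
) -> None:
    """Add truncated-Gaussian blobs in place (3 sd patch per nucleus)."""
    n_z, h, w = stack.shape
    r = int(np.ceil(3.0 * sigma))
    for (y, x), z in zip(coords, zc):
        y0, y1 = max(0, int(y) - r), min(h, int(y) + r + 1)
        x0, x1 = max(0, int(x) - r), min(w, int(x) + r + 1)
        yy = np.arange(y0, y1)[:, None] - y
        xx = np.arange(x0, x1)[None, :] - x
        rr2 = yy**2 + xx**2
        patch = np.exp(-rr2 / (2.0 * sigma**2))
        patch[rr2 > (3.0 * sigma) ** 2] = 0.0
        for k in range(n_z):
            wz = (np.exp(-((k - z) ** 2) / (2.0 * z_sigma_planes**2))
                  if n_z > 1 else 1.0)
            if wz < 1e-3:
                continue
            stack[k, y0:y1, x0:x1] += peak * wz * patch


# ---------------------------------------------------------------------------
# calibration fixtures
# ---------------------------------------------------------------------------

def make_area_count_pairs(
    slope: float,
    intercept: float,
    noise_sd: float,
    n: int,
    seed: int,
    area_range: tuple[float, float] = (2e4, 1e5),
) -> pd.DataFrame:
    """ROI-area / cell-count pairs from a noisy line, for calibration tests.

    Counts are ``slope*area + intercept + N(0, noise_sd)``, floored at 0
    and rounded to integers.  Returns a frame with columns ``area, count``.
    """
    if n < 2:
        raise ValueError("need at least 2 pairs to constrain a line")
    rng = np.random.default_rng(seed)
    areas = rng.uniform(*area_range, size=n)
    counts = slope * areas + intercept
    if noise_sd > 0:
        counts = counts + rng.normal(0.0, noise_sd, size=n)
    counts = np.rint(np.maximum(counts, 0.0)).astype(int)
    return pd.DataFrame({"area": areas, "count": counts})


def make_intensity_population(
    n: int,
    r_target: float,
    seed: int,
    mean: tuple[float, float] = (100.0, 100.0),
    sd: tuple[float, float] = (25.0, 25.0),
) -> pd.DataFrame:
    """Paired per-cell intensities with population correlation ``r_target``.

    Bivariate Gaussian draws; returns columns ``cell, a, b``.
    """
    if not (-1.0 <= r_target <= 1.0):
        raise ValueError(f"r_target={r_target} outside [-1, 1]")
    if n < 3:
        raise ValueError("need at least 3 cells")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(n)
    z2 = rng.standard_normal(n)
    a = mean[0] + sd[0] * z1
    b = mean[1] + sd[1] * (r_target * z1 + np.sqrt(1.0 - r_target**2) * z2)
    return pd.DataFrame({"cell": np.arange(n), "a": a, "b": b})
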