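"""End-to-end pipeline: simulate or quantify, aggregate, test, report.

Two entry points produce the same result bundle:

* :func:`simulate_experiment` — count-level simulation only (fast; no
  images), for power analyses and calibration of the rate statistics;
* :func:`run_pipeline` — full image path: render (or load) slices, detect
  particles per channel, confirm against Hoechst, colocalize, tabulate,
  then the same rate aggregation and inference layer.

Every stage's intermediate table can be written to the configured output
directory; all randomness descends from the single configured seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import census, imaging, inference, rates, synthetic

logger = logging.getLogger(__name__)


@dataclass
class GroupSpec:
    """One experimental condition: its truth parameters and cohort size."""

    truth: synthetic.EnsembleGroundTruth
    n_animals: int = 6
    batch: str = "b1"


@dataclass
class PipelineConfig:
    """Declarative description of one run.

    ``groups`` maps condition name -> :class:`GroupSpec`; ``control_group``
    names the condition used for batch normalization and as the reference
    arm of between-group tests.
    """

    groups: dict[str, GroupSpec]
    control_group: str = "control"
    n_slices_per_animal: int = 3
    seed: int = 0
    normalize_by_batch: bool = True
    render: synthetic.RenderParams | None = None
    detection: imaging.DetectionParams = field(
        default_factory=imaging.DetectionParams
    )
    hoechst_mode: str = "direct"  # "direct" count or "area_model"
    area_model: census.AreaCountModel | None = None
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.control_group not in self.groups:
            raise ValueError(
                f"control group {self.control_group!r} not among groups "
                f"{sorted(self.groups)}"
            )
        if self.hoechst_mode not in ("direct", "area_model"):
            raise ValueError(f"unknown hoechst_mode {self.hoechst_mode!r}")
        if self.hoechst_mode == "area_model" and self.area_model is None:
            raise ValueError("hoechst_mode='area_model' requires area_model")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        groups = {
            name: GroupSpec(
                truth=synthetic.EnsembleGroundTruth(**g["truth"]),
                n_animals=g.get("n_animals", 6),
                batch=g.get("batch", "b1"),
            )
            for name, g in raw.pop("groups").items()
        }
        render = raw.pop("render", None)
        if render is not None:
            render = synthetic.RenderParams(**render)
        detection = imaging.DetectionParams(**raw.pop("detection", {}))
        return cls(groups=groups, render=render, detection=detection, **raw)


@dataclass
class ResultBundle:
    """Everything one run produces, stage by stage."""

    counts: pd.DataFrame  # per slice x region
    slice_rates: pd.DataFrame
    animal_rates: pd.DataFrame  # per animal x region (optionally normalized)
    tests: list[dict]
    config_seed: int

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(out / "counts.csv", index=False)
        self.slice_rates.to_csv(out / "slice_rates.csv", index=False)
        self.animal_rates.to_csv(out / "animal_rates.csv", index=False)
        report = {"seed": self.config_seed, "tests": self.tests}
        (out / "report.json").write_text(json.dumps(report, indent=2))


def _test_record(name: str, region: str, res: inference.TestResult) -> dict:
    rec = {"comparison": name, "region": region, **asdict(res)}
    rec["n"] = list(res.n)
    return rec


def _analyze_counts(counts: pd.DataFrame, config: PipelineConfig) -> ResultBundle:
    """Shared downstream: rates, per-animal means, normalization, tests."""
    slice_rates = rates.rates_table(counts)
    animal_rates = rates.aggregate_animal(slice_rates)
    if config.normalize_by_batch:
        animal_rates = rates.normalize_to_control(
            animal_rates, control_group=config.control_group
        )

    tests: list[dict] = []
    names = sorted(config.groups)
    treated = [g for g in names if g != config.control_group]
    for region in ("total", "upper", "lower"):
        sub = animal_rates[animal_rates["region"] == region]
        # within-group: observed vs chance overlap, paired per animal
        for g in names:
            gsub = sub[sub["group"] == g]
            if len(gsub) >= 3:
                res = inference.compare(
                    gsub["observed_overlap"], gsub["chance_overlap"], "paired"
                )
                tests.append(_test_record(f"{g}: observed vs chance", region, res))
        # between groups, control vs each treated arm
        for g in treated:
            a = sub[sub["group"] == config.control_group]
            b = sub[sub["group"] == g]
            if len(a) < 3 or len(b) < 3:
                continue
            for col, label in (
                ("obs_over_chance", "observed/chance"),
                ("reactivation_rate", "reactivation rate"),
                ("observed_overlap", "% GFP+Fos+"),
                ("similarity_index", "similarity index"),
            ):
                x = a[col].dropna()
                y = b[col].dropna()
                if len(x) < 3 or len(y) < 3:
                    continue
                res = inference.compare(x, y, "independent")
                tests.append(_test_record(
                    f"{config.control_group} vs {g}: {label}", region, res
                ))
    bundle = ResultBundle(
        counts=counts, slice_rates=slice_rates, animal_rates=animal_rates,
        tests=tests, config_seed=config.seed,
    )
    if config.outdir:
        bundle.write(config.outdir)
    return bundle


def simulate_experiment(config: PipelineConfig) -> ResultBundle:
    """Count-level simulation of the whole experiment (no images)."""
    root = np.random.SeedSequence(config.seed)
    group_seqs = root.spawn(len(config.groups))
    frames = []
    for (name, spec), seq in zip(sorted(config.groups.items()), group_seqs):
        frames.append(synthetic.make_count_table(
            spec.truth, spec.n_animals, config.n_slices_per_animal,
            seed=seq.generate_state(1)[0] % (2**31),
            group=name, batch=spec.batch,
        ))
    counts = pd.concat(frames, ignore_index=True)
    return _analyze_counts(counts, config)


def quantify_slice(
    bundle: synthetic.ImageBundle,
    params: imaging.DetectionParams,
    hoechst_mode: str = "direct",
    area_model: census.AreaCountModel | None = None,
) -> dict[str, census.SliceCounts]:
    """Image stage for one slice: detect, confirm, colocalize, tabulate."""
    projections = {
        ch: imaging.clear_outside_roi(
            imaging.project_stack(stack, params.background_radius),
            bundle.mask("total"),
        )
        for ch, stack in bundle.channels.items()
    }
    dets = {
        ch: imaging.detect_particles(
            projections[ch], params, channel=ch,
            stack=bundle.channels[ch] if params.require_plane_support else None,
        )
        for ch in projections
    }
    gfp = imaging.confirm_nuclei(dets["gfp"], dets["hoechst"], params)
    fos = imaging.confirm_nuclei(dets["fos"], dets["hoechst"], params)
    pairs = imaging.colocalize(gfp, fos, params)

    if hoechst_mode == "direct":
        labels = bundle.region_labels
        nearest = None
        hoechst_counts = {"upper": 0, "lower": 0}
        for d in dets["hoechst"]:
            region = census._assign_region(d, labels, nearest)
            hoechst_counts[region] += 1
        hoechst_estimate: int | dict[str, int] = hoechst_counts
    else:
        if area_model is None:
            raise ValueError("area_model required for hoechst_mode='area_model'")
        total_area = float(bundle.mask("total").sum())
        total = census.estimate_total_cells(
            total_area, area_model, floor_count=len(dets["hoechst"])
        )
        hoechst_estimate = total
    return census.tabulate_slice(
        gfp, fos, pairs, hoechst_estimate, bundle.region_labels
    )


def run_pipeline(config: PipelineConfig) -> ResultBundle:
    """Full image-path run: render each slice, quantify, then analyze.

    Stage failures are re-raised annotated with the slice/animal identity.
    """
    if config.render is None:
        raise ValueError("run_pipeline requires render parameters "
                         "(use simulate_experiment for count-level runs)")
    root = np.random.SeedSequence(config.seed)
    rows = []
    for name, spec in sorted(config.groups.items()):
        for a_idx in range(1, spec.n_animals + 1):
            animal = f"{name}_a{a_idx}"
            for s_idx in range(1, config.n_slices_per_animal + 1):
                child = root.spawn(1)[0]
                rp = replace(
                    config.render,
                    seed=int(child.generate_state(1)[0] % (2**31)),
                )
                try:
                    img, _truth = synthetic.render_slice(spec.truth, rp)
                    per_region = quantify_slice(
                        img, config.detection,
                        hoechst_mode=config.hoechst_mode,
                        area_model=config.area_model,
                    )
                except Exception as exc:
                    raise RuntimeError(
                        f"stage failure at {name}/{animal}/s{s_idx}: {exc}"
                    ) from exc
                rows.append(census.counts_frame(
                    per_region, group=name, batch=spec.batch,
                    animal=animal, slice_id=f"s{s_idx}",
                ))
    counts = pd.concat(rows, ignore_index=True)[synthetic.COUNT_COLUMNS]
    return _analyze_counts(counts, config)
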