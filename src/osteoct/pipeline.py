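"""Study orchestration: batch quantification and end-to-end reports.

``run_quantify`` applies the fixed-protocol quantification (uniform
threshold → VOI → trabecular morphometry → plate metrics) to a batch of
volumes; ``run_study`` assembles or simulates a cohort and produces the
summary tables and ANOVA report.  Everything is driven by a ``RunConfig``
that round-trips through YAML, so a study is reproducible from its config
and seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import reference_tables
from .io_volumes import read_roi_stack, read_volume, write_report
from .morphometry3d import compute_morphometry
from .phantoms import simulate_cohort
from .plate import (DEFAULT_GAP_BRIDGE_UM, PlateRegion,
                    compute_plate_metrics)
from .segmentation import ThresholdChoice, apply_threshold, despeckle, \
    suggest_threshold
from .stats_longitudinal import ALPHA, LongitudinalDataset, build_tables, \
    rm_anova
from .voi import rasterize_voi

log = logging.getLogger("osteoct")


@dataclass
class RunConfig:
    """Study-wide configuration with the protocol's fixed parameters."""

    spacing_um: float = 8.7
    threshold: int | None = None  # None -> suggest on first volume
    despeckle_min_size: int = 0
    voi_start: int = 0
    voi_n_slices: int = 52
    plate_width_mm: float = 1.5
    plate_length_mm: float = 2.5
    gap_bridge_um: float = DEFAULT_GAP_BRIDGE_UM
    alpha: float = ALPHA
    holm_family: str = "per-parameter-compartment"
    gate_on_anova: bool = True
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.voi_n_slices < 1:
            raise ValueError("voi_n_slices must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not self.spacing_um > 0:
            raise ValueError("spacing_um must be > 0")

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(dataclasses.asdict(self),
                                       sort_keys=True))
        return path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


@dataclass
class VolumeJob:
    """One volume to quantify: image stack + ROI file + identity labels."""

    volume_path: str
    roi_path: str
    animal: object = ""
    limb: str = ""
    week: object = ""


@dataclass
class BatchResult:
    records: pd.DataFrame
    failures: list[tuple[VolumeJob, str]] = field(default_factory=list)


def _quantify_one(job: VolumeJob, config: RunConfig,
                  threshold: ThresholdChoice) -> list[dict]:
    gray = read_volume(job.volume_path, config.spacing_um)
    mask = apply_threshold(gray, threshold)
    if config.despeckle_min_size:
        mask = despeckle(mask, config.despeckle_min_size)
    rois = read_roi_stack(job.roi_path)
    vois = rasterize_voi(rois, gray.shape, gray.spacing)
    morpho = compute_morphometry(mask, vois)
    regions = {}
    for comp in ("medial", "lateral"):
        sub = vois[comp].voxels.any(axis=0)
        ys, xs = sub.nonzero()
        if ys.size == 0:
            raise ValueError(f"empty {comp} VOI")
        regions[comp] = PlateRegion(int(ys.min()), int(ys.max()) + 1,
                                    int(xs.min()), int(xs.max()) + 1)
    plates = compute_plate_metrics(mask, regions, config.gap_bridge_um)
    rows = []
    for comp in ("medial", "lateral", "total"):
        m = morpho[comp]
        rows.append({
            "animal": job.animal, "limb": job.limb, "week": job.week,
            "compartment": comp,
            "bv_mm3": m.bv, "tv_mm3": m.tv, "bvtv_pct": m.bvtv,
            "tbth_um": m.tbth, "tbsp_um": m.tbsp, "tbn_per_mm": m.tbn,
            "plth_um": plates[comp].pl_th,
            "plpor_pct": plates[comp].pl_por,
            "threshold": threshold.value,
        })
    return rows


def run_quantify(config: RunConfig, jobs: list[VolumeJob]) -> BatchResult:
    """Quantify a batch of volumes under one uniform threshold.

    The threshold is taken from the config or, if unset, suggested once on
    the first readable volume (the calibration volume) and reused for the
    whole batch.  Per-volume failures are collected, not fatal.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.threshold is not None:
        threshold = ThresholdChoice(config.threshold)
    else:
        threshold = suggest_threshold(
            read_volume(jobs[0].volume_path, config.spacing_um))
        log.info("calibrated threshold %d on %s", threshold.value,
                 jobs[0].volume_path)
    all_rows: list[dict] = []
    failures: list[tuple[VolumeJob, str]] = []
    for job in jobs:
        try:
            rows = _quantify_one(job, config, threshold)
        except Exception as exc:  # per-volume isolation
            log.warning("volume %s failed: %s", job.volume_path, exc)
            failures.append((job, str(exc)))
            continue
        all_rows.extend(rows)
        stem = Path(job.volume_path).stem
        (out_dir / f"{stem}.morphometry.json").write_text(
            json.dumps(rows, indent=1))
        log.info("quantified %s: threshold=%d voi=[%d,+%d) spacing=%.3f",
                 job.volume_path, threshold.value, config.voi_start,
                 config.voi_n_slices, config.spacing_um)
    if not all_rows:
        raise ValueError("every volume in the batch failed")
    df = pd.DataFrame(all_rows)
    write_report(df, out_dir / "morphometry.csv")
    return BatchResult(df, failures)


def run_study(config: RunConfig,
              cohort: pd.DataFrame | None = None) -> dict:
    """Run the longitudinal analysis end to end and write the report bundle.

    ``cohort`` is a long-format record table (animal, limb, week,
    compartment, parameter, value); when omitted, a cohort is simulated
    from the built-in reference design under ``config.seed``.  Outputs: the
    summary table (CSV), the ANOVA summary (JSON), and the cohort itself.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if cohort is None:
        design = reference_tables.reference_cohort_design(
            compartments=("medial", "lateral", "total"), seed=config.seed)
        cohort = simulate_cohort(design)
    dataset = LongitudinalDataset(cohort)
    if dataset.n_animals < 2:
        raise ValueError(
            "inference refused: the cohort has fewer than 2 animals"
        )
    anovas = []
    for param in dataset.parameters:
        sub = dataset.records[dataset.records["parameter"] == param]
        for comp in sorted(sub["compartment"].unique()):
            a = rm_anova(dataset, param, comp)
            anovas.append(dataclasses.asdict(a))
    table = build_tables(dataset, alpha=config.alpha,
                         gate=config.gate_on_anova)
    cohort.to_csv(out_dir / "cohort.csv", index=False)
    table.to_csv(out_dir / "summary_table.csv", index=False)
    (out_dir / "anova.json").write_text(json.dumps(anovas, indent=1))
    return {"table": table, "anova": anovas, "cohort": cohort}
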