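"""End-to-end runs: simulate (or load) -> screen -> select -> evaluate -> report.

A :class:`PipelineConfig` (JSON or YAML) fully determines a run; everything
random flows from its single seed, and rerunning the same config produces a
byte-identical ``summary.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .volumes import write_volume
from .simulate import CohortSpec, generate_cohort, load_cohort, write_cohort, read_volume
from .screening import ScreeningConfig
from .rfe import RFEConfig
from .report import regions_to_frame
from .model import CoarseToFineVBM

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("vbmlearn")


@dataclass
class PipelineConfig:
    """Everything an end-to-end run needs.

    Exactly one of ``cohort`` (a synthetic CohortSpec) or ``phenotype``
    (path to a subject table with real volumes) must be set.
    """

    cohort: CohortSpec | None = None
    phenotype: str | None = None
    mask: str | None = None
    atlas: str | None = None
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    rfe: RFEConfig = field(default_factory=RFEConfig)
    mode: str = "nested"
    seed: int = 0
    out_dir: str = "vbmlearn_run"
    write_volumes: bool = False

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.phenotype is None):
            raise ValueError("set exactly one of cohort (synthetic) or phenotype (files)")
        if self.mode not in ("nested", "pooled"):
            raise ValueError(f"mode must be 'nested' or 'pooled', got {self.mode!r}")
        if self.cohort is not None and not isinstance(self.cohort, CohortSpec):
            self.cohort = CohortSpec(**self.cohort)
        if not isinstance(self.screening, ScreeningConfig):
            self.screening = ScreeningConfig(**self.screening)
        if not isinstance(self.rfe, RFEConfig):
            self.rfe = RFEConfig(**self.rfe)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))

    def hash(self) -> str:
        """Digest of the scientific content (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        d.pop("write_volumes", None)
        canonical = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages, write artifacts under ``config.out_dir``, return summary.

    Artifacts: t_map / p_map / surviving / retained_mask NIfTIs, cluster and
    region TSVs, ranking TSV, per-fold TSV, ROC TSV, and ``summary.json``
    with metrics, counts and a provenance block (config hash, seed, version).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _stage(name):
    log.info("stage: %s", name)


def _run(config: PipelineConfig, out: Path) -> dict:
    truth = None
    if config.cohort is not None:
        _stage("simulate")
        spec = dataclasses.replace(config.cohort, seed=config.seed)
        volumes, labels, truth = generate_cohort(spec)
        if config.write_volumes:
            write_cohort(volumes, labels, out / "cohort", truth=truth, spec=spec)
        from .volumes import to_matrix

        mask = read_volume(config.mask) if config.mask else "all"
        cohort = to_matrix(volumes, labels, mask)
    else:
        _stage("load")
        cohort = load_cohort(config.phenotype, mask=config.mask)

    model = CoarseToFineVBM(cohort, screening=config.screening, rfe=config.rfe)

    _stage("screen+select")
    res = model.fit()
    write_volume(res.screening.t_map, out / "t_map.nii.gz")
    write_volume(res.screening.p_map, out / "p_map.nii.gz")
    write_volume(res.screening.surviving, out / "surviving.nii.gz")
    write_volume(res.retained_mask(), out / "retained_mask.nii.gz")
    write_volume(res.weight_volume(), out / "svm_weights.nii.gz")
    _write_ranking(res, out / "ranking.tsv")

    _stage("evaluate")
    evaluation = model.evaluate(mode=config.mode)
    evaluation.to_frame().to_csv(out / "folds.tsv", sep="\t", index=False)
    pd.DataFrame(evaluation.roc_points, columns=["fpr", "tpr"]).to_csv(
        out / "roc.tsv", sep="\t", index=False
    )

    _stage("report")
    atlas = read_volume(config.atlas) if config.atlas else None
    records = res.regions(atlas=atlas)
    regions_to_frame(records).to_csv(out / "regions.tsv", sep="\t", index=False)

    summary = {
        "provenance": {
            "config_hash": config.hash(),
            "seed": config.seed,
            "version": __version__,
            "mode": config.mode,
        },
        "n_subjects": cohort.n_subjects,
        "n_voxels": cohort.n_voxels,
        "n_surviving": res.n_screened,
        "n_retained": res.n_retained,
        "n_regions": len(records),
        "metrics": evaluation.metrics.as_dict(),
    }
    if truth is not None:
        blob_cols = truth.effect_columns(cohort)
        surv = set(res.screening.selected_columns.tolist())
        summary["ground_truth"] = {
            "n_effect_voxels": int(blob_cols.size),
            "screening_recall": (
                float(np.mean([c in surv for c in blob_cols])) if blob_cols.size else None
            ),
        }
    (out / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=2) + "\n"
    )
    (out / "summary.txt").write_text(res.summary(evaluation) + "\n")
    log.info("done: %s", out / "summary.json")
    return summary


def _write_ranking(res, path) -> None:
    reduced = res.reduced
    world = reduced.column_world_coords()
    frame = pd.DataFrame(
        {
            "voxel_i": reduced.mask_indices[:, 0],
            "voxel_j": reduced.mask_indices[:, 1],
            "voxel_k": reduced.mask_indices[:, 2],
            "world_x_mm": world[:, 0],
            "world_y_mm": world[:, 1],
            "world_z_mm": world[:, 2],
            "rank": res.ranking.rank[res.ranking.retained],
            "weight": res.svm.weights,
        }
    )
    frame.sort_values("rank").to_csv(path, sep="\t", index=False)
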