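"""End-to-end orchestration: volume -> tree -> morphometry, and cohort ->
statistics, with a serializable run configuration and provenance stamping.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .centerline import (DEFAULT_PRUNE_MM, DEFAULT_SMOOTHING_MM, DEFAULT_STEP_MM,
                         identify_vessel_tree, skeletonize)
from .morphometry import (DEFAULT_DOMINANCE_MM, DEFAULT_EVEN_MM, basilar_bending,
                          tree_morphometry, vertebral_dominance)
from .segmentation import (DEFAULT_LOWER, DEFAULT_UPPER, largest_components,
                           threshold_segment)
from .stats import DEFAULT_ALPHA, analysis_battery
from .synthetic import EffectConfig, generate_cohort
from .volume import IntensityVolume
from .wmh import score_cohort

__all__ = ["RunConfig", "StageError", "run_subject", "run_cohort"]

log = logging.getLogger("vbmorph")


@dataclass
class RunConfig:
    """Every tunable of the measurement and analysis pipeline."""

    lower_threshold: float = DEFAULT_LOWER
    upper_threshold: float = DEFAULT_UPPER
    smooth_lambda: float = 0.5
    smooth_mu: float = -0.53
    smooth_iters: int = 10
    prune_mm: float = DEFAULT_PRUNE_MM
    resample_step_mm: float = DEFAULT_STEP_MM
    resample_smoothing_mm: float = DEFAULT_SMOOTHING_MM
    dominance_threshold_mm: float = DEFAULT_DOMINANCE_MM
    even_threshold_mm: float = DEFAULT_EVEN_MM
    flip_lr: bool = False
    alpha: float = DEFAULT_ALPHA
    seed: int = 0
    cohort_n: int = 290

    def validate(self) -> None:
        if self.lower_threshold >= self.upper_threshold:
            raise ValueError("lower threshold must be below upper threshold")
        if not 0 < self.smooth_lambda < 1:
            raise ValueError("smooth_lambda must be in (0, 1)")
        if self.smooth_iters < 0 or self.prune_mm < 0:
            raise ValueError("smooth_iters and prune_mm must be >= 0")
        for name in ("resample_step_mm", "dominance_threshold_mm",
                     "even_threshold_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.cohort_n < 1:
            raise ValueError("cohort_n must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg

    def save(self, path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2) if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict()))
        path.write_text(text)

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        d = (json.loads(path.read_text()) if path.suffix == ".json"
             else yaml.safe_load(path.read_text()))
        return cls.from_dict(d)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


class StageError(RuntimeError):
    """Pipeline failure annotated with the failing stage and subject."""

    def __init__(self, stage: str, subject: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for subject {subject!r}: {cause}")
        self.stage = stage
        self.subject = subject
        self.cause = cause


def run_subject(volume, config: RunConfig | None = None,
                subject_id: str = "subject") -> dict:
    """Measure one subject: segmentation -> component selection -> skeleton
    -> labeled tree -> per-branch morphometry + dominance + bending.

    ``volume`` may be an IntensityVolume or a path to a NIfTI file. Returns
    a flat record (one CSV row) stamped with the config hash; identical
    inputs and config produce identical rows.
    """
    cfg = config or RunConfig()
    cfg.validate()
    stage = "load"
    try:
        if not isinstance(volume, IntensityVolume):
            volume = IntensityVolume.load(volume)
        stage = "threshold_segment"
        t0 = time.perf_counter()
        mask = threshold_segment(volume, cfg.lower_threshold, cfg.upper_threshold)
        stage = "largest_components"
        mask = largest_components(mask, k=1)
        stage = "skeletonize"
        skel = skeletonize(mask, prune_mm=cfg.prune_mm)
        stage = "identify_vessel_tree"
        tree = identify_vessel_tree(skel, step=cfg.resample_step_mm,
                                    smoothing_mm=cfg.resample_smoothing_mm,
                                    flip_lr=cfg.flip_lr)
        stage = "morphometry"
        metrics = tree_morphometry(tree, mask)
        bend = basilar_bending(tree, cfg.even_threshold_mm)
        dom = vertebral_dominance(metrics["va_left"], metrics["va_right"],
                                  cfg.dominance_threshold_mm)
        log.info("subject %s measured in %.2f s", subject_id,
                 time.perf_counter() - t0)
    except Exception as e:  # noqa: BLE001 - re-raise annotated
        raise StageError(stage, subject_id, e) from e

    row = {"subject_id": subject_id, "config_hash": cfg.config_hash}
    for lbl, m in metrics.items():
        row.update({
            f"{lbl}_length_mm": m.length_mm,
            f"{lbl}_mean_curvature": m.mean_curvature,
            f"{lbl}_median_curvature": m.median_curvature,
            f"{lbl}_mean_torsion": m.mean_torsion,
            f"{lbl}_tortuosity": m.tortuosity,
            f"{lbl}_volume_mm3": m.volume_mm3,
            f"{lbl}_mean_area_mm2": m.mean_cross_section_mm2,
            f"{lbl}_mean_diameter_mm": m.mean_diameter_mm,
        })
    row.update({
        "dominance": dom.side,
        "va_diameter_diff_mm": dom.diameter_difference_mm,
        "curve_direction": bend.direction,
        "ba_deviation_extent_mm": bend.deviation_extent_mm,
        "ba_deviation_signed_mm": bend.signed_lateral_mm,
        "ba_chord_mm": bend.chord_mm,
    })
    return row


def run_cohort(config: RunConfig | None = None,
               effect_config: EffectConfig | None = None,
               cohort_csv=None, lesions_csv=None,
               out_dir=None) -> dict:
    """Cohort-level analysis: load (or synthesize) the cohort, derive WMH
    scores and lateralities, and run the statistical battery.

    Returns a bundle with the scored cohort, lesion table, battery report
    and a provenance block; writes CSV/JSON to ``out_dir`` when given.
    """
    cfg = config or RunConfig()
    cfg.validate()
    if cohort_csv is not None:
        subjects = pd.read_csv(cohort_csv)
        lesions = (pd.read_csv(lesions_csv) if lesions_csv is not None
                   else pd.DataFrame(columns=["subject_id", "region", "side",
                                              "diameter_mm", "confluent", "diffuse"]))
        _check_schema(subjects, lesions)
    else:
        ecfg = effect_config or EffectConfig(n=cfg.cohort_n,
                                             even_threshold_mm=cfg.even_threshold_mm)
        subjects, lesions = generate_cohort(ecfg, seed=cfg.seed)
    scored = score_cohort(subjects, lesions)
    report = analysis_battery(scored, lesions, alpha=cfg.alpha)
    provenance = {"config_hash": cfg.config_hash, "seed": cfg.seed,
                  "n": int(len(scored)), "vbmorph_version": __version__,
                  "config": cfg.to_dict()}
    bundle = {"cohort": scored, "lesions": lesions, "report": report,
              "provenance": provenance}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scored.to_csv(out / "cohort_scored.csv", index=False)
        lesions.to_csv(out / "lesions.csv", index=False)
        report.to_csv(out / "battery_report.csv", index=False)
        (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return bundle


_SUBJECT_REQUIRED = ["subject_id", "age", "group_or_lesions"]


def _check_schema(subjects: pd.DataFrame, lesions: pd.DataFrame) -> None:
    need_subj = {"subject_id", "age", "dominance", "curve_direction",
                 "ba_deviation_signed_mm"}
    need_les = {"subject_id", "region", "side", "diameter_mm", "confluent", "diffuse"}
    missing = [f"subjects.{c}" for c in sorted(need_subj - set(subjects.columns))]
    missing += [f"lesions.{c}" for c in sorted(need_les - set(lesions.columns))]
    if missing:
        raise ValueError("schema mismatch, missing columns: " + ", ".join(missing))
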