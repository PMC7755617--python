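"""End-to-end subject pipeline and cohort normative-model building.

Configuration lives in one validated :class:`PipelineConfig` (YAML-backed)
so the protocol parameters — echo times 30/119 ms, the 1.96 SD band
multiplier, fit clamp range, profile bin count — are inspectable defaults
rather than magic numbers. Each stage logs its name, wall time, and input
hashes to make clinical-audit-style provenance possible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import os
import time
from dataclasses import dataclass, field

import yaml

from . import imaging_io, morphometry_profiles as mp, qreport, qt2_mapping
from .normative_model import NormativeModel, build_normative, flag_subject
from .qt2_mapping import FitConfig

__all__ = ["PipelineConfig", "PipelineError", "run_subject_pipeline", "run_cohort_build"]

log = logging.getLogger("hippoquant")
if not log.handlers:  # library default: stderr, terse
    _h = logging.StreamHandler()
    _h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(_h)
    log.setLevel(logging.INFO)

CONFIG_SCHEMA = "hippoquant-config/1"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All tunable pipeline parameters with their protocol defaults."""

    schema: str = CONFIG_SCHEMA
    te1_ms: float = 30.0
    te2_ms: float = 119.0
    t2_clamp_ms: tuple[float, float] = (1.0, 2000.0)
    noise_floor: float = 1e-6
    n_bins: int = 20
    summary_statistic: str = "mean"  # or "median"
    normative_min_n: int = 20
    band_multiplier: float = 1.96  # fixed: the report's bands are mean +/- 1.96 SD
    seed: int = 0

    def validate(self) -> None:
        if self.schema != CONFIG_SCHEMA:
            raise ValueError(f"unknown config schema {self.schema!r}")
        if not 0 < self.te1_ms < self.te2_ms:
            raise ValueError("need 0 < te1_ms < te2_ms")
        if self.t2_clamp_ms[0] <= 0 or self.t2_clamp_ms[1] <= self.t2_clamp_ms[0]:
            raise ValueError("t2_clamp_ms must be an increasing positive interval")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.summary_statistic not in ("mean", "median"):
            raise ValueError("summary_statistic must be 'mean' or 'median'")
        if self.band_multiplier != 1.96:
            raise ValueError("band multiplier is fixed at 1.96 (mean +/- 1.96 SD bands)")

    @property
    def fit_config(self) -> FitConfig:
        return FitConfig(eps=self.noise_floor, t2_min=self.t2_clamp_ms[0],
                         t2_max=self.t2_clamp_ms[1])

    def to_yaml(self, path: str | None = None) -> str:
        doc = dataclasses.asdict(self)
        doc["t2_clamp_ms"] = list(self.t2_clamp_ms)
        text = yaml.safe_dump(doc, sort_keys=True)
        if path:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if "t2_clamp_ms" in doc:
            doc["t2_clamp_ms"] = tuple(doc["t2_clamp_ms"])
        cfg = cls(**doc)
        cfg.validate()
        return cfg


def _sha1(path: str) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


class _Stage:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        log.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        dt = time.perf_counter() - self.t0
        if exc is None:
            log.info("stage %s: done in %.2fs", self.name, dt)
            return False
        log.error("stage %s: failed after %.2fs: %s", self.name, dt, exc)
        raise PipelineError(f"stage {self.name!r} failed: {exc}") from exc


def run_subject_pipeline(
    config: PipelineConfig,
    echo1_path: str,
    echo2_path: str,
    left_mask_path: str,
    right_mask_path: str,
    model: NormativeModel,
    meta: dict,
    t1_path: str | None = None,
) -> qreport.QReportDoc:
    """qT2 -> global metrics -> profiles -> flags -> report, with stage logs.

    Deterministic and idempotent for fixed inputs; any stage error aborts
    cleanly with the stage name.
    """
    config.validate()
    for p in (echo1_path, echo2_path, left_mask_path, right_mask_path):
        if not os.path.exists(p):
            raise PipelineError(f"stage 'load' failed: missing input file {p}")
    log.info("inputs: %s", {os.path.basename(p): _sha1(p)
                            for p in (echo1_path, echo2_path, left_mask_path, right_mask_path)})

    with _Stage("load"):
        echo1 = imaging_io.read_volume(echo1_path)
        echo2 = imaging_io.read_volume(echo2_path)
        echo1.meta["te_ms"] = config.te1_ms
        echo2.meta["te_ms"] = config.te2_ms
        left = imaging_io.read_mask(left_mask_path, "left")
        right = imaging_io.read_mask(right_mask_path, "right")
        for v in (echo2, left, right):
            imaging_io.assert_same_grid(echo1, v)

    with _Stage("qt2"):
        roi = (left.data | right.data).astype(bool)
        t2map = qt2_mapping.compute_t2_map(echo1, echo2, roi=roi, config=config.fit_config)
        qc = qt2_mapping.qc_fit(t2map, roi)

    with _Stage("metrics"):
        metrics = mp.compute_global_metrics(left, right, t2map, config.summary_statistic)

    with _Stage("profiles"):
        profiles = {}
        for mask in (left, right):
            frame = mp.long_axis_frame(mask)
            profiles[mask.side] = mp.profile(mask, t2map, frame, config.n_bins,
                                             config.summary_statistic)

    with _Stage("flags"):
        flags = flag_subject(metrics, profiles, model)

    with _Stage("report"):
        snapshots = []
        if t1_path is not None:
            t1 = imaging_io.read_volume(t1_path)
            snapshots = sorted(qreport.render_snapshots(t1, left, right))
        doc = qreport.assemble_report(meta, metrics, profiles, model, qc, flags,
                                      snapshots=snapshots)
    return doc


def run_cohort_build(config: PipelineConfig, manifest_path: str) -> NormativeModel:
    """Per-subject metrics/profiles over a cohort manifest, then the model.

    The manifest CSV needs columns echo1, echo2, mask_left, mask_right
    (paths relative to the manifest's directory). All unreadable subjects
    are listed in one error; cohorts below ``normative_min_n`` are refused.
    The model is invariant to manifest row order.
    """
    import pandas as pd

    config.validate()
    base = os.path.dirname(os.path.abspath(manifest_path))
    manifest = pd.read_csv(manifest_path)
    required = {"echo1", "echo2", "mask_left", "mask_right"}
    if not required <= set(manifest.columns):
        raise PipelineError(f"manifest lacks columns {sorted(required - set(manifest.columns))}")

    bad = []
    for _, row in manifest.iterrows():
        for col in sorted(required):
            p = os.path.join(base, str(row[col]))
            if not os.path.exists(p):
                bad.append(p)
    if bad:
        raise PipelineError(f"unreadable cohort inputs: {bad}")

    # sort rows so the (permutation-invariant) build also logs stably
    sort_col = "subject_id" if "subject_id" in manifest.columns else "echo1"
    manifest = manifest.sort_values(sort_col).reset_index(drop=True)

    cohort = []
    for i, row in manifest.iterrows():
        with _Stage(f"subject[{i + 1}/{len(manifest)}]"):
            echo1 = imaging_io.read_volume(os.path.join(base, row["echo1"]))
            echo2 = imaging_io.read_volume(os.path.join(base, row["echo2"]))
            echo1.meta["te_ms"] = config.te1_ms
            echo2.meta["te_ms"] = config.te2_ms
            left = imaging_io.read_mask(os.path.join(base, row["mask_left"]), "left")
            right = imaging_io.read_mask(os.path.join(base, row["mask_right"]), "right")
            roi = (left.data | right.data).astype(bool)
            t2map = qt2_mapping.compute_t2_map(echo1, echo2, roi=roi, config=config.fit_config)
            metrics = mp.compute_global_metrics(left, right, t2map, config.summary_statistic)
            profiles = {}
            for mask in (left, right):
                frame = mp.long_axis_frame(mask)
                profiles[mask.side] = mp.profile(mask, t2map, frame, config.n_bins,
                                                 config.summary_statistic)
            cohort.append((metrics, profiles))

    with _Stage("build_normative"):
        model = build_normative(cohort, min_n=config.normative_min_n, seed=config.seed)
    return model
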