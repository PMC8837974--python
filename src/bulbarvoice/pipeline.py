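"""End-to-end driver: preprocess -> features -> selection -> classification.

All stage defaults (decimation factor 5, 150 ms segment, 7-band scheme,
alpha 0.05, 10-fold CV with training-fold upsampling) live in
:class:`RunConfig` and are serialized into the run manifest so every number
in a report is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import warnings
from dataclasses import dataclass, field

import pandas as pd

from . import __version__
from .classify import CVConfig, CVReport, run_cv
from .phonatory import PHONATORY_FEATURE_NAMES, extract_phonatory_features
from .preprocess import VowelRecording, preprocess_recording, read_wav
from .selection import COMPARISONS, SelectionResult, make_comparison, screen_features
from .synthvoice import make_cohort
from .tffeatures import TF_FEATURE_NAMES, BandScheme, extract_tf_features

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "FEATURE_NAMES", "extract_features",
           "extract_feature_table", "run_pipeline", "PipelineResult"]

FEATURE_NAMES = PHONATORY_FEATURE_NAMES + TF_FEATURE_NAMES  # 15 + 35 = 50


@dataclass
class RunConfig:
    decimation_factor: int = 5
    segment_duration: float = 0.150
    pitch_floor: float = 75.0
    pitch_ceiling: float = 600.0
    voicing_threshold: float = 0.45
    sigma: float = 1.0
    use_analytic: bool = True
    time_step: int = 4
    band_edges: tuple = (0.0, 80.0, 250.0, 550.0, 900.0, 1500.0, 3000.0, 4410.0)
    alpha: float = 0.05
    n_folds: int = 10
    threshold: float = 0.5
    upsample: bool = True
    group_by_subject: bool = False
    per_subject_mean: bool = False
    seed: int = 0
    max_error_fraction: float = 0.2

    @property
    def bands(self) -> BandScheme:
        return BandScheme(edges=self.band_edges)

    def cv_config(self) -> CVConfig:
        return CVConfig(n_folds=self.n_folds, threshold=self.threshold,
                        upsample=self.upsample, seed=self.seed,
                        group_by_subject=self.group_by_subject)

    def to_manifest(self) -> dict:
        cfg = dataclasses.asdict(self)
        raw = json.dumps(cfg, sort_keys=True, default=str)
        return {
            "package_version": __version__,
            "config": cfg,
            "config_hash": hashlib.sha256(raw.encode()).hexdigest()[:16],
        }


def extract_features(rec: VowelRecording, config: RunConfig | None = None) -> dict:
    """Preprocess one recording and compute all 50 features."""
    config = config or RunConfig()
    seg = preprocess_recording(
        rec, factor=config.decimation_factor, duration=config.segment_duration
    )
    row = extract_phonatory_features(
        seg, floor=config.pitch_floor, ceiling=config.pitch_ceiling,
        voicing_threshold=config.voicing_threshold,
    )
    row.update(extract_tf_features(
        seg, bands=config.bands, sigma=config.sigma,
        use_analytic=config.use_analytic, time_step=config.time_step,
    ))
    return row


def extract_feature_table(
    recordings: list[VowelRecording], config: RunConfig | None = None
) -> pd.DataFrame:
    """One row per (subject, vowel): 4 id columns + 50 feature columns.

    Per-recording failures are logged and skipped; the run aborts if more
    than ``config.max_error_fraction`` of the recordings fail.
    """
    config = config or RunConfig()
    rows, errors = [], []
    for rec in recordings:
        try:
            row = dict(subject_id=rec.subject_id, sex=rec.sex,
                       vowel=rec.vowel, group=rec.group)
            row.update(extract_features(rec, config))
            rows.append(row)
        except Exception as exc:
            errors.append((rec.subject_id, rec.vowel, repr(exc)))
            log.error("feature extraction failed for %s/%s: %s",
                      rec.subject_id, rec.vowel, exc)
    if recordings and len(errors) / len(recordings) > config.max_error_fraction:
        raise RuntimeError(
            f"{len(errors)}/{len(recordings)} recordings failed feature "
            f"extraction; first errors: {errors[:3]}"
        )
    table = pd.DataFrame(rows)
    return table[["subject_id", "sex", "vowel", "group"] + list(FEATURE_NAMES)]


def load_recordings(metadata_csv: str, root: str | None = None) -> list[VowelRecording]:
    """Load WAV files listed in a metadata CSV (subject_id, sex, group, vowel, path)."""
    meta = pd.read_csv(metadata_csv)
    root = root or os.path.dirname(os.path.abspath(metadata_csv))
    recs = []
    for _, r in meta.iterrows():
        path = r["path"]
        if not os.path.isabs(path):
            path = os.path.join(root, path)
        recs.append(read_wav(path, subject_id=str(r["subject_id"]), sex=r["sex"],
                             group=r["group"], vowel=r["vowel"]))
    return recs


@dataclass
class PipelineResult:
    table: pd.DataFrame
    selections: dict = field(default_factory=dict)   # (comparison, sex) -> SelectionResult
    reports: dict = field(default_factory=dict)      # (comparison, sex) -> CVReport
    manifest: dict = field(default_factory=dict)


def run_pipeline(
    config: RunConfig | None = None,
    *,
    recordings: list[VowelRecording] | None = None,
    metadata_csv: str | None = None,
    synthetic_n_per_group: int | None = None,
    sexes: tuple = ("F",),
    comparisons: tuple = COMPARISONS,
    out_dir: str | None = None,
) -> PipelineResult:
    """Run the full pipeline and (optionally) write all artifacts to ``out_dir``."""
    config = config or RunConfig()
    if recordings is None:
        if synthetic_n_per_group is not None:
            recordings = []
            for sex in sexes:
                recs, _, _ = make_cohort(synthetic_n_per_group, sex=sex,
                                         seed=config.seed)
                recordings.extend(recs)
        elif metadata_csv is not None:
            recordings = load_recordings(metadata_csv)
        else:
            raise ValueError("provide recordings, metadata_csv or synthetic_n_per_group")

    table = extract_feature_table(recordings, config)
    if config.per_subject_mean:
        table = (table.groupby(["subject_id", "sex", "group"], as_index=False)
                 [list(FEATURE_NAMES)].mean())
        table.insert(2, "vowel", "mean")

    result = PipelineResult(table=table, manifest=config.to_manifest())
    for sex in sexes:
        for name in comparisons:
            cmp = make_comparison(name, sex=sex)
            try:
                sel = screen_features(table, cmp, alpha=config.alpha)
            except ValueError as exc:
                log.warning("selection skipped for %s/%s: %s", name, sex, exc)
                continue
            result.selections[(name, sex)] = sel
            if not sel.selected:
                log.warning("no features selected for %s/%s; skipping CV", name, sex)
                continue
            try:
                result.reports[(name, sex)] = run_cv(
                    table, sel.selected, cmp, config.cv_config())
            except ValueError as exc:
                log.warning("CV skipped for %s/%s: %s", name, sex, exc)

    if out_dir is not None:
        write_artifacts(result, out_dir)
    return result


def write_artifacts(result: PipelineResult, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    result.table.to_csv(os.path.join(out_dir, "features.csv"), index=False)
    if result.selections:
        pd.concat([s.to_frame() for s in result.selections.values()]).to_csv(
            os.path.join(out_dir, "selection.csv"), index=False)
        with open(os.path.join(out_dir, "selected_features.json"), "w") as fh:
            json.dump({f"{k[0]}/{k[1]}": v.selected
                       for k, v in result.selections.items()}, fh, indent=2)
    if result.reports:
        pd.concat([r.to_frame() for r in result.reports.values()]).to_csv(
            os.path.join(out_dir, "classification.csv"), index=False)
        detail = {
            f"{k[0]}/{k[1]}": {"metrics": r.metrics, "counts": r.counts,
                               "fold_counts": r.fold_counts}
            for k, r in result.reports.items()
        }
        with open(os.path.join(out_dir, "classification.json"), "w") as fh:
            json.dump(detail, fh, indent=2)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(result.manifest, fh, indent=2)
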