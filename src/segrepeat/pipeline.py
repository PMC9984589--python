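"""End-to-end study orchestration: simulate/ingest → morph → cut → metrics → stats.

A single `StudyConfig` drives the whole repeatability analysis.  For every
subject × muscle the attachment points are morphed from the atlas via the
landmark-fitted affine (optionally snapped to the bone surface), the
iliopsoas is standardized by removing its proximal end above the
iliac-crest plane, every repeated segmentation is decomposed into ten
nested sub-volumes, agreement metrics are computed across repeat pairs, and
each metric is compared across levels with the normality-gated
repeated-measures chain.  Outputs are plain CSV/JSON files; re-running with
the same config and seed reproduces them byte-for-byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from importlib.metadata import PackageNotFoundError, version as pkg_version
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as met
from . import repstats
from .registration import apply_transform, fit_affine, snap_to_surface
from .subvolumes import cut_series, make_axis, standardize_proximal
from .synthetic import NoiseModel, PhantomSpec, PhantomStudy, make_phantom, simulate_repeats
from .volio import LandmarkSet, read_label_volume, read_landmarks, read_stl

log = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyResult", "run_study", "summarize"]

#: phantom geometry per muscle: a simple straight/tapered tube for the
#: gluteus medius, a longer laterally bowed tube for the iliopsoas.
_MUSCLE_GEOMETRY = {
    "gluteus_medius": dict(muscle_kind="tapered_tube", length_mm=100.0,
                           max_radius_mm=20.0, taper=0.4, wrap_offset_mm=0.0),
    "iliopsoas": dict(muscle_kind="wrapped_tube", length_mm=180.0,
                      max_radius_mm=15.0, taper=0.3, wrap_offset_mm=25.0),
}

#: iliopsoas volumes are standardized before cutting; gluteus medius is not.
_STANDARDIZE_DEFAULT = {"gluteus_medius": False, "iliopsoas": True}


@dataclass
class StudyConfig:
    mode: str = "synthetic"                      # "synthetic" | "files"
    muscles: list[str] = dc_field(default_factory=lambda: ["gluteus_medius", "iliopsoas"])
    n_subjects: int = 20
    n_repeats: int = 3
    noise: NoiseModel = dc_field(default_factory=NoiseModel)
    step_fraction: float = 0.05
    n_levels: int = 10
    alpha: float = 0.05
    seed: int = 0
    snap_attachments: bool = False
    max_snap_mm: float = 15.0
    standardize: dict[str, bool] = dc_field(default_factory=dict)
    landmark_jitter_mm: float = 0.0
    output_dir: str | None = None
    subjects: list[dict] = dc_field(default_factory=list)   # files mode
    atlas_landmarks_path: str | None = None                 # files mode
    atlas_attachments_path: str | None = None               # files mode
    attachment_names: dict[str, dict] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.step_fraction * self.n_levels > 0.5 + 1e-12:
            raise ValueError("step_fraction * n_levels must not exceed 0.5 "
                             "(the cutting planes cannot pass the attachments)")
        for m in self.muscles:
            self.standardize.setdefault(m, _STANDARDIZE_DEFAULT.get(m, False))

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "noise" in raw and isinstance(raw["noise"], dict):
            raw["noise"] = NoiseModel(**raw["noise"])
        return cls(**raw)

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


@dataclass
class StudyResult:
    records: pd.DataFrame                       # tidy per-(subject,muscle,level)
    summary: pd.DataFrame                       # per-(muscle,level) mean (min, max)
    reports: dict                               # muscle -> metric -> TestReport
    failed_subjects: dict                       # subject_id -> error message
    output_dir: Path | None = None


# ---------------------------------------------------------------------------
# Subject-level processing


def _subject_records(
    study: PhantomStudy | dict,
    subject_id: str,
    muscle: str,
    config: StudyConfig,
) -> list[met.MetricRecord]:
    """Morph attachments, standardize, cut and score one subject's repeats."""
    if isinstance(study, PhantomStudy):
        repeats = study.repeats
        landmarks = study.landmarks
        atlas_landmarks = study.atlas_landmarks
        atlas_attachments = study.atlas_attachments
        bone = study.bone_surface
        origin_name, insertion_name = "origin", "insertion"
    else:
        repeats = study["repeats"]
        landmarks = study["landmarks"]
        atlas_landmarks = study["atlas_landmarks"]
        atlas_attachments = study["atlas_attachments"]
        bone = study.get("bone_surface")
        names = config.attachment_names.get(muscle, {})
        origin_name = names.get("origin", f"{muscle}_origin")
        insertion_name = names.get("insertion", f"{muscle}_insertion")

    transform = fit_affine(atlas_landmarks, landmarks)
    log.info("subject %s: affine fit RMS residual %.4f mm", subject_id,
             transform.rms_residual_mm)
    morphed = apply_transform(transform, atlas_attachments)
    origin = morphed[origin_name]
    insertion = morphed[insertion_name]
    if config.snap_attachments and bone is not None:
        origin, o_snapped = snap_to_surface(origin, bone, config.max_snap_mm)
        insertion, i_snapped = snap_to_surface(insertion, bone, config.max_snap_mm)
        log.info("subject %s: snapped origin=%s insertion=%s", subject_id,
                 o_snapped, i_snapped)
    axis = make_axis(origin, insertion)

    if config.standardize.get(muscle, False):
        plane_point = 0.5 * (landmarks["iliac_crest_L"] + landmarks["iliac_crest_R"])
        repeats = [standardize_proximal(r, axis, plane_point) for r in repeats]

    series = [cut_series(r, axis, config.step_fraction, config.n_levels) for r in repeats]
    return met.compare_repeats(series, subject_id=subject_id, muscle=muscle)


def _synthetic_subject(config: StudyConfig, muscle: str, index: int) -> PhantomStudy:
    geometry = _MUSCLE_GEOMETRY.get(muscle, _MUSCLE_GEOMETRY["gluteus_medius"])
    m_idx = config.muscles.index(muscle) if muscle in config.muscles else 0
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(m_idx, index))
    sub_seed = int(ss.generate_state(1)[0] % (2**31))
    spec = PhantomSpec(seed=sub_seed, **geometry)
    study = make_phantom(spec, landmark_jitter_mm=config.landmark_jitter_mm)
    noise = NoiseModel(
        belly_sigma_mm=config.noise.belly_sigma_mm,
        extremity_sigma_mm=config.noise.extremity_sigma_mm,
        correlation_length_mm=config.noise.correlation_length_mm,
        end_slice_dropout_prob=config.noise.end_slice_dropout_prob,
        seed=sub_seed,
    )
    study.repeats = simulate_repeats(study.truth, study.true_axis, noise,
                                     config.n_repeats)
    study.noise = noise
    return study


def _files_subject(entry: dict) -> dict:
    out = {
        "repeats": [read_label_volume(p) for p in entry["repeats"]],
        "landmarks": read_landmarks(entry["landmarks"]),
        "atlas_landmarks": read_landmarks(entry["atlas_landmarks"]),
        "atlas_attachments": read_landmarks(entry["atlas_attachments"]),
    }
    if entry.get("bone_surface"):
        out["bone_surface"] = read_stl(entry["bone_surface"])
    return out


# ---------------------------------------------------------------------------
# Study-level driver


def run_study(config: StudyConfig) -> StudyResult:
    """Run the full repeatability analysis described by `config`.

    Subjects failing any stage are excluded with a logged error; the run
    aborts only if fewer than 3 subjects survive for a muscle.  When
    `config.output_dir` is set, metrics.csv, summary_table.csv, per-metric
    post hoc matrices, stats.json and run_manifest.json are written there.
    """
    all_records: list[met.MetricRecord] = []
    failed: dict[str, str] = {}

    if config.mode == "synthetic":
        for muscle in config.muscles:
            for i in range(config.n_subjects):
                sid = f"{muscle}_{i:03d}"
                try:
                    study = _synthetic_subject(config, muscle, i)
                    all_records.extend(_subject_records(study, sid, muscle, config))
                except Exception as exc:  # noqa: BLE001 — per-subject isolation
                    failed[sid] = str(exc)
                    log.error("subject %s failed: %s", sid, exc)
    else:
        for entry in config.subjects:
            sid = str(entry.get("id", f"subject_{len(all_records)}"))
            muscle = entry["muscle"]
            entry = dict(entry)
            entry.setdefault("atlas_landmarks", config.atlas_landmarks_path)
            entry.setdefault("atlas_attachments", config.atlas_attachments_path)
            try:
                data = _files_subject(entry)
                all_records.extend(_subject_records(data, sid, muscle, config))
            except Exception as exc:  # noqa: BLE001
                failed[sid] = str(exc)
                log.error("subject %s failed: %s", sid, exc)

    records_df = _records_frame(all_records)
    reports: dict[str, dict[str, repstats.TestReport]] = {}
    for muscle in config.muscles:
        sub = records_df[(records_df.muscle == muscle) & (~records_df.excluded)]
        n_sub = sub.subject.nunique()
        if n_sub < 3:
            raise RuntimeError(
                f"muscle {muscle}: only {n_sub} subject(s) survived processing; "
                "at least 3 are required for the statistical comparison"
            )
        reports[muscle] = {}
        for metric in ("ji_mean", "hd_mean_mm", "nvv_percent"):
            mat = _metric_matrix(records_df, muscle, metric, config.n_levels)
            reports[muscle][metric] = repstats.analyze_metric(mat, alpha=config.alpha)

    summary = summarize(records_df)
    result = StudyResult(records=records_df, summary=summary, reports=reports,
                         failed_subjects=failed)
    if config.output_dir is not None:
        result.output_dir = _write_outputs(result, config)
    return result


def _records_frame(records: list[met.MetricRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "subject": r.subject_id,
            "muscle": r.muscle,
            "level_percent": r.level_percent,
            "ji_mean": r.ji_mean,
            "hd_mean_mm": r.hd_mean_mm,
            "nvv_percent": r.nvv_percent,
            "n_pairs": len(r.pairwise_ji),
            "volumes_mm3": ";".join(f"{v:.6f}" for v in r.volumes_mm3),
            "excluded": r.excluded,
        })
    df = pd.DataFrame(rows)
    return df.sort_values(["muscle", "subject", "level_percent"]).reset_index(drop=True)


def _metric_matrix(df: pd.DataFrame, muscle: str, metric: str,
                   n_levels: int) -> repstats.MetricMatrix:
    sub = df[df.muscle == muscle]
    pivot = sub.pivot_table(index="subject", columns="level_percent", values=metric,
                            aggfunc="first", dropna=False)
    pivot = pivot.sort_index()
    labels = sorted(sub.level_percent.unique())
    return repstats.MetricMatrix(pivot[labels].to_numpy(), metric_name=f"{muscle}:{metric}",
                                 level_labels=[int(x) for x in labels])


def summarize(records: pd.DataFrame | list[met.MetricRecord]) -> pd.DataFrame:
    """Per (muscle, level) `mean (min, max)` of JI, HD and nVV across subjects."""
    df = records if isinstance(records, pd.DataFrame) else _records_frame(records)
    rows = []
    for (muscle, level), grp in df[~df.excluded].groupby(["muscle", "level_percent"]):
        row = {"muscle": muscle, "level_percent": int(level), "n_subjects": len(grp)}
        for metric, label in (("ji_mean", "JI"), ("hd_mean_mm", "HD_mm"),
                              ("nvv_percent", "nVV_percent")):
            vals = grp[metric].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if len(vals) == 0:
                row[label] = "NA"
                log.warning("muscle %s level %s: no usable %s values", muscle, level, label)
            else:
                row[label] = f"{vals.mean():.3f} ({vals.min():.3f}, {vals.max():.3f})"
        rows.append(row)
    # a level fully excluded for a muscle still gets a (NA) row
    for muscle in df.muscle.unique():
        present = {int(x) for x in df[df.muscle == muscle].level_percent.unique()}
        summarized = {r["level_percent"] for r in rows if r["muscle"] == muscle}
        for level in sorted(present - summarized):
            log.warning("muscle %s level %d: all subjects excluded", muscle, level)
            rows.append({"muscle": muscle, "level_percent": level, "n_subjects": 0,
                         "JI": "NA", "HD_mm": "NA", "nVV_percent": "NA"})
    out = pd.DataFrame(rows).sort_values(["muscle", "level_percent"]).reset_index(drop=True)
    return out


def _write_outputs(result: StudyResult, config: StudyConfig) -> Path:
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.records.to_csv(out_dir / "metrics.csv", index=False, float_format="%.9g")
    result.summary.to_csv(out_dir / "summary_table.csv", index=False)
    stats_obj = {
        muscle: {metric: report.to_dict() for metric, report in by_metric.items()}
        for muscle, by_metric in result.reports.items()
    }
    (out_dir / "stats.json").write_text(json.dumps(stats_obj, indent=2, sort_keys=True))
    for muscle, by_metric in result.reports.items():
        for metric, report in by_metric.items():
            mat = pd.DataFrame(report.posthoc_p, index=report.level_labels,
                               columns=report.level_labels)
            mat.to_csv(out_dir / f"posthoc_{muscle}_{metric}.csv", float_format="%.9g")
    try:
        ver = pkg_version("segrepeat")
    except PackageNotFoundError:
        ver = "unknown"
    manifest = {
        "software": {"name": "segrepeat", "version": ver},
        "config": _jsonable(config.to_dict()),
        "failed_subjects": result.failed_subjects,
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2,
                                                          sort_keys=True))
    return out_dir


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
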