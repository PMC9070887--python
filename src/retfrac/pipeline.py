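"""End-to-end orchestration: image -> per-image metrics -> per-patient
aggregation -> cohort statistics.

Per image, the measurement sequence is: segment the vessels, build the
disc-anchored annuli, then read the metrics off their zones — calibers
(CRAE/CRVE/AVR) from vessels crossing the caliber annulus, the tortuosity
index and monofractal D_f / lacunarity in the mid annulus, and the
multifractal spectrum on the whole segmented image minus the disc.
Metrics from all images of both eyes of a patient are averaged
(unweighted) into one patient record; a corrupt image yields a recorded
failure, never an aborted cohort run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fractal, morphometry, roi, segmentation, stats

logger = logging.getLogger("retfrac")

__all__ = [
    "RunConfig",
    "run_image",
    "run_image_file",
    "aggregate_patient",
    "run_cohort",
    "stats_report",
    "label_segments_by_reference",
    "load_manifest",
]


@dataclass(frozen=True)
class RunConfig:
    """All pipeline knobs, validated up front; hashed into every output."""

    segmentation: segmentation.SegmentationParams = field(
        default_factory=segmentation.SegmentationParams
    )
    fractal: fractal.FractalSettings = field(default_factory=fractal.FractalSettings)
    tortuosity_convention: str = "chord_over_arc"
    um_per_px: float | None = None
    poor_max_score: int = 1  # collateral scores <= this are "poor"
    classifier_features: tuple[str, ...] = stats.DEFAULT_CLASSIFIER_FEATURES
    learner: str = "svm_sigmoid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tortuosity_convention not in ("chord_over_arc", "arc_over_chord"):
            raise ValueError(
                f"unknown tortuosity convention {self.tortuosity_convention!r}"
            )
        if self.um_per_px is not None and self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.poor_max_score not in (0, 1, 2):
            raise ValueError("poor_max_score must be 0, 1 or 2")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix in (".yml", ".yaml"):
            raw = yaml.safe_load(path.read_text()) or {}
        elif path.suffix == ".toml":
            raw = tomllib.loads(path.read_text())
        else:
            raise ValueError(f"config must be YAML or TOML, got {path.suffix}")
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "segmentation" in kwargs:
            seg = dict(kwargs["segmentation"])
            if "line_lengths" in seg:
                seg["line_lengths"] = tuple(seg["line_lengths"])
            kwargs["segmentation"] = segmentation.SegmentationParams(**seg)
        if "fractal" in kwargs:
            fr = dict(kwargs["fractal"])
            if fr.get("box_sizes"):
                fr["box_sizes"] = tuple(fr["box_sizes"])
            kwargs["fractal"] = fractal.FractalSettings(**fr)
        if "classifier_features" in kwargs:
            kwargs["classifier_features"] = tuple(kwargs["classifier_features"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# per-image measurement

def label_segments_by_reference(
    segments: list[morphometry.CenterlineSegment],
    reference: dict[str, np.ndarray],
    max_distance_px: float = 6.0,
) -> None:
    """Assign vessel classes by nearest reference centerline (in place).

    ``reference`` maps class name -> (n, 2) centerline points (e.g. phantom
    truth).  A segment takes the class of the reference polyline closest to
    its median point, when within ``max_distance_px``.
    """
    for seg in segments:
        mid = seg.points[len(seg.points) // 2]
        best_cls, best_d = "unknown", math.inf
        for cls, pts in reference.items():
            d = float(np.min(np.hypot(pts[:, 0] - mid[0], pts[:, 1] - mid[1])))
            if d < best_d:
                best_cls, best_d = cls, d
        if best_d <= max_distance_px:
            seg.vessel_class = best_cls


def run_image(
    image: np.ndarray,
    disc: roi.OpticDisc,
    config: RunConfig | None = None,
    segment_labels: dict[int, str] | None = None,
    label_reference: dict[str, np.ndarray] | None = None,
) -> dict:
    """Measure one fundus image; returns a flat metric record.

    ``segment_labels`` maps segment_id -> arteriole/venule (the annotation
    sidecar); ``label_reference`` instead labels segments from reference
    centerlines (phantom truth).  Calibers are NaN when no labelled vessel
    crosses the caliber annulus.
    """
    config = config or RunConfig()
    t0 = time.perf_counter()
    disc.validate_within(image.shape[:2])

    mask = segmentation.segment_vessels(image, config.segmentation)
    m = mask.pixels

    roi1 = roi.make_roi1(disc)
    roi2 = roi.make_roi2(disc)
    roi3 = roi.make_roi3(disc)
    roi2_mask = roi.rasterize_roi(roi2, disc, m.shape)
    roi3_mask = roi.rasterize_roi(roi3, disc, m.shape)

    segments = morphometry.extract_segments(m)
    if segment_labels:
        for seg in segments:
            if seg.segment_id in segment_labels:
                seg.vessel_class = segment_labels[seg.segment_id]
    elif label_reference:
        label_segments_by_reference(segments, label_reference)

    record: dict = {k: math.nan for k in stats.RETINAL_FEATURES}
    record["caliber_units"] = "um" if config.um_per_px else "px"

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        arts, vens, units = morphometry.crossing_widths(
            segments, roi1, disc, config.um_per_px
        )
        try:
            cal = morphometry.caliber_summary(arts, vens, units)
            record.update(crae_um=cal.crae_um, crve_um=cal.crve_um, avr=cal.avr)
        except morphometry.UndefinedCaliberError:
            logger.warning("no labelled vessels cross the caliber annulus")

        tort = morphometry.tortuosity_index(
            segments, roi2, disc, config.tortuosity_convention
        )
        record["tortuosity_index"] = tort.index

    mono_input = m & roi2_mask
    if mono_input.any():
        mono = fractal.monofractal_metrics(mono_input, config.fractal)
        record["df"] = mono.df
        record["lacunarity"] = mono.lacunarity

    mf_input = m & roi3_mask
    if mf_input.any():
        spectrum = fractal.multifractal_metrics(mf_input, config.fractal)
        record.update(spectrum.as_dict())

    record["n_segments"] = len(segments)
    record["vessel_px"] = int(m.sum())
    record["elapsed_s"] = round(time.perf_counter() - t0, 3)
    record["config_hash"] = config.config_hash()
    return record


def run_image_file(
    image_path: str | Path,
    disc_path: str | Path,
    config: RunConfig | None = None,
    labels_path: str | Path | None = None,
) -> dict:
    """File-based wrapper of :func:`run_image` (PNG/TIFF + JSON sidecars)."""
    import imageio.v3 as iio

    image = np.asarray(iio.imread(image_path))
    disc = roi.load_disc_annotation(disc_path)
    segment_labels = None
    if labels_path:
        entries = json.loads(Path(labels_path).read_text())
        segment_labels = {int(e["segment_id"]): e["class"] for e in entries}
    rec = run_image(segmentation.to_grayscale(image), disc, config, segment_labels)
    rec["image_path"] = str(image_path)
    return rec


# ---------------------------------------------------------------------------
# patient aggregation and cohort run

def aggregate_patient(records: list[dict]) -> dict:
    """Average metric records from all images of both eyes of one patient.

    NaN metrics are skipped per feature; a patient with zero successful
    records cannot be aggregated.
    """
    ok = [r for r in records if r and not r.get("failed")]
    if not ok:
        raise stats.InsufficientDataError("no successful image records to aggregate")
    out: dict = {"n_images": len(ok)}
    for feat in stats.RETINAL_FEATURES:
        vals = [r[feat] for r in ok if feat in r and not pd.isna(r[feat])]
        out[feat] = float(np.mean(vals)) if vals else math.nan
    out["single_record"] = len(ok) == 1
    return out


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read the study manifest CSV (one row per image)."""
    df = pd.read_csv(path)
    required = {"patient_id", "image_path", "disc_annotation_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns {sorted(missing)}")
    if df.empty:
        raise ValueError("manifest has no rows")
    return df


def run_cohort(
    manifest: pd.DataFrame,
    config: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Process every manifest image, aggregate patients, run the statistics.

    Returns (feature table, stats report).  Per-image failures are logged
    and recorded; they never abort the run.
    """
    config = config or RunConfig()
    if manifest.empty:
        raise ValueError("empty manifest")
    records: dict[str, list[dict]] = {}
    failures: list[dict] = []
    for _, row in manifest.iterrows():
        pid = str(row["patient_id"])
        try:
            rec = run_image_file(
                row["image_path"],
                row["disc_annotation_path"],
                config,
                row.get("labels_path") if "labels_path" in row else None,
            )
        except Exception as exc:
            logger.warning("image %s of %s failed: %s", row["image_path"], pid, exc)
            failures.append(
                {"patient_id": pid, "image_path": str(row["image_path"]),
                 "error": str(exc), "failed": True}
            )
            continue
        records.setdefault(pid, []).append(rec)

    rows = []
    meta_cols = [
        c for c in ("group", "collateral_score", "collateral_class")
        if c in manifest.columns
    ]
    for pid, recs in records.items():
        try:
            agg = aggregate_patient(recs)
        except stats.InsufficientDataError:
            logger.warning("patient %s excluded: no usable images", pid)
            continue
        agg["patient_id"] = pid
        first = manifest[manifest["patient_id"].astype(str) == pid].iloc[0]
        for c in meta_cols:
            agg[c] = first[c]
        rows.append(agg)
    table = pd.DataFrame(rows)

    report = stats_report(table, config) if not table.empty else {}
    report["n_image_failures"] = len(failures)
    report["config_hash"] = config.config_hash()

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "feature_table.csv", index=False)
        (out_dir / "stats_report.json").write_text(
            json.dumps(report, indent=2, default=_jsonable)
        )
        (out_dir / "report.md").write_text(render_markdown_report(table, report))
    return table, report


def _jsonable(obj):
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return str(obj)


def stats_report(table: pd.DataFrame, config: RunConfig | None = None) -> dict:
    """Cohort statistics on a per-patient feature table.

    Runs the control-vs-stroke and poor-vs-good comparisons over every
    available retinal metric, PCA (3 components) on the retinal metrics,
    and the leave-one-out classifier; stages with too little data are
    reported as skipped rather than failing the run.
    """
    config = config or RunConfig()
    report: dict = {}
    t = table.copy()
    if "collateral_class" not in t.columns and "collateral_score" in t.columns:
        t["collateral_class"] = stats.dichotomize_collaterals(
            pd.to_numeric(t["collateral_score"], errors="coerce"),
            config.poor_max_score,
        )

    if "group" in t.columns and t["group"].nunique() == 2:
        report["control_vs_stroke"] = stats.compare_many(
            t, stats.RETINAL_FEATURES, "group", "control", "stroke"
        )
    if "collateral_class" in t.columns:
        sub = t.dropna(subset=["collateral_class"])
        if sub["collateral_class"].nunique() == 2:
            report["good_vs_poor"] = stats.compare_many(
                sub, stats.RETINAL_FEATURES, "collateral_class", "good", "poor"
            )
            avail = [f for f in stats.RETINAL_FEATURES if f in sub.columns
                     and sub[f].notna().all()]
            if len(avail) >= 3 and len(sub) >= 3:
                pca = stats.pca_project(sub, tuple(avail), 3)
                report["pca"] = {
                    "explained_variance_fractions":
                        pca.explained_variance_fractions.tolist(),
                    "cumulative_fraction": pca.cumulative_fraction,
                }
            counts = sub["collateral_class"].value_counts()
            if counts.min() >= 2:
                rep = stats.loocv_classify(
                    sub, config.classifier_features, config.learner
                )
                report["classifier"] = {
                    "learner": rep.learner,
                    "confusion_matrix": rep.confusion_matrix.tolist(),
                    "accuracy": rep.accuracy,
                    "sensitivity_poor": rep.sensitivity_poor,
                    "specificity_poor": rep.specificity_poor,
                    "sensitivity_weighted": rep.sensitivity_weighted,
                    "specificity_weighted": rep.specificity_weighted,
                }
            else:
                report["classifier"] = "skipped: <2 patients per class"
    return report


def render_markdown_report(table: pd.DataFrame, report: dict) -> str:
    """Human-readable run summary mirroring the cohort tables."""
    lines = ["# Cohort report", "", f"Patients: {len(table)}", ""]
    for key in ("control_vs_stroke", "good_vs_poor"):
        cmp_df = report.get(key)
        if isinstance(cmp_df, pd.DataFrame) and not cmp_df.empty:
            lines.append(f"## {key.replace('_', ' ')}")
            lines.append("")
            sub = cmp_df[["feature", "mean_a", "sd_a", "mean_b", "sd_b", "p_value"]]
            lines.append("```")
            lines.append(sub.round(4).to_string(index=False))
            lines.append("```")
            lines.append("")
    clf = report.get("classifier")
    if isinstance(clf, dict):
        lines.append("## Classifier (leave-one-out)")
        lines.append("")
        lines.append(f"- learner: {clf['learner']}")
        lines.append(f"- accuracy: {clf['accuracy']:.3f}")
        lines.append(f"- sensitivity (poor positive): {clf['sensitivity_poor']:.3f}")
        lines.append(f"- specificity (poor positive): {clf['specificity_poor']:.3f}")
        lines.append(f"- confusion matrix [poor, good]: {clf['confusion_matrix']}")
    if "config_hash" in report:
        lines.append("")
        lines.append(f"config: `{report['config_hash']}`")
    return "\n".join(lines) + "\n"
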