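"""Cohort orchestration: manifest ingestion, eligibility, end-to-end runs.

The pipeline stages mirror the study workflow: case-eligibility filtering
(age, post-mortem interval, resuscitation/ICU/emphysema flags), random
selection of fields per slide, segmentation, morphometry, case aggregation
and the diagnostic statistics, with every output row traceable to a
(case, slide, field) triple.  Reruns with the same manifest, config and seed
produce identical CSV/JSON content.

Two entry points exist: :func:`run_pipeline` consumes a manifest of image
files on disk, while :func:`run_synthetic_study` composes the synthetic
generator with the same analysis stages in memory (no image IO), which is
how the calibration and recovery experiments are run.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .morphometry import (
    CaseSummary,
    case_summaries_frame,
    measure_objects,
    summarize_case,
    summarize_field,
)
from .segmentation import FieldImage, SegmentationParams, segment_air_spaces
from .stats import AirspaceDiagnostics, DiagnosticReport

logger = logging.getLogger("lungmorph")

MANIFEST_COLUMNS = [
    "case_id",
    "group",
    "slide_id",
    "field_id",
    "image_path",
    "um_per_px",
    "age_years",
    "pmi_hours",
    "cpr_high_pressure_o2",
    "icu_admission",
    "chronic_emphysema",
]

#: eligibility rules: (rule name, required column, row-level predicate)
EXCLUSION_RULES = [
    ("age over 65 years", "age_years", lambda s: s > 65),
    ("PMI longer than 30 h", "pmi_hours", lambda s: s > 30),
    (
        "high-pressure oxygen in CPR",
        "cpr_high_pressure_o2",
        lambda s: s.astype(bool),
    ),
    ("ICU admission", "icu_admission", lambda s: s.astype(bool)),
    ("chronic pulmonary emphysema", "chronic_emphysema", lambda s: s.astype(bool)),
]

_TRUE_STRINGS = {"true", "1", "yes", "y", "t"}


def _coerce_bool(series: pd.Series) -> pd.Series:
    if series.dtype == bool:
        return series
    return series.map(
        lambda v: str(v).strip().lower() in _TRUE_STRINGS if not isinstance(v, (bool, np.bool_)) else bool(v)
    )


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    fields_per_slide: int = 6
    reference_group: str = "drowning"
    positive_group: str = "pbt"
    bonferroni_all_pairs: bool = False
    seed: int = 0
    outdir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.fields_per_slide < 1:
            raise ValueError("fields_per_slide must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        seg = SegmentationParams(**raw.pop("segmentation", {}))
        return cls(segmentation=seg, **raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["outdir"] = str(self.outdir) if self.outdir else None
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort manifest CSV."""
    manifest = pd.read_csv(path)
    return validate_manifest(manifest)


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise ValueError(f"manifest missing required columns: {missing}")
    manifest = manifest.copy()
    for col in ("cpr_high_pressure_o2", "icu_admission", "chronic_emphysema"):
        manifest[col] = _coerce_bool(manifest[col])
    key = manifest[["case_id", "slide_id", "field_id"]]
    if key.duplicated().any():
        dupes = key[key.duplicated()].iloc[0].tolist()
        raise ValueError(f"duplicate (case_id, slide_id, field_id): {dupes}")
    if manifest["group"].isna().any() or (manifest["group"] == "").any():
        raise ValueError("manifest contains empty group labels")
    per_case_cal = manifest.groupby("case_id")["um_per_px"].nunique()
    bad = per_case_cal[per_case_cal > 1]
    if len(bad):
        raise ValueError(
            f"um_per_px not constant within case(s): {list(bad.index)}"
        )
    return manifest


def filter_eligible_cases(
    manifest: pd.DataFrame,
) -> tuple[pd.DataFrame, list[dict]]:
    """Apply the case-level exclusion criteria.

    A case is excluded when any of its rows triggers a rule; every exclusion
    is logged with the first rule that fired.  Idempotent: re-filtering the
    retained manifest removes nothing further.
    """
    for _, column, _ in EXCLUSION_RULES:
        if column not in manifest.columns:
            raise ValueError(f"manifest missing metadata column {column!r}")
    manifest = manifest.copy()
    for col in ("cpr_high_pressure_o2", "icu_admission", "chronic_emphysema"):
        manifest[col] = _coerce_bool(manifest[col])
    exclusions: list[dict] = []
    excluded_cases: set = set()
    for rule_name, column, predicate in EXCLUSION_RULES:
        hits = manifest.loc[predicate(manifest[column]), "case_id"].unique()
        for case in hits:
            if case not in excluded_cases:
                excluded_cases.add(case)
                exclusions.append({"case_id": case, "rule": rule_name})
                logger.info("excluded case %s: %s", case, rule_name)
    retained = manifest[~manifest["case_id"].isin(excluded_cases)].reset_index(
        drop=True
    )
    return retained, exclusions


def sample_fields(
    manifest: pd.DataFrame, fields_per_slide: int, seed: int
) -> pd.DataFrame:
    """Uniformly sample fields per slide, without replacement, seeded.

    Slides with fewer than ``fields_per_slide`` fields keep all of them (the
    shortfall is logged, not an error).
    """
    if fields_per_slide < 1:
        raise ValueError("fields_per_slide must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5F1E1D]))
    picked_index: list = []
    for (case, slide), grp in sorted(
        manifest.groupby(["case_id", "slide_id"], sort=True),
        key=lambda kv: kv[0],
    ):
        grp = grp.sort_values("field_id")
        if len(grp) <= fields_per_slide:
            if len(grp) < fields_per_slide:
                logger.info(
                    "slide %s/%s has only %d fields (requested %d); keeping all",
                    case,
                    slide,
                    len(grp),
                    fields_per_slide,
                )
            picked_index.extend(grp.index)
        else:
            chosen = rng.choice(len(grp), size=fields_per_slide, replace=False)
            picked_index.extend(grp.index[np.sort(chosen)])
    return manifest.loc[picked_index].reset_index(drop=True)


def _read_image(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return tifffile.imread(path)
    import imageio.v3 as iio

    return iio.imread(path)


def _analyze_fields(
    field_iter,
    seg_params: SegmentationParams,
) -> tuple[pd.DataFrame, pd.DataFrame, list[CaseSummary]]:
    """Shared measurement loop: (FieldImage, meta) -> object/field/case tables."""
    object_rows = []
    field_summaries = []
    for image in field_iter:
        labels = segment_air_spaces(image, seg_params)
        measurements = measure_objects(labels)
        for m in measurements:
            object_rows.append(
                {
                    "case_id": image.case_id,
                    "slide_id": image.slide_id,
                    "field_id": image.field_id,
                    "object_id": m.object_id,
                    "area_um2": m.area_um2,
                    "max_feret_um": m.max_feret_um,
                    "min_feret_um": m.min_feret_um,
                    "edge_truncated": m.edge_truncated,
                }
            )
        field_summaries.append(
            summarize_field(
                measurements,
                image.field_area_um2,
                case_id=image.case_id,
                slide_id=image.slide_id,
                field_id=image.field_id,
                group=image.group,
            )
        )
    fields_df = pd.DataFrame([vars(f) for f in field_summaries])
    objects_df = pd.DataFrame(
        object_rows,
        columns=[
            "case_id",
            "slide_id",
            "field_id",
            "object_id",
            "area_um2",
            "max_feret_um",
            "min_feret_um",
            "edge_truncated",
        ],
    )
    summaries = []
    if len(fields_df):
        for case_id in fields_df["case_id"].unique():
            case_fields = [
                f for f in field_summaries if f.case_id == case_id
            ]
            summaries.append(summarize_case(case_fields))
    return objects_df, fields_df, summaries


@dataclass
class PipelineResult:
    """Bundle of tables and the fitted diagnostic report from one run."""

    objects: pd.DataFrame
    fields: pd.DataFrame
    cases: pd.DataFrame
    report: DiagnosticReport
    exclusions: list[dict]
    case_summaries: list[CaseSummary]

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "objects": outdir / "objects.csv",
            "fields": outdir / "fields.csv",
            "cases": outdir / "cases.csv",
            "group_comparisons": outdir / "group_comparisons.csv",
            "roc": outdir / "roc.csv",
            "report": outdir / "report.json",
        }
        fmt = "%.10g"
        self.objects.to_csv(paths["objects"], index=False, float_format=fmt)
        self.fields.to_csv(paths["fields"], index=False, float_format=fmt)
        self.cases.to_csv(paths["cases"], index=False, float_format=fmt)
        self.report.table_group_comparisons().to_csv(
            paths["group_comparisons"], index=False, float_format=fmt
        )
        self.report.table_roc().to_csv(paths["roc"], index=False, float_format=fmt)
        self.report.to_json(paths["report"])
        return paths


def run_pipeline(
    manifest: pd.DataFrame | str | Path, config: RunConfig
) -> PipelineResult:
    """Execute filter -> sample -> segment -> measure -> summarize -> stats.

    Unreadable images are skipped (the case's field count shrinks); a case
    whose fields all fail is a hard error.
    """
    if not isinstance(manifest, pd.DataFrame):
        base_dir = Path(manifest).parent
        manifest = load_manifest(manifest)
    else:
        base_dir = Path(".")
        manifest = validate_manifest(manifest)

    retained, exclusions = filter_eligible_cases(manifest)
    sampled = sample_fields(retained, config.fields_per_slide, config.seed)

    failed_cases: dict[str, int] = {}

    def field_iter():
        for row in sampled.itertuples(index=False):
            path = Path(row.image_path)
            if not path.is_absolute():
                path = base_dir / path
            try:
                pixels = _read_image(path)
            except (OSError, ValueError, RuntimeError) as exc:
                logger.warning(
                    "skipping unreadable field %s/%s/%s: %s",
                    row.case_id,
                    row.slide_id,
                    row.field_id,
                    exc,
                )
                failed_cases[row.case_id] = failed_cases.get(row.case_id, 0) + 1
                continue
            yield FieldImage(
                pixels=pixels,
                um_per_px=float(row.um_per_px),
                case_id=str(row.case_id),
                slide_id=str(row.slide_id),
                field_id=str(row.field_id),
                group=str(row.group),
            )

    objects_df, fields_df, summaries = _analyze_fields(
        field_iter(), config.segmentation
    )
    expected = sampled.groupby("case_id").size()
    analyzed = set(fields_df["case_id"]) if len(fields_df) else set()
    dead = [c for c in expected.index if c not in analyzed]
    if dead:
        raise RuntimeError(f"all fields failed for case(s): {dead}")

    report = AirspaceDiagnostics.from_case_summaries(
        summaries,
        reference_group=config.reference_group,
        positive_group=config.positive_group,
        bonferroni_all_pairs=config.bonferroni_all_pairs,
    ).fit()
    result = PipelineResult(
        objects=objects_df,
        fields=fields_df,
        cases=case_summaries_frame(summaries),
        report=report,
        exclusions=exclusions,
        case_summaries=summaries,
    )
    if config.outdir is not None:
        result.write(config.outdir)
    return result


def run_synthetic_study(
    preset_spec,
    slides_per_case: int,
    fields_per_slide: int,
    seed: int,
    segmentation_params: SegmentationParams | None = None,
    reference_group: str = "drowning",
    positive_group: str = "pbt",
) -> PipelineResult:
    """Generate a synthetic cohort and analyse it entirely in memory.

    Equivalent to generate_cohort + run_pipeline for a fully eligible cohort
    where every generated field is used, but with no image files written.
    """
    from .synthetic import generate_field, iter_cohort

    seg = segmentation_params or SegmentationParams()

    def field_iter():
        for meta, params, fseed in iter_cohort(
            preset_spec, slides_per_case, fields_per_slide, seed
        ):
            image, _ = generate_field(
                params,
                fseed,
                case_id=meta["case_id"],
                slide_id=meta["slide_id"],
                field_id=meta["field_id"],
                group=meta["group"],
            )
            yield image

    objects_df, fields_df, summaries = _analyze_fields(field_iter(), seg)
    report = AirspaceDiagnostics.from_case_summaries(
        summaries,
        reference_group=reference_group,
        positive_group=positive_group,
    ).fit()
    return PipelineResult(
        objects=objects_df,
        fields=fields_df,
        cases=case_summaries_frame(summaries),
        report=report,
        exclusions=[],
        case_summaries=summaries,
    )
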