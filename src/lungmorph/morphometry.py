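"""Per-object, per-field and per-case air-space morphometry.

Parameters follow the standard particle-analysis vocabulary:

- CAS: count of air spaces in a field,
- AAS: total area occupied by air spaces (µm²),
- PAS: percentage of the field area occupied by air spaces,
- MaxDAS / MinDAS: maximum / minimum Feret (caliper) diameter of each air
  collection (µm).

Feret diameters use the pixel-center convention: the maximum Feret is the
largest pairwise distance between boundary pixel centers (computed on the
convex hull), and the minimum Feret is the exact minimal width of the hull
over all orientations (attained perpendicular to some hull edge).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
from scipy.spatial import ConvexHull, QhullError

from .segmentation import LabeledAirSpaces


@dataclass
class AirSpaceMeasurement:
    """Geometry of one detected air collection."""

    object_id: int
    area_um2: float
    max_feret_um: float
    min_feret_um: float
    edge_truncated: bool
    centroid: tuple[float, float]  # (row, col) px


@dataclass
class FieldMorphometry:
    """Morphometric summary of one field; diameter means are NaN when CAS=0."""

    cas: int
    aas_um2: float
    pas_percent: float
    mean_max_das_um: float
    mean_min_das_um: float
    field_area_um2: float
    case_id: str = ""
    slide_id: str = ""
    field_id: str = ""
    group: str | None = None


@dataclass
class CaseSummary:
    """Per-case aggregates over fields (the unit entering group statistics).

    ``mean_ratio_aas_cas_um2`` is the per-field AAS/CAS ratio averaged over
    fields with CAS > 0 (mean of ratios, not ratio of means); diameter means
    are object-weighted over all air spaces of the case.
    """

    case_id: str
    group: str | None
    n_fields: int
    total_cas: int
    mean_cas_per_field: float
    mean_aas_um2: float
    mean_ratio_aas_cas_um2: float
    mean_pas_percent: float
    mean_max_das_um: float
    mean_min_das_um: float


def _feret_diameters_px(coords: np.ndarray) -> tuple[float, float]:
    """Max and min Feret diameter (px) of a pixel-coordinate set.

    Degenerate objects (single pixel, collinear pixels) fall back to the
    extent along the principal direction with the cross extent floored at
    one pixel, so diameters stay positive.
    """
    pts = coords.astype(np.float64)
    if len(pts) == 1:
        return 1.0, 1.0
    hull_pts = None
    if len(pts) >= 3:
        try:
            hull = ConvexHull(pts)
            hull_pts = pts[hull.vertices]
        except QhullError:
            hull_pts = None
    if hull_pts is None:
        # collinear or two-point object: brute-force pairwise span
        diffs = pts[:, None, :] - pts[None, :, :]
        maxf = float(np.sqrt(np.einsum("ijk,ijk->ij", diffs, diffs).max()))
        return max(maxf, 1.0), 1.0
    diffs = hull_pts[:, None, :] - hull_pts[None, :, :]
    maxf = float(np.sqrt(np.einsum("ijk,ijk->ij", diffs, diffs).max()))
    # minimal width: for each hull edge, the farthest vertex distance to its
    # supporting line; the min over edges is the exact minimal caliper width
    minf = math.inf
    n = len(hull_pts)
    for i in range(n):
        p, q = hull_pts[i], hull_pts[(i + 1) % n]
        e = q - p
        norm = float(np.hypot(e[0], e[1]))
        if norm == 0:
            continue
        u = e / norm
        rel = hull_pts - p
        widths = np.abs(u[0] * rel[:, 1] - u[1] * rel[:, 0])
        minf = min(minf, float(widths.max()))
    if not math.isfinite(minf):
        minf = 1.0
    return max(maxf, 1.0), max(minf, 1.0)


def measure_objects(
    labels: LabeledAirSpaces, um_per_px: float | None = None
) -> list[AirSpaceMeasurement]:
    """Measure every retained air space (empty list when none)."""
    um = labels.um_per_px if um_per_px is None else um_per_px
    if um <= 0:
        raise ValueError("um_per_px must be positive")
    out: list[AirSpaceMeasurement] = []
    if labels.n_objects == 0:
        return out
    slices = ndi.find_objects(labels.label_image)
    for i in range(1, labels.n_objects + 1):
        sl = slices[i - 1]
        local = labels.label_image[sl] == i
        coords = np.argwhere(local)
        coords[:, 0] += sl[0].start
        coords[:, 1] += sl[1].start
        maxf, minf = _feret_diameters_px(coords)
        out.append(
            AirSpaceMeasurement(
                object_id=i,
                area_um2=float(labels.pixel_counts[i - 1]) * um**2,
                max_feret_um=maxf * um,
                min_feret_um=minf * um,
                edge_truncated=bool(labels.edge_flags[i - 1]),
                centroid=(float(coords[:, 0].mean()), float(coords[:, 1].mean())),
            )
        )
    return out


def summarize_field(
    measurements: list[AirSpaceMeasurement],
    field_area_um2: float,
    case_id: str = "",
    slide_id: str = "",
    field_id: str = "",
    group: str | None = None,
) -> FieldMorphometry:
    """CAS / AAS / PAS and per-field diameter means from object records."""
    if field_area_um2 <= 0:
        raise ValueError("field_area_um2 must be positive")
    for m in measurements:
        if m.area_um2 < 0:
            raise ValueError(f"negative object area for object {m.object_id}")
    cas = len(measurements)
    aas = float(sum(m.area_um2 for m in measurements))
    return FieldMorphometry(
        cas=cas,
        aas_um2=aas,
        pas_percent=100.0 * aas / field_area_um2,
        mean_max_das_um=(
            float(np.mean([m.max_feret_um for m in measurements]))
            if cas
            else math.nan
        ),
        mean_min_das_um=(
            float(np.mean([m.min_feret_um for m in measurements]))
            if cas
            else math.nan
        ),
        field_area_um2=field_area_um2,
        case_id=case_id,
        slide_id=slide_id,
        field_id=field_id,
        group=group,
    )


def summarize_case(
    fields: list[FieldMorphometry],
    case_id: str | None = None,
    group: str | None = None,
) -> CaseSummary:
    """Aggregate field summaries into the per-case record.

    Fields with CAS = 0 contribute to the CAS/AAS/PAS means but are dropped
    from the AAS/CAS-ratio mean; diameter means are recovered object-weighted
    (each field's mean weighted by its CAS).  Order of fields is irrelevant.
    """
    if not fields:
        raise ValueError("summarize_case requires at least one field")
    if case_id is None:
        case_id = fields[0].case_id
    if group is None:
        group = fields[0].group
    cas = np.array([f.cas for f in fields], dtype=float)
    aas = np.array([f.aas_um2 for f in fields])
    pas = np.array([f.pas_percent for f in fields])
    with_objects = cas > 0
    total_cas = int(cas.sum())
    if with_objects.any():
        ratio = float(np.mean(aas[with_objects] / cas[with_objects]))
        maxdas = np.array([f.mean_max_das_um for f in fields])
        mindas = np.array([f.mean_min_das_um for f in fields])
        w = cas[with_objects]
        mean_max = float(np.average(maxdas[with_objects], weights=w))
        mean_min = float(np.average(mindas[with_objects], weights=w))
    else:
        ratio = mean_max = mean_min = math.nan
    return CaseSummary(
        case_id=case_id,
        group=group,
        n_fields=len(fields),
        total_cas=total_cas,
        mean_cas_per_field=float(cas.mean()),
        mean_aas_um2=float(aas.mean()),
        mean_ratio_aas_cas_um2=ratio,
        mean_pas_percent=float(pas.mean()),
        mean_max_das_um=mean_max,
        mean_min_das_um=mean_min,
    )


def case_summaries_frame(summaries: list[CaseSummary]) -> pd.DataFrame:
    """Tabulate case summaries (one row per case)."""
    return pd.DataFrame([vars(s) for s in summaries])
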