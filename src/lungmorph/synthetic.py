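"""Seeded synthetic H&E-like lung parenchyma with ground truth.

The generator emulates a brightfield photomicrograph of lung parenchyma at
low magnification: eosin-stained alveolar walls enclosing near-white air
spaces, with optional oedema, vessel (erythrocyte) and intra-alveolar cell
artifacts.  Alveolar architecture is a Voronoi tessellation of Poisson-
sampled seed points; walls are the tessellation edges thickened to a target
physical thickness.  Over-distension is emulated by deleting a fraction of
walls, which merges adjacent spaces into larger, irregular air collections.

All structural parameters are in physical units (seed points per mm², wall
thickness in µm, artifact densities per mm²), so a preset describes tissue
rather than pixels and transfers across image geometry and calibration.

Every field comes with a :class:`GroundTruth`: a per-pixel categorical label
mask and a per-object table of true air spaces, which downstream tests use
as the segmentation oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError, cKDTree
from skimage.measure import label as cc_label

from .segmentation import FieldImage

# ground-truth label codes
AIR = 0
WALL = 1
OEDEMA = 2
VESSEL = 3
CELLS = 4

LABEL_NAMES = {AIR: "air", WALL: "wall", OEDEMA: "oedema", VESSEL: "vessel", CELLS: "cells"}

#: artifact radius ranges in µm (uniformly sampled)
ARTIFACT_RADIUS_UM = {
    "oedema": (15.0, 40.0),
    "vessel": (10.0, 25.0),
    "cells": (6.0, 15.0),
}


@dataclass(frozen=True)
class StainPalette:
    """RGB triplets for the rendered tissue classes (8-bit)."""

    air: tuple[int, int, int] = (247, 244, 246)
    wall: tuple[int, int, int] = (199, 112, 148)
    oedema: tuple[int, int, int] = (243, 199, 199)
    vessel: tuple[int, int, int] = (186, 60, 65)
    cells: tuple[int, int, int] = (72, 64, 148)

    def as_lut(self) -> np.ndarray:
        return np.array(
            [self.air, self.wall, self.oedema, self.vessel, self.cells], dtype=np.uint8
        )


@dataclass(frozen=True)
class TissueParams:
    """Parameters of one synthetic parenchyma field.

    Defaults describe a 12 MPx field at 0.33 µm/px (≈1.307 mm² of tissue)
    with drowning-like architecture; group presets override the structural
    parameters and tests typically use a smaller geometry.
    """

    field_width_px: int = 4000
    field_height_px: int = 3000
    um_per_px: float = 0.33
    seed_point_density: float = 66.0  # alveolar seed points per mm²
    wall_thickness_um: float = 47.0
    wall_merge_fraction: float = 0.06  # fraction of walls deleted (over-distension)
    oedema_per_mm2: float = 8.0
    vessels_per_mm2: float = 3.0
    cell_clusters_per_mm2: float = 5.0
    stain_palette: StainPalette = field(default_factory=StainPalette)
    noise_sd: float = 6.0  # additive Gaussian noise per channel, 8-bit scale

    def __post_init__(self) -> None:
        if self.field_width_px <= 0 or self.field_height_px <= 0:
            raise ValueError(
                f"field dimensions must be positive, got "
                f"{self.field_width_px}x{self.field_height_px}"
            )
        if self.um_per_px <= 0:
            raise ValueError(f"um_per_px must be positive, got {self.um_per_px}")
        if not 0.0 <= self.wall_merge_fraction <= 1.0:
            raise ValueError(
                f"wall_merge_fraction must be in [0, 1], got {self.wall_merge_fraction}"
            )
        if self.wall_thickness_um <= 0:
            raise ValueError("wall_thickness_um must be positive")
        for name in (
            "seed_point_density",
            "oedema_per_mm2",
            "vessels_per_mm2",
            "cell_clusters_per_mm2",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def replace(self, **kwargs) -> "TissueParams":
        return dataclasses.replace(self, **kwargs)

    @property
    def field_area_um2(self) -> float:
        return (
            self.field_width_px * self.field_height_px * self.um_per_px**2
        )

    @property
    def field_area_mm2(self) -> float:
        return self.field_area_um2 / 1e6


@dataclass
class GroundTruth:
    """Per-pixel truth labels and the true air-space object table."""

    label_mask: np.ndarray  # uint8, codes AIR..CELLS
    object_table: pd.DataFrame  # object_id, area_um2, bbox, centroid
    um_per_px: float

    @property
    def n_objects(self) -> int:
        return len(self.object_table)

    @property
    def mean_object_area_um2(self) -> float:
        if len(self.object_table) == 0:
            return float("nan")
        return float(self.object_table["area_um2"].mean())


def _union_find_regions(n: int, edges: np.ndarray, deleted: np.ndarray) -> np.ndarray:
    """Merge Voronoi cells across deleted walls; returns region id per seed."""
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for (a, b), gone in zip(edges, deleted):
        if gone:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    roots = np.array([find(i) for i in range(n)])
    # compact to consecutive ids
    _, region = np.unique(roots, return_inverse=True)
    return region


def _delaunay_edges(points: np.ndarray) -> np.ndarray:
    """Sorted unique neighbor pairs of the Delaunay triangulation.

    Falls back to all pairs for tiny or degenerate point sets.
    """
    n = len(points)
    if n < 2:
        return np.empty((0, 2), dtype=int)
    if n >= 4:
        try:
            tri = Delaunay(points)
            pairs = set()
            for simplex in tri.simplices:
                for i in range(3):
                    a, b = simplex[i], simplex[(i + 1) % 3]
                    pairs.add((min(a, b), max(a, b)))
            return np.array(sorted(pairs), dtype=int)
        except QhullError:
            pass
    return np.array(
        [(a, b) for a in range(n) for b in range(a + 1, n)], dtype=int
    )


def _wall_mask(
    params: TissueParams, points_um: np.ndarray, region: np.ndarray
) -> np.ndarray:
    """Pixels lying within wall_thickness of a boundary between regions.

    A pixel is wall when the distance (in µm) to the nearest seed of a
    *different* merged region exceeds its own-seed distance by less than the
    wall thickness — a thickened-bisector construction that keeps wall
    thickness uniform along every retained tessellation edge.
    """
    h, w = params.field_height_px, params.field_width_px
    n = len(points_um)
    if n < 2 or len(np.unique(region)) < 2:
        return np.zeros((h, w), dtype=bool)
    tree = cKDTree(points_um)
    k = min(8, n)
    cols_um = (np.arange(w) + 0.5) * params.um_per_px
    wall = np.empty((h, w), dtype=bool)
    # row-chunked query keeps memory bounded at full 12 MPx geometry
    chunk = max(1, int(2_000_000 // max(w, 1)))
    for r0 in range(0, h, chunk):
        r1 = min(h, r0 + chunk)
        rows_um = (np.arange(r0, r1) + 0.5) * params.um_per_px
        grid = np.stack(
            [
                np.repeat(rows_um, w),
                np.tile(cols_um, r1 - r0),
            ],
            axis=1,
        )
        dist, idx = tree.query(grid, k=k)
        if k == 1:
            dist = dist[:, None]
            idx = idx[:, None]
        neigh_regions = region[idx]
        own_region = neigh_regions[:, 0]
        other = np.where(neigh_regions != own_region[:, None], dist, np.inf).min(axis=1)
        wall[r0:r1] = ((other - dist[:, 0]) < params.wall_thickness_um).reshape(
            r1 - r0, w
        )
    return wall


def _paint_artifacts(
    params: TissueParams, labels: np.ndarray, rng: np.random.Generator
) -> None:
    """Stamp oedema/vessel/cell-cluster discs onto air pixels, in place."""
    h, w = labels.shape
    specs = [
        ("oedema", params.oedema_per_mm2, OEDEMA),
        ("vessel", params.vessels_per_mm2, VESSEL),
        ("cells", params.cell_clusters_per_mm2, CELLS),
    ]
    rows_um = (np.arange(h) + 0.5) * params.um_per_px
    cols_um = (np.arange(w) + 0.5) * params.um_per_px
    for name, density, code in specs:
        count = rng.poisson(density * params.field_area_mm2)
        for _ in range(count):
            cy = rng.uniform(0, h * params.um_per_px)
            cx = rng.uniform(0, w * params.um_per_px)
            lo, hi = ARTIFACT_RADIUS_UM[name]
            radius = rng.uniform(lo, hi)
            r0 = max(0, int((cy - radius) / params.um_per_px) - 1)
            r1 = min(h, int((cy + radius) / params.um_per_px) + 2)
            c0 = max(0, int((cx - radius) / params.um_per_px) - 1)
            c1 = min(w, int((cx + radius) / params.um_per_px) + 2)
            if r0 >= r1 or c0 >= c1:
                continue
            dy = rows_um[r0:r1, None] - cy
            dx = cols_um[None, c0:c1] - cx
            disc = dy * dy + dx * dx <= radius * radius
            window = labels[r0:r1, c0:c1]
            window[disc & (window == AIR)] = code


def _object_table(air_mask: np.ndarray, um_per_px: float) -> pd.DataFrame:
    lab = cc_label(air_mask, connectivity=2)
    n = int(lab.max())
    if n == 0:
        return pd.DataFrame(
            columns=[
                "object_id",
                "area_um2",
                "min_row",
                "min_col",
                "max_row",
                "max_col",
            ]
        )
    areas_px = np.bincount(lab.ravel())[1:]
    import scipy.ndimage as ndi

    slices = ndi.find_objects(lab)
    rows = []
    for i, sl in enumerate(slices, start=1):
        rows.append(
            {
                "object_id": i,
                "area_um2": float(areas_px[i - 1]) * um_per_px**2,
                "min_row": sl[0].start,
                "min_col": sl[1].start,
                "max_row": sl[0].stop,
                "max_col": sl[1].stop,
            }
        )
    return pd.DataFrame(rows)


def generate_field(
    params: TissueParams,
    seed: int,
    case_id: str = "synthetic",
    slide_id: str = "s1",
    field_id: str = "f1",
    group: str | None = None,
) -> tuple[FieldImage, GroundTruth]:
    """Render one synthetic parenchyma field and its ground truth.

    Deterministic for fixed ``(params, seed)``: the seed feeds independent
    child streams for seed-point placement, wall deletion, artifact placement
    and pixel noise, so e.g. changing the merge fraction leaves the sampled
    architecture otherwise untouched (wall deletions are coupled across merge
    fractions: each wall carries one uniform draw and is deleted when it
    falls below the fraction).
    """
    if not isinstance(seed, (int, np.integer)) or seed < 0:
        raise ValueError(f"seed must be a non-negative integer, got {seed!r}")
    ss = np.random.SeedSequence([int(seed)])
    seed_rng, edge_rng, artifact_rng, noise_rng = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    h, w = params.field_height_px, params.field_width_px

    n_seeds = int(seed_rng.poisson(params.seed_point_density * params.field_area_mm2))
    points_um = seed_rng.uniform(
        low=[0.0, 0.0],
        high=[h * params.um_per_px, w * params.um_per_px],
        size=(n_seeds, 2),
    )

    edges = _delaunay_edges(points_um)
    edge_u = edge_rng.uniform(size=len(edges))
    deleted = edge_u < params.wall_merge_fraction
    region = (
        _union_find_regions(n_seeds, edges, deleted)
        if n_seeds
        else np.zeros(0, dtype=int)
    )

    labels = np.zeros((h, w), dtype=np.uint8)
    labels[_wall_mask(params, points_um, region)] = WALL
    _paint_artifacts(params, labels, artifact_rng)

    lut = params.stain_palette.as_lut()
    img = lut[labels].astype(np.float32)
    if params.noise_sd > 0:
        img += noise_rng.standard_normal(img.shape, dtype=np.float32) * params.noise_sd
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    image = FieldImage(
        pixels=pixels,
        um_per_px=params.um_per_px,
        case_id=case_id,
        slide_id=slide_id,
        field_id=field_id,
        group=group,
    )
    truth = GroundTruth(
        label_mask=labels,
        object_table=_object_table(labels == AIR, params.um_per_px),
        um_per_px=params.um_per_px,
    )
    return image, truth


# ---------------------------------------------------------------------------
# group presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupPreset:
    """Tissue-parameter distribution for one study group.

    Per-case structural parameters are drawn from truncated normal
    distributions around the preset centers, giving between-case biological
    variability on top of field-to-field sampling noise.  The barotrauma
    preset has a strictly higher wall-merge fraction and lower seed density
    than the two control presets, encoding air-space over-distension.
    """

    name: str
    seed_point_density: tuple[float, float]  # (mean, sd) per mm²
    wall_merge_fraction: tuple[float, float]
    wall_thickness_um: tuple[float, float]
    base: TissueParams = field(default_factory=TissueParams)

    def sample_case_params(self, rng: np.random.Generator) -> TissueParams:
        density = max(5.0, rng.normal(*self.seed_point_density))
        merge = float(np.clip(rng.normal(*self.wall_merge_fraction), 0.0, 0.95))
        thickness = max(5.0, rng.normal(*self.wall_thickness_um))
        return self.base.replace(
            seed_point_density=density,
            wall_merge_fraction=merge,
            wall_thickness_um=thickness,
        )


def default_presets(base: TissueParams | None = None) -> dict[str, GroupPreset]:
    """The three calibrated group presets (pbt, drowning, control).

    Centers were calibrated by grid search against pipeline-measured PAS
    (targets ≈65 / 38 / 42%); spreads give between-case PAS variability
    comparable, in relative terms, to the reference cohort.
    """
    base = base if base is not None else TissueParams()
    return {
        "pbt": GroupPreset(
            name="pbt",
            seed_point_density=(48.0, 8.0),
            wall_merge_fraction=(0.45, 0.10),
            wall_thickness_um=(56.0, 8.0),
            base=base,
        ),
        "drowning": GroupPreset(
            name="drowning",
            seed_point_density=(66.0, 10.0),
            wall_merge_fraction=(0.06, 0.04),
            wall_thickness_um=(47.0, 3.5),
            base=base,
        ),
        "control": GroupPreset(
            name="control",
            seed_point_density=(72.0, 12.0),
            wall_merge_fraction=(0.06, 0.04),
            wall_thickness_um=(42.0, 9.0),
            base=base,
        ),
    }


def field_seed(master_seed: int, group_idx: int, case_idx: int, slide_idx: int, fld_idx: int) -> int:
    """Deterministic per-field sub-seed derived from the master seed."""
    ss = np.random.SeedSequence(
        [int(master_seed), group_idx, case_idx, slide_idx, fld_idx]
    )
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def iter_cohort(
    preset_spec: list[tuple[GroupPreset, int]],
    slides_per_case: int,
    fields_per_slide: int,
    seed: int,
):
    """Yield (metadata dict, case TissueParams, field seed) for every field.

    Shared by the disk-writing cohort generator and the in-memory study
    runner so both produce identical cohorts for a given master seed.
    """
    if not preset_spec:
        raise ValueError("preset_spec must list at least one (preset, n_cases)")
    if slides_per_case < 1 or fields_per_slide < 1:
        raise ValueError("slides_per_case and fields_per_slide must be >= 1")
    for gi, (preset, n_cases) in enumerate(preset_spec):
        if n_cases < 1:
            raise ValueError(f"n_cases must be >= 1 for preset {preset.name!r}")
        for ci in range(n_cases):
            case_ss = np.random.SeedSequence([int(seed), gi, ci])
            case_rng = np.random.default_rng(case_ss)
            case_params = preset.sample_case_params(case_rng)
            meta = {
                "case_id": f"{preset.name}_{ci + 1:02d}",
                "group": preset.name,
                "age_years": int(case_rng.integers(25, 65)),
                "pmi_hours": round(float(case_rng.uniform(4, 28)), 1),
                "cpr_high_pressure_o2": False,
                "icu_admission": False,
                "chronic_emphysema": False,
            }
            for si in range(slides_per_case):
                for fi in range(fields_per_slide):
                    fmeta = dict(
                        meta,
                        slide_id=f"sl{si + 1:02d}",
                        field_id=f"f{fi + 1:02d}",
                    )
                    yield fmeta, case_params, field_seed(seed, gi, ci, si, fi)


def generate_cohort(
    preset_spec: list[tuple[GroupPreset, int]],
    slides_per_case: int,
    fields_per_slide: int,
    seed: int,
    outdir: str | Path,
    image_format: str = "tiff",
) -> pd.DataFrame:
    """Write a full synthetic cohort (images, truth masks, manifest) to disk.

    Returns the manifest as a DataFrame; also written to
    ``outdir/manifest.csv``.  Ground-truth object tables are concatenated in
    ``outdir/truth_objects.csv``.
    """
    import imageio.v3 as iio
    import tifffile

    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)
    ext = {"tiff": "tif", "png": "png"}.get(image_format)
    if ext is None:
        raise ValueError(f"image_format must be 'tiff' or 'png', got {image_format!r}")

    rows = []
    truth_tables = []
    for meta, case_params, fseed in iter_cohort(
        preset_spec, slides_per_case, fields_per_slide, seed
    ):
        stem = f"{meta['case_id']}_{meta['slide_id']}_{meta['field_id']}"
        image, truth = generate_field(
            case_params,
            fseed,
            case_id=meta["case_id"],
            slide_id=meta["slide_id"],
            field_id=meta["field_id"],
            group=meta["group"],
        )
        image_path = outdir / "images" / f"{stem}.{ext}"
        truth_path = outdir / "truth" / f"{stem}_truth.png"
        if ext == "tif":
            tifffile.imwrite(image_path, image.pixels, photometric="rgb")
        else:
            iio.imwrite(image_path, image.pixels)
        iio.imwrite(truth_path, truth.label_mask)
        table = truth.object_table.copy()
        table.insert(0, "field_id", meta["field_id"])
        table.insert(0, "slide_id", meta["slide_id"])
        table.insert(0, "case_id", meta["case_id"])
        truth_tables.append(table)
        rows.append(
            {
                "case_id": meta["case_id"],
                "group": meta["group"],
                "slide_id": meta["slide_id"],
                "field_id": meta["field_id"],
                "image_path": str(image_path.relative_to(outdir)),
                "truth_path": str(truth_path.relative_to(outdir)),
                "um_per_px": case_params.um_per_px,
                "age_years": meta["age_years"],
                "pmi_hours": meta["pmi_hours"],
                "cpr_high_pressure_o2": meta["cpr_high_pressure_o2"],
                "icu_admission": meta["icu_admission"],
                "chronic_emphysema": meta["chronic_emphysema"],
            }
        )
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    pd.concat(truth_tables, ignore_index=True).to_csv(
        outdir / "truth_objects.csv", index=False
    )
    return manifest


def sample_parameter_cohort(
    group_params: dict[str, tuple[float, float]],
    n_per_group: int,
    seed: int,
) -> dict[str, np.ndarray]:
    """Draw per-case values of one morphometric parameter for each group.

    ``group_params`` maps group name to (mean, sd); values are independent
    normal draws, reproducible for a fixed seed.  This parameter-level
    sampler backs the statistics-layer simulations that work directly from
    published group summaries without rendering any images.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    for name, (_, sd) in group_params.items():
        if sd < 0:
            raise ValueError(f"negative sd for group {name!r}")
    rng = np.random.default_rng(seed)
    return {
        name: rng.normal(mean, sd, size=n_per_group)
        for name, (mean, sd) in group_params.items()
    }
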