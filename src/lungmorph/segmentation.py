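"""Air-space detection in calibrated RGB histology fields.

The detector follows the particle-analysis recipe used for emphysema-style
morphometry: an adaptive threshold on the red channel separates unstained
air from eosin-stained parenchyma, the candidate map is binarized
automatically (Otsu), chromatic rules drop oedema / erythrocyte / nuclear
pixels that are bright in red but visibly stained, an optional morphological
opening cleans speckle, and connected components smaller than a minimum
physical area (default 100 µm²) are discarded.  Objects truncated by the
field border are retained and measured as-is.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import binary_opening, disk

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import GroundTruth


@dataclass
class FieldImage:
    """One calibrated RGB microscope field."""

    pixels: np.ndarray  # H x W x 3, uint8
    um_per_px: float
    case_id: str = ""
    slide_id: str = ""
    field_id: str = ""
    group: str | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError(
                f"expected an HxWx3 RGB array, got shape {arr.shape}"
            )
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("image must have positive dimensions")
        if self.um_per_px <= 0:
            raise ValueError(f"um_per_px must be positive, got {self.um_per_px}")
        self.pixels = arr

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def field_area_um2(self) -> float:
        h, w = self.shape
        return h * w * self.um_per_px**2


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable knobs of the air-space detector.

    ``adaptive_window_px`` / ``adaptive_offset`` control the local red-channel
    threshold (a pixel is candidate air when red >= local window mean +
    offset).  ``chroma_exclusion_threshold`` is the maximum |R - B| allowed
    inside air (oedema and residual eosin tinge exceed it); erythrocytes are
    dropped by red excess over green at low brightness and nuclei by blue
    excess over red.  ``unstained_red_floor`` decides near-uniform images for
    which Otsu binarization is undefined.
    """

    adaptive_window_px: int = 301
    adaptive_offset: float = -10.0
    bimodal_min_separation: float = 20.0
    chroma_exclusion_threshold: float = 25.0
    erythrocyte_red_excess: float = 60.0
    erythrocyte_max_brightness: float = 130.0
    hematoxylin_blue_excess: float = 30.0
    unstained_red_floor: float = 225.0
    min_area_um2: float = 100.0
    connectivity: int = 8
    cleanup_radius_px: int = 0

    def __post_init__(self) -> None:
        if self.min_area_um2 <= 0:
            raise ValueError("min_area_um2 must be positive")
        if self.adaptive_window_px < 3 or self.adaptive_window_px % 2 == 0:
            raise ValueError(
                f"adaptive_window_px must be odd and >= 3, got {self.adaptive_window_px}"
            )
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")
        if self.cleanup_radius_px < 0:
            raise ValueError("cleanup_radius_px must be >= 0")

    def replace(self, **kwargs) -> "SegmentationParams":
        return dataclasses.replace(self, **kwargs)


@dataclass
class LabeledAirSpaces:
    """Connected air-space components surviving the minimum-area filter.

    ``label_image`` holds consecutive positive integer labels (0 = non-air);
    per-object pixel counts and border-contact flags are index-aligned so
    object ``i`` (1-based) maps to ``pixel_counts[i - 1]``.
    """

    label_image: np.ndarray  # H x W int32, 0 = background
    n_objects: int
    pixel_counts: np.ndarray  # (n_objects,)
    edge_flags: np.ndarray  # (n_objects,) bool
    um_per_px: float

    @property
    def areas_um2(self) -> np.ndarray:
        return self.pixel_counts * self.um_per_px**2

    @property
    def air_mask(self) -> np.ndarray:
        return self.label_image > 0


@dataclass
class ExclusionMask:
    """Manual artifact-correction mask; True pixels are forced non-air."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        if self.mask.ndim != 2:
            raise ValueError("exclusion mask must be a 2-D array")


def _binarize_candidates(red: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Local-mean adaptive stage followed by automatic global binarization."""
    redf = red.astype(np.float64)
    local_mean = ndi.uniform_filter(redf, size=params.adaptive_window_px, mode="reflect")
    candidate = redf - local_mean >= params.adaptive_offset
    # automatic binarization: Otsu on the red histogram; Otsu is meaningless
    # on a unimodal histogram (uniform stain, or bare noise), so the split is
    # accepted only when the two classes it induces are well separated —
    # otherwise an absolute unstained-red floor decides
    threshold = None
    if red.max() > red.min():
        t = threshold_otsu(red)
        lo, hi = redf[redf <= t], redf[redf > t]
        if len(lo) and len(hi) and hi.mean() - lo.mean() >= params.bimodal_min_separation:
            threshold = t
    if threshold is None:
        global_air = redf >= params.unstained_red_floor
    else:
        global_air = redf > threshold
    return candidate & global_air


def _chroma_exclusions(pixels: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """True where color rules identify oedema, erythrocytes or nuclei."""
    r = pixels[..., 0].astype(np.int16)
    g = pixels[..., 1].astype(np.int16)
    b = pixels[..., 2].astype(np.int16)
    brightness = (r + g + b) / 3.0
    oedema = np.abs(r - b) > params.chroma_exclusion_threshold
    erythro = (r - g > params.erythrocyte_red_excess) & (
        brightness < params.erythrocyte_max_brightness
    )
    nuclei = b - r > params.hematoxylin_blue_excess
    return oedema | erythro | nuclei


def _label_and_filter(
    air: np.ndarray, params: SegmentationParams, um_per_px: float
) -> LabeledAirSpaces:
    conn = 2 if params.connectivity == 8 else 1
    raw = cc_label(air, connectivity=conn)
    n_raw = int(raw.max())
    if n_raw == 0:
        return LabeledAirSpaces(
            label_image=raw.astype(np.int32),
            n_objects=0,
            pixel_counts=np.zeros(0, dtype=np.int64),
            edge_flags=np.zeros(0, dtype=bool),
            um_per_px=um_per_px,
        )
    counts = np.bincount(raw.ravel(), minlength=n_raw + 1)
    min_px = params.min_area_um2 / um_per_px**2
    keep = np.flatnonzero(counts[1:] * um_per_px**2 >= params.min_area_um2) + 1
    # relabel consecutively in first-encounter (scan) order
    remap = np.zeros(n_raw + 1, dtype=np.int32)
    remap[keep] = np.arange(1, len(keep) + 1, dtype=np.int32)
    labels = remap[raw]
    border = np.zeros(n_raw + 1, dtype=bool)
    for edge in (raw[0, :], raw[-1, :], raw[:, 0], raw[:, -1]):
        border[np.unique(edge)] = True
    del min_px
    return LabeledAirSpaces(
        label_image=labels,
        n_objects=len(keep),
        pixel_counts=counts[keep].astype(np.int64),
        edge_flags=border[keep],
        um_per_px=um_per_px,
    )


def segment_air_spaces(
    image: FieldImage, params: SegmentationParams | None = None
) -> LabeledAirSpaces:
    """Detect air spaces in one field.

    Pipeline: adaptive red-channel threshold -> automatic binarization ->
    chromatic artifact exclusion -> optional opening -> connected-component
    labeling -> minimum-area filter.  Border-touching objects are retained.
    """
    params = params or SegmentationParams()
    if not isinstance(image, FieldImage):
        raise TypeError("segment_air_spaces expects a FieldImage")
    pixels = image.pixels
    air = _binarize_candidates(pixels[..., 0], params)
    air &= ~_chroma_exclusions(pixels, params)
    if params.cleanup_radius_px > 0:
        air = binary_opening(air, disk(params.cleanup_radius_px))
    return _label_and_filter(air, params, image.um_per_px)


def apply_manual_exclusion(
    labels: LabeledAirSpaces,
    mask: ExclusionMask | np.ndarray,
    params: SegmentationParams | None = None,
) -> LabeledAirSpaces:
    """Remove masked pixels from all objects, then relabel and re-filter.

    Mirrors the manual correction step of the original workflow: an operator
    paints artifact regions, those pixels are forced out of every air space,
    and the minimum-area filter is applied again (an object bisected by the
    mask may yield two retained objects; a fully covered object disappears).
    """
    params = params or SegmentationParams()
    if isinstance(mask, np.ndarray):
        mask = ExclusionMask(mask)
    if mask.mask.shape != labels.label_image.shape:
        raise ValueError(
            f"mask shape {mask.mask.shape} does not match label image "
            f"shape {labels.label_image.shape}"
        )
    air = labels.air_mask & ~mask.mask
    return _label_and_filter(air, params, labels.um_per_px)


def segmentation_quality(labels: LabeledAirSpaces, truth: "GroundTruth") -> float:
    """Intersection-over-union of detected air vs ground-truth air pixels.

    Returns 1.0 when both are empty (vacuously identical).
    """
    from .synthetic import AIR

    truth_air = truth.label_mask == AIR
    if truth_air.shape != labels.label_image.shape:
        raise ValueError(
            f"ground truth shape {truth_air.shape} does not match labels "
            f"shape {labels.label_image.shape}"
        )
    detected = labels.air_mask
    union = np.count_nonzero(detected | truth_air)
    if union == 0:
        return 1.0
    inter = np.count_nonzero(detected & truth_air)
    return inter / union
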