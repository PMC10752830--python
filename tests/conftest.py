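import numpy as np
import pytest

from lungmorph import FieldImage, StainPalette, TissueParams

#: compact field geometry used throughout the tests (≈0.096 mm² of tissue)
SMALL_GEOMETRY = dict(field_width_px=256, field_height_px=192, um_per_px=1.4)

PALETTE = StainPalette()


@pytest.fixture
def small_params() -> TissueParams:
    return TissueParams(**SMALL_GEOMETRY)


def uniform_image(rgb, h=120, w=160, um_per_px=1.0) -> FieldImage:
    pixels = np.tile(np.array(rgb, dtype=np.uint8), (h, w, 1))
    return FieldImage(pixels=pixels, um_per_px=um_per_px)


def discs_on_background(
    disc_specs, h, w, um_per_px, fg=PALETTE.air, bg=PALETTE.wall
) -> FieldImage:
    """Rasterize white discs (center_row, center_col, radius_um) on stain."""
    pixels = np.tile(np.array(bg, dtype=np.uint8), (h, w, 1))
    yy, xx = np.mgrid[0:h, 0:w]
    for cy, cx, r_um in disc_specs:
        r_px = r_um / um_per_px
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r_px**2
        pixels[mask] = fg
    return FieldImage(pixels=pixels, um_per_px=um_per_px)
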