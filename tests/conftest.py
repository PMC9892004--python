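import numpy as np
import pytest

from camquant.imaging import LabelMask
from camquant.synthetic import PairParams, make_cell_pair


def label_mask_from_truth(stack, truth) -> LabelMask:
    """Ground-truth two-cell label mask for a generated doublet."""
    lab = np.zeros(stack.shape, dtype=np.int16)
    lab[truth.mask1] = 1
    lab[truth.mask2] = 2
    return LabelMask(lab, stack.voxel_size)


@pytest.fixture(scope="session")
def symmetric_doublet():
    """Equal-radius doublet r=50, d=50 (theta = 120 deg, chord ~ 86.6 um)."""
    stack, truth = make_cell_pair(PairParams(r1=50, r2=50, d=50))
    return stack, truth, label_mask_from_truth(stack, truth)


def render_disc(radius_px: int, pixel_um: float = 1.0, margin_px: int = 12):
    """Boolean disc rendered on a square grid, centre at a pixel centre."""
    n = 2 * radius_px + 2 * margin_px
    yy, xx = np.mgrid[:n, :n]
    c = n / 2
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2
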