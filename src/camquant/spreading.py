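"""Footprint morphometrics and spreading kinetics.

A spreading cell's binarized footprint is reduced per frame to its area
``A`` (µm²), perimeter ``p`` (µm, marching-squares contour length),
circularity ``c = p² / (4·pi·A)`` (1 for a disc, larger for irregular
outlines) and roundness ``1/c``.  A time series of areas is fitted with
the power law ``A = b * t**alpha``:

* ``fixed_quarter`` keeps ``alpha = 1/4`` and solves the through-origin
  least-squares problem in closed form,
  ``b = sum(A_i * t_i**0.25) / sum(t_i**0.5)``;
* ``free_exponent`` fits ``log A`` on ``log t`` by ordinary least squares
  (slope = alpha, intercept = log b), excluding zero-area frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import CamquantError, FitError
from .imaging import BinaryMask, extract_contour

__all__ = ["SpreadFrame", "SpreadFit", "footprint_metrics", "fit_spreading"]


@dataclass
class SpreadFrame:
    """Morphometrics of one footprint frame."""

    t: float  # minutes
    area: float  # µm²
    perimeter: float  # µm
    circularity: float  # p² / (4 pi A)
    n_components: int = 1

    @property
    def roundness(self) -> float:
        return 1.0 / self.circularity


@dataclass
class SpreadFit:
    """Fitted spreading-rate coefficient and exponent."""

    b: float  # µm² · min^-alpha
    alpha: float
    rss: float
    n_frames: int
    n_excluded: int = 0


def footprint_metrics(
    mask: BinaryMask, t: float = 0.0, smooth_um: float | None = None
) -> SpreadFrame:
    """Area, perimeter and circularity of a 2D footprint mask.

    Interior holes are filled; multiple components (a cell may fragment at
    threshold) are unioned for the area and their contour lengths summed
    for the perimeter, with the component count recorded.  ``smooth_um``
    is passed to :func:`~camquant.imaging.extract_contour`; smaller values
    preserve sharp corners (thin protrusions) at the cost of a slightly
    larger staircase bias on smooth outlines.
    """
    plane = ndimage.binary_fill_holes(mask.plane())
    if not plane.any():
        raise CamquantError("empty footprint mask")
    labeled, n = ndimage.label(plane, structure=np.ones((3, 3), dtype=int))
    _, dy, dx = mask.voxel_size
    area = float(plane.sum()) * dy * dx
    perim = 0.0
    for lab in range(1, n + 1):
        comp = BinaryMask(labeled == lab, mask.voxel_size)
        perim += extract_contour(comp, smooth_um=smooth_um).perimeter
    c = perim * perim / (4 * math.pi * area)
    return SpreadFrame(t=t, area=area, perimeter=perim, circularity=c, n_components=n)


def fit_spreading(frames: list[SpreadFrame], mode: str = "fixed_quarter") -> SpreadFit:
    """Fit ``A = b * t**alpha`` to a series of footprint frames.

    ``mode='fixed_quarter'`` fixes alpha at 1/4 (needs >= 2 frames);
    ``mode='free_exponent'`` fits alpha freely on log-log axes (needs
    >= 3 frames); frames with zero area (and, for the log fit, t = 0) are
    excluded and counted in ``n_excluded``.
    """
    t = np.array([f.t for f in frames], dtype=float)
    A = np.array([f.area for f in frames], dtype=float)
    if t.size != np.unique(t).size or np.any(t < 0):
        raise CamquantError("times must be distinct and non-negative")
    keep = (A > 0) & (t > 0)
    n_excluded = int((~keep).sum())
    t, A = t[keep], A[keep]
    if not A.size:
        raise FitError("all areas are zero: degenerate fit")

    if mode == "fixed_quarter":
        if t.size < 2:
            raise CamquantError("fixed_quarter fit needs >= 2 usable frames")
        tq = t**0.25
        b = float(np.sum(A * tq) / np.sum(tq * tq))
        alpha = 0.25
    elif mode == "free_exponent":
        if t.size < 3:
            raise CamquantError("free_exponent fit needs >= 3 usable frames")
        slope, intercept = np.polyfit(np.log(t), np.log(A), 1)
        alpha = float(slope)
        b = float(math.exp(intercept))
    else:
        raise CamquantError(f"unknown mode {mode!r}")

    rss = float(np.sum((A - b * t**alpha) ** 2))
    return SpreadFit(b=b, alpha=alpha, rss=rss, n_frames=int(t.size), n_excluded=n_excluded)
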