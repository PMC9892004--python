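"""Contact-angle and interface-enrichment metrics for cell doublets.

A segmented two-cell pair (a :class:`~camquant.imaging.LabelMask` with
labels 1 and 2) is reduced to:

* the interface chord between the two contact points;
* the pair contact angle, estimated by fitting a circle to each cell's
  free (non-interface) boundary and evaluating, for cell *i*,
  ``alpha_i = arccos(s_i / r_i)`` where ``s_i`` is the signed distance from
  the fitted centre to the chord line (positive when the centre lies on
  cell *i*'s own side).  The reported pair angle is ``alpha_1 + alpha_2``,
  the full (two-sided) opening angle in [0, 360) deg — for physical
  doublets in [0, 180];
* the enrichment fraction: the share of a membrane channel's signal lying
  within the interface region of the cell's membrane band.

Doublets are analyzed on 2D max projections, matching the standard
confocal figure pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import FitError, GeometryError, NoContactError
from .imaging import BinaryMask, Contour, ImageStack, LabelMask, extract_contour

__all__ = [
    "InterfaceGeometry",
    "ContactAngleResult",
    "EnrichmentResult",
    "find_interface",
    "contact_angle",
    "enrichment_fraction",
    "fit_circle",
]


@dataclass
class InterfaceGeometry:
    """Interface chord and free boundaries of a segmented doublet."""

    contact_points: np.ndarray = field(repr=False)  # (2, 2) (y, x) µm
    chord_length: float = 0.0
    free_contours: dict[int, np.ndarray] = field(default_factory=dict, repr=False)
    interface_points: np.ndarray = field(default=None, repr=False)

    @property
    def has_contact(self) -> bool:
        return self.chord_length > 0


@dataclass
class ContactAngleResult:
    """Per-cell and pair contact angles with the fitted circle geometry."""

    alpha_deg: tuple[float, float]
    theta_pair_deg: float
    centers: np.ndarray = field(repr=False)  # (2, 2) fitted (y, x) µm
    radii: tuple[float, float] = (0.0, 0.0)
    chord_length: float = 0.0
    # circle-intersection angle evaluated from the fitted circles alone;
    # identical at both contact points under the two-circle model
    theta_circles_deg: float = float("nan")


@dataclass
class EnrichmentResult:
    """Interface share of a membrane-localized signal."""

    f: float
    interface_signal: float
    total_membrane_signal: float
    band_width: float = 0.0
    interface_dilation: float = 0.0


def fit_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic (Kasa) least-squares circle fit.

    Parameters are (N, 2) planar points; returns (centre, radius).

    Raises
    ------
    FitError
        If the points are too few or collinear (singular normal matrix or
        non-finite radius).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise FitError("circle fit needs at least 3 points")
    y, x = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * y, 2 * x, np.ones_like(y)])
    rhs = y * y + x * x
    sol, _, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
    if rank < 3:
        raise FitError("collinear contour: circle fit is singular")
    cy, cx, c = sol
    r2 = c + cy * cy + cx * cx
    if not np.isfinite(r2) or r2 <= 0:
        raise FitError("circle fit produced a non-finite radius")
    return np.array([cy, cx]), float(math.sqrt(r2))


def _boundary(mask: np.ndarray) -> np.ndarray:
    return mask & ~ndimage.binary_erosion(mask, np.ones((3, 3), dtype=bool))


def _coords_um(idx: tuple[np.ndarray, np.ndarray], dy: float, dx: float) -> np.ndarray:
    """Pixel indices -> voxel-centre (y, x) positions in µm."""
    return np.column_stack([(idx[0] + 0.5) * dy, (idx[1] + 0.5) * dx])


def find_interface(
    mask: LabelMask, contact_window_px: float = 3.0
) -> InterfaceGeometry:
    """Locate the interface chord and the free boundary of each cell.

    Interface pixels are boundary pixels of either label lying within one
    pixel (8-connectivity) of the other label.  The two contact points are
    the extremal interface pixels (greatest pairwise separation), refined
    to subpixel positions by averaging the nearest vertex of each cell's
    marching-squares contour.  Free contours exclude contour points within
    ``contact_window_px`` pixels of either contact point and points
    adjacent to the other cell.

    Two labels that never touch yield a "no contact" result with chord
    length 0 (not an error).
    """
    labels = mask.labels
    if labels != [1, 2]:
        raise GeometryError(f"expected exactly labels [1, 2], got {labels}")
    plane = mask.plane()
    _, dy, dx = mask.voxel_size
    m1, m2 = plane == 1, plane == 2

    dilate = np.ones((3, 3), dtype=bool)
    near2 = ndimage.binary_dilation(m2, dilate)
    near1 = ndimage.binary_dilation(m1, dilate)
    iface = (_boundary(m1) & near2) | (_boundary(m2) & near1)
    if not iface.any():
        return InterfaceGeometry(
            contact_points=np.zeros((2, 2)),
            chord_length=0.0,
            interface_points=np.zeros((0, 2)),
        )

    pts = _coords_um(np.nonzero(iface), dy, dx)
    # extremal pair (O(n^2) on the interface band only)
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    ends = pts[[i, j]]

    contours = {
        lab: extract_contour(BinaryMask(plane == lab, mask.voxel_size)).points
        for lab in (1, 2)
    }
    trees = {lab: cKDTree(c) for lab, c in contours.items()}
    refined = []
    for e in ends:
        near = [contours[lab][trees[lab].query(e)[1]] for lab in (1, 2)]
        refined.append(np.mean(near, axis=0))
    refined = np.asarray(refined)
    chord = float(np.linalg.norm(refined[0] - refined[1]))

    w = contact_window_px * dy
    free: dict[int, np.ndarray] = {}
    for lab, other in ((1, 2), (2, 1)):
        c = contours[lab]
        d_other = trees[other].query(c)[0]
        d_ends = np.minimum(
            np.linalg.norm(c - refined[0], axis=1),
            np.linalg.norm(c - refined[1], axis=1),
        )
        keep = (d_other > 1.5 * dy) & (d_ends > w)
        free[lab] = c[keep]
    return InterfaceGeometry(
        contact_points=refined,
        chord_length=chord,
        free_contours=free,
        interface_points=pts,
    )


def contact_angle(
    mask: LabelMask, contact_window_px: float = 3.0
) -> ContactAngleResult:
    """Estimate the doublet contact angle from a two-label mask.

    Fits a circle to each cell's free contour and applies the
    signed-distance formula (see module docstring).  Angles above 90° per
    cell (partial engulfment, fitted centre on the far side of the chord)
    are handled by the sign of the distance.

    Raises
    ------
    NoContactError
        If the two labels share no interface.
    FitError
        If a free contour is degenerate.
    GeometryError
        If a fitted centre lies farther from the chord than the fitted
        radius (internally inconsistent geometry).
    """
    geo = find_interface(mask, contact_window_px=contact_window_px)
    if not geo.has_contact:
        raise NoContactError("labels 1 and 2 share no interface")
    for lab in (1, 2):
        if geo.free_contours.get(lab) is None or len(geo.free_contours[lab]) < 20:
            raise FitError(
                f"free contour of cell {lab} has "
                f"{0 if geo.free_contours.get(lab) is None else len(geo.free_contours[lab])}"
                " points; need >= 20"
            )

    plane = mask.plane()
    _, dy, dx = mask.voxel_size
    centroids = {
        lab: _coords_um(np.nonzero(plane == lab), dy, dx).mean(axis=0)
        for lab in (1, 2)
    }

    p0, p1 = geo.contact_points
    t_hat = (p1 - p0) / np.linalg.norm(p1 - p0)
    n_hat = np.array([-t_hat[1], t_hat[0]])  # unit normal to the chord line

    alphas = []
    centers = []
    radii = []
    for lab in (1, 2):
        center, radius = fit_circle(geo.free_contours[lab])
        side = math.copysign(1.0, float(np.dot(centroids[lab] - p0, n_hat)))
        s = float(np.dot(center - p0, n_hat)) * side
        if abs(s) > radius * (1 + 1e-6):
            raise GeometryError(
                f"cell {lab}: fitted centre lies {abs(s):.2f} µm from the "
                f"chord but the fitted radius is only {radius:.2f} µm"
            )
        alphas.append(math.degrees(math.acos(max(-1.0, min(1.0, s / radius)))))
        centers.append(center)
        radii.append(radius)

    # diagnostic: intersection angle of the two fitted circles
    d_c = float(np.linalg.norm(centers[0] - centers[1]))
    r1, r2 = radii
    cosv = (r1 * r1 + r2 * r2 - d_c * d_c) / (2 * r1 * r2)
    theta_circ = (
        180.0 - math.degrees(math.acos(max(-1.0, min(1.0, cosv))))
        if abs(cosv) <= 1
        else float("nan")
    )
    return ContactAngleResult(
        alpha_deg=(alphas[0], alphas[1]),
        theta_pair_deg=alphas[0] + alphas[1],
        centers=np.asarray(centers),
        radii=(radii[0], radii[1]),
        chord_length=geo.chord_length,
        theta_circles_deg=theta_circ,
    )


def enrichment_fraction(
    mask: LabelMask,
    stack: ImageStack,
    channel: str,
    cell: int = 1,
    band_width: float | None = None,
    interface_dilation: float | None = None,
    subtract_background: bool = True,
) -> EnrichmentResult:
    """Fraction of a membrane channel's signal at the cell-cell interface.

    The membrane band is the set of pixels within ``band_width/2`` of the
    cell's boundary (default band_width: 3 px); the interface band is its
    subset within ``interface_dilation`` of the other cell (default: 2 px).
    ``f = interface signal / total membrane-band signal``.

    With ``subtract_background`` (default) the mean intensity of pixels
    far from every cell is subtracted before summing — without it, camera
    noise floors inflate the membrane-band total and bias f toward the
    band-area ratio.  The fraction is clipped to [0, 1].

    Raises
    ------
    GeometryError
        If the membrane band carries no signal at all.
    """
    labels = mask.labels
    if cell not in labels:
        raise GeometryError(f"label {cell} not present in mask (labels {labels})")
    plane = mask.plane()
    _, dy, dx = mask.voxel_size
    if band_width is None:
        band_width = 3.0 * dy
    if interface_dilation is None:
        interface_dilation = 2.0 * dy

    m = plane == cell
    others = (plane > 0) & ~m
    img = stack.channel(channel)[0]

    # EDT measures centre-to-centre distance; the true mask boundary lies
    # half a pixel before the first opposite-phase centre, so shift by dy/2
    inside = ndimage.distance_transform_edt(m, sampling=(dy, dx)) - dy / 2
    outside = ndimage.distance_transform_edt(~m, sampling=(dy, dx)) - dy / 2
    half = band_width / 2
    band = (m & (inside <= half)) | (~m & (outside <= half))

    d_other = ndimage.distance_transform_edt(~others, sampling=(dy, dx)) - dy / 2
    iface_band = band & (d_other <= interface_dilation)

    img = img.astype(float)
    if subtract_background:
        d_any = ndimage.distance_transform_edt(
            ~(plane > 0), sampling=(dy, dx)
        )
        far = d_any > 2 * band_width
        if far.any():
            img = img - img[far].mean()

    total = float(img[band].sum())
    if total <= 0:
        raise GeometryError("membrane band carries zero total signal")
    interface = float(img[iface_band].sum())
    return EnrichmentResult(
        f=float(np.clip(interface / total, 0.0, 1.0)),
        interface_signal=interface,
        total_membrane_signal=total,
        band_width=band_width,
        interface_dilation=interface_dilation,
    )
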