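"""Synthetic fluorescence-microscopy fixtures with exact ground truth.

Every input class the metric modules consume can be generated here:

* two-cell doublets with a lens-shaped interface and a membrane channel
  whose interface enrichment is set exactly (:func:`make_cell_pair`);
* spreading footprints following the power law ``A = b * t**alpha`` in an
  expansive (disc) or protrusive ("fried egg": disc plus thin radial rays)
  morphology (:func:`make_spreading_series`);
* two-channel 3D spheroids in mixed, core-shell or bilobed configurations
  at anisotropic voxel size (:func:`make_assembly_stack`) plus a continuous
  solid core-shell phantom (:func:`make_solid_core_shell`);
* centroid sets realizing alternating / bridging / cyclic contact patterns
  with exactly enumerated adjacency truth (:func:`make_contact_pattern`).

All generators are deterministic under a fixed seed, and each returns the
closed-form truth of every quantity the corresponding metric estimates, so
estimator accuracy can be asserted without any external data.

Default intensities before noise: background 0, cytosol 100, membrane 200.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import PackingError, ParameterError
from .imaging import BinaryMask, ImageStack

__all__ = [
    "PairParams",
    "PairTruth",
    "SpreadParams",
    "SpreadFrameTruth",
    "SpreadTruth",
    "AssemblyParams",
    "AssemblyTruth",
    "PatternParams",
    "PatternTruth",
    "lens_geometry",
    "make_cell_pair",
    "make_spreading_series",
    "make_assembly_stack",
    "make_solid_core_shell",
    "make_contact_pattern",
]

CYTO_LEVEL = 100.0
MEMBRANE_LEVEL = 200.0


# ---------------------------------------------------------------------------
# lens geometry (closed-form oracle for doublet interfaces)
# ---------------------------------------------------------------------------

def lens_geometry(r1: float, r2: float, d: float) -> dict[str, float]:
    """Closed-form geometry of two overlapping circles (a "lens").

    With centre separation ``d`` the radical chord sits at distance
    ``a1 = (d² + r1² − r2²) / 2d`` from centre 1 (``a2 = d − a1`` from
    centre 2) and the half-chord is ``h = sqrt(r1² − a1²)``.  The per-cell
    contact angle is ``alpha_i = arccos(a_i / r_i)`` and the pair contact
    angle their sum.  For a tangent or separated pair (``d ≥ r1 + r2``) all
    angles and the chord are zero.

    Returns a dict with keys ``a1, a2, h, chord, alpha1_deg, alpha2_deg,
    theta_deg, free_arc1, free_arc2`` (free arc = boundary length of the
    cell outside the interface).
    """
    if r1 <= 0 or r2 <= 0 or d <= 0:
        raise ParameterError("radii and separation must be positive")
    if d <= abs(r1 - r2):
        raise ParameterError(
            "one circle engulfs the other (d <= |r1 - r2|): not a doublet"
        )
    if d >= r1 + r2:
        return {
            "a1": r1, "a2": r2, "h": 0.0, "chord": 0.0,
            "alpha1_deg": 0.0, "alpha2_deg": 0.0, "theta_deg": 0.0,
            "free_arc1": 2 * math.pi * r1, "free_arc2": 2 * math.pi * r2,
        }
    a1 = (d * d + r1 * r1 - r2 * r2) / (2 * d)
    a2 = d - a1
    h = math.sqrt(max(r1 * r1 - a1 * a1, 0.0))
    alpha1 = math.acos(max(-1.0, min(1.0, a1 / r1)))
    alpha2 = math.acos(max(-1.0, min(1.0, a2 / r2)))
    return {
        "a1": a1,
        "a2": a2,
        "h": h,
        "chord": 2 * h,
        "alpha1_deg": math.degrees(alpha1),
        "alpha2_deg": math.degrees(alpha2),
        "theta_deg": math.degrees(alpha1 + alpha2),
        "free_arc1": r1 * (2 * math.pi - 2 * alpha1),
        "free_arc2": r2 * (2 * math.pi - 2 * alpha2),
    }


# ---------------------------------------------------------------------------
# cell pairs
# ---------------------------------------------------------------------------

@dataclass
class PairParams:
    """Parameters of a synthetic two-cell doublet (2D max-projection analog).

    ``enrichment_f`` is either the exact fraction of total membrane-channel
    signal to place on the interface chord band, or ``"uniform"`` for a
    uniformly painted membrane (the fraction is then fixed by arc lengths).
    ``noise_sd`` is Gaussian noise expressed as a fraction of each
    channel's foreground level; negative excursions are clipped at 0.
    """

    r1: float = 50.0
    r2: float = 50.0
    d: float = 50.0
    enrichment_f: float | str = "uniform"
    membrane_width: float = 1.6
    pixel_size: float = 0.4
    noise_sd: float = 0.0
    seed: int = 0
    cyto_overlap_um: float = 0.0  # widen each cytosol past the chord by this much

    def __post_init__(self) -> None:
        if self.d <= 0 or self.r1 <= 0 or self.r2 <= 0:
            raise ParameterError("r1, r2, d must be positive")
        if self.membrane_width <= 0 or self.pixel_size <= 0:
            raise ParameterError("membrane_width and pixel_size must be positive")
        if not isinstance(self.enrichment_f, str):
            f = float(self.enrichment_f)
            if not 0.0 <= f <= 1.0:
                raise ParameterError("enrichment_f must be in [0, 1]")
        elif self.enrichment_f != "uniform":
            raise ParameterError("enrichment_f must be a fraction or 'uniform'")


@dataclass
class PairTruth:
    """Exact ground truth of a generated doublet."""

    theta_deg: float
    alpha1_deg: float
    alpha2_deg: float
    chord_um: float
    f_true: float
    centers: np.ndarray = field(repr=False)  # (2, 2) (y, x) µm, canvas frame
    radii: tuple[float, float] = (0.0, 0.0)
    mask1: np.ndarray = field(default=None, repr=False)
    mask2: np.ndarray = field(default=None, repr=False)


def make_cell_pair(p: PairParams) -> tuple[ImageStack, PairTruth]:
    """Render a doublet with channels ``cyto1``, ``cyto2``, ``membrane``.

    Cell 1 occupies the circle-1 side of the radical chord, cell 2 the
    other side; the membrane channel paints a band of ``membrane_width``
    along cell 1's boundary, with the chord-band intensity scaled so the
    painted interface fraction equals ``enrichment_f`` exactly.
    """
    overlap = p.d < p.r1 + p.r2
    geom = lens_geometry(p.r1, p.r2, p.d)
    if not overlap and not (
        p.enrichment_f == "uniform" or float(p.enrichment_f) == 0.0
    ):
        raise ParameterError(
            "non-overlapping circles cannot carry interface enrichment"
        )

    px = p.pixel_size
    w = p.membrane_width
    margin = w + 4 * px
    x_lo, x_hi = -p.r1 - margin, p.d + p.r2 + margin
    r_max = max(p.r1, p.r2)
    y_lo, y_hi = -r_max - margin, r_max + margin
    nx = int(math.ceil((x_hi - x_lo) / px))
    ny = int(math.ceil((y_hi - y_lo) / px))
    # voxel-centre coordinates in the circle frame (centre 1 at origin)
    xs = x_lo + (np.arange(nx) + 0.5) * px
    ys = y_lo + (np.arange(ny) + 0.5) * px
    X, Y = np.meshgrid(xs, ys)

    in1 = X * X + Y * Y <= p.r1 * p.r1
    in2 = (X - p.d) ** 2 + Y * Y <= p.r2 * p.r2
    a1 = geom["a1"]
    if overlap:
        mask1 = in1 & (X <= a1)
        mask2 = in2 & (X > a1)
        ov = p.cyto_overlap_um / 2
        cyto1 = in1 & (X <= a1 + ov)
        cyto2 = in2 & (X > a1 - ov)
    else:
        mask1, mask2 = in1, in2
        cyto1, cyto2 = in1, in2

    rho1 = np.hypot(X, Y)
    band = np.abs(rho1 - p.r1) <= w / 2
    if overlap:
        h = geom["h"]
        chord_band = (np.abs(X - a1) <= w / 2) & (np.abs(Y) <= h)
        free_band = band & (X <= a1) & ~chord_band
    else:
        chord_band = np.zeros_like(band)
        free_band = band

    membrane = np.zeros_like(X)
    n_free = int(free_band.sum())
    n_chord = int(chord_band.sum())
    if p.enrichment_f == "uniform":
        membrane[free_band] = MEMBRANE_LEVEL
        membrane[chord_band] = MEMBRANE_LEVEL
        f_true = (
            geom["chord"] / (geom["chord"] + geom["free_arc1"]) if overlap else 0.0
        )
    else:
        f = float(p.enrichment_f)
        if f == 0.0:
            membrane[free_band] = MEMBRANE_LEVEL
            f_true = 0.0
        elif f == 1.0:
            membrane[chord_band] = MEMBRANE_LEVEL
            f_true = 1.0
        else:
            if n_chord == 0:
                raise ParameterError("interface band is empty; cannot place signal")
            # scale chord intensity so painted fraction equals f exactly
            k = f * n_free / ((1.0 - f) * n_chord)
            membrane[free_band] = MEMBRANE_LEVEL
            membrane[chord_band] = MEMBRANE_LEVEL * k
            s_i = MEMBRANE_LEVEL * k * n_chord
            f_true = s_i / (s_i + MEMBRANE_LEVEL * n_free)

    channels = {
        "cyto1": np.where(cyto1, CYTO_LEVEL, 0.0),
        "cyto2": np.where(cyto2, CYTO_LEVEL, 0.0),
        "membrane": membrane,
    }
    if p.noise_sd > 0:
        rng = np.random.default_rng(p.seed)
        for name, img in channels.items():
            level = CYTO_LEVEL if name.startswith("cyto") else MEMBRANE_LEVEL
            img = img + rng.normal(0.0, p.noise_sd * level, img.shape)
            channels[name] = np.clip(img, 0.0, None)
    channels = {k: v.astype(np.float32)[None] for k, v in channels.items()}

    # canvas-frame centres (y, x) in µm, voxel-centre convention
    centers = np.array([[0.0 - y_lo, 0.0 - x_lo], [0.0 - y_lo, p.d - x_lo]])
    truth = PairTruth(
        theta_deg=geom["theta_deg"],
        alpha1_deg=geom["alpha1_deg"],
        alpha2_deg=geom["alpha2_deg"],
        chord_um=geom["chord"],
        f_true=f_true,
        centers=centers,
        radii=(p.r1, p.r2),
        mask1=mask1[None],
        mask2=mask2[None],
    )
    return ImageStack(channels, (1.0, px, px)), truth


# ---------------------------------------------------------------------------
# spreading footprints
# ---------------------------------------------------------------------------

@dataclass
class SpreadParams:
    """Parameters of a synthetic spreading time series.

    ``b`` is the spreading-rate coefficient in µm²·min^-alpha and ``alpha``
    the kinetic exponent of the footprint-area law ``A = b * t**alpha``.
    Protrusive mode renders a central disc holding 70% of the area plus
    ``n_rays`` thin radial rays holding the remaining 30% (a "fried egg").
    """

    b: float = 100.0
    alpha: float = 0.25
    shape_mode: str = "expansive"  # or "protrusive"
    n_rays: int = 8
    ray_width: float = 2.0
    times: tuple[float, ...] = tuple(float(t) for t in range(5, 125, 5))
    pixel_size: float = 0.25
    seed: int = 0
    canvas_um: float | None = None

    def __post_init__(self) -> None:
        if self.b < 0:
            raise ParameterError("b must be >= 0")
        t = np.asarray(self.times, dtype=float)
        if t.size == 0 or np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ParameterError("times must be strictly increasing and positive")
        if self.shape_mode not in ("expansive", "protrusive"):
            raise ParameterError(f"unknown shape_mode {self.shape_mode!r}")
        if self.shape_mode == "protrusive" and (self.n_rays < 1 or self.ray_width <= 0):
            raise ParameterError("protrusive mode needs n_rays >= 1, ray_width > 0")


@dataclass
class SpreadFrameTruth:
    t: float
    area: float
    perimeter: float
    circularity: float


@dataclass
class SpreadTruth:
    b: float
    alpha: float
    shape_mode: str
    frames: list[SpreadFrameTruth]


def _protrusive_geometry(A: float, n_rays: int, w: float) -> dict[str, float]:
    """Closed-form composite geometry of the disc-plus-rays footprint.

    The core disc holds 0.7*A.  Each ray is a rectangle of width ``w``
    whose inner edge is the chord of the core circle at distance
    ``x0 = sqrt(R0² − (w/2)²)`` (so the union is simply connected) and
    whose length is chosen so the ray area *outside* the disc is exactly
    0.3*A/n_rays, making the union area exactly A.
    """
    A_core = 0.7 * A
    R0 = math.sqrt(A_core / math.pi)
    if w / 2 >= R0:
        raise ParameterError("ray_width exceeds core disc diameter")
    theta_h = math.asin((w / 2) / R0)
    x0 = math.sqrt(R0 * R0 - (w / 2) ** 2)
    seg = R0 * R0 * theta_h - x0 * w / 2  # circular segment beyond the chord
    L = (0.3 * A / n_rays + seg) / w
    perimeter = (2 * math.pi - 2 * n_rays * theta_h) * R0 + n_rays * (2 * L + w)
    return {"R0": R0, "x0": x0, "L": L, "perimeter": perimeter}


def protrusive_polygon(A: float, n_rays: int, w: float, n_arc: int = 2048) -> np.ndarray:
    """Explicit (x, y) polygon of the protrusive footprint (oracle helper).

    Arcs are discretized with ``n_arc`` vertices over the full circle; the
    shoelace area/perimeter of this polygon converge to the closed forms.
    """
    g = _protrusive_geometry(A, n_rays, w)
    R0, x0, L = g["R0"], g["x0"], g["L"]
    theta_h = math.asin((w / 2) / R0)
    pts: list[tuple[float, float]] = []
    for k in range(n_rays):
        phi = 2 * math.pi * k / n_rays
        c, s = math.cos(phi), math.sin(phi)

        def ray_pt(u: float, v: float) -> tuple[float, float]:
            return (u * c - v * s, u * s + v * c)

        # CCW: enter the ray at v=-w/2, go out, across the tip, back in
        pts.append(ray_pt(x0, -w / 2))
        pts.append(ray_pt(x0 + L, -w / 2))
        pts.append(ray_pt(x0 + L, w / 2))
        pts.append(ray_pt(x0, w / 2))
        # arc from phi + theta_h to phi + 2*pi/n_rays - theta_h
        a0 = phi + theta_h
        a1 = phi + 2 * math.pi / n_rays - theta_h
        n_seg = max(int(n_arc * (a1 - a0) / (2 * math.pi)), 2)
        for a in np.linspace(a0, a1, n_seg, endpoint=False)[1:]:
            pts.append((R0 * math.cos(a), R0 * math.sin(a)))
    return np.asarray(pts)


def make_spreading_series(p: SpreadParams) -> tuple[list[BinaryMask], SpreadTruth]:
    """Render one binary footprint per timepoint with exact truth.

    Truth records, per frame, the exact area ``b * t**alpha`` and the
    closed-form perimeter and circularity of the continuous shape.
    """
    times = [float(t) for t in p.times]
    areas = [p.b * t ** p.alpha for t in times]
    # outer extent of the largest frame
    if p.shape_mode == "expansive":
        r_out = math.sqrt(max(areas) / math.pi)
    else:
        g = _protrusive_geometry(max(areas), p.n_rays, p.ray_width)
        r_out = g["x0"] + g["L"]
    need = 2 * (r_out + 3.0)
    if p.canvas_um is not None and p.canvas_um < need:
        raise ParameterError(
            f"canvas {p.canvas_um} µm too small; need >= {need:.1f} µm"
        )
    side = p.canvas_um if p.canvas_um is not None else need
    n = int(math.ceil(side / p.pixel_size))
    coords = (np.arange(n) + 0.5) * p.pixel_size - side / 2
    X, Y = np.meshgrid(coords, coords)

    masks: list[BinaryMask] = []
    frames: list[SpreadFrameTruth] = []
    for t, A in zip(times, areas):
        if p.shape_mode == "expansive":
            R = math.sqrt(A / math.pi)
            mask = X * X + Y * Y <= R * R
            perim = 2 * math.pi * R
        else:
            g = _protrusive_geometry(A, p.n_rays, p.ray_width)
            R0, x0, L, perim = g["R0"], g["x0"], g["L"], g["perimeter"]
            mask = X * X + Y * Y <= R0 * R0
            for k in range(p.n_rays):
                phi = 2 * math.pi * k / p.n_rays
                U = X * math.cos(phi) + Y * math.sin(phi)
                V = -X * math.sin(phi) + Y * math.cos(phi)
                mask |= (U >= x0) & (U <= x0 + L) & (np.abs(V) <= p.ray_width / 2)
        masks.append(BinaryMask(mask, (1.0, p.pixel_size, p.pixel_size)))
        frames.append(
            SpreadFrameTruth(
                t=t,
                area=A,
                perimeter=perim,
                circularity=perim * perim / (4 * math.pi * A),
            )
        )
    return masks, SpreadTruth(p.b, p.alpha, p.shape_mode, frames)


# ---------------------------------------------------------------------------
# 3D assemblies (sorting-assay spheroids)
# ---------------------------------------------------------------------------

@dataclass
class AssemblyParams:
    """Parameters of a synthetic two-channel spheroid.

    Defaults model a small L929 aggregate: ~12 µm cell diameter, ~40 cells
    in a ball of 60 µm radius, imaged with a 10 µm z-step over 0.6 µm
    pixels (strongly anisotropic voxels).
    """

    configuration: str = "mixed"  # mixed | core_shell | bilobed
    n_per_channel: tuple[int, int] = (20, 20)
    cell_radius: float = 6.0
    assembly_radius: float = 60.0
    voxel_size: tuple[float, float, float] = (10.0, 0.6, 0.6)
    seed: int = 0
    channel_names: tuple[str, str] = ("chA", "chB")
    max_attempts: int = 10_000

    def __post_init__(self) -> None:
        if self.configuration not in ("mixed", "core_shell", "bilobed"):
            raise ParameterError(f"unknown configuration {self.configuration!r}")
        if min(self.n_per_channel) < 0 or max(self.n_per_channel) < 1:
            raise ParameterError("n_per_channel must include at least one cell")
        if not 0 < self.cell_radius < self.assembly_radius:
            raise ParameterError("need 0 < cell_radius < assembly_radius")


@dataclass
class AssemblyTruth:
    centers: np.ndarray = field(repr=False)  # (n, 3) (z, y, x) µm, grid frame
    channels: list[str] = field(default_factory=list)
    cell_radius: float = 0.0
    configuration: str = ""
    expected_sign: str = ""  # 'positive' for S(shell, core) > 0, else 'near-zero'


def _sample_ball(rng: np.random.Generator, r_lo: float, r_hi: float) -> np.ndarray:
    """Uniform point in the spherical shell r_lo <= r <= r_hi."""
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    u = rng.random()
    r = (r_lo**3 + u * (r_hi**3 - r_lo**3)) ** (1.0 / 3.0)
    return v * r


def make_assembly_stack(p: AssemblyParams) -> tuple[ImageStack, AssemblyTruth]:
    """Place non-overlapping spheres per configuration and voxelize them.

    Channel A of a core-shell assembly is confined to the core (centre
    radius < assembly_radius/2), channel B to the shell; mixed interleaves
    both uniformly; bilobed puts A and B in opposite half-balls.  Placement
    is seeded rejection sampling with minimum centre distance
    ``2 * cell_radius``; a :class:`PackingError` is raised after
    ``max_attempts`` failed draws.
    """
    rng = np.random.default_rng(p.seed)
    R, rc = p.assembly_radius, p.cell_radius
    r_free = R - rc
    n_a, n_b = p.n_per_channel

    def region(channel: int) -> tuple[float, float, int]:
        # (r_lo, r_hi, half-space sign or 0)
        if p.configuration == "mixed":
            return 0.0, r_free, 0
        if p.configuration == "core_shell":
            return (0.0, R / 2, 0) if channel == 0 else (R / 2, r_free, 0)
        return (0.0, r_free, -1) if channel == 0 else (0.0, r_free, +1)

    centers: list[np.ndarray] = []
    chans: list[str] = []
    attempts = 0
    for ch_idx, n_cells in ((0, n_a), (1, n_b)):
        r_lo, r_hi, half = region(ch_idx)
        placed = 0
        while placed < n_cells:
            if attempts >= p.max_attempts:
                raise PackingError(
                    f"could not place {n_a + n_b} cells of radius {rc} in "
                    f"{p.configuration} configuration after {p.max_attempts} "
                    "attempts; try fewer cells or a smaller cell_radius"
                )
            attempts += 1
            c = _sample_ball(rng, r_lo, r_hi)
            if half and np.sign(c[0]) != half and c[0] != 0:
                continue
            if any(np.linalg.norm(c - q) < 2 * rc for q in centers):
                continue
            centers.append(c)
            chans.append(p.channel_names[ch_idx])
            placed += 1

    dz, dy, dx = p.voxel_size
    n_z = int(math.ceil(2 * R / dz))
    n_y = int(math.ceil(2 * R / dy))
    n_x = int(math.ceil(2 * R / dx))
    zc = (np.arange(n_z) + 0.5) * dz
    yc = (np.arange(n_y) + 0.5) * dy
    xc = (np.arange(n_x) + 0.5) * dx
    offset = np.array([n_z * dz / 2, n_y * dy / 2, n_x * dx / 2])

    vols = {
        name: np.zeros((n_z, n_y, n_x), dtype=np.float32)
        for name in p.channel_names
    }
    centers_grid = np.asarray(
        [np.array([c[0], c[1], c[2]]) + offset for c in centers]
    ) if centers else np.zeros((0, 3))
    # centres were sampled as (x?, ...); treat sampled axes as (z, y, x)
    for c, name in zip(centers_grid, chans):
        z0, y0, x0 = c
        iz = np.nonzero(np.abs(zc - z0) <= rc)[0]
        iy = np.nonzero(np.abs(yc - y0) <= rc)[0]
        ix = np.nonzero(np.abs(xc - x0) <= rc)[0]
        if iz.size == 0 or iy.size == 0 or ix.size == 0:
            continue
        ZZ, YY, XX = np.meshgrid(zc[iz], yc[iy], xc[ix], indexing="ij")
        inside = (ZZ - z0) ** 2 + (YY - y0) ** 2 + (XX - x0) ** 2 <= rc * rc
        sub = vols[name][np.ix_(iz, iy, ix)]
        sub[inside] = CYTO_LEVEL
        vols[name][np.ix_(iz, iy, ix)] = sub

    stack = ImageStack(vols, p.voxel_size)
    truth = AssemblyTruth(
        centers=centers_grid,
        channels=chans,
        cell_radius=rc,
        configuration=p.configuration,
        expected_sign="positive" if p.configuration == "core_shell" else "near-zero",
    )
    return stack, truth


def make_solid_core_shell(
    core_radius: float = 20.0,
    shell_radius: float = 40.0,
    voxel_size: tuple[float, float, float] = (10.0, 0.6, 0.6),
) -> dict[str, BinaryMask]:
    """Voxelized continuous core-shell phantom (no individual cells).

    Channel ``core`` fills r < core_radius, channel ``shell`` fills
    core_radius <= r < shell_radius; in the continuous limit with
    equal-width radial bins the occupancy-weighted mean radii are
    ``core_radius/2`` and ``(core_radius + shell_radius)/2``.
    """
    if not 0 < core_radius < shell_radius:
        raise ParameterError("need 0 < core_radius < shell_radius")
    dz, dy, dx = voxel_size
    R = shell_radius
    n_z = int(math.ceil(2 * R / dz))
    n_y = int(math.ceil(2 * R / dy))
    n_x = int(math.ceil(2 * R / dx))
    zc = (np.arange(n_z) + 0.5) * dz - n_z * dz / 2
    yc = (np.arange(n_y) + 0.5) * dy - n_y * dy / 2
    xc = (np.arange(n_x) + 0.5) * dx - n_x * dx / 2
    ZZ, YY, XX = np.meshgrid(zc, yc, xc, indexing="ij", sparse=True)
    r2 = ZZ**2 + YY**2 + XX**2
    core = r2 < core_radius**2
    shell = (r2 >= core_radius**2) & (r2 < shell_radius**2)
    return {
        "core": BinaryMask(core, voxel_size),
        "shell": BinaryMask(shell, voxel_size),
    }


# ---------------------------------------------------------------------------
# contact patterns (centroid sets)
# ---------------------------------------------------------------------------

@dataclass
class PatternParams:
    """Parameters of a synthetic typed contact pattern."""

    pattern: str = "alternating"  # alternating | bridging | cyclic
    n_cells: int = 12
    spacing: float = 15.0
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in ("alternating", "bridging", "cyclic"):
            raise ParameterError(f"unknown pattern {self.pattern!r}")
        if self.n_cells < 2:
            raise ParameterError("n_cells must be >= 2")
        if self.spacing <= 0:
            raise ParameterError("spacing must be positive")
        if self.jitter_sd >= self.spacing / 2:
            raise ParameterError(
                "jitter_sd >= spacing/2 no longer guarantees the adjacency"
            )


@dataclass
class PatternTruth:
    """Exact contact-probability truth from enumerated adjacencies."""

    table: pd.DataFrame
    edges: list[tuple[int, int]]
    positions_exact: np.ndarray = field(repr=False)


def _cyclic_lattice(n: int, spacing: float) -> tuple[np.ndarray, list[str]]:
    """First ``n`` sites of a 3-coloured triangular lattice around the origin.

    Axial coordinates (q, r) map to the plane as
    ``spacing * (q + r/2, r * sqrt(3)/2)``; colouring ``(q - r) mod 3``
    gives every unit triangle one cell of each type.
    """
    k = int(math.ceil(math.sqrt(n))) + 2
    sites = []
    for q in range(-k, k + 1):
        for r in range(-k, k + 1):
            x = spacing * (q + r / 2)
            y = spacing * (r * math.sqrt(3) / 2)
            sites.append((x * x + y * y, r, q, x, y))
    sites.sort()
    chosen = sites[:n]
    pos = np.array([[s[3], s[4]] for s in chosen])
    types = ["ABC"[(s[2] - s[1]) % 3] for s in chosen]
    return pos, types


def make_contact_pattern(p: PatternParams) -> tuple[pd.DataFrame, PatternTruth]:
    """Generate a typed centroid set realizing a named contact pattern.

    Returns a centroid table (columns ``id, x_um, y_um, z_um, type``) and
    the exact interaction-probability truth enumerated from the jitter-free
    adjacencies.  Patterns: ``alternating`` is an A/B checker chain,
    ``bridging`` an A-B-C-B... chain (B bridges A and C, A never touches
    C), ``cyclic`` a triangular A-B-C tiling in which every unit triangle
    contains all three types.
    """
    s = p.spacing
    if p.pattern == "alternating":
        pos = np.array([[i * s, 0.0] for i in range(p.n_cells)])
        types = ["AB"[i % 2] for i in range(p.n_cells)]
    elif p.pattern == "bridging":
        seq = "ABCB"
        pos = np.array([[i * s, 0.0] for i in range(p.n_cells)])
        types = [seq[i % 4] for i in range(p.n_cells)]
    else:
        pos, types = _cyclic_lattice(p.n_cells, s)

    # exact adjacency: lattice neighbours sit at distance exactly `spacing`
    edges = []
    for i in range(p.n_cells):
        for j in range(i + 1, p.n_cells):
            if np.linalg.norm(pos[i] - pos[j]) <= s * (1 + 1e-9):
                edges.append((i, j))

    type_names = sorted(set(types))
    counts = pd.DataFrame(0.0, index=type_names, columns=type_names)
    for i, j in edges:
        a, b = sorted((types[i], types[j]))
        counts.loc[a, b] += 1
        if a != b:
            counts.loc[b, a] += 1
    # probability over unordered pairs: symmetric entries mirror one count
    n_edges = len(edges)
    table = counts / n_edges if n_edges else counts

    jittered = pos.copy()
    if p.jitter_sd > 0:
        rng = np.random.default_rng(p.seed)
        jittered = pos + rng.normal(0.0, p.jitter_sd, pos.shape)

    cells = pd.DataFrame(
        {
            "id": np.arange(p.n_cells),
            "x_um": jittered[:, 0],
            "y_um": jittered[:, 1],
            "z_um": 0.0,
            "type": types,
        }
    )
    return cells, PatternTruth(table=table, edges=edges, positions_exact=pos)
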