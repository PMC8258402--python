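"""Analytic ground-truth curves and their rasterized vessel masks.

These phantoms stand in for manually delineated perforating arteries:
each curve family has a closed-form (or high-resolution quadrature)
arc length, chord, and critical-point count, so every downstream stage
of the pipeline — skeletonization, path extraction, tortuosity metrics —
can be checked against exact values.

Curves are sampled uniformly in *arc length*, not in the curve
parameter, so that rasterization density is even along the vessel the
way a pixel-wise manual tracing is.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, interpolate

from .types import Centerline, VesselMask

_DENSITY_FACTOR = 200   # dense-grid oversampling for quadrature / resampling


class CurveFamily(str, enum.Enum):
    STRAIGHT = "straight"
    CIRCULAR_ARC = "circular_arc"
    SINUSOID = "sinusoid"
    SPLINE = "spline"


@dataclass(frozen=True)
class CurveSpec:
    """Recipe for one analytic planar curve.

    ``parameters`` are family-specific:

    * ``circular_arc`` — ``arc_angle`` (rad, subtended angle in (0, 2*pi))
    * ``sinusoid``     — ``amplitude`` (mm), ``n_half`` (half-waves, int >= 1)
    * ``spline``       — ``amplitude`` (mm, control-point jitter SD),
                         ``n_control`` (int >= 4)
    """

    family: CurveFamily | str
    chord_length: float = 10.0
    sample_count: int = 200
    parameters: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "family", CurveFamily(self.family))
        if self.chord_length <= 0:
            raise ValueError("chord_length must be positive")
        if self.sample_count < 2:
            raise ValueError("sample_count must be >= 2")
        if self.parameters.get("amplitude", 0.0) < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class CurveGroundTruth:
    """Exact quantities for a generated curve, used as test oracles."""

    arc_length: float
    chord: float
    dm_true: float
    critical_point_count_true: int


def _curve_xy(spec: CurveSpec):
    """Return (x(t), y(t)) on a dense parameter grid t in [0, 1] with the
    chord lying on the x-axis from (0, 0) to (chord, 0)."""
    c = spec.chord_length
    t = np.linspace(0.0, 1.0, spec.sample_count * _DENSITY_FACTOR + 1)
    fam = spec.family
    if fam is CurveFamily.STRAIGHT:
        return t * c, np.zeros_like(t)
    if fam is CurveFamily.CIRCULAR_ARC:
        phi = float(spec.parameters.get("arc_angle", np.pi))
        if not 0 < phi < 2 * np.pi:
            raise ValueError(f"arc_angle must be in (0, 2*pi), got {phi}")
        r = c / (2 * np.sin(phi / 2))
        # arc from (0,0) to (c,0), bulging toward +y
        ang = np.pi / 2 + phi / 2 - t * phi
        cx, cy = c / 2, -r * np.cos(phi / 2)
        return cx + r * np.cos(ang), cy + r * np.sin(ang)
    if fam is CurveFamily.SINUSOID:
        a = float(spec.parameters.get("amplitude", 1.0))
        k = int(spec.parameters.get("n_half", 2))
        if k < 1:
            raise ValueError("n_half must be >= 1")
        x = t * c
        return x, a * np.sin(k * np.pi * x / c)
    if fam is CurveFamily.SPLINE:
        a = float(spec.parameters.get("amplitude", 1.0))
        n_ctrl = int(spec.parameters.get("n_control", 6))
        if n_ctrl < 4:
            raise ValueError("n_control must be >= 4")
        rng = np.random.default_rng(spec.seed)
        xc = np.linspace(0.0, c, n_ctrl)
        yc = rng.normal(0.0, a, n_ctrl)
        yc[0] = yc[-1] = 0.0           # pin endpoints to the chord
        sp = interpolate.CubicSpline(xc, yc, bc_type="natural")
        x = t * c
        return x, sp(x)
    raise ValueError(f"unknown curve family: {fam}")


def _dy_dx(spec: CurveSpec):
    """Analytic dy/dx as a function of x, for graph-form families."""
    c = spec.chord_length
    if spec.family is CurveFamily.STRAIGHT:
        return lambda x: np.zeros_like(np.asarray(x, dtype=float))
    if spec.family is CurveFamily.SINUSOID:
        a = float(spec.parameters.get("amplitude", 1.0))
        k = int(spec.parameters.get("n_half", 2))
        w = k * np.pi / c
        return lambda x: a * w * np.cos(w * np.asarray(x, dtype=float))
    if spec.family is CurveFamily.SPLINE:
        a = float(spec.parameters.get("amplitude", 1.0))
        n_ctrl = int(spec.parameters.get("n_control", 6))
        rng = np.random.default_rng(spec.seed)
        xc = np.linspace(0.0, c, n_ctrl)
        yc = rng.normal(0.0, a, n_ctrl)
        yc[0] = yc[-1] = 0.0
        sp = interpolate.CubicSpline(xc, yc, bc_type="natural")
        return sp.derivative()
    return None


def _ground_truth(spec: CurveSpec) -> CurveGroundTruth:
    c = spec.chord_length
    fam = spec.family
    if fam is CurveFamily.STRAIGHT:
        return CurveGroundTruth(c, c, 1.0, 0)
    if fam is CurveFamily.CIRCULAR_ARC:
        phi = float(spec.parameters.get("arc_angle", np.pi))
        arc = c * phi / (2 * np.sin(phi / 2))
        # one apex: the chord-aligned slope changes sign once
        return CurveGroundTruth(arc, c, arc / c, 1)
    # graph-form families: quadrature of sqrt(1 + y'(x)^2), N from the
    # sign changes of y' on a dense grid
    dy = _dy_dx(spec)
    arc, _ = integrate.quad(
        lambda x: np.sqrt(1.0 + dy(x) ** 2), 0.0, c, limit=400
    )
    xs = np.linspace(0.0, c, spec.sample_count * _DENSITY_FACTOR + 1)
    slope = dy(xs)
    sign = np.sign(slope)
    sign = sign[sign != 0]
    n_crit = int(np.count_nonzero(np.diff(sign) != 0))
    return CurveGroundTruth(float(arc), c, float(arc) / c, n_crit)


def generate_curve(spec: CurveSpec) -> tuple[Centerline, CurveGroundTruth]:
    """Sample a curve of the given family at arc-length-uniform spacing.

    Returns the sampled centerline (with the chord on the x-axis) and
    its exact ground truth.  Degenerate flat curves (zero amplitude)
    collapse onto the straight-line truth automatically.
    """
    x, y = _curve_xy(spec)
    steps = np.hypot(np.diff(x), np.diff(y))
    s = np.concatenate([[0.0], np.cumsum(steps)])
    target = np.linspace(0.0, s[-1], spec.sample_count)
    xs = np.interp(target, s, x)
    ys = np.interp(target, s, y)
    truth = _ground_truth(spec)
    return Centerline(np.column_stack([xs, ys])), truth


def reference_curve_ladder() -> list[CurveSpec]:
    """A fixed panel of 20 analytic curves (arcs, sinusoids, splines)
    spanning the tortuosity range of real perforating arteries, used to
    validate the rasterize -> skeletonize -> measure chain end to end."""
    specs: list[CurveSpec] = []
    for phi in (0.4, 0.8, 1.2, 1.6, 2.0, 2.4, 2.8):
        specs.append(CurveSpec("circular_arc", chord_length=15.0,
                               sample_count=400,
                               parameters={"arc_angle": phi}))
    for amp, n_half in ((0.5, 1), (1.0, 1), (1.5, 2), (1.0, 2),
                        (2.0, 2), (1.5, 3), (2.5, 3)):
        specs.append(CurveSpec("sinusoid", chord_length=18.0,
                               sample_count=400,
                               parameters={"amplitude": amp,
                                           "n_half": n_half}))
    for seed in range(6):
        specs.append(CurveSpec("spline", chord_length=20.0, sample_count=400,
                               parameters={"amplitude": 1.0}, seed=seed))
    return specs


def rasterize_curve(
    curve: Centerline,
    spacing: float | tuple[float, float],
    width: int = 1,
    spur_count: int = 0,
    spur_length_px: int = 3,
    seed: int = 0,
    margin_px: int = 3,
    shape: tuple[int, int] | None = None,
) -> VesselMask:
    """Rasterize a centerline into a binary vessel mask.

    The curve is densely resampled so the marked pixel path is
    8-connected.  ``width`` > 1 dilates the path with a disk.  With
    ``spur_count`` > 0, short false branches (``spur_length_px`` pixels)
    are grown from random interior path pixels — emulating the spurs
    thinning introduces on a hand-traced delineation.

    If ``shape`` is given the canvas size is fixed and a curve that
    does not fit raises ``ValueError``; otherwise the canvas is sized
    to the curve plus ``margin_px``.
    """
    if isinstance(spacing, (int, float)):
        spacing = (float(spacing), float(spacing))
    if min(spacing) <= 0:
        raise ValueError("spacing must be positive")
    if width < 1:
        raise ValueError("width must be >= 1")
    pts = curve.points
    # resample at just under one pixel per step; Bresenham chaining below
    # keeps the stroke 8-connected without doubling pixels along diagonals
    step_mm = min(spacing) * 0.9
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    n_dense = max(int(np.ceil(s[-1] / step_mm)) + 1, 2)
    t = np.linspace(0.0, s[-1], n_dense)
    xd = np.interp(t, s, pts[:, 0])
    yd = np.interp(t, s, pts[:, 1])

    origin = (pts[:, 0].min() - margin_px * spacing[1],
              pts[:, 1].min() - margin_px * spacing[0])
    cols = np.rint((xd - origin[0]) / spacing[1]).astype(int)
    rows = np.rint((yd - origin[1]) / spacing[0]).astype(int)
    if shape is None:
        shape = (rows.max() + margin_px + 1, cols.max() + margin_px + 1)
    if rows.min() < 0 or cols.min() < 0 or rows.max() >= shape[0] or cols.max() >= shape[1]:
        raise ValueError("curve extends outside the requested canvas")

    # chain Bresenham segments between successive pixels so the stroke is
    # one pixel wide and 8-connected (nearest-pixel marking alone doubles
    # up along diagonals, which thinning then erodes at the vessel ends)
    from skimage.draw import line as _bres_line

    raster = np.zeros(shape, dtype=bool)
    raster[rows[0], cols[0]] = True
    for i in range(1, len(rows)):
        if rows[i] == rows[i - 1] and cols[i] == cols[i - 1]:
            continue
        rr, cc = _bres_line(rows[i - 1], cols[i - 1], rows[i], cols[i])
        raster[rr, cc] = True
    rows, cols = np.nonzero(raster)

    if width > 1:
        from skimage.morphology import dilation, disk

        raster = dilation(raster, disk(width // 2))

    if spur_count > 0:
        rng = np.random.default_rng(seed)
        path_px = np.unique(np.column_stack([rows, cols]), axis=0)
        interior = path_px[(path_px[:, 0] > spur_length_px)
                           & (path_px[:, 1] > spur_length_px)
                           & (path_px[:, 0] < shape[0] - spur_length_px - 1)
                           & (path_px[:, 1] < shape[1] - spur_length_px - 1)]
        idx = rng.choice(len(interior), size=min(spur_count, len(interior)),
                         replace=False)
        dirs = np.array([(-1, -1), (-1, 0), (-1, 1), (0, -1),
                         (0, 1), (1, -1), (1, 0), (1, 1)])
        for r0, c0 in interior[idx]:
            d = dirs[rng.integers(len(dirs))]
            for k in range(1, spur_length_px + 1):
                raster[r0 + k * d[0], c0 + k * d[1]] = True

    return VesselMask(raster, spacing, origin)
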