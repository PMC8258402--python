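"""Per-vessel tortuosity metrics and per-subject summaries.

The composite vessel tortuosity index combines local and global
centerline features:

    VTI = 0.1 * SD_theta * N * M * L_A / L_C

where SD_theta is the standard deviation of the tangent-line angles
along the centerline (degrees by default), N the number of critical
points (sign changes of the tangent slope), M the mean arc/chord ratio
over inflection segments, L_A the centerline path length, and L_C the
endpoint chord.  A straight vessel gives VTI = 0 (N = 0 and
SD_theta = 0); there is no upper bound.

Angles, critical points and inflections are computed in a chord-aligned
frame by default: the centerline is rotated so its endpoint chord lies
on the x-axis.  This makes every metric invariant to rigid motion of
the delineation; the raw image frame is available via ``align=False``.
"""

from __future__ import annotations

import numpy as np

from .types import Centerline, SubjectMorphometry, TortuosityMetrics

DEFAULT_WINDOW = 3


def chord_align(c: Centerline) -> Centerline:
    """Translate the start point to the origin and rotate the endpoint
    chord onto the +x axis."""
    pts = c.points - c.points[0]
    end = pts[-1]
    chord = np.linalg.norm(end)
    if chord == 0:
        raise ValueError("coincident endpoints: chord alignment undefined")
    cos, sin = end / chord
    rot = np.array([[cos, sin], [-sin, cos]])
    return Centerline(pts @ rot.T, c.source_spacing)


def vessel_length(c: Centerline) -> float:
    """Path length L_A: sum of Euclidean steps between consecutive points."""
    return float(np.linalg.norm(np.diff(c.points, axis=0), axis=1).sum())


def distance_metric(c: Centerline) -> float:
    """Conventional tortuosity DM = L_A / L_C (1 for a straight vessel)."""
    chord = c.chord
    if chord == 0:
        raise ValueError("coincident endpoints: distance metric undefined")
    return vessel_length(c) / chord


def _windowed_diffs(pts: np.ndarray, window: int) -> np.ndarray:
    """Finite-difference tangent vectors over +/- ``window`` points,
    one-sided at the ends."""
    n = len(pts)
    idx = np.arange(n)
    j0 = np.maximum(idx - window, 0)
    j1 = np.minimum(idx + window, n - 1)
    return pts[j1] - pts[j0]


def tangent_angles(
    c: Centerline, window: int = DEFAULT_WINDOW, align: bool = True,
    degrees: bool = True,
) -> np.ndarray:
    """Tangent-line angle at every centerline point.

    Angles are measured against the x-axis of the (chord-aligned by
    default) frame and unwrapped along the path so consecutive values
    never jump by more than half a turn.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(c) <= window:
        raise ValueError(
            f"centerline has {len(c)} points; needs more than window={window}"
        )
    pts = (chord_align(c) if align else c).points
    d = _windowed_diffs(pts, window)
    ang = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    return np.degrees(ang) if degrees else ang


def sd_theta(angles: np.ndarray) -> float:
    """Sample standard deviation (n-1) of the tangent angles."""
    angles = np.asarray(angles, dtype=float)
    if angles.size < 2:
        raise ValueError("need at least 2 angles")
    return float(np.std(angles, ddof=1))


def _sign_changes(values: np.ndarray, rel_tol: float = 1e-9
                  ) -> tuple[int, list[int]]:
    """Strict sign changes in a sequence, zero runs collapsed so a
    plateau contributes at most one candidate.  Returns the count and
    the indices (into ``values``) where the new sign first appears.

    Values within ``rel_tol`` of zero (relative to the largest
    magnitude) count as zero, so floating-point dust from a rigid
    motion cannot move a detected crossing."""
    values = np.asarray(values, dtype=float)
    scale = np.abs(values).max() if values.size else 0.0
    sign = np.sign(np.where(np.abs(values) <= rel_tol * scale, 0.0, values))
    nz = np.nonzero(sign)[0]
    if nz.size < 2:
        return 0, []
    flips = np.nonzero(np.diff(sign[nz]) != 0)[0]
    return int(flips.size), [int(nz[i + 1]) for i in flips]


def critical_points(
    c: Centerline, window: int = DEFAULT_WINDOW, align: bool = True,
) -> tuple[int, list[int]]:
    """Count N of critical points: locations where the slope of the
    tangent line changes sign (first derivative of the chord-aligned
    curve vanishes).  Returns (N, point indices)."""
    pts = (chord_align(c) if align else c).points
    d = _windowed_diffs(pts, window)
    # sign of the slope flips exactly where the tangent crosses
    # horizontal, i.e. where the y-component of the tangent changes sign
    return _sign_changes(d[:, 1])


def inflection_segments(
    c: Centerline, window: int = DEFAULT_WINDOW, align: bool = True,
    min_turn_deg: float = 10.0,
) -> list[Centerline]:
    """Split the centerline where the curvature changes sign.

    Segments cover the whole curve and overlap only at the cut points;
    endpoints always bound the first and last segment.

    A curvature-sign run only counts as a genuine bend if its
    integrated turning exceeds ``min_turn_deg``; weaker runs — the
    micro-wiggles digitization and tracing jitter leave on a vessel —
    are merged into their strongest neighbour.  Without this hysteresis
    the segment count explodes on rasterized centerlines and drags the
    curvature magnitude toward 1.
    """
    pts_aligned = (chord_align(c) if align else c).points
    d = _windowed_diffs(pts_aligned, window)
    ang = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
    turn = np.diff(ang)
    _, cuts = _sign_changes(turn)
    bounds = [0] + [i + 1 for i in cuts if 0 < i + 1 < len(c) - 1] + [len(c) - 1]
    bounds = sorted(set(bounds))

    def net_turn(a: int, b: int) -> float:
        return float(np.degrees(turn[a:b].sum()))

    # merge weak-turn segments until every remaining one is a real bend
    while len(bounds) > 2:
        turns = [abs(net_turn(a, b)) for a, b in zip(bounds[:-1], bounds[1:])]
        weakest = int(np.argmin(turns))
        if turns[weakest] >= min_turn_deg:
            break
        del bounds[weakest + 1 if weakest == 0 else weakest]

    segments = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if b - a >= 1:
            segments.append(Centerline(c.points[a:b + 1], c.source_spacing))
    return segments


def magnitude(
    c: Centerline, window: int = DEFAULT_WINDOW, align: bool = True,
) -> float:
    """Curvature magnitude M: mean arc/chord ratio over inflection
    segments (equal to DM when the curve has a single segment)."""
    ratios = []
    for seg in inflection_segments(c, window, align):
        chord = seg.chord
        if chord == 0:
            raise ValueError("inflection segment with coincident endpoints")
        ratios.append(vessel_length(seg) / chord)
    return float(np.mean(ratios))


def vti(
    c: Centerline, window: int = DEFAULT_WINDOW, align: bool = True,
    degrees: bool = True,
) -> float:
    """Composite vessel tortuosity index; exactly 0 when N = 0."""
    n_crit, _ = critical_points(c, window, align)
    if n_crit == 0:
        return 0.0
    sd = sd_theta(tangent_angles(c, window, align, degrees))
    m = magnitude(c, window, align)
    return 0.1 * sd * n_crit * m * vessel_length(c) / c.chord


def compute_metrics(
    c: Centerline, window: int = DEFAULT_WINDOW, align: bool = True,
    degrees: bool = True,
) -> TortuosityMetrics:
    """All per-vessel metrics in one pass."""
    vl = vessel_length(c)
    chord = c.chord
    n_crit, _ = critical_points(c, window, align)
    sd = sd_theta(tangent_angles(c, window, align, degrees))
    m = magnitude(c, window, align)
    value = 0.0 if n_crit == 0 else 0.1 * sd * n_crit * m * vl / chord
    return TortuosityMetrics(
        vl=vl, chord=chord, dm=vl / chord, sd_theta=sd,
        n_critical=n_crit, magnitude=m, vti=value,
    )


def summarize_subject(metrics: list[TortuosityMetrics]) -> SubjectMorphometry:
    """Per-subject vessel count plus mean/median/SD of VL, DM and VTI.

    SD uses the n-1 denominator; a single-vessel subject reports SD 0
    rather than NaN so no subject drops out of downstream statistics.
    """
    if not metrics:
        raise ValueError("cannot summarize an empty vessel list")
    out: dict[str, dict[str, float]] = {}
    for name in ("vl", "dm", "vti"):
        values = np.array([getattr(m, name) for m in metrics], dtype=float)
        sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
        out[name] = {
            "mean": float(values.mean()),
            "median": float(np.median(values)),
            "sd": sd,
        }
    return SubjectMorphometry(lsa_count=len(metrics), summaries=out)
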