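"""Core domain containers shared across the pipeline.

Physical coordinates are always millimetres.  A 2D raster is indexed
``[row, col]``; the physical position of pixel ``(r, c)`` is

    x = origin[0] + c * spacing[1]      (column axis)
    y = origin[1] + r * spacing[0]      (row axis)

i.e. ``spacing = (row_mm, col_mm)`` and ``origin`` is the physical
coordinate of the *centre* of pixel ``(0, 0)``.  Anisotropic spacing is
first-class: clinical minIP grids are typically 0.44 x 0.66 mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DisconnectedSkeletonError(ValueError):
    """Skeleton has more than one connected component."""

    def __init__(self, n_components: int):
        self.n_components = n_components
        super().__init__(
            f"skeleton has {n_components} connected components; expected 1"
        )


@dataclass(frozen=True)
class VesselMask:
    """Binary vessel delineation on a physical raster grid."""

    raster: np.ndarray                  # 2D bool
    spacing: tuple[float, float]        # (row mm, col mm)
    origin: tuple[float, float] = (0.0, 0.0)   # physical (x, y) of pixel (0,0)

    def __post_init__(self):
        raster = np.asarray(self.raster, dtype=bool)
        object.__setattr__(self, "raster", raster)
        if raster.ndim != 2:
            raise ValueError(f"raster must be 2D, got {raster.ndim}D")
        if not raster.any():
            raise ValueError("mask has no foreground pixels")
        if min(self.spacing) <= 0:
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    def pixel_to_physical(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """Map pixel indices to (x, y) mm using pixel centres."""
        x = self.origin[0] + np.asarray(cols) * self.spacing[1]
        y = self.origin[1] + np.asarray(rows) * self.spacing[0]
        return np.column_stack([x, y])


@dataclass(frozen=True)
class Centerline:
    """Ordered simple path of physical points — the object every
    tortuosity metric consumes."""

    points: np.ndarray                  # (n, 2) float, mm, ordered
    source_spacing: tuple[float, float] | None = None

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError(f"points must be (n, 2), got {pts.shape}")
        if len(pts) < 2:
            raise ValueError("centerline needs at least 2 points")
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError("consecutive centerline points must be distinct")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def chord(self) -> float:
        """Euclidean distance between the two endpoints (L_C)."""
        return float(np.linalg.norm(self.points[-1] - self.points[0]))


@dataclass(frozen=True)
class TortuosityMetrics:
    """Per-vessel tortuosity record.

    ``vl`` is the centerline path length L_A, ``chord`` the endpoint
    distance L_C, ``dm`` their ratio, ``sd_theta`` the SD of the tangent
    angles (degrees), ``n_critical`` the count of slope sign changes N,
    ``magnitude`` the mean arc/chord ratio over inflection segments M,
    and ``vti = 0.1 * sd_theta * n_critical * magnitude * vl / chord``.
    """

    vl: float
    chord: float
    dm: float
    sd_theta: float
    n_critical: int
    magnitude: float
    vti: float

    def __post_init__(self):
        if self.chord <= 0:
            raise ValueError("chord must be positive")
        if self.vl < self.chord * (1 - 1e-9):
            raise ValueError("path length cannot be shorter than its chord")
        if self.sd_theta < 0 or self.n_critical < 0 or self.vti < 0:
            raise ValueError("sd_theta, n_critical and vti must be non-negative")


@dataclass(frozen=True)
class SubjectMorphometry:
    """Per-subject summary: vessel count plus mean/median/SD of each metric."""

    lsa_count: int
    summaries: dict[str, dict[str, float]] = field(default_factory=dict)
    # summaries[metric][stat] for metric in {vl, dm, vti}, stat in {mean, median, sd}

    def as_row(self, prefix: str = "") -> dict[str, float]:
        row: dict[str, float] = {f"{prefix}lsa_count": self.lsa_count}
        for metric, stats in self.summaries.items():
            for stat, value in stats.items():
                row[f"{prefix}{stat}_{metric}"] = value
        return row


@dataclass(frozen=True)
class StatResult:
    """One statistical comparison, with its Bonferroni family bookkeeping."""

    comparison: str
    effect: float                       # group-mean difference or rank correlation
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    n: int = 0
    family: str = ""

    def adjusted(self, m: int) -> "StatResult":
        from dataclasses import replace

        return replace(self, p_adjusted=min(1.0, self.p_raw * m))
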