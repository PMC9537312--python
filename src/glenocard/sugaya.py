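"""Best-fit-circle (Sugaya) quantification of anterior glenoid bone loss.

The inferior glenoid approximates a circle when viewed en face.  A circle is
fitted to the traced inferior rim; the bone defect is the part of that circle
with no bone, and the defect ratio is D = A / S, with A the in-circle defect
area and S the circle area.  Severity follows the standard surgical grading:
small (< 5 %), medium (5–20 %), large (> 20 %).

The circle fit is the Taubin algebraic least-squares fit (exact on noise-free
circular data) refined by geometric least squares.  Region areas are computed
with shapely; the fitted disc is represented by a 1024-vertex inscribed
polygon (relative area error < 3e-5) for the polygon–circle intersection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import cached_property
from typing import Literal, Optional

import numpy as np
from scipy.optimize import least_squares
from shapely.geometry import Point, Polygon

from .errors import DegenerateInputError, DomainError, InvalidGeometryError

__all__ = [
    "RimTrace",
    "FitCircle",
    "DefectRegion",
    "DefectResult",
    "fit_circle",
    "polygon_area",
    "defect_fraction",
    "classify_severity",
    "disc_polygon",
]

#: vertices used to polygonize a disc (relative area error ~ 2*pi^2/(3*m^2))
DISC_VERTICES = 1024


@dataclass(frozen=True)
class RimTrace:
    """Ordered (x, y) points in mm tracing the intact inferior glenoid rim."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise DegenerateInputError(
                f"rim trace needs an (n >= 3, 2) point array, got shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise DegenerateInputError("rim trace contains non-finite coordinates")
        object.__setattr__(self, "points", pts)


@dataclass(frozen=True)
class FitCircle:
    """Fitted inferior-glenoid circle: centre and radius in mm."""

    center: tuple[float, float]
    radius: float
    rms_residual: float = 0.0

    def __post_init__(self) -> None:
        if self.radius <= 0 or not math.isfinite(self.radius):
            raise DomainError(f"circle radius must be positive and finite, got {self.radius}")
        if not math.isfinite(self.rms_residual) or self.rms_residual < 0:
            raise DomainError(f"rms_residual must be finite and >= 0, got {self.rms_residual}")

    @property
    def area_mm2(self) -> float:
        return math.pi * self.radius**2


@dataclass(frozen=True)
class DefectRegion:
    """Closed, non-self-intersecting polygon outlining the missing bone (mm).

    The first vertex is not repeated at the end; closure is implicit.
    """

    polygon: np.ndarray

    def __post_init__(self) -> None:
        verts = np.asarray(self.polygon, dtype=float)
        if verts.ndim != 2 or verts.shape[1] != 2 or verts.shape[0] < 3:
            raise InvalidGeometryError(
                f"defect outline needs an (n >= 3, 2) vertex array, got shape {verts.shape}"
            )
        if not np.all(np.isfinite(verts)):
            raise InvalidGeometryError("defect outline contains non-finite coordinates")
        if np.allclose(verts[0], verts[-1]):
            raise InvalidGeometryError(
                "first vertex repeated at the end; closure is implicit"
            )
        poly = Polygon(verts)
        if not poly.is_valid:
            raise InvalidGeometryError(
                "defect outline is self-intersecting or otherwise invalid"
            )
        if poly.area <= 0:
            raise InvalidGeometryError("defect outline encloses no area")
        object.__setattr__(self, "polygon", verts)

    @cached_property
    def shapely(self) -> Polygon:
        return Polygon(self.polygon)


@dataclass(frozen=True)
class DefectResult:
    """Defect quantification D = A / S with severity grading."""

    defect_fraction: float
    defect_area_mm2: float
    circle_area_mm2: float
    severity: Literal["small", "medium", "large"]
    method: str = "sugaya"

    @property
    def percent(self) -> float:
        return 100.0 * self.defect_fraction


def _taubin_fit(pts: np.ndarray) -> tuple[float, float, float]:
    """Taubin algebraic circle fit (Chernov's SVD formulation)."""
    mx, my = pts.mean(axis=0)
    x = pts[:, 0] - mx
    y = pts[:, 1] - my
    z = x * x + y * y
    zmean = z.mean()
    if zmean <= 0:
        raise DegenerateInputError("all rim points coincide")
    z0 = (z - zmean) / (2.0 * math.sqrt(zmean))
    m = np.column_stack([z0, x, y])
    _, s, vt = np.linalg.svd(m, full_matrices=False)
    a0, b, c = vt[2]
    a = a0 / (2.0 * math.sqrt(zmean))
    d = -zmean * a
    if abs(a) < 1e-12 / max(math.sqrt(zmean), 1e-30):
        raise DegenerateInputError("rim points are collinear; no finite circle fits")
    cx = -b / (2.0 * a)
    cy = -c / (2.0 * a)
    rad2 = cx * cx + cy * cy - d / a
    if rad2 <= 0 or not math.isfinite(rad2):
        raise DegenerateInputError("degenerate circle fit")
    return cx + mx, cy + my, math.sqrt(rad2)


def fit_circle(trace: RimTrace, refine: bool = True) -> FitCircle:
    """Least-squares circle through the rim trace.

    Taubin's algebraic fit provides the estimate (and the starting point for
    an optional geometric refinement minimizing the sum of squared radial
    distances).  Raises :class:`DegenerateInputError` for < 3 points or
    collinear input.
    """
    pts = trace.points
    # collinearity check: relative thickness of the point cloud
    centered = pts - pts.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[0] <= 0 or sv[-1] / sv[0] < 1e-9:
        raise DegenerateInputError("rim points are collinear; no finite circle fits")
    cx, cy, r = _taubin_fit(pts)
    if refine:
        def radial(p):
            return np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1]) - p[2]

        sol = least_squares(radial, x0=[cx, cy, r], method="lm")
        cx, cy, r = sol.x
    res = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) - r
    return FitCircle(
        center=(float(cx), float(cy)),
        radius=float(r),
        rms_residual=float(np.sqrt(np.mean(res**2))),
    )


def polygon_area(defect: DefectRegion) -> float:
    """Enclosed area in mm^2, independent of vertex orientation."""
    return float(defect.shapely.area)


def disc_polygon(circle: FitCircle, n_vertices: int = DISC_VERTICES) -> Polygon:
    """Inscribed regular-polygon approximation of the fitted disc."""
    return Point(*circle.center).buffer(circle.radius, quad_segs=n_vertices // 4)


def classify_severity(d: float) -> Literal["small", "medium", "large"]:
    """Surgical severity grade: small (< 5 %), medium (5–20 %), large (> 20 %).

    The boundaries 5 % and 20 % are assigned to 'medium' (the inclusive
    reading of the 5–20 % band).
    """
    if not 0.0 <= d <= 1.0 or not math.isfinite(d):
        raise DomainError(f"defect fraction must lie in [0, 1], got {d}")
    if d < 0.05:
        return "small"
    if d <= 0.20:
        return "medium"
    return "large"


def defect_fraction(
    circle: FitCircle, defect: Optional[DefectRegion], method: str = "sugaya"
) -> DefectResult:
    """Defect ratio D = A / S of the fitted circle.

    A is the area of the defect polygon clipped to the fitted disc (a defect
    extending past the best-fit circle contributes only its in-disc part);
    S = pi R^2.  ``defect=None`` means no missing bone (D = 0).
    """
    s = circle.area_mm2
    if defect is None:
        a = 0.0
    else:
        inter = defect.shapely.intersection(disc_polygon(circle))
        a = float(inter.area)
    d = min(a / s, 1.0)
    return DefectResult(
        defect_fraction=d,
        defect_area_mm2=a,
        circle_area_mm2=s,
        severity=classify_severity(d),
        method=method,
    )
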