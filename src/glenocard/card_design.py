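"""Equal-area comparison-card geometry.

The comparison card is a transparent circular overlay used to read anterior
glenoid bone loss directly as a percentage.  A disc of radius ``r`` is split
into ``n`` vertical strips of equal area per quadrant, and each strip is
halved by a horizontal line, giving ``8 n`` grid cells that each hold exactly
``1/(8 n)`` of the disc area (2.5 % for the standard 50 mm card with
``n = 5``).  Because every cell covers the same known fraction, counting the
cells that fall inside a bone defect converts directly into a defect
percentage with no planimetry software.

The vertical cut abscissae ``k_1 < k_2 < ... < k_{n-1}`` solve the
quarter-circle area equation

    integral_0^{k_i} sqrt(r^2 - x^2) dx = i * pi r^2 / (4 n),

whose antiderivative is ``F(x) = x sqrt(r^2 - x^2)/2 + (r^2/2) asin(x/r)``.
The horizontal split ordinate of each strip solves the arc-aware condition
``area below y within the strip = pi r^2 / (8 n)``: in inner strips the arc
clears the split line and the ordinate reduces to the rectangle rule
``y = (pi r^2 / 8 n) / (strip width)``; in the outermost strip the arc dips
below the candidate line and the full piecewise form must be solved by
root-finding.  Both equations involve strictly monotone area functions, so
bracketed root-finding (Brent) is guaranteed to converge.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
from scipy.optimize import brentq

from .errors import DomainError

__all__ = [
    "CardSpec",
    "QuarterPartition",
    "GridCell",
    "CardGeometry",
    "quarter_area_integral",
    "solve_cut_points",
    "strip_area_below",
    "solve_split_ordinates",
    "build_card",
    "export_svg",
]

# Absolute area residual accepted by the solvers, in units of r^2.
AREA_TOL = 1e-10

# Number of canonical chord vertices used when a circle/arc is polygonized.
# A regular m-gon inscribed in a disc underestimates its area by a relative
# (2 pi^2)/(3 m^2); for m = 1024 that is < 3e-5.
ARC_RESOLUTION = 1024

_QUADRANT_SIGNS = {1: (1.0, 1.0), 2: (-1.0, 1.0), 3: (-1.0, -1.0), 4: (1.0, -1.0)}


def quarter_area_integral(x: float, r: float) -> float:
    """Area under the quarter-circle arc ``sqrt(r^2 - t^2)`` from 0 to ``x``.

    Closed form ``F(x) = x sqrt(r^2 - x^2)/2 + (r^2/2) asin(x/r)``; strictly
    increasing from ``F(0) = 0`` to ``F(r) = pi r^2 / 4``.
    """
    if r <= 0:
        raise DomainError(f"radius must be positive, got {r}")
    if not 0.0 <= x <= r:
        raise DomainError(f"abscissa {x} outside [0, {r}]")
    return 0.5 * x * math.sqrt(r * r - x * x) + 0.5 * r * r * math.asin(x / r)


def solve_cut_points(r: float, n: int) -> list[float]:
    """Abscissae splitting the quarter disc into ``n`` equal-area vertical strips.

    The i-th cut solves ``F(k_i) = i * pi r^2 / (4 n)``.  Solved on the unit
    circle and scaled by ``r`` (the partition is scale-equivariant), with a
    bracketed Brent root-find on the monotone ``F``.
    """
    if r <= 0:
        raise DomainError(f"radius must be positive, got {r}")
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise DomainError(f"strips per quadrant must be a positive integer, got {n}")
    quarter = math.pi / 4.0
    cuts = []
    for i in range(1, n):
        target = i * quarter / n
        k = brentq(
            lambda x: quarter_area_integral(x, 1.0) - target,
            0.0,
            1.0,
            xtol=1e-15,
            maxiter=200,
        )
        cuts.append(k * r)
    return cuts


def strip_area_below(y: float, a: float, b: float, r: float) -> float:
    """Area of ``{(x, t): a <= x <= b, 0 <= t <= min(y, sqrt(r^2 - x^2))}``.

    Piecewise closed form with ``x_y = sqrt(max(r^2 - y^2, 0))``:
    the horizontal line sits fully below the arc (``x_y >= b``, rectangle),
    fully above it (``x_y <= a``, whole strip), or crosses it inside the
    strip (mixed term).  Non-decreasing in ``y`` and saturating at the strip
    area.
    """
    if r <= 0:
        raise DomainError(f"radius must be positive, got {r}")
    if not 0.0 <= a < b <= r:
        raise DomainError(f"invalid strip edges a={a}, b={b} for radius {r}")
    if y < 0:
        raise DomainError(f"ordinate must be non-negative, got {y}")
    x_y = math.sqrt(max(r * r - y * y, 0.0))
    if x_y >= b:
        return y * (b - a)
    full = quarter_area_integral(b, r) - quarter_area_integral(a, r)
    if x_y <= a:
        return full
    return y * (x_y - a) + quarter_area_integral(b, r) - quarter_area_integral(x_y, r)


def solve_split_ordinates(r: float, cuts: Sequence[float]) -> list[float]:
    """Ordinate halving each vertical strip of the quarter-disc partition.

    For strip ``[a_i, b_i]`` the ordinate solves
    ``strip_area_below(y_i) = pi r^2 / (8 n)``.  Where the arc clears the
    candidate line across the whole strip the closed-form rectangle rule
    applies; otherwise (the outermost, arc-bounded strip) the monotone area
    function is solved by bracketed root-finding.
    """
    if r <= 0:
        raise DomainError(f"radius must be positive, got {r}")
    cuts = list(cuts)
    edges = [0.0, *cuts, r]
    if any(not 0.0 < c < r for c in cuts) or any(
        e2 <= e1 for e1, e2 in zip(edges, edges[1:])
    ):
        raise DomainError(f"cuts {cuts} are not strictly increasing inside (0, {r})")
    n = len(cuts) + 1
    target = math.pi * r * r / (8.0 * n)
    ordinates = []
    for a, b in zip(edges[:-1], edges[1:]):
        arc_at_b = math.sqrt(max(r * r - b * b, 0.0))
        y_rect = target / (b - a)
        if y_rect <= arc_at_b:
            ordinates.append(y_rect)
        else:
            arc_at_a = math.sqrt(r * r - a * a)
            ordinates.append(
                brentq(
                    lambda y: strip_area_below(y, a, b, r) - target,
                    0.0,
                    arc_at_a,
                    xtol=1e-13,
                    maxiter=200,
                )
            )
    return ordinates


@dataclass(frozen=True)
class CardSpec:
    """Design parameters of a comparison card.

    ``radius_mm`` is the card circle radius (standard card: 25 mm, i.e. a
    50 mm diameter) and ``strips_per_quadrant`` the number of equal-area
    vertical strips per quadrant (standard: 5, giving 40 cells of 2.5 % each).
    """

    radius_mm: float = 25.0
    strips_per_quadrant: int = 5

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise DomainError(f"radius_mm must be positive, got {self.radius_mm}")
        if (
            not isinstance(self.strips_per_quadrant, (int, np.integer))
            or self.strips_per_quadrant < 1
        ):
            raise DomainError(
                f"strips_per_quadrant must be a positive integer, got {self.strips_per_quadrant}"
            )

    @property
    def n_cells(self) -> int:
        return 8 * self.strips_per_quadrant

    @property
    def unit_fraction(self) -> float:
        """Disc-area fraction held by one grid cell, 1/(8 n)."""
        return 1.0 / self.n_cells

    @property
    def unit_pct(self) -> float:
        """One grid cell as a percentage of the disc (2.5 for n = 5)."""
        return 100.0 / self.n_cells


@dataclass(frozen=True)
class QuarterPartition:
    """Solved equal-area partition of the first quadrant."""

    cuts_mm: tuple[float, ...]
    split_ordinates_mm: tuple[float, ...]


@dataclass(frozen=True)
class GridCell:
    """One equal-area cell of the card.

    The boundary is a closed polyline over ``vertices``; if ``arc_edge`` is
    not None, the edge from ``vertices[arc_edge]`` to the next vertex follows
    the card circle (centred at the origin) instead of a straight segment.
    ``layer`` is 'lower' (between the x-axis and the split ordinate) or
    'upper' (between the split ordinate and the arc).
    """

    id: int
    quadrant: int
    strip_index: int
    layer: Literal["lower", "upper"]
    vertices: tuple[tuple[float, float], ...]
    arc_edge: Optional[int]
    area_mm2: float

    def polygon_points(self, radius: float, resolution: int = ARC_RESOLUTION) -> np.ndarray:
        """Boundary as an (m, 2) vertex array, the arc edge polygonized.

        Intermediate arc vertices are taken from a canonical set of
        ``resolution`` equally spaced angles on the card circle, so that
        cells mirrored across either axis polygonize consistently.
        """
        pts: list[tuple[float, float]] = []
        nv = len(self.vertices)
        for i, p in enumerate(self.vertices):
            pts.append(p)
            if self.arc_edge is not None and i == self.arc_edge:
                q = self.vertices[(i + 1) % nv]
                pts.extend(_canonical_arc_points(p, q, radius, resolution))
        return np.asarray(pts, dtype=float)


def _canonical_arc_points(
    p: tuple[float, float], q: tuple[float, float], r: float, resolution: int
) -> list[tuple[float, float]]:
    """Canonical-grid circle points strictly between ``p`` and ``q`` (short way)."""
    t0 = math.atan2(p[1], p[0])
    t1 = math.atan2(q[1], q[0])
    delta = (t1 - t0) % (2.0 * math.pi)
    if delta > math.pi:  # go the short way, clockwise
        t0, t1 = t1, t0
        delta = 2.0 * math.pi - delta
        reverse = True
    else:
        reverse = False
    step = 2.0 * math.pi / resolution
    i0 = math.floor(t0 / step) + 1
    out = []
    i = i0
    while i * step < t0 + delta - 1e-12:
        ang = i * step
        out.append((r * math.cos(ang), r * math.sin(ang)))
        i += 1
    if reverse:
        out.reverse()
    return out


@dataclass
class CardGeometry:
    """A fully solved comparison card: spec, quarter partition and 8 n cells."""

    spec: CardSpec
    partition: QuarterPartition
    cells: tuple[GridCell, ...]
    area_tolerance: float = AREA_TOL
    _poly_cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def cell_area_mm2(self) -> float:
        return self.spec.unit_fraction * math.pi * self.spec.radius_mm**2

    def to_dict(self) -> dict:
        return {
            "radius_mm": self.spec.radius_mm,
            "strips_per_quadrant": self.spec.strips_per_quadrant,
            "unit_pct": self.spec.unit_pct,
            "cuts_mm": list(self.partition.cuts_mm),
            "split_ordinates_mm": list(self.partition.split_ordinates_mm),
            "cells": [
                {
                    "id": c.id,
                    "quadrant": c.quadrant,
                    "strip_index": c.strip_index,
                    "layer": c.layer,
                    "area_mm2": c.area_mm2,
                }
                for c in self.cells
            ],
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _quadrant1_cells(spec: CardSpec, cuts: list[float], ordinates: list[float]):
    """Cells of the first quadrant as (strip, layer, vertices, arc_edge, area)."""
    r = spec.radius_mm
    edges = [0.0, *cuts, r]
    half = math.pi * r * r / (8.0 * spec.strips_per_quadrant)
    out = []
    for i, (a, b) in enumerate(zip(edges[:-1], edges[1:])):
        y = ordinates[i]
        h_a = math.sqrt(r * r - a * a)
        h_b = math.sqrt(max(r * r - b * b, 0.0))
        lower_area = strip_area_below(y, a, b, r)
        strip_area = quarter_area_integral(b, r) - quarter_area_integral(a, r)
        upper_area = strip_area - lower_area
        if y <= h_b:
            # Arc clears the split line: lower cell is a rectangle, upper cell
            # is bounded below by the split line and above by the arc.
            lower = ((a, 0.0), (b, 0.0), (b, y), (a, y))
            out.append((i, "lower", lower, None, lower_area))
            upper = ((a, y), (b, y), (b, h_b), (a, h_a))
            out.append((i, "upper", upper, 2, upper_area))
        else:
            # Arc dips below the split line inside the strip (outermost strip).
            x_c = math.sqrt(r * r - y * y)
            lower = ((a, 0.0), (b, 0.0), (b, h_b), (x_c, y), (a, y))
            if h_b == 0.0:
                lower = ((a, 0.0), (b, 0.0), (x_c, y), (a, y))
                out.append((i, "lower", lower, 1, lower_area))
            else:
                out.append((i, "lower", lower, 2, lower_area))
            upper = ((a, y), (x_c, y), (a, h_a))
            out.append((i, "upper", upper, 1, upper_area))
    return out


def build_card(spec: CardSpec) -> CardGeometry:
    """Solve the equal-area partition and mirror it into the full 8 n-cell card."""
    r = spec.radius_mm
    n = spec.strips_per_quadrant
    cuts = solve_cut_points(r, n)
    ordinates = solve_split_ordinates(r, cuts)
    q1 = _quadrant1_cells(spec, cuts, ordinates)
    cells: list[GridCell] = []
    cid = 0
    for quadrant in (1, 2, 3, 4):
        sx, sy = _QUADRANT_SIGNS[quadrant]
        for strip, layer, verts, arc_edge, area in q1:
            mirrored = tuple((sx * x, sy * y) for (x, y) in verts)
            cells.append(
                GridCell(
                    id=cid,
                    quadrant=quadrant,
                    strip_index=strip,
                    layer=layer,
                    vertices=mirrored,
                    arc_edge=arc_edge,
                    area_mm2=area,
                )
            )
            cid += 1
    card = CardGeometry(
        spec=spec,
        partition=QuarterPartition(tuple(cuts), tuple(ordinates)),
        cells=tuple(cells),
    )
    total = sum(c.area_mm2 for c in card.cells)
    disc = math.pi * r * r
    if abs(total - disc) > 1e-9 * disc:
        raise AssertionError(
            f"cell areas sum to {total}, expected {disc} (conservation violated)"
        )
    return card


def _fmt(v: float) -> str:
    return f"{v:.4f}"


def export_svg(card: CardGeometry, path) -> None:
    """Write the card as a stroke-only SVG 1.1 overlay (user units = mm).

    Contains the outer circle, both axes, the vertical cut chords mirrored to
    both half-planes, and the horizontal split segments of every strip clipped
    to the disc — suitable for printing on transparent film at 1:1 scale.
    Output is deterministic: re-exporting the same card yields identical bytes.
    """
    r = card.spec.radius_mm
    margin = 0.05 * r
    half = r + margin
    lines: list[tuple[float, float, float, float]] = []
    # axes
    lines.append((-r, 0.0, r, 0.0))
    lines.append((0.0, -r, 0.0, r))
    # vertical cut chords, mirrored across the y-axis
    for k in card.partition.cuts_mm:
        h = math.sqrt(r * r - k * k)
        lines.append((k, -h, k, h))
        lines.append((-k, -h, -k, h))
    # horizontal split segments per strip, mirrored to all four quadrants
    edges = [0.0, *card.partition.cuts_mm, r]
    for (a, b), y in zip(zip(edges[:-1], edges[1:]), card.partition.split_ordinates_mm):
        x_end = min(b, math.sqrt(max(r * r - y * y, 0.0)))
        for sx in (1.0, -1.0):
            for sy in (1.0, -1.0):
                lines.append((sx * a, sy * y, sx * x_end, sy * y))
    parts = [
        '<?xml version="1.0" encoding="UTF-8"?>\n',
        f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
        f'width="{_fmt(2 * half)}mm" height="{_fmt(2 * half)}mm" '
        f'viewBox="{_fmt(-half)} {_fmt(-half)} {_fmt(2 * half)} {_fmt(2 * half)}">\n',
        '<g transform="scale(1,-1)" fill="none" stroke="#000000" stroke-width="0.2">\n',
        f'<circle cx="0" cy="0" r="{_fmt(r)}"/>\n',
    ]
    for x1, y1, x2, y2 in lines:
        parts.append(
            f'<line x1="{_fmt(x1)}" y1="{_fmt(y1)}" x2="{_fmt(x2)}" y2="{_fmt(y2)}"/>\n'
        )
    parts.append("</g>\n</svg>\n")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("".join(parts))
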