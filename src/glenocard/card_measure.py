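"""Overlay measurement: register the comparison card and count grid cells.

The card is superimposed on the en-face glenoid so its centre coincides with
the centre of the best-fit inferior circle, and scaled so the card circle
matches the fitted circle.  The defect percentage is then read by counting:
every fully covered cell contributes one grid unit u = 100/(8 n) percent
(2.5 % on the standard card), and each partially covered cell is read with
the half-grid tolerance rule

    reading = u/2 + alpha  if more than half the cell is filled,
              u/2 - alpha  if less than half,
              u/2          if exactly half,

with tolerance alpha (0.5 % by default).  The worst-case reading error of a
single partial cell is max(u/2 - alpha, alpha) — 0.75 % at the defaults —
and errors add linearly over partial cells (3 % over four).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from shapely.geometry import Polygon
from shapely.prepared import prep

from .card_design import ARC_RESOLUTION, CardGeometry
from .errors import DomainError
from .sugaya import DefectRegion, FitCircle, classify_severity

__all__ = [
    "CardRegistration",
    "PartialCell",
    "GridReadings",
    "MeasurementResult",
    "register_card",
    "count_grids",
    "grid_reading",
    "defect_percent",
    "quantization_error_bound",
    "measure_with_card",
]

#: fill fractions within EPS of 0 (1) are classified empty (full)
EPS_FILL = 1e-6


@dataclass(frozen=True)
class CardRegistration:
    """Similarity transform (translation + isotropic scale, optional rotation)
    mapping card coordinates onto image coordinates."""

    translation: tuple[float, float]
    scale: float
    rotation_rad: float = 0.0

    def __post_init__(self) -> None:
        if self.scale <= 0 or not math.isfinite(self.scale):
            raise DomainError(f"registration scale must be positive, got {self.scale}")

    def to_card_frame(self, points: np.ndarray) -> np.ndarray:
        """Map image-frame points into the card frame (inverse transform)."""
        p = np.asarray(points, dtype=float) - np.asarray(self.translation)
        if self.rotation_rad != 0.0:
            c, s = math.cos(-self.rotation_rad), math.sin(-self.rotation_rad)
            p = p @ np.array([[c, s], [-s, c]])
        return p / self.scale


@dataclass(frozen=True)
class PartialCell:
    cell_id: int
    fill_fraction: float
    reading_pct: float


@dataclass(frozen=True)
class GridReadings:
    """Counting outcome of one card overlay."""

    full_count: int
    partials: tuple[PartialCell, ...]
    unit_pct: float
    alpha_pct: float

    @property
    def n_partial(self) -> int:
        return len(self.partials)


@dataclass(frozen=True)
class MeasurementResult:
    """Defect percentage with method label, counts and worst-case error bound."""

    method: str
    percent: float
    severity: str
    full_count: int
    n_partial: int
    unit_pct: float
    alpha_pct: float
    error_bound_pct: float


def register_card(
    card: CardGeometry, circle: FitCircle, rotation_rad: float = 0.0
) -> CardRegistration:
    """Centre the card on the fitted circle and scale it to the same radius.

    Angular alignment of the card axes is not determined by the overlay
    procedure; rotation defaults to the identity and may be set explicitly.
    """
    return CardRegistration(
        translation=circle.center,
        scale=circle.radius / card.spec.radius_mm,
        rotation_rad=rotation_rad,
    )


def grid_reading(fill_fraction: float, unit_pct: float, alpha_pct: float) -> float:
    """Half-grid tolerance reading of one partially filled cell (percent)."""
    if unit_pct <= 0:
        raise DomainError(f"unit_pct must be positive, got {unit_pct}")
    if not 0.0 <= alpha_pct <= unit_pct / 2.0:
        raise DomainError(
            f"alpha_pct must lie in [0, unit/2] = [0, {unit_pct / 2}], got {alpha_pct}"
        )
    if not 0.0 < fill_fraction < 1.0:
        raise DomainError(
            f"fill_fraction of a partial cell must lie in (0, 1), got {fill_fraction}"
        )
    half = unit_pct / 2.0
    if abs(fill_fraction - 0.5) <= 1e-12:
        return half
    return half + alpha_pct if fill_fraction > 0.5 else half - alpha_pct


def count_grids(
    card: CardGeometry,
    registration: CardRegistration,
    defect: Optional[DefectRegion],
    alpha_pct: float = 0.5,
    eps: float = EPS_FILL,
) -> GridReadings:
    """Classify every card cell against the defect region.

    The defect is mapped into the card frame; each cell's fill fraction is
    area(cell ∩ defect) / area(cell), computed on the cell's polygonized
    boundary (cells lie inside the card disc, so the defect is implicitly
    clipped to the registered circle).  Fractions within ``eps`` of 0 or 1
    are classified empty or full; anything in between is a partial cell read
    with the tolerance rule.
    """
    unit = card.spec.unit_pct
    if not 0.0 <= alpha_pct <= unit / 2.0:
        raise DomainError(
            f"alpha_pct must lie in [0, unit/2] = [0, {unit / 2}], got {alpha_pct}"
        )
    if defect is None:
        return GridReadings(0, (), unit, alpha_pct)
    local = Polygon(registration.to_card_frame(defect.polygon))
    if not local.is_valid:
        local = local.buffer(0)
    cell_polys = _cell_polygons(card)
    prepared = prep(local)
    full = 0
    partials = []
    for cell, poly in zip(card.cells, cell_polys):
        if not prepared.intersects(poly):
            continue
        if prepared.contains_properly(poly):
            full += 1
            continue
        frac = poly.intersection(local).area / poly.area
        if frac >= 1.0 - eps:
            full += 1
        elif frac > eps:
            partials.append(
                PartialCell(cell.id, float(frac), grid_reading(frac, unit, alpha_pct))
            )
    return GridReadings(full, tuple(partials), unit, alpha_pct)


def _cell_polygons(card: CardGeometry) -> list[Polygon]:
    key = ("cells", ARC_RESOLUTION)
    if key not in card._poly_cache:
        card._poly_cache[key] = [
            Polygon(c.polygon_points(card.spec.radius_mm)) for c in card.cells
        ]
    return card._poly_cache[key]


def defect_percent(readings: GridReadings) -> float:
    """Total defect percentage p = full_count · u + Σ partial readings."""
    return readings.full_count * readings.unit_pct + sum(
        p.reading_pct for p in readings.partials
    )


def quantization_error_bound(
    n_partial: int, unit_pct: float = 2.5, alpha_pct: float = 0.5
) -> float:
    """Worst-case |read − true| percentage over all partial-fill configurations.

    A partial cell holding true percentage t ∈ (0, u) is read as u/2 ± alpha
    (or u/2), so its worst-case error is max(u/2 − alpha, alpha); errors add
    over the ``n_partial`` partial cells (full and empty cells are exact).
    """
    if n_partial < 0:
        raise DomainError(f"n_partial must be >= 0, got {n_partial}")
    if not 0.0 <= alpha_pct <= unit_pct / 2.0:
        raise DomainError(
            f"alpha_pct must lie in [0, unit/2] = [0, {unit_pct / 2}], got {alpha_pct}"
        )
    return n_partial * max(unit_pct / 2.0 - alpha_pct, alpha_pct)


def measure_with_card(
    card: CardGeometry,
    circle: FitCircle,
    defect: Optional[DefectRegion],
    alpha_pct: float = 0.5,
    rotation_rad: float = 0.0,
) -> MeasurementResult:
    """End-to-end card measurement: register, count, read, bound the error."""
    reg = register_card(card, circle, rotation_rad)
    readings = count_grids(card, reg, defect, alpha_pct=alpha_pct)
    p = defect_percent(readings)
    return MeasurementResult(
        method="card",
        percent=p,
        severity=classify_severity(min(max(p / 100.0, 0.0), 1.0)),
        full_count=readings.full_count,
        n_partial=readings.n_partial,
        unit_pct=readings.unit_pct,
        alpha_pct=readings.alpha_pct,
        error_bound_pct=quantization_error_bound(
            readings.n_partial, readings.unit_pct, readings.alpha_pct
        ),
    )
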