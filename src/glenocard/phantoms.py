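"""Synthetic en-face glenoid phantoms with known true defect fraction.

A phantom is an inferior-glenoid circle of known centre and radius, an
anterior bone defect of known area fraction, and a cosmetic pear-shaped
superior extension of the outline (which neither measurement method may
see, since both operate on the inferior circle).  Phantoms stand in for
en-face CT reconstructions, so every downstream stage — circle fitting,
the area-ratio method, card counting and the agreement statistics — can be
validated against ground truth.

Two defect shapes are provided:

* ``chord`` — the bone anterior to a vertical line x = d is missing; d is
  obtained in closed form by inverting the circular-segment area
  f(d) = (r^2 arccos(d/r) - d sqrt(r^2 - d^2)) / (pi r^2).
* ``bite``  — a chord edge perturbed by a seeded smooth wiggle, with the
  offset re-solved so the realized in-disc fraction still hits the target.

Observer simulation adds isotropic Gaussian jitter to the rim points and to
the defect outline, with random streams keyed by (observer seed, phantom
seed, occasion) so any single measurement is reproducible in isolation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy.optimize import brentq
from scipy.stats import truncnorm
from shapely.geometry import Polygon

from .errors import DomainError
from .sugaya import DefectRegion, FitCircle, RimTrace, disc_polygon

__all__ = [
    "GlenoidPhantom",
    "ObserverModel",
    "segment_fraction",
    "chord_offset_for_fraction",
    "make_phantom",
    "observe",
    "cohort",
]

#: default inferior-circle radius of a phantom, mm (adult glenoid scale)
DEFAULT_RADIUS_MM = 12.5

_SEED_MASK = 2**31 - 1


def segment_fraction(d: float, r: float) -> float:
    """Disc-area fraction of the circular segment { x > d } for |d| <= r."""
    if r <= 0:
        raise DomainError(f"radius must be positive, got {r}")
    if not -r <= d <= r:
        raise DomainError(f"chord offset {d} outside [-{r}, {r}]")
    return (r * r * math.acos(d / r) - d * math.sqrt(r * r - d * d)) / (math.pi * r * r)


def chord_offset_for_fraction(fraction: float, r: float) -> float:
    """Invert :func:`segment_fraction` for a target fraction in [0, 0.5]."""
    if not 0.0 <= fraction <= 0.5:
        raise DomainError(f"chord fraction must lie in [0, 0.5], got {fraction}")
    if fraction == 0.0:
        return r
    if fraction == 0.5:
        return 0.0
    return brentq(lambda d: segment_fraction(d, r) - fraction, 0.0, r, xtol=1e-12 * r)


@dataclass(frozen=True)
class ObserverModel:
    """Per-observer measurement noise: rim and defect-edge jitter SDs in mm."""

    rim_noise_sd: float = 0.2
    defect_edge_noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rim_noise_sd < 0 or self.defect_edge_noise_sd < 0:
            raise DomainError("noise SDs must be >= 0")


@dataclass(frozen=True)
class GlenoidPhantom:
    """Ground-truth scene: inferior circle, outline, defect, true fraction."""

    inferior_circle: FitCircle
    outline: np.ndarray
    defect: Optional[DefectRegion]
    true_fraction: float
    rim_gap_halfangle: float  # rim arc (radians around +x) removed by the defect
    seed: int
    shape: str

    @property
    def radius(self) -> float:
        return self.inferior_circle.radius


def _pear_outline(r: float) -> np.ndarray:
    """Closed outline: inferior semicircle plus a tapered superior lobe.

    The lobe rises 0.6 r above the circle and narrows laterally — the 'pear'
    silhouette of a real glenoid.  Purely cosmetic: measurements use the rim
    trace and defect, never this outline.
    """
    inf_angles = np.linspace(math.pi, 2.0 * math.pi, 64)
    inferior = np.column_stack([r * np.cos(inf_angles), r * np.sin(inf_angles)])
    sup_angles = np.linspace(0.0, math.pi, 48)[1:-1]
    taper = 1.0 - 0.3 * np.sin(sup_angles)
    lobe = np.column_stack(
        [r * np.cos(sup_angles) * taper, 1.6 * r * np.sin(sup_angles)]
    )
    return np.vstack([inferior, lobe])


def _chord_defect_polygon(d: float, r: float, n_edge: int = 41) -> np.ndarray:
    """Rectangle covering { x > d } over the disc, medial edge densified."""
    reach = 1.5 * r
    ys = np.linspace(-reach, reach, n_edge)
    edge = np.column_stack([np.full(n_edge, d), ys])
    return np.vstack([edge, [[reach, reach], [reach, -reach]]])


def _bite_defect_polygon(
    d: float, r: float, rng: np.random.Generator, n_edge: int = 81
) -> tuple[np.ndarray, float]:
    """Chord defect with a seeded smooth medial-edge wiggle.

    Returns the vertex array and the minimum medial-edge x (for the rim gap).
    """
    amps = rng.uniform(0.0, 0.05 * r, size=3)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=3)
    freqs = np.array([1.0, 2.0, 3.0])
    reach = 1.5 * r
    ys = np.linspace(-reach, reach, n_edge)
    wiggle = sum(
        a * np.sin(2.0 * math.pi * f * ys / (2.0 * r) + p)
        for a, f, p in zip(amps, freqs, phases)
    )
    xs = d + wiggle
    verts = np.vstack(
        [np.column_stack([xs, ys]), [[reach, reach], [reach, -reach]]]
    )
    return verts, float(xs.min())


def make_phantom(
    radius: float = DEFAULT_RADIUS_MM,
    target_fraction: float = 0.10,
    shape: Literal["chord", "bite"] = "chord",
    seed: int = 0,
    center: tuple[float, float] = (0.0, 0.0),
) -> GlenoidPhantom:
    """Build a phantom whose in-disc defect fraction equals ``target_fraction``.

    Chord defects hit the target through the closed-form segment inversion;
    bite defects re-solve the offset against the shapely-measured in-disc
    area of the perturbed outline (monotone in the offset, so bracketed
    root-finding applies).  Deterministic for a given seed.
    """
    if radius <= 0:
        raise DomainError(f"radius must be positive, got {radius}")
    if not 0.0 <= target_fraction < 0.5:
        raise DomainError(
            f"target_fraction must lie in [0, 0.5) for an anterior defect, got {target_fraction}"
        )
    circle = FitCircle(center=center, radius=radius)
    offset = np.asarray(center, dtype=float)
    outline = _pear_outline(radius) + offset
    if target_fraction == 0.0:
        return GlenoidPhantom(circle, outline, None, 0.0, 0.0, seed, shape)
    disc = disc_polygon(circle)

    if shape == "chord":
        d = chord_offset_for_fraction(target_fraction, radius)
        defect = DefectRegion(_chord_defect_polygon(d, radius) + offset)
        true_fraction = segment_fraction(d, radius)
        min_edge_x = d
    elif shape == "bite":
        # wiggle drawn once per seed; the offset is then re-solved so the
        # realized in-disc fraction of the perturbed edge hits the target
        rng = np.random.default_rng([seed & _SEED_MASK, 797])
        base, _ = _bite_defect_polygon(0.0, radius, rng)
        local_disc = Polygon(np.asarray(disc.exterior.coords)[:-1] - offset)

        def realized_fraction(d: float) -> float:
            poly = Polygon(base + np.array([d, 0.0]))
            return poly.intersection(local_disc).area / circle.area_mm2

        d = brentq(
            lambda d: realized_fraction(d) - target_fraction,
            -1.2 * radius,
            1.45 * radius,
            xtol=1e-9 * radius,
        )
        defect = DefectRegion(base + np.array([d, 0.0]) + offset)
        true_fraction = realized_fraction(d)
        min_edge_x = float(base[: base.shape[0] - 2, 0].min() + d)
    else:
        raise DomainError(f"unknown defect shape {shape!r}")

    realized = defect.shapely.intersection(disc).area / circle.area_mm2
    if abs(realized - true_fraction) > 1e-4:
        raise AssertionError(
            f"phantom self-check failed: realized fraction {realized} vs "
            f"declared {true_fraction}"
        )
    gap = (
        math.acos(min(max(min_edge_x / radius, -1.0), 1.0))
        if min_edge_x < radius
        else 0.0
    )
    return GlenoidPhantom(circle, outline, defect, float(true_fraction), gap, seed, shape)


def observe(
    phantom: GlenoidPhantom,
    model: ObserverModel,
    occasion: int = 0,
    n_rim: int = 48,
) -> tuple[RimTrace, Optional[DefectRegion]]:
    """Simulate one observer's tracing of the phantom on one occasion.

    Rim points are sampled on the intact inferior arc of the true circle
    (avoiding the defect gap) with isotropic Gaussian noise; defect vertices
    are jittered likewise.  The random stream is keyed by
    (model.seed, phantom.seed, occasion).
    """
    if n_rim < 24:
        raise DomainError(f"need at least 24 rim points, got {n_rim}")
    rng = np.random.default_rng(
        [model.seed & _SEED_MASK, phantom.seed & _SEED_MASK, int(occasion) & _SEED_MASK]
    )
    r = phantom.radius
    cx, cy = phantom.inferior_circle.center
    lo = phantom.rim_gap_halfangle + 0.05
    angles = np.linspace(lo, 2.0 * math.pi - lo, n_rim)
    rim = np.column_stack([cx + r * np.cos(angles), cy + r * np.sin(angles)])
    rim = rim + rng.normal(0.0, model.rim_noise_sd, size=rim.shape)
    if phantom.defect is None:
        return RimTrace(rim), None
    verts = phantom.defect.polygon + rng.normal(
        0.0, model.defect_edge_noise_sd, size=phantom.defect.polygon.shape
    )
    poly = Polygon(verts)
    if not poly.is_valid:
        # jitter occasionally folds the outline; heal and keep the main part
        healed = poly.buffer(0)
        if healed.geom_type == "MultiPolygon":
            healed = max(healed.geoms, key=lambda g: g.area)
        verts = np.asarray(healed.exterior.coords)[:-1]
    return RimTrace(rim), DefectRegion(verts)


def cohort(
    n_patients: int = 33,
    fraction_mean: float = 0.10,
    fraction_sd: float = 0.08,
    fraction_bounds: tuple[float, float] = (0.0, 0.45),
    seed: int = 0,
    radius: float = DEFAULT_RADIUS_MM,
    shape: Literal["chord", "bite"] = "chord",
) -> list[GlenoidPhantom]:
    """Seeded cohort with defect fractions drawn from a truncated normal.

    Defaults mirror a realistic bony-Bankart case mix (mean 10 %, SD 8 %,
    bounded to [0, 45 %]) so all three severity classes occur.
    """
    if n_patients < 1:
        raise DomainError(f"n_patients must be >= 1, got {n_patients}")
    lo, hi = fraction_bounds
    if not 0.0 <= lo < hi <= 0.5:
        raise DomainError(f"fraction bounds must satisfy 0 <= lo < hi <= 0.5, got {fraction_bounds}")
    rng = np.random.default_rng([seed & _SEED_MASK, 131071])
    if fraction_sd == 0.0:
        fractions = np.full(n_patients, fraction_mean)
    else:
        a = (lo - fraction_mean) / fraction_sd
        b = (hi - fraction_mean) / fraction_sd
        fractions = truncnorm.rvs(
            a, b, loc=fraction_mean, scale=fraction_sd, size=n_patients, random_state=rng
        )
    # clamp away from the open upper bound of the chord construction
    fractions = np.clip(fractions, lo, min(hi, 0.499))
    return [
        make_phantom(
            radius=radius,
            target_fraction=float(f),
            shape=shape,
            seed=int(rng.integers(0, _SEED_MASK)),
        )
        for f in fractions
    ]
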