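"""Card geometry: the quarter-circle area integral, equal-area cuts and splits."""

import math
import xml.etree.ElementTree as ET

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from glenocard.card_design import (
    CardSpec,
    build_card,
    export_svg,
    quarter_area_integral,
    solve_cut_points,
    solve_split_ordinates,
    strip_area_below,
)
from glenocard.errors import DomainError


def bisect_area(target, r, lo=0.0, hi=None, iters=80):
    """Independent bisection oracle on the monotone quarter-circle area."""
    hi = r if hi is None else hi
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if quarter_area_integral(mid, r) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


class TestQuarterAreaIntegral:
    @pytest.mark.parametrize(
        "x, r, expected",
        [
            (0.0, 25.0, 0.0),
            (25.0, 25.0, math.pi * 625 / 4),
            (4.0, 4.0, math.pi * 16 / 4),
        ],
    )
    def test_endpoint_values(self, x, r, expected):
        assert quarter_area_integral(x, r) == pytest.approx(expected, abs=1e-10)

    def test_matches_numerical_quadrature(self):
        # closed form against direct numerical integration of the arc height
        for x in (1.615, 3.94, 12.0, 24.9):
            num, _ = quad(lambda t: math.sqrt(625 - t * t), 0.0, x)
            assert quarter_area_integral(x, 25.0) == pytest.approx(num, abs=1e-8)

    @pytest.mark.parametrize("x, r", [(-0.1, 25.0), (25.1, 25.0), (1.0, 0.0), (1.0, -2.0)])
    def test_domain_errors(self, x, r):
        with pytest.raises(DomainError):
            quarter_area_integral(x, r)

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=1e-6, max_value=0.999999))
    def test_bijection_roundtrip(self, frac):
        # F is a strict bijection [0, r] -> [0, pi r^2 / 4]
        r = 25.0
        target = frac * math.pi * r * r / 4
        x = bisect_area(target, r)
        assert quarter_area_integral(x, r) == pytest.approx(target, abs=1e-9 * r * r)


class TestCutPoints:
    def test_standard_card_cut_residuals(self):
        # each cut holds an exact multiple of the strip area
        r, n = 25.0, 5
        cuts = solve_cut_points(r, n)
        assert len(cuts) == 4
        assert all(c1 < c2 for c1, c2 in zip(cuts, cuts[1:]))
        for i, k in enumerate(cuts, start=1):
            assert abs(quarter_area_integral(k, r) - i * math.pi * r * r / 20) <= 1e-10 * r * r

    def test_against_independent_bisection(self):
        r, n = 1.0, 5
        cuts = solve_cut_points(r, n)
        oracle = [bisect_area(i * math.pi / 20, 1.0) for i in range(1, 5)]
        assert cuts == pytest.approx(oracle, abs=1e-10)
        # frozen oracle values for the unit-radius card
        assert cuts == pytest.approx([0.15774, 0.31969, 0.49186, 0.68705], abs=5e-6)

    def test_half_split_small_circle(self):
        # r = 4, two strips: the cut halves the quarter disc
        (k,) = solve_cut_points(4.0, 2)
        assert quarter_area_integral(k, 4.0) == pytest.approx(2 * math.pi, abs=1e-10)

    def test_single_strip_has_no_cuts(self):
        assert solve_cut_points(25.0, 1) == []

    @pytest.mark.parametrize("c", [0.1, 2.0, 25.0])
    def test_scale_equivariance(self, c):
        base = np.array(solve_cut_points(1.0, 5))
        scaled = np.array(solve_cut_points(c, 5))
        assert scaled == pytest.approx(c * base, rel=1e-12)

    @pytest.mark.parametrize("r, n", [(0.0, 5), (-1.0, 5), (25.0, 0), (25.0, -3)])
    def test_domain_errors(self, r, n):
        with pytest.raises(DomainError):
            solve_cut_points(r, n)


class TestStripAreaBelow:
    def test_zero_and_saturation(self):
        assert strip_area_below(0.0, 3.94, 7.99, 25.0) == 0.0
        full = quarter_area_integral(7.99, 25.0) - quarter_area_integral(3.94, 25.0)
        assert strip_area_below(30.0, 3.94, 7.99, 25.0) == pytest.approx(full, abs=1e-12)

    def test_arc_bounded_strip_against_2d_oracle(self):
        # mixed rectangle + arc term, cross-checked by midpoint-rule integration
        y, a, b, r = 6.5119, 17.1762, 25.0, 25.0
        xs = np.linspace(a, b, 200001)
        mid = 0.5 * (xs[:-1] + xs[1:])
        heights = np.minimum(y, np.sqrt(np.clip(r * r - mid * mid, 0.0, None)))
        oracle = float(np.sum(heights) * (b - a) / mid.size)
        assert strip_area_below(y, a, b, r) == pytest.approx(oracle, abs=1e-3)
        assert strip_area_below(y, a, b, r) == pytest.approx(math.pi * r * r / 40, abs=1e-2)

    @settings(derandomize=True, max_examples=30)
    @given(st.floats(min_value=0.0, max_value=26.0), st.floats(min_value=0.0, max_value=26.0))
    def test_monotone_in_y(self, y1, y2):
        lo, hi = sorted((y1, y2))
        assert strip_area_below(lo, 5.0, 20.0, 25.0) <= strip_area_below(hi, 5.0, 20.0, 25.0) + 1e-12

    @pytest.mark.parametrize("y, a, b, r", [(1.0, 5.0, 5.0, 25.0), (1.0, 7.0, 5.0, 25.0), (1.0, 0.0, 26.0, 25.0), (-1.0, 0.0, 5.0, 25.0)])
    def test_domain_errors(self, y, a, b, r):
        with pytest.raises(DomainError):
            strip_area_below(y, a, b, r)


class TestSplitOrdinates:
    def test_each_ordinate_halves_its_strip(self):
        r = 25.0
        cuts = solve_cut_points(r, 5)
        ys = solve_split_ordinates(r, cuts)
        edges = [0.0, *cuts, r]
        for (a, b), y in zip(zip(edges[:-1], edges[1:]), ys):
            assert abs(strip_area_below(y, a, b, r) - math.pi * r * r / 40) <= 1e-10 * r * r

    def test_first_strip_rectangle_closed_form(self):
        r = 25.0
        cuts = solve_cut_points(r, 5)
        ys = solve_split_ordinates(r, cuts)
        assert ys[0] == pytest.approx((math.pi * r * r / 40) / cuts[0], rel=1e-12)

    def test_single_strip_unit_radius_against_bisection(self):
        # y such that area below it within the whole quadrant equals pi/8
        (y,) = solve_split_ordinates(1.0, [])
        lo, hi = 0.0, 1.0
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if strip_area_below(mid, 0.0, 1.0, 1.0) < math.pi / 8:
                lo = mid
            else:
                hi = mid
        assert y == pytest.approx(0.5 * (lo + hi), abs=1e-9)
        assert y == pytest.approx(0.40397, abs=1e-5)

    @pytest.mark.parametrize("c", [0.1, 2.0, 25.0])
    def test_scale_equivariance(self, c):
        base = np.array(solve_split_ordinates(1.0, solve_cut_points(1.0, 5)))
        scaled = np.array(solve_split_ordinates(c, solve_cut_points(c, 5)))
        assert scaled == pytest.approx(c * base, rel=1e-9)

    def test_bad_cuts_rejected(self):
        with pytest.raises(DomainError):
            solve_split_ordinates(25.0, [10.0, 5.0])
        with pytest.raises(DomainError):
            solve_split_ordinates(25.0, [0.0, 5.0])


def cell_area_oracle(card, cell):
    """Cell area by adaptive 1-D quadrature of the cell's height profile."""
    r = card.spec.radius_mm
    edges = [0.0, *card.partition.cuts_mm, r]
    a, b = edges[cell.strip_index], edges[cell.strip_index + 1]
    y = card.partition.split_ordinates_mm[cell.strip_index]

    def height(x):
        arc = math.sqrt(max(r * r - x * x, 0.0))
        if cell.layer == "lower":
            return min(y, arc)
        return max(arc - y, 0.0)

    crossing = math.sqrt(max(r * r - y * y, 0.0))
    pts = [crossing] if a < crossing < b else None
    val, _ = quad(height, a, b, points=pts, limit=200, epsabs=1e-12, epsrel=1e-12)
    return val


class TestBuildCard:
    def test_cell_count_and_unit_area(self, standard_card):
        assert len(standard_card.cells) == 40
        assert standard_card.cell_area_mm2 == pytest.approx(49.087385, abs=1e-5)

    def test_area_conservation(self, standard_card):
        total = sum(c.area_mm2 for c in standard_card.cells)
        disc = math.pi * 625
        assert abs(total - disc) <= 1e-9 * disc

    def test_every_cell_area_against_quadrature_oracle(self, standard_card):
        expected = standard_card.cell_area_mm2
        for cell in standard_card.cells:
            oracle = cell_area_oracle(standard_card, cell)
            assert oracle == pytest.approx(expected, rel=1e-8)
            assert cell.area_mm2 == pytest.approx(oracle, rel=1e-8)

    def test_reflection_symmetry(self, standard_card):
        # the cell multiset is invariant under reflection across either axis
        def keys(sign_x, sign_y):
            out = set()
            for c in standard_card.cells:
                verts = frozenset(
                    (round(sign_x * x, 9), round(sign_y * y, 9)) for x, y in c.vertices
                )
                out.add((c.strip_index, c.layer, verts))
            return out

        assert keys(1, 1) == keys(-1, 1) == keys(1, -1) == keys(-1, -1)

    def test_degenerate_single_strip_card(self):
        card = build_card(CardSpec(25.0, 1))
        assert len(card.cells) == 8
        for c in card.cells:
            assert c.area_mm2 == pytest.approx(math.pi * 625 / 8, rel=1e-10)

    def test_cells_lie_inside_disc(self, standard_card):
        r = standard_card.spec.radius_mm
        for cell in standard_card.cells:
            pts = cell.polygon_points(r)
            assert np.all(np.hypot(pts[:, 0], pts[:, 1]) <= r * (1 + 1e-9))


class TestExportSvg:
    def test_valid_svg_with_circle_and_cut_lines(self, standard_card, tmp_path):
        path = tmp_path / "card.svg"
        export_svg(standard_card, path)
        root = ET.parse(path).getroot()
        assert root.tag.endswith("svg")
        ns = {"svg": "http://www.w3.org/2000/svg"}
        circles = root.findall(".//svg:circle", ns)
        assert len(circles) == 1 and float(circles[0].get("r")) == 25.0
        lines = root.findall(".//svg:line", ns)
        verticals = sorted(
            {abs(float(l.get("x1"))) for l in lines if l.get("x1") == l.get("x2")} - {0.0}
        )
        assert verticals == pytest.approx([3.9434, 7.9923, 12.2965, 17.1762], abs=5e-4)
        # stroke-only overlay: nothing filled
        group = root.find(".//svg:g", ns)
        assert group.get("fill") == "none"

    def test_reexport_is_byte_identical(self, standard_card, tmp_path):
        p1, p2 = tmp_path / "a.svg", tmp_path / "b.svg"
        export_svg(standard_card, p1)
        export_svg(standard_card, p2)
        assert p1.read_bytes() == p2.read_bytes()
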