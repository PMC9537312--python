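# Methods

## The measurement problem

Anterior glenoid bone loss after bony Bankart lesions is quantified on an
en-face view of the glenoid. The inferior glenoid is nearly circular, so
both methods implemented here start from the best-fit circle of the
inferior rim: the area-ratio (Sugaya) method divides the missing in-circle
area A by the circle area S, D = A/S; the comparison-card method reads the
same quantity by counting equal-area grid cells on a transparent overlay.
Severity grading (small < 5 %, medium 5–20 %, large > 20 %) follows the
thresholds used for surgical decision-making; the boundary values 5 % and
20 % are assigned to "medium".

## Card geometry

A disc of radius r is partitioned, per quadrant, into n vertical strips of
equal area and each strip is halved horizontally, giving 8 n cells of
area πr²/(8n) each. With F(x) = x√(r² − x²)/2 + (r²/2)·asin(x/r) (the area
under the quarter-circle arc), the i-th cut solves F(kᵢ) = i·πr²/(4n) and
the split ordinate of strip [a, b] solves the arc-aware condition
area{a ≤ x ≤ b, 0 ≤ y ≤ min(yᵢ, √(r² − x²))} = πr²/(8n). Where the arc
clears the candidate line over the whole strip this reduces to the
rectangle rule yᵢ = πr²/(8n)/(b − a); in the outermost strip the arc dips
below the line and the full piecewise form is solved. The exact arc-aware
rule is normative throughout: the rectangle shortcut applied to the last
strip of the standard card would give 6.27 mm, while the exact solution is
6.51 mm, and only the exact value halves the strip.

Both area functions are strictly monotone, so all roots are found by
bracketed Brent iteration (absolute area residual ≤ 1e−10·r²). Cuts are
solved on the unit circle and scaled by r (the partition is
scale-equivariant). The quarter-circle solution is mirrored across both
axes; cells are tagged (quadrant, strip, layer) and carry an exact boundary
description (segments plus at most one arc of the card circle).

For the standard card (r = 25 mm, n = 5) the solved values are
cuts 3.9434, 7.9923, 12.2965, 17.1762 mm and ordinates 12.4480, 12.1237,
11.4044, 10.0596, 6.5119 mm; each of the 40 cells holds 49.0874 mm²
(2.5 %). Full precision is kept internally; rounding happens only at
presentation. n generalizes beyond 5 (the unit percentage becomes
100/(8n) %), and n = 1 degenerates to the 8-cell card.

The SVG export is plain SVG 1.1, millimetre user units, stroke-only
(transparent fill) so the card can be printed on film or overlaid on an
image; output is byte-deterministic. Printing calibration (DPI, physical
scaling) is out of scope.

## Circle fitting

Rim traces are fitted with the Taubin algebraic least-squares circle
(Chernov's SVD formulation), which is exact on noise-free circular data and
nearly unbiased on arcs, followed by geometric least-squares refinement of
(centre, radius) with Levenberg–Marquardt. Collinear input is rejected via
the relative thickness (singular-value ratio < 1e−9) of the centered point
cloud. The RMS radial residual is reported with the fit.

## Region areas and clipping

Defect outlines are closed simple polygons (validated with shapely;
self-intersecting input is rejected, and implicit closure is required).
The fitted disc is represented by an inscribed 1024-gon, whose relative
area error is 2π²/(3·1024²) < 3e−5 — negligible against every tolerance in
play (the card quantization bound is 0.75 % per partial cell). A is the
area of defect ∩ disc, so defects extending past the best-fit circle
(superior extension) contribute only their in-disc part; S = πR² exactly.
Consequences of the polygonization: a defect covering the whole disc reads
99.997 % rather than 100.000 % in the area-ratio method, and rigid-motion
invariance of D holds to ~1e−5 rather than machine precision (the card
method, which compares polygonized cells against the polygonized defect,
reads a full disc as exactly 100 %).

## Card registration and counting

The card is registered to the fitted circle by a similarity transform:
translation to the circle centre and scale R/r. The overlay procedure does
not determine an angular alignment, so rotation defaults to the identity
and is exposed as a parameter; rotation changes which cells are partial
but never the error bound. Counting maps the defect into the card frame
(the inverse transform — cheaper than transforming 40 cells) and computes
each cell's fill fraction as area(cell ∩ defect)/area(cell) on the cell's
polygonized boundary. Cell arcs are polygonized on a canonical grid of
1024 angles shared with the disc polygon, so mirrored cells and the disc
tile consistently. Fractions within 1e−6 of 0 or 1 classify as empty/full;
everything between is a partial cell read with the tolerance rule
(u/2 − α, u/2, u/2 + α for less than, exactly, more than half full;
α ∈ [0, u/2], default 0.5 %). The worst-case error of one partial cell is
max(u/2 − α, α) and adds linearly over partial cells; the brute-force
maximization over fill fractions confirms the closed form to < 1e−3.

## Synthetic phantoms and observers

Phantoms stand in for en-face CT reconstructions. Default inferior-circle
radius is 12.5 mm (adult glenoid scale), which also exercises a non-trivial
registration scale against the 50 mm card. Two defect shapes:

- *chord*: bone anterior to x = d is missing; d inverts the circular
  segment fraction f(d) = (r²·arccos(d/r) − d√(r² − d²))/(πr²) in closed
  form, so the true fraction is known analytically.
- *bite*: the chord edge perturbed by a seeded smooth wiggle (three
  sinusoids, amplitudes up to 0.05 r); the offset is re-solved against the
  shapely-measured in-disc area so the realized fraction still hits the
  target (the fraction is monotone in the offset).

Every phantom validates at construction that its declared fraction matches
the geometrically measured one within 1e−4. The outline adds a tapered
superior lobe rising 0.6 r above the circle (the glenoid "pear"); it is
cosmetic and must not influence either method — this is itself tested.

Observer simulation samples ≥ 24 rim points on the intact inferior arc
(excluding the defect gap) and jitters rim points and defect vertices with
isotropic Gaussian noise (default SD 0.2 mm, a plausible tracing error at
CT resolution). Random streams are keyed by (observer seed, phantom seed,
occasion), so any single measurement is reproducible in isolation. Jitter
that folds the defect outline is healed by taking the largest polygon of a
zero-width buffer.

Cohorts draw true fractions from a truncated normal (mean 0.10, SD 0.08,
bounds [0, 0.45]), a realistic bony-Bankart case mix that populates all
three severity classes. The default cohort shape is "chord" (closed-form
construction keeps large simulation studies cheap); "bite" is exercised in
dedicated tests.

What the phantoms do *not* emulate: CT texture and segmentation error,
partial-volume effects, the 3-D-to-en-face projection step (and its known
angular bias), free bony fragments, and truly irregular multi-lobed
defects. Passing tests therefore demonstrate the internal consistency and
quantization behavior of the two methods, not their clinical accuracy on
patient CTs.

## Statistics

ICC defaults to two-way random effects, absolute agreement, single
measures — ICC(2,1) = (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n) — with
a one-way option; a constant table raises an explicit undefined-ICC error.
Grades: good > 0.75, fair 0.4–0.75, poor < 0.4. Bland–Altman reports bias,
sample SD of differences (n − 1), limits bias ± 1.96 SD and a t-based 95 %
CI of the bias. Group means across the area-ratio column and the card
observers are compared with one-way fixed-effects ANOVA (Kruskal–Wallis
available as an option). Inter-observer reliability is ambiguous between
"per occasion" and "of averaged occasions"; we compute it per occasion and
additionally report the mean of the per-occasion coefficients.

The default validation study is 33 phantoms × 3 observers × 2 occasions
with 0.2 mm noise — small enough to run in under a second, large enough
for stable ICCs. In the ANOVA table the area-ratio column is the
observer-mean per phantom; Bland–Altman compares observer-averaged card
percentages against observer-averaged area-ratio percentages per phantom.

## Numerical choices at a glance

| quantity | choice | default |
|---|---|---|
| root-finding | bracketed Brent on monotone area functions | residual ≤ 1e−10·r² |
| disc/arc polygonization | canonical 1024-angle grid | rel. area error < 3e−5 |
| full/empty cell threshold | fill fraction within ε of 0/1 | ε = 1e−6 |
| reading tolerance α | configurable in [0, u/2] | 0.5 % |
| card rotation | identity unless specified | 0 |
| phantom radius | adult inferior glenoid | 12.5 mm |
| observer noise | isotropic Gaussian on vertices | SD 0.2 mm |

## Known limitations

- The area-ratio denominator is exact (πR²) while the numerator uses the
  1024-gon disc, so percentages carry a systematic deficit of at most
  3e−3 percentage points at 100 % defect.
- The card's partial-cell count (hence its error bound) depends on the
  unspecified card rotation; the bound holds for every rotation.
- The defect outline must arrive as a closed polygon; how a hand-drawn
  "free curve" is closed against the rim is left to the operator.
- 2-D only: projection from the 3-D glenoid to the en-face plane, DICOM
  input and fragment-area accounting are out of scope.
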