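# Methods

`teapick` implements a side-view (2-D) picking-point workflow for tea
shoots on a continuously advancing harvester: synthetic scene generation
with exact ground truth, skeleton-based localization of the cut point,
S-curve vertical motion planning, and trial scoring. This note records
the models, the parameters that matter, the numerical choices, and the
known limitations.

## The localization model

A strip-clamped tea shoot seen from the side has a characteristic
topology: blank space above, a narrow bud at the top, two leaves
diverging from the bud–leaf junction, and a single stalk below. The
pipeline exploits exactly this structure, per detection box:

1. **Binarize** the crop (Otsu by default; fixed threshold available).
2. **Thin** the mask to a unit-width skeleton with the classic fast
   parallel (two-subiteration) thinning rules.
3. **Scan** skeleton rows top to bottom; the first row containing two or
   more skeleton pixels marks the bud–leaf intersection (above it only
   the single bud line exists). Within that row the pixel nearest a
   skeleton junction pixel (≥3 neighbors) is chosen.
4. **Trace** the skeleton downward from the intersection. At branchings
   the walk takes the branch that can reach the deepest row (computed
   exactly by depth-first search): leaf branches dead-end within a few
   millimetres while the stalk continues to the bottom of the box. A
   purely local "largest row step" rule was tried first and diverts onto
   leaf skeletons near merged junctions; the reach-based rule is the
   faithful reading of "maximizing downward progress".
5. **Fit** the growth curve `column = f(row)` by least squares
   (default cubic, degree automatically reduced for short or perfectly
   vertical traces; a vertical trace collapses to a constant).
6. **Offset** 4 mm down the curve. The offset is a vertical drop:
   `dz_px = offset_mm · Ht / Hs` (20 px at the default calibration). An
   arc-length mode is available behind `LocateConfig.offset_mode="arc"`
   but vertical is the default, because the calibration maps vertical
   pixels to millimetres.
7. **Calibrate** to world coordinates by the proportionality
   `Zt/Ht = Zs/Hs`, with the horizontal axis at the same mm/px scale.
   Defaults: `Hs = 196 mm`, `Hz = 212 mm` (blade park height), so the
   blade's first move from park is `(Hz − Hs) + Zs`.

### Known bias

On rendered shoots the thinned skeleton merges leaf and stalk for the
first ~1 mm below the anatomical junction (the medial axis of a Y-shaped
union bifurcates below the attachment point, by about half the stalk
width). The detected intersection therefore sits systematically
~0.5–1.3 mm below the true junction, and the emitted picking point
inherits that bias. Measured over 150 shoots (50 scenes): mean error
≈ 1.0 mm, maximum ≈ 1.6 mm — comfortably inside the ±3 mm positioning
requirement, but see the trial-scoring interaction below.

## The synthetic scene generator

The generator is the test bed for the whole pipeline; its defaults are
the measured field conditions:

| parameter | default | origin |
| --- | --- | --- |
| shoot length L | U(27.5, 30.2) mm | field measurement |
| stalk diameter Φ | U(1.1, 2.3) mm | field measurement |
| pickable region A2 | U(11.2, 15.3) mm | field measurement |
| leaf angle β | U(45.6, 54.2)° | field measurement |
| tip height above canopy | U(50, 110) mm | field measurement |
| tip spacing | U(50, 80) mm | field measurement |
| curvature amplitude | U(0, 3) mm | generator choice (moderate bow) |
| window height | 196 mm (= Hs) | rig calibration |
| px_per_mm | 5 (→ Ht = 980 px) | rig calibration |

Each stem is a single-bow quadratic from the tip down to the canopy
surface — the simplest shape that exercises the curve fit. Leaves are
kite polygons attached at the tip by a narrow petiole (0.3 mm half-width)
and pointing down-and-outward at ±β from the stem axis, so that the
bud–leaf junction is the topmost multi-branch point of the skeleton —
the property the row scan relies on. The bud is a narrow upward-tapering
wedge (7 mm) whose skeleton is a clean single line. The true picking
point is placed exactly 4 mm (vertical drop) below the tip, on the stem
curve. All randomness flows from one seed; rasterization maps world
coordinate `v` to index coordinate `v·px_per_mm − 0.5` (pixel centers on
the world grid) and optional Gaussian noise never alters the
ground-truth boxes.

What the generator does **not** emulate: lighting, occlusion between
shoots, motion blur, background canopy clutter, leaf serration and
curl, and detector errors (boxes are exact). Passing tests therefore
demonstrate the geometric correctness of the pipeline under the
measured shoot geometry, not robustness to field imaging conditions.

## Thinning

The two-subiteration parallel rules are applied to a fixpoint, with all
deletion decisions taken on the grid state at the start of each
subiteration; a one-pixel background ring makes the neighbor rules
total. The implementation is vectorized; the test suite holds it
bit-identical to a naive per-pixel reference implementation on random
masks, plus fixpoint, subset, and component-count checks.

Limitation (inherent to the original rules, reproduced by both
implementations): structures that are everywhere ≤2 px thick can be
deleted entirely — an isolated 2×2 block vanishes, and thin diagonal
ribbons can follow it. Component-count preservation is therefore
guaranteed (and tested, 200 seeded masks) for blob-like shapes with
interior pixels, which is what binarized shoots are; the degenerate case
has its own regression test.

## Motion planning

Vertical velocity is commanded as a function of distance by the logistic
`Vl(s) = vl0 + (vlmax − vl0)/(1 + e^{−a(s−b)})` on a fixed acceleration
distance `S1`, a uniform segment `Sy = |S| − 2·S1` at `vlmax`, and the
mirrored logistic on the deceleration distance `S1`. Since the logistic
never reaches its asymptotes, `a` and `b` are calibrated in closed form
from a boundary tolerance `eps` (default 0.01): `b = S1/2`,
`a = 2·ln((1−eps)/eps)/S1`, which pins `v(0) = eps·vlmax`,
`v(S1) = (1−eps)·vlmax`, and `v(S1/2) = vlmax/2` exactly. Explicit
`a`/`b` values can be passed instead to reproduce hand-tuned
controllers; the historically used pair (a = 0.0067, b = 0.02) leaves
the ramp near `vlmax/2` at the segment end, which is why calibration is
the default. Defaults: `vlmax = 0.12 m/s`, `S1 = 0.04 m`.

Numerical choices: profiles are sampled at `ds = 0.1 mm`; duration is
the trapezoidal integral of `ds/v` with `v` floored at `eps·vlmax` so
the dwell at the near-zero endpoints stays finite. Moves shorter than
`2·S1` degenerate to two symmetric halves with the ramp re-calibrated to
the half distance (peak = logistic midpoint), and are flagged. A
consequence of parameterizing velocity by distance is a long slow tail:
the first millimetres are crossed at `~eps·vlmax`, so a 100 mm cycle
takes ≈3 s with the defaults — row schedules are only feasible for slow
carriage speeds (0.005–0.01 m/s in the examples and tests).

Row scheduling charges each shoot the horizontal arrival time `ΔX/V`
against the vertical cycle duration plus the 10 mm waiting-zone dwell,
and enforces the 0.7 s minimum cycle interval of the recognition loop;
infeasible shoots are skipped (the head holds its height), mirroring the
device's miss behavior. The first cycle starts from the parked blade
(`Hz − Hs = 16 mm` above the window top) with a 200 mm approach lead.

## Trial scoring

Predictions are matched to true picking points greedily on Euclidean
world distance within a 10 mm radius. A shoot is *clamped* when its
matched cycle was feasible, and *picked* when additionally the cut is
within the tolerance (default 3 mm) of the true point and the residual
stalk — arc length along the true stem from the cut up to the bud base —
is shorter than 5 mm. Success rates use the total shoot count as
denominator and are truncated (not rounded) to one decimal, which is how
field-trial tables print them: (98, 90, 82) → (91.8, 83.6).

Interaction worth knowing: with the cut commanded 4 mm below the
*detected* junction and the detection biased ~1 mm low, residual stalks
cluster right at the strict 5 mm gate, so noise-free desk trials
typically pick 30–100 % of shoots depending on the seed even though
every localization error is ≤1.6 mm. This mirrors the marginal
"overlong stalk" failures a physical trial reports and is a property of
the 4 mm offset sitting only 1 mm inside the 5 mm agronomic bound.

## Problem sizes

Default desk experiment: 50 scenes × 3 shoots at 5 px/mm (980-row
images), which the full pipeline processes in a few seconds; the
thinning property suite uses 200 random 32×32 masks against the naive
reference implementation.
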