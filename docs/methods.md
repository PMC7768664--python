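# Methods

This note records the models, parameter choices, and numerical decisions
behind `bezridge`, and what the synthetic experiments do and do not show.

## Preprocessing

The chain is the standard one for ridge imagery: pixel-wise mean/variance
normalization `out = m₀ + sign(x−m)·sqrt(v₀(x−m)²/v)` clipped to [0,255]
(defaults m₀ = 128, v₀ = 10000); orientation from the smoothed gradient
covariance tensor (window 17 px, odd so the window is centered); a single
global ridge frequency from the radial power-spectrum peak (periods 3–25 px);
an even-symmetric Gabor bank at 16 quantized orientations (σ = 4 px both
axes), each pixel taking the response of the kernel nearest its local
orientation; local-mean binarization (window 33 px, dark ridges →
foreground); and Zhang–Suen thinning (Guo–Hall available). Pixels whose
orientation coherence falls below 0.15 pass through the Gabor stage
unfiltered and are flagged — segmentation and quality maps are out of scope,
so low-coherence areas are left alone rather than masked.

Thinning output is post-processed by removing 8-simple pixels from any fully
foreground 2×2 block, enforcing strict single-pixel width without changing
the number of 8-connected components. Already-binary inputs skip
normalization and enhancement entirely (there is no gray-level noise to
remove), which makes the pipeline idempotent on skeletons.

## Ridge model

Ridges are traced on the skeleton with 8-connectivity; paths terminate at
endpoints (one neighbor) and junction pixels (three or more), junctions
being shared as terminal points by every incident ridge so that bifurcation
structure survives. Pure cycles are returned as loop ridges and spliced open
at their topmost pixel for fitting. Fitting is least squares with pinned
endpoints, started from whichever of two canonical parameterizations fits
better — chord length (natural for pixel chains) or uniform index (exact
for curves sampled uniformly in the Bezier parameter) — then alternated
with Newton footpoint reprojection; each refit takes whichever of a
tangent-distance step (fast near the optimum, unstable far away) or a plain
least-squares step improves the residual more. When the residual is small but not at the
quantization floor (between 10⁻⁶ and 0.6 px), a short bounded
`scipy.optimize.least_squares` polish follows: the alternating scheme can
stall in the nearly flat valley along the end-tangent directions, and the
polish is what pins the generating control points of exactly sampled cubics.
Note an intrinsic limit: for nearly straight curves, control points are not
identifiable from the trace at sub-pixel accuracy (distinct cubics coincide
to ~10⁻³ px), so control-point recovery claims are made only for genuinely
curved spans.

Paths split first at corners (interior secant angle below 100°), then by
recursive bisection at the maximum-error pixel until every pixel lies within
`max_fit_error` (default 1.0 px) of its span. Ridges shorter than 4 px
collapse to a degenerate span. Serialized coordinates are quantized to
0.1 px, so serialize→parse is an exact round trip.

## Damage detection

The inter-ridge period is estimated from the skeleton's radial power
spectrum; because a comb of thin lines puts comparable power into every
harmonic, the estimator takes the lowest annulus reaching 40% of the peak
annular power rather than the single strongest bin. The foreground is then
dilated by the smallest radius that robustly closes the inter-ridge gap,
⌈period/2⌉ + 1. Interior damage appears as enclosed holes in the dilated
image; marginal damage as background inside the convex hull of the dilated
foreground that touches the hull's rim. Because a hole in the dilated image
underestimates the damaged area by exactly the dilation radius, each
detected component is grown back by that radius before the minimum-area cut
(period², suppressing pore-scale artifacts); marginal candidates must also
contain a pixel at least 2 px deep, which rejects the thin slivers a
slightly non-convex pattern edge produces along the hull rim. A larger
dilation radius (e.g. 0.75·period) would blind the detector to ablations
below ~2 periods in diameter — the dilated ridge stubs re-cover them — which
is why the smallest closing radius is used.

## Breakpoint matching

Breakpoints are ridge endpoints within 2 px of a damaged region. Tangents
point from the terminus back along the ridge (the unique convention under
which collinear, mutually facing fragments score the optimum φ = 0) and are
averaged over secants 3–5 steps back to damp pixel jitter. The region
boundary (Moore contour, clockwise from the topmost-leftmost pixel, so
ordering is reproducible) is cut at its two most distant points into arcs A
and B; breakpoints take the side of their nearest boundary pixel and are
ranked along the arc, both sides running in the same spatial direction.

φ uses the two back-tangents a⃗₁, a⃗₂ and the connecting directions
a⃗₃ = unit(p₂−p₁), a⃗₄ = −a⃗₃: when the tangents are nearly anti-parallel
(angle above θ = 165°, taken in degrees) φ = 2π − ∠(a⃗₁,a⃗₃) − ∠(a⃗₂,a⃗₄);
otherwise φ = max(π − ∠(a⃗₁,a⃗₃), π − ∠(a⃗₂,a⃗₄)). Pairing minimizes total φ
over order-preserving (non-crossing) alignments by dynamic programming,
lexicographically maximizing the number of pairs with φ ≤ π/2 first; the DP
is verified against exhaustive enumeration for groups of up to six.
Unmatched breakpoints are forwarded: in marginal regions they are paired
with uniform bisection points of the segment between the two extremal
boundary points (fractions i/(n+1)); elsewhere they trigger the bifurcation
searches below.

## Restoration

For a matched pair, lines through each breakpoint and its ridge neighbor are
rotated by −20…20° in 10° steps; control points sit at fractions
{0.25, 0.5, 0.75, 1.0} of the distance from each endpoint to the rotated
lines' intersection (400 candidates/pair; parallel lines fall back to a
third of the endpoint gap along each direction). The unrotated candidate of
minimal maximum |B''| is the *reference*. Candidates are ranked by δ_ℓ with
n = 5 samples at t = i/n against the prior neighbor (the previously chosen
curve, or the nearest intact flank for the first pair) and the subsequent
neighbor (the next pair's reference candidate, or the far intact flank for
the last pair), sweeping the region side to side. With no intact flank at
all, references are used outright; with a single flank it serves as both
neighbors (single-sided judgment). As printed, the δ baseline does not
interpolate s₁ at i = 1 while its i = n term is always zero; the formula is
implemented literally, asymmetry and all.

A *latent* bifurcation (junction surviving on a region-adjacent ridge) is
sought among ridge points turning more than 25° over a 5-step secant window,
minimizing distance-to-opposite-breakpoint divided by turning angle — a
stated design choice, as the smoothness/distance trade-off is genuinely
open. The reconnecting curve uses the bifurcation point as both endpoint E₁
and control point C₁ (freeing the junction tangent), with C₂ on the broken
branch's tangent line at a δ-selected fraction of the endpoint gap.

A *covered* bifurcation is recognized when a forwarded breakpoint's best φ
partner is already claimed by a matched pair — one starting point
corresponding to two ending points. The claimed breakpoint becomes the main
track E₃; an isosceles right triangle with the right angle at its neighbor
P₃ and circumcenter at E₃ supplies the shared branch tangent (hypotenuse
vertices E₃ ± |E₃−P₃|·u, u ⊥ E₃−P₃). Temporary curves join the branches to
E₃; the refined estimate E₃′ is the midpoint of their t = 0.5 midpoints, the
main track is extended straight to E₃′, and the curves are rebuilt with a
fresh triangle anchored at E₃′ (E₃ taking the P₃ role — the construction is
"repeated", and this anchoring is the explicit reading chosen here).

Restored curves are rasterized and clipped to the damaged neighborhoods
(regions dilated by 2 px); original skeleton pixels are never modified.

## Synthetic data

The generator emulates the five standard pattern classes. Orientation
fields come from the zero-pole model θ(z) = ½Σ arg(z−cᵢ) − ½Σ arg(z−dⱼ)
(cores +½ Poincaré index, deltas −½; plain arch from a singularity-free
arch phase field). Singularity-free patterns are rendered directly from the
phase; patterns with cores/deltas evolve a seeded stripe field under
iterated oriented filtering at the target period (six iterations, 16
orientation bins, tanh squashing). Ground-truth skeletons are thinned from
the noise-free render and pruned of spur branches under 6 px; additive
Gaussian noise (σ = noise_level·128) models capture noise. Defaults: 300×300
px, period 8 px, noise 0 — a clean, dense print.

Controlled experiments use skeleton-level fixtures: parallel gratings,
concentric arcs, and a Y scene whose central ridge bifurcates (divergence
saturating at half a period so the final branch separation equals the
period, neighbors following a decaying envelope as around a real
bifurcation). Damage is scripted: elliptic patches filled with the estimated
background intensity for gray images, set subtraction for skeletons.

What passing these tests shows: the geometry of the method — detection,
matching, candidate selection, bifurcation reconstruction — behaves as
specified on clean, known-truth inputs. What they do not show: robustness to
real sensor artifacts (pores, scars, wet/dry smearing, low contrast), to
densely packed minutiae, or to the segmentation errors of real captures;
the stripe renders are far cleaner than genuine latents.

## Evaluation

Skeleton recovery is distance-transform based: recall is the fraction of
true skeleton pixels inside the damage mask within tolerance (2 px default)
of the restored image; precision the converse. The improvement ratio
r = (S_restore − S_frac)/(S_ideal − S_frac) is affine-invariant in the
matcher scale and undefined when the ideal and fractured scores coincide.
EER interpolates linearly where FMR and FNMR cross; FMR1000 is FNMR at the
lowest threshold achieving FMR ≤ 0.1% (the standard convention — the
highest-threshold reading would always be ≈1). Matcher scores are accepted
as CSV exports; no matcher is bundled.

On representation size: a 300×300 period-8 print yields roughly 300–450
spans, ~52 bytes per text line, i.e. ~20–25% of the uncompressed 90 kB
raster — but several times larger than the deflate-compressed PNG of so
sparse a binary image (~5 kB). The control-point text is a structured,
editable vector form, not a rate-optimal code; entropy coding is a
non-goal.

## Problem sizes

Defaults used by the test suite and `scripts/acceptance.py`: 10–20 synthetic
fingerprints at 300×300 for compression statistics, 20 seeded scenes each
for damage detection and end-to-end restoration, 50 sampled cubics for fit
round trips, 10⁴ scores per class for EER checks. These sizes give stable
means (restoration recall/precision vary by ~0.01 across seeds) while
keeping a full run in the minutes range on one CPU.

## Known limitations

- Junction *clusters* (adjacent junction pixels) are treated as separate
  nodes, so noisy renders produce many 2-px junction-to-junction segments;
  harmless for restoration but inflating curve counts.
- Marginal repair aims breakpoints at bisection points of the chord between
  the region's extremal boundary points; on strongly curved margins the
  chord is a crude stand-in for the lost edge ridge.
- The candidate grid is fixed (400/pair); pathological geometries needing
  rotations beyond ±20° fall back to visibly suboptimal curves.
- Restoration assumes the damage detector's region masks; damage it cannot
  see (below ~1.5 periods across) is never repaired.
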