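# Methods

## Model

A snake (parametric active contour) is a closed curve
X(s) = [x(s), y(s)], s ∈ [0, 1], that relaxes toward a minimum of

    E = ∫ ½ [ α |X′(s)|² + β |X″(s)|² ] + E_ext(X(s)) ds,

where α and β weight tension and rigidity and E_ext is an image-derived
potential. The stationarity condition is the force balance
α X″ − β X⁗ − ∇E_ext = 0; the curve is made dynamic,
X_t = α X″ − β X⁗ + F_ext, and stepped until the motion vanishes.

The package implements four standard external energies on an image
I(x, y) normalised to [0, 1]: E₁ = −|∇I|², E₂ = −|∇(G_σ ⊗ I)|², and the
line-drawing forms E₃ = I, E₄ = G_σ ⊗ I. The force is F = −∇E. All
derivatives are central differences (replicated borders), which keeps
the force perpendicular to boundaries at every orientation; convolution
uses reflected borders so the image frame does not attract the snake.

### Time discretisation

The dynamics are integrated with a semi-implicit scheme,

    (I − Δt·A) X_{k+1} = X_k + Δt·F_ext(X_k),

with A = α·D2/Δs² − β·D4/Δs⁴ under periodic (closed-curve) finite
differences. A is circulant, so each step is solved exactly by FFT
division in O(n log n). The scheme is unconditionally stable in the
internal term; the explicit external term limits the usable step (see
force scaling below). An explicit-Euler mode exists purely as a
cross-check at tiny Δt. "Equilibrium" is operationalised as a maximum
per-point displacement below `tol` (default 1e−3 px) or exhaustion of
the iteration budget, whichever comes first.

## Gradient vector flow (GVF)

The GVF field V = (u, v) minimises
ε = ∬ μ(u_x²+u_y²+v_x²+v_y²) + |∇f|²·|V−∇f|² dx dy for an edge map
f = −E_ext. Its Euler–Lagrange equations μ∇²u = (u−f_x)(f_x²+f_y²)
(and likewise v) are solved by the explicit Jacobi iteration

    u_{n+1} = (1 − b·Δt)·u_n + r·(u_E+u_S+u_W+u_N − 4u_n) + c1·Δt,

with b = f_x²+f_y², c1 = b·f_x, c2 = b·f_y and r = μΔt/(ΔxΔy), stable
for r ≤ 1/4. Choices:

* (u, v) initialised at ∇f, so the data term is satisfied at edges from
  step 0.
* Synchronous (Jacobi) updates keep the diffusion left–right symmetric
  by construction; a sequential two-pass sweep (left-to-right then
  right-to-left) is available for replication studies only.
* 5-point Laplacian with replicated borders; divergence guard at field
  magnitude 1e6, reporting the offending r.
* The r ≤ 1/4 bound comes from the pure-diffusion mode analysis
  (checkerboard amplification 1 − 8r). The data-term decay (1 − b·Δt)
  shifts the worst mode slightly *past* −1 where b is large, so a
  binary edge map can diverge at exactly r = 0.25; with a
  gradient-based edge map normalised to unit peak (b ≲ 0.15) the bound
  holds as printed. The stability experiment therefore uses the
  normalised E₂-based edge map of a square.

## Coordinate regeneration (CRM)

The coarse-to-fine scheme that replaces GVF diffusion:

1. build an external field from a heavily blurred copy of the image
   (long capture range, rough "virtual boundary");
2. run an ordinary snake on it;
3. *regenerate* the contour — each inter-point gap longer than the
   target spacing (default 1 px) is filled with interpolated points
   (linear by default, periodic cubic spline optional), keeping every
   original point and its order;
4. repeat on a less-blurred copy until the blur is negligible.

Regeneration is applied at the start of every stage (a no-op on
well-sampled contours), because snake evolution bunches points where
forces are strong and leaves long chords across concavity mouths — the
chords are exactly what the next, finer stage needs sample points on.
Stages stop early when a stage moves the contour by a mean displacement
below 0.1 px.

### Blur-scale mapping

The reference schedule for binary objects is three Gaussian stages of
nominal kernel length n = 16, 10, 2, mapped to pixel-domain sigmas
σ = n. The rationale is capture range: a kernel of length n extends a
boundary's blurred influence roughly n pixels, and the coarse stage
must reach a snake initialised ~15–20 px outside the object; σ = 7.5
(an (n−1)/2 mapping) was measured to strand such an initialisation.
LOG stages map kernel size n to σ = (n−1)/6 (±3σ support).

### Per-stage force scaling

Neither the energies nor the iteration counts fix the force magnitude,
so each stage's field is normalised to unit peak magnitude and scaled
by gain = strength·σ/Δt. Two constraints motivate this:

* travel: the normalised field decays like exp(−d²/σ²) away from the
  boundary; a maximum step of strength·σ per iteration lets a far
  initialisation cross the capture range within ~100 iterations;
* stability: near an edge the normalised field reverses sign with slope
  ≈ 2.3/σ, so the step–slope product is ≈ 2.3·strength, independent of
  scale, and stays below the oscillation limit (2) for strength < 0.86.

The reference schedule uses strength 0.8 for the travelling stages and
0.5 for the final settling stage.

### LOG stages and the optic-disc pipeline

For fundus images the stage fields are built from the
Laplacian-of-Gaussian response L: the stage energy is L², whose
negative gradient attracts the contour to the zero-crossing ring of L —
the locus where the field from the two sides of the disc rim balances.
For a bright disc the zero-crossing ring of a large-σ LOG lies outside
the true rim and moves onto it as σ shrinks, which is why the snake
first expands and then shrinks onto the boundary over the kernel
schedule {281, 211, 151, 111, 81, 51, 31, 11} (10 iterations each,
α = 0.2, β = 0, Δs = 1, Δt = 0.01).

The automatic pipeline: red channel (vessels have lowest contrast
there) → pixelwise max with a σ = 24 px Gaussian blur (smooths the
surround) → greyscale closing with a flat 10×10 element (erases
vessels, which are narrower than the element) → seed at the centre of
the 41 px window of maximal intensity variance → 300×300 working patch
→ circular snake of radius patch/6 (50 px, 64 points) → CRM with the
LOG schedule. The variance seed is computed on the *raw* channel: the
cue is the contrast of dark vessels crossing the bright disc, which the
enhancement and closing steps deliberately destroy. The seed typically
lands at a vessel crossing inside the disc, not at its centre; the
long-range first LOG stage makes the pipeline insensitive to that
offset.

## Synthetic phantoms

* `u_shape`: a disc (R = 70 px) with a rectangular notch (40×15 px) cut
  into the rim — a boundary concavity that defeats a single-scale snake
  from a far initialisation. A disc base shape keeps a circular far
  initialisation roughly equidistant from the boundary. The notch
  depth is configurable; the three-stage reference schedule resolves
  depths up to roughly 2σ of the middle stage, and deeper pockets need
  extra intermediate stages (the mid-to-fine capture gap leaves a
  residual at the pocket floor otherwise).
* `star`: a spiked polygon for distance-metric tests. Rasterisation
  truncates the last ~1 px of its acute tips; the truth contour is the
  analytic polygon.
* `disc_fundus`: bright disc (intensity 0.9, radius 45 px, centre
  jittered ±20 px) on a darker background (0.35) with a diagonal
  gradient (amplitude 0.15), crossed by 3 dark (0.15) vessels of width
  4–8 px radiating from the disc centre, plus optional clipped Gaussian
  noise. This emulates the features that matter to the algorithm —
  rim contrast, vessel distracters, background drift — and none of the
  photometric texture of real fundus photographs; passing tests
  demonstrate the mechanism, not clinical performance.

All generators are pure functions of their spec (seeded noise).

## Evaluation

`boundary_error` reports the mean/max distance from contour points to
the nearest truth-mask boundary pixel centre, and per-direction
diameter errors |est − true|/true·100 with widths measured as max−min
projections (horizontal, vertical, both diagonals). Truth widths are
measured on boundary pixel centres, which is exact on the axes and ~1%
small on the diagonals for circular masks — a rasterisation bias
documented rather than corrected.

## Problem sizes and numerical choices

Validation runs use 256² binary phantoms (three 100-iteration stages,
~600–900 contour points), 400² fundus phantoms (eight 10-iteration
stages on a 300² patch), 16² edge maps for the dense GVF oracle and
64² for stability bracketing. Ties in the variance seed break to the
smallest row then column; contours are stored counter-clockwise and
reoriented on input; degenerate regeneration inputs (perimeter
< 3×spacing) are rejected.

## Known limitations

* Concavity depth vs. schedule: see above; the stage list must be
  matched to the object's geometry (it is fully configurable).
* The diffusion stability boundary is edge-map dependent near the
  r = 1/4 corner case (data-term decay), as described.
* The variance seed assumes the disc is the brightest, highest-contrast
  structure; bright lesions would defeat it.
* Open snakes, topology changes and geometric (level-set) contours are
  out of scope.
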