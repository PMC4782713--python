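# crmsnake

Parametric active contours (snakes) with **coordinate regeneration** —
a coarse-to-fine alternative to gradient-vector-flow snakes — plus a
fully automatic optic-disc boundary detector for retinal fundus
images.

A snake is a closed curve X(s) evolved to minimise

    E = ∫ ½[ α|X′(s)|² + β|X″(s)|² ] + E_ext(X(s)) ds,

with image forces F = −∇E_ext. Plain snakes only converge when started
near the boundary and stall at concavities; GVF snakes fix the capture
range by diffusing the edge-map gradient (implemented here as well, via
the explicit iteration with its r = μΔt/(ΔxΔy) ≤ ¼ stability bound).
Coordinate regeneration takes a different route: run an ordinary snake
on a heavily Gaussian-blurred copy of the image (long-range field,
rough boundary), resample the resulting contour so the gaps left by
point bunching are filled by interpolation, and feed it to the next,
less-blurred stage. A shrinking blur schedule (nominal kernel lengths
n = 16, 10, 2 for binary objects; Laplacian-of-Gaussian kernel sizes
281 → 11 for fundus images) walks the contour into the exact boundary,
including concavities where both plain and GVF snakes fail.

Intended users: image-analysis researchers who need a transparent,
dependency-light 2-D boundary tracker with reproducible synthetic
benchmarks; the optic-disc pipeline doubles as a worked example of the
method on a realistic task.

## Worked example

Recover the boundary of a concave object (a disc with a notch) from a
circle initialised ≥ 15 px outside it — the configuration where a
single-scale snake fails:

```python
from crmsnake import (PhantomSpec, make_phantom, make_initial_circle,
                      default_concave_schedule, run_crm, boundary_error)

phantom = make_phantom(PhantomSpec(kind="u_shape", seed=1))
cx, cy = phantom.spec.resolved_centre()
init = make_initial_circle(cx, cy, 85, 64)          # >= 15 px outside everywhere
final, traces = run_crm(phantom.image, init, default_concave_schedule())
err = boundary_error(final, phantom.mask)
for t in traces:
    stage_err = boundary_error(t.final, phantom.mask)
    print(f"stage {t.index}: {t.n_points_regenerated} points, "
          f"mean error {stage_err.mean_distance:.2f} px")
print(f"final: mean {err.mean_distance:.2f} px, max {err.max_distance:.2f} px, "
      f"diameter error {err.mean_pct_diameter_error:.2f}%")
```

prints

```
stage 0: 576 points, mean error 1.43 px
stage 1: 712 points, mean error 0.56 px
stage 2: 826 points, mean error 0.56 px
final: mean 0.56 px, max 0.91 px, diameter error 0.72%
```

The 64-point initial circle grows to 826 points as regeneration fills
the gaps the forces tear open; the mean boundary error drops below a
pixel after the coarse stage and settles at ~0.5 px. The same snake on
the unblurred image stays several pixels away (`mean > 3 px`).

The command-line interface exposes the same operations
(`crmsnake make-phantom | gvf-field | snake | crm | disc-segment |
evaluate`); every run writes a provenance record next to its outputs.
The disc detector is one call:

```
crmsnake make-phantom --kind disc_fundus --seed 4 --out-dir fundus
crmsnake disc-segment --image fundus/image.png --out-contour disc.csv --overlay overlay.png
# -> disc contour written to disc.csv (seed (236, 213),
#    stage radii [72.4, 66.3, 56.9, 51.9, 49.0, 46.4, 45.2, 44.7])
```

The stage radii show the characteristic expand-then-shrink behaviour:
the large first LOG kernel balances the snake outside the true rim
(radius 72 vs. a true 45), and the shrinking kernels walk it back onto
the boundary.

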