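"""Deterministic phantom generators with known ground-truth boundaries.

Two families of test objects:

* binary shapes with deep boundary concavities (``u_shape``: a square
  with a rectangular notch; ``star``: a spiked polygon) — the classic
  hard cases for snake convergence; and
* ``disc_fundus``: a fundus-like greyscale image with a bright circular
  disc on a darker background gradient, crossed by dark curvilinear
  vessel distracters radiating from the disc centre.

Every generator is a pure function of its spec (noise is drawn from a
seeded generator), so fixtures regenerate identically across runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from skimage.draw import polygon2mask

from .exceptions import InvalidParameterError
from .snake_core import Contour

__all__ = ["PhantomSpec", "Phantom", "make_phantom", "make_initial_circle"]


@dataclass
class PhantomSpec:
    """Parameters of a synthetic test object.

    Geometry fields are interpreted per ``kind``; unused fields are
    ignored.  ``centre`` is (x, y); ``None`` picks the image centre
    (``disc_fundus`` jitters it by up to ±20 px from the seed so the
    disc is not always perfectly centred).  For ``disc_fundus`` the
    default 256² canvas is widened to 400² so a 300² working patch
    always fits.
    """

    kind: str = "u_shape"
    size: tuple[int, int] = (256, 256)  # (height, width)
    centre: tuple[float, float] | None = None
    noise_sd: float = 0.0
    seed: int = 0
    # u_shape geometry (px): a disc with a rectangular notch cut from the top
    u_radius: float = 70.0
    notch_width: float = 40.0
    notch_depth: float = 15.0
    # star geometry
    n_spikes: int = 5
    r_inner: float = 20.0
    r_outer: float = 50.0
    # disc_fundus geometry
    disc_radius: float = 45.0
    disc_intensity: float = 0.9
    background: float = 0.35
    gradient_amplitude: float = 0.15
    n_vessels: int = 3
    vessel_width_range: tuple[float, float] = (4.0, 8.0)
    vessel_intensity: float = 0.15

    def __post_init__(self) -> None:
        if self.kind not in ("u_shape", "star", "disc_fundus"):
            raise InvalidParameterError(f"unknown phantom kind {self.kind!r}")
        if self.noise_sd < 0:
            raise InvalidParameterError("noise_sd must be >= 0")
        h, w = self.size
        margin = 10.0
        if self.kind == "u_shape":
            extent = self.u_radius
            if not 0 < self.notch_width < 2 * self.u_radius:
                raise InvalidParameterError("notch_width must lie in (0, 2*u_radius)")
            if not 0 < self.notch_depth < self.u_radius + math.sqrt(
                self.u_radius**2 - (self.notch_width / 2.0) ** 2
            ):
                raise InvalidParameterError("notch_depth must keep the notch inside the disc")
        elif self.kind == "star":
            extent = self.r_outer
        else:
            if self.size == (256, 256):
                self.size = (400, 400)
                h, w = self.size
            extent = self.disc_radius
        cx, cy = self.resolved_centre()
        if (cx - extent < margin or cy - extent < margin
                or cx + extent > w - margin or cy + extent > h - margin):
            raise InvalidParameterError(
                f"{self.kind} geometry (extent {extent}) does not fit in {self.size} "
                "with a 10 px margin"
            )

    def resolved_centre(self) -> tuple[float, float]:
        if self.centre is not None:
            return self.centre
        h, w = self.size
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        if self.kind == "disc_fundus":
            rng = np.random.default_rng(self.seed)
            jit = rng.uniform(-20.0, 20.0, size=2)
            return (cx + jit[0], cy + jit[1])
        return (cx, cy)


@dataclass
class Phantom:
    """Rendered phantom: image, filled truth mask, sub-pixel truth boundary."""

    image: np.ndarray
    mask: np.ndarray
    boundary: Contour
    spec: PhantomSpec


def _densify(vertices: np.ndarray, spacing: float = 0.5) -> np.ndarray:
    out = []
    n = len(vertices)
    for i in range(n):
        a, b = vertices[i], vertices[(i + 1) % n]
        seg = b - a
        length = math.hypot(*seg)
        k = max(1, math.ceil(length / spacing))
        for j in range(k):
            out.append(a + seg * (j / k))
    return np.asarray(out)


def _polygon_phantom(vertices: np.ndarray, spec: PhantomSpec) -> Phantom:
    mask = polygon2mask(spec.size, vertices[:, ::-1])  # polygon2mask wants (row, col)
    image = mask.astype(float)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        image = np.clip(image + rng.normal(0.0, spec.noise_sd, image.shape), 0.0, 1.0)
    boundary = Contour(_densify(vertices)).oriented_ccw()
    return Phantom(image=image, mask=mask, boundary=boundary, spec=spec)


def _u_shape_vertices(spec: PhantomSpec) -> np.ndarray:
    """Disc of radius R with a rectangular notch cut in from the top edge.

    The two lobes either side of the notch are the "arms" of the U; a
    circle slightly larger than the disc is everywhere roughly the same
    distance from the boundary, which makes this the reference object for
    circular far initialisations.
    """
    cx, cy = spec.resolved_centre()
    R = spec.u_radius
    half_w = spec.notch_width / 2.0
    wall_dy = math.sqrt(R**2 - half_w**2)  # walls meet the circle at cy - wall_dy
    notch_bottom = cy - R + spec.notch_depth

    # arc from the right wall/circle junction, the long way round (through
    # the bottom of the disc), to the left wall/circle junction
    theta_right = math.atan2(-wall_dy, half_w)
    theta_left = math.atan2(-wall_dy, -half_w) + 2.0 * math.pi
    theta = np.linspace(theta_right, theta_left, 181)[:-1]
    arc = np.column_stack([cx + R * np.cos(theta), cy + R * np.sin(theta)])

    slot = np.asarray([
        (cx - half_w, cy - wall_dy),
        (cx - half_w, notch_bottom),
        (cx + half_w, notch_bottom),
        (cx + half_w, cy - wall_dy),
    ])
    # slot[-1] coincides with arc[0] (the contour is closed implicitly)
    return np.vstack([arc, slot[:-1]])


def _star_vertices(spec: PhantomSpec) -> np.ndarray:
    cx, cy = spec.resolved_centre()
    angles = np.arange(2 * spec.n_spikes) * math.pi / spec.n_spikes
    radii = np.where(np.arange(2 * spec.n_spikes) % 2 == 0, spec.r_outer, spec.r_inner)
    return np.column_stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)])


def _disc_fundus(spec: PhantomSpec) -> Phantom:
    h, w = spec.size
    cx, cy = spec.resolved_centre()
    # separate stream from the centre jitter (which consumes default_rng(seed))
    rng = np.random.default_rng([spec.seed, 1])
    yy, xx = np.mgrid[0:h, 0:w].astype(float)

    # smooth diagonal background gradient around the base level
    image = spec.background + spec.gradient_amplitude * (
        (xx / (w - 1) - 0.5) + (yy / (h - 1) - 0.5)
    )

    # bright disc with a ~2 px soft edge (anti-aliased)
    rho = np.hypot(xx - cx, yy - cy)
    blend = np.clip((spec.disc_radius - rho) / 2.0 + 0.5, 0.0, 1.0)
    image = image * (1.0 - blend) + spec.disc_intensity * blend

    # dark vessels: rays from the disc centre to beyond the frame
    reach = 2.0 * max(h, w)
    for _ in range(spec.n_vessels):
        theta = rng.uniform(0.0, 2.0 * math.pi)
        width = rng.uniform(*spec.vessel_width_range)
        dx_, dy_ = math.cos(theta), math.sin(theta)
        # distance from each pixel to the ray (clamped to the segment)
        t = np.clip((xx - cx) * dx_ + (yy - cy) * dy_, 0.0, reach)
        dist = np.hypot(xx - (cx + t * dx_), yy - (cy + t * dy_))
        vblend = np.clip((width / 2.0 - dist) / 1.0 + 0.5, 0.0, 1.0)
        image = image * (1.0 - vblend) + spec.vessel_intensity * vblend

    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, image.shape)
    image = np.clip(image, 0.0, 1.0)

    mask = rho <= spec.disc_radius
    n_pts = max(64, int(2.0 * math.pi * spec.disc_radius))
    boundary = make_initial_circle(cx, cy, spec.disc_radius, n_pts)
    return Phantom(image=image, mask=mask, boundary=boundary, spec=spec)


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Render a phantom image with its ground-truth mask and boundary."""
    if spec.kind == "u_shape":
        return _polygon_phantom(_u_shape_vertices(spec), spec)
    if spec.kind == "star":
        return _polygon_phantom(_star_vertices(spec), spec)
    return _disc_fundus(spec)


def make_initial_circle(cx: float, cy: float, r: float, n_points: int = 64) -> Contour:
    """``n_points`` equally spaced points on a circle, CCW, starting at angle 0."""
    if n_points < 3:
        raise InvalidParameterError("a circle contour needs >= 3 points")
    if not r > 0:
        raise InvalidParameterError("radius must be positive")
    theta = 2.0 * math.pi * np.arange(n_points) / n_points
    return Contour(np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)]))
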