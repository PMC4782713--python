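"""Closed parametric snake evolution under internal and external forces.

A snake is a closed curve X(s) = [x(s), y(s)] that relaxes toward a
minimum of

    E = ∫ ½ [ α |X'(s)|² + β |X''(s)|² ] + E_ext(X(s)) ds,

whose stationary condition is the force balance
α X''(s) − β X''''(s) − ∇E_ext = 0.  The curve is made dynamic,
X_t = α X'' − β X'''' + F_ext, and stepped to equilibrium with a
semi-implicit scheme: the stiff internal term is treated implicitly and
the sampled external force explicitly,

    (I − Δt·A) X_{k+1} = X_k + Δt·F_ext(X_k),

where A = α D2/Δs² − β D4/Δs⁴ with periodic (closed-curve) finite
differences.  A is circulant, so each step is two FFT solves.  An
explicit-Euler mode exists for cross-checking at tiny Δt.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import InvalidInputError, InvalidParameterError, NumericalDivergenceError
from .image_ops import VectorField

__all__ = ["Contour", "SnakeParams", "internal_force_operator", "sample_field", "evolve"]


@dataclass
class Contour:
    """An ordered closed planar curve of (x, y) points.

    Coordinates are 0-based pixel centres, x = column, y = row.  Contours
    are stored counter-clockwise in coordinate space (positive shoelace
    area); use :meth:`oriented_ccw` to normalise an input curve.
    """

    points: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise InvalidInputError(f"contour points must have shape (n, 2), got {pts.shape}")
        if pts.shape[0] < 3:
            raise InvalidInputError(f"a contour needs >= 3 points, got {pts.shape[0]}")
        if not np.all(np.isfinite(pts)):
            raise InvalidInputError("contour contains non-finite coordinates")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.points[:, 1]

    def signed_area(self) -> float:
        x, y = self.x, self.y
        return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def oriented_ccw(self) -> "Contour":
        if self.signed_area() < 0:
            return Contour(self.points[::-1].copy(), closed=self.closed)
        return self

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def perimeter(self) -> float:
        seg = np.roll(self.points, -1, axis=0) - self.points
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    def mean_radius(self, centre: np.ndarray | None = None) -> float:
        c = self.centroid() if centre is None else np.asarray(centre, dtype=float)
        d = self.points - c
        return float(np.hypot(d[:, 0], d[:, 1]).mean())


@dataclass
class SnakeParams:
    """Snake evolution parameters.

    alpha, beta     tension and rigidity weights (>= 0)
    delta_s         arclength step between contour points, px
    delta_t         time step of the evolution
    iterations      iteration budget for one run
    gain            global multiplier on the sampled external force
    tol             stop early when the max per-point displacement of an
                    iteration falls below this (px); None disables
    """

    alpha: float = 0.2
    beta: float = 0.0
    delta_s: float = 1.0
    delta_t: float = 0.01
    iterations: int = 100
    gain: float = 1.0
    tol: float | None = 1e-3

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise InvalidParameterError("alpha and beta must be non-negative")
        if not (self.delta_s > 0 and self.delta_t > 0):
            raise InvalidParameterError("delta_s and delta_t must be positive")
        if self.iterations < 1:
            raise InvalidParameterError("iterations must be >= 1")


def _operator_column(n_points: int, params: SnakeParams) -> np.ndarray:
    """First column of the circulant internal-force operator A."""
    min_pts = 5 if params.beta > 0 else 3
    if n_points < min_pts:
        raise InvalidParameterError(
            f"need >= {min_pts} points for alpha={params.alpha}, beta={params.beta}, "
            f"got {n_points}"
        )
    a = params.alpha / params.delta_s**2
    b = params.beta / params.delta_s**4
    col = np.zeros(n_points)
    col[0] = -2.0 * a - 6.0 * b
    col[1] += a + 4.0 * b
    col[-1] += a + 4.0 * b
    col[2 % n_points] += -b
    col[-2 % n_points] += -b
    return col


def internal_force_operator(n_points: int, params: SnakeParams) -> np.ndarray:
    """Dense cyclic banded matrix A = α·D2/Δs² − β·D4/Δs⁴ (periodic).

    The same operator acts independently on the x and y coordinate
    vectors of the contour.
    """
    col = _operator_column(n_points, params)
    idx = (np.arange(n_points)[:, None] - np.arange(n_points)[None, :]) % n_points
    return col[idx]


def sample_field(field: VectorField, pts: np.ndarray | Contour) -> np.ndarray:
    """Bilinearly interpolate (u, v) at contour positions.

    Points outside the grid are clamped to the nearest boundary pixel.
    Returns an (n, 2) array of force vectors.
    """
    if isinstance(pts, Contour):
        pts = pts.points
    pts = np.asarray(pts, dtype=float)
    if pts.size == 0:
        raise InvalidParameterError("cannot sample a field at zero points")
    coords = np.vstack([pts[:, 1], pts[:, 0]])  # map_coordinates wants (row, col)
    fu = ndimage.map_coordinates(field.u, coords, order=1, mode="nearest")
    fv = ndimage.map_coordinates(field.v, coords, order=1, mode="nearest")
    return np.column_stack([fu, fv])


def evolve(
    contour: Contour,
    field: VectorField,
    params: SnakeParams,
    explicit: bool = False,
) -> tuple[Contour, np.ndarray]:
    """Run the snake for up to ``params.iterations`` steps.

    Returns the final contour and the per-iteration maximum point
    displacement (the convergence trace).  ``explicit=True`` selects the
    forward-Euler scheme, used only for oracle cross-checks at tiny Δt.
    """
    X = contour.points.copy()
    n = X.shape[0]
    col = _operator_column(n, params)
    dt = params.delta_t

    identity_system = bool(np.all(col == 0.0))
    if not explicit and not identity_system:
        sys_col = -dt * col
        sys_col[0] += 1.0
        denom = np.fft.fft(sys_col)
        if np.any(np.abs(denom) < 1e-12):
            raise NumericalDivergenceError(
                "singular semi-implicit system (I - dt*A); check alpha/beta/delta_t"
            )

    trace = []
    for _ in range(params.iterations):
        F = sample_field(field, X) * params.gain
        if explicit:
            AX = np.real(np.fft.ifft(
                np.fft.fft(col)[:, None] * np.fft.fft(X, axis=0), axis=0))
            X_new = X + dt * (AX + F)
        elif identity_system:
            X_new = X + dt * F  # internal operator vanishes; no solve needed
        else:
            b = X + dt * F
            X_new = np.real(np.fft.ifft(np.fft.fft(b, axis=0) / denom[:, None], axis=0))
        disp = float(np.hypot(*(X_new - X).T).max())
        trace.append(disp)
        X = X_new
        if not np.all(np.isfinite(X)):
            raise NumericalDivergenceError("snake evolution produced non-finite coordinates")
        if params.tol is not None and disp < params.tol:
            break
    return Contour(X, closed=contour.closed), np.asarray(trace)
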