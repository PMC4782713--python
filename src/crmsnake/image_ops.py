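"""Edge maps, Gaussian / Laplacian-of-Gaussian filtering, and image force fields.

Images are 2-D ``numpy`` arrays of finite intensities, normalised to ``[0, 1]``
on load (:mod:`crmsnake.io`).  The coordinate convention throughout the
package is 0-based pixel centres with ``x`` = column and ``y`` = row.

The external energies follow the classical snake formulation: for a grey
image :math:`I(x, y)` the four standard choices are

* ``variant=1``:  :math:`E = -|\\nabla I|^2`
* ``variant=2``:  :math:`E = -|\\nabla (G_\\sigma \\otimes I)|^2`
* ``variant=3``:  :math:`E = I` (line-drawing convention)
* ``variant=4``:  :math:`E = G_\\sigma \\otimes I`

and the potential force that drives a snake is :math:`F = -\\nabla E`.
All spatial derivatives are central differences; image borders are
replicated for differentiation and reflected for convolution, so that the
frame of the image does not itself generate spurious edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal

from .exceptions import InvalidInputError, InvalidParameterError

__all__ = [
    "VectorField",
    "KernelSpec",
    "as_image",
    "sigma_from_n",
    "gaussian_blur",
    "log_kernel",
    "log_filter",
    "edge_energy",
    "gradient_central",
    "potential_force_field",
    "normalise_field",
]

#: kernel area above which convolution switches to the FFT path
FFT_KERNEL_AREA_THRESHOLD = 31 * 31


@dataclass(frozen=True)
class VectorField:
    """A planar vector field sampled on the pixel grid.

    ``u`` holds the x-components (columns), ``v`` the y-components (rows);
    both share the shape of the source image.
    """

    u: np.ndarray
    v: np.ndarray

    def __post_init__(self) -> None:
        u = np.asarray(self.u, dtype=float)
        v = np.asarray(self.v, dtype=float)
        if u.shape != v.shape or u.ndim != 2:
            raise InvalidInputError(
                f"u and v must be 2-D arrays of identical shape, got {u.shape} and {v.shape}"
            )
        if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
            raise InvalidInputError("vector field contains non-finite entries")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "v", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.u.shape

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)


@dataclass(frozen=True)
class KernelSpec:
    """Specification of a Gaussian or Laplacian-of-Gaussian kernel.

    ``n`` is the nominal kernel length in pixels; ``sigma`` the standard
    deviation in pixels.  Either may be omitted: a missing ``sigma`` is
    derived from ``n`` (Gaussian: ``(n-1)/2`` so the length-``n`` support
    covers about ±2σ; LOG: ``(n-1)/6`` for ±3σ), and a missing ``n`` from
    ``sigma`` (odd length covering ±3σ).
    """

    kind: str
    n: int | None = None
    sigma: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("gaussian", "log"):
            raise InvalidParameterError(f"unknown kernel kind {self.kind!r}")
        if self.n is None and self.sigma is None:
            raise InvalidParameterError("KernelSpec needs n and/or sigma")
        if self.n is not None and self.n < 2:
            raise InvalidParameterError(f"kernel length n must be >= 2, got {self.n}")
        if self.sigma is not None and not self.sigma > 0:
            raise InvalidParameterError(f"sigma must be positive, got {self.sigma}")

    def resolved_sigma(self) -> float:
        if self.sigma is not None:
            return float(self.sigma)
        assert self.n is not None
        if self.kind == "gaussian":
            return (self.n - 1) / 2.0
        return max((self.n - 1) / 6.0, 0.5)

    def resolved_length(self) -> int:
        """Odd sampling length: max(n, 2*ceil(3 sigma)+1), even n rounded up."""
        sigma = self.resolved_sigma()
        length = 2 * math.ceil(3.0 * sigma) + 1
        if self.n is not None:
            length = max(length, self.n + 1 if self.n % 2 == 0 else self.n)
        return length


def as_image(img: np.ndarray, min_size: int = 1) -> np.ndarray:
    """Validate and return ``img`` as a finite 2-D float array."""
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise InvalidInputError(f"expected a 2-D image, got shape {arr.shape}")
    if arr.shape[0] < min_size or arr.shape[1] < min_size:
        raise InvalidParameterError(
            f"image of shape {arr.shape} smaller than required {min_size}x{min_size}"
        )
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("image contains non-finite values")
    return arr


def sigma_from_n(n: int, scale: float = 1.0 / 62.0) -> float:
    """Map a blur kernel length ``n`` to a standard deviation ``scale*(n-1)``.

    With the default ``scale = 1/62`` this is the printed coarse-to-fine
    blur rule σ=(n−1)/62.  Taken literally in pixel units it yields
    sub-pixel sigmas, so the blurring stages of :mod:`crmsnake.crm` use a
    separate pixel-domain mapping (``(n-1)/2``, see :class:`KernelSpec`);
    this function exists to keep the published rule available verbatim.
    """
    if n < 2:
        raise InvalidParameterError(f"n must be >= 2, got {n}")
    if not scale > 0:
        raise InvalidParameterError(f"scale must be positive, got {scale}")
    return scale * (n - 1)


def gaussian_blur(img: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Convolve with a unit-sum Gaussian, reflected boundary."""
    if spec.kind != "gaussian":
        raise InvalidParameterError(f"gaussian_blur needs kind='gaussian', got {spec.kind!r}")
    arr = as_image(img)
    sigma = spec.resolved_sigma()
    radius = (spec.resolved_length() - 1) // 2
    return ndimage.gaussian_filter(arr, sigma=sigma, mode="reflect", truncate=radius / sigma)


def log_kernel(spec: KernelSpec) -> np.ndarray:
    """Sampled Laplacian-of-Gaussian kernel, corrected to zero sum.

    The continuous kernel is ∇²G_σ; sampling breaks the zero-integral
    property, so the discrete mean is subtracted (the standard correction)
    to make the kernel annihilate constants exactly.
    """
    if spec.kind != "log":
        raise InvalidParameterError(f"log_kernel needs kind='log', got {spec.kind!r}")
    sigma = spec.resolved_sigma()
    length = spec.resolved_length()
    half = (length - 1) // 2
    x = np.arange(-half, half + 1, dtype=float)
    xx, yy = np.meshgrid(x, x)
    r2 = xx**2 + yy**2
    kern = (r2 - 2.0 * sigma**2) / sigma**4 * np.exp(-r2 / (2.0 * sigma**2))
    kern -= kern.mean()
    return kern


def _convolve_reflect(img: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Same-size convolution with symmetric (reflected) boundary.

    Direct convolution for small kernels; FFT (overlap-free, identical up to
    roundoff) once the kernel area passes ``FFT_KERNEL_AREA_THRESHOLD``.
    """
    kh, kw = kernel.shape
    if kh > img.shape[0] or kw > img.shape[1]:
        raise InvalidParameterError(
            f"kernel {kernel.shape} larger than image {img.shape}"
        )
    pad_y, pad_x = kh // 2, kw // 2
    padded = np.pad(img, ((pad_y, pad_y), (pad_x, pad_x)), mode="symmetric")
    method = "fft" if kernel.size > FFT_KERNEL_AREA_THRESHOLD else "direct"
    return signal.convolve(padded, kernel, mode="valid", method=method)


def log_filter(img: np.ndarray, spec: KernelSpec) -> np.ndarray:
    """Laplacian-of-Gaussian response of the image (same shape)."""
    arr = as_image(img)
    return _convolve_reflect(arr, log_kernel(spec))


def gradient_central(img: np.ndarray) -> VectorField:
    """Central-difference gradient with replicated borders.

    Interior pixels use ``(f[i+1] - f[i-1]) / 2`` along each axis; at the
    border the out-of-range sample is replicated, halving the one-sided
    difference.  Central differences keep the force perpendicular to
    boundaries in every orientation, which one-sided stencils do not.
    """
    arr = as_image(img, min_size=3)
    p = np.pad(arr, 1, mode="edge")
    u = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0
    v = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0
    return VectorField(u=u, v=v)


def edge_energy(
    img: np.ndarray, variant: int, spec: KernelSpec | None = None
) -> np.ndarray:
    """One of the four classical external energies (see module docstring)."""
    arr = as_image(img)
    if variant == 1:
        g = gradient_central(arr)
        return -(g.u**2 + g.v**2)
    if variant == 2:
        if spec is None:
            raise InvalidParameterError("variant 2 requires a Gaussian KernelSpec")
        g = gradient_central(gaussian_blur(arr, spec))
        return -(g.u**2 + g.v**2)
    if variant == 3:
        return arr.copy()
    if variant == 4:
        if spec is None:
            raise InvalidParameterError("variant 4 requires a Gaussian KernelSpec")
        return gaussian_blur(arr, spec)
    raise InvalidParameterError(f"unknown edge-energy variant {variant!r}")


def potential_force_field(
    img: np.ndarray, variant: int = 1, spec: KernelSpec | None = None
) -> VectorField:
    """Potential force ``F = -grad(E)`` of the selected edge energy."""
    grad = gradient_central(edge_energy(img, variant, spec))
    return VectorField(u=-grad.u, v=-grad.v)


def normalise_field(field: VectorField) -> VectorField:
    """Scale a field so its maximum magnitude is 1 (no-op on a zero field)."""
    peak = float(field.magnitude().max())
    if peak == 0.0:
        return field
    return VectorField(u=field.u / peak, v=field.v / peak)
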