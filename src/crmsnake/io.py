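"""Raster and contour I/O plus run provenance records.

Conventions (stated in every output header): coordinates are 0-based
pixel centres, x = column, y = row, y increasing downward.  Images are
scaled to [0, 1] on load (8-bit by 255, 16-bit by 65535).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .exceptions import InvalidInputError
from .snake_core import Contour

__all__ = [
    "load_image",
    "save_image",
    "read_contour",
    "write_contour",
    "write_provenance",
]

COORD_NOTE = "0-based pixel-centre coordinates, x=column, y=row"


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF/PGM raster, scaled to [0, 1].

    Returns a 2-D array for greyscale input and an (H, W, 3) array for
    colour (an alpha channel is dropped).
    """
    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # pragma: no cover - backend specific
        raise InvalidInputError(f"cannot read image {path}: {exc}") from exc
    if arr.dtype == np.uint8:
        out = arr.astype(float) / 255.0
    elif arr.dtype == np.uint16:
        out = arr.astype(float) / 65535.0
    elif np.issubdtype(arr.dtype, np.integer):
        out = arr.astype(float) / float(np.iinfo(arr.dtype).max)
    else:
        out = np.clip(arr.astype(float), 0.0, 1.0)
    if out.ndim == 3 and out.shape[-1] == 4:
        out = out[..., :3]
    if out.ndim not in (2, 3):
        raise InvalidInputError(f"unsupported image dimensionality {arr.shape} in {path}")
    return out


def save_image(path: str | Path, img: np.ndarray) -> None:
    """Write an image (values in [0, 1]) as an 8-bit raster."""
    arr = np.clip(np.asarray(img, dtype=float), 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255.0 + 0.5).astype(np.uint8))


def write_contour(path: str | Path, contour: Contour) -> None:
    """Write a contour as CSV (``.csv``) or JSON (anything else)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        lines = [f"# {COORD_NOTE}", "x,y"]
        lines += [f"{float(x)!r},{float(y)!r}" for x, y in contour.points]
        path.write_text("\n".join(lines) + "\n")
    else:
        path.write_text(
            json.dumps(
                {
                    "points": contour.points.tolist(),
                    "closed": contour.closed,
                    "coordinate_convention": COORD_NOTE,
                },
                indent=1,
            )
        )


def read_contour(path: str | Path) -> Contour:
    """Read a contour written by :func:`write_contour` (CSV or JSON)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        pts = []
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#") or line.lower().startswith("x,"):
                continue
            parts = line.split(",")
            try:
                pts.append((float(parts[0]), float(parts[1])))
            except (IndexError, ValueError) as exc:
                raise InvalidInputError(f"{path}:{lineno}: malformed row {line!r}") from exc
        return Contour(np.asarray(pts, dtype=float))
    try:
        payload = json.loads(path.read_text())
        return Contour(np.asarray(payload["points"], dtype=float),
                       closed=bool(payload.get("closed", True)))
    except (KeyError, json.JSONDecodeError) as exc:
        raise InvalidInputError(f"{path}: malformed contour JSON: {exc}") from exc


def write_provenance(path: str | Path, config: dict, seed: int | None = None) -> None:
    """Write a machine-readable record of a run (config + versions + seed)."""
    import scipy

    from . import __version__

    record = {
        "crmsnake": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "seed": seed,
        "config": config,
    }
    Path(path).write_text(json.dumps(record, indent=1, default=str))
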