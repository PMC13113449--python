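"""Fovea-centered concentric annular partition of an en-face OCTA image.

An image is divided into ``N = ceil(r_max / R)`` annuli of radial step ``R``
pixels around the foveal center, where ``r_max`` is the distance from the
center to the nearest image border.  The outermost annulus is truncated at
``r_max`` when ``r_max`` is not a multiple of ``R`` (e.g. a 1024x1024 scan
with R=75 yields seven annuli with boundaries 0, 75, ..., 450, 512).  Each
annulus is half-open ``[r_in, r_out)``; the last is closed at ``r_max`` so
the partition covers the inscribed disk exactly once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RegionScheme",
    "RegionMaskSet",
    "build_region_scheme",
    "compute_region_masks",
    "analytic_region_area",
    "export_label_image",
]


@dataclass(frozen=True)
class RegionScheme:
    """Geometry of the concentric partition.

    Attributes
    ----------
    center : (float, float)
        Foveal center in (row, col) pixel coordinates.
    radial_step : float
        Radial increment R between annulus boundaries, in pixels.
    r_max : float
        Outer radial limit: distance from the center to the nearest
        image border.
    n_regions : int
        Number of annuli, ``ceil(r_max / R)``.
    boundaries : tuple of float
        ``n_regions + 1`` radii, ``0, R, 2R, ..., r_max``.
    """

    center: tuple[float, float]
    radial_step: float
    r_max: float
    n_regions: int
    boundaries: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n_regions != math.ceil(self.r_max / self.radial_step):
            raise ValueError("n_regions inconsistent with r_max / radial_step")
        b = np.asarray(self.boundaries, dtype=float)
        if len(b) != self.n_regions + 1 or b[0] != 0 or b[-1] != self.r_max:
            raise ValueError("boundaries must run from 0 to r_max")
        if np.any(np.diff(b) <= 0):
            raise ValueError("boundaries must be strictly increasing")


@dataclass(frozen=True)
class RegionMaskSet:
    """Binary masks of the annuli, pairwise disjoint, covering the
    inscribed disk of radius ``r_max``."""

    image_shape: tuple[int, int]
    masks: tuple[np.ndarray, ...] = field(repr=False)

    @property
    def n_regions(self) -> int:
        return len(self.masks)

    def label_image(self) -> np.ndarray:
        """8-bit label map: 0 outside every annulus, k for annulus k (1-based)."""
        lab = np.zeros(self.image_shape, dtype=np.uint8)
        for k, m in enumerate(self.masks, start=1):
            lab[m] = k
        return lab


def _default_center(image_shape: tuple[int, int]) -> tuple[float, float]:
    h, w = image_shape
    return ((h - 1) / 2.0, (w - 1) / 2.0)


def build_region_scheme(
    image_shape: tuple[int, int],
    radial_step: float = 75.0,
    center: tuple[float, float] | None = None,
) -> RegionScheme:
    """Construct the concentric annular scheme for an image.

    ``r_max`` is the distance from the center to the nearest physical image
    border (512 for a fovea-centered 1024x1024 scan).  The number of annuli
    is ``ceil(r_max / R)``; the outermost annulus is truncated at ``r_max``.

    Parameters
    ----------
    image_shape : (height, width)
    radial_step : float
        Radial increment R in pixels (default 75, the configuration that
        yields seven annuli on a 1024-pixel scan).
    center : (row, col), optional
        Foveal center override; defaults to the geometric image center
        (scans are fovea-centered by acquisition protocol).
    """
    h, w = int(image_shape[0]), int(image_shape[1])
    if h < 1 or w < 1:
        raise ValueError(f"image shape {image_shape!r} is degenerate")
    if radial_step <= 0:
        raise ValueError(f"radial step must be positive, got {radial_step}")
    if center is None:
        center = _default_center((h, w))
    cr, cc = float(center[0]), float(center[1])
    if not (-0.5 <= cr <= h - 0.5 and -0.5 <= cc <= w - 0.5):
        raise ValueError(f"center {center!r} lies outside a {h}x{w} image")
    # distance from the center to the nearest physical border (pixel i spans
    # [i-0.5, i+0.5], so borders sit at -0.5 and dim-0.5)
    r_max = min(cr + 0.5, h - 0.5 - cr, cc + 0.5, w - 0.5 - cc)
    if r_max < 1:
        raise ValueError(
            f"center {center!r} is within 1 px of the border; no annulus fits"
        )
    n = math.ceil(r_max / radial_step)
    bounds = [i * radial_step for i in range(n)] + [r_max]
    return RegionScheme(
        center=(cr, cc),
        radial_step=float(radial_step),
        r_max=float(r_max),
        n_regions=n,
        boundaries=tuple(float(b) for b in bounds),
    )


def _distance_map(scheme: RegionScheme, image_shape: tuple[int, int]) -> np.ndarray:
    h, w = image_shape
    rows = np.arange(h, dtype=float)[:, None] - scheme.center[0]
    cols = np.arange(w, dtype=float)[None, :] - scheme.center[1]
    return np.hypot(rows, cols)


def compute_region_masks(
    scheme: RegionScheme, image_shape: tuple[int, int]
) -> RegionMaskSet:
    """Rasterize the scheme into per-annulus binary masks.

    A pixel (taken at its integer-grid center) belongs to annulus *i* iff
    ``boundaries[i-1] <= d < boundaries[i]``; the final annulus is closed
    at ``r_max``.  Pixels beyond ``r_max`` (image corners) belong to no
    annulus.
    """
    h, w = int(image_shape[0]), int(image_shape[1])
    cr, cc = scheme.center
    if not (-0.5 <= cr <= h - 0.5 and -0.5 <= cc <= w - 0.5):
        raise ValueError(f"scheme center {scheme.center!r} outside {h}x{w} image")
    d = _distance_map(scheme, (h, w))
    b = scheme.boundaries
    masks = []
    for i in range(scheme.n_regions):
        if i < scheme.n_regions - 1:
            masks.append((d >= b[i]) & (d < b[i + 1]))
        else:
            masks.append((d >= b[i]) & (d <= b[i + 1]))
    return RegionMaskSet(image_shape=(h, w), masks=tuple(masks))


def analytic_region_area(scheme: RegionScheme, region_index: int) -> float:
    """Closed-form annulus area in px^2.

    For an untruncated annulus ``n`` this is ``pi ((nR)^2 - ((n-1)R)^2)``;
    the truncated outermost annulus has area ``pi (r_max^2 - ((N-1)R)^2)``.

    Parameters
    ----------
    region_index : int
        1-based annulus index.
    """
    if not 1 <= region_index <= scheme.n_regions:
        raise IndexError(
            f"region index {region_index} out of range 1..{scheme.n_regions}"
        )
    r_in = scheme.boundaries[region_index - 1]
    r_out = scheme.boundaries[region_index]
    return math.pi * (r_out**2 - r_in**2)


def export_label_image(mask_set: RegionMaskSet, path: str) -> None:
    """Write the annulus label map as an 8-bit PNG (0 = outside, k = annulus k)."""
    from PIL import Image

    Image.fromarray(mask_set.label_image(), mode="L").save(path, format="PNG")
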