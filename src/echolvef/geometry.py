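"""Scalar LV geometry extracted from masks and endocardial traces.

The pipeline reduces every frame to a handful of numbers: the LV area
(foreground pixel count), the LV length (apex to mid-annulus distance),
and a fixed-length shape-feature vector (area, principal-axis height and
a five-level width profile) that feeds the length regressor.  Everything
here works in pixel units; ejection fraction is dimensionless so the
calibration to centimetres cancels downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: fractional positions (of the height) at which widths are measured
WIDTH_LEVELS = (0.1, 0.3, 0.5, 0.7, 0.9)


@dataclass(frozen=True)
class AreaCurve:
    """Per-frame LV area in px**2, the pipeline's central 1-D signal."""

    areas: np.ndarray
    frame_indices: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        areas = np.asarray(self.areas, dtype=float)
        if areas.ndim != 1:
            raise ValueError("areas must be one-dimensional")
        if np.any(areas < 0):
            raise ValueError("areas must be non-negative")
        object.__setattr__(self, "areas", areas)
        idx = self.frame_indices
        if idx is None:
            idx = np.arange(areas.size)
        idx = np.asarray(idx)
        if idx.shape != areas.shape:
            raise ValueError("frame_indices length must match areas")
        object.__setattr__(self, "frame_indices", idx)

    def __len__(self) -> int:
        return self.areas.size


@dataclass(frozen=True)
class ShapeFeatures:
    """Mask shape descriptors correlated with LV length.

    ``height`` is the extent along the principal axis; ``widths`` are
    extents perpendicular to it at the :data:`WIDTH_LEVELS` fractions of
    the height (base to apex along the axis).
    """

    area: float
    height: float
    widths: tuple[float, ...]

    def __post_init__(self):
        if len(self.widths) != len(WIDTH_LEVELS):
            raise ValueError(f"widths must have {len(WIDTH_LEVELS)} entries")
        if self.area < 0 or self.height < 0 or any(w < 0 for w in self.widths):
            raise ValueError("features must be non-negative")

    def as_vector(self) -> np.ndarray:
        return np.array([self.area, self.height, *self.widths], dtype=float)

    @staticmethod
    def names() -> list[str]:
        return ["area", "height"] + [f"w{i+1}" for i in range(len(WIDTH_LEVELS))]


def mask_area(mask: np.ndarray) -> float:
    """LV area in px**2 as the foreground pixel count of a binary mask."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    return float(np.count_nonzero(mask))


def polygon_area(points) -> float:
    """Absolute shoelace area of an (x, y) polygon; orientation-free."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
        raise ValueError("polygon needs at least 3 (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)


def lv_length(p, q) -> float:
    """Euclidean distance between the apex and the mid-annulus point."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(np.hypot(*(p - q)))


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(mask)
    if n <= 1:
        return mask
    logger.warning("mask has %d connected components; keeping the largest", n)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def extract_features(mask: np.ndarray) -> ShapeFeatures:
    """Area, principal-axis height and 5-level width profile of a mask.

    The principal axis comes from the eigen-decomposition of the
    foreground pixels' second central moments; its direction is
    canonicalised by the sign of the third moment of the projections so
    the width profile is stable under rotation.  With several connected
    components only the largest is measured.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        raise ValueError("cannot extract features from an empty mask")
    mask = _largest_component(mask)

    rows, cols = np.nonzero(mask)
    coords = np.column_stack([rows, cols]).astype(float)
    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / coords.shape[0]
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    perp = evecs[:, np.argmin(evals)]

    proj = centred @ axis
    skew = np.mean(proj**3)
    if skew < 0 or (skew == 0 and (axis[0] < 0 or (axis[0] == 0 and axis[1] < 0))):
        axis = -axis
        proj = -proj

    lo, hi = proj.min(), proj.max()
    height = float(hi - lo + 1.0)  # pixel extent, not centre-to-centre span

    perp_proj = centred @ perp
    widths = []
    for frac in WIDTH_LEVELS:
        level = lo + frac * (hi - lo)
        band = np.abs(proj - level) <= 0.5
        if band.any():
            widths.append(float(perp_proj[band].max() - perp_proj[band].min() + 1.0))
        else:
            widths.append(0.0)
    return ShapeFeatures(area=float(coords.shape[0]), height=height, widths=tuple(widths))


def area_curve(masks) -> AreaCurve:
    """Element-wise :func:`mask_area` over a frame-ordered mask stack."""
    masks = list(masks)
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    return AreaCurve(np.array([mask_area(m) for m in masks], dtype=float))
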