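"""All-cycle ED/ES identification and percentile-based area refinement.

End-diastole shows as a local maximum of the LV area curve and
end-systole as a local minimum.  Candidate extrema are kept only when
their topographic prominence exceeds half the curve's global range and
retained peaks are at least ``min_distance`` frames apart (the
horizontal stepsize, default 20); each ED is then paired with the first
ES that follows it before the next ED.  Two refinements of the raw
single-frame ED/ES areas are provided: the plain 90th/10th percentile
baseline, and the improved Jeffrey's method, which pools the per-cycle
peak area with the top-10% areas of the whole curve and of the ED-to-ES
window and averages the pool — suppressing single-frame segmentation
outliers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, peak_prominences

from .geometry import AreaCurve

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PeakParams:
    min_distance: int = 20
    prominence_fraction: float = 0.5

    def __post_init__(self):
        if self.min_distance < 1:
            raise ValueError("min_distance must be at least 1 frame")
        if not 0.0 < self.prominence_fraction < 1.0:
            raise ValueError("prominence_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class CycleSet:
    """Ordered (ed_frame, es_frame) pairs on an area curve."""

    pairs: tuple[tuple[int, int], ...]
    curve_ref: AreaCurve

    def __post_init__(self):
        n = len(self.curve_ref)
        prev_ed = -1
        for ed, es in self.pairs:
            if not (prev_ed < ed < es < n):
                raise ValueError("cycle pairs must satisfy ed_i < es_i < ed_{i+1}")
            prev_ed = ed

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class RefinedAreas:
    per_cycle: tuple[tuple[float, float], ...]  # (a_ed, a_es)
    method: str


def _prominent_extrema(x: np.ndarray, threshold: float, min_distance: int) -> np.ndarray:
    """Local maxima with prominence strictly above threshold, then pruned
    so survivors are >= min_distance apart (higher peaks win)."""
    candidates, _ = find_peaks(x)  # all strict/plateau local maxima
    if candidates.size == 0:
        return candidates
    prom = peak_prominences(x, candidates)[0]
    candidates = candidates[prom > threshold]
    if candidates.size == 0:
        return candidates
    # keep-by-height pruning, identical in spirit to find_peaks' distance rule
    order = np.argsort(x[candidates])[::-1]
    kept: list[int] = []
    for idx in candidates[order]:
        if all(abs(idx - k) >= min_distance for k in kept):
            kept.append(int(idx))
    return np.array(sorted(kept), dtype=int)


def detect_ed_es(curve: AreaCurve, params: PeakParams = PeakParams()) -> CycleSet:
    """Find all (ED, ES) pairs on an LV area curve.

    A constant curve, or one shorter than two stepsizes, yields an empty
    cycle set with a warning rather than an error.
    """
    x = curve.areas
    if x.size < 2 * params.min_distance:
        logger.warning(
            "curve of %d frames is shorter than two stepsizes; no cycles", x.size
        )
        return CycleSet(pairs=(), curve_ref=curve)
    rng_ = float(x.max() - x.min())
    if rng_ == 0.0:
        logger.warning("constant area curve; no cycles detected")
        return CycleSet(pairs=(), curve_ref=curve)
    threshold = params.prominence_fraction * rng_
    eds = _prominent_extrema(x, threshold, params.min_distance)
    ess = _prominent_extrema(-x, threshold, params.min_distance)
    pairs = []
    for i, ed in enumerate(eds):
        next_ed = eds[i + 1] if i + 1 < eds.size else x.size
        after = ess[(ess > ed) & (ess < next_ed)]
        if after.size:
            pairs.append((int(ed), int(after[0])))
    return CycleSet(pairs=tuple(pairs), curve_ref=curve)


def _top_fraction(values: np.ndarray, fraction: float, largest: bool) -> np.ndarray:
    """Top ceil(fraction*n) values (at least one), descending or ascending."""
    n = values.size
    k = max(1, math.ceil(fraction * n))
    srt = np.sort(values)
    return srt[-k:][::-1] if largest else srt[:k]


def refine_jeffrey(
    curve: AreaCurve,
    cycles: CycleSet,
    cycle_index: int,
    fraction: float = 0.10,
    pooling: str = "pooled",
) -> tuple[float, float]:
    """Improved Jeffrey's refinement of one cycle's ED and ES areas.

    The ED area is the mean of three pooled parts: (1) the area at this
    cycle's ED frame; (2) the top 10% of all frame areas (descending);
    (3) the top 10% of the areas between this cycle's ED and ES frames
    inclusive.  The ES area is the mirror image with ascending sorts.
    ``pooling="three_part"`` averages the three part-means instead of the
    pooled multiset.
    """
    if not 0 <= cycle_index < len(cycles):
        raise IndexError(f"cycle_index {cycle_index} out of range")
    if pooling not in {"pooled", "three_part"}:
        raise ValueError(f"unknown pooling mode: {pooling}")
    x = curve.areas
    ed, es = cycles.pairs[cycle_index]
    window = x[ed : es + 1]

    def _combine(parts: list[np.ndarray]) -> float:
        if pooling == "pooled":
            return float(np.mean(np.concatenate(parts)))
        return float(np.mean([np.mean(p) for p in parts]))

    a_ed = _combine(
        [np.array([x[ed]]), _top_fraction(x, fraction, True), _top_fraction(window, fraction, True)]
    )
    a_es = _combine(
        [np.array([x[es]]), _top_fraction(x, fraction, False), _top_fraction(window, fraction, False)]
    )
    if a_ed <= a_es:
        raise ValueError(f"degenerate cycle {cycle_index}: refined a_ed <= a_es")
    return a_ed, a_es


def refine_raw(curve: AreaCurve, cycles: CycleSet, cycle_index: int) -> tuple[float, float]:
    """Raw single-frame ED/ES areas for one cycle."""
    ed, es = cycles.pairs[cycle_index]
    return float(curve.areas[ed]), float(curve.areas[es])


def baseline_percentile(curve: AreaCurve) -> tuple[float, float]:
    """90th/10th percentiles of the areas as (a_ed, a_es).

    Linear interpolation between order statistics.
    """
    if len(curve) == 0:
        raise ValueError("empty curve")
    a_ed, a_es = np.percentile(curve.areas, [90.0, 10.0])
    return float(a_ed), float(a_es)


def refine_areas(
    curve: AreaCurve,
    cycles: CycleSet,
    method: str = "jeffrey",
    fraction: float = 0.10,
    pooling: str = "pooled",
) -> RefinedAreas:
    """Per-cycle (a_ed, a_es) under the chosen refinement method."""
    out = []
    for i in range(len(cycles)):
        if method == "jeffrey":
            out.append(refine_jeffrey(curve, cycles, i, fraction, pooling))
        elif method == "raw":
            out.append(refine_raw(curve, cycles, i))
        elif method == "percentile":
            out.append(baseline_percentile(curve))
        else:
            raise ValueError(f"unknown refinement method: {method}")
    return RefinedAreas(per_cycle=tuple(out), method=method)
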