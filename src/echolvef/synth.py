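"""Ground-truthed synthetic echo generator.

A pulsating prolate ellipse stands in for the left ventricle seen in the
apical-4-chamber plane.  For a continuous ellipse the area-length volume
8*A^2/(3*pi*L) with A = pi*L*D/4 reduces exactly to the prolate-spheroid
volume pi*L*D^2/6, so every simulated video carries an analytic ejection
fraction: shrinking both axes isotropically by s between end-diastole
and end-systole gives EF = 1 - s^3.  Rhythm can be regular (sinus) or
log-normally irregular (AF-like); speckle texture and frame-level area
corruption exercise the robustness machinery downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import AreaCurve
from .io import EchoVideo

#: fraction of each cycle at which end-systole is placed (systole < diastole)
ES_PHASE = 0.4


@dataclass(frozen=True)
class RhythmSpec:
    """Cardiac rhythm: cycle count, mean period and period irregularity."""

    n_cycles: int = 3
    mean_period: float = 40.0
    period_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_cycles < 1:
            raise ValueError("need at least one cycle")
        if self.mean_period < 4:
            raise ValueError("mean_period must be at least 4 frames")
        if self.period_cv < 0:
            raise ValueError("period_cv must be non-negative")

    def periods(self) -> np.ndarray:
        """Realised integer cycle lengths (frames), each >= 4."""
        if self.period_cv == 0:
            return np.full(self.n_cycles, int(round(self.mean_period)))
        rng = np.random.default_rng(self.seed)
        sigma2 = np.log1p(self.period_cv**2)
        mu = np.log(self.mean_period) - sigma2 / 2.0
        raw = rng.lognormal(mean=mu, sigma=np.sqrt(sigma2), size=self.n_cycles)
        return np.maximum(4, np.round(raw).astype(int))


@dataclass(frozen=True)
class LVShapeSpec:
    """End-diastolic ellipse geometry and per-cycle EF targets."""

    long_axis_ed: float = 80.0
    short_axis_ed: float = 40.0
    per_cycle_ef: tuple[float, ...] = (55.0, 55.0, 55.0)
    canvas: tuple[int, int] = (112, 112)
    centre: tuple[float, float] | None = None
    orientation: float = 0.0

    def __post_init__(self):
        for ef in self.per_cycle_ef:
            if not 0.0 < ef < 100.0:
                raise ValueError("per-cycle EF targets must lie strictly in (0, 100)")
        if self.centre is None:
            object.__setattr__(
                self, "centre", ((self.canvas[0] - 1) / 2.0, (self.canvas[1] - 1) / 2.0)
            )
        half_diag = np.hypot(self.long_axis_ed, self.short_axis_ed) / 2.0
        r, c = self.centre
        if (
            r - half_diag < -0.5
            or c - half_diag < -0.5
            or r + half_diag > self.canvas[0] - 0.5
            or c + half_diag > self.canvas[1] - 0.5
        ):
            raise ValueError("end-diastolic ellipse does not fit inside the canvas")


@dataclass(frozen=True)
class SyntheticTruth:
    """Analytic ground truth attached to a simulated video."""

    areas: np.ndarray          # per-frame analytic area, px^2
    long_axes: np.ndarray      # per-frame long axis, px
    ed_frames: np.ndarray      # one per cycle, cycle-start end-diastole
    es_frames: np.ndarray      # one per cycle
    per_cycle_ef: np.ndarray   # percent
    overall_ef: float          # mean of per-cycle EFs, percent

    def as_dict(self) -> dict:
        return {
            "areas": self.areas.tolist(),
            "long_axes": self.long_axes.tolist(),
            "ed_frames": self.ed_frames.tolist(),
            "es_frames": self.es_frames.tolist(),
            "per_cycle_ef": self.per_cycle_ef.tolist(),
            "overall_ef": self.overall_ef,
        }


@dataclass(frozen=True)
class SyntheticEcho:
    video: EchoVideo
    masks: np.ndarray
    truth: SyntheticTruth


def _half_cosine(n: int, start: float, stop: float) -> np.ndarray:
    """Smooth monotone profile over n frames from start to stop (excl. stop)."""
    t = np.arange(n, dtype=float) / n
    return stop + (start - stop) * 0.5 * (1.0 + np.cos(np.pi * t))


def make_axis_curves(rhythm: RhythmSpec, shape: LVShapeSpec):
    """Per-frame (long_axis, short_axis) in px, plus the analytic truth.

    Each cycle runs ED -> ES -> next ED with a raised-cosine profile and
    the ES phase at :data:`ES_PHASE` of the cycle.  ES axes are the ED
    axes scaled by s = (1 - EF/100)**(1/3), so the prolate-spheroid EF of
    the cycle is exactly the target.  A rising lead-in and a falling tail
    keep every truth ED/ES an interior extremum of the area curve.
    """
    if len(shape.per_cycle_ef) != rhythm.n_cycles:
        raise ValueError("per_cycle_ef length must equal n_cycles")
    periods = rhythm.periods()
    efs = np.asarray(shape.per_cycle_ef, dtype=float)
    shrink = np.cbrt(1.0 - efs / 100.0)

    l_ed, d_ed = shape.long_axis_ed, shape.short_axis_ed
    long_parts, ed_frames, es_frames = [], [], []

    # lead-in: second (relaxation) half of a notional preceding cycle
    n_lead = max(2, int(round((1 - ES_PHASE) * periods[0] / 2)))
    long_parts.append(_half_cosine(n_lead, (l_ed + shrink[0] * l_ed) / 2, l_ed)[::1])
    cursor = n_lead

    for i in range(rhythm.n_cycles):
        p = int(periods[i])
        t_es = max(1, int(round(ES_PHASE * p)))
        t_es = min(t_es, p - 1)
        l_es = shrink[i] * l_ed
        ed_frames.append(cursor)
        es_frames.append(cursor + t_es)
        sys_part = _half_cosine(t_es, l_ed, l_es)
        dia_part = _half_cosine(p - t_es, l_es, l_ed)
        long_parts.append(np.concatenate([sys_part, dia_part]))
        cursor += p

    # closing ED then a short falling tail (no interior minimum)
    n_tail = max(2, int(round(ES_PHASE * periods[-1] / 2)))
    tail = _half_cosine(2 * n_tail, l_ed, shrink[-1] * l_ed)[:n_tail]
    long_parts.append(tail)

    long_axes = np.concatenate(long_parts)
    short_axes = long_axes * (d_ed / l_ed)  # isotropic shrink
    ed = np.asarray(ed_frames)
    es = np.asarray(es_frames)
    truth = SyntheticTruth(
        areas=np.pi * long_axes * short_axes / 4.0,
        long_axes=long_axes,
        ed_frames=ed,
        es_frames=es,
        per_cycle_ef=efs,
        overall_ef=float(np.mean(efs)),
    )
    return long_axes, short_axes, truth


def render_masks(long_axes, short_axes, shape: LVShapeSpec):
    """Rasterise per-frame filled ellipses; returns (masks, analytic areas).

    Pixel-centre convention: a pixel belongs to the mask when its centre
    lies inside the ellipse.  Analytic area is pi*L*D/4.
    """
    long_axes = np.asarray(long_axes, dtype=float)
    short_axes = np.asarray(short_axes, dtype=float)
    rows, cols = shape.canvas
    cr, cc = shape.centre
    rr, cc_grid = np.mgrid[0:rows, 0:cols]
    dr = rr - cr
    dc = cc_grid - cc
    ct, st = np.cos(shape.orientation), np.sin(shape.orientation)
    # long axis along rows when orientation = 0
    u = ct * dr + st * dc
    v = -st * dr + ct * dc

    half = np.hypot(long_axes, short_axes) / 2.0
    if np.any(
        (cr - half < -0.5)
        | (cc - half < -0.5)
        | (cr + half > rows - 0.5)
        | (cc + half > cols - 0.5)
    ):
        bad = int(np.argmax((cr + half > rows - 0.5) | (cc + half > cols - 0.5)))
        raise ValueError(f"ellipse exceeds the canvas at frame {bad}")

    masks = np.empty((long_axes.size, rows, cols), dtype=bool)
    for t in range(long_axes.size):
        a = long_axes[t] / 2.0
        b = short_axes[t] / 2.0
        masks[t] = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    return masks, np.pi * long_axes * short_axes / 4.0


def add_speckle(masks, snr: float = 5.0, seed: int = 0) -> EchoVideo:
    """Texture a mask stack into a grey-scale video.

    The blood pool (mask interior) is dark, the endocardial rim bright and
    the far field mid-grey; multiplicative uniform noise of amplitude
    1/snr is applied.  Deterministic for a fixed seed.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    masks = np.asarray(masks).astype(bool)
    rng = np.random.default_rng(seed)
    frames = np.empty(masks.shape, dtype=float)
    for t, m in enumerate(masks):
        rim = ndimage.binary_dilation(m, iterations=2) & ~ndimage.binary_erosion(
            m, iterations=2
        )
        frame = np.full(m.shape, 0.35)
        frame[m] = 0.15
        frame[rim] = 0.85
        frames[t] = frame
    noise = rng.uniform(-1.0 / snr, 1.0 / snr, size=frames.shape)
    frames = np.clip(frames * (1.0 + noise), 0.0, 1.0)
    return EchoVideo(id="synthetic", frames=frames, fps=None, source="synthetic")


def corrupt_curve(curve: AreaCurve, frames, factor, seed: int | None = None) -> AreaCurve:
    """Multiply the listed frames' areas by ``factor`` (outlier injection).

    ``factor`` may be a scalar, or a (lo, hi) range from which one
    multiplier per listed frame is drawn with the given seed.
    """
    frames = np.asarray(frames, dtype=int)
    if frames.size and (frames.min() < 0 or frames.max() >= len(curve)):
        raise ValueError("corruption frame index out of range")
    if np.ndim(factor) == 0:
        if factor <= 0:
            raise ValueError("factor must be positive")
        mult = np.full(frames.size, float(factor))
    else:
        lo, hi = factor
        if lo <= 0:
            raise ValueError("factor range must be positive")
        mult = np.random.default_rng(seed).uniform(lo, hi, size=frames.size)
    areas = curve.areas.copy()
    areas[frames] *= mult
    return AreaCurve(areas, curve.frame_indices)


def simulate(
    rhythm: RhythmSpec,
    shape: LVShapeSpec,
    snr: float = 5.0,
    seed: int | None = None,
) -> SyntheticEcho:
    """Full simulation: axis curves -> masks -> speckled video + truth."""
    long_axes, short_axes, truth = make_axis_curves(rhythm, shape)
    masks, _ = render_masks(long_axes, short_axes, shape)
    video = add_speckle(masks, snr=snr, seed=rhythm.seed if seed is None else seed)
    return SyntheticEcho(video=video, masks=masks, truth=truth)
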