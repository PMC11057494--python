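"""Area-length volumes, per-cycle and all-cycle LVEF, HF phenotyping.

The ellipsoid single-plane (area-length) model gives the LV volume from
a single apical-4-chamber plane as V = 8 A^2 / (3 pi L), with A the LV
area and L the apex-to-mid-annulus length.  Ejection fraction per cycle
is (EDV - ESV) / EDV x 100 and the video-level LVEF averages the
per-cycle values over every detected cardiac cycle.  Heart-failure
phenotype follows the guideline cut-points: HFrEF below 40%, HFmrEF in
[40, 50), HFpEF at or above 50%.

``run_pipeline`` orchestrates the full chain — segmentation (optional),
area curve, all-cycle ED/ES detection, area refinement, length
prediction, volumes, EF, phenotype — and assembles the beat-to-beat
visualiser payload.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cycles import CycleSet, PeakParams, detect_ed_es, refine_areas
from .geometry import AreaCurve, area_curve, extract_features
from .length import LengthModel, predict_length


def volume_area_length(a: float, l: float) -> float:
    """LV volume 8*a^2/(3*pi*l) in px^3 (area-length, single plane)."""
    if l <= 0:
        raise ValueError("LV length must be positive")
    if a < 0:
        raise ValueError("LV area must be non-negative")
    return 8.0 * a * a / (3.0 * np.pi * l)


def cycle_ef(edv: float, esv: float) -> float:
    """Single-beat ejection fraction (EDV - ESV)/EDV in percent."""
    if edv <= 0:
        raise ValueError("EDV must be positive")
    return 100.0 * (edv - esv) / edv


def mean_ef(cycle_efs) -> float:
    """All-cycle LVEF: the arithmetic mean over the available cycles."""
    cycle_efs = np.asarray(cycle_efs, dtype=float)
    if cycle_efs.size == 0:
        raise ValueError("no cycles available to average")
    return float(cycle_efs.mean())


PHENOTYPES = ("HFrEF", "HFmrEF", "HFpEF")


def classify_hf(ef: float) -> str:
    """Guideline phenotype: HFrEF < 40 <= HFmrEF < 50 <= HFpEF."""
    if not 0.0 <= ef <= 100.0:
        raise ValueError(f"EF {ef} outside [0, 100]")
    if ef < 40.0:
        return "HFrEF"
    if ef < 50.0:
        return "HFmrEF"
    return "HFpEF"


@dataclass(frozen=True)
class CycleMeasurement:
    cycle_index: int
    ed_frame: int
    es_frame: int
    a_ed: float
    a_es: float
    l_ed: float
    l_es: float
    edv: float
    esv: float
    ef: float

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "cycle_index", "ed_frame", "es_frame", "a_ed", "a_es",
            "l_ed", "l_es", "edv", "esv", "ef",
        )}


@dataclass(frozen=True)
class LVEFResult:
    cycles: tuple[CycleMeasurement, ...]
    n_cycles: int
    mean_ef: float | None
    phenotype: str | None
    hfref_flag: bool
    status: str = "ok"  # "ok" | "insufficient cycles"

    def as_dict(self) -> dict:
        return {
            "cycles": [c.as_dict() for c in self.cycles],
            "n_cycles": self.n_cycles,
            "mean_ef": self.mean_ef,
            "phenotype": self.phenotype,
            "hfref_flag": self.hfref_flag,
            "status": self.status,
        }


@dataclass(frozen=True)
class BeatToBeatSeries:
    """Serialisable payload behind the beat-to-beat visualiser: the area
    curve with ED/ES markers, per-cycle EF labels and the summary banner."""

    frame_indices: tuple[int, ...]
    areas: tuple[float, ...]
    ed_markers: tuple[int, ...]
    es_markers: tuple[int, ...]
    ef_labels: tuple[str, ...]
    banner: str

    def as_dict(self) -> dict:
        return {
            "frame_indices": list(self.frame_indices),
            "areas": list(self.areas),
            "ed_markers": list(self.ed_markers),
            "es_markers": list(self.es_markers),
            "ef_labels": list(self.ef_labels),
            "banner": self.banner,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict())


def summarise_cycles(measurements) -> LVEFResult:
    """Video-level result from per-cycle measurements (empty -> status)."""
    measurements = tuple(measurements)
    if not measurements:
        return LVEFResult(
            cycles=(), n_cycles=0, mean_ef=None, phenotype=None,
            hfref_flag=False, status="insufficient cycles",
        )
    m_ef = mean_ef([c.ef for c in measurements])
    pheno = classify_hf(min(max(m_ef, 0.0), 100.0))
    return LVEFResult(
        cycles=measurements,
        n_cycles=len(measurements),
        mean_ef=m_ef,
        phenotype=pheno,
        hfref_flag=m_ef < 40.0,
    )


def build_visualiser(curve: AreaCurve, cycles: CycleSet, result: LVEFResult) -> BeatToBeatSeries:
    """Assemble the beat-to-beat payload; marker counts match cycles."""
    if len(cycles) != result.n_cycles:
        raise ValueError("cycle set and result disagree on the cycle count")
    if result.n_cycles == 0:
        banner = "no cycles detected"
        labels: tuple[str, ...] = ()
    else:
        banner = f"LVEF {result.mean_ef:.2f}% over {result.n_cycles} cycles - {result.phenotype}"
        labels = tuple(f"{c.ef:.2f}%" for c in result.cycles)
    return BeatToBeatSeries(
        frame_indices=tuple(int(i) for i in curve.frame_indices),
        areas=tuple(float(a) for a in curve.areas),
        ed_markers=tuple(ed for ed, _ in cycles.pairs),
        es_markers=tuple(es for _, es in cycles.pairs),
        ef_labels=labels,
        banner=banner,
    )


def plot_beat_to_beat(series: BeatToBeatSeries, path) -> None:
    """Render the beat-to-beat payload to an image file.

    LV area against frame number, ED peaks and ES troughs marked, each
    cycle labelled with its EF, and the all-cycle banner as the title.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frames = np.asarray(series.frame_indices)
    areas = np.asarray(series.areas)
    fig, ax = plt.subplots(figsize=(8, 3.2))
    ax.plot(frames, areas, lw=1.2, color="tab:blue")
    ed = np.asarray(series.ed_markers, dtype=int)
    es = np.asarray(series.es_markers, dtype=int)
    if ed.size:
        ax.plot(frames[ed], areas[ed], "v", color="tab:red", label="ED")
        ax.plot(frames[es], areas[es], "^", color="tab:green", label="ES")
        for e, label in zip(ed, series.ef_labels):
            ax.annotate(label, (frames[e], areas[e]), textcoords="offset points",
                        xytext=(0, 8), ha="center", fontsize=8)
        ax.legend(loc="lower right", fontsize=8)
    ax.set_xlabel("frame")
    ax.set_ylabel("LV area (px$^2$)")
    ax.set_title(series.banner, fontsize=10)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass(frozen=True)
class PipelineConfig:
    peaks: PeakParams = field(default_factory=PeakParams)
    refinement: str = "jeffrey"  # "jeffrey" | "raw" | "percentile"
    jeffrey_fraction: float = 0.10
    jeffrey_pooling: str = "pooled"


def ef_from_curve(
    curve: AreaCurve,
    lengths,
    config: PipelineConfig = PipelineConfig(),
    cycles: CycleSet | None = None,
) -> tuple[LVEFResult, BeatToBeatSeries]:
    """EF from an area curve plus per-frame LV lengths.

    This is the measurement core of :func:`run_pipeline`, usable
    directly when areas and lengths come from elsewhere (traces,
    simulations) rather than a segmentation model.
    """
    lengths = np.asarray(lengths, dtype=float)
    if lengths.shape != curve.areas.shape:
        raise ValueError("need one LV length per frame")
    if cycles is None:
        cycles = detect_ed_es(curve, config.peaks)
    if len(cycles) == 0:
        result = summarise_cycles(())
        return result, build_visualiser(curve, cycles, result)
    refined = refine_areas(
        curve, cycles, method=config.refinement,
        fraction=config.jeffrey_fraction, pooling=config.jeffrey_pooling,
    )
    measurements = []
    for i, ((ed, es), (a_ed, a_es)) in enumerate(zip(cycles.pairs, refined.per_cycle)):
        l_ed, l_es = float(lengths[ed]), float(lengths[es])
        edv = volume_area_length(a_ed, l_ed)
        esv = volume_area_length(a_es, l_es)
        measurements.append(
            CycleMeasurement(
                cycle_index=i, ed_frame=ed, es_frame=es, a_ed=a_ed, a_es=a_es,
                l_ed=l_ed, l_es=l_es, edv=edv, esv=esv, ef=cycle_ef(edv, esv),
            )
        )
    result = summarise_cycles(measurements)
    return result, build_visualiser(curve, cycles, result)


def run_pipeline(
    video_or_masks,
    seg_model=None,
    length_model: LengthModel | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[LVEFResult, BeatToBeatSeries]:
    """Full chain from a video or mask stack to an LVEF result.

    A raw video requires a segmentation model; a boolean mask stack
    bypasses segmentation.  LV length per frame comes from the length
    ensemble applied to the frame's mask features, or — when no model is
    given — from the mask's principal-axis height, which coincides with
    the LV long axis for an apex-to-base aligned ventricle.
    """
    from .io import EchoVideo

    if isinstance(video_or_masks, EchoVideo):
        if seg_model is None:
            raise ValueError("a raw video requires a segmentation model")
        from .segmentation import segment_video

        masks = segment_video(seg_model, video_or_masks)
    else:
        masks = np.asarray(video_or_masks).astype(bool)
        if masks.ndim != 3:
            raise ValueError("mask stack must be (frame, row, col)")

    curve = area_curve(list(masks))
    lengths = np.zeros(len(curve))
    for t, mask in enumerate(masks):
        if not mask.any():
            continue
        feats = extract_features(mask)
        lengths[t] = (
            predict_length(length_model, feats) if length_model is not None else feats.height
        )
    return ef_from_curve(curve, lengths, config)
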