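"""Readers and writers for the formats the pipeline touches.

Videos come in as AVI/MP4 (via imageio, where an ffmpeg backend is
available) or multi-page TIFF (via tifffile, the format used throughout
the tests); annotation CSVs follow the EchoNet-Dynamic dialects
(VolumeTracings: one chord per row; FileList: one video per row with EF,
EDV and ESV labels); results go out as JSON or flat CSV and round-trip
exactly.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from skimage.transform import resize as _sk_resize


@dataclass
class EchoVideo:
    """Grey-scale frame stack with intensities normalised to [0, 1]."""

    id: str
    frames: np.ndarray  # (frame, row, col)
    fps: float | None = None
    source: str = ""

    def __post_init__(self):
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim != 3 or frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (frame, row, col) stack")
        if frames.min() < 0.0 or frames.max() > 1.0:
            raise ValueError("intensities must lie in [0, 1]")
        self.frames = frames

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class TraceAnnotation:
    """One frame's endocardial trace: an ordered point list plus the
    indices of the two points (apex, mid-annulus) defining LV length."""

    video_id: str
    frame_index: int
    points: tuple[tuple[float, float], ...]  # (x, y), 0-based pixel centres
    axis_pair: tuple[int, int]

    def __post_init__(self):
        if len(self.points) >= 3:
            pass  # polygon-capable
        i, j = self.axis_pair
        n = len(self.points)
        if i == j or not (0 <= i < n and 0 <= j < n):
            raise ValueError("axis_pair must be two distinct valid point indices")


@dataclass(frozen=True)
class LabelRecord:
    video_id: str
    ef_ref: float
    edv_ref: float | None = None
    esv_ref: float | None = None
    ed_frame: int | None = None
    es_frame: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.ef_ref <= 100.0:
            raise ValueError(f"reference EF {self.ef_ref} outside [0, 100]")
        if (
            self.edv_ref is not None
            and self.esv_ref is not None
            and self.edv_ref < self.esv_ref
        ):
            raise ValueError("EDV must be >= ESV")


def _normalise(frames: np.ndarray) -> np.ndarray:
    if np.issubdtype(frames.dtype, np.integer):
        return frames.astype(float) / np.iinfo(frames.dtype).max
    frames = frames.astype(float)
    if frames.size and frames.max() > 1.0:
        frames = frames / frames.max()
    return np.clip(frames, 0.0, 1.0)


def read_video(path, target_size: tuple[int, int] | None = None) -> EchoVideo:
    """Read an AVI/MP4/multi-page-TIFF video as a normalised frame stack.

    Intensities are divided by the dtype maximum; colour frames are
    averaged to grey; ``target_size`` triggers bilinear resizing followed
    by clipping to [0, 1].
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"video file not found: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in {".tif", ".tiff"}:
            raw = tifffile.imread(str(path))
        else:
            import imageio.v3 as iio

            raw = iio.imread(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with the path
        raise IOError(f"could not read video {path}: {exc}") from exc
    raw = np.asarray(raw)
    if raw.ndim == 2:
        raw = raw[None]
    if raw.ndim == 4:  # colour -> grey
        raw = raw.mean(axis=-1).astype(raw.dtype)
    if raw.ndim != 3 or raw.shape[0] == 0:
        raise ValueError(f"no frames found in {path}")
    frames = _normalise(raw)
    if target_size is not None:
        frames = np.stack(
            [
                np.clip(
                    _sk_resize(f, target_size, order=1, anti_aliasing=False), 0.0, 1.0
                )
                for f in frames
            ]
        )
    return EchoVideo(id=path.stem, frames=frames, source=str(path))


def write_video_tiff(video: EchoVideo, path, dtype=np.uint8) -> None:
    """Write a frame stack to multi-page TIFF (8-bit by default)."""
    if np.issubdtype(dtype, np.integer):
        data = np.round(video.frames * np.iinfo(dtype).max).astype(dtype)
    else:
        data = video.frames.astype(dtype)
    tifffile.imwrite(str(path), data, photometric="minisblack")


def read_mask_stack(path, target_size: tuple[int, int] | None = None) -> np.ndarray:
    """Read a TIFF mask stack as boolean frames (nearest-neighbour resize)."""
    raw = tifffile.imread(str(path))
    if raw.ndim == 2:
        raw = raw[None]
    masks = raw > (np.iinfo(raw.dtype).max // 2 if np.issubdtype(raw.dtype, np.integer) else 0.5)
    if target_size is not None:
        masks = np.stack(
            [_sk_resize(m.astype(float), target_size, order=0) > 0.5 for m in masks]
        )
    return masks


def write_mask_stack(masks, path) -> None:
    tifffile.imwrite(
        str(path), np.asarray(masks).astype(np.uint8) * 255, photometric="minisblack"
    )


_TRACING_COLUMNS = ["FileName", "X1", "Y1", "X2", "Y2", "Frame"]


def read_tracings(path) -> dict[str, list[TraceAnnotation]]:
    """Parse an EchoNet VolumeTracings-dialect CSV.

    Each row is one chord; the rows of one (FileName, Frame) block are
    assembled into a single trace whose polygon runs down the first
    chord endpoints and back up the second, with the first chord taken
    as the long axis (apex to mid-annulus).
    """
    df = pd.read_csv(path)
    missing = [c for c in _TRACING_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tracing CSV missing columns: {', '.join(missing)}")
    for col in ["X1", "Y1", "X2", "Y2", "Frame"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(
                f"non-numeric value in column {col} at CSV row {int(bad[0]) + 2}"
            )
        df[col] = coerced
    out: dict[str, list[TraceAnnotation]] = {}
    for (name, frame), block in df.groupby(["FileName", "Frame"], sort=False):
        p1 = list(zip(block["X1"].to_numpy(float), block["Y1"].to_numpy(float)))
        p2 = list(zip(block["X2"].to_numpy(float), block["Y2"].to_numpy(float)))
        points = tuple(p1) + tuple(p2[::-1])  # closed polygon, order preserved
        ann = TraceAnnotation(
            video_id=str(name),
            frame_index=int(frame),
            points=points,
            axis_pair=(0, len(points) - 1),  # first chord = long axis
        )
        out.setdefault(str(name), []).append(ann)
    return out


def read_labels(path) -> list[LabelRecord]:
    """Parse an EchoNet FileList-dialect CSV of per-video EF/EDV/ESV labels."""
    df = pd.read_csv(path)
    required = ["FileName", "EF", "EDV", "ESV"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"label CSV missing columns: {', '.join(missing)}")
    records = []
    for idx, row in df.iterrows():
        try:
            ef = float(row["EF"])
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric EF at CSV row {int(idx) + 2}") from exc
        if not 0.0 <= ef <= 100.0:
            raise ValueError(f"EF {ef} outside [0, 100] at CSV row {int(idx) + 2}")
        records.append(
            LabelRecord(
                video_id=str(row["FileName"]),
                ef_ref=ef,
                edv_ref=float(row["EDV"]) if pd.notna(row["EDV"]) else None,
                esv_ref=float(row["ESV"]) if pd.notna(row["ESV"]) else None,
            )
        )
    return records


def write_report(result, path, format: str = "json") -> None:
    """Persist an LVEF result; ``read_report`` reproduces it exactly."""
    path = Path(path)
    payload = result.as_dict()
    if format == "json":
        path.write_text(json.dumps(payload, indent=2))
    elif format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["cycle_index", "ed_frame", "es_frame", "a_ed", "a_es", "l_ed",
                 "l_es", "edv", "esv", "ef", "n_cycles", "mean_ef", "phenotype",
                 "hfref_flag", "status"]
            )
            meta = [payload["n_cycles"], payload["mean_ef"], payload["phenotype"],
                    payload["hfref_flag"], payload["status"]]
            if payload["cycles"]:
                for c in payload["cycles"]:
                    writer.writerow(
                        [c["cycle_index"], c["ed_frame"], c["es_frame"], c["a_ed"],
                         c["a_es"], c["l_ed"], c["l_es"], c["edv"], c["esv"],
                         c["ef"]] + meta
                    )
            else:
                writer.writerow([""] * 10 + meta)
    else:
        raise ValueError(f"unknown report format: {format}")


def read_report(path) -> dict:
    """Read back a report written by :func:`write_report` as a dict."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return json.loads(path.read_text())
    df = pd.read_csv(path)
    first = df.iloc[0]
    cycles = []
    if not df["cycle_index"].isna().all():
        for _, row in df.iterrows():
            cycles.append(
                {
                    "cycle_index": int(row["cycle_index"]),
                    "ed_frame": int(row["ed_frame"]),
                    "es_frame": int(row["es_frame"]),
                    "a_ed": float(row["a_ed"]),
                    "a_es": float(row["a_es"]),
                    "l_ed": float(row["l_ed"]),
                    "l_es": float(row["l_es"]),
                    "edv": float(row["edv"]),
                    "esv": float(row["esv"]),
                    "ef": float(row["ef"]),
                }
            )
    return {
        "cycles": cycles,
        "n_cycles": int(first["n_cycles"]),
        "mean_ef": None if pd.isna(first["mean_ef"]) else float(first["mean_ef"]),
        "phenotype": None if pd.isna(first["phenotype"]) else str(first["phenotype"]),
        "hfref_flag": bool(first["hfref_flag"]),
        "status": str(first["status"]),
    }
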