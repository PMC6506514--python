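"""Frame ingestion and result writers.

Video sources: uncompressed AVI files (via :mod:`gaitkin.avi`) or a
directory of PNG frames in lexicographic order.  Color frames are reduced
to luminance with ITU-R BT.601 weights.  Result writers emit the per-frame
CSV and summary JSON; the debug overlay writer draws blob outline, skeleton
and the A-D points onto PNG frames.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .avi import read_avi

BT601 = np.array([0.299, 0.587, 0.114])


def to_luminance(img: np.ndarray) -> np.ndarray:
    """RGB(A) or gray image -> uint8 luminance."""
    img = np.asarray(img)
    if img.ndim == 2:
        return img.astype(np.uint8)
    rgb = img[..., :3].astype(np.float64)
    return np.clip(np.rint(rgb @ BT601), 0, 255).astype(np.uint8)


def load_frames(source: str | Path) -> tuple[np.ndarray, float | None]:
    """Load a video source into a (n, h, w) uint8 stack.

    Returns ``(frames, fps)`` with fps None when the source does not carry
    a frame rate (PNG directories).
    """
    source = Path(source)
    if source.is_dir():
        paths = sorted(source.glob("*.png"))
        if not paths:
            raise IOError(f"no PNG frames in {source}")
        frames = np.stack([to_luminance(iio.imread(p)) for p in paths])
        return frames, None
    if not source.exists():
        raise IOError(f"no such video source: {source}")
    if source.suffix.lower() == ".avi":
        frames, fps = read_avi(source)
        return frames, (fps or None)
    raise IOError(f"unsupported video source {source} "
                  "(expected .avi or a PNG directory)")


def write_png_frames(frames: np.ndarray, outdir: str | Path,
                     prefix: str = "frame") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    width = len(str(max(len(frames) - 1, 1)))
    for k, frame in enumerate(frames):
        iio.imwrite(outdir / f"{prefix}_{k:0{width}d}.png", frame)


def write_trace_csv(trace, path: str | Path) -> None:
    """Per-frame CSV: time, validity, A-D coordinates, angles, amplitude."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["frame_index", "time_ms", "valid", "invalid_reason",
                     "ax", "ay", "bx", "by", "cx", "cy", "dx", "dy",
                     "alpha_deg", "beta_deg", "gamma_deg",
                     "amplitude_px", "amplitude_bl"])
        for f in trace.frames:
            t_ms = 1000.0 * f.frame_index / trace.fps
            if f.valid and f.points is not None:
                coords = [f"{v:.4f}" for v in f.points.as_array().ravel()]
                vals = [f"{f.alpha_deg:.4f}", f"{f.beta_deg:.4f}",
                        f"{f.gamma_deg:.4f}", f"{f.amplitude_px:.4f}",
                        f"{f.amplitude_bl:.6f}"]
            else:
                coords = [""] * 8
                vals = [""] * 5
            wr.writerow([f.frame_index, f"{t_ms:.3f}", int(f.valid),
                         f.invalid_reason, *coords, *vals])


def read_trace_csv(path: str | Path, fps: float | None = None,
                   body_length_px: float | None = None):
    """Rebuild a :class:`~gaitkin.kinematics.GaitTrace` from a per-frame CSV."""
    from .kinematics import FrameKinematics, GaitTrace
    from .midline import MidlinePoints

    frames = []
    times = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            valid = bool(int(row["valid"]))
            times.append(float(row["time_ms"]))
            if valid:
                pts = MidlinePoints(
                    A=(float(row["ax"]), float(row["ay"])),
                    B=(float(row["bx"]), float(row["by"])),
                    C=(float(row["cx"]), float(row["cy"])),
                    D=(float(row["dx"]), float(row["dy"])))
                frames.append(FrameKinematics(
                    frame_index=int(row["frame_index"]), valid=True,
                    alpha_deg=float(row["alpha_deg"]),
                    beta_deg=float(row["beta_deg"]),
                    gamma_deg=float(row["gamma_deg"]),
                    amplitude_px=float(row["amplitude_px"]),
                    amplitude_bl=float(row["amplitude_bl"]),
                    points=pts))
            else:
                frames.append(FrameKinematics(
                    frame_index=int(row["frame_index"]), valid=False,
                    invalid_reason=row["invalid_reason"]))
    if fps is None:
        if len(times) >= 2 and times[1] > times[0]:
            fps = 1000.0 / (times[1] - times[0])
        else:
            raise IOError("cannot infer fps from trace CSV; pass fps")
    if body_length_px is None:
        amps_px = [f.amplitude_px for f in frames
                   if f.valid and f.amplitude_bl > 0]
        amps_bl = [f.amplitude_bl for f in frames
                   if f.valid and f.amplitude_bl > 0]
        body_length_px = (float(np.median(np.array(amps_px)
                                          / np.array(amps_bl)))
                          if amps_px else 1.0)
    return GaitTrace(fps=fps, body_length_px=body_length_px, frames=frames)


def write_summary_json(summary, path: str | Path, config_echo: dict | None
                       = None, accepted: bool | None = None) -> None:
    from . import __version__
    doc = summary.as_dict()
    doc["software_version"] = __version__
    if accepted is not None:
        doc["accepted"] = accepted
    if config_echo is not None:
        doc["config"] = config_echo
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_overlay(frame: np.ndarray, path: str | Path, blob=None,
                  skeleton_points: np.ndarray | None = None,
                  points_abcd: np.ndarray | None = None,
                  offset: tuple[int, int] = (0, 0)) -> None:
    """PNG debug overlay: blob outline (red), skeleton (green), A-D (blue)."""
    from scipy import ndimage

    rgb = np.stack([frame] * 3, axis=-1).astype(np.uint8)
    ox, oy = offset
    if blob is not None:
        eroded = ndimage.binary_erosion(blob.mask)
        ry, rx = np.nonzero(blob.mask & ~eroded)
        rgb[ry + oy, rx + ox] = (255, 0, 0)
    if skeleton_points is not None:
        pts = np.rint(skeleton_points).astype(int)
        rgb[pts[:, 1] + oy, pts[:, 0] + ox] = (0, 200, 0)
    if points_abcd is not None:
        h, w = frame.shape
        for x, y in np.rint(points_abcd).astype(int):
            y0, y1 = max(y + oy - 2, 0), min(y + oy + 3, h)
            x0, x1 = max(x + ox - 2, 0), min(x + ox + 3, w)
            rgb[y0:y1, x0:x1] = (0, 80, 255)
    iio.imwrite(path, rgb)
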