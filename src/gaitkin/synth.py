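"""Ground-truthed synthetic videos of an undulating fish silhouette.

The body midline follows a single sinusoidal traveling wave — the canonical
kinematic model of carangiform swimming: lateral displacement

    y(s, t) = A(s) * sin(2*pi*f*t - 2*pi*s / lambda_bl)

where s in [0, 1] is the arc-length position (head to tail), f the tail-beat
frequency in Hz, lambda_bl the body wavelength in body lengths, and A(s) a
linear amplitude envelope growing from head to tail.  Bending preserves body
length: the axial extent is compressed until the curve's arc length equals
``body_length_px``, so amplitude never changes body length and BL-normalized
outputs stay well defined.

The rendered silhouette is darker than the background, matching silhouette
imaging of a fish in a back-lit flow tunnel and fixing the binarization
polarity used pipeline-wide.  Ground-truth angles and amplitudes are
computed by the *same* geometry functions the analysis pipeline uses
(:func:`gaitkin.kinematics.joint_angles`, ``tail_amplitude`` and the
arc-length resampling in :mod:`gaitkin.midline`), so there is no second
implementation to drift.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from . import midline as _midline
from . import kinematics as _kinematics
from .segmentation import binarize, otsu_threshold


def linear_envelope(amp_head_px: float, amp_tail_px: float
                    ) -> Callable[[np.ndarray], np.ndarray]:
    """Linear head-to-tail amplitude ramp in pixels."""
    def env(s: np.ndarray) -> np.ndarray:
        return amp_head_px + (amp_tail_px - amp_head_px) * np.asarray(s)
    return env


def default_thickness(half_width_px: float = 8.0
                      ) -> Callable[[np.ndarray], np.ndarray]:
    """Half-width profile of an adult zebrafish-like body.

    Widest over the head/anterior trunk, tapering toward the caudal
    peduncle; floored at 1.2 px so the rendered tail stays connected.
    """
    def profile(s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, dtype=np.float64)
        shape = (0.25 + 0.75 * np.exp(-((s - 0.15) / 0.35) ** 2)) * (1 - 0.8 * s)
        return np.maximum(half_width_px * shape, 1.2)
    return profile


@dataclass
class FishModelConfig:
    """Parameters of the synthetic fish and its imaging.

    Defaults mirror the intended operating point of the analysis — steady
    swimming at a tail-beat frequency near 10 Hz filmed at 1000 fps for 1 s —
    at a scaled-down frame geometry (body 200 px in a 400x160 px frame).
    """

    body_length_px: float = 200.0
    n_midline_samples: int = 128
    wave_frequency_hz: float = 10.0
    wavelength_bl: float = 1.0
    amp_head_px: float = 1.0
    amp_tail_px: float = 15.0
    amplitude_envelope: Callable[[np.ndarray], np.ndarray] | None = None
    thickness_profile: Callable[[np.ndarray], np.ndarray] | None = None
    frame_size: tuple[int, int] = (400, 160)  # (width, height)
    fps: float = 1000.0
    duration_s: float = 1.0
    background_intensity: int = 200
    fish_intensity: int = 40
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_envelope is None:
            self.amplitude_envelope = linear_envelope(self.amp_head_px,
                                                      self.amp_tail_px)
        if self.thickness_profile is None:
            self.thickness_profile = default_thickness()
        if self.body_length_px <= 0 or self.wave_frequency_hz <= 0:
            raise ValueError("body length and frequency must be positive")
        if self.wavelength_bl <= 0 or self.n_midline_samples < 16:
            raise ValueError("need wavelength > 0 and >= 16 midline samples")
        if not (0 <= self.fish_intensity < self.background_intensity <= 255):
            raise ValueError("fish must be darker than background, in [0,255]")
        if self.noise_sigma < 0 or self.fps <= 0 or self.duration_s <= 0:
            raise ValueError("noise_sigma >= 0, fps > 0, duration > 0 required")
        s = np.linspace(0, 1, 101)
        if (np.asarray(self.amplitude_envelope(s)) < 0).any():
            raise ValueError("amplitude envelope must be non-negative")
        w, h = self.frame_size
        max_thick = float(np.max(self.thickness_profile(s)))
        if self.body_length_px + 2 * max_thick > w:
            raise ValueError("fish does not fit inside the frame width")
        lateral = 2 * (float(np.max(self.amplitude_envelope(s))) + max_thick)
        if lateral > h:
            raise ValueError("lateral excursion exceeds frame height")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class GroundTruthFrame:
    """Exact per-frame pose of the synthetic fish."""

    frame_index: int
    midline: np.ndarray                    # (n, 2) subpixel (x, y), head first
    points_abcd: _midline.MidlinePoints
    angles_true: tuple[float, float, float]  # (alpha, beta, gamma) degrees
    amplitude_true: float                  # px


def midline_at_time(cfg: FishModelConfig, t: float) -> np.ndarray:
    """Subpixel midline points (head to tail) at time t seconds.

    The lateral displacement is the traveling wave evaluated at the sample
    positions; the axial coordinate is then compressed by a scalar factor
    (solved so the polyline arc length equals ``body_length_px``) and the
    curve is centered in the frame.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    s = np.linspace(0.0, 1.0, cfg.n_midline_samples)
    phase = (2 * np.pi * cfg.wave_frequency_hz * t
             - 2 * np.pi * s / cfg.wavelength_bl)
    y_lat = np.asarray(cfg.amplitude_envelope(s)) * np.sin(phase)
    L = cfg.body_length_px

    def arclen_minus_L(c: float) -> float:
        dx = np.diff(c * s * L)
        dy = np.diff(y_lat)
        return float(np.hypot(dx, dy).sum()) - L

    if np.allclose(y_lat, 0.0):
        c = 1.0
    else:
        lo = 1e-6
        if arclen_minus_L(lo) > 0:
            raise ValueError("amplitude too large: lateral path alone "
                             "exceeds the body length")
        c = brentq(arclen_minus_L, lo, 1.0, xtol=1e-12)
    w, h = cfg.frame_size
    x = (w - c * L) / 2.0 + c * s * L
    y = h / 2.0 + y_lat
    return np.column_stack([x, y])


def ground_truth_frame(cfg: FishModelConfig, frame_index: int
                       ) -> GroundTruthFrame:
    """Ground truth via the same geometry the analysis pipeline uses."""
    ml = midline_at_time(cfg, frame_index / cfg.fps)
    pts = _midline.midline_points(ml)
    angles = _kinematics.joint_angles(pts)
    amp = _kinematics.tail_amplitude(pts)
    return GroundTruthFrame(frame_index=frame_index, midline=ml,
                            points_abcd=pts, angles_true=angles,
                            amplitude_true=amp)


def _polyline_clearance(midline: np.ndarray, cfg: FishModelConfig,
                        shape: tuple[int, int]) -> np.ndarray:
    """Signed clearance of every pixel center: distance to the midline minus
    the local half-width.  Negative or zero = inside the fish body.

    Exact point-to-segment distances are computed, restricted to a window
    of segments near each pixel's nearest densely-resampled midline sample
    (valid because the body curve is smooth at the scale of its thickness).
    """
    # densify the midline so nearest-sample lookup localizes the segment
    step = 0.35
    pts = midline
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seglen)])
    n_dense = max(int(np.ceil(cum[-1] / step)) + 1, 2)
    frac = np.linspace(0.0, 1.0, n_dense)
    dense = _midline.resample_polyline(pts, frac)
    half_w = np.asarray(cfg.thickness_profile(frac), dtype=np.float64)
    max_w = float(half_w.max())

    h, w = shape
    x0 = max(int(np.floor(dense[:, 0].min() - max_w - 2)), 0)
    x1 = min(int(np.ceil(dense[:, 0].max() + max_w + 2)) + 1, w)
    y0 = max(int(np.floor(dense[:, 1].min() - max_w - 2)), 0)
    y1 = min(int(np.ceil(dense[:, 1].max() + max_w + 2)) + 1, h)

    xs, ys = np.meshgrid(np.arange(x0, x1), np.arange(y0, y1))
    pix = np.column_stack([xs.ravel(), ys.ravel()]).astype(np.float64)

    tree = cKDTree(dense)
    _, nearest = tree.query(pix, k=1)

    # exact distance to the segments adjacent to the nearest dense sample
    best = np.full(len(pix), np.inf)
    for off in (-2, -1, 0, 1):
        i = np.clip(nearest + off, 0, n_dense - 2)
        a = dense[i]
        b = dense[i + 1]
        ab = b - a
        denom = np.einsum("ij,ij->i", ab, ab)
        tproj = np.einsum("ij,ij->i", pix - a, ab) / np.where(denom > 0,
                                                              denom, 1.0)
        tproj = np.clip(tproj, 0.0, 1.0)
        proj = a + tproj[:, None] * ab
        d = np.linalg.norm(pix - proj, axis=1)
        wi = half_w[i] + tproj * (half_w[np.minimum(i + 1, n_dense - 1)]
                                  - half_w[i])
        best = np.minimum(best, d - wi)

    clearance = np.full(shape, np.inf)
    clearance[y0:y1, x0:x1] = best.reshape(y1 - y0, x1 - x0)
    return clearance


def render_frame(midline: np.ndarray, cfg: FishModelConfig,
                 frame_index: int = 0) -> np.ndarray:
    """Render one uint8 grayscale frame of the fish silhouette.

    Pixels within the local half-width of the midline get
    ``fish_intensity``, all others ``background_intensity``; i.i.d. Gaussian
    noise of ``noise_sigma`` is then added and the result clipped to
    [0, 255].  Rendering is a pure function of (cfg, frame_index): repeated
    calls are bit-identical.
    """
    midline = np.asarray(midline, dtype=np.float64)
    w, h = cfg.frame_size
    s_probe = np.linspace(0, 1, len(midline))
    max_w = float(np.max(cfg.thickness_profile(s_probe)))
    if (midline[:, 0].min() < max_w - 0.5 or midline[:, 0].max() > w - max_w + 0.5
            or midline[:, 1].min() < max_w - 0.5
            or midline[:, 1].max() > h - max_w + 0.5):
        raise ValueError("midline (after dilation by thickness) leaves frame")

    clearance = _polyline_clearance(midline, cfg, (h, w))
    frame = np.full((h, w), float(cfg.background_intensity))
    frame[clearance <= 0] = float(cfg.fish_intensity)
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, frame_index]))
        frame = frame + rng.normal(0.0, cfg.noise_sigma, frame.shape)
    return np.clip(np.rint(frame), 0, 255).astype(np.uint8)


def generate_video(cfg: FishModelConfig
                   ) -> tuple[np.ndarray, list[GroundTruthFrame]]:
    """Frame stack plus exact ground truth, sampled at t = k / fps.

    For frequency recovery the duration should cover at least two full wave
    periods.
    """
    n = cfg.n_frames
    frames = np.empty((n, cfg.frame_size[1], cfg.frame_size[0]),
                      dtype=np.uint8)
    truth: list[GroundTruthFrame] = []
    for k in range(n):
        gt = ground_truth_frame(cfg, k)
        frames[k] = render_frame(gt.midline, cfg, frame_index=k)
        truth.append(gt)
    return frames, truth


def corrupt_frames(frames: np.ndarray, indices: Sequence[int], mode: str,
                   seed: int = 0) -> np.ndarray:
    """Degrade selected frames to exercise the pipeline's validity checks.

    ``blank``: frame replaced by flat background (no blob downstream).
    ``split_blob``: a background-colored vertical band cuts the fish into
    two components.  ``speckle``: many small dark specks are scattered over
    the frame.  Untouched frames are returned bit-identical.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError("expected a (n_frames, h, w) stack")
    n = frames.shape[0]
    idx = sorted(set(int(i) for i in indices))
    if any(i < 0 or i >= n for i in idx):
        raise ValueError("frame index out of range")
    if mode not in ("blank", "split_blob", "speckle"):
        raise ValueError(f"unknown corruption mode {mode!r}")
    out = frames.copy()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0]))
    for i in idx:
        frame = out[i]
        background = int(np.median(frame))
        if mode == "blank":
            frame[:] = background
        elif mode == "split_blob":
            t = otsu_threshold(frame)
            fg = binarize(frame, t, "dark_fish")
            cols = np.nonzero(fg.any(axis=0))[0]
            cx = int((cols.min() + cols.max()) // 2) if len(cols) else \
                frame.shape[1] // 2
            frame[:, max(cx - 3, 0):cx + 4] = background
        else:  # speckle
            h, w = frame.shape
            ys = rng.integers(0, h - 1, size=300)
            xs = rng.integers(0, w - 1, size=300)
            dark = max(background - 160, 0)
            for y, x in zip(ys, xs):
                frame[y:y + 2, x:x + 2] = dark
    return out


# ---------------------------------------------------------------------------
# On-disk outputs
# ---------------------------------------------------------------------------

def write_ground_truth_csv(truth: list[GroundTruthFrame], path: str | Path
                           ) -> None:
    """Ground truth as CSV: frame index, A-D coordinates, angles, amplitude."""
    with open(path, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["frame_index", "ax", "ay", "bx", "by", "cx", "cy",
                     "dx", "dy", "alpha_deg", "beta_deg", "gamma_deg",
                     "amplitude_px"])
        for gt in truth:
            p = gt.points_abcd.as_array()
            wr.writerow([gt.frame_index,
                         *(f"{v:.4f}" for v in p.ravel()),
                         *(f"{v:.4f}" for v in gt.angles_true),
                         f"{gt.amplitude_true:.4f}"])


def write_config(cfg: FishModelConfig, path: str | Path) -> None:
    """Flat key-value dump of the scalar configuration fields."""
    keys = ["body_length_px", "n_midline_samples", "wave_frequency_hz",
            "wavelength_bl", "amp_head_px", "amp_tail_px", "fps",
            "duration_s", "background_intensity", "fish_intensity",
            "noise_sigma", "seed"]
    with open(path, "w") as fh:
        for k in keys:
            fh.write(f"{k} = {getattr(cfg, k)}\n")
        fh.write(f"frame_width = {cfg.frame_size[0]}\n")
        fh.write(f"frame_height = {cfg.frame_size[1]}\n")
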