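"""Per-frame orchestration, validity rules and video acceptance.

Every frame runs the full chain: preprocess -> motion clip -> Otsu ->
binarize -> blob detection -> fish-blob selection -> thinning -> longest
path -> orientation -> A-D points -> angles and amplitude.  Checks at each
stage (number of qualifying blobs, blob size/shape, inclusion of the
skeleton in the blob, degenerate histograms, cyclic skeletons, coincident
points) mark individual frames invalid; a video is accepted only when the
fraction of invalid frames is strictly below the configured maximum
(default 0.10 — strictly less than 10% invalid frames).
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import segmentation as seg
from . import midline as mid
from . import kinematics as kin

logger = logging.getLogger(__name__)

INVALID_REASONS = ("no_blob", "multiple_candidates", "blob_size",
                   "blob_shape", "skeleton_outside_blob", "cyclic_skeleton",
                   "degenerate_histogram", "coincident_points")


@dataclass(frozen=True)
class ValidityPolicy:
    """Which per-frame checks are enforced and the video-level threshold."""

    expect_single_blob: bool = True
    blob_criteria: seg.SelectionCriteria = field(
        default_factory=seg.SelectionCriteria)
    require_skeleton_in_blob: bool = True
    max_invalid_fraction: float = 0.10

    def __post_init__(self) -> None:
        if not (0 < self.max_invalid_fraction < 1):
            raise ValueError("max_invalid_fraction must be in (0, 1)")


@dataclass
class FrameReport:
    frame_index: int
    valid: bool
    invalid_reason: str = ""
    kinematics: kin.FrameKinematics | None = None

    def __post_init__(self) -> None:
        if self.valid != (self.invalid_reason == ""):
            raise ValueError("valid flag inconsistent with invalid_reason")


@dataclass
class PipelineConfig:
    """All tunables of the analysis chain (every default is overridable)."""

    fps: float = 1000.0
    roi: seg.Roi | None = None            # None = full frame
    gaussian_sigma: float = 1.5
    low_pct: float = 1.0
    high_pct: float = 99.0
    polarity: str = "dark_fish"
    motion_margin_px: int = 10
    motion_diff_threshold: float = 10.0
    min_motion_frac: float = 1e-4
    background_frames: int = 25
    criteria: seg.SelectionCriteria = field(
        default_factory=seg.SelectionCriteria)
    policy: ValidityPolicy | None = None
    orient_policy: str = "thickness"
    orient_x_sign: int = -1
    smooth_hz: float = kin.DEFAULT_SMOOTH_HZ
    max_gap: int = 20
    body_length_px: float | None = None   # None = median path arc length
    start_ms: float = 0.0
    duration_ms: float | None = None

    def __post_init__(self) -> None:
        if self.policy is None:
            self.policy = ValidityPolicy(blob_criteria=self.criteria)


def validate_frame(blob: seg.Blob | None,
                   skeleton_points: np.ndarray | None,
                   policy: ValidityPolicy,
                   n_candidates: int) -> tuple[bool, str]:
    """Apply the per-frame validity rules; returns (valid, reason)."""
    if blob is None:
        return False, "no_blob"
    if policy.expect_single_blob and n_candidates > 1:
        return False, "multiple_candidates"
    if (policy.require_skeleton_in_blob and skeleton_points is not None
            and not blob.contains_points(skeleton_points)):
        return False, "skeleton_outside_blob"
    return True, ""


def accept_video(reports: list[FrameReport],
                 policy: ValidityPolicy) -> tuple[bool, float]:
    """Video-level rule: accepted iff invalid fraction < the threshold.

    The inequality is strict: at exactly the threshold the video is
    rejected.
    """
    if not reports:
        raise ValueError("no frame reports")
    invalid_fraction = sum(not r.valid for r in reports) / len(reports)
    return invalid_fraction < policy.max_invalid_fraction, invalid_fraction


def _analyze_one_frame(region: np.ndarray, box: seg.Roi, roi_area: float,
                       cfg: PipelineConfig, frame_index: int,
                       ) -> tuple[FrameReport, dict]:
    """Segmentation through kinematics for one motion-clipped region.

    Returns the report plus debug artifacts (blob, skeleton, points) in
    full-frame coordinates.
    """
    policy = cfg.policy
    debug: dict = {}

    def invalid(reason: str) -> tuple[FrameReport, dict]:
        return FrameReport(frame_index=frame_index, valid=False,
                           invalid_reason=reason,
                           kinematics=kin.FrameKinematics(
                               frame_index=frame_index, valid=False,
                               invalid_reason=reason)), debug

    try:
        threshold = seg.otsu_threshold(region)
    except seg.DegenerateHistogramError:
        return invalid("degenerate_histogram")
    mask = seg.binarize(region, threshold, cfg.polarity)
    blobs = seg.find_blobs(mask)
    candidates = seg.qualifying_blobs(blobs, cfg.criteria, roi_area)
    blob = seg.select_fish_blob(blobs, cfg.criteria, roi_area)
    if blob is None:
        return invalid("no_blob")
    debug["blob"] = blob
    debug["offset"] = (box.x0, box.y0)

    try:
        skeleton = mid.skeletonize(blob.mask)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            path = mid.longest_path(skeleton)
            path = mid.orient_path(path, blob, cfg.orient_policy,
                                   cfg.orient_x_sign)
    except mid.CyclicSkeletonError:
        return invalid("cyclic_skeleton")
    except ValueError:
        return invalid("cyclic_skeleton")

    ok, reason = validate_frame(blob, path.points, policy,
                                len(candidates))
    if not ok:
        return invalid(reason)

    offset = np.array([box.x0, box.y0], dtype=np.float64)
    refined = mid.refine_path(path, blob)
    path_full = mid.SkeletonPath(refined.points + offset,
                                 refined.arc_length_px)
    debug["skeleton_points"] = path.points + offset

    try:
        points = mid.midline_points(path_full)
        alpha, beta, gamma = kin.joint_angles(points)
        amplitude = kin.tail_amplitude(points)
    except ValueError:
        return invalid("coincident_points")
    debug["points_abcd"] = points.as_array()
    debug["arc_length_px"] = path_full.arc_length_px

    fk = kin.FrameKinematics(
        frame_index=frame_index, valid=True, alpha_deg=alpha, beta_deg=beta,
        gamma_deg=gamma, amplitude_px=amplitude,
        amplitude_bl=np.nan,  # filled once body length is known
        points=points)
    return FrameReport(frame_index=frame_index, valid=True,
                       kinematics=fk), debug


def analyze_frames(frames: np.ndarray, cfg: PipelineConfig,
                   collect_debug: bool = False
                   ) -> tuple[kin.GaitTrace, kin.GaitSummary | None,
                              list[FrameReport], bool, list[dict]]:
    """Run the full chain over an in-memory frame stack.

    Returns ``(trace, summary, reports, accepted, debug)``; the summary is
    computed only when the video passes the invalid-frame rule, mirroring
    "used in the evaluation" semantics (None otherwise, reports and trace
    are always emitted).
    """
    frames = np.asarray(frames)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise IOError("empty or malformed frame stack")
    cfg.__post_init__()  # ensure policy exists after field mutation
    roi = cfg.roi or seg.Roi.full(frames.shape[1:])

    pre = np.stack([seg.preprocess(f, cfg.gaussian_sigma, cfg.low_pct,
                                   cfg.high_pct) for f in frames])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        boxes = seg.motion_clip(pre, roi, cfg.motion_margin_px,
                                cfg.motion_diff_threshold,
                                cfg.min_motion_frac, cfg.background_frames)

    reports: list[FrameReport] = []
    debug_all: list[dict] = []
    arc_lengths: list[float] = []
    for k in range(frames.shape[0]):
        sl = boxes[k].slices()
        report, debug = _analyze_one_frame(pre[k][sl], boxes[k], roi.area,
                                           cfg, k)
        reports.append(report)
        if report.valid:
            arc_lengths.append(debug["arc_length_px"])
        if collect_debug:
            debug_all.append(debug)

    body_length = cfg.body_length_px or (
        float(np.median(arc_lengths)) if arc_lengths else np.nan)
    for r in reports:
        if r.valid:
            r.kinematics.amplitude_bl = r.kinematics.amplitude_px / body_length

    trace = kin.GaitTrace(fps=cfg.fps, body_length_px=body_length,
                          frames=[r.kinematics for r in reports])
    accepted, invalid_fraction = accept_video(reports, cfg.policy)
    reasons = Counter(r.invalid_reason for r in reports if not r.valid)
    logger.info("analyzed %d frames: %.1f%% invalid %s; accepted=%s",
                len(reports), 100 * invalid_fraction, dict(reasons), accepted)

    summary = None
    if accepted and any(r.valid for r in reports):
        summary = kin.summarize(trace, cfg.smooth_hz, cfg.max_gap)
    return trace, summary, reports, accepted, debug_all


def analyze_video(source, cfg: PipelineConfig, collect_debug: bool = False):
    """Analyze an AVI path, PNG frame directory, or in-memory stack.

    The analysis window (``start_ms``/``duration_ms``) selects a fragment of
    the video before processing; the default is the whole video.
    """
    if isinstance(source, (str, Path)):
        from .io import load_frames
        frames, fps = load_frames(source)
        if fps and cfg.fps <= 0:
            cfg.fps = fps
    else:
        frames = np.asarray(source)
    if frames.ndim != 3 or frames.shape[0] == 0:
        raise IOError("video source yielded no frames")
    start = int(round(cfg.start_ms * cfg.fps / 1000.0))
    if cfg.duration_ms is not None:
        stop = start + int(round(cfg.duration_ms * cfg.fps / 1000.0))
    else:
        stop = frames.shape[0]
    if not (0 <= start < frames.shape[0]) or stop <= start:
        raise IOError("analysis window outside the video")
    return analyze_frames(frames[start:stop], cfg, collect_debug)
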