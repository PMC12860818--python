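"""Maximum-upslope myocardial blood flow estimation.

The maximum-upslope model relates tissue contrast uptake to flow:

    MBF = max d/dt c_tissue(t) / max c_arterial(t)

The ratio is a perfusion fraction per second; multiplying by 6000 converts to
the conventional mL / 100 mL / min.  Segment-wise MBF is normalized to the
best-perfused ("remote") AHA segment, giving the relative MBF used for
obstructive-CAD detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import InvalidInputError
from .types import DynamicVolume

__all__ = [
    "PerfusionResult",
    "extract_aif",
    "max_upslope",
    "estimate_mbf",
    "mbf_map",
    "segment_mbf",
    "remote_and_relative",
    "MaxUpslopeFlow",
]

#: (fraction / s) -> mL / 100 mL / min
UPSLOPE_TO_MBF = 6000.0


@dataclass
class PerfusionResult:
    """Voxel MBF map plus per-segment statistics."""

    mbf_map: np.ndarray | None            # 3D, mL/100mL/min
    segment_mbf: dict                     # segment id -> mean MBF
    remote_flow: float                    # highest included segment MBF
    remote_segment: int
    relative_mbf: dict                    # segment id -> MBF / remote
    aif_curve: np.ndarray = field(default=None)
    aif_peak: float = float("nan")
    aif_peak_index: int = -1


def extract_aif(volume, aif_roi: np.ndarray) -> np.ndarray:
    """Frame-wise mean concentration over the arterial ROI."""
    data = volume.data if isinstance(volume, DynamicVolume) else np.asarray(volume)
    roi = np.asarray(aif_roi, dtype=bool)
    if data.ndim != 4:
        raise InvalidInputError("extract_aif expects a 4D volume")
    if roi.shape != data.shape[:3]:
        raise InvalidInputError("AIF ROI shape must match the spatial grid")
    if not roi.any():
        raise InvalidInputError("AIF ROI is empty")
    return data[roi].mean(axis=0)


def _smooth(curve: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return curve
    if window % 2 != 1:
        raise InvalidInputError("smooth window must be odd")
    pad = window // 2
    padded = np.pad(curve, pad, mode="edge")
    kernel = np.ones(window) / window
    return np.convolve(padded, kernel, mode="valid")


def max_upslope(
    curve: np.ndarray,
    frame_times_s: np.ndarray,
    window: tuple | None = None,
    smooth_window: int = 1,
) -> float:
    """Maximum first-difference slope of a (optionally smoothed) curve.

    ``window = (i0, i1)`` restricts the search to differences starting at
    frame indices i0 <= i < i1 (the first-pass window).
    """
    curve = np.asarray(curve, dtype=np.float64)
    t = np.asarray(frame_times_s, dtype=np.float64)
    if curve.size < 4:
        raise InvalidInputError("max_upslope requires at least 4 frames")
    if t.shape != curve.shape or np.any(np.diff(t) <= 0):
        raise InvalidInputError("frame times must match the curve and increase")
    curve = _smooth(curve, smooth_window)
    slopes = np.diff(curve) / np.diff(t)
    if window is not None:
        i0, i1 = window
        slopes = slopes[max(i0, 0): i1]
        if slopes.size == 0:
            raise InvalidInputError("empty first-pass window")
    return float(slopes.max())


def first_pass_window(aif_curve: np.ndarray, lag: int = 2) -> tuple:
    """Search window from bolus start to AIF peak + ``lag`` frames."""
    peak = int(np.argmax(aif_curve))
    return (0, peak + lag)


def estimate_mbf(
    tissue_curve: np.ndarray,
    aif_curve: np.ndarray,
    frame_times_s: np.ndarray,
    smooth_window: int = 1,
    lag: int = 2,
) -> float:
    """MBF (mL/100mL/min) = max upslope of tissue / AIF peak x 6000.

    Invariant to constant baselines on the tissue curve.  The upslope search
    is restricted to the first pass (bolus start to AIF peak + ``lag``).
    """
    aif_curve = np.asarray(aif_curve, dtype=np.float64)
    if aif_curve.shape != np.shape(tissue_curve):
        raise InvalidInputError("tissue and AIF curves must share the time grid")
    peak = float(aif_curve.max())
    if peak <= 0:
        raise InvalidInputError("AIF peak must be > 0")
    slope = max_upslope(
        tissue_curve, frame_times_s,
        window=first_pass_window(aif_curve, lag),
        smooth_window=smooth_window,
    )
    return max(slope, 0.0) / peak * UPSLOPE_TO_MBF


def mbf_map(
    volume,
    aif_curve: np.ndarray,
    frame_times_s: np.ndarray,
    mask: np.ndarray | None = None,
    smooth_window: int = 1,
    lag: int = 2,
) -> np.ndarray:
    """Voxelwise maximum-upslope MBF map (3D), clipped at 0 outside/negative."""
    data = volume.data if isinstance(volume, DynamicVolume) else np.asarray(volume)
    t = np.asarray(frame_times_s, dtype=np.float64)
    aif_curve = np.asarray(aif_curve, dtype=np.float64)
    peak = float(aif_curve.max())
    if peak <= 0:
        raise InvalidInputError("AIF peak must be > 0")
    i0, i1 = first_pass_window(aif_curve, lag)
    curves = data
    if smooth_window > 1:
        pad = smooth_window // 2
        padded = np.pad(curves, [(0, 0)] * 3 + [(pad, pad)], mode="edge")
        kernel = np.ones(smooth_window) / smooth_window
        curves = np.apply_along_axis(
            lambda c: np.convolve(c, kernel, mode="valid"), -1, padded
        )
    slopes = np.diff(curves, axis=-1) / np.diff(t)
    slopes = slopes[..., max(i0, 0): i1]
    out = slopes.max(axis=-1) / peak * UPSLOPE_TO_MBF
    out = np.clip(out, 0.0, None)
    if mask is not None:
        out = np.where(np.asarray(mask, bool), out, 0.0)
    return out


def segment_mbf(
    volume,
    rois: dict,
    aif_curve: np.ndarray,
    frame_times_s: np.ndarray,
    smooth_window: int = 1,
    lag: int = 2,
) -> dict:
    """Per-segment MBF from the ROI-mean tissue curve (noise-robust).

    Averaging the tissue curve over the ROI before taking the maximum upslope
    avoids the upward bias of maximizing noisy voxelwise differences; in the
    noise-free limit it equals the ROI mean of the voxel map.
    """
    data = volume.data if isinstance(volume, DynamicVolume) else np.asarray(volume)
    out = {}
    for seg, roi in rois.items():
        roi = np.asarray(roi, dtype=bool)
        if not roi.any():
            out[seg] = np.nan
            continue
        curve = data[roi].mean(axis=0)
        out[seg] = estimate_mbf(
            curve, aif_curve, frame_times_s, smooth_window=smooth_window, lag=lag
        )
    return out


def remote_and_relative(segment_mbf_table: dict, included=None):
    """Remote flow (highest included segment MBF) and relative MBF per segment.

    Ties for the remote segment break to the lowest segment index.  Returns
    ``(remote_flow, remote_segment, relative: dict)``.
    """
    if included is None:
        included = {s: np.isfinite(v) for s, v in segment_mbf_table.items()}
    eligible = {
        s: v for s, v in segment_mbf_table.items()
        if included.get(s, False) and np.isfinite(v)
    }
    if not eligible:
        raise InvalidInputError("no included segments to define remote flow")
    remote = max(eligible.values())
    remote_segment = min(s for s, v in eligible.items() if v == remote)
    if remote <= 0:
        raise InvalidInputError("remote flow must be > 0")
    relative = {s: v / remote for s, v in eligible.items()}
    return float(remote), int(remote_segment), relative


class MaxUpslopeFlow(BaseEstimator, TransformerMixin):
    """Maximum-upslope MBF transformer.

    ``fit`` extracts and stores the arterial input function from the AIF ROI;
    ``transform`` maps a concentration volume to a voxelwise 3D MBF map.

    Parameters
    ----------
    aif_roi : ndarray of bool
        Arterial blood-pool ROI on the spatial grid.
    smooth_window : int, default=1
        Odd moving-average width applied before differencing (1 = off).
    lag : int, default=2
        Frames past the AIF peak included in the first-pass search window.
    """

    def __init__(self, aif_roi=None, smooth_window=1, lag=2):
        self.aif_roi = aif_roi
        self.smooth_window = smooth_window
        self.lag = lag

    def fit(self, X, y=None):
        if self.aif_roi is None:
            raise InvalidInputError("aif_roi is required")
        self.aif_curve_ = extract_aif(X, self.aif_roi)
        self.aif_peak_ = float(self.aif_curve_.max())
        self.aif_peak_index_ = int(np.argmax(self.aif_curve_))
        return self

    def transform(self, X) -> np.ndarray:
        t = X.frame_times_s if isinstance(X, DynamicVolume) else None
        if t is None:
            raise InvalidInputError("transform requires a DynamicVolume")
        return mbf_map(
            X, self.aif_curve_, t,
            smooth_window=self.smooth_window, lag=self.lag,
        )
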