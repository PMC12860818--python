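"""Noise standardization and intensity conversion for dynamic CTP volumes.

Two-step denoising: a 3x3x3 spatial median filter per frame, followed by a
spatial bilateral filter per frame whose range sigma adapts to the measured
noise of unenhanced myocardium (sigma_range = 1.96 * SD of the baseline-frame
left-ventricular myocardium).  Filters act on the spatial dimensions only;
temporal filtering would distort the upslopes the flow estimation relies on.

Hounsfield units are then converted to absolute iodine concentrations by a
linear enhancement model, HU = baseline + slope * concentration, with
tube-voltage-dependent slope (configurable calibration constants).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .exceptions import DegenerateInputError, InvalidInputError, UnitError
from .types import UNIT_CONC, UNIT_HU, DynamicVolume

__all__ = [
    "DenoiseParams",
    "ConversionParams",
    "DEFAULT_SLOPES",
    "detect_baseline_frames",
    "estimate_sigma_range",
    "denoise",
    "hu_to_concentration",
    "concentration_to_hu",
    "TwoStepDenoiser",
    "HUToConcentration",
]

#: Iodine enhancement slope, HU per (mg I/mL), by tube voltage.  These are
#: configurable calibration constants of the conversion model.
DEFAULT_SLOPES = {80: 25.0, 70: 30.0}


@dataclass
class DenoiseParams:
    """Two-step denoising parameters (median window is fixed at 3x3x3)."""

    sigma_domain_vox: float = 2.0
    sigma_range: float | None = None    # intensity units; estimated if None
    truncate: float = 2.0               # bilateral kernel radius = ceil(truncate*sigma)
    baseline_frames: tuple | None = None

    def __post_init__(self):
        if self.sigma_domain_vox <= 0:
            raise InvalidInputError("sigma_domain_vox must be > 0")
        if self.sigma_range is not None and self.sigma_range <= 0:
            raise InvalidInputError("sigma_range must be > 0")


@dataclass
class ConversionParams:
    """HU -> mg I/mL conversion: (HU - baseline) / slope."""

    kv: int = 80
    slope: float | None = None          # HU per (mg I/mL); from kv table if None
    subtract_baseline: bool = True
    baseline_frames: tuple | None = None

    def resolved_slope(self) -> float:
        slope = DEFAULT_SLOPES.get(self.kv) if self.slope is None else self.slope
        if slope is None or slope <= 0:
            raise InvalidInputError("enhancement slope must be > 0")
        return float(slope)


def detect_baseline_frames(curve: np.ndarray) -> tuple:
    """Indices of frames before contrast arrival on a global reference curve.

    Arrival is the first frame exceeding the early-baseline mean by more than
    max(2 * baseline SD, 2% of the curve's dynamic range).  At least the first
    frame is always returned.
    """
    curve = np.asarray(curve, dtype=np.float64)
    n0 = max(2, min(3, curve.size - 1))
    mean0, sd0 = curve[:n0].mean(), curve[:n0].std()
    thresh = mean0 + max(2.0 * sd0, 0.02 * (curve.max() - mean0))
    above = np.nonzero(curve > thresh)[0]
    onset = int(above[0]) if above.size else curve.size
    return tuple(range(max(onset, 1)))


def estimate_sigma_range(
    volume,
    myocardium_mask: np.ndarray,
    baseline_frames=None,
) -> float:
    """sigma_range = 1.96 * SD of unenhanced LV myocardium.

    The SD pools all masked voxels over the baseline (pre-contrast) frames.
    """
    data = volume.data if isinstance(volume, DynamicVolume) else np.asarray(volume)
    mask = np.asarray(myocardium_mask, dtype=bool)
    if not mask.any():
        raise InvalidInputError("myocardium mask is empty")
    if baseline_frames is None:
        baseline_frames = detect_baseline_frames(data[mask].mean(axis=0))
    baseline_frames = list(baseline_frames)
    sd = float(data[mask][:, baseline_frames].std())
    if sd == 0.0:
        raise DegenerateInputError(
            "baseline myocardium has zero variance (noise-free input); "
            "set sigma_range explicitly to use the bilateral filter"
        )
    return 1.96 * sd


@njit(cache=True)
def _bilateral3d(img, domain_w, radius, sigma_range):  # pragma: no cover - jitted
    nx, ny, nz = img.shape
    out = np.empty_like(img)
    inv2sr2 = 1.0 / (2.0 * sigma_range * sigma_range)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                c = img[i, j, k]
                num = 0.0
                den = 0.0
                for a in range(-radius, radius + 1):
                    ii = min(max(i + a, 0), nx - 1)
                    for b in range(-radius, radius + 1):
                        jj = min(max(j + b, 0), ny - 1)
                        for d in range(-radius, radius + 1):
                            kk = min(max(k + d, 0), nz - 1)
                            v = img[ii, jj, kk]
                            w = domain_w[a + radius, b + radius, d + radius] * math.exp(
                                -(v - c) * (v - c) * inv2sr2
                            )
                            num += w * v
                            den += w
                out[i, j, k] = num / den
    return out


def _domain_weights(sigma: float, radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    return g[:, None, None] * g[None, :, None] * g[None, None, :]


def bilateral_filter_3d(
    img: np.ndarray, sigma_domain: float, sigma_range: float, truncate: float = 2.0
) -> np.ndarray:
    """Edge-preserving bilateral filter on a single 3D frame (replicate padding)."""
    radius = int(math.ceil(truncate * sigma_domain))
    w = _domain_weights(sigma_domain, radius)
    return _bilateral3d(np.ascontiguousarray(img, dtype=np.float64),
                        w, radius, float(sigma_range))


def denoise(volume, params: DenoiseParams | None = None, myocardium_mask=None):
    """Two-step denoising: 3x3x3 median then adaptive bilateral, per frame.

    Accepts a :class:`DynamicVolume` or a plain 4D array.  If
    ``params.sigma_range`` is None it is estimated from the myocardium mask
    (required in that case).
    """
    params = params or DenoiseParams()
    is_dv = isinstance(volume, DynamicVolume)
    data = volume.data if is_dv else np.asarray(volume, dtype=np.float64)
    if data.ndim != 4:
        raise InvalidInputError("denoise expects a 4D volume")
    if min(data.shape[:3]) < 3:
        raise InvalidInputError("spatial axes must have at least 3 voxels")
    sigma_range = params.sigma_range
    if sigma_range is None:
        if myocardium_mask is None:
            raise InvalidInputError(
                "sigma_range not set and no myocardium mask given to estimate it"
            )
        sigma_range = estimate_sigma_range(data, myocardium_mask,
                                           params.baseline_frames)
    out = np.empty_like(data)
    for f in range(data.shape[3]):
        med = ndimage.median_filter(data[..., f], size=3, mode="nearest")
        out[..., f] = bilateral_filter_3d(
            med, params.sigma_domain_vox, sigma_range, params.truncate
        )
    return volume.with_data(out) if is_dv else out


def hu_to_concentration(
    volume: DynamicVolume, params: ConversionParams | None = None
) -> DynamicVolume:
    """Convert a HU volume to absolute iodine concentration (mg I/mL)."""
    params = params or ConversionParams()
    if not isinstance(volume, DynamicVolume):
        raise InvalidInputError("hu_to_concentration expects a DynamicVolume")
    if volume.unit != UNIT_HU:
        raise UnitError(f"volume is already in {volume.unit}, expected HU")
    slope = params.resolved_slope()
    data = volume.data
    if params.subtract_baseline:
        frames = params.baseline_frames
        if frames is None:
            # contrast arrives first (and strongest) in arterial blood: detect
            # the onset on the mean curve of the top-1% enhancing voxels
            flat = data.reshape(-1, data.shape[3])
            enhancement = flat.max(axis=1) - flat[:, 0]
            k = max(1, flat.shape[0] // 100)
            ref = flat[np.argsort(enhancement)[-k:]].mean(axis=0)
            frames = detect_baseline_frames(ref)
        baseline = data[..., list(frames)].mean(axis=-1, keepdims=True)
    else:
        baseline = 0.0
    return volume.with_data((data - baseline) / slope, unit=UNIT_CONC)


def concentration_to_hu(
    volume: DynamicVolume, params: ConversionParams, baseline=0.0
) -> DynamicVolume:
    """Inverse of :func:`hu_to_concentration` given the subtracted baseline."""
    if volume.unit != UNIT_CONC:
        raise UnitError(f"volume is in {volume.unit}, expected {UNIT_CONC}")
    slope = params.resolved_slope()
    baseline = np.asarray(baseline)
    if baseline.ndim == 3:
        baseline = baseline[..., None]
    return volume.with_data(volume.data * slope + baseline, unit=UNIT_HU)


class TwoStepDenoiser(BaseEstimator, TransformerMixin):
    """Median + adaptive bilateral denoiser with sklearn transformer API.

    Parameters mirror :class:`DenoiseParams`; ``mask`` (the LV myocardium) is
    used during :meth:`fit` to estimate ``sigma_range_`` when ``sigma_range``
    is not given.
    """

    def __init__(self, sigma_domain=2.0, sigma_range=None, truncate=2.0,
                 mask=None, baseline_frames=None):
        self.sigma_domain = sigma_domain
        self.sigma_range = sigma_range
        self.truncate = truncate
        self.mask = mask
        self.baseline_frames = baseline_frames

    def fit(self, X, y=None):
        if self.sigma_range is not None:
            self.sigma_range_ = float(self.sigma_range)
        else:
            if self.mask is None:
                raise InvalidInputError("need a myocardium mask or sigma_range")
            self.sigma_range_ = estimate_sigma_range(
                X, self.mask, self.baseline_frames
            )
        return self

    def transform(self, X):
        params = DenoiseParams(
            sigma_domain_vox=self.sigma_domain,
            sigma_range=self.sigma_range_,
            truncate=self.truncate,
            baseline_frames=self.baseline_frames,
        )
        return denoise(X, params)


class HUToConcentration(BaseEstimator, TransformerMixin):
    """HU -> mg I/mL conversion transformer (stateless)."""

    def __init__(self, kv=80, slope=None, subtract_baseline=True,
                 baseline_frames=None):
        self.kv = kv
        self.slope = slope
        self.subtract_baseline = subtract_baseline
        self.baseline_frames = baseline_frames

    def fit(self, X, y=None):
        self.slope_ = ConversionParams(kv=self.kv, slope=self.slope).resolved_slope()
        return self

    def transform(self, X) -> DynamicVolume:
        return hu_to_concentration(
            X,
            ConversionParams(
                kv=self.kv,
                slope=self.slope,
                subtract_baseline=self.subtract_baseline,
                baseline_frames=self.baseline_frames,
            ),
        )
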