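"""Synthetic 4D dynamic stress CT perfusion phantom.

Emulates a ~30 s dynamic stress acquisition sampled about once per second: a
gamma-variate arterial input function (first-pass iodine bolus), a digital
short-axis left ventricle (hollow cylinder capped by an ellipsoidal apex) with
analytic AHA 17-segment labels, and tissue time-attenuation curves whose
maximum upslope encodes the local myocardial blood flow (MBF).

Two ischemia patterns can be assigned per coronary territory, mirroring the
distinct hemodynamic footprints of the two disease entities:

* ``obstructive`` — a spatially uniform reduction of flow across the whole
  downstream territory (homogeneous exhaustion of vasodilator capacity behind
  an epicardial stenosis), optionally with a transmural endo->epi gradient;
* ``microvascular`` — a patchy, spatially correlated multiplicative reduction
  field (heterogeneous exhaustion of vasodilator capacity), producing a
  complex, irregular perfusion pattern at moderately reduced mean flow.

Healthy myocardium additionally carries a mild multiplicative physiological
flow heterogeneity (log-normal, spatially correlated): perfusion texture whose
amplitude scales with local flow is what the fractal-dimension mapping reads
out, so its dispersion and correlation length are explicit calibration knobs
of the phantom (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .aha import TERRITORIES, territory_of
from .exceptions import InvalidInputError
from .types import UNIT_HU, DynamicVolume

__all__ = [
    "AIFParams",
    "PhantomConfig",
    "PhantomStudy",
    "make_aif_curve",
    "make_tissue_curve",
    "build_lv_geometry",
    "make_phantom",
]

#: Iodine enhancement slope in HU per (mg I / mL), by tube voltage.
#: Configurable calibration constants (see preprocess.ConversionParams).
ENHANCEMENT_SLOPE_HU_PER_MG_ML = {80: 25.0, 70: 30.0}

PATTERNS = ("none", "obstructive", "microvascular")


@dataclass
class AIFParams:
    """Gamma-variate arterial input function parameters.

    The curve is ``A * (tau/tp)^shape * exp(shape * (1 - tau/tp))`` for
    ``tau = t - onset_s > 0`` (zero before onset), with time-to-peak
    ``tp = shape * scale_s`` and peak value exactly ``amplitude``.
    """

    amplitude: float = 12.0   # peak concentration, mg I/mL
    onset_s: float = 3.0
    shape: float = 3.0
    scale_s: float = 2.0      # time-to-peak = shape * scale_s = 6 s


@dataclass
class PhantomConfig:
    """Configuration of a synthetic dynamic stress CTP study.

    Flow values are stress-level MBF in mL/100 mL/min.  ``seed`` fixes all
    randomness.  Defaults are the calibrated study conditions documented in
    docs/methods.md.
    """

    shape: tuple = (64, 64, 16)                 # spatial grid (nx, ny, nz)
    n_frames: int = 30
    spacing_mm: tuple = (0.75, 0.75, 1.5)
    frame_interval_s: float = 1.0
    frame_jitter_sd_s: float = 0.0
    aif: AIFParams = field(default_factory=AIFParams)
    territory_mbf: dict = field(
        default_factory=lambda: {"LAD": 160.0, "RCA": 160.0, "LCX": 160.0}
    )
    territory_pattern: dict = field(
        default_factory=lambda: {"LAD": "none", "RCA": "none", "LCX": "none"}
    )
    obstructive_reduction: float = 0.40         # flow fraction in obstructive
    transmural_gradient: bool = False           # endo->epi gradient (obstructive)
    micro_mean_reduction: float = 0.65          # mean flow fraction (microvascular)
    micro_heterogeneity_sd: float = 0.20        # relative SD of the patchy field
    micro_corr_mm: float = 6.0                  # patch correlation length
    phys_heterogeneity_sd: float = 0.50         # physiological texture, relative SD
    phys_spectral_beta: float = 0.0             # power-law exponent of its spectrum
    arrival_jitter_sd_s: float = 0.6            # per-voxel bolus arrival dispersion
    baseline_myo_hu: float = 80.0
    baseline_blood_hu: float = 50.0
    background_hu: float = 40.0
    noise_sd_hu: float = 1.5
    kv: int = 80
    r_out_mm: float | None = 18.0               # derived from the grid if None
    wall_mm: float | None = 8.0
    de_segments: tuple = ()                     # delayed-enhancement segments
    seed: int = 0

    def __post_init__(self):
        if self.n_frames < 8:
            raise InvalidInputError("n_frames must be >= 8")
        if self.noise_sd_hu < 0:
            raise InvalidInputError("noise_sd_hu must be >= 0")
        if self.kv not in ENHANCEMENT_SLOPE_HU_PER_MG_ML:
            raise InvalidInputError("kv must be 70 or 80")
        for terr in set(self.territory_mbf) | set(self.territory_pattern):
            if terr not in TERRITORIES:
                raise InvalidInputError(
                    f"territory must be one of {TERRITORIES}, got {terr!r}"
                )
        for terr, mbf in self.territory_mbf.items():
            if mbf <= 0:
                raise InvalidInputError(f"MBF for {terr} must be > 0, got {mbf}")
        for terr, pat in self.territory_pattern.items():
            if pat not in PATTERNS:
                raise InvalidInputError(
                    f"pattern must be one of {PATTERNS}, got {pat!r}"
                )
        if not 0 < self.obstructive_reduction <= 1:
            raise InvalidInputError("obstructive_reduction must be in (0, 1]")
        if not 0 < self.micro_mean_reduction <= 1:
            raise InvalidInputError("micro_mean_reduction must be in (0, 1]")


@dataclass
class PhantomStudy:
    """A generated phantom with ground truth."""

    volume: DynamicVolume                  # HU, with noise
    labels: np.ndarray                     # AHA segments, 0 = background
    myocardium_mask: np.ndarray
    aif_mask: np.ndarray                   # arterial blood-pool ROI
    de_mask: np.ndarray | None             # delayed-enhancement mask (optional)
    true_mbf_field: np.ndarray             # 3D voxelwise ground-truth MBF
    true_segment_mbf: dict                 # segment id -> mean true MBF
    true_territory_class: dict             # territory -> none/obstructive/microvascular
    true_remote_flow: float                # max segment-mean true MBF
    config: PhantomConfig


def make_aif_curve(params: AIFParams, frame_times_s: np.ndarray) -> np.ndarray:
    """Sampled gamma-variate arterial concentration curve (mg I/mL)."""
    t = np.asarray(frame_times_s, dtype=np.float64)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise InvalidInputError("frame_times_s must be strictly increasing")
    if params.amplitude < 0:
        raise InvalidInputError("AIF amplitude must be >= 0")
    if params.shape <= 0 or params.scale_s <= 0:
        raise InvalidInputError("AIF shape and scale must be > 0")
    tp = params.shape * params.scale_s
    tau = t - params.onset_s
    curve = np.zeros_like(t)
    pos = tau > 0
    x = tau[pos] / tp
    curve[pos] = params.amplitude * x**params.shape * np.exp(
        params.shape * (1.0 - x)
    )
    return curve


def make_tissue_curve(
    aif: np.ndarray,
    frame_times_s: np.ndarray,
    true_mbf: float,
    baseline: float = 0.0,
) -> np.ndarray:
    """Tissue concentration curve whose maximum upslope encodes ``true_mbf``.

    Uses the single-compartment uptake model c(t) = MBF/6000 * int_0^t AIF,
    discretized with a left-rectangle rule so that the maximum frame-to-frame
    upslope of the sampled curve equals ``true_mbf/6000 * max(aif)`` exactly
    (the AIF peak must lie before the final frame).
    """
    if np.ndim(true_mbf) == 0 and true_mbf <= 0:
        raise InvalidInputError("true_mbf must be > 0")
    t = np.asarray(frame_times_s, dtype=np.float64)
    aif = np.asarray(aif, dtype=np.float64)
    increments = aif[:-1] * np.diff(t)          # left-rectangle quadrature
    cum = np.concatenate([[0.0], np.cumsum(increments)])
    return baseline + (true_mbf / 6000.0) * cum


def _fractal_field(
    rng: np.random.Generator,
    shape: tuple,
    spacing_mm: tuple,
    mean: float,
    rel_sd: float,
    beta: float,
) -> np.ndarray:
    """Multiplicative field with a power-law (fractal) spatial spectrum.

    Spectral synthesis: white Gaussian noise shaped by |k|^(-beta/2), then a
    symmetric multiplicative transform mean * (1 + rel_sd * g), clipped away
    from zero.  Real myocardial flow heterogeneity is scale-invariant (its
    relative dispersion follows a power law in aggregation scale), which is
    the texture property the blanket FD reads out; ``beta`` sets the
    roughness.  The symmetric (rather than log-normal) form keeps the local
    median equal to the local mean, so median filtering in the denoising
    stage does not bias ROI-mean flow.
    """
    if rel_sd <= 0:
        return np.full(shape, mean)
    white = rng.standard_normal(shape)
    spec = np.fft.fftn(white)
    ks = np.meshgrid(
        *[np.fft.fftfreq(n, d=s) for n, s in zip(shape, spacing_mm)],
        indexing="ij",
    )
    k = np.sqrt(sum(a**2 for a in ks))
    k[0, 0, 0] = np.inf  # drop the DC mode
    spec *= k ** (-beta / 2.0)
    g = np.fft.ifftn(spec).real
    g = (g - g.mean()) / g.std()
    return np.clip(mean * (1.0 + rel_sd * g), 0.05 * mean, None)


def _correlated_lognormal(
    rng: np.random.Generator,
    shape: tuple,
    spacing_mm: tuple,
    mean: float,
    rel_sd: float,
    corr_mm: float,
) -> np.ndarray:
    """Spatially correlated multiplicative field with E = mean, SD = mean*rel_sd."""
    if rel_sd <= 0:
        return np.full(shape, mean)
    g = rng.standard_normal(shape)
    sigmas = [max(corr_mm / s, 1e-6) / 2.0 for s in spacing_mm]  # corr len ~ 2 sigma
    g = ndimage.gaussian_filter(g, sigma=sigmas, mode="wrap")
    g = (g - g.mean()) / g.std()
    s = np.sqrt(np.log1p(rel_sd**2))
    return mean * np.exp(s * g - 0.5 * s**2)


def build_lv_geometry(config: PhantomConfig):
    """Analytic short-axis LV: labels (AHA 1..17), myocardium and AIF masks."""
    nx, ny, nz = config.shape
    dx, dy, dz = config.spacing_mm
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    z = np.arange(nz) * dz
    xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")

    extent = min(nx * dx, ny * dy)
    r_out = config.r_out_mm if config.r_out_mm is not None else 0.19 * extent
    wall = config.wall_mm if config.wall_mm is not None else 0.42 * r_out
    r_in = r_out - wall

    z_tip = 0.05 * z[-1]
    z_base = 0.95 * z[-1]
    h_cap = 0.22 * (z_base - z_tip)
    z0 = z_tip + h_cap                      # cap / cylinder junction

    r_xy = np.hypot(xx, yy)
    # effective radius: cylindrical above z0, ellipsoidal cap below
    dip = np.clip(z0 - zz, 0.0, None) * (r_out / h_cap)
    rho = np.sqrt(r_xy**2 + dip**2)
    myo = (rho >= r_in) & (rho <= r_out) & (zz >= z_tip) & (zz <= z_base)

    # cavity vanishes where the inner surface closes; below that is the apex cap
    z_cav_end = z0 - h_cap * (r_in / r_out)
    labels = np.zeros(config.shape, dtype=np.int16)
    theta = np.degrees(np.arctan2(yy, xx)) % 360.0

    long_axis = (zz - z_cav_end) / max(z_base - z_cav_end, 1e-9)
    apex = myo & (zz < z_cav_end)
    apical = myo & ~apex & (long_axis < 1.0 / 3.0)
    mid = myo & (long_axis >= 1.0 / 3.0) & (long_axis < 2.0 / 3.0)
    basal = myo & (long_axis >= 2.0 / 3.0)

    labels[apex] = 17
    sector6 = (((theta + 30.0) % 360.0) // 60.0).astype(int)  # 0..5
    sector4 = (((theta + 45.0) % 360.0) // 90.0).astype(int)  # 0..3
    order6 = np.array([1, 2, 3, 4, 5, 6])     # anterior, anteroseptal, ...
    order4 = np.array([13, 14, 15, 16])       # anterior, septal, inferior, lateral
    labels[basal] = order6[sector6[basal]]
    labels[mid] = order6[sector6[mid]] + 6
    labels[apical] = order4[sector4[apical]]

    # arterial blood-pool ROI: central cavity cylinder, well clear of the wall
    aif_r = max(r_in - 2.0, 0.45 * r_in)
    zc_lo = z0 + 0.3 * (z_base - z0)
    zc_hi = z0 + 0.8 * (z_base - z0)
    aif_mask = (r_xy <= aif_r) & (zz >= zc_lo) & (zz <= zc_hi)
    aif_mask &= ~myo
    return labels, myo, aif_mask


def make_phantom(config: PhantomConfig) -> PhantomStudy:
    """Generate a seeded synthetic dynamic stress CTP study with ground truth."""
    rng = np.random.default_rng(config.seed)
    labels, myo, aif_mask = build_lv_geometry(config)
    nx, ny, nz = config.shape
    nt = config.n_frames

    t = np.arange(nt) * config.frame_interval_s
    if config.frame_jitter_sd_s > 0:
        t = t + rng.normal(0, config.frame_jitter_sd_s, size=nt)
        t = np.sort(t)
        t[0] = 0.0
    aif = make_aif_curve(config.aif, t)

    # --- ground-truth flow field -------------------------------------------
    territory = {terr: np.isin(labels, [s for s in range(1, 18)
                                        if territory_of(s) == terr])
                 for terr in TERRITORIES}
    base = np.zeros(config.shape)
    for terr in TERRITORIES:
        base[territory[terr]] = config.territory_mbf.get(terr, 160.0)

    phys = _fractal_field(
        rng, config.shape, config.spacing_mm,
        mean=1.0, rel_sd=config.phys_heterogeneity_sd,
        beta=config.phys_spectral_beta,
    )

    pattern = np.ones(config.shape)
    for terr in TERRITORIES:
        pat = config.territory_pattern.get(terr, "none")
        m = territory[terr]
        if pat == "obstructive":
            red = np.full(config.shape, config.obstructive_reduction)
            if config.transmural_gradient:
                # deeper reduction sub-endocardially: scale by wall depth
                depth = _transmural_depth(config, labels)
                red = red * (1.0 - 0.3 * (1.0 - depth))
            pattern[m] = red[m]
        elif pat == "microvascular":
            field_ = _correlated_lognormal(
                rng, config.shape, config.spacing_mm,
                mean=config.micro_mean_reduction,
                rel_sd=config.micro_heterogeneity_sd,
                corr_mm=config.micro_corr_mm,
            )
            pattern[m] = np.clip(field_[m], 0.05, 1.0)

    true_mbf = np.where(myo, base * phys * pattern, 0.0)

    # --- dynamic HU volume --------------------------------------------------
    slope = ENHANCEMENT_SLOPE_HU_PER_MG_ML[config.kv]
    increments = aif[:-1] * np.diff(t)
    cum = np.concatenate([[0.0], np.cumsum(increments)])  # mg s / mL
    if config.arrival_jitter_sd_s > 0:
        # voxelwise bolus arrival dispersion: evaluate the cumulative uptake on
        # a locally shifted time grid (temporal perfusion texture that scales
        # with flow; spatial-only denoising does not remove it)
        delay = rng.normal(0.0, config.arrival_jitter_sd_s, size=config.shape)
        shifted = t[None, None, None, :] - delay[..., None]
        conc_t = np.interp(shifted.ravel(), t, cum).reshape(shifted.shape)
        conc = (true_mbf[..., None] / 6000.0) * conc_t
    else:
        conc = (true_mbf[..., None] / 6000.0) * cum[None, None, None, :]

    baseline = np.where(myo, config.baseline_myo_hu, config.background_hu)
    vol = np.broadcast_to(baseline[..., None], (nx, ny, nz, nt)).copy()
    vol += slope * conc
    vol[aif_mask] = config.baseline_blood_hu + slope * aif
    if config.noise_sd_hu > 0:
        vol += rng.normal(0.0, config.noise_sd_hu, size=vol.shape)

    volume = DynamicVolume(
        data=vol, spacing_mm=config.spacing_mm, frame_times_s=t,
        unit=UNIT_HU, kv=config.kv,
    )

    # --- ground-truth tables -----------------------------------------------
    seg_mbf = {}
    for seg in range(1, 18):
        m = labels == seg
        seg_mbf[seg] = float(true_mbf[m].mean()) if m.any() else np.nan
    terr_class = {
        terr: config.territory_pattern.get(terr, "none") for terr in TERRITORIES
    }
    de_mask = None
    if config.de_segments:
        de_mask = np.isin(labels, list(config.de_segments))
    remote = float(np.nanmax(list(seg_mbf.values())))
    return PhantomStudy(
        volume=volume,
        labels=labels,
        myocardium_mask=myo,
        aif_mask=aif_mask,
        de_mask=de_mask,
        true_mbf_field=true_mbf,
        true_segment_mbf=seg_mbf,
        true_territory_class=terr_class,
        true_remote_flow=remote,
        config=config,
    )


def _transmural_depth(config: PhantomConfig, labels: np.ndarray) -> np.ndarray:
    """Normalized wall depth, 0 at endocardium to 1 at epicardium (approx)."""
    nx, ny, nz = config.shape
    dx, dy, dz = config.spacing_mm
    x = (np.arange(nx) - (nx - 1) / 2.0) * dx
    y = (np.arange(ny) - (ny - 1) / 2.0) * dy
    xx, yy = np.meshgrid(x, y, indexing="ij")
    extent = min(nx * dx, ny * dy)
    r_out = config.r_out_mm if config.r_out_mm is not None else 0.19 * extent
    wall = config.wall_mm if config.wall_mm is not None else 0.42 * r_out
    r_in = r_out - wall
    depth = (np.hypot(xx, yy) - r_in) / wall
    return np.clip(depth, 0.0, 1.0)[..., None] * np.ones((1, 1, nz))
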