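"""End-to-end single-study analysis and cohort evaluation.

A study (4D HU volume + AHA label map + arterial ROI, optionally a
delayed-enhancement mask) is processed in the fixed stage order

    denoise -> HU-to-concentration -> AIF extraction
            -> local FD mapping -> maximum-upslope MBF
            -> per-segment statistics -> exclusions -> classification

yielding per-segment, per-vessel and per-patient results.  A cohort of such
results is then evaluated against a reference standard (contingency tables,
ROC/AUC, paired tests), optionally stratified by remote flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import diagstats
from .aha import (TERRITORIES, apply_exclusions, new_segment_table,
                  segment_rois)
from .classify import (Cutoffs, aggregate_patient, aggregate_vessel,
                       classify_fd, classify_relmbf)
from .exceptions import InvalidInputError
from .fractal import fd_map, fill_outside_mask
from .perfusion import extract_aif, mbf_map, remote_and_relative, segment_mbf
from .preprocess import ConversionParams, DenoiseParams, denoise, hu_to_concentration
from .types import UNIT_CONC, DynamicVolume

__all__ = ["AnalysisParams", "CaseResult", "analyze_study", "evaluate_cohort"]


@dataclass
class AnalysisParams:
    """Tunable parameters of the analysis pipeline."""

    denoise: DenoiseParams = field(default_factory=DenoiseParams)
    conversion: ConversionParams = field(default_factory=ConversionParams)
    eps_max: int = 4
    kernel: int = 3
    neighborhood: str = "chebyshev"
    intensity_gain: float = 80.0        # blanket units per (mg I/mL); calibrated
    fd_lag: int = 2                     # first-pass crop: frames up to AIF peak + lag
    fd_collapse: str = "peak_window"    # {"peak_window", "all"}
    margin_mm: float = 1.0              # ROI distance from endo/epi borders
    de_overlap_threshold: float = 0.25
    cutoffs: Cutoffs = field(default_factory=Cutoffs)
    smooth_window: int = 1              # upslope smoothing (1 = off)
    upslope_lag: int = 2
    skip_denoise: bool = False          # e.g. for noise-free volumes


@dataclass
class CaseResult:
    """Per-study analysis output."""

    segments: pd.DataFrame              # one row per AHA segment
    vessels: pd.DataFrame               # one row per territory
    patient_class_fd: str | None        # three-class call from FD
    patient_positive_relmbf: bool | None
    remote_flow: float
    remote_segment: int
    aif_curve: np.ndarray
    aif_peak: float
    aif_peak_index: int
    patient_excluded: bool
    fd_map_3d: np.ndarray | None = None
    mbf_map_3d: np.ndarray | None = None


def analyze_study(
    volume: DynamicVolume,
    labels: np.ndarray,
    myocardium_mask: np.ndarray,
    aif_mask: np.ndarray,
    de_mask: np.ndarray | None = None,
    params: AnalysisParams | None = None,
    keep_maps: bool = False,
) -> CaseResult:
    """Run the full single-study pipeline on a 4D HU volume."""
    params = params or AnalysisParams()
    if not isinstance(volume, DynamicVolume):
        raise InvalidInputError("analyze_study expects a DynamicVolume")
    t = volume.frame_times_s

    # 1) noise standardization
    if params.skip_denoise:
        vol = volume
    else:
        vol = denoise(volume, params.denoise, myocardium_mask=myocardium_mask)

    # 2) HU -> iodine concentration
    conversion = params.conversion
    if conversion.kv != volume.kv and conversion.slope is None:
        conversion = replace(conversion, kv=volume.kv)
    conc = vol if vol.unit == UNIT_CONC else hu_to_concentration(vol, conversion)

    # 3) arterial input function (ROI eroded away from the blood-pool border:
    # the spatial filters mix boundary voxels with surrounding tissue, which
    # would depress the AIF peak and inflate every MBF estimate)
    from .aha import erode_margin

    aif_roi = erode_margin(aif_mask, volume.spacing_mm, params.margin_mm)
    if not aif_roi.any():
        aif_roi = aif_mask
    aif = extract_aif(conc, aif_roi)
    peak_idx = int(np.argmax(aif))
    peak = float(aif[peak_idx])

    # 4) local fractal dimension on the first-pass window, myocardium-filled
    crop_end = min(peak_idx + params.fd_lag + 1, conc.n_frames)
    filled = fill_outside_mask(conc.data[..., :crop_end], myocardium_mask)
    fdm = fd_map(
        filled,
        eps_max=params.eps_max,
        kernel=params.kernel,
        neighborhood=params.neighborhood,
        intensity_gain=params.intensity_gain,
    )
    if params.fd_collapse == "peak_window":
        fd3 = fdm.fd[..., peak_idx:crop_end].mean(axis=-1)
    elif params.fd_collapse == "all":
        fd3 = fdm.fd.mean(axis=-1)
    else:
        raise InvalidInputError(f"unknown fd_collapse {params.fd_collapse!r}")

    # 5) per-segment ROIs and statistics
    rois = segment_rois(labels, volume.spacing_mm, params.margin_mm,
                        myocardium_mask)
    table = new_segment_table(labels, rois)
    table = apply_exclusions(table, labels, de_mask,
                             params.de_overlap_threshold)
    seg_mbf = segment_mbf(conc, rois, aif, t,
                          smooth_window=params.smooth_window,
                          lag=params.upslope_lag)
    table["mean_mbf"] = table["segment"].map(seg_mbf)
    table["mean_fd"] = [
        float(fd3[rois[s]].mean()) if rois[s].any() else np.nan
        for s in table["segment"]
    ]

    patient_excluded = bool(table.attrs.get("patient_excluded", False))
    if patient_excluded:
        return CaseResult(
            segments=table, vessels=_empty_vessels(), patient_class_fd=None,
            patient_positive_relmbf=None, remote_flow=np.nan, remote_segment=-1,
            aif_curve=aif, aif_peak=peak, aif_peak_index=peak_idx,
            patient_excluded=True,
        )

    # 6) remote flow and relative MBF (excluded segments ineligible as remote)
    included = dict(zip(table["segment"], table["included"]))
    remote, remote_seg, relative = remote_and_relative(seg_mbf, included)
    table["relative_mbf"] = table["segment"].map(relative)

    # 7) segment / vessel / patient classification
    table["class_fd"] = [
        classify_fd(fd, params.cutoffs) if inc and np.isfinite(fd) else None
        for fd, inc in zip(table["mean_fd"], table["included"])
    ]
    vessels = _vessel_table(table, params.cutoffs)
    included_vessels = vessels.loc[~vessels["excluded"]]
    patient_class = aggregate_patient(included_vessels["class_fd"])
    patient_pos = bool(included_vessels["positive_relmbf"].any())

    return CaseResult(
        segments=table,
        vessels=vessels,
        patient_class_fd=patient_class,
        patient_positive_relmbf=patient_pos,
        remote_flow=remote,
        remote_segment=remote_seg,
        aif_curve=aif,
        aif_peak=peak,
        aif_peak_index=peak_idx,
        patient_excluded=False,
        fd_map_3d=fd3 if keep_maps else None,
        mbf_map_3d=(
            mbf_map(conc, aif, t, mask=myocardium_mask,
                    smooth_window=params.smooth_window, lag=params.upslope_lag)
            if keep_maps else None
        ),
    )


def _empty_vessels() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["territory", "class_fd", "score_fd", "score_relmbf",
                 "positive_relmbf", "excluded"]
    )


def _vessel_table(segments: pd.DataFrame, cutoffs: Cutoffs) -> pd.DataFrame:
    rows = []
    for terr in TERRITORIES:
        segs = segments[segments["territory"] == terr]
        inc = segs[segs["included"]]
        if inc.empty:
            rows.append({"territory": terr, "class_fd": None, "score_fd": np.nan,
                         "score_relmbf": np.nan, "positive_relmbf": None,
                         "excluded": True})
            continue
        vessel_class, score_fd = aggregate_vessel(
            inc["class_fd"].tolist(), inc["mean_fd"].tolist()
        )
        score_rel = float(np.nanmin(inc["relative_mbf"]))
        rows.append({
            "territory": terr,
            "class_fd": vessel_class,
            "score_fd": score_fd,
            "score_relmbf": score_rel,
            "positive_relmbf": classify_relmbf(score_rel, cutoffs) == "positive",
            "excluded": False,
        })
    return pd.DataFrame(rows)


def evaluate_cohort(
    vessel_scores_fd,
    vessel_scores_rel,
    vessel_truth,
    patient_pred_fd=None,
    patient_pred_rel=None,
    patient_truth=None,
    remote_flows=None,
    stratify_boundaries=None,
) -> dict:
    """Cohort diagnostic-accuracy report for obstructive-CAD detection.

    Vessel-level: AUCs (low score = disease) for the FD and relative-MBF
    scores with a paired DeLong comparison.  Patient-level (optional): 2x2
    contingency metrics and McNemar tests of paired sensitivity/specificity.
    With ``remote_flows`` given, patient-level results are additionally
    stratified into low/intermediate/high remote-flow groups.
    """
    truth = np.asarray(vessel_truth, dtype=bool)
    report = {
        "vessel": {
            "auc_fd": diagstats.roc_auc(vessel_scores_fd, truth),
            "auc_relmbf": diagstats.roc_auc(vessel_scores_rel, truth),
            "delong": diagstats.delong_test(
                vessel_scores_fd, vessel_scores_rel, truth
            ),
            "youden_fd": diagstats.youden_cutoff(vessel_scores_fd, truth),
            "youden_relmbf": diagstats.youden_cutoff(vessel_scores_rel, truth),
        }
    }
    if patient_truth is not None:
        pt = np.asarray(patient_truth, dtype=bool)
        pfd = np.asarray(patient_pred_fd, dtype=bool)
        prel = np.asarray(patient_pred_rel, dtype=bool)
        tab_fd = diagstats.ContingencyTable.from_labels(pfd, pt)
        tab_rel = diagstats.ContingencyTable.from_labels(prel, pt)
        # discordant pairs among diseased (sensitivity) / healthy (specificity)
        b_sens = int((pfd & ~prel & pt).sum())
        c_sens = int((~pfd & prel & pt).sum())
        b_spec = int((~pfd & prel & ~pt).sum())
        c_spec = int((pfd & ~prel & ~pt).sum())
        report["patient"] = {
            "fd": diagstats.sens_spec(tab_fd),
            "relmbf": diagstats.sens_spec(tab_rel),
            "mcnemar_sensitivity": diagstats.mcnemar_test(b_sens, c_sens),
            "mcnemar_specificity": diagstats.mcnemar_test(b_spec, c_spec),
        }
        if remote_flows is not None:
            groups = diagstats.tertile_stratify(
                remote_flows, boundaries=stratify_boundaries
            )
            strata = {}
            assign = np.array(groups.assignments)
            for g in ("low", "intermediate", "high"):
                sel = assign == g
                if sel.sum() == 0:
                    continue
                strata[g] = {
                    "fd": diagstats.sens_spec(
                        diagstats.ContingencyTable.from_labels(
                            pfd[sel], pt[sel], stratum=g
                        )
                    ),
                    "relmbf": diagstats.sens_spec(
                        diagstats.ContingencyTable.from_labels(
                            prel[sel], pt[sel], stratum=g
                        )
                    ),
                    "n": int(sel.sum()),
                }
            report["patient"]["by_remote_flow"] = strata
            report["patient"]["stratification"] = {
                "boundaries": groups.boundaries,
                "source": groups.source,
            }
    return report
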