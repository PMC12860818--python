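"""AHA 17-segment ROI machinery.

Left-ventricular myocardium is reported on the standardized 17-segment model
of the American Heart Association: six basal (1-6), six mid-cavity (7-12),
four apical (13-16) segments plus the apex cap (17).  Segments map onto the
three coronary territories (LAD, RCA, LCX) by the conventional assignment.
ROIs keep a safety margin from the endocardial and epicardial borders to
avoid partial-volume contamination, and segments overlapping a
delayed-enhancement (infarct/fibrosis) mask are excluded from analysis.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import ndimage

from .exceptions import InvalidInputError

__all__ = [
    "DEFAULT_TERRITORY_MAP",
    "TERRITORIES",
    "territory_of",
    "segments_of_territory",
    "erode_margin",
    "segment_rois",
    "new_segment_table",
    "apply_exclusions",
]

TERRITORIES = ("LAD", "RCA", "LCX")

#: Conventional AHA segment -> coronary territory assignment.
DEFAULT_TERRITORY_MAP = {
    1: "LAD", 2: "LAD", 7: "LAD", 8: "LAD", 13: "LAD", 14: "LAD", 17: "LAD",
    3: "RCA", 4: "RCA", 9: "RCA", 10: "RCA", 15: "RCA",
    5: "LCX", 6: "LCX", 11: "LCX", 12: "LCX", 16: "LCX",
}


def territory_of(segment_id: int, territory_map: dict | None = None) -> str:
    """Coronary territory (LAD/RCA/LCX) of an AHA segment."""
    tmap = DEFAULT_TERRITORY_MAP if territory_map is None else territory_map
    if segment_id not in range(1, 18):
        raise InvalidInputError(f"AHA segment id must be in 1..17, got {segment_id}")
    territory = tmap[segment_id]
    if territory not in TERRITORIES:
        raise InvalidInputError(f"unknown territory {territory!r}")
    return territory


def segments_of_territory(territory: str, territory_map: dict | None = None) -> list:
    tmap = DEFAULT_TERRITORY_MAP if territory_map is None else territory_map
    if territory not in TERRITORIES:
        raise InvalidInputError(f"territory must be one of {TERRITORIES}")
    return sorted(s for s, t in tmap.items() if t == territory)


def erode_margin(
    segment_mask: np.ndarray,
    spacing_mm: tuple,
    margin_mm: float = 1.0,
    border_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Shrink an ROI away from tissue borders by ``margin_mm``.

    Erodes by ceil(margin / spacing) voxels along each axis (anisotropic box
    structuring element).  When ``border_mask`` is given (typically the whole
    myocardium), the erosion is computed on that mask and intersected with the
    segment, so only endo-/epicardial borders are retreated from, not the
    borders between adjacent segments.  An empty result is returned as-is; the
    caller flags the segment as excluded.
    """
    if margin_mm < 0:
        raise InvalidInputError("margin_mm must be >= 0")
    segment_mask = np.asarray(segment_mask, dtype=bool)
    if margin_mm == 0:
        return segment_mask.copy()
    radii = [math.ceil(margin_mm / s) for s in spacing_mm]
    structure = np.ones([2 * r + 1 for r in radii], dtype=bool)
    base = segment_mask if border_mask is None else np.asarray(border_mask, bool)
    eroded = ndimage.binary_erosion(base, structure=structure)
    return segment_mask & eroded


def segment_rois(
    labels: np.ndarray,
    spacing_mm: tuple,
    margin_mm: float = 1.0,
    myocardium_mask: np.ndarray | None = None,
) -> dict:
    """Per-segment ROI masks after the border-margin erosion.

    ROIs are pairwise disjoint and nested in their parent segments.
    """
    labels = np.asarray(labels)
    if myocardium_mask is None:
        myocardium_mask = labels > 0
    rois = {}
    for seg in range(1, 18):
        mask = labels == seg
        rois[seg] = erode_margin(
            mask, spacing_mm, margin_mm, border_mask=myocardium_mask
        )
    return rois


def new_segment_table(
    labels: np.ndarray,
    rois: dict,
    territory_map: dict | None = None,
) -> pd.DataFrame:
    """Fresh per-segment bookkeeping table (one row per AHA segment 1..17)."""
    rows = []
    for seg in range(1, 18):
        n_seg = int((labels == seg).sum())
        n_roi = int(rois[seg].sum()) if seg in rois else 0
        empty = n_roi == 0
        rows.append(
            {
                "segment": seg,
                "territory": territory_of(seg, territory_map),
                "n_voxels": n_seg,
                "n_roi_voxels": n_roi,
                "included": not empty,
                "exclusion_reason": "empty-after-erosion" if empty else "none",
                "mean_fd": np.nan,
                "mean_mbf": np.nan,
                "relative_mbf": np.nan,
            }
        )
    return pd.DataFrame(rows)


def apply_exclusions(
    table: pd.DataFrame,
    labels: np.ndarray,
    delayed_enhancement_mask: np.ndarray | None,
    overlap_threshold: float = 0.25,
) -> pd.DataFrame:
    """Exclude segments with delayed enhancement; cascade to vessels/patient.

    A segment is excluded when the delayed-enhancement mask covers at least
    ``overlap_threshold`` of its voxels.  A vessel (territory) is excluded when
    all its segments are excluded; the patient when all vessels are excluded.
    Returns a copy of the table with updated flags plus ``vessel_excluded``
    and ``patient_excluded`` columns/attribute.
    """
    table = table.copy()
    if delayed_enhancement_mask is not None:
        de = np.asarray(delayed_enhancement_mask, dtype=bool)
        if de.shape != np.asarray(labels).shape:
            raise InvalidInputError(
                "delayed-enhancement mask shape does not match the label map"
            )
        for i, row in table.iterrows():
            seg_mask = labels == row["segment"]
            n = seg_mask.sum()
            if n == 0:
                continue
            overlap = (seg_mask & de).sum() / n
            if overlap >= overlap_threshold:
                table.loc[i, "included"] = False
                table.loc[i, "exclusion_reason"] = "delayed-enhancement"
    vessel_excluded = {
        terr: bool(~grp["included"].any())
        for terr, grp in table.groupby("territory")
    }
    table["vessel_excluded"] = table["territory"].map(vessel_excluded)
    table.attrs["vessel_excluded"] = vessel_excluded
    table.attrs["patient_excluded"] = all(vessel_excluded.values())
    return table
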