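"""Three-class ischemia calls from fractal dimension and relative MBF.

Fractal dimension classifies each segment into obstructive CAD (FD <= 4.31),
microvascular ischemia (4.31 < FD <= 4.41) or normal perfusion (FD > 4.41);
the cutoffs were derived and externally validated upstream of this package and
are configurable.  Relative MBF supports only a binary call (positive for
obstructive CAD at <= 0.674) because a scalar flow deficit cannot separate the
two ischemia entities.  Segment calls aggregate to vessels (most severe
segment) and to the patient (most severe vessel).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from .exceptions import InvalidInputError

__all__ = [
    "Cutoffs",
    "CLASS_NORMAL",
    "CLASS_MICRO",
    "CLASS_OBSTRUCTIVE",
    "SEVERITY",
    "classify_fd",
    "classify_relmbf",
    "aggregate_vessel",
    "aggregate_patient",
    "FDThresholdClassifier",
]

CLASS_NORMAL = "normal"
CLASS_MICRO = "microvascular"
CLASS_OBSTRUCTIVE = "obstructive"

#: severity order for aggregation (higher = worse)
SEVERITY = {CLASS_NORMAL: 0, CLASS_MICRO: 1, CLASS_OBSTRUCTIVE: 2}


@dataclass
class Cutoffs:
    """Decision thresholds (all inclusive on the diseased side)."""

    fd_obstructive: float = 4.31
    fd_microvascular: float = 4.41
    relmbf_positive: float = 0.674

    def __post_init__(self):
        if not self.fd_obstructive < self.fd_microvascular:
            raise InvalidInputError("fd_obstructive must be < fd_microvascular")
        if not 0 < self.relmbf_positive < 1:
            raise InvalidInputError("relmbf_positive must be in (0, 1)")


def classify_fd(fd: float, cutoffs: Cutoffs | None = None) -> str:
    """FD <= 4.31 -> obstructive; 4.31 < FD <= 4.41 -> microvascular; else normal."""
    cutoffs = cutoffs or Cutoffs()
    if not np.isfinite(fd):
        raise InvalidInputError(f"FD must be finite, got {fd}")
    if fd <= cutoffs.fd_obstructive:
        return CLASS_OBSTRUCTIVE
    if fd <= cutoffs.fd_microvascular:
        return CLASS_MICRO
    return CLASS_NORMAL


def classify_relmbf(relative_mbf: float, cutoffs: Cutoffs | None = None) -> str:
    """Binary call for obstructive CAD: 'positive' iff relative MBF <= cutoff."""
    cutoffs = cutoffs or Cutoffs()
    if not (np.isfinite(relative_mbf) and 0 < relative_mbf <= 1):
        raise InvalidInputError(
            f"relative MBF must lie in (0, 1], got {relative_mbf}"
        )
    return "positive" if relative_mbf <= cutoffs.relmbf_positive else "negative"


def aggregate_vessel(segment_classes, segment_scores=None):
    """Vessel class = most severe included segment class.

    ``segment_scores`` (e.g. segment FD or relative MBF) reduce to the vessel
    ROC score by the minimum (worst) segment statistic.  Returns
    ``(vessel_class, vessel_score)``; score is None when no scores are given.
    Raises when no segment is included (excluded vessel).
    """
    classes = [c for c in segment_classes if c is not None]
    if not classes:
        raise InvalidInputError("no included segments in territory")
    for c in classes:
        if c not in SEVERITY:
            raise InvalidInputError(f"unknown segment class {c!r}")
    vessel_class = max(classes, key=lambda c: SEVERITY[c])
    score = None
    if segment_scores is not None:
        finite = [s for s in segment_scores if s is not None and np.isfinite(s)]
        if finite:
            score = float(min(finite))
    return vessel_class, score


def aggregate_patient(vessel_classes, binary: bool = False) -> str:
    """Patient class from vessel classes, precedence obstructive > micro > normal.

    With ``binary=True`` (the relative-MBF convention, which cannot separate
    the two ischemia entities) any non-normal vessel makes the patient
    'obstructive'.
    """
    classes = [c for c in vessel_classes if c is not None]
    if not classes:
        raise InvalidInputError("no included vessels")
    worst = max(classes, key=lambda c: SEVERITY[c])
    if binary and SEVERITY[worst] > 0:
        return CLASS_OBSTRUCTIVE
    return worst


class FDThresholdClassifier(BaseEstimator, ClassifierMixin):
    """Threshold classifier on segment-mean fractal dimension.

    A fixed-rule classifier exposing the sklearn API: ``fit`` only validates
    and records the class labels; ``predict`` maps FD values to
    {normal, microvascular, obstructive}.

    Parameters
    ----------
    fd_obstructive, fd_microvascular : float
        Upper FD bounds (inclusive) of the obstructive and microvascular
        classes.
    """

    def __init__(self, fd_obstructive=4.31, fd_microvascular=4.41):
        self.fd_obstructive = fd_obstructive
        self.fd_microvascular = fd_microvascular

    def fit(self, X=None, y=None):
        self.cutoffs_ = Cutoffs(
            fd_obstructive=self.fd_obstructive,
            fd_microvascular=self.fd_microvascular,
        )
        self.classes_ = np.array([CLASS_MICRO, CLASS_NORMAL, CLASS_OBSTRUCTIVE])
        return self

    def predict(self, X):
        if not hasattr(self, "cutoffs_"):
            self.fit()
        X = np.asarray(X, dtype=np.float64).ravel()
        return np.array([classify_fd(v, self.cutoffs_) for v in X])
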