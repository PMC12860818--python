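"""Diagnostic-accuracy statistics.

Contingency metrics with exact (Clopper-Pearson) confidence intervals, ROC/AUC
with DeLong variance and the paired DeLong test, McNemar's chi-square test for
paired sensitivities/specificities, the Youden-index cutoff, Cohen's kappa for
inter-reader agreement, and remote-flow tertile stratification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.inter_rater import cohens_kappa as _sm_cohens_kappa
from statsmodels.stats.proportion import proportion_confint

from .exceptions import DegenerateInputError, InvalidInputError

__all__ = [
    "ContingencyTable",
    "StratifiedGroups",
    "round_half_away",
    "sens_spec",
    "roc_auc",
    "delong_test",
    "mcnemar_test",
    "youden_cutoff",
    "cohen_kappa",
    "tertile_stratify",
    "PAPER_REMOTE_FLOW_BOUNDARIES",
]

#: Remote-flow group boundaries (mL/100mL/min): low <= 135, high >= 172.
PAPER_REMOTE_FLOW_BOUNDARIES = (135.0, 172.0)


@dataclass
class ContingencyTable:
    """2x2 diagnostic contingency counts."""

    tp: int
    fp: int
    fn: int
    tn: int
    level: str = "patient"          # {"patient", "vessel"}
    stratum: str = "all"            # {"all", "high", "intermediate", "low"}

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InvalidInputError("contingency counts must be >= 0")

    @classmethod
    def from_labels(cls, predicted, truth, **kw) -> "ContingencyTable":
        predicted = np.asarray(predicted, dtype=bool)
        truth = np.asarray(truth, dtype=bool)
        if predicted.shape != truth.shape:
            raise InvalidInputError("predicted and truth must be paired")
        return cls(
            tp=int((predicted & truth).sum()),
            fp=int((predicted & ~truth).sum()),
            fn=int((~predicted & truth).sum()),
            tn=int((~predicted & ~truth).sum()),
            **kw,
        )

    def __add__(self, other: "ContingencyTable") -> "ContingencyTable":
        return ContingencyTable(
            tp=self.tp + other.tp, fp=self.fp + other.fp,
            fn=self.fn + other.fn, tn=self.tn + other.tn,
            level=self.level, stratum="all",
        )


def round_half_away(x: float) -> int:
    """Round to integer, halves away from zero (the convention of report tables)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _proportion_block(k: int, n: int) -> dict:
    if n == 0:
        return {"defined": False, "pct": None, "ci_pct": None, "fraction": (k, n)}
    lo, hi = proportion_confint(k, n, alpha=0.05, method="beta")
    return {
        "defined": True,
        "pct": round_half_away(100.0 * k / n),
        "value": k / n,
        "ci_pct": (round_half_away(100.0 * lo), round_half_away(100.0 * hi)),
        "ci": (float(lo), float(hi)),
        "fraction": (k, n),
    }


def sens_spec(table: ContingencyTable) -> dict:
    """Sensitivity and specificity (percent, Clopper-Pearson exact 95% CIs).

    Percentages are rounded half-away-from-zero to integers for reporting.
    Zero denominators yield an undefined-flagged metric, not an error.
    """
    return {
        "sensitivity": _proportion_block(table.tp, table.tp + table.fn),
        "specificity": _proportion_block(table.tn, table.tn + table.fp),
        "level": table.level,
        "stratum": table.stratum,
    }


# --- DeLong machinery -------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _delong_components(scores: np.ndarray, truth: np.ndarray):
    """AUC and the DeLong structural components V10 (diseased), V01 (healthy)."""
    pos = scores[truth]
    neg = scores[~truth]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise InvalidInputError("both classes must be present")
    tz = _midrank(np.concatenate([pos, neg]))
    tx = _midrank(pos)
    ty = _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (tz[:m] - tx) / n                  # one per diseased case
    v01 = 1.0 - (tz[m:] - ty) / m            # one per healthy case
    return float(auc), v10, v01


def _orient(scores, truth, low_scores_positive):
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape:
        raise InvalidInputError("scores and truth must be paired")
    return (-scores if low_scores_positive else scores), truth


def roc_auc(scores, truth, low_scores_positive: bool = True) -> dict:
    """AUC (Mann-Whitney estimator) with a 95% DeLong confidence interval.

    ``low_scores_positive`` declares that low scores indicate disease (true
    for both FD and relative MBF).
    """
    s, truth = _orient(scores, truth, low_scores_positive)
    auc, v10, v01 = _delong_components(s, truth)
    m, n = v10.size, v01.size
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + (
        np.var(v01, ddof=1) / n if n > 1 else 0.0
    )
    half = 1.959963984540054 * math.sqrt(max(var, 0.0))
    return {
        "auc": auc,
        "ci": (max(auc - half, 0.0), min(auc + half, 1.0)),
        "variance": var,
        "n_diseased": m,
        "n_healthy": n,
    }


def delong_test(scores_a, scores_b, truth, low_scores_positive: bool = True) -> dict:
    """Two-sided paired DeLong test comparing two AUCs on the same cases."""
    a, t1 = _orient(scores_a, truth, low_scores_positive)
    b, t2 = _orient(scores_b, truth, low_scores_positive)
    if a.shape != b.shape:
        raise InvalidInputError("paired score vectors must have equal length")
    auc_a, v10a, v01a = _delong_components(a, t1)
    auc_b, v10b, v01b = _delong_components(b, t2)
    m, n = v10a.size, v01a.size
    var = 0.0
    if m > 1:
        var += np.var(v10a - v10b, ddof=1) / m
    if n > 1:
        var += np.var(v01a - v01b, ddof=1) / n
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0 if diff == 0 else math.inf * math.copysign(1, diff)
    else:
        z = diff / math.sqrt(var)
    p = 1.0 if var <= 0 and diff == 0 else 2.0 * stats.norm.sf(abs(z))
    return {"auc_a": auc_a, "auc_b": auc_b, "z": z, "p": float(p)}


def mcnemar_test(b: int, c: int, continuity_correction: bool = False) -> dict:
    """McNemar's chi-square test from the discordant-pair counts b and c.

    chi2 = (|b - c| [- 1])^2 / (b + c), 1 df, two-sided.  b + c = 0 is a
    degenerate (flagged) case with p = 1.
    """
    if b < 0 or c < 0:
        raise InvalidInputError("discordant counts must be >= 0")
    if b + c == 0:
        return {"chi2": 0.0, "p": 1.0, "degenerate": True}
    d = abs(b - c) - (1.0 if continuity_correction else 0.0)
    chi2 = max(d, 0.0) ** 2 / (b + c)
    return {"chi2": chi2, "p": float(stats.chi2.sf(chi2, df=1)), "degenerate": False}


def youden_cutoff(scores, truth, low_scores_positive: bool = True) -> dict:
    """Cutoff maximizing the Youden index J = sensitivity + specificity - 1.

    Uses the '<= cutoff is positive' rule over the observed score values (with
    ``low_scores_positive=False`` the rule is '>= cutoff').  Ties in J break
    toward the cutoff with higher specificity.
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape:
        raise InvalidInputError("scores and truth must be paired")
    if truth.all() or not truth.any():
        raise InvalidInputError("both classes must be present")
    best = None
    for thr in np.unique(scores):
        pos = scores <= thr if low_scores_positive else scores >= thr
        sens = (pos & truth).sum() / truth.sum()
        spec = (~pos & ~truth).sum() / (~truth).sum()
        j = sens + spec - 1.0
        key = (j, spec)
        if best is None or key > best[0]:
            best = (key, float(thr), float(sens), float(spec))
    (j, _), cutoff, sens, spec = best
    return {"cutoff": cutoff, "J": j, "sensitivity": sens, "specificity": spec}


def cohen_kappa(ratings_a, ratings_b) -> dict:
    """Cohen's kappa with an asymptotic 95% confidence interval."""
    a = pd.Series(ratings_a)
    b = pd.Series(ratings_b)
    if len(a) != len(b):
        raise InvalidInputError("ratings must be paired")
    cats = sorted(set(a) | set(b))
    table = pd.crosstab(
        pd.Categorical(a, categories=cats), pd.Categorical(b, categories=cats),
        dropna=False,
    ).to_numpy()
    n = table.sum()
    pe = float((table.sum(0) / n) @ (table.sum(1) / n))
    if pe >= 1.0:
        raise DegenerateInputError("chance agreement is 1; kappa undefined")
    res = _sm_cohens_kappa(table, return_results=True)
    return {
        "kappa": float(res.kappa),
        "ci": (float(res.kappa_low), float(res.kappa_upp)),
        "se": float(np.sqrt(res.var_kappa)),
    }


@dataclass
class StratifiedGroups:
    """Remote-flow stratification of patients into low/intermediate/high."""

    boundaries: tuple                      # (b1, b2)
    assignments: list = field(default_factory=list)
    source: str = "tertiles"               # {"tertiles", "explicit"}
    degenerate: bool = False

    def counts(self) -> dict:
        return {g: self.assignments.count(g) for g in ("low", "intermediate", "high")}


def tertile_stratify(remote_flows, boundaries: tuple | None = None) -> StratifiedGroups:
    """Split patients into low/intermediate/high remote-flow groups.

    Without explicit ``boundaries`` the sample tertiles are used and ties go
    to the lower group (low <= q1/3 < intermediate <= q2/3 < high).  With
    explicit boundaries (b1, b2) — e.g. the published preset
    :data:`PAPER_REMOTE_FLOW_BOUNDARIES` — the rule is low <= b1,
    high >= b2, intermediate in between.
    """
    flows = np.asarray(remote_flows, dtype=np.float64)
    if flows.size < 3 and boundaries is None:
        raise InvalidInputError("need at least 3 patients for tertiles")
    degenerate = bool(np.all(flows == flows[0])) if flows.size else True
    if boundaries is None:
        b1, b2 = np.quantile(flows, [1 / 3, 2 / 3])
        assign = [
            "low" if f <= b1 else ("intermediate" if f <= b2 else "high")
            for f in flows
        ]
        source = "tertiles"
    else:
        b1, b2 = boundaries
        if not b1 < b2:
            raise InvalidInputError("boundaries must satisfy b1 < b2")
        assign = [
            "low" if f <= b1 else ("high" if f >= b2 else "intermediate")
            for f in flows
        ]
        source = "explicit"
    return StratifiedGroups(
        boundaries=(float(b1), float(b2)),
        assignments=assign,
        source=source,
        degenerate=degenerate,
    )
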