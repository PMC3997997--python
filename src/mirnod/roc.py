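"""Per-miRNA ROC curves and AUC for case/control discrimination.

AUC is computed by the Mann–Whitney identity — the probability that a random
case sample scores above a random control sample, with tied pairs credited
1/2 — via the rank formula, and the full curve is traced over every score
threshold. Because a biomarker can be down-regulated, each miRNA is oriented
by the sign of its fold change before scoring: down-regulated miRNAs have
their intensities negated (recorded as ``orientation="flipped"``) so the AUC
always reads as discriminatory accuracy.

Confidence intervals use the classical Hanley–McNeil standard error by
default; DeLong's covariance-based variance is available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ROCResult",
    "compute_auc",
    "auc_confidence_interval",
    "summarize_auc_table",
    "AUCSummary",
]

AS_IS = "as_is"
FLIPPED = "flipped"


@dataclass
class ROCResult:
    mirna_id: str
    auc: float
    curve_points: list[tuple[float, float]]   # (fpr, tpr), (0,0) → (1,1)
    orientation: str
    n_case: int
    n_control: int
    ci_low: float = float("nan")
    ci_high: float = float("nan")


@dataclass
class AUCSummary:
    auc_min: float
    auc_max: float
    n_at_or_above: int
    threshold: float


def _case_mask(labels: Sequence[str]) -> np.ndarray:
    lab = np.asarray(labels)
    mask = lab == "case"
    if mask.all() or (~mask).all():
        raise ValueError("both classes (case and control) must be present")
    return mask


def compute_auc(
    scores: Sequence[float],
    labels: Sequence[str],
    direction: int = 1,
    mirna_id: str = "",
) -> ROCResult:
    """ROC curve and Mann–Whitney AUC of per-sample scores.

    ``labels`` holds "case"/"control" per sample. ``direction=-1`` negates
    the scores first (down-regulated marker) and records the flip.
    """
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    mask = _case_mask(labels)
    oriented = direction * s
    n1 = int(mask.sum())
    n0 = int((~mask).sum())
    ranks = stats.rankdata(oriented)
    auc = (float(ranks[mask].sum()) - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    fpr, tpr, _ = _sk_roc_curve(mask.astype(int), oriented, drop_intermediate=False)
    return ROCResult(
        mirna_id=mirna_id,
        auc=float(auc),
        curve_points=list(zip(fpr.tolist(), tpr.tolist())),
        orientation=FLIPPED if direction == -1 else AS_IS,
        n_case=n1,
        n_control=n0,
    )


def auc_confidence_interval(
    roc: "ROCResult | float",
    n_case: int | None = None,
    n_control: int | None = None,
    level: float = 0.95,
    method: str = "hanley",
    scores: Sequence[float] | None = None,
    labels: Sequence[str] | None = None,
) -> tuple[float, float]:
    """Confidence interval for an AUC, truncated to [0, 1].

    ``method="hanley"`` uses the Hanley–McNeil standard error
    SE² = [A(1−A) + (n₁−1)(Q₁−A²) + (n₂−1)(Q₂−A²)] / (n₁ n₂) with
    Q₁ = A/(2−A), Q₂ = 2A²/(1+A). ``method="delong"`` needs the raw
    ``scores`` and ``labels`` and uses the placement-value variance.
    """
    if not (0.0 < level < 1.0):
        raise ValueError("level must be in (0, 1)")
    if isinstance(roc, ROCResult):
        auc, n1, n2 = roc.auc, roc.n_case, roc.n_control
    else:
        auc = float(roc)
        if n_case is None or n_control is None:
            raise ValueError("n_case and n_control required with a bare AUC")
        n1, n2 = n_case, n_control
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    z = stats.norm.ppf(0.5 + level / 2.0)
    if method == "hanley":
        q1 = auc / (2.0 - auc)
        q2 = 2.0 * auc * auc / (1.0 + auc)
        se2 = (
            auc * (1.0 - auc)
            + (n1 - 1) * (q1 - auc * auc)
            + (n2 - 1) * (q2 - auc * auc)
        ) / (n1 * n2)
        se = math.sqrt(max(se2, 0.0))
    elif method == "delong":
        if scores is None or labels is None:
            raise ValueError("delong CI requires scores and labels")
        se = math.sqrt(_delong_variance(np.asarray(scores, float), _case_mask(labels)))
    else:
        raise ValueError(f"unknown CI method {method!r}")
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return lo, hi


def _delong_variance(scores: np.ndarray, case_mask: np.ndarray) -> float:
    cases = scores[case_mask]
    controls = scores[~case_mask]
    n1, n2 = cases.size, controls.size
    # placement values: per-case fraction of controls beaten (ties 1/2), and vice versa
    v10 = np.array(
        [((c > controls).sum() + 0.5 * (c == controls).sum()) / n2 for c in cases]
    )
    v01 = np.array(
        [((cases > c).sum() + 0.5 * (cases == c).sum()) / n1 for c in controls]
    )
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    return float(v10.var(ddof=1) / n1 + v01.var(ddof=1) / n2)


def summarize_auc_table(
    rocs: "Sequence[ROCResult | float]", threshold: float = 0.90
) -> AUCSummary:
    """Min, max and the count of AUCs at or above ``threshold``."""
    if len(rocs) == 0:
        raise ValueError("empty AUC list")
    aucs = [r.auc if isinstance(r, ROCResult) else float(r) for r in rocs]
    return AUCSummary(
        auc_min=min(aucs),
        auc_max=max(aucs),
        n_at_or_above=sum(1 for a in aucs if a >= threshold),
        threshold=threshold,
    )


def trapezoid_area(curve_points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under an ROC curve's (fpr, tpr) points."""
    pts = np.asarray(curve_points, dtype=float)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))
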