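"""Case/control miRNA expression and differential-expression candidate selection.

The expression input is a normalized miRNA × sample intensity matrix (linear
scale, unitless) with a binary sample grouping (case vs control). Candidate
miRNAs are selected by a two-sided pooled-variance (classic Student) two-sample
t-test at a raw P threshold together with a group-mean fold-change filter.

Fold-change convention: for group means (c, k) with c = mean(case) and
k = mean(control), up-regulation is reported as c/k (≥1) and down-regulation
with the signed convention −(k/c), so a halving appears as −2 rather than 0.5.
The selection filter uses the magnitude, |FC| ≥ threshold. log2 fold change is
log2(c/k), flagged unavailable (NaN) when either mean is nonpositive.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "DEResult",
    "load_expression",
    "student_t",
    "fold_change",
    "select_candidates",
    "de_results_to_frame",
]

CASE = "case"
CONTROL = "control"


@dataclass
class ExpressionMatrix:
    """miRNA × sample matrix of normalized intensities with group labels."""

    values: pd.DataFrame            # rows: miRNA ids, columns: sample ids
    sample_labels: pd.Series        # sample id -> "case" | "control"

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate miRNA row ids: {dupes}")
        missing = [s for s in self.values.columns if s not in self.sample_labels.index]
        if missing:
            raise ValueError(f"samples without labels: {missing}")
        bad = sorted(set(self.sample_labels) - {CASE, CONTROL})
        if bad:
            raise ValueError(f"unknown group labels: {bad}")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    def group_columns(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_labels[s] == group]

    @property
    def case_values(self) -> pd.DataFrame:
        return self.values[self.group_columns(CASE)]

    @property
    def control_values(self) -> pd.DataFrame:
        return self.values[self.group_columns(CONTROL)]

    def write_tsv(self, expr_path: str | Path, labels_path: str | Path | None = None) -> None:
        self.values.to_csv(expr_path, sep="\t", index_label="mirna")
        if labels_path is not None:
            self.sample_labels.rename("group").to_csv(
                labels_path, sep="\t", index_label="sample"
            )


@dataclass
class DEResult:
    mirna_id: str
    t_stat: float
    p_value: float
    fc_linear: float
    fc_log2: float
    is_candidate: bool
    q_value: float = float("nan")


def load_expression(path: str | Path, label_map: Mapping[str, str]) -> ExpressionMatrix:
    """Load an expression TSV (header = sample ids, one row per miRNA).

    Every sample id must appear in ``label_map``. Rows containing any
    non-numeric cell are dropped with a warning naming the row ids; a
    duplicate miRNA row id is an error.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if not df.index.is_unique:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate miRNA row ids: {dupes}")
    unknown = [s for s in df.columns if s not in label_map]
    if unknown:
        raise ValueError(f"{path}: sample ids missing from label map: {unknown}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad_rows = numeric.index[numeric.isna().any(axis=1)].tolist()
    if bad_rows:
        warnings.warn(
            f"{path}: dropped {len(bad_rows)} rows with non-numeric cells: {bad_rows}",
            stacklevel=2,
        )
        numeric = numeric.drop(index=bad_rows)
    labels = pd.Series({s: label_map[s] for s in numeric.columns}, name="group")
    numeric.index.name = None
    return ExpressionMatrix(values=numeric.astype(float), sample_labels=labels)


def student_t(
    case_values: Sequence[float], control_values: Sequence[float]
) -> tuple[float, float]:
    """Two-sided pooled-variance two-sample t-test (textbook Student form).

    Degenerate inputs with zero pooled variance follow the documented
    convention: equal means → (t=0, p=1); unequal means → (t=±inf, p=0).
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 samples")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in input")
    n1, n2 = x.size, y.size
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    diff = x.mean() - y.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    t = diff / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(min(p, 1.0))


def fold_change(
    case_values: Sequence[float], control_values: Sequence[float]
) -> tuple[float, float]:
    """Signed linear fold change and log2 fold change of group means.

    Returns NaN for both when either group mean is nonpositive (the ratio is
    then undefined for intensity data).
    """
    c = float(np.mean(np.asarray(case_values, dtype=float)))
    k = float(np.mean(np.asarray(control_values, dtype=float)))
    if c <= 0 or k <= 0:
        return float("nan"), float("nan")
    ratio = c / k
    fc_log2 = math.log2(ratio)
    fc_linear = ratio if ratio >= 1.0 else -(k / c)
    return fc_linear, fc_log2


def _fc_magnitude(fc_linear: float) -> float:
    return abs(fc_linear) if math.isfinite(fc_linear) else float("nan")


def select_candidates(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    fc_threshold: float = 2.0,
    bh: bool = False,
    test_scale: str = "log2",
) -> list[DEResult]:
    """Per-miRNA DE results with the conjunctive candidate rule.

    A miRNA is a candidate iff its (raw, or BH-adjusted when ``bh``) P value
    is below ``alpha`` AND its fold-change magnitude is at least
    ``fc_threshold``. The t-test runs on log2 intensities by default (the
    standard scale for microarray DE, where multiplicative noise becomes
    additive and near-Gaussian); ``test_scale="linear"`` tests the raw
    intensities, and matrices containing nonpositive values fall back to the
    linear scale with a warning. Fold change is always computed from the
    linear-scale group means. Rows with zero variance in both groups are
    reported (with the degenerate t conventions), never dropped.
    """
    if test_scale not in ("log2", "linear"):
        raise ValueError("test_scale must be 'log2' or 'linear'")
    case = matrix.case_values.to_numpy()
    control = matrix.control_values.to_numpy()
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    if test_scale == "log2" and (np.any(case <= 0) or np.any(control <= 0)):
        warnings.warn(
            "nonpositive intensities: t-test falls back to the linear scale",
            stacklevel=2,
        )
        test_scale = "linear"
    if test_scale == "log2":
        t_case, t_control = np.log2(case), np.log2(control)
    else:
        t_case, t_control = case, control
    results: list[DEResult] = []
    pvals = np.empty(len(matrix.values))
    rows: list[tuple[str, float, float, float, float]] = []
    for i, mid in enumerate(matrix.values.index):
        t, p = student_t(t_case[i], t_control[i])
        fc_lin, fc_l2 = fold_change(case[i], control[i])
        pvals[i] = p
        rows.append((mid, t, p, fc_lin, fc_l2))
    if bh:
        qvals = _benjamini_hochberg(pvals)
    else:
        qvals = np.full_like(pvals, np.nan)
    selection_p = qvals if bh else pvals
    for i, (mid, t, p, fc_lin, fc_l2) in enumerate(rows):
        mag = _fc_magnitude(fc_lin)
        is_cand = bool(selection_p[i] < alpha) and bool(mag >= fc_threshold)
        results.append(DEResult(mid, t, p, fc_lin, fc_l2, is_cand, float(qvals[i])))
    return results


def _benjamini_hochberg(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    n = pvals.size
    ranked = pvals[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def de_results_to_frame(results: Sequence[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mirna": [r.mirna_id for r in results],
            "t": [r.t_stat for r in results],
            "p": [r.p_value for r in results],
            "fc_linear": [r.fc_linear for r in results],
            "fc_log2": [r.fc_log2 for r in results],
            "q": [r.q_value for r in results],
            "candidate": [r.is_candidate for r in results],
        }
    )
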