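"""Expression filtering and differential-expression calls on an FPKM matrix.

The RNA-seq side of the study compares two conditions with three biological
replicates each (a 3 + 3 design per pairwise comparison), on FPKM-normalised
expression. Genes enter the comparison only if they are expressed above a
floor (FPKM >= 1 in at least 3 of the 6 samples) and reproducible across
replicates (coefficient of variation < 0.2 within each condition whose
replicate mean reaches the floor). Differential expression then requires at
least a twofold change together with a Benjamini–Hochberg adjusted p <= 0.05.

FPKM is a normalised abundance, not a count, so the test is a Welch t on
log2(FPKM + 1) — a pluggable default, since the upstream protocol names no
test. Fold changes use a pseudo-FPKM of 0.1 to keep ratios finite without
materially moving 2-fold calls at the FPKM >= 1 floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, DomainError

__all__ = ["ExpressionMatrix", "bh_adjust", "expression_filter", "differential_call"]

#: Expression floor (FPKM) and replicate-variability cap used by the filter.
FPKM_FLOOR = 1.0
CV_MAX = 0.2

#: Pseudo-FPKM added to group means before the fold-change ratio.
FOLD_EPSILON = 0.1


@dataclass
class ExpressionMatrix:
    """Gene-by-sample FPKM matrix with a 2-condition, 3-replicate design.

    ``fpkm``: DataFrame, rows = gene ids, columns = sample ids, values >= 0.
    ``conditions``: sample id -> condition label; exactly two conditions with
    three samples each.
    """

    fpkm: pd.DataFrame
    conditions: dict[str, str]

    def __post_init__(self) -> None:
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        missing = [s for s in self.fpkm.columns if s not in self.conditions]
        if missing:
            raise DesignError(f"samples without a condition label: {missing}")
        counts = pd.Series({s: self.conditions[s] for s in self.fpkm.columns}).value_counts()
        if len(counts) != 2 or not (counts == 3).all():
            raise DesignError(
                f"a comparison needs exactly 2 conditions x 3 replicates, got {counts.to_dict()}"
            )

    @property
    def condition_labels(self) -> tuple[str, str]:
        seen: list[str] = []
        for s in self.fpkm.columns:
            c = self.conditions[s]
            if c not in seen:
                seen.append(c)
        return (seen[0], seen[1])

    def samples_of(self, condition: str) -> list[str]:
        return [s for s in self.fpkm.columns if self.conditions[s] == condition]


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, in input order.

    ``q(i) = min_{j >= i} p(j) * m / j`` over the sorted p-values, capped at
    1; monotone in p. Raises on values outside [0, 1].
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def expression_filter(matrix: ExpressionMatrix, cv_scope: str = "within") -> pd.Index:
    """Genes passing the expression floor and replicate-reproducibility rules.

    Keep a gene iff (a) FPKM >= 1 in at least 3 of the 6 samples, and (b) the
    coefficient of variation (sd/mean, sample sd) is < 0.2 among replicates.
    With ``cv_scope="within"`` (default) the CV rule applies separately to
    each condition's 3 replicates, and only to conditions whose replicate
    mean reaches the floor (a condition where the gene is off is allowed to
    be noisy). ``cv_scope="all"`` applies one CV across all 6 samples when
    the overall mean reaches the floor.
    """
    if cv_scope not in ("within", "all"):
        raise ValueError("cv_scope must be 'within' or 'all'")
    f = matrix.fpkm
    floor_ok = (f >= FPKM_FLOOR).sum(axis=1) >= 3
    keep = floor_ok.copy()
    if cv_scope == "within":
        for cond in matrix.condition_labels:
            sub = f[matrix.samples_of(cond)].to_numpy(dtype=float)
            means = sub.mean(axis=1)
            cvs = np.where(means > 0, sub.std(axis=1, ddof=1) / np.where(means > 0, means, 1.0), np.nan)
            applies = means >= FPKM_FLOOR
            keep &= ~applies | (cvs < CV_MAX)
    else:
        sub = f.to_numpy(dtype=float)
        means = sub.mean(axis=1)
        cvs = np.where(means > 0, sub.std(axis=1, ddof=1) / np.where(means > 0, means, 1.0), np.nan)
        applies = means >= FPKM_FLOOR
        keep &= ~applies | (cvs < CV_MAX)
    return f.index[keep]


def differential_call(
    matrix: ExpressionMatrix,
    kept: pd.Index | None = None,
    epsilon: float = FOLD_EPSILON,
    lfc_threshold: float = 1.0,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-gene differential-expression records for one 3 + 3 comparison.

    ``log2fc = log2((mean_1 + eps) / (mean_2 + eps))`` on raw FPKM group
    means (condition order as in the matrix); p from a Welch (unequal
    variance) two-sample t on log2(FPKM + 1); q by BH adjustment over the
    genes that passed the expression filter (the tested family). A gene is a
    DEG iff it passed the filter, ``|log2fc| >= lfc_threshold`` and
    ``q <= q_threshold``. Genes with zero variance in both groups and equal
    means get p = 1.

    Returns a DataFrame indexed by gene id with columns ``log2fc, p, q,
    direction, passed_expression_filter, is_deg``.
    """
    if kept is None:
        kept = expression_filter(matrix)
    if len(kept) == 0:
        raise ValueError("kept gene set is empty")
    c1, c2 = matrix.condition_labels
    g1 = matrix.fpkm[matrix.samples_of(c1)].to_numpy(dtype=float)
    g2 = matrix.fpkm[matrix.samples_of(c2)].to_numpy(dtype=float)
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    log2fc = np.log2((m1 + epsilon) / (m2 + epsilon))

    l1, l2 = np.log2(g1 + 1.0), np.log2(g2 + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(l1, l2, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    zero_var = (l1.std(axis=1) == 0) & (l2.std(axis=1) == 0)
    p = np.where(zero_var & (l1.mean(axis=1) == l2.mean(axis=1)), 1.0, p)
    p = np.where(zero_var & (l1.mean(axis=1) != l2.mean(axis=1)), 0.0, p)
    p = np.where(np.isnan(p), 1.0, p)

    passed = matrix.fpkm.index.isin(kept)
    q = np.full(len(p), np.nan)
    q[passed] = bh_adjust(p[passed])

    is_deg = passed & (np.abs(log2fc) >= lfc_threshold) & (q <= q_threshold)
    direction = np.where(log2fc > 0, "up", np.where(log2fc < 0, "down", "none"))
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "p": p,
            "q": q,
            "direction": direction,
            "passed_expression_filter": passed,
            "is_deg": is_deg,
        },
        index=matrix.fpkm.index,
    )
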