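"""Comparison of irrigation treatments across experiment phases.

Three kinds of comparison mirror the reference protocol: percentage
reductions of a trait in a treatment group relative to a reference group over
a phase; a fixed-effects two-way ANOVA with treatment and day as crossed
factors (type II sums of squares, computed from least-squares model
comparisons rather than delegated to a stats package, so the decomposition is
explicit and testable); and a Tukey HSD post-hoc built directly from the
studentized-range definition — the classic "q" companion to ANOVA.

Repeated measures on the same pot across days are deliberately ignored (day
is a plain fixed factor); longitudinal modelling is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .design import PhaseDesign
from .errors import DesignError

__all__ = ["relative_reduction", "two_way_anova", "group_posthoc"]


def relative_reduction(
    traits: pd.DataFrame,
    trait: str,
    treatment: str,
    reference: str,
    design: PhaseDesign,
    phase: str,
) -> float:
    """Percent reduction of ``trait`` in ``treatment`` vs ``reference`` over ``phase``.

    ``100 * (1 - mean_treatment / mean_reference)`` where each mean pools all
    pot-days of the group inside the phase. Positive means the treatment is
    lower; identical groups give 0. NaN when the reference mean is zero or a
    group has no coverage.
    """
    if phase not in design.phases:
        raise DesignError(f"phase {phase!r} not in the design calendar")
    start, end = design.phases[phase]
    df = traits[(traits["date"] >= start) & (traits["date"] < end)]
    labels = df["pot_id"].map(design.treatments)
    m_trt = df.loc[labels == treatment, trait].mean()
    m_ref = df.loc[labels == reference, trait].mean()
    if not np.isfinite(m_trt) or not np.isfinite(m_ref) or m_ref == 0:
        return float("nan")
    return 100.0 * (1.0 - m_trt / m_ref)


def _dummies(labels: np.ndarray) -> tuple[np.ndarray, list]:
    levels = sorted(pd.unique(labels).tolist())
    if len(levels) < 2:
        return np.empty((len(labels), 0)), levels
    cols = np.column_stack([(labels == lv).astype(float) for lv in levels[1:]])
    return cols, levels


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    return float(r @ r)


def two_way_anova(values, factor_a, factor_b) -> pd.DataFrame:
    """Fixed-effects two-way ANOVA with interaction, type II sums of squares.

    ``values`` is the response; ``factor_a``/``factor_b`` the two categorical
    factors (e.g. treatment and day), each with at least two levels. Sums of
    squares come from least-squares model comparisons:
    ``SS_A = RSS(B) - RSS(A+B)``, ``SS_B = RSS(A) - RSS(A+B)``,
    ``SS_AB = RSS(A+B) - RSS(A+B+AB)``. On balanced designs this coincides
    with the classical decomposition ``SS_total = SS_A + SS_B + SS_AB +
    SS_resid``. P-values come from the F distribution; if the response has no
    variance at all, the convention F = 0, p = 1 is returned.

    Returns a table indexed by ``["factor_a", "factor_b", "interaction",
    "residual"]`` with columns ``ss, df, F, p``.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a)
    b = np.asarray(factor_b)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("values and factors must have equal length")
    ok = np.isfinite(y)
    y, a, b = y[ok], a[ok], b[ok]
    Xa, la = _dummies(a)
    Xb, lb = _dummies(b)
    if len(la) < 2 or len(lb) < 2:
        raise DesignError("each factor needs at least two levels")
    n = len(y)
    one = np.ones((n, 1))
    Xab = np.column_stack([Xa[:, i] * Xb[:, j] for i in range(Xa.shape[1]) for j in range(Xb.shape[1])])
    X_b = np.hstack([one, Xb])
    X_a = np.hstack([one, Xa])
    X_ab_main = np.hstack([one, Xa, Xb])
    X_full = np.hstack([one, Xa, Xb, Xab])

    rss_b = _rss(X_b, y)
    rss_a = _rss(X_a, y)
    rss_main = _rss(X_ab_main, y)
    rss_full = _rss(X_full, y)

    ss_a = max(rss_b - rss_main, 0.0)
    ss_b = max(rss_a - rss_main, 0.0)
    ss_ab = max(rss_main - rss_full, 0.0)
    ss_res = rss_full

    df_a = len(la) - 1
    df_b = len(lb) - 1
    df_ab = df_a * df_b
    df_res = n - len(la) * len(lb)
    if df_res <= 0:
        raise DesignError("no residual degrees of freedom (need replication per cell)")

    ss_total = float(np.sum((y - y.mean()) ** 2))
    rows = {}
    ms_res = ss_res / df_res
    for name, ss, df in (("factor_a", ss_a, df_a), ("factor_b", ss_b, df_b), ("interaction", ss_ab, df_ab)):
        if ss_total <= 1e-300:  # all values identical: no variance to explain
            F, p = 0.0, 1.0
        elif ms_res <= 0:
            F, p = np.inf, 0.0
        else:
            F = (ss / df) / ms_res
            p = float(stats.f.sf(F, df, df_res))
        rows[name] = {"ss": ss, "df": df, "F": F, "p": p}
    rows["residual"] = {"ss": ss_res, "df": df_res, "F": float("nan"), "p": float("nan")}
    return pd.DataFrame(rows).T[["ss", "df", "F", "p"]]


@dataclass(frozen=True)
class PairwiseComparison:
    group1: str
    group2: str
    diff: float
    q: float
    p_adj: float


def group_posthoc(groups: dict, method: str = "tukey_hsd") -> pd.DataFrame:
    """Pairwise post-hoc comparisons of group means with family-wise adjustment.

    ``groups`` maps label -> array of observations (>= 2 each, >= 2 groups).
    The default (and currently only) method is Tukey's honestly-significant-
    difference: for each pair, the studentized-range statistic

        q_ij = |ȳ_i - ȳ_j| / sqrt( MSE/2 * (1/n_i + 1/n_j) )

    with MSE the pooled within-group variance on N - g degrees of freedom,
    and the adjusted p from the studentized-range distribution with g groups
    (the Tukey–Kramer form for unequal group sizes).
    """
    if method != "tukey_hsd":
        raise ValueError(f"unknown post-hoc method {method!r}")
    labels = list(groups)
    if len(labels) < 2:
        raise DesignError("need at least two groups")
    arrs = {g: np.asarray(groups[g], dtype=float) for g in labels}
    for g, arr in arrs.items():
        if len(arr) < 2:
            raise DesignError(f"group {g!r} needs >= 2 observations")
    n_total = sum(len(a) for a in arrs.values())
    g = len(labels)
    df_err = n_total - g
    mse = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrs.values()) / df_err
    rows = []
    for g1, g2 in combinations(labels, 2):
        a1, a2 = arrs[g1], arrs[g2]
        diff = float(a1.mean() - a2.mean())
        se = np.sqrt(mse / 2.0 * (1.0 / len(a1) + 1.0 / len(a2)))
        if se == 0:
            q = 0.0 if diff == 0 else np.inf
        else:
            q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, g, df_err)) if np.isfinite(q) else 0.0
        rows.append(PairwiseComparison(g1, g2, diff, float(q), min(max(p, 0.0), 1.0)))
    return pd.DataFrame([r.__dict__ for r in rows])
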