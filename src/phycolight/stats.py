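"""Fixed-effects one-way and two-way ANOVA (with interaction) plus Tukey HSD
post-hoc comparisons, built from explicit sums of squares.

Balanced two-way designs use the classical decomposition; unbalanced
designs fall back to partial (Type II) sums of squares from nested
least-squares model comparisons — identical in the balanced case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "FactorialData", "EffectRow", "PairResult", "AnovaResult",
    "one_way_anova", "two_way_anova", "tukey_hsd",
]


@dataclass
class FactorialData:
    """Response values with one mandatory factor and one optional factor."""

    values: np.ndarray
    factor_a: np.ndarray
    factor_b: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.factor_a = np.asarray(self.factor_a)
        if self.factor_a.shape != self.values.shape:
            raise ValueError("factor_a must match values in length")
        if self.factor_b is not None:
            self.factor_b = np.asarray(self.factor_b)
            if self.factor_b.shape != self.values.shape:
                raise ValueError("factor_b must match values in length")


@dataclass
class EffectRow:
    effect: str
    df: int
    ss: float
    F: float
    p: float


@dataclass
class PairResult:
    pair: tuple[str, str]
    mean_diff: float
    p_adj: float


@dataclass
class AnovaResult:
    effects: list[EffectRow]
    residual_df: int
    residual_ss: float
    tukey: list[PairResult] = field(default_factory=list)

    def effect(self, name: str) -> EffectRow:
        for row in self.effects:
            if row.effect == name:
                return row
        raise KeyError(name)


def _f_and_p(ss: float, df: int, ms_resid: float, df_resid: int) -> tuple[float, float]:
    ms = ss / df
    if ms_resid <= 0:
        if ms <= 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = ms / ms_resid
    return F, float(sps.f.sf(F, df, df_resid))


def one_way_anova(data: FactorialData) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA from between/within sums of squares."""
    if data.factor_b is not None:
        raise ValueError("one_way_anova takes a single factor; use two_way_anova")
    y = data.values
    labels = data.factor_a
    groups = [y[labels == g] for g in np.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("empty group")
    n = y.size
    df_between = len(groups) - 1
    df_resid = n - len(groups)
    if df_resid < 1:
        raise ValueError("residual degrees of freedom must be at least 1")
    grand = y.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    F, p = _f_and_p(ssb, df_between, ssw / df_resid, df_resid)
    return AnovaResult(
        effects=[EffectRow("factor_a", df_between, float(ssb), F, p)],
        residual_df=df_resid,
        residual_ss=float(ssw),
    )


def _design(labels: np.ndarray) -> np.ndarray:
    """Treatment-coded dummy columns (reference level dropped)."""
    levels = np.unique(labels)
    return np.column_stack([(labels == lv).astype(float) for lv in levels[1:]]) \
        if len(levels) > 1 else np.empty((labels.size, 0))


def _rss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def two_way_anova(data: FactorialData) -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction.

    Sums of squares come from nested least-squares model comparisons
    (partial / Type II); on balanced designs this coincides with the
    classical sequential decomposition.
    """
    if data.factor_b is None:
        raise ValueError("two_way_anova requires factor_b")
    y = data.values
    a, b = data.factor_a, data.factor_b
    levels_a, levels_b = np.unique(a), np.unique(b)
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ValueError("each factor needs at least 2 levels")
    for la in levels_a:
        for lb in levels_b:
            if not np.any((a == la) & (b == lb)):
                raise ValueError(f"empty cell ({la}, {lb}): interaction not estimable")

    ones = np.ones((y.size, 1))
    Xa, Xb = _design(a), _design(b)
    Xab = np.column_stack([Xa[:, i] * Xb[:, j]
                           for i in range(Xa.shape[1]) for j in range(Xb.shape[1])])
    X_full = np.hstack([ones, Xa, Xb, Xab])
    df_resid = y.size - X_full.shape[1]
    if df_resid < 1:
        raise ValueError("residual degrees of freedom must be at least 1")

    rss_full = _rss(y, X_full)
    rss_ab = _rss(y, np.hstack([ones, Xa, Xb]))
    rss_a_only = _rss(y, np.hstack([ones, Xa]))
    rss_b_only = _rss(y, np.hstack([ones, Xb]))

    ss_a = max(rss_b_only - rss_ab, 0.0)
    ss_b = max(rss_a_only - rss_ab, 0.0)
    ss_ab = max(rss_ab - rss_full, 0.0)
    df_a, df_b = Xa.shape[1], Xb.shape[1]
    df_ab = Xab.shape[1]
    ms_resid = rss_full / df_resid

    rows = []
    for name, ss, df in (("factor_a", ss_a, df_a), ("factor_b", ss_b, df_b),
                         ("interaction", ss_ab, df_ab)):
        F, p = _f_and_p(ss, df, ms_resid, df_resid)
        rows.append(EffectRow(name, df, float(ss), F, p))
    return AnovaResult(effects=rows, residual_df=df_resid, residual_ss=rss_full)


def tukey_hsd(data: FactorialData, effect: str = "factor_a") -> list[PairResult]:
    """Tukey (Kramer) HSD pairwise comparisons for one factor's levels.

    Uses the residual mean square and degrees of freedom of the fitted
    ANOVA (two-way when factor_b is present) and the studentized range
    distribution for adjusted p-values.
    """
    if effect not in ("factor_a", "factor_b"):
        raise ValueError("effect must be 'factor_a' or 'factor_b'")
    labels = data.factor_a if effect == "factor_a" else data.factor_b
    if labels is None:
        raise ValueError(f"{effect} not present in data")
    if data.factor_b is None:
        result = one_way_anova(data)
    else:
        result = two_way_anova(data)
    ms_resid = result.residual_ss / result.residual_df
    y = data.values
    levels = np.unique(labels)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups for pairwise comparisons")
    k = len(levels)
    out: list[PairResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            gi, gj = y[labels == levels[i]], y[labels == levels[j]]
            diff = gi.mean() - gj.mean()
            se = np.sqrt(ms_resid / 2.0 * (1.0 / gi.size + 1.0 / gj.size))
            if se == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, result.residual_df))
            out.append(PairResult((str(levels[i]), str(levels[j])), float(diff),
                                  min(max(p, 0.0), 1.0)))
    return out
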