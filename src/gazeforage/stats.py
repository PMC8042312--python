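"""Statistical comparison machinery for model scores.

Implements the repeated-measures comparison pipeline used to decide
whether model-generated scanpaths are distinguishable from human ones:
distribution gates (Shapiro-Wilk normality with Bonferroni correction,
Bartlett/Levene homoscedasticity) that route to ANOVA or to the
non-parametric path, the Friedman rank test with tie correction, the
Nemenyi post-hoc Critical Difference, Cohen's d effect sizes, and kernel
density summaries of score distributions.  Significance level is
alpha = 0.05 throughout unless stated otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ScoreMatrix",
    "FriedmanResult",
    "friedman",
    "nemenyi_cd",
    "distribution_gates",
    "effect_size",
    "score_densities",
    "NEMENYI_Q",
]


@dataclass
class ScoreMatrix:
    """Blocks x groups score matrix: rows are clips, columns are models."""

    values: np.ndarray
    columns: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("score matrix must be 2-D")
        n, k = self.values.shape
        if k < 2 or n < 2:
            raise ValueError("need >= 2 groups (columns) and >= 2 blocks (rows)")
        if len(self.columns) != k:
            raise ValueError("column names must match matrix width")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score matrix must have no missing entries")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, value_col: str, block_col="clip", group_col="model"):
        wide = df.pivot(index=block_col, columns=group_col, values=value_col)
        if wide.isna().any().any():
            raise ValueError("missing (block, group) combinations")
        return cls(values=wide.to_numpy(), columns=list(wide.columns))


@dataclass
class FriedmanResult:
    statistic: float
    p_value: float
    mean_ranks: np.ndarray
    columns: list[str] | None = None


def _asmatrix(matrix) -> tuple[np.ndarray, list[str] | None]:
    if isinstance(matrix, ScoreMatrix):
        return matrix.values, matrix.columns
    arr = np.asarray(matrix, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows and columns")
    return arr, None


def friedman(matrix) -> FriedmanResult:
    """Friedman rank test over a blocks x groups matrix, with tie correction.

    Within each block the groups are ranked (average ranks on ties); the
    statistic is chi-square distributed with k-1 degrees of freedom under
    the null of no group effect.  A matrix whose rows are all constant
    (every block a complete tie) yields statistic 0 and p = 1.
    """
    values, columns = _asmatrix(matrix)
    n, k = values.shape
    ranks = sps.rankdata(values, axis=1)
    mean_ranks = ranks.mean(axis=0)
    ssq = float(np.sum((mean_ranks - (k + 1) / 2.0) ** 2))
    # tie correction: 1 - sum(t^3 - t) / (N k (k^2 - 1)); tie-group sizes are
    # run lengths in the row-sorted values
    srt = np.sort(values, axis=1)
    breaks = np.diff(srt, axis=1) != 0
    tie_sum = 0.0
    for i in range(n):
        counts = np.diff(np.concatenate(([0], np.flatnonzero(breaks[i]) + 1, [k])))
        tie_sum += float(np.sum(counts.astype(float) ** 3 - counts))
    correction = 1.0 - tie_sum / (n * k * (k**2 - 1))
    if correction <= 0:
        return FriedmanResult(0.0, 1.0, mean_ranks, columns)
    stat = 12.0 * n / (k * (k + 1)) * ssq / correction
    p = float(sps.chi2.sf(stat, k - 1))
    return FriedmanResult(float(stat), p, mean_ranks, columns)


# Studentized-range based Nemenyi critical values q_alpha(k) (infinite df,
# divided by sqrt(2)), k = number of groups.
NEMENYI_Q = {
    0.05: {
        2: 1.959964, 3: 2.343701, 4: 2.569032, 5: 2.727774, 6: 2.849705,
        7: 2.948319, 8: 3.030879, 9: 3.101730, 10: 3.163684,
    },
    0.10: {
        2: 1.644854, 3: 2.052293, 4: 2.291341, 5: 2.459516, 6: 2.588521,
        7: 2.692732, 8: 2.779947, 9: 2.854606, 10: 2.920063,
    },
}


def nemenyi_cd(k: int, n: int, alpha: float = 0.05) -> float:
    """Nemenyi Critical Difference: CD = q_alpha(k) * sqrt(k(k+1)/(6N)).

    Two groups differ significantly when their mean ranks differ by more
    than the CD.  ``alpha`` must be one of the tabulated levels (0.05,
    0.10) and k between 2 and 10.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if alpha not in NEMENYI_Q:
        raise ValueError(f"alpha {alpha} not tabulated; use one of {sorted(NEMENYI_Q)}")
    table = NEMENYI_Q[alpha]
    if k not in table:
        raise ValueError(f"k={k} outside tabulated range 2..10")
    return float(table[k] * np.sqrt(k * (k + 1) / (6.0 * n)))


def distribution_gates(matrix, alpha: float = 0.05) -> dict:
    """Normality and homoscedasticity gates routing ANOVA vs Friedman.

    Per-column Shapiro-Wilk at the Bonferroni-corrected level alpha/k;
    if every column passes, homoscedasticity is tested with Bartlett,
    otherwise with Levene.  The recommendation is 'anova' only when both
    normality and homoscedasticity hold, else 'friedman'.
    Degenerate (constant) columns are flagged and routed to 'friedman'.
    """
    values, columns = _asmatrix(matrix)
    n, k = values.shape
    names = columns or [f"col{i}" for i in range(k)]
    report: dict = {"alpha": alpha, "columns": {}}
    degenerate = False
    normal = True
    for j, name in enumerate(names):
        col = values[:, j]
        if np.ptp(col) == 0:
            report["columns"][name] = {"shapiro_p": None, "normal": None, "degenerate": True}
            degenerate = True
            continue
        w, p = sps.shapiro(col)
        is_norm = bool(p >= alpha / k)
        report["columns"][name] = {
            "shapiro_w": float(w), "shapiro_p": float(p),
            "normal": is_norm, "degenerate": False,
        }
        normal = normal and is_norm
    report["degenerate"] = degenerate
    if degenerate:
        report.update(
            homoscedastic=None, variance_test=None,
            all_normal=False, recommendation="friedman",
        )
        return report
    cols = [values[:, j] for j in range(k)]
    if normal:
        stat, p = sps.bartlett(*cols)
        test = "bartlett"
    else:
        stat, p = sps.levene(*cols)
        test = "levene"
    homo = bool(p >= alpha)
    report.update(
        all_normal=normal,
        variance_test=test,
        variance_stat=float(stat),
        variance_p=float(p),
        homoscedastic=homo,
        recommendation="anova" if (normal and homo) else "friedman",
    )
    return report


_D_LABELS = ((0.2, "negligible"), (0.5, "small"), (0.8, "medium"))


def effect_size(scores_a: Sequence[float], scores_b: Sequence[float]) -> tuple[float, str]:
    """Cohen's d with pooled standard deviation, plus a magnitude label.

    |d| < 0.2 negligible, < 0.5 small, < 0.8 medium, else large.  The
    sign follows mean(a) - mean(b).  Raises on zero pooled SD.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    na, nb = len(a), len(b)
    va = a.var(ddof=1) if na > 1 else 0.0
    vb = b.var(ddof=1) if nb > 1 else 0.0
    denom_df = max(na + nb - 2, 1)
    pooled = np.sqrt(((na - 1) * va + (nb - 1) * vb) / denom_df)
    if pooled == 0:
        if a.mean() == b.mean():
            return 0.0, "negligible"
        raise ValueError("zero pooled standard deviation with unequal means")
    d = float((a.mean() - b.mean()) / pooled)
    for cut, label in _D_LABELS:
        if abs(d) < cut:
            return d, label
    return d, "large"


def score_densities(
    score_table: pd.DataFrame,
    score_cols: Sequence[str] | None = None,
    group_col: str = "model",
    n_grid: int = 256,
) -> dict:
    """Gaussian kernel density estimates of score distributions.

    For each group and each score column (>= 5 points required) a KDE
    with Scott's reference bandwidth is evaluated on a regular grid
    spanning the data padded by two bandwidths.  Returns
    {(group, score): {"grid": ..., "density": ...}} ready for plotting.
    """
    if score_cols is None:
        score_cols = [c for c in score_table.columns if c not in (group_col, "clip")]
    out = {}
    for group, sub in score_table.groupby(group_col):
        for col in score_cols:
            pts = sub[col].dropna().to_numpy(float)
            if len(pts) < 5:
                raise ValueError(
                    f"group {group!r}, score {col!r}: need >= 5 points, got {len(pts)}"
                )
            kde = sps.gaussian_kde(pts)  # Scott's rule
            bw = kde.factor * pts.std(ddof=1)
            grid = np.linspace(pts.min() - 2 * bw, pts.max() + 2 * bw, n_grid)
            out[(group, col)] = {"grid": grid, "density": kde(grid)}
    return out
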