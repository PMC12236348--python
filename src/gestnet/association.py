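"""Bivariate Spearman correlations between schizotypy and gesture measures.

Ties are handled with average ranks (Likert sums are heavily tied), so rho is
the Pearson correlation of midranks.  Two-sided p-values use the t
approximation with n - 2 degrees of freedom; an exact permutation option is
available for small samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class CorrelationResult:
    var1: str
    var2: str
    rho: float
    p: float
    n: int


def spearman_rho(x, y, var1: str = "x", var2: str = "y",
                 method: str = "t") -> CorrelationResult:
    """Spearman rank correlation with pairwise deletion of missing values.

    ``method='t'`` gives the asymptotic t-approximation p-value;
    ``method='permutation'`` an exact/randomized permutation p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 4:
        raise ValueError("need at least 4 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant vector")
    if method == "t":
        res = stats.spearmanr(x, y)
        rho, p = float(res.statistic), float(res.pvalue)
    elif method == "permutation":
        perm = stats.permutation_test(
            (x,), lambda xs: stats.spearmanr(xs, y).statistic,
            permutation_type="pairings", n_resamples=9999,
            rng=np.random.default_rng(0))
        rho, p = float(perm.statistic), float(perm.pvalue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrelationResult(var1=var1, var2=var2, rho=rho, p=min(p, 1.0), n=n)


def correlation_matrix(table: pd.DataFrame,
                       columns: list[str] | None = None) -> pd.DataFrame:
    """All pairwise Spearman correlations, long format.

    Returns a DataFrame (var1, var2, rho, p, n) over unordered pairs with
    pairwise-complete observations.
    """
    if columns is None:
        columns = [c for c in table.columns if c != "participant_id"]
    if len(columns) < 2:
        raise ValueError("need at least 2 columns")
    rows = []
    for a, b in combinations(columns, 2):
        r = spearman_rho(table[a], table[b], var1=a, var2=b)
        rows.append((r.var1, r.var2, r.rho, r.p, r.n))
    return pd.DataFrame(rows, columns=["var1", "var2", "rho", "p", "n"])


def correlation_square(table: pd.DataFrame,
                       columns: list[str] | None = None) -> pd.DataFrame:
    """Square symmetric rho matrix with unit diagonal."""
    if columns is None:
        columns = [c for c in table.columns if c != "participant_id"]
    long = correlation_matrix(table, columns)
    m = pd.DataFrame(np.eye(len(columns)), index=columns, columns=columns)
    for _, row in long.iterrows():
        m.loc[row.var1, row.var2] = row.rho
        m.loc[row.var2, row.var1] = row.rho
    return m
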