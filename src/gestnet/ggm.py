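"""Non-regularized partial Spearman correlation network with bootstrap
percentile-CI edge selection.

The network is a Gaussian graphical model on rank-transformed data: edge
weights are partial correlations obtained by inverting and standardizing the
rank-based (Spearman, copula-corrected) correlation matrix.  Edges are
selected by a nonparametric bootstrap
decision rule: resample participants with replacement, re-estimate all partial
correlations, and include an edge iff the 95% percentile confidence interval
of its bootstrap distribution excludes zero.  Selected edges carry the
full-sample estimate (not the bootstrap mean); non-selected edges are zero in
the selected graph view.  This estimate-then-select approach is preferred to
regularization when observations greatly outnumber variables.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

EIG_FLOOR = 1e-8


def spearman_matrix(x: np.ndarray) -> np.ndarray:
    """Spearman correlation matrix: Pearson correlation of column midranks."""
    ranks = stats.rankdata(x, axis=0)
    return np.corrcoef(ranks, rowvar=False)


def rank_correlation_matrix(x: np.ndarray, copula: bool = True) -> np.ndarray:
    """Rank-based correlation matrix used for network estimation.

    With ``copula=True`` (default) the Spearman matrix is mapped through
    ``r = 2 sin(pi * rho_s / 6)`` — the rank-based estimator of the latent
    Gaussian correlation.  Inverting the raw Spearman matrix entrywise is
    slightly inconsistent for partial correlations of a latent Gaussian
    (structural zeros come out nonzero in population), which inflates the
    false-inclusion rate of the bootstrap decision rule; the sine map removes
    that distortion while keeping Spearman's rho as the dependence input.
    """
    s = spearman_matrix(x)
    if not copula:
        return s
    r = 2.0 * np.sin(np.pi * s / 6.0)
    np.fill_diagonal(r, 1.0)
    return r


def nearest_positive_definite(m: np.ndarray, floor: float = EIG_FLOOR) -> np.ndarray:
    """Repair an indefinite symmetric correlation matrix by eigenvalue
    clipping; the diagonal is renormalized back to 1.  A matrix that is
    already positive definite is returned unchanged."""
    m = np.asarray(m, dtype=float)
    if not np.allclose(m, m.T):
        raise ValueError("matrix must be symmetric")
    if np.linalg.eigvalsh(m).min() >= floor:
        return m
    out = m
    # diagonal renormalization can nudge the smallest eigenvalue back below
    # the floor; iterate clip + renormalize (converges in a few passes)
    for _ in range(100):
        w, v = np.linalg.eigh(out)
        if w.min() >= floor:
            break
        w = np.clip(w, floor * 1.5, None)
        out = (v * w) @ v.T
        d = np.sqrt(np.diag(out))
        out = out / np.outer(d, d)
        np.fill_diagonal(out, 1.0)
        out = (out + out.T) / 2.0
    return out


def partial_correlations(corr: np.ndarray, repair: bool = True) -> np.ndarray:
    """Partial-correlation matrix from a correlation matrix.

    With P the precision matrix (inverse of ``corr``),
    ``partial(i, j) = -P[i, j] / sqrt(P[i, i] * P[j, j])``; unit diagonal.
    A non-positive-definite input is routed through eigenvalue-clipping
    repair first (unless ``repair=False``).
    """
    corr = np.asarray(corr, dtype=float)
    if repair:
        corr = nearest_positive_definite(corr)
    try:
        prec = np.linalg.inv(corr)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(f"correlation matrix is singular: {e}") from e
    d = np.sqrt(np.diag(prec))
    pcor = -prec / np.outer(d, d)
    np.fill_diagonal(pcor, 1.0)
    return (pcor + pcor.T) / 2.0


@dataclass(frozen=True)
class EstimatedNetwork:
    """Estimated partial-correlation network with bootstrap edge selection.

    ``weights`` holds the full-sample partial correlations with a zero
    diagonal (graph convention); ``included`` is the bootstrap decision mask;
    ``selected_weights`` zeroes the non-selected edges.
    """

    node_labels: tuple[str, ...]
    weights: np.ndarray
    included: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n: int
    n_boot: int
    alpha: float
    seed: int | None = None
    repair_count: int = 0
    redraw_count: int = 0

    @property
    def selected_weights(self) -> np.ndarray:
        return np.where(self.included, self.weights, 0.0)

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_nodes):
            for j in range(i + 1, self.n_nodes):
                rows.append((self.node_labels[i], self.node_labels[j],
                             self.weights[i, j], self.ci_lower[i, j],
                             self.ci_upper[i, j], bool(self.included[i, j])))
        return pd.DataFrame(rows, columns=["node1", "node2", "weight",
                                           "ci_lower", "ci_upper", "included"])

    def metadata(self) -> dict:
        return {
            "n": self.n, "n_boot": self.n_boot, "alpha": self.alpha,
            "seed": self.seed, "repair_count": self.repair_count,
            "redraw_count": self.redraw_count,
            "n_included_edges": int(self.included[np.triu_indices(self.n_nodes, 1)].sum()),
        }

    def metadata_json(self) -> str:
        return json.dumps(self.metadata(), indent=2)


def _table_matrix(table: pd.DataFrame,
                  columns: list[str] | None) -> tuple[np.ndarray, tuple[str, ...]]:
    if columns is None:
        columns = [c for c in table.columns
                   if c not in ("participant_id", "SPQ_total")]
    x = table[columns].to_numpy(dtype=float)
    x = x[~np.isnan(x).any(axis=1)]
    return x, tuple(columns)


def estimate_pcor(table: pd.DataFrame,
                  columns: list[str] | None = None) -> tuple[np.ndarray, tuple[str, ...]]:
    """Full-sample partial Spearman correlations (complete rows)."""
    x, cols = _table_matrix(table, columns)
    return partial_correlations(rank_correlation_matrix(x)), cols


def bootstrap_edge_selection(
    table: pd.DataFrame,
    columns: list[str] | None = None,
    n_boot: int = 5000,
    ci: float = 0.95,
    alpha: float = 0.05,
    seed: int | None = None,
    allow_mismatch: bool = False,
) -> EstimatedNetwork:
    """Estimate the network and select edges by bootstrap percentile CIs.

    Per replicate, participants are resampled with replacement, ranks are
    recomputed within the replicate, and the partial-correlation matrix is
    re-estimated (with eigenvalue-clipping repair of indefinite Spearman
    matrices).  An edge is included iff its percentile CI at coverage ``ci``
    excludes zero.  ``ci`` and ``alpha`` are redundant; ``ci = 1 - alpha`` is
    enforced unless ``allow_mismatch`` is set explicitly.

    Replicates that produce a constant column (no rank variation) are redrawn
    and counted in ``redraw_count``.
    """
    if not allow_mismatch and abs(ci - (1.0 - alpha)) > 1e-12:
        raise ValueError(
            f"ci={ci} and alpha={alpha} disagree with ci = 1 - alpha; "
            f"pass allow_mismatch=True to override")
    x, cols = _table_matrix(table, columns)
    n, p = x.shape
    if n < p:
        raise ValueError(f"need at least as many complete rows ({n}) as nodes ({p})")
    if n < 10 * p:
        import warnings
        warnings.warn(f"only {n} rows for {p} nodes; edge selection may be unstable")

    full = partial_correlations(rank_correlation_matrix(x))
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(p, 1)
    boots = np.empty((n_boot, iu[0].size))
    repair_count = 0
    redraw_count = 0
    b = 0
    while b < n_boot:
        xb = x[rng.integers(0, n, size=n)]
        if np.any(np.ptp(xb, axis=0) == 0):
            redraw_count += 1
            continue
        corr = rank_correlation_matrix(xb)
        if np.linalg.eigvalsh(corr).min() < EIG_FLOOR:
            repair_count += 1
            corr = nearest_positive_definite(corr)
        boots[b] = partial_correlations(corr, repair=False)[iu]
        b += 1

    lo_q, hi_q = 100 * (1 - ci) / 2, 100 * (1 + ci) / 2
    lo = np.percentile(boots, lo_q, axis=0)
    hi = np.percentile(boots, hi_q, axis=0)

    ci_lower = np.zeros((p, p)); ci_upper = np.zeros((p, p))
    included = np.zeros((p, p), dtype=bool)
    ci_lower[iu] = lo; ci_upper[iu] = hi
    included[iu] = (lo > 0) | (hi < 0)
    ci_lower += ci_lower.T; ci_upper += ci_upper.T
    included |= included.T

    weights = full.copy()
    np.fill_diagonal(weights, 0.0)
    return EstimatedNetwork(
        node_labels=cols, weights=weights, included=included,
        ci_lower=ci_lower, ci_upper=ci_upper, n=n, n_boot=n_boot,
        alpha=alpha, seed=seed, repair_count=repair_count,
        redraw_count=redraw_count)
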