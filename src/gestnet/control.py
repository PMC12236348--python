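"""Average and modal controllability of network nodes.

The selected signed network is interpreted as the coupling matrix A of a
discrete-time linear system x(t+1) = A x(t) + B u(t).  A is first stabilized
by dividing by c = 1 + |lambda_max(A)| so all eigenvalues lie strictly inside
the unit circle.  For input at a single node i (B = e_i):

* average controllability is trace(W_i) of the infinite-horizon
  controllability Gramian, W = A W A' + B B' — large values mean the node can
  steer the system into many easily reachable states; the tau = 0 term
  contributes 1, so avg_ctrl >= 1 always;
* modal controllability is phi_i = sum_j (1 - lambda_j^2) v_ij^2 over the
  eigendecomposition A = V diag(lambda) V' — large values mean the node
  couples strongly into the fast-decaying (hard-to-reach) modes.

Control dynamics respect edge signs, so the signed selected weights are the
default input (configurable).  The normalization constant is recorded in the
output because alternative conventions change absolute values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg

from .ggm import EstimatedNetwork


def normalize_adjacency(weights: np.ndarray) -> tuple[np.ndarray, float]:
    """Scale a symmetric zero-diagonal coupling matrix to spectral radius < 1.

    Returns (A / c, c) with c = 1 + |lambda_max(A)|.
    """
    weights = np.asarray(weights, dtype=float)
    if not np.allclose(weights, weights.T):
        raise ValueError("adjacency must be symmetric")
    lam = np.linalg.eigvalsh(weights)
    c = 1.0 + float(np.max(np.abs(lam)))
    return weights / c, c


def average_controllability(a_norm: np.ndarray) -> np.ndarray:
    """Per-node trace of the infinite-horizon controllability Gramian."""
    a_norm = np.asarray(a_norm, dtype=float)
    n = a_norm.shape[0]
    if np.max(np.abs(np.linalg.eigvalsh(a_norm))) >= 1.0:
        raise ValueError("dynamics matrix must be Schur stable (spectral radius < 1)")
    out = np.empty(n)
    for i in range(n):
        bbt = np.zeros((n, n))
        bbt[i, i] = 1.0
        w = linalg.solve_discrete_lyapunov(a_norm, bbt)
        out[i] = float(np.trace(w))
    return out


def modal_controllability(a_norm: np.ndarray) -> np.ndarray:
    """phi_i = sum_j (1 - lambda_j^2) v_ij^2 from the real eigendecomposition."""
    a_norm = np.asarray(a_norm, dtype=float)
    if not np.allclose(a_norm, a_norm.T):
        raise ValueError("dynamics matrix must be symmetric")
    lam, v = np.linalg.eigh(a_norm)
    return ((1.0 - lam**2) * v**2).sum(axis=1)


@dataclass(frozen=True)
class ControllabilityScores:
    node_labels: tuple[str, ...]
    avg_ctrl: np.ndarray
    modal_ctrl: np.ndarray
    normalization: float
    spectral_radius: float

    def table(self) -> pd.DataFrame:
        return pd.DataFrame({"node": self.node_labels,
                             "avg_ctrl": self.avg_ctrl,
                             "modal_ctrl": self.modal_ctrl})

    def metadata_json(self) -> str:
        return json.dumps({"normalization_constant": self.normalization,
                           "spectral_radius_after": self.spectral_radius},
                          indent=2)


def controllability_scores(network: EstimatedNetwork | np.ndarray,
                           labels: tuple[str, ...] | None = None,
                           signed: bool = True) -> ControllabilityScores:
    """Average and modal controllability of every node of the selected network."""
    if isinstance(network, EstimatedNetwork):
        weights, labels = network.selected_weights, network.node_labels
    else:
        weights = np.asarray(network, dtype=float)
        if labels is None:
            labels = tuple(str(i) for i in range(weights.shape[0]))
    if not signed:
        weights = np.abs(weights)
    a_norm, c = normalize_adjacency(weights)
    rho = float(np.max(np.abs(np.linalg.eigvalsh(a_norm))))
    return ControllabilityScores(
        node_labels=tuple(labels),
        avg_ctrl=average_controllability(a_norm),
        modal_ctrl=modal_controllability(a_norm),
        normalization=c, spectral_radius=rho)
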