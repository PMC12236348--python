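"""Node predictability: variance of each node explained by its neighbors.

Each node is regressed (ordinary least squares with intercept) on the nodes
it shares a selected edge with; the regression runs on rank-transformed data
to stay consistent with the Spearman network, so R-squared is invariant to
monotone transforms of any variable.  A node with no included edges has
predictability 0 by convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .ggm import EstimatedNetwork, _table_matrix


def node_predictability(table: pd.DataFrame,
                        network: EstimatedNetwork) -> pd.DataFrame:
    """Per-node R-squared from regressing each node on its selected neighbors.

    Returns a tidy table (node, r2, neighbors).  Constant neighbor columns
    are dropped from the design.
    """
    x, cols = _table_matrix(table, list(network.node_labels))
    ranks = stats.rankdata(x, axis=0)
    rows = []
    for i, lab in enumerate(cols):
        nbr = [j for j in range(len(cols)) if network.included[i, j] and j != i]
        nbr = [j for j in nbr if np.ptp(ranks[:, j]) > 0]
        if not nbr:
            rows.append((lab, 0.0, ""))
            continue
        y = ranks[:, i]
        design = np.column_stack([np.ones(len(y)), ranks[:, nbr]])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ beta
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = 0.0 if tss == 0 else 1.0 - float((resid ** 2).sum()) / tss
        rows.append((lab, max(0.0, min(1.0, r2)),
                     ",".join(cols[j] for j in nbr)))
    return pd.DataFrame(rows, columns=["node", "r2", "neighbors"])
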