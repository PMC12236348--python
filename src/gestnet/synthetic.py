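"""Synthetic participant data with a known ground-truth partial-correlation network.

The analysis pipeline operates on nine subscale-level variables measured by
three instruments: three schizotypy facets (SPQ-B), four self-reported gesture
dispositions (BAG), and two speech-gesture matching performance indices.  No
raw data accompany the study design this package implements, so every
downstream stage is exercised on data simulated here from a latent
multivariate Gaussian whose partial-correlation structure is known exactly.

The default ground truth has three within-instrument blocks with positive
partial correlations and a small set of signed cross-block "bridge" edges
concentrated on the BAG social-production node; all other cross-block partial
correlations are structurally zero.  Item-level responses are obtained by
disaggregating each subscale latent into equicorrelated item latents (a latent
Gaussian copula) and cutting them at standard-normal quantile thresholds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

# --------------------------------------------------------------------------
# Node layout: 9 subscale variables in three instrument blocks
# --------------------------------------------------------------------------

NODE_LABELS: tuple[str, ...] = (
    "CogPerc", "Interp", "Disorg",          # SPQ-B schizotypy facets
    "Perc", "Prod", "SocPerc", "SocProd",   # BAG self-report subscales
    "Icon", "Metaph",                        # gesture-matching task indices
)

#: instrument block of each node (0 = schizotypy, 1 = self-report, 2 = task)
DEFAULT_COMMUNITIES: dict[str, int] = {
    "CogPerc": 0, "Interp": 0, "Disorg": 0,
    "Perc": 1, "Prod": 1, "SocPerc": 1, "SocProd": 1,
    "Icon": 2, "Metaph": 2,
}

#: signed cross-block edges; SocProd carries the bulk of the bridging weight
DEFAULT_BRIDGE_EDGES: tuple[tuple[str, str, float], ...] = (
    ("SocProd", "Icon", 0.15),
    ("SocProd", "Metaph", 0.12),
    ("SocProd", "CogPerc", 0.12),
    ("Disorg", "Metaph", -0.10),
    ("Interp", "Perc", -0.10),
    ("Prod", "Icon", -0.10),
    ("Prod", "Disorg", 0.10),
    ("Prod", "Interp", -0.10),
)

DEFAULT_WITHIN_STRENGTH: tuple[float, float] = (0.2, 0.4)


@dataclass(frozen=True)
class GroundTruthNetwork:
    """A known generating partial-correlation network over the 9 variables.

    Attributes
    ----------
    node_labels : ordered variable names.
    pcor : symmetric partial-correlation matrix, unit diagonal.
    communities : node -> instrument block assignment.
    zero_mask : boolean matrix, True exactly where ``pcor == 0``.
    """

    node_labels: tuple[str, ...]
    pcor: np.ndarray
    communities: dict[str, int] = field(default_factory=dict)

    @property
    def zero_mask(self) -> np.ndarray:
        return self.pcor == 0.0

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def validate(self) -> None:
        p = self.pcor
        if p.shape != (self.n_nodes, self.n_nodes):
            raise ValueError("pcor shape does not match node_labels")
        if not np.allclose(p, p.T):
            raise ValueError("pcor must be symmetric")
        if not np.all(np.diag(p) == 1.0):
            raise ValueError("pcor diagonal must be exactly 1")
        off = p[~np.eye(self.n_nodes, dtype=bool)]
        if np.any(np.abs(off) >= 1.0):
            raise ValueError("off-diagonal partial correlations must lie in (-1, 1)")
        w = np.linalg.eigvalsh(_pcor_to_precision_shape(p))
        if w.min() <= 0:
            raise ValueError(
                f"implied precision matrix is not positive definite "
                f"(minimum eigenvalue {w.min():.6g})"
            )

    def to_json(self) -> str:
        return json.dumps(
            {
                "node_labels": list(self.node_labels),
                "pcor": self.pcor.tolist(),
                "communities": self.communities,
                "zero_mask": self.zero_mask.tolist(),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthNetwork":
        d = json.loads(text)
        return cls(
            node_labels=tuple(d["node_labels"]),
            pcor=np.asarray(d["pcor"], dtype=float),
            communities={k: int(v) for k, v in d["communities"].items()},
        )

    def edge_list(self) -> pd.DataFrame:
        """Weighted edge list (nonzero off-diagonal entries, upper triangle)."""
        rows = []
        for i in range(self.n_nodes):
            for j in range(i + 1, self.n_nodes):
                if self.pcor[i, j] != 0.0:
                    rows.append((self.node_labels[i], self.node_labels[j],
                                 self.pcor[i, j]))
        return pd.DataFrame(rows, columns=["node1", "node2", "weight"])


def _pcor_to_precision_shape(pcor: np.ndarray) -> np.ndarray:
    """Unit-diagonal precision matrix whose standardized negated off-diagonals
    equal ``pcor``.  Any diagonal rescaling of this matrix yields the same
    partial correlations, so unit diagonal is a canonical choice."""
    omega = -pcor.copy()
    np.fill_diagonal(omega, 1.0)
    return omega


def make_ground_truth(
    within_strength: tuple[float, float] = DEFAULT_WITHIN_STRENGTH,
    bridge_edges: tuple[tuple[str, str, float], ...] = DEFAULT_BRIDGE_EDGES,
    seed: int = 0,
    node_labels: tuple[str, ...] = NODE_LABELS,
    communities: dict[str, int] | None = None,
) -> GroundTruthNetwork:
    """Build a generating network with known block structure and known zeros.

    Within-block partial correlations are drawn uniformly from
    ``within_strength``; the listed ``bridge_edges`` are placed across blocks;
    every other cross-block entry is exactly zero.  The construction is
    validated, not repaired: a request whose implied precision matrix is not
    positive definite raises with the offending minimum eigenvalue.
    """
    if communities is None:
        communities = dict(DEFAULT_COMMUNITIES)
    lo, hi = within_strength
    if not (-1 < lo <= hi < 1):
        raise ValueError("within_strength bounds must satisfy -1 < lo <= hi < 1")
    rng = np.random.default_rng(seed)
    idx = {lab: i for i, lab in enumerate(node_labels)}
    p = len(node_labels)
    pcor = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            if communities[node_labels[i]] == communities[node_labels[j]]:
                pcor[i, j] = pcor[j, i] = rng.uniform(lo, hi)
    for a, b, w in bridge_edges:
        i, j = idx[a], idx[b]
        if communities[a] == communities[b]:
            raise ValueError(f"bridge edge {a}-{b} lies within one block")
        pcor[i, j] = pcor[j, i] = float(w)
    gt = GroundTruthNetwork(node_labels=tuple(node_labels), pcor=pcor,
                            communities=communities)
    gt.validate()
    return gt


def pcor_to_covariance(gt: GroundTruthNetwork) -> np.ndarray:
    """Correlation-scaled covariance matrix implied by the ground truth.

    Inverts the canonical precision matrix and standardizes the result;
    standardizing the negated off-diagonals of its inverse recovers
    ``gt.pcor`` entrywise (exactly, up to floating round-off).
    """
    gt.validate()
    omega = _pcor_to_precision_shape(gt.pcor)
    sigma = np.linalg.inv(omega)
    d = np.sqrt(np.diag(sigma))
    if np.any(d <= 0):
        raise np.linalg.LinAlgError("singular intermediate covariance")
    sigma = sigma / np.outer(d, d)
    return (sigma + sigma.T) / 2.0


def simulate_subscales(gt: GroundTruthNetwork, n: int, seed: int = 0) -> pd.DataFrame:
    """Draw ``n`` participants' subscale scores from the latent Gaussian.

    Returns a DataFrame with ``participant_id`` plus one column per node in
    ``gt.node_labels`` order.
    """
    if n < 10:
        raise ValueError("n must be at least 10 for downstream estimation")
    sigma = pcor_to_covariance(gt)
    rng = np.random.default_rng(seed)
    x = rng.multivariate_normal(np.zeros(gt.n_nodes), sigma, size=n,
                                method="cholesky")
    df = pd.DataFrame(x, columns=list(gt.node_labels))
    df.insert(0, "participant_id", np.arange(1, n + 1))
    return df


# --------------------------------------------------------------------------
# Item-level simulation (latent Gaussian copula with quantile thresholds)
# --------------------------------------------------------------------------

#: default probability cut points; thresholds are the standard-normal quantiles
DEFAULT_THRESHOLDS: dict[str, tuple[float, ...]] = {
    # 22 binary items, ~30% endorsement
    "spq": (0.70,),
    # 12 items on 1-5, mildly peaked in the middle
    "bag": (0.10, 0.35, 0.65, 0.90),
    # 8 ratings on 1-7
    "video": (0.05, 0.20, 0.40, 0.60, 0.80, 0.95),
}

DEFAULT_ITEM_LOADING = 0.7

#: condition labels for the gesture-matching videos: Abstract/Concrete sentences
#: with Related/Unrelated gestures, two videos each
VIDEO_CONDITIONS: tuple[str, ...] = ("AR1", "AR2", "AU1", "AU2",
                                     "CR1", "CR2", "CU1", "CU2")

SPQ_ITEMS: tuple[str, ...] = tuple(f"spq_{k:02d}" for k in range(1, 23))
BAG_ITEMS: tuple[str, ...] = tuple(f"bag_{k:02d}" for k in range(1, 13))

#: subscale of each item: SPQ-B 8/8/6, BAG 3 items per subscale
DEFAULT_SPQ_MAP: dict[str, str] = {
    **{f"spq_{k:02d}": "CogPerc" for k in range(1, 9)},
    **{f"spq_{k:02d}": "Interp" for k in range(9, 17)},
    **{f"spq_{k:02d}": "Disorg" for k in range(17, 23)},
}
DEFAULT_BAG_MAP: dict[str, str] = {
    "bag_01": "Perc", "bag_02": "Perc", "bag_03": "Perc",
    "bag_04": "Prod", "bag_05": "Prod", "bag_06": "Prod",
    "bag_07": "SocPerc", "bag_08": "SocPerc", "bag_09": "SocPerc",
    "bag_10": "SocProd", "bag_11": "SocProd", "bag_12": "SocProd",
}
#: the scale's perception example item is negatively worded
DEFAULT_BAG_REVERSE: frozenset[str] = frozenset({"bag_01"})

#: which latent each video loads on and with which sign (Related +, Unrelated -)
_VIDEO_LOADING: dict[str, tuple[str, float]] = {
    "AR1": ("Metaph", +1), "AR2": ("Metaph", +1),
    "AU1": ("Metaph", -1), "AU2": ("Metaph", -1),
    "CR1": ("Icon", +1), "CR2": ("Icon", +1),
    "CU1": ("Icon", -1), "CU2": ("Icon", -1),
}


def _validate_thresholds(thresholds: dict[str, tuple[float, ...]]) -> None:
    expected = {"spq": 1, "bag": 4, "video": 6}
    for inst, want in expected.items():
        cuts = thresholds[inst]
        if len(cuts) != want:
            raise ValueError(
                f"{inst} needs {want} thresholds for its response range, "
                f"got {len(cuts)}")
        arr = np.asarray(cuts, dtype=float)
        if np.any(arr <= 0) or np.any(arr >= 1) or np.any(np.diff(arr) <= 0):
            raise ValueError(f"{inst} thresholds must be strictly increasing in (0, 1)")


def _discretize(latent: np.ndarray, cut_probs: tuple[float, ...],
                base: int) -> np.ndarray:
    """Cut standard-normal latents at quantile thresholds into ordinal codes
    starting at ``base``."""
    z_cuts = stats.norm.ppf(np.asarray(cut_probs, dtype=float))
    return base + np.searchsorted(z_cuts, latent, side="right")


def simulate_item_responses(
    gt: GroundTruthNetwork,
    n: int,
    thresholds: dict[str, tuple[float, ...]] | None = None,
    attention_fail_rate: float = 0.04,
    seed: int = 0,
    item_loading: float = DEFAULT_ITEM_LOADING,
    bag_reverse: frozenset[str] = DEFAULT_BAG_REVERSE,
) -> pd.DataFrame:
    """Generate raw item-level responses for the three instruments.

    Each subscale latent is disaggregated into equicorrelated item latents
    (loading ``item_loading`` on the subscale factor), which are then cut at
    the instrument's quantile thresholds.  Reverse-keyed BAG items and the
    Unrelated video conditions load negatively.  ``attention_pass`` is an
    independent Bernoulli(1 - attention_fail_rate) flag.
    """
    if thresholds is None:
        thresholds = dict(DEFAULT_THRESHOLDS)
    _validate_thresholds(thresholds)
    if not (0 <= attention_fail_rate < 1):
        raise ValueError("attention_fail_rate must be in [0, 1)")
    if not (0 < item_loading < 1):
        raise ValueError("item_loading must be in (0, 1)")

    latents = simulate_subscales(gt, n, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1]))
    resid_sd = float(np.sqrt(1.0 - item_loading**2))

    out = pd.DataFrame({"participant_id": latents["participant_id"]})

    def item_latent(sub: str, sign: float) -> np.ndarray:
        z = latents[sub].to_numpy()
        return sign * item_loading * z + resid_sd * rng.standard_normal(n)

    for item in SPQ_ITEMS:
        y = item_latent(DEFAULT_SPQ_MAP[item], +1.0)
        out[item] = _discretize(y, thresholds["spq"], base=0)
    for item in BAG_ITEMS:
        sign = -1.0 if item in bag_reverse else +1.0
        y = item_latent(DEFAULT_BAG_MAP[item], sign)
        out[item] = _discretize(y, thresholds["bag"], base=1)
    for cond in VIDEO_CONDITIONS:
        sub, sign = _VIDEO_LOADING[cond]
        y = item_latent(sub, sign)
        out[cond] = _discretize(y, thresholds["video"], base=1)
    out["attention_pass"] = rng.random(n) >= attention_fail_rate
    return out
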