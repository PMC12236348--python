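"""Scoring: raw item responses -> the nine analysis variables.

SPQ-B (22 binary items) is summed into three facet subscales (8/8/6 items:
cognitive-perceptual, interpersonal, disorganization) plus a total score.
BAG (12 items, 1-5) is summed into four 3-item subscales after recoding
reverse-keyed items as ``6 - response``.  The speech-gesture matching task
yields two congruence-sensitivity indices: for each sentence type the mean
relatedness rating of Related videos minus the mean rating of Unrelated
videos (positive = better discrimination).

Item-to-subscale maps and the reverse-key set are configuration data with
documented defaults rather than hard-coded constants, because alternative
keyings are a legitimate researcher degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import (
    BAG_ITEMS,
    DEFAULT_BAG_MAP,
    DEFAULT_BAG_REVERSE,
    DEFAULT_SPQ_MAP,
    SPQ_ITEMS,
    VIDEO_CONDITIONS,
)

SPQ_SUBSCALES = ("CogPerc", "Interp", "Disorg")
BAG_SUBSCALES = ("Perc", "Prod", "SocPerc", "SocProd")
TASK_INDICES = ("Icon", "Metaph")

#: the 9 network variables, in canonical order
NETWORK_COLUMNS = SPQ_SUBSCALES + BAG_SUBSCALES + TASK_INDICES


@dataclass(frozen=True)
class ExclusionReport:
    n_input: int
    n_excluded: int

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_excluded

    @property
    def proportion_excluded(self) -> float:
        return self.n_excluded / self.n_input if self.n_input else 0.0


def apply_attention_filter(responses: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Drop participants who failed the attention-check video description.

    Failing participants contribute no task-based data; the report records how
    many were removed.  An empty retained set is permitted.
    """
    if "attention_pass" not in responses.columns:
        raise ValueError("attention_pass column is required")
    keep = responses["attention_pass"].astype(bool)
    retained = responses.loc[keep].reset_index(drop=True)
    return retained, ExclusionReport(n_input=len(responses),
                                     n_excluded=int((~keep).sum()))


def _check_partition(item_map: dict[str, str], items: tuple[str, ...],
                     instrument: str) -> None:
    if set(item_map) != set(items):
        missing = set(items) - set(item_map)
        extra = set(item_map) - set(items)
        raise ValueError(
            f"{instrument} item map must cover each item exactly once "
            f"(missing: {sorted(missing)}, unexpected: {sorted(extra)})")


def score_spq(responses: pd.DataFrame,
              item_map: dict[str, str] | None = None) -> pd.DataFrame:
    """SPQ-B subscale sums and total.  Rows with any missing item get NaN on
    the affected subscale (complete-case per variable)."""
    if item_map is None:
        item_map = DEFAULT_SPQ_MAP
    _check_partition(item_map, SPQ_ITEMS, "SPQ-B")
    vals = responses[list(SPQ_ITEMS)]
    bad = ~(vals.isin([0, 1]) | vals.isna())
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(f"SPQ-B response out of range at row {r}, item {bad.columns[c]}")
    out = pd.DataFrame(index=responses.index)
    for sub in SPQ_SUBSCALES:
        cols = [it for it, s in item_map.items() if s == sub]
        out[sub] = vals[cols].sum(axis=1, min_count=len(cols))
    out["SPQ_total"] = vals.sum(axis=1, min_count=len(SPQ_ITEMS))
    return out


def score_bag(responses: pd.DataFrame,
              item_map: dict[str, str] | None = None,
              reverse_keyed: frozenset[str] = DEFAULT_BAG_REVERSE) -> pd.DataFrame:
    """BAG subscale sums with reverse-keyed items recoded as 6 - response."""
    if item_map is None:
        item_map = DEFAULT_BAG_MAP
    _check_partition(item_map, BAG_ITEMS, "BAG")
    vals = responses[list(BAG_ITEMS)].astype(float)
    bad = ~(vals.isin([1, 2, 3, 4, 5]) | vals.isna())
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(f"BAG response out of range at row {r}, item {bad.columns[c]}")
    for it in reverse_keyed:
        vals[it] = 6.0 - vals[it]
    out = pd.DataFrame(index=responses.index)
    for sub in BAG_SUBSCALES:
        cols = [it for it, s in item_map.items() if s == sub]
        out[sub] = vals[cols].sum(axis=1, min_count=len(cols))
    return out


def score_gesture_task(ratings: pd.DataFrame) -> pd.DataFrame:
    """Congruence-sensitivity indices from the 8 condition-labeled ratings.

    Icon  = mean(CR) - mean(CU)  (concrete sentences, iconic gestures)
    Metaph = mean(AR) - mean(AU) (abstract sentences, metaphoric gestures)
    Both lie in [-6, +6] for 7-point ratings.
    """
    missing = set(VIDEO_CONDITIONS) - set(ratings.columns)
    if missing:
        raise ValueError(f"missing video conditions: {sorted(missing)}")
    vals = ratings[list(VIDEO_CONDITIONS)].astype(float)
    bad = ~(vals.isin(range(1, 8)) | vals.isna())
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(f"rating out of range at row {r}, item {bad.columns[c]}")

    def pair_mean(a: str, b: str) -> pd.Series:
        return vals[[a, b]].mean(axis=1, skipna=False)

    out = pd.DataFrame(index=ratings.index)
    out["Icon"] = pair_mean("CR1", "CR2") - pair_mean("CU1", "CU2")
    out["Metaph"] = pair_mean("AR1", "AR2") - pair_mean("AU1", "AU2")
    return out


def score_responses(
    responses: pd.DataFrame,
    spq_map: dict[str, str] | None = None,
    bag_map: dict[str, str] | None = None,
    bag_reverse: frozenset[str] = DEFAULT_BAG_REVERSE,
    apply_filter: bool = True,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Full scoring pass: attention filter, then all three instruments.

    Returns the subscale table (participant_id, 3 SPQ facets + total, 4 BAG
    subscales, 2 task indices) and the exclusion report.
    """
    if apply_filter:
        responses, report = apply_attention_filter(responses)
    else:
        report = ExclusionReport(n_input=len(responses), n_excluded=0)
    parts = [responses[["participant_id"]].reset_index(drop=True)] if \
        "participant_id" in responses.columns else []
    frames = [score_spq(responses, spq_map).reset_index(drop=True),
              score_bag(responses, bag_map, bag_reverse).reset_index(drop=True),
              score_gesture_task(responses).reset_index(drop=True)]
    table = pd.concat(parts + frames, axis=1)
    return table, report
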