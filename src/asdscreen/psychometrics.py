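"""Raw scale scoring and internal-consistency reliability.

Scores are raw sums over the subscale's items per informant; when both
mother and father reported, the child's score is the average of the two
informant sums.  Within an informant's report a missing item scores 0, but
an informant missing more than ``max_missing_frac`` of the subscale's items
(default 10%) is dropped for that scale.

Cronbach's alpha is computed on informant-averaged item scores pooled over
the sample at hand, with the conventional interpretation bands
(0.50/0.60/0.70/0.80/0.90: poor / questionable / acceptable / good /
excellent; closed-open intervals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .registry import SubscaleDefinition
from .simulate import ItemResponseTable

__all__ = [
    "ReliabilityResult",
    "score_scale",
    "informant_item_means",
    "cronbach_alpha",
    "alpha_band",
]

logger = logging.getLogger(__name__)

ALPHA_BAND_EDGES = (0.60, 0.70, 0.80, 0.90)
ALPHA_BAND_NAMES = ("poor", "questionable", "acceptable", "good", "excellent")


@dataclass(frozen=True)
class ReliabilityResult:
    alpha: float
    band: str
    k: int  # items
    n: int  # children


def alpha_band(alpha: float) -> str:
    """Interpretation band for an alpha value (values below 0.60 are
    reported as poor; the cited convention starts its poor band at 0.50)."""
    idx = int(np.searchsorted(ALPHA_BAND_EDGES, alpha, side="right"))
    return ALPHA_BAND_NAMES[idx]


def score_scale(
    table: ItemResponseTable,
    subscale: SubscaleDefinition,
    case_map: Mapping[str, bool],
    age_split: float = 12.0,
    max_missing_frac: float = 0.1,
) -> pd.DataFrame:
    """Per-child informant-averaged raw sum scores.

    Returns one row per child with columns ``child_id, score, group,
    is_case, gender, age_band, n_informants``.  ``case_map`` maps each
    primary-classification group to case/control status for the target
    disorder; groups not in the map are excluded (e.g. when a disorder
    group is removed from a control set).  ``age_band`` is ``"child"``
    for age < ``age_split`` else ``"adolescent"``.
    """
    if not subscale.item_ids:
        raise ValueError("cannot score an empty subscale")
    rows = table.responses[table.responses["item_id"].isin(subscale.item_ids)]
    k = len(subscale.item_ids)
    per_informant = rows.groupby(["child_id", "informant"], sort=False).agg(
        total=("score", "sum"), n_items=("score", "size")
    )
    # informants that answered at least (1 - max_missing_frac) of the items
    min_items = int(np.ceil((1.0 - max_missing_frac) * k))
    kept = per_informant[per_informant["n_items"] >= min_items]
    dropped = len(per_informant) - len(kept)
    if dropped:
        logger.warning(
            "%s: dropped %d informant report(s) missing more than %.0f%% of items",
            subscale.name, dropped, 100 * max_missing_frac,
        )
    per_child = kept.groupby(level="child_id").agg(
        score=("total", "mean"), n_informants=("total", "size")
    )
    out = per_child.reset_index().merge(table.children, on="child_id", how="left")
    lost = set(table.children["child_id"]) - set(out["child_id"])
    if lost:
        logger.warning(
            "%s: %d child(ren) excluded (no usable informant)", subscale.name, len(lost)
        )
    out = out[out["group"].isin(case_map.keys())].copy()
    out["is_case"] = out["group"].map(case_map).astype(bool)
    out["age_band"] = np.where(out["age"] < age_split, "child", "adolescent")
    return out[
        ["child_id", "score", "group", "is_case", "gender", "age_band", "n_informants"]
    ].reset_index(drop=True)


def informant_item_means(
    table: ItemResponseTable, item_ids: frozenset[int] | set[int]
) -> pd.DataFrame:
    """Children x items matrix of informant-averaged item scores (the input
    to :func:`cronbach_alpha`); children missing an item entirely get NaN
    and are dropped listwise by the alpha computation."""
    rows = table.responses[table.responses["item_id"].isin(item_ids)]
    return rows.pivot_table(index="child_id", columns="item_id", values="score",
                            aggfunc="mean")


def cronbach_alpha(item_matrix: pd.DataFrame | np.ndarray) -> ReliabilityResult:
    """Cronbach's alpha of a children x items score matrix.

    ``alpha = k/(k-1) * (1 - sum of item variances / variance of row sums)``
    with sample variances (denominator n-1).  Rows with any missing item are
    dropped listwise.
    """
    m = np.asarray(item_matrix, dtype=float)
    if m.ndim != 2:
        raise ValueError("item matrix must be 2-dimensional")
    m = m[~np.isnan(m).any(axis=1)]
    n, k = m.shape
    if k < 2:
        raise ValueError("alpha needs at least 2 items")
    if n < 3:
        raise ValueError("alpha needs at least 3 children with complete items")
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total-score variance is zero; alpha undefined")
    item_var = m.var(axis=0, ddof=1).sum()
    alpha = k / (k - 1) * (1.0 - item_var / total_var)
    return ReliabilityResult(float(alpha), alpha_band(alpha), k=k, n=n)
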