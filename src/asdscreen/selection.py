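"""Item-selection rules producing the two screening subscales.

Data-driven rule: an item enters the subscale when the ASD group scored
significantly higher than at least ``min_groups`` of the ``n_comparison_groups``
comparison groups (default 7 of 10, the "70% inclusion criterion") at the
configured significance level (default 0.001).

Clinician-expert rule: an item enters when at least ``min_votes`` of the
``n_clinicians`` clinicians (default 11 of 15, i.e. 73.33%) marked it as
characteristic for ASD.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .mixed_model import ComparisonVerdicts
from .registry import SubscaleDefinition

__all__ = ["SelectionConfig", "select_items_data_driven", "select_items_clinician",
           "vote_fraction"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    """Thresholds for both selection rules.

    ``min_fraction``, when given, is converted to the integer rule
    ``ceil(min_fraction * n_comparison_groups)``; an explicit ``min_groups``
    wins when both are set.
    """

    alpha: float = 0.001
    min_groups: int | None = 7
    n_comparison_groups: int = 10
    min_votes: int = 11
    n_clinicians: int = 15
    min_fraction: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.effective_min_groups <= self.n_comparison_groups:
            raise ValueError("min_groups must be in 1..n_comparison_groups")
        if not 0 < self.min_votes <= self.n_clinicians:
            raise ValueError("min_votes must be in 1..n_clinicians")

    @property
    def effective_min_groups(self) -> int:
        if self.min_groups is not None:
            return self.min_groups
        if self.min_fraction is None:
            raise ValueError("one of min_groups or min_fraction must be set")
        return math.ceil(self.min_fraction * self.n_comparison_groups)


def select_items_data_driven(
    verdicts: Iterable[ComparisonVerdicts],
    config: SelectionConfig = SelectionConfig(),
) -> SubscaleDefinition:
    """Apply the comparison-group voting rule to per-item verdicts.

    Items whose verdicts are missing simply cannot be selected; callers
    excluding non-converged fits should log them (this function logs the
    count of verdicts it received).
    """
    selected = {
        v.item_id
        for v in verdicts
        if v.n_significant >= config.effective_min_groups
    }
    return SubscaleDefinition("DataDriven", frozenset(selected))


def select_items_clinician(
    ratings: pd.DataFrame,
    config: SelectionConfig = SelectionConfig(),
) -> SubscaleDefinition:
    """Apply the clinician vote threshold to a complete 0/1 ratings matrix
    (clinician x item, columns are item ids)."""
    if ratings.isna().any().any():
        raise ValueError("clinician ratings matrix must be complete (no missing cells)")
    if not ratings.isin((0, 1)).all().all():
        raise ValueError("clinician ratings must be binary 0/1")
    votes = ratings.sum(axis=0)
    selected = frozenset(int(i) for i, v in votes.items() if v >= config.min_votes)
    return SubscaleDefinition("ClinicianExpert", selected)


def vote_fraction(config: SelectionConfig = SelectionConfig()) -> float:
    """The clinician vote threshold as a percentage, two decimals
    (11 of 15 -> 73.33)."""
    return round(100.0 * config.min_votes / config.n_clinicians, 2)
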