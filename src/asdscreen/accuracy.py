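"""ROC machinery for screening-scale validation.

AUC is the Mann-Whitney probability that a random case outscores a random
control, with ties counted one half.  Its standard error and 95% CI use the
DeLong structural-component variance.  Correlated curves (same cases and
controls, different scales) are compared with the DeLong paired z-test;
curves from independent samples with the Hanley-McNeil z-test using the
approximate variance with ``Q1 = A/(2-A)`` and ``Q2 = 2A^2/(1+A)``.

Cut-offs are constructed per gender x age-band stratum from the candidate
thresholds (midpoints between adjacent distinct observed scores plus +-inf)
with the screening convention ``score >= cutoff -> positive``:

* subclinical cut-off: the largest threshold whose sensitivity still
  reaches the target (default 80%);
* clinical cut-off: the threshold maximising Youden's J
  (sensitivity + specificity - 1), ties broken toward the lower threshold;
  minimising ``|sensitivity - specificity|`` is available behind a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROCResult",
    "CurveComparison",
    "CutoffTable",
    "auc",
    "delong_paired_test",
    "hanley_mcneil_se",
    "hanley_mcneil_independent_test",
    "candidate_thresholds",
    "sens_spec_at_cutoff",
    "choose_cutoffs",
]

logger = logging.getLogger(__name__)

AUC_BAND_EDGES = (0.70, 0.80, 0.90)
AUC_BAND_NAMES = ("poor", "fair", "good", "excellent")


@dataclass(frozen=True)
class ROCResult:
    auc: float
    se: float
    ci95: tuple[float, float]
    band: str
    n_cases: int
    n_controls: int


@dataclass(frozen=True)
class CurveComparison:
    method: str  # "delong_paired" | "hanley_mcneil_independent"
    auc_a: float
    auc_b: float
    z: float
    p: float
    verdict: str  # "a_better" | "b_better" | "equal"


@dataclass
class CutoffTable:
    """Stratified subclinical/clinical cut-offs with their operating points.

    ``strata`` has one row per (gender, age_band) with columns
    subclinical_cutoff, clinical_cutoff and the sensitivity/specificity at
    each; ``pooled`` aggregates cases/controls over strata after applying
    each stratum's own cut-offs.
    """

    strata: pd.DataFrame
    pooled: dict[str, float]


def _split_scores(scores: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    cases = scores.loc[scores["is_case"], "score"].to_numpy(float)
    controls = scores.loc[~scores["is_case"], "score"].to_numpy(float)
    return cases, controls


def _auc_band(a: float) -> str:
    return AUC_BAND_NAMES[int(np.searchsorted(AUC_BAND_EDGES, a, side="right"))]


def _structural_components(cases: np.ndarray, controls: np.ndarray):
    """DeLong placement values: V10 per case, V01 per control, and the AUC."""
    order = np.concatenate([cases, controls])
    m, n = cases.size, controls.size
    ranks_all = stats.rankdata(order)  # midranks handle ties
    ranks_cases = stats.rankdata(cases)
    ranks_controls = stats.rankdata(controls)
    v10 = (ranks_all[:m] - ranks_cases) / n
    v01 = 1.0 - (ranks_all[m:] - ranks_controls) / m
    return v10, v01, float(v10.mean())


def auc(scores: pd.DataFrame) -> ROCResult:
    """AUC with DeLong SE and Wald 95% CI from a scored table.

    ``scores`` needs columns ``score`` and boolean ``is_case``.
    """
    cases, controls = _split_scores(scores)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("AUC needs at least one case and one control")
    v10, v01, a = _structural_components(cases, controls)
    var = 0.0
    if cases.size > 1:
        var += v10.var(ddof=1) / cases.size
    if controls.size > 1:
        var += v01.var(ddof=1) / controls.size
    se = float(np.sqrt(var))
    half = 1.959963984540054 * se
    ci = (max(0.0, a - half), min(1.0, a + half))
    return ROCResult(a, se, ci, _auc_band(a), cases.size, controls.size)


def delong_paired_test(
    scores_a: pd.DataFrame, scores_b: pd.DataFrame, level: float = 0.05
) -> CurveComparison:
    """DeLong test for two correlated AUCs (same children, two scales).

    Both tables must contain the same children in the same case/control
    classes; rows are aligned on ``child_id`` when present.
    """
    if "child_id" in scores_a.columns and "child_id" in scores_b.columns:
        merged = scores_a.merge(
            scores_b, on="child_id", suffixes=("_a", "_b"), how="inner"
        )
        if len(merged) != len(scores_a) or len(merged) != len(scores_b):
            raise ValueError("paired comparison needs identical children")
        if not (merged["is_case_a"] == merged["is_case_b"]).all():
            raise ValueError("case/control membership differs between scales")
        is_case = merged["is_case_a"].to_numpy(bool)
        xa = merged["score_a"].to_numpy(float)
        xb = merged["score_b"].to_numpy(float)
    else:
        if len(scores_a) != len(scores_b):
            raise ValueError("paired comparison needs aligned rows")
        is_case = scores_a["is_case"].to_numpy(bool)
        if not np.array_equal(is_case, scores_b["is_case"].to_numpy(bool)):
            raise ValueError("case/control membership differs between scales")
        xa = scores_a["score"].to_numpy(float)
        xb = scores_b["score"].to_numpy(float)

    v10a, v01a, auc_a = _structural_components(xa[is_case], xa[~is_case])
    v10b, v01b, auc_b = _structural_components(xb[is_case], xb[~is_case])
    m, n = int(is_case.sum()), int((~is_case).sum())
    var = 0.0
    if m > 1:
        s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
        var += (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
    if n > 1:
        s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
        var += (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        if diff == 0:
            logger.warning("degenerate DeLong variance; reporting curves as equal")
            return CurveComparison("delong_paired", auc_a, auc_b, 0.0, 1.0, "equal")
        raise ValueError("zero DeLong variance with unequal AUCs")
    z = diff / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z)))
    return CurveComparison(
        "delong_paired", auc_a, auc_b, float(z), p, _verdict(auc_a, auc_b, p, level)
    )


def _verdict(auc_a: float, auc_b: float, p: float, level: float) -> str:
    if p >= level or auc_a == auc_b:
        return "equal"
    return "a_better" if auc_a > auc_b else "b_better"


def hanley_mcneil_se(a: float, n_cases: int, n_controls: int) -> float:
    """Hanley-McNeil approximate standard error of an AUC."""
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_cases - 1) * (q1 - a * a)
        + (n_controls - 1) * (q2 - a * a)
    ) / (n_cases * n_controls)
    return float(np.sqrt(max(var, 0.0)))


def hanley_mcneil_independent_test(
    roc_a: ROCResult, roc_b: ROCResult, level: float = 0.05
) -> CurveComparison:
    """z-test for two AUCs from independent samples (different case and
    control definitions), with Hanley-McNeil standard errors."""
    se_a = hanley_mcneil_se(roc_a.auc, roc_a.n_cases, roc_a.n_controls)
    se_b = hanley_mcneil_se(roc_b.auc, roc_b.n_cases, roc_b.n_controls)
    denom = np.hypot(se_a, se_b)
    if denom == 0:
        raise ValueError("both standard errors are zero")
    z = (roc_a.auc - roc_b.auc) / denom
    p = float(2.0 * stats.norm.sf(abs(z)))
    return CurveComparison(
        "hanley_mcneil_independent", roc_a.auc, roc_b.auc, float(z), p,
        _verdict(roc_a.auc, roc_b.auc, p, level),
    )


def candidate_thresholds(values: np.ndarray) -> np.ndarray:
    """Midpoints between adjacent distinct observed scores, plus +-inf."""
    distinct = np.unique(values)
    mids = (distinct[1:] + distinct[:-1]) / 2.0
    return np.concatenate([[-np.inf], mids, [np.inf]])


def sens_spec_at_cutoff(scores: pd.DataFrame, cutoff: float) -> tuple[float, float]:
    """(sensitivity, specificity) with the rule score >= cutoff -> positive."""
    cases, controls = _split_scores(scores)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("need at least one case and one control")
    sens = float(np.mean(cases >= cutoff))
    spec = float(np.mean(controls < cutoff))
    return sens, spec


def _pick_cutoffs(
    cases: np.ndarray, controls: np.ndarray,
    target_sensitivity: float, equilibrium: str,
) -> tuple[float, float]:
    thresholds = candidate_thresholds(np.concatenate([cases, controls]))
    sens = (cases[None, :] >= thresholds[:, None]).mean(axis=1)
    spec = (controls[None, :] < thresholds[:, None]).mean(axis=1)
    feasible = np.flatnonzero(sens >= target_sensitivity)
    subclinical = float(thresholds[feasible.max()])  # thresholds ascend
    if equilibrium == "youden":
        j = sens + spec - 1.0
        clinical = float(thresholds[int(np.argmax(j))])  # first max = lowest
    elif equilibrium == "balance":
        clinical = float(thresholds[int(np.argmin(np.abs(sens - spec)))])
    else:
        raise ValueError("equilibrium must be 'youden' or 'balance'")
    return subclinical, clinical


def choose_cutoffs(
    scores: pd.DataFrame,
    target_sensitivity: float = 0.80,
    equilibrium: str = "youden",
) -> CutoffTable:
    """Stratified subclinical/clinical cut-offs (gender x age band).

    Strata with no cases or no controls are omitted with a log message.
    The pooled sensitivity/specificity applies each stratum's own cut-offs
    and then pools the classification counts.
    """
    rows = []
    counts = {"sub_tp": 0, "sub_fn": 0, "sub_tn": 0, "sub_fp": 0,
              "clin_tp": 0, "clin_fn": 0, "clin_tn": 0, "clin_fp": 0}
    for (gender, band), stratum in scores.groupby(["gender", "age_band"], sort=True):
        cases, controls = _split_scores(stratum)
        if cases.size == 0 or controls.size == 0:
            logger.warning(
                "stratum (%s, %s) has no %s; omitted", gender, band,
                "cases" if cases.size == 0 else "controls",
            )
            continue
        sub, clin = _pick_cutoffs(cases, controls, target_sensitivity, equilibrium)
        sub_sens, sub_spec = sens_spec_at_cutoff(stratum, sub)
        clin_sens, clin_spec = sens_spec_at_cutoff(stratum, clin)
        rows.append({
            "gender": gender, "age_band": band,
            "n_cases": cases.size, "n_controls": controls.size,
            "subclinical_cutoff": sub, "subclinical_sensitivity": sub_sens,
            "subclinical_specificity": sub_spec,
            "clinical_cutoff": clin, "clinical_sensitivity": clin_sens,
            "clinical_specificity": clin_spec,
        })
        counts["sub_tp"] += int((cases >= sub).sum())
        counts["sub_fn"] += int((cases < sub).sum())
        counts["sub_tn"] += int((controls < sub).sum())
        counts["sub_fp"] += int((controls >= sub).sum())
        counts["clin_tp"] += int((cases >= clin).sum())
        counts["clin_fn"] += int((cases < clin).sum())
        counts["clin_tn"] += int((controls < clin).sum())
        counts["clin_fp"] += int((controls >= clin).sum())
    strata = pd.DataFrame(rows)
    pooled = {}
    if counts["sub_tp"] + counts["sub_fn"] > 0:
        pooled = {
            "subclinical_sensitivity": counts["sub_tp"] / (counts["sub_tp"] + counts["sub_fn"]),
            "subclinical_specificity": counts["sub_tn"] / (counts["sub_tn"] + counts["sub_fp"]),
            "clinical_sensitivity": counts["clin_tp"] / (counts["clin_tp"] + counts["clin_fn"]),
            "clinical_specificity": counts["clin_tn"] / (counts["clin_tn"] + counts["clin_fp"]),
        }
    return CutoffTable(strata, pooled)
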