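"""Synthetic multi-informant ordinal cohorts.

Emulates the structure of the study samples this pipeline targets: children
belong to one of eleven primary-classification groups (ASD, nine clinical
comparison groups, and a typically developing group); each child is rated by
up to two informants (mother/father, independently missing); each of the 120
items is scored 0/1/2.

Responses arise from a latent-Normal threshold model.  For child ``c``, item
``j``, informant ``i``::

    L = delta_j * 1[group = ASD, j planted]
        + age_slope * (age_c - mean age) + sex_shift * 1[girl]
        + u_c + eps_ic,
    u_c ~ N(0, tau^2),  eps_ic ~ N(0, sigma^2),
    score = #{thresholds strictly below L}.

The planted item set (with its latent shift ``delta``) is the ground truth
that item-selection recovery tests check against.  The latent intraclass
correlation between two informants of the same child is
``tau^2 / (tau^2 + sigma^2)``.

Default group proportions mirror the development sample of the target study
(ASD ~16% of the clinical subsample, ADHD the largest comparison group, a
small typically developing subsample); informant missingness defaults mirror
its mother/father return rates.  Effect sizes, variance components and
thresholds are the generator's own choices and are documented in the methods
note, not estimates from any empirical sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "COMPARISON_GROUPS",
    "CohortConfig",
    "ItemResponseTable",
    "default_group_sizes",
    "generate_cohort",
    "generate_clinician_ratings",
    "write_cohort",
    "read_cohort",
]

#: Primary-classification groups: ASD, nine clinical comparison groups, TD.
GROUPS = (
    "ASD",
    "ADHD",
    "Anxiety",
    "PTSD",
    "Affective",
    "OCD",
    "Behavioral",
    "NOS",
    "OtherDiagnosis",
    "NoDiagnosis",
    "TD",
)
COMPARISON_GROUPS = GROUPS[1:]

# Development-sample head counts (clinical subsample n=1625 plus TD n=41)
# used as default proportions.
_REFERENCE_SIZES = {
    "ASD": 270,
    "ADHD": 724,
    "Anxiety": 203,
    "PTSD": 91,
    "Affective": 61,
    "OCD": 56,
    "Behavioral": 34,
    "NOS": 52,
    "OtherDiagnosis": 69,
    "NoDiagnosis": 65,
    "TD": 41,
}

N_ITEMS = 120


def default_group_sizes(total: int = 1666) -> dict[str, int]:
    """Group sizes proportional to the development sample, scaled to ``total``.

    Largest-remainder rounding; every group is kept non-empty.
    """
    ref_total = sum(_REFERENCE_SIZES.values())
    raw = {g: total * n / ref_total for g, n in _REFERENCE_SIZES.items()}
    sizes = {g: max(1, int(np.floor(v))) for g, v in raw.items()}
    remainders = sorted(raw, key=lambda g: raw[g] - np.floor(raw[g]), reverse=True)
    i = 0
    while sum(sizes.values()) < total:
        sizes[remainders[i % len(remainders)]] += 1
        i += 1
    return sizes


@dataclass(frozen=True)
class CohortConfig:
    """Stated world of one simulated cohort (all latent-scale units)."""

    n_per_group: Mapping[str, int] = field(
        default_factory=lambda: default_group_sizes(1666)
    )
    age_range: tuple[float, float] = (6.0, 18.0)
    p_girl: float = 0.37
    mother_present_prob: float = 0.97
    father_present_prob: float = 0.78
    planted_items: frozenset[int] = frozenset()
    delta: float = 0.8
    tau: float = 0.7
    sigma: float = 0.7
    thresholds: tuple[float, float] = (0.8, 1.8)
    age_slope: float = -0.02
    sex_shift: float = -0.15
    n_items: int = N_ITEMS
    seed: int = 0
    #: selection needs ASD plus all ten comparison groups; reduced designs
    #: (method studies, unit fixtures) may opt out
    require_all_groups: bool = True

    @property
    def latent_icc(self) -> float:
        """Intraclass correlation of two informants' latent values."""
        return self.tau**2 / (self.tau**2 + self.sigma**2)

    def validate(self) -> None:
        for name in ("p_girl", "mother_present_prob", "father_present_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.thresholds[0] < self.thresholds[1]:
            raise ValueError("thresholds must be strictly increasing")
        if self.tau < 0 or self.sigma <= 0:
            raise ValueError("tau must be >= 0 and sigma > 0")
        if self.require_all_groups:
            missing = [g for g in GROUPS if self.n_per_group.get(g, 0) <= 0]
            if missing:
                raise ValueError(
                    "item selection needs all 10 comparison groups plus ASD; "
                    f"groups with no children: {missing}"
                )
        elif sum(self.n_per_group.values()) <= 0:
            raise ValueError("cohort must contain at least one child")
        bad = self.planted_items - set(range(1, self.n_items + 1))
        if bad:
            raise ValueError(f"planted items outside 1..{self.n_items}: {sorted(bad)}")

    def replace(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


@dataclass
class ItemResponseTable:
    """Long-format item responses plus the per-child covariate table.

    ``responses`` columns: child_id, informant ("mother"/"father"), item_id,
    score (0/1/2).  ``children`` columns: child_id, age, gender
    ("girl"/"boy"), group, subsample ("clinical"/"TD").
    """

    responses: pd.DataFrame
    children: pd.DataFrame

    RESPONSE_COLUMNS = ("child_id", "informant", "item_id", "score")
    CHILD_COLUMNS = ("child_id", "age", "gender", "group", "subsample")

    def validate(self) -> None:
        for col in self.RESPONSE_COLUMNS:
            if col not in self.responses.columns:
                raise ValueError(f"responses table missing column {col!r}")
        for col in self.CHILD_COLUMNS:
            if col not in self.children.columns:
                raise ValueError(f"children table missing column {col!r}")
        scores = self.responses["score"]
        if not scores.isin((0, 1, 2)).all():
            bad = sorted(scores[~scores.isin((0, 1, 2))].unique())
            raise ValueError(f"scores outside {{0,1,2}}: {bad}")
        keys = self.responses[["child_id", "informant", "item_id"]]
        if keys.duplicated().any():
            raise ValueError("(child_id, informant, item_id) rows must be unique")
        if self.children["child_id"].duplicated().any():
            raise ValueError("duplicate child_id in children table")
        unknown = set(self.responses["child_id"]) - set(self.children["child_id"])
        if unknown:
            raise ValueError(f"responses for unknown child_id: {sorted(unknown)[:5]}")


def generate_cohort(config: CohortConfig) -> tuple[ItemResponseTable, frozenset[int]]:
    """Draw one cohort under ``config``; returns the table and planted truth.

    Deterministic given ``config.seed`` (identical config implies an
    identical table).  Informants are dropped independently with the
    configured missingness; a child who would lose both informants keeps the
    mother so that every child has at least one informant.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    groups = [g for g in GROUPS if config.n_per_group.get(g, 0) > 0]
    counts = [int(config.n_per_group[g]) for g in groups]
    n_children = int(sum(counts))
    group = np.repeat(groups, counts)
    child_id = np.arange(1, n_children + 1)
    lo, hi = config.age_range
    age = rng.uniform(lo, hi, size=n_children)
    girl = rng.random(n_children) < config.p_girl
    u = rng.normal(0.0, config.tau, size=n_children)

    mother = rng.random(n_children) < config.mother_present_prob
    father = rng.random(n_children) < config.father_present_prob
    mother[~mother & ~father] = True  # guarantee >= 1 informant

    item_ids = np.arange(1, config.n_items + 1)
    planted = np.isin(item_ids, sorted(config.planted_items))
    is_asd = group == "ASD"
    # child x item latent mean
    shift = np.outer(is_asd, planted) * config.delta
    covar = config.age_slope * (age - age.mean()) + config.sex_shift * girl
    mean = shift + covar[:, None] + u[:, None]

    frames = []
    for informant, present in (("mother", mother), ("father", father)):
        eps = rng.normal(0.0, config.sigma, size=(n_children, config.n_items))
        latent = mean + eps
        score = (latent[:, :, None] > np.asarray(config.thresholds)).sum(axis=2)
        keep = np.flatnonzero(present)
        frames.append(
            pd.DataFrame(
                {
                    "child_id": np.repeat(child_id[keep], config.n_items),
                    "informant": informant,
                    "item_id": np.tile(item_ids, keep.size),
                    "score": score[keep].ravel().astype(np.int8),
                }
            )
        )
    responses = pd.concat(frames, ignore_index=True)
    children = pd.DataFrame(
        {
            "child_id": child_id,
            "age": age,
            "gender": np.where(girl, "girl", "boy"),
            "group": group,
            "subsample": np.where(group == "TD", "TD", "clinical"),
        }
    )
    table = ItemResponseTable(responses, children)
    table.validate()
    return table, frozenset(config.planted_items)


def generate_clinician_ratings(
    n_clinicians: int = 15,
    p_vote: Mapping[int, float] | float = 0.1,
    seed: int = 0,
    n_items: int = N_ITEMS,
) -> pd.DataFrame:
    """Independent Bernoulli clinician votes (clinician x item 0/1 matrix).

    ``p_vote`` is either a single probability applied to every item or a
    mapping item_id -> probability (unlisted items default to 0).
    """
    item_ids = np.arange(1, n_items + 1)
    if isinstance(p_vote, Mapping):
        p = np.array([float(p_vote.get(i, 0.0)) for i in item_ids])
    else:
        p = np.full(n_items, float(p_vote))
    if ((p < 0) | (p > 1)).any():
        raise ValueError("vote probabilities must be in [0, 1]")
    rng = np.random.default_rng(seed)
    votes = (rng.random((n_clinicians, n_items)) < p).astype(int)
    return pd.DataFrame(
        votes, index=pd.RangeIndex(1, n_clinicians + 1, name="clinician_id"),
        columns=pd.Index(item_ids, name="item_id"),
    )


def write_cohort(
    table: ItemResponseTable,
    outdir: str | Path,
    truth: frozenset[int] | None = None,
    config: CohortConfig | None = None,
) -> None:
    """Write responses.csv, children.csv and a truth.json sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.responses.to_csv(outdir / "responses.csv", index=False)
    table.children.to_csv(outdir / "children.csv", index=False)
    sidecar: dict = {"planted_items": sorted(truth or ())}
    if config is not None:
        sidecar["config"] = {
            "n_per_group": dict(config.n_per_group),
            "age_range": list(config.age_range),
            "p_girl": config.p_girl,
            "mother_present_prob": config.mother_present_prob,
            "father_present_prob": config.father_present_prob,
            "planted_items": sorted(config.planted_items),
            "delta": config.delta,
            "tau": config.tau,
            "sigma": config.sigma,
            "thresholds": list(config.thresholds),
            "age_slope": config.age_slope,
            "sex_shift": config.sex_shift,
            "n_items": config.n_items,
            "seed": config.seed,
        }
    with open(outdir / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=2)


def read_cohort(indir: str | Path) -> tuple[ItemResponseTable, frozenset[int]]:
    """Read a cohort written by :func:`write_cohort` (or user data in the
    same schema; truth.json is optional for ingested data)."""
    indir = Path(indir)
    responses = pd.read_csv(indir / "responses.csv")
    children = pd.read_csv(indir / "children.csv")
    table = ItemResponseTable(responses, children)
    table.validate()
    truth_path = indir / "truth.json"
    planted: frozenset[int] = frozenset()
    if truth_path.exists():
        with open(truth_path, encoding="utf-8") as fh:
            planted = frozenset(json.load(fh).get("planted_items", ()))
    return table, planted
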