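"""End-to-end orchestration: develop, validate, cross-validate, report.

The development stage fits the per-item mixed models on the development
cohort, applies both selection rules (data-driven voting over the group
comparisons, clinician vote threshold), and validates every configured
subscale on the development cohort: reliability, AUC with CI, stratified
subclinical/clinical cut-offs, and curve comparisons (DeLong paired within
the ASD-target family, Hanley-McNeil against the DSM-oriented subscales,
whose case/control definitions differ).

Cross-validation applies the frozen subscales and the development-derived
cut-offs to independent cohorts; nothing is re-selected or re-tuned
downstream of development (leakage guard).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import accuracy, mixed_model, psychometrics, registry, selection, simulate

__all__ = [
    "RunConfig",
    "ScaleValidation",
    "SampleReport",
    "DevelopmentResult",
    "run_development",
    "run_cross_validation",
    "validate_sample",
    "apply_frozen_cutoffs",
    "overlap_table",
    "write_report",
]

logger = logging.getLogger(__name__)

#: Subscales whose screening target is the ASD group (case = ASD,
#: control = everyone else, including the typically developing subsample).
ASD_TARGET_SUBSCALES = (
    "WithdrawnDepressed", "ThoughtProblems", "SocialProblems", "ASDProfile",
    "WTP", "Ooi", "So", "DataDriven", "ClinicianExpert",
)
#: DSM-oriented subscales and the generator group holding their target
#: disorder.  The simulated world has a single behavioral-disorders group;
#: it stands in for the ODD-related target, and the conduct-disorder target
#: has no group of its own (reported as unavailable, as in sparse samples).
DSM_TARGET_GROUP = {
    "Affective": "Affective",
    "Anxiety": "Anxiety",
    "ADH": "ADHD",
    "ODD": "Behavioral",
    "Conduct": None,
}

DEFAULT_SUBSCALES = ASD_TARGET_SUBSCALES + tuple(DSM_TARGET_GROUP)


@dataclass
class ScaleValidation:
    name: str
    scores: pd.DataFrame
    roc: accuracy.ROCResult
    reliability: psychometrics.ReliabilityResult | None
    cutoffs: accuracy.CutoffTable


@dataclass
class SampleReport:
    sample: str
    scales: dict[str, ScaleValidation]
    comparisons: pd.DataFrame


@dataclass
class DevelopmentResult:
    data_driven: registry.SubscaleDefinition
    clinician_expert: registry.SubscaleDefinition
    audit: pd.DataFrame
    report: SampleReport
    frozen_cutoffs: dict[str, accuracy.CutoffTable] = field(default_factory=dict)


@dataclass
class RunConfig:
    """Desk-scale study configuration (see ``RunConfig.from_yaml``)."""

    mode: str = "simulate"
    seed: int = 0
    outdir: Path = Path("asdscreen_out")
    development: simulate.CohortConfig | str | Path | None = None
    crossval: Sequence[simulate.CohortConfig | str | Path] = ()
    selection: selection.SelectionConfig = field(default_factory=selection.SelectionConfig)
    subscales: Sequence[str] = DEFAULT_SUBSCALES
    registry_path: str | Path | None = None
    clinician_p_selected: float = 0.95
    clinician_p_other: float = 0.10
    target_sensitivity: float = 0.80
    equilibrium: str = "youden"
    age_split: float = 12.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        seed = int(raw.get("seed", 0))
        seeds = derived_seeds(seed, 1 + len(raw.get("crossval", []) or []))
        kwargs: dict = {
            "mode": raw.get("mode", "simulate"),
            "seed": seed,
            "outdir": Path(raw.get("outdir", "asdscreen_out")),
            "registry_path": raw.get("registry"),
            "subscales": tuple(raw.get("subscales", DEFAULT_SUBSCALES)),
            "target_sensitivity": float(raw.get("target_sensitivity", 0.80)),
            "equilibrium": raw.get("equilibrium", "youden"),
            "age_split": float(raw.get("age_split", 12.0)),
        }
        if "selection" in raw:
            kwargs["selection"] = selection.SelectionConfig(**raw["selection"])
        clin = raw.get("clinician", {})
        kwargs["clinician_p_selected"] = float(clin.get("p_selected", 0.95))
        kwargs["clinician_p_other"] = float(clin.get("p_other", 0.10))
        if kwargs["mode"] == "simulate":
            kwargs["development"] = _cohort_config(raw.get("development", {}), seeds[0])
            kwargs["crossval"] = tuple(
                _cohort_config(c, s)
                for c, s in zip(raw.get("crossval", []) or [], seeds[1:])
            )
        else:
            kwargs["development"] = raw.get("development")
            kwargs["crossval"] = tuple(raw.get("crossval", []) or [])
        return cls(**kwargs)


def derived_seeds(root: int, n: int) -> list[int]:
    """Per-stage child seeds (< 2**31) from a single root seed."""
    ss = np.random.SeedSequence(root)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _cohort_config(raw: Mapping, seed: int) -> simulate.CohortConfig:
    cfg = simulate.CohortConfig(seed=seed)
    kwargs: dict = {"seed": seed}
    if "total" in raw:
        kwargs["n_per_group"] = simulate.default_group_sizes(int(raw["total"]))
    if "n_per_group" in raw:
        kwargs["n_per_group"] = dict(raw["n_per_group"])
    planted = raw.get("planted", "data_driven")
    if planted == "data_driven":
        _, subs = registry.load_registry()
        kwargs["planted_items"] = registry.get_subscale(subs, "DataDriven").item_ids
    elif planted:
        kwargs["planted_items"] = frozenset(int(i) for i in planted)
    for key in ("delta", "tau", "sigma", "p_girl", "mother_present_prob",
                "father_present_prob", "age_slope", "sex_shift"):
        if key in raw:
            kwargs[key] = float(raw[key])
    if "thresholds" in raw:
        kwargs["thresholds"] = tuple(float(t) for t in raw["thresholds"])
    return cfg.replace(**kwargs)


def _case_map(name: str, groups: Sequence[str]) -> Mapping[str, bool] | None:
    if name in ASD_TARGET_SUBSCALES:
        return {g: g == "ASD" for g in groups}
    target = DSM_TARGET_GROUP.get(name)
    if target is None or target not in groups:
        return None
    return {g: g == target for g in groups}


def validate_sample(
    table: simulate.ItemResponseTable,
    subscales: Mapping[str, registry.SubscaleDefinition],
    sample_name: str = "sample",
    target_sensitivity: float = 0.80,
    equilibrium: str = "youden",
    age_split: float = 12.0,
) -> SampleReport:
    """Score and validate every subscale on one cohort.

    Computes reliability, AUC and freshly derived stratified cut-offs, plus
    the curve-comparison matrix: DeLong paired tests within the ASD-target
    family (same cases/controls) and Hanley-McNeil tests against the
    DSM-oriented subscales (independent case/control definitions).
    """
    groups = list(pd.unique(table.children["group"]))
    scales: dict[str, ScaleValidation] = {}
    for name, sub in subscales.items():
        cmap = _case_map(name, groups)
        if cmap is None:
            logger.info("%s/%s: target group unavailable; skipped", sample_name, name)
            continue
        if not sub.item_ids:
            logger.info("%s/%s: empty subscale; skipped", sample_name, name)
            continue
        scores = psychometrics.score_scale(table, sub, cmap, age_split=age_split)
        try:
            rel = psychometrics.cronbach_alpha(
                psychometrics.informant_item_means(table, sub.item_ids)
            )
        except ValueError as exc:
            logger.warning("%s/%s: reliability unavailable (%s)", sample_name, name, exc)
            rel = None
        roc = accuracy.auc(scores)
        cut = accuracy.choose_cutoffs(scores, target_sensitivity, equilibrium)
        scales[name] = ScaleValidation(name, scores, roc, rel, cut)
    comparisons = _comparison_matrix(scales)
    return SampleReport(sample_name, scales, comparisons)


def _comparison_matrix(scales: Mapping[str, ScaleValidation]) -> pd.DataFrame:
    new_scales = [n for n in ("DataDriven", "ClinicianExpert") if n in scales]
    rows = []
    paired_done = set()
    for name_a in new_scales:
        for name_b in scales:
            if name_b == name_a:
                continue
            key = frozenset((name_a, name_b))
            if name_b in ASD_TARGET_SUBSCALES:
                if key in paired_done:
                    continue
                paired_done.add(key)
                cmp = accuracy.delong_paired_test(
                    scales[name_a].scores, scales[name_b].scores
                )
            else:
                cmp = accuracy.hanley_mcneil_independent_test(
                    scales[name_a].roc, scales[name_b].roc
                )
            rows.append({
                "scale_a": name_a, "scale_b": name_b, "method": cmp.method,
                "auc_a": cmp.auc_a, "auc_b": cmp.auc_b, "z": cmp.z, "p": cmp.p,
                "verdict": cmp.verdict,
            })
    return pd.DataFrame(rows)


def run_development(
    table: simulate.ItemResponseTable,
    clinician_ratings: pd.DataFrame,
    config: RunConfig = RunConfig(),
) -> DevelopmentResult:
    """Full development stage on one cohort (see module docstring)."""
    items, packaged = registry.load_registry(config.registry_path)
    fits = mixed_model.fit_all_items(table, reference_group="ASD")
    usable = [f for f in fits if f.converged]
    for f in fits:
        if not f.converged:
            logger.warning("item %d: fit did not converge; excluded", f.item_id)
    comparison_groups = tuple(
        g for g in sorted(pd.unique(table.children["group"])) if g != "ASD"
    )
    verdicts = [
        mixed_model.compare_to_groups(f, config.selection.alpha, comparison_groups)
        for f in usable
    ]
    data_driven = selection.select_items_data_driven(verdicts, config.selection)
    clinician_expert = selection.select_items_clinician(
        clinician_ratings, config.selection
    )
    audit = mixed_model.fits_to_frame(fits).merge(
        pd.DataFrame(
            {"item_id": [v.item_id for v in verdicts],
             "n_significant": [v.n_significant for v in verdicts],
             "selected": [v.item_id in data_driven.item_ids for v in verdicts]}
        ),
        on="item_id", how="left",
    )

    subscales = {name: registry.get_subscale(packaged, name)
                 for name in config.subscales
                 if name not in ("DataDriven", "ClinicianExpert")}
    subscales["DataDriven"] = data_driven
    subscales["ClinicianExpert"] = clinician_expert
    report = validate_sample(
        table, subscales, "development",
        config.target_sensitivity, config.equilibrium, config.age_split,
    )
    frozen = {name: sv.cutoffs for name, sv in report.scales.items()}
    return DevelopmentResult(data_driven, clinician_expert, audit, report, frozen)


def apply_frozen_cutoffs(
    scores: pd.DataFrame, cutoffs: accuracy.CutoffTable
) -> pd.DataFrame:
    """Sensitivity/specificity of development cut-offs on new scores,
    per stratum plus a pooled row (stratum cut-offs applied, then counts
    pooled).  Strata without a development cut-off are skipped."""
    rows = []
    pooled = {k: 0 for k in ("sub_tp", "sub_fn", "sub_tn", "sub_fp",
                             "clin_tp", "clin_fn", "clin_tn", "clin_fp")}
    for _, dev_row in cutoffs.strata.iterrows():
        stratum = scores[(scores["gender"] == dev_row["gender"]) &
                         (scores["age_band"] == dev_row["age_band"])]
        cases = stratum.loc[stratum["is_case"], "score"].to_numpy(float)
        controls = stratum.loc[~stratum["is_case"], "score"].to_numpy(float)
        if cases.size == 0 or controls.size == 0:
            logger.warning(
                "stratum (%s, %s): no cases or controls in new sample; skipped",
                dev_row["gender"], dev_row["age_band"],
            )
            continue
        sub, clin = dev_row["subclinical_cutoff"], dev_row["clinical_cutoff"]
        rows.append({
            "gender": dev_row["gender"], "age_band": dev_row["age_band"],
            "subclinical_cutoff": sub,
            "subclinical_sensitivity": float((cases >= sub).mean()),
            "subclinical_specificity": float((controls < sub).mean()),
            "clinical_cutoff": clin,
            "clinical_sensitivity": float((cases >= clin).mean()),
            "clinical_specificity": float((controls < clin).mean()),
        })
        pooled["sub_tp"] += int((cases >= sub).sum())
        pooled["sub_fn"] += int((cases < sub).sum())
        pooled["sub_tn"] += int((controls < sub).sum())
        pooled["sub_fp"] += int((controls >= sub).sum())
        pooled["clin_tp"] += int((cases >= clin).sum())
        pooled["clin_fn"] += int((cases < clin).sum())
        pooled["clin_tn"] += int((controls < clin).sum())
        pooled["clin_fp"] += int((controls >= clin).sum())
    out = pd.DataFrame(rows)
    if rows:
        out = pd.concat([out, pd.DataFrame([{
            "gender": "all", "age_band": "all",
            "subclinical_cutoff": np.nan,
            "subclinical_sensitivity": pooled["sub_tp"] / max(pooled["sub_tp"] + pooled["sub_fn"], 1),
            "subclinical_specificity": pooled["sub_tn"] / max(pooled["sub_tn"] + pooled["sub_fp"], 1),
            "clinical_cutoff": np.nan,
            "clinical_sensitivity": pooled["clin_tp"] / max(pooled["clin_tp"] + pooled["clin_fn"], 1),
            "clinical_specificity": pooled["clin_tn"] / max(pooled["clin_tn"] + pooled["clin_fp"], 1),
        }])], ignore_index=True)
    return out


def run_cross_validation(
    table: simulate.ItemResponseTable,
    subscales: Mapping[str, registry.SubscaleDefinition],
    frozen_cutoffs: Mapping[str, accuracy.CutoffTable],
    config: RunConfig = RunConfig(),
    sample_name: str = "crossval",
) -> tuple[SampleReport, dict[str, pd.DataFrame]]:
    """Validate frozen subscales on an independent cohort.

    Subscale membership and cut-offs come from development and are never
    re-derived here; the per-sample report carries AUCs, reliability and
    curve comparisons, and the returned mapping holds the operating points
    of the frozen cut-offs on the new sample.
    """
    report = validate_sample(
        table, dict(subscales), sample_name,
        config.target_sensitivity, config.equilibrium, config.age_split,
    )
    applied = {}
    for name, sv in report.scales.items():
        if name in frozen_cutoffs:
            applied[name] = apply_frozen_cutoffs(sv.scores, frozen_cutoffs[name])
    return report, applied


def overlap_table(
    subscales: Mapping[str, registry.SubscaleDefinition] | None = None,
) -> pd.DataFrame:
    """Pairwise item-overlap counts (defaults to the packaged registry)."""
    if subscales is None:
        _, packaged = registry.load_registry()
        subscales = {s.name: s for s in packaged}
    names = list(subscales)
    rows = []
    for a, b in itertools.combinations(names, 2):
        rows.append({
            "scale_a": a, "scale_b": b,
            "overlap": registry.item_overlap(subscales[a], subscales[b]),
        })
    return pd.DataFrame(rows)


def _accuracy_frame(report: SampleReport, applied: Mapping[str, pd.DataFrame] | None = None) -> pd.DataFrame:
    rows = []
    for name, sv in report.scales.items():
        rows.append({
            "sample": report.sample, "subscale": name, "stratum": "overall",
            "n_cases": sv.roc.n_cases, "n_controls": sv.roc.n_controls,
            "auc": sv.roc.auc, "auc_se": sv.roc.se,
            "auc_ci_low": sv.roc.ci95[0], "auc_ci_high": sv.roc.ci95[1],
            "auc_band": sv.roc.band,
            "alpha": sv.reliability.alpha if sv.reliability else np.nan,
            "alpha_band": sv.reliability.band if sv.reliability else "",
        })
        source = applied.get(name) if applied else (
            sv.cutoffs.strata if len(sv.cutoffs.strata) else None
        )
        if source is None:
            continue
        for _, r in source.iterrows():
            rows.append({
                "sample": report.sample, "subscale": name,
                "stratum": f"{r['gender']}/{r['age_band']}",
                "subclinical_cutoff": r.get("subclinical_cutoff", np.nan),
                "subclinical_sensitivity": r["subclinical_sensitivity"],
                "subclinical_specificity": r["subclinical_specificity"],
                "clinical_cutoff": r.get("clinical_cutoff", np.nan),
                "clinical_sensitivity": r["clinical_sensitivity"],
                "clinical_specificity": r["clinical_specificity"],
            })
    return pd.DataFrame(rows)


def write_report(
    outdir: str | Path,
    development: DevelopmentResult,
    crossval_reports: Sequence[tuple[SampleReport, Mapping[str, pd.DataFrame]]] = (),
) -> None:
    """Write the report bundle: accuracy, comparisons, audit, subscale and
    overlap tables as CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frames = [_accuracy_frame(development.report)]
    comp_frames = [development.report.comparisons.assign(sample=development.report.sample)]
    for report, applied in crossval_reports:
        frames.append(_accuracy_frame(report, applied))
        comp_frames.append(report.comparisons.assign(sample=report.sample))
    pd.concat(frames, ignore_index=True).to_csv(outdir / "accuracy.csv", index=False)
    pd.concat(comp_frames, ignore_index=True).to_csv(outdir / "comparisons.csv", index=False)
    development.audit.to_csv(outdir / "selection_audit.csv", index=False)
    pd.DataFrame({
        "subscale": ["DataDriven"] * len(development.data_driven.item_ids)
        + ["ClinicianExpert"] * len(development.clinician_expert.item_ids),
        "item_id": sorted(development.data_driven.item_ids)
        + sorted(development.clinician_expert.item_ids),
    }).to_csv(outdir / "selected_subscales.csv", index=False)
    overlap_table().to_csv(outdir / "overlap.csv", index=False)
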