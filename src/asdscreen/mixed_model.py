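"""Per-item informant-nested linear mixed models.

Each of the 120 items is analysed in its own two-level model: informant
reports (level 1) nested in children (level 2) via a child random intercept,

    score_ic = x_ic' beta + u_c + eps_ic,
    u_c ~ N(0, tau^2),  eps_ic ~ N(0, sigma^2),

with fixed effects for primary-classification group (categorical, ASD as the
reference), mean-centred age, and gender (girl = 1).  Ordinal 0/1/2 scores
are treated as numeric, matching the mean-comparison reading of the
selection rule.  Children with a single informant contribute through the
marginal covariance (no listwise deletion).

Estimation is REML (ML available) with the single variance ratio
``lambda = tau^2 / sigma^2`` profiled: for fixed lambda the GLS estimates
and the profiled residual variance are closed-form through per-child
sufficient statistics, so one item fit reduces to a bounded one-dimensional
optimisation with an explicit boundary check at lambda = 0.  Wald inference
uses a Normal reference (large-sample); this is a documented limitation for
small samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .simulate import ItemResponseTable

__all__ = [
    "ItemModelFit",
    "ComparisonVerdicts",
    "fit_item_model",
    "fit_all_items",
    "compare_to_groups",
    "fits_to_frame",
]

_LOG_LAMBDA_BOUNDS = (-12.0, 9.0)
_BOUNDARY_LAMBDA = 1e-8


@dataclass
class ItemModelFit:
    """REML estimates for one item's random-intercept model."""

    item_id: int
    params: pd.Series
    se: pd.Series
    pvals: pd.Series  # two-sided Wald p per group contrast
    tau2: float
    sigma2: float
    n_children: int
    n_rows: int
    converged: bool
    reference_group: str
    comparison_groups: tuple[str, ...]
    method: str = "reml"

    def contrast(self, group: str) -> float:
        """Fixed-effect contrast of ``group`` versus the reference group."""
        return float(self.params[f"group:{group}"])


@dataclass
class ComparisonVerdicts:
    """Directional significance verdicts: ASD above each comparison group."""

    item_id: int
    flags: dict[str, bool]
    inestimable: tuple[str, ...] = ()

    @property
    def n_significant(self) -> int:
        return int(sum(self.flags.values()))


class _SharedDesign:
    """Fixed-effect design and per-child aggregates shared across items.

    Rows must be sorted by child so per-child reductions are ``reduceat``
    over precomputed boundaries.
    """

    def __init__(self, X: np.ndarray, child_starts: np.ndarray, names: list[str]):
        self.X = X
        self.names = names
        self.n, self.p = X.shape
        self.child_starts = child_starts  # first row of each child block
        self.k = np.diff(np.append(child_starts, self.n))  # informants/child
        self.n_children = child_starts.size
        self.XtX = X.T @ X
        t = np.add.reduceat(X, child_starts, axis=0)  # per-child column sums
        self.t = t
        self.k_values = np.unique(self.k)
        self.A = {}  # k -> sum over children with k informants of t_i t_i'
        self.k_masks = {}
        for kv in self.k_values:
            mask = self.k == kv
            self.k_masks[kv] = mask
            self.A[kv] = t[mask].T @ t[mask]
        self.m = {kv: int(self.k_masks[kv].sum()) for kv in self.k_values}


def _build_design(
    table: ItemResponseTable, reference_group: str
) -> tuple[_SharedDesign, pd.DataFrame, tuple[str, ...]]:
    """Pivot to one row per (child, informant) and build the design matrix."""
    wide = table.responses.pivot_table(
        index=["child_id", "informant"], columns="item_id", values="score",
        aggfunc="first",
    )
    wide = wide.reset_index().merge(table.children, on="child_id", how="left")
    wide = wide.sort_values(["child_id", "informant"], kind="stable").reset_index(drop=True)

    groups = sorted(pd.unique(table.children["group"]))
    if reference_group not in groups:
        raise ValueError(f"reference group {reference_group!r} not present")
    comparison = tuple(g for g in groups if g != reference_group)

    n = len(wide)
    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    for g in comparison:
        cols.append((wide["group"] == g).to_numpy(float))
        names.append(f"group:{g}")
    age = wide["age"].to_numpy(float)
    if np.ptp(age) > 0:  # constant covariates are dropped (degenerate design)
        cols.append(age - age.mean())
        names.append("age")
    girl = (wide["gender"] == "girl").to_numpy(float)
    if 0.0 < girl.mean() < 1.0:
        cols.append(girl)
        names.append("gender")
    X = np.column_stack(cols)

    child_codes = wide["child_id"].to_numpy()
    starts = np.flatnonzero(np.r_[True, child_codes[1:] != child_codes[:-1]])
    return _SharedDesign(X, starts, names), wide, comparison


def _profile(design: _SharedDesign, stats_y, lam: float):
    """GLS quantities at a fixed variance ratio ``lam``.

    Returns (beta, XtVX, rVr, logdet_V, logdet_XtVX) for V* = I + lam ZZ'.
    """
    Xty, yty, B, Sw2 = stats_y
    XtVX = design.XtX.copy()
    XtVy = Xty.copy()
    yVy = yty
    logdet_V = 0.0
    for kv in design.k_values:
        c = lam / (1.0 + lam * kv)
        XtVX -= c * design.A[kv]
        XtVy = XtVy - c * B[kv]
        yVy -= c * Sw2[kv]
        logdet_V += design.m[kv] * np.log1p(lam * kv)
    try:
        beta = np.linalg.solve(XtVX, XtVy)
        sign, logdet_X = np.linalg.slogdet(XtVX)
    except np.linalg.LinAlgError:
        return None
    if sign <= 0:
        return None
    rVr = yVy - beta @ XtVy
    return beta, XtVX, float(rVr), float(logdet_V), float(logdet_X)


def _neg2_reml(design: _SharedDesign, stats_y, lam: float, reml: bool) -> float:
    prof = _profile(design, stats_y, lam)
    if prof is None:
        return np.inf
    _, _, rVr, logdet_V, logdet_X = prof
    if rVr <= 0:
        return np.inf
    if reml:
        return (design.n - design.p) * np.log(rVr) + logdet_V + logdet_X
    return design.n * np.log(rVr) + logdet_V


def _fit_one(
    design: _SharedDesign, y: np.ndarray, item_id: int,
    reference_group: str, comparison: tuple[str, ...], reml: bool,
) -> ItemModelFit:
    Xty = design.X.T @ y
    yty = float(y @ y)
    w = np.add.reduceat(y, design.child_starts)
    B = {kv: design.t[design.k_masks[kv]].T @ w[design.k_masks[kv]]
         for kv in design.k_values}
    Sw2 = {kv: float(w[design.k_masks[kv]] @ w[design.k_masks[kv]])
           for kv in design.k_values}
    stats_y = (Xty, yty, B, Sw2)

    converged = True
    if np.all(design.k == 1):
        # no within-child replication anywhere: the variance ratio is
        # unidentified and the criterion is flat; fall back to tau2 = 0
        warnings.warn(
            f"item {item_id}: no child has two informants; tau2 set to 0",
            stacklevel=3,
        )
        lam_hat = 0.0
    else:
        obj = lambda u: _neg2_reml(design, stats_y, np.exp(u), reml)
        res = optimize.minimize_scalar(
            obj, bounds=_LOG_LAMBDA_BOUNDS, method="bounded",
            options={"xatol": 1e-10},
        )
        converged = bool(res.success) and np.isfinite(res.fun)
        lam_hat = float(np.exp(res.x))
        if _neg2_reml(design, stats_y, 0.0, reml) <= res.fun:
            lam_hat = 0.0
        elif lam_hat < _BOUNDARY_LAMBDA:
            lam_hat = 0.0

    prof = _profile(design, stats_y, lam_hat)
    if prof is None:
        converged = False
        prof = _profile(design, stats_y, 0.0)
        lam_hat = 0.0
    beta, XtVX, rVr, _, _ = prof
    dof = design.n - design.p if reml else design.n
    sigma2 = max(rVr / dof, np.finfo(float).tiny)
    tau2 = lam_hat * sigma2
    cov = sigma2 * np.linalg.inv(XtVX)
    se = np.sqrt(np.diag(cov))
    params = pd.Series(beta, index=design.names)
    se_s = pd.Series(se, index=design.names)
    zstats = params / se_s
    contrast_names = [f"group:{g}" for g in comparison]
    pvals = pd.Series(
        2.0 * stats.norm.sf(np.abs(zstats[contrast_names].to_numpy())),
        index=comparison,
    )
    return ItemModelFit(
        item_id=item_id, params=params, se=se_s, pvals=pvals,
        tau2=float(tau2), sigma2=float(sigma2),
        n_children=design.n_children, n_rows=design.n,
        converged=converged, reference_group=reference_group,
        comparison_groups=comparison, method="reml" if reml else "ml",
    )


def fit_all_items(
    table: ItemResponseTable,
    item_ids: list[int] | None = None,
    reference_group: str = "ASD",
    reml: bool = True,
) -> list[ItemModelFit]:
    """Fit the random-intercept model for every requested item.

    The fixed-effect design (group dummies, centred age, gender) is shared
    across items, so per-item work reduces to per-child sufficient
    statistics plus a one-dimensional REML profile.  Items with missing
    scores for some informant rows are refit on their complete rows.
    """
    design, wide, comparison = _build_design(table, reference_group)
    if item_ids is None:
        item_ids = sorted(c for c in wide.columns if isinstance(c, (int, np.integer)))
    fits = []
    for item_id in item_ids:
        if item_id not in wide.columns:
            raise KeyError(f"item {item_id} not present in the response table")
        y = wide[item_id].to_numpy(float)
        if np.isnan(y).any():
            fits.append(_fit_item_subset(wide, y, item_id, reference_group, reml))
        else:
            fits.append(_fit_one(design, y, item_id, reference_group, comparison, reml))
    return fits


def _fit_item_subset(wide, y, item_id, reference_group, reml) -> ItemModelFit:
    """Fallback for an item with missing rows: rebuild the design on the
    complete rows only (all available data, no listwise deletion of
    children)."""
    keep = ~np.isnan(y)
    sub_children_ids = wide.loc[keep, "child_id"].unique()
    responses = wide.loc[keep, ["child_id", "informant", item_id]].rename(
        columns={item_id: "score"}
    )
    responses["item_id"] = item_id
    child_cols = ["child_id", "age", "gender", "group", "subsample"]
    children = (
        wide.loc[wide["child_id"].isin(sub_children_ids), child_cols]
        .drop_duplicates("child_id")
        .reset_index(drop=True)
    )
    sub = ItemResponseTable(responses.reset_index(drop=True), children)
    design, sub_wide, comparison = _build_design(sub, reference_group)
    y_sub = sub_wide[item_id].to_numpy(float)
    return _fit_one(design, y_sub, item_id, reference_group, comparison, reml)


def fit_item_model(
    table: ItemResponseTable,
    item_id: int,
    reference_group: str = "ASD",
    reml: bool = True,
) -> ItemModelFit:
    """Fit the model for a single item (see :func:`fit_all_items`)."""
    return fit_all_items(table, [item_id], reference_group, reml)[0]


def compare_to_groups(
    fit: ItemModelFit,
    alpha: float = 0.001,
    groups: tuple[str, ...] | None = None,
) -> ComparisonVerdicts:
    """ASD-versus-group verdicts for one fitted item.

    A group's flag is true iff the two-sided Wald p-value of its contrast is
    below ``alpha`` AND the fitted contrast indicates the reference (ASD)
    group scoring higher (negative group-minus-ASD coefficient).  Groups
    requested but absent from the fit are inestimable: flag false, reported
    in ``inestimable``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if groups is None:
        groups = fit.comparison_groups
    flags: dict[str, bool] = {}
    inestimable = []
    for g in groups:
        if g not in fit.pvals.index or not np.isfinite(fit.pvals[g]):
            flags[g] = False
            inestimable.append(g)
            continue
        flags[g] = bool(fit.pvals[g] < alpha and fit.contrast(g) < 0)
    return ComparisonVerdicts(fit.item_id, flags, tuple(inestimable))


def fits_to_frame(fits: list[ItemModelFit]) -> pd.DataFrame:
    """Flatten fits into one row per item (audit-trail CSV schema)."""
    rows = []
    for f in fits:
        row: dict = {
            "item_id": f.item_id, "tau2": f.tau2, "sigma2": f.sigma2,
            "n_children": f.n_children, "n_rows": f.n_rows,
            "converged": f.converged, "method": f.method,
        }
        for name, val in f.params.items():
            row[f"beta_{name}"] = val
        for name, val in f.se.items():
            row[f"se_{name}"] = val
        for g, p in f.pvals.items():
            row[f"pval_{g}"] = p
        rows.append(row)
    return pd.DataFrame(rows)
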