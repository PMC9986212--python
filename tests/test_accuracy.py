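"""ROC machinery: brute-force oracles, symmetry properties, cut-off scans."""

import numpy as np
import pandas as pd
import pytest
from asdscreen import accuracy
from asdscreen.accuracy import (
    auc,
    candidate_thresholds,
    choose_cutoffs,
    delong_paired_test,
    hanley_mcneil_independent_test,
    hanley_mcneil_se,
    sens_spec_at_cutoff,
)


def brute_auc(cases, controls):
    wins = sum(
        1.0 if c > d else (0.5 if c == d else 0.0)
        for c in cases for d in controls
    )
    return wins / (len(cases) * len(controls))


def test_auc_tied_pair_example(make_scores):
    r = auc(make_scores([2, 3], [1, 2]))
    assert r.auc == pytest.approx(0.875)  # (1 + 0.5 + 1 + 1) / 4


def test_auc_separated_and_identical(make_scores):
    assert auc(make_scores([5, 6], [1, 2])).auc == 1.0
    assert auc(make_scores([1, 2, 3], [1, 2, 3])).auc == 0.5


def test_auc_single_class_rejected(make_scores):
    with pytest.raises(ValueError):
        auc(make_scores([1, 2], []))


def test_auc_label_negation_symmetry(make_scores):
    rng = np.random.default_rng(0)
    for _ in range(20):
        cases = rng.integers(0, 10, rng.integers(2, 15))
        controls = rng.integers(0, 10, rng.integers(2, 15))
        a = auc(make_scores(cases, controls)).auc
        b = auc(make_scores(-cases, -controls)).auc
        assert a + b == pytest.approx(1.0)


def test_auc_matches_bruteforce_random_instances(make_scores):
    rng = np.random.default_rng(1)
    for _ in range(300):
        cases = rng.integers(0, 6, rng.integers(1, 12))
        controls = rng.integers(0, 6, rng.integers(1, 12))
        r = auc(make_scores(cases, controls))
        assert r.auc == pytest.approx(brute_auc(cases, controls), abs=1e-12)


def test_auc_band_cutpoints(make_scores):
    # band is a function of the AUC value at 0.70/0.80/0.90
    assert accuracy._auc_band(0.69) == "poor"
    assert accuracy._auc_band(0.70) == "fair"
    assert accuracy._auc_band(0.80) == "good"
    assert accuracy._auc_band(0.90) == "excellent"


def test_delong_variance_shrinks_with_n(make_scores):
    rng = np.random.default_rng(2)
    ses = []
    for n in (50, 200, 800):
        cases = rng.normal(1, 1, n)
        controls = rng.normal(0, 1, n)
        ses.append(auc(make_scores(cases, controls)).se)
    assert ses[0] > ses[1] > ses[2] > 0
    # O(1/sqrt(n)) scaling within a loose band
    assert ses[0] / ses[2] == pytest.approx(4.0, rel=0.5)


def test_delong_self_comparison(make_scores):
    s = make_scores([3, 4, 5], [1, 2, 3])
    c = delong_paired_test(s, s)
    assert c.z == 0.0 and c.p == 1.0 and c.verdict == "equal"


def test_delong_antisymmetry(make_scores):
    rng = np.random.default_rng(3)
    n = 30
    latent = rng.normal(size=2 * n) + np.r_[np.ones(n), np.zeros(n)]
    sa = make_scores(latent[:n] + rng.normal(0, 0.5, n),
                     latent[n:] + rng.normal(0, 0.5, n))
    sb = make_scores(latent[:n] + rng.normal(0, 0.8, n),
                     latent[n:] + rng.normal(0, 0.8, n))
    ab = delong_paired_test(sa, sb)
    ba = delong_paired_test(sb, sa)
    assert ab.z == pytest.approx(-ba.z)
    assert ab.p == pytest.approx(ba.p)


def test_delong_requires_same_membership(make_scores):
    sa = make_scores([1, 2], [3, 4])
    sb = make_scores([1, 2, 3], [4])
    sb["child_id"] = sa["child_id"].to_numpy()
    with pytest.raises(ValueError, match="membership"):
        delong_paired_test(sa, sb)


def test_delong_z_matches_bootstrap_oracle(make_scores):
    """DeLong z against a stratified-bootstrap z of the AUC difference."""
    rng = np.random.default_rng(4)
    B = 20000
    for _ in range(6):
        m = n = 25
        z_lat = rng.normal(size=m + n) + np.r_[np.full(m, 0.8), np.zeros(n)]
        xa = z_lat + rng.normal(0, 0.6, m + n)
        xb = z_lat + rng.normal(0, 0.9, m + n)
        sa = make_scores(xa[:m], xa[m:])
        sb = make_scores(xb[:m], xb[m:])
        res = delong_paired_test(sa, sb)
        ci = rng.integers(0, m, (B, m))
        di = rng.integers(0, n, (B, n)) + m
        diff = np.empty(B)
        for lo in range(0, B, 2000):  # chunked vectorised bootstrap
            hi = min(lo + 2000, B)
            ca, da = xa[ci[lo:hi]][:, :, None], xa[di[lo:hi]][:, None, :]
            cb, db = xb[ci[lo:hi]][:, :, None], xb[di[lo:hi]][:, None, :]
            auc_a = ((ca > da) + 0.5 * (ca == da)).mean(axis=(1, 2))
            auc_b = ((cb > db) + 0.5 * (cb == db)).mean(axis=(1, 2))
            diff[lo:hi] = auc_a - auc_b
        z_boot = (res.auc_a - res.auc_b) / diff.std(ddof=1)
        assert res.z == pytest.approx(z_boot, abs=0.6)


def test_hanley_mcneil_se_closed_form():
    a, m, n = 0.80, 50, 50
    q1 = a / (2 - a)
    q2 = 2 * a * a / (1 + a)
    var = (a * (1 - a) + (m - 1) * (q1 - a * a) + (n - 1) * (q2 - a * a)) / (m * n)
    assert hanley_mcneil_se(a, m, n) == pytest.approx(np.sqrt(var), abs=1e-15)


def test_hanley_mcneil_equal_aucs_z_zero():
    r = accuracy.ROCResult(0.75, 0.03, (0.69, 0.81), "fair", 50, 60)
    c = hanley_mcneil_independent_test(r, r)
    assert c.z == 0.0 and c.verdict == "equal"


def test_hanley_mcneil_z_monotone_in_auc_gap():
    base = accuracy.ROCResult(0.70, 0.03, (0.64, 0.76), "fair", 50, 50)
    zs = []
    for a in (0.72, 0.76, 0.82, 0.88):
        other = accuracy.ROCResult(a, 0.03, (a - 0.06, a + 0.06), "fair", 50, 50)
        zs.append(abs(hanley_mcneil_independent_test(other, base).z))
    assert zs == sorted(zs) and zs[0] > 0


@pytest.mark.parametrize(
    "cutoff, expected",
    [(-np.inf, (1.0, 0.0)), (np.inf, (0.0, 1.0)), (2.0, (1.0, 0.5))],
)
def test_sens_spec_examples(make_scores, cutoff, expected):
    s = make_scores([2, 3], [1, 2])
    assert sens_spec_at_cutoff(s, cutoff) == pytest.approx(expected)


def scan_oracle(cases, controls, target, equilibrium="youden"):
    """Exhaustive threshold scan with the stated rules."""
    thresholds = candidate_thresholds(np.concatenate([cases, controls]))
    best_sub, best_clin, best_j, best_bal = None, None, -np.inf, np.inf
    for t in thresholds:
        sens = np.mean(cases >= t)
        spec = np.mean(controls < t)
        if sens >= target and (best_sub is None or t > best_sub):
            best_sub = t
        if equilibrium == "youden":
            j = sens + spec - 1
            if j > best_j:
                best_j, best_clin = j, t
        else:
            bal = abs(sens - spec)
            if bal < best_bal:
                best_bal, best_clin = bal, t
    return best_sub, best_clin


def test_cutoffs_match_exhaustive_scan(make_scores):
    rng = np.random.default_rng(5)
    for _ in range(200):
        cases = rng.integers(0, 12, rng.integers(2, 20)).astype(float)
        controls = rng.integers(0, 12, rng.integers(2, 20)).astype(float)
        ct = choose_cutoffs(make_scores(cases, controls))
        row = ct.strata.iloc[0]
        sub_o, clin_o = scan_oracle(cases, controls, 0.80)
        assert row["subclinical_cutoff"] == sub_o
        assert row["clinical_cutoff"] == clin_o


def test_cutoffs_example_and_reported_rates_consistent(make_scores):
    s = make_scores([3, 4, 5, 6, 7], [1, 2, 3, 4, 5])
    ct = choose_cutoffs(s)
    row = ct.strata.iloc[0]
    sub_o, clin_o = scan_oracle(
        np.array([3, 4, 5, 6, 7.0]), np.array([1, 2, 3, 4, 5.0]), 0.80
    )
    assert row["subclinical_cutoff"] == sub_o and row["clinical_cutoff"] == clin_o
    # reported sensitivity/specificity match an exact recomputation
    assert (row["subclinical_sensitivity"], row["subclinical_specificity"]) == (
        pytest.approx(sens_spec_at_cutoff(s, row["subclinical_cutoff"]))
    )
    assert (row["clinical_sensitivity"], row["clinical_specificity"]) == (
        pytest.approx(sens_spec_at_cutoff(s, row["clinical_cutoff"]))
    )


def test_subclinical_cutoff_monotone_in_target(make_scores):
    rng = np.random.default_rng(6)
    cases = rng.integers(0, 10, 25).astype(float)
    controls = rng.integers(0, 10, 25).astype(float)
    s = make_scores(cases, controls)
    prev = np.inf
    for target in (0.5, 0.6, 0.7, 0.8, 0.9, 1.0):
        cut = choose_cutoffs(s, target_sensitivity=target).strata.iloc[0]
        assert cut["subclinical_cutoff"] <= prev
        prev = cut["subclinical_cutoff"]


def test_cutoffs_invariant_under_monotone_transform(make_scores):
    rng = np.random.default_rng(7)
    cases = rng.normal(1, 1, 30)
    controls = rng.normal(0, 1, 30)
    base = choose_cutoffs(make_scores(cases, controls)).strata.iloc[0]
    warped = choose_cutoffs(
        make_scores(np.exp(cases), np.exp(controls))
    ).strata.iloc[0]
    for col in (
        "subclinical_sensitivity", "subclinical_specificity",
        "clinical_sensitivity", "clinical_specificity",
    ):
        assert base[col] == pytest.approx(warped[col])


def test_cutoffs_stratified_and_pooled(make_scores):
    rng = np.random.default_rng(8)
    frames = []
    for gender in ("girl", "boy"):
        for band in ("child", "adolescent"):
            f = make_scores(
                rng.normal(2, 1, 20), rng.normal(0, 1, 20), gender, band
            )
            frames.append(f)
    s = pd.concat(frames, ignore_index=True)
    s["child_id"] = np.arange(len(s))
    ct = choose_cutoffs(s)
    assert len(ct.strata) == 4
    assert set(ct.pooled) == {
        "subclinical_sensitivity", "subclinical_specificity",
        "clinical_sensitivity", "clinical_specificity",
    }
    assert ct.pooled["subclinical_sensitivity"] >= 0.8 - 1e-12


def test_empty_stratum_omitted(make_scores, caplog):
    s = pd.concat(
        [
            make_scores([3, 4], [1, 2], "girl", "child"),
            make_scores([5, 6], [], "boy", "child"),  # no controls
        ],
        ignore_index=True,
    )
    ct = choose_cutoffs(s)
    assert len(ct.strata) == 1
    assert ct.strata.iloc[0]["gender"] == "girl"


def test_perfect_separation_reaches_unit_rates(make_scores):
    ct = choose_cutoffs(make_scores([10, 11, 12], [1, 2, 3]))
    row = ct.strata.iloc[0]
    assert row["clinical_sensitivity"] == 1.0
    assert row["clinical_specificity"] == 1.0
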