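"""Exact recurrence statistics and ddCt relative quantification."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from meningioma_subgroups import (
    ConfigurationError,
    ContingencyTable2x2,
    CtTable,
    InsufficientDataError,
    SimConfig,
    ddct_fold_change,
    fisher_exact_two_tailed,
    mann_whitney_exact,
    recurrence_summary,
    simulate_cohort,
)


def fisher_enumeration_oracle(a, b, c, d):
    """Sum of hypergeometric probabilities of tables at least as improbable
    as the observed one, enumerated with binomial coefficients only."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    denom = math.comb(n, c1)

    def prob(x):
        return math.comb(r1, x) * math.comb(r2, c1 - x) / denom

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = prob(a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def mw_enumeration_oracle(x, y):
    """Two-sided exact Mann-Whitney p via the U statistic counted directly
    from values (pairs won + half ties), over all group assignments."""
    pooled = list(x) + list(y)
    nx = len(x)
    n = len(pooled)

    def u_stat(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(n) if i not in set(idx)]
        u = 0.0
        for xi in xs:
            for yj in ys:
                u += (xi > yj) + 0.5 * (xi == yj)
        return u

    mu = nx * (n - nx) / 2.0
    u_obs = u_stat(range(nx))
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(n), nx):
        total += 1
        hits += abs(u_stat(idx) - mu) >= dev - 1e-12
    return hits / total


# --------------------------------------------------------------------------
# Fisher exact
# --------------------------------------------------------------------------

def test_fisher_reported_recurrence_table():
    """benignA 0/9 vs benignB 6/11 gives the reported two-tailed p of 0.014."""
    p = fisher_exact_two_tailed(ContingencyTable2x2(0, 9, 6, 5))
    assert round(p, 3) == 0.014
    assert p == pytest.approx(0.0141, abs=5e-5)


def test_fisher_symmetric_balanced_table():
    assert fisher_exact_two_tailed(ContingencyTable2x2(1, 1, 1, 1)) == 1.0


def test_fisher_zero_margin_single_table():
    assert fisher_exact_two_tailed(ContingencyTable2x2(0, 5, 0, 7)) == 1.0


def test_fisher_matches_enumeration_oracle_exhaustively():
    """All 2x2 tables with n <= 12 plus random tables with n <= 30."""
    for n in range(1, 13):
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    d = n - a - b - c
                    t = ContingencyTable2x2(a, b, c, d)
                    assert fisher_exact_two_tailed(t) == pytest.approx(
                        fisher_enumeration_oracle(a, b, c, d), abs=1e-9
                    )
    rng = np.random.default_rng(77)
    for _ in range(200):
        a, b, c, d = rng.integers(0, 8, size=4)
        if a + b + c + d == 0:
            continue
        t = ContingencyTable2x2(int(a), int(b), int(c), int(d))
        assert fisher_exact_two_tailed(t) == pytest.approx(
            fisher_enumeration_oracle(int(a), int(b), int(c), int(d)), abs=1e-9
        )


def test_fisher_invariant_to_row_and_column_swaps():
    rng = np.random.default_rng(11)
    for _ in range(50):
        a, b, c, d = (int(v) for v in rng.integers(0, 10, size=4))
        if a + b + c + d == 0:
            continue
        p = fisher_exact_two_tailed(ContingencyTable2x2(a, b, c, d))
        assert fisher_exact_two_tailed(ContingencyTable2x2(c, d, a, b)) == pytest.approx(p, abs=1e-12)
        assert fisher_exact_two_tailed(ContingencyTable2x2(b, a, d, c)) == pytest.approx(p, abs=1e-12)


def test_contingency_rejects_negative_counts():
    with pytest.raises(ConfigurationError):
        ContingencyTable2x2(-1, 2, 3, 4)


# --------------------------------------------------------------------------
# recurrence summary
# --------------------------------------------------------------------------

def test_recurrence_summary_reported_counts():
    labels = {f"a{i}": "benignA" for i in range(9)}
    labels |= {f"b{i}": "benignB" for i in range(11)}
    labels |= {f"t{i}": "atypical" for i in range(8)}
    outcomes = {s: False for s in labels}
    for i in range(6):
        outcomes[f"b{i}"] = True
    for i in range(7):
        outcomes[f"t{i}"] = True
    summary = recurrence_summary(labels, outcomes)
    assert summary.table == ContingencyTable2x2(0, 9, 6, 5)
    assert round(summary.p_value, 3) == 0.014
    assert summary.per_group.loc["benignB", "rate"] == pytest.approx(6 / 11)


def test_recurrence_summary_no_events_p_one():
    labels = {"a1": "benignA", "a2": "benignA", "b1": "benignB", "b2": "benignB"}
    outcomes = {s: False for s in labels}
    with pytest.warns(UserWarning):  # empty atypical group flagged
        summary = recurrence_summary(labels, outcomes)
    assert summary.p_value == 1.0
    assert math.isnan(summary.per_group.loc["atypical", "rate"])


def test_recurrence_summary_missing_outcome_rejected():
    with pytest.raises(ConfigurationError):
        recurrence_summary({"s": "benignA"}, {})


def test_recurrence_rates_match_planted_probabilities():
    cfg = SimConfig(
        n_benignA=500, n_benignB=500, n_atypical=14, seed=3,
        spectrum_points=1024, n_probes=10, n_planted_de=4,
    )
    bundle = simulate_cohort(cfg)
    labels = dict(bundle.true_labels)
    outcomes = {s.sample_id: s.recurrence_4y for s in bundle.samples}
    summary = recurrence_summary(labels, outcomes)
    for group in ("benignA", "benignB"):
        p = cfg.recur_prob[group]
        n = summary.per_group.loc[group, "n"]
        se = math.sqrt(p * (1 - p) / n)
        assert abs(summary.per_group.loc[group, "rate"] - p) <= 3 * se + 1e-12


# --------------------------------------------------------------------------
# ddCt
# --------------------------------------------------------------------------

def _ct_table(rows):
    return CtTable(pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"]), "GAPDH")


def test_ddct_one_cycle_is_twofold():
    rows = [
        ("c1", "ctrl", "GAPDH", 20.0), ("c1", "ctrl", "g", 26.0),
        ("c2", "ctrl", "GAPDH", 20.0), ("c2", "ctrl", "g", 26.0),
        ("t1", "case", "GAPDH", 20.0), ("t1", "case", "g", 25.0),
    ]
    res = ddct_fold_change(_ct_table(rows), "g", "ctrl")
    per = res.per_sample.set_index("sample_id")
    assert per.loc["t1", "ddct"] == pytest.approx(-1.0)
    assert per.loc["t1", "rel_expr"] == pytest.approx(2.0)
    assert per.loc["c1", "rel_expr"] == pytest.approx(1.0)


def test_ddct_zero_is_unity_and_control_mean_is_one():
    rows = [
        ("c1", "ctrl", "GAPDH", 20.0), ("c1", "ctrl", "g", 25.0),
        ("c2", "ctrl", "GAPDH", 21.0), ("c2", "ctrl", "g", 27.0),
        ("t1", "case", "GAPDH", 20.0), ("t1", "case", "g", 25.5),
    ]
    res = ddct_fold_change(_ct_table(rows), "g", "ctrl")
    # a sample whose delta-Ct equals the control mean has fold exactly 1
    control_mean_dct = res.per_sample[res.per_sample["group"] == "ctrl"]["delta_ct"].mean()
    assert 2.0 ** -(control_mean_dct - control_mean_dct) == 1.0
    geo_mean = np.exp(np.mean(np.log(res.per_sample[res.per_sample["group"] == "ctrl"]["rel_expr"])))
    assert geo_mean == pytest.approx(1.0)


def test_ddct_arithmetic_example():
    """Ct_target 24, Ct_ref 20, control mean delta-Ct 6 -> ddCt -2, fold 4."""
    rows = [
        ("c1", "ctrl", "GAPDH", 20.0), ("c1", "ctrl", "g", 26.0),
        ("c2", "ctrl", "GAPDH", 22.0), ("c2", "ctrl", "g", 28.0),
        ("t1", "case", "GAPDH", 20.0), ("t1", "case", "g", 24.0),
    ]
    res = ddct_fold_change(_ct_table(rows), "g", "ctrl")
    t1 = res.per_sample.set_index("sample_id").loc["t1"]
    assert t1["ddct"] == pytest.approx(-2.0)
    assert t1["rel_expr"] == pytest.approx(4.0)


def test_ddct_missing_reference_sample_excluded():
    rows = [
        ("c1", "ctrl", "GAPDH", 20.0), ("c1", "ctrl", "g", 26.0),
        ("c2", "ctrl", "GAPDH", 20.0), ("c2", "ctrl", "g", 26.0),
        ("t1", "case", "g", 24.0),  # no GAPDH row
    ]
    with pytest.warns(UserWarning, match="t1"):
        res = ddct_fold_change(_ct_table(rows), "g", "ctrl")
    assert "t1" not in set(res.per_sample["sample_id"])


# --------------------------------------------------------------------------
# Mann-Whitney exact
# --------------------------------------------------------------------------

def test_mw_separated_quartets():
    assert mann_whitney_exact([1, 2, 3, 4], [5, 6, 7, 8]) == pytest.approx(2 / 70)


def test_mw_single_observations():
    assert mann_whitney_exact([1.0], [2.0]) == 1.0


def test_mw_symmetric():
    rng = np.random.default_rng(2)
    for _ in range(20):
        x = rng.normal(size=int(rng.integers(1, 6)))
        y = rng.normal(size=int(rng.integers(1, 6)))
        assert mann_whitney_exact(x, y) == pytest.approx(mann_whitney_exact(y, x), abs=1e-12)


def test_mw_matches_enumeration_oracle_including_ties(rng):
    for _ in range(25):
        nx, ny = int(rng.integers(1, 6)), int(rng.integers(1, 6))
        x = rng.integers(0, 5, size=nx).astype(float)  # small support forces ties
        y = rng.integers(0, 5, size=ny).astype(float)
        assert mann_whitney_exact(x, y) == pytest.approx(mw_enumeration_oracle(x, y), abs=1e-12)


def test_mw_matches_scipy_exact_without_ties():
    from scipy import stats

    rng = np.random.default_rng(8)
    for _ in range(10):
        x = rng.normal(size=5)
        y = rng.normal(size=6)
        p_scipy = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert mann_whitney_exact(x, y) == pytest.approx(p_scipy, abs=1e-12)


def test_mw_empty_sample_rejected():
    with pytest.raises(InsufficientDataError):
        mann_whitney_exact([], [1.0])


def test_mw_null_type_i_error_conservative():
    """At alpha = 0.05 with n = 4 vs 4 the exact test rejects at most
    0.05 + 3 SE of the time under the null (discreteness makes it conservative)."""
    rng = np.random.default_rng(99)
    rejections = 0
    n_sim = 2000
    for _ in range(n_sim):
        x = rng.normal(size=4)
        y = rng.normal(size=4)
        rejections += mann_whitney_exact(x, y) <= 0.05
    rate = rejections / n_sim
    se = math.sqrt(0.05 * 0.95 / n_sim)
    assert rate <= 0.05 + 3 * se
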