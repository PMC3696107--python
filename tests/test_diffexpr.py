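"""Fold-change conventions, BH step-up, the combined DE filter, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats
from scipy.cluster.hierarchy import fcluster

from meningioma_subgroups import (
    ConfigurationError,
    InsufficientDataError,
    bh_stepup,
    hierarchical_cluster,
    select_de,
    signed_fold_change,
    ttest_per_probe,
)


def bh_bruteforce(p):
    """Independent step-up oracle: q_i = min over p_(j) >= p_i of p_(j) * m / rank(j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    q = np.empty(m)
    for i in range(m):
        candidates = [sorted_p[j] * m / (j + 1) for j in range(m) if sorted_p[j] >= sorted_p[i] - 1e-300]
        q[order[i]] = min(1.0, min(c for j, c in enumerate(candidates)))
    # ties share the value of their last sorted occurrence by construction
    return q


# --------------------------------------------------------------------------
# signed fold change
# --------------------------------------------------------------------------

@pytest.mark.parametrize(
    "diff,expected",
    [(0.0, 1.0), (2.0, 4.0), (-2.0, -4.0), (1.0, 2.0), (np.log2(3), 3.0)],
)
def test_signed_fold_change_back_transform(diff, expected):
    ref = [5.0 + diff, 5.0 + diff, 5.0 + diff]
    cmp_ = [5.0, 5.0, 5.0]
    assert signed_fold_change(ref, cmp_) == pytest.approx(expected)


def test_signed_fold_change_antisymmetric(rng):
    for _ in range(20):
        a = rng.normal(7, 1, size=5)
        b = rng.normal(6, 1, size=4)
        fab = signed_fold_change(a, b)
        fba = signed_fold_change(b, a)
        if abs(fab) > 1:
            assert fab == pytest.approx(-fba)


def test_signed_fold_change_needs_two_per_group():
    with pytest.raises(InsufficientDataError):
        signed_fold_change([1.0], [2.0, 3.0])


# --------------------------------------------------------------------------
# per-probe t-test
# --------------------------------------------------------------------------

def _matrix(rows, samples_a=3, samples_b=3):
    cols = [f"a{i}" for i in range(samples_a)] + [f"b{i}" for i in range(samples_b)]
    df = pd.DataFrame(rows, columns=cols)
    df.index = [f"p{i}" for i in range(len(df))]
    labels = pd.Series(["A"] * samples_a + ["B"] * samples_b, index=cols)
    return df, labels


def test_ttest_per_probe_matches_oracle():
    df, labels = _matrix([[1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1]])
    p = ttest_per_probe(df, labels)
    assert p["p0"] == pytest.approx(2 * stats.t.sf(3.674, 4), abs=1e-4)
    assert p["p1"] == 1.0  # constant probe: degenerate convention


def test_ttest_per_probe_invariant_to_within_group_permutation():
    df, labels = _matrix([[1.0, 2.5, 3.1, 7.0, 8.2, 6.9]])
    shuffled = df[["a2", "a0", "a1", "b1", "b2", "b0"]]
    p1 = ttest_per_probe(df, labels)
    p2 = ttest_per_probe(shuffled, labels[shuffled.columns])
    assert p1["p0"] == pytest.approx(p2["p0"], abs=1e-15)


# --------------------------------------------------------------------------
# BH step-up
# --------------------------------------------------------------------------

def test_bh_single_test_unchanged():
    assert bh_stepup([0.01])[0] == pytest.approx(0.01)


def test_bh_hand_computed_example():
    q = bh_stepup([0.01, 0.02, 0.04])
    assert np.allclose(q, [0.03, 0.03, 0.04])


def test_bh_matches_bruteforce_oracle_on_random_vectors(rng):
    for _ in range(50):
        m = int(rng.integers(1, 21))
        p = rng.random(m)
        if rng.random() < 0.3:  # force ties
            p = np.round(p, 1)
        np.testing.assert_allclose(bh_stepup(p), bh_bruteforce(p), atol=1e-12)


def test_bh_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(5)
    p = rng.random(200)
    q_sm = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(bh_stepup(p), q_sm, atol=1e-12)


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=30))
def test_bh_monotone_and_max_preserving(p):
    q = bh_stepup(p)
    order = np.argsort(p, kind="mergesort")
    assert np.all(np.diff(q[order]) >= -1e-12)  # monotone along sorted p
    assert np.max(q) == pytest.approx(np.max(p))
    assert np.all((q >= 0) & (q <= 1))


def test_bh_rejects_invalid_p():
    with pytest.raises(ConfigurationError):
        bh_stepup([0.5, 1.5])


# --------------------------------------------------------------------------
# combined DE filter
# --------------------------------------------------------------------------

def _planted_matrix(rng, n_probes=1000, n_planted=50, effect=2.0, noise_sd=0.25, n_a=7, n_b=8):
    baseline = rng.normal(7, 1, size=n_probes)
    x = np.tile(baseline[:, None], (1, n_a + n_b))
    planted = rng.choice(n_probes, size=n_planted, replace=False)
    signs = np.where(np.arange(n_planted) % 2 == 0, 1.0, -1.0)
    for s, i in zip(signs, planted):
        x[i, n_a:] += s * effect
    x += rng.normal(0, noise_sd, size=x.shape)
    cols = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    df = pd.DataFrame(x, index=[f"p{i:04d}" for i in range(n_probes)], columns=cols)
    labels = pd.Series(["benignA"] * n_a + ["benignB"] * n_b, index=cols)
    return df, labels, {f"p{i:04d}" for i in planted}


def test_select_de_identical_groups_empty():
    df, labels = _matrix([[5.0] * 6, [7.0] * 6])
    assert select_de(df, labels) == []


def test_select_de_recovers_planted_probes():
    """Planted |log2 FC| = 2 probes at noise SD 0.25 (7 vs 8 samples):
    at least 45 of 50 recovered, at most 2 false positives."""
    rng = np.random.default_rng(42)
    df, labels, planted = _planted_matrix(rng)
    records = select_de(df, labels)
    selected = {r.probeset_id for r in records}
    assert len(selected & planted) >= 45
    assert len(selected - planted) <= 2


def test_select_de_sorted_by_fold_change_desc():
    rng = np.random.default_rng(0)
    df, labels, _ = _planted_matrix(rng, n_probes=200, n_planted=20)
    records = select_de(df, labels)
    fcs = [r.fold_change for r in records]
    assert fcs == sorted(fcs, reverse=True)
    assert all(abs(f) >= 2.0 for f in fcs)


def test_select_de_invariant_to_probe_and_sample_order():
    rng = np.random.default_rng(3)
    df, labels, _ = _planted_matrix(rng, n_probes=300, n_planted=10)
    base = select_de(df, labels)
    perm_probes = df.sample(frac=1.0, random_state=1)
    r2 = select_de(perm_probes, labels)
    cols = list(df.columns)
    rng.shuffle(cols)
    r3 = select_de(df[cols], labels[cols])
    key = lambda recs: sorted((r.probeset_id, round(r.fold_change, 9)) for r in recs)
    assert key(base) == key(r2) == key(r3)


def test_select_de_null_false_discovery_control():
    """Under the global null the mean false-discovery proportion over 200
    simulations stays within 0.005 + 3 SE."""
    rng = np.random.default_rng(2024)
    fdps = []
    for _ in range(200):
        df, labels, _ = _planted_matrix(rng, n_probes=1000, n_planted=0)
        records = select_de(df, labels)
        fdps.append(len(records) / max(len(records), 1) if records else 0.0)
    fdps = np.array(fdps)
    se = fdps.std(ddof=1) / np.sqrt(len(fdps)) if fdps.std() > 0 else 0.0
    assert fdps.mean() <= 0.005 + 3 * se


# --------------------------------------------------------------------------
# hierarchical clustering
# --------------------------------------------------------------------------

def average_linkage_bruteforce(dist):
    """Naive agglomeration oracle: merge the closest pair, average distance
    over all inter-cluster sample pairs; returns sorted merge heights."""
    clusters = [[i] for i in range(dist.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([dist[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(heights)


def test_duplicated_samples_merge_at_height_zero():
    rng = np.random.default_rng(8)
    base = rng.normal(size=(20, 1))
    df = pd.DataFrame(
        np.hstack([base, base, rng.normal(size=(20, 2))]),
        columns=["s0", "s1", "s2", "s3"],
    )
    z, _ = hierarchical_cluster(df)
    assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
    assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}


def test_cluster_recovers_two_planted_groups():
    rng = np.random.default_rng(15)
    df, labels, _ = _planted_matrix(rng, n_probes=200, n_planted=60, effect=3.0, noise_sd=0.2)
    records = select_de(df, labels)
    selected = df.loc[[r.probeset_id for r in records]]
    z, order = hierarchical_cluster(selected)
    assignment = fcluster(z, t=2, criterion="maxclust")
    groups = labels[selected.columns].to_numpy()
    # adjusted Rand = 1 <=> the 2-cut reproduces the labels exactly (up to renaming)
    tab = pd.crosstab(assignment, groups).to_numpy()
    assert np.sum(tab > 0) == 2 and tab.max(axis=0).sum() == len(groups)
    assert set(order) == set(df.columns)


def test_cluster_merge_heights_match_bruteforce_oracle(rng):
    for _ in range(10):
        n = int(rng.integers(3, 7))
        df = pd.DataFrame(rng.normal(size=(12, n)), columns=[f"s{i}" for i in range(n)])
        z, _ = hierarchical_cluster(df)
        corr = np.corrcoef(df.to_numpy(), rowvar=False)
        dist = 1 - corr
        np.fill_diagonal(dist, 0.0)
        np.testing.assert_allclose(sorted(z[:, 2]), average_linkage_bruteforce(dist), atol=1e-10)


def test_cluster_zero_variance_sample_warns():
    df = pd.DataFrame(
        {"s0": [1.0, 2.0, 3.0], "s1": [1.0, 1.0, 1.0], "s2": [3.0, 2.0, 1.0]}
    )
    with pytest.warns(UserWarning, match="zero-variance"):
        z, order = hierarchical_cluster(df)
    assert len(order) == 3
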