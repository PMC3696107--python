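"""Recurrence association and RT-PCR relative quantification.

Four-year recurrence is a binary outcome compared between subgroups with
the exact two-tailed Fisher test (sum of all tables with the observed
margins whose hypergeometric probability does not exceed that of the
observed table). RT-PCR expression is quantified by the ddCt method:
target Ct normalized to a reference gene within each sample, then to the
mean delta-Ct of a control group; relative expression is 2^(-ddCt),
assuming 100% amplification efficiency so one cycle equals a twofold
difference in starting copy. Group differences in relative expression
use the exact two-sided Mann-Whitney rank-sum test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError

EXACT_MW_MAX_N = 20


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = subgroup and columns = recurrence yes/no."""

    a: int  # group 1, event
    b: int  # group 1, no event
    c: int  # group 2, event
    d: int  # group 2, no event

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ConfigurationError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d < 1:
            raise InsufficientDataError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def fisher_exact_two_tailed(table: ContingencyTable2x2) -> float:
    """Exact two-tailed Fisher p for a 2x2 table.

    Standard two-sided definition: the sum of hypergeometric
    probabilities of all tables with the same margins that are at most as
    probable as the observed table. A zero margin admits a single table,
    so p = 1.
    """
    arr = table.as_array()
    if min(arr.sum(axis=0).min(), arr.sum(axis=1).min()) == 0:
        return 1.0
    return float(stats.fisher_exact(arr, alternative="two-sided")[1])


@dataclass
class RecurrenceSummary:
    """Per-group recurrence rates and the benignA-vs-benignB exact test."""

    per_group: pd.DataFrame  # index group; columns n, recurrences, rate
    table: ContingencyTable2x2 | None
    p_value: float | None


def recurrence_summary(labels, outcomes) -> RecurrenceSummary:
    """Per-group recurrence rates plus the benignA-vs-benignB Fisher test.

    ``labels`` maps sample id to subgroup label (or is a list of objects
    with ``sample_id``/``label``); ``outcomes`` maps sample id to a
    recurrence boolean. Every labeled patient must have an outcome. The
    2x2 test is built from the benignA and benignB rows only. A group
    with n = 0 keeps an undefined (NaN) rate.
    """
    if not isinstance(labels, dict):
        labels = {lab.sample_id: lab.label for lab in labels}
    missing = set(labels) - set(outcomes)
    if missing:
        raise ConfigurationError(f"samples without recurrence outcome: {sorted(missing)}")
    rows = {}
    for group in ("benignA", "benignB", "atypical"):
        ids = [s for s, g in labels.items() if g == group]
        n = len(ids)
        rec = sum(bool(outcomes[s]) for s in ids)
        rate = rec / n if n else math.nan
        rows[group] = {"n": n, "recurrences": rec, "rate": rate}
        if n == 0:
            warnings.warn(f"group {group!r} has no patients; rate undefined", stacklevel=2)
    per_group = pd.DataFrame.from_dict(rows, orient="index")
    na, nb = rows["benignA"]["n"], rows["benignB"]["n"]
    if na and nb:
        tab = ContingencyTable2x2(
            rows["benignA"]["recurrences"],
            na - rows["benignA"]["recurrences"],
            rows["benignB"]["recurrences"],
            nb - rows["benignB"]["recurrences"],
        )
        p = fisher_exact_two_tailed(tab)
    else:
        tab, p = None, None
    return RecurrenceSummary(per_group, tab, p)


@dataclass
class CtTable:
    """Long-format RT-PCR cycle-threshold table.

    ``data`` has columns sample_id, group, gene, ct; ``reference_gene``
    (GAPDH in the validation design) must be measured in every sample.
    """

    data: pd.DataFrame
    reference_gene: str

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "gene", "ct"}
        if not required.issubset(self.data.columns):
            raise ConfigurationError(f"CtTable needs columns {sorted(required)}")
        ct = self.data["ct"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ct)) or np.any(ct <= 0):
            raise ConfigurationError("Ct values must be finite and > 0")
        if self.reference_gene not in set(self.data["gene"]):
            raise ConfigurationError(f"reference gene {self.reference_gene!r} absent from table")

    def genes(self) -> list[str]:
        return [g for g in pd.unique(self.data["gene"]) if g != self.reference_gene]


@dataclass
class DdctResult:
    """ddCt relative expression for one target gene."""

    target_gene: str
    control_group: str
    per_sample: pd.DataFrame  # sample_id, group, delta_ct, ddct, rel_expr
    group_summary: pd.DataFrame  # index group; columns n, mean, sd


def ddct_fold_change(ct: CtTable, target_gene: str, control_group: str) -> DdctResult:
    """Relative expression by the ddCt method.

    Per sample, delta-Ct = Ct_target - Ct_reference; ddCt subtracts the
    control group's mean delta-Ct; relative expression is 2^(-ddCt).
    Samples missing the target or reference measurement are excluded with
    a warning.
    """
    df = ct.data
    ref = df[df["gene"] == ct.reference_gene].set_index("sample_id")["ct"]
    tgt = df[df["gene"] == target_gene]
    if tgt.empty:
        raise ConfigurationError(f"target gene {target_gene!r} absent from Ct table")
    rows = []
    for _, row in tgt.iterrows():
        sid = row["sample_id"]
        if sid not in ref.index:
            warnings.warn(f"sample {sid!r} lacks reference-gene Ct; excluded", stacklevel=2)
            continue
        rows.append((sid, row["group"], float(row["ct"]) - float(ref.loc[sid])))
    per = pd.DataFrame(rows, columns=["sample_id", "group", "delta_ct"])
    control = per[per["group"] == control_group]
    if control.empty:
        raise InsufficientDataError(f"control group {control_group!r} has no usable samples")
    baseline = control["delta_ct"].mean()
    per["ddct"] = per["delta_ct"] - baseline
    per["rel_expr"] = 2.0 ** (-per["ddct"])
    summary = (
        per.groupby("group", sort=False)["rel_expr"]
        .agg(n="size", mean="mean", sd=lambda v: v.std(ddof=1))
        .astype({"n": int})
    )
    return DdctResult(target_gene, control_group, per, summary)


def _rank_sum_midranks(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled, method="average")  # mid-ranks for ties
    return ranks, float(ranks[: x.size].sum())


def mann_whitney_exact(x, y) -> float:
    """Two-sided Mann-Whitney rank-sum p-value, exact for small samples.

    For total n <= 20 the p-value is computed from the full permutation
    distribution of the rank-sum statistic (mid-ranks under ties): the
    fraction of group assignments whose rank sum deviates from its null
    mean at least as much as observed. Larger samples fall back to the
    tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InsufficientDataError("both samples must be non-empty")
    n = x.size + y.size
    if n > EXACT_MW_MAX_N:
        return float(
            stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        )
    ranks, w_obs = _rank_sum_midranks(x, y)
    mu = x.size * (n + 1) / 2.0
    dev_obs = abs(w_obs - mu)
    count = 0
    total = 0
    for idx in combinations(range(n), x.size):
        w = ranks[list(idx)].sum()
        if abs(w - mu) >= dev_obs - 1e-12:
            count += 1
        total += 1
    return count / total
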