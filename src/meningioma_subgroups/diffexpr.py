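"""Two-group differential expression with a combined FC / p / FDR filter.

Expression enters as a log2-scale probes x samples matrix (RMA-style
normalization is assumed upstream). Candidate probe sets must pass all
of: absolute fold change >= 2, pooled-t p < 0.005, and Benjamini-Hochberg
step-up FDR <= 0.005 computed over the full probe set. Fold changes are
signed symmetrically about +-1: positive means higher in the reference
group (benignA), negative means higher in the comparison group, and a
ratio r < 1 is reported as -1/r.

Sample structure is visualized by unsupervised agglomerative clustering
with 1 - Pearson correlation distance and average linkage, the
prevailing microarray convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

from .errors import ConfigurationError, InsufficientDataError

FC_MIN = 2.0
P_MAX = 0.005
FDR_MAX = 0.005


def validate_expression_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check a probes x samples log2 matrix: finite values, unique identifiers."""
    if not matrix.index.is_unique:
        raise ConfigurationError("probe identifiers are not unique")
    if not matrix.columns.is_unique:
        raise ConfigurationError("sample identifiers are not unique")
    values = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ConfigurationError("expression matrix contains non-finite values")
    return matrix


@dataclass
class DERecord:
    """One Table-1-style differential-expression row."""

    probeset_id: str
    p_value: float
    fdr: float
    fold_change: float  # signed, |FC| >= 1; positive = higher in reference group
    gene_title: str | None = None
    gene_symbol: str | None = None
    chromosomal_location: str | None = None

    def __post_init__(self) -> None:
        if abs(self.fold_change) < 1.0:
            raise ValueError("signed fold change magnitude must be >= 1")
        if not (0.0 <= self.p_value <= 1.0 and 0.0 <= self.fdr <= 1.0):
            raise ValueError("p-value and FDR must lie in [0, 1]")


def signed_fold_change(group_ref_log2, group_cmp_log2) -> float:
    """Signed fold change from log2 group means: r = 2^(mean_ref - mean_cmp), -1/r when r < 1."""
    a = np.asarray(group_ref_log2, dtype=float)
    b = np.asarray(group_cmp_log2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs at least 2 samples")
    r = 2.0 ** (a.mean() - b.mean())
    return float(r if r >= 1.0 else -1.0 / r)


def _split_groups(matrix: pd.DataFrame, labels: pd.Series) -> tuple[np.ndarray, np.ndarray, str, str]:
    labels = pd.Series(labels)
    groups = list(pd.unique(labels))
    if len(groups) != 2:
        raise ConfigurationError(f"labels must define exactly 2 groups, got {len(groups)}")
    ref, cmp_ = groups
    cols_ref = labels.index[labels == ref]
    cols_cmp = labels.index[labels == cmp_]
    if len(cols_ref) < 2 or len(cols_cmp) < 2:
        raise InsufficientDataError("each group needs at least 2 samples")
    # contiguous copies so reductions are layout-independent (bitwise
    # reproducible whether the matrix came from memory or from disk)
    return (
        np.ascontiguousarray(matrix[cols_ref].to_numpy(dtype=float)),
        np.ascontiguousarray(matrix[cols_cmp].to_numpy(dtype=float)),
        str(ref),
        str(cmp_),
    )


def ttest_per_probe(matrix: pd.DataFrame, labels: pd.Series) -> pd.Series:
    """Two-sided pooled-variance t-test per probe; first label encountered is the reference.

    Probes with zero pooled variance use the degenerate convention
    p = 1 when the group means are equal, p = 0 otherwise.
    """
    validate_expression_matrix(matrix)
    xa, xb, *_ = _split_groups(matrix, labels)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(xa, xb, axis=1, equal_var=True)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        equal_means = np.isclose(xa.mean(axis=1), xb.mean(axis=1))
        p[degenerate] = np.where(equal_means[degenerate], 1.0, 0.0)
    return pd.Series(p, index=matrix.index, name="p_value")


def bh_stepup(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min over j >= i of p_(j) * m / j along the sorted p-values;
    tied p-values share the q of their last sorted occurrence.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ConfigurationError("p_values must be 1D")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ConfigurationError("p-values must be finite and lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def select_de(
    matrix: pd.DataFrame,
    labels: pd.Series,
    fc_min: float = FC_MIN,
    p_max: float = P_MAX,
    fdr_max: float = FDR_MAX,
) -> list[DERecord]:
    """Combined differential-expression filter, Table-1 conventions.

    A probe is kept iff |FC| >= fc_min AND p < p_max AND q <= fdr_max,
    with q computed by BH step-up over the full probe set before any
    thresholding. Output is sorted by signed fold change, descending.
    The reference group (positive fold changes) is the first label
    encountered in ``labels``.
    """
    validate_expression_matrix(matrix)
    xa, xb, *_ = _split_groups(matrix, labels)
    p = ttest_per_probe(matrix, labels).to_numpy()
    q = bh_stepup(p)
    diff = xa.mean(axis=1) - xb.mean(axis=1)
    ratio = 2.0**diff
    fc = np.where(ratio >= 1.0, ratio, -1.0 / ratio)
    keep = (np.abs(fc) >= fc_min) & (p < p_max) & (q <= fdr_max)
    records = [
        DERecord(str(pid), float(pv), float(qv), float(f))
        for pid, pv, qv, f in zip(matrix.index[keep], p[keep], q[keep], fc[keep])
    ]
    records.sort(key=lambda r: r.fold_change, reverse=True)
    return records


def consistent_with_filter(
    record: DERecord,
    fc_min: float = FC_MIN,
    p_max: float = P_MAX,
    fdr_max: float = FDR_MAX,
    printed_decimals: int = 4,
) -> bool:
    """Whether a published record is compatible with the combined filter.

    Published tables print p-values and FDR rounded (4 decimals in the
    reference table), so a printed value equal to the threshold is
    compatible with an unrounded value that passed the strict test. The
    check therefore compares at printed precision: p <= p_max and
    q <= fdr_max after rounding, |FC| >= fc_min exactly.
    """
    half_ulp = 0.5 * 10.0**-printed_decimals
    return (
        abs(record.fold_change) >= fc_min
        and record.p_value < p_max + half_ulp
        and record.fdr <= fdr_max + half_ulp
    )


def hierarchical_cluster(matrix: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Cluster samples on 1 - Pearson correlation with average linkage.

    Returns the scipy linkage matrix and the dendrogram leaf order as
    sample identifiers. A zero-variance sample has undefined
    correlations; they are set to 0 (distance 1) with a warning.
    """
    if matrix.shape[1] < 2 or matrix.shape[0] < 2:
        raise InsufficientDataError("need at least 2 samples and 2 probes to cluster")
    values = matrix.to_numpy(dtype=float)
    sds = values.std(axis=0)
    if np.any(sds == 0):
        flat = [str(s) for s in matrix.columns[sds == 0]]
        warnings.warn(f"zero-variance samples {flat}; their correlations set to 0", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    order = [str(matrix.columns[i]) for i in leaves_list(z)]
    return z, order
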