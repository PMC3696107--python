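"""FISH deletion calling and cytogenetic abnormality summaries.

Interphase FISH scores per-nucleus signal counts for a test probe (1p36,
chromosome 14, chromosome 22) against a control probe. A nucleus with
fewer test than control signals (ratios 0/1, 0/2, 1/2, 1/3, ...) is
scored deleted; a balanced disomic 2/2 pattern is normal. A sample is
called deleted for a probe when the fraction of deleted nuclei strictly
exceeds the cutoff — by default the >20% rule, or a cutoff derived from
non-neoplastic control tissue as median + 3·SD of the control fractions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .errors import InsufficientDataError

DEFAULT_CUTOFF = 0.20
MIN_INFORMATIVE_NUCLEI = 50


class NucleusStatus(str, Enum):
    NORMAL = "normal"
    DELETED = "deleted"
    UNINFORMATIVE = "uninformative"


@dataclass
class NucleiCounts:
    """Per-nucleus (test, control) signal counts for one sample and probe.

    ``regions`` tags each nucleus with the tissue-core region it was
    scored in; region structure is bookkeeping only and never affects the
    call. Scoring 100-200 nuclei per probe is conventional; totals
    outside that range trigger a warning, not an error.
    """

    sample_id: str
    probe: str
    test_signals: np.ndarray
    control_signals: np.ndarray
    regions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.test_signals = np.asarray(self.test_signals, dtype=int)
        self.control_signals = np.asarray(self.control_signals, dtype=int)
        if self.test_signals.shape != self.control_signals.shape:
            raise ValueError("test and control signal vectors differ in length")
        if np.any(self.test_signals < 0) or np.any(self.control_signals < 0):
            raise ValueError("signal counts must be non-negative")
        if self.regions is not None:
            self.regions = np.asarray(self.regions)
            if self.regions.shape != self.test_signals.shape:
                raise ValueError("regions vector differs in length from counts")
        n = self.test_signals.size
        if not 100 <= n <= 200:
            warnings.warn(
                f"{self.sample_id}/{self.probe}: {n} nuclei scored; 100-200 preferred", stacklevel=2
            )

    @property
    def n_nuclei(self) -> int:
        return int(self.test_signals.size)


def classify_nucleus(test_signals: int, control_signals: int) -> NucleusStatus:
    """Score one nucleus as normal, deleted, or uninformative.

    Deleted when the test probe shows fewer signals than the control or
    at most one signal against a present control (0/1, 0/2, 1/2, 1/3 ...);
    a nucleus with no signal from either probe is uninformative and is
    excluded from the denominator. Everything else (2/2 and balanced or
    test-excess patterns) is scored normal: the calling rules cover
    deletions/imbalances, not gains.
    """
    if test_signals < 0 or control_signals < 0:
        raise ValueError("signal counts must be non-negative")
    if test_signals == 0 and control_signals == 0:
        return NucleusStatus.UNINFORMATIVE
    if test_signals < control_signals or (test_signals <= 1 and control_signals >= 1):
        return NucleusStatus.DELETED
    return NucleusStatus.NORMAL


@dataclass
class AlterationCall:
    """Sample-level deletion call for one probe."""

    sample_id: str
    probe: str
    abnormal_fraction: float
    cutoff_used: float
    status: str  # "deletion" | "normal"
    n_informative: int = 0

    def __post_init__(self) -> None:
        expected = "deletion" if self.abnormal_fraction > self.cutoff_used else "normal"
        if self.status != expected:
            raise ValueError("status inconsistent with abnormal_fraction vs cutoff")


def call_probe(counts: NucleiCounts, cutoff: float = DEFAULT_CUTOFF) -> AlterationCall:
    """Call deletion for a probe when deleted nuclei strictly exceed the cutoff fraction.

    Uninformative (0/0) nuclei are excluded from the denominator; at
    least 50 informative nuclei are required for a call.
    """
    statuses = [
        classify_nucleus(int(t), int(c))
        for t, c in zip(counts.test_signals, counts.control_signals)
    ]
    n_inf = sum(s is not NucleusStatus.UNINFORMATIVE for s in statuses)
    if n_inf < MIN_INFORMATIVE_NUCLEI:
        raise InsufficientDataError(
            f"{counts.sample_id}/{counts.probe}: only {n_inf} informative nuclei (< {MIN_INFORMATIVE_NUCLEI})"
        )
    frac = sum(s is NucleusStatus.DELETED for s in statuses) / n_inf
    status = "deletion" if frac > cutoff else "normal"
    return AlterationCall(counts.sample_id, counts.probe, frac, cutoff, status, n_inf)


def derive_cutoff(control_fractions) -> float:
    """Control-tissue cutoff: median + 3·SD of deleted-nucleus fractions, floored at 0.

    ``control_fractions`` are per-control-sample deleted fractions for
    the same probe measured in non-neoplastic tissue. SD uses the n-1
    denominator.
    """
    fr = np.asarray(control_fractions, dtype=float)
    if fr.size < 3:
        raise InsufficientDataError("need at least 3 control fractions to derive a cutoff")
    sd = float(fr.std(ddof=1))
    return max(float(np.median(fr)) + 3.0 * sd, 0.0)


@dataclass
class KaryotypeSummary:
    """Combined FISH + karyotype abnormality summary for one sample.

    ``abnormal_beyond_22`` is the classification-relevant flag: monosomy
    22 alone is the canonical meningioma alteration and is tolerated in
    the benignA subgroup.
    """

    sample_id: str
    alterations: frozenset[str]
    has_any_alteration: bool
    abnormal_beyond_22: bool
    source: str  # "fish" | "karyotype" | "both" | "none"

    def __post_init__(self) -> None:
        if self.abnormal_beyond_22 and not self.has_any_alteration:
            raise ValueError("abnormal_beyond_22 implies has_any_alteration")


def _probe_chromosome(probe: str) -> str:
    """Map a probe name to its chromosome label (1p36 -> 1p, etc.)."""
    p = probe.lower()
    if p.startswith("1p"):
        return "1p"
    for label in ("14", "22"):
        if label in p:
            return label
    return probe


def summarize_karyotype(
    fish_calls: list[AlterationCall] | None = None,
    karyotype_alterations: set[str] | None = None,
    sample_id: str = "",
) -> KaryotypeSummary:
    """Union FISH deletions with karyotype alterations into one summary.

    ``karyotype_alterations`` is an opaque set of chromosome labels from
    conventional cytogenetics (``None`` when no karyotype was obtained,
    an empty set for a normal karyotype). ``source`` records which
    evidence streams were present.
    """
    fish_present = fish_calls is not None
    karyo_present = karyotype_alterations is not None
    alterations: set[str] = set()
    if fish_calls:
        if not sample_id:
            sample_id = fish_calls[0].sample_id
        for call in fish_calls:
            if call.status == "deletion":
                alterations.add(_probe_chromosome(call.probe))
    if karyotype_alterations:
        alterations |= set(karyotype_alterations)
    if fish_present and karyo_present:
        source = "both"
    elif fish_present:
        source = "fish"
    elif karyo_present:
        source = "karyotype"
    else:
        source = "none"
    beyond = bool(alterations - {"22"})
    return KaryotypeSummary(sample_id, frozenset(alterations), bool(alterations), beyond, source)
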