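"""benignA / benignB / atypical classification of meningioma samples.

WHO grade II tumors are labeled atypical outright. A grade I tumor is
assigned to the benignB subgroup when it shows chromosomal abnormalities
beyond monosomy 22 (by FISH and/or karyotype) or "metabolic
aggressiveness": at least three of the four marker metabolites (choline,
lactate, taurine, fatty acids) within two standard deviations of the
atypical-group reference levels. Grade I tumors fulfilling neither
criterion form the benignA subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, UnclassifiableError
from .fish import KaryotypeSummary
from .nmr import MARKER_METABOLITES, MetaboliteProfile

MARKERS_REQUIRED = 3
SD_MULTIPLIER = 2.0


@dataclass(frozen=True)
class AtypicalReference:
    """Per-marker mean and SD of metabolite levels in the atypical group."""

    means: dict[str, float]
    sds: dict[str, float]
    n_per_marker: dict[str, int]

    def interval(self, metabolite: str, sd_multiplier: float = SD_MULTIPLIER) -> tuple[float, float]:
        m, s = self.means[metabolite], self.sds[metabolite]
        return m - sd_multiplier * s, m + sd_multiplier * s


@dataclass(frozen=True)
class SubgroupLabel:
    """Classification outcome with the evidence that produced it."""

    sample_id: str
    label: str  # "benignA" | "benignB" | "atypical"
    chromosomal_evidence: bool = False
    metabolic_evidence: bool = False
    n_markers_in_range: int = 0
    missing_markers: frozenset[str] = frozenset()


def build_reference(
    atypical_profiles: list[MetaboliteProfile],
    markers: tuple[str, ...] = MARKER_METABOLITES,
) -> AtypicalReference:
    """Mean and sample SD (n-1) of each marker over the atypical group.

    A profile missing a marker (e.g. its peak fit failed QC) is excluded
    from that marker's statistics only; per-marker n is tracked. Each
    marker needs at least two usable samples.
    """
    means: dict[str, float] = {}
    sds: dict[str, float] = {}
    ns: dict[str, int] = {}
    for marker in markers:
        values = np.array(
            [p.levels[marker] for p in atypical_profiles if marker in p.levels], dtype=float
        )
        if values.size < 2:
            raise InsufficientDataError(
                f"marker {marker!r}: only {values.size} atypical samples with an accepted level (< 2)"
            )
        means[marker] = float(values.mean())
        sds[marker] = float(values.std(ddof=1))
        ns[marker] = int(values.size)
    return AtypicalReference(means, sds, ns)


def metabolic_aggressiveness(
    profile: MetaboliteProfile,
    ref: AtypicalReference,
    markers_required: int = MARKERS_REQUIRED,
    sd_multiplier: float = SD_MULTIPLIER,
) -> tuple[int, bool]:
    """Count markers within the atypical 2-SD band; aggressive at >= 3 of 4.

    The band is two-sided and inclusive at both ends. A marker absent
    from the profile (failed QC) counts as not-in-range.
    """
    n_in_range = 0
    for marker in ref.means:
        level = profile.levels.get(marker)
        if level is None:
            continue
        lo, hi = ref.interval(marker, sd_multiplier)
        if lo <= level <= hi:
            n_in_range += 1
    return n_in_range, n_in_range >= markers_required


def classify_sample(
    grade: str,
    karyo: KaryotypeSummary | None,
    profile: MetaboliteProfile | None,
    ref: AtypicalReference | None,
    markers_required: int = MARKERS_REQUIRED,
    sd_multiplier: float = SD_MULTIPLIER,
    sample_id: str = "",
) -> SubgroupLabel:
    """Assign benignA / benignB / atypical to one sample.

    Grade II takes precedence: atypical regardless of molecular data.
    Grade I requires at least one evidence stream (karyotype summary or
    metabolite profile with a reference); the two streams combine by
    inclusive OR, so either suffices for benignB on its own.
    """
    grade = str(grade).strip().upper()
    if grade in {"II", "2"}:
        sid = sample_id or (profile.sample_id if profile else "") or (karyo.sample_id if karyo else "")
        return SubgroupLabel(sid, "atypical")
    if grade not in {"I", "1"}:
        raise UnclassifiableError(f"unsupported WHO grade {grade!r}; expected I or II")

    has_karyo = karyo is not None and karyo.source != "none"
    has_metab = profile is not None and ref is not None
    if not has_karyo and not has_metab:
        raise UnclassifiableError(
            f"sample {sample_id!r}: neither chromosomal nor metabolite data available"
        )
    sid = sample_id or (profile.sample_id if profile else "") or (karyo.sample_id if karyo else "")

    chromosomal = bool(karyo.abnormal_beyond_22) if has_karyo else False
    if has_metab:
        n_in_range, metabolic = metabolic_aggressiveness(profile, ref, markers_required, sd_multiplier)
        missing = frozenset(m for m in ref.means if m not in profile.levels)
    else:
        n_in_range, metabolic, missing = 0, False, frozenset()

    label = "benignB" if (chromosomal or metabolic) else "benignA"
    return SubgroupLabel(sid, label, chromosomal, metabolic, n_in_range, missing)
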