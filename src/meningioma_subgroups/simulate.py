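"""Synthetic meningioma cohorts with the structure the analysis assumes.

The generator produces complete cohorts — clinical metadata with 4-year
recurrence, true metabolite levels and synthetic 1D spectra, per-nucleus
FISH signal counts, a log2 expression matrix with planted differential
effects, and an RT-PCR Ct table — so every downstream stage can be
exercised and validated without any external data.

Group structure emulated: benignA tumors carry low marker-metabolite
levels and at most a monosomy-22 FISH signal pattern; benignB and
atypical tumors carry marker levels near the atypical reference and
additional 1p/14 alterations; planted probe sets separate benignA from
benignB by a fixed log2 effect; recurrence is Bernoulli per group; Ct
values follow the sample's log2 expression with a noise-free constant
reference gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .nmr import PeakLibrary, Spectrum, default_peak_library
from .fish import NucleiCounts
from .outcomes import CtTable

GROUPS = ("benignA", "benignB", "atypical")
FISH_PROBES = ("1p", "14", "22")
REFERENCE_GENE = "GAPDH"
REFERENCE_CT = 20.0
CT_INTERCEPT = 30.0

#: Non-marker resonances included in synthetic spectra so that the total
#: spectral area is dominated by metabolites common to all groups, as in
#: tissue spectra (creatine, NAA, glutamate, myo-inositol region, ...).
#: (ppm center, hwhm, area) — all outside the marker fit windows.
BACKGROUND_COMPONENTS: tuple[tuple[float, float, float], ...] = (
    (2.01, 8e-4, 10.0),
    (2.35, 8e-4, 6.0),
    (3.03, 8e-4, 12.0),
    (3.55, 8e-4, 8.0),
    (3.93, 8e-4, 8.0),
    (4.10, 8e-4, 6.0),
)

_DEFAULT_METAB_MEANS = {
    "benignA": {"choline": 1.0, "lactate": 2.0, "taurine": 1.0, "fatty_acids": 1.5},
    "benignB": {"choline": 2.0, "lactate": 5.0, "taurine": 2.5, "fatty_acids": 4.0},
    "atypical": {"choline": 2.0, "lactate": 5.0, "taurine": 2.5, "fatty_acids": 4.0},
}

_DEFAULT_FISH_FRACS = {
    "benignA": {"1p": 0.05, "14": 0.05, "22": 0.40},
    "benignB": {"1p": 0.45, "14": 0.30, "22": 0.50},
    "atypical": {"1p": 0.70, "14": 0.50, "22": 0.60},
}


def _default_metab_sds() -> dict[str, dict[str, float]]:
    return {
        g: {m: 0.15 * v for m, v in means.items()} for g, means in _DEFAULT_METAB_MEANS.items()
    }


@dataclass
class SimConfig:
    """Cohort-generator settings; defaults mirror the study conditions.

    Group sizes 20/20/14 and recurrence probabilities 0.0 / 0.545 / 0.9
    follow the reported cohort; planted expression effects default to
    |log2 FC| = 2 with residual noise SD 0.25 log2 units.
    """

    n_benignA: int = 20
    n_benignB: int = 20
    n_atypical: int = 14
    n_probes: int = 1000
    n_planted_de: int = 50
    de_log2_effect: float = 2.0
    expr_noise_sd: float = 0.25
    recur_prob: dict[str, float] = field(
        default_factory=lambda: {"benignA": 0.0, "benignB": 0.545, "atypical": 0.9}
    )
    metab_means: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in _DEFAULT_METAB_MEANS.items()}
    )
    metab_sds: dict[str, dict[str, float]] = field(default_factory=_default_metab_sds)
    fish_alteration_fracs: dict[str, dict[str, float]] = field(
        default_factory=lambda: {g: dict(v) for g, v in _DEFAULT_FISH_FRACS.items()}
    )
    nuclei_per_region: int = 30
    n_regions: int = 4
    ct_noise_sd: float = 0.15
    spectrum_noise_sd: float = 0.4
    spectrum_points: int = 16384
    ppm_range: tuple[float, float] = (0.0, 5.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_benignA", "n_benignB", "n_atypical", "n_probes", "nuclei_per_region", "n_regions"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.n_planted_de < 0 or self.n_planted_de > self.n_probes:
            raise ConfigurationError("n_planted_de must satisfy 0 <= n_planted_de <= n_probes")
        for g, p in self.recur_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"recur_prob[{g!r}] must lie in [0, 1]")
        for name in ("expr_noise_sd", "ct_noise_sd", "spectrum_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for g, sds in self.metab_sds.items():
            for m, s in sds.items():
                if s < 0:
                    raise ConfigurationError(f"metab_sds[{g!r}][{m!r}] must be >= 0")
        for g, fracs in self.fish_alteration_fracs.items():
            for p_name, f in fracs.items():
                if not 0.0 <= f <= 1.0:
                    raise ConfigurationError(
                        f"fish_alteration_fracs[{g!r}][{p_name!r}] must lie in [0, 1]"
                    )
        if self.spectrum_points < 1024:
            raise ConfigurationError("spectrum_points must be >= 1024")

    @property
    def group_sizes(self) -> dict[str, int]:
        return {"benignA": self.n_benignA, "benignB": self.n_benignB, "atypical": self.n_atypical}


@dataclass
class SampleRecord:
    """Clinical metadata for one simulated patient."""

    sample_id: str
    who_grade: str  # "I" | "II"
    true_subgroup: str
    recurrence_4y: bool


@dataclass
class CohortBundle:
    """Everything the pipeline consumes, keyed by shared sample identifiers."""

    config: SimConfig
    samples: list[SampleRecord]
    metabolite_truth: pd.DataFrame  # samples x metabolites, true areas (a.u.)
    spectra: dict[str, Spectrum]
    fish_counts: dict[str, dict[str, NucleiCounts]]
    fish_control_fractions: dict[str, np.ndarray]
    expression: pd.DataFrame  # probes x samples, log2
    planted_de_ids: list[str]
    ct_table: CtTable
    true_labels: dict[str, str]

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        for name, got in (
            ("metabolite_truth", list(self.metabolite_truth.index)),
            ("spectra", list(self.spectra)),
            ("fish_counts", list(self.fish_counts)),
            ("expression", list(self.expression.columns)),
            ("true_labels", list(self.true_labels)),
        ):
            if sorted(got) != sorted(ids):
                raise ConfigurationError(f"{name} sample identifiers do not match metadata")
        if not set(self.planted_de_ids) <= set(self.expression.index):
            raise ConfigurationError("planted_de_ids must be a subset of probe identifiers")

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]


def synth_spectrum(
    metabolite_levels: dict[str, float],
    peak_library: PeakLibrary,
    noise_sd: float,
    n_points: int = 16384,
    ppm_range: tuple[float, float] = (0.0, 5.0),
    rng: np.random.Generator | int | None = None,
    extra_components: tuple[tuple[float, float, float], ...] = (),
    sample_id: str = "",
) -> Spectrum:
    """Sum-of-Lorentzians spectrum with i.i.d. Gaussian noise.

    Each metabolite's components are scaled so their total full-line
    integrated area equals its level (split by component weight). The
    ppm axis is strictly decreasing, the NMR plotting convention.
    ``extra_components`` adds fixed (center, hwhm, area) resonances, e.g.
    the non-marker background of tissue spectra.
    """
    if n_points < 1024:
        raise ConfigurationError("n_points must be >= 1024")
    unknown = sorted(set(metabolite_levels) - set(peak_library))
    if unknown:
        raise ConfigurationError(f"metabolites absent from peak library: {unknown}")
    lo, hi = ppm_range
    ppm = np.linspace(hi, lo, n_points)  # decreasing
    intensity = np.zeros(n_points)
    for name, level in metabolite_levels.items():
        definition = peak_library[name]
        total_weight = sum(c.weight for c in definition.components)
        for comp in definition.components:
            area = level * comp.weight / total_weight
            intensity += (area / np.pi) * comp.hwhm / ((ppm - comp.center) ** 2 + comp.hwhm**2)
    for center, hwhm, area in extra_components:
        intensity += (area / np.pi) * hwhm / ((ppm - center) ** 2 + hwhm**2)
    if noise_sd > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        intensity = intensity + rng.normal(0.0, noise_sd, n_points)
    return Spectrum(ppm, intensity, sample_id=sample_id)


def simulate_cohort(config: SimConfig | None = None) -> CohortBundle:
    """Draw a full cohort from a single seeded generator.

    Deterministic given ``config.seed``; every random draw flows from one
    ``numpy.random.Generator``, so identical configs yield identical
    bundles.
    """
    config = config if config is not None else SimConfig()
    rng = np.random.default_rng(config.seed)
    library = default_peak_library()
    metabolites = list(library)

    samples: list[SampleRecord] = []
    true_labels: dict[str, str] = {}
    k = 0
    for group in GROUPS:
        for _ in range(config.group_sizes[group]):
            k += 1
            sid = f"MEN{k:03d}"
            grade = "II" if group == "atypical" else "I"
            recur = bool(rng.random() < config.recur_prob.get(group, 0.0))
            samples.append(SampleRecord(sid, grade, group, recur))
            true_labels[sid] = group

    # --- metabolite truth and spectra -----------------------------------
    truth = {}
    spectra: dict[str, Spectrum] = {}
    for rec in samples:
        g = rec.true_subgroup
        levels = {
            m: max(rng.normal(config.metab_means[g][m], config.metab_sds[g][m]), 0.0)
            for m in metabolites
        }
        truth[rec.sample_id] = levels
        spectra[rec.sample_id] = synth_spectrum(
            levels,
            library,
            config.spectrum_noise_sd,
            n_points=config.spectrum_points,
            ppm_range=config.ppm_range,
            rng=rng,
            extra_components=BACKGROUND_COMPONENTS,
            sample_id=rec.sample_id,
        )
    metabolite_truth = pd.DataFrame.from_dict(truth, orient="index")[metabolites]
    metabolite_truth.index.name = "sample_id"

    # --- FISH nuclei counts ---------------------------------------------
    deleted_patterns = np.array([(1, 2), (0, 2), (0, 1), (1, 3)])
    fish_counts: dict[str, dict[str, NucleiCounts]] = {}
    n_nuclei = config.nuclei_per_region * config.n_regions
    for rec in samples:
        g = rec.true_subgroup
        per_probe: dict[str, NucleiCounts] = {}
        for probe in FISH_PROBES:
            frac = config.fish_alteration_fracs[g][probe]
            abnormal = rng.random(n_nuclei) < frac
            test = np.full(n_nuclei, 2, dtype=int)
            control = np.full(n_nuclei, 2, dtype=int)
            idx = np.nonzero(abnormal)[0]
            patterns = deleted_patterns[rng.integers(0, len(deleted_patterns), idx.size)]
            test[idx], control[idx] = patterns[:, 0], patterns[:, 1]
            uninformative = (~abnormal) & (rng.random(n_nuclei) < 0.03)
            test[uninformative] = 0
            control[uninformative] = 0
            regions = np.repeat(np.arange(config.n_regions), config.nuclei_per_region)
            per_probe[probe] = NucleiCounts(rec.sample_id, probe, test, control, regions)
        fish_counts[rec.sample_id] = per_probe

    # Non-neoplastic control fractions per probe, for cutoff derivation.
    # Centers are calibrated so median + 3*SD lands inside the cutoff ranges
    # reported for these probes (1p 14-21%, 14 16-22%, 22 15-20%).
    control_center = {"1p": 0.115, "14": 0.13, "22": 0.115}
    fish_control_fractions = {
        probe: np.clip(rng.normal(control_center.get(probe, 0.12), 0.02, size=10), 0.0, 1.0)
        for probe in FISH_PROBES
    }

    # --- expression matrix with planted effects -------------------------
    probe_ids = [f"probe_{i:05d}" for i in range(config.n_probes)]
    planted = list(rng.choice(config.n_probes, size=config.n_planted_de, replace=False))
    planted_ids = [probe_ids[i] for i in sorted(planted)]
    baseline = rng.normal(7.0, 1.0, size=config.n_probes)
    n_samples = len(samples)
    expr = np.tile(baseline[:, None], (1, n_samples))
    group_of = np.array([s.true_subgroup for s in samples])
    # planted probes: alternate direction; benignB and atypical share the shift
    shifted_cols = np.isin(group_of, ("benignB", "atypical"))
    for j, i_probe in enumerate(sorted(planted)):
        sign = 1.0 if j % 2 == 0 else -1.0
        expr[i_probe, shifted_cols] += sign * config.de_log2_effect
    expr = expr + rng.normal(0.0, config.expr_noise_sd, size=expr.shape)
    expression = pd.DataFrame(expr, index=probe_ids, columns=[s.sample_id for s in samples])
    expression.index.name = "probeset_id"

    # --- RT-PCR Ct table -------------------------------------------------
    ct_genes = planted_ids[:4] if len(planted_ids) >= 4 else planted_ids
    rows = []
    for group in GROUPS:
        members = [s.sample_id for s in samples if s.true_subgroup == group][:4]
        for sid in members:
            rows.append((sid, group, REFERENCE_GENE, REFERENCE_CT))
            for gene in ct_genes:
                ct = CT_INTERCEPT - float(expression.at[gene, sid]) + rng.normal(0.0, config.ct_noise_sd)
                rows.append((sid, group, gene, ct))
    ct_table = CtTable(
        pd.DataFrame(rows, columns=["sample_id", "group", "gene", "ct"]), REFERENCE_GENE
    )

    return CohortBundle(
        config=config,
        samples=samples,
        metabolite_truth=metabolite_truth,
        spectra=spectra,
        fish_counts=fish_counts,
        fish_control_fractions=fish_control_fractions,
        expression=expression,
        planted_de_ids=planted_ids,
        ct_table=ct_table,
        true_labels=true_labels,
    )


def config_as_dict(config: SimConfig) -> dict:
    """JSON-serializable view of a SimConfig (for run manifests)."""
    d = asdict(config)
    d["ppm_range"] = list(d["ppm_range"])
    return d
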