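"""End-to-end orchestration: cohort in, labels / DE / statistics out.

The pipeline either simulates a cohort or reads one from a directory of
TSV files, then runs every stage in order: metabolite quantification
(peak fitting on spectra, or a precomputed levels table), FISH deletion
calling, benignA/benignB/atypical classification against the
atypical-group metabolite reference, differential expression with the
combined FC/p/FDR filter, hierarchical clustering of the selected
probes, the recurrence Fisher test, and ddCt quantification of the
simulated validation genes. Outputs are plain TSVs plus a JSON manifest;
reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .diffexpr import FC_MIN, FDR_MAX, P_MAX, hierarchical_cluster, select_de
from .errors import ConfigurationError, MeningiomaError
from .fish import DEFAULT_CUTOFF, call_probe, derive_cutoff, summarize_karyotype
from .nmr import MARKER_METABOLITES, default_peak_library, quantify_metabolites
from .outcomes import ddct_fold_change, mann_whitney_exact, recurrence_summary
from .simulate import SimConfig, config_as_dict, simulate_cohort
from .subgroups import MARKERS_REQUIRED, SD_MULTIPLIER, build_reference, classify_sample

logger = logging.getLogger("meningioma_subgroups")


@dataclass
class PipelineConfig:
    """Settings for one pipeline run.

    ``fish_cutoff_policy`` selects between the fixed >20% rule and
    cutoffs derived from non-neoplastic control fractions (median + 3·SD)
    when controls are available.
    """

    out_dir: str | Path = "results/pipeline"
    simulate: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    input_dir: str | Path | None = None
    seed: int | None = None  # overrides sim.seed when simulating
    fc_min: float = FC_MIN
    p_max: float = P_MAX
    fdr_max: float = FDR_MAX
    fish_cutoff_policy: str = "controls"  # "controls" | "fixed"
    fish_cutoff: float = DEFAULT_CUTOFF
    markers_required: int = MARKERS_REQUIRED
    sd_multiplier: float = SD_MULTIPLIER
    quantify_from_spectra: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for name in ("fc_min", "p_max", "fdr_max", "fish_cutoff", "sd_multiplier"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.markers_required > len(MARKER_METABOLITES):
            raise ConfigurationError("markers_required exceeds the number of marker metabolites")
        if self.fish_cutoff_policy not in {"controls", "fixed"}:
            raise ConfigurationError("fish_cutoff_policy must be 'controls' or 'fixed'")
        if not self.simulate and self.input_dir is None:
            raise ConfigurationError("input_dir is required when simulate is False")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load a flat key-value YAML/JSON config document."""
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        sim_raw = raw.pop("sim", {})
        sim = SimConfig(**sim_raw) if isinstance(sim_raw, dict) else sim_raw
        return cls(sim=sim, **raw)


class StageError(MeningiomaError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def decorate(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc

        return wrapped

    return decorate


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write results under ``config.out_dir``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bundle, inputs = _load_inputs(config)
    profiles = _metabolite_stage(config, inputs)
    karyo = _fish_stage(config, inputs)
    labels = _classify_stage(config, inputs, profiles, karyo, out)
    de_records, leaf_order = _expression_stage(config, inputs, labels, out)
    recur = _recurrence_stage(inputs, labels, out)
    ddct = _ddct_stage(inputs, out)

    manifest = {
        "config": _config_as_dict(config),
        "seed": config.seed if config.seed is not None else config.sim.seed,
        "versions": _versions(),
        "counts": {
            "samples": len(inputs["samples"]),
            "de_records": len(de_records),
            "clustered_samples": len(leaf_order),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline finished: %d samples, %d DE records", len(inputs["samples"]), len(de_records))
    return out


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------

@_stage("load_inputs")
def _load_inputs(config: PipelineConfig):
    if config.simulate:
        sim = config.sim
        if config.seed is not None:
            sim = dataclasses.replace(sim, seed=config.seed)
        bundle = simulate_cohort(sim)
        samples = pd.DataFrame(
            {
                "who_grade": {s.sample_id: s.who_grade for s in bundle.samples},
                "recurrence_4y": {s.sample_id: s.recurrence_4y for s in bundle.samples},
            }
        )
        samples.index.name = "sample_id"
        inputs = {
            "samples": samples,
            "spectra": bundle.spectra,
            "metabolite_levels": bundle.metabolite_truth,
            "fish_counts": bundle.fish_counts,
            "fish_controls": bundle.fish_control_fractions,
            "expression": bundle.expression,
            "ct_table": bundle.ct_table,
            "true_labels": bundle.true_labels,
            "planted_de_ids": bundle.planted_de_ids,
        }
        return bundle, inputs
    indir = Path(config.input_dir)
    samples = mio.read_samples(indir / "samples.tsv")
    spectra = {}
    specdir = indir / "spectra"
    if config.quantify_from_spectra and specdir.is_dir():
        for f in sorted(specdir.glob("*.tsv")):
            spectra[f.stem] = mio.read_spectrum(f)
    levels_path = indir / "metabolites.tsv"
    levels = (
        pd.read_csv(levels_path, sep="\t", index_col="sample_id", float_precision="round_trip")
        if levels_path.exists()
        else None
    )
    controls_path = indir / "fish_controls.tsv"
    controls = (
        {
            c: pd.read_csv(controls_path, sep="\t", float_precision="round_trip")[c].to_numpy()
            for c in pd.read_csv(controls_path, sep="\t").columns
        }
        if controls_path.exists()
        else {}
    )
    inputs = {
        "samples": samples,
        "spectra": spectra,
        "metabolite_levels": levels,
        "fish_counts": mio.read_fish_counts(indir / "fish_counts.tsv"),
        "fish_controls": controls,
        "expression": mio.read_expression(indir / "expression.tsv"),
        "ct_table": mio.read_ct_table(indir / "ct.tsv", reference_gene="GAPDH"),
        "true_labels": dict(samples["true_subgroup"]) if "true_subgroup" in samples else None,
        "planted_de_ids": None,
    }
    return None, inputs


@_stage("metabolite_quantification")
def _metabolite_stage(config: PipelineConfig, inputs) -> dict:
    if config.quantify_from_spectra and inputs["spectra"]:
        library = default_peak_library()
        profiles = {
            sid: quantify_metabolites(spec, library) for sid, spec in inputs["spectra"].items()
        }
        logger.info("quantified %d spectra over %d windows", len(profiles), len(library))
    elif inputs["metabolite_levels"] is not None:
        profiles = {p.sample_id: p for p in mio.profiles_from_levels(inputs["metabolite_levels"])}
        logger.info("loaded %d metabolite profiles from levels table", len(profiles))
    else:
        raise ConfigurationError("no spectra and no metabolite levels table available")
    return profiles


@_stage("fish_calling")
def _fish_stage(config: PipelineConfig, inputs) -> dict:
    cutoffs: dict[str, float] = {}
    if config.fish_cutoff_policy == "controls" and inputs["fish_controls"]:
        for probe, fractions in inputs["fish_controls"].items():
            cutoffs[probe] = derive_cutoff(fractions)
            logger.info("probe %s: control-derived cutoff %.3f", probe, cutoffs[probe])
    karyo = {}
    n_deletions = 0
    for sid, per_probe in inputs["fish_counts"].items():
        calls = [
            call_probe(counts, cutoff=cutoffs.get(probe, config.fish_cutoff))
            for probe, counts in per_probe.items()
        ]
        n_deletions += sum(c.status == "deletion" for c in calls)
        karyo[sid] = summarize_karyotype(calls, None, sample_id=sid)
    logger.info("FISH: %d samples, %d deletion calls", len(karyo), n_deletions)
    return karyo


@_stage("classification")
def _classify_stage(config: PipelineConfig, inputs, profiles, karyo, out: Path):
    samples = inputs["samples"]
    atypical_profiles = [
        profiles[sid] for sid in samples.index if str(samples.at[sid, "who_grade"]).upper() in {"II", "2"}
        and sid in profiles
    ]
    ref = build_reference(atypical_profiles)
    labels = {}
    for sid in samples.index:
        labels[sid] = classify_sample(
            samples.at[sid, "who_grade"],
            karyo.get(sid),
            profiles.get(sid),
            ref,
            markers_required=config.markers_required,
            sd_multiplier=config.sd_multiplier,
            sample_id=str(sid),
        )
    rows = [
        {
            "sample_id": sid,
            "label": lab.label,
            "chromosomal_evidence": lab.chromosomal_evidence,
            "metabolic_evidence": lab.metabolic_evidence,
            "n_markers_in_range": lab.n_markers_in_range,
        }
        for sid, lab in labels.items()
    ]
    pd.DataFrame(rows).to_csv(out / "labels.tsv", sep="\t", index=False)
    counts = pd.Series([l.label for l in labels.values()]).value_counts().to_dict()
    logger.info("classification: %s", counts)
    return labels


@_stage("differential_expression")
def _expression_stage(config: PipelineConfig, inputs, labels, out: Path):
    expr = inputs["expression"]
    benign_ids = [sid for sid in expr.columns if labels[sid].label in {"benignA", "benignB"}]
    group = pd.Series({sid: labels[sid].label for sid in benign_ids})
    # benignA first so positive fold changes mean higher in benignA
    ordered = [s for s in benign_ids if group[s] == "benignA"] + [
        s for s in benign_ids if group[s] == "benignB"
    ]
    records = select_de(
        expr[ordered], group[ordered], fc_min=config.fc_min, p_max=config.p_max, fdr_max=config.fdr_max
    )
    logger.info("DE filter: %d of %d probes retained", len(records), expr.shape[0])
    mio.write_de_records(records, out / "de.tsv")
    leaf_order: list[str] = []
    if len(records) >= 2:
        selected = expr.loc[[r.probeset_id for r in records]]
        _, leaf_order = hierarchical_cluster(selected)
        pd.DataFrame({"leaf_order": leaf_order}).to_csv(out / "cluster_leaf_order.tsv", sep="\t", index=False)
    return records, leaf_order


@_stage("recurrence")
def _recurrence_stage(inputs, labels, out: Path):
    outcomes = {sid: bool(v) for sid, v in inputs["samples"]["recurrence_4y"].items()}
    summary = recurrence_summary({sid: lab.label for sid, lab in labels.items()}, outcomes)
    per_group = summary.per_group.copy()
    per_group.index.name = "group"
    per_group.to_csv(out / "recurrence.tsv", sep="\t")
    if summary.table is not None:
        t = summary.table
        stats_line = (
            f"benignA {t.a}/{t.a + t.b} vs benignB {t.c}/{t.c + t.d}; "
            f"two-tailed Fisher p = {summary.p_value:.3f}\n"
        )
    else:
        stats_line = "2x2 recurrence table undefined (an empty subgroup)\n"
    (out / "recurrence_stats.txt").write_text(stats_line)
    logger.info("recurrence: %s", stats_line.strip())
    return summary


@_stage("rtpcr_ddct")
def _ddct_stage(inputs, out: Path):
    ct = inputs["ct_table"]
    rows = []
    results = {}
    for gene in ct.genes():
        res = ddct_fold_change(ct, gene, control_group="benignA")
        results[gene] = res
        control_vals = res.per_sample.loc[res.per_sample["group"] == "benignA", "rel_expr"]
        for grp, sub in res.per_sample.groupby("group", sort=False):
            p = (
                mann_whitney_exact(sub["rel_expr"], control_vals)
                if grp != "benignA"
                else float("nan")
            )
            rows.append(
                {
                    "gene": gene,
                    "group": grp,
                    "n": len(sub),
                    "mean_rel_expr": sub["rel_expr"].mean(),
                    "sd_rel_expr": sub["rel_expr"].std(ddof=1),
                    "p_vs_benignA": p,
                }
            )
    pd.DataFrame(rows).to_csv(out / "ddct.tsv", sep="\t", index=False)
    logger.info("ddCt: %d validation genes", len(results))
    return results


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _config_as_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["sim"] = config_as_dict(config.sim)
    d["out_dir"] = str(d["out_dir"])
    d["input_dir"] = str(d["input_dir"]) if d["input_dir"] is not None else None
    return d


def _versions() -> dict[str, str]:
    import scipy

    from . import __version__

    return {
        "meningioma_subgroups": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
    }
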