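"""Readers and writers for the pipeline's TSV formats.

All files are UTF-8, tab-delimited, with a header row, decimal points
and no quoting. The packaged reference table of 59 probe sets
differentially expressed between the benignA and benignB subgroups ships
as printed (decimal commas, typographic minus, "–" for missing
annotation); its loader normalizes those at read time.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .diffexpr import DERecord
from .errors import ConfigurationError
from .fish import NucleiCounts
from .nmr import MetaboliteProfile, PeakFitResult, Spectrum
from .outcomes import CtTable
from .simulate import CohortBundle, config_as_dict

DE_COLUMNS = ["Probeset ID", "Gene Title", "Gene Symbol", "Chromosomal Location", "p-value", "FDR", "FC"]
TABLE1_RESOURCE = "table1_benignA_vs_benignB.tsv"


# --------------------------------------------------------------------------
# spectra
# --------------------------------------------------------------------------

def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Two-column ppm/intensity TSV."""
    df = pd.DataFrame({"ppm": spectrum.ppm, "intensity": spectrum.intensity})
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_spectrum(path: str | Path, sample_id: str | None = None) -> Spectrum:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if not {"ppm", "intensity"}.issubset(df.columns):
        raise ConfigurationError(f"{path}: expected columns ppm, intensity")
    sid = sample_id if sample_id is not None else Path(path).stem
    return Spectrum(df["ppm"].to_numpy(), df["intensity"].to_numpy(), sample_id=sid)


# --------------------------------------------------------------------------
# metabolite profiles
# --------------------------------------------------------------------------

def write_profiles(profiles: list[MetaboliteProfile], path: str | Path) -> None:
    """Rows = samples; per metabolite a level, accepted and residual column."""
    metabolites = sorted({m for p in profiles for m in (set(p.levels) | p.missing)})
    rows = []
    for p in profiles:
        row: dict[str, object] = {"sample_id": p.sample_id}
        for m in metabolites:
            fit = p.fits.get(m)
            row[m] = p.levels.get(m, np.nan)
            row[f"{m}_accepted"] = m in p.levels
            row[f"{m}_residual"] = fit.residual_error if fit is not None else np.nan
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_profiles(path: str | Path) -> list[MetaboliteProfile]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    metabolites = [c for c in df.columns if c != "sample_id" and not c.endswith(("_accepted", "_residual"))]
    profiles = []
    for _, row in df.iterrows():
        levels, missing, fits = {}, set(), {}
        for m in metabolites:
            accepted_col = f"{m}_accepted"
            accepted = bool(row[accepted_col]) if accepted_col in df.columns else not pd.isna(row[m])
            residual_col = f"{m}_residual"
            residual = float(row[residual_col]) if residual_col in df.columns and not pd.isna(row.get(residual_col)) else np.nan
            if accepted and not pd.isna(row[m]):
                levels[m] = float(row[m])
            else:
                missing.add(m)
            fits[m] = PeakFitResult(m, float(row[m]) if not pd.isna(row[m]) else np.nan, residual, accepted)
        profiles.append(MetaboliteProfile(str(row["sample_id"]), levels, missing, fits))
    return profiles


def profiles_from_levels(levels: pd.DataFrame) -> list[MetaboliteProfile]:
    """Wrap a samples x metabolites levels table (e.g. simulated truth) as profiles."""
    out = []
    for sid, row in levels.iterrows():
        lv = {m: float(v) for m, v in row.items() if not pd.isna(v)}
        missing = {m for m, v in row.items() if pd.isna(v)}
        out.append(MetaboliteProfile(str(sid), lv, missing))
    return out


# --------------------------------------------------------------------------
# FISH counts
# --------------------------------------------------------------------------

def write_fish_counts(fish_counts: dict[str, dict[str, NucleiCounts]], path: str | Path) -> None:
    """One row per nucleus: sample_id, probe, region, test_signals, control_signals."""
    rows = []
    for sid, per_probe in fish_counts.items():
        for probe, counts in per_probe.items():
            regions = counts.regions if counts.regions is not None else np.zeros(counts.n_nuclei, dtype=int)
            for r, t, c in zip(regions, counts.test_signals, counts.control_signals):
                rows.append((sid, probe, int(r), int(t), int(c)))
    pd.DataFrame(rows, columns=["sample_id", "probe", "region", "test_signals", "control_signals"]).to_csv(
        path, sep="\t", index=False
    )


def read_fish_counts(path: str | Path) -> dict[str, dict[str, NucleiCounts]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, dict[str, NucleiCounts]] = {}
    for (sid, probe), sub in df.groupby(["sample_id", "probe"], sort=False):
        out.setdefault(str(sid), {})[str(probe)] = NucleiCounts(
            str(sid),
            str(probe),
            sub["test_signals"].to_numpy(),
            sub["control_signals"].to_numpy(),
            sub["region"].to_numpy(),
        )
    return out


# --------------------------------------------------------------------------
# expression / Ct / metadata tables
# --------------------------------------------------------------------------

def write_expression(matrix: pd.DataFrame, path: str | Path) -> None:
    """First column probeset_id, remaining columns samples, log2 values."""
    out = matrix.copy()
    out.index.name = "probeset_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_expression(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probeset_id", float_precision="round_trip")


def write_ct_table(ct: CtTable, path: str | Path) -> None:
    ct.data.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_ct_table(path: str | Path, reference_gene: str) -> CtTable:
    return CtTable(pd.read_csv(path, sep="\t", float_precision="round_trip"), reference_gene)


def write_samples(samples, path: str | Path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "who_grade": s.who_grade,
            "true_subgroup": s.true_subgroup,
            "recurrence_4y": bool(s.recurrence_4y),
        }
        for s in samples
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_samples(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"who_grade": str}).set_index("sample_id")


# --------------------------------------------------------------------------
# cohort bundle
# --------------------------------------------------------------------------

def write_cohort(bundle: CohortBundle, outdir: str | Path, with_spectra: bool = True) -> Path:
    """Write a simulated cohort as a directory of TSV files plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_samples(bundle.samples, outdir / "samples.tsv")
    truth = bundle.metabolite_truth.copy()
    truth.index.name = "sample_id"
    truth.to_csv(outdir / "metabolites.tsv", sep="\t", float_format="%.17g")
    write_fish_counts(bundle.fish_counts, outdir / "fish_counts.tsv")
    pd.DataFrame(
        {probe: fr for probe, fr in bundle.fish_control_fractions.items()}
    ).to_csv(outdir / "fish_controls.tsv", sep="\t", index=False, float_format="%.17g")
    write_expression(bundle.expression, outdir / "expression.tsv")
    write_ct_table(bundle.ct_table, outdir / "ct.tsv")
    if with_spectra:
        specdir = outdir / "spectra"
        specdir.mkdir(exist_ok=True)
        for sid, spec in bundle.spectra.items():
            write_spectrum(spec, specdir / f"{sid}.tsv")
    manifest = {
        "config": config_as_dict(bundle.config),
        "seed": bundle.config.seed,
        "planted_de_ids": bundle.planted_de_ids,
        "reference_gene": bundle.ct_table.reference_gene,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return outdir


# --------------------------------------------------------------------------
# published differential-expression tables
# --------------------------------------------------------------------------

def _parse_number(token: str, path: str, lineno: int, column: str) -> float:
    """Normalize printed numerics: decimal comma, typographic minus, '<' bounds."""
    t = token.strip().replace("−", "-").replace(",", ".")
    if t.startswith("<"):
        t = t[1:]  # printed as an upper bound; only the bound is recoverable
    try:
        return float(t)
    except ValueError as exc:
        raise ConfigurationError(f"{path}:{lineno}: bad {column} value {token!r}") from exc


def load_published_de_table(path: str | Path) -> list[DERecord]:
    """Parse a printed-table TSV of differentially expressed probe sets.

    Expects the seven columns of the reference table layout; "–" (or an
    empty field) marks missing gene annotation. Raises a parse error
    naming the offending line.
    """
    path = Path(path)
    records: list[DERecord] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 7:
            raise ConfigurationError(f"{path}:1: expected 7 tab-separated columns")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 7:
                raise ConfigurationError(
                    f"{path}:{lineno}: expected 7 fields, found {len(fields)}"
                )
            probeset, title, symbol, location, p_raw, fdr_raw, fc_raw = fields

            def _annot(s: str) -> str | None:
                s = s.strip()
                return None if s in {"–", "-", ""} else s

            records.append(
                DERecord(
                    probeset_id=probeset.strip(),
                    gene_title=_annot(title),
                    gene_symbol=_annot(symbol),
                    chromosomal_location=_annot(location),
                    p_value=_parse_number(p_raw, str(path), lineno, "p-value"),
                    fdr=_parse_number(fdr_raw, str(path), lineno, "FDR"),
                    fold_change=_parse_number(fc_raw, str(path), lineno, "FC"),
                )
            )
    return records


def load_table1_fixture() -> list[DERecord]:
    """The packaged 59-record benignA-vs-benignB reference table."""
    ref = resources.files("meningioma_subgroups").joinpath("data", TABLE1_RESOURCE)
    with resources.as_file(ref) as path:
        return load_published_de_table(path)


def write_de_records(records: list[DERecord], path: str | Path) -> None:
    """DE output TSV mirroring the reference-table columns."""
    rows = [
        {
            "Probeset ID": r.probeset_id,
            "Gene Title": r.gene_title if r.gene_title is not None else "–",
            "Gene Symbol": r.gene_symbol if r.gene_symbol is not None else "–",
            "Chromosomal Location": r.chromosomal_location if r.chromosomal_location is not None else "–",
            "p-value": r.p_value,
            "FDR": r.fdr,
            "FC": r.fold_change,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=DE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_de_records(path: str | Path) -> list[DERecord]:
    return load_published_de_table(path)
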