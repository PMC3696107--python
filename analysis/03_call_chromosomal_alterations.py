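#!/usr/bin/env python
"""Call chromosomal deletions from FISH nuclei counts.

Derives per-probe cutoffs from the non-neoplastic control fractions
(median + 3*SD), scores every nucleus against the deletion ratio rules,
calls each sample/probe at the strict >cutoff threshold, and writes
results/fish_calls.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from meningioma_subgroups import call_probe, derive_cutoff
from meningioma_subgroups import io as mio


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--out", type=Path, default=Path("results/fish_calls.tsv"))
    args = parser.parse_args()

    counts = mio.read_fish_counts(args.cohort / "fish_counts.tsv")
    controls = pd.read_csv(args.cohort / "fish_controls.tsv", sep="\t", float_precision="round_trip")
    cutoffs = {probe: derive_cutoff(controls[probe]) for probe in controls.columns}
    for probe, cutoff in cutoffs.items():
        print(f"  probe {probe}: control-derived cutoff {cutoff:.1%}")

    rows = []
    for sid, per_probe in counts.items():
        for probe, nuclei in per_probe.items():
            call = call_probe(nuclei, cutoff=cutoffs[probe])
            rows.append(
                {
                    "sample_id": sid,
                    "probe": probe,
                    "abnormal_fraction": call.abnormal_fraction,
                    "cutoff_used": call.cutoff_used,
                    "status": call.status,
                    "n_informative": call.n_informative,
                }
            )
    calls = pd.DataFrame(rows)
    calls.to_csv(args.out, sep="\t", index=False, float_format="%.6g")
    rates = calls.groupby("probe")["status"].apply(lambda s: (s == "deletion").mean())
    print(f"wrote {len(calls)} calls -> {args.out}")
    for probe, rate in rates.items():
        print(f"  {probe}: deletion in {rate:.0%} of samples")


if __name__ == "__main__":
    main()
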