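#!/usr/bin/env python
"""Differential expression between the benignA and benignB subgroups.

Applies the combined filter (|FC| >= 2, pooled-t p < 0.005, BH FDR
<= 0.005 over all probes) to the cohort expression matrix using the
labels from the classification step, clusters samples on the selected
probes (1 - Pearson, average linkage), and compares the outcome with the
packaged 59-record published table.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from meningioma_subgroups import hierarchical_cluster, select_de
from meningioma_subgroups import io as mio


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    parser.add_argument("--labels", type=Path, default=Path("results/labels.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results/de.tsv"))
    args = parser.parse_args()

    expr = mio.read_expression(args.cohort / "expression.tsv")
    labels = pd.read_csv(args.labels, sep="\t").set_index("sample_id")["label"]
    benign = labels[labels.isin(["benignA", "benignB"])]
    ordered = list(benign[benign == "benignA"].index) + list(benign[benign == "benignB"].index)

    records = select_de(expr[ordered], benign[ordered])
    mio.write_de_records(records, args.out)
    n_up_a = sum(r.fold_change > 0 for r in records)
    print(f"{len(records)} probes pass the combined filter -> {args.out}")
    print(f"  higher in benignA: {n_up_a}; higher in benignB: {len(records) - n_up_a}")

    manifest = json.loads((args.cohort / "manifest.json").read_text())
    planted = set(manifest.get("planted_de_ids", []))
    if planted:
        selected = {r.probeset_id for r in records}
        print(f"  planted-probe recovery: {len(selected & planted)}/{len(planted)}, "
              f"false positives: {len(selected - planted)}")

    if len(records) >= 2:
        selected_matrix = expr.loc[[r.probeset_id for r in records]]
        _, leaf_order = hierarchical_cluster(selected_matrix)
        pd.DataFrame({"leaf_order": leaf_order}).to_csv(
            args.out.with_name("cluster_leaf_order.tsv"), sep="\t", index=False
        )
        print(f"  clustered {len(leaf_order)} samples on the selected probes")

    published = mio.load_table1_fixture()
    print(f"  published benignA-vs-benignB table: {len(published)} records "
          f"({sum(r.fold_change < 0 for r in published)} higher in benignB)")


if __name__ == "__main__":
    main()
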