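"""Pairwise subtype separability: every pair of subtypes at k = 2.

For each of the six subtype pairs, restricts the cohort to those two
subtypes, re-selects features with each filter method, clusters with
PAM(k=2) on Gower distances, and compares against the pair's all-features
baseline.  Single-feature selections are flagged NC (purity not computed:
the distance matrix needs at least two features).
"""

import argparse
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from gbscluster.data_model import load_dataset
from gbscluster.protocol import ALL_METHODS, pairwise_experiment
from gbscluster.reports import render_pairwise


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", default="results/data/synthetic.csv")
    ap.add_argument("--schema", default="results/data/synthetic.schema")
    ap.add_argument("--transform", default="sqrt")
    ap.add_argument("--out", default="results/pairwise.tsv")
    args = ap.parse_args()

    ds = load_dataset(args.data, args.schema)
    report = pairwise_experiment(ds, ALL_METHODS, k=2, transform=args.transform)
    text = render_pairwise(report, ALL_METHODS, discretization="mdl", init="build")
    os.makedirs(os.path.dirname(args.out), exist_ok=True)
    with open(args.out, "w") as fh:
        fh.write(text)
    print(text)
    wins = sum(
        any(r.purity is not None and r.purity >= report.baselines[pair]
            for r in report.results[pair].values())
        for pair in report.pairs
    )
    print(f"filtered clustering reached the baseline in {wins}/6 pairs")


if __name__ == "__main__":
    main()
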