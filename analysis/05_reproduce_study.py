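#!/usr/bin/env python
"""Reproduce the field study's tables from the deposited matrices.

Expects the seven deposited bat x plant interaction CSVs under
``data/dryad/`` named after ``batplant.study.STUDY_NETWORKS`` (bats as
rows; pass --transpose if exported the other way).  Produces the
study-style metrics table with 1,000-replicate null z-scores, the
between-forest / between-season beta-diversity table, and per-network
sampling completeness.
"""

import argparse
from pathlib import Path

from batplant.dissimilarity import beta_table
from batplant.pipeline import analyze_network, completeness_table, reports_to_table
from batplant.study import STUDY_NETWORKS, STUDY_PAIRS, load_study_matrices

BASE = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=BASE / "data" / "dryad")
    parser.add_argument("--out", type=Path, default=BASE / "results" / "study")
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--nulls", type=int, default=1000)
    parser.add_argument("--transpose", action="store_true")
    args = parser.parse_args()

    nets = load_study_matrices(args.data, transpose=args.transpose)
    order = [n for n in STUDY_NETWORKS if n in nets] + sorted(
        set(nets) - set(STUDY_NETWORKS)
    )
    args.out.mkdir(parents=True, exist_ok=True)

    reports = []
    for name in order:
        report, _ = analyze_network(
            nets[name], name, n_nulls=args.nulls, reps=10, seed=args.seed
        )
        (args.out / f"{name}.report.json").write_text(report.to_json())
        reports.append(report)
    table = reports_to_table(reports)
    table.to_csv(args.out / "structure_table.tsv", sep="\t")
    print(table.to_string(), "\n")

    pairs = [(a, b) for a, b in STUDY_PAIRS if a in nets and b in nets]
    if pairs:
        bt = beta_table(nets, pairs)
        bt.to_csv(args.out / "beta_table.tsv", sep="\t", index=False)
        print(bt.to_string(index=False), "\n")

    ct = completeness_table(nets)
    ct.to_csv(args.out / "completeness.tsv", sep="\t", index=False)
    print(ct.to_string(index=False))


if __name__ == "__main__":
    main()
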