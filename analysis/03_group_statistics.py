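#!/usr/bin/env python
"""Compare conditions for every quantified metric: one-way ANOVA with Tukey
HSD pairwise families on the normalized values, with the four-star
significance convention.

Writes results/comparisons.csv and prints the significant contrasts.
"""

import argparse
from pathlib import Path

from organoquant import cli

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument(
        "--records", type=Path, default=ROOT / "results" / "records.csv"
    )
    parser.add_argument(
        "--out", type=Path, default=ROOT / "results" / "comparisons.csv"
    )
    args = parser.parse_args()

    records = cli.read_table(args.records)
    table = cli.stats_run(records)
    cli.write_table(args.out, table, {"source": args.records.name})

    print(f"{len(table)} pairwise comparisons across "
          f"{table[['assay', 'metric']].drop_duplicates().shape[0]} metrics")
    sig = table[table["p_adjusted"] < 0.05]
    for row in sig.itertuples():
        print(
            f"  {row.metric}: {row.group1} vs {row.group2} "
            f"diff={row.estimate:+.3f} p_adj={row.p_adjusted:.2e} {row.stars}"
        )
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
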