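"""Aggregate raw event streams into annual dyadic count/opportunity tables.

Builds all nine tables (grooming / support / foraging x all partners / adult
females / adult males) from results/data/ and reports the totals, mirroring
the structure of a field study's partner-dataset summary.
"""

import argparse
from pathlib import Path

from capsoc.interactions import build_partner_dataset
from capsoc.io import read_bundle, write_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    bundle = read_bundle(args.results / "data")
    bundle.validate()
    print(f"{'behavior':<10} {'partners':<14} {'dyad-years':>10} {'events':>8} {'opportunities':>14}")
    for behavior in ["grooming", "support", "foraging"]:
        for partners in ["all", "adult_females", "adult_males"]:
            df = build_partner_dataset(bundle, behavior, partners)
            write_table(df, args.results / "dyads" / f"dyads_{behavior}_{partners}.csv")
            print(f"{behavior:<10} {partners:<14} {len(df):>10} "
                  f"{df['count'].sum():>8} {df.opportunities.sum():>14}")


if __name__ == "__main__":
    main()
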