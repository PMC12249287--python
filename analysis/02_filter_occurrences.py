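"""Apply the validity and independence filters to the occurrence records.

Unconfirmed (C3) records are removed outright; of the rest, one record per
area per day is kept. Prints the SCALP composition and the reduction to
independent events, and writes the filtered table for the occupancy stage.
"""

import argparse
from pathlib import Path

import pandas as pd

from wolfrecol import records


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results/inputs"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    occ = pd.read_csv(args.indir / "occurrences.csv", parse_dates=["date"])
    records.validate_occurrences(occ)
    composition = occ["scalp"].value_counts().to_dict()

    kept = records.filter_scalp(occ)
    independent = records.daily_independence(kept)
    independent.to_csv(args.outdir / "occurrences_filtered.csv", index=False)

    print(f"SCALP composition: {composition}")
    print(f"{len(occ)} raw records -> {len(kept)} C1/C2 -> "
          f"{len(independent)} independent events "
          f"({100 * len(independent) / len(occ):.0f}% retained)")


if __name__ == "__main__":
    main()
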