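"""Which landscape covariates separate Permanent from Sporadic cells?

Takes the second-period classifications, screens the covariates for
collinearity (|r| > 0.7), fits every subset as a binomial GLM, ranks by AICc
and model-averages the competitor set (delta AICc < 2).
"""

import argparse
from pathlib import Path

import pandas as pd

from wolfrecol import models


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--indir", type=Path, default=Path("results"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()

    statuses = pd.read_csv(args.indir / "cell_status.csv")
    cov = pd.read_csv(args.indir / "inputs" / "covariates.csv")
    last_period = statuses["period"].iloc[-1]
    occupied = statuses[(statuses["period"] == last_period)
                        & statuses["status"].isin(["Permanent", "Sporadic"])]
    table = occupied.merge(cov, on="cell_id")
    table["status"] = (table["status"] == "Permanent").astype(int)
    covnames = [c for c in cov.columns if c != "cell_id"]
    print(f"{len(table)} occupied cells in {last_period} "
          f"({table['status'].sum()} Permanent, {(1 - table['status']).sum()} Sporadic)")

    kept = models.collinearity_screen(table, covnames)
    dropped = sorted(set(covnames) - set(kept))
    print(f"collinearity screen dropped {dropped}; {len(kept)} covariates -> "
          f"{2 ** len(kept)} candidate models")

    ranking = models.fit_all_subsets(table, kept, screen=False)
    rank_tbl = ranking.table()
    rank_tbl.to_csv(args.outdir / "model_ranking.csv", index=False)
    print(rank_tbl.head(5).round(4).to_string(index=False))

    averaged = models.average_models(ranking)
    pd.DataFrame(averaged.items(), columns=["term", "coefficient"]).to_csv(
        args.outdir / "model_averaged.csv", index=False
    )
    print(f"{len(ranking.competitors)} competitor model(s); "
          f"averaged coefficients: { {k: round(v, 3) for k, v in averaged.items()} }")


if __name__ == "__main__":
    main()
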