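"""Fit the affect and life-satisfaction models under all four pivots.

For each affect (happiness, anxiousness, tiredness) a Bayesian multilevel
model is fitted at the day level with between- and within-person ilr
coordinates, covariates and a person random intercept — unadjusted and
adjusted, once per sign-matrix pivot so each behaviour's
"relative to the rest" coefficient is directly readable.  Life
satisfaction is fitted cross-sectionally by OLS.  Writes the Table 3/4
style coefficient tables and a convergence log to results/.
"""

import argparse
import pickle
from pathlib import Path

import pandas as pd

from timeuse_coda import models, pipeline, preprocess

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--table", type=Path, default=ROOT / "results" / "analysis_table.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    table = pd.read_csv(args.table, parse_dates=["date"])
    bundle = pipeline.fit_bundle(table, seed=args.seed)

    affects = list(preprocess.AFFECTS)
    coef = models.summarize_fits(
        {o: bundle["adjusted"][o] for o in affects},
        {o: bundle["unadjusted"][o] for o in affects},
    )
    coef.to_csv(args.out / "affect_coefficients.csv", index=False)
    ls = models.summarize_linear_fits(
        bundle["adjusted"]["life_satisfaction"],
        bundle["unadjusted"]["life_satisfaction"],
    )
    ls.to_csv(args.out / "life_satisfaction.csv", index=False)
    with open(args.out / "fits.pkl", "wb") as fh:
        pickle.dump(bundle, fh)

    sig = coef.loc[coef["adjusted_significant"]]
    print(f"affect coefficient rows: {len(coef)} (3 outcomes x 2 levels x 4 pivots)")
    print("significant adjusted ilr1 coefficients:")
    print(sig[["outcome", "level", "pivot", "adjusted_mean"]].to_string(index=False)
          if not sig.empty else "  none")
    print("\nlife satisfaction (adjusted):")
    print(ls[["pivot", "adjusted_coef", "adjusted_p", "adjusted_r2"]]
          .round(3).to_string(index=False))


if __name__ == "__main__":
    main()
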