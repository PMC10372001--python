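"""NUE sensitivity to the deposition product choice.

Computes NUE = N_CR / (N_SF + N_MN + N_BNF + N_AD) per country-year from the
budget table, then the two sensitivity parameters against the reference
product: the elementwise NUE difference and the per-country correlation of
NUE series over 1961-2020.  With the synthetic budget all deposition columns
are identical, so differences are exactly zero and correlations exactly one
— the degenerate baseline any real multi-product comparison departs from.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from cropdep.io import read_budget_csv
from cropdep.nue import PRODUCTS, nue_correlation, nue_difference, nue_table

ROOT = Path(__file__).resolve().parent.parent
WORLD = ROOT / "scratch" / "world"
OUT = ROOT / "results" / "nue"
REFERENCE = "wl"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    budget = read_budget_csv(WORLD / "budget.csv")
    tables = {p: nue_table(budget, p) for p in PRODUCTS}
    ref = tables[REFERENCE]
    print(f"reference NUE ({REFERENCE.upper()}), country means over 1961-2020:")
    print(ref.mean(axis=1).round(3).to_string())
    for p in PRODUCTS:
        if p == REFERENCE:
            continue
        diff = nue_difference(tables[p], ref)
        corr = nue_correlation(tables[p], ref)
        diff.to_csv(OUT / f"nue_diff_{p}_vs_{REFERENCE}.csv", na_rep="NaN")
        corr.to_csv(OUT / f"nue_corr_{p}_vs_{REFERENCE}.csv", na_rep="NaN")
        print(f"{p.upper()} vs {REFERENCE.upper()}: max |dNUE| = "
              f"{np.nanmax(np.abs(diff.to_numpy())):.3g}, "
              f"median r = {corr.median():.3f}")


if __name__ == "__main__":
    main()
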