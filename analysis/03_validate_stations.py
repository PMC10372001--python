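"""Compare the built product against station precipitation-chemistry records.

For every country with station records, annualizes the daily wet-deposition
fluxes (conc x precip x 0.01, then 365 x mean over available days) and checks
whether the product's national value for 2000 falls inside the station
interquartile range and the full station range.  Writes one summary row per
country to results/station_validation.csv.
"""

from pathlib import Path

import pandas as pd

from cropdep.io import read_national_table
from cropdep.stations import compare_to_stations, read_station_csv

ROOT = Path(__file__).resolve().parent.parent
WORLD = ROOT / "scratch" / "world"
PRODUCT = ROOT / "results" / "products" / "4_WL.csv"
OUT = ROOT / "results" / "station_validation.csv"


def main():
    table = read_national_table(PRODUCT)
    records = pd.read_csv(WORLD / "stations.csv")
    rows = []
    for code, grp in records.groupby("country"):
        tmp = WORLD / f"_stations_{code}.csv"
        grp.to_csv(tmp, index=False)
        stations = read_station_csv(tmp)
        tmp.unlink()
        summary = compare_to_stations(table.loc[[code]], stations, country=code)
        if 2000 in summary.index:
            row = summary.loc[2000].to_dict()
            row["country"] = code
            rows.append(row)
    out = pd.DataFrame(rows).set_index("country")
    OUT.parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(OUT)
    n = len(out)
    print(f"{n} countries compared for year 2000")
    print(f"product within station range: {int(out['within_range'].sum())}/{n}; "
          f"within IQR: {int(out['within_iqr'].sum())}/{n}")
    print(out[["station_median", "product", "within_iqr", "within_range"]]
          .round(2).to_string())


if __name__ == "__main__":
    main()
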