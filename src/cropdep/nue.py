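"""Nitrogen-use-efficiency sensitivity to the choice of deposition product.

NUE for a country-year is crop N removal over the sum of N inputs:

    NUE = N_CR / (N_SF + N_MN + N_BNF + N_AD)

with synthetic fertilizer (SF), manure (MN), biological fixation (BNF) and
atmospheric deposition (AD), all in the same mass unit.  NUE is not capped
at 1 — soil N mining can push it above.  Sensitivity across deposition
products is summarized by the per-country-year NUE difference against the
reference product and the per-country correlation of NUE series over years.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

BUDGET_COMPONENTS = ("n_cr", "n_sf", "n_mn", "n_bnf")
PRODUCTS = ("ah", "al", "wh", "wl")


def nue(budget: pd.DataFrame, product: str) -> pd.Series:
    """NUE per row of a budget table for one deposition product.

    ``budget`` columns: n_cr, n_sf, n_mn, n_bnf and n_ad_<product>.
    Zero total input gives NaN; negative components are rejected.
    """
    ad_col = f"n_ad_{product.lower()}"
    cols = list(BUDGET_COMPONENTS) + [ad_col]
    missing = [c for c in cols if c not in budget.columns]
    if missing:
        raise ValueError(f"budget table missing columns {missing}")
    vals = budget[cols]
    if (vals.dropna() < 0).any().any():
        raise ValueError("budget components must be non-negative")
    denom = budget["n_sf"] + budget["n_mn"] + budget["n_bnf"] + budget[ad_col]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = budget["n_cr"] / denom.where(denom > 0)
    return out.rename(f"nue_{product.lower()}")


def nue_table(budget: pd.DataFrame, product: str) -> pd.DataFrame:
    """Country x year NUE matrix from a long budget table (country, year rows)."""
    b = budget.set_index(["country", "year"]) if {"country", "year"} <= set(budget.columns) else budget
    s = nue(b.reset_index(), product)
    s.index = pd.MultiIndex.from_frame(b.reset_index()[["country", "year"]])
    return s.unstack("year")


def nue_difference(nue_p: pd.DataFrame, nue_ref: pd.DataFrame) -> pd.DataFrame:
    """Elementwise NUE_p - NUE_ref; NaN propagates; indices must align."""
    if not nue_p.index.equals(nue_ref.index) or not nue_p.columns.equals(nue_ref.columns):
        raise ValueError("NUE tables are misaligned")
    return nue_p - nue_ref


def nue_correlation(nue_p: pd.DataFrame, nue_ref: pd.DataFrame,
                    method: str = "pearson", min_pairs: int = 3) -> pd.Series:
    """Per-country correlation of NUE_p with NUE_ref over years.

    NaN years are pairwise-deleted.  Countries with fewer than ``min_pairs``
    paired years, or a constant series, yield NaN (with a warning for the
    former).
    """
    if not nue_p.index.equals(nue_ref.index):
        raise ValueError("NUE tables are misaligned")
    out = {}
    for c in nue_p.index:
        x = nue_p.loc[c].to_numpy(dtype=float)
        y = nue_ref.loc[c].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < min_pairs:
            warnings.warn(f"country {c}: only {int(ok.sum())} paired years, correlation undefined")
            out[c] = np.nan
            continue
        xs, ys = x[ok], y[ok]
        if np.ptp(xs) == 0 or np.ptp(ys) == 0:
            out[c] = np.nan
            continue
        if method == "pearson":
            out[c] = float(np.corrcoef(xs, ys)[0, 1])
        elif method == "spearman":
            from scipy.stats import spearmanr
            out[c] = float(spearmanr(xs, ys).statistic)
        else:
            raise ValueError("method must be 'pearson' or 'spearman'")
    s = pd.Series(out, name=f"r_{method}")
    s.index.name = "country"
    return s
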