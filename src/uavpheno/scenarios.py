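"""Temporal aggregation of per-plot VI time series.

Three scenarios summarize the multi-date record of each plot:

* **TS-1** — the raw values of one flight date;
* **TS-2** — the mean over flights falling inside the accession's
  anthesis window (inclusive at both ends); if no flight falls inside,
  the two flights bracketing the window midpoint are averaged and the
  row is flagged ``fallback`` so analysts can exclude it;
* **TS-3** — the mean over all available flight dates.

Means are unweighted and missing VI values are simply ignored (the
count of contributing dates is recorded).  Aggregations are invariant
to the ordering of input rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .indices import VI_NAMES

__all__ = ["ts1", "ts2", "ts3", "available_dates"]

_ID_COLS = ("plot_id", "accession_id", "species", "block")


def _id_frame(vi_table: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in _ID_COLS if c in vi_table.columns]
    return vi_table[cols].drop_duplicates("plot_id").set_index("plot_id")

def _vi_cols(vi_table: pd.DataFrame) -> list[str]:
    return [c for c in VI_NAMES if c in vi_table.columns]


def available_dates(vi_table: pd.DataFrame) -> list[int]:
    return sorted(int(d) for d in vi_table["date_das"].dropna().unique())


def ts1(vi_table: pd.DataFrame, date: int) -> pd.DataFrame:
    """Single-date scenario: project out one flight date unchanged."""
    dates = available_dates(vi_table)
    if int(date) not in dates:
        raise ValueError(f"date {date} DAS not present; available dates: {dates}")
    out = vi_table.loc[vi_table["date_das"] == int(date)].copy()
    out["scenario"] = f"TS1@{int(date)}"
    keep = [c for c in _ID_COLS if c in out.columns] + ["scenario"] + _vi_cols(vi_table)
    return out[keep].reset_index(drop=True)


def ts2(vi_table: pd.DataFrame, phenology: pd.DataFrame) -> pd.DataFrame:
    """Anthesis scenario: per plot, mean VI over flights in the window.

    ``vi_table`` must carry ``accession_id`` so each plot can be matched
    to its accession's anthesis window; a missing phenology record is an
    error naming the accession.
    """
    if "accession_id" not in vi_table.columns:
        raise KeyError("vi_table needs an accession_id column for TS-2")
    vi_table = vi_table[vi_table["accession_id"].notna()]
    phen = phenology.set_index("accession_id")
    ids = _id_frame(vi_table)
    vi_cols = _vi_cols(vi_table)
    dates = np.array(available_dates(vi_table))

    rows = []
    for plot_id, grp in vi_table.groupby("plot_id", sort=True):
        acc = ids.loc[plot_id, "accession_id"]
        if acc not in phen.index:
            raise KeyError(f"no phenology record for accession {acc!r}")
        a0 = float(phen.loc[acc, "anthesis_start"])
        a1 = float(phen.loc[acc, "anthesis_end"])
        in_window = dates[(dates >= a0) & (dates <= a1)]
        fallback = False
        if in_window.size == 0:
            mid = (a0 + a1) / 2.0
            below = dates[dates <= mid]
            above = dates[dates > mid]
            picks = []
            if below.size:
                picks.append(int(below.max()))
            if above.size:
                picks.append(int(above.min()))
            in_window = np.array(picks)
            fallback = True
        sel = grp[grp["date_das"].isin(in_window)]
        rec = {"plot_id": plot_id, "scenario": "TS2", "fallback": fallback,
               "dates_used": ";".join(str(int(d)) for d in sorted(in_window))}
        for c in vi_cols:
            vals = sel[c].dropna()
            rec[c] = float(vals.mean()) if len(vals) else np.nan
        rows.append(rec)
    return _reattach_ids(pd.DataFrame(rows), ids, vi_cols)


def ts3(vi_table: pd.DataFrame) -> pd.DataFrame:
    """Full-season scenario: per plot, mean VI over all available dates."""
    vi_cols = _vi_cols(vi_table)
    ids = _id_frame(vi_table)
    rows = []
    for plot_id, grp in vi_table.groupby("plot_id", sort=True):
        rec = {"plot_id": plot_id, "scenario": "TS3"}
        n = 0
        for c in vi_cols:
            vals = grp[c].dropna()
            rec[c] = float(vals.mean()) if len(vals) else np.nan
            n = max(n, len(vals))
        rec["n_dates"] = n
        rows.append(rec)
    return _reattach_ids(pd.DataFrame(rows), ids, vi_cols)


def _reattach_ids(out: pd.DataFrame, ids: pd.DataFrame, vi_cols: list[str]) -> pd.DataFrame:
    merged = out.merge(ids, left_on="plot_id", right_index=True, how="left")
    lead = ["plot_id"] + [c for c in _ID_COLS[1:] if c in merged.columns] + ["scenario"]
    extra = [c for c in merged.columns if c not in lead + vi_cols]
    return merged[lead + vi_cols + [c for c in extra if c != "plot_id"]]
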