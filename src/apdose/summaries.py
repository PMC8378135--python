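"""Summary statistics over exposure assessments.

Medians and quartiles of the total chlorpromazine-equivalent daily dose by
administration-route stratum and timepoint, the share of patients whose total
was modified by data cleaning, the share on concurrent (>= 2 distinct drugs)
therapy, and box-plot data (type-7 linear-interpolation quantiles, whiskers
at the most extreme values within 1.5 x IQR of the quartiles) comparing raw
and cleaned totals.

Empty strata are simply absent from the outputs, never reported as zero.
Percentages are rounded to one decimal in written files only; functions
return full precision.
"""

from __future__ import annotations

from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "assessments_frame",
    "median_dose_by_route",
    "percent_modified",
    "percent_concurrent",
    "summary_table",
    "dose_distribution_plot_data",
]


def assessments_frame(assessments: Iterable) -> pd.DataFrame:
    rows = [
        dict(
            patient_id=a.patient_id,
            timepoint_days=a.timepoint_days,
            route_class=a.route_class.value,
            n_claims=len(a.contributing_claim_ids),
            n_drugs=a.n_drugs,
            total_cpz_mg_raw=a.total_cpz_mg_raw,
            total_cpz_mg_cleaned=a.total_cpz_mg_cleaned,
            modified_by_cleaning=a.modified_by_cleaning,
        )
        for a in assessments
    ]
    cols = ["patient_id", "timepoint_days", "route_class", "n_claims", "n_drugs",
            "total_cpz_mg_raw", "total_cpz_mg_cleaned", "modified_by_cleaning"]
    return pd.DataFrame(rows, columns=cols)


def _as_frame(assessments) -> pd.DataFrame:
    if isinstance(assessments, pd.DataFrame):
        return assessments
    return assessments_frame(assessments)


def median_dose_by_route(assessments) -> pd.DataFrame:
    """n, median, Q1, Q3 of cleaned totals per (timepoint, route stratum)."""
    df = _as_frame(assessments)
    rows = []
    for (t, route), g in df.groupby(["timepoint_days", "route_class"], sort=True):
        v = g["total_cpz_mg_cleaned"].to_numpy(dtype=float)
        rows.append(
            dict(
                timepoint_days=t,
                route_class=route,
                n=len(v),
                median_cpz_mg=float(np.percentile(v, 50)),
                q1_cpz_mg=float(np.percentile(v, 25)),
                q3_cpz_mg=float(np.percentile(v, 75)),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["timepoint_days", "route_class", "n", "median_cpz_mg", "q1_cpz_mg", "q3_cpz_mg"],
    )


def percent_modified(assessments) -> pd.DataFrame:
    """Percent of patients whose total dose was modified by cleaning, per stratum."""
    df = _as_frame(assessments)
    rows = []
    for (t, route), g in df.groupby(["timepoint_days", "route_class"], sort=True):
        rows.append(
            dict(
                timepoint_days=t,
                route_class=route,
                n=len(g),
                percent_modified=100.0 * float(g["modified_by_cleaning"].mean()),
            )
        )
    return pd.DataFrame(rows, columns=["timepoint_days", "route_class", "n", "percent_modified"])


def percent_concurrent(assessments) -> pd.DataFrame:
    """Percent of assessed patients with >= 2 distinct contributing drugs, per timepoint."""
    df = _as_frame(assessments)
    rows = []
    for t, g in df.groupby("timepoint_days", sort=True):
        rows.append(
            dict(
                timepoint_days=t,
                n=len(g),
                percent_concurrent=100.0 * float((g["n_drugs"] >= 2).mean()),
            )
        )
    return pd.DataFrame(rows, columns=["timepoint_days", "n", "percent_concurrent"])


def summary_table(assessments) -> pd.DataFrame:
    """Stratified summary: dose quartiles and cleaning impact per stratum,
    with per-timepoint active counts and concurrency merged in."""
    med = median_dose_by_route(assessments)
    mod = percent_modified(assessments)
    conc = percent_concurrent(assessments)
    out = med.merge(mod, on=["timepoint_days", "route_class", "n"])
    out = out.merge(
        conc.rename(columns={"n": "n_active"}), on="timepoint_days", how="left"
    )
    out["percent_modified"] = out["percent_modified"].round(1)
    out["percent_concurrent"] = out["percent_concurrent"].round(1)
    return out


def dose_distribution_plot_data(assessments, timepoint_days: int) -> pd.DataFrame:
    """Box-plot table at one timepoint: raw and cleaned totals side by side.

    Whiskers extend to the smallest/largest observations within 1.5 x IQR of
    the quartiles; observations beyond them are listed as outliers.
    """
    df = _as_frame(assessments)
    df = df[df["timepoint_days"] == timepoint_days]
    rows = []
    for route, g in df.groupby("route_class", sort=True):
        for label, col in (("raw", "total_cpz_mg_raw"), ("cleaned", "total_cpz_mg_cleaned")):
            v = np.sort(g[col].to_numpy(dtype=float))
            q1, med, q3 = (float(np.percentile(v, p)) for p in (25, 50, 75))
            iqr = q3 - q1
            lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            inside = v[(v >= lo_fence) & (v <= hi_fence)]
            outliers = v[(v < lo_fence) | (v > hi_fence)]
            rows.append(
                dict(
                    timepoint_days=timepoint_days,
                    route_class=route,
                    field=label,
                    n=len(v),
                    q1=q1,
                    median=med,
                    q3=q3,
                    whisker_low=float(inside.min()),
                    whisker_high=float(inside.max()),
                    outliers=";".join(repr(float(x)) for x in outliers),
                )
            )
    return pd.DataFrame(
        rows,
        columns=["timepoint_days", "route_class", "field", "n", "q1", "median", "q3",
                 "whisker_low", "whisker_high", "outliers"],
    )
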