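"""Cell-based validation assays: FACS proliferation z-scores and
live-imaging relative proliferation.

The FACS assay follows the fraction of fluorescent (construct-positive)
cells over a multi-day time course; within each experiment and
timepoint, replicate percentages are averaged per variant and normalized
across the variant panel as Z-scores.  A variant is a proliferation hit
in an experiment when its Z-score exceeds the cutoff (default +-0.8)
with the same sign on at least two timepoints of that experiment.

The live-imaging assay integrates cell-confluency area over a time
interval per variant and replicate, normalizes by the median across all
variants, and compares each variant against a designated reference with
Welch's two-sided t-test (star codes at 0.05 / 0.01 / 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["facs_zscores", "call_proliferation_hits",
           "relative_proliferation"]

_FACS_COLS = ("experiment", "timepoint", "variant", "replicate",
              "pct_yfp_positive")


def facs_zscores(table: pd.DataFrame, average_replicates: bool = True
                 ) -> pd.DataFrame:
    """Z-scores of percent-positive cells across variants per stratum.

    Parameters
    ----------
    table : DataFrame
        Long format with columns ``experiment``, ``timepoint``,
        ``variant``, ``replicate``, ``pct_yfp_positive`` (0-100).
    average_replicates : bool
        Average replicates within (experiment, timepoint, variant)
        before z-scoring (default).

    Returns
    -------
    DataFrame with columns experiment, timepoint, variant, pct_mean, z.
    """
    missing = set(_FACS_COLS) - set(table.columns)
    if missing:
        raise ValueError(f"FACS table lacks columns {sorted(missing)}")
    pct = table["pct_yfp_positive"].to_numpy(float)
    if np.any((pct < 0) | (pct > 100)):
        raise ValueError("percentages must lie in [0, 100]")
    if average_replicates:
        per_var = (table.groupby(["experiment", "timepoint", "variant"],
                                 sort=True)["pct_yfp_positive"]
                   .mean().rename("pct_mean").reset_index())
    else:
        per_var = table.rename(columns={"pct_yfp_positive": "pct_mean"})[
            ["experiment", "timepoint", "variant", "pct_mean"]]

    grp = per_var.groupby(["experiment", "timepoint"], sort=True)["pct_mean"]
    sizes = grp.transform("size")
    if int(sizes.min()) < 3:
        raise ValueError("each (experiment, timepoint) stratum needs >= 3 "
                         "variants for z-scoring")
    sd = grp.transform("std")            # ddof=1
    z = (per_var["pct_mean"] - grp.transform("mean")) / sd
    per_var = per_var.assign(z=z.where(sd > 0, 0.0))
    return per_var.sort_values(["experiment", "timepoint", "variant"],
                               ignore_index=True)


def call_proliferation_hits(zscores: pd.DataFrame, cutoff: float = 0.8,
                            min_timepoints: int = 2) -> pd.DataFrame:
    """Two-timepoint |Z| >= cutoff hit rule, same sign required.

    A variant is a hit in an experiment when its Z-score is beyond the
    cutoff (inclusive) in the same direction on at least
    ``min_timepoints`` timepoints of that experiment.  Returns one row
    per (experiment, variant) hit with the direction and the qualifying
    timepoints.
    """
    rows = []
    for (exp, var), g in zscores.groupby(["experiment", "variant"], sort=True):
        for sign in (1, -1):
            qual = g[(sign * g["z"]) >= cutoff]
            if len(qual) >= min_timepoints:
                rows.append((exp, var, "up" if sign > 0 else "down",
                             len(qual),
                             ",".join(str(t) for t in sorted(qual["timepoint"]))))
    return pd.DataFrame(rows, columns=["experiment", "variant", "direction",
                                       "n_timepoints", "timepoints"])


@dataclass
class ProliferationResult:
    table: pd.DataFrame           # variant, replicate values, normalized, p, stars
    reference: str
    norm_factor: float


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def relative_proliferation(
    series: pd.DataFrame,
    reference: str,
    t_start: Optional[float] = None,
    t_end: Optional[float] = None,
) -> ProliferationResult:
    """Median-normalized proliferation with Welch t-tests vs a reference.

    Parameters
    ----------
    series : DataFrame
        Long format with columns ``variant``, ``replicate``, ``time``,
        ``confluency``; times strictly increasing within a replicate.
    reference : str
        Variant against which the Welch two-sided t-test is run (scaling
        by the common median does not change the test).
    t_start, t_end : float, optional
        Interval over which confluency area is integrated (trapezoid);
        defaults to the full common range.

    Returns
    -------
    ProliferationResult with a per-variant table: mean normalized
    proliferation, replicate n, p-value and star code.
    """
    need = {"variant", "replicate", "time", "confluency"}
    if need - set(series.columns):
        raise ValueError(f"series lacks columns {sorted(need - set(series.columns))}")

    per_rep = []
    for (var, rep), g in series.groupby(["variant", "replicate"], sort=True):
        g = g.sort_values("time")
        t = g["time"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"times not strictly increasing for {var}/{rep}")
        lo = t_start if t_start is not None else t[0]
        hi = t_end if t_end is not None else t[-1]
        m = (t >= lo) & (t <= hi)
        if m.sum() < 2:
            raise ValueError(f"interval [{lo}, {hi}] covers < 2 points for {var}/{rep}")
        area = float(np.trapezoid(g["confluency"].to_numpy(float)[m], t[m]))
        per_rep.append((var, rep, area))
    rep_df = pd.DataFrame(per_rep, columns=["variant", "replicate", "area"])

    per_var = rep_df.groupby("variant", sort=True)["area"].mean()
    norm = float(per_var.median())
    if norm == 0:
        raise ValueError("median proliferation is zero; cannot normalize")
    if reference not in per_var.index:
        raise ValueError(f"reference variant {reference!r} absent")

    ref_vals = rep_df.loc[rep_df["variant"] == reference, "area"].to_numpy()
    rows = []
    for var, vals in rep_df.groupby("variant", sort=True)["area"]:
        v = vals.to_numpy()
        if var == reference:
            p = 1.0
        else:
            p = float(stats.ttest_ind(v, ref_vals, equal_var=False).pvalue)
        rows.append((var, len(v), float(v.mean()) / norm, p, _stars(p)))
    table = pd.DataFrame(rows, columns=["variant", "n_replicates",
                                        "normalized_proliferation", "p_value",
                                        "stars"])
    return ProliferationResult(table, reference, norm)
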