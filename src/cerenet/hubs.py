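"""Hub detection and metric–response-time correlation.

A hub profile counts, per ROI, the fraction of subjects in a population
whose maximum betweenness (or degree) lands on that ROI; ties credit every
tied ROI, so fractions can sum above 1.  The response-time analysis
correlates each ROI's metric values across subjects with their median
response times (MRT) and selects the ROI with the largest positive
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class HubProfile:
    """Per-ROI argmax fractions for one population and metric."""

    fractions: pd.Series  # index = ROI labels
    population: str
    metric: str
    n_subjects: int

    def top_roi(self) -> str:
        return str(self.fractions.idxmax())


@dataclass
class MrtCorrelation:
    """Per-ROI Pearson r (and p) between a tree metric and MRT."""

    r: pd.Series  # index = ROI labels, NaN where undefined
    p: pd.Series
    best_roi: str | None  # ROI with the largest positive r (or largest |r|)
    n_subjects: int


def hub_fractions(
    metric_table: pd.DataFrame,
    population: np.ndarray | pd.Series | None = None,
    population_label: str = "all",
    metric_name: str = "",
    tie_tolerance: float = 1e-12,
) -> HubProfile:
    """Fraction of subjects whose metric maximum falls on each ROI.

    ``metric_table`` is subjects x ROIs; ``population`` is a boolean mask or
    index selecting the subjects to count.  Every ROI within
    ``tie_tolerance`` of a subject's maximum is credited.
    """
    table = metric_table if population is None else metric_table.loc[population]
    if len(table) == 0:
        raise ValueError("population is empty")
    values = table.to_numpy(float)
    peaks = values.max(axis=1, keepdims=True)
    hits = values >= peaks - tie_tolerance
    fractions = pd.Series(hits.mean(axis=0), index=metric_table.columns)
    return HubProfile(fractions, population_label, metric_name, len(table))


def mrt_correlation(
    metric_table: pd.DataFrame,
    mrt: np.ndarray | pd.Series,
    population: np.ndarray | pd.Series | None = None,
    select_by_abs: bool = False,
) -> MrtCorrelation:
    """Correlate each ROI's metric with MRT across a subject population.

    p-values come from the two-sided t distribution with n-2 degrees of
    freedom.  ROIs with a constant metric are reported NaN; the selected
    ``best_roi`` is the ROI with the largest positive r (or largest |r|
    when ``select_by_abs``), None when every ROI is undefined or, in the
    default mode, no ROI correlates positively.
    """
    mrt = pd.Series(np.asarray(mrt, dtype=float), index=metric_table.index)
    if population is not None:
        metric_table = metric_table.loc[population]
        mrt = mrt.loc[population]
    n = len(metric_table)
    if n < 4:
        raise ValueError(f"need at least 4 subjects, got {n}")
    mrt_values = mrt.to_numpy()
    if np.ptp(mrt_values) == 0:
        raise ValueError("MRT is constant across the population")
    r_vals, p_vals = {}, {}
    for roi in metric_table.columns:
        col = metric_table[roi].to_numpy(float)
        if np.ptp(col) == 0:  # exact constancy; std can carry float dust
            r_vals[roi] = np.nan
            p_vals[roi] = np.nan
            continue
        r, p = stats.pearsonr(col, mrt_values)
        r_vals[roi] = float(r)
        p_vals[roi] = float(p)
    r_series = pd.Series(r_vals)
    p_series = pd.Series(p_vals)
    if r_series.isna().all():
        raise ValueError("metric is constant at every ROI")
    if select_by_abs:
        best = r_series.abs().idxmax()
    else:
        positive = r_series[r_series > 0]
        best = positive.idxmax() if len(positive) else None
    return MrtCorrelation(r_series, p_series, None if best is None else str(best), n)
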