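"""Group statistics: log transform, one-way unbalanced ANOVA, BH-FDR.

The comparison design log-transforms each metric (natural log with a tiny
additive constant so exact zeros stay finite), runs a classic pooled-variance
one-way ANOVA on two unequal-size groups per metric, and controls the false
discovery rate across the metric family within each contrast with the
Benjamini–Hochberg step-up procedure at alpha = 0.05.  Reported group means
and SDs stay on the original metric scale; only inference runs on the
transformed scale.

The degree-correlation metric is negative, so it is shifted by +1 before the
log transform (mapping (-1, 1] onto (0, 2]); the shift is recorded on the
result rows it affects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

#: Additive constant guarding ln(0).
LOG_EPS = 1e-24
DEFAULT_ALPHA = 0.05

#: Global metrics entering the group comparisons.
GLOBAL_METRICS = (
    "c_w", "l_w", "sigma", "conn",
    "d", "r", "l_f", "t_h", "kappa", "r_deg",
)

#: Metrics that can be negative and need a +1 shift before the log transform.
SHIFTED_METRICS = frozenset({"r_deg"})

#: The five population contrasts of the study design, as
#: (label, filter for side A, filter for side B) with filters on
#: (group, gender); None matches anything.
FIVE_CONTRASTS: tuple[tuple[str, tuple, tuple], ...] = (
    ("low_vs_high", ("low", None), ("high", None)),
    ("male_low_vs_male_high", ("low", "male"), ("high", "male")),
    ("female_low_vs_female_high", ("low", "female"), ("high", "female")),
    ("male_vs_female_within_low", ("low", "male"), ("low", "female")),
    ("male_vs_female_within_high", ("high", "male"), ("high", "female")),
)


@dataclass
class ComparisonResult:
    """One metric within one contrast."""

    contrast: str
    metric: str
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    n_a: int
    n_b: int
    f_statistic: float
    p_value: float
    p_fdr: float = np.nan
    significant: bool = False
    shifted: bool = False  # +1 shift applied before log transform
    degenerate: bool = False  # zero within-group variance with unequal means


def log_transform(values: np.ndarray | pd.Series, shift: float = 0.0) -> np.ndarray:
    """x -> ln(x + shift + 1e-24), elementwise."""
    arr = np.asarray(values, dtype=float) + shift
    if np.any(arr <= -LOG_EPS):
        raise ValueError("log transform undefined for values <= -1e-24")
    return np.log(arr + LOG_EPS)


def one_way_anova(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Classic fixed-effects one-way ANOVA for two unequal-size groups.

    F = MS_between / MS_within on (1, n_a + n_b - 2) degrees of freedom.
    Zero within-group variance yields F = 0, p = 1 when the means agree and
    F = inf, p = 0 when they differ.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    n = len(a) + len(b)
    grand = np.concatenate([a, b]).mean()
    ss_between = len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    ss_within = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    df_between, df_within = 1, n - 2
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return float(f), p


def fdr_bh(
    p_values: np.ndarray | list[float], alpha: float = DEFAULT_ALPHA
) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: adjusted p-values and rejection flags."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adjusted, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adjusted, reject


@dataclass
class ContrastDesign:
    """Contrast list plus the metric family tested within each contrast."""

    contrasts: tuple = FIVE_CONTRASTS
    metrics: tuple = GLOBAL_METRICS
    alpha: float = DEFAULT_ALPHA
    fdr_family: str = "per_contrast"  # or "global"
    #: "error" raises on a contrast side with < 2 subjects; "skip" drops the
    #: contrast with a log entry (useful for small pilot cohorts)
    on_insufficient: str = "error"


def run_contrasts(
    table: pd.DataFrame,
    design: ContrastDesign | None = None,
) -> pd.DataFrame:
    """Run every contrast of the design over its metric family.

    ``table`` holds one row per subject with ``group`` and ``gender``
    columns plus one column per metric.  Per contrast and metric the values
    are log-transformed (shifting the degree correlation by +1), compared by
    one-way unbalanced ANOVA, and BH-corrected across the metric family; the
    returned frame mirrors the published layout (original-scale means ± SD,
    F, p, corrected p, significance flag).
    """
    design = design or ContrastDesign()
    if "subject_id" in table and table["subject_id"].duplicated().any():
        raise ValueError("duplicated subject ids in metric table")
    rows: list[ComparisonResult] = []
    for label, filt_a, filt_b in design.contrasts:
        side_a = _select(table, *filt_a)
        side_b = _select(table, *filt_b)
        if len(side_a) < 2 or len(side_b) < 2:
            if design.on_insufficient == "skip":
                logger.warning(
                    "contrast %s skipped: population sizes %d / %d",
                    label, len(side_a), len(side_b),
                )
                continue
            raise ValueError(
                f"contrast {label!r} has an empty or too-small population "
                f"({len(side_a)} / {len(side_b)} subjects)"
            )
        contrast_rows: list[ComparisonResult] = []
        for metric in design.metrics:
            if metric not in table.columns:
                logger.warning("metric %s absent from table; skipped", metric)
                continue
            a = side_a[metric].to_numpy(float)
            b = side_b[metric].to_numpy(float)
            if np.isnan(a).any() or np.isnan(b).any():
                logger.warning(
                    "metric %s undefined for some subjects in %s; skipped",
                    metric, label,
                )
                continue
            shift = 1.0 if metric in SHIFTED_METRICS else 0.0
            f, p = one_way_anova(log_transform(a, shift), log_transform(b, shift))
            contrast_rows.append(
                ComparisonResult(
                    contrast=label,
                    metric=metric,
                    mean_a=float(a.mean()), sd_a=float(a.std(ddof=1)),
                    mean_b=float(b.mean()), sd_b=float(b.std(ddof=1)),
                    n_a=len(a), n_b=len(b),
                    f_statistic=f, p_value=p,
                    shifted=shift != 0,
                    degenerate=not np.isfinite(f),
                )
            )
        if design.fdr_family == "per_contrast":
            _apply_fdr(contrast_rows, design.alpha)
        rows.extend(contrast_rows)
    if design.fdr_family == "global":
        _apply_fdr(rows, design.alpha)
    return pd.DataFrame([vars(r) for r in rows])


def _apply_fdr(rows: list[ComparisonResult], alpha: float) -> None:
    if not rows:
        return
    adjusted, reject = fdr_bh([r.p_value for r in rows], alpha)
    for row, p_adj, rej in zip(rows, adjusted, reject):
        row.p_fdr = float(p_adj)
        row.significant = bool(rej)


def _select(table: pd.DataFrame, group: str | None, gender: str | None) -> pd.DataFrame:
    mask = pd.Series(True, index=table.index)
    if group is not None:
        mask &= table["group"] == group
    if gender is not None:
        mask &= table["gender"] == gender
    return table[mask]
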