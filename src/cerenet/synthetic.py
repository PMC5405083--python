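"""Synthetic cohort generator.

Produces ROI time-series and subject metadata with the statistical structure
the downstream network analysis assumes: modular correlation blocks, an
optional planted hub region, per-group scaling of connectivity, a left-skewed
discrete score distribution, and an optional planted correlation between a
tree metric and median response time (MRT) in one group.

The temporal model is multivariate Gaussian noise with a configurable target
correlation matrix and an optional AR(1) filter; it makes no attempt to model
hemodynamics, scanner noise or motion.  Its purpose is to give every stage of
the pipeline inputs whose ground truth is known exactly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Default number of cerebellar regions after excluding Vermis Crus I.
DEFAULT_N_ROIS = 27
#: Default number of frames in a 15-minute resting-state run.
DEFAULT_N_FRAMES = 1200
#: Default repetition time in seconds.
DEFAULT_TR = 0.72

#: Cohort sizes and male fractions emulating the study population:
#: 69 low-IQ subjects (25 male / 44 female), 67 high-IQ (29 male / 38 female).
DEFAULT_GROUP_SIZES = {"low": 69, "high": 67}
DEFAULT_MALE_FRACTION = {"low": 25 / 69, "high": 29 / 67}

#: Score intervals used to assign scores consistent with a subject's group.
GROUP_SCORE_INTERVALS = {"low": (4, 10), "high": (22, 24), "mid": (11, 21)}

#: Log-scale parameters of the MRT marginal (milliseconds).  The median of
#: exp(9.6) ~ 14.8 s is typical of matrix-reasoning item response times.
DEFAULT_MRT_LOG_MU = 9.6
DEFAULT_MRT_LOG_SIGMA = 0.35


@dataclass
class SubjectRecord:
    """Per-subject metadata row."""

    subject_id: str
    gender: str  # "male" | "female"
    iq_score: int  # correct responses, in [3, 27]
    median_response_time: float  # milliseconds, > 0
    group: str  # "low" | "high" | "mid" | "excluded"

    def __post_init__(self) -> None:
        if not (3 <= self.iq_score <= 27):
            raise ValueError(f"iq_score {self.iq_score} outside [3, 27]")
        if self.median_response_time <= 0:
            raise ValueError("median_response_time must be positive")
        if self.gender not in ("male", "female"):
            raise ValueError(f"unknown gender {self.gender!r}")


@dataclass
class CohortConfig:
    """Parameters of a synthetic cohort.

    ``group_sizes`` maps group label to subject count.  ``group_effects``
    maps group label to ``(within_multiplier, between_multiplier)`` applied
    to the correlation targets, so density/clustering differences between
    groups can be planted.  ``mrt_link`` is ``(group, roi_index, rho)``: the
    MRT of subjects in that group is generated with population correlation
    approximately ``rho`` against a caller-supplied per-subject metric at
    that ROI (Gaussian-copula construction with a log-normal marginal).
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_rois: int = DEFAULT_N_ROIS
    n_frames: int = DEFAULT_N_FRAMES
    sampling_interval: float = DEFAULT_TR
    module_assignment: np.ndarray | None = None  # ROI -> community label
    n_modules: int = 4
    within_module_corr: float = 0.35
    between_module_corr: float = 0.10
    hub_roi: int | None = None
    hub_boost: float = 0.0
    group_effects: dict[str, tuple[float, float]] | None = None
    mrt_link: tuple[str, int, float] | None = None
    male_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MALE_FRACTION)
    )
    ar_coefficient: float = 0.0
    mrt_log_mu: float = DEFAULT_MRT_LOG_MU
    mrt_log_sigma: float = DEFAULT_MRT_LOG_SIGMA
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.between_module_corr <= self.within_module_corr < 1.0):
            raise ValueError(
                "need 0 <= between_module_corr <= within_module_corr < 1, got "
                f"between={self.between_module_corr}, within={self.within_module_corr}"
            )
        if self.module_assignment is None:
            self.module_assignment = default_module_assignment(
                self.n_rois, self.n_modules
            )
        else:
            self.module_assignment = np.asarray(self.module_assignment)
            if self.module_assignment.shape != (self.n_rois,):
                raise ValueError("module_assignment must have length n_rois")
        if self.hub_roi is not None and not (0 <= self.hub_roi < self.n_rois):
            raise ValueError(f"hub_roi {self.hub_roi} outside [0, {self.n_rois})")
        if self.mrt_link is not None:
            group, roi, rho = self.mrt_link
            if group not in self.group_sizes:
                raise ValueError(f"mrt_link group {group!r} not in group_sizes")
            if not (0 <= roi < self.n_rois):
                raise ValueError(f"mrt_link ROI {roi} outside [0, {self.n_rois})")
            if abs(rho) >= 1:
                raise ValueError(f"mrt_link correlation {rho} must satisfy |rho| < 1")

    def roi_labels(self) -> list[str]:
        return [f"ROI{i:02d}" for i in range(self.n_rois)]


def default_module_assignment(n_rois: int, n_modules: int) -> np.ndarray:
    """Contiguous, near-equal community blocks (e.g. 27 ROIs -> 7/7/7/6)."""
    sizes = np.full(n_modules, n_rois // n_modules)
    sizes[: n_rois % n_modules] += 1
    return np.repeat(np.arange(n_modules), sizes)


# ---------------------------------------------------------------------------
# Correlation targets
# ---------------------------------------------------------------------------

def build_correlation_target(
    config: CohortConfig,
    within: float | None = None,
    between: float | None = None,
) -> np.ndarray:
    """Target correlation matrix implied by the cohort configuration.

    Entries are ``within`` inside a community and ``between`` across
    communities; the hub ROI's row/column is raised by ``hub_boost`` and
    clipped below 1.  The result is repaired to positive semi-definiteness
    by clipping negative eigenvalues at zero and re-normalising the diagonal;
    a repair is logged.  A target whose smallest eigenvalue is below -0.5
    before repair is rejected as a configuration error.
    """
    within = config.within_module_corr if within is None else within
    between = config.between_module_corr if between is None else between
    modules = config.module_assignment
    same = modules[:, None] == modules[None, :]
    target = np.where(same, within, between).astype(float)
    if config.hub_roi is not None and config.hub_boost:
        i = config.hub_roi
        target[i, :] += config.hub_boost
        target[:, i] += config.hub_boost
        np.clip(target, None, 0.99, out=target)
    np.fill_diagonal(target, 1.0)

    eigvals = np.linalg.eigvalsh(target)
    if eigvals[0] < -0.5:
        raise ValueError(
            f"correlation target is not repairable (min eigenvalue {eigvals[0]:.3f})"
        )
    if eigvals[0] < -1e-10:
        target = _clip_to_psd(target)
        logger.warning(
            "correlation target repaired to PSD (min eigenvalue was %.4f)",
            eigvals[0],
        )
    return target


def _clip_to_psd(matrix: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(matrix)
    vals = np.clip(vals, 0.0, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    return (repaired + repaired.T) / 2


# ---------------------------------------------------------------------------
# Time-series sampling
# ---------------------------------------------------------------------------

def sample_timeseries(
    target: np.ndarray,
    n_frames: int,
    rng: np.random.Generator | int,
    ar_coefficient: float = 0.0,
) -> np.ndarray:
    """Draw a frames x ROIs Gaussian series with the given target correlation.

    An optional AR(1) filter (``x_t = phi x_{t-1} + e_t``) adds temporal
    smoothness; because the filter is applied to each latent component before
    mixing, the cross-ROI correlation structure is unchanged in expectation.
    """
    if n_frames < 3:
        raise ValueError("n_frames must be >= 3 for downstream correlation")
    rng = np.random.default_rng(rng)
    n = target.shape[0]
    vals, vecs = np.linalg.eigh(np.asarray(target, dtype=float))
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    latent = rng.standard_normal((n_frames, n))
    if ar_coefficient:
        phi = float(ar_coefficient)
        if not (-1.0 < phi < 1.0):
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        for t in range(1, n_frames):
            latent[t] = phi * latent[t - 1] + math.sqrt(1 - phi**2) * latent[t]
    return latent @ root.T


# ---------------------------------------------------------------------------
# Metadata simulation
# ---------------------------------------------------------------------------

def sample_iq_scores(rng: np.random.Generator, n: int, lam: float = 11.0) -> np.ndarray:
    """Left-skewed discrete scores on [3, 27].

    Scores are 27 minus a Poisson(``lam``) error count (a right tail of
    misses), rejection-sampled into [3, 27]; the default rate puts the median
    near 16 with negative skewness.
    """
    out = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        draw = 27 - rng.poisson(lam, size=2 * (n - filled) + 16)
        draw = draw[(draw >= 3) & (draw <= 27)]
        take = min(len(draw), n - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _iq_score_for_group(rng: np.random.Generator, group: str) -> int:
    """Rejection-sample the global score distribution into a group interval."""
    lo, hi = GROUP_SCORE_INTERVALS.get(group, (3, 27))
    while True:
        score = int(sample_iq_scores(rng, 1)[0])
        if lo <= score <= hi:
            return score


def _latent_link_coefficient(z_metric: np.ndarray, sigma: float, rho: float) -> float:
    """Latent Gaussian coefficient that plants a Pearson correlation ``rho``.

    MRT is log-normal: exp(mu + sigma * (a * X + sqrt(1 - a^2) * eps)) with
    X the standardised metric.  Because the exponential marginal both
    attenuates the correlation and, for skewed X, inflates it through the
    X–Z^2 term, the naive choice a = rho misses the target.  The Pearson
    correlation implied by a is available in closed form over the empirical
    distribution of X, so ``a`` is found by root bisection:

        corr(a) = cov(X, e^{sigma a X}) * e^{b^2/2}
                  / sqrt(E[e^{2 sigma a X}] e^{2 b^2} - E[e^{sigma a X}]^2 e^{b^2})

    with b^2 = sigma^2 (1 - a^2) the residual log-scale variance.
    """
    from scipy.optimize import brentq

    if rho == 0:
        return 0.0
    x = np.asarray(z_metric, dtype=float)

    def implied_corr(a: float) -> float:
        ex = np.exp(sigma * a * x)
        cov = float(np.mean(x * ex) - x.mean() * ex.mean())
        b2 = sigma**2 * (1 - a**2)
        var_mrt = float(np.mean(ex**2)) * math.exp(2 * b2) - float(
            np.mean(ex)
        ) ** 2 * math.exp(b2)
        return cov * math.exp(b2 / 2) / math.sqrt(var_mrt)

    hi = 0.999999
    if not implied_corr(-hi) <= rho <= implied_corr(hi):
        raise ValueError(
            f"target correlation {rho} not attainable with the log-normal "
            "marginal for this metric distribution"
        )
    return float(brentq(lambda a: implied_corr(a) - rho, -hi, hi, xtol=1e-10))


def simulate_metadata(
    config: CohortConfig,
    per_subject_metric: np.ndarray | None = None,
    groups: list[str] | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[SubjectRecord]:
    """Generate subject records (gender, score, MRT, group).

    ``per_subject_metric`` is a subjects x ROIs array of metric values and is
    required when ``config.mrt_link`` is set: MRT for linked-group subjects
    is built with a Gaussian copula so its population correlation with the
    metric at the planted ROI is approximately the requested ``rho`` (the
    log-normal marginal attenuates it by under 4% at the default spread).
    """
    rng = np.random.default_rng(config.seed if rng is None else rng)
    if groups is None:
        groups = [
            g for g, size in config.group_sizes.items() for _ in range(size)
        ]
    n = len(groups)
    if config.mrt_link is not None:
        if per_subject_metric is None:
            raise ValueError("mrt_link requires per_subject_metric")
        per_subject_metric = np.asarray(per_subject_metric, dtype=float)
        if per_subject_metric.shape != (n, config.n_rois):
            raise ValueError(
                f"per_subject_metric must be {n} x {config.n_rois}, "
                f"got {per_subject_metric.shape}"
            )

    z = rng.standard_normal(n)
    if config.mrt_link is not None:
        group, roi, rho = config.mrt_link
        mask = np.array([g == group for g in groups])
        metric = per_subject_metric[mask, roi]
        if metric.std() == 0:
            raise ValueError("metric at linked ROI is constant; cannot plant link")
        z_metric = (metric - metric.mean()) / metric.std()
        rho_latent = _latent_link_coefficient(z_metric, config.mrt_log_sigma, rho)
        # orthogonalise the noise against the metric so the planted
        # correlation is controlled in-sample, not just in expectation
        eps = z[mask]
        eps = eps - eps.mean() - z_metric * float(np.mean(eps * z_metric))
        eps /= eps.std()
        z[mask] = rho_latent * z_metric + math.sqrt(1 - rho_latent**2) * eps
    mrt = np.exp(config.mrt_log_mu + config.mrt_log_sigma * z)

    records = []
    for i, group in enumerate(groups):
        male_frac = config.male_fraction.get(group, 0.5)
        gender = "male" if rng.random() < male_frac else "female"
        records.append(
            SubjectRecord(
                subject_id=f"S{i:04d}",
                gender=gender,
                iq_score=_iq_score_for_group(rng, group),
                median_response_time=float(mrt[i]),
                group=group,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Whole-cohort convenience
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Generated time-series plus the group label of each subject.

    Metadata (scores, gender, MRT) is attached by :func:`simulate_metadata`,
    usually after tree metrics have been computed so an MRT link can be
    planted against real metric values.
    """

    config: CohortConfig
    timeseries: list[np.ndarray]  # frames x ROIs per subject
    groups: list[str]
    roi_labels: list[str]

    @property
    def n_subjects(self) -> int:
        return len(self.timeseries)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Sample one time-series matrix per subject, honouring group effects."""
    rng = np.random.default_rng(config.seed)
    effects = config.group_effects or {}
    targets = {}
    for group in config.group_sizes:
        w_mult, b_mult = effects.get(group, (1.0, 1.0))
        targets[group] = build_correlation_target(
            config,
            within=min(config.within_module_corr * w_mult, 0.99),
            between=min(config.between_module_corr * b_mult, 0.99),
        )
    series, groups = [], []
    for group, size in config.group_sizes.items():
        for _ in range(size):
            series.append(
                sample_timeseries(
                    targets[group], config.n_frames, rng, config.ar_coefficient
                )
            )
            groups.append(group)
    return SyntheticCohort(config, series, groups, config.roi_labels())


# ---------------------------------------------------------------------------
# Benchmark weighted graphs
# ---------------------------------------------------------------------------

def modular_small_world_graph(
    seed: int | np.random.Generator = 0,
    n_rois: int = DEFAULT_N_ROIS,
    n_modules: int = 4,
    within_weight: float = 0.6,
    between_weight: float = 0.2,
    between_density: float = 0.3,
    hub_rois: tuple[int, ...] = (0, 7, 14),
    hub_weight: float = 0.6,
    jitter: float = 0.05,
) -> np.ndarray:
    """Clustered modular weighted graph with hub shortcuts.

    Within-module edges are uniformly strong; between-module edges are
    present with probability ``between_density`` at moderate weight; hub
    nodes connect strongly to every module.  The combination of dense
    local triangles and hub shortcuts is the weighted small-world
    archetype: clustering well above a rewired null at comparable path
    length.  Note a fully dense block graph is useless as a benchmark
    here — with every edge present there is nothing for a degree- and
    weight-preserving rewiring to change.
    """
    rng = np.random.default_rng(seed)
    modules = default_module_assignment(n_rois, n_modules)
    hubs = set(hub_rois)
    weights = np.zeros((n_rois, n_rois))
    for i in range(n_rois):
        for j in range(i + 1, n_rois):
            if modules[i] == modules[j]:
                w = within_weight + jitter * rng.standard_normal()
            elif i in hubs or j in hubs:
                w = hub_weight + jitter * rng.standard_normal()
            elif rng.random() < between_density:
                w = between_weight + jitter * rng.standard_normal()
            else:
                continue
            weights[i, j] = weights[j, i] = float(np.clip(w, 0.01, 0.99))
    return weights


def ring_lattice_graph(
    seed: int | np.random.Generator = 0,
    n_rois: int = DEFAULT_N_ROIS,
    neighbours: int = 4,
    n_shortcuts: int = 0,
    lattice_weight: float = 0.6,
    shortcut_weight: float = 0.6,
    jitter: float = 0.05,
) -> np.ndarray:
    """Weighted ring lattice, optionally with random shortcut edges.

    With no shortcuts this is the maximally segregated reference
    (clustering far above any rewired null); a handful of shortcuts turns
    it into the classic Watts–Strogatz small-world graph.
    """
    rng = np.random.default_rng(seed)
    weights = np.zeros((n_rois, n_rois))
    for i in range(n_rois):
        for step in range(1, neighbours // 2 + 1):
            j = (i + step) % n_rois
            w = float(np.clip(lattice_weight + jitter * rng.standard_normal(), 0.01, 0.99))
            weights[i, j] = weights[j, i] = w
    added = 0
    while added < n_shortcuts:
        i, j = rng.integers(0, n_rois, size=2)
        if i != j and weights[i, j] == 0:
            w = float(np.clip(shortcut_weight + jitter * rng.standard_normal(), 0.01, 0.99))
            weights[i, j] = weights[j, i] = w
            added += 1
    return weights


def write_cohort(
    cohort: SyntheticCohort,
    records: list[SubjectRecord],
    out_dir,
) -> None:
    """Write per-subject TSVs (frames x ROIs) and a metadata CSV."""
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for record, values in zip(records, cohort.timeseries):
        pd.DataFrame(values, columns=cohort.roi_labels).to_csv(
            out_dir / f"{record.subject_id}_timeseries.tsv", sep="\t", index=False
        )
    metadata_frame(records).to_csv(out_dir / "metadata.csv", index=False)


def metadata_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "gender": [r.gender for r in records],
            "iq_score": [r.iq_score for r in records],
            "mrt": [r.median_response_time for r in records],
            "group": [r.group for r in records],
        }
    )
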