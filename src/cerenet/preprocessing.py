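"""Input preparation: ROI atlases, time-series, connectivity, score groups.

Turns raw inputs (per-ROI time-series tables, or a 4D volume plus an integer
label volume) into the analysis-ready objects the network stages consume:
an ordered ROI atlas with exclusions applied, frames x ROIs time-series,
symmetric nonnegative connectivity matrices, and per-subject group labels
derived from score intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import SubjectRecord

#: The 28 cerebellar lobule labels of the SUIT anatomical parcellation,
#: in conventional atlas order.  Vermis Crus I is vanishingly small
#: (<0.005% of cerebellar volume) and is excluded by default downstream.
SUIT_LOBULE_LABELS: tuple[str, ...] = (
    "Left I-IV", "Right I-IV",
    "Left V", "Right V",
    "Left VI", "Vermis VI", "Right VI",
    "Left Crus I", "Vermis Crus I", "Right Crus I",
    "Left Crus II", "Vermis Crus II", "Right Crus II",
    "Left VIIb", "Vermis VIIb", "Right VIIb",
    "Left VIIIa", "Vermis VIIIa", "Right VIIIa",
    "Left VIIIb", "Vermis VIIIb", "Right VIIIb",
    "Left IX", "Vermis IX", "Right IX",
    "Left X", "Vermis X", "Right X",
)

DEFAULT_EXCLUSIONS: tuple[str, ...] = ("Vermis Crus I",)

#: Score intervals printed for the study population: low scorers 4-10
#: (median minus one quartile down to above the floor), high scorers 22-24,
#: with the two floor scores of 3 removed outright.
DEFAULT_LOW_INTERVAL: tuple[int, int] = (4, 10)
DEFAULT_HIGH_INTERVAL: tuple[int, int] = (22, 24)
DEFAULT_REMOVAL_SCORES: frozenset[int] = frozenset({3})


@dataclass
class RoiAtlas:
    """Ordered ROI naming shared by every downstream matrix."""

    roi_labels: list[str]
    roi_ids: list[int] | None = None
    voxel_counts: list[int] | None = None

    def __post_init__(self) -> None:
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("ROI labels must be unique")
        if self.roi_ids is None:
            self.roi_ids = list(range(1, len(self.roi_labels) + 1))
        if len(self.roi_ids) != len(self.roi_labels):
            raise ValueError("roi_ids length must match roi_labels")
        if len(set(self.roi_ids)) != len(self.roi_ids) or min(self.roi_ids) <= 0:
            raise ValueError("roi_ids must be unique positive integers")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)


def suit_atlas() -> RoiAtlas:
    """The 28-lobule cerebellar atlas with ids 1..28 in label order."""
    return RoiAtlas(list(SUIT_LOBULE_LABELS))


def exclude_rois(atlas: RoiAtlas, exclusion_names: list[str]) -> RoiAtlas:
    """Drop named ROIs, preserving the original relative order."""
    unknown = [name for name in exclusion_names if name not in atlas.roi_labels]
    if unknown:
        raise ValueError(f"unknown ROI name(s): {unknown}")
    excluded = set(exclusion_names)
    keep = [i for i, name in enumerate(atlas.roi_labels) if name not in excluded]
    return RoiAtlas(
        [atlas.roi_labels[i] for i in keep],
        [atlas.roi_ids[i] for i in keep],
        None if atlas.voxel_counts is None else [atlas.voxel_counts[i] for i in keep],
    )


@dataclass
class RoiTimeSeries:
    """Frames x ROIs signal matrix in atlas order."""

    values: np.ndarray
    roi_labels: list[str]
    sampling_interval: float = 0.72

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (frames x ROIs)")
        if self.values.shape[0] < 3:
            raise ValueError("need at least 3 frames")
        if self.values.shape[1] != len(self.roi_labels):
            raise ValueError(
                f"{self.values.shape[1]} columns but {len(self.roi_labels)} labels"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("time-series contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]


@dataclass
class ConnectivityMatrix:
    """Symmetric nonnegative weighted adjacency over ROIs.

    The diagonal is stored as exactly 0 so the matrix doubles as an
    adjacency matrix; negative correlations are treated as absent edges.
    """

    weights: np.ndarray
    roi_labels: list[str]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        n = len(self.roi_labels)
        if self.weights.shape != (n, n):
            raise ValueError("weights must be square and match roi_labels")
        if not np.allclose(self.weights, self.weights.T, atol=1e-12):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(self.weights) != 0):
            raise ValueError("diagonal must be exactly 0")
        if self.weights.min() < 0 or self.weights.max() > 1:
            raise ValueError("weights must lie in [0, 1]")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)


def extract_roi_means(
    volume_series: np.ndarray,
    label_volume: np.ndarray,
    atlas: RoiAtlas,
    sampling_interval: float = 0.72,
) -> RoiTimeSeries:
    """Average the 4D signal over each ROI's voxels, per frame.

    ``volume_series`` is (x, y, z, frames); ``label_volume`` is an integer
    (x, y, z) field with 0 as background, sharing the spatial grid.
    """
    volume_series = np.asarray(volume_series, dtype=float)
    label_volume = np.asarray(label_volume)
    if volume_series.ndim != 4:
        raise ValueError("volume_series must be 4-D (x, y, z, frames)")
    if label_volume.shape != volume_series.shape[:3]:
        raise ValueError(
            f"spatial grid mismatch: labels {label_volume.shape} vs "
            f"volumes {volume_series.shape[:3]}"
        )
    n_frames = volume_series.shape[3]
    out = np.empty((n_frames, atlas.n_rois))
    for col, (roi_id, name) in enumerate(zip(atlas.roi_ids, atlas.roi_labels)):
        mask = label_volume == roi_id
        if not mask.any():
            raise ValueError(f"ROI {name!r} (id {roi_id}) absent from label volume")
        out[:, col] = volume_series[mask].mean(axis=0)
    return RoiTimeSeries(out, list(atlas.roi_labels), sampling_interval)


def extract_roi_means_nifti(
    volume_path, label_path, atlas: RoiAtlas, sampling_interval: float = 0.72
) -> RoiTimeSeries:
    """NIfTI front-end for :func:`extract_roi_means`."""
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(volume_path)).dataobj)
    labels = np.asanyarray(nib.load(str(label_path)).dataobj).astype(int)
    return extract_roi_means(vol, labels, atlas, sampling_interval)


def form_iq_groups(
    records: list[SubjectRecord],
    low_interval: tuple[int, int] = DEFAULT_LOW_INTERVAL,
    high_interval: tuple[int, int] = DEFAULT_HIGH_INTERVAL,
    removal_scores: frozenset[int] | set[int] = DEFAULT_REMOVAL_SCORES,
) -> tuple[list[SubjectRecord], dict[str, int]]:
    """Assign each record to low / high / mid / excluded by its score.

    Returns new records (inputs are not mutated) plus per-group counts.
    """
    low_lo, low_hi = low_interval
    high_lo, high_hi = high_interval
    if low_lo > low_hi or high_lo > high_hi:
        raise ValueError("intervals must be [lo, hi] with lo <= hi")
    if low_hi >= high_lo:
        raise ValueError(
            f"low interval {low_interval} must lie strictly below high {high_interval}"
        )
    out = []
    counts = {"low": 0, "high": 0, "mid": 0, "excluded": 0}
    for record in records:
        score = record.iq_score
        if score in removal_scores:
            group = "excluded"
        elif low_lo <= score <= low_hi:
            group = "low"
        elif high_lo <= score <= high_hi:
            group = "high"
        else:
            group = "mid"
        counts[group] += 1
        out.append(
            SubjectRecord(
                record.subject_id,
                record.gender,
                score,
                record.median_response_time,
                group,
            )
        )
    return out, counts


def build_connectivity(ts: RoiTimeSeries) -> ConnectivityMatrix:
    """Pearson-correlation connectivity with negatives discarded.

    w_ij is the correlation of ROI columns i and j, floored at 0 (an absent
    edge); the diagonal is set to 0.
    """
    stds = ts.values.std(axis=0)
    dead = np.flatnonzero(stds == 0)
    if dead.size:
        names = [ts.roi_labels[i] for i in dead]
        raise ValueError(f"zero-variance ROI column(s): {names}")
    weights = np.corrcoef(ts.values, rowvar=False)
    weights = np.clip(weights, 0.0, 1.0)
    np.fill_diagonal(weights, 0.0)
    weights = (weights + weights.T) / 2
    return ConnectivityMatrix(weights, list(ts.roi_labels))


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def read_timeseries(path, sampling_interval: float = 0.72) -> RoiTimeSeries:
    """Read a frames x ROIs TSV/CSV with an ROI-name header row."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    frame = pd.read_csv(path, sep=sep)
    return RoiTimeSeries(frame.to_numpy(float), list(frame.columns), sampling_interval)


def read_metadata(path) -> list[SubjectRecord]:
    """Read a metadata CSV (subject_id, gender, iq_score, mrt[, group])."""
    frame = pd.read_csv(path)
    return [
        SubjectRecord(
            str(row.subject_id),
            str(row.gender),
            int(row.iq_score),
            float(row.mrt),
            str(getattr(row, "group", "mid")),
        )
        for row in frame.itertuples(index=False)
    ]


def write_connectivity(conn: ConnectivityMatrix, path) -> None:
    pd.DataFrame(conn.weights, index=conn.roi_labels, columns=conn.roi_labels).to_csv(
        path, sep="\t"
    )


def read_connectivity(path) -> ConnectivityMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(frame.to_numpy(float), list(frame.columns))
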