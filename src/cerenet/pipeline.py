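"""End-to-end orchestration: simulate -> connect -> metrics -> mst -> hubs -> compare.

``run_all`` executes the full analysis on either a synthetic cohort or a
directory of per-subject time-series TSVs plus a metadata CSV, writes every
intermediate table (connectivity matrices, tree edge lists, subject x metric
panel, hub profiles, MRT correlations, contrast results) under the output
directory, and records a JSON manifest with the seed, configuration hash and
per-stage row counts so runs are reproducible and stages re-runnable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import hubs as hubs_mod
from . import mst as mst_mod
from . import network as net_mod
from . import preprocessing as prep
from . import stats as stats_mod
from . import synthetic as synth

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: Path
    simulation: synth.CohortConfig | None = None
    input_dir: Path | None = None  # per-subject TSVs + metadata.csv
    n_null: int = 100
    alpha: float = stats_mod.DEFAULT_ALPHA
    seed: int = 0
    exclusions: tuple[str, ...] = prep.DEFAULT_EXCLUSIONS
    low_interval: tuple[int, int] = prep.DEFAULT_LOW_INTERVAL
    high_interval: tuple[int, int] = prep.DEFAULT_HIGH_INTERVAL
    removal_scores: frozenset[int] = prep.DEFAULT_REMOVAL_SCORES
    write_intermediates: bool = True

    def __post_init__(self) -> None:
        if self.simulation is None and self.input_dir is None:
            raise ValueError("need either a simulation config or an input directory")
        if self.input_dir is not None and not Path(self.input_dir).exists():
            raise FileNotFoundError(f"input directory not found: {self.input_dir}")


@dataclass
class RunResult:
    metric_table: pd.DataFrame  # one row per subject
    local_tables: dict[str, pd.DataFrame]  # metric -> subjects x ROIs
    hub_profiles: list[hubs_mod.HubProfile]
    mrt_correlations: dict[str, hubs_mod.MrtCorrelation]
    contrast_results: pd.DataFrame
    manifest: dict = field(default_factory=dict)


def run_all(config: RunConfig) -> RunResult:
    """Run every stage and persist all tables plus a manifest."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    # --- stage 1: inputs -------------------------------------------------
    if config.simulation is not None:
        sim = config.simulation
        cohort = synth.generate_cohort(sim)
        series = [
            prep.RoiTimeSeries(v, cohort.roi_labels, sim.sampling_interval)
            for v in cohort.timeseries
        ]
        subject_ids = [f"S{i:04d}" for i in range(len(series))]
        records = None  # built after tree metrics, so an MRT link can be planted
        groups = cohort.groups
    else:
        input_dir = Path(config.input_dir)
        meta_path = input_dir / "metadata.csv"
        if not meta_path.exists():
            raise FileNotFoundError(f"metadata file not found: {meta_path}")
        records = prep.read_metadata(meta_path)
        records, counts = prep.form_iq_groups(
            records, config.low_interval, config.high_interval, config.removal_scores
        )
        logger.info("group counts: %s", counts)
        series, kept = [], []
        for record in records:
            ts_path = input_dir / f"{record.subject_id}_timeseries.tsv"
            if not ts_path.exists():
                raise FileNotFoundError(
                    f"time-series for subject {record.subject_id} not found: {ts_path}"
                )
            series.append(prep.read_timeseries(ts_path))
            kept.append(record)
        records = kept
        subject_ids = [r.subject_id for r in records]
        groups = [r.group for r in records]

    # --- stage 2: connectivity ------------------------------------------
    conn_mats = []
    for sid, ts in zip(subject_ids, series):
        try:
            conn_mats.append(prep.build_connectivity(ts))
        except ValueError as err:
            raise RuntimeError(f"connectivity stage failed for {sid}: {err}") from err

    # --- stage 3: small-world panel -------------------------------------
    sw_rows = []
    for sid, conn in zip(subject_ids, conn_mats):
        child_seed = int(rng.integers(0, 2**31 - 1))
        sw = net_mod.small_worldness(conn, n_null=config.n_null, seed=child_seed)
        sw_rows.append(
            dict(subject_id=sid, c_w=sw.c_w, l_w=sw.l_w, gamma=sw.gamma,
                 lam=sw.lam, sigma=sw.sigma, conn=sw.conn)
        )
    sw_table = pd.DataFrame(sw_rows)

    # --- stage 4: spanning trees ----------------------------------------
    trees, global_rows = [], []
    local_vectors = {"deg": [], "bc": [], "ecc": []}
    for sid, conn in zip(subject_ids, conn_mats):
        try:
            tree = mst_mod.maximum_spanning_tree(conn)
        except mst_mod.DisconnectedGraphError as err:
            raise RuntimeError(f"spanning-tree stage failed for {sid}: {err}") from err
        trees.append(tree)
        local = mst_mod.local_metrics(tree)
        gmetrics = mst_mod.global_metrics(tree, local)
        local_vectors["deg"].append(local.degree)
        local_vectors["bc"].append(local.betweenness)
        local_vectors["ecc"].append(local.eccentricity)
        global_rows.append(
            dict(subject_id=sid, d=gmetrics.diameter, r=gmetrics.radius,
                 l_f=gmetrics.leaf_fraction, t_h=gmetrics.tree_hierarchy,
                 kappa=gmetrics.kappa, r_deg=gmetrics.degree_correlation)
        )
    roi_labels = conn_mats[0].roi_labels
    local_tables = {
        name: pd.DataFrame(np.vstack(vecs), index=subject_ids, columns=roi_labels)
        for name, vecs in local_vectors.items()
    }
    global_table = pd.DataFrame(global_rows)

    # --- stage 5: metadata (simulated cohorts only) ---------------------
    if records is None:
        link_metric = local_tables["deg"].to_numpy()
        records = synth.simulate_metadata(
            config.simulation, per_subject_metric=link_metric, groups=groups, rng=rng
        )
        for record, sid in zip(records, subject_ids):
            record.subject_id = sid

    meta = synth.metadata_frame(records)
    metric_table = meta.merge(sw_table, on="subject_id").merge(
        global_table, on="subject_id"
    )

    # --- stage 6: hubs and MRT correlations -----------------------------
    populations = _populations(metric_table)
    hub_profiles = []
    for pop_label, mask in populations.items():
        if not mask.any():
            continue
        for metric_name in ("bc", "deg"):
            hub_profiles.append(
                hubs_mod.hub_fractions(
                    local_tables[metric_name], mask.to_numpy(),
                    population_label=pop_label, metric_name=metric_name,
                )
            )
    mrt_correlations = {}
    for pop_label, mask in populations.items():
        if mask.sum() < 4:
            continue
        mrt = metric_table.loc[mask, "mrt"].to_numpy()
        for metric_name in ("bc", "deg"):
            subtable = local_tables[metric_name].loc[mask.to_numpy()]
            try:
                mrt_correlations[f"{pop_label}_{metric_name}"] = hubs_mod.mrt_correlation(
                    subtable, mrt
                )
            except ValueError as err:
                logger.warning("MRT correlation skipped for %s: %s", pop_label, err)

    # --- stage 7: group contrasts ---------------------------------------
    design = stats_mod.ContrastDesign(alpha=config.alpha, on_insufficient="skip")
    contrast_results = stats_mod.run_contrasts(metric_table, design)

    manifest = {
        "seed": config.seed,
        "n_null": config.n_null,
        "alpha": config.alpha,
        "n_subjects": len(subject_ids),
        "n_rois": len(roi_labels),
        "n_connectivity_matrices": len(conn_mats),
        "n_spanning_trees": len(trees),
        "n_contrast_rows": len(contrast_results),
        "config_hash": _config_hash(config),
    }

    if config.write_intermediates:
        _write_outputs(
            out_dir, config, conn_mats, trees, subject_ids, metric_table,
            local_tables, hub_profiles, mrt_correlations, contrast_results, manifest,
        )
    return RunResult(
        metric_table, local_tables, hub_profiles, mrt_correlations,
        contrast_results, manifest,
    )


def _populations(metric_table: pd.DataFrame) -> dict[str, pd.Series]:
    pops = {}
    for group in ("low", "high"):
        in_group = metric_table["group"] == group
        pops[group] = in_group
        for gender in ("male", "female"):
            pops[f"{group}_{gender}"] = in_group & (metric_table["gender"] == gender)
    return pops


def _config_hash(config: RunConfig) -> str:
    blob = repr(config).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_outputs(
    out_dir, config, conn_mats, trees, subject_ids, metric_table,
    local_tables, hub_profiles, mrt_correlations, contrast_results, manifest,
) -> None:
    conn_dir = out_dir / "connectivity"
    tree_dir = out_dir / "trees"
    conn_dir.mkdir(exist_ok=True)
    tree_dir.mkdir(exist_ok=True)
    for sid, conn, tree in zip(subject_ids, conn_mats, trees):
        prep.write_connectivity(conn, conn_dir / f"{sid}_connectivity.tsv")
        pd.DataFrame(
            [(tree.roi_labels[i], tree.roi_labels[j], w) for i, j, w in tree.edges],
            columns=["node_i", "node_j", "weight"],
        ).to_csv(tree_dir / f"{sid}_mst.tsv", sep="\t", index=False)
    metric_table.to_csv(out_dir / "metrics.tsv", sep="\t", index=False)
    for name, table in local_tables.items():
        table.to_csv(out_dir / f"local_{name}.tsv", sep="\t")
    if hub_profiles:
        pd.DataFrame(
            {f"{h.population}_{h.metric}": h.fractions for h in hub_profiles}
        ).to_csv(out_dir / "hub_fractions.tsv", sep="\t")
    if mrt_correlations:
        pd.DataFrame(
            {key: corr.r for key, corr in mrt_correlations.items()}
        ).to_csv(out_dir / "mrt_correlations.tsv", sep="\t")
        pd.DataFrame(
            [
                dict(population=key, best_roi=corr.best_roi, n=corr.n_subjects)
                for key, corr in mrt_correlations.items()
            ]
        ).to_csv(out_dir / "mrt_best_roi.tsv", sep="\t", index=False)
    contrast_results.to_csv(out_dir / "contrasts.tsv", sep="\t", index=False)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
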