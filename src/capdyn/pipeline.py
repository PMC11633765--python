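"""End-to-end orchestration of the CAP analysis.

Given per-subject inputs (series + motion + nuisance + covariates), the
pipeline preprocesses each subject, selects high-seed-activation frames,
builds reference CAPs from the pooled control frames (consensus-scanned K
or a fixed override), assigns patient frames against the reference
thresholds, derives per-subject state sequences and temporal metrics, and
runs the covariate-adjusted group comparisons with FDR within three
families: entries, durations, and the K x K transition cells.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assign as assign_mod
from . import cluster as cluster_mod
from . import dynamics as dyn_mod
from . import frames as frames_mod
from . import preproc as preproc_mod
from . import stats as stats_mod
from .config import AnalysisConfig
from .synth import SubjectBundle
from .types import SeedMask, UNASSIGNED

__all__ = ["PipelineResult", "run_pipeline"]

log = logging.getLogger("capdyn")


@dataclass
class PipelineResult:
    """Everything a run produces, in memory."""

    config: AnalysisConfig
    chosen_k: int
    consensus: cluster_mod.ConsensusResult | None
    caps: cluster_mod.CAPSet
    sequences: dict[str, dyn_mod.StateSequence]
    metrics: dict[str, dyn_mod.TemporalMetrics]
    covariates: pd.DataFrame
    metric_tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    group_stats: dict[str, pd.DataFrame] = field(default_factory=dict)
    unassigned_counts: dict[str, int] = field(default_factory=dict)

    def metric_frame(self, family: str) -> pd.DataFrame:
        return self.metric_tables[family]


def _metric_tables(
    metrics: dict[str, dyn_mod.TemporalMetrics], k: int
) -> dict[str, pd.DataFrame]:
    """Wide per-subject tables: one column per CAP metric / transition cell."""
    idx = list(metrics)
    ent = pd.DataFrame(
        {f"entries_cap{j + 1}": [metrics[s].entries[j] for s in idx] for j in range(k)},
        index=idx,
    )
    dur = pd.DataFrame(
        {
            f"duration_cap{j + 1}": [metrics[s].mean_duration[j] for s in idx]
            for j in range(k)
        },
        index=idx,
    )
    occ = pd.DataFrame(
        {f"occupancy_cap{j + 1}": [metrics[s].occupancy[j] for s in idx] for j in range(k)},
        index=idx,
    )
    trans = pd.DataFrame(
        {
            f"T_cap{m + 1}_to_cap{n + 1}": [metrics[s].transition[m, n] for s in idx]
            for m in range(k)
            for n in range(k)
        },
        index=idx,
    )
    return {"entries": ent, "duration": dur, "occupancy": occ, "transition": trans}


def run_pipeline(
    subjects: list[SubjectBundle],
    seed: SeedMask | np.ndarray,
    config: AnalysisConfig | None = None,
    until: str = "stats",
) -> PipelineResult:
    """Run the full analysis on a cohort of subject bundles.

    ``seed`` is a SeedMask over the series' voxel index (or a flat index
    array of seed voxels, turned into a binary mask).  ``until`` stops
    the run early at one of: preprocess, select, cluster, assign,
    metrics, stats.
    """
    config = config or AnalysisConfig()
    stages = ("preprocess", "select", "cluster", "assign", "metrics", "stats")
    if until not in stages:
        raise ValueError(f"unknown stage {until!r}")
    stop = stages.index(until)

    n_voxels = subjects[0].series.n_voxels
    if not isinstance(seed, SeedMask):
        w = np.zeros(n_voxels)
        w[np.asarray(seed, dtype=np.intp)] = 1.0
        seed = SeedMask(weights=w)

    # -- preprocess ---------------------------------------------------------
    preprocessed: dict[str, object] = {}
    n_excluded: dict[str, int] = {}
    for sub in subjects:
        series, excl = preproc_mod.preprocess(
            sub.series,
            sub.motion,
            wm=sub.nuisance["wm"].to_numpy() if sub.nuisance is not None else None,
            csf=sub.nuisance["csf"].to_numpy() if sub.nuisance is not None else None,
            global_signal=config.global_signal,
            highpass_hz=config.highpass_hz,
            fd_threshold_mm=config.fd_threshold_mm,
            head_radius_mm=config.head_radius_mm,
            smooth_fwhm_vox=config.smooth_fwhm_vox,
        )
        preprocessed[sub.subject_id] = series
        n_excluded[sub.subject_id] = excl
        log.info("preprocessed %s: %d frames excluded", sub.subject_id, excl)

    # -- frame selection ----------------------------------------------------
    framesets = {}
    if stop >= 1:
        value = (
            config.select_z if config.select_mode == "z_threshold" else config.top_fraction
        )
        for sub in subjects:
            fs = frames_mod.select_frames(
                preprocessed[sub.subject_id],
                seed,
                mode=config.select_mode,
                value=value,
                subject_id=sub.subject_id,
            )
            framesets[sub.subject_id] = fs
            log.info("selected %d frames for %s", fs.n_frames, sub.subject_id)

    # -- reference clustering on pooled control frames ----------------------
    consensus = None
    caps = None
    chosen_k = config.fixed_k or 0
    control_ids = [s.subject_id for s in subjects if s.group == "control"]
    patient_ids = [s.subject_id for s in subjects if s.group != "control"]
    if stop >= 2:
        pooled = np.vstack([framesets[s].data for s in control_ids])
        pooled_owner = np.concatenate(
            [np.full(framesets[s].n_frames, i) for i, s in enumerate(control_ids)]
        )
        if config.fixed_k is None:
            consensus = cluster_mod.consensus_cluster(
                pooled,
                k_range=config.k_range,
                n_subsamples=config.n_subsamples,
                subsample_frac=config.subsample_frac,
                rng_seed=config.rng_seed,
                pac_bounds=config.pac_bounds,
            )
            chosen_k = cluster_mod.select_k(consensus)
            log.info("PAC table: %s", consensus.table())
        caps = cluster_mod.kmeans_final(
            pooled,
            chosen_k,
            n_restarts=config.n_restarts,
            rng_seed=config.rng_seed,
            assign_percentile=config.assign_percentile,
        )
        log.info("chose K=%d, member counts %s", chosen_k, caps.member_counts.tolist())

    # -- assignment + state sequences ---------------------------------------
    sequences: dict[str, dyn_mod.StateSequence] = {}
    unassigned: dict[str, int] = {}
    if stop >= 3:
        # Controls keep their k-means labels unless symmetric re-assignment
        # is requested; patients always go through the threshold.
        offsets = np.cumsum([0] + [framesets[s].n_frames for s in control_ids])
        for sub in subjects:
            fs = framesets[sub.subject_id]
            if sub.subject_id in control_ids and not config.reassign_controls:
                i = control_ids.index(sub.subject_id)
                labels = caps.labels[offsets[i] : offsets[i + 1]]
            else:
                labels = assign_mod.assign_frames(fs, caps)
            unassigned[sub.subject_id] = int(np.sum(labels == UNASSIGNED))
            sequences[sub.subject_id] = dyn_mod.build_state_sequence(
                n_frames=preprocessed[sub.subject_id].n_frames,
                frame_valid=preprocessed[sub.subject_id].frame_valid,
                selected_indices=fs.indices,
                assigned_labels=labels,
                k=caps.k,
                tr=preprocessed[sub.subject_id].tr,
                subject_id=sub.subject_id,
            )

    # -- temporal metrics ----------------------------------------------------
    metrics: dict[str, dyn_mod.TemporalMetrics] = {}
    metric_tables: dict[str, pd.DataFrame] = {}
    if stop >= 4:
        for sid, seq in sequences.items():
            metrics[sid] = dyn_mod.compute_metrics(seq, gap_mode=config.gap_mode)
        metric_tables = _metric_tables(metrics, caps.k)

    # -- covariates ----------------------------------------------------------
    cov = pd.DataFrame([s.covariates for s in subjects]).set_index("subject_id")
    cov["n_excluded"] = pd.Series(n_excluded)
    if framesets:
        cov["n_selected"] = pd.Series({s: framesets[s].n_frames for s in framesets})
    cov["sex"] = (cov.get("sex", "F").astype(str) == "F").astype(int)

    # -- group statistics ----------------------------------------------------
    group_stats: dict[str, pd.DataFrame] = {}
    if stop >= 5 and patient_ids and control_ids:
        for family in ("entries", "duration", "transition"):
            table = metric_tables[family].loc[cov.index]
            group_stats[family] = stats_mod.compare_metrics(table, cov)
        log.info("group comparison done (sign convention: patient - control)")

    return PipelineResult(
        config=config,
        chosen_k=chosen_k if caps is None else caps.k,
        consensus=consensus,
        caps=caps,
        sequences=sequences,
        metrics=metrics,
        covariates=cov,
        metric_tables=metric_tables,
        group_stats=group_stats,
        unassigned_counts=unassigned,
    )
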