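"""Temporal characteristics of CAP occupancy.

Everything here derives from a :class:`StateSequence`: one label per
*original* acquisition timepoint, so censored and unselected frames keep
their place in time.  Entries count maximal runs of a CAP; durations are
mean run length times TR; the transition matrix is estimated from pairs
of timepoints that are adjacent in the original timeline and both carry a
CAP label.  Gaps (censored, not-selected, unassigned) break runs and
contribute no transitions in the default ``strict`` mode; a ``collapse``
mode that splices assigned frames together across gaps is provided for
sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import CENSORED, NOT_SELECTED, UNASSIGNED, ConfigurationError

__all__ = [
    "StateSequence",
    "TemporalMetrics",
    "build_state_sequence",
    "entries",
    "mean_duration",
    "occupancy",
    "transition_matrix",
    "compute_metrics",
]

_GAPS = (NOT_SELECTED, UNASSIGNED, CENSORED)


@dataclass
class StateSequence:
    """Per-timepoint state labels for one subject.

    Labels are CAP indices ``0..k-1`` or the negative sentinels
    ``NOT_SELECTED`` / ``UNASSIGNED`` / ``CENSORED``.  Length equals the
    acquisition frame count; CENSORED appears exactly where the frame was
    scrubbed.
    """

    subject_id: str
    labels: np.ndarray
    k: int
    tr: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ConfigurationError("state labels must be 1-D")
        if self.k < 1:
            raise ConfigurationError("k must be >= 1")
        bad = (self.labels >= self.k) | (
            (self.labels < 0) & ~np.isin(self.labels, _GAPS)
        )
        if np.any(bad):
            raise ConfigurationError("state labels outside 0..k-1 and known sentinels")

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]


@dataclass
class TemporalMetrics:
    """Per-subject temporal summary of CAP occupancy.

    ``entries[k]``: number of maximal runs of CAP k.
    ``mean_duration[k]``: mean run length x TR, in seconds (NaN if the CAP
    never occurs — a missing value, never zero).
    ``occupancy[k]``: fraction of assigned frames in CAP k.
    ``transition``: K x K row-stochastic matrix; rows with zero observed
    transitions are NaN and flagged in ``missing_rows``.
    ``transition_counts``: the raw pair counts behind it.
    """

    subject_id: str
    entries: np.ndarray
    mean_duration: np.ndarray
    occupancy: np.ndarray
    transition: np.ndarray
    transition_counts: np.ndarray
    missing_rows: np.ndarray
    n_assigned: int


def build_state_sequence(
    n_frames: int,
    frame_valid: np.ndarray,
    selected_indices: np.ndarray,
    assigned_labels: np.ndarray,
    k: int,
    tr: float,
    subject_id: str = "",
) -> StateSequence:
    """Compose the per-timepoint label vector from pipeline outputs.

    Valid-but-unselected frames get NOT_SELECTED, scrubbed frames
    CENSORED, and selected frames the assignment result (a CAP index or
    UNASSIGNED).
    """
    frame_valid = np.asarray(frame_valid, dtype=bool)
    labels = np.full(n_frames, NOT_SELECTED, dtype=int)
    labels[~frame_valid] = CENSORED
    selected_indices = np.asarray(selected_indices, dtype=np.intp)
    if selected_indices.size and not frame_valid[selected_indices].all():
        raise ConfigurationError("selected frames include censored timepoints")
    labels[selected_indices] = np.asarray(assigned_labels, dtype=int)
    return StateSequence(subject_id=subject_id, labels=labels, k=k, tr=tr)


def _runs(labels: np.ndarray, k: int) -> list[int]:
    """Lengths of maximal runs of label ``k`` (any other label breaks a run)."""
    lengths: list[int] = []
    count = 0
    for v in labels:
        if v == k:
            count += 1
        elif count:
            lengths.append(count)
            count = 0
    if count:
        lengths.append(count)
    return lengths


def entries(seq: StateSequence, k: int) -> int:
    """Number of entries into CAP ``k``: maximal runs of consecutive k-frames."""
    return len(_runs(seq.labels, k))


def mean_duration(seq: StateSequence, k: int) -> float:
    """Mean dwell time in CAP ``k`` in seconds (mean run length x TR).

    NaN when the CAP never occurs: an unobserved duration is missing, not
    zero.
    """
    runs = _runs(seq.labels, k)
    if not runs:
        return float("nan")
    return float(np.mean(runs) * seq.tr)


def occupancy(seq: StateSequence) -> np.ndarray:
    """Fraction of assigned frames spent in each CAP (sums to 1).

    All-NaN when no frame is assigned.
    """
    assigned = seq.labels[seq.labels >= 0]
    if assigned.size == 0:
        return np.full(seq.k, np.nan)
    counts = np.bincount(assigned, minlength=seq.k)
    return counts / assigned.size


def transition_matrix(
    seq: StateSequence, gap_mode: str = "strict"
) -> tuple[np.ndarray, np.ndarray]:
    """Row-stochastic CAP-to-CAP transition probabilities plus raw counts.

    ``strict``: only pairs (t, t+1) adjacent in the original timeline with
    CAP labels at both endpoints are counted; any gap discards the pair.
    ``collapse``: gap frames are removed first, so assigned frames
    separated by a gap become adjacent (sensitivity mode).

    Rows with zero observed transitions are NaN in the probability matrix.
    """
    if gap_mode not in ("strict", "collapse"):
        raise ConfigurationError(f"unknown gap_mode: {gap_mode!r}")
    labels = seq.labels
    if gap_mode == "collapse":
        labels = labels[labels >= 0]
    counts = np.zeros((seq.k, seq.k), dtype=int)
    a, b = labels[:-1], labels[1:]
    ok = (a >= 0) & (b >= 0)
    np.add.at(counts, (a[ok], b[ok]), 1)
    row_sums = counts.sum(axis=1)
    t = np.full((seq.k, seq.k), np.nan)
    nz = row_sums > 0
    t[nz] = counts[nz] / row_sums[nz, None]
    return t, counts


def compute_metrics(seq: StateSequence, gap_mode: str = "strict") -> TemporalMetrics:
    """All temporal metrics for one subject's state sequence."""
    ent = np.array([entries(seq, j) for j in range(seq.k)])
    dur = np.array([mean_duration(seq, j) for j in range(seq.k)])
    occ = occupancy(seq)
    t, counts = transition_matrix(seq, gap_mode=gap_mode)
    return TemporalMetrics(
        subject_id=seq.subject_id,
        entries=ent,
        mean_duration=dur,
        occupancy=occ,
        transition=t,
        transition_counts=counts,
        missing_rows=counts.sum(axis=1) == 0,
        n_assigned=int((seq.labels >= 0).sum()),
    )
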