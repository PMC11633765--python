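"""Seed time-course extraction and high-activation frame selection.

Only moments at which the seed nucleus is highly active are retained: the
weighted-mean seed course is thresholded at a z value (default 0.84, the
80th percentile of a standard normal), or alternatively the top fraction
of valid frames is kept directly.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .types import AlignmentError, ConfigurationError, FrameSet, SeedMask, VolumeSeries

__all__ = ["seed_timecourse", "percentile_threshold", "select_frames"]

#: z threshold corresponding to the 80th percentile of a standard normal.
DEFAULT_SELECT_Z = 0.84


def seed_timecourse(
    series: VolumeSeries, seed: SeedMask, standardize: bool = True
) -> np.ndarray:
    """Weighted mean seed activation per frame.

    Weights are normalized to sum to one (probabilistic atlas weights are
    used as-is, not binarized).  With ``standardize`` the course is then
    z-scored over valid frames, which is the default convention for
    thresholding; censored frames get the same affine rescaling but stay
    excluded from selection.
    """
    if seed.n_voxels != series.n_voxels:
        raise AlignmentError(
            f"seed mask has {seed.n_voxels} voxels, series has {series.n_voxels}"
        )
    w = seed.weights / seed.weights.sum()
    tc = series.data @ w
    if standardize:
        valid = series.frame_valid
        sd = tc[valid].std(ddof=1)
        if sd <= 0:
            raise ConfigurationError("seed time course has zero variance")
        tc = (tc - tc[valid].mean()) / sd
    return tc


def percentile_threshold(p: float) -> float:
    """z threshold at percentile ``p`` of the standard normal (e.g. 0.80 -> 0.84)."""
    if not 0.0 < p < 1.0:
        raise ConfigurationError("percentile must lie strictly between 0 and 1")
    return float(stats.norm.ppf(p))


def select_frames(
    series: VolumeSeries,
    seed: SeedMask,
    mode: str = "z_threshold",
    value: float = DEFAULT_SELECT_Z,
    subject_id: str = "",
    standardize_seed: bool = True,
) -> FrameSet:
    """Select valid frames at which the seed is highly active.

    ``z_threshold`` keeps valid frames whose seed activation exceeds
    ``value``; ``top_fraction`` keeps the ``value`` fraction of valid
    frames with highest activation.  An empty result yields a warning,
    not an error.
    """
    tc = seed_timecourse(series, seed, standardize=standardize_seed)
    valid_idx = np.flatnonzero(series.frame_valid)
    if mode == "z_threshold":
        chosen = valid_idx[tc[valid_idx] > value]
    elif mode == "top_fraction":
        if not 0.0 < value <= 1.0:
            raise ConfigurationError("top_fraction value must lie in (0, 1]")
        n_keep = int(round(value * valid_idx.size))
        order = np.argsort(tc[valid_idx])[::-1][:n_keep]
        chosen = np.sort(valid_idx[order])
    else:
        raise ConfigurationError(f"unknown selection mode: {mode!r}")
    if chosen.size == 0:
        warnings.warn(
            f"no frame survived {mode}={value} for subject {subject_id or '<unnamed>'}",
            stacklevel=2,
        )
    return FrameSet(subject_id=subject_id, indices=chosen, data=series.data[chosen])
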