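"""Reference-based assignment of frames to CAPs.

Each selected frame is matched to the reference CAP with which it has the
highest Pearson spatial correlation; if that correlation falls below the
CAP's 5th-percentile member-correlation threshold the frame stays
UNASSIGNED.  Reference (healthy-control) frames keep their k-means labels
by default — the procedure is deliberately asymmetric — but a symmetric
re-assignment mode is available for sensitivity analyses.
"""

from __future__ import annotations

import numpy as np

from .cluster import CAPSet, _row_corr
from .types import AlignmentError, FrameSet, UNASSIGNED

__all__ = ["assign_frames"]


def assign_frames(
    frames: FrameSet, caps: CAPSet, apply_threshold: bool = True
) -> np.ndarray:
    """Label each frame with its best-matching CAP or ``UNASSIGNED``.

    For every frame the Pearson correlation with each CAP map is computed;
    the argmax CAP (ties broken toward the lower index) is accepted only
    if the correlation reaches that CAP's stored threshold.  Frames with
    zero spatial variance are UNASSIGNED.

    Returns an int array aligned with ``frames.indices``: values in
    ``0..K-1`` or the ``UNASSIGNED`` sentinel.
    """
    if frames.n_frames == 0:
        return np.empty(0, dtype=int)
    if frames.data.shape[1] != caps.maps.shape[1]:
        raise AlignmentError(
            f"frames have {frames.data.shape[1]} voxels, CAP maps have "
            f"{caps.maps.shape[1]}"
        )
    flat = frames.data.std(axis=1) <= 0
    corr = _row_corr(frames.data, caps.maps)
    best = np.argmax(corr, axis=1)  # np.argmax takes the first (lowest) on ties
    labels = best.copy()
    if apply_threshold:
        r_best = corr[np.arange(len(best)), best]
        labels[r_best < caps.thresholds[best]] = UNASSIGNED
    labels[flat] = UNASSIGNED
    return labels
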