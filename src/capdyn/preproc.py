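"""Nuisance regression, temporal filtering, scrubbing and z-scoring.

The stage order is fixed: nuisance regression -> high-pass filtering ->
optional spatial smoothing -> motion scrubbing (flagging) -> per-voxel
z-scoring.  Frames are never removed: censored frames keep their position
so that temporal adjacency stays meaningful for the dynamics stage, they
are merely flagged invalid and excluded from every fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .types import ConfigurationError, MotionParams, VolumeSeries

__all__ = [
    "NuisanceDesign",
    "build_nuisance_design",
    "compute_fd",
    "scrub",
    "regress_nuisance",
    "highpass",
    "smooth",
    "zscore",
    "preprocess",
]

#: Power's convention: rotations are converted to arc length on a sphere
#: of this radius (mm) before summing displacements.
DEFAULT_HEAD_RADIUS_MM = 50.0

#: Scrubbing threshold of the framewise-displacement criterion (mm).
DEFAULT_FD_THRESHOLD_MM = 0.5

#: High-pass cutoff (Hz) below which slow drifts are removed.
DEFAULT_HIGHPASS_HZ = 0.01


@dataclass
class NuisanceDesign:
    """Frames x regressors nuisance design with column labels.

    Columns typically hold polynomial trends (constant/linear/quadratic),
    mean white-matter and CSF courses, the six motion parameters and the
    global signal.  Near-collinear columns are pruned at construction so
    the design is full column rank.
    """

    matrix: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=np.float64))
        if not self.labels:
            self.labels = [f"x{i}" for i in range(self.matrix.shape[1])]
        if len(self.labels) != self.matrix.shape[1]:
            raise ConfigurationError("design labels must match column count")

    @property
    def n_frames(self) -> int:
        return self.matrix.shape[0]


def _prune_collinear(matrix: np.ndarray, labels: list[str], tol: float = 1e-10):
    """Greedy rank-preserving column selection; returns kept cols and dropped labels."""
    kept: list[int] = []
    dropped: list[str] = []
    for j in range(matrix.shape[1]):
        cand = matrix[:, kept + [j]]
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(cand).max())) == len(kept) + 1:
            kept.append(j)
        else:
            dropped.append(labels[j])
    return kept, dropped


def build_nuisance_design(
    n_frames: int,
    *,
    motion: MotionParams | None = None,
    wm: np.ndarray | None = None,
    csf: np.ndarray | None = None,
    global_signal: np.ndarray | None = None,
    poly_order: int = 2,
) -> NuisanceDesign:
    """Assemble constant/linear/quadratic trends plus nuisance courses.

    Near-collinear columns are pruned with a warning; a design that is
    still rank deficient afterwards cannot occur by construction.
    """
    t = np.linspace(-1.0, 1.0, n_frames)
    cols = [np.ones(n_frames)]
    labels = ["constant"]
    if poly_order >= 1:
        cols.append(t)
        labels.append("linear")
    if poly_order >= 2:
        cols.append(t**2)
        labels.append("quadratic")
    if wm is not None:
        cols.append(np.asarray(wm, dtype=float))
        labels.append("wm")
    if csf is not None:
        cols.append(np.asarray(csf, dtype=float))
        labels.append("csf")
    if motion is not None:
        if motion.n_frames != n_frames:
            raise ConfigurationError("motion frame count does not match series")
        for i, name in enumerate(("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")):
            cols.append(motion.values[:, i])
            labels.append(f"motion_{name}")
    if global_signal is not None:
        cols.append(np.asarray(global_signal, dtype=float))
        labels.append("global")
    matrix = np.column_stack(cols)
    if matrix.shape[0] != n_frames:
        raise ConfigurationError("nuisance columns must have one value per frame")
    kept, dropped = _prune_collinear(matrix, labels)
    if dropped:
        warnings.warn(
            f"pruned collinear nuisance columns: {', '.join(dropped)}", stacklevel=2
        )
    return NuisanceDesign(matrix[:, kept], [labels[k] for k in kept])


def compute_fd(motion: MotionParams, head_radius: float = DEFAULT_HEAD_RADIUS_MM) -> np.ndarray:
    """Framewise displacement: sum of absolute backward differentials.

    ``FD(t) = sum_i |d trans_i(t)| + sum_j |r * d rot_j(t)|`` with
    rotations converted to arc length at radius ``head_radius`` mm;
    ``FD(0) = 0`` by convention.
    """
    if motion.n_frames < 2:
        raise ConfigurationError("framewise displacement needs at least 2 frames")
    d = np.diff(motion.values, axis=0)
    d[:, 3:] *= head_radius
    fd = np.zeros(motion.n_frames)
    fd[1:] = np.abs(d).sum(axis=1)
    return fd


def scrub(
    series: VolumeSeries,
    fd: np.ndarray,
    threshold: float = DEFAULT_FD_THRESHOLD_MM,
) -> tuple[VolumeSeries, int]:
    """Flag frames with FD above threshold as invalid (censored).

    Returns the updated series and the number of *newly* excluded frames
    (the "excluded frames" covariate used downstream).  Frames are never
    dropped from the matrix.
    """
    if threshold <= 0:
        raise ConfigurationError("scrubbing threshold must be positive")
    fd = np.asarray(fd, dtype=float)
    if fd.shape != (series.n_frames,):
        raise ConfigurationError("FD length must match series frame count")
    out = series.copy()
    bad = fd > threshold
    newly = int(np.count_nonzero(bad & out.frame_valid))
    out.frame_valid &= ~bad
    return out, newly


def regress_nuisance(series: VolumeSeries, design: NuisanceDesign) -> VolumeSeries:
    """Residualize every voxel against the nuisance design by OLS.

    The fit uses valid frames only; residuals are stored for valid frames
    while censored frames carry their original values through (still
    flagged, so they never enter later fits either).
    """
    if design.n_frames != series.n_frames:
        raise ConfigurationError("design frame count does not match series")
    valid = series.frame_valid
    X = design.matrix[valid]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        kept, dropped = _prune_collinear(X, design.labels)
        raise ConfigurationError(
            "rank-deficient nuisance design; collinear columns: "
            + ", ".join(dropped or design.labels)
        )
    beta, *_ = np.linalg.lstsq(X, series.data[valid], rcond=None)
    out = series.copy()
    out.data[valid] = series.data[valid] - X @ beta
    return out


def _dct_drift_basis(n_frames: int, tr: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine basis spanning periods slower than 1/cutoff.

    Component k has frequency k / (2 * N * TR); the constant (k=0) is
    included so any DC offset is removed with the drifts.
    """
    order = int(np.floor(2.0 * n_frames * tr * cutoff))
    t = np.arange(n_frames)
    ks = np.arange(order + 1)
    basis = np.cos(np.pi * np.outer(2 * t + 1, ks) / (2.0 * n_frames))
    return basis


def highpass(series: VolumeSeries, cutoff: float = DEFAULT_HIGHPASS_HZ) -> VolumeSeries:
    """Remove slow drifts below ``cutoff`` Hz by DCT-basis projection.

    Exactly linear (a regression, not an IIR filter), so censored frames
    cannot leak into the fit: the basis is fit on valid frames only.
    """
    nyquist = 0.5 / series.tr
    if cutoff >= nyquist:
        raise ConfigurationError(
            f"high-pass cutoff {cutoff} Hz is at or above Nyquist {nyquist:.4f} Hz"
        )
    if cutoff <= 0:
        raise ConfigurationError("high-pass cutoff must be positive")
    basis = _dct_drift_basis(series.n_frames, series.tr, cutoff)
    valid = series.frame_valid
    B = basis[valid]
    beta, *_ = np.linalg.lstsq(B, series.data[valid], rcond=None)
    out = series.copy()
    out.data[valid] = series.data[valid] - B @ beta
    return out


def smooth(series: VolumeSeries, fwhm_vox: float) -> VolumeSeries:
    """Gaussian spatial smoothing on the voxel grid (FWHM in voxel units).

    Frames are embedded into the 3-D grid, filtered, and re-extracted at
    the masked voxels; values outside the mask are treated as zero.
    """
    if fwhm_vox <= 0:
        raise ConfigurationError("smoothing FWHM must be positive")
    sigma = fwhm_vox / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    coords = tuple(series.voxel_coords.T)
    out = series.copy()
    for t in range(series.n_frames):
        vol = np.zeros(series.grid_shape)
        vol[coords] = series.data[t]
        out.data[t] = ndimage.gaussian_filter(vol, sigma=sigma)[coords]
    return out


def zscore(series: VolumeSeries, ddof: int = 1) -> VolumeSeries:
    """Standardize each voxel to mean 0, SD 1 over valid frames.

    Zero-variance voxels are set to 0 and flagged in
    ``series.zero_variance`` instead of raising.
    """
    valid = series.frame_valid
    if valid.sum() < 2:
        raise ConfigurationError("z-scoring needs at least 2 valid frames")
    mean = series.data[valid].mean(axis=0)
    sd = series.data[valid].std(axis=0, ddof=ddof)
    flat = sd <= 0
    sd_safe = np.where(flat, 1.0, sd)
    out = series.copy(data=(series.data - mean) / sd_safe)
    out.data[:, flat] = 0.0
    out.zero_variance = flat
    return out


def preprocess(
    series: VolumeSeries,
    motion: MotionParams,
    *,
    wm: np.ndarray | None = None,
    csf: np.ndarray | None = None,
    global_signal: bool = True,
    highpass_hz: float = DEFAULT_HIGHPASS_HZ,
    fd_threshold_mm: float = DEFAULT_FD_THRESHOLD_MM,
    head_radius_mm: float = DEFAULT_HEAD_RADIUS_MM,
    smooth_fwhm_vox: float | None = None,
) -> tuple[VolumeSeries, int]:
    """Full preprocessing chain; returns the z-scored series and the
    number of frames excluded by scrubbing.

    Order: regress -> highpass -> (smooth) -> scrub -> zscore.  The global
    signal regressor is the whole-mask mean course and is on by default.
    """
    gs = series.data.mean(axis=1) if global_signal else None
    design = build_nuisance_design(
        series.n_frames, motion=motion, wm=wm, csf=csf, global_signal=gs
    )
    out = regress_nuisance(series, design)
    out = highpass(out, highpass_hz)
    if smooth_fwhm_vox is not None:
        out = smooth(out, smooth_fwhm_vox)
    fd = compute_fd(motion, head_radius_mm)
    out, n_excluded = scrub(out, fd, fd_threshold_mm)
    out = zscore(out)
    return out, n_excluded
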