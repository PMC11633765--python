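"""Synthetic resting-state cohorts with latent state-switching structure.

The generator produces exactly the structure the analysis assumes: a
hidden first-order Markov chain over a quiescent baseline plus ``k_true``
co-activation states; each state paints a distinct smooth spatial blob
(always with positive loading on the seed nucleus) onto Gaussian noise.
Group differences are expressed through the per-group transition matrix —
the patient group's diagonal (self-transition) entries are boosted, i.e.
higher state persistence.  Motion spikes are injected as instantaneous
translation jumps so the framewise-displacement criterion has something
real to scrub, and subject covariates are drawn on the scales of the
study's descriptive table.

A single integer seed fans out deterministically to per-subject
substreams, so cohorts are byte-identical across runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import ConfigurationError, MotionParams, MOTION_COLUMNS, VolumeSeries

__all__ = [
    "SimConfig",
    "GroundTruth",
    "SubjectBundle",
    "default_transition_matrix",
    "stationary_distribution",
    "make_patterns",
    "planted_frames",
    "simulate_state_sequence",
    "render_series",
    "generate_cohort",
]

GROUPS = ("control", "patient")


def default_transition_matrix(
    k: int, p_stay: float, baseline_stay: float = 0.70, p_cross: float = 0.05
) -> np.ndarray:
    """Row-stochastic (k+1) x (k+1) matrix over {baseline, state_1..k}.

    The baseline row stays with probability ``baseline_stay`` and splits
    the rest evenly over states; each state row stays with ``p_stay``,
    moves to every other state with ``p_cross``, and returns to baseline
    with the remainder.
    """
    if k < 1:
        raise ConfigurationError("need at least one state")
    to_base = 1.0 - p_stay - (k - 1) * p_cross
    if to_base < 0:
        raise ConfigurationError("p_stay/p_cross leave no mass for the baseline return")
    m = np.zeros((k + 1, k + 1))
    m[0, 0] = baseline_stay
    m[0, 1:] = (1.0 - baseline_stay) / k
    for i in range(1, k + 1):
        m[i, 1:] = p_cross
        m[i, i] = p_stay
        m[i, 0] = to_base
    return m


def _default_matrices(k: int) -> dict[str, np.ndarray]:
    # Patients carry a +0.10 diagonal (persistence) boost over controls,
    # with the exit mass (baseline returns and cross-state switches)
    # reduced proportionally: higher persistence means uniformly less
    # switching, so the boost stays visible in the observed transition
    # estimates even though baseline exits are censored by frame selection.
    return {
        "control": default_transition_matrix(k, p_stay=0.50, p_cross=0.05),
        "patient": default_transition_matrix(k, p_stay=0.60, p_cross=0.04),
    }


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults reflect the emulated acquisition: two groups of 14 subjects,
    300 frames at TR = 1.3 s, three planted co-activation patterns, unit
    pattern amplitude over Gaussian noise of SD 0.5, and occasional
    motion spikes large enough to trip a 0.5 mm FD threshold.
    """

    n_per_group: int = 14
    n_frames: int = 300
    tr: float = 1.3
    grid_shape: tuple[int, int, int] = (12, 12, 8)
    k_true: int = 3
    seed_voxels: np.ndarray | None = None
    transition_matrix_by_group: dict[str, np.ndarray] | None = None
    pattern_amplitude: float = 1.0
    noise_sd: float = 0.5
    motion_spike_prob: float = 0.02
    #: 0 = covariates independent of group (except the structurally
    #: patient-only medication flag); 1 = full descriptive-table group shift.
    covariate_confound: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.seed_voxels is None:
            self.seed_voxels = self._central_seed_block()
        self.seed_voxels = np.asarray(self.seed_voxels, dtype=np.intp)
        if self.transition_matrix_by_group is None:
            self.transition_matrix_by_group = _default_matrices(self.k_true)
        self.validate()

    def _central_seed_block(self) -> np.ndarray:
        """2x2x2 voxel block at the grid centre, as flat grid indices."""
        nx, ny, nz = self.grid_shape
        cx, cy, cz = nx // 2, ny // 2, nz // 2
        idx = [
            np.ravel_multi_index((cx + dx, cy + dy, cz + dz), self.grid_shape)
            for dx in (0, 1)
            for dy in (0, 1)
            for dz in (0, 1)
        ]
        return np.array(idx, dtype=np.intp)

    def validate(self) -> None:
        if self.k_true < 1:
            raise ConfigurationError("k_true must be >= 1")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if self.n_frames < 2 or self.n_per_group < 1:
            raise ConfigurationError("n_frames >= 2 and n_per_group >= 1 required")
        if not 0.0 <= self.motion_spike_prob <= 1.0:
            raise ConfigurationError("motion_spike_prob must lie in [0, 1]")
        n_grid = int(np.prod(self.grid_shape))
        if self.seed_voxels.size == 0:
            raise ConfigurationError("seed_voxels must be nonempty")
        if self.seed_voxels.min() < 0 or self.seed_voxels.max() >= n_grid:
            raise ConfigurationError("seed_voxels fall outside the grid")
        for group, m in self.transition_matrix_by_group.items():
            m = np.asarray(m, dtype=float)
            if m.shape != (self.k_true + 1, self.k_true + 1):
                raise ConfigurationError(
                    f"transition matrix for {group!r} must be "
                    f"({self.k_true + 1}, {self.k_true + 1})"
                )
            if np.any(m < 0) or np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-12):
                raise ConfigurationError(
                    f"transition matrix for {group!r} is not row-stochastic"
                )

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))


@dataclass
class GroundTruth:
    """What was planted for one subject: latent labels, patterns, motion."""

    state_labels: np.ndarray  # per frame; 0 = baseline, 1..k = states
    patterns: np.ndarray  # (k_true, n_voxels)
    motion_params: pd.DataFrame  # frames x 6, MOTION_COLUMNS


@dataclass
class SubjectBundle:
    """Everything the pipeline consumes for one synthetic subject."""

    subject_id: str
    group: str
    series: VolumeSeries
    motion: MotionParams
    nuisance: pd.DataFrame  # columns wm, csf, global
    covariates: dict
    truth: GroundTruth


def stationary_distribution(matrix: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    m = np.asarray(matrix, dtype=float)
    vals, vecs = np.linalg.eig(m.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


# --- spatial patterns ------------------------------------------------------

_CORNER_ORDER = [
    (0, 0, 0), (1, 1, 1), (1, 0, 0), (0, 1, 1),
    (0, 1, 0), (1, 0, 1), (0, 0, 1), (1, 1, 0),
]


def make_patterns(config: SimConfig) -> np.ndarray:
    """Plant ``k_true`` separable spatial maps on the grid.

    Each pattern is a smooth Gaussian blob at one of the grid's inner
    corners (corners are mutually far apart, which keeps pairwise spatial
    correlation low), made spatially zero-mean — co-activation in the
    blob balanced by weak co-deactivation elsewhere, as real CAPs mix
    activations and deactivations — plus a unit positive loading on the
    seed voxels so that seed activation marks state frames.  The zero
    mean matters: it keeps the latent state out of the global-signal
    regressor, which would otherwise absorb the seed signal.
    Deterministic given the config.  Raises if the grid cannot hold
    ``k_true`` separated blobs.
    """
    k = config.k_true
    if k > len(_CORNER_ORDER):
        raise ConfigurationError(
            f"grid placement supports at most {len(_CORNER_ORDER)} separated blobs"
        )
    shape = np.array(config.grid_shape, dtype=float)
    margin = shape / 4.0
    sigma = float(shape.min()) / 3.0
    coords = np.stack(
        np.meshgrid(*[np.arange(s) for s in config.grid_shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    patterns = np.zeros((k, config.n_voxels))
    for j in range(k):
        corner = np.array(_CORNER_ORDER[j], dtype=float)
        center = margin + corner * (shape - 1 - 2 * margin)
        d2 = ((coords - center) ** 2).sum(axis=1)
        blob = np.exp(-d2 / (2.0 * sigma**2))
        blob /= blob.max()
        blob[config.seed_voxels] = 0.0  # identical seed loading across states
        blob -= blob.mean()
        blob[config.seed_voxels] += 1.0
        patterns[j] = blob
    if k > 1:
        c = np.corrcoef(patterns)
        off = c[np.triu_indices(k, 1)]
        if np.any(off >= 0.5):
            raise ConfigurationError(
                f"grid {config.grid_shape} too small for {k} separable blobs "
                f"(max pairwise r = {off.max():.2f})"
            )
    return patterns


def planted_frames(
    n_frames: int,
    n_voxels: int,
    k: int,
    amplitude: float = 1.0,
    noise_sd: float = 0.5,
    rng: np.random.Generator | int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flat (geometry-free) frame sample from k planted patterns.

    Patterns are smooth bumps over disjoint voxel blocks (pairwise
    correlation well under 0.5); every frame carries exactly one pattern
    at ``amplitude`` plus white Gaussian noise, states drawn uniformly.
    Returns ``(frames, state_labels, patterns)``.  Used for clustering
    benchmarks where no 3-D grid is needed.
    """
    if k * 2 > n_voxels:
        raise ConfigurationError("too few voxels for the requested pattern count")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    block = n_voxels // k
    x = np.arange(n_voxels)
    patterns = np.zeros((k, n_voxels))
    for j in range(k):
        center = block * j + block / 2.0
        patterns[j] = np.exp(-((x - center) ** 2) / (2.0 * (block / 4.0) ** 2))
    labels = rng.integers(k, size=n_frames)
    frames = amplitude * patterns[labels] + rng.normal(0.0, noise_sd, (n_frames, n_voxels))
    return frames, labels, patterns


# --- temporal structure ----------------------------------------------------

def simulate_state_sequence(
    config: SimConfig, group: str, rng: np.random.Generator | None = None
) -> np.ndarray:
    """First-order Markov chain over {baseline, state_1..k_true}.

    Started from the stationary distribution of the group's transition
    matrix; label 0 is the baseline (seed quiescent).
    """
    if group not in config.transition_matrix_by_group:
        raise ConfigurationError(f"no transition matrix configured for group {group!r}")
    m = np.asarray(config.transition_matrix_by_group[group], dtype=float)
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    cdf = np.cumsum(m, axis=1)
    labels = np.empty(config.n_frames, dtype=int)
    labels[0] = rng.choice(m.shape[0], p=stationary_distribution(m))
    u = rng.random(config.n_frames - 1)
    for t in range(1, config.n_frames):
        labels[t] = int(np.searchsorted(cdf[labels[t - 1]], u[t - 1], side="right"))
    return labels


def _simulate_motion(
    config: SimConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, np.ndarray]:
    """Random-walk head motion with instantaneous spike jumps.

    Ordinary motion is a gentle random walk (steps far below the FD
    threshold); spiked frames get a persistent +/-1 mm translation jump,
    which puts FD above 0.5 mm at exactly the spike frame.
    """
    n = config.n_frames
    steps = np.zeros((n, 6))
    steps[1:, :3] = rng.normal(0.0, 0.01, (n - 1, 3))  # mm
    steps[1:, 3:] = rng.normal(0.0, 0.0001, (n - 1, 3))  # rad
    spikes = np.zeros(n, dtype=bool)
    spikes[1:] = rng.random(n - 1) < config.motion_spike_prob
    signs = np.where(rng.random(n) < 0.5, -1.0, 1.0)
    steps[spikes, 0] += signs[spikes] * 1.0
    values = np.cumsum(steps, axis=0)
    return pd.DataFrame(values, columns=list(MOTION_COLUMNS)), spikes


def render_series(
    config: SimConfig,
    truth_labels: np.ndarray,
    patterns: np.ndarray,
    rng: np.random.Generator,
) -> tuple[VolumeSeries, pd.DataFrame, GroundTruth]:
    """Turn a latent state sequence into a noisy volume series + tables.

    Frame t is ``amplitude * pattern(state_t)`` plus white Gaussian noise
    (baseline frames are pure noise), with weak white-matter/CSF nuisance
    components mixed in so the regression stage has real work to do.
    """
    n, v = config.n_frames, config.n_voxels
    data = rng.normal(0.0, config.noise_sd, (n, v))
    for s in range(1, config.k_true + 1):
        on = truth_labels == s
        data[on] += config.pattern_amplitude * patterns[s - 1]
    # AR(1) nuisance courses with a weak spatial footprint in the data.
    wm = np.empty(n)
    csf = np.empty(n)
    wm[0], csf[0] = rng.normal(size=2)
    for t in range(1, n):
        wm[t] = 0.9 * wm[t - 1] + rng.normal(0.0, np.sqrt(1 - 0.81))
        csf[t] = 0.9 * csf[t - 1] + rng.normal(0.0, np.sqrt(1 - 0.81))
    # footprint scales with the noise floor, vanishing in the noiseless limit
    data += 0.2 * config.noise_sd * np.outer(wm, rng.normal(0.0, 1.0, v) / np.sqrt(v))
    data += 0.2 * config.noise_sd * np.outer(csf, rng.normal(0.0, 1.0, v) / np.sqrt(v))

    motion_df, _ = _simulate_motion(config, rng)
    nuisance = pd.DataFrame(
        {"wm": wm, "csf": csf, "global": data.mean(axis=1)}
    )
    coords = np.stack(
        np.meshgrid(*[np.arange(s) for s in config.grid_shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    series = VolumeSeries(
        data=data, tr=config.tr, voxel_coords=coords, grid_shape=config.grid_shape
    )
    truth = GroundTruth(
        state_labels=truth_labels, patterns=patterns, motion_params=motion_df
    )
    return series, nuisance, truth


# --- cohort ----------------------------------------------------------------

def _draw_covariates(
    group: str, rng: np.random.Generator, confound: float
) -> dict:
    """Covariates on the study's descriptive scales.

    At ``confound = 0`` depression/anxiety are drawn from the pooled
    scale for both groups; ``confound = 1`` applies the full
    patient-vs-control mean separation of the descriptive table.  The
    medication flag is structurally patient-only.
    """
    patient = group == "patient"
    w = confound if patient else -confound
    bdi_mean = 7.5 + w * 4.6  # pooled midpoint of 12.2 vs 2.93
    stai_mean = 34.9 + w * 3.3  # pooled midpoint of 38.1 vs 31.6
    cov = {
        "age": float(np.round(rng.uniform(20, 58), 1)),
        "sex": "F" if rng.random() < 11 / 14 else "M",
        "medication": int(patient and rng.random() < 6 / 14),
        "bdi": float(np.round(max(0.0, rng.normal(bdi_mean, 8.0)), 1)),
        "stai_s": float(np.round(max(20.0, rng.normal(stai_mean, 9.0)), 1)),
    }
    if patient:
        cov["seizure_count"] = int(rng.negative_binomial(0.25, 0.25 / 6.75))
    return cov


def generate_cohort(config: SimConfig) -> list[SubjectBundle]:
    """Simulate both groups; each subject gets a reproducible substream.

    Substreams are spawned from ``SeedSequence(rng_seed, (group, idx))``,
    so the cohort is byte-identical across runs of the same seed and
    subjects are independent.
    """
    if config.k_true < 2:
        warnings.warn(
            "k_true < 2: downstream cluster-number selection is degenerate",
            stacklevel=2,
        )
    patterns = make_patterns(config)
    bundles: list[SubjectBundle] = []
    for g_idx, group in enumerate(GROUPS):
        for i in range(config.n_per_group):
            ss = np.random.SeedSequence(config.rng_seed, spawn_key=(g_idx, i))
            rng = np.random.default_rng(ss)
            labels = simulate_state_sequence(config, group, rng)
            series, nuisance, truth = render_series(config, labels, patterns, rng)
            bundles.append(
                SubjectBundle(
                    subject_id=f"{group}_{i + 1:02d}",
                    group=group,
                    series=series,
                    motion=MotionParams(truth.motion_params.to_numpy()),
                    nuisance=nuisance,
                    covariates={"subject_id": f"{group}_{i + 1:02d}", "group": group}
                    | _draw_covariates(group, rng, config.covariate_confound),
                    truth=truth,
                )
            )
    return bundles
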