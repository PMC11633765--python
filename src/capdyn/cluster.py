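"""Consensus clustering of pooled reference frames and CAP extraction.

The number of co-activation patterns K is chosen by stability: for each
candidate K, k-means is run on many random subsamples of the pooled
frames, pairwise co-clustering frequencies form a consensus matrix, and
the proportion of ambiguously clustered pairs (PAC) — pairs whose
frequency is neither near 0 nor near 1 — scores the candidate.  The K
maximizing 1 - PAC wins; the full PAC table and consensus matrices are
kept for visual inspection.  A final multi-restart k-means at the chosen
K defines the CAP maps and the per-CAP correlation null used later for
reference-based assignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .types import ConfigurationError

__all__ = [
    "ConsensusResult",
    "CAPSet",
    "consensus_cluster",
    "pac",
    "select_k",
    "kmeans_final",
]

DEFAULT_K_RANGE = (2, 15)
DEFAULT_N_SUBSAMPLES = 100
DEFAULT_SUBSAMPLE_FRAC = 0.8
DEFAULT_PAC_BOUNDS = (0.1, 0.9)
DEFAULT_ASSIGN_PERCENTILE = 5.0


@dataclass
class ConsensusResult:
    """Per-K consensus matrices with PAC scores.

    ``consensus[K]`` holds pairwise co-clustering frequencies in [0, 1]
    (unit diagonal); ``cosampled[K]`` marks pairs that appeared together
    in at least one subsample — pairs never co-sampled are stored as 0
    and excluded from PAC.
    """

    ks: list[int]
    consensus: dict[int, np.ndarray]
    cosampled: dict[int, np.ndarray]
    pac_values: dict[int, float]

    @property
    def stability(self) -> dict[int, float]:
        """1 - PAC per K (higher = more stable)."""
        return {k: 1.0 - v for k, v in self.pac_values.items()}

    def table(self) -> list[tuple[int, float, float]]:
        """(K, PAC, 1-PAC) rows for the human-inspection diagnostic."""
        return [(k, self.pac_values[k], 1.0 - self.pac_values[k]) for k in self.ks]


@dataclass
class CAPSet:
    """Reference CAPs: K spatial maps plus the assignment null.

    ``maps`` are z-scored across voxels.  ``member_corrs[k]`` is the
    distribution of Pearson correlations between CAP k's own member
    frames and its map; ``thresholds[k]`` is the 5th percentile of that
    distribution, below which a new frame is left unassigned.  CAPs are
    ordered by descending member count, so CAP 0 is the most occupied.
    """

    maps: np.ndarray  # (K, n_voxels)
    labels: np.ndarray  # per reference frame, in 0..K-1
    member_corrs: list[np.ndarray] = field(default_factory=list)
    thresholds: np.ndarray = None  # type: ignore[assignment]

    @property
    def k(self) -> int:
        return self.maps.shape[0]

    @property
    def member_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.k)


def _zscore_rows(x: np.ndarray, ddof: int = 1) -> np.ndarray:
    mu = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    sd = np.where(sd <= 0, 1.0, sd)
    return (x - mu) / sd


def _row_corr(frames: np.ndarray, maps: np.ndarray) -> np.ndarray:
    """Pearson spatial correlation of each frame row with each map row."""
    n = frames.shape[1]
    zf = _zscore_rows(frames)
    zm = _zscore_rows(maps)
    return zf @ zm.T / (n - 1)


def pac(
    consensus: np.ndarray,
    u1: float = DEFAULT_PAC_BOUNDS[0],
    u2: float = DEFAULT_PAC_BOUNDS[1],
    cosampled: np.ndarray | None = None,
) -> float:
    """Proportion of ambiguously clustered pairs.

    The fraction of off-diagonal co-sampled pairs whose consensus value
    lies strictly inside ``(u1, u2)``.  Crisp consensus matrices (values
    only near 0 or 1) give PAC near 0.
    """
    if not 0.0 <= u1 < u2 <= 1.0:
        raise ConfigurationError("PAC bounds must satisfy 0 <= u1 < u2 <= 1")
    consensus = np.asarray(consensus, dtype=float)
    n = consensus.shape[0]
    iu = np.triu_indices(n, k=1)
    vals = consensus[iu]
    if cosampled is not None:
        keep = np.asarray(cosampled, dtype=bool)[iu]
        vals = vals[keep]
    if vals.size == 0:
        return 0.0
    return float(np.mean((vals > u1) & (vals < u2)))


def consensus_cluster(
    frames: np.ndarray,
    k_range: tuple[int, int] = DEFAULT_K_RANGE,
    n_subsamples: int = DEFAULT_N_SUBSAMPLES,
    subsample_frac: float = DEFAULT_SUBSAMPLE_FRAC,
    rng_seed: int = 0,
    pac_bounds: tuple[float, float] = DEFAULT_PAC_BOUNDS,
) -> ConsensusResult:
    """Subsampled k-means consensus over a range of cluster numbers.

    For each K, ``n_subsamples`` k-means runs are performed on random
    ``subsample_frac`` subsets without replacement;
    ``consensus(i, j) = co-clustered count / co-sampled count``.
    Deterministic under a fixed ``rng_seed``.
    """
    frames = np.asarray(frames, dtype=np.float64)
    n = frames.shape[0]
    k_lo, k_hi = int(k_range[0]), int(k_range[1])
    if k_lo < 2:
        raise ConfigurationError("consensus clustering needs K >= 2")
    if k_hi > n:
        raise ConfigurationError(
            f"largest K ({k_hi}) exceeds the number of pooled frames ({n})"
        )
    if not 0.0 < subsample_frac <= 1.0:
        raise ConfigurationError("subsample_frac must lie in (0, 1]")
    m = max(k_hi, int(round(subsample_frac * n)))
    rng = np.random.default_rng(rng_seed)
    ks = list(range(k_lo, k_hi + 1))
    consensus: dict[int, np.ndarray] = {}
    cosampled: dict[int, np.ndarray] = {}
    pac_values: dict[int, float] = {}
    for k in ks:
        together = np.zeros((n, n))
        sampled = np.zeros((n, n))
        for _ in range(n_subsamples):
            idx = rng.choice(n, size=m, replace=False) if m < n else np.arange(n)
            km = KMeans(
                n_clusters=k,
                n_init=1,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(frames[idx])
            same = km.labels_[:, None] == km.labels_[None, :]
            together[np.ix_(idx, idx)] += same
            sampled[np.ix_(idx, idx)] += 1.0
        seen = sampled > 0
        cons = np.zeros((n, n))
        cons[seen] = together[seen] / sampled[seen]
        np.fill_diagonal(cons, 1.0)
        consensus[k] = cons
        cosampled[k] = seen
        pac_values[k] = pac(cons, *pac_bounds, cosampled=seen)
    return ConsensusResult(ks, consensus, cosampled, pac_values)


def select_k(result: ConsensusResult) -> int:
    """K with maximal stability 1 - PAC; ties break toward smaller K."""
    best_k, best_pac = None, None
    tie = False
    for k in result.ks:
        v = result.pac_values[k]
        if best_pac is None or v < best_pac - 1e-15:
            best_k, best_pac = k, v
            tie = False
        elif abs(v - best_pac) <= 1e-15:
            tie = True
    if tie:
        warnings.warn(
            f"PAC tie across candidate cluster numbers; keeping smallest K={best_k}",
            stacklevel=2,
        )
    return int(best_k)


def kmeans_final(
    frames: np.ndarray,
    k: int,
    n_restarts: int = 20,
    rng_seed: int = 0,
    assign_percentile: float = DEFAULT_ASSIGN_PERCENTILE,
) -> CAPSet:
    """Final k-means at K clusters; builds CAP maps and assignment nulls.

    The best-inertia solution over ``n_restarts`` restarts is kept.  Each
    CAP map is the voxel-wise mean of its member frames, z-scored across
    voxels; labels are re-indexed by descending member count so CAP 0 is
    the most occupied.  The per-CAP member-frame correlation distribution
    and its ``assign_percentile`` percentile (the assignment threshold)
    are stored.
    """
    frames = np.asarray(frames, dtype=np.float64)
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if frames.shape[0] < k:
        raise ConfigurationError("fewer frames than clusters")
    if k == 1:
        labels = np.zeros(frames.shape[0], dtype=int)
    else:
        labels = None
        for attempt in range(10):
            km = KMeans(
                n_clusters=k, n_init=n_restarts, random_state=rng_seed + attempt
            ).fit(frames)
            if len(np.unique(km.labels_)) == k:
                labels = km.labels_
                break
        if labels is None:
            raise ConfigurationError(
                f"k-means produced an empty cluster in 10 seeded attempts (k={k})"
            )
    # Relabel by descending member count (stable for equal counts).
    counts = np.bincount(labels, minlength=k)
    order = np.argsort(-counts, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    labels = remap[labels]

    maps = np.vstack([frames[labels == j].mean(axis=0) for j in range(k)])
    maps = _zscore_rows(maps)
    corr = _row_corr(frames, maps)
    member_corrs = [corr[labels == j, j] for j in range(k)]
    thresholds = np.array(
        [float(np.percentile(c, assign_percentile)) for c in member_corrs]
    )
    return CAPSet(maps=maps, labels=labels, member_corrs=member_corrs, thresholds=thresholds)
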