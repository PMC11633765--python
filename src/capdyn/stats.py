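"""Group inference on temporal metrics, descriptive tests, and overlap summaries.

The core comparison is a linear model ``metric ~ group + covariates`` on
complete cases; the group coefficient carries the adjusted difference
(sign convention: patient - control, stated in output headers) and
Cohen's d is computed on covariate-residualized values with a pooled-SD
standardizer.  Families of tests are corrected with Benjamini-Hochberg
FDR.  Welch's t from printed summaries and a tie-corrected Mann-Whitney Z
reproduce the descriptive-table statistics; Spearman correlation links
temporal metrics to seizure counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .preproc import _prune_collinear
from .types import ConfigurationError

__all__ = [
    "GroupResultRow",
    "adjust_and_compare",
    "compare_metrics",
    "fdr_bh",
    "welch_t_from_summary",
    "mann_whitney_z",
    "metric_seizure_correlation",
    "network_overlap",
]

#: Default adjustment covariates mirroring the study design: technical
#: (excluded/selected frame counts), demographic (age, sex) and clinical
#: (psychotropic medication, depression and state-anxiety scores).
DEFAULT_COVARIATES = (
    "n_excluded",
    "n_selected",
    "age",
    "sex",
    "medication",
    "bdi",
    "stai_s",
)


@dataclass
class GroupResultRow:
    """Adjusted group comparison for one metric (sign: patient - control)."""

    metric: str
    adjusted_diff: float
    t: float
    df: float
    p: float
    p_fdr: float
    cohens_d: float
    n_patient: int
    n_control: int

    @property
    def is_missing(self) -> bool:
        return not np.isfinite(self.t)


def _missing_row(name: str, n1: int = 0, n2: int = 0) -> GroupResultRow:
    nan = float("nan")
    return GroupResultRow(name, nan, nan, nan, nan, nan, nan, n1, n2)


def adjust_and_compare(
    values: np.ndarray | pd.Series,
    covariates: pd.DataFrame,
    covariate_columns: tuple[str, ...] = DEFAULT_COVARIATES,
    metric_name: str = "metric",
) -> GroupResultRow:
    """Covariate-adjusted patient-vs-control comparison of one metric.

    Fits ``metric ~ group + covariates`` by OLS on complete cases; the
    group-indicator coefficient (patient = 1, control = 0) is the
    adjusted difference, with its t statistic and two-sided p.  Cohen's d
    is computed from residuals of ``metric ~ covariates`` (group left
    out), standardized by the pooled SD, sign patient - control.
    Collinear covariates are pruned with a warning; fewer than 3 usable
    subjects per group yields a missing row.
    """
    if "group" not in covariates.columns:
        raise ConfigurationError("covariate table must contain a 'group' column")
    y = np.asarray(values, dtype=float)
    if y.shape[0] != len(covariates):
        raise ConfigurationError("metric length must match covariate rows")
    cols = [c for c in covariate_columns if c in covariates.columns]
    grp = (covariates["group"].astype(str) == "patient").to_numpy(dtype=float)
    X_cov = covariates[cols].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    ok = np.isfinite(y) & np.all(np.isfinite(X_cov), axis=1)
    y, grp, X_cov = y[ok], grp[ok], X_cov[ok]
    n1, n2 = int(grp.sum()), int((1 - grp).sum())
    if n1 < 3 or n2 < 3:
        return _missing_row(metric_name, n1, n2)

    labels = ["const"] + list(cols)
    Z = np.column_stack([np.ones(len(y)), X_cov])
    kept, dropped = _prune_collinear(Z, labels)
    if dropped:
        warnings.warn(f"pruned collinear covariates: {', '.join(dropped)}", stacklevel=2)
    Z = Z[:, kept]

    X = np.column_stack([Z, grp])
    if len(y) <= X.shape[1]:
        return _missing_row(metric_name, n1, n2)
    fit = sm.OLS(y, X).fit()
    diff = float(fit.params[-1])
    t_stat = float(fit.tvalues[-1])
    p = float(fit.pvalues[-1])
    df = float(fit.df_resid)

    # Cohen's d on covariate-residualized values, pooled SD.
    resid = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    r1, r2 = resid[grp == 1], resid[grp == 0]
    pooled = np.sqrt(
        ((n1 - 1) * r1.var(ddof=1) + (n2 - 1) * r2.var(ddof=1)) / (n1 + n2 - 2)
    )
    d = float((r1.mean() - r2.mean()) / pooled) if pooled > 0 else float("nan")
    return GroupResultRow(metric_name, diff, t_stat, df, p, float("nan"), d, n1, n2)


def compare_metrics(
    metric_table: pd.DataFrame,
    covariates: pd.DataFrame,
    covariate_columns: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Adjusted comparison of every column of ``metric_table``, FDR-corrected.

    All columns are treated as one FDR family (callers split families —
    e.g. the K^2 transition cells vs the K entries — before calling).
    Returns a DataFrame with the sign convention noted in its attrs.
    """
    rows = [
        adjust_and_compare(metric_table[c], covariates, covariate_columns, metric_name=c)
        for c in metric_table.columns
    ]
    raw = np.array([r.p for r in rows])
    finite = np.isfinite(raw)
    adj = np.full_like(raw, np.nan)
    if finite.any():
        adj[finite] = fdr_bh(raw[finite])
    for r, q in zip(rows, adj):
        r.p_fdr = float(q)
    out = pd.DataFrame([vars(r) for r in rows]).set_index("metric")
    out.attrs["sign_convention"] = "patient - control"
    return out


def fdr_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, clipped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def welch_t_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float, float]:
    """Welch's t test from group summaries: (t, Welch-Satterthwaite df, p)."""
    if sd1 <= 0 or sd2 <= 0:
        raise ConfigurationError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ConfigurationError("each group needs n >= 2")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    t = (mean1 - mean2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def mann_whitney_z(values1, values2) -> tuple[float, float]:
    """Rank-sum Z with tie- and continuity-corrected normal approximation.

    Sign convention: positive Z means group 1 tends to exceed group 2.
    All-tied data give Z = 0, p = 1.
    """
    x = np.asarray(values1, dtype=float)
    y = np.asarray(values2, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 1 or n2 < 1:
        raise ConfigurationError("each group needs at least one observation")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 0.0, 1.0
    cc = 0.5 * np.sign(u1 - mu)  # continuity correction toward the null
    z = (u1 - mu - cc) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return float(z), float(p)


def metric_seizure_correlation(metric_values, seizure_counts) -> tuple[float, float]:
    """Spearman correlation of a temporal metric with seizure counts.

    Rank-based because seizure counts are strongly skewed count data.
    Requires at least 4 patients with both values; zero-variance inputs
    give a missing result.
    """
    m = np.asarray(metric_values, dtype=float)
    s = np.asarray(seizure_counts, dtype=float)
    ok = np.isfinite(m) & np.isfinite(s)
    m, s = m[ok], s[ok]
    if m.size < 4:
        raise ConfigurationError("insufficient n for seizure correlation (need >= 4)")
    if m.std() == 0 or s.std() == 0:
        return float("nan"), float("nan")
    rho, p = sps.spearmanr(m, s)
    return float(rho), float(p)


def network_overlap(
    cap_map: np.ndarray,
    atlas_labels: np.ndarray,
    z_thresh: float = 1.04,
    exclude: np.ndarray | None = None,
) -> dict[str, dict[int, float]]:
    """Per-network percentage of suprathreshold CAP voxels, split by sign.

    Among voxels with z above ``+z_thresh`` (respectively below
    ``-z_thresh``) that carry an atlas label, the percentage falling in
    each label is reported; each sign's percentages sum to 100.  Atlas
    label 0 means unlabeled; ``exclude`` (e.g. seed voxels) are removed
    before counting.  No suprathreshold voxels on a side yields an empty
    dict with a warning.
    """
    cap_map = np.asarray(cap_map, dtype=float)
    atlas_labels = np.asarray(atlas_labels)
    if cap_map.shape != atlas_labels.shape:
        raise ConfigurationError("atlas must be aligned to the CAP map voxels")
    keep = atlas_labels > 0
    if exclude is not None:
        mask = np.ones_like(keep)
        mask[np.asarray(exclude, dtype=np.intp)] = False
        keep &= mask
    out: dict[str, dict[int, float]] = {}
    for sign, sel in (
        ("positive", (cap_map > z_thresh) & keep),
        ("negative", (cap_map < -z_thresh) & keep),
    ):
        total = int(sel.sum())
        if total == 0:
            warnings.warn(f"no suprathreshold voxels on the {sign} side", stacklevel=2)
            out[sign] = {}
            continue
        labels, counts = np.unique(atlas_labels[sel], return_counts=True)
        out[sign] = {int(l): 100.0 * c / total for l, c in zip(labels, counts)}
    return out
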