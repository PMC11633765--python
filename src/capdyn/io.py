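"""File formats and run provenance.

NIfTI in/out through nibabel, TSV tables through pandas, and a JSON run
manifest (config hash, seeds, package versions, per-stage frame counts)
written with every run.  Errors name the offending file and column.
"""

from __future__ import annotations

import json
import sys
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cluster import CAPSet
from .types import (
    AlignmentError,
    CapdynError,
    MOTION_COLUMNS,
    MotionParams,
    SeedMask,
    VolumeSeries,
)

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "read_motion",
    "read_nuisance",
    "read_covariates",
    "write_cap_maps",
    "write_tsv",
    "write_manifest",
]

NUISANCE_COLUMNS = ("wm", "csf", "global")
COVARIATE_COLUMNS = ("subject_id", "group", "age", "sex", "medication", "bdi", "stai_s")


def read_volume(path: str | Path, gm_mask_path: str | Path | None = None) -> VolumeSeries:
    """Load a 4-D NIfTI, optionally restricted to a gray-matter mask.

    The mask (3-D, probabilistic or binary) keeps voxels with value
    > 0.5; without one every voxel enters.  TR is taken from the header's
    fourth zoom.
    """
    img = nib.load(str(path))
    data4d = np.asanyarray(img.dataobj, dtype=np.float64)
    if data4d.ndim != 4:
        raise CapdynError(f"{path}: expected a 4-D series, got shape {data4d.shape}")
    grid_shape = data4d.shape[:3]
    if gm_mask_path is not None:
        mimg = nib.load(str(gm_mask_path))
        mdata = np.asanyarray(mimg.dataobj, dtype=np.float64)
        if mdata.shape != grid_shape:
            raise AlignmentError(
                f"{gm_mask_path}: mask grid {mdata.shape} does not match series "
                f"grid {grid_shape} of {path}"
            )
        mask = mdata > 0.5
    else:
        mask = np.ones(grid_shape, dtype=bool)
    coords = np.argwhere(mask)
    data = data4d[mask].T  # frames x voxels
    if not np.all(np.isfinite(data)):
        raise CapdynError(f"{path}: series contains non-finite values")
    tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 1.0
    return VolumeSeries(
        data=data,
        tr=tr,
        voxel_coords=coords,
        grid_shape=tuple(grid_shape),
        affine=np.asarray(img.affine),
    )


def write_volume(series: VolumeSeries, path: str | Path) -> None:
    """Write a VolumeSeries back to a 4-D NIfTI (unmasked voxels are 0)."""
    vol4d = np.zeros(series.grid_shape + (series.n_frames,))
    coords = tuple(series.voxel_coords.T)
    for t in range(series.n_frames):
        vol4d[coords + (t,)] = series.data[t]
    img = nib.Nifti1Image(vol4d, series.affine)
    img.header.set_zooms((1.0, 1.0, 1.0, series.tr))
    nib.save(img, str(path))


def read_mask(path: str | Path, series: VolumeSeries) -> SeedMask:
    """Load a 3-D seed mask aligned to the series' voxel index."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=np.float64)
    if data.shape != series.grid_shape:
        raise AlignmentError(
            f"{path}: mask grid {data.shape} does not match series grid "
            f"{series.grid_shape}"
        )
    return SeedMask(weights=data[tuple(series.voxel_coords.T)])


def _read_tsv(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CapdynError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def read_motion(path: str | Path) -> MotionParams:
    """Motion-parameter TSV with the six realignment columns."""
    df = _read_tsv(path, MOTION_COLUMNS)
    return MotionParams(df[list(MOTION_COLUMNS)].to_numpy(dtype=float))


def read_nuisance(path: str | Path) -> pd.DataFrame:
    """Nuisance-course TSV with wm/csf/global columns."""
    return _read_tsv(path, NUISANCE_COLUMNS)


def read_covariates(path: str | Path) -> pd.DataFrame:
    """Cohort covariates TSV (one row per subject)."""
    return _read_tsv(path, COVARIATE_COLUMNS)


def write_cap_maps(caps: CAPSet, series: VolumeSeries, out_dir: str | Path) -> list[Path]:
    """Write each z-scored CAP map as a 3-D NIfTI in the series grid."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    coords = tuple(series.voxel_coords.T)
    for j in range(caps.k):
        vol = np.zeros(series.grid_shape)
        vol[coords] = caps.maps[j]
        p = out_dir / f"cap_{j + 1}.nii.gz"
        nib.save(nib.Nifti1Image(vol, series.affine), str(p))
        paths.append(p)
    return paths


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def write_manifest(out_dir: str | Path, config, extra: dict | None = None) -> Path:
    """JSON run manifest: config + hash, seed, versions, stage summaries."""
    import sklearn
    import scipy
    import statsmodels

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "rng_seed": config.rng_seed,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__,
            "statsmodels": statsmodels.__version__,
            "nibabel": nib.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
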