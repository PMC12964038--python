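"""Data ingestion: VOI extraction, confound regression, table IO.

Time-series tables are TSV with one column per region; covariate tables
are CSV with ``subject``, ``group`` and ``hr_bpm`` columns.  Volumes of
interest are spheres in MNI world coordinates (mm); the default atlas
ships the six left-lateralised central-autonomic-network nodes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "VOISpec",
    "RoiTimeseries",
    "CAN_ATLAS",
    "load_atlas",
    "extract_voi",
    "dct_highpass_basis",
    "nuisance_regress",
    "read_bold_tsv",
    "write_bold_tsv",
    "read_participants",
    "write_participants",
    "read_motion_tsv",
    "read_ppg_tsv",
    "write_matrix_tsv",
    "read_matrix_tsv",
]


@dataclass(frozen=True)
class VOISpec:
    """A spherical volume of interest in MNI world coordinates."""

    label: str
    center: tuple[float, float, float]  # mm
    radius: float                       # mm

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")


#: The six CAN spheres (left-lateralised; MNI mm).
CAN_ATLAS = (
    VOISpec("vmPFC", (0.0, 44.0, -14.0), 8.0),
    VOISpec("ACC", (0.0, 47.0, 11.0), 8.0),
    VOISpec("INS", (-41.0, 3.0, 6.0), 8.0),
    VOISpec("AMY", (-24.0, -4.0, -18.0), 5.0),
    VOISpec("HYPO", (-2.0, -4.0, -10.0), 5.0),
    VOISpec("BS", (-3.0, -43.0, -55.0), 3.0),
)


def load_atlas(path) -> tuple[VOISpec, ...]:
    """Read an atlas YAML: list of {label, center: [x,y,z], radius}."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    return tuple(
        VOISpec(e["label"], tuple(float(c) for c in e["center"]), float(e["radius"]))
        for e in entries
    )


@dataclass
class RoiTimeseries:
    data: np.ndarray             # time x N
    labels: tuple[str, ...]
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("region labels must be unique")
        if self.data.shape[1] != len(self.labels):
            raise ValueError("label count must match columns")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite time-series values")


def extract_voi(
    image4d,
    affine: np.ndarray | None = None,
    spec: VOISpec | None = None,
    summary: str = "eigenvariate",
) -> np.ndarray:
    """Summarize the voxels within a sphere into one time series.

    ``image4d`` is a 4D array (with ``affine``), a nibabel spatial image,
    or a NIfTI path.  Membership is inclusive (world-space distance <=
    radius, voxel centers via the affine).  ``summary="mean"`` averages;
    the default first eigenvariate is the leading principal component,
    sign-aligned with the mean series and scaled back to mean voxel
    amplitude.
    """
    if isinstance(image4d, (str, Path)):
        import nibabel as nib

        image4d = nib.load(image4d)
    if hasattr(image4d, "get_fdata"):  # nibabel image
        affine = image4d.affine
        image4d = image4d.get_fdata()
    if affine is None or spec is None:
        raise ValueError("affine and spec are required with a plain array")
    data = np.asarray(image4d)
    if data.ndim != 4:
        raise ValueError("expected a 4D image array (x, y, z, t)")
    nx, ny, nz, _ = data.shape
    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    vox = np.column_stack([ii.ravel(), jj.ravel(), kk.ravel(), np.ones(ii.size)])
    world = vox @ np.asarray(affine, float).T
    d2 = np.sum((world[:, :3] - np.asarray(spec.center)) ** 2, axis=1)
    mask = d2 <= spec.radius**2
    if not np.any(mask):
        raise ValueError(f"sphere '{spec.label}' contains 0 voxels on this grid")
    vals = data.reshape(-1, data.shape[3])[mask].T.astype(float)  # time x voxels
    if summary == "mean":
        return vals.mean(axis=1)
    if summary != "eigenvariate":
        raise ValueError("summary must be 'mean' or 'eigenvariate'")
    centered = vals - vals.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    pc = u[:, 0] * s[0]
    mean_series = vals.mean(axis=1)
    if np.dot(pc, mean_series - mean_series.mean()) < 0:
        pc = -pc
    # rescale to mean voxel amplitude and restore the mean level
    sd_pc = pc.std()
    sd_vox = centered.std(axis=0).mean()
    if sd_pc > 0:
        pc = pc * (sd_vox / sd_pc)
    return pc + mean_series.mean()


def dct_highpass_basis(n_frames: int, tr: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift basis: all components slower than the cutoff."""
    order = int(np.floor(2.0 * n_frames * tr / cutoff_s))
    t = np.arange(n_frames)
    cols = [
        np.sqrt(2.0 / n_frames) * np.cos(np.pi * k * (2 * t + 1) / (2.0 * n_frames))
        for k in range(1, order + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_frames, 0))


def nuisance_regress(
    roi: RoiTimeseries,
    confounds: np.ndarray | None = None,
    highpass_s: float = 128.0,
) -> RoiTimeseries:
    """Project out confounds plus a 128-s discrete-cosine drift basis.

    Residuals are orthogonal to every regressor (including the implicit
    intercept).  Collinear confounds trigger a warning carrying the
    condition number.  The operation is idempotent.
    """
    import warnings

    y = roi.data
    n = y.shape[0]
    parts = [np.ones((n, 1)), dct_highpass_basis(n, roi.tr, highpass_s)]
    if confounds is not None:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.shape[0] != n:
            raise ValueError("confound rows must align with frames")
        parts.append(confounds)
    x = np.column_stack([p for p in parts if p.size])
    sv = np.linalg.svd(x, compute_uv=False)
    cond = sv[0] / max(sv[-1], 1e-300)
    if cond > 1e8:
        warnings.warn(f"confound matrix ill-conditioned (condition number {cond:.3g})")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return RoiTimeseries(resid, roi.labels, roi.tr)


# ---------------------------------------------------------------------------
# table readers / writers (round-trip identity)


def write_bold_tsv(path, roi: RoiTimeseries) -> None:
    pd.DataFrame(roi.data, columns=list(roi.labels)).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_bold_tsv(path, tr: float) -> RoiTimeseries:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected one column per region")
    try:
        data = df.to_numpy(dtype=float)
    except ValueError as err:
        raise ValueError(f"{path}: non-numeric cell ({err})") from err
    return RoiTimeseries(data, tuple(df.columns), tr)


def write_participants(path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False, float_format="%.17g")


def read_participants(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"subject", "group"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(required)}")
    if "hr_bpm" in df.columns:
        df["missing_hr"] = df["hr_bpm"].isna()
    return df


def read_motion_tsv(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    arr = df.to_numpy(dtype=float)
    if arr.shape[1] != 6:
        raise ValueError(f"{path}: motion table must have 6 columns, has {arr.shape[1]}")
    return arr


def read_ppg_tsv(path) -> tuple[np.ndarray, float]:
    """Returns (amplitude, fs) from a (time, amplitude) TSV."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] != 2:
        raise ValueError(f"{path}: PPG table must have (time, amplitude) columns")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    dt = np.diff(t)
    if dt.size == 0 or np.any(dt <= 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    return df.iloc[:, 1].to_numpy(dtype=float), 1.0 / float(np.median(dt))


def write_matrix_tsv(path, matrix: np.ndarray, labels) -> None:
    """Write an N x N matrix with region labels; NaN cells are blank."""
    df = pd.DataFrame(matrix, index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", na_rep="", float_format="%.17g")


def read_matrix_tsv(path) -> tuple[np.ndarray, tuple[str, ...]]:
    """Blank cells map back to NaN (below-threshold), never to 0."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return df.to_numpy(dtype=float), tuple(df.columns)
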