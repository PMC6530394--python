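"""Functional connectivity from ROI time series.

The connectivity matrix is the pairwise Pearson correlation of the regional
time series, Fisher r-to-z transformed (``z = atanh(r)``) to approximate a
Gaussian sampling distribution.  Following the usual convention for weighted
graph analysis, negative correlations are removed (set to zero) by default,
so the matrix can serve directly as a nonnegative edge-weight matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import RoiDefinition
from .errors import DegenerateInputError, EmptyRoiError

__all__ = [
    "TimeSeriesPanel",
    "FcMatrix",
    "extract_roi_timeseries",
    "fc_matrix",
    "mean_strength",
    "read_timeseries_tsv",
    "write_timeseries_tsv",
]

_R_CLIP = 1.0 - 1e-7


@dataclass
class TimeSeriesPanel:
    """Per-subject ROI time series: a T x N matrix plus region labels."""

    subject_id: str
    data: np.ndarray
    roi_names: list[str]

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a T x N matrix")
        if self.data.shape[1] != len(self.roi_names):
            raise ValueError(
                f"{self.data.shape[1]} columns but {len(self.roi_names)} ROI names"
            )
        if not np.isfinite(self.data).all():
            raise ValueError(f"non-finite values in time series for {self.subject_id}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    def constant_columns(self) -> list[str]:
        """Names of zero-variance (constant) channels."""
        sd = self.data.std(axis=0)
        return [name for name, s in zip(self.roi_names, sd) if s == 0.0]


@dataclass
class FcMatrix:
    """Fisher-z functional-connectivity matrix with zero diagonal."""

    z: np.ndarray
    roi_names: list[str] = field(default_factory=list)
    negatives_removed: bool = True
    n_timepoints: int | None = None

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        n = self.z.shape[0]
        if self.z.shape != (n, n):
            raise ValueError("z must be square")
        if not np.allclose(self.z, self.z.T, atol=1e-12):
            raise ValueError("z must be symmetric")
        self.z = (self.z + self.z.T) / 2.0
        np.fill_diagonal(self.z, 0.0)
        if self.negatives_removed and (self.z < 0).any():
            raise ValueError("negatives_removed is set but negative entries remain")
        if not self.roi_names:
            self.roi_names = [f"roi{i:02d}" for i in range(n)]

    @property
    def n_regions(self) -> int:
        return self.z.shape[0]

    @classmethod
    def from_correlation(
        cls, r: np.ndarray, roi_names=None, remove_negatives: bool = True
    ) -> "FcMatrix":
        """Build an FcMatrix from a correlation matrix (e.g. a population one)."""
        r = np.asarray(r, dtype=float).copy()
        np.fill_diagonal(r, 0.0)
        r = np.clip(r, -_R_CLIP, _R_CLIP)
        z = np.arctanh(r)
        if remove_negatives:
            z[z < 0] = 0.0
        return cls(
            z=z,
            roi_names=list(roi_names) if roi_names is not None else [],
            negatives_removed=remove_negatives,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.z, index=self.roi_names, columns=self.roi_names)

    def edge_list(self) -> pd.DataFrame:
        """Long-format upper-triangle edge list (roi_i, roi_j, z)."""
        rows = []
        n = self.n_regions
        for i in range(n):
            for j in range(i + 1, n):
                rows.append((self.roi_names[i], self.roi_names[j], self.z[i, j]))
        return pd.DataFrame(rows, columns=["roi_i", "roi_j", "z"])


def extract_roi_timeseries(image, atlas: list[RoiDefinition], subject_id: str = "subject"):
    """Average voxel time series within each spherical ROI of a 4D image.

    A voxel belongs to an ROI when its center (mapped to mm space through
    the image affine) lies within ``radius`` mm of the ROI coordinate.
    Overlapping spheres share voxels.

    Parameters
    ----------
    image
        A nibabel spatial image with 4D data and an affine mapping voxel
        indices to mm coordinates.
    atlas
        Nonempty list of ROI definitions.
    """
    if not atlas:
        raise ValueError("atlas must be nonempty")
    affine = getattr(image, "affine", None)
    if affine is None:
        raise ValueError("image has no affine; cannot map voxels to mm space")
    data = np.asarray(image.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D image, got shape {data.shape}")
    nx, ny, nz, nt = data.shape

    ii, jj, kk = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    vox = np.stack([ii, jj, kk, np.ones_like(ii)], axis=-1).reshape(-1, 4)
    mm = vox @ np.asarray(affine, dtype=float).T  # voxel centers in mm

    cols = np.empty((nt, len(atlas)), dtype=float)
    flat = data.reshape(-1, nt)
    for c, roi in enumerate(atlas):
        d2 = ((mm[:, :3] - np.array(roi.center, dtype=float)) ** 2).sum(axis=1)
        mask = d2 <= roi.radius**2
        if not mask.any():
            raise EmptyRoiError(f"ROI {roi.name!r} contains no voxels of the image grid")
        cols[:, c] = flat[mask].mean(axis=0)
    return TimeSeriesPanel(
        subject_id=subject_id, data=cols, roi_names=[r.name for r in atlas]
    )


def fc_matrix(panel: TimeSeriesPanel, remove_negatives: bool = True) -> FcMatrix:
    """Pearson + Fisher r-to-z connectivity matrix of a time-series panel.

    Correlations of magnitude 1 (degenerate duplicated channels) are clipped
    to ``1 - 1e-7`` before ``atanh`` with a warning; with ``remove_negatives``
    every negative correlation becomes a zero-weight (absent) edge.
    """
    if panel.n_timepoints < 3:
        raise DegenerateInputError(
            f"need at least 3 timepoints, got {panel.n_timepoints}"
        )
    constant = panel.constant_columns()
    if constant:
        raise DegenerateInputError(
            f"zero-variance channel(s) {constant} for subject {panel.subject_id}"
        )
    r = np.corrcoef(panel.data, rowvar=False)
    np.fill_diagonal(r, 0.0)
    if (np.abs(r) > _R_CLIP).any():
        warnings.warn(
            f"perfectly correlated channel pair(s) in {panel.subject_id}; "
            "clipping |r| before Fisher transform",
            stacklevel=2,
        )
        r = np.clip(r, -_R_CLIP, _R_CLIP)
    z = np.arctanh(r)
    if remove_negatives:
        z[z < 0] = 0.0
    z = (z + z.T) / 2.0
    return FcMatrix(
        z=z,
        roi_names=list(panel.roi_names),
        negatives_removed=remove_negatives,
        n_timepoints=panel.n_timepoints,
    )


def mean_strength(fc: FcMatrix) -> float:
    """Mean connection strength: average z over all N(N-1)/2 region pairs.

    Pairs whose negative correlation was removed count as zeros, so the
    denominator is always the full number of pairs.
    """
    n = fc.n_regions
    iu = np.triu_indices(n, 1)
    return float(fc.z[iu].mean())


def read_timeseries_tsv(path, subject_id: str | None = None) -> TimeSeriesPanel:
    """Read a T x N time-series TSV whose header holds the ROI names."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return TimeSeriesPanel(
        subject_id=subject_id or path.stem,
        data=df.to_numpy(dtype=float),
        roi_names=list(df.columns),
    )


def write_timeseries_tsv(panel: TimeSeriesPanel, path) -> None:
    # default float formatting is repr-based and round-trips exactly
    pd.DataFrame(panel.data, columns=panel.roi_names).to_csv(
        path, sep="\t", index=False
    )
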