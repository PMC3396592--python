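"""Regional value extraction and nuisance-covariate removal.

Structural covariance networks start from one scalar per subject per brain
region (gray-matter volume, cortical thickness, surface area, ...).  This
module turns per-subject voxel images plus a parcellation into that
subjects × regions table, ingests pre-extracted tables from CSV/XLSX, and
removes nuisance covariates (total brain volume, age, ...) by ordinary
least-squares regression, substituting the residuals for the raw values.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RegionalDataTable",
    "CovariateTable",
    "extract_regional_means",
    "residualize",
    "read_regional_table",
    "read_covariate_table",
]


@dataclass
class RegionalDataTable:
    """Subjects × regions matrix of regional values (raw or residualized).

    Parameters
    ----------
    values : ndarray, shape (n_subjects, n_regions)
        Regional morphometric values; arbitrary units.
    region_labels : sequence of str
        Unique region names, one per column.
    subject_ids : sequence of str
        One identifier per row.
    group : str
        Group tag (e.g. ``"patients"``), carried through reports.
    """

    values: np.ndarray
    region_labels: Sequence[str]
    subject_ids: Sequence[str] = field(default_factory=list)
    group: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D subjects x regions matrix")
        n_subj, n_reg = self.values.shape
        self.region_labels = [str(r) for r in self.region_labels]
        if len(self.region_labels) != n_reg:
            raise ValueError(
                f"{len(self.region_labels)} region labels for {n_reg} columns"
            )
        if len(set(self.region_labels)) != n_reg:
            raise ValueError("region labels must be unique")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i:03d}" for i in range(n_subj)]
        self.subject_ids = [str(s) for s in self.subject_ids]
        if len(self.subject_ids) != n_subj:
            raise ValueError("subject_ids length does not match rows")
        # network construction itself needs >= 3 regions and >= 3 subjects;
        # that is enforced at correlation time so extraction can also produce
        # small intermediate tables
        if not np.isfinite(self.values).all():
            raise ValueError("regional values contain missing/non-finite entries")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_regions(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.subject_ids, columns=self.region_labels
        )


@dataclass
class CovariateTable:
    """Subjects × covariates design values, aligned row-for-row with the data."""

    values: np.ndarray
    covariate_labels: Sequence[str]
    subject_ids: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] == 1 and len(self.covariate_labels) == 1:
            # a single covariate given as a flat vector
            self.values = self.values.T if self.values.shape[1] > 1 else self.values
        self.covariate_labels = [str(c) for c in self.covariate_labels]
        if len(self.covariate_labels) != self.values.shape[1]:
            raise ValueError("covariate_labels length does not match columns")
        if not np.isfinite(self.values).all():
            raise ValueError("covariates contain non-finite entries")
        variances = self.values.var(axis=0)
        dead = [l for l, v in zip(self.covariate_labels, variances) if v == 0]
        if dead:
            raise ValueError(f"covariate(s) with zero variance: {dead}")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i:03d}" for i in range(self.values.shape[0])]
        self.subject_ids = [str(s) for s in self.subject_ids]


def _load_volume(img) -> np.ndarray:
    """Accept a nibabel image, a path to one, or a bare ndarray."""
    if isinstance(img, (str, os.PathLike)):
        import nibabel as nib

        return np.asanyarray(nib.load(os.fspath(img)).dataobj, dtype=float)
    if hasattr(img, "dataobj"):  # nibabel image
        return np.asanyarray(img.dataobj, dtype=float)
    return np.asarray(img, dtype=float)


def extract_regional_means(
    images: Sequence,
    rois,
    *,
    subject_ids: Sequence[str] | None = None,
    region_labels: Sequence[str] | None = None,
    group: str = "",
) -> RegionalDataTable:
    """Average each subject's image over each region of interest.

    Parameters
    ----------
    images : sequence
        Per-subject volumes: NIfTI paths, nibabel images, or ndarrays, all on
        the same voxel grid as the ROIs.
    rois : sequence of masks, or a single labeled atlas
        Either a sequence of binary mask volumes (region order follows the
        sequence) or one integer-labeled atlas volume (regions are the
        distinct nonzero labels, ascending).
    region_labels, subject_ids, group : optional metadata for the result.

    Returns
    -------
    RegionalDataTable
        Entry ``(s, r)`` is the unweighted mean of image *s* over the voxels
        where ROI *r* is nonzero.
    """
    vols = [_load_volume(im) for im in images]
    if not vols:
        raise ValueError("no images given")
    shape = vols[0].shape
    for idx, v in enumerate(vols):
        if v.shape != shape:
            raise ValueError(
                f"dimension mismatch: image 0 has shape {shape}, "
                f"image {idx} has shape {v.shape}"
            )

    # Resolve ROI definitions into a list of boolean masks.
    if isinstance(rois, (list, tuple)):
        masks = []
        for ridx, roi in enumerate(rois):
            m = _load_volume(roi)
            if m.shape != shape:
                raise ValueError(
                    f"dimension mismatch: ROI {ridx} has shape {m.shape}, "
                    f"images have shape {shape}"
                )
            masks.append(m != 0)
        labels = list(region_labels) if region_labels is not None else [
            f"roi-{i:03d}" for i in range(len(masks))
        ]
    else:
        atlas = _load_volume(rois)
        if atlas.shape != shape:
            raise ValueError(
                f"dimension mismatch: atlas has shape {atlas.shape}, "
                f"images have shape {shape}"
            )
        atlas_int = np.rint(atlas).astype(int)
        label_values = np.unique(atlas_int)
        label_values = label_values[label_values != 0]
        masks = [atlas_int == lv for lv in label_values]
        labels = list(region_labels) if region_labels is not None else [
            f"roi-{int(lv)}" for lv in label_values
        ]

    for lab, m in zip(labels, masks):
        if not m.any():
            raise ValueError(f"empty ROI: {lab}")

    values = np.empty((len(vols), len(masks)))
    for s, v in enumerate(vols):
        for r, m in enumerate(masks):
            values[s, r] = v[m].mean()
    return RegionalDataTable(values, labels, subject_ids or [], group)


def residualize(data: RegionalDataTable, cov: CovariateTable) -> RegionalDataTable:
    """Replace each region's values with OLS residuals on [intercept + covariates].

    Every region is regressed independently on the full covariate set; the
    residuals are substituted for the raw values, so downstream correlations
    are free of the covariates' shared variance.  An intercept is always
    included, hence residuals per region sum to zero.
    """
    if cov.values.shape[0] != data.n_subjects:
        raise ValueError(
            f"subject-count mismatch: data has {data.n_subjects} subjects, "
            f"covariates have {cov.values.shape[0]} rows"
        )
    design = np.column_stack([np.ones(data.n_subjects), cov.values])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank deficient covariate design (with intercept)")
    beta, *_ = np.linalg.lstsq(design, data.values, rcond=None)
    resid = data.values - design @ beta
    return RegionalDataTable(
        resid, data.region_labels, data.subject_ids, data.group
    )


def read_regional_table(path, *, group: str = "") -> RegionalDataTable:
    """Read a subjects × regions table from CSV or XLSX.

    The header row holds region labels; the first column holds subject IDs.
    """
    df = _read_table(path)
    return RegionalDataTable(
        df.to_numpy(dtype=float),
        list(df.columns),
        [str(i) for i in df.index],
        group,
    )


def read_covariate_table(path) -> CovariateTable:
    """Read a subjects × covariates table from CSV or XLSX (same layout)."""
    df = _read_table(path)
    return CovariateTable(
        df.to_numpy(dtype=float), list(df.columns), [str(i) for i in df.index]
    )


def _read_table(path) -> pd.DataFrame:
    p = os.fspath(path)
    if p.lower().endswith((".xlsx", ".xls")):
        return pd.read_excel(p, index_col=0)
    return pd.read_csv(p, index_col=0)
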