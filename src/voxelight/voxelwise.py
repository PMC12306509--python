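"""Mask construction, covariate-adjusted voxel-wise group contrasts, FDR,
cluster extraction, and effect sizes.

The group contrast at each voxel is the t statistic on the group indicator
from the linear model ``GMV ~ group + covariates`` (covariates typically age,
gender, education, and total intracranial volume).  Multiple comparisons are
handled by Benjamini-Hochberg FDR; significant voxels are reduced to
face-connected clusters with peak statistics and optional atlas labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .containers import BrainMask, CohortVolumes, unmask


def build_mask(cohort: CohortVolumes, threshold: float = 0.2) -> BrainMask:
    """Group brain mask: voxels whose mean across subjects exceeds ``threshold``."""
    mean_map = cohort.data.mean(axis=0)
    inside = mean_map > threshold
    if not inside.any():
        raise ValueError(
            f"empty mask: no voxel has mean gray matter above {threshold}"
        )
    return BrainMask(inside, cohort.affine, threshold=threshold,
                     n_subjects_averaged=cohort.n_subjects)


@dataclass
class StatMap:
    """Per-voxel t statistics with raw and FDR-adjusted p-values."""

    t: np.ndarray  # (n_voxels,) in mask order
    p: np.ndarray
    q: np.ndarray | None
    mask: BrainMask | None
    df: int
    covariates: list[str] = field(default_factory=list)

    def t_volume(self) -> np.ndarray:
        if self.mask is None:
            raise ValueError("this map was computed from a plain matrix, not volumes")
        return unmask(self.t, self.mask)

    def significance_mask(self, level: float = 0.05) -> np.ndarray:
        """Boolean volume of voxels with q <= level (requires FDR applied)."""
        if self.q is None:
            raise ValueError("FDR has not been applied to this map")
        if self.mask is None:
            raise ValueError("this map was computed from a plain matrix, not volumes")
        return unmask((self.q <= level).astype(float), self.mask) > 0.5


def _design_matrix(
    groups: np.ndarray, covariates: pd.DataFrame | None
) -> tuple[np.ndarray, list[str]]:
    uniq = np.unique(groups)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {list(uniq)}")
    # alphabetically first group coded 1 so the sign convention is stable
    indicator = (groups == uniq[0]).astype(float)
    cols = [indicator, np.ones_like(indicator)]
    names = ["group", "intercept"]
    if covariates is not None and len(covariates.columns):
        for c in covariates.columns:
            cols.append(covariates[c].to_numpy(dtype=float))
            names.append(c)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify which columns are redundant for the error message
        bad = []
        for j in range(X.shape[1]):
            keep = [k for k in range(X.shape[1]) if k != j]
            if np.linalg.matrix_rank(X[:, keep]) == rank:
                bad.append(names[j])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    return X, names


def group_tmap(
    data: np.ndarray | CohortVolumes,
    groups: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    mask: BrainMask | None = None,
) -> StatMap:
    """Voxel-wise two-group contrast adjusted for covariates.

    ``data`` is either a subjects x voxels matrix or a :class:`CohortVolumes`
    (then ``mask`` is required).  The t statistic tests the group indicator
    in an ordinary least-squares fit per voxel; p-values are two-sided.
    """
    if isinstance(data, CohortVolumes):
        if mask is None:
            raise ValueError("mask is required with CohortVolumes input")
        Y = data.masked_matrix(mask)
    else:
        Y = np.asarray(data, dtype=float)
    groups = np.asarray(groups)
    X, names = _design_matrix(groups, covariates)
    n, p = X.shape
    counts = pd.Series(groups).value_counts()
    if counts.min() < p:
        warnings.warn(
            f"smallest group ({counts.min()}) below number of design columns ({p})"
        )
    df = n - p
    if df <= 0:
        raise ValueError("not enough subjects for the requested covariates")

    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ (X.T @ Y)  # (p, n_voxels)
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.maximum(sigma2, 0.0) * xtx_inv[0, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[0] / se, 0.0)
    p_two = 2.0 * stats.t.sf(np.abs(t), df)
    return StatMap(t=t, p=p_two, q=None, mask=mask, df=df, covariates=names[2:])


def fdr_correct(p: np.ndarray, q_level: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up q-values and the significance mask q <= level."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    _, qvals, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
    return qvals, qvals <= q_level


def with_fdr(stat_map: StatMap, q_level: float = 0.05) -> StatMap:
    """Return a copy of the map with BH q-values filled in."""
    qvals, _ = fdr_correct(stat_map.p, q_level)
    return StatMap(stat_map.t, stat_map.p, qvals, stat_map.mask, stat_map.df,
                   list(stat_map.covariates))


# 6-connectivity: faces only
_FACE_STRUCTURE = ndimage.generate_binary_structure(3, 1)


def extract_clusters(
    significant: np.ndarray,
    t_volume: np.ndarray,
    affine: np.ndarray,
    min_extent: int = 10,
    atlas: np.ndarray | None = None,
    atlas_names: dict[int, str] | None = None,
) -> pd.DataFrame:
    """Reduce a boolean significance volume to a table of face-connected clusters.

    Each row reports cluster size, the peak |t| voxel with its t value, the
    peak in voxel indices and mm (via the affine), and the atlas label at the
    peak when an atlas is given.  Clusters below ``min_extent`` are dropped.
    """
    labels, n_found = ndimage.label(significant, structure=_FACE_STRUCTURE)
    rows = []
    for lab in range(1, n_found + 1):
        members = np.argwhere(labels == lab)
        if len(members) < min_extent:
            continue
        t_here = t_volume[tuple(members.T)]
        peak_idx = members[np.abs(t_here).argmax()]
        peak_t = t_volume[tuple(peak_idx)]
        peak_mm = (affine @ np.append(peak_idx, 1.0))[:3]
        atlas_label = int(atlas[tuple(peak_idx)]) if atlas is not None else None
        rows.append(
            {
                "size": len(members),
                "peak_t": float(peak_t),
                "peak_i": int(peak_idx[0]),
                "peak_j": int(peak_idx[1]),
                "peak_k": int(peak_idx[2]),
                "peak_x_mm": float(peak_mm[0]),
                "peak_y_mm": float(peak_mm[1]),
                "peak_z_mm": float(peak_mm[2]),
                "atlas_label": atlas_label,
                "atlas_name": (
                    atlas_names.get(atlas_label) if atlas_names and atlas_label else None
                ),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "size", "peak_t", "peak_i", "peak_j", "peak_k",
            "peak_x_mm", "peak_y_mm", "peak_z_mm", "atlas_label", "atlas_name",
        ],
    )
    return table.sort_values("size", ascending=False, ignore_index=True)


def residualize_cohort(
    cohort: CohortVolumes, covariates: pd.DataFrame
) -> CohortVolumes:
    """Regress the covariates (plus intercept) out of every voxel.

    Sensitivity-analysis helper for feature-based stages, which by default
    run on unadjusted volumes (covariates are adjusted only inside the
    t-map model).
    """
    n = cohort.n_subjects
    X = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
    flat = cohort.data.reshape(n, -1)
    beta, *_ = np.linalg.lstsq(X, flat, rcond=None)
    resid = (flat - X @ beta).reshape(cohort.data.shape)
    return CohortVolumes(resid, cohort.affine, list(cohort.subject_ids))


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Standardized mean difference (mean_x - mean_y) / pooled sd."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = len(x), len(y)
    if nx < 2 or ny < 2:
        raise ValueError("need at least two observations per group")
    pooled_var = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if pooled_var == 0:
        return 0.0
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))
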