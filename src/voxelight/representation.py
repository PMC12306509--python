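"""Per-voxel prediction of cognitive composites from searchlight features.

At every constrained voxel, the sphere's PCA features enter a linear model
predicting a cognitive domain composite.  The Pearson correlation between
predicted and observed scores measures how well the voxel's neighborhood
represents that domain; its significance comes from a permutation null, and
Benjamini-Hochberg FDR is applied per domain across constrained voxels
(default level 0.001).  In the map the permutation shuffles the observed
scores and re-applies the whole (linear) prediction step to each shuffle,
which keeps the null faithful to the prediction mode; the simple
shuffle-the-predicted-vector scheme is available as
:func:`permutation_null` for fixed prediction/observation pairs.

Predictions are out-of-fold by default — in-sample linear-model correlations
are optimistically biased — with an ``insample`` switch for the literal
fit-then-correlate reading.  The permutation null is computed on whichever
predictions are active.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .containers import BrainMask, CohortVolumes
from .searchlight import RegionPartition, neighborhood_index, searchlight_features
from .voxelwise import fdr_correct


@dataclass
class RepresentationSpec:
    """Settings of the representation stage."""

    n_perm: int = 10_000
    fdr_level: float = 0.001
    cv_folds: int = 10
    variance_retained: float = 0.8
    radius_mm: float = 2.0
    insample: bool = False
    seed: int = 0


@dataclass
class RepresentationMap:
    """Per constrained voxel, per domain: r, permutation p, FDR q."""

    table: pd.DataFrame  # columns: voxel (flat pos), domain, r, p, q, significant
    voxel_coords: np.ndarray  # (n_constrained, 3) voxel indices
    spec: RepresentationSpec
    n_subjects_used: dict[str, int] = field(default_factory=dict)

    def domain_table(self, domain: str) -> pd.DataFrame:
        sub = self.table[self.table["domain"] == domain]
        if sub.empty:
            raise KeyError(f"domain {domain!r} not in map")
        return sub


def predict_scores(
    features: np.ndarray,
    observed: np.ndarray,
    cv_folds: int | None = 10,
    seed: int = 0,
) -> np.ndarray:
    """Linear-model predictions of ``observed`` from ``features``.

    With ``cv_folds`` set, every subject's prediction comes from a model fit
    with that subject held out (k-fold); with ``cv_folds=None`` the model is
    fit once on everyone and in-sample fitted values are returned.
    Rank-deficient feature blocks lose their redundant columns with a
    warning (lstsq minimum-norm solution).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(observed, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("features and scores have different lengths")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("rank-deficient features; using minimum-norm solution")
    Xd = np.column_stack([np.ones(n), X])
    if cv_folds is None:
        beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        return Xd @ beta
    if n <= X.shape[1] + 1:
        raise ValueError("need more subjects than features plus intercept")
    pred = np.empty(n)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in kf.split(Xd):
        beta, *_ = np.linalg.lstsq(Xd[train_idx], y[train_idx], rcond=None)
        pred[test_idx] = Xd[test_idx] @ beta
    return pred


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def permutation_null(
    predicted: np.ndarray,
    observed: np.ndarray,
    n_perm: int = 10_000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Two-sided permutation p-value for r(predicted, observed).

    The predicted vector is shuffled ``n_perm`` times; the p-value is the
    add-one estimator ``(1 + #{|r_perm| >= |r_obs|}) / (n_perm + 1)``.
    Returns ``(r_obs, p)``.  Constant inputs give r = 0, p = 1.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    n = len(observed)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if predicted.std() == 0 or observed.std() == 0:
        warnings.warn("constant vector in permutation test; p = 1")
        return 0.0, 1.0
    r_obs = _pearson(predicted, observed)
    if rng is None:
        rng = np.random.default_rng(seed)
    # vectorized: permute the predicted vector, correlate against observed
    pc = predicted - predicted.mean()
    oc = observed - observed.mean()
    oc_norm = np.sqrt((oc**2).sum())
    pc_norm = np.sqrt((pc**2).sum())
    perms = np.empty((n_perm, n))
    for i in range(n_perm):
        perms[i] = pc[rng.permutation(n)]
    r_perm = (perms @ oc) / (pc_norm * oc_norm)
    p = (1.0 + np.sum(np.abs(r_perm) >= np.abs(r_obs) - 1e-12)) / (n_perm + 1.0)
    return r_obs, float(p)


def _prediction_operator(
    X: np.ndarray, cv_folds: int | None, seed: int
) -> np.ndarray:
    """The linear map H with predictions = H @ y.

    For the in-sample mode H is the ordinary hat matrix; for the
    cross-validated mode each held-out block's rows come from the model fit
    on the remaining folds.  Predictions being linear in the scores is what
    lets the permutation null re-run the whole prediction step per shuffle
    at matrix-multiply cost.
    """
    n = X.shape[0]
    Xd = np.column_stack([np.ones(n), X])
    if cv_folds is None:
        return Xd @ np.linalg.pinv(Xd)
    H = np.zeros((n, n))
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in kf.split(Xd):
        H[np.ix_(test_idx, train_idx)] = Xd[test_idx] @ np.linalg.pinv(Xd[train_idx])
    return H


def permutation_pvalue_refit(
    H: np.ndarray,
    observed: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Permutation p for r(H y, y) with the scores shuffled and the
    prediction step re-applied to each shuffle.

    Re-predicting per permutation keeps the null distribution faithful to
    the prediction mode: held-out predictions carry a negative correlation
    bias under the null, and a null built from shuffles of the *fixed*
    predicted vector would not reproduce it (see the methods note).  The
    test is one-sided on r — predictive skill means correlating *better*
    than chance, and the chance level of cross-validated predictions is
    below zero — with the add-one estimator.
    """
    y = np.asarray(observed, dtype=float)
    n = len(y)
    r_obs = _pearson(H @ y, y)
    perm_idx = np.empty((n, n_perm), dtype=np.intp)
    for j in range(n_perm):
        perm_idx[:, j] = rng.permutation(n)
    Yp = y[perm_idx]  # n x n_perm
    Up = H @ Yp
    Uc = Up - Up.mean(axis=0)
    Yc = Yp - Yp.mean(axis=0)
    denom = np.sqrt((Uc**2).sum(axis=0) * (Yc**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r_perm = np.where(denom > 0, (Uc * Yc).sum(axis=0) / denom, 0.0)
    p = (1.0 + np.sum(r_perm >= r_obs - 1e-12)) / (n_perm + 1.0)
    return float(r_obs), float(p)


def representation_map(
    cohort: CohortVolumes,
    mask: BrainMask,
    partition: RegionPartition,
    composites: pd.DataFrame,
    spec: RepresentationSpec | None = None,
    domains: list[str] | None = None,
) -> RepresentationMap:
    """r / permutation p / FDR q per constrained voxel per cognitive domain.

    ``composites`` is a subject-aligned table with a ``subject_id`` column
    and one column per domain; subjects with a missing composite are dropped
    for that domain (count recorded).  Deterministic under ``spec.seed``.
    """
    spec = spec or RepresentationSpec()
    if domains is None:
        domains = [c for c in composites.columns if c != "subject_id"]
    constrained_vol = partition.constrained
    if not constrained_vol.any():
        raise ValueError("empty constrained set; nothing to map")
    in_mask_pos = np.flatnonzero(constrained_vol[mask.data])
    coords = mask.indices[in_mask_pos]

    Y = cohort.masked_matrix(mask)
    neighbors = neighborhood_index(mask, spec.radius_mm)
    comp = composites.set_index("subject_id").loc[cohort.subject_ids]

    rows = []
    n_used: dict[str, int] = {}
    for domain in domains:
        scores_all = comp[domain].to_numpy(dtype=float)
        keep = np.isfinite(scores_all)
        n_used[domain] = int(keep.sum())
        if (~keep).any():
            warnings.warn(
                f"domain {domain!r}: dropped {int((~keep).sum())} subjects with "
                "missing composites"
            )
        scores = scores_all[keep]
        rng = np.random.default_rng([spec.seed, zlib.crc32(domain.encode())])
        for pos in in_mask_pos:
            feats, degenerate = searchlight_features(
                Y[np.ix_(keep, neighbors[pos])], spec.variance_retained
            )
            if degenerate:
                rows.append((pos, domain, 0.0, 1.0))
                continue
            H = _prediction_operator(
                feats, None if spec.insample else spec.cv_folds, spec.seed
            )
            r, p = permutation_pvalue_refit(H, scores, spec.n_perm, rng)
            rows.append((pos, domain, r, p))

    table = pd.DataFrame(rows, columns=["voxel", "domain", "r", "p"])
    table["q"] = np.nan
    table["significant"] = False
    for domain in domains:
        sel = table["domain"] == domain
        qvals, sig = fdr_correct(table.loc[sel, "p"].to_numpy(), spec.fdr_level)
        table.loc[sel, "q"] = qvals
        table.loc[sel, "significant"] = sig
    return RepresentationMap(table, coords, spec, n_used)


def domain_coverage(rep_map: RepresentationMap) -> pd.Series:
    """Per domain, the fraction of constrained voxels significant at the map's FDR level."""
    return rep_map.table.groupby("domain")["significant"].mean()


def contrast_domains(
    rep_map: RepresentationMap,
    domain_a: str,
    domain_b: str,
    atlas: np.ndarray | None = None,
) -> pd.DataFrame:
    """Constrained voxels significant for ``domain_a`` but not ``domain_b``.

    Returns their voxel coordinates (plus the atlas label when given).
    """
    ta = rep_map.domain_table(domain_a)
    tb = rep_map.domain_table(domain_b)
    sig_a = set(ta.loc[ta["significant"], "voxel"])
    sig_b = set(tb.loc[tb["significant"], "voxel"])
    only_a = sorted(sig_a - sig_b)
    pos_index = {pos: i for i, pos in enumerate(ta["voxel"])}
    coords = np.array([rep_map.voxel_coords[pos_index[p]] for p in only_a]).reshape(-1, 3)
    out = pd.DataFrame(coords, columns=["i", "j", "k"])
    out.insert(0, "voxel", only_a)
    if atlas is not None and len(out):
        out["atlas_label"] = atlas[coords[:, 0], coords[:, 1], coords[:, 2]]
    return out
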