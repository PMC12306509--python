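"""Longitudinal analyses: voxel-wise annual decline rates, group contrasts
on rate maps, rate-cognition correlation, mediation, and the two-level
growth model of cognitive aging.

The annual decline rate at a voxel is the signed fractional change of
baseline gray matter per year, ``(V_t2 - V_t1) / (V_t1 * dt)`` (negative =
atrophy); an absolute-difference mode ``(V_t2 - V_t1) / dt`` is available.
Rates aggregate to atlas regions by in-mask means.  The growth model is the
standard two-level mixed model: level 1 regresses each subject's cognitive
score on time since baseline; level 2 moderates the subject intercept and
slope by baseline age, gender, education, and exposure group, with
correlated random intercepts and slopes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .containers import BrainMask, CohortVolumes
from .voxelwise import StatMap, extract_clusters, group_tmap, with_fdr


@dataclass
class DeclineRateMap:
    """Per subject, per in-mask voxel: annual rate of gray-matter change."""

    rates: np.ndarray  # (n_subjects, n_voxels), NaN where baseline == 0
    mask: BrainMask
    subject_ids: list[str]
    interval_years: np.ndarray
    mode: str = "fractional"  # or "absolute"
    n_undefined: int = 0


def annual_decline_rate(
    baseline: CohortVolumes,
    followup: CohortVolumes,
    interval_years: np.ndarray | pd.Series,
    mask: BrainMask,
    mode: str = "fractional",
) -> DeclineRateMap:
    """Per-subject voxel-wise annual change rate between two scans.

    ``fractional`` mode normalizes by baseline (fraction of baseline volume
    per year); voxels with zero baseline are undefined (NaN) and counted.
    ``absolute`` mode is the raw difference per year.
    """
    if baseline.grid_dims != followup.grid_dims:
        raise ValueError("baseline and follow-up grids differ")
    if baseline.subject_ids != followup.subject_ids:
        raise ValueError("baseline and follow-up subject orders differ")
    dt = np.asarray(interval_years, dtype=float)
    if np.any(dt <= 0):
        raise ValueError("all follow-up intervals must be positive")
    v1 = baseline.masked_matrix(mask)
    v2 = followup.masked_matrix(mask)
    diff = (v2 - v1) / dt[:, None]
    if mode == "fractional":
        with np.errstate(divide="ignore", invalid="ignore"):
            rates = np.where(v1 > 0, diff / v1, np.nan)
        n_undef = int((v1 <= 0).sum())
    elif mode == "absolute":
        rates = diff
        n_undef = 0
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DeclineRateMap(
        rates, mask, list(baseline.subject_ids), dt, mode=mode, n_undefined=n_undef
    )


def region_rates(rate_map: DeclineRateMap, atlas: np.ndarray) -> pd.DataFrame:
    """Subject x region table of mean rates over each atlas region's in-mask voxels."""
    if atlas.shape != rate_map.mask.data.shape:
        raise ValueError("atlas grid does not match rate-map grid")
    labels_in_mask = atlas[rate_map.mask.data]
    out = pd.DataFrame({"subject_id": rate_map.subject_ids})
    for lab in np.unique(labels_in_mask):
        if lab == 0:
            continue
        cols = labels_in_mask == lab
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN regions
            out[f"region_{lab}"] = np.nanmean(rate_map.rates[:, cols], axis=1)
    return out


def rate_group_diff(
    rate_map: DeclineRateMap,
    groups: np.ndarray | pd.Series,
    covariates: pd.DataFrame | None = None,
    q_level: float = 0.05,
    min_extent: int = 10,
    atlas: np.ndarray | None = None,
) -> tuple[StatMap, pd.DataFrame]:
    """Voxel-wise two-group contrast on decline rates, FDR-corrected, clustered."""
    rates = np.nan_to_num(rate_map.rates, nan=0.0)
    stat = with_fdr(
        group_tmap(rates, np.asarray(groups), covariates, rate_map.mask), q_level
    )
    clusters = extract_clusters(
        stat.significance_mask(q_level),
        stat.t_volume(),
        rate_map.mask.affine,
        min_extent=min_extent,
        atlas=atlas,
    )
    return stat, clusters


def rate_cognition_correlation(
    region_table: pd.DataFrame, cognitive_change: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r (two-sided p) of each region's rate with each domain's change.

    Both tables need a ``subject_id`` column; rows are matched on it and
    incomplete pairs dropped per cell.
    """
    merged = region_table.merge(cognitive_change, on="subject_id")
    regions = [c for c in region_table.columns if c != "subject_id"]
    domains = [c for c in cognitive_change.columns if c != "subject_id"]
    rows = []
    for reg in regions:
        for dom in domains:
            sub = merged[[reg, dom]].dropna()
            if len(sub) < 5:
                raise ValueError(
                    f"fewer than 5 complete pairs for {reg} x {dom}"
                )
            r, p = stats.pearsonr(sub[reg], sub[dom])
            rows.append({"region": reg, "domain": dom, "r": r, "p": p, "n": len(sub)})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# mediation


@dataclass
class MediationResult:
    """Product-of-coefficients mediation with percentile bootstrap CIs.

    Paths: a (group -> mediator), b (mediator -> outcome | group),
    c (total group effect), c' (direct effect).  The proportion mediated
    a*b/c is reported only when a*b and c agree in sign.
    """

    a: float
    b: float
    c_total: float
    c_direct: float
    indirect: float  # a * b
    proportion_mediated: float | None
    indirect_ci: tuple[float, float]
    proportion_ci: tuple[float, float] | None
    indirect_p: float
    n_boot: int
    seed: int
    n: int

    def summary(self) -> str:
        lines = [
            "Mediation (product of coefficients, percentile bootstrap)",
            f"  n = {self.n}, bootstrap draws = {self.n_boot}",
            f"  a  (exposure -> mediator)          = {self.a: .5f}",
            f"  b  (mediator -> outcome | exposure) = {self.b: .5f}",
            f"  c  (total effect)                  = {self.c_total: .5f}",
            f"  c' (direct effect)                 = {self.c_direct: .5f}",
            f"  a*b (indirect) = {self.indirect: .5f}  "
            f"95% CI [{self.indirect_ci[0]: .5f}, {self.indirect_ci[1]: .5f}]  "
            f"p = {self.indirect_p:.4f}",
        ]
        if self.proportion_mediated is not None:
            lines.append(
                f"  proportion mediated = {self.proportion_mediated: .3f}  "
                f"95% CI [{self.proportion_ci[0]: .3f}, {self.proportion_ci[1]: .3f}]"
            )
        else:
            lines.append("  proportion mediated: undefined (sign disagreement or tiny total effect)")
        return "\n".join(lines)


def _ols_beta(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.linalg.solve(X.T @ X, X.T @ y)


def mediate(
    group: np.ndarray,
    mediator: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | pd.DataFrame | None = None,
    n_boot: int = 5000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> MediationResult:
    """Covariate-adjusted mediation of a binary exposure through a mediator.

    Two OLS fits give the paths — mediator ~ group + covariates (a) and
    outcome ~ mediator + group + covariates (b, c'); c = a*b + c'.  The
    indirect effect and the proportion mediated get percentile bootstrap
    CIs over subject resamples.  The proportion is undefined when the
    indirect and total effects disagree in sign or the total effect is
    negligible.
    """
    g = np.asarray(group, dtype=float)
    m = np.asarray(mediator, dtype=float)
    y = np.asarray(outcome, dtype=float)
    n = len(g)
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.asarray(covariates, dtype=float).reshape(n, -1)
    ones = np.ones((n, 1))

    def paths(idx: np.ndarray) -> tuple[float, float, float]:
        Xa = np.column_stack([ones[idx], g[idx], C[idx]])
        a_hat = _ols_beta(Xa, m[idx])[1]
        Xb = np.column_stack([ones[idx], m[idx], g[idx], C[idx]])
        bb = _ols_beta(Xb, y[idx])
        return float(a_hat), float(bb[1]), float(bb[2])

    idx_all = np.arange(n)
    a_hat, b_hat, c_direct = paths(idx_all)
    indirect = a_hat * b_hat
    c_total = indirect + c_direct

    rng = np.random.default_rng(seed)
    boots_ind = np.empty(n_boot)
    boots_prop = np.full(n_boot, np.nan)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        ab, bb_, cd = paths(idx)
        boots_ind[i] = ab * bb_
        tot = ab * bb_ + cd
        if tot != 0:
            boots_prop[i] = ab * bb_ / tot
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(boots_ind, [alpha / 2, 1 - alpha / 2])
    # two-sided bootstrap p for the indirect effect (sign-crossing fraction)
    frac = min(np.mean(boots_ind < 0), np.mean(boots_ind > 0))
    p_ind = float(min(1.0, 2.0 * frac + 2.0 / n_boot))

    tol = 1e-12
    if abs(c_total) < tol or np.sign(indirect) != np.sign(c_total):
        prop, prop_ci = None, None
    else:
        prop = indirect / c_total
        finite = boots_prop[np.isfinite(boots_prop)]
        prop_ci = tuple(np.quantile(finite, [alpha / 2, 1 - alpha / 2]))
    return MediationResult(
        a=a_hat, b=b_hat, c_total=c_total, c_direct=c_direct,
        indirect=indirect, proportion_mediated=prop,
        indirect_ci=(float(lo), float(hi)), proportion_ci=prop_ci,
        indirect_p=p_ind, n_boot=n_boot, seed=seed, n=n,
    )


# --------------------------------------------------------------------------
# two-level growth model


@dataclass
class NullModelResult:
    """Intercept-only two-level model: variance partition of repeated scores."""

    icc: float
    var_between: float
    var_within: float
    converged: bool
    loglik: float

    def summary(self) -> str:
        return (
            "Null (intercept-only) two-level model\n"
            f"  between-subject variance = {self.var_between:.4f}\n"
            f"  within-subject variance  = {self.var_within:.4f}\n"
            f"  ICC = {self.icc:.3f}   (converged: {self.converged})"
        )


@dataclass
class GrowthModelResult:
    """Fixed and random effects of the two-level growth model.

    Fixed effects follow the conventional naming: b0x moderate the subject
    intercept (x = 0 intercept, 1 baseline age, 2 gender, 3 education,
    4 exposure group) and b1x moderate the time slope.
    """

    fixed_effects: pd.Series  # b00..b04, b10..b14
    standard_errors: pd.Series
    p_values: pd.Series
    var_intercept: float
    var_slope: float
    cov_intercept_slope: float
    var_residual: float
    converged: bool
    loglik: float
    n_subjects: int
    n_observations: int
    boundary: bool = False  # a random-effect variance collapsed to ~0

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2)
        lo = self.fixed_effects - z * self.standard_errors
        hi = self.fixed_effects + z * self.standard_errors
        return pd.DataFrame({"lower": lo, "upper": hi})

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Two-level growth model (random intercept and slope, ML)",
            f"  subjects = {self.n_subjects}, observations = {self.n_observations}, "
            f"logLik = {self.loglik:.2f}, converged = {self.converged}",
            f"  {'effect':<6} {'est':>9} {'se':>8} {'p':>8} {'95% CI':>20}",
        ]
        for k in self.fixed_effects.index:
            lines.append(
                f"  {k:<6} {self.fixed_effects[k]:9.4f} {self.standard_errors[k]:8.4f} "
                f"{self.p_values[k]:8.4f} [{ci.loc[k, 'lower']:8.4f}, {ci.loc[k, 'upper']:8.4f}]"
            )
        lines.append(
            f"  var(r0) = {self.var_intercept:.4f}, var(r1) = {self.var_slope:.5f}, "
            f"cov(r0,r1) = {self.cov_intercept_slope:.5f}, var(e) = {self.var_residual:.4f}"
        )
        if self.boundary:
            lines.append("  note: a random-effect variance is at the boundary (~0)")
        return "\n".join(lines)


_REQUIRED_LONG_COLS = ("subject_id", "time", "score")


def fit_null_model(long_scores: pd.DataFrame, score_col: str = "score") -> NullModelResult:
    """Intercept-only mixed model; ICC = between / (between + within) variance."""
    df = long_scores.rename(columns={score_col: "score"})
    for c in ("subject_id", "score"):
        if c not in df.columns:
            raise KeyError(f"long table needs column {c!r}")
    counts = df.groupby("subject_id").size()
    if (counts < 2).all():
        raise ValueError("no subject has repeated observations")
    model = sm.MixedLM.from_formula("score ~ 1", groups="subject_id", data=df)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=False)
    var_b = float(fit.cov_re.iloc[0, 0])
    var_w = float(fit.scale)
    return NullModelResult(
        icc=var_b / (var_b + var_w),
        var_between=var_b,
        var_within=var_w,
        converged=bool(fit.converged),
        loglik=float(fit.llf),
    )


def fit_growth_model(
    long_scores: pd.DataFrame,
    score_col: str = "score",
    center_covariates: bool = True,
) -> GrowthModelResult:
    """ML fit of the two-level growth model.

    Level 1: score = pi0 + pi1 * time + e.  Level 2: pi0 and pi1 are linear
    in baseline age, gender, education, and exposure group with random
    intercept r0 and slope r1 (correlated).  The long table needs columns
    ``subject_id, time, score, age_baseline, gender, education, group``
    (time in years since baseline; group coded 0/1 or two labels).
    Non-convergence and boundary variance estimates are flagged, never
    silent.
    """
    df = long_scores.rename(columns={score_col: "score"}).copy()
    needed = [*_REQUIRED_LONG_COLS, "age_baseline", "gender", "education", "group"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise KeyError(f"long table missing columns: {missing}")
    if df["group"].dtype == object:
        labels = sorted(df["group"].unique())
        if len(labels) != 2:
            raise ValueError(f"need a binary group, got {labels}")
        df["group"] = (df["group"] == labels[0]).astype(float)
    if center_covariates:
        for c in ("age_baseline", "education"):
            df[c] = df[c] - df[c].mean()

    formula = (
        "score ~ age_baseline + gender + education + group "
        "+ time + time:age_baseline + time:gender + time:education + time:group"
    )
    model = smf.mixedlm(formula, df, groups="subject_id", re_formula="~time")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(reml=False, method="lbfgs", maxiter=500)
            if not fit.converged:
                fit = model.fit(reml=False, method="powell", maxiter=1000)
        except np.linalg.LinAlgError:
            fit = model.fit(reml=False, method="powell", maxiter=1000)
    converged = bool(fit.converged)
    if not converged:
        warnings.warn("growth model did not converge; estimates are unreliable")

    name_map = {
        "Intercept": "b00", "age_baseline": "b01", "gender": "b02",
        "education": "b03", "group": "b04",
        "time": "b10", "time:age_baseline": "b11", "time:gender": "b12",
        "time:education": "b13", "time:group": "b14",
    }
    fe = fit.fe_params.rename(name_map)
    se = fit.bse_fe.rename(name_map)
    pv = fit.pvalues[fit.fe_params.index].rename(name_map)
    order = ["b00", "b01", "b02", "b03", "b04", "b10", "b11", "b12", "b13", "b14"]
    cov_re = fit.cov_re
    var_i = float(cov_re.iloc[0, 0])
    var_s = float(cov_re.iloc[1, 1])
    cov_is = float(cov_re.iloc[0, 1])
    # a random-effect variance is "at the boundary" when it is negligible
    # next to the residual variance — ML pushes it to ~0 rather than exactly 0
    floor = max(1e-10, 1e-2 * float(fit.scale))
    boundary = var_s < floor or var_i < floor
    return GrowthModelResult(
        fixed_effects=fe[order],
        standard_errors=se[order],
        p_values=pv[order],
        var_intercept=var_i,
        var_slope=var_s,
        cov_intercept_slope=cov_is,
        var_residual=float(fit.scale),
        converged=converged,
        loglik=float(fit.llf),
        n_subjects=df["subject_id"].nunique(),
        n_observations=len(df),
        boundary=boundary,
    )


def cognitive_change(
    baseline: pd.DataFrame, followup: pd.DataFrame, interval_years: pd.Series
) -> pd.DataFrame:
    """(follow-up composite - baseline composite) / interval, per domain.

    All three inputs are aligned on ``subject_id`` (interval indexed by it).
    """
    domains = [c for c in baseline.columns if c != "subject_id"]
    b = baseline.set_index("subject_id")
    f = followup.set_index("subject_id")
    common = b.index.intersection(f.index).intersection(interval_years.index)
    dt = interval_years.loc[common]
    out = pd.DataFrame({"subject_id": common})
    for d in domains:
        out[d] = ((f.loc[common, d] - b.loc[common, d]) / dt).to_numpy()
    return out
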