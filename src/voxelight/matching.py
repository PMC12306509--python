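"""Propensity-score matching of the two exposure groups.

The propensity model is a logistic regression of exposure on demographics
and comorbidity flags.  Pairs are formed by greedy nearest-neighbor 1:1
matching without replacement on the logit of the score, inside a caliper
expressed in standard deviations of the logit (0.2 by default, the most
common published recipe).  Balance is reported as standardized mean
differences before and after matching.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)


class SeparationError(RuntimeError):
    """The covariates separate the groups perfectly; the MLE diverges."""


@dataclass
class PropensityResult:
    """Fitted scores, matched pairs, and balance diagnostics."""

    coefficients: pd.Series
    scores: pd.Series  # indexed by subject_id, in (0, 1)
    covariates: list[str]
    group_col: str = "group"
    exposed_label: str = "DD"
    pairs: list[tuple[str, str]] = field(default_factory=list)  # (exposed, control)
    smd_before: pd.Series | None = None
    smd_after: pd.Series | None = None
    penalized: bool = False

    @property
    def matched_ids(self) -> list[str]:
        return [s for pair in self.pairs for s in pair]


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return np.log(p / (1 - p))


def fit_propensity(
    phenotypes: pd.DataFrame,
    covariates: list[str],
    group_col: str = "group",
    exposed_label: str = "DD",
    allow_penalized_fallback: bool = True,
) -> PropensityResult:
    """Logistic model of exposure given covariates; scores in (0, 1).

    Perfect separation is flagged; with ``allow_penalized_fallback`` the fit
    falls back to an L2-penalized logistic model instead of raising.
    """
    missing = [c for c in covariates if c not in phenotypes.columns]
    if missing:
        raise KeyError(f"covariates not in phenotype table: {missing}")
    X = phenotypes[covariates].to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        const = [c for c in covariates if phenotypes[c].std() == 0]
        raise ValueError(f"constant covariates cannot be used: {const}")
    y = (phenotypes[group_col] == exposed_label).to_numpy(dtype=float)
    if y.min() == y.max():
        raise ValueError("phenotype table does not contain both groups")
    design = sm.add_constant(X)

    penalized = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = sm.Logit(y, design).fit(disp=0)
            params = fit.params
            probs = fit.predict(design)
            if not np.isfinite(params).all():
                raise SeparationError("non-finite propensity coefficients")
        except (
            PerfectSeparationWarning,
            PerfectSeparationError,
            SeparationError,
            np.linalg.LinAlgError,
        ) as err:
            if not allow_penalized_fallback:
                raise SeparationError(
                    f"perfect separation in propensity model: {err}"
                ) from err
            warnings.warn(
                "perfect separation detected; falling back to an L2-penalized fit"
            )
            penalized = True
            from sklearn.linear_model import LogisticRegression

            lr = LogisticRegression(C=1.0, max_iter=1000)  # L2 by default
            lr.fit(X, y)
            params = np.r_[lr.intercept_, lr.coef_.ravel()]
            probs = lr.predict_proba(X)[:, 1]

    names = ["intercept", *covariates]
    return PropensityResult(
        coefficients=pd.Series(params, index=names),
        scores=pd.Series(probs, index=phenotypes["subject_id"].to_numpy()),
        covariates=list(covariates),
        group_col=group_col,
        exposed_label=exposed_label,
        penalized=penalized,
    )


def match_pairs(
    result: PropensityResult,
    phenotypes: pd.DataFrame,
    caliper_sd: float = 0.2,
    seed: int = 0,
) -> PropensityResult:
    """Greedy nearest-neighbor 1:1 matching without replacement.

    Distance is |logit score difference|; a pair is admissible when the
    distance is within ``caliper_sd`` standard deviations of the pooled
    logit scores.  Exposed subjects are visited in a seed-shuffled order
    (ties inside the shuffle broken by subject id), each taking the nearest
    still-available control.
    """
    exposed_mask = phenotypes[result.group_col] == result.exposed_label
    exp_ids = phenotypes.loc[exposed_mask, "subject_id"].to_numpy()
    ctl_ids = phenotypes.loc[~exposed_mask, "subject_id"].to_numpy()
    logit = _logit(result.scores.to_numpy(dtype=float))
    logit_s = pd.Series(logit, index=result.scores.index)
    caliper = caliper_sd * float(np.std(logit, ddof=1))

    order = np.argsort(exp_ids, kind="stable")  # id order, then shuffled
    rng = np.random.default_rng(seed)
    order = order[rng.permutation(len(order))]

    ctl_logit = logit_s.loc[ctl_ids].to_numpy()
    available = np.ones(len(ctl_ids), dtype=bool)
    pairs: list[tuple[str, str]] = []
    for i in order:
        eid = exp_ids[i]
        d = np.abs(ctl_logit - logit_s.loc[eid])
        d[~available] = np.inf
        j = int(d.argmin())
        if np.isfinite(d[j]) and d[j] <= caliper:
            pairs.append((eid, ctl_ids[j]))
            available[j] = False
    if not pairs:
        raise ValueError(
            "no admissible pairs: caliper "
            f"{caliper:.4g} on logit scores spanning "
            f"[{logit.min():.3g}, {logit.max():.3g}]"
        )
    out = PropensityResult(
        coefficients=result.coefficients,
        scores=result.scores,
        covariates=result.covariates,
        group_col=result.group_col,
        exposed_label=result.exposed_label,
        pairs=sorted(pairs),
        penalized=result.penalized,
    )
    out.smd_before, out.smd_after = balance_table(phenotypes, out)
    return out


def standardized_mean_difference(x: np.ndarray, y: np.ndarray) -> float:
    """(mean_x - mean_y) / pooled sd; 0 with a warning if the pooled sd is 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.sqrt((x.var(ddof=1) + y.var(ddof=1)) / 2.0)
    if pooled == 0:
        warnings.warn("zero pooled sd; reporting SMD = 0")
        return 0.0
    return float((x.mean() - y.mean()) / pooled)


def balance_table(
    phenotypes: pd.DataFrame, result: PropensityResult
) -> tuple[pd.Series, pd.Series]:
    """Per-covariate SMD on the full sample and on the matched sample."""
    if not result.pairs:
        raise ValueError("no pairs: run match_pairs first")
    pheno = phenotypes.set_index("subject_id")
    exposed = phenotypes[result.group_col] == result.exposed_label
    exp_all = phenotypes.loc[exposed]
    ctl_all = phenotypes.loc[~exposed]
    exp_m = pheno.loc[[p[0] for p in result.pairs]]
    ctl_m = pheno.loc[[p[1] for p in result.pairs]]
    before, after = {}, {}
    for c in result.covariates:
        before[c] = standardized_mean_difference(exp_all[c], ctl_all[c])
        after[c] = standardized_mean_difference(exp_m[c], ctl_m[c])
    return pd.Series(before), pd.Series(after)
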