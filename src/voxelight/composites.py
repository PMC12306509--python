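"""Exposure-group assignment and cognitive domain composite scores.

Group membership comes from a single technology-use frequency item (0-5):
never/yearly/monthly users form the low-use (DD) group, weekly/daily users
the regular-use (ODD) group, and the in-between score of 3 is assigned to
neither.  Each cognitive domain's composite is a weighted sum of its
standardized test scores, the weights being single-factor loadings estimated
per domain (a domain with one test uses that test's z-score directly).
Timing-based tests are sign-flipped before standardization so that a higher
score always means better performance.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.decomposition import FactorAnalysis

DD = "DD"
ODD = "ODD"
EXCLUDED = "excluded"


def assign_group(ict_frequency: int) -> str:
    """Map the 0-5 use-frequency item to DD / ODD / excluded.

    0 (never), 1 (at least yearly), 2 (at least monthly) -> DD;
    4 (at least weekly), 5 (every day) -> ODD; 3 -> excluded.
    """
    score = int(ict_frequency)
    if score != ict_frequency or not (0 <= score <= 5):
        raise ValueError(f"use-frequency item must be an integer in 0..5, got {ict_frequency!r}")
    if score in (0, 1, 2):
        return DD
    if score in (4, 5):
        return ODD
    return EXCLUDED


def _standardize(tests: pd.DataFrame, invert: set[str] | frozenset[str]) -> pd.DataFrame:
    z = pd.DataFrame(index=tests.index)
    for col in tests.columns:
        x = tests[col].astype(float)
        sd = x.std(ddof=1)
        if sd == 0:
            raise ValueError(f"test {col!r} is constant; cannot standardize")
        zc = (x - x.mean()) / sd
        z[col] = -zc if col in invert else zc
    return z


def estimate_loadings(
    tests: pd.DataFrame,
    domain_map: dict[str, str],
    invert: set[str] | frozenset[str] = frozenset(),
    method: str = "ml",
) -> dict[str, pd.Series]:
    """Per-domain single-factor loadings of the standardized tests.

    ``method='ml'`` fits a one-factor maximum-likelihood factor model per
    domain; ``method='pca'`` uses first-principal-component loadings.  Each
    loading vector is sign-fixed so that its majority is positive.  A domain
    with a single test gets weight 1.  Externally estimated weights can be
    passed straight to :func:`composite_scores` instead.
    """
    domains = sorted(set(domain_map.values()))
    z = _standardize(tests[list(domain_map)], invert)
    n = len(z)
    loadings: dict[str, pd.Series] = {}
    for domain in domains:
        cols = [t for t, d in domain_map.items() if d == domain]
        if len(cols) == 1:
            loadings[domain] = pd.Series([1.0], index=cols)
            continue
        if n <= len(cols):
            raise ValueError(
                f"domain {domain!r}: need more subjects ({n}) than tests ({len(cols)})"
            )
        block = z[cols].to_numpy()
        cov = np.cov(block, rowvar=False)
        if not np.isfinite(cov).all():
            raise ValueError(f"domain {domain!r}: singular test covariance")
        if method == "ml":
            fa = FactorAnalysis(n_components=1, random_state=0)
            fa.fit(block)
            lam = fa.components_.ravel()
        elif method == "pca":
            eigvals, eigvecs = np.linalg.eigh(cov)
            lam = eigvecs[:, -1] * np.sqrt(eigvals[-1])
        else:
            raise ValueError(f"unknown method {method!r}")
        if (lam > 0).sum() < (lam < 0).sum() or (np.sign(lam).sum() == 0 and lam.sum() < 0):
            lam = -lam
        loadings[domain] = pd.Series(lam, index=cols)
    return loadings


def composite_scores(
    tests: pd.DataFrame,
    weights: dict[str, pd.Series],
    invert: set[str] | frozenset[str] = frozenset(),
    subject_ids: pd.Series | None = None,
) -> pd.DataFrame:
    """Weighted sums of standardized tests, z-scaled across subjects.

    A subject missing any test of a domain gets a missing composite for that
    domain (propagated downstream as exclusion).
    """
    all_tests = [t for s in weights.values() for t in s.index]
    z = _standardize(tests[all_tests].dropna(how="all"), invert)
    # reattach rows that were all-missing
    z = z.reindex(tests.index)
    out = pd.DataFrame(index=tests.index)
    for domain, w in weights.items():
        raw = z[list(w.index)].to_numpy() @ w.to_numpy()
        comp = pd.Series(raw, index=tests.index)
        comp[z[list(w.index)].isna().any(axis=1)] = np.nan
        sd = comp.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            raise ValueError(f"domain {domain!r}: degenerate composite")
        out[domain] = (comp - comp.mean()) / sd
    if subject_ids is not None:
        out.insert(0, "subject_id", subject_ids.to_numpy())
    return out


def composites_from_tests(
    cognition: pd.DataFrame,
    domain_map: dict[str, str],
    invert: set[str] | frozenset[str] = frozenset(),
    method: str = "ml",
) -> tuple[pd.DataFrame, dict[str, pd.Series]]:
    """Estimate loadings and build composites in one step.

    ``cognition`` must carry a ``subject_id`` column plus one column per
    test in ``domain_map``.
    """
    tests = cognition[list(domain_map)]
    weights = estimate_loadings(tests, domain_map, invert, method=method)
    comps = composite_scores(tests, weights, invert, subject_ids=cognition["subject_id"])
    return comps, weights
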