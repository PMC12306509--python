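"""Recovery and calibration studies on synthetic cohorts.

Each function runs one self-contained study — planted-region recovery
through the full searchlight stage, null calibration of the accuracy map,
uniformity of the representation permutation p-values, agreement with
long-hand oracles, decline-rate round-trips, and coverage of the growth and
mediation estimators — and returns the measured quantities as a flat
``{name: {"value": ..., "n": ...}}`` dict.  The study sizes are fixed here
(they are the conditions the quantities are quoted for); only the seed
varies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import BrainMask
from .longitudinal import annual_decline_rate, fit_growth_model, mediate
from .representation import _pearson, permutation_null
from .searchlight import SearchlightSpec, accuracy_map, constrain_regions
from .synthetic import (
    EffectRegion,
    SynthConfig,
    generate_cohort,
    generate_followup,
    simulate_growth,
    simulate_mediation,
)
from .voxelwise import build_mask, fdr_correct, group_tmap, with_fdr

COVARIATES = ["age", "gender", "education", "tiv"]


def variance_explained_study(r: float = 0.17) -> dict:
    """Percent of variance implied by a correlation coefficient (R^2)."""
    return {
        "mfg_memory_variance_explained_pct": {"value": 100.0 * r**2, "n": 1}
    }


def planted_recovery_study(seed: int) -> dict:
    """Full searchlight stage on one cohort with a planted |d| = 1.2 sphere
    (24^3 grid, 1.5 mm voxels, 80 per group): how much of the planted
    region lands in the constrained set, and how much of the null brain.
    """
    cfg = SynthConfig(
        n_per_group=80,
        effect_regions=[EffectRegion("temporal", (9, 9, 12), 6.0, -1.2)],
        cognitive_weights={"executive_function": {"temporal": 0.5}},
        seed=seed,
    )
    phen, vols, _, truth = generate_cohort(cfg)
    mask = build_mask(vols)
    stat = with_fdr(
        group_tmap(vols, phen["group"].to_numpy(), phen[COVARIATES], mask), 0.05
    )
    spec = SearchlightSpec(seed=seed)
    amap = accuracy_map(vols, mask, phen["group"].to_numpy(), spec)
    part = constrain_regions(amap, stat.significance_mask(0.05))
    planted = truth.planted_masks["temporal"] & mask.data
    null = mask.data & ~planted
    n_mask = int(mask.n_voxels)
    return {
        "planted_voxels_constrained_pct": {
            "value": 100.0 * part.constrained[planted].mean(),
            "n": int(planted.sum()),
        },
        "null_voxels_constrained_pct": {
            "value": 100.0 * part.constrained[null].mean(),
            "n": int(null.sum()),
        },
        "searchlight_voxels_scored": {"value": n_mask, "n": n_mask},
    }


def null_calibration_study(seed: int, n_seeds: int = 10) -> dict:
    """Accuracy maps on no-effect cohorts (40 per group, ``n_seeds``
    replicates): the mean accuracy and the fraction of voxels above the
    0.6 constraining threshold."""
    accs = []
    for k in range(n_seeds):
        cfg = SynthConfig(
            n_per_group=40,
            effect_regions=[EffectRegion("temporal", (9, 9, 12), 6.0, 0.0)],
            cognitive_weights={},
            seed=int(np.random.default_rng([seed, k]).integers(2**31)),
        )
        phen, vols, _, _ = generate_cohort(cfg)
        mask = build_mask(vols)
        amap = accuracy_map(
            vols, mask, phen["group"].to_numpy(), SearchlightSpec(seed=seed + k)
        )
        accs.append(amap.accuracy)
    accs = np.concatenate(accs)
    return {
        "null_mean_searchlight_accuracy": {"value": float(accs.mean()), "n": len(accs)},
        "null_high_accuracy_voxel_pct": {
            "value": 100.0 * float((accs > 0.6).mean()),
            "n": len(accs),
        },
    }


def permutation_uniformity_study(seed: int, n_voxels: int = 200,
                                 n_perm: int = 500) -> dict:
    """Representation p-values under a shuffled-cognition null at
    ``n_voxels`` voxels: Kolmogorov-Smirnov comparison against U(0,1).

    Each voxel is tested against its own independent shuffle of the
    cognition vector.  A single shared score vector would leave the
    p-values mutually dependent through the spatially correlated features,
    and the KS test requires independent samples.
    """
    from .representation import _prediction_operator, permutation_pvalue_refit
    from .searchlight import neighborhood_index, searchlight_features

    cfg = SynthConfig(n_per_group=30, effect_regions=[], cognitive_weights={},
                      seed=seed)
    phen, vols, _, _ = generate_cohort(cfg)
    mask = build_mask(vols)
    Y = vols.masked_matrix(mask)
    neighbors = neighborhood_index(mask, 2.0)
    rng = np.random.default_rng([seed, 17])
    pick = rng.choice(mask.n_voxels, size=n_voxels, replace=False)
    base_scores = rng.normal(size=vols.n_subjects)
    pvals = []
    for pos in pick:
        feats, degenerate = searchlight_features(Y[:, neighbors[pos]], 0.8)
        if degenerate:
            continue
        scores = base_scores[rng.permutation(vols.n_subjects)]
        H = _prediction_operator(feats, 10, seed)
        _, p = permutation_pvalue_refit(H, scores, n_perm, rng)
        pvals.append(p)
    ks = stats.kstest(pvals, "uniform")
    return {
        "null_permutation_pvalue_ks_pvalue": {"value": float(ks.pvalue), "n": len(pvals)},
    }


def oracle_agreement_study(seed: int) -> dict:
    """Largest disagreements between the package's statistics and
    independent long-hand oracles."""
    rng = np.random.default_rng([seed, 23])

    # covariate-adjusted voxel-wise t vs per-voxel OLS
    n, n_vox = 40, 100
    Y = rng.normal(size=(n, n_vox))
    groups = np.array(["DD"] * 20 + ["ODD"] * 20)
    cov = pd.DataFrame({"age": rng.normal(70, 5, n), "tiv": rng.normal(1450, 100, n)})
    stat = group_tmap(Y, groups, cov)
    X = np.column_stack(
        [(groups == "DD").astype(float), np.ones(n), cov["age"], cov["tiv"]]
    )
    xtx_inv_00 = np.linalg.inv(X.T @ X)[0, 0]
    t_err = 0.0
    for v in range(n_vox):
        beta, *_ = np.linalg.lstsq(X, Y[:, v], rcond=None)
        resid = Y[:, v] - X @ beta
        se = np.sqrt(resid @ resid / (n - 4) * xtx_inv_00)
        t_err = max(t_err, abs(stat.t[v] - beta[0] / se))

    # BH q-values vs sort-and-step-up oracle on 1000 random vectors
    q_err = 0.0
    for _ in range(1000):
        p = rng.uniform(size=int(rng.integers(1, 40)))
        q, _ = fdr_correct(p, 0.05)
        m = len(p)
        order = np.argsort(p)
        running = 1.0
        q_oracle = np.empty(m)
        for rank in range(m, 0, -1):
            running = min(running, p[order[rank - 1]] * m / rank)
            q_oracle[order[rank - 1]] = running
        q_err = max(q_err, float(np.abs(q - q_oracle).max()))

    # exhaustive permutation p at n=4 vs direct enumeration
    import itertools

    pred = np.array([0.3, -1.2, 0.7, 2.1])
    obs = np.array([0.1, -0.9, 1.4, 1.0])
    r_obs = _pearson(pred, obs)
    perms = [_pearson(pred[list(pm)], obs) for pm in itertools.permutations(range(4))]
    p_enum = (1 + sum(abs(r) >= abs(r_obs) - 1e-12 for r in perms)) / (len(perms) + 1)

    class _AllPerms:
        def __init__(self):
            self._it = iter(itertools.permutations(range(4)))

        def permutation(self, n):
            return np.array(next(self._it))

    _, p_impl = permutation_null(pred, obs, n_perm=24, rng=_AllPerms())
    perm_err = abs(p_impl - p_enum)

    return {
        "tmap_vs_ols_oracle_max_abs_diff": {"value": float(t_err), "n": n_vox},
        "bh_vs_stepup_oracle_max_abs_diff": {"value": float(q_err), "n": 1000},
        "exhaustive_permutation_p_abs_diff": {"value": float(perm_err), "n": 24},
    }


def rate_exactness_study(seed: int) -> dict:
    """Round-trip of the planted decline rates with jitter and follow-up
    noise off: largest voxel-wise absolute error."""
    cfg = SynthConfig(
        n_per_group=10, effect_regions=[], cognitive_weights={},
        interval_jitter_sd=0.0, followup_noise_sd=0.0, seed=seed,
    )
    phen, vols, _, truth = generate_cohort(cfg)
    follow, phen2, _, _ = generate_followup(vols, phen, truth, cfg)
    mask = build_mask(vols)
    rm = annual_decline_rate(vols, follow, phen2["interval_years"], mask)
    region = truth.decline_masks["frontal"][mask.data]
    exposed = (phen2["group"] == "DD").to_numpy()
    expected = np.full(rm.rates.shape, cfg.decline_rate_base)
    expected[np.ix_(exposed, region)] += cfg.decline_rate_delta
    err = float(np.abs(rm.rates - expected).max())
    return {
        "decline_rate_roundtrip_max_abs_error": {"value": err, "n": rm.rates.size}
    }


def growth_coverage_study(seed: int, n_replicates: int = 200) -> dict:
    """Wald 95% CI coverage of the exposure-by-time fixed effect across
    replicated two-level simulations (200 subjects x 3 visits)."""
    rng = np.random.default_rng([seed, 31])
    covered = 0
    for _ in range(n_replicates):
        rep_seed = int(rng.integers(2**31))
        long_df, truth = simulate_growth(n_subjects=200, n_visits=3, seed=rep_seed)
        res = fit_growth_model(long_df)
        ci = res.conf_int(0.95).loc["b14"]
        if ci["lower"] <= truth["b14"] <= ci["upper"]:
            covered += 1
    return {
        "growth_b14_ci_coverage_pct": {
            "value": 100.0 * covered / n_replicates,
            "n": n_replicates,
        }
    }


def mediation_coverage_study(seed: int, n_seeds: int = 20) -> dict:
    """Bootstrap CI coverage of the true proportion mediated at n=500."""
    rng = np.random.default_rng([seed, 37])
    covered = 0
    usable = 0
    for _ in range(n_seeds):
        rep_seed = int(rng.integers(2**31))
        df, truth = simulate_mediation(n=500, seed=rep_seed)
        res = mediate(
            df["group"], df["rate"], df["change"], df[["age"]],
            n_boot=5000, seed=rep_seed,
        )
        if res.proportion_ci is None:
            continue
        usable += 1
        if res.proportion_ci[0] <= truth["proportion_mediated"] <= res.proportion_ci[1]:
            covered += 1
    return {
        "mediation_proportion_ci_coverage_pct": {
            "value": 100.0 * covered / max(usable, 1),
            "n": usable,
        }
    }
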