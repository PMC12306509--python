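"""Synthetic volumetric cohorts with known ground truth.

Generates everything the analysis stages consume — per-subject gray-matter
volumes on a small grid, a phenotype table, raw cognitive test scores, and a
follow-up timepoint — while recording exactly what was planted (effect
regions, cognitive wiring, decline rates) so each downstream stage has a
recovery test against truth.

The anatomy is deliberately schematic: a smooth spherical "brain" whose
gray-matter values fall off toward the edge, plus spatially smoothed Gaussian
noise per subject.  Group differences are planted as mean shifts of
``d x pooled_sd`` inside spherical effect regions; cognitive domain scores
are noisy linear functions of regional mean gray matter; atrophy between
timepoints is multiplicative at a per-year rate that differs by group inside
a planted decline region.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .containers import BrainMask, CohortVolumes, default_affine

# FWHM-to-sigma factor for a Gaussian kernel
_FWHM_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

#: test -> cognitive domain for the generated battery (two tests per domain,
#: one for language, mirroring a battery where verbal fluency stands alone)
TEST_DOMAINS: dict[str, str] = {
    "list_recall": "memory",
    "figure_recall": "memory",
    "clock_drawing": "visual_spatial",
    "figure_copy": "visual_spatial",
    "symbol_digit": "processing_speed",
    "trails_a_time": "processing_speed",
    "stroop_time": "executive_function",
    "trails_b_time": "executive_function",
    "digit_span": "working_memory",
    "nback_correct": "working_memory",
    "verbal_fluency": "language",
}

#: timing-based tests where a larger raw score means worse performance
TIMING_TESTS: frozenset[str] = frozenset({"trails_a_time", "stroop_time", "trails_b_time"})

DOMAINS: tuple[str, ...] = (
    "memory",
    "visual_spatial",
    "processing_speed",
    "executive_function",
    "working_memory",
    "language",
)


@dataclass(frozen=True)
class EffectRegion:
    """Spherical region with a planted standardized group difference."""

    name: str
    center: tuple[int, int, int]  # voxel indices
    radius_mm: float
    d: float  # Cohen d of exposed minus control inside the region


@dataclass
class SynthConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a matched aging cohort at desk scale: a 24^3 grid of
    1.5 mm voxels, 8 mm FWHM smoothing, an exposed group 3 years older
    before matching, one planted temporal effect region, executive function
    and processing speed wired to it, and a frontal region where the exposed
    group loses extra gray matter per year.
    """

    grid_dims: tuple[int, int, int] = (24, 24, 24)
    voxel_size_mm: float = 1.5
    n_per_group: int = 80
    effect_regions: list[EffectRegion] = field(
        default_factory=lambda: [EffectRegion("temporal", (9, 9, 12), 6.0, -0.35)]
    )
    cognitive_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "executive_function": {"temporal": 0.5},
            "processing_speed": {"temporal": 0.45},
        }
    )
    noise_sd: float = 1.0  # sd of the latent cognitive noise (z scale)
    gm_noise_sd: float = 0.5  # pre-smoothing voxel noise sd
    smoothing_fwhm_mm: float = 8.0
    brain_radius_mm: float = 15.0
    decline_rate_base: float = -0.005  # fraction of baseline per year
    decline_rate_delta: float = -0.010  # extra exposed-group decline in the region
    decline_region: EffectRegion = field(
        default_factory=lambda: EffectRegion("frontal", (15, 14, 11), 6.0, 0.0)
    )
    followup_interval_years: float = 3.2
    interval_jitter_sd: float = 0.3
    followup_noise_sd: float = 0.2  # pre-smoothing scan noise at timepoint 2
    #: per-domain drivers of cognitive change per year: a base slope, an
    #: extra slope in the exposed group, and a weight on the standardized
    #: decline-region rate (the mediation pathway)
    change_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "memory": {"base": -0.03, "group": -0.02, "rate": 0.15},
            "executive_function": {"base": -0.04, "group": -0.02, "rate": 0.0},
            "processing_speed": {"base": -0.04, "group": -0.02, "rate": 0.0},
            "visual_spatial": {"base": -0.02, "group": 0.0, "rate": 0.0},
            "working_memory": {"base": -0.02, "group": 0.0, "rate": 0.0},
            "language": {"base": -0.02, "group": 0.0, "rate": 0.0},
        }
    )
    change_noise_sd: float = 0.1  # per-year latent change noise
    age_shift_years: float = 3.0  # pre-matching exposed-group age excess
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.n_per_group < 4:
            raise ValueError("n_per_group must be at least 4")
        for reg in [*self.effect_regions, self.decline_region]:
            if reg.radius_mm <= 0:
                raise ValueError(f"region {reg.name!r}: radius must be positive")
            r_vox = reg.radius_mm / self.voxel_size_mm
            for c, dim in zip(reg.center, self.grid_dims):
                if c - r_vox < -0.5 or c + r_vox > dim - 0.5:
                    raise ValueError(
                        f"effect region {reg.name!r} extends outside the grid "
                        f"(center {reg.center}, radius {reg.radius_mm} mm)"
                    )


@dataclass
class SyntheticTruth:
    """Everything that was planted, for recovery tests."""

    planted_masks: dict[str, np.ndarray]  # region name -> bool volume
    effect_sizes: dict[str, float]
    cognitive_weights: dict[str, dict[str, float]]
    decline_masks: dict[str, np.ndarray]
    decline_rates: dict[str, dict[str, float]]  # group -> {region/background: rate/yr}
    brain_mask: np.ndarray  # bool volume of the generated anatomy
    region_sds: dict[str, float]  # pooled voxel sd used for each planted shift
    latent_scores: pd.DataFrame | None = None  # per-subject latent domain scores


def _sphere_mask(grid_dims, center, radius_mm, voxel_size_mm) -> np.ndarray:
    grids = np.indices(grid_dims, dtype=float)
    dist2 = sum((g - c) ** 2 for g, c in zip(grids, center)) * voxel_size_mm**2
    return dist2 <= radius_mm**2


def _base_pattern(config: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Smooth spherical anatomy: gray matter high centrally, 0 outside."""
    dims = np.asarray(config.grid_dims, dtype=float)
    center = (dims - 1) / 2.0
    grids = np.indices(config.grid_dims, dtype=float)
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center))) * config.voxel_size_mm
    rel = r / config.brain_radius_mm
    inside = rel <= 1.0
    base = np.where(inside, 0.25 + 0.45 * (1.0 - rel**2), 0.0)
    return base, inside


def generate_cohort(
    config: SynthConfig,
) -> tuple[pd.DataFrame, CohortVolumes, pd.DataFrame, SyntheticTruth]:
    """Generate baseline volumes, phenotypes, and cognitive test scores.

    Returns ``(phenotypes, volumes, cognition, truth)``.  The exposed group
    is labelled ``DD`` (low technology use), the control group ``ODD``;
    planted effect sizes are exposed minus control.
    """
    rng = np.random.default_rng([config.seed, 0])
    n = 2 * config.n_per_group
    base, brain = _base_pattern(config)
    sigma_vox = config.smoothing_fwhm_mm / _FWHM_SIGMA / config.voxel_size_mm

    noise = rng.normal(0.0, config.gm_noise_sd, size=(n, *config.grid_dims))
    for i in range(n):
        noise[i] = gaussian_filter(noise[i], sigma_vox)
    vols = base[None, :, :, :] + noise
    vols[:, ~brain] = 0.0
    np.clip(vols, 0.0, None, out=vols)

    group = np.array(["DD"] * config.n_per_group + ["ODD"] * config.n_per_group)
    exposed = group == "DD"

    # plant group mean shifts of d x pooled voxel sd inside each region
    planted_masks: dict[str, np.ndarray] = {}
    region_sds: dict[str, float] = {}
    for reg in config.effect_regions:
        m = _sphere_mask(config.grid_dims, reg.center, reg.radius_mm, config.voxel_size_mm)
        m &= brain
        planted_masks[reg.name] = m
        sd = float(vols[:, m].std(axis=0, ddof=1).mean())
        region_sds[reg.name] = sd
        shifted = vols[exposed]
        shifted[:, m] += reg.d * sd
        vols[exposed] = shifted
    np.clip(vols, 0.0, None, out=vols)

    subject_ids = [f"S{i:04d}" for i in range(n)]
    affine = default_affine(config.voxel_size_mm)
    cohort = CohortVolumes(vols, affine, subject_ids)

    # phenotypes: exposed group older pre-matching so the matcher has work
    age = rng.normal(71.0, 5.0, size=n) + np.where(exposed, config.age_shift_years, 0.0)
    age = np.clip(age, 65.0, 90.0)
    gender = rng.integers(0, 2, size=n)
    education = np.clip(np.round(rng.normal(11.0, 3.0, size=n)), 6, 22)
    tiv = rng.normal(1450.0, 120.0, size=n)
    ict = np.where(exposed, rng.integers(0, 3, size=n), rng.integers(4, 6, size=n))
    phenotypes = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "group": group,
            "ict_frequency": ict,
            "age": age,
            "gender": gender,
            "education": education,
            "hypertension": rng.binomial(1, 0.40, size=n),
            "diabetes": rng.binomial(1, 0.20, size=n),
            "hyperlipidemia": rng.binomial(1, 0.30, size=n),
            "tiv": tiv,
        }
    )

    # cognitive domains: latent = weights . z(regional mean GMV) + noise
    region_means = {
        name: vols[:, m].mean(axis=1) for name, m in planted_masks.items()
    }
    latent_by_domain: dict[str, np.ndarray] = {}
    for domain in DOMAINS:
        latent = rng.normal(0.0, config.noise_sd, size=n)
        for region, w in config.cognitive_weights.get(domain, {}).items():
            rm = region_means[region]
            latent = latent + w * (rm - rm.mean()) / rm.std(ddof=1)
        latent_by_domain[domain] = latent
    cognition = _tests_from_latent(latent_by_domain, rng, subject_ids)

    decline_mask = (
        _sphere_mask(
            config.grid_dims,
            config.decline_region.center,
            config.decline_region.radius_mm,
            config.voxel_size_mm,
        )
        & brain
    )
    truth = SyntheticTruth(
        planted_masks=planted_masks,
        effect_sizes={r.name: r.d for r in config.effect_regions},
        cognitive_weights={d: dict(w) for d, w in config.cognitive_weights.items()},
        decline_masks={config.decline_region.name: decline_mask},
        decline_rates={
            "DD": {
                config.decline_region.name: config.decline_rate_base
                + config.decline_rate_delta,
                "background": config.decline_rate_base,
            },
            "ODD": {
                config.decline_region.name: config.decline_rate_base,
                "background": config.decline_rate_base,
            },
        },
        brain_mask=brain,
        region_sds=region_sds,
        latent_scores=pd.DataFrame({"subject_id": subject_ids, **latent_by_domain}),
    )
    return phenotypes, cohort, cognition, truth


def _tests_from_latent(
    latents: dict[str, np.ndarray], rng: np.random.Generator, subject_ids: list[str]
) -> pd.DataFrame:
    """Raw test battery from latent domain scores (loading 0.8 per test)."""
    n = len(subject_ids)
    cognition = pd.DataFrame({"subject_id": subject_ids})
    for test, domain in TEST_DOMAINS.items():
        loading = 0.8
        z = loading * latents[domain] + rng.normal(0.0, np.sqrt(1 - loading**2), size=n)
        if test in TIMING_TESTS:
            raw = 60.0 - 15.0 * z  # seconds: slower = worse
        else:
            raw = 50.0 + 10.0 * z
        cognition[test] = raw
    return cognition


def generate_followup(
    cohort: CohortVolumes,
    phenotypes: pd.DataFrame,
    truth: SyntheticTruth,
    config: SynthConfig,
) -> tuple[CohortVolumes, pd.DataFrame, pd.DataFrame, dict]:
    """Planted multiplicative decline plus scan noise: timepoint 2.

    ``V_t2 = V_t1 * (1 + rate * dt) + scan noise`` voxel-wise, where the
    rate is the base rate everywhere plus the group-specific delta inside
    the planted decline region, and the scan noise is smoothed Gaussian
    noise of sd ``followup_noise_sd`` (0 disables it, making the planted
    rates recoverable to machine precision).  Follow-up cognitive tests are
    regenerated from latent scores advanced by ``change_weights``: a base
    slope per year, an exposed-group extra slope, and a weight on the
    subject's standardized decline-region rate (the mediation pathway).

    Returns ``(followup volumes, phenotypes with interval_years, followup
    cognition, report)``; the report counts voxels clipped at zero.
    """
    rng = np.random.default_rng([config.seed, 1])
    n = cohort.n_subjects
    dt = config.followup_interval_years + rng.normal(
        0.0, config.interval_jitter_sd, size=n
    )
    dt = np.clip(dt, 0.25, None)  # intervals must stay positive
    if config.interval_jitter_sd == 0:
        dt[:] = config.followup_interval_years

    decline_name = config.decline_region.name
    region = truth.decline_masks[decline_name]
    exposed = (phenotypes["group"] == "DD").to_numpy()

    rate = np.full((n, *cohort.grid_dims), config.decline_rate_base)
    rate_exp = rate[exposed]
    rate_exp[:, region] += config.decline_rate_delta
    rate[exposed] = rate_exp
    v2 = cohort.data * (1.0 + rate * dt[:, None, None, None])
    if config.followup_noise_sd > 0:
        sigma_vox = config.smoothing_fwhm_mm / _FWHM_SIGMA / config.voxel_size_mm
        noise = rng.normal(0.0, config.followup_noise_sd, size=v2.shape)
        for i in range(n):
            v2[i] += gaussian_filter(noise[i], sigma_vox)
        v2[:, ~truth.brain_mask] = 0.0
    n_clipped = int((v2 < 0).sum())
    np.clip(v2, 0.0, None, out=v2)

    phenotypes = phenotypes.copy()
    phenotypes["interval_years"] = dt
    followup = CohortVolumes(v2, cohort.affine, list(cohort.subject_ids))

    # follow-up cognition: latent drifts by base + group + rate pathways
    observed_rate = np.where(
        cohort.data[:, region] > 0,
        (v2[:, region] - cohort.data[:, region])
        / (cohort.data[:, region] * dt[:, None]),
        np.nan,
    ).mean(axis=1)
    rate_sd = observed_rate.std(ddof=1)
    rate_z = (
        (observed_rate - observed_rate.mean()) / rate_sd
        if rate_sd > 0
        else np.zeros_like(observed_rate)
    )
    cognition2 = None
    if truth.latent_scores is not None:
        latents2: dict[str, np.ndarray] = {}
        for domain in DOMAINS:
            w = config.change_weights.get(domain, {})
            slope = (
                w.get("base", 0.0)
                + w.get("group", 0.0) * exposed
                + rng.normal(0.0, config.change_noise_sd, size=n)
            )
            drift = slope * dt + w.get("rate", 0.0) * rate_z
            latents2[domain] = truth.latent_scores[domain].to_numpy() + drift
        cognition2 = _tests_from_latent(latents2, rng, list(cohort.subject_ids))
    report = {"n_voxels_clipped": n_clipped}
    return followup, phenotypes, cognition2, report


_FACE_OFFSETS = [(-1, 0, 0), (1, 0, 0), (0, -1, 0), (0, 1, 0), (0, 0, -1), (0, 0, 1)]


def make_atlas(mask: BrainMask, n_regions: int, seed: int) -> np.ndarray:
    """Partition the in-mask voxels into ``n_regions`` connected regions.

    Random in-mask seed voxels grow by breadth-first face-adjacent expansion
    until every in-mask voxel carries exactly one integer label in
    ``1..n_regions``.  Out-of-mask voxels are labelled 0.
    """
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    coords = mask.indices
    if n_regions > len(coords):
        raise ValueError(
            f"n_regions={n_regions} exceeds in-mask voxel count {len(coords)}"
        )
    rng = np.random.default_rng(seed)
    seeds = coords[rng.choice(len(coords), size=n_regions, replace=False)]
    labels = np.zeros(mask.data.shape, dtype=np.int32)
    queue: deque[tuple[int, int, int]] = deque()
    for lab, (i, j, k) in enumerate(seeds, start=1):
        labels[i, j, k] = lab
        queue.append((i, j, k))
    dims = mask.data.shape
    while queue:
        i, j, k = queue.popleft()
        lab = labels[i, j, k]
        for di, dj, dk in _FACE_OFFSETS:
            ni, nj, nk = i + di, j + dj, k + dk
            if 0 <= ni < dims[0] and 0 <= nj < dims[1] and 0 <= nk < dims[2]:
                if mask.data[ni, nj, nk] and labels[ni, nj, nk] == 0:
                    labels[ni, nj, nk] = lab
                    queue.append((ni, nj, nk))
    unreached = mask.data & (labels == 0)
    if unreached.any():
        # disconnected mask component: attach each leftover voxel to the
        # nearest seed so the partition property still holds
        warnings.warn("mask has components unreachable from atlas seeds")
        left = np.argwhere(unreached)
        d2 = ((left[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        labels[tuple(left.T)] = d2.argmin(axis=1) + 1
    return labels


def simulate_growth(
    n_subjects: int = 200,
    n_visits: int = 3,
    visit_spacing_years: float = 2.0,
    beta: dict[str, float] | None = None,
    sd_intercept: float = 0.7,
    sd_slope: float = 0.10,
    sd_resid: float = 0.30,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulate long-format cognitive scores from the two-level growth model.

    Level 1: score = pi0 + pi1 * time + e.  Level 2: subject intercept and
    slope are linear in baseline age, gender, education, and exposure group,
    plus random effects.  Returns the long table and the generating fixed
    effects (keys b00..b14).
    """
    defaults = {
        "b00": 0.0, "b01": -0.03, "b02": 0.05, "b03": 0.04, "b04": -0.20,
        "b10": -0.05, "b11": -0.005, "b12": 0.01, "b13": 0.005, "b14": -0.06,
    }
    if beta:
        defaults.update(beta)
    b = defaults
    rng = np.random.default_rng(seed)
    age0 = rng.normal(72.0, 5.0, n_subjects)
    age_c = age0 - 72.0
    gender = rng.integers(0, 2, n_subjects).astype(float)
    edu = np.clip(np.round(rng.normal(11.0, 3.0, n_subjects)), 6, 22)
    edu_c = edu - 11.0
    group = rng.integers(0, 2, n_subjects).astype(float)  # 1 = exposed
    r0 = rng.normal(0.0, sd_intercept, n_subjects)
    r1 = rng.normal(0.0, sd_slope, n_subjects)
    pi0 = b["b00"] + b["b01"] * age_c + b["b02"] * gender + b["b03"] * edu_c + b["b04"] * group + r0
    pi1 = b["b10"] + b["b11"] * age_c + b["b12"] * gender + b["b13"] * edu_c + b["b14"] * group + r1

    rows = []
    for visit in range(n_visits):
        t = visit * visit_spacing_years
        score = pi0 + pi1 * t + rng.normal(0.0, sd_resid, n_subjects)
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": [f"S{i:04d}" for i in range(n_subjects)],
                    "time": t,
                    "score": score,
                    "age_baseline": age0,
                    "gender": gender,
                    "education": edu,
                    "group": group,
                }
            )
        )
    return pd.concat(rows, ignore_index=True), b


def simulate_mediation(
    n: int = 500,
    a: float = -0.02,
    b: float = 5.0,
    c_direct: float = -0.05,
    sd_rate: float = 0.01,
    sd_change: float = 0.15,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulate exposure -> regional decline rate -> cognitive change.

    ``rate = a*group + covariate effects + noise`` and
    ``change = b*rate + c_direct*group + covariate effects + noise``.
    Returns the table and the generating paths (a, b, c_direct, and the
    implied total effect and proportion mediated).
    """
    rng = np.random.default_rng(seed)
    group = rng.integers(0, 2, n).astype(float)
    age = rng.normal(72.0, 5.0, n)
    age_c = age - 72.0
    rate = -0.005 + a * group - 0.0003 * age_c + rng.normal(0.0, sd_rate, n)
    change = b * rate + c_direct * group - 0.004 * age_c + rng.normal(0.0, sd_change, n)
    df = pd.DataFrame(
        {
            "subject_id": [f"S{i:04d}" for i in range(n)],
            "group": group,
            "age": age,
            "rate": rate,
            "change": change,
        }
    )
    total = a * b + c_direct
    truth = {
        "a": a,
        "b": b,
        "c_direct": c_direct,
        "c_total": total,
        "proportion_mediated": a * b / total,
    }
    return df, truth
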