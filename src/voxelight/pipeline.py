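"""Stage orchestration: simulate -> match -> composite -> vbm -> searchlight
-> represent -> rates -> growth, with on-disk artifacts and resume.

Each stage reads its inputs from the run directory, writes its declared
outputs there, and appends a manifest record.  A stage whose outputs all
exist is skipped on resume, so deleting one stage's outputs recomputes that
stage only (and anything after it that is also missing).  All randomness
derives from the single top-level seed through fixed per-stage offsets.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import composites as comp_mod
from . import io as vio
from . import longitudinal as long_mod
from .containers import BrainMask, CohortVolumes, unmask
from .matching import fit_propensity, match_pairs
from .representation import (
    RepresentationSpec,
    domain_coverage,
    representation_map,
)
from .searchlight import SearchlightSpec, accuracy_map, constrain_regions
from .synthetic import (
    TEST_DOMAINS,
    TIMING_TESTS,
    EffectRegion,
    SynthConfig,
    generate_cohort,
    generate_followup,
    make_atlas,
)
from .voxelwise import build_mask, extract_clusters, group_tmap, with_fdr

STAGES = (
    "simulate", "match", "composite", "vbm",
    "searchlight", "represent", "rates", "growth",
)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synthetic": {},  # overrides for SynthConfig fields
    "matching": {
        "covariates": ["age", "gender", "education",
                       "hypertension", "diabetes", "hyperlipidemia"],
        "caliper_sd": 0.2,
    },
    "vbm": {"mask_threshold": 0.2, "q_level": 0.05, "min_extent": 10,
            "covariates": ["age", "gender", "education", "tiv"]},
    "searchlight": {},  # overrides for SearchlightSpec fields
    "representation": {"n_perm": 1000, "fdr_level": 0.001},
    "longitudinal": {"q_level": 0.05, "min_extent": 10, "n_regions": 12,
                     "n_boot": 5000, "mediation_domain": "memory"},
}


def load_config(path: str | Path | None) -> dict:
    """Merge a YAML/JSON config file over the defaults (one level deep)."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _outputs_exist(run_dir: Path, names: list[str]) -> bool:
    return all((run_dir / n).exists() for n in names)


def _synth_config(cfg: dict) -> SynthConfig:
    over = dict(cfg.get("synthetic", {}))
    if "effect_regions" in over:
        over["effect_regions"] = [
            EffectRegion(r["name"], tuple(r["center"]), r["radius_mm"], r["d"])
            for r in over["effect_regions"]
        ]
    if "decline_region" in over:
        r = over["decline_region"]
        over["decline_region"] = EffectRegion(
            r["name"], tuple(r["center"]), r["radius_mm"], r.get("d", 0.0)
        )
    return SynthConfig(seed=cfg.get("seed", 0), **over)


def stage_simulate(cfg: dict, run_dir: Path) -> list[str]:
    out = ["baseline.nii.gz", "followup.nii.gz", "phenotype.csv",
           "cognition.csv", "cognition_followup.csv", "truth.json"]
    scfg = _synth_config(cfg)
    phen, vols, cog, truth = generate_cohort(scfg)
    followup, phen, cog2, report = generate_followup(vols, phen, truth, scfg)
    vio.write_cohort(vols, run_dir / "baseline.nii.gz")
    vio.write_cohort(followup, run_dir / "followup.nii.gz")
    phen.to_csv(run_dir / "phenotype.csv", index=False)
    cog.to_csv(run_dir / "cognition.csv", index=False)
    cog2.to_csv(run_dir / "cognition_followup.csv", index=False)
    truth_doc = {
        "effect_sizes": truth.effect_sizes,
        "decline_rates": truth.decline_rates,
        "region_sds": truth.region_sds,
        "cognitive_weights": truth.cognitive_weights,
        "clip_report": report,
        "config": {
            k: (str(v) if isinstance(v, (list, dict)) else v)
            for k, v in dataclasses.asdict(scfg).items()
        },
    }
    (run_dir / "truth.json").write_text(json.dumps(truth_doc, indent=2, default=str))
    return out


def _load_cohorts(run_dir: Path) -> tuple[pd.DataFrame, CohortVolumes, CohortVolumes]:
    phen = vio.read_phenotype(run_dir / "phenotype.csv")
    ids = phen["subject_id"].tolist()
    vols = vio.read_cohort(run_dir / "baseline.nii.gz", ids)
    follow = vio.read_cohort(run_dir / "followup.nii.gz", ids)
    return phen, vols, follow


def stage_match(cfg: dict, run_dir: Path) -> list[str]:
    out = ["matched.csv", "balance.tsv"]
    phen = vio.read_phenotype(run_dir / "phenotype.csv")
    mcfg = cfg["matching"]
    result = fit_propensity(phen, mcfg["covariates"])
    result = match_pairs(result, phen, mcfg["caliper_sd"], seed=cfg.get("seed", 0))
    matched = phen[phen["subject_id"].isin(result.matched_ids)]
    matched.to_csv(run_dir / "matched.csv", index=False)
    balance = pd.DataFrame(
        {"smd_before": result.smd_before, "smd_after": result.smd_after}
    )
    balance.to_csv(run_dir / "balance.tsv", sep="\t")
    return out


def stage_composite(cfg: dict, run_dir: Path) -> list[str]:
    out = ["composites.csv", "composites_followup.csv", "weights.json"]
    cog = pd.read_csv(run_dir / "cognition.csv")
    comps, weights = comp_mod.composites_from_tests(cog, TEST_DOMAINS, TIMING_TESTS)
    comps.to_csv(run_dir / "composites.csv", index=False)
    cog2 = pd.read_csv(run_dir / "cognition_followup.csv")
    comps2 = comp_mod.composite_scores(
        cog2[list(TEST_DOMAINS)], weights, TIMING_TESTS, subject_ids=cog2["subject_id"]
    )
    comps2.to_csv(run_dir / "composites_followup.csv", index=False)
    (run_dir / "weights.json").write_text(
        json.dumps({d: w.to_dict() for d, w in weights.items()}, indent=2)
    )
    return out


def _matched_cohort(run_dir: Path) -> tuple[pd.DataFrame, CohortVolumes, CohortVolumes]:
    matched = vio.read_phenotype(run_dir / "matched.csv")
    ids = matched["subject_id"].tolist()
    vols = vio.read_cohort(run_dir / "baseline.nii.gz",
                           vio.read_phenotype(run_dir / "phenotype.csv")["subject_id"].tolist())
    follow = vio.read_cohort(run_dir / "followup.nii.gz", vols.subject_ids)
    return matched, vols.select(ids), follow.select(ids)


def stage_vbm(cfg: dict, run_dir: Path) -> list[str]:
    out = ["mask.nii.gz", "tmap.nii.gz", "qmap.nii.gz", "clusters.tsv"]
    matched, vols, _ = _matched_cohort(run_dir)
    vcfg = cfg["vbm"]
    mask = build_mask(vols, vcfg["mask_threshold"])
    stat = with_fdr(
        group_tmap(vols, matched["group"].to_numpy(), matched[vcfg["covariates"]], mask),
        vcfg["q_level"],
    )
    vio.write_volume(mask.data.astype(float), mask.affine, run_dir / "mask.nii.gz")
    vio.write_volume(stat.t_volume(), mask.affine, run_dir / "tmap.nii.gz")
    vio.write_volume(unmask(stat.q, mask, fill=1.0), mask.affine, run_dir / "qmap.nii.gz")
    clusters = extract_clusters(
        stat.significance_mask(vcfg["q_level"]), stat.t_volume(), mask.affine,
        min_extent=vcfg["min_extent"],
    )
    clusters.to_csv(run_dir / "clusters.tsv", sep="\t", index=False)
    return out


def stage_searchlight(cfg: dict, run_dir: Path) -> list[str]:
    out = ["accuracy.nii.gz", "constrained.nii.gz", "excluded.nii.gz"]
    matched, vols, _ = _matched_cohort(run_dir)
    mask_data, affine = vio.read_volume(run_dir / "mask.nii.gz")
    mask = BrainMask(mask_data > 0.5, affine, threshold=cfg["vbm"]["mask_threshold"])
    slcfg = dict(cfg.get("searchlight", {}))
    if slcfg.pop("residualize", False):
        from .voxelwise import residualize_cohort

        vols = residualize_cohort(vols, matched[cfg["vbm"]["covariates"]])
    spec = SearchlightSpec(seed=cfg.get("seed", 0), **slcfg)
    acc = accuracy_map(vols, mask, matched["group"].to_numpy(), spec)
    qmap, _ = vio.read_volume(run_dir / "qmap.nii.gz")
    significant = (qmap <= cfg["vbm"]["q_level"]) & mask.data
    part = constrain_regions(acc, significant)
    vio.write_volume(acc.volume(), affine, run_dir / "accuracy.nii.gz")
    vio.write_volume(part.constrained.astype(float), affine, run_dir / "constrained.nii.gz")
    vio.write_volume(part.excluded.astype(float), affine, run_dir / "excluded.nii.gz")
    return out


def stage_represent(cfg: dict, run_dir: Path) -> list[str]:
    out = ["representation.tsv", "coverage.tsv"]
    matched, vols, _ = _matched_cohort(run_dir)
    mask_data, affine = vio.read_volume(run_dir / "mask.nii.gz")
    mask = BrainMask(mask_data > 0.5, affine)
    constrained, _ = vio.read_volume(run_dir / "constrained.nii.gz")
    excluded, _ = vio.read_volume(run_dir / "excluded.nii.gz")
    if not (constrained > 0.5).any():
        warnings.warn("constrained set empty; representation stage skipped")
        pd.DataFrame().to_csv(run_dir / "representation.tsv", sep="\t")
        pd.DataFrame().to_csv(run_dir / "coverage.tsv", sep="\t")
        return out
    from .searchlight import RegionPartition

    part = RegionPartition(constrained > 0.5, excluded > 0.5,
                           cfg.get("searchlight", {}).get("accuracy_threshold", 0.6))
    comps = pd.read_csv(run_dir / "composites.csv")
    comps = comps[comps["subject_id"].isin(matched["subject_id"])]
    rcfg = cfg["representation"]
    spec = RepresentationSpec(
        n_perm=rcfg["n_perm"], fdr_level=rcfg["fdr_level"], seed=cfg.get("seed", 0)
    )
    rmap = representation_map(vols, mask, part, comps, spec)
    rmap.table.to_csv(run_dir / "representation.tsv", sep="\t", index=False)
    domain_coverage(rmap).rename("coverage").to_csv(run_dir / "coverage.tsv", sep="\t")
    return out


def stage_rates(cfg: dict, run_dir: Path) -> list[str]:
    out = ["rates.nii.gz", "region_rates.csv", "atlas.nii.gz",
           "rate_tmap.nii.gz", "rate_clusters.tsv", "mediation.json"]
    matched, vols, follow = _matched_cohort(run_dir)
    mask_data, affine = vio.read_volume(run_dir / "mask.nii.gz")
    mask = BrainMask(mask_data > 0.5, affine)
    lcfg = cfg["longitudinal"]
    rate_map = long_mod.annual_decline_rate(
        vols, follow, matched["interval_years"].to_numpy(), mask
    )
    vio.write_volume(
        np.moveaxis(
            np.stack([unmask(r, mask) for r in np.nan_to_num(rate_map.rates)]), 0, -1
        ),
        affine, run_dir / "rates.nii.gz",
    )
    atlas = make_atlas(mask, lcfg["n_regions"], seed=cfg.get("seed", 0))
    vio.write_volume(atlas.astype(float), affine, run_dir / "atlas.nii.gz")
    region_table = long_mod.region_rates(rate_map, atlas)
    region_table.to_csv(run_dir / "region_rates.csv", index=False)
    stat, clusters = long_mod.rate_group_diff(
        rate_map, matched["group"].to_numpy(),
        matched[cfg["vbm"]["covariates"]], lcfg["q_level"], lcfg["min_extent"], atlas,
    )
    vio.write_volume(stat.t_volume(), affine, run_dir / "rate_tmap.nii.gz")
    clusters.to_csv(run_dir / "rate_clusters.tsv", sep="\t", index=False)

    # mediation: exposure -> decline-region rate -> cognitive change
    comps = pd.read_csv(run_dir / "composites.csv")
    comps2 = pd.read_csv(run_dir / "composites_followup.csv")
    change = long_mod.cognitive_change(
        comps, comps2, matched.set_index("subject_id")["interval_years"]
    )
    domain = lcfg["mediation_domain"]
    # mediator: rate in the cluster with the strongest group difference,
    # falling back to the global in-mask mean when no cluster survives
    if len(clusters):
        peak = clusters.iloc[0]
        lab = atlas[int(peak["peak_i"]), int(peak["peak_j"]), int(peak["peak_k"])]
        mediator_col = f"region_{lab}"
    else:
        mediator_col = region_table.columns[1]
    merged = matched.merge(region_table, on="subject_id").merge(change, on="subject_id")
    merged = merged.dropna(subset=[mediator_col, domain])
    med = long_mod.mediate(
        (merged["group"] == "DD").to_numpy(float),
        merged[mediator_col].to_numpy(),
        merged[domain].to_numpy(),
        merged[["age", "gender", "education"]].to_numpy(float),
        n_boot=lcfg["n_boot"], seed=cfg.get("seed", 0),
    )
    doc = {
        "domain": domain, "mediator": mediator_col,
        **{k: getattr(med, k) for k in
           ("a", "b", "c_total", "c_direct", "indirect",
            "proportion_mediated", "indirect_p", "n", "n_boot")},
        "indirect_ci": list(med.indirect_ci),
        "proportion_ci": list(med.proportion_ci) if med.proportion_ci else None,
    }
    (run_dir / "mediation.json").write_text(json.dumps(doc, indent=2))
    return out


def stage_growth(cfg: dict, run_dir: Path) -> list[str]:
    matched = vio.read_phenotype(run_dir / "matched.csv", require_interval=True)
    comps = pd.read_csv(run_dir / "composites.csv")
    comps2 = pd.read_csv(run_dir / "composites_followup.csv")
    domains = [c for c in comps.columns if c != "subject_id"]
    out = [f"growth_{d}.json" for d in domains]
    base = matched[["subject_id", "age", "gender", "education", "group",
                    "interval_years"]].rename(columns={"age": "age_baseline"})
    for domain in domains:
        rows = []
        for tbl, tcol in ((comps, 0.0), (comps2, None)):
            m = base.merge(tbl[["subject_id", domain]], on="subject_id")
            m["time"] = 0.0 if tcol == 0.0 else m["interval_years"]
            m["score"] = m[domain]
            rows.append(m[["subject_id", "time", "score", "age_baseline",
                           "gender", "education", "group"]])
        long_df = pd.concat(rows, ignore_index=True).dropna(subset=["score"])
        null_res = long_mod.fit_null_model(long_df)
        growth = long_mod.fit_growth_model(long_df)
        doc = {
            "domain": domain,
            "icc": null_res.icc,
            "fixed_effects": growth.fixed_effects.to_dict(),
            "standard_errors": growth.standard_errors.to_dict(),
            "p_values": growth.p_values.to_dict(),
            "var_intercept": growth.var_intercept,
            "var_slope": growth.var_slope,
            "cov_intercept_slope": growth.cov_intercept_slope,
            "var_residual": growth.var_residual,
            "converged": growth.converged,
            "boundary": growth.boundary,
            "loglik": growth.loglik,
        }
        (run_dir / f"growth_{domain}.json").write_text(json.dumps(doc, indent=2))
    return out


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "match": stage_match,
    "composite": stage_composite,
    "vbm": stage_vbm,
    "searchlight": stage_searchlight,
    "represent": stage_represent,
    "rates": stage_rates,
    "growth": stage_growth,
}

# outputs checked for resume (growth outputs depend on domains, checked inside)
_STAGE_OUTPUTS = {
    "simulate": ["baseline.nii.gz", "followup.nii.gz", "phenotype.csv",
                 "cognition.csv", "cognition_followup.csv", "truth.json"],
    "match": ["matched.csv", "balance.tsv"],
    "composite": ["composites.csv", "composites_followup.csv", "weights.json"],
    "vbm": ["mask.nii.gz", "tmap.nii.gz", "qmap.nii.gz", "clusters.tsv"],
    "searchlight": ["accuracy.nii.gz", "constrained.nii.gz", "excluded.nii.gz"],
    "represent": ["representation.tsv", "coverage.tsv"],
    "rates": ["rates.nii.gz", "region_rates.csv", "atlas.nii.gz",
              "rate_tmap.nii.gz", "rate_clusters.tsv", "mediation.json"],
    "growth": ["growth_memory.json"],
}


def run_pipeline(
    config: dict,
    run_dir: str | Path,
    stages: list[str] | None = None,
    resume: bool = True,
) -> dict[str, str]:
    """Execute the pipeline, skipping stages whose outputs already exist.

    Returns a stage -> status ("ran" / "skipped") map.  A failing stage
    halts the run with its manifest recording the failure.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    stages = list(stages or STAGES)
    unknown = [s for s in stages if s not in _STAGE_FUNCS]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    status: dict[str, str] = {}
    seed = config.get("seed", 0)
    for stage in STAGES:
        if stage not in stages:
            continue
        if resume and _outputs_exist(run_dir, _STAGE_OUTPUTS[stage]):
            status[stage] = "skipped"
            continue
        with vio.stage_manifest(run_dir, stage, config, seed) as man:
            outputs = _STAGE_FUNCS[stage](config, run_dir)
            for o in outputs:
                man.add_output(run_dir / o)
        status[stage] = "ran"
    return status
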