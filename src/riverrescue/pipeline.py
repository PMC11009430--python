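"""End-to-end orchestration: simulate/ingest -> QC -> diversity & kinship ->
Ne, growth, dispersal -> rescue plan, with seeded stages and a manifest.

Stages communicate only through written artifacts, so a run directory can
be inspected or partially rerun; a rerun with the same config and inputs
is bit-identical for the deterministic stages.  Each stochastic stage
derives its own substream from the global seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import diversity, dispersal, growth, kinship, ne, qc, rescue, simulate
from .genotypes import read_genotypes, write_csv

STAGE_SEED_OFFSETS = {
    "simulate": 0, "qc": 11, "kinship": 23, "amova": 31, "ne": 47,
}


def _stage_seed(seed: int, stage: str) -> int:
    return (seed + STAGE_SEED_OFFSETS.get(stage, 0)) % (2**31 - 1)


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return validate_config(cfg, base=Path(path).parent)


def validate_config(cfg: dict, base=Path(".")) -> dict:
    cfg = dict(cfg)
    cfg.setdefault("seed", 0)
    cfg.setdefault("qc", {})
    cfg.setdefault("life_history", {"AL": 23.0, "alpha": 3.0})
    cfg.setdefault("plan", {"f_target": 0.1, "ne_over_n": 0.17})
    inputs = cfg.get("inputs")
    if inputs:
        for key, p in inputs.items():
            p = Path(p)
            if not p.is_absolute():
                p = base / p
            if not p.exists():
                raise FileNotFoundError(f"configured input {key!r} not found: {p}")
            inputs[key] = str(p)
    elif "simulate" not in cfg:
        raise ValueError("config needs either an 'inputs' block or a 'simulate' block")
    return cfg


def _fail(stage: str, exc: Exception):
    raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def run_pipeline(config: dict, outdir) -> dict:
    """Run every stage in dependency order; returns the report bundle dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    bundle = {}

    # ---- inputs: simulate or load ------------------------------------
    try:
        if "simulate" in config:
            sim_kwargs = dict(config["simulate"])
            sim_kwargs.setdefault("seed", _stage_seed(seed, "simulate"))
            sim_cfg = simulate.SimConfig(**sim_kwargs)
            truth = simulate.simulate_pedigree(sim_cfg)
            geno_all = simulate.drop_genotypes(truth, sim_cfg)
            samples, flow = simulate.render_observations(truth, sim_cfg, geno_all)
            geno = simulate.observed_genotypes(geno_all, samples, sim_cfg)
            simulate.write_truth(
                truth, outdir / "truth_individuals.tsv", outdir / "truth_breeders.tsv"
            )
        else:
            inputs = config["inputs"]
            fmt = "vcf" if inputs["genotypes"].endswith(".vcf") else "csv"
            geno = read_genotypes(
                inputs["genotypes"], fmt, locus_metadata=inputs.get("locus_metadata")
            )
            samples = pd.read_csv(inputs["samples"], sep="\t")
            flow = pd.read_csv(inputs["flow"], sep="\t")
        simulate.write_sample_table(samples, outdir / "samples.tsv")
        simulate.write_flow(flow, outdir / "flow.tsv")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        _fail("inputs", exc)

    # ---- qc -----------------------------------------------------------
    try:
        qc_par = config.get("qc", {})
        geno_f, rep1 = qc.standard_filters(
            geno,
            max_ind_missing=qc_par.get("max_ind_missing", 0.3),
            min_reproducibility=qc_par.get("min_reproducibility", 0.95),
            max_locus_missing=qc_par.get("max_locus_missing", 0.2),
            one_per_tag=qc_par.get("one_per_tag", "random"),
            seed=_stage_seed(seed, "qc"),
        )
        geno_f, rep2 = qc.excess_het_filter(geno_f, alpha=qc_par.get("alpha", 0.05))
        report = qc.FilterReport(steps=rep1.steps + rep2.steps)
        report.to_json(outdir / "qc_report.json")
        write_csv(geno_f, outdir / "genotypes_filtered.csv")
        bundle["qc"] = report.to_dict()
    except Exception as exc:
        _fail("qc", exc)

    # ---- diversity ----------------------------------------------------
    try:
        het = diversity.individual_heterozygosity(geno_f)
        het.to_csv(outdir / "pht.tsv", sep="\t", index=False)
        pops = samples.set_index("sample_id")["population"]
        groups = diversity.group_heterozygosity(het, pops)
        bundle["pht_by_population"] = groups.to_dict(orient="records")
    except Exception as exc:
        _fail("diversity", exc)

    # ---- kinship ------------------------------------------------------
    try:
        dup = kinship.find_duplicates(geno_f)
        rel = kinship.pairwise_relatedness(geno_f)
        cohort_map = {}
        if "birth_year" in samples.columns:
            cohort_map = samples.set_index("sample_id")["birth_year"].dropna().to_dict()
        fams = kinship.cluster_full_sib_families(
            rel, cohorts=cohort_map or None, seed=_stage_seed(seed, "kinship")
        )
        fams.duplicate_sets = dup
        if fams.families is not None:
            fams.families.to_csv(outdir / "families.tsv", sep="\t", index=False)
        bundle["kinship"] = {
            "n_duplicate_sets": len(dup),
            "n_families": int(fams.families["family_id"].nunique()) if len(fams.families) else 0,
        }
    except Exception as exc:
        _fail("kinship", exc)

    # ---- cohorts & growth --------------------------------------------
    try:
        assign = growth.assign_cohorts(samples, breaks=config.get("cohort_breaks", "auto"))
        adf = assign.assignments.merge(samples, on="sample_id")
        adf["age"] = [
            growth.nominal_age(pd.Timestamp(c), int(b)) if not pd.isna(b) else np.nan
            for c, b in zip(adf["capture_date"], adf["birth_year"])
        ]
        ok = adf.dropna(subset=["age", "total_length_mm"])
        fit = growth.fit_gompertz(ok["age"], ok["total_length_mm"])
        resid = growth.growth_residuals(fit, ok, ok["age"])
        resid.to_csv(outdir / "growth_residuals.tsv", sep="\t", index=False)
        ibd = growth.inbreeding_depression_suite(resid, het)
        bundle["growth"] = {
            "gompertz": {"L_inf": fit.L_inf, "k": fit.k, "t0": fit.t0,
                         "parameterization": "L_inf*exp(-exp(-k*(t-t0)))"},
            "recapture_consistency": assign.recapture_consistency,
            "ibd_pooled_slope": ibd["pht_pooled"]["slope"],
            "ibd_pooled_p": ibd["pht_pooled"]["p"],
        }
        cohorts_of = ok.set_index("sample_id")["birth_year"].astype(int)
    except Exception as exc:
        _fail("growth", exc)

    # ---- ne per cohort ------------------------------------------------
    try:
        lh = ne.LifeHistory(**config["life_history"])
        p_crit = config.get("ne", {}).get("p_crit", 0.01)
        per_cohort = {}
        nb_values = []
        for year, ids in cohorts_of.groupby(cohorts_of).groups.items():
            ids = [i for i in ids if i in geno_f.samples]
            if len(ids) < 10:
                continue
            sub = geno_f.take_samples(ids)
            try:
                est = ne.ldne(sub, p_crit=p_crit, jackknife=False)
            except ValueError:
                continue
            est = ne.adjust_nb(est, lh)
            per_cohort[int(year)] = est.rounded() | {"S": est.S}
            if np.isfinite(est.nb_adj):
                nb_values.append(est.nb_adj)
        bundle["ne_per_cohort"] = per_cohort
        nb_base = float(np.mean(nb_values)) if nb_values else float("nan")
    except Exception as exc:
        _fail("ne", exc)

    # ---- dispersal ----------------------------------------------------
    try:
        if bundle["kinship"]["n_families"] >= 10:
            fam_df = fams.families.rename(columns={"modal_cohort": "modal_cohort"})
            disp = dispersal.family_max_distance(fam_df, samples)
            disp = disp.merge(
                fam_df.groupby("family_id")["modal_cohort"].first().rename("birth_year"),
                left_on="family_id", right_index=True, how="left", suffixes=("_drop", ""),
            )
            disp["birth_year"] = disp["birth_year"].astype("Float64")
            try:
                bundle["dispersal_model"] = dispersal.flow_dispersal_model(
                    disp.rename(columns={"birth_year": "birth_year"}), flow
                )
            except ValueError as exc:
                bundle["dispersal_model"] = {"skipped": str(exc)}
            disp.to_csv(outdir / "family_dispersal.tsv", sep="\t", index=False)
    except Exception as exc:
        _fail("dispersal", exc)

    # ---- rescue plan ---------------------------------------------------
    try:
        plan_par = config.get("plan", {})
        by_pop = {g["group"]: g["pht_mean"] for g in bundle["pht_by_population"]}
        pht_target = by_pop.get("target")
        pht_source = by_pop.get("source")
        if pht_target is None or pht_source is None or not np.isfinite(nb_base):
            bundle["rescue_plan"] = {"skipped": "needs target+source PHt and an Nb base"}
        else:
            plan = rescue.build_rescue_plan(
                pht_target, pht_source, nb_base,
                f_target=plan_par.get("f_target", 0.1),
                ne_over_n=plan_par.get("ne_over_n", 0.17),
                release_counts=plan_par.get("release_counts"),
            )
            plan.to_json(outdir / "rescue_plan.json")
            bundle["rescue_plan"] = plan.to_dict()
    except Exception as exc:
        _fail("rescue", exc)

    manifest = {
        "package_version": __version__,
        "python": sys.version.split()[0],
        "seed": seed,
        "config_sha256": hashlib.sha256(
            yaml.safe_dump(config, sort_keys=True).encode()
        ).hexdigest(),
        "stages": list(bundle.keys()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    with open(outdir / "report.json", "w") as fh:
        json.dump(bundle, fh, indent=2, default=_jsonable)
    return bundle


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    return str(o)
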