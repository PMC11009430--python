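"""Per-cohort effective numbers of breeders: LD method with life-history
adjustment, and the sibship-frequency method, against true breeder counts."""

import importlib.util
import json
from pathlib import Path

import numpy as np
import pandas as pd

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from riverrescue import ne  # noqa: E402

cfg, truth, geno, samples, flow, filtered = common.study_dataset()
lh = ne.LifeHistory(AL=cfg.adult_lifespan, alpha=cfg.age_maturity)

by = truth.individuals.set_index("id")["birth_year"]
iid = samples.set_index("sample_id")["individual_id"]
rows = []
for year in cfg.years:
    cohort_ids = [s for s in filtered.samples
                  if by.get(iid[s]) == year and not s.endswith("_b")]
    if len(cohort_ids) < 12:
        continue
    est = ne.ldne(filtered.take_samples(cohort_ids), p_crit=0.01, jackknife=False)
    est = ne.adjust_nb(est, lh)
    fs, hs = ne.truth_sib_dyads(truth.individuals, [iid[s] for s in cohort_ids])
    sib = ne.sibship_nb(
        [(a, b) for a, b in fs], len(cohort_ids),
        hs_pairs=hs, n_bootstrap=200, seed=common.SEED,
    )
    true_b = truth.breeders_by_year.set_index("year")["n_breeders"].get(year)
    r = est.rounded()
    rows.append(dict(
        cohort=year, n=len(cohort_ids), true_breeders=int(true_b),
        nb_hat_ld=r["nb_hat"], nb_adj=r["nb_adj"], ne_adj=r["ne_adj"],
        nb_sibship=round(sib.nb_hat, 1) if np.isfinite(sib.nb_hat) else "inf",
    ))

table = pd.DataFrame(rows)
table.to_csv(common.RESULTS / "nb_by_cohort.tsv", sep="\t", index=False)
print(table.to_string(index=False))
print(f"adjustment divisors: {ne.adjustment_divisors(lh)}")
finite = table[pd.to_numeric(table["nb_adj"], errors="coerce").notna()]
print("mean adjusted Nb across cohorts:", round(finite["nb_adj"].mean(), 1))
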