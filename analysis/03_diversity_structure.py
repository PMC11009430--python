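"""Heterozygosity, ancestry classification and spatial structure.

Reports PHt means by population and cohort, the PCoA-based admixture
call (with the admixed percentage), and a one-level AMOVA by site.
"""

import importlib.util
import json
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from riverrescue import diversity  # noqa: E402

cfg, truth, geno, samples, flow, filtered = common.study_dataset()

het = diversity.individual_heterozygosity(filtered)
pops = samples.set_index("sample_id")["population"]
by_pop = diversity.group_heterozygosity(het, pops)
by_pop.to_csv(common.RESULTS / "pht_by_population.tsv", sep="\t", index=False)

by = truth.individuals.set_index("id")["birth_year"]
cohorts = samples.assign(birth_year=samples["individual_id"].map(by))
cohort_map = cohorts.set_index("sample_id")["birth_year"]
target = cohorts[(cohorts["population"] == "target")
                 & (cohorts["birth_year"] >= cfg.start_year)]
by_cohort = diversity.group_heterozygosity(
    het, target.set_index("sample_id")["birth_year"])
by_cohort.to_csv(common.RESULTS / "pht_by_cohort.tsv", sep="\t", index=False)

res = diversity.pcoa(filtered, k=2)
refs = {s: p for s, p in pops.items() if p in ("target", "source") and s in filtered.samples}
labelled = diversity.classify_ancestry(res, refs)
n_admixed = int((labelled.labels == "admixed").sum())
n_cohort_fish = int((cohorts["birth_year"] >= cfg.start_year).sum())
pct = diversity.admixed_percentage(n_admixed, n_cohort_fish)

am = diversity.amova_one_level(
    filtered.take_samples(list(target["sample_id"])[:400]),
    target.set_index("sample_id")["site"], n_perm=499, seed=common.SEED,
)

summary = {
    "pht_by_population": by_pop.round(4).to_dict(orient="records"),
    "pc1_percent_variance": round(float(res.percent_variance[0]), 1),
    "n_admixed": n_admixed,
    "admixed_percent": pct,
    "amova_site_percent": round(am["percent_among"], 1),
    "amova_p": am["p_value"],
}
(common.RESULTS / "diversity_summary.json").write_text(json.dumps(summary, indent=2))
print(json.dumps(summary, indent=2))
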