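"""Simulate the monitored riverscape and summarize what the survey 'sees'.

Writes per-year breeder truth, per-cohort sample counts and the flow table.
"""

import importlib.util
import sys
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from riverrescue import dispersal  # noqa: E402

cfg, truth, geno, samples, flow, filtered = common.study_dataset()

breeders = truth.breeders_by_year
breeders.to_csv(common.RESULTS / "true_breeders_by_year.tsv", sep="\t", index=False)

by = truth.individuals.set_index("id")["birth_year"]
cohort = samples.assign(birth_year=samples["individual_id"].map(by))
counts = (
    cohort[cohort["birth_year"] >= cfg.start_year]
    .groupby(["birth_year", "site"]).size().unstack(fill_value=0)
)
counts.to_csv(common.RESULTS / "sample_counts_by_cohort_site.tsv", sep="\t")

yearly_flow = dispersal.mean_flow_by_year(flow).round(1)
yearly_flow.to_csv(common.RESULTS / "mean_flow_by_year.tsv", sep="\t")

print(f"simulated {len(truth.individuals)} fish, {len(samples)} capture events")
print("true breeders per year:")
print(breeders.to_string(index=False))
print("yearly mean flow (ML/day):")
print(yearly_flow.to_string())
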