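"""Sibling-based dispersal: family spreads, directions, and the flow model."""

import importlib.util
import json
from collections import Counter
from pathlib import Path

import pandas as pd

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from riverrescue import dispersal, kinship  # noqa: E402

cfg, truth, geno, samples, flow, filtered = common.study_dataset()

rel = kinship.pairwise_relatedness(filtered)
by = truth.individuals.set_index("id")["birth_year"]
cohort_map = samples.assign(birth_year=samples["individual_id"].map(by)) \
    .set_index("sample_id")["birth_year"].dropna().astype(int).to_dict()
fams = kinship.cluster_full_sib_families(rel, cohorts=cohort_map, seed=common.SEED)

disp = dispersal.family_max_distance(fams.families.rename(columns={}), samples)
disp["birth_year"] = disp["family_id"].map(
    fams.families.groupby("family_id")["modal_cohort"].first())
disp.to_csv(common.RESULTS / "family_dispersal.tsv", sep="\t", index=False)

directions = Counter()
for fid, members in fams.family_members().items():
    if len(members) >= 5:
        directions[dispersal.infer_direction(sorted(members), samples)] += 1

model = dispersal.flow_dispersal_model(disp, flow)

summary = {
    "n_families": int(disp.shape[0]),
    "max_spread_km": round(float(disp["max_distance_km"].max()), 1),
    "directions_families_ge5": dict(directions),
    "flow_model": {k: (round(v, 4) if isinstance(v, float) else v)
                   for k, v in model.items()},
}
(common.RESULTS / "dispersal_summary.json").write_text(json.dumps(summary, indent=2))
print(json.dumps(summary, indent=2))
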