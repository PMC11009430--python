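"""Duplicate detection and full-sib family reconstruction, scored on truth."""

import importlib.util
import itertools
import json
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from riverrescue import kinship  # noqa: E402

cfg, truth, geno, samples, flow, filtered = common.study_dataset()

dups = kinship.find_duplicates(filtered, min_match=0.95)
n_recaptures = int(samples["sample_id"].str.endswith("_b").sum())

rel = kinship.pairwise_relatedness(filtered)
by = truth.individuals.set_index("id")["birth_year"]
cohort_map = samples.assign(birth_year=samples["individual_id"].map(by)) \
    .set_index("sample_id")["birth_year"].dropna().astype(int).to_dict()
fams = kinship.cluster_full_sib_families(rel, cohorts=cohort_map, seed=common.SEED)
fams.families.to_csv(common.RESULTS / "families.tsv", sep="\t", index=False)

# score pairwise against pedigree truth for sampled cohort fish
iid = samples.set_index("sample_id")["individual_id"]
off = truth.individuals.dropna(subset=["dam"]).set_index("id")
true_pairs = set()
sampled = [s for s in filtered.samples if iid[s] in off.index]
fam_of = {s: (off.loc[iid[s], "dam"], off.loc[iid[s], "sire"], off.loc[iid[s], "birth_year"])
          for s in sampled}
for a, b in itertools.combinations(sorted(sampled), 2):
    if fam_of[a] == fam_of[b] and iid[a] != iid[b]:
        true_pairs.add((a, b))
inferred = set()
for members in fams.family_members().values():
    for a, b in itertools.combinations(sorted(members), 2):
        if iid.get(a) != iid.get(b):
            inferred.add((a, b))
inferred = {p for p in inferred if p[0] in fam_of and p[1] in fam_of}
tp = len(true_pairs & inferred)

sizes = fams.families.groupby("family_id").size()
summary = {
    "n_duplicate_sets": len(dups),
    "n_planted_recaptures": n_recaptures,
    "n_families": int(sizes.size),
    "family_size_min_max": [int(sizes.min()), int(sizes.max())],
    "pairwise_precision": round(tp / max(len(inferred), 1), 3),
    "pairwise_recall": round(tp / max(len(true_pairs), 1), 3),
    "n_flagged_cross_cohort": len(fams.flagged_families),
}
(common.RESULTS / "kinship_summary.json").write_text(json.dumps(summary, indent=2))
print(json.dumps(summary, indent=2))
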