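"""Apply the SNP QC pipeline and report what each rule removed."""

import importlib.util
import json
from pathlib import Path

spec = importlib.util.spec_from_file_location(
    "common", Path(__file__).parent / "00_common.py")
common = importlib.util.module_from_spec(spec)
spec.loader.exec_module(common)

from riverrescue import qc, simulate  # noqa: E402

cfg = common.study_config()
truth = simulate.simulate_pedigree(cfg)
geno = simulate.drop_genotypes(truth, cfg)
samples, _ = simulate.render_observations(truth, cfg, geno)
observed = simulate.observed_genotypes(geno, samples, cfg)

filtered, rep1 = qc.standard_filters(observed, seed=common.SEED, **qc.DEFAULT_PROFILE)
filtered, rep2 = qc.excess_het_filter(filtered, alpha=0.05)
report = qc.FilterReport(steps=rep1.steps + rep2.steps)

common.RESULTS.mkdir(parents=True, exist_ok=True)
report.to_json(common.RESULTS / "qc_report.json")

print(f"input: {observed.n_samples} samples x {observed.n_loci} loci")
print(f"output: {filtered.n_samples} samples x {filtered.n_loci} loci")
print(json.dumps(report.to_dict()["steps"], indent=2))
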