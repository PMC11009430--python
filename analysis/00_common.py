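"""Shared study conditions for the analysis scripts.

Every numbered script rebuilds what it needs from this one seeded
configuration, so each can be run on its own and all agree on the same
simulated riverscape: five cohort years (2016-2020), seven sites over
18 km, flow-tracking breeder numbers, translocations of 31/28/12 source
fish in 2017-2019, and a 2000-SNP ascertained panel.
"""

from pathlib import Path

from riverrescue import qc, simulate

SEED = 42
RESULTS = Path(__file__).resolve().parents[1] / "results" / "analysis"


def study_config(**overrides):
    kw = dict(seed=SEED, n_loci=2000, cross_population_mating_rate=0.05)
    kw.update(overrides)
    return simulate.SimConfig(**kw)


def study_dataset():
    """(config, truth, genotypes, samples, flow, observed+QC-filtered matrix)."""
    cfg = study_config()
    truth = simulate.simulate_pedigree(cfg)
    geno = simulate.drop_genotypes(truth, cfg)
    samples, flow = simulate.render_observations(truth, cfg, geno)
    observed = simulate.observed_genotypes(geno, samples, cfg)
    filtered, _ = qc.standard_filters(observed, seed=SEED)
    filtered, _ = qc.excess_het_filter(filtered)
    RESULTS.mkdir(parents=True, exist_ok=True)
    return cfg, truth, geno, samples, flow, filtered
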