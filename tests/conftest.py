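import warnings

import numpy as np
import pytest

from riverrescue import diversity, qc, simulate

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)
warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def riverscape():
    """One medium riverscape run shared across tests: truth + genotypes +
    observations + QC-filtered observed matrix."""
    cfg = simulate.SimConfig(seed=5, n_loci=1500, cross_population_mating_rate=0.1)
    truth = simulate.simulate_pedigree(cfg)
    geno = simulate.drop_genotypes(truth, cfg)
    samples, flow = simulate.render_observations(truth, cfg, geno)
    observed = simulate.observed_genotypes(geno, samples, cfg)
    filtered, _ = qc.standard_filters(observed, seed=1)
    filtered, _ = qc.excess_het_filter(filtered)
    return dict(
        cfg=cfg, truth=truth, geno=geno, samples=samples, flow=flow,
        observed=observed, filtered=filtered,
    )


@pytest.fixture(scope="session")
def riverscape_het(riverscape):
    return diversity.individual_heterozygosity(riverscape["filtered"])


def make_fs_hs_panel(seed=0, n_loci=2000, n_fs_pairs=500, n_hs_pairs=500):
    """Gene-drop panel of full-sib pairs, half-sib pairs and their parents.

    Families are mutually unrelated, so sample allele frequencies are
    nearly unbiased for the base population.
    Returns (GenotypeMatrix of offspring, list of FS pairs, list of HS pairs).
    """
    import pandas as pd

    rows = []
    fs, hs = [], []
    k = 0

    def founder():
        nonlocal k
        k += 1
        return f"P{k:05d}"

    def kid(dam, sire):
        nonlocal k
        k += 1
        iid = f"K{k:05d}"
        rows.append(
            dict(id=iid, dam=dam, sire=sire, birth_year=2016, sex="F",
                 population="target", natal_site="Reservoir", natal_km=0.0,
                 founder_autozygosity=np.nan, release_year=np.nan)
        )
        return iid

    founders = []
    for _ in range(n_fs_pairs):
        d, s = founder(), founder()
        founders += [d, s]
        a, b = kid(d, s), kid(d, s)
        fs.append((a, b))
    for _ in range(n_hs_pairs):
        d, s1, s2 = founder(), founder(), founder()
        founders += [d, s1, s2]
        a, b = kid(d, s1), kid(d, s2)
        hs.append((a, b))
    frows = [
        dict(id=f, dam=None, sire=None, birth_year=2010, sex="M",
             population="target", natal_site="Reservoir", natal_km=0.0,
             founder_autozygosity=0.0, release_year=np.nan)
        for f in founders
    ]
    cfg = simulate.SimConfig(seed=seed, n_loci=n_loci, missing_call_rate=0.0,
                             target_founder_inbreeding=0.0, source_drift=0.0)
    truth = simulate.PedigreeTruth(
        pd.DataFrame(frows + rows), None, cfg
    )
    g = simulate.drop_genotypes(truth, cfg)
    offspring_ids = [r["id"] for r in rows]
    return g.take_samples(offspring_ids), fs, hs
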