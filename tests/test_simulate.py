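"""Riverscape simulator contracts: determinism, Mendelian gene drop,
configured breeder counts, family sizes, heterozygosity design and
flow-dependent dispersal."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from riverrescue import simulate
from riverrescue.genotypes import MISSING


def small_cfg(**kw):
    base = dict(seed=2, n_loci=300, n_founders=100,
                translocation_schedule=[], cross_population_mating_rate=0.0)
    base.update(kw)
    return simulate.SimConfig(**base)


class TestPedigree:
    def test_same_seed_identical_outputs(self):
        cfg = small_cfg()
        t1, t2 = simulate.simulate_pedigree(cfg), simulate.simulate_pedigree(cfg)
        pd.testing.assert_frame_equal(t1.individuals, t2.individuals)
        g1, g2 = simulate.drop_genotypes(t1, cfg), simulate.drop_genotypes(t2, cfg)
        assert np.array_equal(g1.calls, g2.calls)
        s1, f1 = simulate.render_observations(t1, cfg, g1)
        s2, f2 = simulate.render_observations(t2, cfg, g2)
        pd.testing.assert_frame_equal(s1, s2)
        pd.testing.assert_frame_equal(f1, f2)

    def test_two_breeders_make_one_full_sib_family(self):
        cfg = small_cfg(n_years=1, breeders_per_year={2016: 2},
                        polygamy_extra_pair_frac=0.0)
        truth = simulate.simulate_pedigree(cfg)
        kids = truth.cohort(2016)
        assert len(kids) >= 2
        assert kids["dam"].nunique() == 1 and kids["sire"].nunique() == 1

    def test_realized_breeder_count_matches_configuration(self):
        cfg = small_cfg(n_years=3, n_founders=200,
                        breeders_per_year={y: 50 for y in (2016, 2017, 2018)})
        truth = simulate.simulate_pedigree(cfg)
        assert truth.breeders_by_year["n_breeders"].tolist() == [50, 50, 50]

    def test_breeders_exceeding_pool_names_year(self):
        cfg = small_cfg(n_founders=10, breeders_per_year={y: 40 for y in range(2016, 2021)})
        with pytest.raises(ValueError, match="2016"):
            simulate.simulate_pedigree(cfg)

    def test_offspring_born_after_parents(self):
        truth = simulate.simulate_pedigree(small_cfg())
        by = truth.individuals.set_index("id")["birth_year"]
        off = truth.individuals.dropna(subset=["dam"])
        assert (off["birth_year"].to_numpy() > by.reindex(off["dam"]).to_numpy()).all()


class TestGeneDrop:
    def test_mendelian_consistency_exhaustive(self):
        """No offspring call can oppose a parental homozygote, and two
        homozygous parents determine the offspring call exactly."""
        cfg = small_cfg(missing_call_rate=0.0)
        truth = simulate.simulate_pedigree(cfg)
        g = simulate.drop_genotypes(truth, cfg)
        idx = {s: i for i, s in enumerate(g.samples)}
        off = truth.individuals.dropna(subset=["dam"])
        for _, row in off.iterrows():
            child = g.calls[idx[row["id"]]]
            dam = g.calls[idx[row["dam"]]]
            sire = g.calls[idx[row["sire"]]]
            assert not ((child == 0) & ((dam == 2) | (sire == 2))).any()
            assert not ((child == 2) & ((dam == 0) | (sire == 0))).any()
            both_hom = (dam % 2 == 0) & (sire % 2 == 0)
            assert np.array_equal(
                child[both_hom], (dam[both_hom] + sire[both_hom]) // 2
            )

    def test_missing_calls_injected_at_configured_rate(self):
        cfg = small_cfg(missing_call_rate=0.05, n_loci=2000)
        truth = simulate.simulate_pedigree(cfg)
        g = simulate.drop_genotypes(truth, cfg)
        rate = (g.calls == MISSING).mean()
        assert abs(rate - 0.05) < 0.005

    def test_family_sizes_match_truncated_negative_binomial(self):
        rng = np.random.default_rng(123)
        mean, disp = 5.3, 1.2
        draws = simulate._draw_family_sizes(rng, 5000, mean, disp)
        p = disp / (disp + mean)
        kmax = draws.max()
        ks = np.arange(2, kmax + 1)
        pmf = stats.nbinom.pmf(ks, disp, p)
        pmf = pmf / pmf.sum()
        obs = np.bincount(draws, minlength=kmax + 1)[2:]
        # pool the sparse tail for a valid chi-square
        exp = pmf * len(draws)
        keep = exp >= 5
        obs_p = np.append(obs[keep], obs[~keep].sum())
        exp_p = np.append(exp[keep], exp[~keep].sum())
        chi2 = ((obs_p - exp_p) ** 2 / exp_p).sum()
        pval = stats.chi2.sf(chi2, df=len(obs_p) - 1)
        assert pval > 0.01

    def test_target_source_heterozygosity_ratio(self):
        """Raw founder panels reproduce the configured PHt deficit within 5%."""
        ratios = []
        for seed in (21, 22, 23):
            cfg = small_cfg(
                seed=seed, n_loci=5000, n_years=1, breeders_per_year={2016: 2},
                translocation_schedule=[(2016, 60, ("Vanitys",))],
                missing_call_rate=0.0,
            )
            truth = simulate.simulate_pedigree(cfg)
            g = simulate.drop_genotypes(truth, cfg)
            pht = simulate.individual_realized_pht(g)
            pop = truth.individuals.set_index("id")["population"]
            ratios.append(
                pht[pop == "target"].mean() / pht[pop == "source"].mean()
            )
        design = 1.0 - simulate.SimConfig().target_founder_inbreeding
        assert abs(np.mean(ratios) - design) / design < 0.05

    def test_f1_heterozygosity_exceeds_both_parent_groups(self):
        """Crosses between the drifted populations recover ancestral
        diversity, so F1 mean PHt tops both parental means."""
        f1_excess_t, f1_excess_s = [], []
        for seed in range(20):
            rows = []
            for i in range(30):
                for pop in ("target", "source"):
                    rows.append(dict(
                        id=f"{pop[0]}{i}", dam=None, sire=None, birth_year=2010,
                        sex="F" if i % 2 else "M", population=pop,
                        natal_site="Reservoir", natal_km=0.0,
                        founder_autozygosity=(
                            0.382 if pop == "target" else 0.0),
                        release_year=np.nan,
                    ))
            for j in range(20):
                rows.append(dict(
                    id=f"x{j}", dam=f"t{2 * (j % 15)}", sire=f"s{2 * (j % 15) + 1}",
                    birth_year=2016, sex="F", population="admixed",
                    natal_site="Reservoir", natal_km=0.0,
                    founder_autozygosity=np.nan, release_year=np.nan,
                ))
            cfg = small_cfg(seed=100 + seed, n_loci=5000, missing_call_rate=0.0)
            truth = simulate.PedigreeTruth(pd.DataFrame(rows), None, cfg)
            g = simulate.drop_genotypes(truth, cfg)
            pht = simulate.individual_realized_pht(g)
            pop = truth.individuals.set_index("id")["population"]
            f1 = pht[pop == "admixed"].mean()
            f1_excess_t.append(f1 - pht[pop == "target"].mean())
            f1_excess_s.append(f1 - pht[pop == "source"].mean())
        assert np.mean(f1_excess_t) > 0
        assert np.mean(f1_excess_s) > 0


class TestObservations:
    def test_gompertz_asymptote_and_inflection(self):
        L = simulate.gompertz_length(np.array([1e9, 1.4]), 350.0, 0.35, 1.4)
        assert L[0] == pytest.approx(350.0)
        assert L[1] == pytest.approx(350.0 / np.e)

    def test_lengths_always_positive(self, riverscape):
        assert (riverscape["samples"]["total_length_mm"] > 0).all()

    def test_dispersal_grows_with_flow(self):
        """Mean displacement between natal and capture site is larger for
        cohorts born in high-flow years."""
        def mean_disp(flow):
            cfg = small_cfg(
                seed=31, n_years=1, n_founders=300,
                breeders_per_year={2016: 100}, family_size_mean=12.0,
                flow_by_year={2016: flow}, dispersal_flow_coef=0.008,
                sample_fraction=1.0, larva_fraction=0.0, n_loci=4,
            )
            truth = simulate.simulate_pedigree(cfg)
            samples, _ = simulate.render_observations(truth, cfg)
            natal = truth.individuals.set_index("id")["natal_km"]
            off = truth.individuals.dropna(subset=["dam"])["id"]
            s = samples[samples["individual_id"].isin(set(off))]
            return (s["river_km"] - s["individual_id"].map(natal)).abs().mean()

        assert mean_disp(300.0) > mean_disp(20.0)

    def test_daily_flow_series_tracks_yearly_means(self):
        cfg = small_cfg()
        flow = simulate.simulate_flow_series(cfg)
        got = flow.assign(year=pd.to_datetime(flow["date"]).dt.year).groupby(
            "year"
        )["discharge_ml_day"].mean()
        for year, mean in cfg.flow_by_year.items():
            assert abs(got[year] - mean) / mean < 0.1
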