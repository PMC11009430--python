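"""Heterozygosity, ordination, ancestry calls, AMOVA and trend models."""

import numpy as np
import pandas as pd
import pytest

from riverrescue import diversity, simulate
from riverrescue.genotypes import MISSING, GenotypeMatrix


class TestPHt:
    def test_worked_examples(self):
        calls = np.array(
            [[0, 1, 2, 1, MISSING], [0, 0, 2, 2, 0]], dtype=np.int8
        )
        het = diversity.individual_heterozygosity(GenotypeMatrix(calls, ["a", "b"]))
        assert het.set_index("sample_id").loc["a", "pht"] == pytest.approx(0.5)
        assert het.set_index("sample_id").loc["b", "pht"] == 0.0

    def test_all_missing_individual_flagged_and_excluded_from_means(self):
        calls = np.array([[1, 1], [MISSING, MISSING]], dtype=np.int8)
        with pytest.warns(UserWarning):
            het = diversity.individual_heterozygosity(GenotypeMatrix(calls, ["a", "b"]))
        assert np.isnan(het.set_index("sample_id").loc["b", "pht"])
        groups = diversity.group_heterozygosity(het, {"a": "g", "b": "g"})
        assert groups.loc[0, "n"] == 1

    def test_group_mean_equals_mean_of_individuals(self, riverscape, riverscape_het):
        pops = riverscape["samples"].set_index("sample_id")["population"]
        groups = diversity.group_heterozygosity(riverscape_het, pops)
        t = groups.set_index("group").loc["target"]
        ids = pops[pops == "target"].index
        manual = riverscape_het.set_index("sample_id")["pht"].reindex(ids).dropna()
        assert t["pht_mean"] == pytest.approx(manual.mean())


def two_population_panel(n_fixed=200, n_shared=100, n_f1=4, seed=0):
    rng = np.random.default_rng(seed)
    p_shared = rng.uniform(0.2, 0.8, n_shared)
    def hw(n, p):
        return ((rng.random((n, len(p))) < p).astype(np.int8)
                + (rng.random((n, len(p))) < p).astype(np.int8))
    a_fixed = np.zeros((30, n_fixed), dtype=np.int8)
    b_fixed = np.full((30, n_fixed), 2, dtype=np.int8)
    f1_fixed = np.ones((n_f1, n_fixed), dtype=np.int8)
    calls = np.vstack(
        [
            np.hstack([a_fixed, hw(30, p_shared)]),
            np.hstack([b_fixed, hw(30, p_shared)]),
            np.hstack([f1_fixed, hw(n_f1, p_shared)]),
        ]
    )
    samples = (
        [f"a{i}" for i in range(30)]
        + [f"b{i}" for i in range(30)]
        + [f"x{i}" for i in range(n_f1)]
    )
    return GenotypeMatrix(calls, samples)


class TestPCoA:
    def test_identical_genotypes_identical_coordinates(self):
        g = two_population_panel()
        rows = [0, 0, 1, 2, 31, 32]
        dup = GenotypeMatrix(
            g.calls[rows], ["c0", "c0b", "a1", "a2", "b1", "b2"], g.loci
        )
        res = diversity.pcoa(dup, k=2)
        c = res.coords.set_index("sample_id")
        np.testing.assert_allclose(
            c.loc["c0", ["PC1", "PC2"]], c.loc["c0b", ["PC1", "PC2"]], atol=1e-8
        )

    def test_fixed_differences_separate_populations_with_f1_between(self):
        res = diversity.pcoa(two_population_panel(), k=2)
        pc1 = res.coords.set_index("sample_id")["PC1"]
        a = pc1[[s for s in pc1.index if s.startswith("a")]]
        b = pc1[[s for s in pc1.index if s.startswith("b")]]
        x = pc1[[s for s in pc1.index if s.startswith("x")]]
        lo, hi = (a, b) if a.mean() < b.mean() else (b, a)
        assert lo.max() < x.min() and x.max() < hi.min()
        assert res.percent_variance[0] > res.percent_variance[1]

    def test_unstructured_population_has_no_dominant_axis(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(0.1, 0.9, 1000)
        calls = ((rng.random((100, 1000)) < p).astype(np.int8)
                 + (rng.random((100, 1000)) < p).astype(np.int8))
        res = diversity.pcoa(GenotypeMatrix(calls, [f"i{k}" for k in range(100)]), k=2)
        assert res.percent_variance[0] / res.percent_variance[1] < 2.0


class TestAncestryClassification:
    def test_reference_center_keeps_reference_label(self):
        g = two_population_panel()
        res = diversity.pcoa(g, k=1)
        refs = {s: ("A" if s.startswith("a") else "B")
                for s in g.samples if not s.startswith("x")}
        out = diversity.classify_ancestry(res, refs)
        assert out.labels["a0"] == "A" and out.labels["b0"] == "B"

    def test_f1s_called_admixed(self):
        g = two_population_panel(n_f1=20, seed=1)
        res = diversity.pcoa(g, k=1)
        refs = {s: ("A" if s.startswith("a") else "B")
                for s in g.samples if not s.startswith("x")}
        out = diversity.classify_ancestry(res, refs)
        f1 = out.labels[[s for s in g.samples if s.startswith("x")]]
        assert (f1 == "admixed").mean() >= 0.95

    def test_simulated_admixture_recovered(self, riverscape):
        """Mixed-ancestry fish land between the population clusters on PC1
        and are labelled admixed."""
        g = riverscape["filtered"]
        pops = riverscape["samples"].set_index("sample_id")["population"]
        res = diversity.pcoa(g, k=1)
        refs = {s: p for s, p in pops.items()
                if p in ("target", "source") and s in g.samples}
        out = diversity.classify_ancestry(res, refs)
        truth_admixed = {s for s, p in pops.items() if p == "admixed"}
        called = set(out.labels[out.labels == "admixed"].index)
        assert len(called & truth_admixed) / len(truth_admixed) >= 0.95

    def test_overlapping_references_refused(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.2, 0.8, 300)
        calls = ((rng.random((40, 300)) < p).astype(np.int8)
                 + (rng.random((40, 300)) < p).astype(np.int8))
        g = GenotypeMatrix(calls, [f"i{k}" for k in range(40)])
        res = diversity.pcoa(g, k=1)
        refs = {f"i{k}": ("A" if k < 20 else "B") for k in range(40)}
        with pytest.raises(ValueError, match="overlap"):
            diversity.classify_ancestry(res, refs)

    def test_admixed_percentage_worked_example(self):
        assert diversity.admixed_percentage(2, 446) == 0.45


class TestAmova:
    def test_fixed_differences_give_maximal_structure(self):
        g = two_population_panel(n_f1=0, n_shared=20)
        groups = {s: s[0] for s in g.samples}
        out = diversity.amova_one_level(g, groups, n_perm=99, seed=0)
        assert out["percent_among"] > 90
        assert out["p_value"] == pytest.approx(1 / 100)

    def test_null_split_shows_no_structure(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0.2, 0.8, 400)
        calls = ((rng.random((60, 400)) < p).astype(np.int8)
                 + (rng.random((60, 400)) < p).astype(np.int8))
        g = GenotypeMatrix(calls, [f"i{k}" for k in range(60)])
        groups = {f"i{k}": ("x" if k < 30 else "y") for k in range(60)}
        out = diversity.amova_one_level(g, groups, n_perm=99, seed=1)
        assert out["percent_among"] < 2.0

    def test_seeded_permutation_p_reproducible(self):
        g = two_population_panel(n_f1=0, n_shared=20)
        groups = {s: s[0] for s in g.samples}
        a = diversity.amova_one_level(g, groups, n_perm=199, seed=42)
        b = diversity.amova_one_level(g, groups, n_perm=199, seed=42)
        assert a == b

    def test_too_few_permutations_refused(self):
        g = two_population_panel(n_f1=0, n_shared=20)
        with pytest.raises(ValueError, match="99"):
            diversity.amova_one_level(g, {s: s[0] for s in g.samples}, n_perm=50)


class TestTrendModels:
    @staticmethod
    def _frame(n=60, slope=-0.001, seed=0, noise=0.0):
        rng = np.random.default_rng(seed)
        km = rng.uniform(0, 18, n)
        birth = rng.integers(2016, 2021, n)
        age = rng.uniform(0.2, 4.0, n)
        pht = 0.09 + slope * km + rng.normal(0, noise, n)
        samples = pd.DataFrame(
            {"sample_id": [f"i{k}" for k in range(n)], "river_km": km,
             "birth_year": birth, "age": age}
        )
        het = pd.DataFrame({"sample_id": samples["sample_id"], "pht": pht})
        return het, samples

    def test_exact_linear_relation_recovered(self):
        het, samples = self._frame(noise=0.0)
        out = diversity.diversity_trend_models(het, samples)
        m = out["pht_vs_river_km"]
        assert m["slopes"]["river_km"] == pytest.approx(-0.001, rel=1e-9)
        assert m["r2_adj"] == pytest.approx(1.0)

    def test_upstream_declining_diversity_detected(self):
        """Founders with an upstream-increasing autozygosity gradient show a
        significant negative PHt-vs-km slope in most replicates."""
        hits = 0
        for seed in range(10):
            cfg = simulate.SimConfig(
                seed=700 + seed, n_loci=600, n_founders=400, n_years=1,
                breeders_per_year={2016: 2}, translocation_schedule=[],
                cross_population_mating_rate=0.0,
                site_inbreeding_gradient=0.02,
                founder_sample_fraction=1.0, sample_fraction=0.0,
            )
            truth = simulate.simulate_pedigree(cfg)
            g = simulate.drop_genotypes(truth, cfg)
            samples, _ = simulate.render_observations(truth, cfg, g)
            founders = truth.individuals[truth.individuals["dam"].isna()]
            s = samples[samples["individual_id"].isin(set(founders["id"]))].copy()
            s["birth_year"] = s["individual_id"].map(
                truth.individuals.set_index("id")["birth_year"]
            )
            s["age"] = 2016 - s["birth_year"]
            het = diversity.individual_heterozygosity(
                g.take_samples(list(s["sample_id"]))
            )
            out = diversity.diversity_trend_models(het, s)
            m = out["pht_vs_river_km"]
            if m["slopes"]["river_km"] < 0 and m["p_values"]["river_km"] < 0.05:
                hits += 1
        assert hits >= 9

    def test_null_gradient_false_positive_rate(self):
        """Without a spatial gradient the km slope rejects at ~5%."""
        rng = np.random.default_rng(99)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            het, samples = self._frame(n=120, slope=0.0, noise=0.008,
                                       seed=rng.integers(2**31))
            out = diversity.diversity_trend_models(het, samples)
            if out["pht_vs_river_km"]["p_values"]["river_km"] < 0.05:
                hits += 1
        assert 0.01 <= hits / n_rep <= 0.10

    def test_cohort_anova_with_tukey_reported(self, riverscape, riverscape_het):
        truth = riverscape["truth"]
        s = riverscape["samples"].copy()
        by = truth.individuals.set_index("id")["birth_year"]
        s["birth_year"] = s["individual_id"].map(by)
        s = s[s["birth_year"] >= 2016]
        s["age"] = 2021 - s["birth_year"]
        out = diversity.diversity_trend_models(riverscape_het, s)
        assert "anova_p" in out["pht_by_cohort"]
        assert len(out["pht_by_cohort"]["tukey"]) >= 3
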