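"""Duplicate detection, relatedness calibration, sibship clustering and
exclusion parentage against gene-drop ground truth."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_fs_hs_panel
from riverrescue import kinship, simulate
from riverrescue.genotypes import MISSING, GenotypeMatrix


@pytest.fixture(scope="module")
def fs_hs_panel():
    return make_fs_hs_panel(seed=4, n_loci=2000, n_fs_pairs=500, n_hs_pairs=500)


@pytest.fixture(scope="module")
def fs_relatedness(fs_hs_panel):
    g, fs, hs = fs_hs_panel
    return kinship.pairwise_relatedness(g), fs, hs


class TestDuplicates:
    def test_copy_with_missing_calls_detected(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.1, 0.9, 500)
        base = ((rng.random((5, 500)) < p).astype(np.int8)
                + (rng.random((5, 500)) < p).astype(np.int8))
        copy = base[0].copy()
        copy[rng.random(500) < 0.05] = MISSING
        calls = np.vstack([base, copy])
        g = GenotypeMatrix(calls, ["a", "b", "c", "d", "e", "a_recap"])
        sets = kinship.find_duplicates(g, min_match=0.95)
        assert sets == [{"a", "a_recap"}]

    def test_full_sibs_not_merged(self, fs_hs_panel):
        g, fs, _ = fs_hs_panel
        sub = g.take_samples([fs[0][0], fs[0][1], fs[1][0], fs[1][1]])
        assert kinship.find_duplicates(sub, min_match=0.995) == []

    def test_min_match_domain(self, fs_hs_panel):
        g, _, _ = fs_hs_panel
        with pytest.raises(ValueError):
            kinship.find_duplicates(g, min_match=0.5)


class TestRelatedness:
    def test_self_relatedness_near_one(self, fs_relatedness):
        rel, _, _ = fs_relatedness
        assert abs(np.nanmean(np.diag(rel.r)) - 1.0) < 0.05

    def test_full_sib_mean_near_half(self, fs_relatedness):
        rel, fs, _ = fs_relatedness
        idx = {s: i for i, s in enumerate(rel.samples)}
        vals = [rel.r[idx[a], idx[b]] for a, b in fs]
        assert 0.47 <= np.mean(vals) <= 0.53

    def test_half_sib_mean_near_quarter(self, fs_relatedness):
        rel, _, hs = fs_relatedness
        idx = {s: i for i, s in enumerate(rel.samples)}
        vals = [rel.r[idx[a], idx[b]] for a, b in hs]
        assert 0.22 <= np.mean(vals) <= 0.28

    def test_unrelated_mean_near_zero(self, fs_relatedness):
        rel, fs, hs = fs_relatedness
        related = {frozenset(p) for p in fs} | {frozenset(p) for p in hs}
        rng = np.random.default_rng(1)
        idx = rng.integers(0, len(rel.samples), size=(4000, 2))
        vals = [
            rel.r[i, j]
            for i, j in idx
            if i != j and frozenset((rel.samples[i], rel.samples[j])) not in related
        ]
        assert abs(np.mean(vals)) <= 0.02

    def test_monomorphic_only_input_refused(self):
        g = GenotypeMatrix(np.zeros((4, 10), dtype=np.int8), list("abcd"))
        with pytest.raises(ValueError, match="monomorphic"):
            kinship.pairwise_relatedness(g)


class TestFamilyClustering:
    def test_two_disjoint_families_recovered_exactly(self):
        # two 5-member families, gene-dropped directly, plus an unrelated
        # reference panel supplying honest allele frequencies
        rows, frows = [], []
        for k in range(100):
            frows.append(dict(id=f"ref{k}", dam=None, sire=None, birth_year=2010,
                              sex="M", population="target", natal_site="Reservoir",
                              natal_km=0.0, founder_autozygosity=0.0,
                              release_year=np.nan))
        for fam, (d, s) in enumerate([("D1", "S1"), ("D2", "S2")]):
            frows += [
                dict(id=x, dam=None, sire=None, birth_year=2010, sex="F",
                     population="target", natal_site="Reservoir", natal_km=0.0,
                     founder_autozygosity=0.0, release_year=np.nan)
                for x in (d, s)
            ]
            for j in range(5):
                rows.append(dict(id=f"f{fam}k{j}", dam=d, sire=s, birth_year=2016,
                                 sex="F", population="target",
                                 natal_site="Reservoir", natal_km=0.0,
                                 founder_autozygosity=np.nan, release_year=np.nan))
        cfg = simulate.SimConfig(seed=13, n_loci=2000, missing_call_rate=0.0,
                                 target_founder_inbreeding=0.0, source_drift=0.0)
        truth = simulate.PedigreeTruth(pd.DataFrame(frows + rows), None, cfg)
        full = simulate.drop_genotypes(truth, cfg)
        g = full.take_samples([r["id"] for r in rows])
        ref = full.take_samples([f"ref{k}" for k in range(100)])
        # a 10-fish two-family sample cannot estimate population
        # frequencies on its own
        rel = kinship.pairwise_relatedness(g, allele_freq=ref.alt_allele_freq())
        fams = kinship.cluster_full_sib_families(rel, seed=0)
        members = sorted(sorted(m) for m in fams.family_members().values())
        assert members == [
            [f"f0k{j}" for j in range(5)], [f"f1k{j}" for j in range(5)]
        ]

    def test_exact_threshold_pair_is_an_edge(self):
        r = np.array([[1.0, 0.35], [0.35, 1.0]])
        rel = kinship.RelatednessMatrix(r=r, n_loci=np.full((2, 2), 1000),
                                        samples=["a", "b"])
        fams = kinship.cluster_full_sib_families(rel, n_replicates=1, seed=0)
        assert fams.family_members() == {"F0001": {"a", "b"}}

    def test_cross_cohort_component_flagged(self):
        r = np.full((3, 3), 0.5)
        np.fill_diagonal(r, 1.0)
        rel = kinship.RelatednessMatrix(r=r, n_loci=np.full((3, 3), 1000),
                                        samples=["a", "b", "c"])
        fams = kinship.cluster_full_sib_families(
            rel, cohorts={"a": 2016, "b": 2016, "c": 2019}, n_replicates=1, seed=0
        )
        assert fams.flagged_families == ["F0001"]

    def test_seeded_clustering_deterministic(self, fs_relatedness):
        rel, _, _ = fs_relatedness
        sub_idx = list(range(60))
        small = kinship.RelatednessMatrix(
            r=rel.r[np.ix_(sub_idx, sub_idx)],
            n_loci=rel.n_loci[np.ix_(sub_idx, sub_idx)],
            samples=[rel.samples[i] for i in sub_idx],
        )
        a = kinship.cluster_full_sib_families(small, seed=5)
        b = kinship.cluster_full_sib_families(small, seed=5)
        pd.testing.assert_frame_equal(a.families, b.families)

    def test_few_loci_degrade_gracefully_with_report(self):
        g, fs, _ = make_fs_hs_panel(seed=21, n_loci=200, n_fs_pairs=30,
                                    n_hs_pairs=30)
        rel = kinship.pairwise_relatedness(g)
        fams = kinship.cluster_full_sib_families(rel, seed=1)
        assert "support" in fams.families.columns
        assert fams.families["support"].between(0, 1).all()



@pytest.fixture(scope="module")
def trio_panel():
    """Two offspring sharing one sampled parent, plus unrelated candidates."""
    rows = [
        dict(id=i, dam=None, sire=None, birth_year=2010, sex=x, population="target",
             natal_site="Reservoir", natal_km=0.0, founder_autozygosity=0.0,
             release_year=np.nan)
        for i, x in [("shared_sire", "M"), ("damA", "F"), ("damB", "F")]
        + [(f"u{k}", "M") for k in range(10)]
    ]
    rows += [
        dict(id="off1", dam="damA", sire="shared_sire", birth_year=2016, sex="F",
             population="target", natal_site="Reservoir", natal_km=0.0,
             founder_autozygosity=np.nan, release_year=np.nan),
        dict(id="off2", dam="damB", sire="shared_sire", birth_year=2016, sex="F",
             population="target", natal_site="Reservoir", natal_km=0.0,
             founder_autozygosity=np.nan, release_year=np.nan),
    ]
    cfg = simulate.SimConfig(seed=31, n_loci=2000, missing_call_rate=0.0,
                             target_founder_inbreeding=0.0, source_drift=0.0,
                             founder_beta=(2.0, 2.0), founder_freq_min=0.2)
    truth = simulate.PedigreeTruth(pd.DataFrame(rows), None, cfg)
    g = simulate.drop_genotypes(truth, cfg)
    return g, truth


class TestParentage:
    def test_true_parent_has_zero_opposing_homozygotes(self, trio_panel):
        g, _ = trio_panel
        off = g.take_samples(["off1"])
        cand = g.take_samples(["shared_sire"])
        counts, comp = kinship.opposing_homozygote_counts(off, cand)
        assert counts[0, 0] == 0

    def test_unrelated_counts_match_brute_force_expectation(self, trio_panel):
        """Expected opposing homozygotes for an unrelated pair is
        sum(2 p^2 q^2) over loci, computed from the realized frequencies."""
        g, _ = trio_panel
        off = g.take_samples(["off1", "off2"])
        cand = g.take_samples([f"u{k}" for k in range(10)])
        counts, comp = kinship.opposing_homozygote_counts(off, cand)
        p = g.alt_allele_freq()
        expected = float((2 * p**2 * (1 - p) ** 2).sum())
        assert abs(counts.mean() - expected) / expected < 0.25
        tol = kinship.exclusion_tolerance(comp, kinship.ErrorModel())
        assert (counts > tol).all()  # every unrelated candidate rejected

    def test_shared_parent_reported_for_both_offspring(self, trio_panel):
        g, _ = trio_panel
        off = g.take_samples(["off1", "off2"])
        cand = g.take_samples(["shared_sire"] + [f"u{k}" for k in range(10)])
        out = kinship.assign_parentage(off, cand)
        assert (out["parent"] == "shared_sire").all()
        hs = kinship.shared_parent_half_sibs(out)
        assert set(hs.iloc[0][["a", "b"]]) == {"off1", "off2"}

    def test_unsampled_parent_reported_when_no_candidate_fits(self, trio_panel):
        g, _ = trio_panel
        off = g.take_samples(["off1"])
        cand = g.take_samples([f"u{k}" for k in range(10)])
        out = kinship.assign_parentage(off, cand)
        assert not out.loc[0, "accepted"] and out.loc[0, "parent"] is None

    def test_offspring_excluded_as_own_candidate(self, trio_panel):
        g, _ = trio_panel
        off = g.take_samples(["off1"])
        cand = g.take_samples(["off1", "shared_sire"])
        out = kinship.assign_parentage(off, cand)
        assert out.loc[0, "parent"] == "shared_sire"

    def test_tolerance_scales_linearly_with_locus_count(self):
        em = kinship.ErrorModel()
        t = [float(kinship.exclusion_tolerance(n, em)) for n in (500, 1000, 2000)]
        assert t[0] < t[1] < t[2]
        assert 1.5 <= t[1] / t[0] <= 2.5 and 1.5 <= t[2] / t[1] <= 2.5

    def test_error_model_domain(self):
        with pytest.raises(ValueError):
            kinship.ErrorModel(dropout_rate=0.5)
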