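"""Duplicate detection, relatedness, sibship clustering and exclusion parentage.

Pairwise relatedness uses an allele-frequency-weighted product-moment
estimator (Queller-Goodnight family): genotypes are centred at twice the
sample allele frequency and scaled by the binomial SD, and the per-pair
mean cross-product over pairwise-complete loci estimates the relationship
coefficient r (0 unrelated, 0.25 half-sibs, 0.5 full-sibs or
parent-offspring, ~1 self).  Full-sib families are connected components of
the r >= threshold graph, stabilized over seeded replicate runs.
Parentage is by opposing-homozygote exclusion with a binomial tolerance
from the genotyping error model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .genotypes import GenotypeMatrix

#: defaults mirror the midpoints between relationship expectation tiers
FULL_SIB_MIN = 0.35
HALF_SIB_BAND = (0.15, 0.35)


@dataclass
class ErrorModel:
    """Genotyping error rates used for the parentage exclusion tolerance."""

    dropout_rate: float = 0.01
    other_error_rate: float = 0.001

    def __post_init__(self):
        for v in (self.dropout_rate, self.other_error_rate):
            if not (0 <= v <= 0.1):
                raise ValueError("error rates must lie in [0, 0.1]")

    @property
    def per_locus(self) -> float:
        return self.dropout_rate + self.other_error_rate


@dataclass
class RelatednessMatrix:
    r: np.ndarray  # symmetric, NaN where undefined
    n_loci: np.ndarray  # pairwise-complete locus counts
    samples: list[str]

    def pair(self, a: str, b: str) -> float:
        i, j = self.samples.index(a), self.samples.index(b)
        return float(self.r[i, j])


@dataclass
class FamilySet:
    """Inferred duplicate sets, parent-offspring pairs and full-sib families."""

    duplicate_sets: list = field(default_factory=list)  # list of sets of sample ids
    parent_offspring: pd.DataFrame | None = None
    families: pd.DataFrame | None = None  # family_id, member, cohort, support
    flagged_families: list = field(default_factory=list)  # cross-cohort suspects
    half_sib_pairs: pd.DataFrame | None = None

    def family_members(self) -> dict:
        out = {}
        if self.families is not None:
            for fid, grp in self.families.groupby("family_id"):
                out[fid] = set(grp["member"])
        return out

    def n_sib_dyads(self) -> int:
        return sum(
            len(m) * (len(m) - 1) // 2 for m in self.family_members().values()
        )


# ---------------------------------------------------------------------------
# duplicates
# ---------------------------------------------------------------------------

def find_duplicates(
    g: GenotypeMatrix, min_match: float = 0.95, min_comparable: int = 100
) -> list[set]:
    """Merge samples whose call concordance exceeds ``min_match``.

    Concordance is the fraction of identical calls over pairwise-complete
    loci; qualifying pairs are merged by transitive closure.  Pairs with
    fewer than ``min_comparable`` shared loci are excluded with a warning.
    """
    if not (0.9 < min_match <= 1.0):
        raise ValueError("min_match must lie in (0.9, 1]")
    obs = g.observed()
    match = np.zeros((g.n_samples, g.n_samples))
    for v in (0, 1, 2):
        b = ((g.calls == v) & obs).astype(np.float32)
        match += b @ b.T
    comp = obs.astype(np.float32) @ obs.astype(np.float32).T
    with np.errstate(invalid="ignore"):
        conc = match / comp
    thin = (comp < min_comparable) & (comp > 0)
    np.fill_diagonal(thin, False)
    if thin.any():
        warnings.warn(
            f"{int(thin.sum() // 2)} pair(s) with <{min_comparable} comparable loci excluded"
        )
    adj = (conc >= min_match) & ~thin & (comp >= 1)
    np.fill_diagonal(adj, False)
    n_comp, lab = connected_components(csr_matrix(adj), directed=False)
    out = []
    for c in range(n_comp):
        members = {g.samples[i] for i in np.flatnonzero(lab == c)}
        if len(members) > 1:
            out.append(members)
    return out


# ---------------------------------------------------------------------------
# relatedness
# ---------------------------------------------------------------------------

def pairwise_relatedness(
    g: GenotypeMatrix, allele_freq: np.ndarray | None = None
) -> RelatednessMatrix:
    """Allele-frequency-weighted pairwise relatedness over complete loci.

    Frequencies default to the sample estimate (adequate for the large
    mixed samples the pipeline feeds in); for small or family-structured
    panels pass reference frequencies via ``allele_freq`` (aligned to the
    locus table).  Monomorphic loci carry no information and are dropped;
    if none remain the estimate is undefined and an error is raised.
    """
    if allele_freq is not None:
        allele_freq = np.asarray(allele_freq, dtype=float)
        if len(allele_freq) != g.n_loci:
            raise ValueError("allele_freq length does not match locus count")
        poly = (allele_freq > 0) & (allele_freq < 1)
    else:
        poly = ~g.is_monomorphic()
    if not poly.any():
        raise ValueError("relatedness undefined: all loci monomorphic")
    keep = np.flatnonzero(poly)
    p_ref = allele_freq[keep] if allele_freq is not None else None
    g = g.subset(locus_idx=keep)
    p = p_ref if p_ref is not None else g.alt_allele_freq()
    obs = g.observed()
    # ratio-of-sums weighting: rare loci contribute little information and
    # would dominate the variance under per-locus standardization
    w = np.where(obs, g.calls - 2.0 * p[None, :], 0.0)
    m = obs.astype(np.float64)
    h = 2.0 * p * (1.0 - p)
    num = w @ w.T
    denom = (m * h[None, :]) @ m.T
    n = m @ m.T
    with np.errstate(invalid="ignore", divide="ignore"):
        r = num / denom
    r[n == 0] = np.nan
    if np.isnan(r).any():
        warnings.warn("pair(s) with no shared loci flagged as NaN")
    return RelatednessMatrix(r=r, n_loci=n.astype(int), samples=list(g.samples))


# ---------------------------------------------------------------------------
# full-sib clustering
# ---------------------------------------------------------------------------

def cluster_full_sib_families(
    r: RelatednessMatrix,
    cohorts: dict | None = None,
    full_sib_min: float = FULL_SIB_MIN,
    half_sib_band: tuple = HALF_SIB_BAND,
    n_replicates: int = 5,
    min_support_runs: int = 3,
    seed: int = 0,
    threshold_jitter: float = 0.03,
) -> FamilySet:
    """Full-sib families as stabilized connected components of the r-graph.

    Each replicate perturbs the threshold by a seeded uniform jitter and
    recomputes components; a pair is kept iff it lands in the same family
    in at least ``min_support_runs`` replicates (with a single replicate
    the closed, unjittered threshold applies: r exactly at the threshold
    is an edge).  Because a single borderline half-sib edge would chain
    two families together, every component is refined by average-linkage
    clustering cut at the same threshold: families merge only when their
    *average* cross relatedness reaches full-sib level.  Families mixing
    cohorts more than one year apart are flagged — such clusters may
    represent other relationships.
    """
    if not (half_sib_band[0] < half_sib_band[1] <= full_sib_min):
        raise ValueError("half_sib_band must lie below full_sib_min")
    rng = np.random.default_rng(seed)
    rr = np.array(r.r, dtype=float)
    np.fill_diagonal(rr, -np.inf)
    rr = np.where(np.isnan(rr), -np.inf, rr)
    n = len(r.samples)

    support = np.zeros((n, n), dtype=np.int32)
    for rep in range(n_replicates):
        thr = full_sib_min
        if n_replicates > 1:
            thr = full_sib_min + rng.uniform(-threshold_jitter, threshold_jitter)
        lab = _families_at_threshold(rr, thr)
        same = lab[:, None] == lab[None, :]
        support += same  # pair credited when it lands in one family this run

    keep = support >= min(min_support_runs, n_replicates)
    np.fill_diagonal(keep, False)
    n_comp, lab = connected_components(csr_matrix(keep), directed=False)

    rows = []
    flagged = []
    fam_counter = 0
    for c in range(n_comp):
        members = [r.samples[i] for i in np.flatnonzero(lab == c)]
        if len(members) < 2:
            continue
        fam_counter += 1
        fid = f"F{fam_counter:04d}"
        cohort_vals = [cohorts.get(m) for m in members] if cohorts else [None] * len(members)
        known = [c_ for c_ in cohort_vals if c_ is not None]
        modal = max(set(known), key=known.count) if known else None
        modal_frac = known.count(modal) / len(known) if known else np.nan
        if known and (max(known) - min(known) > 1):
            flagged.append(fid)
        idx = [r.samples.index(m) for m in members]
        for m, cv in zip(members, cohort_vals):
            i = r.samples.index(m)
            sup = [
                support[i, j] / n_replicates for j in idx if j != i and keep[i, j]
            ]
            rows.append(
                dict(
                    family_id=fid,
                    member=m,
                    cohort=cv,
                    modal_cohort=modal,
                    modal_cohort_frac=modal_frac,
                    support=float(np.mean(sup)) if sup else 1.0,
                )
            )
    fams = pd.DataFrame(
        rows, columns=["family_id", "member", "cohort", "modal_cohort",
                       "modal_cohort_frac", "support"]
    )
    return FamilySet(families=fams, flagged_families=flagged)


def _families_at_threshold(rr: np.ndarray, thr: float) -> np.ndarray:
    """Component labels at threshold, refined by average linkage.

    Connected components of the r >= thr graph, then each multi-member
    component is re-cut with average-linkage hierarchical clustering at
    distance 1 - thr (inclusive), so one spurious edge cannot chain two
    families whose average cross relatedness is sub-threshold.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    adj = rr >= thr
    n_comp, lab = connected_components(csr_matrix(adj), directed=False)
    out = lab.copy()
    next_label = n_comp
    for c in range(n_comp):
        idx = np.flatnonzero(lab == c)
        if len(idx) < 3:
            continue
        sub = rr[np.ix_(idx, idx)].copy()
        sub = np.where(np.isfinite(sub), sub, -1.0)
        d = np.maximum(1.0 - sub, 0.0)  # r > 1 (duplicates) => distance 0
        np.fill_diagonal(d, 0.0)
        z = linkage(squareform(d, checks=False), method="average")
        cl = fcluster(z, t=1.0 - thr, criterion="distance")
        for u in np.unique(cl):
            members = idx[cl == u]
            out[members] = next_label
            next_label += 1
    return out


def half_sib_band_pairs(
    r: RelatednessMatrix, band: tuple = HALF_SIB_BAND
) -> pd.DataFrame:
    """Pairs whose relatedness falls in the half-sib band [lo, hi)."""
    lo, hi = band
    iu = np.triu_indices(len(r.samples), k=1)
    vals = r.r[iu]
    sel = (vals >= lo) & (vals < hi)
    return pd.DataFrame(
        {
            "a": [r.samples[i] for i in iu[0][sel]],
            "b": [r.samples[j] for j in iu[1][sel]],
            "r": vals[sel],
        }
    )


# ---------------------------------------------------------------------------
# exclusion parentage
# ---------------------------------------------------------------------------

def opposing_homozygote_counts(
    offspring: GenotypeMatrix, candidates: GenotypeMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """(counts, comparable-locus counts) for every offspring x candidate pair."""
    shared = [l for l in offspring.loci["locus_id"] if l in set(candidates.loci["locus_id"])]
    if not shared:
        raise ValueError("offspring and candidates share no loci")
    o_idx = {l: i for i, l in enumerate(offspring.loci["locus_id"])}
    c_idx = {l: i for i, l in enumerate(candidates.loci["locus_id"])}
    go = offspring.calls[:, [o_idx[l] for l in shared]]
    gc = candidates.calls[:, [c_idx[l] for l in shared]]
    o0 = (go == 0).astype(np.float32)
    o2 = (go == 2).astype(np.float32)
    c0 = (gc == 0).astype(np.float32)
    c2 = (gc == 2).astype(np.float32)
    counts = o0 @ c2.T + o2 @ c0.T
    comp = (go >= 0).astype(np.float32) @ (gc >= 0).astype(np.float32).T
    return counts.astype(int), comp.astype(int)


def exclusion_tolerance(n_loci, error_model: ErrorModel, quantile: float = 0.999):
    """Opposing-homozygote tolerance: binomial quantile at the error rate.

    A true parent-offspring pair shows an opposing homozygote only through
    genotyping error (dropout + other), so the acceptance cap is the
    ``quantile`` point of Binomial(n_loci, per-locus error).
    """
    return stats.binom.ppf(quantile, np.asarray(n_loci), error_model.per_locus)


def assign_parentage(
    offspring: GenotypeMatrix,
    candidates: GenotypeMatrix,
    errors: ErrorModel | None = None,
) -> pd.DataFrame:
    """Exclusion-based parentage: fewest opposing homozygotes wins.

    A candidate is accepted when its opposing-homozygote count does not
    exceed the binomial tolerance implied by the error model at the number
    of comparable loci; among accepted candidates the minimal count wins.
    Offspring with no accepted candidate are reported with parent ``None``
    (parent unsampled).  A candidate with the offspring's own sample id is
    excluded.
    """
    errors = errors or ErrorModel()
    counts, comp = opposing_homozygote_counts(offspring, candidates)
    tol = exclusion_tolerance(comp, errors)
    rows = []
    cand_ids = np.array(candidates.samples)
    for i, off_id in enumerate(offspring.samples):
        ok = (counts[i] <= tol[i]) & (cand_ids != off_id)
        if not ok.any():
            rows.append(
                dict(offspring=off_id, parent=None, opposing_homozygotes=np.nan,
                     n_loci=int(comp[i].max()), accepted=False)
            )
            continue
        order = np.flatnonzero(ok)
        best = order[np.argmin(counts[i, order])]
        rows.append(
            dict(
                offspring=off_id,
                parent=cand_ids[best],
                opposing_homozygotes=int(counts[i, best]),
                n_loci=int(comp[i, best]),
                accepted=True,
            )
        )
    return pd.DataFrame(rows)


def shared_parent_half_sibs(parentage: pd.DataFrame) -> pd.DataFrame:
    """Offspring pairs sharing an assigned parent (reported as half-sibs)."""
    acc = parentage[parentage["accepted"]]
    rows = []
    for parent, grp in acc.groupby("parent"):
        kids = sorted(grp["offspring"])
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                rows.append(dict(a=kids[i], b=kids[j], shared_parent=parent))
    return pd.DataFrame(rows, columns=["a", "b", "shared_parent"])
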