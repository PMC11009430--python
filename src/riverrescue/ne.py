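"""Effective-number-of-breeders estimation and life-history adjustment.

Two single-cohort estimators:

* **LD method** — the weighted mean squared correlation of unphased
  genotype counts across locus pairs (composite LD), bias-corrected by
  the small-sample expectation E[r^2 | S] and inverted to an estimate of
  the effective number of breeders N_b via the standard random-mating
  quadratic.  Confidence intervals come from a delete-one-individual
  jackknife on the corrected mean r^2.
* **Sibship-frequency method** — the fraction Q of offspring dyads
  sharing at least one parent; under equal sex ratio and random mating
  Q = 1 - (1 - 2/N_b)^2, inverted as N_b = 2 (1 + sqrt(1 - Q)) / Q.

A cohort-based estimate from an iteroparous, age-structured population is
then adjusted by the life-history regressions of Waples and colleagues:
N_b(adj) = N_b / (1.03 - 0.245 log10(AL/alpha)) and N_e(adj) = N_b(adj) /
(0.485 + 0.758 log10(AL/alpha)), where AL is adult life span and alpha
the age at maturity (23 and 3 years for the study species, giving the
divisor 0.8133 and the ratio 1.156).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix


@dataclass
class LifeHistory:
    """Adult life span and age at maturity, in years."""

    AL: float = 23.0
    alpha: float = 3.0

    def __post_init__(self):
        if not self.AL > self.alpha >= 1:
            raise ValueError("require AL > alpha >= 1")


@dataclass
class NbEstimate:
    method: str  # "LD" or "sibship"
    nb_hat: float  # may be math.inf
    ci: tuple = (math.nan, math.nan)
    S: float = math.nan  # harmonic-mean pairwise-complete sample size
    p_crit: float = math.nan
    n_locus_pairs: int = 0
    r2_mean: float = math.nan
    r2_prime: float = math.nan
    nb_adj: float = math.nan
    ne_adj: float = math.nan
    nb_adj_ci: tuple = (math.nan, math.nan)
    ne_adj_ci: tuple = (math.nan, math.nan)
    divisors: dict = field(default_factory=dict)

    def rounded(self) -> dict:
        """Presentation-layer integers (internal values stay exact)."""

        def r(v):
            return v if not np.isfinite(v) else int(round(v))

        return {
            "nb_hat": r(self.nb_hat),
            "nb_adj": r(self.nb_adj),
            "ne_adj": r(self.ne_adj),
            "ci": tuple(r(v) for v in self.ci),
        }


# ---------------------------------------------------------------------------
# composite-LD r^2
# ---------------------------------------------------------------------------

def _pair_stats(calls: np.ndarray):
    """Sufficient statistics for pairwise-complete genotype correlations.

    Returns full LxL matrices (n, Sx, Sy, Sxy, Sxx, Syy) where entry (i, j)
    sums over individuals with both loci called; Sx is the sum of locus i
    over that set (and Sy its transpose counterpart).
    """
    m = (calls >= 0).astype(np.float64)
    a = np.where(calls >= 0, calls, 0).astype(np.float64)
    a2 = a * a
    n = m.T @ m
    sx = a.T @ m
    sxy = a.T @ a
    sxx = a2.T @ m
    return n, sx, sxy, sxx


def _r2_from_stats(n, sx, sxy, sxx, min_n: int):
    """Pairwise r^2 matrix and validity mask from sufficient statistics."""
    sy = sx.T
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sy
        varx = n * sxx - sx * sx
        vary = n * syy - sy * sy
        # (n/(n-1))^2 matches the Burrows composite-disequilibrium
        # convention the small-sample expectations were calibrated on;
        # capped at 1 so a perfectly duplicated locus reads r^2 = 1
        r2 = np.minimum((cov * cov) / (varx * vary) * (n / (n - 1)) ** 2, 1.0)
    valid = (n >= min_n) & (varx > 0) & (vary > 0)
    return r2, valid


def mean_ld_r2(
    g: GenotypeMatrix, p_crit: float = 0.01, min_pair_ind: int = 10
) -> tuple[float, float, int]:
    """Weighted mean composite-LD r^2 over retained locus pairs.

    Loci with overall-sample minor allele frequency below ``p_crit`` are
    ignored.  Each pair's r^2 is the squared Pearson correlation of the
    {0,1,2} genotype vectors over pairwise-complete individuals; pairs are
    weighted by that individual count.  Returns ``(r2_mean, S, n_pairs)``
    with S the harmonic mean of per-pair counts.
    """
    r2m, S, npairs, _ = _mean_ld_r2_full(g, p_crit, min_pair_ind)
    return r2m, S, npairs


def _mean_ld_r2_full(g: GenotypeMatrix, p_crit: float, min_pair_ind: int):
    keep = np.flatnonzero(g.minor_allele_freq() >= p_crit)
    if len(keep) < 2:
        raise ValueError(f"fewer than 2 loci pass P_crit={p_crit}")
    if g.n_samples < 10:
        raise ValueError("need at least 10 individuals for LD estimation")
    g = g.subset(locus_idx=keep)
    calls = g.calls.astype(np.int16)
    n, sx, sxy, sxx = _pair_stats(calls)
    r2, valid = _r2_from_stats(n, sx, sxy, sxx, min_pair_ind)
    iu = np.triu_indices(calls.shape[1], k=1)
    v = valid[iu]
    if not v.any():
        raise ValueError(
            f"no locus pair with >= {min_pair_ind} pairwise-complete individuals"
        )
    w = n[iu][v]
    r2v = r2[iu][v]
    r2_mean = float(np.average(r2v, weights=w))
    S = float(len(w) / np.sum(1.0 / w))
    return r2_mean, S, int(v.sum()), (calls, n, sx, sxy, sxx, iu, v, min_pair_ind)


def expected_r2(S: float) -> float:
    """Small-sample expectation of r^2 for unlinked loci (sample size S)."""
    if S >= 30:
        return 1.0 / S + 3.19 / S**2
    return 0.0018 + 0.907 / S + 4.44 / S**2


def nb_from_r2_prime(r2p: float, S: float) -> float:
    """Invert corrected mean r^2 to N_b (random-mating calibration)."""
    if r2p <= 0:
        return math.inf
    if S >= 30:
        disc = 1.0 / 9.0 - 2.76 * r2p
        if disc < 0:
            return math.inf
        return (1.0 / 3.0 + math.sqrt(disc)) / (2.0 * r2p)
    disc = 0.308**2 - 2.08 * r2p
    if disc < 0:
        return math.inf
    return (0.308 + math.sqrt(disc)) / (2.0 * r2p)


def ldne(
    g: GenotypeMatrix,
    p_crit: float = 0.01,
    jackknife: bool = True,
    min_pair_ind: int = 10,
) -> NbEstimate:
    """LD-method N_b with optional jackknife-across-individuals CI.

    The delete-one jackknife recomputes the weighted mean r^2 with each
    individual removed (rank-one downdates of the pair statistics), takes
    the jackknife variance of the bias-corrected r^2', and maps the
    normal-theory interval through the monotone N_b transform.
    """
    r2_mean, S, n_pairs, ctx = _mean_ld_r2_full(g, p_crit, min_pair_ind)
    r2p = r2_mean - expected_r2(S)
    nb = nb_from_r2_prime(r2p, S)
    est = NbEstimate(
        method="LD", nb_hat=nb, S=S, p_crit=p_crit, n_locus_pairs=n_pairs,
        r2_mean=r2_mean, r2_prime=r2p,
    )
    if not jackknife:
        return est
    calls, n, sx, sxy, sxx, iu, valid_mask, min_n = ctx
    n_ind = calls.shape[0]
    if not (calls < 0).any():
        thetas = _jackknife_thetas_complete(calls, sxy)
    else:
        thetas = _jackknife_thetas_general(calls, n, sx, sxy, sxx, iu, min_n)
    thetas = np.array(thetas)
    m = len(thetas)
    var_jk = (m - 1) / m * np.sum((thetas - thetas.mean()) ** 2)
    se = math.sqrt(var_jk)
    lo_r2p, hi_r2p = r2p - 1.96 * se, r2p + 1.96 * se
    # N_b is decreasing in r^2', so the CI flips through the transform
    est.ci = (nb_from_r2_prime(hi_r2p, S), nb_from_r2_prime(lo_r2p, S))
    return est


def _jackknife_thetas_complete(calls: np.ndarray, sxy: np.ndarray):
    """Delete-one corrected mean r^2 for matrices without missing calls."""
    n_ind, L = calls.shape
    x = calls.astype(np.float64)
    sx = x.sum(axis=0)
    sxx = (x * x).sum(axis=0)
    thetas = []
    np_ = n_ind - 1
    for k in range(n_ind):
        xk = x[k]
        sxk = sx - xk
        sxyk = sxy - np.outer(xk, xk)
        sxxk = sxx - xk * xk
        cov = np_ * sxyk - np.outer(sxk, sxk)
        var = np_ * sxxk - sxk * sxk
        denom = np.outer(var, var)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.minimum((cov * cov) / denom * (np_ / (np_ - 1)) ** 2, 1.0)
        ok = (var > 0)[:, None] & (var > 0)[None, :]
        np.fill_diagonal(ok, False)
        mean_r2 = float(r2[ok].sum() / ok.sum())  # symmetric: halves cancel
        thetas.append(mean_r2 - expected_r2(np_))
    return thetas


def _jackknife_thetas_general(calls, n, sx, sxy, sxx, iu, min_n):
    thetas = []
    for k in range(calls.shape[0]):
        mk = (calls[k] >= 0).astype(np.float64)
        ak = np.where(calls[k] >= 0, calls[k], 0).astype(np.float64)
        nk = n - np.outer(mk, mk)
        sxk = sx - np.outer(ak, mk)
        sxyk = sxy - np.outer(ak, ak)
        sxxk = sxx - np.outer(ak * ak, mk)
        r2k, validk = _r2_from_stats(nk, sxk, sxyk, sxxk, min_n)
        v = validk[iu]
        if not v.any():
            continue
        w = nk[iu][v]
        r2v = r2k[iu][v]
        Sk = float(len(w) / np.sum(1.0 / w))
        thetas.append(float(np.average(r2v, weights=w)) - expected_r2(Sk))
    return thetas


# ---------------------------------------------------------------------------
# sibship-frequency method
# ---------------------------------------------------------------------------

def nb_from_q(q: float) -> float:
    """N_b from the sib-dyad fraction under equal sex ratio, random mating."""
    if q < 0 or q > 1:
        raise ValueError("Q must lie in [0, 1]")
    if q == 0:
        return math.inf
    return 2.0 * (1.0 + math.sqrt(1.0 - q)) / q


def sibship_nb(
    fs_pairs,
    n_offspring: int,
    hs_pairs=None,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> NbEstimate:
    """Sibship-frequency N_b from full-sib (and shared-parent) dyads.

    ``fs_pairs`` / ``hs_pairs`` are iterables of 2-tuples of offspring ids
    from one cohort.  Q is the fraction of the C(n, 2) offspring dyads
    sharing at least one parent.  The CI is a percentile bootstrap over
    offspring: individuals are resampled with replacement and dyads
    recounted over cross-individual pairs only (pairs of copies of one
    individual are resampling artifacts and are excluded from both the
    numerator and the denominator).
    """
    if n_offspring < 10:
        raise ValueError("need at least 10 offspring")
    if n_bootstrap < 200:
        raise ValueError("n_bootstrap must be >= 200")
    fs = {frozenset(p) for p in fs_pairs if len(set(p)) == 2}
    hs = {frozenset(p) for p in (hs_pairs or []) if len(set(p)) == 2} - fs
    total = n_offspring * (n_offspring - 1) // 2
    q = (len(fs) + len(hs)) / total
    est = NbEstimate(method="sibship", nb_hat=nb_from_q(q), S=n_offspring)
    est.r2_mean = math.nan
    ids = sorted({i for p in fs | hs for i in p})
    id_to_pairs = fs | hs
    rng = np.random.default_rng(seed)
    universe = np.array(ids + [f"__solo{i}" for i in range(n_offspring - len(ids))])
    boots = []
    for _ in range(n_bootstrap):
        take = rng.choice(universe, size=n_offspring, replace=True)
        counts = {}
        for t in take:
            counts[t] = counts.get(t, 0) + 1
        hits = 0
        self_pairs = 0
        items = list(counts.items())
        for i, (a, ca) in enumerate(items):
            self_pairs += ca * (ca - 1) // 2
            for b, cb in items[i + 1 :]:
                if frozenset((a, b)) in id_to_pairs:
                    hits += ca * cb
        denom = total - self_pairs
        boots.append(nb_from_q(min(hits / denom, 1.0)) if denom > 0 else math.inf)
    boots = np.array(boots)
    est.ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    return est


def truth_sib_dyads(pedigree_df, cohort_ids) -> tuple[list, list]:
    """Brute-force full-sib and half-sib dyads from a truth pedigree table."""
    sub = pedigree_df[pedigree_df["id"].isin(set(cohort_ids))]
    recs = list(zip(sub["id"], sub["dam"], sub["sire"]))
    fs, hs = [], []
    for i in range(len(recs)):
        for j in range(i + 1, len(recs)):
            a, da, sa = recs[i]
            b, db, sb = recs[j]
            shared = int(da == db) + int(sa == sb)
            if da == db and sa == sb:
                fs.append((a, b))
            elif da == db or sa == sb:
                hs.append((a, b))
    return fs, hs


# ---------------------------------------------------------------------------
# life-history adjustment
# ---------------------------------------------------------------------------

def adjustment_divisors(lh: LifeHistory) -> tuple[float, float]:
    """(N_b divisor, N_b/N_e ratio) from adult life span and age at maturity."""
    lr = math.log10(lh.AL / lh.alpha)
    divisor_b = 1.03 - 0.245 * lr
    ratio = 0.485 + 0.758 * lr
    if divisor_b <= 0:
        raise ValueError(
            f"life-history divisor {divisor_b:.4f} <= 0 (AL/alpha={lh.AL / lh.alpha:.1f} "
            "outside the calibrated range)"
        )
    return divisor_b, ratio


def adjust_nb(raw: NbEstimate, lh: LifeHistory | None = None) -> NbEstimate:
    """Attach life-history-adjusted N_b(adj) and N_e(adj) (CIs transformed too).

    Infinite estimates propagate as infinite, never NaN.
    """
    lh = lh or LifeHistory()
    divisor_b, ratio = adjustment_divisors(lh)
    raw.divisors = {"nb_divisor": divisor_b, "nb_over_ne": ratio}

    def adj(v):
        return v / divisor_b

    raw.nb_adj = adj(raw.nb_hat)
    raw.ne_adj = raw.nb_adj / ratio
    if all(np.isfinite(c) or math.isinf(c) for c in raw.ci):
        raw.nb_adj_ci = tuple(adj(c) for c in raw.ci)
        raw.ne_adj_ci = tuple(c / ratio for c in raw.nb_adj_ci)
    return raw
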