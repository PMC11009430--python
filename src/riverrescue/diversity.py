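"""Individual heterozygosity, ordination, AMOVA and diversity-trend models.

PHt — the proportion of heterozygous calls among an individual's
non-missing loci — is the working proxy for (lack of) individual
inbreeding throughout the pipeline.  Population structure is assessed by
principal coordinate analysis of standardized genotypes; individuals of
mixed ancestry sit between the two parental clusters on PC1.  A one-level
AMOVA partitions molecular variance among predefined groups with a
permutation test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .genotypes import GenotypeMatrix, mean_imputed


# ---------------------------------------------------------------------------
# heterozygosity
# ---------------------------------------------------------------------------

def individual_heterozygosity(g: GenotypeMatrix) -> pd.DataFrame:
    """Per-individual PHt = (# heterozygous calls) / (# non-missing calls).

    Individuals with no non-missing calls get ``NaN`` (flagged, excluded
    from group means by the aggregation helper).
    """
    obs = g.observed()
    n = obs.sum(axis=1)
    if (n == 0).any():
        warnings.warn("individual(s) with all calls missing flagged with NaN PHt")
    with np.errstate(invalid="ignore"):
        pht = ((g.calls == 1) & obs).sum(axis=1) / n
    pht = np.where(n > 0, pht, np.nan)
    return pd.DataFrame({"sample_id": g.samples, "pht": pht, "n_typed": n})


def group_heterozygosity(het: pd.DataFrame, groups: dict | pd.Series) -> pd.DataFrame:
    """Group mean/SD of PHt, skipping flagged (NaN) individuals."""
    df = het.copy()
    df["group"] = df["sample_id"].map(groups)
    out = (
        df.dropna(subset=["pht", "group"])
        .groupby("group")["pht"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    return out.rename(columns={"mean": "pht_mean", "std": "pht_sd", "count": "n"})


# ---------------------------------------------------------------------------
# ordination and ancestry classification
# ---------------------------------------------------------------------------

@dataclass
class AncestryResult:
    coords: pd.DataFrame  # sample_id + PC1..PCk
    percent_variance: np.ndarray
    labels: pd.Series | None = None  # target / source / admixed


def _standardized(g: GenotypeMatrix) -> np.ndarray:
    x = mean_imputed(g)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def pcoa(g: GenotypeMatrix, k: int = 2) -> AncestryResult:
    """Principal coordinates of standardized genotypes (squared-Euclidean).

    Missing calls are mean-imputed per locus.  PCoA on a Euclidean distance
    matrix equals PCA of the underlying vectors; coordinates come from
    scikit-bio's eigendecomposition of the double-centred matrix.  ``k``
    beyond the available rank is truncated with a warning.
    """
    if g.n_samples < 2:
        raise ValueError("need at least 2 individuals for ordination")
    from scipy.spatial.distance import pdist, squareform
    from skbio.stats.distance import DistanceMatrix
    from skbio.stats.ordination import pcoa as skbio_pcoa

    x = _standardized(g)
    dm = DistanceMatrix(squareform(pdist(x)), ids=g.samples)
    rank = min(g.n_samples - 1, g.n_loci)
    if k > rank:
        warnings.warn(f"k={k} exceeds rank {rank}; truncated")
        k = rank
    res = skbio_pcoa(dm, number_of_dimensions=k)
    coords = res.samples.iloc[:, :k].copy()
    coords.columns = [f"PC{i + 1}" for i in range(k)]
    coords.insert(0, "sample_id", g.samples)
    coords = coords.reset_index(drop=True)
    pct = 100.0 * res.proportion_explained.to_numpy()[:k]
    return AncestryResult(coords=coords, percent_variance=pct)


def classify_ancestry(
    result: AncestryResult,
    reference_labels: dict,
    m_sd: float = 3.0,
) -> AncestryResult:
    """Label individuals target/source/admixed from PC1 reference clusters.

    Cluster centres and SDs come from the reference individuals of each
    population.  An unlabeled individual is "admixed" iff its PC1 value
    lies between the two centres AND more than ``m_sd`` cluster SDs from
    both; otherwise it takes the nearer cluster's label.  Classification
    is refused when the reference clusters overlap on PC1.
    """
    pops = sorted(set(reference_labels.values()))
    if len(pops) != 2:
        raise ValueError("exactly two reference populations required")
    pc1 = result.coords.set_index("sample_id")["PC1"]
    stats_ = {}
    for p in pops:
        ids = [s for s, lab in reference_labels.items() if lab == p and s in pc1.index]
        if not ids:
            raise ValueError(f"reference population {p!r} not represented")
        vals = pc1.loc[ids]
        stats_[p] = (float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0)
    (pa, (ca, sa)), (pb, (cb, sb)) = sorted(stats_.items(), key=lambda kv: kv[1][0])
    if abs(cb - ca) < 3.0 * (sa + sb):
        raise ValueError(
            f"reference clusters overlap on PC1 (centres {ca:.2f}, {cb:.2f}; "
            f"SDs {sa:.2f}, {sb:.2f}): classification refused"
        )
    labels = {}
    for s, v in pc1.items():
        if s in reference_labels:
            labels[s] = reference_labels[s]
            continue
        da, db = abs(v - ca), abs(v - cb)
        between = ca < v < cb
        if between and da > m_sd * max(sa, 1e-12) and db > m_sd * max(sb, 1e-12):
            labels[s] = "admixed"
        else:
            labels[s] = pa if da <= db else pb
    out = pd.Series(labels, name="ancestry").reindex(result.coords["sample_id"].to_numpy())
    return AncestryResult(result.coords, result.percent_variance, labels=out)


def admixed_percentage(n_admixed: int, n_total: int, ndigits: int = 2) -> float:
    """Admixed proportion as a percentage (e.g. 2 of 446 -> 0.45)."""
    return round(100.0 * n_admixed / n_total, ndigits)


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def amova_one_level(
    g: GenotypeMatrix, groups, n_perm: int = 999, seed: int = 0
) -> dict:
    """One-level AMOVA on squared-Euclidean genotype distances.

    Returns the among-group percent of molecular variance and a
    permutation p-value (fraction of label permutations with among-group
    percent >= observed, with the +1 correction).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    labels = pd.Series(groups)
    if labels.index.tolist() != list(range(len(labels))):
        labels = labels.reindex(g.samples)
    codes, uniq = pd.factorize(labels.to_numpy())
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("every group needs at least 2 members")
    x = mean_imputed(g)
    N, k = len(codes), len(uniq)

    def components(code_vec):
        ss_total = float(((x - x.mean(axis=0)) ** 2).sum())
        ss_within = 0.0
        for c in range(k):
            xi = x[code_vec == c]
            ss_within += float(((xi - xi.mean(axis=0)) ** 2).sum())
        n_g = np.bincount(code_vec, minlength=k)
        ms_among = (ss_total - ss_within) / (k - 1)
        ms_within = ss_within / (N - k)
        n0 = (N - (n_g**2).sum() / N) / (k - 1)
        sigma_a = max((ms_among - ms_within) / n0, 0.0)
        sigma_w = ms_within
        pct = 100.0 * sigma_a / (sigma_a + sigma_w) if sigma_a + sigma_w > 0 else 0.0
        return pct

    observed = components(codes)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = codes.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        if components(perm) >= observed:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return {"percent_among": observed, "p_value": p, "n_perm": n_perm}


# ---------------------------------------------------------------------------
# diversity trend models (PHt over time, space and age)
# ---------------------------------------------------------------------------

def _ols_summary(fit) -> dict:
    params = fit.params.drop(labels=["Intercept"], errors="ignore")
    pvals = fit.pvalues.drop(labels=["Intercept"], errors="ignore")
    return {
        "slopes": params.to_dict(),
        "p_values": pvals.to_dict(),
        "r2_adj": float(fit.rsquared_adj),
        "n": int(fit.nobs),
    }


def diversity_trend_models(het: pd.DataFrame, samples: pd.DataFrame) -> dict:
    """Diversity-trend regressions on individual PHt.

    Fits: PHt ~ birth year (drift over time), PHt ~ cohort as category
    (ANOVA + all-pairs Tukey HSD), PHt ~ river km (spatial decline),
    PHt ~ age, and age ~ river km.  ``samples`` must carry
    ``birth_year``, ``river_km`` and ``age`` joined by ``sample_id``.
    """
    df = samples.merge(het[["sample_id", "pht"]], on="sample_id").dropna(
        subset=["pht"]
    )
    for col in ("birth_year", "river_km", "age"):
        if col not in df.columns:
            raise ValueError(f"samples table lacks required column {col!r}")
    out = {}
    specs = {
        "pht_vs_birth_year": ("pht ~ birth_year", "birth_year"),
        "pht_vs_river_km": ("pht ~ river_km", "river_km"),
        "pht_vs_age": ("pht ~ age", "age"),
        "age_vs_river_km": ("age ~ river_km", "river_km"),
    }
    for name, (formula, xvar) in specs.items():
        if df[xvar].nunique() < 3:
            raise ValueError(f"{name}: fewer than 3 distinct values of {xvar}")
        fit = smf.ols(formula, data=df).fit()
        out[name] = _ols_summary(fit)
    # cohort as category: one-way ANOVA with Tukey HSD contrasts
    aov_fit = smf.ols("pht ~ C(birth_year)", data=df).fit()
    aov = sm.stats.anova_lm(aov_fit, typ=2)
    tukey = pairwise_tukeyhsd(df["pht"], df["birth_year"].astype(str))
    out["pht_by_cohort"] = {
        "anova_p": float(aov.loc["C(birth_year)", "PR(>F)"]),
        "r2_adj": float(aov_fit.rsquared_adj),
        "tukey": pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        ).to_dict(orient="records"),
    }
    return out
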