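"""Gompertz growth, length-based cohort assignment and inbreeding-depression models.

Length at age t follows L(t) = L_inf * exp(-exp(-k (t - t0))).  Residuals
from the fitted curve measure whether a fish is longer or shorter than
average for its age and serve as the fitness proxy in the
heterozygosity-fitness (inbreeding depression) regressions: a one-way
cohort ANOVA with Tukey contrasts, a pooled and per-cohort OLS of
residuals on PHt, and a random-intercept (birth year) mixed model.

Cohort convention: spawning is nominally 15 November, so the cohort year
is the calendar year of spawning — larvae sampled in December belong to
that year's cohort, juveniles sampled February-March to the previous
year's.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import optimize, signal, stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .simulate import SPAWN_DAY, SPAWN_MONTH, gompertz_length

AGE_GROUP_LABELS = ["YOY", "1-2YO", "2-3YO", "3-4YO", "older"]


@dataclass
class GrowthFit:
    L_inf: float
    k: float
    t0: float
    residual_sd: float
    converged: bool
    n: int
    sse: float

    def predict(self, ages):
        return gompertz_length(np.asarray(ages, dtype=float), self.L_inf, self.k, self.t0)


def fit_gompertz(ages, lengths) -> GrowthFit:
    """Nonlinear least-squares Gompertz fit with multistart initialization.

    Starts pair an L_inf guess (max length scaled up) with k/t0 from a
    log-linearized pass; a coarse grid backs it up.  Raises on fewer than
    6 points or fewer than 2 distinct ages, and reports the best loss if
    no start converges.
    """
    t = np.asarray(ages, dtype=float)
    y = np.asarray(lengths, dtype=float)
    if len(t) < 6:
        raise ValueError("need at least 6 (age, length) points")
    if len(np.unique(t)) < 2:
        raise ValueError("ages must span at least 2 distinct values")

    starts = []
    for fac in (1.05, 1.2, 1.5):
        L0 = float(y.max()) * fac
        frac = np.clip(y / L0, 1e-6, 1 - 1e-6)
        z = np.log(-np.log(frac))
        slope, intercept, *_ = stats.linregress(t, z)
        if slope < 0:
            k0 = -slope
            t00 = intercept / k0
            starts.append((L0, k0, t00))
        for k0 in (0.2, 0.5, 1.0):
            starts.append((L0, k0, float(np.median(t))))

    best = None
    best_sse = np.inf
    for p0 in starts:
        try:
            popt, _ = optimize.curve_fit(
                gompertz_length, t, y, p0=p0,
                bounds=([1e-6, 1e-6, -10.0], [10 * y.max(), 10.0, 20.0]),
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        sse = float(((y - gompertz_length(t, *popt)) ** 2).sum())
        if sse < best_sse:
            best_sse, best = sse, popt
    if best is None:
        raise RuntimeError("Gompertz fit failed to converge from any start")
    resid = y - gompertz_length(t, *best)
    return GrowthFit(
        L_inf=float(best[0]), k=float(best[1]), t0=float(best[2]),
        residual_sd=float(resid.std(ddof=3)) if len(t) > 3 else np.nan,
        converged=True, n=len(t), sse=best_sse,
    )


def growth_residuals(fit: GrowthFit, samples: pd.DataFrame, ages) -> pd.DataFrame:
    """Observed minus fitted length per individual (mm).

    ``ages`` aligns with ``samples`` rows; rows without a length are
    excluded with a warning.  Carries cohort labels through when present.
    """
    df = samples.copy().reset_index(drop=True)
    df["age"] = np.asarray(ages, dtype=float)
    missing = df["total_length_mm"].isna()
    if missing.any():
        warnings.warn(f"{int(missing.sum())} individual(s) without length excluded")
        df = df[~missing]
    df["residual_mm"] = df["total_length_mm"] - fit.predict(df["age"])
    keep = ["sample_id", "age", "residual_mm"]
    for extra in ("birth_year", "cohort", "population"):
        if extra in df.columns:
            keep.append(extra)
    return df[keep]


# ---------------------------------------------------------------------------
# cohort assignment
# ---------------------------------------------------------------------------

@dataclass
class CohortAssignment:
    assignments: pd.DataFrame  # sample_id, age_group, age_class, birth_year, rule
    recapture_consistency: float  # fraction of recaptured fish with one birth year
    rule: str


def spawning_year(cap: pd.Timestamp) -> int:
    """Calendar year of the spawning event most recently preceding capture."""
    return cap.year if (cap.month, cap.day) >= (SPAWN_MONTH, SPAWN_DAY) else cap.year - 1


def nominal_age(cap: pd.Timestamp, birth_year: int) -> float:
    """Age in years from the nominal spawning date of the birth cohort."""
    return (cap - pd.Timestamp(birth_year, SPAWN_MONTH, SPAWN_DAY)).days / 365.25


def _auto_breaks(lengths: np.ndarray, max_classes: int = 6) -> list[float]:
    """Valley detection on a kernel-smoothed length histogram.

    Finds modes with meaningful prominence and cuts at the density
    minimum between consecutive modes, so sparse tails cannot spawn
    spurious breaks.
    """
    if len(lengths) < 10 or np.ptp(lengths) < 1e-9:
        return []
    kde = stats.gaussian_kde(lengths, bw_method=0.15)
    grid = np.linspace(lengths.min(), lengths.max(), 512)
    dens = kde(grid)
    peaks, _ = signal.find_peaks(dens, prominence=0.05 * dens.max())
    if len(peaks) < 2:
        return []
    if len(peaks) > max_classes:
        order = np.argsort(dens[peaks])[::-1][:max_classes]
        peaks = np.sort(peaks[order])
    cuts = []
    for a, b in zip(peaks, peaks[1:]):
        j = a + int(np.argmin(dens[a:b]))
        cuts.append(float(grid[j]))
    return sorted(cuts)


def assign_cohorts(
    samples: pd.DataFrame,
    breaks="auto",
    ambiguity_band_mm: float = 0.0,
) -> CohortAssignment:
    """Assign age class and birth year from capture date and total length.

    ``breaks`` is either ``"auto"`` (valley detection on the smoothed
    per-capture-window length distribution — operator-reviewable) or a
    mapping ``{(capture_year, window): [cut1, cut2, ...]}`` of increasing
    length cuts, where window is ``"spawn"`` (captures from mid-November
    through January, age class 0 = larvae of the current spawning year)
    or ``"survey"`` (February onward).  Lengths within
    ``ambiguity_band_mm/2`` of a cut are labelled ``uncertain`` rather
    than silently guessed.  Recaptured individuals are checked for a
    consistent birth year.
    """
    df = samples.copy().reset_index(drop=True)
    if "capture_date" not in df.columns or "total_length_mm" not in df.columns:
        raise ValueError("samples need capture_date and total_length_mm")
    cap = pd.to_datetime(df["capture_date"])
    df["_spawn_year"] = [spawning_year(c) for c in cap]
    df["_window"] = ["spawn" if m in (11, 12, 1) else "survey" for m in cap.dt.month]
    df["_win_year"] = df["_spawn_year"]

    rule = "explicit" if breaks != "auto" else "auto"
    rows = []
    for (wy, win), grp in df.groupby(["_win_year", "_window"]):
        lengths = grp["total_length_mm"].to_numpy()
        cuts = (
            _auto_breaks(lengths)
            if breaks == "auto"
            else list(breaks.get((wy, win), [])) or list(breaks.get(win, []))
        )
        cuts = sorted(cuts)
        for idx, L in zip(grp.index, lengths):
            cls = int(np.searchsorted(cuts, L, side="right"))
            uncertain = any(abs(L - c) <= ambiguity_band_mm / 2 for c in cuts)
            # in the spawn window class 0 is this year's larvae; survey-window
            # class 0 fish were born at the previous spawning
            birth = wy - cls
            if uncertain:
                group = "uncertain"
            elif win == "spawn" and cls == 0:
                group = "larva"
            else:
                group = AGE_GROUP_LABELS[min(cls, len(AGE_GROUP_LABELS) - 1)]
            rows.append(
                dict(
                    sample_id=df.loc[idx, "sample_id"],
                    age_class=cls if not uncertain else -1,
                    age_group=group,
                    birth_year=np.nan if uncertain else birth,
                    rule=rule,
                )
            )
    out = pd.DataFrame(rows).set_index("sample_id").reindex(df["sample_id"]).reset_index()

    consistency = 1.0
    if "individual_id" in samples.columns:
        merged = out.merge(
            samples[["sample_id", "individual_id"]], on="sample_id", how="left"
        )
        counts = merged.groupby("individual_id")["sample_id"].nunique()
        recap_ids = counts[counts > 1].index
        sub = merged[merged["individual_id"].isin(recap_ids)].dropna(subset=["birth_year"])
        per = sub.groupby("individual_id")["birth_year"].nunique()
        if len(per):
            consistency = float((per == 1).mean())
    return CohortAssignment(assignments=out, recapture_consistency=consistency, rule=rule)


# ---------------------------------------------------------------------------
# inbreeding-depression regression suite
# ---------------------------------------------------------------------------

def inbreeding_depression_suite(
    residuals: pd.DataFrame,
    het: pd.DataFrame,
    cohort_col: str = "birth_year",
    min_cohort_n: int = 10,
) -> dict:
    """Growth-residual models: cohort ANOVA, PHt regressions, mixed model.

    * cohort ANOVA of residuals (+ Tukey all-pairs contrasts)
    * pooled OLS residual ~ PHt and the same fit per cohort
    * random-intercept mixed model (birth year) with PHt fixed slope,
      REML estimates, plus an ML likelihood-ratio comparison against the
      pooled OLS.
    Cohorts with fewer than ``min_cohort_n`` members are excluded from the
    per-cohort fits with a warning.
    """
    df = residuals.merge(het[["sample_id", "pht"]], on="sample_id").dropna(
        subset=["pht", "residual_mm", cohort_col]
    )
    if df[cohort_col].nunique() < 2:
        raise ValueError("need at least 2 cohorts")
    df = df.rename(columns={cohort_col: "cohort"})
    df["cohort"] = df["cohort"].astype(int)

    out = {}
    aov_fit = smf.ols("residual_mm ~ C(cohort)", data=df).fit()
    aov = sm.stats.anova_lm(aov_fit, typ=2)
    tukey = pairwise_tukeyhsd(df["residual_mm"], df["cohort"].astype(str))
    out["cohort_anova"] = {
        "p": float(aov.loc["C(cohort)", "PR(>F)"]),
        "r2_adj": float(aov_fit.rsquared_adj),
        "percent_variance": 100.0 * float(max(aov_fit.rsquared, 0.0)),
        "tukey": pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        ).to_dict(orient="records"),
    }

    pooled = smf.ols("residual_mm ~ pht", data=df).fit()
    out["pht_pooled"] = {
        "slope": float(pooled.params["pht"]),
        "intercept": float(pooled.params["Intercept"]),
        "p": float(pooled.pvalues["pht"]),
        "r2_adj": float(pooled.rsquared_adj),
        "n": int(pooled.nobs),
    }

    per = {}
    for c, grp in df.groupby("cohort"):
        if len(grp) < min_cohort_n:
            warnings.warn(f"cohort {c}: n={len(grp)} < {min_cohort_n}, excluded")
            continue
        fit = smf.ols("residual_mm ~ pht", data=grp).fit()
        per[int(c)] = {
            "slope": float(fit.params["pht"]),
            "p": float(fit.pvalues["pht"]),
            "r2_adj": float(fit.rsquared_adj),
            "n": int(fit.nobs),
        }
    out["pht_per_cohort"] = per

    mixed = smf.mixedlm("residual_mm ~ pht", data=df, groups=df["cohort"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mfit = mixed.fit(reml=True)
        mfit_ml = mixed.fit(reml=False)
        ols_ll = float(smf.ols("residual_mm ~ pht", data=df).fit().llf)
    lr = 2.0 * (float(mfit_ml.llf) - ols_ll)
    out["pht_mixed"] = {
        "slope": float(mfit.params["pht"]),
        "p": float(mfit.pvalues["pht"]),
        "random_intercept_var": float(mfit.cov_re.iloc[0, 0]),
        "lr_vs_ols": lr,
        # boundary-constrained test: halved chi-square tail
        "lr_p": float(0.5 * stats.chi2.sf(max(lr, 0.0), df=1)),
    }
    return out
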