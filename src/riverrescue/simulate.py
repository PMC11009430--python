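"""Riverscape pedigree, gene-drop and observation simulator.

Emulates the study system: a small, inbred resident population in a 1-D
regulated river augmented by translocations from a larger, more diverse
source population.  Spawning happens once a year (nominally 15 November);
per-year breeder numbers track river flow; mating is polygamous and
produces full-sib families of negative-binomial size; juveniles disperse
along the river with a flow-dependent, downstream-biased kernel; length at
age follows a Gompertz curve with an optional heterozygosity x stress-year
growth effect.  Every stage records ground truth so downstream estimators
can be tested for parameter recovery.

Units: river coordinates in km upstream of the most-downstream site,
lengths in mm, discharge in ML/day, ages in years.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
import yaml

from .genotypes import MISSING, GenotypeMatrix, default_locus_table

#: nominal spawning date (month, day); cohort year = calendar year of spawning
SPAWN_MONTH, SPAWN_DAY = 11, 15

DEFAULT_SITES = [
    ("Reservoir", 0.0),
    ("Condor", 2.5),
    ("Motherhole", 5.0),
    ("Vanitys", 8.0),
    ("Spur", 10.5),
    ("Pipeline", 14.7),
    ("Burkes", 18.0),
]

#: yearly mean discharge (ML/day) for the default five study years
DEFAULT_FLOW = {2016: 222.0, 2017: 97.0, 2018: 48.0, 2019: 52.0, 2020: 130.0}

DEFAULT_TRANSLOCATIONS = [
    (2017, 31, ("Pipeline", "Spur", "Vanitys")),
    (2018, 28, ("Pipeline", "Spur", "Vanitys")),
    (2019, 12, ("Pipeline", "Spur", "Vanitys")),
]


@dataclass
class SimConfig:
    """Study conditions for the riverscape simulator.

    Defaults reproduce the monitored system: five cohort years, seven
    sites over ~18 km, flow-tracking breeder numbers, a source population
    ~1.6x more heterozygous than the target (target founder inbreeding
    F = 0.382 via Balding-Nichols drift), and an adult life span / age at
    maturity of 23 / 3 years.
    """

    n_years: int = 5
    start_year: int = 2016
    sites: list = field(default_factory=lambda: list(DEFAULT_SITES))
    flow_by_year: dict = field(default_factory=lambda: dict(DEFAULT_FLOW))
    breeders_per_year: dict | None = None  # explicit {year: count}; else from flow
    flow_breeder_intercept: float = 20.0
    flow_breeder_slope: float = 0.2  # breeders per ML/day
    polygamy_extra_pair_frac: float = 0.3
    family_size_mean: float = 5.3  # of the >=2-truncated distribution target
    family_size_dispersion: float = 1.2  # negative-binomial size parameter
    mating: str = "family"  # "family" or "random_union" (idealized, Nb ~= census)
    offspring_per_year: int | None = None  # random_union mode only
    n_founders: int = 150
    n_loci: int = 2000
    founder_beta: tuple = (0.3, 7.6)  # ancestral allele-frequency model
    founder_freq_min: float = 0.02  # SNP-panel ascertainment floor
    source_drift: float = 0.05  # source population's own drift from the ancestor
    target_founder_inbreeding: float = 0.382
    source_het_multiplier: float | None = None  # overrides F when given
    site_inbreeding_gradient: float = 0.0  # extra founder autozygosity per km
    translocation_schedule: list = field(
        default_factory=lambda: [tuple(t) for t in DEFAULT_TRANSLOCATIONS]
    )
    cross_population_mating_rate: float = 0.02
    dispersal_base_sd_km: float = 0.5
    dispersal_flow_coef: float = 0.008  # km of kernel SD per ML/day
    dispersal_downstream_bias_km: float = 0.8  # mean downstream drift per year
    growth_L_inf: float = 350.0
    growth_k: float = 0.35
    growth_t0: float = 1.4
    growth_noise_sd: float = 8.0
    stress_years: list = field(default_factory=lambda: [2018])
    inbreeding_growth_slope: float = 340.0  # mm per unit PHt, stress cohorts
    missing_call_rate: float = 0.02
    tag_duplicate_frac: float = 0.15
    low_repro_frac: float = 0.03
    sample_fraction: float = 1.0
    founder_sample_fraction: float = 0.1
    larva_fraction: float = 0.1
    recapture_rate: float = 0.015
    adult_lifespan: float = 23.0  # AL
    age_maturity: float = 3.0  # alpha
    seed: int = 0

    def __post_init__(self):
        probs = [
            self.cross_population_mating_rate,
            self.missing_call_rate,
            self.sample_fraction,
            self.founder_sample_fraction,
            self.larva_fraction,
            self.recapture_rate,
        ]
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        kms = [km for _, km in self.sites]
        if any(k < 0 for k in kms) or any(b <= a for a, b in zip(kms, kms[1:])):
            raise ValueError("site river_km must be non-negative and strictly increasing")
        if not (0 <= self.target_founder_inbreeding < 1):
            raise ValueError("target_founder_inbreeding must be in [0, 1)")
        if self.source_het_multiplier is not None and self.source_het_multiplier <= 1:
            raise ValueError("source_het_multiplier must exceed 1")
        if self.adult_lifespan <= self.age_maturity:
            raise ValueError("adult_lifespan must exceed age_maturity")

    @property
    def years(self) -> list[int]:
        return list(range(self.start_year, self.start_year + self.n_years))

    def breeders_for(self, year: int) -> int:
        if self.breeders_per_year is not None:
            n = int(self.breeders_per_year[year])
        else:
            flow = self.flow_by_year[year]
            n = int(round(self.flow_breeder_intercept + self.flow_breeder_slope * flow))
        if n < 2:
            raise ValueError(f"breeder count for {year} must be >= 2 (got {n})")
        return n - (n % 2)  # pairs of distinct parents: keep it even

    @property
    def founder_inbreeding(self) -> float:
        if self.source_het_multiplier is not None:
            return 1.0 - 1.0 / self.source_het_multiplier
        return self.target_founder_inbreeding

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["sites"] = [list(s) for s in d["sites"]]
        d["translocation_schedule"] = [
            [y, n, list(s)] for y, n, s in d["translocation_schedule"]
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass
class PedigreeTruth:
    """Simulator ground truth: one row per individual plus per-year breeder counts.

    ``individuals`` columns: id, dam, sire (None for founders), birth_year,
    sex, population (target/source/admixed), natal_site, natal_km,
    founder_autozygosity.
    """

    individuals: pd.DataFrame
    breeders_by_year: pd.DataFrame  # year, n_breeders (realized distinct parents)
    config: SimConfig

    def cohort(self, year: int) -> pd.DataFrame:
        return self.individuals[self.individuals["birth_year"] == year]

    def parents_of(self, ind_id: str) -> tuple:
        row = self.individuals.set_index("id").loc[ind_id]
        return row["dam"], row["sire"]


def _site_km(config: SimConfig) -> dict:
    return dict(config.sites)


def _draw_family_sizes(rng, n, mean, dispersion) -> np.ndarray:
    """Negative-binomial family sizes truncated to >= 2 by resampling.

    ``mean`` parameterizes the untruncated distribution; truncation raises
    the realized mean slightly (documented, deterministic given the seed).
    """
    size = dispersion
    p = size / (size + mean)
    out = np.empty(n, dtype=int)
    filled = 0
    while filled < n:
        draw = rng.negative_binomial(size, p, size=2 * (n - filled) + 8)
        draw = draw[draw >= 2][: n - filled]
        out[filled : filled + len(draw)] = draw
        filled += len(draw)
    return out


def _ascertained_freqs(rng, L: int, config: SimConfig) -> np.ndarray:
    """Ancestral allele frequencies for an ascertained (polymorphic) SNP panel.

    Reduced-representation panels only report loci discovered polymorphic,
    so frequencies are Beta draws truncated away from fixation.  The
    default Beta(0.3, 7.6) on [0.02, 0.98] gives an ancestral expected
    heterozygosity of ~0.152; Balding-Nichols drift (a mild
    ``source_drift`` for the source impoundment, a strong deficit for the
    target) then yields source PHt ~0.144 and target ~0.089 — and F1
    crosses recover the ancestral level, exceeding both parents.
    """
    a, b = config.founder_beta
    lo = config.founder_freq_min
    out = np.empty(L)
    filled = 0
    while filled < L:
        draw = rng.beta(a, b, size=2 * (L - filled) + 16)
        draw = draw[(draw >= lo) & (draw <= 1 - lo)][: L - filled]
        out[filled : filled + len(draw)] = draw
        filled += len(draw)
    return out


def simulate_pedigree(config: SimConfig) -> PedigreeTruth:
    """Simulate overlapping-generation breeding over the configured years.

    Each year exactly the configured (even) number of distinct mature
    individuals breed: base monogamous pairs cover every breeder, and a
    configurable fraction of extra (polygamous) pairs re-mate already
    selected breeders, creating half-sib structure without changing the
    distinct-parent count.  Translocated source fish join the mature pool
    in their release year and replace a local parent in a pair with
    probability ``cross_population_mating_rate``.
    """
    rng = np.random.default_rng(config.seed)
    site_names = [s for s, _ in config.sites]
    km = _site_km(config)

    rows = []
    counter = 0

    def new_id(prefix):
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:05d}"

    # founders: resident adults alive (and mostly mature) at the first spawning
    founder_ages = rng.uniform(config.age_maturity, min(config.adult_lifespan, 15.0),
                               size=config.n_founders)
    for a in founder_ages:
        site = site_names[rng.integers(len(site_names))]
        auto = config.founder_inbreeding
        if config.site_inbreeding_gradient > 0:
            auto = min(0.95, auto + config.site_inbreeding_gradient * km[site])
        rows.append(
            dict(
                id=new_id("T"),
                dam=None,
                sire=None,
                birth_year=config.start_year - int(np.ceil(a)),
                sex="F" if rng.random() < 0.5 else "M",
                population="target",
                natal_site=site,
                natal_km=km[site],
                founder_autozygosity=auto,
                release_year=np.nan,
            )
        )

    ped = pd.DataFrame(rows)
    breeder_counts = []

    for year in config.years:
        # translocations arrive before spawning
        for (ty, count, release_sites) in config.translocation_schedule:
            if ty != year:
                continue
            for _ in range(count):
                site = release_sites[rng.integers(len(release_sites))]
                ped.loc[len(ped)] = dict(
                    id=new_id("S"),
                    dam=None,
                    sire=None,
                    birth_year=year - int(rng.integers(3, 7)),
                    sex="F" if rng.random() < 0.5 else "M",
                    population="source",
                    natal_site=site,
                    natal_km=km[site],
                    founder_autozygosity=0.0,
                    release_year=float(year),
                )

        age = year - ped["birth_year"].to_numpy()
        mature = (age >= config.age_maturity) & (age <= config.adult_lifespan)
        local = mature & (ped["population"] != "source").to_numpy()
        src = mature & (ped["population"] == "source").to_numpy()

        n_b = config.breeders_for(year)
        fem = np.flatnonzero(local & (ped["sex"] == "F").to_numpy())
        mal = np.flatnonzero(local & (ped["sex"] == "M").to_numpy())
        n_pairs = n_b // 2
        if len(fem) < n_pairs or len(mal) < n_pairs:
            raise ValueError(
                f"year {year}: {n_b} breeders requested but only "
                f"{len(fem)} mature females / {len(mal)} mature males available"
            )
        dams = rng.choice(fem, size=n_pairs, replace=False)
        sires = rng.choice(mal, size=n_pairs, replace=False)

        # rare cross-population matings: swap one local parent for a source fish
        src_f = list(np.flatnonzero(src & (ped["sex"] == "F").to_numpy()))
        src_m = list(np.flatnonzero(src & (ped["sex"] == "M").to_numpy()))
        rng.shuffle(src_f)
        rng.shuffle(src_m)
        dams, sires = list(dams), list(sires)
        for i in range(n_pairs):
            if rng.random() < config.cross_population_mating_rate:
                if rng.random() < 0.5 and src_f:
                    dams[i] = src_f.pop()
                elif src_m:
                    sires[i] = src_m.pop()

        if config.mating == "random_union":
            # idealized random union: each offspring draws its parents
            # independently, so effective Nb tracks the census breeder count
            n_off = config.offspring_per_year or int(
                round(config.family_size_mean * n_pairs)
            )
            pairs = [
                (dams[rng.integers(n_pairs)], sires[rng.integers(n_pairs)])
                for _ in range(n_off)
            ]
            sizes = np.ones(len(pairs), dtype=int)
        else:
            pairs = list(zip(dams, sires))
            n_extra = int(round(config.polygamy_extra_pair_frac * n_pairs))
            for _ in range(n_extra):
                d = dams[rng.integers(n_pairs)]
                s = sires[rng.integers(n_pairs)]
                pairs.append((d, s))
            sizes = _draw_family_sizes(
                rng, len(pairs), config.family_size_mean, config.family_size_dispersion
            )
        new_rows = []
        for (d_idx, s_idx), fam_size in zip(pairs, sizes):
            dam, sire = ped.iloc[d_idx], ped.iloc[s_idx]
            pops = {dam["population"], sire["population"]}
            pop = "admixed" if len(pops) > 1 else pops.pop()
            if pop == "admixed" or "admixed" in pops:
                pop = "admixed"
            natal = dam["natal_site"]
            for _ in range(fam_size):
                new_rows.append(
                    dict(
                        id=new_id("C"),
                        dam=dam["id"],
                        sire=sire["id"],
                        birth_year=year,
                        sex="F" if rng.random() < 0.5 else "M",
                        population=pop,
                        natal_site=natal,
                        natal_km=km[natal],
                        founder_autozygosity=np.nan,
                        release_year=np.nan,
                    )
                )
        realized = len(set(i for pr in pairs for i in pr))
        breeder_counts.append(dict(year=year, n_breeders=realized))
        ped = pd.concat([ped, pd.DataFrame(new_rows)], ignore_index=True)

    truth = PedigreeTruth(ped, pd.DataFrame(breeder_counts), config)
    _check_acyclic(truth)
    return truth


def _check_acyclic(truth: PedigreeTruth) -> None:
    by = truth.individuals.set_index("id")["birth_year"]
    ind = truth.individuals
    for col in ("dam", "sire"):
        has = ind[col].notna()
        parent_by = by.reindex(ind.loc[has, col]).to_numpy()
        child_by = ind.loc[has, "birth_year"].to_numpy()
        if not (child_by > parent_by).all():
            raise AssertionError("offspring born no later than a parent")


# ---------------------------------------------------------------------------
# gene drop
# ---------------------------------------------------------------------------

def drop_genotypes(pedigree: PedigreeTruth, config: SimConfig) -> GenotypeMatrix:
    """Mendelian gene-drop over the pedigree.

    Source founders are Hardy-Weinberg draws from Beta-distributed allele
    frequencies; target founders come from per-locus Balding-Nichols
    frequencies at the configured founder inbreeding F (drifted relative to
    the source), plus optional individual autozygosity for the upstream
    inbreeding gradient.  Every offspring allele is an independent fair draw
    of one of the corresponding parent's two alleles.
    """
    if config.n_loci < 1:
        raise ValueError("locus count must be >= 1")
    rng = np.random.default_rng(config.seed + 1)
    ind = pedigree.individuals
    n = len(ind)
    L = config.n_loci

    def balding_nichols(p0, f):
        if f <= 0:
            return p0.copy()
        shape = (1.0 - f) / f
        return rng.beta(np.maximum(p0 * shape, 1e-6), np.maximum((1 - p0) * shape, 1e-6))

    p_ancestral = _ascertained_freqs(rng, L, config)
    p_source = balding_nichols(p_ancestral, config.source_drift)
    # configured F is the *observed* target deficit relative to the source:
    # 1 - (1-F_abs)/(1-F_s) = F  =>  F_abs = 1 - (1-F)(1-F_s)
    F = config.founder_inbreeding
    f_abs = 1.0 - (1.0 - F) * (1.0 - config.source_drift)
    p_target = balding_nichols(p_ancestral, f_abs)

    calls = np.full((n, L), MISSING, dtype=np.int8)
    idx_of = {s: i for i, s in enumerate(ind["id"])}

    is_founder = ind["dam"].isna().to_numpy()
    founder_rows = np.flatnonzero(is_founder)
    for i in founder_rows:
        row = ind.iloc[i]
        p = p_source if row["population"] == "source" else p_target
        auto = row["founder_autozygosity"]
        g = rng.binomial(1, p) + rng.binomial(1, p)
        extra = auto - config.founder_inbreeding if row["population"] == "target" else 0.0
        if extra and extra > 0:
            autoz = rng.random(L) < extra
            one = rng.binomial(1, p[autoz])
            g[autoz] = 2 * one
        calls[i] = g

    # offspring cohort by cohort (parents always from earlier years)
    for year in sorted(ind.loc[~is_founder, "birth_year"].unique()):
        rows = np.flatnonzero((~is_founder) & (ind["birth_year"] == year).to_numpy())
        dam_idx = np.array([idx_of[d] for d in ind.iloc[rows]["dam"]])
        sire_idx = np.array([idx_of[s] for s in ind.iloc[rows]["sire"]])
        gd = calls[dam_idx].astype(np.int16)
        gs = calls[sire_idx].astype(np.int16)
        if (gd == MISSING).any() or (gs == MISSING).any():
            raise AssertionError("parent genotyped after offspring")
        off = rng.binomial(1, gd / 2.0) + rng.binomial(1, gs / 2.0)
        calls[rows] = off.astype(np.int8)

    if config.missing_call_rate > 0:
        mask = rng.random(calls.shape) < config.missing_call_rate
        calls[mask] = MISSING

    loci = default_locus_table(L)
    # a fraction of tags carry two SNPs (pseudo-replicated within a fragment)
    n_dup = int(config.tag_duplicate_frac * L / 2)
    if n_dup > 0:
        first = rng.choice(L - 1, size=n_dup, replace=False)
        tags = loci["tag_id"].to_numpy().copy()
        tags[first + 1] = tags[first]
        loci["tag_id"] = tags
    repro = 1.0 - np.abs(rng.normal(0, 0.003, size=L))
    low = rng.random(L) < config.low_repro_frac
    repro[low] = rng.uniform(0.85, 0.99, size=low.sum())
    loci["reproducibility"] = np.clip(repro, 0.0, 1.0)
    loci["info_score"] = rng.uniform(0.3, 1.0, size=L)

    return GenotypeMatrix(calls, list(ind["id"]), loci)


# ---------------------------------------------------------------------------
# observation rendering
# ---------------------------------------------------------------------------

def gompertz_length(age, L_inf, k, t0):
    age = np.asarray(age, dtype=float)
    return L_inf * np.exp(-np.exp(-k * (age - t0)))


def _spawn_date(year: int) -> date:
    return date(year, SPAWN_MONTH, SPAWN_DAY)


def individual_realized_pht(g: GenotypeMatrix) -> pd.Series:
    obs = g.observed()
    het = (g.calls == 1) & obs
    with np.errstate(invalid="ignore"):
        pht = het.sum(axis=1) / obs.sum(axis=1)
    return pd.Series(pht, index=g.samples)


def render_observations(
    pedigree: PedigreeTruth, config: SimConfig, genotypes: GenotypeMatrix | None = None
):
    """Capture events, lengths and a daily flow series.

    Returns ``(sample_table, flow_series)``.  The sample table carries one
    row per capture event: ``sample_id, individual_id, population, site,
    river_km, capture_date, total_length_mm`` (individual_id is a truth
    key used only for recapture bookkeeping and validation).  When the
    genotype matrix is supplied, stress-year cohorts get the configured
    heterozygosity x growth effect computed from each fish's realized PHt.
    """
    rng = np.random.default_rng(config.seed + 2)
    ind = pedigree.individuals
    km_vals = np.array([k for _, k in config.sites])
    names = [s for s, _ in config.sites]
    last_capture_year = config.start_year + config.n_years  # one season past final cohort

    pht = None
    if genotypes is not None:
        pht = individual_realized_pht(genotypes)

    # per-cohort mean PHt, so the stress effect is centred within cohort
    cohort_mean_pht = {}
    if pht is not None:
        for y in config.stress_years:
            ids = ind.loc[ind["birth_year"] == y, "id"]
            if len(ids):
                cohort_mean_pht[y] = float(pht.reindex(ids).mean())

    rows = []

    def add_capture(row, cap_date, suffix=""):
        birth = int(row["birth_year"])
        age = (cap_date - _spawn_date(birth)).days / 365.25
        if age <= 0:
            return False
        mean_len = gompertz_length(age, config.growth_L_inf, config.growth_k, config.growth_t0)
        if pht is not None and birth in config.stress_years:
            mean_len = mean_len + config.inbreeding_growth_slope * (
                pht[row["id"]] - cohort_mean_pht[birth]
            )
        length = rng.normal(mean_len, config.growth_noise_sd)
        while length <= 1.0:  # never emit non-positive length
            length = rng.normal(mean_len, config.growth_noise_sd)
        flow = config.flow_by_year.get(birth, np.mean(list(config.flow_by_year.values())))
        # displacement accumulates with time at large: downstream drift per
        # year of age, spread growing with sqrt(age) and with flow at birth
        sd = config.dispersal_base_sd_km + config.dispersal_flow_coef * flow
        disp = rng.normal(
            -config.dispersal_downstream_bias_km * age, sd * np.sqrt(age)
        )
        pos = np.clip(row["natal_km"] + disp, km_vals[0], km_vals[-1])
        site_i = int(np.argmin(np.abs(km_vals - pos)))
        rows.append(
            dict(
                sample_id=row["id"] + suffix,
                individual_id=row["id"],
                population=row["population"],
                site=names[site_i],
                river_km=km_vals[site_i],
                capture_date=cap_date.isoformat(),
                total_length_mm=float(length),
            )
        )
        return True

    sim_years = set(config.years)
    for _, row in ind.iterrows():
        birth = int(row["birth_year"])
        if birth in sim_years and row["dam"] is not None and not pd.isna(row["dam"]):
            if rng.random() >= config.sample_fraction:
                continue
            if rng.random() < config.larva_fraction:
                cap = date(birth, 12, 10) + timedelta(days=int(rng.integers(0, 10)))
                add_capture(row, cap)
                continue
            age_group = rng.choice([0, 1, 2], p=[0.6, 0.3, 0.1])
            cap_year = min(birth + 1 + age_group, last_capture_year)
            cap = date(cap_year, 2, 1) + timedelta(days=int(rng.integers(0, 59)))
            ok = add_capture(row, cap)
            if ok and rng.random() < config.recapture_rate:
                re_year = cap_year + int(rng.integers(1, 3))
                if re_year <= last_capture_year:
                    re_cap = date(re_year, 2, 1) + timedelta(days=int(rng.integers(0, 59)))
                    add_capture(row, re_cap, suffix="_b")
        elif row["population"] == "source" and not pd.isna(row.get("release_year", np.nan)):
            # translocated fish are measured and tissue-sampled at release
            ry = int(row["release_year"])
            cap = date(ry, 10, 1) + timedelta(days=int(rng.integers(0, 14)))
            age = (cap - _spawn_date(int(row["birth_year"]))).days / 365.25
            length = rng.normal(
                gompertz_length(age, config.growth_L_inf, config.growth_k, config.growth_t0),
                config.growth_noise_sd,
            )
            rows.append(
                dict(
                    sample_id=row["id"],
                    individual_id=row["id"],
                    population="source",
                    site=row["natal_site"],
                    river_km=row["natal_km"],
                    capture_date=cap.isoformat(),
                    total_length_mm=float(max(length, 1.0)),
                )
            )
        elif row["population"] != "source" and pd.isna(row["dam"]):
            if rng.random() < config.founder_sample_fraction:
                cap_year = int(rng.integers(config.start_year, last_capture_year + 1))
                cap = date(cap_year, 2, 1) + timedelta(days=int(rng.integers(0, 59)))
                add_capture(row, cap)

    samples = pd.DataFrame(
        rows,
        columns=[
            "sample_id",
            "individual_id",
            "population",
            "site",
            "river_km",
            "capture_date",
            "total_length_mm",
        ],
    )
    flow = simulate_flow_series(config, rng)
    return samples, flow


def simulate_flow_series(config: SimConfig, rng=None) -> pd.DataFrame:
    """Daily discharge around the configured yearly means (lognormal noise)."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    sigma = 0.4
    recs = []
    for year in sorted(config.flow_by_year):
        mean = config.flow_by_year[year]
        d = date(year, 1, 1)
        while d.year == year:
            q = mean * np.exp(rng.normal(0, sigma) - sigma**2 / 2)
            recs.append(dict(date=d.isoformat(), discharge_ml_day=float(q)))
            d += timedelta(days=1)
    return pd.DataFrame(recs)


def observed_genotypes(
    g: GenotypeMatrix, samples: pd.DataFrame, config: SimConfig
) -> GenotypeMatrix:
    """Genotype matrix with one entry per capture event.

    Recaptured fish were tissue-sampled and genotyped at each capture, so
    a recapture contributes a second, independently missing copy of the
    same genome — the substrate for duplicate detection.
    """
    rng = np.random.default_rng(config.seed + 4)
    base = {s: i for i, s in enumerate(g.samples)}
    calls = np.empty((len(samples), g.n_loci), dtype=np.int8)
    for r, (sid, iid) in enumerate(zip(samples["sample_id"], samples["individual_id"])):
        col = g.calls[base[iid]].copy()
        if sid != iid:  # recapture event: fresh assay, fresh missingness
            extra = rng.random(g.n_loci) < config.missing_call_rate
            col[extra] = MISSING
        calls[r] = col
    return GenotypeMatrix(calls, list(samples["sample_id"]), g.loci.copy())


def simulate_ld_reference_cohort(
    n_breeders: int,
    n_offspring: int,
    n_loci: int,
    seed: int = 0,
    n_generations: int = 5,
    freq_range: tuple = (0.05, 0.95),
    missing_call_rate: float = 0.0,
) -> GenotypeMatrix:
    """Single cohort bred at a constant effective size, at drift-LD equilibrium.

    Validation cohorts for LD-based breeder estimation must carry the
    *equilibrium* level of linkage disequilibrium for unlinked loci: a
    cohort whose parents were drawn fresh from an unstructured pool holds
    only one generation of drift LD (~3/4 of equilibrium, since unlinked
    LD decays by half per generation and equilibrates at 4/3 of the
    per-generation input).  This helper burns in ``n_generations`` of
    discrete random-union generations at ``n_breeders`` (equal sex ratio)
    before emitting ``n_offspring`` genotypes from the final spawning.
    Allele frequencies start uniform on ``freq_range`` — the
    common-allele spectrum the LD small-sample calibrations were built
    on.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(*freq_range, size=n_loci)
    pool = (rng.random((max(n_breeders, 2), n_loci)) < p).astype(np.int8) + (
        rng.random((max(n_breeders, 2), n_loci)) < p
    ).astype(np.int8)
    half = n_breeders // 2
    for gen in range(n_generations):
        last = gen == n_generations - 1
        n_out = n_offspring if last else n_breeders
        dams = pool[:half][rng.integers(half, size=n_out)]
        sires = pool[half:][rng.integers(n_breeders - half, size=n_out)]
        pool = (
            rng.binomial(1, dams / 2.0) + rng.binomial(1, sires / 2.0)
        ).astype(np.int8)
    calls = pool
    if missing_call_rate > 0:
        mask = rng.random(calls.shape) < missing_call_rate
        calls = calls.copy()
        calls[mask] = MISSING
    return GenotypeMatrix(calls, [f"o{i:04d}" for i in range(n_out)])


def simulate_rescue_generation(
    n_local_breeders: int,
    n_migrant_breeders: int,
    n_offspring: int = 200,
    n_source_benchmark: int = 80,
    n_loci: int = 2000,
    seed: int = 0,
    config: SimConfig | None = None,
) -> dict:
    """One generation of interbreeding between local and migrant breeders.

    Builds a mixed breeder pool (equal sex ratios within each origin),
    breeds ``n_offspring`` by random union of gametes, gene-drops
    genotypes, and returns mean PHt of the offspring cohort alongside a
    fresh source benchmark sample — the ingredients for recomputing the
    population inbreeding F = 1 - PHt_offspring / PHt_source after the
    prescribed number of effective migrants has bred.
    """
    config = config or SimConfig(seed=seed, n_loci=n_loci, missing_call_rate=0.0)
    config = dataclasses.replace(config, seed=seed, n_loci=n_loci)
    rng = np.random.default_rng(seed + 9)
    rows = []

    def founder(i, pop):
        rows.append(
            dict(
                id=f"{pop[0].upper()}{i:04d}",
                dam=None, sire=None,
                birth_year=config.start_year - 5,
                sex="F" if i % 2 == 0 else "M",
                population=pop,
                natal_site=config.sites[0][0], natal_km=0.0,
                founder_autozygosity=(
                    config.founder_inbreeding if pop == "target" else 0.0
                ),
                release_year=np.nan,
            )
        )

    for i in range(n_local_breeders):
        founder(i, "target")
    for i in range(n_migrant_breeders):
        founder(n_local_breeders + i, "source")
    n_bench_offset = n_local_breeders + n_migrant_breeders
    for i in range(n_source_benchmark):
        founder(n_bench_offset + i, "source")

    pool = pd.DataFrame(rows[: n_local_breeders + n_migrant_breeders])
    fem = pool[pool["sex"] == "F"]["id"].to_numpy()
    mal = pool[pool["sex"] == "M"]["id"].to_numpy()
    for j in range(n_offspring):
        dam = fem[rng.integers(len(fem))]
        sire = mal[rng.integers(len(mal))]
        rows.append(
            dict(
                id=f"O{j:04d}", dam=dam, sire=sire,
                birth_year=config.start_year, sex="F" if j % 2 == 0 else "M",
                population="offspring",
                natal_site=config.sites[0][0], natal_km=0.0,
                founder_autozygosity=np.nan, release_year=np.nan,
            )
        )
    ped = PedigreeTruth(pd.DataFrame(rows), pd.DataFrame(), config)
    g = drop_genotypes(ped, config)
    pht = individual_realized_pht(g)
    ids = ped.individuals.set_index("id")["population"]
    off_mean = float(pht[ids == "offspring"].mean())
    bench_ids = [r["id"] for r in rows[n_bench_offset : n_bench_offset + n_source_benchmark]]
    src_mean = float(pht[bench_ids].mean())
    return {
        "pht_offspring": off_mean,
        "pht_source": src_mean,
        "migrant_fraction_realized": n_migrant_breeders
        / (n_local_breeders + n_migrant_breeders),
    }


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_truth(truth: PedigreeTruth, individuals_path, breeders_path) -> None:
    truth.individuals.to_csv(individuals_path, sep="\t", index=False)
    truth.breeders_by_year.to_csv(breeders_path, sep="\t", index=False)


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def write_flow(flow: pd.DataFrame, path) -> None:
    flow.to_csv(path, sep="\t", index=False)
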