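"""Genetic-rescue planning calculus.

The planning chain converts heterozygosity of the inbred target
population, benchmarked against an assumed-outbred source, into a
required number of migrants:

* population inbreeding  F = 1 - PHt_target / PHt_source
* migrant fraction needed to reach the target inbreeding F_t:
  f = 1 - sqrt(F_t / F)   (so that F_t = F (1 - f)^2)
* effective migrants  N_m = f N_b / (1 - f)  on a breeder base N_b
* census migrants  N_m / (N_e/N)  using the species' effective-to-census
  ratio (0.17 for the study species).

All values are exact floats internally; rounding to integers happens
only at the presentation layer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

#: effective-to-census ratio estimated for the study species
DEFAULT_NE_OVER_N = 0.17
DEFAULT_F_TARGET = 0.1


def inbreeding_from_het(
    pht_target: float, pht_source: float, f_source: float = 0.0
) -> float:
    """Population inbreeding from the heterozygosity ratio.

    F = 1 - PHt_target / PHt_source, with the source assumed outbred by
    default; a known nonzero source inbreeding rescales the benchmark.
    Returns 0 with a warning when the target is not less diverse.
    """
    if pht_target <= 0 or pht_source <= 0:
        raise ValueError("heterozygosities must be positive")
    if not (0 <= f_source < 1):
        raise ValueError("f_source must lie in [0, 1)")
    benchmark = pht_source / (1.0 - f_source)
    if pht_target > benchmark:
        warnings.warn("target heterozygosity exceeds source benchmark; F set to 0")
        return 0.0
    return 1.0 - pht_target / benchmark


def migrant_fraction(f_current: float, f_target: float = DEFAULT_F_TARGET) -> float:
    """Fraction of the augmented population that must derive from migrants."""
    if not (0 <= f_target < 1) or not (0 <= f_current < 1):
        raise ValueError("inbreeding coefficients must lie in [0, 1)")
    if f_target >= f_current:
        warnings.warn("target inbreeding already met; zero migrants needed")
        return 0.0
    return 1.0 - (f_target / f_current) ** 0.5


def migrants_needed(
    f: float, nb: float, ne_over_n: float | None = DEFAULT_NE_OVER_N
) -> tuple[int, int | None]:
    """(effective migrants, census migrants) for migrant fraction f.

    N_m = f N_b / (1 - f); the census figure divides by the
    effective-to-census ratio.  Nearest-integer rounding is applied here,
    at the presentation boundary.
    """
    if not (0 <= f < 1):
        raise ValueError("migrant fraction must lie in [0, 1); f -> 1 is unbounded")
    if nb <= 0:
        raise ValueError("breeder base must be positive")
    nm_eff = int(round(f * nb / (1.0 - f)))
    nm_census = None
    if ne_over_n is not None:
        if not (0 < ne_over_n <= 1):
            raise ValueError("ne_over_n must lie in (0, 1]")
        # census scaling operates on the reported (rounded) effective number
        nm_census = int(round(nm_eff / ne_over_n))
    return nm_eff, nm_census


def expected_effective_breeders(
    release_counts, ne_over_n: float = DEFAULT_NE_OVER_N
) -> tuple[list[int], int]:
    """Expected effective breeders among translocated fish, per release year.

    Each year's value is round(count x ratio); the total sums the rounded
    values (so (31, 28, 12) at 0.17 gives (5, 5, 2), total 12).
    """
    if not (0 < ne_over_n <= 1):
        raise ValueError("ne_over_n must lie in (0, 1]")
    counts = list(release_counts)
    if any(c < 0 for c in counts):
        raise ValueError("release counts must be non-negative")
    per_year = [int(round(c * ne_over_n)) for c in counts]
    return per_year, int(sum(per_year))


@dataclass
class RescuePlan:
    pht_target_mean: float
    pht_source_mean: float
    f_current: float
    f_target: float
    migrant_fraction: float
    nb_base: float
    n_m_effective: int
    ne_over_n: float | None
    n_m_census: int | None
    expected_breeders_per_year: list = field(default_factory=list)
    expected_breeders_total: int | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def build_rescue_plan(
    pht_target: float,
    pht_source: float,
    nb_base: float,
    f_target: float = DEFAULT_F_TARGET,
    ne_over_n: float | None = DEFAULT_NE_OVER_N,
    release_counts=None,
    f_source: float = 0.0,
) -> RescuePlan:
    """Full planning chain from heterozygosity means to migrant numbers."""
    F = inbreeding_from_het(pht_target, pht_source, f_source=f_source)
    f = migrant_fraction(F, f_target)
    if f == 0.0:
        nm_eff, nm_census = 0, 0 if ne_over_n else None
    else:
        nm_eff, nm_census = migrants_needed(f, nb_base, ne_over_n)
    per_year, total = [], None
    if release_counts is not None and ne_over_n is not None:
        per_year, total = expected_effective_breeders(release_counts, ne_over_n)
    return RescuePlan(
        pht_target_mean=pht_target,
        pht_source_mean=pht_source,
        f_current=F,
        f_target=f_target,
        migrant_fraction=f,
        nb_base=nb_base,
        n_m_effective=nm_eff,
        ne_over_n=ne_over_n,
        n_m_census=nm_census,
        expected_breeders_per_year=per_year,
        expected_breeders_total=total,
    )
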