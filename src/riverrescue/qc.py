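"""Locus and individual quality-control filters for SNP genotype matrices.

The standard pipeline removes, in a fixed order: individuals with too much
missing data, loci with low technical reproducibility, loci missing in too
many individuals, monomorphic loci, and all but one SNP per sequencing tag.
A separate filter removes loci whose observed heterozygosity significantly
exceeds 0.5 — the signature of two collapsed (incorrectly merged) loci,
since a single biallelic Hardy-Weinberg locus cannot exceed He = 0.5.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .genotypes import GenotypeMatrix

#: default thresholds used throughout the study pipeline
DEFAULT_PROFILE = dict(
    max_ind_missing=0.3, min_reproducibility=0.95, max_locus_missing=0.2
)
#: stricter profile used upstream of parentage/sibship analyses
PARENTAGE_PROFILE = dict(
    max_ind_missing=0.2, min_reproducibility=0.99, max_locus_missing=0.2
)


@dataclass
class FilterReport:
    """Counts of individuals/loci removed per rule, in application order."""

    steps: list = field(default_factory=list)  # (rule, axis, n_removed)

    def add(self, rule: str, axis: str, n_removed: int) -> None:
        self.steps.append((rule, axis, int(n_removed)))

    def removed(self, rule: str) -> int:
        return sum(n for r, _, n in self.steps if r == rule)

    def total(self, axis: str) -> int:
        return sum(n for _, a, n in self.steps if a == axis)

    def to_dict(self) -> dict:
        return {
            "steps": [
                {"rule": r, "axis": a, "n_removed": n} for r, a, n in self.steps
            ],
            "individuals_removed": self.total("individual"),
            "loci_removed": self.total("locus"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def standard_filters(
    g: GenotypeMatrix,
    max_ind_missing: float = 0.3,
    min_reproducibility: float = 0.95,
    max_locus_missing: float = 0.2,
    one_per_tag: str = "random",
    seed: int = 0,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the standard locus/individual filters in a fixed order.

    Order: individuals by missingness -> loci by reproducibility -> loci by
    missingness -> monomorphic loci -> one SNP per tag.  ``one_per_tag``
    is ``"random"`` (seeded) or ``"best"`` (highest info-content score per
    tag; first wins on ties).  Raises if every locus is removed.
    """
    for thr in (max_ind_missing, min_reproducibility, max_locus_missing):
        if not (0 <= thr <= 1):
            raise ValueError("thresholds must lie in [0, 1]")
    if one_per_tag not in ("random", "best"):
        raise ValueError("one_per_tag must be 'random' or 'best'")
    report = FilterReport()

    keep_ind = np.flatnonzero(g.individual_missing_rate() <= max_ind_missing)
    report.add("individual_missingness", "individual", g.n_samples - len(keep_ind))
    g = g.subset(sample_idx=keep_ind)

    keep = np.flatnonzero(g.loci["reproducibility"].to_numpy() >= min_reproducibility)
    report.add("reproducibility", "locus", g.n_loci - len(keep))
    g = g.subset(locus_idx=keep)

    keep = np.flatnonzero(1.0 - g.locus_call_rate() <= max_locus_missing)
    report.add("locus_missingness", "locus", g.n_loci - len(keep))
    g = g.subset(locus_idx=keep)

    keep = np.flatnonzero(~g.is_monomorphic())
    report.add("monomorphic", "locus", g.n_loci - len(keep))
    g = g.subset(locus_idx=keep)

    rng = np.random.default_rng(seed)
    tags = g.loci["tag_id"].to_numpy()
    info = g.loci["info_score"].to_numpy()
    keep_mask = np.ones(g.n_loci, dtype=bool)
    order = {}
    for j, t in enumerate(tags):
        order.setdefault(t, []).append(j)
    for t, idx in order.items():
        if len(idx) == 1:
            continue
        if one_per_tag == "random":
            chosen = idx[rng.integers(len(idx))]
        else:
            chosen = idx[int(np.argmax(info[idx]))]
        for j in idx:
            keep_mask[j] = j == chosen
    report.add("one_per_tag", "locus", int((~keep_mask).sum()))
    g = g.subset(locus_idx=np.flatnonzero(keep_mask))

    if g.n_loci == 0:
        raise ValueError("all loci removed by standard filters")
    return g, report


def excess_het_filter(
    g: GenotypeMatrix, alpha: float = 0.05
) -> tuple[GenotypeMatrix, FilterReport]:
    """Drop loci with heterozygosity significantly above 0.5.

    One-sided exact binomial test per locus of the observed heterozygote
    count against a null proportion of 0.5 over non-missing calls; loci
    with p < alpha are removed.  Loci with zero non-missing calls are
    skipped with a warning (and retained).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    k, n = g.het_counts()
    report = FilterReport()
    empty = n == 0
    if empty.any():
        warnings.warn(f"{int(empty.sum())} locus/loci with zero non-missing calls skipped")
    # P(X >= k) under Binomial(n, 0.5); sf(k-1) is the upper tail including k
    with np.errstate(invalid="ignore"):
        p = stats.binom.sf(k - 1, np.maximum(n, 1), 0.5)
    drop = (p < alpha) & ~empty
    report.add("excess_heterozygosity", "locus", int(drop.sum()))
    g = g.subset(locus_idx=np.flatnonzero(~drop))
    if g.n_loci == 0:
        raise ValueError("all loci removed by excess-heterozygosity filter")
    return g, report
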