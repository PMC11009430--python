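"""Genotype matrix container and file I/O (VCF and CSV).

Genotypes are biallelic SNP calls coded as the count of alternate alleles
(0, 1, 2) with ``-1`` for a missing call.  Per-locus metadata carries the
reduced-representation tag id, a technical reproducibility score in [0, 1]
and an optional information-content score, which are the operands of the
QC filters.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: columns every locus table carries
LOCUS_COLUMNS = ["locus_id", "tag_id", "reproducibility", "info_score"]


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci with {0,1,2,missing} calls.

    Parameters
    ----------
    calls
        ``int8`` array of shape ``(n_samples, n_loci)``; ``-1`` is missing.
    samples
        Unique sample identifiers, one per row.
    loci
        Per-locus metadata with at least :data:`LOCUS_COLUMNS`.
    """

    calls: np.ndarray
    samples: list[str]
    loci: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.samples = [str(s) for s in self.samples]
        if self.calls.ndim != 2:
            raise ValueError("calls must be 2-D (samples x loci)")
        if len(self.samples) != self.calls.shape[0]:
            raise ValueError("sample count does not match call matrix rows")
        if len(set(self.samples)) != len(self.samples):
            dupes = pd.Series(self.samples)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValueError(f"duplicate sample id(s): {dupes}")
        if self.loci is None:
            self.loci = default_locus_table(self.calls.shape[1])
        self.loci = self.loci.reset_index(drop=True)
        if len(self.loci) != self.calls.shape[1]:
            raise ValueError("locus table length does not match call matrix columns")
        bad = ~np.isin(self.calls, [MISSING, 0, 1, 2])
        if bad.any():
            raise ValueError("calls must be in {-1, 0, 1, 2}")

    # -- basic shape -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.calls.shape[0]

    @property
    def n_loci(self) -> int:
        return self.calls.shape[1]

    def observed(self) -> np.ndarray:
        """Boolean mask of non-missing calls."""
        return self.calls != MISSING

    # -- per-locus / per-individual summaries ----------------------------
    def locus_call_rate(self) -> np.ndarray:
        return self.observed().mean(axis=0)

    def individual_missing_rate(self) -> np.ndarray:
        return 1.0 - self.observed().mean(axis=1)

    def alt_allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per locus, ignoring missing calls."""
        obs = self.observed()
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            p = np.where(obs, self.calls, 0).sum(axis=0) / (2.0 * n)
        return np.where(n > 0, p, np.nan)

    def minor_allele_freq(self) -> np.ndarray:
        p = self.alt_allele_freq()
        return np.minimum(p, 1.0 - p)

    def is_monomorphic(self) -> np.ndarray:
        """True where only one allele is observed (or no calls at all)."""
        maf = self.minor_allele_freq()
        return ~(maf > 0)

    def het_counts(self) -> tuple[np.ndarray, np.ndarray]:
        """(heterozygote count, non-missing count) per locus."""
        return (self.calls == 1).sum(axis=0), self.observed().sum(axis=0)

    # -- subsetting ------------------------------------------------------
    def subset(self, sample_idx=None, locus_idx=None) -> "GenotypeMatrix":
        calls = self.calls
        samples = self.samples
        loci = self.loci
        if sample_idx is not None:
            sample_idx = np.asarray(sample_idx)
            calls = calls[sample_idx, :]
            samples = [self.samples[i] for i in sample_idx]
        if locus_idx is not None:
            locus_idx = np.asarray(locus_idx)
            calls = calls[:, locus_idx]
            loci = loci.iloc[locus_idx]
        return GenotypeMatrix(calls.copy(), list(samples), loci.copy())

    def take_samples(self, ids: list[str]) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"sample id(s) not in matrix: {missing[:5]}")
        return self.subset(sample_idx=[pos[s] for s in ids])

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and list(self.loci["locus_id"]) == list(other.loci["locus_id"])
            and np.array_equal(self.calls, other.calls)
        )


def default_locus_table(n_loci: int) -> pd.DataFrame:
    ids = [f"L{i:05d}" for i in range(n_loci)]
    return pd.DataFrame(
        {
            "locus_id": ids,
            "tag_id": ids,
            "reproducibility": 1.0,
            "info_score": 1.0,
        }
    )


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_genotypes(path, fmt: str, locus_metadata=None) -> GenotypeMatrix:
    """Read a genotype matrix from ``vcf`` or ``csv``.

    CSV layout: first column ``sample_id``, remaining columns one per locus
    with values 0/1/2 and empty or ``NA``/-1 for missing.  ``locus_metadata``
    optionally points at a CSV with columns ``locus_id, tag_id,
    reproducibility, info_score``.

    Multiallelic VCF records are rejected (error names the site).
    """
    if fmt == "vcf":
        return _read_vcf(str(path))
    if fmt == "csv":
        return _read_csv(str(path), locus_metadata)
    raise ValueError(f"unknown format: {fmt!r} (expected 'vcf' or 'csv')")


def _read_vcf(path: str) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample id in VCF header")
    cols, meta = [], []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multiallelic site {var.CHROM}:{var.POS} "
                f"({var.REF}->{','.join(var.ALT)}) not supported"
            )
        # gt_types: 0=hom ref, 1=het, 2=unknown, 3=hom alt
        gt = var.gt_types
        col = np.full(len(samples), MISSING, dtype=np.int8)
        col[gt == 0] = 0
        col[gt == 1] = 1
        col[gt == 3] = 2
        cols.append(col)
        info = dict(var.INFO)
        lid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        meta.append(
            {
                "locus_id": lid,
                "tag_id": str(info.get("TAG", lid)),
                "reproducibility": float(info.get("REPRO", 1.0)),
                "info_score": float(info.get("INFOSCORE", 1.0)),
            }
        )
    if not cols:
        raise ValueError(f"no variant records in {path}")
    calls = np.column_stack(cols)
    return GenotypeMatrix(calls, samples, pd.DataFrame(meta))


def _read_csv(path: str, locus_metadata) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, dtype={0: str})
    except pd.errors.ParserError as exc:  # keep the line number pandas reports
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first CSV column must be 'sample_id'")
    samples = df["sample_id"].tolist()
    body = df.drop(columns=["sample_id"])
    calls = body.to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), MISSING, calls).astype(np.int8)
    loci = None
    if locus_metadata is not None:
        loci = pd.read_csv(locus_metadata)
        missing_cols = [c for c in LOCUS_COLUMNS if c not in loci.columns]
        if missing_cols:
            raise ValueError(f"{locus_metadata}: missing columns {missing_cols}")
        loci = loci.set_index("locus_id").loc[list(body.columns)].reset_index()
    else:
        loci = default_locus_table(calls.shape[1])
        loci["locus_id"] = list(body.columns)
        loci["tag_id"] = list(body.columns)
    return GenotypeMatrix(calls, samples, loci)


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Write a minimal biallelic VCF (GT only, './.' missing)."""
    buf = io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##contig=<ID=1>\n")
    buf.write('##INFO=<ID=TAG,Number=1,Type=String,Description="Tag id">\n')
    buf.write('##INFO=<ID=REPRO,Number=1,Type=Float,Description="Reproducibility">\n')
    buf.write('##INFO=<ID=INFOSCORE,Number=1,Type=Float,Description="Info content">\n')
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(g.samples) + "\n")
    for j in range(g.n_loci):
        rec = g.loci.iloc[j]
        info = (
            f"TAG={rec['tag_id']};REPRO={rec['reproducibility']:.4f};"
            f"INFOSCORE={rec['info_score']:.4f}"
        )
        gts = "\t".join(_GT_CODE[int(c)] for c in g.calls[:, j])
        buf.write(f"1\t{j + 1}\t{rec['locus_id']}\tA\tG\t.\tPASS\t{info}\tGT\t{gts}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def write_csv(g: GenotypeMatrix, path, locus_metadata_path=None) -> None:
    body = pd.DataFrame(
        np.where(g.calls == MISSING, np.nan, g.calls),
        columns=list(g.loci["locus_id"]),
    )
    body.insert(0, "sample_id", g.samples)
    body.to_csv(path, index=False)
    if locus_metadata_path is not None:
        g.loci[LOCUS_COLUMNS].to_csv(locus_metadata_path, index=False)


def mean_imputed(g: GenotypeMatrix) -> np.ndarray:
    """Float calls with missing replaced by the per-locus mean.

    Loci with no observed calls impute to 0 with a warning.
    """
    x = g.calls.astype(float)
    obs = g.observed()
    n = obs.sum(axis=0)
    if (n == 0).any():
        warnings.warn("locus with zero non-missing calls imputed to 0")
    with np.errstate(invalid="ignore"):
        mu = np.where(obs, x, 0).sum(axis=0) / np.maximum(n, 1)
    return np.where(obs, x, mu[None, :])
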