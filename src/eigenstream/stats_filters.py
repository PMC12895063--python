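"""Per-SNP and per-individual statistics and QC filters.

Denominators are sex-chromosome aware: Y-chromosome statistics count
male individuals only (females should carry no Y variants), while
X-chromosome statistics count all individuals.  Symmetrically, the
per-individual missing rate of a non-male individual excludes Y SNPs
from its denominator.  ``--ignore-sex`` treats every chromosome as
autosomal; ``--ignore-unknown`` additionally drops sex=U individuals
from X/Y denominators.

Genotypes are kept diploid-coded throughout (pseudo-haploid data uses
0/2), so allele frequency is always ref_count / (2 * n_obs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import MISSING, EigenstreamError, IndRecord, SnpRecord

logger = logging.getLogger("eigenstream")

DEFAULT_SEX_CHR = (23, 24)


@dataclass
class SnpStats:
    """Per-SNP statistics, one array entry per chunk row.

    ``freq`` is NaN when no genotype was observed; ``missing_rate`` is 1.0
    when the denominator is empty (nothing observable means nothing
    observed).
    """

    n_considered: np.ndarray
    n_obs: np.ndarray
    ref_count: np.ndarray
    freq: np.ndarray
    maf: np.ndarray
    missing_rate: np.ndarray


@dataclass
class IndStats:
    """Per-individual missingness over the SNPs that entered each
    individual's denominator."""

    n_considered: np.ndarray
    n_missing: np.ndarray
    missing_rate: np.ndarray


def considered_matrix(
    chroms: np.ndarray,
    sexes: np.ndarray,
    sex_chr_codes: tuple[int, int] = DEFAULT_SEX_CHR,
    ignore_sex: bool = False,
    ignore_unknown: bool = False,
) -> np.ndarray:
    """Boolean (SNPs x individuals) matrix of cells entering denominators.

    Autosomes and X: all individuals; Y: males only.  With
    ``ignore_unknown``, sex=U individuals are dropped from both X and Y
    rows; with ``ignore_sex`` every row is treated autosomally.
    """
    n_rows, n_cols = len(chroms), len(sexes)
    considered = np.ones((n_rows, n_cols), dtype=bool)
    if ignore_sex:
        return considered
    x_code, y_code = sex_chr_codes
    is_y = chroms == y_code
    not_male = sexes != "M"
    if is_y.any() and not_male.any():
        considered[np.ix_(is_y, not_male)] = False
    if ignore_unknown:
        is_x = chroms == x_code
        unknown = sexes == "U"
        if (is_x | is_y).any() and unknown.any():
            considered[np.ix_(is_x | is_y, unknown)] = False
    return considered


def calculate_snp_stats(
    values: np.ndarray,
    chroms: np.ndarray,
    sexes: np.ndarray,
    sex_chr_codes: tuple[int, int] = DEFAULT_SEX_CHR,
    ignore_sex: bool = False,
    ignore_unknown: bool = False,
) -> SnpStats:
    """Allele frequency, MAF and missing rate for each row of a chunk.

    ``values`` is (SNPs x individuals) over {0,1,2,9}; ``chroms`` aligns
    with rows, ``sexes`` ('M'/'F'/'U') with columns.  The caller must
    already have applied the individual mask: statistics see only
    retained individuals.
    """
    values = np.asarray(values)
    considered = considered_matrix(
        np.asarray(chroms), np.asarray(sexes), sex_chr_codes, ignore_sex, ignore_unknown
    )
    observed = considered & (values != MISSING)
    n_considered = considered.sum(axis=1)
    n_obs = observed.sum(axis=1)
    ref_count = np.where(observed, values, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_obs > 0, ref_count / (2.0 * np.maximum(n_obs, 1)), np.nan)
        missing_rate = np.where(
            n_considered > 0,
            (n_considered - n_obs) / np.maximum(n_considered, 1),
            1.0,
        )
    maf = np.minimum(freq, 1.0 - freq)
    return SnpStats(n_considered, n_obs, ref_count, freq, maf, missing_rate)


# conventional import name
snp_stats = calculate_snp_stats


class IndMissingAccumulator:
    """Accumulate per-individual missingness across chunks.

    Fed with every chunk's surviving rows (after SNP selection, before the
    missing-rate/MAF filters), it reproduces the whole-matrix computation
    exactly regardless of chunk boundaries.
    """

    def __init__(
        self,
        sexes: Sequence[str],
        sex_chr_codes: tuple[int, int] = DEFAULT_SEX_CHR,
        ignore_sex: bool = False,
        ignore_unknown: bool = False,
    ):
        self.sexes = np.asarray(sexes)
        self.sex_chr_codes = sex_chr_codes
        self.ignore_sex = ignore_sex
        self.ignore_unknown = ignore_unknown
        self.n_considered = np.zeros(len(self.sexes), dtype=np.int64)
        self.n_missing = np.zeros(len(self.sexes), dtype=np.int64)

    def update(self, values: np.ndarray, chroms: np.ndarray) -> None:
        considered = considered_matrix(
            np.asarray(chroms), self.sexes, self.sex_chr_codes,
            self.ignore_sex, self.ignore_unknown,
        )
        self.n_considered += considered.sum(axis=0)
        self.n_missing += (considered & (np.asarray(values) == MISSING)).sum(axis=0)

    def finalize(self) -> IndStats:
        empty = self.n_considered == 0
        if empty.any():
            logger.warning(
                "%d individual(s) have no SNPs in their missingness "
                "denominator; rate reported as NA", int(empty.sum()),
            )
        with np.errstate(invalid="ignore"):
            rate = np.where(
                ~empty, self.n_missing / np.maximum(self.n_considered, 1), np.nan
            )
        return IndStats(self.n_considered.copy(), self.n_missing.copy(), rate)


# ---------------------------------------------------------------------------
# sex-chromosome sanitization
# ---------------------------------------------------------------------------

def sex_chr_sanitize(
    values: np.ndarray,
    chroms: np.ndarray,
    sexes: np.ndarray,
    sex_chr_codes: tuple[int, int] = DEFAULT_SEX_CHR,
) -> tuple[np.ndarray, int, int]:
    """Set biologically impossible sex-chromosome genotypes to missing.

    Y-chromosome genotypes of non-male (F/U) individuals and heterozygous
    X-chromosome genotypes of males are replaced by 9.  Returns a fresh
    matrix plus the two change counts (Y, X).
    """
    values = np.asarray(values)
    out = values.copy()
    x_code, y_code = sex_chr_codes
    chroms = np.asarray(chroms)
    sexes = np.asarray(sexes)
    y_rows = chroms == y_code
    x_rows = chroms == x_code
    not_male = sexes != "M"
    male = ~not_male

    n_y = 0
    if y_rows.any() and not_male.any():
        block = out[np.ix_(y_rows, not_male)]
        n_y = int((block != MISSING).sum())
        out[np.ix_(y_rows, not_male)] = MISSING
    n_x = 0
    if x_rows.any() and male.any():
        block = out[np.ix_(x_rows, male)]
        het = block == 1
        n_x = int(het.sum())
        block[het] = MISSING
        out[np.ix_(x_rows, male)] = block
    return out, n_y, n_x


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_geno(stats: SnpStats, threshold: float) -> np.ndarray:
    """Keep decision per SNP under the missing-rate threshold.

    A SNP is removed iff its missing rate strictly exceeds the threshold
    (PLINK convention); a SNP exactly at the threshold is kept.
    """
    if not 0.0 <= threshold <= 1.0:
        raise EigenstreamError(f"--geno threshold must be in [0, 1], got {threshold}")
    return stats.missing_rate <= threshold


def filter_maf(
    stats: SnpStats,
    min_maf: float | None = None,
    max_maf: float | None = None,
) -> np.ndarray:
    """Keep decision per SNP under inclusive MAF bounds.

    A SNP with no observed genotypes has its MAF treated as 0, so any
    positive ``min_maf`` removes it along with monomorphic SNPs.
    """
    for name, bound in (("--min-maf", min_maf), ("--max-maf", max_maf)):
        if bound is not None and not 0.0 <= bound <= 0.5:
            raise EigenstreamError(f"{name} must be in [0, 0.5], got {bound}")
    if min_maf is not None and max_maf is not None and min_maf > max_maf:
        raise EigenstreamError("--min-maf exceeds --max-maf")
    maf = np.where(np.isnan(stats.maf), 0.0, stats.maf)
    keep = np.ones(len(maf), dtype=bool)
    if min_maf is not None:
        keep &= maf >= min_maf
    if max_maf is not None:
        keep &= maf <= max_maf
    return keep


# conventional import name
filter_by_maf = filter_maf


# ---------------------------------------------------------------------------
# report tables
# ---------------------------------------------------------------------------

FREQ_COLUMNS = [
    "snp_id", "chrom", "pos", "allele1", "allele2",
    "n_obs", "freq", "maf", "missing_rate",
]
MISSING_COLUMNS = ["sample_id", "population", "n_considered", "n_missing", "missing_rate"]


def freq_table(snp_slice: Sequence[SnpRecord], stats: SnpStats) -> pd.DataFrame:
    return pd.DataFrame({
        "snp_id": [r.snp_id for r in snp_slice],
        "chrom": [r.chromosome for r in snp_slice],
        "pos": [r.physical_pos for r in snp_slice],
        "allele1": [r.allele1 for r in snp_slice],
        "allele2": [r.allele2 for r in snp_slice],
        "n_obs": stats.n_obs,
        "freq": stats.freq,
        "maf": stats.maf,
        "missing_rate": stats.missing_rate,
    }, columns=FREQ_COLUMNS)


def missing_table(ind_records: Sequence[IndRecord], stats: IndStats) -> pd.DataFrame:
    return pd.DataFrame({
        "sample_id": [r.sample_id for r in ind_records],
        "population": [r.population for r in ind_records],
        "n_considered": stats.n_considered,
        "n_missing": stats.n_missing,
        "missing_rate": stats.missing_rate,
    }, columns=MISSING_COLUMNS)
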