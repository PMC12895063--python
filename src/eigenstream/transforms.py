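"""Genotype-level transformations: random pseudo-haploidization and
allele polarization.

Both functions return fresh arrays/records and never mutate their inputs,
so they compose safely inside the streaming pipeline and as library calls.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import MISSING, EigenstreamError, SnpRecord

logger = logging.getLogger("eigenstream")

REASON_HET = "polarize-het"
REASON_MISSING = "polarize-missing"
REASON_UNMATCHED = "polarize-unmatched"


def random_haploidise(
    values: np.ndarray,
    row_indices: np.ndarray | int,
    seed: int,
) -> np.ndarray:
    """Replace every heterozygous call by a random homozygote.

    Each genotype 1 becomes 0 or 2 with probability 1/2; 0, 2 and 9 are
    untouched — the missingness pattern is preserved exactly and the
    expected allele frequency is unchanged.  The draw for a cell is keyed
    to (seed, absolute SNP row) with one deterministic vector per row, so
    the output is identical for every chunk size.  ``row_indices`` gives
    each row's absolute index in the input dataset (or the offset of the
    first row if the block is contiguous).
    """
    values = np.asarray(values)
    if np.isscalar(row_indices):
        row_indices = np.arange(row_indices, row_indices + values.shape[0])
    out = values.copy()
    n_cols = values.shape[1]
    for i, abs_row in enumerate(np.asarray(row_indices)):
        het = out[i] == 1
        if not het.any():
            continue
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(abs_row)]))
        draws = rng.integers(0, 2, size=n_cols).astype(np.int8) * 2
        out[i, het] = draws[het]
    return out


# ---------------------------------------------------------------------------
# polarization
# ---------------------------------------------------------------------------

@dataclass
class PolarizationSource:
    """Where the ancestral allele of each SNP comes from.

    FILE mode carries a SNP-ID -> ancestral-allele table; SAMPLE mode
    carries the dataset-wide genotype column of the chosen reference
    individual (extracted in a prior pass), indexed by absolute SNP row.
    """

    mode: str  # "FILE" or "SAMPLE"
    table: dict[str, str] | None = None
    sample_id: str | None = None
    reference_column: np.ndarray | None = None


def read_ancestral_table(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column (SNP ID, ancestral allele) file."""
    table: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 2:
                raise EigenstreamError(
                    f"{path}:{lineno}: expected 2 columns (SNP ID, ancestral allele)"
                )
            snp_id, allele = tokens
            if snp_id in table:
                raise EigenstreamError(f"{path}: duplicate SNP ID {snp_id!r}")
            table[snp_id] = allele
    return table


def polarize_chunk(
    values: np.ndarray,
    snp_slice: Sequence[SnpRecord],
    source: PolarizationSource,
    row_offset: int = 0,
) -> tuple[np.ndarray, list[SnpRecord], np.ndarray, list[str | None]]:
    """Re-orient one chunk to ancestral/derived allele order.

    For each SNP the ancestral allele is looked up (FILE mode) or derived
    from the reference individual's genotype (SAMPLE mode: 2 -> allele1,
    0 -> allele2).  SNPs already ancestral-first pass unchanged; SNPs with
    the ancestral allele second have their alleles swapped and every
    non-missing genotype recoded g -> 2-g.  SNPs are excluded when the
    reference genotype is heterozygous or missing, or (FILE mode) when
    the SNP is absent from the table or the listed allele matches neither
    allele.  Matching is case-insensitive; strand mismatches are not
    auto-resolved.

    Returns (kept values, kept records, keep mask, per-row removal reason).
    """
    values = np.asarray(values)
    n = len(snp_slice)
    keep = np.ones(n, dtype=bool)
    reasons: list[str | None] = [None] * n
    flip = np.zeros(n, dtype=bool)

    for i, rec in enumerate(snp_slice):
        if source.mode == "FILE":
            ancestral = source.table.get(rec.snp_id)
            if ancestral is None:
                keep[i] = False
                reasons[i] = REASON_UNMATCHED
                continue
            if ancestral.upper() == rec.allele1.upper():
                pass
            elif ancestral.upper() == rec.allele2.upper():
                flip[i] = True
            else:
                keep[i] = False
                reasons[i] = REASON_UNMATCHED
        else:  # SAMPLE
            g = int(source.reference_column[row_offset + i])
            if g == 1:
                keep[i] = False
                reasons[i] = REASON_HET
            elif g == MISSING:
                keep[i] = False
                reasons[i] = REASON_MISSING
            elif g == 0:
                flip[i] = True
            # g == 2: allele1 already ancestral

    out_values = values[keep].copy()
    out_records: list[SnpRecord] = []
    kept_flip = flip[keep]
    for j, rec in enumerate(r for r, k in zip(snp_slice, keep) if k):
        if kept_flip[j]:
            out_records.append(
                dataclasses.replace(rec, allele1=rec.allele2, allele2=rec.allele1)
            )
        else:
            out_records.append(rec)
    if kept_flip.any():
        rows = out_values[kept_flip]
        out_values[kept_flip] = np.where(rows == MISSING, MISSING, 2 - rows)
    return out_values, out_records, keep, reasons
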