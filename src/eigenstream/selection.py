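"""Individual and SNP selection: keep/remove lists, genomic regions and
chromosome specifications.

The individual mask is computed once, globally, and applied to every
chunk's columns.  SNP-level selection is evaluated per chunk row against
pre-loaded membership sets, interval trees and chromosome sets, in the
order: ID lists, then regions, then chromosomes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from intervaltree import IntervalTree

from .io_formats import EigenstreamError, IndRecord, SnpRecord

logger = logging.getLogger("eigenstream")

DEFAULT_SEX_CHR = (23, 24)  # X, Y integer codes

#: characters stripped from digit groups in region specs: regular space,
#: thin/narrow no-break spaces, no-break space, comma, underscore
_DIGIT_SEPARATORS = re.compile(r"[    ,_]")
_RANGE_DASHES = ("–", "−")  # en dash, minus sign -> plain hyphen


def _normalize_dashes(text: str) -> str:
    for dash in _RANGE_DASHES:
        text = text.replace(dash, "-")
    return text


def parse_chrom_token(token: str, sex_chr_codes: tuple[int, int] = DEFAULT_SEX_CHR) -> int:
    """Parse one chromosome name: optional case-insensitive ``chr`` prefix,
    ``X``/``Y`` mapped to the configured sex codes (default 23/24)."""
    item = token.strip()
    if item.lower().startswith("chr"):
        item = item[3:]
    if item.upper() == "X":
        return sex_chr_codes[0]
    if item.upper() == "Y":
        return sex_chr_codes[1]
    try:
        return int(item)
    except ValueError:
        raise EigenstreamError(
            f"cannot parse chromosome {token!r}"
        ) from None


def parse_chrom_spec(
    text: str, sex_chr_codes: tuple[int, int] = DEFAULT_SEX_CHR
) -> set[int]:
    """Parse a chromosome set like ``"1,2,5-6,22"`` or ``"chr1,chrX"``.

    Ranges accept hyphen or en dash; the result is the union of all items.
    """
    spec = _normalize_dashes(text.strip())
    if not spec:
        raise EigenstreamError("empty chromosome specification")
    out: set[int] = set()
    for item in spec.split(","):
        item = item.strip()
        if not item:
            raise EigenstreamError(f"empty item in chromosome spec {text!r}")
        if "-" in item:
            lo_s, _, hi_s = item.partition("-")
            lo = parse_chrom_token(lo_s, sex_chr_codes)
            hi = parse_chrom_token(hi_s, sex_chr_codes)
            if hi < lo:
                raise EigenstreamError(
                    f"reversed chromosome range {item!r} in {text!r}"
                )
            out.update(range(lo, hi + 1))
        else:
            out.add(parse_chrom_token(item, sex_chr_codes))
    return out


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

@dataclass
class RegionSet:
    """Per-chromosome interval index over 1-based inclusive coordinates."""

    trees: dict[int, IntervalTree] = field(default_factory=dict)
    n_intervals: int = 0

    def add(self, chrom: int, start: int, end: int) -> None:
        if start > end:
            raise EigenstreamError(
                f"region start {start} exceeds end {end} on chromosome {chrom}"
            )
        # intervaltree is half-open; store [start, end] as [start, end+1)
        self.trees.setdefault(chrom, IntervalTree()).addi(start, end + 1)
        self.n_intervals += 1

    def contains(self, chrom: int, pos: int) -> bool:
        tree = self.trees.get(chrom)
        return bool(tree is not None and tree[pos])

    def mask(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        return np.fromiter(
            (self.contains(int(c), int(p)) for c, p in zip(chroms, positions)),
            dtype=bool, count=len(chroms),
        )


def parse_region_inline(
    spec: str, sex_chr_codes: tuple[int, int] = DEFAULT_SEX_CHR
) -> tuple[int, int, int]:
    """Parse an inline region like ``"1:1 000 000-2 000 000"``.

    Digit groups may be separated by spaces (including thin spaces) or
    commas; the range dash may be a hyphen or an en dash.  Coordinates are
    1-based inclusive.
    """
    chrom_s, sep, rest = spec.partition(":")
    if not sep or not rest:
        raise EigenstreamError(f"malformed region {spec!r}; expected CHR:START-END")
    chrom = parse_chrom_token(chrom_s, sex_chr_codes)
    rest = _DIGIT_SEPARATORS.sub("", _normalize_dashes(rest))
    start_s, dash, end_s = rest.partition("-")
    if not dash:
        raise EigenstreamError(f"malformed region {spec!r}; expected CHR:START-END")
    try:
        start, end = int(start_s), int(end_s)
    except ValueError:
        raise EigenstreamError(f"non-integer coordinates in region {spec!r}") from None
    if start > end:
        raise EigenstreamError(f"region start {start} exceeds end {end} in {spec!r}")
    return chrom, start, end


def parse_region_file(
    path: str, sex_chr_codes: tuple[int, int] = DEFAULT_SEX_CHR
) -> RegionSet:
    """Read an interval file with columns (chromosome, start, end).

    Coordinates are 1-based inclusive, except that a ``.bed`` extension
    selects the BED convention (0-based half-open starts, converted by
    adding 1 to the start).  Comment/track lines are skipped.
    """
    is_bed = str(path).lower().endswith(".bed")
    regions = RegionSet()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith(("#", "track", "browser")):
                continue
            tokens = stripped.split()
            if len(tokens) < 3:
                raise EigenstreamError(
                    f"{path}:{lineno}: expected >=3 columns (chrom, start, end)"
                )
            chrom = parse_chrom_token(tokens[0], sex_chr_codes)
            try:
                start, end = int(tokens[1]), int(tokens[2])
            except ValueError:
                raise EigenstreamError(
                    f"{path}:{lineno}: non-integer interval coordinates"
                ) from None
            if is_bed:
                start += 1
            regions.add(chrom, start, end)
    return regions


def build_region_set(
    specs: Sequence[str], sex_chr_codes: tuple[int, int] = DEFAULT_SEX_CHR
) -> RegionSet:
    """Build a RegionSet from a mix of interval-file paths and inline
    ``CHR:START-END`` specifications (an existing file path is read as a
    file; anything else is parsed inline)."""
    import os

    regions = RegionSet()
    for spec in specs:
        if os.path.exists(spec):
            file_regions = parse_region_file(spec, sex_chr_codes)
            for chrom, tree in file_regions.trees.items():
                for iv in tree:
                    regions.add(chrom, iv.begin, iv.end - 1)
        else:
            regions.add(*parse_region_inline(spec, sex_chr_codes))
    return regions


# ---------------------------------------------------------------------------
# individual mask
# ---------------------------------------------------------------------------

def build_individual_mask(
    ind_records: Sequence[IndRecord],
    keep_indv: Sequence[str] | None = None,
    remove_indv: Sequence[str] | None = None,
    keep_pop: Sequence[str] | None = None,
    remove_pop: Sequence[str] | None = None,
) -> np.ndarray:
    """Compute the global per-individual boolean mask.

    Population-level filters are applied first, individual-level filters
    second, so an individual exclusion can refine a population inclusion.
    keep and remove of the same kind are contradictory and refused.
    Unknown names in the lists only trigger a warning.
    """
    if keep_indv is not None and remove_indv is not None:
        raise EigenstreamError("keep-indv and remove-indv are mutually exclusive")
    if keep_pop is not None and remove_pop is not None:
        raise EigenstreamError("keep-pop and remove-pop are mutually exclusive")

    sample_ids = [r.sample_id for r in ind_records]
    populations = [r.population for r in ind_records]
    mask = np.ones(len(ind_records), dtype=bool)

    def warn_unknown(names, universe, kind):
        unknown = set(names) - set(universe)
        if unknown:
            logger.warning(
                "%d %s name(s) in list not present in .ind (e.g. %s)",
                len(unknown), kind, sorted(unknown)[0],
            )

    if keep_pop is not None:
        wanted = set(keep_pop)
        warn_unknown(wanted, populations, "population")
        mask &= np.array([p in wanted for p in populations])
    if remove_pop is not None:
        unwanted = set(remove_pop)
        warn_unknown(unwanted, populations, "population")
        mask &= np.array([p not in unwanted for p in populations])
    if keep_indv is not None:
        wanted = set(keep_indv)
        warn_unknown(wanted, sample_ids, "sample")
        mask &= np.array([s in wanted for s in sample_ids])
    if remove_indv is not None:
        unwanted = set(remove_indv)
        warn_unknown(unwanted, sample_ids, "sample")
        mask &= np.array([s not in unwanted for s in sample_ids])

    if not mask.any():
        raise EigenstreamError("no individuals remain after individual/population filtering")
    return mask


# ---------------------------------------------------------------------------
# SNP mask
# ---------------------------------------------------------------------------

def snp_mask_for_chunk(
    snp_slice: Sequence[SnpRecord],
    keep_snps: set[str] | None = None,
    remove_snps: set[str] | None = None,
    regions_keep: RegionSet | None = None,
    regions_remove: RegionSet | None = None,
    chrom_keep: set[int] | None = None,
    chrom_remove: set[int] | None = None,
) -> tuple[np.ndarray, list[str | None]]:
    """Per-row keep mask for one chunk's SNP records.

    Returns (mask, reasons) where ``reasons[i]`` is the removal reason of
    row ``i`` (``"snp-list"``, ``"region"`` or ``"chromosome"``) or None
    if kept.  ID filters are evaluated before region and chromosome
    filters, so the logged reason reflects the first failing stage.
    """
    n = len(snp_slice)
    mask = np.ones(n, dtype=bool)
    reasons: list[str | None] = [None] * n
    for i, r in enumerate(snp_slice):
        if keep_snps is not None and r.snp_id not in keep_snps:
            mask[i] = False
            reasons[i] = "snp-list"
            continue
        if remove_snps is not None and r.snp_id in remove_snps:
            mask[i] = False
            reasons[i] = "snp-list"
            continue
        if regions_keep is not None and not regions_keep.contains(r.chromosome, r.physical_pos):
            mask[i] = False
            reasons[i] = "region"
            continue
        if regions_remove is not None and regions_remove.contains(r.chromosome, r.physical_pos):
            mask[i] = False
            reasons[i] = "region"
            continue
        if chrom_keep is not None and r.chromosome not in chrom_keep:
            mask[i] = False
            reasons[i] = "chromosome"
            continue
        if chrom_remove is not None and r.chromosome in chrom_remove:
            mask[i] = False
            reasons[i] = "chromosome"
    return mask, reasons
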