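"""Metadata updates: population relabeling, SNP renaming, genetic-map
re-interpolation and strand flipping.

When only update options are requested (no output prefix, no processing
flags) these edits are applied to the ``.ind``/``.snp`` files in place,
after copying the original bytes to ``<name>.backup``; the genotype file
is never touched.  When combined with processing, the same functions
operate on the in-memory records and the results flow into the new
output triple instead.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import shutil
from typing import Sequence

import numpy as np

from .io_formats import (
    EigenstreamError,
    IndRecord,
    ParseError,
    SnpRecord,
    read_ind,
    read_snp,
    write_ind,
    write_snp,
)

logger = logging.getLogger("eigenstream")


def read_mapping(path: str | os.PathLike) -> dict[str, str]:
    """Read a two-column key -> value mapping file.

    Duplicate keys are an error: the intended value would be ambiguous.
    """
    mapping: dict[str, str] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 columns, got {len(tokens)}"
                )
            key, value = tokens
            if key in mapping:
                raise EigenstreamError(f"{path}: duplicate key {key!r} in mapping")
            mapping[key] = value
    return mapping


def update_ind(
    records: Sequence[IndRecord], mapping: dict[str, str]
) -> tuple[list[IndRecord], int]:
    """Reassign population labels by sample ID; returns (records, n changed)."""
    out: list[IndRecord] = []
    changed = 0
    seen: set[str] = set()
    for r in records:
        if r.sample_id in mapping:
            seen.add(r.sample_id)
            new_pop = mapping[r.sample_id]
            if new_pop != r.population:
                r = dataclasses.replace(r, population=new_pop)
                changed += 1
        out.append(r)
    unmatched = set(mapping) - seen
    if unmatched:
        logger.warning(
            "%d mapping key(s) not present in .ind (e.g. %s)",
            len(unmatched), sorted(unmatched)[0],
        )
    return out, changed


def update_snp_ids(
    records: Sequence[SnpRecord], mapping: dict[str, str]
) -> tuple[list[SnpRecord], int]:
    """Replace SNP identifiers by mapping; positions and alleles untouched."""
    out: list[SnpRecord] = []
    changed = 0
    seen: set[str] = set()
    for r in records:
        if r.snp_id in mapping:
            seen.add(r.snp_id)
            new_id = mapping[r.snp_id]
            if new_id != r.snp_id:
                r = dataclasses.replace(r, snp_id=new_id)
                changed += 1
        out.append(r)
    ids = [r.snp_id for r in out]
    if len(set(ids)) != len(ids):
        counts: dict[str, int] = {}
        for i in ids:
            counts[i] = counts.get(i, 0) + 1
        dup = next(i for i, c in counts.items() if c > 1)
        raise EigenstreamError(
            f"SNP ID update would create duplicate SNP ID {dup!r}"
        )
    unmatched = set(mapping) - seen
    if unmatched:
        logger.warning(
            "%d SNP mapping key(s) not present in .snp (e.g. %s)",
            len(unmatched), sorted(unmatched)[0],
        )
    return out, changed


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

def read_genetic_map(path: str | os.PathLike) -> dict[int, tuple[np.ndarray, np.ndarray]]:
    """Read a recombination map.

    Expected columns (whitespace-delimited): chromosome, physical position
    (bp), genetic position; a header line whose position columns are
    non-numeric is skipped.  Returns per-chromosome arrays sorted by
    physical position.
    """
    chroms: dict[int, list[tuple[int, float]]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) < 3:
                raise ParseError(
                    f"{path}:{lineno}: expected >=3 columns "
                    f"(chrom, physical pos, genetic pos)"
                )
            try:
                chrom = int(tokens[0].lower().removeprefix("chr"))
                phys = int(float(tokens[1]))
                gen = float(tokens[2])
            except ValueError:
                if lineno == 1:
                    continue  # header
                raise ParseError(
                    f"{path}:{lineno}: non-numeric map entry {line.strip()!r}"
                ) from None
            chroms.setdefault(chrom, []).append((phys, gen))
    gmap: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, points in chroms.items():
        points.sort()
        phys = np.array([p for p, _ in points], dtype=np.int64)
        gen = np.array([g for _, g in points], dtype=np.float64)
        if np.any(np.diff(gen) < 0):
            raise EigenstreamError(
                f"{path}: genetic positions decrease along chromosome {chrom}"
            )
        gmap[chrom] = (phys, gen)
    return gmap


def interpolate_genetic_map(
    records: Sequence[SnpRecord],
    gmap: dict[int, tuple[np.ndarray, np.ndarray]],
    map_unit: str = "cM",
) -> tuple[list[SnpRecord], int]:
    """Recompute each SNP's genetic position from a recombination map.

    Linear interpolation between the bracketing map points of the SNP's
    chromosome; positions outside the map range are clamped to the end
    values (extrapolation could go negative).  ``map_unit`` is the unit of
    the map file's genetic column; the ``.snp`` column is always stored in
    Morgans, so centimorgan maps are divided by 100.

    Returns (updated records, number of SNPs on chromosomes absent from
    the map, which are left unchanged with a warning).
    """
    if map_unit not in ("cM", "M"):
        raise EigenstreamError(f"map unit must be 'cM' or 'M', got {map_unit!r}")
    scale = 0.01 if map_unit == "cM" else 1.0
    for chrom, (phys, _gen) in gmap.items():
        if len(phys) < 2:
            raise EigenstreamError(
                f"genetic map has fewer than 2 points on chromosome {chrom}; "
                f"interpolation is impossible"
            )
    out: list[SnpRecord] = []
    n_unmapped = 0
    for r in records:
        if r.chromosome not in gmap:
            n_unmapped += 1
            out.append(r)
            continue
        phys, gen = gmap[r.chromosome]
        # np.interp clamps to the end values outside the map range
        value = float(np.interp(r.physical_pos, phys, gen)) * scale
        out.append(dataclasses.replace(r, genetic_pos=value))
    if n_unmapped:
        logger.warning(
            "%d SNP(s) on chromosomes absent from the genetic map were left "
            "unchanged", n_unmapped,
        )
    return out, n_unmapped


# ---------------------------------------------------------------------------
# strand flipping
# ---------------------------------------------------------------------------

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C",
               "a": "t", "t": "a", "c": "g", "g": "c"}


def flip_strand(
    records: Sequence[SnpRecord], snp_ids: set[str]
) -> tuple[list[SnpRecord], int]:
    """Replace both alleles of the listed SNPs by their Watson-Crick
    complements.  Genotypes are unaffected (the counted allele merely
    changes name).  Listed SNPs with non-ACGT alleles are skipped with a
    warning."""
    out: list[SnpRecord] = []
    flipped = 0
    skipped = 0
    for r in records:
        if r.snp_id in snp_ids:
            if r.allele1 in _COMPLEMENT and r.allele2 in _COMPLEMENT:
                r = dataclasses.replace(
                    r,
                    allele1=_COMPLEMENT[r.allele1],
                    allele2=_COMPLEMENT[r.allele2],
                )
                flipped += 1
            else:
                skipped += 1
                logger.warning(
                    "SNP %s has non-ACGT allele(s) (%s/%s); strand flip skipped",
                    r.snp_id, r.allele1, r.allele2,
                )
        out.append(r)
    return out, flipped


def read_id_list(path: str | os.PathLike) -> list[str]:
    """Read a one-ID-per-line list file (first token of each line)."""
    ids: list[str] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            tokens = line.split()
            if tokens:
                ids.append(tokens[0])
    return ids


# ---------------------------------------------------------------------------
# update-only mode
# ---------------------------------------------------------------------------

def _backup_then_replace(path: str, writer, records) -> None:
    backup = path + ".backup"
    if os.path.exists(backup):
        raise EigenstreamError(
            f"{backup} already exists; refusing to overwrite the oldest "
            f"recoverable state. Move or remove it, then rerun."
        )
    shutil.copy2(path, backup)
    writer(records, path)
    logger.info("updated %s in place (original preserved as %s)", path, backup)


def apply_update_only(
    snp_path: str,
    ind_path: str,
    update_ind_file: str | None = None,
    update_snp_file: str | None = None,
    genetic_map_file: str | None = None,
    map_unit: str = "cM",
    flip_strand_file: str | None = None,
) -> dict[str, int]:
    """In-place metadata update: edit ``.ind``/``.snp`` directly, keeping a
    ``.backup`` copy of each modified file.  The genotype file is neither
    read nor written.  Returns per-operation change counts."""
    counts: dict[str, int] = {}
    if update_ind_file:
        records, changed = update_ind(read_ind(ind_path), read_mapping(update_ind_file))
        _backup_then_replace(ind_path, write_ind, records)
        counts["populations_updated"] = changed
    if update_snp_file or genetic_map_file or flip_strand_file:
        records = read_snp(snp_path)
        if update_snp_file:
            records, changed = update_snp_ids(records, read_mapping(update_snp_file))
            counts["snp_ids_updated"] = changed
        if genetic_map_file:
            gmap = read_genetic_map(genetic_map_file)
            records, n_unmapped = interpolate_genetic_map(records, gmap, map_unit)
            counts["snps_without_map_chromosome"] = n_unmapped
        if flip_strand_file:
            records, flipped = flip_strand(records, set(read_id_list(flip_strand_file)))
            counts["strands_flipped"] = flipped
        _backup_then_replace(snp_path, write_snp, records)
    return counts
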