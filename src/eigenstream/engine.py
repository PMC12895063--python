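"""Pipeline orchestration.

The processing pipeline applies its operations in a fixed order, chunk by
chunk, mirroring the PLINK-style subset-then-calculate discipline:

  (i)    metadata updates (population labels, SNP IDs, genetic map,
         strand flips)
  (ii)   allele polarization
  (iii)  random pseudo-haploidization
  (iv)   individual/population filtering (global mask, applied to every
         chunk's columns)
  (v)    sex-chromosome handling (sanitization / denominator switches)
  (vi)   SNP-ID selection
  (vii)  region and chromosome filtering
  (viii) --missing / --freq statistics
  (ix)   missing-rate (geno) filtering, then MAF filtering

Statistics therefore always see post-filtering individuals and
post-selection SNPs — allele frequencies are never computed over
individuals that a later stage would have removed.  No stage ever holds
more than one chunk of genotype data plus O(n_ind + n_snp) metadata.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import metadata_update, selection, stats_filters, transforms
from .io_formats import (
    EigenstratReader,
    EigenstreamError,
    PackedGenoWriter,
    TextGenoWriter,
    format_snp_line,
    write_ind,
)

logger = logging.getLogger("eigenstream")

EIGENSTRAT = "eigenstrat"
ANCESTRYMAP = "ancestrymap"

UPDATE_ONLY = "UPDATE_ONLY"
PROCESSING = "PROCESSING"

#: removal reasons, in pipeline order
REMOVAL_REASONS = (
    "polarize-het", "polarize-missing", "polarize-unmatched",
    "snp-list", "region", "chromosome", "geno", "min-maf", "max-maf",
)


@dataclass
class PipelineConfig:
    """Fully resolved run configuration.

    Paths are to existing input files; list/mapping files are read once
    at the start of the run.  ``seed`` drives pseudo-haploidization only.
    """

    geno_path: str
    snp_path: str
    ind_path: str
    out_prefix: str | None = None
    out_format: str = EIGENSTRAT
    chunk_size: int = 1000
    verbose: bool = False
    seed: int = 0

    # update options
    update_ind: str | None = None
    update_snp: str | None = None
    genetic_map: str | None = None
    map_unit: str = "cM"
    flip_strand: str | None = None

    # transforms
    polarize: str | None = None  # file path (FILE mode) or sample ID
    random_haploidise: bool = False

    # individual selection
    keep_indv: str | None = None
    remove_indv: str | None = None
    keep_pop: str | None = None
    remove_pop: str | None = None

    # SNP selection
    keep_snps: str | None = None
    remove_snps: str | None = None
    keep_region: list[str] = field(default_factory=list)
    remove_region: list[str] = field(default_factory=list)
    keep_chr: str | None = None
    remove_chr: str | None = None

    # sex-chromosome handling
    sex_chr: tuple[int, int] = (23, 24)
    sex_chr_missing: bool = False
    ignore_sex: bool = False
    ignore_unknown: bool = False

    # QC filters and reports
    geno: float | None = None
    min_maf: float | None = None
    max_maf: float | None = None
    freq: bool = False
    missing: bool = False

    def has_update_options(self) -> bool:
        return any((self.update_ind, self.update_snp, self.genetic_map, self.flip_strand))

    def has_processing_options(self) -> bool:
        return any((
            self.polarize, self.random_haploidise,
            self.keep_indv, self.remove_indv, self.keep_pop, self.remove_pop,
            self.keep_snps, self.remove_snps,
            self.keep_region, self.remove_region, self.keep_chr, self.remove_chr,
            self.sex_chr_missing,
            self.geno is not None, self.min_maf is not None, self.max_maf is not None,
            self.freq, self.missing,
        ))

    @property
    def mode(self) -> str:
        if (
            self.has_update_options()
            and self.out_prefix is None
            and not self.has_processing_options()
        ):
            return UPDATE_ONLY
        return PROCESSING

    def validate(self) -> None:
        if self.chunk_size < 1:
            raise EigenstreamError("--chunk-size must be >= 1")
        if self.out_format not in (EIGENSTRAT, ANCESTRYMAP):
            raise EigenstreamError(f"unknown output format {self.out_format!r}")
        if self.keep_indv and self.remove_indv:
            raise EigenstreamError("--keep-indv and --remove-indv are contradictory")
        if self.keep_pop and self.remove_pop:
            raise EigenstreamError("--keep-pop and --remove-pop are contradictory")
        if self.keep_snps and self.remove_snps:
            raise EigenstreamError("--keep-snps and --remove-snps are contradictory")
        if self.keep_chr and self.remove_chr:
            raise EigenstreamError("--keep-chr and --remove-chr are contradictory")
        if self.geno is not None and not 0.0 <= self.geno <= 1.0:
            raise EigenstreamError("--geno must be in [0, 1]")
        for name, bound in (("--min-maf", self.min_maf), ("--max-maf", self.max_maf)):
            if bound is not None and not 0.0 <= bound <= 0.5:
                raise EigenstreamError(f"{name} must be in [0, 0.5] (maf cannot exceed 0.5)")
        if self.min_maf is not None and self.max_maf is not None and self.min_maf > self.max_maf:
            raise EigenstreamError("--min-maf exceeds --max-maf")
        if self.mode == PROCESSING and self.out_prefix is None:
            raise EigenstreamError(
                "processing options require --out (only metadata updates may "
                "run without an output prefix)"
            )


@dataclass
class RunSummary:
    """Counts reported at the end of a processing run."""

    n_ind_in: int
    n_ind_out: int
    n_snp_in: int
    n_snp_out: int
    removed_by_reason: dict[str, int]
    metadata_changes: dict[str, int]

    def format(self) -> str:
        lines = [
            f"individuals: {self.n_ind_in} in, {self.n_ind_out} out",
            f"SNPs: {self.n_snp_in} in, {self.n_snp_out} out",
        ]
        for reason in REMOVAL_REASONS:
            n = self.removed_by_reason.get(reason, 0)
            if n:
                lines.append(f"  removed ({reason}): {n}")
        for key, n in self.metadata_changes.items():
            lines.append(f"  {key}: {n}")
        return "\n".join(lines)


def _resolve_polarization(
    config: PipelineConfig, reader: EigenstratReader
) -> transforms.PolarizationSource | None:
    """FILE mode if the argument names an existing file, else SAMPLE mode
    (a prior pass extracts the reference individual's genotype column)."""
    if not config.polarize:
        return None
    if os.path.exists(config.polarize):
        return transforms.PolarizationSource(
            mode="FILE", table=transforms.read_ancestral_table(config.polarize)
        )
    sample_ids = [r.sample_id for r in reader.ind_records]
    try:
        col_idx = sample_ids.index(config.polarize)
    except ValueError:
        raise EigenstreamError(
            f"--polarize argument {config.polarize!r} is neither an existing "
            f"file nor a sample ID in the .ind file"
        ) from None
    column = np.empty(reader.n_snp, dtype=np.int8)
    for chunk in reader.iter_chunks(config.chunk_size):
        column[chunk.row_offset:chunk.row_offset + chunk.n_rows] = chunk.values[:, col_idx]
    logger.info("polarizing against reference individual %s", config.polarize)
    return transforms.PolarizationSource(
        mode="SAMPLE", sample_id=config.polarize, reference_column=column
    )


def run_pipeline(config: PipelineConfig) -> RunSummary | dict[str, int]:
    """Execute the configured run; returns a summary.

    In update-only mode the metadata files are edited in place (with
    ``.backup`` copies) and a change-count dict is returned; otherwise a
    new triple is written under ``config.out_prefix`` and a
    :class:`RunSummary` is returned.
    """
    config.validate()
    if config.mode == UPDATE_ONLY:
        logger.info("update-only mode: editing metadata in place")
        return metadata_update.apply_update_only(
            config.snp_path, config.ind_path,
            update_ind_file=config.update_ind,
            update_snp_file=config.update_snp,
            genetic_map_file=config.genetic_map,
            map_unit=config.map_unit,
            flip_strand_file=config.flip_strand,
        )
    return _run_processing(config)


def _run_processing(config: PipelineConfig) -> RunSummary:
    reader = EigenstratReader(config.geno_path, config.snp_path, config.ind_path)
    ind_records = list(reader.ind_records)
    snp_records = list(reader.snp_records)
    n_ind_in, n_snp_in = len(ind_records), len(snp_records)
    metadata_changes: dict[str, int] = {}

    # (i) metadata updates, applied to the in-memory records
    if config.update_ind:
        ind_records, changed = metadata_update.update_ind(
            ind_records, metadata_update.read_mapping(config.update_ind))
        metadata_changes["populations_updated"] = changed
    if config.update_snp:
        snp_records, changed = metadata_update.update_snp_ids(
            snp_records, metadata_update.read_mapping(config.update_snp))
        metadata_changes["snp_ids_updated"] = changed
    if config.genetic_map:
        gmap = metadata_update.read_genetic_map(config.genetic_map)
        snp_records, n_unmapped = metadata_update.interpolate_genetic_map(
            snp_records, gmap, config.map_unit)
        metadata_changes["snps_without_map_chromosome"] = n_unmapped
    if config.flip_strand:
        snp_records, flipped = metadata_update.flip_strand(
            snp_records, set(metadata_update.read_id_list(config.flip_strand)))
        metadata_changes["strands_flipped"] = flipped

    # (ii) polarization source (SAMPLE mode needs a prior genotype pass)
    pol_source = _resolve_polarization(config, reader)

    # (iv) global individual mask, built from the *updated* records
    read_list = metadata_update.read_id_list
    ind_mask = selection.build_individual_mask(
        ind_records,
        keep_indv=read_list(config.keep_indv) if config.keep_indv else None,
        remove_indv=read_list(config.remove_indv) if config.remove_indv else None,
        keep_pop=read_list(config.keep_pop) if config.keep_pop else None,
        remove_pop=read_list(config.remove_pop) if config.remove_pop else None,
    )
    kept_ind = [r for r, k in zip(ind_records, ind_mask) if k]
    sexes = np.array([r.sex for r in kept_ind])
    n_removed_ind = n_ind_in - len(kept_ind)
    if n_removed_ind:
        logger.info("individual filtering removed %d of %d individuals",
                    n_removed_ind, n_ind_in)

    # (vi)-(vii) SNP selection inputs, loaded once before streaming
    keep_snps = set(read_list(config.keep_snps)) if config.keep_snps else None
    remove_snps = set(read_list(config.remove_snps)) if config.remove_snps else None
    regions_keep = (selection.build_region_set(config.keep_region, config.sex_chr)
                    if config.keep_region else None)
    regions_remove = (selection.build_region_set(config.remove_region, config.sex_chr)
                      if config.remove_region else None)
    chrom_keep = (selection.parse_chrom_spec(config.keep_chr, config.sex_chr)
                  if config.keep_chr else None)
    chrom_remove = (selection.parse_chrom_spec(config.remove_chr, config.sex_chr)
                    if config.remove_chr else None)

    writer_cls = PackedGenoWriter if config.out_format == ANCESTRYMAP else TextGenoWriter
    geno_writer = writer_cls(config.out_prefix + ".geno", len(kept_ind))
    snp_out = open(config.out_prefix + ".snp", "wt", encoding="utf-8")
    freq_out = None
    if config.freq:
        freq_out = open(config.out_prefix + ".frq", "wt", encoding="utf-8")
        freq_out.write("\t".join(stats_filters.FREQ_COLUMNS) + "\n")
    imiss_acc = stats_filters.IndMissingAccumulator(
        sexes, config.sex_chr, config.ignore_sex, config.ignore_unknown
    ) if config.missing else None

    removal_rows: list[tuple[str, str]] = []
    removed_by_reason: dict[str, int] = {}

    def log_removals(records, mask, reasons):
        for rec, kept, reason in zip(records, mask, reasons):
            if not kept:
                removed_by_reason[reason] = removed_by_reason.get(reason, 0) + 1
                if config.verbose:
                    removal_rows.append((rec.snp_id, reason))

    n_snp_out = 0
    try:
        for chunk in reader.iter_chunks(config.chunk_size):
            values = chunk.values
            slice_records = snp_records[chunk.row_offset:chunk.row_offset + chunk.n_rows]
            row_indices = np.arange(chunk.row_offset, chunk.row_offset + chunk.n_rows)

            # (ii) polarization
            if pol_source is not None:
                values, slice_records, keep, reasons = transforms.polarize_chunk(
                    values, slice_records, pol_source, row_offset=chunk.row_offset)
                log_removals(
                    snp_records[chunk.row_offset:chunk.row_offset + chunk.n_rows],
                    keep, reasons)
                row_indices = row_indices[keep]

            # (iii) pseudo-haploidization, keyed to absolute rows
            if config.random_haploidise and values.size:
                values = transforms.random_haploidise(values, row_indices, config.seed)

            # (iv) column subset
            values = values[:, ind_mask]

            # (v) sex-chromosome sanitization
            chroms = np.array([r.chromosome for r in slice_records], dtype=np.int64)
            if config.sex_chr_missing and values.size:
                values, _, _ = stats_filters.sex_chr_sanitize(
                    values, chroms, sexes, config.sex_chr)

            # (vi)-(vii) SNP selection
            mask, reasons = selection.snp_mask_for_chunk(
                slice_records, keep_snps, remove_snps,
                regions_keep, regions_remove, chrom_keep, chrom_remove)
            log_removals(slice_records, mask, reasons)
            values = values[mask]
            slice_records = [r for r, k in zip(slice_records, mask) if k]
            chroms = chroms[mask]

            # (viii) statistics
            need_stats = (config.freq or config.geno is not None
                          or config.min_maf is not None or config.max_maf is not None)
            stats = None
            if need_stats and len(slice_records):
                stats = stats_filters.calculate_snp_stats(
                    values, chroms, sexes, config.sex_chr,
                    config.ignore_sex, config.ignore_unknown)
            if config.freq and stats is not None:
                stats_filters.freq_table(slice_records, stats).to_csv(
                    freq_out, sep="\t", header=False, index=False, na_rep="NA")
            if imiss_acc is not None and len(slice_records):
                imiss_acc.update(values, chroms)

            # (ix) geno filter, then MAF filter
            if stats is not None:
                keep = np.ones(len(slice_records), dtype=bool)
                reasons = [None] * len(slice_records)
                if config.geno is not None:
                    geno_keep = stats_filters.filter_geno(stats, config.geno)
                    for i in np.nonzero(~geno_keep)[0]:
                        if keep[i]:
                            keep[i] = False
                            reasons[i] = "geno"
                if config.min_maf is not None or config.max_maf is not None:
                    maf = np.where(np.isnan(stats.maf), 0.0, stats.maf)
                    for i in range(len(keep)):
                        if not keep[i]:
                            continue
                        if config.min_maf is not None and maf[i] < config.min_maf:
                            keep[i] = False
                            reasons[i] = "min-maf"
                        elif config.max_maf is not None and maf[i] > config.max_maf:
                            keep[i] = False
                            reasons[i] = "max-maf"
                log_removals(slice_records, keep, reasons)
                values = values[keep]
                slice_records = [r for r, k in zip(slice_records, keep) if k]

            if len(slice_records):
                geno_writer.write_chunk(values)
                for rec in slice_records:
                    snp_out.write(format_snp_line(rec) + "\n")
                n_snp_out += len(slice_records)
    finally:
        geno_writer.close()
        snp_out.close()
        if freq_out is not None:
            freq_out.close()

    if n_snp_out == 0:
        raise EigenstreamError(
            "no SNPs remain after filtering; no usable dataset was written"
        )

    write_ind(kept_ind, config.out_prefix + ".ind")
    if imiss_acc is not None:
        stats_filters.missing_table(kept_ind, imiss_acc.finalize()).to_csv(
            config.out_prefix + ".imiss", sep="\t", index=False, na_rep="NA")
    if config.verbose:
        with open(config.out_prefix + ".removed.snp", "wt", encoding="utf-8") as fh:
            for snp_id, reason in removal_rows:
                fh.write(f"{snp_id}\t{reason}\n")

    if config.out_format == ANCESTRYMAP:
        logger.info(
            "packed output written with zero hash fields; set 'hashcheck: NO' "
            "in downstream EIGENSOFT/ADMIXTOOLS parameter files"
        )
    summary = RunSummary(
        n_ind_in=n_ind_in, n_ind_out=len(kept_ind),
        n_snp_in=n_snp_in, n_snp_out=n_snp_out,
        removed_by_reason=removed_by_reason,
        metadata_changes=metadata_changes,
    )
    logger.info("run complete:\n%s", summary.format())
    return summary
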