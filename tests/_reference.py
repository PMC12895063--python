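"""Naive whole-matrix reference implementation used as an oracle.

Everything here loads the full genotype matrix and applies the documented
operations with plain loops, independently of the streaming package code
(the only shared definition is the keyed per-row random draw of
pseudo-haploidization, which is part of the documented output contract
and is re-implemented here from its definition).
"""

from __future__ import annotations

import numpy as np

MISSING = 9


def load_triple(prefix: str):
    """Plain-python whole-file reader for a text triple."""
    ind_rows = [tuple(l.split()) for l in open(prefix + ".ind") if l.strip()]
    snp_rows = []
    for l in open(prefix + ".snp"):
        t = l.split()
        if t:
            snp_rows.append((t[0], int(t[1]), float(t[2]), int(t[3]), t[4], t[5]))
    geno = []
    for l in open(prefix + ".geno"):
        l = l.strip()
        if l:
            geno.append([int(c) for c in l])
    return ind_rows, snp_rows, np.array(geno, dtype=np.int8).reshape(len(geno), -1)


def individual_mask(ind_rows, keep_indv=None, remove_indv=None,
                    keep_pop=None, remove_pop=None):
    mask = []
    for sid, _sex, pop in ind_rows:
        ok = True
        if keep_pop is not None and pop not in keep_pop:
            ok = False
        if remove_pop is not None and pop in remove_pop:
            ok = False
        if keep_indv is not None and sid not in keep_indv:
            ok = False
        if remove_indv is not None and sid in remove_indv:
            ok = False
        mask.append(ok)
    return np.array(mask, dtype=bool)


def in_regions(regions, chrom, pos):
    """Brute-force scan over (chrom, start, end) 1-based inclusive triples."""
    return any(c == chrom and s <= pos <= e for c, s, e in regions)


def snp_keep_reason(snp_row, keep_snps=None, remove_snps=None,
                    regions_keep=None, regions_remove=None,
                    chrom_keep=None, chrom_remove=None):
    snp_id, chrom, _g, pos = snp_row[0], snp_row[1], snp_row[2], snp_row[3]
    if keep_snps is not None and snp_id not in keep_snps:
        return "snp-list"
    if remove_snps is not None and snp_id in remove_snps:
        return "snp-list"
    if regions_keep is not None and not in_regions(regions_keep, chrom, pos):
        return "region"
    if regions_remove is not None and in_regions(regions_remove, chrom, pos):
        return "region"
    if chrom_keep is not None and chrom not in chrom_keep:
        return "chromosome"
    if chrom_remove is not None and chrom in chrom_remove:
        return "chromosome"
    return None


def keyed_haploid_row(seed, abs_row, n_cols):
    """The documented per-row draw: one vector keyed to (seed, row)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(abs_row)]))
    return rng.integers(0, 2, size=n_cols).astype(np.int8) * 2


def snp_statistics(row, chrom, sexes, sex_chr=(23, 24),
                   ignore_sex=False, ignore_unknown=False):
    """(n_considered, n_obs, ref_count, freq, maf, missing_rate) by loops."""
    x_code, y_code = sex_chr
    n_considered = n_obs = ref = 0
    for g, sex in zip(row, sexes):
        if not ignore_sex:
            if chrom == y_code and sex != "M":
                continue
            if ignore_unknown and chrom in (x_code, y_code) and sex == "U":
                continue
        n_considered += 1
        if g != MISSING:
            n_obs += 1
            ref += int(g)
    freq = ref / (2 * n_obs) if n_obs else float("nan")
    maf = min(freq, 1 - freq) if n_obs else float("nan")
    miss = (n_considered - n_obs) / n_considered if n_considered else 1.0
    return n_considered, n_obs, ref, freq, maf, miss


def reference_pipeline(
    ind_rows, snp_rows, matrix,
    keep_indv=None, remove_indv=None, keep_pop=None, remove_pop=None,
    keep_snps=None, remove_snps=None,
    regions_keep=None, regions_remove=None,
    chrom_keep=None, chrom_remove=None,
    sex_chr=(23, 24), sex_chr_missing=False,
    ignore_sex=False, ignore_unknown=False,
    polarize_table=None, polarize_sample=None,
    random_haploidise=False, seed=0,
    geno=None, min_maf=None, max_maf=None,
):
    """Whole-matrix pipeline in the documented stage order.

    Returns (kept ind rows, kept snp rows, output matrix, freq rows,
    imiss rows, removal reasons dict).
    """
    matrix = matrix.copy()
    snp_rows = list(snp_rows)
    removed: dict[str, str] = {}
    x_code, y_code = sex_chr

    # (ii) polarization
    if polarize_table is not None or polarize_sample is not None:
        if polarize_sample is not None:
            ref_col = [sid for sid, _s, _p in ind_rows].index(polarize_sample)
        keep_rows, new_rows = [], []
        for i, rec in enumerate(snp_rows):
            snp_id, chrom, g, p, a1, a2 = rec
            if polarize_table is not None:
                anc = polarize_table.get(snp_id)
                if anc is None or anc.upper() not in (a1.upper(), a2.upper()):
                    removed[snp_id] = "polarize-unmatched"
                    continue
                flip = anc.upper() == a2.upper()
            else:
                rg = int(matrix[i, ref_col])
                if rg == 1:
                    removed[snp_id] = "polarize-het"
                    continue
                if rg == MISSING:
                    removed[snp_id] = "polarize-missing"
                    continue
                flip = rg == 0
            if flip:
                matrix[i] = np.where(matrix[i] == MISSING, MISSING, 2 - matrix[i])
                rec = (snp_id, chrom, g, p, a2, a1)
            keep_rows.append(i)
            new_rows.append(rec)
        abs_indices = np.array(keep_rows, dtype=int)
        matrix = matrix[abs_indices]
        snp_rows = new_rows
    else:
        abs_indices = np.arange(len(snp_rows))

    # (iii) pseudo-haploidization keyed to absolute row indices
    if random_haploidise:
        for i, abs_row in enumerate(abs_indices):
            het = matrix[i] == 1
            if het.any():
                draws = keyed_haploid_row(seed, abs_row, matrix.shape[1])
                matrix[i, het] = draws[het]

    # (iv) individual filtering
    imask = individual_mask(ind_rows, keep_indv, remove_indv, keep_pop, remove_pop)
    kept_ind = [r for r, k in zip(ind_rows, imask) if k]
    matrix = matrix[:, imask]
    sexes = [sex for _sid, sex, _pop in kept_ind]

    # (v) sex-chromosome sanitization
    if sex_chr_missing:
        for i, rec in enumerate(snp_rows):
            chrom = rec[1]
            for j, sex in enumerate(sexes):
                if chrom == y_code and sex != "M":
                    matrix[i, j] = MISSING
                elif chrom == x_code and sex == "M" and matrix[i, j] == 1:
                    matrix[i, j] = MISSING

    # (vi)-(vii) SNP selection
    keep = []
    for i, rec in enumerate(snp_rows):
        reason = snp_keep_reason(rec, keep_snps, remove_snps,
                                 regions_keep, regions_remove,
                                 chrom_keep, chrom_remove)
        if reason is None:
            keep.append(i)
        else:
            removed[rec[0]] = reason
    matrix = matrix[keep]
    snp_rows = [snp_rows[i] for i in keep]

    # (viii) statistics
    freq_rows = []
    stats = []
    for i, rec in enumerate(snp_rows):
        st = snp_statistics(matrix[i], rec[1], sexes, sex_chr,
                            ignore_sex, ignore_unknown)
        stats.append(st)
        freq_rows.append((rec[0],) + st)
    imiss_rows = []
    for j, (sid, sex, _pop) in enumerate(kept_ind):
        n_considered = n_missing = 0
        for i, rec in enumerate(snp_rows):
            chrom = rec[1]
            if not ignore_sex:
                if chrom == y_code and sex != "M":
                    continue
                if ignore_unknown and chrom in (x_code, y_code) and sex == "U":
                    continue
            n_considered += 1
            if matrix[i, j] == MISSING:
                n_missing += 1
        imiss_rows.append((sid, n_considered, n_missing,
                           n_missing / n_considered if n_considered else float("nan")))

    # (ix) geno filter, then MAF filter
    keep = []
    for i, rec in enumerate(snp_rows):
        _nc, n_obs, _ref, _freq, maf, miss = stats[i]
        if geno is not None and miss > geno:
            removed[rec[0]] = "geno"
            continue
        maf_f = maf if n_obs else 0.0
        if min_maf is not None and maf_f < min_maf:
            removed[rec[0]] = "min-maf"
            continue
        if max_maf is not None and maf_f > max_maf:
            removed[rec[0]] = "max-maf"
            continue
        keep.append(i)
    matrix = matrix[keep]
    snp_rows = [snp_rows[i] for i in keep]

    return kept_ind, snp_rows, matrix, freq_rows, imiss_rows, removed
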