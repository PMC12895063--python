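# Methods

## Data model

A dataset is the EIGENSTRAT triple `.geno`/`.snp`/`.ind`.  Genotypes are
held as int8 matrices over {0, 1, 2, 9}: the count of copies of the
`.snp` file's fifth-column allele ("allele1"), with 9 for missing.
Pseudo-haploid data stays diploid-coded (0/2), so the allele-frequency
estimator `ref_count / (2·n_obs)` is correct for both diploid and
pseudo-haploid calls.

The packed ANCESTRYMAP encoding stores one fixed-length record per SNP.
The record length is `max(ceil(n_ind/4), 48)` bytes; the first record is
an ASCII header `GENO <n_ind> <n_snp> <hash> <hash>` null-padded to the
record length.  Individual *j* occupies the 2-bit field at bit positions
`6 − 2·(j mod 4)` of byte `⌊j/4⌋`, with 0→`00`, 1→`01`, 2→`10`, 9→`11`;
pad fields are written as `11` so the file stays self-consistent if the
counts are ever re-derived from it.  The reference hash algorithm used
by `convertf` is undocumented, so both hash fields are written as zero
and downstream EIGENSOFT/ADMIXTOOLS runs must disable `hashcheck`.
Encoding detection is by the 5-byte `GENO ` magic; anything else must be
text whose first line is drawn from {0,1,2,9}.

## Streaming contract

All genotype access goes through a chunk iterator that yields blocks of
at most `chunk_size` SNP rows (default 1000) with their absolute row
offset.  No operation holds more than one chunk of genotype data plus
O(n_ind + n_snp) metadata; output files are appended per chunk.  The
packed writer emits its header first with a zero SNP count and patches
the count on close, so upstream row removals need not be known before
the genotype pass.  Every per-row operation is keyed to the absolute row
index (not the position within a chunk), which makes all outputs
invariant to the chunk size — verified byte-for-byte for chunk sizes
1, 7, 13 and 1000.

## Pipeline order

Operations run in a fixed order (metadata updates, polarization,
pseudo-haploidization, individual filtering, sex-chromosome handling,
SNP-ID selection, region/chromosome filtering, statistics, missing-rate
then MAF filtering).  Two consequences are deliberate and tested:
statistics never see individuals a previous step removed (a constructed
dataset shows a MAF decision flipping when one carrier is excluded), and
the `.frq`/`.imiss` reports describe the SNP set *entering* the QC
filters, not the set surviving them.  Individual-level missing-rate
filtering is intentionally a two-run workflow: compute `.imiss` first,
then rerun with `--remove-indv` on a thresholded list.

## Statistics and sex chromosomes

Per-SNP: `freq = ref_count / (2·n_obs)`, `maf = min(freq, 1−freq)`,
`missing_rate = (n_considered − n_obs)/n_considered`.  Y-chromosome
rows restrict the denominator to sex=M individuals; X rows count
everyone.  Symmetrically, the per-individual missing rate of an F/U
individual excludes Y SNPs from its denominator — the per-SNP rule only
fixes one direction, and the symmetric choice keeps the
missing-cell-conservation identity (sum of per-individual missing counts
over autosomes equals the sum of per-SNP missing counts).  `--ignore-sex`
treats every row autosomally; `--ignore-unknown` additionally removes
sex=U individuals from X/Y denominators.  Both flags are this package's
interpretation of the conventional switches and are documented as such.

Degenerate cases: an all-missing SNP reports `freq = NA` and has its MAF
treated as 0 by the filters (so any positive `--min-maf` removes it,
like monomorphic SNPs); a SNP whose denominator is empty (e.g. a Y SNP
in an all-female subset) has missing rate 1.0; an individual with an
empty denominator reports `NA` with a warning.  The `--geno` filter
removes on strict `>` and the MAF bounds are inclusive, matching the
dominant PLINK convention.

## Transforms

*Pseudo-haploidization* replaces each heterozygous call by 0 or 2 with
probability ½.  The draw vector for a row is generated from
`SeedSequence([seed, absolute_row])`, and column *j* takes element *j*,
so results do not depend on chunk boundaries and are reproducible from
the CLI seed (default 0, logged on every run).  Missingness is preserved
exactly and the expected allele frequency is unchanged; a fixed-seed
binomial check over ≥10 000 heterozygotes guards against bias.

*Polarization* determines each SNP's ancestral allele either from a
two-column table or from a reference individual's genotype (2 → allele1
ancestral, 0 → allele2).  If the ancestral allele is allele2, the
alleles are swapped and genotypes recoded g → 2−g; matching is
case-insensitive.  SNPs are dropped (with a logged reason) when the
reference genotype is heterozygous or missing, or when the table lacks
the SNP or names an allele matching neither — dropping unlisted SNPs
yields a uniformly polarized output, which derived-allele analyses
assume.  Strand-mismatched ancestral states (the complement of an
allele) are not auto-resolved; run `--flip-strand` first.  The reference
individual stays in the output: silently changing the individual count
would be more surprising than leaving one redundant column.

## Metadata updates

Mapping files are strict two-column; duplicate keys error, unmatched
keys warn.  SNP renaming refuses to create duplicate IDs.  Strand
flipping replaces both alleles by Watson–Crick complements (an
involution) and skips non-ACGT alleles with a warning.

Genetic-map interpolation is per-chromosome linear interpolation of the
map's (physical, genetic) points.  The map file is whitespace-delimited
(chromosome, physical bp, genetic position) with an auto-skipped header;
`--map-unit` gives the unit of the *map file* (default cM), while the
`.snp` column is always written in Morgans, so centimorgan maps are
divided by 100.  Positions outside the map range are clamped to the end
values — linear extrapolation can produce negative genetic positions.
SNPs on chromosomes absent from the map are left unchanged with a
warning, which is safer than zeroing when a partial map is supplied.
Chromosomes with fewer than two map points are an error.  On affine maps
the interpolation is exact to machine precision.

In update-only mode every modified file is first copied byte-for-byte to
`<name>.backup`; an existing backup aborts the run rather than
overwriting the oldest recoverable state.

## Selection semantics

Keep and remove lists of the same kind are refused as contradictory.
Population filters apply before individual filters, so `--keep-pop`
plus `--remove-indv` keeps a population minus named members.  Region
coordinates are 1-based inclusive, matching the inline
`CHR:START-END` style (digit groups may contain thin/regular spaces or
commas; hyphen and en dash both work); files with a `.bed` extension are
converted from BED's 0-based half-open starts.  Point-in-region queries
use an interval tree per chromosome and are property-tested against a
brute-force scan.  Chromosome specs accept sets and ranges with an
optional `chr` prefix; `X`/`Y` map to the configured sex codes.

## Synthetic data

The fixture generator draws, per SNP, an allele frequency from a uniform
range (default 0.05–0.95) and genotypes as Binomial(2, f) per
individual, then masks cells to missing with probability
(per-SNP rate × per-individual inflation).  Defaults: two autosomes of
30 SNPs, 10 individuals, sexes M/F/U at 0.5/0.4/0.1, per-SNP missing
rates uniform on 0–0.3.  It emulates the marginal structure every
operation depends on — allele-frequency spectra, missingness profiles,
sex/population composition, sex-chromosome rows including biologically
impossible calls (female Y genotypes, male X heterozygotes) — and
deliberately omits linkage disequilibrium, genotype error and
reference bias, none of which any operation here reads.  Passing tests
therefore certify the bookkeeping (formats, masks, denominators,
ordering, determinism), not population-genetic realism.  Truth tables
are computed by plain-loop enumeration in the fixtures module, which
never calls the statistics or pipeline code, so they are an independent
oracle.  The test suite additionally carries a naive whole-matrix
reference pipeline; agreement is checked on randomly sampled flag
combinations over fixtures of up to ~50 individuals × ~150 SNPs —
sizes chosen so the whole suite replays the full cross-product of chunk
sizes and configurations in seconds.

## Error handling

Malformed metadata lines report the file and line number; genotype-file
defects (wrong line length, bad character, truncated packed record)
report the SNP index.  Dimension mismatches between the three files, and
between the packed header and the metadata, are hard errors before any
output is finalized.  A run ending with zero individuals or zero SNPs is
an error naming the stage.  CLI usage errors exit 2; runtime errors
print a one-line diagnostic and exit 1.

## Known limitations

No TGENO (transposed binary) support; no `convertf`-compatible hash; no
PLINK format conversion; no dataset merging; single-threaded by design
(the streaming layout leaves little to parallelize below I/O).  Y
genotypes are not forced haploid — impossible values are only removed
when `--sex-chr-missing` is requested.
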