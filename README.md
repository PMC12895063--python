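# eigenstream

Chunked, memory-bounded processing of EIGENSTRAT genotype data for
ancient-DNA workflows.

Population-genetic analyses of ancient DNA (PCA, *f*-statistics,
qpWave/qpAdm) run on the EIGENSTRAT triple: a `.geno` file with one text
line per SNP and one character per individual (`0`/`1`/`2` copies of the
first allele, `9` missing), a `.snp` file with SNP metadata (ID,
chromosome code, genetic position in Morgans, physical position, two
alleles) and an `.ind` file with sample ID, sex and population label.
The same genotypes may instead be stored in the packed binary
ANCESTRYMAP layout (a `GENO `-magic header record followed by
fixed-length records of 2-bit genotype fields).

`eigenstream` reads either encoding (auto-detected), streams the
genotype matrix in fixed-size SNP chunks (default 1000), and applies
filtering, QC statistics, transforms and format conversion without ever
holding more than one chunk of genotype data in memory — so datasets of
a million SNPs by tens of thousands of individuals process in well under
a gigabyte of RAM.

## What it does

All operations run in one pass, in a fixed subset-before-calculate
order:

1. metadata updates — population relabeling (`--update-ind`), SNP
   renaming (`--update-snp`), genetic-map re-interpolation
   (`--genetic-map`, `--map-unit`), strand flipping (`--flip-strand`);
2. allele polarization to ancestral/derived orientation (`--polarize`,
   from an ancestral-allele table or a reference individual);
3. random pseudo-haploidization (`--random-haploidise`, `--seed`);
4. individual/population filtering (`--keep-indv`, `--remove-indv`,
   `--keep-pop`, `--remove-pop`);
5. sex-chromosome handling (`--sex-chr-missing`, `--ignore-sex`,
   `--ignore-unknown`; codes configurable via `--sex-chr`, default 23,24);
6. SNP-ID selection (`--keep-snps`, `--remove-snps`);
7. region and chromosome filtering (`--keep-region`/`--remove-region`
   with interval files, BED files or inline `1:1 000 000–2 000 000`
   specs; `--keep-chr`/`--remove-chr` with sets and ranges like
   `1,2,5-6,22`, `chrX`);
8. statistics — per-SNP allele frequency/MAF/missingness (`--freq`) and
   per-individual missingness (`--missing`), with sex-aware
   denominators (Y SNPs count males only; X SNPs count everyone);
9. missing-rate filtering (`--geno`, strict `>`) and minor-allele-
   frequency filtering (`--min-maf`/`--max-maf`, inclusive bounds).

Because individuals are masked before any statistic is computed, allele
frequencies can never include individuals a later step removes.

When **only** metadata-update flags are given (no `--out`, no processing
flags), the `.ind`/`.snp` files are edited **in place**, each original
preserved as `<name>.backup`; the `.geno` file is not even opened.  With
`--out`, updates flow into the new output triple and the inputs are
untouched.

Output format is chosen with `--out-format {eigenstrat, ancestrymap}`.
Packed output is written with zero hash fields, so set `hashcheck: NO`
in downstream EIGENSOFT/ADMIXTOOLS parameter files.  The newer
transposed TGENO binary format is not supported.

## Worked example

The package ships a fixed 6-individual × 10-SNP micro dataset (two
populations; sexes M,M,F,F,U,M; 6 autosomal, 2 X and 2 Y SNPs):

```sh
python -c "from eigenstream.fixtures import write_micro_dataset; write_micro_dataset('micro')"
eigenstream --prefix micro --out qc --keep-chr 1-22 \
            --geno 0.4 --min-maf 0.05 --freq --missing --verbose
```

prints

```
individuals: 6 in, 6 out
SNPs: 10 in, 4 out
  removed (chromosome): 4
  removed (geno): 1
  removed (min-maf): 1
```

`--keep-chr 1-22` drops the four sex-chromosome SNPs; the all-missing
autosomal SNP rs4 (missing rate 1.0 > 0.4) falls to the `--geno` filter,
and the monomorphic rs3 (MAF 0 < 0.05) to `--min-maf`.  `qc.frq` holds
the per-SNP statistics computed at step 8 (i.e. for every SNP surviving
selection, before the QC filters):

```
snp_id	chrom	pos	allele1	allele2	n_obs	freq	maf	missing_rate
rs1	1	1000	A	G	5	0.6	0.4	0.16666666666666666
rs2	1	2000	C	T	5	0.1	0.1	0.16666666666666666
rs3	1	3000	A	C	6	1.0	0.0	0.0
rs4	2	1000	G	T	0	NA	NA	1.0
rs5	2	2000	A	G	6	0.5	0.5	0.0
rs6	2	3000	C	T	4	0.625	0.375	0.3333333333333333
```

For rs1 (genotypes `2 2 1 9 0 1`): 5 of 6 calls observed, reference
allele count 6, frequency 6/(2·5) = 0.6, MAF 0.4, missing rate 1/6 —
exactly the columns above.  `qc.removed.snp` lists each removed SNP with
its reason (`chromosome`, `geno`, `min-maf`, ...).

As a library:

```python
from eigenstream import EigenstratReader, calculate_snp_stats

reader = EigenstratReader.from_prefix("micro")
sexes = [r.sex for r in reader.ind_records]
for chunk in reader.iter_chunks(1000):
    rows = reader.snp_records[chunk.row_offset:chunk.row_offset + chunk.n_rows]
    stats = calculate_snp_stats(chunk.values, [r.chromosome for r in rows], sexes)
```

`filter_by_maf`, `filter_geno`, `random_haploidise`, `polarize_chunk`
and `IndMissingAccumulator` are importable the same way and never mutate
their inputs.

Synthetic test datasets with known truth tables come from the fixture
generator:

```sh
eigenstream fixtures generate --out mydata --seed 7
```

which writes a valid triple plus `.truth.*.tsv` files computed by
independent enumeration.

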