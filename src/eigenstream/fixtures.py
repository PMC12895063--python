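"""Synthetic EIGENSTRAT dataset generation.

Every operation in this package is testable without downloading real
data: :func:`generate` writes a valid text triple with controlled
structure (population sizes, sex ratios, allele-frequency and
missing-rate distributions, sex-chromosome rows) together with
machine-readable truth tables, and :func:`micro_dataset` provides a
fixed, hand-constructed 6-individual x 10-SNP dataset whose every
statistic can be verified by hand.

The truth tables are computed here by direct enumeration with plain
loops — deliberately *not* by calling the statistics or pipeline modules
— so they can serve as an independent oracle for those modules.
Likewise the triple is emitted by direct text writing rather than
through the package's writers.

The generative model is simple on purpose: per SNP an allele frequency
``f`` is drawn from a uniform range and genotypes are Binomial(2, f)
per individual; missingness is Bernoulli per cell with probability
(per-SNP rate x per-individual inflation factor).  No linkage
disequilibrium is simulated — no operation in the package depends on it.
Sex-chromosome rows deliberately contain biologically impossible calls
(female Y genotypes, male X heterozygotes) so sanitization has work to do.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np


@dataclass
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``snp_per_chrom`` maps chromosome code -> SNP count (include 23/24
    for sex-chromosome rows).  ``populations`` maps label -> size and
    must sum to ``n_ind``.  ``sex_proportions`` are the M/F/U fractions.
    ``missing_rate_range`` is the per-SNP uniform range of missing
    probabilities; ``ind_missing_inflation_range`` draws a per-individual
    multiplier applied on top.  Output is deterministic given ``seed``.
    """

    n_ind: int = 10
    snp_per_chrom: dict[int, int] = field(default_factory=lambda: {1: 30, 2: 30})
    populations: dict[str, int] | None = None
    sex_proportions: tuple[float, float, float] = (0.5, 0.4, 0.1)
    freq_range: tuple[float, float] = (0.05, 0.95)
    missing_rate_range: tuple[float, float] = (0.0, 0.3)
    ind_missing_inflation_range: tuple[float, float] = (1.0, 1.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_ind < 1:
            raise ValueError("a fixture needs at least one individual")
        if not self.snp_per_chrom or sum(self.snp_per_chrom.values()) < 1:
            raise ValueError("a fixture needs at least one SNP")
        if self.populations is not None and sum(self.populations.values()) != self.n_ind:
            raise ValueError("population sizes must sum to n_ind")
        if abs(sum(self.sex_proportions) - 1.0) > 1e-9:
            raise ValueError("sex proportions must sum to 1")
        for lo, hi in (self.freq_range, self.missing_rate_range):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("probability ranges must satisfy 0 <= lo <= hi <= 1")


@dataclass
class Fixture:
    """An in-memory synthetic dataset plus its enumerated truth."""

    ind_rows: list[tuple[str, str, str]]  # (sample_id, sex, population)
    snp_rows: list[tuple[str, int, float, int, str, str]]
    genotypes: np.ndarray  # (n_snp x n_ind) over {0,1,2,9}

    @property
    def n_ind(self) -> int:
        return len(self.ind_rows)

    @property
    def n_snp(self) -> int:
        return len(self.snp_rows)

    def write(self, out_prefix: str) -> None:
        with open(out_prefix + ".ind", "wt", encoding="utf-8") as fh:
            for sid, sex, pop in self.ind_rows:
                fh.write(f"{sid} {sex} {pop}\n")
        with open(out_prefix + ".snp", "wt", encoding="utf-8") as fh:
            for sid, chrom, gpos, ppos, a1, a2 in self.snp_rows:
                fh.write(f"{sid} {chrom} {gpos!r} {ppos} {a1} {a2}\n")
        with open(out_prefix + ".geno", "wt", encoding="utf-8") as fh:
            for row in self.genotypes:
                fh.write("".join(str(int(g)) for g in row) + "\n")


_ALLELE_PAIRS = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("T", "A"), ("G", "C")]


def generate(spec: FixtureSpec) -> Fixture:
    """Draw one synthetic dataset from the spec's generative model."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    if spec.populations is None:
        populations = {"Pop1": spec.n_ind}
    else:
        populations = spec.populations
    pop_labels: list[str] = []
    for label, size in populations.items():
        pop_labels.extend([label] * size)
    sexes = rng.choice(["M", "F", "U"], size=spec.n_ind, p=list(spec.sex_proportions))
    ind_rows = [
        (f"S{i + 1}", str(sexes[i]), pop_labels[i]) for i in range(spec.n_ind)
    ]

    snp_rows: list[tuple[str, int, float, int, str, str]] = []
    idx = 0
    for chrom in sorted(spec.snp_per_chrom):
        pos = 0
        for _ in range(spec.snp_per_chrom[chrom]):
            pos += int(rng.integers(500, 5000))
            a1, a2 = _ALLELE_PAIRS[int(rng.integers(0, len(_ALLELE_PAIRS)))]
            snp_rows.append((f"rs{idx + 1}", chrom, 0.0, pos, a1, a2))
            idx += 1
    n_snp = len(snp_rows)

    freqs = rng.uniform(*spec.freq_range, size=n_snp)
    snp_missing = rng.uniform(*spec.missing_rate_range, size=n_snp)
    ind_inflation = rng.uniform(*spec.ind_missing_inflation_range, size=spec.n_ind)

    genotypes = rng.binomial(2, freqs[:, None], size=(n_snp, spec.n_ind)).astype(np.int8)
    p_missing = np.clip(snp_missing[:, None] * ind_inflation[None, :], 0.0, 1.0)
    genotypes[rng.random((n_snp, spec.n_ind)) < p_missing] = 9
    return Fixture(ind_rows, snp_rows, genotypes)


# ---------------------------------------------------------------------------
# truth tables (independent enumeration)
# ---------------------------------------------------------------------------

def truth_snp_stats(
    fixture: Fixture, sex_chr_codes: tuple[int, int] = (23, 24)
) -> list[dict]:
    """Per-SNP frequency/MAF/missingness by direct enumeration.

    Y rows count male individuals only; X and autosomal rows count all.
    """
    x_code, y_code = sex_chr_codes
    out = []
    for row_idx, (snp_id, chrom, _g, _p, _a1, _a2) in enumerate(fixture.snp_rows):
        n_considered = n_obs = ref = 0
        for col, (_sid, sex, _pop) in enumerate(fixture.ind_rows):
            if chrom == y_code and sex != "M":
                continue
            n_considered += 1
            g = int(fixture.genotypes[row_idx, col])
            if g != 9:
                n_obs += 1
                ref += g
        freq = ref / (2 * n_obs) if n_obs else None
        out.append({
            "snp_id": snp_id,
            "n_considered": n_considered,
            "n_obs": n_obs,
            "freq": freq,
            "maf": min(freq, 1 - freq) if freq is not None else None,
            "missing_rate": (n_considered - n_obs) / n_considered if n_considered else 1.0,
        })
    return out


def truth_ind_missing(
    fixture: Fixture, sex_chr_codes: tuple[int, int] = (23, 24)
) -> list[dict]:
    """Per-individual missingness by direct enumeration (Y rows excluded
    from non-male denominators)."""
    _x_code, y_code = sex_chr_codes
    out = []
    for col, (sid, sex, _pop) in enumerate(fixture.ind_rows):
        n_considered = n_missing = 0
        for row_idx, (_sid, chrom, _g, _p, _a1, _a2) in enumerate(fixture.snp_rows):
            if chrom == y_code and sex != "M":
                continue
            n_considered += 1
            if int(fixture.genotypes[row_idx, col]) == 9:
                n_missing += 1
        out.append({
            "sample_id": sid,
            "n_considered": n_considered,
            "n_missing": n_missing,
            "missing_rate": n_missing / n_considered if n_considered else None,
        })
    return out


def truth_filter_removals(
    fixture: Fixture,
    geno: float | None = None,
    min_maf: float | None = None,
    max_maf: float | None = None,
    sex_chr_codes: tuple[int, int] = (23, 24),
) -> dict[str, str]:
    """The exact SNP -> reason map the documented QC filters should
    produce at the given thresholds (geno first, then MAF; strict ``>``
    for geno, inclusive MAF bounds; unobserved SNPs have MAF 0)."""
    removed: dict[str, str] = {}
    for stat in truth_snp_stats(fixture, sex_chr_codes):
        if geno is not None and stat["missing_rate"] > geno:
            removed[stat["snp_id"]] = "geno"
            continue
        maf = stat["maf"] if stat["maf"] is not None else 0.0
        if min_maf is not None and maf < min_maf:
            removed[stat["snp_id"]] = "min-maf"
        elif max_maf is not None and maf > max_maf:
            removed[stat["snp_id"]] = "max-maf"
    return removed


def write_truth_tables(
    fixture: Fixture,
    out_prefix: str,
    geno: float = 0.1,
    min_maf: float = 0.05,
) -> None:
    """Write the enumerated truth next to the triple as TSV files."""
    with open(out_prefix + ".truth.snpstats.tsv", "wt", encoding="utf-8") as fh:
        fh.write("snp_id\tn_considered\tn_obs\tfreq\tmaf\tmissing_rate\n")
        for s in truth_snp_stats(fixture):
            freq = "NA" if s["freq"] is None else repr(s["freq"])
            maf = "NA" if s["maf"] is None else repr(s["maf"])
            fh.write(f"{s['snp_id']}\t{s['n_considered']}\t{s['n_obs']}\t"
                     f"{freq}\t{maf}\t{s['missing_rate']!r}\n")
    with open(out_prefix + ".truth.imiss.tsv", "wt", encoding="utf-8") as fh:
        fh.write("sample_id\tn_considered\tn_missing\tmissing_rate\n")
        for s in truth_ind_missing(fixture):
            rate = "NA" if s["missing_rate"] is None else repr(s["missing_rate"])
            fh.write(f"{s['sample_id']}\t{s['n_considered']}\t{s['n_missing']}\t{rate}\n")
    with open(out_prefix + ".truth.removed.tsv", "wt", encoding="utf-8") as fh:
        fh.write(f"# thresholds: geno={geno} min_maf={min_maf}\n")
        for snp_id, reason in truth_filter_removals(fixture, geno=geno, min_maf=min_maf).items():
            fh.write(f"{snp_id}\t{reason}\n")


# ---------------------------------------------------------------------------
# the micro dataset
# ---------------------------------------------------------------------------

#: 6 individuals (2 populations; sexes M,M,F,F,U,M) x 10 SNPs
#: (6 autosomal, 2 X-coded, 2 Y-coded).  Hand-placed values cover:
#: heterozygotes, missing calls, a monomorphic SNP (rs3), an all-missing
#: SNP (rs4), a MAF exactly on a 0.1 filter boundary (rs2), male X
#: heterozygotes (rs7: S1, S6) and non-male Y calls (rs9: S3, S5) for
#: sanitization, and Y male-only denominators (rs9, rs10).
MICRO_IND = """\
S1 M P1
S2 M P1
S3 F P1
S4 F P2
S5 U P2
S6 M P2
"""

MICRO_SNP = """\
rs1 1 0.0 1000 A G
rs2 1 0.0 2000 C T
rs3 1 0.0 3000 A C
rs4 2 0.0 1000 G T
rs5 2 0.0 2000 A G
rs6 2 0.0 3000 C T
rs7 23 0.0 1000 A G
rs8 23 0.0 2000 T C
rs9 24 0.0 1000 A G
rs10 24 0.0 2000 C T
"""

MICRO_GENO = """\
221901
100009
222222
999999
012102
290192
121021
091210
202922
290092
"""


def micro_dataset() -> Fixture:
    """The fixed worked micro-dataset, parsed from its literal text."""
    ind_rows = [tuple(line.split()) for line in MICRO_IND.strip().splitlines()]
    snp_rows = []
    for line in MICRO_SNP.strip().splitlines():
        sid, chrom, gpos, ppos, a1, a2 = line.split()
        snp_rows.append((sid, int(chrom), float(gpos), int(ppos), a1, a2))
    genotypes = np.array(
        [[int(c) for c in line] for line in MICRO_GENO.strip().splitlines()],
        dtype=np.int8,
    )
    return Fixture(ind_rows, snp_rows, genotypes)


def write_micro_dataset(out_prefix: str) -> None:
    with open(out_prefix + ".ind", "wt", encoding="utf-8") as fh:
        fh.write(MICRO_IND)
    with open(out_prefix + ".snp", "wt", encoding="utf-8") as fh:
        fh.write(MICRO_SNP)
    with open(out_prefix + ".geno", "wt", encoding="utf-8") as fh:
        fh.write(MICRO_GENO)


# ---------------------------------------------------------------------------
# spec files and CLI
# ---------------------------------------------------------------------------

def read_spec_file(path: str) -> FixtureSpec:
    """Parse a flat key-value spec file.

    Recognized keys: ``n_ind``, ``seed``, ``snp_per_chrom`` (e.g.
    ``1:30,2:30,23:5``), ``populations`` (e.g. ``P1:6,P2:4``),
    ``sex_proportions`` (``0.5,0.4,0.1``), ``freq_range``,
    ``missing_rate_range``, ``ind_missing_inflation_range`` (``lo,hi``).
    """
    spec = FixtureSpec()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, sep, value = line.partition("=")
            if not sep:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, value = key.strip(), value.strip()
            if key in ("n_ind", "seed"):
                spec = dataclasses.replace(spec, **{key: int(value)})
            elif key == "snp_per_chrom":
                pairs = dict(
                    (int(k), int(v))
                    for k, v in (item.split(":") for item in value.split(","))
                )
                spec = dataclasses.replace(spec, snp_per_chrom=pairs)
            elif key == "populations":
                pairs = dict(
                    (k, int(v)) for k, v in (item.split(":") for item in value.split(","))
                )
                spec = dataclasses.replace(spec, populations=pairs)
            elif key == "sex_proportions":
                m, f, u = (float(x) for x in value.split(","))
                spec = dataclasses.replace(spec, sex_proportions=(m, f, u))
            elif key in ("freq_range", "missing_rate_range", "ind_missing_inflation_range"):
                lo, hi = (float(x) for x in value.split(","))
                spec = dataclasses.replace(spec, **{key: (lo, hi)})
            else:
                raise ValueError(f"{path}:{lineno}: unknown spec key {key!r}")
    spec.validate()
    return spec


def fixtures_main(argv: list[str]) -> int:
    """`fixtures generate --spec FILE --out PREFIX` subcommand."""
    import argparse

    parser = argparse.ArgumentParser(prog="eigenstream fixtures")
    sub = parser.add_subparsers(dest="command", required=True)
    gen = sub.add_parser("generate", help="write a synthetic triple + truth tables")
    gen.add_argument("--spec", help="flat key-value spec file (defaults used if omitted)")
    gen.add_argument("--out", required=True, help="output prefix")
    gen.add_argument("--seed", type=int, help="override the spec's seed")
    args = parser.parse_args(argv)

    spec = read_spec_file(args.spec) if args.spec else FixtureSpec()
    if args.seed is not None:
        spec = dataclasses.replace(spec, seed=args.seed)
    fixture = generate(spec)
    fixture.write(args.out)
    write_truth_tables(fixture, args.out)
    print(f"wrote {fixture.n_snp} SNPs x {fixture.n_ind} individuals to {args.out}.*")
    return 0
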