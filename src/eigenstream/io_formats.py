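"""Reading and writing EIGENSTRAT genotype triples.

The EIGENSTRAT representation of a genotype dataset is a triple of files:

``.geno``
    one line per SNP, one character per individual; ``0``/``1``/``2`` count
    copies of the first (.snp column 5) allele, ``9`` is missing.
``.snp``
    whitespace-delimited SNP metadata: SNP ID, chromosome code, genetic
    position (Morgans), physical position (bp), allele1, allele2.
``.ind``
    whitespace-delimited individual metadata: sample ID, sex (M/F/U),
    population label.

The ``.geno`` file may instead be in the packed binary ANCESTRYMAP layout:
a fixed-length header record starting with the ASCII magic ``"GENO "``
followed by one fixed-length record per SNP holding 2-bit genotype fields.
Both encodings are auto-detected and exposed through the same chunked
iterator, so no operation ever needs the full genotype matrix in memory.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger("eigenstream")

MISSING = 9
GENO_ALPHABET = frozenset(b"0129")
PACKED_MAGIC = b"GENO "
#: minimum record length of the packed layout, in bytes
PACKED_MIN_RECORD = 48

TEXT = "TEXT"
PACKED = "PACKED"


class EigenstreamError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(EigenstreamError):
    """A file does not conform to its declared or detected format."""


class ParseError(EigenstreamError):
    """A metadata line could not be parsed."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndRecord:
    """One ``.ind`` row: sample ID, sex code (M/F/U), population label."""

    sample_id: str
    sex: str
    population: str


@dataclass(frozen=True)
class SnpRecord:
    """One ``.snp`` row.

    ``genetic_pos`` is in Morgans; ``physical_pos`` is a 1-based bp
    coordinate; ``allele1`` is the allele the genotype values count.
    """

    snp_id: str
    chromosome: int
    genetic_pos: float
    physical_pos: int
    allele1: str
    allele2: str


@dataclass
class GenotypeChunk:
    """A contiguous block of genotype rows.

    ``values`` is a (rows x individuals) int8 matrix over {0,1,2,9};
    ``row_offset`` is the 0-based index of the first row in the full
    dataset.
    """

    values: np.ndarray
    row_offset: int

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# metadata parsing
# ---------------------------------------------------------------------------

_VALID_SEX = {"M", "F", "U"}


def read_ind(path: str | os.PathLike) -> list[IndRecord]:
    """Parse an ``.ind`` file, preserving row order.

    Unknown sex codes are mapped to ``U`` with a logged warning.
    """
    records: list[IndRecord] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 columns "
                    f"(sample ID, sex, population), got {len(tokens)}"
                )
            sample_id, sex, population = tokens
            if sex not in _VALID_SEX:
                logger.warning(
                    "%s:%d: unknown sex code %r for sample %s, using U",
                    path, lineno, sex, sample_id,
                )
                sex = "U"
            records.append(IndRecord(sample_id, sex, population))
    return records


def read_snp(path: str | os.PathLike) -> list[SnpRecord]:
    """Parse a ``.snp`` file, preserving row order.

    Six columns are required; allele-less 4-column files are rejected
    because strand flipping and polarization need the alleles.
    """
    records: list[SnpRecord] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if len(tokens) < 6:
                raise ParseError(
                    f"{path}:{lineno}: expected 6 columns (SNP ID, chrom, "
                    f"genetic pos, physical pos, allele1, allele2), got "
                    f"{len(tokens)}"
                )
            snp_id, chrom_s, gpos_s, ppos_s, a1, a2 = tokens[:6]
            try:
                chrom = int(chrom_s)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer chromosome {chrom_s!r}"
                ) from None
            try:
                gpos = float(gpos_s)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric genetic position {gpos_s!r}"
                ) from None
            try:
                ppos = int(ppos_s)
            except ValueError:
                raise ParseError(
                    f"{path}:{lineno}: non-integer physical position {ppos_s!r}"
                ) from None
            records.append(SnpRecord(snp_id, chrom, gpos, ppos, a1, a2))
    return records


def write_ind(records: Sequence[IndRecord], path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for r in records:
            fh.write(f"{r.sample_id} {r.sex} {r.population}\n")


def format_snp_line(r: SnpRecord) -> str:
    return (
        f"{r.snp_id} {r.chromosome} {r.genetic_pos!r} "
        f"{r.physical_pos} {r.allele1} {r.allele2}"
    )


def write_snp(records: Sequence[SnpRecord], path: str | os.PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for r in records:
            fh.write(format_snp_line(r) + "\n")


# ---------------------------------------------------------------------------
# encoding detection
# ---------------------------------------------------------------------------

def detect_geno_encoding(geno_path: str | os.PathLike) -> str:
    """Return ``PACKED`` or ``TEXT`` for a ``.geno`` file.

    A file is packed iff it begins with the 5 ASCII bytes ``"GENO "``.
    Otherwise its first line must contain only the genotype alphabet
    {0,1,2,9}.
    """
    with open(geno_path, "rb") as fh:
        head = fh.read(5)
        if not head:
            raise FormatError(f"{geno_path}: empty genotype file")
        if head == PACKED_MAGIC:
            return PACKED
        fh.seek(0)
        first = fh.readline().rstrip(b"\r\n")
    for byte in first:
        if byte not in GENO_ALPHABET:
            raise FormatError(
                f"{geno_path}: not packed (no 'GENO ' magic) and first text "
                f"line contains invalid genotype character {chr(byte)!r}"
            )
    return TEXT


# ---------------------------------------------------------------------------
# 2-bit packing
# ---------------------------------------------------------------------------

# genotype value <-> 2-bit code: 0->00, 1->01, 2->10, missing 9->11
_PACK_CODE = np.full(10, 255, dtype=np.uint8)
_PACK_CODE[[0, 1, 2, 9]] = [0, 1, 2, 3]
_UNPACK_CODE = np.array([0, 1, 2, 9], dtype=np.int8)


def packed_record_length(n_ind: int) -> int:
    """Bytes per SNP record: ceil(n_ind/4) with a 48-byte floor."""
    return max(math.ceil(n_ind / 4), PACKED_MIN_RECORD)


def pack_rows(values: np.ndarray, record_len: int) -> bytes:
    """Pack a (rows x n_ind) genotype matrix into packed-record bytes.

    Individual ``j`` occupies the 2-bit field at bit positions
    ``6 - 2*(j % 4)`` of byte ``j // 4``; pad fields are written as 11.
    """
    rows, n_ind = values.shape
    if np.any((values != 0) & (values != 1) & (values != 2) & (values != 9)):
        raise FormatError("genotype value outside {0,1,2,9} cannot be packed")
    codes = _PACK_CODE[values.astype(np.intp)]
    padded = np.full((rows, record_len * 4), 3, dtype=np.uint8)
    padded[:, :n_ind] = codes
    quads = padded.reshape(rows, record_len, 4)
    out = (
        (quads[:, :, 0] << 6)
        | (quads[:, :, 1] << 4)
        | (quads[:, :, 2] << 2)
        | quads[:, :, 3]
    ).astype(np.uint8)
    return out.tobytes()


def unpack_rows(data: bytes, n_rows: int, n_ind: int, record_len: int) -> np.ndarray:
    """Inverse of :func:`pack_rows`; pad fields are discarded."""
    raw = np.frombuffer(data, dtype=np.uint8).reshape(n_rows, record_len)
    fields = np.empty((n_rows, record_len * 4), dtype=np.uint8)
    fields[:, 0::4] = (raw >> 6) & 3
    fields[:, 1::4] = (raw >> 4) & 3
    fields[:, 2::4] = (raw >> 2) & 3
    fields[:, 3::4] = raw & 3
    return _UNPACK_CODE[fields[:, :n_ind]]


def _parse_packed_header(geno_path: str | os.PathLike) -> tuple[int, int]:
    """Return (n_ind, n_snp) from a packed header record."""
    with open(geno_path, "rb") as fh:
        head = fh.read(4096)
    if not head.startswith(PACKED_MAGIC):
        raise FormatError(f"{geno_path}: missing 'GENO ' magic")
    text = head.split(b"\x00", 1)[0].decode("ascii", errors="replace")
    tokens = text.split()
    if len(tokens) < 3:
        raise FormatError(f"{geno_path}: malformed packed header {text!r}")
    try:
        n_ind, n_snp = int(tokens[1]), int(tokens[2])
    except ValueError:
        raise FormatError(
            f"{geno_path}: non-integer counts in packed header {text!r}"
        ) from None
    return n_ind, n_snp


# ---------------------------------------------------------------------------
# dataset handle and chunk iteration
# ---------------------------------------------------------------------------

@dataclass
class DatasetHandle:
    """A validated EIGENSTRAT triple plus its detected genotype encoding."""

    geno_path: str
    snp_path: str
    ind_path: str
    geno_encoding: str
    n_ind: int
    n_snp: int
    ind_records: list[IndRecord] = field(repr=False)
    snp_records: list[SnpRecord] = field(repr=False)


def open_dataset(
    geno_path: str | os.PathLike,
    snp_path: str | os.PathLike,
    ind_path: str | os.PathLike,
) -> DatasetHandle:
    """Open and cross-validate a triple.

    Checks that the ``.geno`` dimensions (packed header counts, or the
    first text line's width) agree with the ``.ind``/``.snp`` line counts.
    """
    ind_records = read_ind(ind_path)
    snp_records = read_snp(snp_path)
    n_ind, n_snp = len(ind_records), len(snp_records)
    encoding = detect_geno_encoding(geno_path)
    if encoding == PACKED:
        h_ind, h_snp = _parse_packed_header(geno_path)
        if h_ind != n_ind or h_snp != n_snp:
            raise FormatError(
                f"{geno_path}: packed header declares {h_ind} individuals x "
                f"{h_snp} SNPs but metadata files have {n_ind} x {n_snp}"
            )
        record_len = packed_record_length(n_ind)
        expected = (n_snp + 1) * record_len
        actual = os.path.getsize(geno_path)
        if actual != expected:
            raise FormatError(
                f"{geno_path}: file size {actual} does not match "
                f"{expected} bytes expected for {n_snp} records of "
                f"{record_len} bytes plus header (truncated?)"
            )
    else:
        with open(geno_path, "rb") as fh:
            first = fh.readline().rstrip(b"\r\n")
        if len(first) != n_ind:
            raise FormatError(
                f"{geno_path}: first line has {len(first)} genotype "
                f"characters but .ind lists {n_ind} individuals"
            )
    return DatasetHandle(
        str(geno_path), str(snp_path), str(ind_path),
        encoding, n_ind, n_snp, ind_records, snp_records,
    )


def _iter_text_chunks(handle: DatasetHandle, chunk_size: int) -> Iterator[GenotypeChunk]:
    n_ind = handle.n_ind
    offset = 0
    buf: list[bytes] = []
    with open(handle.geno_path, "rb") as fh:
        for raw in fh:
            line = raw.rstrip(b"\r\n").rstrip()
            if not line:
                continue
            if len(line) != n_ind:
                raise FormatError(
                    f"{handle.geno_path}: SNP {offset + len(buf)}: line has "
                    f"{len(line)} characters, expected {n_ind}"
                )
            buf.append(line)
            if len(buf) == chunk_size:
                yield _text_lines_to_chunk(buf, offset, handle)
                offset += len(buf)
                buf = []
        if buf:
            yield _text_lines_to_chunk(buf, offset, handle)
            offset += len(buf)
    if offset != handle.n_snp:
        raise FormatError(
            f"{handle.geno_path}: {offset} genotype lines but .snp lists "
            f"{handle.n_snp} SNPs"
        )


def _text_lines_to_chunk(lines: list[bytes], offset: int, handle: DatasetHandle) -> GenotypeChunk:
    arr = np.frombuffer(b"".join(lines), dtype=np.uint8)
    values = (arr - ord("0")).astype(np.int8).reshape(len(lines), -1)
    bad = (values != 0) & (values != 1) & (values != 2) & (values != 9)
    if bad.any():
        row = int(np.argwhere(bad)[0, 0])
        raise FormatError(
            f"{handle.geno_path}: SNP {offset + row}: invalid genotype "
            f"character in line"
        )
    return GenotypeChunk(values, offset)


def _iter_packed_chunks(handle: DatasetHandle, chunk_size: int) -> Iterator[GenotypeChunk]:
    n_ind, n_snp = handle.n_ind, handle.n_snp
    record_len = packed_record_length(n_ind)
    with open(handle.geno_path, "rb") as fh:
        fh.seek(record_len)  # skip header record; hash fields ignored
        offset = 0
        while offset < n_snp:
            n_rows = min(chunk_size, n_snp - offset)
            data = fh.read(n_rows * record_len)
            if len(data) != n_rows * record_len:
                raise FormatError(
                    f"{handle.geno_path}: truncated record at SNP "
                    f"{offset + len(data) // record_len}"
                )
            yield GenotypeChunk(unpack_rows(data, n_rows, n_ind, record_len), offset)
            offset += n_rows


def iter_chunks(handle: DatasetHandle, chunk_size: int = 1000) -> Iterator[GenotypeChunk]:
    """Iterate genotype rows in blocks of ``chunk_size`` SNPs.

    Row-wise concatenation of all chunks equals the full genotype matrix;
    the encodings are indistinguishable through this interface.
    """
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    if handle.geno_encoding == PACKED:
        return _iter_packed_chunks(handle, chunk_size)
    return _iter_text_chunks(handle, chunk_size)


class EigenstratReader:
    """Chunk-based access to an EIGENSTRAT dataset.

    Example::

        reader = EigenstratReader.from_prefix("mydata")
        for chunk in reader.iter_chunks(1000):
            ...  # chunk.values is (rows x individuals) over {0,1,2,9}
    """

    def __init__(self, geno_path, snp_path, ind_path):
        self.handle = open_dataset(geno_path, snp_path, ind_path)

    @classmethod
    def from_prefix(cls, prefix: str) -> "EigenstratReader":
        return cls(prefix + ".geno", prefix + ".snp", prefix + ".ind")

    @property
    def ind_records(self) -> list[IndRecord]:
        return self.handle.ind_records

    @property
    def snp_records(self) -> list[SnpRecord]:
        return self.handle.snp_records

    @property
    def n_ind(self) -> int:
        return self.handle.n_ind

    @property
    def n_snp(self) -> int:
        return self.handle.n_snp

    def iter_chunks(self, chunk_size: int = 1000) -> Iterator[GenotypeChunk]:
        return iter_chunks(self.handle, chunk_size)

    def read_matrix(self) -> np.ndarray:
        """Load the full genotype matrix (convenience; not used by the
        streaming pipeline)."""
        chunks = [c.values for c in self.iter_chunks(8192)]
        if not chunks:
            return np.empty((0, self.n_ind), dtype=np.int8)
        return np.concatenate(chunks, axis=0)


# ---------------------------------------------------------------------------
# streaming writers
# ---------------------------------------------------------------------------

class TextGenoWriter:
    """Append genotype chunks to a text ``.geno`` file."""

    def __init__(self, path: str | os.PathLike, n_ind: int):
        if n_ind < 1:
            raise EigenstreamError("cannot write a genotype file for zero individuals")
        self.n_ind = n_ind
        self.n_written = 0
        self._fh = open(path, "wb")

    def write_chunk(self, values: np.ndarray) -> None:
        if values.shape[1] != self.n_ind:
            raise EigenstreamError(
                f"chunk has {values.shape[1]} columns, writer expects {self.n_ind}"
            )
        chars = (values.astype(np.uint8) + ord("0"))
        lines = np.empty((values.shape[0], self.n_ind + 1), dtype=np.uint8)
        lines[:, :-1] = chars
        lines[:, -1] = ord("\n")
        self._fh.write(lines.tobytes())
        self.n_written += values.shape[0]

    def close(self) -> None:
        self._fh.close()


class PackedGenoWriter:
    """Append genotype chunks to a packed ANCESTRYMAP ``.geno`` file.

    The header record is written first with a zero SNP count and patched
    with the final count on close, so row removals upstream need not be
    known in advance.  Both hash fields are written as 0: downstream
    EIGENSOFT/ADMIXTOOLS runs must set ``hashcheck: NO``.
    """

    def __init__(self, path: str | os.PathLike, n_ind: int):
        if n_ind < 1:
            raise EigenstreamError("cannot write a genotype file for zero individuals")
        self.n_ind = n_ind
        self.record_len = packed_record_length(n_ind)
        self.n_written = 0
        self._fh = open(path, "wb")
        self._fh.write(self._header(0))

    def _header(self, n_snp: int) -> bytes:
        text = f"GENO {self.n_ind} {n_snp} 0 0".encode("ascii")
        if len(text) > self.record_len:
            raise FormatError("packed header does not fit in one record")
        return text.ljust(self.record_len, b"\x00")

    def write_chunk(self, values: np.ndarray) -> None:
        if values.shape[1] != self.n_ind:
            raise EigenstreamError(
                f"chunk has {values.shape[1]} columns, writer expects {self.n_ind}"
            )
        self._fh.write(pack_rows(values, self.record_len))
        self.n_written += values.shape[0]

    def close(self) -> None:
        self._fh.seek(0)
        self._fh.write(self._header(self.n_written))
        self._fh.close()


def write_text(
    ind_records: Sequence[IndRecord],
    snp_records: Sequence[SnpRecord],
    chunks: Iterable[np.ndarray],
    out_prefix: str,
) -> None:
    """Write a full EIGENSTRAT text triple from a chunk stream."""
    _write_triple(ind_records, snp_records, chunks, out_prefix, TextGenoWriter)


def write_packed(
    ind_records: Sequence[IndRecord],
    snp_records: Sequence[SnpRecord],
    chunks: Iterable[np.ndarray],
    out_prefix: str,
) -> None:
    """Write a full packed ANCESTRYMAP triple from a chunk stream."""
    _write_triple(ind_records, snp_records, chunks, out_prefix, PackedGenoWriter)


def _write_triple(ind_records, snp_records, chunks, out_prefix, writer_cls):
    if not ind_records:
        raise EigenstreamError("refusing to write a dataset with zero individuals")
    writer = writer_cls(out_prefix + ".geno", len(ind_records))
    try:
        for values in chunks:
            writer.write_chunk(np.asarray(values, dtype=np.int8))
    finally:
        writer.close()
    if writer.n_written != len(snp_records):
        raise EigenstreamError(
            f"wrote {writer.n_written} genotype rows but {len(snp_records)} "
            f"SNP records were supplied"
        )
    write_snp(snp_records, out_prefix + ".snp")
    write_ind(ind_records, out_prefix + ".ind")
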