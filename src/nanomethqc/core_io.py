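"""Readers and writers for the formats the pipeline touches.

Covers FASTA/FASTQ, BED, bedMethyl, SAM/BAM with MM/ML base-modification
tags, and UCSC chain files, plus decoding of modification tags into
per-cytosine probability calls.

Coordinates are 0-based half-open everywhere; bedMethyl output follows the
BED convention. Modification probabilities use the mid-bin decoding rule
``(ml + 0.5) / 256`` for the 256-bin quantized ML values.
"""

from __future__ import annotations

import array
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pysam
from Bio import SeqIO

__all__ = [
    "GenomeSequence",
    "GenomicInterval",
    "AlignedModRead",
    "BedMethylRecord",
    "ChainAlignment",
    "ChainBlock",
    "ModCall",
    "FastqRead",
    "ParseError",
    "DecodeError",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_bed",
    "read_bedmethyl",
    "write_bedmethyl",
    "parse_chain",
    "write_chain",
    "invert_chain",
    "decode_mod_tags",
    "encode_mod_tags",
    "read_alignments",
    "write_alignments",
    "revcomp",
    "query_to_ref_map",
]

_VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

QUERY_CONSUMING = frozenset("M=XIS")
REF_CONSUMING = frozenset("M=XDN")


class ParseError(ValueError):
    """Malformed input file; the message names the offending location."""


class DecodeError(ValueError):
    """MM/ML modification tags inconsistent with the read sequence."""


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeSequence:
    """One reference contig, upper-case, alphabet {A,C,G,T,N}."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ParseError(
                f"contig {self.name!r}: illegal characters {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval; strand '+', '-' or '.' (unstranded)."""

    contig: str
    start: int
    end: int
    strand: str = "."
    name: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}"
            )
        if self.strand not in "+-.":
            raise ValueError(f"invalid strand {self.strand!r}")


def read_fasta(path) -> list[GenomeSequence]:
    """Parse a FASTA file into contigs, case-folded to upper.

    Raises :class:`ParseError` naming the line on a malformed header or an
    illegal character outside {A,C,G,T,N}.
    """
    _validate_fasta_lines(path)
    with open(path) as fh:
        records = list(SeqIO.parse(fh, "fasta"))
    return [GenomeSequence(rec.id, str(rec.seq).upper()) for rec in records]


def _validate_fasta_lines(path) -> None:
    seen_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                if len(line) == 1:
                    raise ParseError(f"{path}: empty FASTA header at line {lineno}")
                seen_header = True
                continue
            if not seen_header:
                raise ParseError(
                    f"{path}: sequence before any '>' header at line {lineno}"
                )
            bad = set(line.upper()) - _VALID_BASES
            if bad:
                raise ParseError(
                    f"{path}: illegal character(s) {sorted(bad)!r} at line {lineno}"
                )


def write_fasta(contigs: Iterable[GenomeSequence], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for contig in contigs:
            fh.write(f">{contig.name}\n")
            seq = contig.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


class FastqRead(NamedTuple):
    read_id: str
    sequence: str
    qualities: list[int]


def read_fastq(path) -> list[FastqRead]:
    with open(path) as fh:
        return [
            FastqRead(rec.id, str(rec.seq), list(rec.letter_annotations["phred_quality"]))
            for rec in SeqIO.parse(fh, "fastq")
        ]


def write_fastq(reads: Iterable[FastqRead], path) -> None:
    with open(path, "w") as fh:
        for read in reads:
            quals = "".join(chr(q + 33) for q in read.qualities)
            fh.write(f"@{read.read_id}\n{read.sequence}\n+\n{quals}\n")


# ---------------------------------------------------------------------------
# BED / bedMethyl
# ---------------------------------------------------------------------------

def read_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 into intervals (name and strand kept when present)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: fewer than 3 BED columns at line {lineno}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}: non-integer coordinate at line {lineno}") from exc
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "."
            out.append(GenomicInterval(fields[0], start, end, strand, name))
    return out


@dataclass(frozen=True)
class BedMethylRecord:
    """Single-base methylation record in the modbam2bed-style column layout."""

    contig: str
    start: int
    strand: str = "."
    coverage: int = 0
    percent_methylated: float = 0.0

    def __post_init__(self) -> None:
        if self.coverage < 0:
            raise ValueError("coverage must be >= 0")
        if not 0.0 <= self.percent_methylated <= 100.0:
            raise ValueError("percent methylated must lie in [0, 100]")

    @property
    def end(self) -> int:
        return self.start + 1


def write_bedmethyl(records: Sequence[BedMethylRecord], path) -> None:
    """Write records as 11-column bedMethyl; input must be (contig, start)-sorted."""
    _check_sorted(records)
    with open(path, "w") as fh:
        for r in records:
            pct = format(float(r.percent_methylated), "g")
            fh.write(
                f"{r.contig}\t{r.start}\t{r.end}\t5mC\t{min(r.coverage, 1000)}\t"
                f"{r.strand}\t{r.start}\t{r.end}\t0,0,0\t{r.coverage}\t{pct}\n"
            )


def _check_sorted(records: Sequence[BedMethylRecord]) -> None:
    seen_contigs: list[str] = []
    prev_start = -1
    for r in records:
        if not seen_contigs or r.contig != seen_contigs[-1]:
            if r.contig in seen_contigs:
                raise ValueError(f"records not grouped by contig near {r.contig}:{r.start}")
            seen_contigs.append(r.contig)
            prev_start = -1
        if r.start < prev_start:
            raise ValueError(f"records not sorted by start near {r.contig}:{r.start}")
        prev_start = r.start


def read_bedmethyl(path) -> list[BedMethylRecord]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 11:
                raise ParseError(f"{path}: fewer than 11 bedMethyl columns at line {lineno}")
            out.append(
                BedMethylRecord(
                    contig=fields[0],
                    start=int(fields[1]),
                    strand=fields[5],
                    coverage=int(fields[9]),
                    percent_methylated=float(fields[10]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Base-modification tags (MM/ML)
# ---------------------------------------------------------------------------

class ModCall(NamedTuple):
    """A 5mC call: query offset in *original read orientation* + probability."""

    offset: int
    probability: float


_MM_ITEM = re.compile(r"^([ACGTUN])([+-])([a-z]+|\d+)([.?]?)$")


def decode_mod_tags(
    mm_text: str,
    ml_values: Sequence[int],
    sequence: str,
    is_reverse: bool = False,
) -> list[ModCall]:
    """Decode SAM ``MM``/``ML`` tags into per-cytosine 5mC probability calls.

    Skip-counts in the ``C+m`` item are resolved against the cytosines of the
    read in its *original* orientation (the reverse complement of the stored
    sequence for reverse-strand alignments). Probabilities use the mid-bin
    rule ``(ml + 0.5) / 256``. Items for other base/modification pairs are
    skipped, consuming their share of ML values.
    """
    oriented = revcomp(sequence) if is_reverse else sequence
    oriented = oriented.upper()
    c_positions = [i for i, b in enumerate(oriented) if b == "C"]

    calls: list[ModCall] = []
    ml_cursor = 0
    for item in mm_text.rstrip(";").split(";"):
        if not item:
            continue
        head, *counts_txt = item.split(",")
        m = _MM_ITEM.match(head)
        if m is None:
            raise DecodeError(f"unrecognized MM item header {head!r}")
        counts = [int(c) for c in counts_txt]
        base, _strand, mod, _flag = m.groups()
        if base == "C" and mod == "m":
            c_idx = -1
            for skip in counts:
                c_idx += skip + 1
                if c_idx >= len(c_positions):
                    raise DecodeError(
                        f"MM skip-counts exhaust the {len(c_positions)} C bases of the read"
                    )
                if ml_cursor >= len(ml_values):
                    raise DecodeError("ML tag shorter than the number of MM calls")
                prob = (ml_values[ml_cursor] + 0.5) / 256.0
                calls.append(ModCall(c_positions[c_idx], prob))
                ml_cursor += 1
        else:
            ml_cursor += len(counts)
    if ml_cursor != len(ml_values):
        raise DecodeError(
            f"ML tag length {len(ml_values)} does not match {ml_cursor} MM calls"
        )
    return sorted(calls)


def encode_mod_tags(
    calls: Sequence[ModCall], sequence: str, is_reverse: bool = False
) -> tuple[str, list[int]]:
    """Inverse of :func:`decode_mod_tags` for ``C+m`` calls."""
    oriented = revcomp(sequence) if is_reverse else sequence
    oriented = oriented.upper()
    c_ordinal = {i: k for k, i in enumerate(i for i, b in enumerate(oriented) if b == "C")}
    deltas: list[int] = []
    ml: list[int] = []
    prev = -1
    for call in sorted(calls):
        if call.offset not in c_ordinal:
            raise DecodeError(f"call offset {call.offset} is not a C in read orientation")
        k = c_ordinal[call.offset]
        deltas.append(k - prev - 1)
        prev = k
        ml.append(int(np.clip(round(call.probability * 256.0 - 0.5), 0, 255)))
    mm = "C+m" + "".join(f",{d}" for d in deltas) + ";"
    return mm, ml


# ---------------------------------------------------------------------------
# Aligned reads
# ---------------------------------------------------------------------------

_CIGAR_OPS = "MIDNSHP=X"


@dataclass
class AlignedModRead:
    """One aligned read with CIGAR, qualities and 5mC probability calls.

    ``mod_calls`` offsets address cytosines of the read in its original
    orientation; for reverse-strand alignments the stored ``sequence`` is the
    reverse complement of the original read (the usual BAM dialect).
    """

    read_id: str
    contig: str
    ref_start: int
    strand: str
    cigar: list[tuple[str, int]]
    sequence: str
    qualities: list[int]
    mod_calls: list[ModCall] = field(default_factory=list)
    is_primary: bool = True

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        qlen = sum(n for op, n in self.cigar if op in QUERY_CONSUMING)
        if qlen != len(self.sequence):
            raise ValueError(
                f"read {self.read_id}: CIGAR query length {qlen} != sequence length "
                f"{len(self.sequence)}"
            )
        if len(self.qualities) != len(self.sequence):
            raise ValueError(f"read {self.read_id}: quality/sequence length mismatch")
        for call in self.mod_calls:
            if not 0.0 <= call.probability <= 1.0:
                raise ValueError(f"read {self.read_id}: probability outside [0,1]")
            if self._oriented_base(call.offset) != "C":
                raise ValueError(
                    f"read {self.read_id}: mod call offset {call.offset} is not a C "
                    "in original read orientation"
                )

    def _oriented_base(self, offset: int) -> str:
        if self.strand == "+":
            return self.sequence[offset].upper()
        stored = self.sequence[len(self.sequence) - 1 - offset].upper()
        return stored.translate(_COMPLEMENT)

    @property
    def query_length(self) -> int:
        return len(self.sequence)

    @property
    def ref_end(self) -> int:
        return self.ref_start + sum(n for op, n in self.cigar if op in REF_CONSUMING)


def query_to_ref_map(read: AlignedModRead) -> np.ndarray:
    """Reference position for every stored query index; -1 where unaligned."""
    out = np.full(read.query_length, -1, dtype=np.int64)
    q = 0
    r = read.ref_start
    for op, n in read.cigar:
        if op in "M=X":
            out[q : q + n] = np.arange(r, r + n)
            q += n
            r += n
        elif op in "IS":
            q += n
        elif op in "DN":
            r += n
        # H and P consume nothing
    return out


def read_alignments(path, mode: str | None = None) -> list[AlignedModRead]:
    """Load SAM/BAM alignments (with MM/ML tags when present) into memory.

    Unmapped records are skipped; secondary/supplementary records are kept
    with ``is_primary=False`` so downstream stages can exclude them.
    """
    reads: list[AlignedModRead] = []
    with pysam.AlignmentFile(str(path), mode or "r", check_sq=False) as fh:
        for seg in fh:
            if seg.is_unmapped or seg.query_sequence is None:
                continue
            mm = ml = None
            for tag in ("MM", "Mm"):
                if seg.has_tag(tag):
                    mm = seg.get_tag(tag)
                    break
            for tag in ("ML", "Ml"):
                if seg.has_tag(tag):
                    ml = list(seg.get_tag(tag))
                    break
            calls = (
                decode_mod_tags(mm, ml or [], seg.query_sequence, seg.is_reverse)
                if mm
                else []
            )
            # -1 marks absent qualities; accuracy computations reject them
            quals = (
                list(seg.query_qualities)
                if seg.query_qualities is not None
                else [-1] * len(seg.query_sequence)
            )
            reads.append(
                AlignedModRead(
                    read_id=seg.query_name,
                    contig=seg.reference_name,
                    ref_start=seg.reference_start,
                    strand="-" if seg.is_reverse else "+",
                    cigar=[(_CIGAR_OPS[code], n) for code, n in seg.cigartuples],
                    sequence=seg.query_sequence,
                    qualities=quals,
                    mod_calls=calls,
                    is_primary=not (seg.is_secondary or seg.is_supplementary),
                )
            )
    return reads


def write_alignments(
    reads: Iterable[AlignedModRead], contigs: Sequence[GenomeSequence], path
) -> None:
    """Write reads as SAM with MM/ML tags against the given reference contigs."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c.name, "LN": c.length} for c in contigs],
    }
    op_code = {op: i for i, op in enumerate(_CIGAR_OPS)}
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for read in reads:
            seg = pysam.AlignedSegment(fh.header)
            seg.query_name = read.read_id
            seg.reference_name = read.contig
            seg.reference_start = read.ref_start
            seg.mapping_quality = 60
            flag = 0
            if read.strand == "-":
                flag |= 16
            if not read.is_primary:
                flag |= 256
            seg.flag = flag
            seg.cigartuples = [(op_code[op], n) for op, n in read.cigar]
            seg.query_sequence = read.sequence
            seg.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in read.qualities)
            )
            if read.mod_calls:
                mm, ml = encode_mod_tags(read.mod_calls, read.sequence, read.strand == "-")
                seg.set_tag("MM", mm)
                seg.set_tag("ML", array.array("B", ml))
            fh.write(seg)


# ---------------------------------------------------------------------------
# UCSC chain files
# ---------------------------------------------------------------------------

class ChainBlock(NamedTuple):
    size: int
    dt: int  # gap on the source (reference) side after the block
    dq: int  # gap on the target (query) side after the block


@dataclass(frozen=True)
class ChainAlignment:
    """One block-wise alignment between a source and a target assembly."""

    score: float
    source_name: str
    source_size: int
    source_strand: str
    source_start: int
    source_end: int
    target_name: str
    target_size: int
    target_strand: str
    target_start: int
    target_end: int
    blocks: tuple[ChainBlock, ...]
    chain_id: str = "1"

    def __post_init__(self) -> None:
        src_span = sum(b.size + b.dt for b in self.blocks)
        tgt_span = sum(b.size + b.dq for b in self.blocks)
        if src_span != self.source_end - self.source_start:
            raise ParseError(
                f"chain {self.chain_id}: block source span {src_span} != header span "
                f"{self.source_end - self.source_start}"
            )
        if tgt_span != self.target_end - self.target_start:
            raise ParseError(
                f"chain {self.chain_id}: block target span {tgt_span} != header span "
                f"{self.target_end - self.target_start}"
            )
        if self.blocks and (self.blocks[-1].dt or self.blocks[-1].dq):
            raise ParseError(f"chain {self.chain_id}: last block carries gaps")


def parse_chain(path) -> list[ChainAlignment]:
    """Parse a UCSC chain file, validating block arithmetic against headers."""
    chains: list[ChainAlignment] = []
    header: list[str] | None = None
    blocks: list[ChainBlock] = []

    def _flush() -> None:
        nonlocal header, blocks
        if header is None:
            return
        chains.append(
            ChainAlignment(
                score=float(header[1]),
                source_name=header[2],
                source_size=int(header[3]),
                source_strand=header[4],
                source_start=int(header[5]),
                source_end=int(header[6]),
                target_name=header[7],
                target_size=int(header[8]),
                target_strand=header[9],
                target_start=int(header[10]),
                target_end=int(header[11]),
                blocks=tuple(blocks),
                chain_id=header[12] if len(header) > 12 else str(len(chains) + 1),
            )
        )
        header, blocks = None, []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("chain"):
                _flush()
                header = line.split()
                if len(header) < 12:
                    raise ParseError(f"{path}: short chain header at line {lineno}")
            else:
                if header is None:
                    raise ParseError(f"{path}: block line outside a chain at line {lineno}")
                parts = line.split()
                if len(parts) == 1:
                    blocks.append(ChainBlock(int(parts[0]), 0, 0))
                elif len(parts) == 3:
                    blocks.append(ChainBlock(int(parts[0]), int(parts[1]), int(parts[2])))
                else:
                    raise ParseError(f"{path}: malformed block line at line {lineno}")
    _flush()
    return chains


def write_chain(chains: Iterable[ChainAlignment], path) -> None:
    with open(path, "w") as fh:
        for c in chains:
            fh.write(
                f"chain {int(c.score)} {c.source_name} {c.source_size} {c.source_strand} "
                f"{c.source_start} {c.source_end} {c.target_name} {c.target_size} "
                f"{c.target_strand} {c.target_start} {c.target_end} {c.chain_id}\n"
            )
            for b in c.blocks[:-1]:
                fh.write(f"{b.size} {b.dt} {b.dq}\n")
            if c.blocks:
                fh.write(f"{c.blocks[-1].size}\n")
            fh.write("\n")


def invert_chain(chain: ChainAlignment) -> ChainAlignment:
    """Swap source and target roles (dt and dq exchange accordingly)."""
    return ChainAlignment(
        score=chain.score,
        source_name=chain.target_name,
        source_size=chain.target_size,
        source_strand=chain.target_strand,
        source_start=chain.target_start,
        source_end=chain.target_end,
        target_name=chain.source_name,
        target_size=chain.source_size,
        target_strand=chain.source_strand,
        target_start=chain.source_start,
        target_end=chain.source_end,
        blocks=tuple(ChainBlock(b.size, b.dq, b.dt) for b in chain.blocks),
        chain_id=chain.chain_id,
    )
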