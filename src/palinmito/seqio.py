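"""Sequence/alignment I/O and the core in-memory carriers.

Everything downstream works on :class:`NucSeq` (a nucleotide sequence with an
*explicit* topology flag — FASTA has no standard way to say "circular", and
silently guessing is exactly the ambiguity this toolkit exists to resolve) and
:class:`AlignmentRecord` (the minimal mapped-read abstraction a pileup needs).

Coordinates are 0-based half-open everywhere inside the package; 1-based
inclusive positions appear only in user-facing report tables.  On a circular
reference an interval may run past the sequence end (``end <= start + L``),
meaning it wraps once through the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import InputError, ParameterError, ParseError

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

TOPOLOGY_TAG = "[topology=circular]"


def revcomp_str(bases: str) -> str:
    """Reverse complement of a plain base string (N maps to N)."""
    return bases.translate(_COMPLEMENT)[::-1]


def circular_slice(bases: str, start: int, end: int) -> str:
    """Slice ``[start, end)`` of a circular sequence, wrapping once if
    ``end`` exceeds the sequence length."""
    L = len(bases)
    if not 0 <= start < L:
        raise ParameterError(f"slice start {start} outside [0, {L})")
    if end < start or end > start + L:
        raise ParameterError(f"slice end {end} not in [{start}, {start + L}]")
    if end <= L:
        return bases[start:end]
    return bases[start:] + bases[: end - L]


@dataclass(frozen=True)
class NucSeq:
    """A nucleotide sequence with declared topology.

    Parameters
    ----------
    id : str
        Sequence identifier (FASTA id).
    bases : str
        Uppercase bases over ``{A, C, G, T, N}``.
    topology : {"linear", "circular"}
        Whether the molecule is a circle.  Never inferred silently.
    """

    id: str
    bases: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ParameterError(f"unknown topology {self.topology!r}")
        if len(self.bases) < 1:
            raise ParameterError(f"sequence {self.id!r} is empty")
        if not self.bases.isupper():
            object.__setattr__(self, "bases", self.bases.upper())
        bad = set(self.bases) - VALID_BASES
        if bad:
            raise ParseError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.bases)

    @property
    def is_circular(self) -> bool:
        return self.topology == "circular"

    def fetch(self, start: int, end: int) -> str:
        """Bases of ``[start, end)``; wraps through the origin when circular."""
        if not self.is_circular and end > len(self.bases):
            raise ParameterError(
                f"interval [{start}, {end}) exceeds linear sequence of length {len(self)}"
            )
        return circular_slice(self.bases, start, end)

    def revcomp(self, new_id: str | None = None) -> "NucSeq":
        return NucSeq(new_id or self.id, revcomp_str(self.bases), self.topology)


@dataclass(frozen=True)
class FastqRead:
    """A sequencing read with per-base qualities (Sanger/Phred+33)."""

    id: str
    bases: str
    quality: str

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quality):
            raise ParseError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.bases)}"
            )

    def __len__(self) -> int:
        return len(self.bases)


# --------------------------------------------------------------------------- #
# FASTA / FASTQ
# --------------------------------------------------------------------------- #

def read_fasta(path: str | Path, default_topology: str = "linear") -> list[NucSeq]:
    """Read FASTA records into :class:`NucSeq`.

    Topology is ``default_topology`` unless the description line carries a
    ``[topology=circular]`` tag.
    """
    path = Path(path)
    out: list[NucSeq] = []
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            topo = "circular" if TOPOLOGY_TAG in rec.description else default_topology
            out.append(NucSeq(rec.id, str(rec.seq).upper(), topo))
    except ValueError as exc:  # malformed record
        raise ParseError(f"{path}: {exc}") from exc
    return out


def write_fasta(seqs: Iterable[NucSeq], path: str | Path, width: int = 70) -> None:
    """Write sequences to FASTA, tagging circular records in the description."""
    with open(path, "w") as fh:
        for s in seqs:
            header = s.id + (f" {TOPOLOGY_TAG}" if s.is_circular else "")
            fh.write(f">{header}\n")
            for i in range(0, len(s.bases), width):
                fh.write(s.bases[i : i + width] + "\n")


def read_fastq(path: str | Path) -> list[FastqRead]:
    path = Path(path)
    out: list[FastqRead] = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
            out.append(FastqRead(rec.id, str(rec.seq).upper(), qual))
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return out


def write_fastq(reads: Iterable, path: str | Path) -> None:
    """Write anything with ``id``/``bases``/``quality`` attributes as FASTQ."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.bases}\n+\n{r.quality}\n")


# --------------------------------------------------------------------------- #
# Alignments
# --------------------------------------------------------------------------- #

#: edit-string ops: "=" match, "X" mismatch, "I" insertion to reference,
#: "D" deletion from reference.  "=" and "X" consume both sequences, "I" the
#: read only, "D" the reference only.
EDIT_OPS = ("=", "X", "I", "D")
_REF_CONSUMING = frozenset("=XD")
_READ_CONSUMING = frozenset("=XI")


@dataclass(frozen=True)
class AlignmentRecord:
    """A read aligned to a reference interval.

    ``read_bases`` is the aligned portion of the read *in reference
    orientation* (reverse-complemented for ``strand == "-"``), which is what a
    pileup consumes; soft-clipped bases are excluded.  ``edit`` is a
    run-length encoded tuple of ``(op, length)`` over :data:`EDIT_OPS`.
    On a circular reference ``ref_end`` may exceed the reference length,
    meaning the alignment wraps through the origin.
    """

    read_id: str
    ref_id: str
    ref_start: int
    ref_end: int
    strand: str
    edit: tuple[tuple[str, int], ...]
    identity: float
    read_bases: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ParameterError(f"strand must be + or -, got {self.strand!r}")
        ref_len = sum(n for op, n in self.edit if op in _REF_CONSUMING)
        read_len = sum(n for op, n in self.edit if op in _READ_CONSUMING)
        if ref_len != self.ref_end - self.ref_start:
            raise InputError(
                f"{self.read_id}: edit string consumes {ref_len} reference bases "
                f"but interval is {self.ref_end - self.ref_start}"
            )
        if read_len != len(self.read_bases):
            raise InputError(
                f"{self.read_id}: edit string consumes {read_len} read bases "
                f"but {len(self.read_bases)} given"
            )

    @property
    def ref_interval(self) -> tuple[int, int]:
        return (self.ref_start, self.ref_end)


def edit_from_cigar(cigar: str) -> tuple[tuple[str, int], ...]:
    """Parse an extended-CIGAR string (``"100=1X49="``) into edit runs."""
    runs: list[tuple[str, int]] = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            if ch not in EDIT_OPS or not num:
                raise ParseError(f"bad CIGAR {cigar!r}")
            runs.append((ch, int(num)))
            num = ""
    if num:
        raise ParseError(f"bad CIGAR {cigar!r}")
    return tuple(runs)


def identity_from_edit(edit: Sequence[tuple[str, int]]) -> float:
    """Matched columns over total alignment columns."""
    total = sum(n for _, n in edit)
    match = sum(n for op, n in edit if op == "=")
    return match / total if total else 0.0


@dataclass
class IngestResult:
    """Alignments ingested from a SAM file, with skip counters."""

    records: list[AlignmentRecord] = field(default_factory=list)
    n_unmapped: int = 0
    n_secondary: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_alignments(
    path: str | Path,
    references: Mapping[str, NucSeq] | Sequence[NucSeq] | None = None,
) -> IngestResult:
    """Ingest a SAM-dialect text alignment file.

    Only the fields a pileup needs are kept (interval, strand, alignment
    columns); tags are ignored.  ``M`` CIGAR ops are resolved into ``=``/``X``
    against ``references`` (required if any ``M`` is present).  Unmapped and
    secondary/supplementary records are skipped and counted.
    """
    import pysam

    if references is not None and not isinstance(references, Mapping):
        references = {s.id: s for s in references}

    result = IngestResult()
    try:
        sam = pysam.AlignmentFile(str(path), "r", check_sq=False)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    known = set(sam.references)
    with sam:
        for rec in sam:
            if rec.is_unmapped:
                result.n_unmapped += 1
                continue
            if rec.is_secondary or rec.is_supplementary:
                result.n_secondary += 1
                continue
            ref_name = rec.reference_name
            if ref_name not in known:
                raise InputError(f"unknown reference name {ref_name!r}")
            ref_seq = None
            if references is not None:
                if ref_name not in references:
                    raise InputError(f"unknown reference name {ref_name!r}")
                ref_seq = references[ref_name]
            result.records.append(_record_from_pysam(rec, ref_seq))
    return result


def _record_from_pysam(rec, ref_seq: NucSeq | None) -> AlignmentRecord:
    read_bases = rec.query_alignment_sequence
    if read_bases is None:
        raise ParseError(f"{rec.query_name}: SAM record lacks a sequence")
    read_bases = read_bases.upper()
    edit: list[tuple[str, int]] = []
    ref_cursor = rec.reference_start
    read_cursor = 0
    for op, n in rec.cigartuples:
        if op in (4, 5):  # S, H: clipped, not part of the aligned portion
            continue
        if op == 0:  # M: resolve against the reference
            if ref_seq is None:
                raise InputError(
                    f"{rec.query_name}: CIGAR 'M' requires reference sequences"
                )
            ref_chunk = ref_seq.fetch(ref_cursor, ref_cursor + n)
            read_chunk = read_bases[read_cursor : read_cursor + n]
            run_op, run_len = None, 0
            for a, b in zip(read_chunk, ref_chunk):
                this = "=" if a == b else "X"
                if this == run_op:
                    run_len += 1
                else:
                    if run_op:
                        edit.append((run_op, run_len))
                    run_op, run_len = this, 1
            if run_op:
                edit.append((run_op, run_len))
            ref_cursor += n
            read_cursor += n
        elif op == 7:  # =
            edit.append(("=", n))
            ref_cursor += n
            read_cursor += n
        elif op == 8:  # X
            edit.append(("X", n))
            ref_cursor += n
            read_cursor += n
        elif op == 1:  # I
            edit.append(("I", n))
            read_cursor += n
        elif op == 2:  # D
            edit.append(("D", n))
            ref_cursor += n
        else:
            raise ParseError(
                f"{rec.query_name}: unsupported CIGAR op code {op}"
            )
    merged = _merge_runs(edit)
    return AlignmentRecord(
        read_id=rec.query_name,
        ref_id=rec.reference_name,
        ref_start=rec.reference_start,
        ref_end=ref_cursor,
        strand="-" if rec.is_reverse else "+",
        edit=merged,
        identity=identity_from_edit(merged),
        read_bases=read_bases,
    )


def _merge_runs(runs: Sequence[tuple[str, int]]) -> tuple[tuple[str, int], ...]:
    out: list[tuple[str, int]] = []
    for op, n in runs:
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))
    return tuple(out)


# --------------------------------------------------------------------------- #
# BED / TSV
# --------------------------------------------------------------------------- #

def write_bed(
    intervals: Iterable[tuple[str, int, int, str]], path: str | Path
) -> None:
    """Write ``(chrom, start, end, name)`` rows as 0-based half-open BED."""
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def write_tsv(df, path: str | Path, comment: str | None = None) -> None:
    """Write a DataFrame as TSV with an optional leading comment line."""
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        df.to_csv(fh, sep="\t", index=False)
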