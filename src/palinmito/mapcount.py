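"""Lightweight read mapping and per-site allele counting (pileup).

The mapper is a seed-and-extend aligner sized for desk-scale synthetic data:
exact k-mer seeds on both strands, a Hamming fast path for gap-free
candidates, and a banded edit-distance fallback (edlib) when indels are
suspected.  Reads with tied best placements are dropped by default (no random
placement): on the collapsed mitochondrial unit every arm-interior read has a
unique home, and ambiguity arises only for junction-spanning reads in dimer
coordinates — dropping them is precisely the collapse-to-unit strategy.

The pileup applies the standard convention that makes dimer asymmetries
visible: reverse-strand reads are complemented onto the reference strand
before counting, so the two inverted arms of a dimer stack onto the same unit
coordinates and a planted arm difference shows up as a ~50:50 allele mixture.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import namedtuple
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .palindrome import MitoUnit
from .seqio import (
    AlignmentRecord,
    NucSeq,
    identity_from_edit,
    edit_from_cigar,
    revcomp_str,
    write_tsv,
)

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


def _ref_seq(reference: NucSeq | MitoUnit) -> NucSeq:
    return reference.sequence if isinstance(reference, MitoUnit) else reference


@dataclass(frozen=True)
class MapParams:
    """Mapper tuning.

    ``min_identity`` defaults to the short-read setting (0.9); use ~0.8 for
    noisy long reads.  ``band_frac`` sizes the edit-distance band and window
    padding as a fraction of read length.  ``on_tie``: "drop" discards reads
    with tied best placements, "random" places them uniformly (seeded).
    """

    k: int = 15
    min_identity: float = 0.9
    band_frac: float = 0.2
    on_tie: str = "drop"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.min_identity <= 1:
            raise ParameterError("min_identity must be in (0, 1]")
        if self.on_tie not in ("drop", "random"):
            raise ParameterError("on_tie must be 'drop' or 'random'")
        if self.k < 4:
            raise ParameterError("seed k must be >= 4")


class ReferenceIndex:
    """Exact k-mer index of a reference (doubled when circular)."""

    def __init__(self, reference: NucSeq | MitoUnit, k: int = 15):
        seq = _ref_seq(reference)
        self.reference = reference
        self.ref_id = seq.id
        self.L = len(seq)
        self.circular = seq.is_circular
        if k > self.L:
            raise ParameterError(f"k={k} larger than reference ({self.L} bp)")
        self.k = k
        self.stored = seq.bases + seq.bases if self.circular else seq.bases
        index: dict[str, list[int]] = {}
        n_starts = self.L if self.circular else self.L - k + 1
        for j in range(n_starts):
            index.setdefault(self.stored[j : j + k], []).append(j)
        self._index = index

    def seed_hits(self, kmer: str) -> list[int]:
        return self._index.get(kmer, ())


def map_read(
    bases: str,
    index: ReferenceIndex,
    params: MapParams = MapParams(),
    read_id: str = "read",
    rng: np.random.Generator | None = None,
) -> AlignmentRecord | None:
    """Map one read against the indexed reference.

    Returns the unique best alignment with identity >= ``params.min_identity``,
    or ``None`` for unmappable or ambiguous (tied-best) reads.  Deterministic
    (unless ``on_tie='random'``, which uses the supplied rng).
    """
    n = len(bases)
    k = index.k
    if n < k or n > index.L:
        return None
    max_edits = int((1 - params.min_identity) * n)
    offsets = sorted({0, n // 2, n - k})
    candidates: dict[tuple[int, str], None] = {}
    oriented = {"+": bases, "-": revcomp_str(bases)}
    for strand, q in oriented.items():
        for o in offsets:
            for pos in index.seed_hits(q[o : o + k]):
                start = pos - o
                if index.circular:
                    candidates[(start % index.L, strand)] = None
                elif 0 <= start <= index.L - n:
                    candidates[(start, strand)] = None
    if not candidates:
        return None

    scored: list[tuple[int, int, int, str, object]] = []
    for (start, strand), _ in candidates.items():
        q = oriented[strand]
        refseg = index.stored[start : start + n]
        if refseg == q:
            scored.append((0, start, start + n, strand, None))
            continue
        qa = np.frombuffer(q.encode(), dtype=np.uint8)
        ra = np.frombuffer(refseg.encode(), dtype=np.uint8)
        ham = int((qa != ra).sum())
        if ham <= max_edits:
            scored.append((ham, start, start + n, strand, ("ham", qa != ra)))
            continue
        pad = max(8, int(params.band_frac * n))
        w_lo = max(0, start - pad)
        w_hi = min(len(index.stored), start + n + pad)
        res = edlib.align(
            q, index.stored[w_lo:w_hi], mode="HW", task="path", k=max_edits
        )
        if res["editDistance"] < 0:
            continue
        loc = res["locations"][0]
        scored.append(
            (
                res["editDistance"],
                w_lo + loc[0],
                w_lo + loc[1] + 1,
                strand,
                ("cigar", res["cigar"]),
            )
        )
    if not scored:
        return None
    scored.sort(key=lambda t: (t[0], t[1], t[3]))
    best = scored[0]
    ties = [
        t
        for t in scored
        if t[0] == best[0] and (t[1] % index.L, t[3]) != (best[1] % index.L, best[3])
    ]
    if ties:
        if params.on_tie == "drop":
            return None
        pick = (rng or np.random.default_rng(params.seed)).integers(len(ties) + 1)
        best = ([best] + ties)[int(pick)]

    edits, start, end, strand, payload = best
    q = oriented[strand]
    if payload is None:
        edit = (("=", n),)
    elif payload[0] == "ham":
        edit = _runs_from_mismatch_mask(payload[1])
    else:
        edit = edit_from_cigar(payload[1])
    identity = identity_from_edit(edit)
    if identity < params.min_identity:
        return None
    ref_start = start % index.L if index.circular else start
    ref_end = ref_start + (end - start)
    return AlignmentRecord(
        read_id=read_id,
        ref_id=index.ref_id,
        ref_start=ref_start,
        ref_end=ref_end,
        strand=strand,
        edit=edit,
        identity=identity,
        read_bases=q,
    )


def _runs_from_mismatch_mask(mask: np.ndarray) -> tuple[tuple[str, int], ...]:
    runs: list[tuple[str, int]] = []
    ops = np.where(mask, 1, 0)
    boundaries = np.flatnonzero(np.diff(ops)) + 1
    start = 0
    for b in list(boundaries) + [len(ops)]:
        runs.append(("X" if ops[start] else "=", b - start))
        start = b
    return tuple(runs)


@dataclass
class MapResult:
    """Batch-mapping outcome with skip counters."""

    records: list[AlignmentRecord] = field(default_factory=list)
    n_unmapped: int = 0
    n_ambiguous_or_short: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self):
        return len(self.records)


def map_reads(
    reads: Iterable,
    index: ReferenceIndex,
    params: MapParams = MapParams(),
) -> MapResult:
    """Map a batch of reads (anything with ``id`` and ``bases`` attributes,
    or plain strings)."""
    rng = np.random.default_rng(params.seed)
    out = MapResult()
    for i, r in enumerate(reads):
        bases = r if isinstance(r, str) else r.bases
        rid = f"read{i}" if isinstance(r, str) else r.id
        if len(bases) < index.k:
            out.n_ambiguous_or_short += 1
            continue
        rec = map_read(bases, index, params, read_id=rid, rng=rng)
        if rec is None:
            out.n_unmapped += 1
        else:
            out.records.append(rec)
    return out


# --------------------------------------------------------------------------- #
# Pileup
# --------------------------------------------------------------------------- #

SiteCounts = namedtuple(
    "SiteCounts", ["position", "A", "C", "G", "T", "dels", "ins", "depth"]
)


class PileupTable:
    """Column-wise per-position allele counts over a reference.

    Rows cover positions ``1..L`` (1-based in reports, 0-based internally).
    ``counts[i, j]`` is the number of read bases ``"ACGT"[j]`` observed at
    position ``i`` on the reference strand; ``dels``/``ins`` are deletion and
    insertion observations (insertions anchored to the following position).
    """

    def __init__(
        self,
        counts: np.ndarray,
        dels: np.ndarray | None = None,
        ins: np.ndarray | None = None,
        positions: np.ndarray | None = None,
    ):
        counts = np.asarray(counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[1] != 4:
            raise ParameterError("counts must be (L, 4)")
        L = counts.shape[0]
        self.counts = counts
        self.dels = np.zeros(L, np.int64) if dels is None else np.asarray(dels, np.int64)
        self.ins = np.zeros(L, np.int64) if ins is None else np.asarray(ins, np.int64)
        self.positions = (
            np.arange(1, L + 1) if positions is None else np.asarray(positions)
        )
        if (self.counts < 0).any() or (self.dels < 0).any() or (self.ins < 0).any():
            raise ParameterError("counts must be nonnegative")

    def __len__(self) -> int:
        return self.counts.shape[0]

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def site(self, i: int) -> SiteCounts:
        a, c, g, t = (int(x) for x in self.counts[i])
        return SiteCounts(
            int(self.positions[i]), a, c, g, t,
            int(self.dels[i]), int(self.ins[i]), a + c + g + t,
        )

    def iter_sites(self):
        for i in range(len(self)):
            yield self.site(i)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "A": self.counts[:, 0],
                "C": self.counts[:, 1],
                "G": self.counts[:, 2],
                "T": self.counts[:, 3],
                "del": self.dels,
                "ins": self.ins,
                "depth": self.depth,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        write_tsv(self.to_dataframe(), path)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PileupTable":
        counts = df[["A", "C", "G", "T"]].to_numpy(np.int64)
        return cls(
            counts,
            df["del"].to_numpy(np.int64) if "del" in df else None,
            df["ins"].to_numpy(np.int64) if "ins" in df else None,
            df["position"].to_numpy(np.int64),
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PileupTable":
        return cls.from_dataframe(pd.read_csv(path, sep="\t", comment="#"))


def pileup(
    alignments: Iterable[AlignmentRecord],
    reference: NucSeq | MitoUnit,
) -> PileupTable:
    """Tally aligned read bases per reference position.

    Reverse-strand alignments were already complemented onto the reference
    strand when the record was built (``read_bases`` is reference-oriented),
    so counting is strand-agnostic here — this is what collapses the dimer's
    two arms into one signal.  Indels are tallied at their anchor positions.
    Wrapping alignments on a circular reference are folded modulo its length.
    """
    seq = _ref_seq(reference)
    L = len(seq)
    circular = seq.is_circular
    counts = np.zeros((L, 4), dtype=np.int64)
    dels = np.zeros(L, dtype=np.int64)
    ins = np.zeros(L, dtype=np.int64)
    for aln in alignments:
        if aln.ref_id != seq.id:
            raise InputError(
                f"alignment {aln.read_id} refers to {aln.ref_id!r}, not {seq.id!r}"
            )
        if aln.ref_end > (2 * L if circular else L) or aln.ref_start < 0:
            raise InputError(f"alignment {aln.read_id} outside reference bounds")
        codes = _BASE_CODE[np.frombuffer(aln.read_bases.encode(), dtype=np.uint8)]
        rc, qc = aln.ref_start, 0
        for op, num in aln.edit:
            if op in "=X":
                pos = np.arange(rc, rc + num)
                if circular:
                    pos %= L
                seg = codes[qc : qc + num]
                valid = seg >= 0  # skip N bases
                np.add.at(counts, (pos[valid], seg[valid]), 1)
                rc += num
                qc += num
            elif op == "D":
                pos = np.arange(rc, rc + num)
                if circular:
                    pos %= L
                dels[pos] += 1
                rc += num
            elif op == "I":
                ins[rc % L if circular else rc] += 1
                qc += num
    return PileupTable(counts, dels, ins)


def depth_vector(
    alignments: Iterable[AlignmentRecord], length: int, circular: bool = True
) -> np.ndarray:
    """Per-position coverage from alignment reference intervals."""
    diff = np.zeros(length + 1, dtype=np.int64)
    for aln in alignments:
        s, e = aln.ref_start, aln.ref_end
        if e <= length:
            diff[s] += 1
            diff[e] -= 1
        elif circular:
            diff[s] += 1
            diff[length] -= 1
            diff[0] += 1
            diff[e - length] -= 1
        else:
            raise InputError("wrapping alignment on a linear reference")
    return np.cumsum(diff[:length])


def count_reads(
    reference: NucSeq | MitoUnit,
    reads: Iterable,
    params: MapParams = MapParams(),
) -> tuple[PileupTable, MapResult]:
    """Convenience pipeline: index, map, and pile up a read set."""
    index = ReferenceIndex(reference, k=params.k)
    result = map_reads(reads, index, params)
    return pileup(result.records, reference), result
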