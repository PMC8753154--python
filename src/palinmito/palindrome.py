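"""Inverted-repeat (palindromic dimer) architecture detection.

A dimeric mitochondrial chromosome is a circle of the form
``arm1 + junction_small + revcomp(arm2) + junction_large`` with
``arm2 ~ arm1``: in a self-vs-reverse-complement dotplot the two arms appear
as long anti-diagonal chains of exact k-mer matches.  This module automates
the classical manual dotplot inspection: it indexes the reverse complement,
chains co-diagonal k-mer hits (merging across gaps whose base-level identity
stays high, so isolated mismatches such as asymmetric sites or polish noise
do not split an arm), extends chain ends base-by-base with an X-drop rule,
and reports the best arm pair with its junctions.

Circularity is handled by doubling both the contig and its reverse complement
and deduplicating candidate arm pairs modulo the contig length.

Intervals are 0-based half-open; on a circle ``end`` may exceed the contig
length, meaning the interval wraps through the origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InputError, ParameterError
from .seqio import NucSeq, revcomp_str


def revcomp(seq: NucSeq) -> NucSeq:
    """Reverse complement of a :class:`NucSeq` (N maps to N)."""
    return seq.revcomp()


@dataclass(frozen=True)
class RepeatArchitecture:
    """Detected inverted-repeat architecture of a contig.

    ``arm1`` is, by convention, the arm that immediately follows
    ``junction_small`` going forward around the circle; ``arm2`` is its
    reverse-complement partner.  ``arm_identity`` is the fraction of matching
    bases between arm1 and revcomp(arm2).
    """

    contig_id: str
    contig_len: int
    arm1: tuple[int, int]
    arm2: tuple[int, int]
    junction_small: tuple[int, int]
    junction_large: tuple[int, int]
    arm_identity: float
    arm_len: int

    def __post_init__(self) -> None:
        if not 0 < self.arm_identity <= 1:
            raise ParameterError("arm_identity must be in (0, 1]")
        if (self.arm1[1] - self.arm1[0]) != (self.arm2[1] - self.arm2[0]):
            raise InputError("arm lengths differ")
        js = self.junction_small[1] - self.junction_small[0]
        jl = self.junction_large[1] - self.junction_large[0]
        if js > jl:
            raise InputError("junction_small longer than junction_large")
        total = 2 * self.arm_len + js + jl
        if total != self.contig_len:
            raise InputError(
                f"arms + junctions cover {total} bp but contig is {self.contig_len} bp"
            )

    @property
    def junction_lengths(self) -> tuple[int, int]:
        return (
            self.junction_small[1] - self.junction_small[0],
            self.junction_large[1] - self.junction_large[0],
        )

    def arm_pair_key(self) -> tuple:
        """Rotation-stable unordered key for comparing detected arms."""
        a = (self.arm1[0] % self.contig_len, self.arm_len)
        b = (self.arm2[0] % self.contig_len, self.arm_len)
        return tuple(sorted((a, b)))


@dataclass(frozen=True)
class MitoUnit:
    """The collapsed mitochondrial unit extracted from a dimer.

    Layout convention: ``junction_small + arm1 + junction_large``.  The
    ``components`` coordinate map (source interval on the dimer, strand) — not
    the layout — is authoritative for tracing unit positions back to the
    dimer.
    """

    sequence: NucSeq
    components: tuple[tuple[tuple[int, int], str], ...]
    unit_len: int

    def __post_init__(self) -> None:
        if self.sequence.is_circular:
            raise InputError("unit sequence must be linear")
        tiled = sum(iv[1] - iv[0] for iv, _ in self.components)
        if tiled != self.unit_len or self.unit_len != len(self.sequence):
            raise InputError("component intervals do not tile the unit")


# --------------------------------------------------------------------------- #
# Detection
# --------------------------------------------------------------------------- #

def _kmer_hits(s2: str, r2: str, k: int) -> list[tuple[int, int]]:
    """(diagonal, position) pairs of exact k-mer matches between s2 and r2."""
    index: dict[str, list[int]] = {}
    for j in range(len(r2) - k + 1):
        index.setdefault(r2[j : j + k], []).append(j)
    hits: list[tuple[int, int]] = []
    for i in range(len(s2) - k + 1):
        js = index.get(s2[i : i + k])
        if js:
            for j in js:
                hits.append((i - j, i))
    return hits


def _match_mask(s2: np.ndarray, r2: np.ndarray, d: int, lo: int, hi: int) -> np.ndarray:
    """Base-level match mask of S2[lo:hi] against R2 shifted by diagonal d."""
    return s2[lo:hi] == r2[lo - d : hi - d]


def _chain_diagonal(
    positions: np.ndarray,
    k: int,
    s2: np.ndarray,
    r2: np.ndarray,
    d: int,
    min_identity: float,
    max_gap: int,
) -> list[tuple[int, int]]:
    """Merge sorted k-mer start positions on one diagonal into runs.

    Adjacent runs are merged when the gap between them carries only sparse
    mismatches (isolated substitutions split exact k-mer chains without
    breaking the underlying repeat), but never across dense-mismatch
    stretches such as junction sequence.  The allowance is
    ``max(4, 2*(1 - min_identity)*gap)`` mismatching bases per gap, which
    rides over small mutation clusters while a random (~75% mismatch)
    junction of ≳15 bp still always splits the chain.
    Returns matched intervals ``[start, end)`` in S2 coordinates.
    """
    runs: list[tuple[int, int]] = []
    start = prev = int(positions[0])
    mm_frac = 2.0 * (1.0 - min_identity)
    for pos in positions[1:]:
        pos = int(pos)
        gap = pos - (prev + 1)
        if gap <= 0:
            prev = pos
            continue
        gap_lo, gap_hi = prev + k, pos
        merged = False
        if gap_hi - gap_lo <= max_gap:
            if gap_hi <= gap_lo:
                merged = True  # overlapping k-mers, no uncovered bases
            else:
                gap_len = gap_hi - gap_lo
                n_mm = int((~_match_mask(s2, r2, d, gap_lo, gap_hi)).sum())
                merged = n_mm <= max(4.0, mm_frac * gap_len)
        if merged:
            prev = pos
        else:
            runs.append((start, prev + k))
            start = prev = pos
    runs.append((start, prev + k))
    return runs


def _xdrop_extend(
    s2: np.ndarray,
    r2: np.ndarray,
    d: int,
    lo: int,
    hi: int,
    x_drop: int = 5,
    match: int = 1,
    mismatch: int = -3,
) -> tuple[int, int]:
    """Extend [lo, hi) along diagonal d in both directions, X-drop trimmed."""
    n2 = len(s2)
    # right
    best, cur, best_pos = 0, 0, hi
    p = hi
    while p < n2 and p - d < n2:
        cur += match if s2[p] == r2[p - d] else mismatch
        p += 1
        if cur > best:
            best, best_pos = cur, p
        elif cur < best - x_drop:
            break
    hi = best_pos
    # left
    best, cur, best_pos = 0, 0, lo
    p = lo - 1
    while p >= 0 and p - d >= 0:
        cur += match if s2[p] == r2[p - d] else mismatch
        if cur > best:
            best, best_pos = cur, p
        elif cur < best - x_drop:
            break
        p -= 1
    return best_pos, hi


def detect_architecture(
    contig: NucSeq,
    k: int = 15,
    min_arm: int = 200,
    min_identity: float = 0.95,
    max_gap: int = 2000,
    x_drop: int = 5,
) -> RepeatArchitecture | None:
    """Detect the inverted-repeat arm pair of a (circular) contig.

    Returns the best architecture with ``arm_len >= min_arm`` and arm
    identity ``>= min_identity``, or ``None`` if no qualifying arm pair
    exists.  Deterministic: ties are broken by longest arm, then smallest
    start coordinate.

    A linear contig is accepted with a warning; wrap-around matches are then
    not considered.
    """
    L = len(contig)
    if k > L:
        raise ParameterError(f"k={k} larger than contig ({L} bp)")
    if not contig.is_circular:
        warnings.warn(
            f"contig {contig.id!r} is linear: wrap-around arms will be missed",
            stacklevel=2,
        )
    s = contig.bases
    r = revcomp_str(s)
    if contig.is_circular:
        s2_str, r2_str = s + s, r + r
    else:
        s2_str, r2_str = s, r
    s2 = np.frombuffer(s2_str.encode(), dtype=np.uint8)
    r2 = np.frombuffer(r2_str.encode(), dtype=np.uint8)

    hits = _kmer_hits(s2_str, r2_str, k)
    if not hits:
        return None
    hits.sort()
    candidates: dict[tuple, tuple] = {}
    hits_arr = np.asarray(hits)
    diags = hits_arr[:, 0]
    bounds = np.flatnonzero(np.diff(diags) != 0) + 1
    start_idx = 0
    split_points = list(bounds) + [len(hits_arr)]
    for end_idx in split_points:
        group = hits_arr[start_idx:end_idx]
        start_idx = end_idx
        if len(group) == 0:
            continue
        d = int(group[0, 0])
        runs = _chain_diagonal(
            group[:, 1], k, s2, r2, d, min_identity, max_gap
        )
        for lo, hi in runs:
            if hi - lo < min_arm:
                continue
            lo, hi = _xdrop_extend(s2, r2, d, lo, hi, x_drop=x_drop)
            n = hi - lo
            if n < min_arm:
                continue
            n = min(n, L)
            cand = _normalise_pair(lo, lo + n, d, L)
            if cand is None:
                continue
            key, (a, b) = cand
            if key not in candidates:
                ident = _pair_identity(s, a, b, L)
                if ident >= min_identity:
                    candidates[key] = (a, b, ident)
    if not candidates:
        return None
    best = max(
        candidates.values(),
        key=lambda t: (t[0][1] - t[0][0], -min(t[0][0], t[1][0])),
    )
    return _build_architecture(contig, best)


def _normalise_pair(x0: int, x1: int, d: int, L: int):
    """Map an S2/R2 diagonal run to a canonical unordered arm pair mod L."""
    n = x1 - x0
    j1 = x1 - d  # exclusive end in R2 coordinates
    a_start = x0 % L
    b_start = (L - j1) % L
    a = (a_start, a_start + n)
    b = (b_start, b_start + n)
    # overlap (self-palindromic chain) → not a two-arm architecture
    if _circ_overlap(a, b, L):
        return None
    key = tuple(sorted((a, b)))
    return key, key


def _circ_overlap(a: tuple[int, int], b: tuple[int, int], L: int) -> bool:
    def spans(iv):
        s, e = iv
        if e <= L:
            return [(s, e)]
        return [(s, L), (0, e - L)]

    for s1, e1 in spans(a):
        for s2_, e2 in spans(b):
            if s1 < e2 and s2_ < e1:
                return True
    return False


def _pair_identity(s: str, a: tuple[int, int], b: tuple[int, int], L: int) -> float:
    from .seqio import circular_slice

    arm_a = circular_slice(s, a[0], a[1])
    arm_b = circular_slice(s, b[0], b[1])
    x = np.frombuffer(arm_a.encode(), dtype=np.uint8)
    y = np.frombuffer(revcomp_str(arm_b).encode(), dtype=np.uint8)
    return float((x == y).mean())


def _build_architecture(contig: NucSeq, best: tuple) -> RepeatArchitecture | None:
    a, b, ident = best
    L = len(contig)
    n = a[1] - a[0]
    # junction from end of a to start of b, and end of b to start of a
    gap_ab = (b[0] - a[1]) % L
    gap_ba = (a[0] - b[1]) % L
    if gap_ab == 0 and gap_ba == 0:
        return None
    j_a = (a[1] % L, a[1] % L + gap_ab)  # follows arm a
    j_b = (b[1] % L, b[1] % L + gap_ba)  # follows arm b
    if (gap_ab, j_a[0]) <= (gap_ba, j_b[0]):
        junction_small, junction_large = j_a, j_b
        arm1, arm2 = b, a  # arm after j_a is b
    else:
        junction_small, junction_large = j_b, j_a
        arm1, arm2 = a, b
    return RepeatArchitecture(
        contig_id=contig.id,
        contig_len=L,
        arm1=arm1,
        arm2=arm2,
        junction_small=junction_small,
        junction_large=junction_large,
        arm_identity=ident,
        arm_len=n,
    )


# --------------------------------------------------------------------------- #
# Unit extraction and canonical form
# --------------------------------------------------------------------------- #

def extract_unit(contig: NucSeq, arch: RepeatArchitecture) -> MitoUnit:
    """Extract the collapsed unit: junction_small + arm1 + junction_large.

    The component map records, for each unit segment, its source interval on
    the dimer and strand (always ``+`` under this layout).
    """
    if arch.contig_id != contig.id or arch.contig_len != len(contig):
        raise InputError("architecture does not belong to this contig")
    L = len(contig)
    js_len, jl_len = arch.junction_lengths
    start = arch.junction_small[0]
    total = js_len + arch.arm_len + jl_len
    bases = contig.fetch(start, start + total)
    arm1_iv = (arch.junction_small[1] % L, arch.junction_small[1] % L + arch.arm_len)
    components = (
        (arch.junction_small, "+"),
        (arm1_iv, "+"),
        (arch.junction_large, "+"),
    )
    seq = NucSeq(f"{contig.id}|unit", bases, "linear")
    return MitoUnit(sequence=seq, components=components, unit_len=total)


def canonical_rotation(contig: NucSeq, arch: RepeatArchitecture) -> NucSeq:
    """Rotate (and possibly flip) the dimer into a stable reporting frame.

    Position 0 becomes the first base of a smallest junction, with the circle
    read so that an arm follows it.  Among the qualifying start points on
    both strands (two junctions may tie in length), the lexicographically
    smallest linearisation wins, making the result invariant to rotation and
    strand of the input.
    """
    from .seqio import circular_slice

    if not contig.is_circular:
        raise InputError("canonical rotation requires a circular contig")
    L = len(contig)
    js_len, jl_len = arch.junction_lengths
    starts_fwd = [arch.junction_small[0] % L]
    if jl_len == js_len:
        starts_fwd.append(arch.junction_large[0] % L)
    candidates = []
    for s0 in starts_fwd:
        candidates.append(circular_slice(contig.bases, s0, s0 + L))
    rc = revcomp_str(contig.bases)
    # interval [s, e) maps to [(L - e) % L, ...) on the reverse strand
    for junction, j_len in (
        (arch.junction_small, js_len),
        (arch.junction_large, jl_len),
    ):
        if j_len != js_len:
            continue
        s0 = (L - junction[1]) % L
        candidates.append(circular_slice(rc, s0, s0 + L))
    best = min(candidates)
    return NucSeq(f"{contig.id}|canonical", best, "circular")
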