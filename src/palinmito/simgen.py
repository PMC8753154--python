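"""Synthetic atypical-mitogenome simulator with structural ground truth.

The model emulated here is the two-chromosome mitochondrial architecture found
in several isopod lineages: a circular *dimer* made of two inverted
(reverse-complementary) copies of the ~14.4 kb mitochondrial genome separated
by two short unique junctions, coexisting with a linear *monomer* carrying a
single copy capped by telomeric hairpins.  The two arms of the dimer differ at
a handful of planted single-base *asymmetric sites* (in real genomes these
re-assign tRNA anticodons), which is what produces ~50:50 allele mixtures when
reads are mapped to the collapsed unit.

Every generator is driven by a single seeded :class:`numpy.random.Generator`
per invocation, so identical configurations produce byte-identical output.

Coordinate conventions follow the rest of the package: 0-based half-open
internally, 1-based only in the user-facing truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .seqio import NucSeq, revcomp_str, write_bed, write_tsv

_BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def _quality_char(error_rate: float) -> str:
    if error_rate <= 0:
        return "I"  # Q40
    q = int(round(-10.0 * math.log10(error_rate)))
    return chr(33 + max(2, min(40, q)))


# --------------------------------------------------------------------------- #
# Configuration
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class LongReadParams:
    """Long-read (nanopore-like) simulation parameters.

    A read is either a full-length pass of a molecule (probability
    ``full_length_fraction``) or an exponentially sheared fragment with mean
    length ``1/shear_rate`` — the mixture that yields the characteristic
    multimodal length histogram (dominant short-fragment mass plus
    molecule-length modes).
    """

    n_reads: int = 2000
    full_length_fraction: float = 0.2
    shear_rate: float = 1.0 / 1400.0  # per bp; mean fragment ~1.4 kb
    substitution_error: float = 0.05
    min_len: int = 50

    def __post_init__(self) -> None:
        if not 0 <= self.full_length_fraction <= 1:
            raise ParameterError("full_length_fraction must be in [0, 1]")
        if self.shear_rate <= 0:
            raise ParameterError("shear_rate must be > 0")
        if not 0 <= self.substitution_error < 1:
            raise ParameterError("substitution_error must be in [0, 1)")
        if self.n_reads < 0 or self.min_len < 1:
            raise ParameterError("n_reads must be >= 0 and min_len >= 1")


@dataclass(frozen=True)
class ShortReadParams:
    """Short paired-read (Illumina-like) parameters.

    Default geometry is 150 bp paired-end reads from a 150 bp insert, i.e.
    fully overlapping mates.
    """

    n_pairs: int = 5000
    read_len: int = 150
    insert_len: int = 150
    substitution_error: float = 0.002

    def __post_init__(self) -> None:
        if self.read_len < 1 or self.insert_len < self.read_len:
            raise ParameterError("need 1 <= read_len <= insert_len")
        if not 0 <= self.substitution_error < 1:
            raise ParameterError("substitution_error must be in [0, 1)")
        if self.n_pairs < 0:
            raise ParameterError("n_pairs must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Full description of one simulated study.

    Defaults are the published architecture of the *Isocladus armatus*
    mitogenome: a 14 382 bp repeated unit, 155 bp and 591 bp junctions, three
    balanced asymmetric sites, and a positive GC skew flipping sign once at a
    designated origin position.

    ``asym_sites`` entries are ``(unit_position, arm1_base, arm2_base)`` with
    1-based positions on the arm.
    """

    seed: int
    unit_arm_len: int = 14382
    junction_small_len: int = 155
    junction_large_len: int = 591
    gc_fraction: float = 0.36
    skew_amplitude: float = 0.25
    skew_flip_pos: int | None = None  # default: arm midpoint
    asym_sites: tuple[tuple[int, str, str], ...] = (
        (20, "T", "C"),
        (9753, "A", "G"),
        (12226, "C", "G"),
    )
    dimer_monomer_ratio: float = 1.0
    long_read_params: LongReadParams = field(default_factory=LongReadParams)
    short_read_params: ShortReadParams = field(default_factory=ShortReadParams)
    hairpin_fail_prob: float = 0.8

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ParameterError("seed is mandatory")
        for name in ("unit_arm_len", "junction_small_len", "junction_large_len"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if not 0 <= self.gc_fraction <= 1:
            raise ParameterError("gc_fraction must be in [0, 1]")
        if not 0 <= self.skew_amplitude <= 1:
            raise ParameterError("skew_amplitude must be in [0, 1]")
        if not 0 <= self.hairpin_fail_prob <= 1:
            raise ParameterError("hairpin_fail_prob must be in [0, 1]")
        if self.dimer_monomer_ratio < 0:
            raise ParameterError("dimer_monomer_ratio must be >= 0")
        if self.skew_flip_pos is not None and not (
            0 <= self.skew_flip_pos <= self.unit_arm_len
        ):
            raise ParameterError("skew_flip_pos outside the arm")
        seen = set()
        for pos, b1, b2 in self.asym_sites:
            if not 1 <= pos <= self.unit_arm_len:
                raise ParameterError(f"asym position {pos} outside [1, arm]")
            if b1 not in _BASES or b2 not in _BASES:
                raise ParameterError(f"asym bases must be A/C/G/T, got {b1}/{b2}")
            if b1 == b2:
                raise ParameterError(f"asym site {pos}: arm1 and arm2 base equal")
            if pos in seen:
                raise ParameterError(f"asym position {pos} repeated")
            seen.add(pos)

    @property
    def flip_pos(self) -> int:
        return (
            self.skew_flip_pos
            if self.skew_flip_pos is not None
            else self.unit_arm_len // 2
        )

    def scaled(self, **overrides) -> "SimConfig":
        """A copy with fields replaced (convenience for desk-scale runs)."""
        return replace(self, **overrides)


def desk_scale_config(
    seed: int,
    unit_arm_len: int = 2000,
    n_asym: int = 3,
    **overrides,
) -> SimConfig:
    """A small configuration that preserves the paper-scale architecture
    (junction lengths, skew structure) at a tractable arm length.

    Asymmetric sites are spread over the middle of the arm, away from the
    arm/junction boundaries.
    """
    pairs = [("T", "C"), ("A", "G"), ("C", "G"), ("G", "A")]
    lo, hi = unit_arm_len // 5, 4 * unit_arm_len // 5
    positions = np.linspace(lo, hi, n_asym).astype(int) if n_asym else []
    sites = tuple(
        (int(p), pairs[i % len(pairs)][0], pairs[i % len(pairs)][1])
        for i, p in enumerate(positions)
    )
    kwargs = dict(
        seed=seed,
        unit_arm_len=unit_arm_len,
        asym_sites=sites,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


# --------------------------------------------------------------------------- #
# Truth manifest
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class AsymSiteTruth:
    """Ground truth for one planted asymmetric site.

    ``arm_pos`` is 1-based on the arm; ``unit_pos`` is 1-based on the
    canonical extracted unit (junction_small + arm + junction_large), where
    the reference carries ``unit_ref_allele`` and reads from the opposite arm
    contribute ``unit_alt_allele``.
    """

    arm_pos: int
    arm1_base: str
    arm2_base: str
    dimer_pos_arm1: int  # 0-based on the dimer
    dimer_pos_arm2: int  # 0-based on the dimer (mirrored coordinate)
    unit_pos: int
    unit_ref_allele: str
    unit_alt_allele: str


@dataclass(frozen=True)
class TruthManifest:
    """Structural ground truth written at dimer construction time."""

    dimer_seq_id: str
    monomer_seq_id: str | None
    arm_len: int
    dimer_len: int
    arm_intervals: tuple[tuple[int, int], tuple[int, int]]
    junction_small: tuple[int, int]
    junction_large: tuple[int, int]
    asym_sites: tuple[AsymSiteTruth, ...]
    expected_balance: float = 0.5

    def validate(self) -> None:
        covered = sum(e - s for s, e in self.arm_intervals)
        covered += self.junction_small[1] - self.junction_small[0]
        covered += self.junction_large[1] - self.junction_large[0]
        if covered != self.dimer_len:
            raise InputError("manifest intervals do not tile the dimer")
        if len({s.arm_pos for s in self.asym_sites}) != len(self.asym_sites):
            raise InputError("duplicate asymmetric site in manifest")

    @property
    def unit_len(self) -> int:
        js = self.junction_small[1] - self.junction_small[0]
        jl = self.junction_large[1] - self.junction_large[0]
        return self.arm_len + js + jl

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "arm_pos": s.arm_pos,
                "arm1_base": s.arm1_base,
                "arm2_base": s.arm2_base,
                "dimer_pos_arm1": s.dimer_pos_arm1,
                "dimer_pos_arm2": s.dimer_pos_arm2,
                "unit_pos": s.unit_pos,
                "unit_ref_allele": s.unit_ref_allele,
                "unit_alt_allele": s.unit_alt_allele,
            }
            for s in self.asym_sites
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "arm_pos", "arm1_base", "arm2_base", "dimer_pos_arm1",
                "dimer_pos_arm2", "unit_pos", "unit_ref_allele",
                "unit_alt_allele",
            ],
        )

    def write(self, tsv_path: str | Path, bed_path: str | Path | None = None) -> None:
        write_tsv(
            self.to_frame(),
            tsv_path,
            comment=(
                f"dimer={self.dimer_seq_id} len={self.dimer_len} "
                f"arm={self.arm_len} expected_balance={self.expected_balance}"
            ),
        )
        if bed_path is not None:
            ivals = []
            for name, (s, e) in (
                ("arm1", self.arm_intervals[0]),
                ("arm2", self.arm_intervals[1]),
                ("junction_small", self.junction_small),
                ("junction_large", self.junction_large),
            ):
                ivals.append((self.dimer_seq_id, s, e, name))
            write_bed(ivals, bed_path)


# --------------------------------------------------------------------------- #
# Molecules
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class Molecule:
    """A molecule in the sequencing pool.

    ``barriers`` are reference intervals a long read fails to extend across
    with probability ``hairpin_fail_prob`` (telomeric-hairpin model): the
    terminal bases of a linear monomer, the junction intervals of the dimer.
    """

    seq: NucSeq
    copy_count: float = 1.0
    barriers: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.copy_count < 0:
            raise ParameterError("copy_count must be >= 0")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def id(self) -> str:
        return self.seq.id


def _as_molecule(item) -> Molecule:
    if isinstance(item, Molecule):
        return item
    if isinstance(item, NucSeq):
        return Molecule(item, 1.0)
    seq, count = item
    return Molecule(seq, float(count))


# --------------------------------------------------------------------------- #
# Sequence construction
# --------------------------------------------------------------------------- #

def _random_bases(rng: np.random.Generator, n: int, p: Sequence[float]) -> str:
    codes = rng.choice(4, size=n, p=np.asarray(p) / np.sum(p))
    return _BASE_ARR[codes].tobytes().decode()


def _segment_probs(gc: float, skew: float) -> list[float]:
    # order A, C, G, T; positive skew means G over-represented vs C
    at = (1.0 - gc) / 2.0
    return [at, gc / 2.0 * (1.0 - skew), gc / 2.0 * (1.0 + skew), at]


def make_unit(config: SimConfig, seq_id: str = "unit") -> NucSeq:
    """Generate the linear mitochondrial unit (one arm).

    Base composition follows ``gc_fraction``; the G-vs-C strand bias equals
    ``+skew_amplitude`` before the designated origin (``flip_pos``) and
    ``-skew_amplitude`` after it, emulating replication-associated skew with a
    single sign change.
    """
    rng = np.random.default_rng([config.seed, 0])
    L, flip = config.unit_arm_len, config.flip_pos
    head = _random_bases(rng, flip, _segment_probs(config.gc_fraction, config.skew_amplitude))
    tail = _random_bases(rng, L - flip, _segment_probs(config.gc_fraction, -config.skew_amplitude))
    return NucSeq(seq_id, head + tail, "linear")


def _apply_asym(bases: str, sites: Iterable[tuple[int, str, str]], which: int) -> str:
    arr = bytearray(bases, "ascii")
    for pos, b1, b2 in sites:
        arr[pos - 1] = ord(b2 if which == 2 else b1)
    return arr.decode()


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def make_dimer(
    unit: NucSeq, config: SimConfig, seq_id: str = "dimer"
) -> tuple[NucSeq, TruthManifest]:
    """Assemble the circular dimer and its ground-truth manifest.

    Layout: ``arm1 + junction_small + revcomp(arm2) + junction_large`` on a
    circle, where arm2 equals arm1 except at the configured asymmetric sites.
    Junction sequences are random with the global GC fraction.  The two bases
    of each junction adjacent to the palindrome centre are patched, if needed,
    so that a random junction base never extends the inverted repeat by
    chance — the manifest coordinates are then the exact maximal repeat.
    """
    if unit.is_circular:
        raise ParameterError("unit must be linear")
    U = len(unit)
    if U != config.unit_arm_len:
        raise ParameterError("unit length does not match config.unit_arm_len")
    rng = np.random.default_rng([config.seed, 1])
    sj, lj = config.junction_small_len, config.junction_large_len
    p_flat = _segment_probs(config.gc_fraction, 0.0)
    js = bytearray(_random_bases(rng, sj, p_flat), "ascii")
    jl = bytearray(_random_bases(rng, lj, p_flat), "ascii")

    def _patch(j: bytearray) -> None:
        # j[t] pairing comp(j[-1 - t]) would extend the palindrome; force the
        # first two pairs at each centre to mismatch.
        n = len(j)
        for t in range(min(2, n)):
            mate = n - 1 - t
            if mate <= t:
                break
            banned = ord(_COMP[chr(j[t])])
            if j[mate] == banned:
                alts = [b for b in b"ACGT" if b != banned]
                j[mate] = alts[int(rng.integers(len(alts)))]

    _patch(js)
    _patch(jl)

    arm1 = _apply_asym(unit.bases, config.asym_sites, which=1)
    arm2 = _apply_asym(unit.bases, config.asym_sites, which=2)
    bases = arm1 + js.decode() + revcomp_str(arm2) + jl.decode()
    dimer = NucSeq(seq_id, bases, "circular")

    sites = tuple(
        AsymSiteTruth(
            arm_pos=pos,
            arm1_base=b1,
            arm2_base=b2,
            dimer_pos_arm1=pos - 1,
            dimer_pos_arm2=2 * U + sj - pos,
            unit_pos=sj + U - pos + 1,
            unit_ref_allele=_COMP[b2],
            unit_alt_allele=_COMP[b1],
        )
        for pos, b1, b2 in config.asym_sites
    )
    manifest = TruthManifest(
        dimer_seq_id=seq_id,
        monomer_seq_id=None,
        arm_len=U,
        dimer_len=len(bases),
        arm_intervals=((0, U), (U + sj, 2 * U + sj)),
        junction_small=(U, U + sj),
        junction_large=(2 * U + sj, 2 * U + sj + lj),
        asym_sites=sites,
    )
    manifest.validate()
    return dimer, manifest


def make_monomer(
    unit: NucSeq, config: SimConfig, alleles: str = "arm1", seq_id: str = "monomer"
) -> Molecule:
    """Build the linear monomer molecule, hairpin-capped at both ends.

    ``alleles`` selects which arm's base the monomer carries at each
    asymmetric site ('arm1' or 'arm2') — the physical monomer is a renatured
    duplex with mismatched (looped) bases at these sites, so a pool modelling
    it uses an equal mixture of both forms (see :func:`standard_pool`).
    """
    if unit.is_circular:
        raise ParameterError("unit must be linear")
    if alleles not in ("arm1", "arm2"):
        raise ParameterError("alleles must be 'arm1' or 'arm2'")
    bases = _apply_asym(
        unit.bases, config.asym_sites, which=1 if alleles == "arm1" else 2
    )
    L = len(bases)
    seq = NucSeq(seq_id, bases, "linear")
    return Molecule(seq, 1.0, barriers=((0, 1), (L - 1, L)))


def standard_pool(
    config: SimConfig, unit: NucSeq | None = None
) -> tuple[list[Molecule], TruthManifest]:
    """The default study pool: one dimer species plus the monomer duplex.

    The monomer's renatured-duplex nature is modelled as two molecule forms
    (arm1 and arm2 alleles) at half weight each — strand-symmetric reading of
    the mismatched duplex — so the expected allele balance at every planted
    site is 0.5 regardless of ``dimer_monomer_ratio``.  The dimer carries
    hairpin barriers at its two junctions, the monomer at its termini.
    """
    if unit is None:
        unit = make_unit(config)
    dimer, manifest = make_dimer(unit, config)
    d_barriers = (manifest.junction_small, manifest.junction_large)
    pool: list[Molecule] = []
    if config.dimer_monomer_ratio > 0:
        pool.append(Molecule(dimer, config.dimer_monomer_ratio, d_barriers))
    pool.append(
        replace(make_monomer(unit, config, "arm1", "monomer_arm1"), copy_count=0.5)
    )
    pool.append(
        replace(make_monomer(unit, config, "arm2", "monomer_arm2"), copy_count=0.5)
    )
    manifest = replace(manifest, monomer_seq_id="monomer_arm1+monomer_arm2")
    return pool, manifest


def dimer_only_pool(config: SimConfig) -> tuple[list[Molecule], TruthManifest]:
    """A pool containing only the circular dimer (with junction barriers)."""
    unit = make_unit(config)
    dimer, manifest = make_dimer(unit, config)
    pool = [Molecule(dimer, 1.0, (manifest.junction_small, manifest.junction_large))]
    return pool, manifest


# --------------------------------------------------------------------------- #
# Read simulation
# --------------------------------------------------------------------------- #

@dataclass(frozen=True, slots=True)
class SimRead:
    """A simulated read plus its ground truth.

    ``start``/``end`` are the source interval on the molecule's forward
    strand (``end`` may exceed the molecule length for origin-spanning reads
    from a circle); ``strand`` is the strand the read was emitted from.
    """

    id: str
    bases: str
    quality: str
    molecule_id: str
    start: int
    end: int
    strand: str
    n_sub: int

    def __len__(self) -> int:
        return len(self.bases)


def _add_substitutions(
    rng: np.random.Generator, bases: str, rate: float
) -> tuple[str, int]:
    if rate <= 0:
        return bases, 0
    n = len(bases)
    n_sub = rng.binomial(n, rate)
    if n_sub == 0:
        return bases, 0
    positions = rng.choice(n, size=n_sub, replace=False)
    arr = np.frombuffer(bases.encode(), dtype=np.uint8).copy()
    code = np.searchsorted(_BASE_ARR, arr[positions])
    shift = rng.integers(1, 4, size=n_sub)
    arr[positions] = _BASE_ARR[(code + shift) % 4]
    return arr.tobytes().decode(), int(n_sub)


def _truncate_at_barriers(
    rng: np.random.Generator,
    mol: Molecule,
    start: int,
    length: int,
    fail_prob: float,
) -> tuple[int, int]:
    """Apply hairpin-failure truncation to a candidate read interval.

    Walking forward from ``start``, the read stops at the first barrier edge
    it fails to cross.  A read starting inside a barrier may be pushed past
    its end (sequencing cannot initiate within the hairpin).
    """
    if fail_prob <= 0 or not mol.barriers:
        return start, length
    L = len(mol)
    # starting inside a barrier: sequencing cannot initiate in the hairpin
    for bs, be in mol.barriers:
        if bs <= start < be and rng.random() < fail_prob:
            shift = be - start
            length = max(0, length - shift)
            if mol.seq.is_circular:
                start = be % L
            elif be >= L:
                return start, 0  # pushed off the end of a linear molecule
            else:
                start = be
            break
    # forward crossings, nearest first
    events = []
    for bs, be in mol.barriers:
        offset = (bs - start) % L if mol.seq.is_circular else bs - start
        if 0 < offset < length:
            events.append(offset)
    for offset in sorted(events):
        if offset >= length:
            break
        if rng.random() < fail_prob:
            length = offset
            break
    return start, length


def simulate_long_reads(
    pool: Sequence, config: SimConfig
) -> list[SimRead]:
    """Simulate long reads from a molecule pool.

    Molecules are drawn in proportion to ``copy_count``; each read is either
    a full-length pass or an exponentially sheared fragment, possibly
    truncated at hairpin barriers, taken from either strand, with uniform
    substitution errors.  Deterministic per configuration.
    """
    mols = [_as_molecule(m) for m in pool]
    if not mols:
        raise InputError("empty molecule pool")
    rng = np.random.default_rng([config.seed, 2])
    p = config.long_read_params
    weights = np.array([m.copy_count for m in mols], dtype=float)
    if weights.sum() <= 0:
        raise InputError("pool has zero total copy count")
    weights /= weights.sum()
    qual = _quality_char(p.substitution_error)

    mol_idx = rng.choice(len(mols), size=p.n_reads, p=weights)
    reads: list[SimRead] = []
    for i in range(p.n_reads):
        mol = mols[mol_idx[i]]
        L = len(mol)
        circular = mol.seq.is_circular
        if rng.random() < p.full_length_fraction:
            start = int(rng.integers(L)) if circular else 0
            length = L
        else:
            start = int(rng.integers(L))
            length = max(p.min_len, int(math.ceil(rng.exponential(1.0 / p.shear_rate))))
            length = min(length, L if circular else L - start)
        start, length = _truncate_at_barriers(
            rng, mol, start, length, config.hairpin_fail_prob
        )
        if length < 1:
            continue
        bases = mol.seq.fetch(start, start + length)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            bases = revcomp_str(bases)
        bases, n_sub = _add_substitutions(rng, bases, p.substitution_error)
        reads.append(
            SimRead(
                id=f"lr{i:06d}",
                bases=bases,
                quality=qual * length,
                molecule_id=mol.id,
                start=start,
                end=start + length,
                strand=strand,
                n_sub=n_sub,
            )
        )
    return reads


def simulate_short_reads(
    pool: Sequence, config: SimConfig
) -> list[tuple[SimRead, SimRead]]:
    """Simulate paired short reads from a molecule pool.

    Fragments of ``insert_len`` are drawn uniformly from molecules chosen in
    proportion to ``copy_count``; the first mate reads the fragment 5' end,
    the second mate the reverse complement of its 3' end, with the fragment
    itself taken from either strand.  Deterministic per configuration.
    """
    mols = [_as_molecule(m) for m in pool]
    if not mols:
        raise InputError("empty molecule pool")
    rng = np.random.default_rng([config.seed, 3])
    p = config.short_read_params
    for m in mols:
        if p.read_len > len(m):
            raise ParameterError(
                f"read_len {p.read_len} exceeds molecule {m.id!r} length {len(m)}"
            )
        if not m.seq.is_circular and p.insert_len > len(m):
            raise ParameterError(
                f"insert_len {p.insert_len} exceeds linear molecule {m.id!r}"
            )
    weights = np.array([m.copy_count for m in mols], dtype=float)
    if weights.sum() <= 0:
        raise InputError("pool has zero total copy count")
    weights /= weights.sum()
    qual = _quality_char(p.substitution_error) * p.read_len

    mol_idx = rng.choice(len(mols), size=p.n_pairs, p=weights)
    u_start = rng.random(p.n_pairs)
    flip = rng.random(p.n_pairs) < 0.5
    pairs: list[tuple[SimRead, SimRead]] = []
    rl, ins = p.read_len, p.insert_len
    for i in range(p.n_pairs):
        mol = mols[mol_idx[i]]
        L = len(mol)
        if mol.seq.is_circular:
            start = int(u_start[i] * L)
        else:
            start = int(u_start[i] * (L - ins + 1))
        frag = mol.seq.fetch(start, start + ins)
        if flip[i]:
            frag = revcomp_str(frag)
            s1, s2 = "-", "+"
            iv1 = (start + ins - rl, start + ins)
            iv2 = (start, start + rl)
        else:
            s1, s2 = "+", "-"
            iv1 = (start, start + rl)
            iv2 = (start + ins - rl, start + ins)
        m1 = frag[:rl]
        m2 = revcomp_str(frag)[:rl]
        b1, e1 = _add_substitutions(rng, m1, p.substitution_error)
        b2, e2 = _add_substitutions(rng, m2, p.substitution_error)
        pairs.append(
            (
                SimRead(f"sr{i:06d}/1", b1, qual, mol.id, iv1[0], iv1[1], s1, e1),
                SimRead(f"sr{i:06d}/2", b2, qual, mol.id, iv2[0], iv2[1], s2, e2),
            )
        )
    return pairs


def flatten_pairs(pairs: Iterable[tuple[SimRead, SimRead]]) -> list[SimRead]:
    """Interleave mate pairs into a flat read list."""
    out: list[SimRead] = []
    for a, b in pairs:
        out.append(a)
        out.append(b)
    return out
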