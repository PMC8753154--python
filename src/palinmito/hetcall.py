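"""Variable-site calling and classification on the collapsed unit.

On a palindromic dimer the two arms differ at a handful of single bases;
mapping everything to the one collapsed unit turns each such *asymmetric
site* into an apparent SNP whose two alleles should occur at equal
abundances (each arm contributes one).  Sites with clearly unequal allele
frequencies are instead candidates for true heteroplasmy or intraspecific
variation.  This module reproduces that calling scheme:

* indel columns supported by less than a fraction (default 5%) of the mean
  flanking depth are flagged as polish artifacts and removed;
* a site is called when its depth lies in an absolute window (default
  1000–8000 reads) and its minor-allele fraction clears a floor (default
  0.10, which suppresses stray sequencing-error alleles);
* called sites with minor fraction inside a balance band (default
  0.40–0.60, inclusive) are classified ``balanced_asymmetric``, the rest
  ``skewed``.

Percentages are computed as 100·count/depth and rounded half away from
zero, which reproduces published worked examples exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .mapcount import PileupTable

_ALLELES = "ACGT"

CLASS_BALANCED = "balanced_asymmetric"
CLASS_SKEWED = "skewed"
CLASS_MONOMORPHIC = "monomorphic"
CLASS_DEPTH_FAIL = "depth_fail"
CLASS_INDEL_ARTIFACT = "indel_artifact"


@dataclass(frozen=True)
class CallParams:
    """Thresholds for variant calling.

    ``depth_scale`` rescales the absolute depth window (which is expressed in
    reads to match real deep-coverage studies) for desk-scale simulations:
    effective bounds are ``min_depth*depth_scale`` and
    ``max_depth*depth_scale``.
    """

    min_depth: int = 1000
    max_depth: int = 8000
    min_minor_frac: float = 0.10
    balance_band: tuple[float, float] = (0.40, 0.60)
    indel_adjacent_frac: float = 0.05
    depth_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.min_depth <= self.max_depth:
            raise ParameterError("need 0 < min_depth <= max_depth")
        lo, hi = self.balance_band
        if not 0 < self.min_minor_frac < lo <= hi < 1:
            raise ParameterError(
                "need 0 < min_minor_frac < balance low <= balance high < 1"
            )
        if not 0 < self.indel_adjacent_frac < 1:
            raise ParameterError("indel_adjacent_frac must be in (0, 1)")
        if self.depth_scale <= 0:
            raise ParameterError("depth_scale must be > 0")

    @property
    def depth_window(self) -> tuple[float, float]:
        return (self.min_depth * self.depth_scale, self.max_depth * self.depth_scale)


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def allele_percentages(counts: Mapping[str, int]) -> dict[str, int]:
    """Integer percentages of each allele, rounded half away from zero.

    Depth is the sum of all supplied allele counts.
    """
    depth = sum(counts.values())
    if depth == 0:
        raise InputError("zero total count")
    return {a: round_half_away(100.0 * c / depth) for a, c in counts.items()}


@dataclass(frozen=True)
class VariantCall:
    """A classified variable (or depth-failed) site on the unit.

    ``position`` is 1-based.  ``alleles`` holds ``(base, count)`` sorted by
    descending count then base; ``percentages`` are the corresponding
    rounded integer percentages of depth (sum of the four base counts).
    """

    position: int
    alleles: tuple[tuple[str, int], ...]
    depth: int
    klass: str

    @property
    def major(self) -> tuple[str, int]:
        return self.alleles[0]

    @property
    def minor(self) -> tuple[str, int]:
        return self.alleles[1] if len(self.alleles) > 1 else (".", 0)

    @property
    def minor_frac(self) -> float:
        return self.minor[1] / self.depth if self.depth else 0.0

    @property
    def percentages(self) -> tuple[int, ...]:
        return tuple(
            round_half_away(100.0 * c / self.depth) if self.depth else 0
            for _, c in self.alleles
        )

    @property
    def bases_label(self) -> str:
        return "-".join(b for b, _ in self.alleles)

    @property
    def percent_string(self) -> str:
        return " : ".join(str(p) for p in self.percentages)


def _call_from_counts(position: int, counts: Sequence[int], klass: str) -> VariantCall:
    pairs = sorted(
        ((b, int(c)) for b, c in zip(_ALLELES, counts) if c > 0),
        key=lambda t: (-t[1], t[0]),
    )
    if not pairs:
        pairs = [(".", 0)]
    return VariantCall(
        position=position,
        alleles=tuple(pairs),
        depth=int(sum(counts)),
        klass=klass,
    )


# --------------------------------------------------------------------------- #
# Operations
# --------------------------------------------------------------------------- #

def filter_indel_columns(
    table: PileupTable, params: CallParams = CallParams()
) -> tuple[PileupTable, list[tuple[int, str]]]:
    """Remove low-support indel observations (polish artifacts).

    An insertion (deletion) column is an artifact when its indel depth is
    below ``indel_adjacent_frac`` times the mean depth of the two flanking
    sites.  Returns the filtered table and the removed ``(position, kind)``
    list (1-based positions).  Terminal positions, having only one flank,
    are left untouched.
    """
    if len(table) < 3:
        raise InputError("need at least 3 positions to assess flanking depth")
    depth = table.depth.astype(float)
    flank_mean = np.full(len(table), np.inf)
    flank_mean[1:-1] = (depth[:-2] + depth[2:]) / 2.0
    threshold = params.indel_adjacent_frac * flank_mean
    removed: list[tuple[int, str]] = []
    new_dels = table.dels.copy()
    new_ins = table.ins.copy()
    for i in range(1, len(table) - 1):
        if new_ins[i] > 0 and new_ins[i] < threshold[i]:
            removed.append((int(table.positions[i]), "ins"))
            new_ins[i] = 0
        if new_dels[i] > 0 and new_dels[i] < threshold[i]:
            removed.append((int(table.positions[i]), "del"))
            new_dels[i] = 0
    filtered = PileupTable(table.counts.copy(), new_dels, new_ins, table.positions)
    return filtered, removed


def call_variants(
    table: PileupTable,
    params: CallParams = CallParams(),
    include_monomorphic: bool = False,
) -> list[VariantCall]:
    """Call variable sites from per-site allele counts.

    A site is a variant when its depth lies inside the depth window and its
    minor-allele fraction is at least ``min_minor_frac``; variants are
    classified balanced/skewed via :func:`classify_sites`.  Sites whose
    allele pattern qualifies but whose depth does not (including zero-depth
    sites) are recorded as ``depth_fail`` rather than silently dropped;
    in-window monomorphic sites produce no call unless
    ``include_monomorphic`` is set.
    """
    lo, hi = params.depth_window
    counts = table.counts
    depth = counts.sum(axis=1)
    part = np.sort(counts, axis=1)
    minor = part[:, -2]
    with np.errstate(invalid="ignore", divide="ignore"):
        minor_frac = np.where(depth > 0, minor / np.maximum(depth, 1), 0.0)
    in_window = (depth >= lo) & (depth <= hi)
    is_variant = minor_frac >= params.min_minor_frac

    calls: list[VariantCall] = []
    for i in np.flatnonzero(is_variant & in_window):
        calls.append(_call_from_counts(int(table.positions[i]), counts[i], "variant"))
    for i in np.flatnonzero((is_variant | (depth == 0)) & ~in_window):
        calls.append(
            _call_from_counts(int(table.positions[i]), counts[i], CLASS_DEPTH_FAIL)
        )
    if include_monomorphic:
        for i in np.flatnonzero(~is_variant & in_window):
            calls.append(
                _call_from_counts(int(table.positions[i]), counts[i], CLASS_MONOMORPHIC)
            )
    calls.sort(key=lambda c: c.position)
    return classify_sites(calls, params)


def classify_sites(
    calls: Iterable[VariantCall], params: CallParams = CallParams()
) -> list[VariantCall]:
    """Label variant calls balanced_asymmetric vs skewed.

    A variant whose minor-allele fraction lies inside the (inclusive)
    balance band is a candidate inter-arm asymmetry; anything else is a
    skewed variant (candidate true heteroplasmy / intraspecific variant).
    Non-variant classes pass through unchanged; counts are never altered.
    Idempotent, so calls can be re-classified under a different band.
    """
    lo, hi = params.balance_band
    out: list[VariantCall] = []
    for c in calls:
        if c.klass in (CLASS_DEPTH_FAIL, CLASS_MONOMORPHIC, CLASS_INDEL_ARTIFACT):
            out.append(c)
            continue
        klass = CLASS_BALANCED if lo <= c.minor_frac <= hi else CLASS_SKEWED
        out.append(replace(c, klass=klass))
    return out


def summarize_calls(calls: Iterable[VariantCall]) -> pd.DataFrame:
    """Report table: position, bases, counts, percentage string, class.

    Rows are ordered by position; the percentage string lists every observed
    allele ("53 : 47").
    """
    rows = [
        {
            "position": c.position,
            "bases": c.bases_label,
            "counts": " : ".join(str(n) for _, n in c.alleles),
            "percent": c.percent_string,
            "depth": c.depth,
            "class": c.klass,
        }
        for c in sorted(calls, key=lambda c: c.position)
    ]
    return pd.DataFrame(
        rows, columns=["position", "bases", "counts", "percent", "depth", "class"]
    )


def call_pipeline(
    table: PileupTable, params: CallParams = CallParams()
) -> tuple[list[VariantCall], list[tuple[int, str]]]:
    """Indel filtering followed by variant calling and classification."""
    filtered, removed = filter_indel_columns(table, params)
    return call_variants(filtered, params), removed
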