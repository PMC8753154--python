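"""Compositional and coverage evidence profiles.

Three independent lines of evidence for the dimer+monomer architecture:

* **GC skew** — per-window ``(G - C) / (G + C)`` and its cumulative sum.
  Replication-associated strand bias makes the skew change sign at the
  replication origin, so the cumulative series has its extrema at the origin
  and terminus; isopod mitogenomes are notable for a *positive* dominant
  skew.
* **Read-length modes** — a pool containing sheared fragments plus
  full-length monomers (~14 kb) and dimers (~28 kb) yields a roughly
  trimodal length histogram; modes are detected as local maxima of a
  smoothed histogram above a mass floor.
* **Junction depth dips** — telomeric-hairpin-like secondary structure at
  the junctions impedes reads crossing them, and monomer-derived reads carry
  no junction sequence at all, so coverage of the dimer dips at both
  junctions relative to the genome-wide median.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError
from .mapcount import depth_vector
from .palindrome import RepeatArchitecture
from .seqio import AlignmentRecord, NucSeq


# --------------------------------------------------------------------------- #
# GC skew
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class SkewProfile:
    """Windowed GC-skew profile of a sequence."""

    seq_id: str
    window: int
    step: int
    starts: np.ndarray  # window start positions (0-based)
    skew: np.ndarray  # (G - C) / (G + C) per window; 0 where G + C == 0
    cumulative: np.ndarray
    circular: bool

    def __len__(self) -> int:
        return len(self.starts)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "start": self.starts,
                "skew": self.skew,
                "cumulative": self.cumulative,
            }
        )


def gc_skew_profile(seq: NucSeq, window: int = 100, step: int = 100) -> SkewProfile:
    """Sliding-window GC skew, wrapping on circular input.

    Windows with no G or C have skew 0 by convention.  The cumulative series
    is the running sum of per-window skews.
    """
    if window <= 0 or step <= 0:
        raise ParameterError("window and step must be > 0")
    L = len(seq)
    if window > L:
        raise ParameterError(f"window {window} exceeds sequence length {L}")
    if seq.is_circular:
        starts = np.arange(0, L, step)
        padded = seq.bases + seq.bases[: window - 1] if window > 1 else seq.bases
    else:
        n = (L - window) // step + 1
        starts = np.arange(n) * step
        padded = seq.bases
    arr = np.frombuffer(padded.encode(), dtype=np.uint8)
    is_g = np.concatenate([[0], np.cumsum(arr == ord("G"))])
    is_c = np.concatenate([[0], np.cumsum(arr == ord("C"))])
    g = is_g[starts + window] - is_g[starts]
    c = is_c[starts + window] - is_c[starts]
    denom = g + c
    with np.errstate(invalid="ignore", divide="ignore"):
        skew = np.where(denom > 0, (g - c) / np.maximum(denom, 1), 0.0)
    return SkewProfile(
        seq_id=seq.id,
        window=window,
        step=step,
        starts=starts,
        skew=skew,
        cumulative=np.cumsum(skew),
        circular=seq.is_circular,
    )


@dataclass(frozen=True)
class OriginEstimate:
    """Cumulative-skew extrema as origin/terminus proxies.

    ``position`` is the window start minimising the cumulative skew (the
    classical origin proxy for a negative-to-positive skew transition);
    ``max_position`` is the complementary extremum (the sign change from
    positive to negative skew).  Ties resolve to the smallest position.
    """

    position: int | None
    max_position: int | None
    no_signal: bool
    low_confidence: bool


def estimate_origin(profile: SkewProfile) -> OriginEstimate:
    """Locate the cumulative-skew extrema of a profile.

    A constant-zero profile is flagged ``no_signal``; an extremum sitting on
    the first or last window of a profile with no interior sign structure
    (monotone cumulative series) is flagged ``low_confidence``.
    """
    if len(profile) == 0:
        raise InputError("empty profile")
    cum = profile.cumulative
    if np.all(profile.skew == 0):
        return OriginEstimate(None, None, no_signal=True, low_confidence=True)
    i_min = int(np.argmin(cum))
    i_max = int(np.argmax(cum))
    diffs = np.sign(np.diff(cum))
    monotone = np.all(diffs >= 0) or np.all(diffs <= 0)
    at_edge = i_min in (0, len(cum) - 1) or i_max in (0, len(cum) - 1)
    return OriginEstimate(
        position=int(profile.starts[i_min]),
        max_position=int(profile.starts[i_max]),
        no_signal=False,
        low_confidence=bool(monotone and at_edge),
    )


# --------------------------------------------------------------------------- #
# Read-length modes
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class LengthMode:
    location: float  # bin centre, bp
    mass_fraction: float  # smoothed fraction of reads at the mode bin


@dataclass(frozen=True)
class ReadLengthProfile:
    lengths: np.ndarray
    bin_width: int
    bin_edges: np.ndarray
    histogram: np.ndarray
    smoothed: np.ndarray
    modes: tuple[LengthMode, ...]

    @property
    def modality(self) -> int:
        return len(self.modes)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mode_bp": [m.location for m in self.modes],
                "mass_fraction": [m.mass_fraction for m in self.modes],
            }
        )


def read_length_modes(
    lengths: Sequence[int],
    bin_width: int = 250,
    mass_floor: float = 0.01,
    smooth_bins: int = 3,
) -> ReadLengthProfile:
    """Detect modes of a read-length distribution.

    The histogram (bin width ``bin_width``) is smoothed with a fixed
    ``smooth_bins``-bin moving average; modes are local maxima of the
    smoothed histogram whose mass fraction is at least ``mass_floor``
    (default 1% of reads).  A smoothed plateau (e.g. a single-bin spike
    spread flat by the moving average) yields one mode, located at the
    raw-histogram maximum within the plateau.  Modes are returned sorted by
    location.
    """
    lengths = np.asarray(lengths, dtype=np.int64)
    if lengths.size < 1:
        raise ParameterError("need at least one read length")
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    n_bins = int(lengths.max() // bin_width) + 1
    hist = np.bincount(lengths // bin_width, minlength=n_bins).astype(float)
    frac = hist / lengths.size
    kernel = np.ones(smooth_bins) / smooth_bins
    smoothed = np.convolve(frac, kernel, mode="same")
    padded = np.concatenate([[-np.inf], smoothed, [-np.inf]])
    modes: list[LengthMode] = []
    i = 1
    while i <= n_bins:
        if padded[i] > padded[i - 1]:
            # walk any plateau
            j = i
            while j + 1 <= n_bins and padded[j + 1] == padded[j]:
                j += 1
            if padded[j] > padded[j + 1] and smoothed[i - 1] >= mass_floor:
                plateau = np.arange(i - 1, j)
                peak = int(plateau[np.argmax(frac[plateau])])
                modes.append(
                    LengthMode(
                        location=(peak + 0.5) * bin_width,
                        mass_fraction=float(smoothed[peak]),
                    )
                )
            i = j + 1
        else:
            i += 1
    return ReadLengthProfile(
        lengths=lengths,
        bin_width=bin_width,
        bin_edges=np.arange(n_bins + 1) * bin_width,
        histogram=hist,
        smoothed=smoothed,
        modes=tuple(sorted(modes, key=lambda m: m.location)),
    )


# --------------------------------------------------------------------------- #
# Junction depth dips
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class DepthDip:
    """Coverage statistics of one junction interval on the dimer."""

    junction: tuple[int, int]
    flank: int
    junction_mean_depth: float
    flank_mean_depth: float
    genome_median_depth: float
    dip_ratio: float

    def __post_init__(self) -> None:
        if self.dip_ratio < 0:
            raise ParameterError("dip ratio must be >= 0")


def junction_depth_ratio(
    alignments: Iterable[AlignmentRecord],
    arch: RepeatArchitecture,
    flank: int = 500,
) -> list[DepthDip]:
    """Per-junction mean depth over genome-wide median depth on the dimer.

    ``alignments`` must be mapped to the dimer (not the collapsed unit).
    The denominator is the genome-wide *median* so that the junction dip
    itself cannot drag the baseline down.  A dip ratio < 1 at both junctions
    is the coverage signature of hairpin-impeded sequencing plus
    junction-free monomer reads.
    """
    L = arch.contig_len
    depth = depth_vector(list(alignments), L, circular=True)
    median = float(np.median(depth))
    if median <= 0:
        raise InputError("zero genome-wide depth")
    dips: list[DepthDip] = []
    for junction in (arch.junction_small, arch.junction_large):
        s, e = junction
        idx = np.arange(s, e) % L
        j_mean = float(depth[idx].mean()) if e > s else 0.0
        f_idx = np.concatenate(
            [np.arange(s - flank, s), np.arange(e, e + flank)]
        ) % L
        f_mean = float(depth[f_idx].mean()) if flank > 0 else float("nan")
        dips.append(
            DepthDip(
                junction=junction,
                flank=flank,
                junction_mean_depth=j_mean,
                flank_mean_depth=f_mean,
                genome_median_depth=median,
                dip_ratio=j_mean / median,
            )
        )
    return dips


# --------------------------------------------------------------------------- #
# Plots (optional, for the CLI)
# --------------------------------------------------------------------------- #

def plot_skew(profile: SkewProfile, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(2, 1, sharex=True, figsize=(8, 5))
    ax1.plot(profile.starts, profile.skew, lw=0.8)
    ax1.axhline(0, color="grey", lw=0.5)
    ax1.set_ylabel("GC skew")
    ax2.plot(profile.starts, profile.cumulative, lw=1.2, color="darkred")
    ax2.set_ylabel("cumulative skew")
    ax2.set_xlabel("position (bp)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_length_histogram(profile: ReadLengthProfile, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    centres = (profile.bin_edges[:-1] + profile.bin_edges[1:]) / 2
    ax.bar(centres, profile.histogram, width=profile.bin_width * 0.9)
    for m in profile.modes:
        ax.axvline(m.location, color="darkred", ls="--", lw=1)
    ax.set_xlabel("read length (bp)")
    ax.set_ylabel("reads")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_depth(
    alignments: Iterable[AlignmentRecord], arch: RepeatArchitecture, path
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    depth = depth_vector(list(alignments), arch.contig_len, circular=True)
    fig, ax = plt.subplots(figsize=(9, 3.5))
    ax.plot(depth, lw=0.8)
    for s, e in (arch.junction_small, arch.junction_large):
        ax.axvspan(s, e, color="orange", alpha=0.3)
    ax.set_xlabel("dimer position (bp)")
    ax.set_ylabel("depth")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
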