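"""Published worked example: the four variable sites of the *Isocladus
armatus* mitochondrial unit.

These are the printed per-site allele counts from deep Illumina and nanopore
read mapping against the ~14.6 kb collapsed unit of the *I. armatus*
palindromic dimer.  Three sites (20, 9753, 12226) show the ~50:50 allele
balance expected of inter-arm asymmetries (two of them re-assign tRNA
anticodons); the site at 11 578 shows a 2:1 ratio and is a candidate
intraspecific variant.  They serve as ground-truth worked examples for the
calling and summary arithmetic.

In the nanopore counts at position 20, one read carried an uninterpretable
base call; it is stored here as a single count on an otherwise unobserved
allele ("other") so that it participates in depth, as in the published
percentages.
"""

from __future__ import annotations

import numpy as np

from .mapcount import PileupTable

#: Illumina allele counts per unit position (1-based).
ILLUMINA_SITE_COUNTS: dict[int, dict[str, int]] = {
    20: {"T": 1315, "C": 1158},
    9753: {"A": 3347, "G": 3460},
    11578: {"A": 4517, "G": 2504},
    12226: {"C": 3094, "G": 2963},
}

#: Nanopore allele counts per unit position (1-based).  Position 20's single
#: uninterpretable call is stored on "A" (an allele not otherwise observed).
NANOPORE_SITE_COUNTS: dict[int, dict[str, int]] = {
    20: {"T": 114, "C": 71, "A": 1},
    9753: {"A": 156, "G": 113, "C": 1, "T": 4},
    11578: {"A": 257, "G": 8, "C": 2},
    12226: {"C": 134, "G": 119, "A": 6, "T": 3},
}

#: Classification expected of each Illumina site under default parameters.
EXPECTED_ILLUMINA_CLASSES: dict[int, str] = {
    20: "balanced_asymmetric",
    9753: "balanced_asymmetric",
    11578: "skewed",
    12226: "balanced_asymmetric",
}


def site_counts_table(site_counts: dict[int, dict[str, int]]) -> PileupTable:
    """Build a sparse PileupTable holding the given per-position counts."""
    positions = sorted(site_counts)
    counts = np.zeros((len(positions), 4), dtype=np.int64)
    for i, pos in enumerate(positions):
        for base, n in site_counts[pos].items():
            counts[i, "ACGT".index(base)] = n
    return PileupTable(counts, positions=np.asarray(positions))
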