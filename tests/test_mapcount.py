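"""Mapper and pileup contracts, cross-checked against brute force and
an external aligner."""

import shutil
import subprocess

import numpy as np
import pytest

from palinmito.errors import InputError
from palinmito.mapcount import (
    MapParams,
    PileupTable,
    ReferenceIndex,
    count_reads,
    depth_vector,
    map_read,
    map_reads,
    pileup,
)
from palinmito.seqio import (
    AlignmentRecord,
    NucSeq,
    read_alignments,
    revcomp_str,
    write_fasta,
    write_fastq,
)
from palinmito.simgen import (
    Molecule,
    ShortReadParams,
    desk_scale_config,
    flatten_pairs,
    simulate_short_reads,
)

from conftest import mutate, random_nucseq


def brute_force_best(read: str, ref: str) -> list[tuple[int, int, str]]:
    """All (hamming, start, strand) placements at the minimum distance."""
    n = len(read)
    best = []
    for strand, q in (("+", read), ("-", revcomp_str(read))):
        qa = np.frombuffer(q.encode(), np.uint8)
        for s in range(len(ref) - n + 1):
            ra = np.frombuffer(ref[s : s + n].encode(), np.uint8)
            best.append((int((qa != ra).sum()), s, strand))
    m = min(b[0] for b in best)
    return [b for b in best if b[0] == m]


@pytest.fixture(scope="module")
def ref():
    return random_nucseq(42, 2000, "ref")


@pytest.fixture(scope="module")
def index(ref):
    return ReferenceIndex(ref)


class TestMapRead:
    def test_exact_substring(self, ref, index):
        rec = map_read(ref.bases[100:250], index)
        assert rec.ref_interval == (100, 250)
        assert rec.strand == "+"
        assert rec.identity == 1.0

    def test_revcomp_same_interval(self, ref, index):
        rec = map_read(revcomp_str(ref.bases[100:250]), index)
        assert rec.ref_interval == (100, 250)
        assert rec.strand == "-"

    def test_two_substitutions_vs_brute_force(self, ref, index):
        read = mutate(ref.bases[100:250], seed=1, n_sub=2)
        rec = map_read(read, index)
        assert rec.identity == 148 / 150
        ((ham, start, strand),) = brute_force_best(read, ref.bases)
        assert (ham, start, strand) == (2, 100, "+")
        assert rec.ref_interval == (start, start + 150)

    def test_random_reads_match_brute_force(self, ref, index):
        rng = np.random.default_rng(5)
        for _ in range(20):
            s = int(rng.integers(0, 1900))
            read = mutate(ref.bases[s : s + 100], seed=int(rng.integers(1 << 30)), n_sub=3)
            rec = map_read(read, index, MapParams(min_identity=0.9))
            hits = brute_force_best(read, ref.bases)
            if len(hits) == 1:
                assert rec is not None
                assert rec.ref_interval == (hits[0][1], hits[0][1] + 100)

    def test_deletion_read_consumes_interval(self, ref, index):
        read = ref.bases[100:160] + ref.bases[162:250]
        rec = map_read(read, index)
        assert rec.ref_interval == (100, 250)
        ref_len = sum(n for op, n in rec.edit if op in "=XD")
        assert ref_len == 150

    def test_ambiguous_dropped_or_randomly_placed(self):
        base = random_nucseq(7, 500).bases
        dup = NucSeq("dup", base + base)
        idx = ReferenceIndex(dup)
        read = base[100:250]
        assert map_read(read, idx) is None
        rec = map_read(read, idx, MapParams(on_tie="random", seed=3))
        assert rec is not None and rec.ref_start % 500 == 100

    def test_unmappable_returns_none(self, index):
        junk = random_nucseq(99, 150, "junk").bases
        assert map_read(junk, index) is None

    def test_circular_reference_wrapping_read(self):
        circ = random_nucseq(8, 1000, "circ", "circular")
        idx = ReferenceIndex(circ)
        read = circ.bases[950:] + circ.bases[:80]
        rec = map_read(read, idx)
        assert rec.ref_interval == (950, 1080)
        assert rec.identity == 1.0


class TestPileup:
    def test_depth_and_complementation(self, ref):
        # two + reads overlapping position 10, one - read complemented back
        a1 = AlignmentRecord("a", "ref", 0, 50, "+", (("=", 50),), 1.0, ref.bases[:50])
        a2 = AlignmentRecord("b", "ref", 5, 55, "+", (("=", 50),), 1.0, ref.bases[5:55])
        a3 = AlignmentRecord("c", "ref", 0, 50, "-", (("=", 50),), 1.0, ref.bases[:50])
        table = pileup([a1, a2, a3], ref)
        site = table.site(10)
        assert site.depth == 3
        assert getattr(site, ref.bases[10]) == 3  # all counted on reference strand

    def test_indel_anchoring(self, ref):
        edit = (("=", 10), ("D", 2), ("=", 10), ("I", 1), ("=", 10))
        bases = ref.bases[:10] + ref.bases[12:22] + "A" + ref.bases[22:32]
        rec = AlignmentRecord("d", "ref", 0, 32, "+", edit, 30 / 33, bases)
        table = pileup([rec], ref)
        assert table.dels[10] == 1 and table.dels[11] == 1
        assert table.ins[22] == 1

    def test_out_of_bounds_rejected(self, ref):
        bad = AlignmentRecord("e", "ref", 1990, 2040, "+", (("=", 50),), 1.0, "A" * 50)
        with pytest.raises(InputError):
            pileup([bad], ref)

    def test_depth_conservation_on_simulated_batch(self, ref):
        cfg = desk_scale_config(
            seed=31, unit_arm_len=500, n_asym=0,
            short_read_params=ShortReadParams(n_pairs=300, substitution_error=0.01),
        )
        reads = flatten_pairs(simulate_short_reads([Molecule(ref)], cfg))
        table, res = count_reads(ref, reads)
        aligned_bases = sum(
            n for rec in res.records for op, n in rec.edit if op in "=X"
        )
        assert table.counts.sum() == aligned_bases

    def test_tsv_round_trip(self, tmp_path, ref):
        a = AlignmentRecord("a", "ref", 0, 50, "+", (("=", 50),), 1.0, ref.bases[:50])
        table = pileup([a], ref)
        p = tmp_path / "counts.tsv"
        table.to_tsv(p)
        back = PileupTable.from_tsv(p)
        assert (back.counts == table.counts).all()
        assert (back.positions == table.positions).all()


class TestTruthAgreement:
    def test_mapper_recovers_truth_intervals(self):
        """>=1000 error-free reads from a non-repetitive molecule map exactly
        to their simulated source intervals."""
        mol = random_nucseq(17, 3000, "mol")
        cfg = desk_scale_config(
            seed=18, unit_arm_len=500, n_asym=0,
            short_read_params=ShortReadParams(n_pairs=600, substitution_error=0.0),
        )
        reads = flatten_pairs(simulate_short_reads([Molecule(mol)], cfg))
        assert len(reads) >= 1000
        idx = ReferenceIndex(mol)
        result = map_reads(reads, idx)
        assert result.n_unmapped == 0
        by_id = {r.id: r for r in reads}
        for rec in result.records:
            truth = by_id[rec.read_id]
            assert (rec.ref_start, rec.ref_end, rec.strand) == (
                truth.start, truth.end, truth.strand,
            )


@pytest.mark.skipif(shutil.which("minimap2") is None, reason="minimap2 not on PATH")
class TestIngestEquivalence:
    def test_pileup_matches_external_mapper(self, tmp_path):
        """Site-for-site pileup equality between the built-in mapper and an
        externally produced SAM on error-free reads."""
        unit = random_nucseq(23, 1500, "unit")
        cfg = desk_scale_config(
            seed=24, unit_arm_len=500, n_asym=0,
            short_read_params=ShortReadParams(n_pairs=800, substitution_error=0.0),
        )
        reads = flatten_pairs(simulate_short_reads([Molecule(unit)], cfg))
        builtin, _ = count_reads(unit, reads)
        fa, fq, sam = tmp_path / "u.fa", tmp_path / "r.fq", tmp_path / "o.sam"
        write_fasta([unit], fa)
        write_fastq(reads, fq)
        with open(sam, "w") as fh:
            subprocess.run(
                ["minimap2", "-ax", "sr", "--secondary=no", str(fa), str(fq)],
                stdout=fh, stderr=subprocess.DEVNULL, check=True,
            )
        external = pileup(read_alignments(sam, [unit]).records, unit)
        assert (builtin.counts == external.counts).all()


def test_depth_vector_wrapping():
    rec = AlignmentRecord("w", "c", 90, 110, "+", (("=", 20),), 1.0, "A" * 20)
    d = depth_vector([rec], 100, circular=True)
    assert d[95] == 1 and d[5] == 1 and d[50] == 0
    with pytest.raises(InputError):
        depth_vector([rec], 100, circular=False)
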