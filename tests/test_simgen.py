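"""Simulator contracts: determinism, structure, planted-signal recovery."""

import numpy as np
import pytest
from scipy import stats

from palinmito.errors import InputError, ParameterError
from palinmito.seqio import NucSeq, revcomp_str
from palinmito.simgen import (
    LongReadParams,
    Molecule,
    ShortReadParams,
    SimConfig,
    desk_scale_config,
    dimer_only_pool,
    flatten_pairs,
    make_dimer,
    make_monomer,
    make_unit,
    simulate_long_reads,
    simulate_short_reads,
    standard_pool,
)


def binom99(n: int, p: float = 0.5) -> tuple[float, float]:
    lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
    return lo / n, hi / n


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(unit_arm_len=0),
            dict(gc_fraction=1.2),
            dict(skew_amplitude=-0.1),
            dict(asym_sites=((0, "A", "G"),)),
            dict(asym_sites=((5000, "A", "G"),), unit_arm_len=100),
            dict(asym_sites=((10, "A", "A"),)),
            dict(asym_sites=((10, "A", "G"), (10, "C", "T"))),
            dict(dimer_monomer_ratio=-1),
            dict(hairpin_fail_prob=1.5),
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            SimConfig(seed=1, **kwargs)


class TestMakeUnit:
    def test_deterministic(self):
        cfg = SimConfig(seed=7, unit_arm_len=1000, asym_sites=())
        assert make_unit(cfg).bases == make_unit(cfg).bases
        assert len(make_unit(cfg)) == 1000

    def test_gc_zero_gives_at_only(self):
        cfg = SimConfig(seed=2, unit_arm_len=500, gc_fraction=0.0, asym_sites=())
        assert set(make_unit(cfg).bases) <= {"A", "T"}

    def test_skew_sign_structure_by_direct_counting(self):
        cfg = SimConfig(
            seed=1, unit_arm_len=10000, gc_fraction=0.5, skew_amplitude=0.5,
            asym_sites=(),
        )
        u = make_unit(cfg)
        head, tail = u.bases[: cfg.flip_pos], u.bases[cfg.flip_pos :]

        def skew(s):
            g, c = s.count("G"), s.count("C")
            return (g - c) / (g + c)

        assert skew(head) > 0
        assert skew(tail) < 0


class TestMakeDimer:
    def test_length_arithmetic(self):
        cfg = SimConfig(
            seed=3, unit_arm_len=500, junction_small_len=20,
            junction_large_len=50, asym_sites=(),
        )
        dimer, man = make_dimer(make_unit(cfg), cfg)
        assert len(dimer) == 2 * 500 + 20 + 50 == man.dimer_len
        assert dimer.is_circular

    def test_palindrome_property_without_asym(self):
        cfg = SimConfig(
            seed=4, unit_arm_len=500, junction_small_len=20,
            junction_large_len=50, asym_sites=(),
        )
        dimer, man = make_dimer(make_unit(cfg), cfg)
        (a1s, a1e), (a2s, a2e) = man.arm_intervals
        assert dimer.bases[a2s:a2e] == revcomp_str(dimer.bases[a1s:a1e])

    def test_asym_site_mirrored_complement(self):
        cfg = SimConfig(
            seed=5, unit_arm_len=500, junction_small_len=20,
            junction_large_len=50, asym_sites=((100, "A", "G"),),
        )
        unit = make_unit(cfg)
        dimer, man = make_dimer(unit, cfg)
        (site,) = man.asym_sites
        assert dimer.bases[site.dimer_pos_arm1] == "A"
        assert dimer.bases[site.dimer_pos_arm2] == "C"  # complement of G
        # all other arm positions remain exact reverse complements
        (a1s, a1e), (a2s, a2e) = man.arm_intervals
        arm1 = dimer.bases[a1s:a1e]
        rc2 = revcomp_str(dimer.bases[a2s:a2e])
        mism = [i for i in range(len(arm1)) if arm1[i] != rc2[i]]
        assert mism == [99]

    def test_manifest_tiles_dimer(self):
        cfg = desk_scale_config(seed=6, unit_arm_len=800)
        _, man = make_dimer(make_unit(cfg), cfg)
        man.validate()
        assert man.unit_len == 800 + 155 + 591


class TestMakeMonomer:
    def test_identity_and_length(self):
        cfg = SimConfig(seed=3, unit_arm_len=500, asym_sites=())
        unit = make_unit(cfg)
        mon = make_monomer(unit, cfg)
        assert len(mon) == 500
        assert mon.seq.bases == unit.bases
        assert mon.barriers == ((0, 1), (499, 500))

    def test_allele_forms(self):
        cfg = SimConfig(seed=3, unit_arm_len=500, asym_sites=((10, "A", "G"),))
        unit = make_unit(cfg)
        assert make_monomer(unit, cfg, "arm1").seq.bases[9] == "A"
        assert make_monomer(unit, cfg, "arm2").seq.bases[9] == "G"

    @pytest.mark.parametrize("fail_prob,expect_covered", [(0.0, True), (1.0, False)])
    def test_hairpin_terminal_base_coverage(self, fail_prob, expect_covered):
        cfg = SimConfig(
            seed=8, unit_arm_len=500, asym_sites=(),
            hairpin_fail_prob=fail_prob,
            long_read_params=LongReadParams(
                n_reads=300, full_length_fraction=0.5,
                shear_rate=1 / 200, substitution_error=0.0,
            ),
        )
        mon = make_monomer(make_unit(cfg), cfg)
        reads = simulate_long_reads([mon], cfg)
        covers_first = any(r.start == 0 for r in reads)
        covers_last = any(r.end == 500 for r in reads)
        assert (covers_first or covers_last) == expect_covered


class TestLongReads:
    def test_no_noise_full_length_limit(self):
        cfg = SimConfig(
            seed=9, unit_arm_len=400, junction_small_len=30,
            junction_large_len=60, asym_sites=(), hairpin_fail_prob=0.0,
            long_read_params=LongReadParams(
                n_reads=50, full_length_fraction=1.0, substitution_error=0.0,
            ),
        )
        pool, man = standard_pool(cfg)
        by_id = {m.id: m.seq for m in pool}
        for r in simulate_long_reads(pool, cfg):
            mol = by_id[r.molecule_id]
            src = mol.fetch(r.start, r.end)
            assert len(r) == len(mol)
            assert r.bases in (src, revcomp_str(src))

    def test_length_mass_near_molecule_lengths(self):
        cfg = desk_scale_config(
            seed=10, unit_arm_len=2000, hairpin_fail_prob=0.0,
            long_read_params=LongReadParams(
                n_reads=2000, full_length_fraction=0.3, shear_rate=1 / 400,
                substitution_error=0.0,
            ),
        )
        pool, man = standard_pool(cfg)
        lengths = np.array([len(r) for r in simulate_long_reads(pool, cfg)])
        near_unit = ((lengths > 1800) & (lengths < 2200)).mean()
        near_dimer = (lengths > 0.9 * man.dimer_len).mean()
        assert near_unit > 0.05
        assert near_dimer > 0.05

    def test_substitution_rate_calibrated(self):
        rate = 0.05
        cfg = SimConfig(
            seed=11, unit_arm_len=2000, asym_sites=(), hairpin_fail_prob=0.0,
            long_read_params=LongReadParams(
                n_reads=100, full_length_fraction=0.2, shear_rate=1 / 500,
                substitution_error=rate,
            ),
        )
        pool, _ = dimer_only_pool(cfg)
        reads = simulate_long_reads(pool, cfg)
        total = sum(len(r) for r in reads)
        subs = sum(r.n_sub for r in reads)
        assert total >= 10_000
        lo, hi = binom99(total, rate)
        assert lo <= subs / total <= hi

    def test_deterministic_and_empty_pool(self):
        cfg = desk_scale_config(seed=12, unit_arm_len=500)
        pool, _ = dimer_only_pool(cfg)
        r1 = simulate_long_reads(pool, cfg)
        r2 = simulate_long_reads(pool, cfg)
        assert [(r.id, r.bases, r.start) for r in r1] == [
            (r.id, r.bases, r.start) for r in r2
        ]
        with pytest.raises(InputError):
            simulate_long_reads([], cfg)


class TestShortReads:
    def test_exact_kmers_of_molecule(self):
        mol = NucSeq("m", "ACGTACGTACGT")
        cfg = SimConfig(
            seed=13, unit_arm_len=100, asym_sites=(),
            short_read_params=ShortReadParams(
                n_pairs=200, read_len=4, insert_len=6, substitution_error=0.0,
            ),
        )
        kmers = {mol.bases[i : i + 4] for i in range(len(mol) - 3)}
        kmers |= {revcomp_str(s) for s in kmers}
        for a, b in simulate_short_reads([Molecule(mol, 5.0)], cfg):
            assert a.bases in kmers and b.bases in kmers

    def test_read_len_exceeding_molecule_rejected(self):
        cfg = SimConfig(
            seed=14, unit_arm_len=100, asym_sites=(),
            short_read_params=ShortReadParams(n_pairs=1, read_len=50, insert_len=50),
        )
        with pytest.raises(ParameterError):
            simulate_short_reads([Molecule(NucSeq("m", "ACGT" * 10))], cfg)

    def test_dimer_only_truth_balance_at_asym_site(self):
        """Direct tally over emitted reads (no mapper): planted site ~50:50."""
        cfg = SimConfig(
            seed=15, unit_arm_len=600, junction_small_len=40,
            junction_large_len=80, asym_sites=((300, "A", "G"),),
            short_read_params=ShortReadParams(n_pairs=4000, read_len=50,
                                              insert_len=60, substitution_error=0.0),
        )
        pool, man = dimer_only_pool(cfg)
        dimer = pool[0].seq
        (site,) = man.asym_sites
        tallies = {b: 0 for b in "ACGT"}
        for r in flatten_pairs(simulate_short_reads(pool, cfg)):
            for pos in (site.dimer_pos_arm1, site.dimer_pos_arm2):
                off = (pos - r.start) % len(dimer)
                if off < (r.end - r.start):
                    base = r.bases[off] if r.strand == "+" else revcomp_str(r.bases)[off]
                    # complement arm2-locus bases onto arm1 frame
                    if pos == site.dimer_pos_arm2:
                        base = revcomp_str(base)
                    tallies[base] += 1
        n = tallies["A"] + tallies["G"]
        lo, hi = binom99(n)
        assert lo <= tallies["A"] / n <= hi

    def test_monomer_only_pool_is_monomorphic(self):
        cfg = SimConfig(
            seed=16, unit_arm_len=600, asym_sites=((300, "A", "G"),),
            short_read_params=ShortReadParams(n_pairs=800, read_len=50,
                                              insert_len=60, substitution_error=0.0),
        )
        mon = make_monomer(make_unit(cfg), cfg, "arm1")
        seen = set()
        for r in flatten_pairs(simulate_short_reads([mon], cfg)):
            off = 299 - r.start
            if 0 <= off < (r.end - r.start):
                seen.add(r.bases[off] if r.strand == "+" else revcomp_str(r.bases)[off])
        assert seen == {"A"}

    def test_deterministic(self):
        cfg = desk_scale_config(
            seed=17, unit_arm_len=500,
            short_read_params=ShortReadParams(n_pairs=50),
        )
        pool, _ = standard_pool(cfg)
        p1 = simulate_short_reads(pool, cfg)
        p2 = simulate_short_reads(pool, cfg)
        assert [(a.bases, b.bases) for a, b in p1] == [(a.bases, b.bases) for a, b in p2]
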