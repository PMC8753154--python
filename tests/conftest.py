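import numpy as np
import pytest

from palinmito.seqio import NucSeq


def random_nucseq(seed: int, length: int, seq_id: str = "rand",
                  topology: str = "linear") -> NucSeq:
    rng = np.random.default_rng(seed)
    bases = "".join("ACGT"[c] for c in rng.integers(0, 4, length))
    return NucSeq(seq_id, bases, topology)


def mutate(bases: str, seed: int, n_sub: int, region: tuple[int, int] | None = None) -> str:
    """Plant n_sub random substitutions inside region (default: whole seq)."""
    rng = np.random.default_rng(seed)
    lo, hi = region if region else (0, len(bases))
    arr = bytearray(bases, "ascii")
    for p in rng.choice(np.arange(lo, hi), size=n_sub, replace=False):
        old = "ACGT".index(chr(arr[p]))
        arr[p] = ord("ACGT"[(old + int(rng.integers(1, 4))) % 4])
    return arr.decode()


@pytest.fixture
def rng():
    return np.random.default_rng(0)
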