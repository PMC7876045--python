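import numpy as np
import pytest

from sigmapause import EndCountTrack, ReadRecord, TssRecord, build_ri_model


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noisy_minus10_model(rng):
    """Model trained on 200 consensus-like hexamers with 15% noise."""
    train = []
    for _ in range(200):
        s = list("TATAAT")
        for i in range(6):
            if rng.random() < 0.15:
                s[i] = "ACGT"[rng.integers(4)]
        train.append("".join(s))
    return build_ri_model(train)


def make_track(plus=None, minus=None, length=None, total_reads=None):
    """Single-contig track from explicit count vectors (contig 'c')."""
    plus = np.asarray(plus if plus is not None else [], dtype=np.int64)
    minus_arr = np.asarray(
        minus if minus is not None else np.zeros_like(plus), dtype=np.int64
    )
    n = length if length is not None else max(len(plus), len(minus_arr))
    p = np.zeros(n, dtype=np.int64)
    m = np.zeros(n, dtype=np.int64)
    p[: len(plus)] = plus
    m[: len(minus_arr)] = minus_arr
    track = EndCountTrack(
        contig_lengths={"c": n}, counts={("c", "+"): p, ("c", "-"): m}
    )
    track.total_reads = int(total_reads if total_reads is not None else p.sum() + m.sum())
    return track


def plus_read(contig, three_prime, length, name="r"):
    """Plus-strand read whose 3' end sits at ``three_prime``."""
    return ReadRecord(contig, three_prime + 1 - length, three_prime + 1, "+", name)


def minus_read(contig, three_prime, length, name="r"):
    return ReadRecord(contig, three_prime, three_prime + length, "-", name)


def tss(position, strand="+", contig="c", id=None):
    return TssRecord(contig, position, strand, id or f"t{position}{strand}")
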