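"""Order-3 Markov background model matched to a replicon's 4-mer spectrum.

The matS enrichment test asks how many hits a position-specific score
matrix produces on random sequences with the same short-range
composition as the real plasmid.  The canonical generative model whose
stationary 4-mer law matches the observed counts is an order-3 Markov
chain with transitions estimated from circular 4-mer counts; this module
fits that chain and samples from it reproducibly.

Generated sequences are linear strings that downstream scanners treat as
circular, exactly as they treat the real plasmids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .sequence_io import Replicon, _CODE

_BASES = "ACGT"


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def _kmer_count_vector(codes: np.ndarray, k: int) -> np.ndarray:
    """Circular k-mer counts as a (4**k,) vector; windows with N skipped."""
    L = len(codes)
    if k < 1:
        raise ValueError("k must be >= 1")
    if L < k:
        raise ValueError(f"sequence length {L} < k={k}")
    ext = np.concatenate([codes, codes[: k - 1]]) if k > 1 else codes
    ext64 = ext.astype(np.int64)
    idx = np.zeros(L, dtype=np.int64)
    valid = np.ones(L, dtype=bool)
    for j in range(k):
        col = ext64[j : j + L]
        valid &= col < 4
        idx = idx * 4 + np.where(col < 4, col, 0)
    return np.bincount(idx[valid], minlength=4**k)


def _index_to_kmer(index: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BASES[index % 4])
        index //= 4
    return "".join(reversed(out))


@dataclass
class MarkovBackground:
    """Fitted order-3 chain (contexts are 3-mers, from 4-mer counts)."""

    counts4: np.ndarray  # (256,) circular 4-mer counts
    transition: np.ndarray  # (64, 4) rows sum to 1 where context observed
    initial: np.ndarray  # (64,) distribution over starting 3-mers
    valid_context: np.ndarray  # (64,) bool

    order: int = 3

    @property
    def kmer_counts(self) -> dict[str, int]:
        """4-mer → circular count, omitting unobserved 4-mers."""
        return {
            _index_to_kmer(i, 4): int(c)
            for i, c in enumerate(self.counts4)
            if c > 0
        }


def fit_background(replicon: Replicon | str) -> MarkovBackground:
    """Fit the order-3 chain to a replicon's circular 4-mer counts.

    transition(c -> b) = count(c+b) / sum_b' count(c+b'); the initial
    3-mer distribution is the 3-mer marginal of the 4-mer counts.
    Windows containing N are excluded; a sequence with fewer than 4
    unambiguous positions cannot be fit.
    """
    seq = replicon.seq if isinstance(replicon, Replicon) else replicon.upper()
    codes = _encode(seq)
    if np.count_nonzero(codes < 4) < 4:
        raise ValueError("sequence too short (or too ambiguous) to fit 4-mer counts")
    counts4 = _kmer_count_vector(codes, 4)
    if counts4.sum() == 0:
        raise ValueError("no N-free 4-mer windows; cannot fit background")
    by_context = counts4.reshape(64, 4)
    totals = by_context.sum(axis=1)
    valid = totals > 0
    transition = np.zeros((64, 4), dtype=float)
    transition[valid] = by_context[valid] / totals[valid, None]
    initial = totals / totals.sum()
    return MarkovBackground(
        counts4=counts4,
        transition=transition,
        initial=initial,
        valid_context=valid,
    )


@njit(cache=True)
def _generate_kernel(cum_trans, valid, cum_init, u_emit, u_restart, start_ctx, out):
    """Walk the chain; emit one base per step into ``out``.

    A context absent from the model (possible only for a caller-supplied
    start) restarts from the initial 3-mer distribution.
    """
    ctx = start_ctx
    n = out.shape[0]
    for t in range(n):
        if not valid[ctx]:
            u = u_restart[t]
            ctx = 0
            while ctx < 63 and u >= cum_init[ctx]:
                ctx += 1
        u = u_emit[t]
        b = 0
        while b < 3 and u >= cum_trans[ctx, b]:
            b += 1
        out[t] = b
        ctx = ((ctx * 4) + b) % 64


def generate_codes(
    background: MarkovBackground, length: int, seed: int
) -> np.ndarray:
    """Sample ``length`` bases (integer codes) from the chain, reproducibly."""
    if length < 4:
        raise ValueError("length must be >= 4")
    rng = np.random.default_rng(seed)
    cum_init = np.cumsum(background.initial)
    ctx = int(np.searchsorted(cum_init, rng.random(), side="right"))
    ctx = min(ctx, 63)
    cum_trans = np.cumsum(background.transition, axis=1)
    out = np.empty(length, dtype=np.uint8)
    _generate_kernel(
        cum_trans,
        background.valid_context,
        cum_init,
        rng.random(length),
        rng.random(length),
        ctx,
        out,
    )
    return out


def generate(background: MarkovBackground, length: int, seed: int) -> str:
    """Sample a random sequence matching the fitted 4-mer composition.

    Deterministic for a fixed (background, length, seed).  Replicate
    streams for the null ensemble use seed + replicate index.
    """
    codes = generate_codes(background, length, seed)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def kmer_tv_distance(seq_a: str, seq_b: str, k: int) -> float:
    """Total-variation distance between circular k-mer frequency vectors.

    0.5 * sum |f_A - f_B| over all 4**k words; 0 for identical
    sequences, 1 for disjoint k-mer supports.
    """
    ca = _kmer_count_vector(_encode(seq_a), k)
    cb = _kmer_count_vector(_encode(seq_b), k)
    fa = ca / ca.sum()
    fb = cb / cb.sum()
    return 0.5 * float(np.abs(fa - fb).sum())
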