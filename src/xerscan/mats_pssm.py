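"""matS detection by PSSM scan and enrichment against a Markov-recoded null.

matS is a 13 bp palindromic MatP-binding site, degenerate at its three
central positions.  A position-specific score matrix is built from
training 13-mers as per-column log2-odds against a background base
distribution; the detection threshold is calibrated as the minimum
training-site score, so that every training site is recovered by
construction and selectivity is a measured property, not an optimized
one.

Enrichment on a replicon compares the observed hit count k with the
mean count lambda over a null ensemble of sequences recoded from the
replicon's own 4-mer composition (order-3 Markov chain, 1000 replicates
by default).  The null count distribution is well approximated by
Poisson(lambda); the reported point probability is
P(X=k) = lambda^k exp(-lambda)/k!, with the upper tail P(X>=k) as a
secondary column.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from numba import njit
from scipy import stats

from .markov_background import MarkovBackground, fit_background, generate_codes
from .sequence_io import Replicon, _CODE

MATS_WIDTH = 13
_NEG = -1e30  # effective -inf for N columns; keeps numba arithmetic finite


@dataclass
class MotifHit:
    """One motif instance on a replicon (0-based start of the window)."""

    position: int
    strand: str
    score: float
    kind: str = "matS"


@dataclass
class Pssm:
    """Log-odds matrix with an optional calibrated detection threshold.

    ``matrix`` has shape (width, 4) over A,C,G,T in that order.
    """

    width: int
    matrix: np.ndarray
    pseudocount: float
    background: np.ndarray
    threshold: float | None = None
    counts: np.ndarray | None = None

    def max_score(self) -> float:
        return float(self.matrix.max(axis=1).sum())

    def min_score(self) -> float:
        return float(self.matrix.min(axis=1).sum())

    def information_content(self) -> float:
        """Total relative entropy (bits) of the column frequency estimates."""
        n = self.counts.sum(axis=1, keepdims=True)
        freq = (self.counts + self.pseudocount) / (n + 4 * self.pseudocount)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = freq * np.log2(freq / self.background[None, :])
        return float(np.nansum(terms))


def _sites_to_counts(sites: list[str], width: int) -> np.ndarray:
    counts = np.zeros((width, 4), dtype=float)
    for s in sites:
        codes = _CODE[np.frombuffer(s.upper().encode("ascii"), dtype=np.uint8)]
        if len(codes) != width or (codes > 3).any():
            raise ValueError(
                f"training site {s!r}: need length {width} over {{A,C,G,T}}"
            )
        counts[np.arange(width), codes] += 1.0
    return counts


def build_matrix(
    sites: list[str],
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
) -> Pssm:
    """Generic-width log-odds matrix from aligned training sites.

    matrix[j, b] = log2( (count(b,j)+pc) / (n+4*pc) / background(b) ).
    """
    if len(sites) < 2:
        raise ValueError("need at least 2 training sites")
    width = len(sites[0])
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    counts = _sites_to_counts(sites, width)
    n = len(sites)
    with np.errstate(divide="ignore"):
        matrix = np.log2(
            (counts + pseudocount) / (n + 4.0 * pseudocount) / background[None, :]
        )
    return Pssm(
        width=width,
        matrix=matrix,
        pseudocount=pseudocount,
        background=background,
        counts=counts,
    )


def build_pssm(
    training_sites: list[str],
    pseudocount: float = 0.5,
    background: np.ndarray | None = None,
) -> Pssm:
    """matS PSSM from 13 bp training sites (width enforced)."""
    if any(len(s) != MATS_WIDTH for s in training_sites):
        raise ValueError(f"matS training sites must be {MATS_WIDTH} bp")
    return build_matrix(training_sites, pseudocount, background)


def score_window(pssm: Pssm, window: str) -> float:
    """Additive log-odds score of one N-free window of width ``pssm.width``."""
    codes = _CODE[np.frombuffer(window.upper().encode("ascii"), dtype=np.uint8)]
    if len(codes) != pssm.width:
        raise ValueError(f"window length {len(codes)} != width {pssm.width}")
    if (codes > 3).any():
        raise ValueError("window contains N; N windows are skipped upstream")
    return float(pssm.matrix[np.arange(pssm.width), codes].sum())


def calibrate_threshold(pssm: Pssm, training_sites: list[str]) -> float:
    """Set threshold = min training-site score (all sites detected)."""
    scores = [score_window(pssm, s) for s in training_sites]
    pssm.threshold = float(min(scores))
    return pssm.threshold


def _padded_matrices(pssm: Pssm) -> tuple[np.ndarray, np.ndarray]:
    """(width, 5) forward and reverse-strand matrices; column 4 kills N."""
    w = pssm.width
    matf = np.full((w, 5), _NEG, dtype=np.float64)
    matf[:, :4] = pssm.matrix
    matr = np.full((w, 5), _NEG, dtype=np.float64)
    matr[:, :4] = pssm.matrix[::-1, ::-1]  # revcomp: flip columns and bases
    return matf, matr


def _score_scan(codes: np.ndarray, mat: np.ndarray) -> np.ndarray:
    """Vectorized window scores at every circular start position."""
    w = mat.shape[0]
    L = len(codes)
    ext = np.concatenate([codes, codes[: w - 1]]).astype(np.intp)
    out = np.zeros(L, dtype=np.float64)
    for j in range(w):
        out += mat[j][ext[j : j + L]]
    return out


def scan_mats(pssm: Pssm, replicon: Replicon) -> list[MotifHit]:
    """Circular both-strand scan; palindromic strand duplicates merged.

    All windows scoring >= the calibrated threshold are reported (matS
    sites do not overlap on real chromosomes, so no suppression beyond
    the palindrome merge: a window passing on both strands is one site,
    kept with its higher-scoring strand).
    """
    if pssm.threshold is None:
        raise ValueError("PSSM is not calibrated; call calibrate_threshold first")
    codes = replicon.codes()
    matf, matr = _padded_matrices(pssm)
    fwd = _score_scan(codes, matf)
    rev = _score_scan(codes, matr)
    hits = []
    for pos in np.nonzero((fwd >= pssm.threshold) | (rev >= pssm.threshold))[0]:
        f, r = fwd[pos], rev[pos]
        if f >= r:
            hits.append(MotifHit(position=int(pos), strand="+", score=float(f)))
        else:
            hits.append(MotifHit(position=int(pos), strand="-", score=float(r)))
    return hits


@njit(cache=True)
def _count_hits_kernel(ext, L, matf, matr, sufmax_f, sufmax_r, thr):
    w = matf.shape[0]
    count = 0
    for p in range(L):
        s = 0.0
        hit = True
        for j in range(w):
            s += matf[j, ext[p + j]]
            if s + sufmax_f[j + 1] < thr:
                hit = False
                break
        if not hit:
            s = 0.0
            hit = True
            for j in range(w):
                s += matr[j, ext[p + j]]
                if s + sufmax_r[j + 1] < thr:
                    hit = False
                    break
        if hit:
            count += 1
    return count


def _suffix_max(mat: np.ndarray) -> np.ndarray:
    w = mat.shape[0]
    out = np.zeros(w + 1)
    for j in range(w - 1, -1, -1):
        out[j] = out[j + 1] + mat[j, :4].max()
    return out


def count_hits(pssm: Pssm, codes: np.ndarray) -> int:
    """Merged both-strand hit count on an integer-coded circular sequence."""
    if pssm.threshold is None:
        raise ValueError("PSSM is not calibrated")
    matf, matr = _padded_matrices(pssm)
    w = pssm.width
    ext = np.concatenate([codes, codes[: w - 1]])
    return int(
        _count_hits_kernel(
            ext,
            len(codes),
            matf,
            matr,
            _suffix_max(matf),
            _suffix_max(matr),
            pssm.threshold,
        )
    )


@dataclass
class MatsEnrichment:
    """Observed count vs the Markov-recoded null ensemble."""

    k: int
    lam: float
    p_point: float
    p_tail: float
    n_null: int
    seed: int


def mats_enrichment(
    replicon: Replicon,
    pssm: Pssm,
    n_null: int = 1000,
    seed: int = 0,
    background: MarkovBackground | None = None,
) -> MatsEnrichment:
    """Poisson test of the observed matS count against recoded sequences.

    ``n_null`` sequences of the replicon's length are generated from its
    own fitted 4-mer background (replicate i uses seed+i) and scanned
    like the real sequence; lambda is their mean hit count.  p_point is
    the paper-style Poisson point probability P(X=k); p_tail is
    P(X>=k).  k=0 with lambda=0 gives p_point=1 by convention.
    """
    if background is None:
        background = fit_background(replicon)
    k = len(scan_mats(pssm, replicon))
    counts = np.empty(n_null, dtype=np.int64)
    for i in range(n_null):
        null_codes = generate_codes(background, replicon.length, seed + i)
        counts[i] = count_hits(pssm, null_codes)
    lam = float(counts.mean())
    p_point = float(stats.poisson.pmf(k, lam))
    p_tail = float(stats.poisson.sf(k - 1, lam))
    tiny = float(np.nextafter(0.0, 1.0))
    return MatsEnrichment(
        k=k,
        lam=lam,
        p_point=min(max(p_point, tiny), 1.0),
        p_tail=min(max(p_tail, tiny), 1.0),
        n_null=n_null,
        seed=seed,
    )


def load_training_sites(path=None) -> list[str]:
    """13-mer training sites, one per line; default is the shipped fixture.

    The shipped file is a synthetic stand-in built around the published
    matS palindromic consensus (GTGACRNYGTCAC), not the chromosome's
    annotated site list.
    """
    if path is None:
        text = (
            resources.files("xerscan.data")
            .joinpath("mats_training_sites_synthetic.txt")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    sites = [ln.strip().upper() for ln in text.splitlines() if ln.strip()]
    if not sites:
        raise ValueError("no training sites found")
    return sites


def default_pssm(pseudocount: float = 0.5) -> Pssm:
    """Calibrated matS PSSM from the shipped training fixture."""
    sites = load_training_sites()
    pssm = build_pssm(sites, pseudocount=pseudocount)
    calibrate_threshold(pssm, sites)
    return pssm
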