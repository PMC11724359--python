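"""Sequence containers, circular-coordinate arithmetic and flat-file I/O.

Everything downstream works on circular replicons, so this module owns the
coordinate conventions: 0-based half-open internally (BED keeps that
convention on output); human-readable reports print 1-based inclusive.
Positions on a circle are always reduced modulo the replicon length.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import SeqIO

VALID_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# A=0 C=1 G=2 T=3, N=4 (never matches any motif, excluded from k-mer counts)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


class SequenceAlphabetError(ValueError):
    """A sequence contains characters outside {A, C, G, T, N}."""


@dataclass
class Replicon:
    """A circular DNA molecule (plasmid, chromid or chromosome).

    ``seq`` is uppercase over {A,C,G,T,N}; ``length`` is the number of
    bases.  ``circular`` defaults to True — every replicon this package
    analyses is a covalently closed circle, and several operations
    (rotation, wrap-around motif matching) require it.
    """

    id: str
    seq: str
    circular: bool = True

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise ValueError(f"replicon {self.id!r}: empty sequence")
        bad = re.search(f"[^{''.join(sorted(VALID_ALPHABET))}]", self.seq)
        if bad:
            raise SequenceAlphabetError(
                f"replicon {self.id!r}: illegal character {bad.group()!r} "
                f"at offset {bad.start()}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def codes(self) -> np.ndarray:
        """Integer encoding (A=0 C=1 G=2 T=3 N=4) as a uint8 array."""
        return _CODE[np.frombuffer(self.seq.encode("ascii"), dtype=np.uint8)]


@dataclass
class FeatureRecord:
    """One located feature (KOPS, matS, xrs or accessory sequence).

    Coordinates are 0-based half-open on the replicon's forward strand.
    A feature crossing the origin is stored with ``wraps=True`` and
    ``end`` reduced modulo L (so start > end flags the wrap as well).
    """

    replicon_id: str
    start: int
    end: int
    strand: str
    kind: str
    score: float = 0.0
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.wraps and not 0 <= self.start < self.end:
            raise ValueError(
                f"bad coordinates [{self.start}, {self.end}) for "
                f"non-wrapping feature on {self.replicon_id!r}"
            )


@dataclass(frozen=True)
class OffsetMap:
    """Bidirectional coordinate map produced by :func:`rotate_to_center`."""

    shift: int
    length: int

    def to_rotated(self, pos: int) -> int:
        return (pos - self.shift) % self.length

    def to_original(self, pos: int) -> int:
        return (pos + self.shift) % self.length


def read_fasta(path) -> list[Replicon]:
    """Read a (multi-)FASTA file into a list of :class:`Replicon`.

    Record order is preserved and sequences are uppercased.  An empty
    file and any character outside {A,C,G,T,N} are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no records")
    return [Replicon(id=rec.id, seq=str(rec.seq)) for rec in records]


def write_fasta(replicons: list[Replicon], path) -> None:
    with open(path, "w") as fh:
        for rep in replicons:
            fh.write(f">{rep.id}\n")
            for i in range(0, rep.length, 70):
                fh.write(rep.seq[i : i + 70] + "\n")


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N."""
    bad = set(seq.upper()) - VALID_ALPHABET
    if bad:
        raise SequenceAlphabetError(f"illegal character(s) {sorted(bad)}")
    return seq.upper().translate(_COMPLEMENT)[::-1]


def circular_slice(seq: str, start: int, length: int) -> str:
    """``length`` bases starting at ``start`` (mod L), wrapping the origin."""
    L = len(seq)
    if length > L:
        raise ValueError(f"slice length {length} exceeds sequence length {L}")
    start %= L
    end = start + length
    if end <= L:
        return seq[start:end]
    return seq[start:] + seq[: end - L]


def rotate_to_center(replicon: Replicon, pos: int) -> tuple[Replicon, OffsetMap]:
    """Rotate a circular replicon so base ``pos`` sits at mid-sequence.

    The base at input position ``pos`` maps to output position
    ``floor(L/2)``.  Returns the rotated replicon and an
    :class:`OffsetMap` converting coordinates both ways.
    """
    if not replicon.circular:
        raise ValueError(f"replicon {replicon.id!r} is not circular; cannot rotate")
    L = replicon.length
    if not 0 <= pos < L:
        raise ValueError(f"position {pos} out of range [0, {L})")
    shift = (pos - L // 2) % L
    rotated = replicon.seq[shift:] + replicon.seq[:shift]
    return (
        Replicon(id=replicon.id, seq=rotated, circular=True),
        OffsetMap(shift=shift, length=L),
    )


def gc_skew_profile(
    replicon: Replicon, window: int, step: int | None = None
) -> np.ndarray:
    """Sliding (G−C)/(G+C) over circular windows.

    Returns a structured-free (n, 2) array of (window start, skew), one
    row per ``step``.  Windows wrap the origin; a window with no G or C
    emits 0 by convention.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    L = replicon.length
    if window > L:
        raise ValueError(f"window {window} longer than replicon ({L} bp)")
    if step is None:
        step = window
    codes = replicon.codes()
    ext = np.concatenate([codes, codes[: window - 1]]) if window > 1 else codes
    is_g = (ext == 2).astype(np.int64)
    is_c = (ext == 1).astype(np.int64)
    cg = np.concatenate([[0], np.cumsum(is_g)])
    cc = np.concatenate([[0], np.cumsum(is_c)])
    starts = np.arange(0, L, step)
    g = cg[starts + window] - cg[starts]
    c = cc[starts + window] - cc[starts]
    denom = g + c
    skew = np.zeros(len(starts), dtype=float)
    nz = denom > 0
    skew[nz] = (g[nz] - c[nz]) / denom[nz]
    return np.column_stack([starts.astype(float), skew])


def write_bed(features: list[FeatureRecord], path) -> None:
    """BED6: 0-based half-open, score column carries the motif score."""
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                f"{f.replicon_id}\t{f.start}\t{f.end}\t{f.kind}\t"
                f"{f.score:.4g}\t{f.strand}\n"
            )
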