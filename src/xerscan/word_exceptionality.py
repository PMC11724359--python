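"""Over/under-representation of a degenerate word under the maximal Markov model.

For a word of length h the maximal model has order h-2: the expected
count of w is estimated from the observed counts of its two (h-1)-mers
and its central (h-2)-mer,

    E[w] = N(w[1..h-1]) * N(w[2..h]) / N(w[2..h-1])

(1-based inclusive slices), i.e. the null preserves everything about the
sequence except the identity of the full h-mer.  A degenerate family
such as GGGNAGGG is scored by summing expectation and asymptotic
variance over its instantiations; the normalized score
(observed - expected)/sigma is treated as a standard normal deviate,
with +/-3 the conventional thresholds for calling a word over- or
under-represented.  Counting is single-strand and circular; the reverse
complement is a separate query.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import product

UNDER_THRESHOLD = -3.0
OVER_THRESHOLD = 3.0


@dataclass
class WordExceptionality:
    word: str
    observed: int
    expected: float
    sigma: float
    score: float
    order: int
    verdict: str  # under | normal | over


def _expand_pattern(pattern: str) -> list[str]:
    pattern = pattern.upper()
    if set(pattern) - set("ACGTN"):
        raise ValueError(f"pattern {pattern!r} not over {{A,C,G,T,N}}")
    slots = [("ACGT" if b == "N" else b) for b in pattern]
    return ["".join(w) for w in product(*slots)]


def _count_circular(seq: str, word: str) -> int:
    """Occurrences of a literal word on one strand, circular, overlaps kept."""
    ext = seq + seq[: len(word) - 1]
    return sum(1 for _ in re.finditer(f"(?={re.escape(word)})", ext))


def count_word_family(seq: str, pattern: str) -> int:
    """Total circular occurrences over all instantiations of N positions."""
    seq = seq.upper()
    return sum(_count_circular(seq, w) for w in _expand_pattern(pattern))


def exceptionality_score(seq: str, pattern: str) -> WordExceptionality:
    """Maximal-model exceptionality score of a degenerate word family.

    The family variance sums the per-instantiation asymptotic variances

        var(w) = E[w] * (1 - N(prefix)/N(mid)) * (1 - N(suffix)/N(mid));

    covariances between instantiations are neglected.  Every (h-1)- and
    (h-2)-mer the estimator touches must occur in the sequence.
    """
    seq = seq.upper()
    h = len(pattern)
    if h < 3:
        raise ValueError("word must be at least 3 bp for a maximal model")
    observed = 0
    expected = 0.0
    variance = 0.0
    # counts are cached because instantiations share their flanking words
    cache: dict[str, int] = {}

    def count(word: str) -> int:
        if word not in cache:
            cache[word] = _count_circular(seq, word)
        return cache[word]

    for w in _expand_pattern(pattern):
        n_mid = count(w[1 : h - 1])
        if n_mid == 0:
            raise ValueError(
                f"({h - 2})-mer {w[1:h - 1]!r} absent from sequence; "
                "maximal-model estimator undefined"
            )
        n_pre = count(w[: h - 1])
        n_suf = count(w[1:])
        e_w = n_pre * n_suf / n_mid
        observed += count(w)
        expected += e_w
        variance += e_w * (1.0 - n_pre / n_mid) * (1.0 - n_suf / n_mid)
    sigma = variance**0.5
    if sigma == 0.0:
        raise ValueError("degenerate null: zero variance for this word family")
    score = (observed - expected) / sigma
    if score <= UNDER_THRESHOLD:
        verdict = "under"
    elif score >= OVER_THRESHOLD:
        verdict = "over"
    else:
        verdict = "normal"
    return WordExceptionality(
        word=pattern.upper(),
        observed=observed,
        expected=expected,
        sigma=sigma,
        score=score,
        order=h - 2,
        verdict=verdict,
    )
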