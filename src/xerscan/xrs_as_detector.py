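"""Detection of Xer recombination sites (xrs) and their accessory sequences.

An xrs is a 28-30 bp pseudo-palindrome: an 11 bp XerC binding site, a
6-8 bp non-conserved central region and an 11 bp XerD binding site.
Detection operationalizes three empirical rules as filter parameters:
(i) the internal 5 bp of the two half-sites tend to form a palindrome
(soft constraint, minimum match count m), (ii) the XerD half is better
conserved than the XerC half (the XerD threshold is stricter), and
(iii) the central region is 6-8 bp with free sequence.

Plasmid xrs that recombine independently of FtsK carry a ~200 bp
accessory sequence (AS) adjacent to the XerC half-site, recognizable by
an ArgR or ArcA operator at a constrained position; sites devoid of AS
and exactly 28 bp long are the FtsK-dependent, chromosome-like class.

The shipped seed alignment contains the functionally characterized
E. coli dif site and the corrected R27 plasmid site, padded with
synthetic pseudo-palindromic variants emulating the diversity of
characterized plasmid sites (the fixture filename marks it synthetic);
ArgR/ArcA matrices are likewise built from synthetic operator sets
around consensus-like motifs, and all thresholds are tunable.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .mats_pssm import Pssm, build_matrix, calibrate_threshold, score_window, _padded_matrices, _score_scan
from .sequence_io import Replicon, revcomp

HALF_LEN = 11
CENTRAL_LENGTHS = (6, 7, 8)
INNER = 5  # palindromy is checked on the inner 5 bp of each half-site


@dataclass
class XrsCandidate:
    """One candidate site; ``position`` is the XerC half-site start."""

    position: int
    strand: str
    xerC_half: str
    central: str
    xerD_half: str
    total_len: int
    score_xerC: float
    score_xerD: float
    palindromy_inner5: int
    combined_score: float

    @property
    def end(self) -> int:
        return self.position + self.total_len


@dataclass
class AccessoryRegion:
    kind: str  # ArgR | ArcA
    motif_score: float
    offset: int  # bp from the XerC-side end of the xrs
    span: int


@dataclass
class XrsClassification:
    category: str  # AS_associated | AS_free_28bp | AS_free_other_len | none


@dataclass
class ScanParams:
    """Thresholds for the rule-based scan; XerD held to a stricter bar."""

    t_xerC: float
    t_xerD: float
    min_palindromy: int = 3
    central_lengths: tuple[int, ...] = CENTRAL_LENGTHS


@dataclass
class SeedXrs:
    name: str
    seq: str
    xerC: tuple[int, int]
    central: tuple[int, int]
    xerD: tuple[int, int]


_HEADER_RE = re.compile(
    r"(\S+)\s+xerC=(\d+):(\d+)\s+central=(\d+):(\d+)\s+xerD=(\d+):(\d+)"
)


def load_seed_xrs(path=None) -> list[SeedXrs]:
    """Seed alignment: FASTA whose headers annotate half-site boundaries.

    Header grammar: ``>name xerC=a:b central=b:c xerD=c:d`` with 0-based
    half-open coordinates.  Defaults to the shipped (partly synthetic)
    fixture.
    """
    if path is None:
        text = (
            resources.files("xerscan.data")
            .joinpath("xrs_seeds_synthetic.fasta")
            .read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    seeds = []
    header, chunks = None, []
    entries = []
    for line in text.splitlines():
        if line.startswith(">"):
            if header is not None:
                entries.append((header, "".join(chunks)))
            header, chunks = line[1:].strip(), []
        elif line.strip():
            chunks.append(line.strip().upper())
    if header is not None:
        entries.append((header, "".join(chunks)))
    for header, seq in entries:
        m = _HEADER_RE.match(header)
        if not m:
            raise ValueError(
                f"seed {header.split()[0]!r}: missing half-site boundary annotation"
            )
        name = m.group(1)
        a, b, b2, c, c2, d = (int(m.group(i)) for i in range(2, 8))
        if not (a == 0 and b == b2 and c == c2 and d == len(seq)):
            raise ValueError(f"seed {name!r}: inconsistent boundaries")
        if b - a != HALF_LEN or d - c != HALF_LEN or not 6 <= c - b <= 8:
            raise ValueError(f"seed {name!r}: bad half-site/central geometry")
        seeds.append(
            SeedXrs(name=name, seq=seq, xerC=(a, b), central=(b, c), xerD=(c, d))
        )
    if not seeds:
        raise ValueError("no seed xrs found")
    return seeds


def build_halfsite_pwms(seeds: list[SeedXrs], pseudocount: float = 0.5):
    """11-column log-odds PWMs for the XerC and XerD half-sites.

    Central regions are excluded (their sequence is not conserved).
    Each PWM's threshold is calibrated on the seed half-sites it was
    built from, XerD-style: threshold = min seed score.
    """
    xerC_sites = [s.seq[s.xerC[0] : s.xerC[1]] for s in seeds]
    xerD_sites = [s.seq[s.xerD[0] : s.xerD[1]] for s in seeds]
    xerC_pwm = build_matrix(xerC_sites, pseudocount=pseudocount)
    xerD_pwm = build_matrix(xerD_sites, pseudocount=pseudocount)
    calibrate_threshold(xerC_pwm, xerC_sites)
    calibrate_threshold(xerD_pwm, xerD_sites)
    return xerC_pwm, xerD_pwm


def default_params(xerC_pwm: Pssm, xerD_pwm: Pssm) -> ScanParams:
    """Default thresholds from the seed calibration.

    XerD keeps its strict min-seed threshold; XerC is relaxed by 20% of
    its PWM's achievable score range, reflecting the weaker conservation
    of the XerC half.
    """
    span = xerC_pwm.max_score() - xerC_pwm.min_score()
    return ScanParams(
        t_xerC=xerC_pwm.threshold - 0.2 * span,
        t_xerD=xerD_pwm.threshold,
    )


def _palindromy_counts(codes: np.ndarray, gap: int, L: int) -> np.ndarray:
    """Matches between XerC inner-5 and revcomp of XerD inner-5.

    For a candidate starting at p with central length c (gap = 11 + c),
    compares base p+6+i with the complement of base p+gap+4-i.
    """
    ext = np.concatenate([codes, codes[: gap + HALF_LEN]]).astype(np.int16)
    out = np.zeros(L, dtype=np.int8)
    for i in range(INNER):
        a = ext[6 + i : 6 + i + L]
        b = ext[gap + 4 - i : gap + 4 - i + L]
        out += ((a < 4) & (a == 3 - b)).astype(np.int8)
    return out


def scan_xrs(
    replicon: Replicon,
    pwms: tuple[Pssm, Pssm],
    params: ScanParams | None = None,
) -> list[XrsCandidate]:
    """Rule-based circular scan for candidate xrs on both strands.

    A candidate is accepted at (position, strand, central length) iff
    the XerD half scores >= t_xerD, the XerC half scores >= t_xerC and
    the inner-5 palindromy has >= m matches.  Overlapping candidates
    are pruned greedily, keeping the highest combined score.
    """
    xerC_pwm, xerD_pwm = pwms
    if params is None:
        params = default_params(xerC_pwm, xerD_pwm)
    L = replicon.length
    out: list[XrsCandidate] = []
    for strand, seq in (("+", replicon.seq), ("-", revcomp(replicon.seq))):
        codes = Replicon(id="_", seq=seq).codes()
        cf, _ = _padded_matrices(xerC_pwm)
        df, _ = _padded_matrices(xerD_pwm)
        sC = _score_scan(codes, cf)
        sD = _score_scan(codes, df)
        for c_len in params.central_lengths:
            gap = HALF_LEN + c_len
            total = 2 * HALF_LEN + c_len
            if total > L:
                continue
            pal = _palindromy_counts(codes, gap, L)
            sD_shift = np.roll(sD, -gap)
            keep = (
                (sC >= params.t_xerC)
                & (sD_shift >= params.t_xerD)
                & (pal >= params.min_palindromy)
            )
            for p in np.nonzero(keep)[0]:
                p = int(p)
                site = seq[p : p + total] if p + total <= L else seq[p:] + seq[: p + total - L]
                start = p if strand == "+" else (L - p - total) % L
                out.append(
                    XrsCandidate(
                        position=start,
                        strand=strand,
                        xerC_half=site[:HALF_LEN],
                        central=site[HALF_LEN:gap],
                        xerD_half=site[gap:],
                        total_len=total,
                        score_xerC=float(sC[p]),
                        score_xerD=float(sD_shift[p]),
                        palindromy_inner5=int(pal[p]),
                        combined_score=float(sC[p] + sD_shift[p]),
                    )
                )
    # greedy overlap pruning, best combined score first
    out.sort(key=lambda c: -c.combined_score)
    kept: list[XrsCandidate] = []
    for cand in out:
        span = set((cand.position + i) % L for i in range(cand.total_len))
        if all(
            span.isdisjoint((k.position + i) % L for i in range(k.total_len))
            for k in kept
        ):
            kept.append(cand)
    kept.sort(key=lambda c: c.position)
    return kept


def load_as_pwms(pseudocount: float = 0.5) -> dict[str, Pssm]:
    """Calibrated ArgR and ArcA operator PWMs from the shipped fixtures."""
    pwms = {}
    for kind, fname in (
        ("ArgR", "argr_sites_synthetic.txt"),
        ("ArcA", "arca_sites_synthetic.txt"),
    ):
        text = resources.files("xerscan.data").joinpath(fname).read_text()
        sites = [ln.strip().upper() for ln in text.splitlines() if ln.strip()]
        pwm = build_matrix(sites, pseudocount=pseudocount)
        calibrate_threshold(pwm, sites)
        pwms[kind] = pwm
    return pwms


def detect_as(
    replicon: Replicon,
    candidate: XrsCandidate,
    argr_pwm: Pssm,
    arca_pwm: Pssm,
    window: int = 200,
    band: tuple[int, int] = (10, 200),
) -> AccessoryRegion | None:
    """Best ArgR/ArcA operator hit in the AS window on the XerC side.

    The window extends ``window`` bp away from the XerC end of the
    candidate (upstream for '+' candidates, downstream for '-'); a hit
    qualifies if it passes its PWM threshold and its offset from the
    xrs lies inside ``band``.  Both strands of the window are scanned.
    Returns None when nothing qualifies.
    """
    L = replicon.length
    if candidate.strand == "+":
        start = (candidate.position - window) % L
    else:
        start = (candidate.position + candidate.total_len) % L
    region = "".join(
        replicon.seq[(start + i) % L] for i in range(window)
    )
    best: AccessoryRegion | None = None
    for kind, pwm in (("ArgR", argr_pwm), ("ArcA", arca_pwm)):
        w = pwm.width
        for p in range(window - w + 1):
            # offset of the motif from the XerC-side end of the xrs
            offset = (window - p - w) if candidate.strand == "+" else p
            if not band[0] <= offset <= band[1]:
                continue
            win = region[p : p + w]
            if "N" in win:
                continue
            for oriented in (win, revcomp(win)):
                s = score_window(pwm, oriented)
                if s >= pwm.threshold and (best is None or s > best.motif_score):
                    best = AccessoryRegion(
                        kind=kind, motif_score=s, offset=offset, span=window
                    )
    return best


def classify_xrs(
    candidate: XrsCandidate, accessory: AccessoryRegion | None
) -> XrsClassification:
    """AS_associated > AS_free_28bp (FtsK-type prediction) > other length."""
    if accessory is not None:
        return XrsClassification(category="AS_associated")
    if candidate.total_len == 28:
        return XrsClassification(category="AS_free_28bp")
    return XrsClassification(category="AS_free_other_len")
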