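"""Synthetic replicon cohorts with planted, fully known architecture.

Real surveys of dimer-resolution systems lack per-replicon ground
truth; this module builds plasmids where every motif is planted on a
background scrubbed of chance instances, so each pipeline stage can be
scored against a truth table.  The generator emulates the qualitative
structure of an enterobacterial replicon cohort: a bimodal size
distribution; small high-copy plasmids carrying an AS-associated xrs;
mid-size plasmids carrying only a self-encoded recombinase (an input
flag, since recombinase detection is outside this package); and large
replicons carrying a 28 bp AS-free xrs with converging KOPS orientation
bias and planted matS sites.

The background is scrubbed by mutating one base of each chance instance
of a planted motif class (bounded number of passes); whatever survives
— including instances created at plant junctions — is recorded in the
truth row rather than erased, so the truth stays honest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mats_pssm as mp
from .kops_circular import find_kops
from .sequence_io import Replicon, revcomp, write_fasta
from .xrs_as_detector import (
    build_halfsite_pwms,
    default_params,
    load_as_pwms,
    load_seed_xrs,
    scan_xrs,
)

ARGR_CONSENSUS = "AATGAATAATTATTCATT"
AS_OFFSET = 100  # bp between the planted ArgR box and the XerC end of the xrs


@dataclass
class PlasmidSpec:
    """Recipe for one synthetic plasmid.

    ``kops_orientation_bias`` is the probability that a forward KOPS
    falls in the half-circle preceding the xrs (0.5 = no convergence
    signal); reverse KOPS mirror it.
    """

    length: int
    gc: float = 0.5
    xrs: str = "none"  # none | AS_type | FtsK_type
    n_forward_kops: int = 0
    n_reverse_kops: int = 0
    kops_orientation_bias: float = 0.5
    n_mats: int = 0
    has_recombinase_flag: bool = False
    seed: int = 0
    id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.length < 1000:
            raise ValueError("plasmid length must be >= 1 kb")
        if self.xrs not in ("none", "AS_type", "FtsK_type"):
            raise ValueError(f"unknown xrs type {self.xrs!r}")
        if not 0.5 <= self.kops_orientation_bias <= 1.0:
            raise ValueError("bias must be in [0.5, 1]")


class _Toolkit:
    """Default detectors used for scrubbing and planting (built once)."""

    def __init__(self) -> None:
        self.pssm = mp.default_pssm()
        self.training_sites = mp.load_training_sites()
        self.seeds = load_seed_xrs()
        self.pwms = build_halfsite_pwms(self.seeds)
        self.params = default_params(*self.pwms)
        self.as_pwms = load_as_pwms()


_toolkit: _Toolkit | None = None


def _get_toolkit() -> _Toolkit:
    global _toolkit
    if _toolkit is None:
        _toolkit = _Toolkit()
    return _toolkit


def _scrub(seq_arr: np.ndarray, rng, tk: _Toolkit, max_passes: int = 4) -> dict:
    """Mutate one base of each chance motif instance; report what survives."""
    bases = np.frombuffer(b"ACGT", dtype="S1")
    for _ in range(max_passes):
        rep = Replicon(id="_", seq=seq_arr.tobytes().decode("ascii"))
        fwd, rev = find_kops(rep)
        mats = mp.scan_mats(tk.pssm, rep)
        xrs = scan_xrs(rep, tk.pwms, tk.params)
        # mutate a constrained base of each instance (index 4 is the free
        # N of the forward pattern's reverse complement, hence index 3 there)
        dirty = (
            [(p + 4) % rep.length for p in fwd]
            + [(p + 3) % rep.length for p in rev]
            + [(h.position + 2) % rep.length for h in mats]  # arm, not the free center
            + [(c.position + c.total_len - 3) % rep.length for c in xrs]
        )
        if not dirty:
            return {"residual_kops": 0, "residual_mats": 0, "residual_xrs": 0}
        for pos in dirty:
            cur = seq_arr[pos]
            choices = bases[bases != cur]
            seq_arr[pos] = rng.choice(choices)
    rep = Replicon(id="_", seq=seq_arr.tobytes().decode("ascii"))
    fwd, rev = find_kops(rep)
    return {
        "residual_kops": len(fwd) + len(rev),
        "residual_mats": len(mp.scan_mats(tk.pssm, rep)),
        "residual_xrs": len(scan_xrs(rep, tk.pwms, tk.params)),
    }


def _place(rng, length: int, n: int, taken: list[tuple[int, int]], lo: int, hi: int):
    """Draw n non-overlapping [start, start+length) intervals in [lo, hi)."""
    out = []
    for _ in range(n):
        for _attempt in range(200):
            start = int(rng.integers(lo, hi - length))
            iv = (start - 1, start + length + 1)
            if all(iv[1] <= a or iv[0] >= b for a, b in taken):
                taken.append(iv)
                out.append(start)
                break
        else:
            raise ValueError("cannot place features without overlap")
    return out


def _biased_position(rng, L: int, center: int, bias: float, forward: bool) -> tuple[int, int]:
    """(lo, hi) window for one KOPS in the xrs-centered frame, then mapped back.

    Forward KOPS fall with probability ``bias`` in the rotated half
    (0, L/2) (the half preceding the centered site); reverse KOPS in the
    other half.
    """
    in_first = rng.random() < bias
    if not forward:
        in_first = not in_first
    margin = 300
    if in_first:
        rot = int(rng.integers(margin, L // 2 - margin))
    else:
        rot = int(rng.integers(L // 2 + margin, L - margin))
    return (rot + center - L // 2) % L


def make_plasmid(spec: PlasmidSpec, toolkit: _Toolkit | None = None):
    """Build one synthetic plasmid and its ground-truth row.

    Deterministic for a fixed spec (including its seed).  The truth row
    records every planted locus plus the residual chance motifs the
    scrub pass could not remove.
    """
    tk = toolkit or _get_toolkit()
    rng = np.random.default_rng(spec.seed)
    L = spec.length
    p = np.array([(1 - spec.gc) / 2, spec.gc / 2, spec.gc / 2, (1 - spec.gc) / 2])
    seq_arr = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=L, p=p)
    residue = _scrub(seq_arr, rng, tk)

    taken: list[tuple[int, int]] = []
    truth: dict = {
        "id": spec.id,
        "length": L,
        "xrs_type": spec.xrs,
        "has_recombinase": spec.has_recombinase_flag,
        "kops_bias": spec.kops_orientation_bias,
        "seed": spec.seed,
        **residue,
    }

    def plant(start: int, motif: str) -> None:
        arr = np.frombuffer(motif.encode("ascii"), dtype="S1")
        idx = (np.arange(len(motif)) + start) % L
        seq_arr[idx] = arr

    # xrs (and its accessory region for AS_type plasmids)
    xrs_pos = None
    if spec.xrs != "none":
        if spec.xrs == "FtsK_type":
            pool = [s for s in tk.seeds if len(s.seq) == 28]
        else:
            pool = tk.seeds
        seed_site = pool[int(rng.integers(len(pool)))]
        margin = AS_OFFSET + len(ARGR_CONSENSUS) + 50
        xrs_pos = _place(rng, len(seed_site.seq), 1, taken, margin, L - margin)[0]
        plant(xrs_pos, seed_site.seq)
        truth.update(
            xrs_position=xrs_pos,
            xrs_len=len(seed_site.seq),
            xrs_seed=seed_site.name,
        )
        if spec.xrs == "AS_type":
            as_start = xrs_pos - AS_OFFSET - len(ARGR_CONSENSUS)
            taken.append((as_start - 1, as_start + len(ARGR_CONSENSUS) + 1))
            plant(as_start, ARGR_CONSENSUS)
            truth["as_offset"] = AS_OFFSET

    # KOPS with orientation bias converging on the xrs
    center = xrs_pos if xrs_pos is not None else L // 2
    kops_f, kops_r = [], []
    for forward, n in ((True, spec.n_forward_kops), (False, spec.n_reverse_kops)):
        for _ in range(n):
            for _attempt in range(200):
                pos = _biased_position(
                    rng, L, center, spec.kops_orientation_bias, forward
                )
                iv = (pos - 1, pos + 9)
                if all(iv[1] <= a or iv[0] >= b for a, b in taken):
                    taken.append(iv)
                    break
            else:
                raise ValueError("cannot place KOPS without overlap")
            word = "GGG" + "ACGT"[int(rng.integers(4))] + "AGGG"
            if not forward:
                word = revcomp(word)
            plant(pos, word)
            (kops_f if forward else kops_r).append(pos)
    truth["kops_forward"] = sorted(kops_f)
    truth["kops_reverse"] = sorted(kops_r)

    # matS drawn from the training fixture (score diversity on purpose)
    mats_positions = []
    for _ in range(spec.n_mats):
        pos = _place(rng, 13, 1, taken, 50, L - 50)[0]
        site = tk.training_sites[int(rng.integers(len(tk.training_sites)))]
        if rng.random() < 0.5:
            site = revcomp(site)
        plant(pos, site)
        mats_positions.append(pos)
    truth["mats"] = sorted(mats_positions)

    truth["category"] = {
        "AS_type": "AS_plasmid",
        "FtsK_type": "FtsK_chromosome_like",
        "none": "self_encoded_only" if spec.has_recombinase_flag else "unresolved",
    }[spec.xrs]

    replicon = Replicon(id=spec.id, seq=seq_arr.tobytes().decode("ascii"))
    return replicon, truth


#: (weight, size range in bp, class name) for the three cohort strata,
#: mirroring a bimodal enterobacterial size distribution: ~25% small
#: high-copy plasmids, the bulk mid-size, a tail of mega-replicons.
DEFAULT_MIXTURE = (0.25, 0.60, 0.15)
_SIZE_RANGES = {
    "small": (2_000, 25_000),
    "mid": (30_000, 150_000),
    "large": (250_000, 500_000),
}


def spec_for_class(cls: str, length: int, seed: int, ident: str, rng) -> PlasmidSpec:
    if cls == "small":
        return PlasmidSpec(
            length=length, xrs="AS_type", seed=seed, id=ident,
            gc=float(rng.uniform(0.45, 0.55)),
        )
    if cls == "mid":
        return PlasmidSpec(
            length=length, xrs="none", has_recombinase_flag=True,
            seed=seed, id=ident, gc=float(rng.uniform(0.45, 0.55)),
        )
    n_kops = max(20, length // 8000)
    return PlasmidSpec(
        length=length,
        xrs="FtsK_type",
        n_forward_kops=n_kops,
        n_reverse_kops=n_kops,
        kops_orientation_bias=0.9,
        n_mats=max(2, round(length / 100_000)),
        has_recombinase_flag=bool(rng.random() < 0.5),
        seed=seed,
        id=ident,
        gc=float(rng.uniform(0.45, 0.55)),
    )


def make_cohort(
    n: int = 60,
    mixture_weights: tuple[float, float, float] = DEFAULT_MIXTURE,
    seed: int = 0,
    fasta_path=None,
    truth_path=None,
):
    """A cohort of synthetic replicons plus its truth table.

    ``mixture_weights`` are the (small, mid, large) class probabilities
    and must sum to 1.  Small plasmids carry an AS-associated xrs,
    mid-size ones only the recombinase flag, large ones the full
    chromosome-like architecture, so every replicon above 250 kb carries
    an FtsK-type xrs by construction.
    """
    if abs(sum(mixture_weights) - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    rng = np.random.default_rng(seed)
    tk = _get_toolkit()
    classes = rng.choice(
        ["small", "mid", "large"], size=n, p=list(mixture_weights)
    )
    replicons, rows = [], []
    for i, cls in enumerate(classes):
        lo, hi = _SIZE_RANGES[cls]
        length = int(rng.integers(lo, hi))
        child_seed = int(rng.integers(0, 2**31 - 1))
        spec = spec_for_class(cls, length, child_seed, f"plasmid_{i:04d}", rng)
        rep, truth = make_plasmid(spec, toolkit=tk)
        truth["size_class"] = cls
        replicons.append(rep)
        rows.append(truth)
    truth_df = pd.DataFrame(rows)
    if fasta_path is not None:
        write_fasta(replicons, fasta_path)
    if truth_path is not None:
        out = truth_df.copy()
        for col in ("kops_forward", "kops_reverse", "mats"):
            out[col] = out[col].map(lambda v: ",".join(map(str, v)))
        out.to_csv(truth_path, sep="\t", index=False)
    return replicons, truth_df
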