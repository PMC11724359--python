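"""Xer site scanning, accessory-sequence detection and site classification."""

import numpy as np
import pytest

from xerscan.sequence_io import Replicon, revcomp
from xerscan.xrs_as_detector import (
    AccessoryRegion,
    build_halfsite_pwms,
    classify_xrs,
    default_params,
    detect_as,
    load_seed_xrs,
    scan_xrs,
)
from xerscan.synthetic_data import ARGR_CONSENSUS

R27_XRS = "AGTACATATAACAAAGATTATGTTAAAT"  # 28 bp, central CAAAGA


def _background(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestSeeds:
    def test_fixture_geometry(self, xrs_seeds):
        for s in xrs_seeds:
            assert s.xerC[1] - s.xerC[0] == 11
            assert s.xerD[1] - s.xerD[0] == 11
            assert 6 <= s.central[1] - s.central[0] <= 8
            assert len(s.seq) in (28, 29, 30)

    def test_r27_site_in_fixture(self, xrs_seeds):
        assert any(s.seq == R27_XRS for s in xrs_seeds)

    def test_missing_annotation_rejected(self, tmp_path):
        f = tmp_path / "bad.fa"
        f.write_text(">noboundaries\n" + R27_XRS + "\n")
        with pytest.raises(ValueError, match="boundary annotation"):
            load_seed_xrs(f)


class TestPwms:
    def test_identical_seeds_dominant_columns(self, xrs_seeds):
        seeds = [xrs_seeds[0]] * 3
        xerC, xerD = build_halfsite_pwms(seeds)
        for pwm, half in ((xerC, seeds[0].seq[:11]), (xerD, seeds[0].seq[17:])):
            consensus = "".join("ACGT"[b] for b in pwm.matrix.argmax(axis=1))
            assert consensus == half

    def test_strand_flip_symmetry(self, xrs_seeds):
        """Rebuilding from reverse-complemented seeds swaps the PWMs into
        their reverse-complement forms (XerC' = revcomp of XerD)."""
        from dataclasses import replace

        flipped = []
        for s in xrs_seeds:
            L = len(s.seq)
            flipped.append(
                replace(
                    s,
                    seq=revcomp(s.seq),
                    xerC=(0, 11),
                    central=(11, L - 11),
                    xerD=(L - 11, L),
                )
            )
        xerC, xerD = build_halfsite_pwms(xrs_seeds)
        fC, fD = build_halfsite_pwms(flipped)
        assert np.allclose(fC.matrix, xerD.matrix[::-1, ::-1])
        assert np.allclose(fD.matrix, xerC.matrix[::-1, ::-1])

    def test_xerD_better_conserved_than_xerC(self, halfsite_pwms):
        xerC, xerD = halfsite_pwms
        assert xerD.information_content() >= xerC.information_content()


class TestScan:
    def test_planted_r27_recovered(self, halfsite_pwms, scan_params, rng):
        bg = _background(rng, 50_000)
        seq = bg[:20_000] + R27_XRS + bg[20_000:]
        hits = scan_xrs(Replicon(id="p", seq=seq), halfsite_pwms, scan_params)
        assert [(h.position, h.strand, h.total_len) for h in hits] == [
            (20_000, "+", 28)
        ]
        assert hits[0].xerC_half == R27_XRS[:11]
        assert hits[0].xerD_half == R27_XRS[17:]

    def test_reverse_complement_planting(self, halfsite_pwms, scan_params, rng):
        bg = _background(rng, 50_000)
        seq = bg[:20_000] + revcomp(R27_XRS) + bg[20_000:]
        hits = scan_xrs(Replicon(id="p", seq=seq), halfsite_pwms, scan_params)
        assert [(h.position, h.strand) for h in hits] == [(20_000, "-")]

    def test_planted_recovery_rate(self, halfsite_pwms, scan_params, xrs_seeds, rng):
        """>= 99% of planted seed sites recovered within 1 bp."""
        recovered = 0
        for i in range(200):
            seed = xrs_seeds[i % len(xrs_seeds)]
            site = seed.seq if i % 2 == 0 else revcomp(seed.seq)
            bg = _background(rng, 10_000)
            pos = int(rng.integers(100, 9_000))
            seq = bg[:pos] + site + bg[pos:]
            hits = scan_xrs(Replicon(id=f"p{i}", seq=seq), halfsite_pwms, scan_params)
            recovered += any(abs(h.position - pos) <= 1 for h in hits)
        assert recovered >= 198

    def test_rotation_invariance(self, halfsite_pwms, scan_params, rng):
        bg = _background(rng, 30_000)
        seq = bg[:10_000] + R27_XRS + bg[10_000:]
        L = len(seq)
        shift = 17_345
        rotated = seq[shift:] + seq[:shift]
        h1 = scan_xrs(Replicon(id="a", seq=seq), halfsite_pwms, scan_params)
        h2 = scan_xrs(Replicon(id="b", seq=rotated), halfsite_pwms, scan_params)
        loci1 = {(h.position, h.strand, h.total_len) for h in h1}
        loci2 = {((h.position + shift) % L, h.strand, h.total_len) for h in h2}
        assert loci1 == loci2

    def test_false_positive_rate(self, halfsite_pwms, scan_params, rng):
        """Empirical FPR of the default thresholds on random sequence."""
        n_hits = sum(
            len(scan_xrs(Replicon(id=f"r{i}", seq=_background(rng, 50_000)),
                         halfsite_pwms, scan_params))
            for i in range(30)
        )
        assert n_hits / 30 < 0.1


class TestAccessory:
    def _plant(self, rng, xrs_strand="+", argr_side="xerC"):
        bg = _background(rng, 8_000)
        pos = 4_000
        site = R27_XRS if xrs_strand == "+" else revcomp(R27_XRS)
        arr = list(bg[:pos] + site + bg[pos:])
        # XerC side is upstream for '+', downstream for '-'
        if argr_side == "xerC":
            mpos = pos - 100 - len(ARGR_CONSENSUS) if xrs_strand == "+" else pos + 28 + 100
        else:
            mpos = pos + 28 + 100 if xrs_strand == "+" else pos - 100 - len(ARGR_CONSENSUS)
        arr[mpos : mpos + len(ARGR_CONSENSUS)] = ARGR_CONSENSUS
        return Replicon(id="as", seq="".join(arr)), pos

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_argr_on_xerc_side_detected(self, halfsite_pwms, scan_params, as_pwms, rng, strand):
        rep, _ = self._plant(rng, xrs_strand=strand, argr_side="xerC")
        (cand,) = scan_xrs(rep, halfsite_pwms, scan_params)
        acc = detect_as(rep, cand, as_pwms["ArgR"], as_pwms["ArcA"])
        assert acc is not None and acc.kind == "ArgR"
        assert 10 <= acc.offset <= 200

    def test_motif_on_xerd_side_ignored(self, halfsite_pwms, scan_params, as_pwms, rng):
        rep, _ = self._plant(rng, argr_side="xerD")
        (cand,) = scan_xrs(rep, halfsite_pwms, scan_params)
        assert detect_as(rep, cand, as_pwms["ArgR"], as_pwms["ArcA"]) is None

    def test_no_motif_none(self, halfsite_pwms, scan_params, as_pwms, rng):
        bg = _background(rng, 8_000)
        seq = bg[:4_000] + R27_XRS + bg[4_000:]
        (cand,) = scan_xrs(Replicon(id="x", seq=seq), halfsite_pwms, scan_params)
        assert detect_as(Replicon(id="x", seq=seq), cand,
                         as_pwms["ArgR"], as_pwms["ArcA"]) is None


class TestClassification:
    def _cand(self, total_len):
        from xerscan.xrs_as_detector import XrsCandidate

        return XrsCandidate(
            position=0, strand="+", xerC_half="A" * 11, central="A" * (total_len - 22),
            xerD_half="A" * 11, total_len=total_len, score_xerC=0, score_xerD=0,
            palindromy_inner5=5, combined_score=0,
        )

    def test_as_associated(self):
        acc = AccessoryRegion(kind="ArgR", motif_score=1.0, offset=100, span=200)
        assert classify_xrs(self._cand(28), acc).category == "AS_associated"

    def test_as_free_28(self):
        assert classify_xrs(self._cand(28), None).category == "AS_free_28bp"

    def test_as_free_other_len(self):
        assert classify_xrs(self._cand(30), None).category == "AS_free_other_len"
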