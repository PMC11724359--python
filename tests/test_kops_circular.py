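"""KOPS detection, angular projection and the Rayleigh clustering test."""

import math

import numpy as np
import pytest

from xerscan.kops_circular import (
    ClusteringStat,
    circular_summary,
    convergence_call,
    find_kops,
    project_angles,
    rayleigh_p,
    rayleigh_power,
)
from xerscan.sequence_io import Replicon, revcomp


def _stat(mean_dir, p, n=30):
    return ClusteringStat(r2=0.5, mean_direction=mean_dir, z=n * 0.5, p_rayleigh=p, n=n)


class TestFindKops:
    def test_single_forward_in_motif_free_context(self):
        # A/T-only flanks can host neither pattern by themselves
        rep = Replicon(id="r", seq="AT" * 100 + "GGGTAGGG" + "TA" * 100)
        fwd, rev = find_kops(rep)
        assert fwd == [200] and rev == []

    def test_reverse_pattern(self):
        rep = Replicon(id="r", seq="AT" * 50 + "CCCTACCC" + "TA" * 50)
        fwd, rev = find_kops(rep)
        assert fwd == [] and rev == [100]

    def test_wrap_spanning_match(self):
        seq = "AGGG" + "AT" * 50 + "GGGT"  # GGGTAGGG crosses the origin
        fwd, rev = find_kops(Replicon(id="r", seq=seq))
        assert fwd == [104]

    def test_strand_symmetry(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=30_000, p=[0.2, 0.3, 0.3, 0.2]))
        f1, r1 = find_kops(Replicon(id="a", seq=seq))
        f2, r2 = find_kops(Replicon(id="b", seq=revcomp(seq)))
        assert len(f1) == len(r2) and len(r1) == len(f2)

    def test_overlapping_matches_all_reported(self):
        rep = Replicon(id="r", seq="AT" * 40 + "GGGGAGGGGAGGG" + "TA" * 40)
        fwd, _ = find_kops(rep)
        assert len(fwd) == 2


class TestProjectAngles:
    def test_direct_formula(self):
        # center at L//2 makes the rotation the identity
        proj = project_angles([250, 0, 500], 1000, center_pos=500)
        assert np.allclose(proj.angles, [np.pi / 2, 0.0, np.pi])

    def test_center_site_lands_at_pi(self):
        proj = project_angles([123], 1000, center_pos=123)
        assert proj.angles[0] == pytest.approx(np.pi)

    def test_position_out_of_range(self):
        with pytest.raises(ValueError):
            project_angles([1000], 1000, 0)


def _series_p(z, n):
    """Independent transcription of the Rayleigh series approximation."""
    t1 = (2 * z - z**2) / (4 * n)
    t2 = (24 * z - 132 * z**2 + 76 * z**3 - 9 * z**4) / (288 * n**2)
    return math.exp(-z) * (1 + t1 - t2)


class TestCircularSummary:
    def test_degenerate_angles(self):
        proj = project_angles([100] * 20, 1000, center_pos=500)
        stat = circular_summary(proj)
        assert stat.r2 == pytest.approx(1.0, abs=1e-12)
        assert stat.mean_direction == pytest.approx(2 * np.pi * 100 / 1000, abs=1e-9)

    def test_four_symmetric_angles(self):
        proj = project_angles([0, 250, 500, 750], 1000, center_pos=500)
        assert circular_summary(proj).r2 == pytest.approx(0.0, abs=1e-12)

    def test_empty_errors(self):
        proj = project_angles([], 1000, 0)
        with pytest.raises(ValueError):
            circular_summary(proj)

    def test_r2_matches_bruteforce(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 60))
            theta = rng.uniform(0, 2 * np.pi, n)
            proj = project_angles([0], 10, 5)
            proj.angles, proj.n = theta, n
            stat = circular_summary(proj)
            r2 = (sum(np.cos(theta)) / n) ** 2 + (sum(np.sin(theta)) / n) ** 2
            assert stat.r2 == pytest.approx(r2, abs=1e-12)
            assert stat.p_rayleigh == pytest.approx(
                min(1.0, max(_series_p(stat.z, n), 0.0)), abs=1e-12
            )

    def test_p_against_independent_circular_package(self, rng):
        """Agreement with pingouin's Rayleigh test.

        pingouin implements Zar's approximation rather than the series
        form used here; the tolerated gap per sample size is the
        measured analytic divergence of the two published
        approximations (they agree asymptotically).
        """
        from pingouin.circular import circ_rayleigh

        for n, tol in ((5, 5e-3), (20, 5e-4), (100, 2e-5)):
            for _ in range(40):
                theta = rng.uniform(0, 2 * np.pi, n)
                proj = project_angles([0], 10, 5)
                proj.angles, proj.n = theta, n
                stat = circular_summary(proj)
                _, p_ref = circ_rayleigh(theta)
                assert stat.p_rayleigh == pytest.approx(p_ref, abs=tol)


class TestPower:
    def test_null_power_is_alpha(self):
        pw = rayleigh_power(30, kappa=0.0, alpha=0.05, n_sims=4000, seed=1)
        se = math.sqrt(0.05 * 0.95 / 4000)
        assert abs(pw - 0.05) < 3 * se

    def test_strong_clustering_saturates(self):
        assert rayleigh_power(50, kappa=10.0, n_sims=1000, seed=1) > 0.99

    def test_monotone_in_n(self):
        pows = [
            rayleigh_power(n, kappa=1.0, n_sims=3000, seed=2)
            for n in (5, 10, 15, 30, 60)
        ]
        se = 2 * math.sqrt(0.25 / 3000)
        assert all(b >= a - se for a, b in zip(pows, pows[1:]))

    def test_power_below_half_under_fifteen_motifs(self):
        """Weak unimodal clustering: <15 motifs leaves power under 0.5."""
        assert rayleigh_power(10, kappa=1.0, n_sims=3000, seed=3) < 0.5
        assert rayleigh_power(15, kappa=1.0, n_sims=3000, seed=3) > 0.5

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            rayleigh_power(0, 1.0)


class TestConvergenceCall:
    def test_convergent(self):
        call = convergence_call(
            _stat(np.pi / 2, 0.001), _stat(3 * np.pi / 2, 0.001), alpha=0.05
        )
        assert call.verdict == "convergent_at_xrs"

    def test_uniform_is_non_convergent(self):
        call = convergence_call(_stat(np.pi / 2, 0.8), _stat(3 * np.pi / 2, 0.9))
        assert call.verdict == "non_convergent"

    def test_wrong_halves_non_convergent(self):
        call = convergence_call(
            _stat(3 * np.pi / 2, 0.001), _stat(np.pi / 2, 0.001)
        )
        assert call.verdict == "non_convergent"

    def test_underpowered_below_fifteen(self):
        call = convergence_call(_stat(np.pi / 2, 0.001, n=10), _stat(3 * np.pi / 2, 0.001))
        assert call.verdict == "underpowered"

    def test_insufficient_below_three(self):
        call = convergence_call(_stat(np.pi / 2, 0.001, n=2), _stat(3 * np.pi / 2, 0.001))
        assert call.verdict == "insufficient_motifs"
        assert convergence_call(None, _stat(0.1, 0.5)).verdict == "insufficient_motifs"


def test_planted_bias_puts_forward_mean_in_first_half():
    """With orientation bias >= 0.8 and N >= 30, the forward-KOPS mean
    direction falls in (0, pi) in nearly all replicates once the
    replicon is centered on the planted xrs."""
    from xerscan.synthetic_data import _biased_position

    L, center, ok = 100_000, 34_567, 0
    rng = np.random.default_rng(5)
    for _ in range(200):
        pos = [_biased_position(rng, L, center, 0.8, forward=True) for _ in range(30)]
        stat = circular_summary(project_angles(pos, L, center))
        ok += 0.0 < stat.mean_direction < np.pi
    assert ok >= 190
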