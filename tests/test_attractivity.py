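import numpy as np
import pytest

import lgrefuge as lg
from lgrefuge.attractivity import (
    EPSILON_CAP,
    _first_round,
    check_conditions,
    strictness_margin,
)
from lgrefuge.model import sample_parameters


def assert_monotone_bracketing(seq, x_star, y_star):
    """The four sequences must be monotone, positive, and strictly
    bracket the equilibrium at every round."""
    assert np.all(np.diff(seq.M1) <= 0) and np.all(np.diff(seq.M2) <= 0)
    assert np.all(np.diff(seq.m1) >= 0) and np.all(np.diff(seq.m2) >= 0)
    assert np.all(seq.m1 > 0) and np.all(seq.m2 > 0)
    assert np.all(seq.m1 <= seq.M1) and np.all(seq.m2 <= seq.M2)
    assert np.all(seq.m1 < x_star) and np.all(seq.M1 > x_star)
    assert np.all(seq.m2 < y_star) and np.all(seq.M2 > y_star)


class TestConditions:
    def test_worked_example_margins(self, example):
        rep = check_conditions(example)
        # C3 margin: a2 b1 r1 k1 - a1(1-m)^2 r1 r2 - a1(1-m) b1 r2 k2
        #          = 715 - 126.72 - 192
        assert rep.c3.margin == pytest.approx(396.28, abs=1e-9)
        assert rep.c3.holds
        # C1 margin: 715 - 352 - 320 = 43
        assert rep.c1.margin == pytest.approx(43.0, abs=1e-9)
        # C4 margin: 715 - 126.72
        assert rep.c4.margin == pytest.approx(588.28, abs=1e-9)
        assert any("k2=0" in n for n in rep.notes)

    def test_c3_equals_c1_without_refuge(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            p = sample_parameters(rng, m_max=0.0)
            rep = check_conditions(p)
            assert rep.c3.margin == rep.c1.margin  # identical formula at m = 0

    def test_refuge_only_strengthens_c3(self, example):
        # the C3 margin is non-decreasing in m: more refuge, easier coexistence
        margins = [
            check_conditions(example.replace(m=m)).c3.margin
            for m in (0.0, 0.2, 0.4, 0.6, 0.8)
        ]
        assert np.all(np.diff(margins) > 0)


class TestEpsilon:
    def test_example_epsilon_valid(self, example):
        eps = lg.choose_epsilon(example)
        assert eps > 0
        assert strictness_margin(example, eps) > 0
        M1, M2, m1, m2 = _first_round(example, eps)
        assert 0 < m1 <= M1 and 0 < m2 <= M2

    def test_epsilon_vanishes_with_margin(self, example):
        # closer to the C3 boundary (larger a1), the margin shrinks and
        # the chosen epsilon shrinks toward zero with it
        margins, epsilons = [], []
        for a1 in (4.0, 8.5, 8.95):
            p = example.replace(a1=a1)
            margins.append(check_conditions(p).c3.margin)
            epsilons.append(lg.choose_epsilon(p))
        assert margins[0] > margins[1] > margins[2] > 0
        assert epsilons[0] > epsilons[1] > epsilons[2] > 0
        # near-critical margin forces a near-zero epsilon
        assert epsilons[2] < 0.01 * epsilons[0]

    def test_requires_c3(self, example):
        p = example.replace(a1=400.0)  # predation overwhelms protection
        assert not check_conditions(p).c3.holds
        with pytest.raises(lg.CertificateError):
            lg.choose_epsilon(p)
        with pytest.raises(lg.CertificateError):
            lg.permanence_bounds(p)
        with pytest.raises(lg.CertificateError):
            lg.iterate_bounds(p)


class TestIterateBounds:
    def test_worked_example_certificate(self, example):
        seq = lg.iterate_bounds(example, n_max=200)
        assert seq.converged
        (e,) = lg.positive_equilibria(example)
        assert_monotone_bracketing(seq, e.x, e.y)
        x_hi, x_lo, y_hi, y_lo = seq.limits
        assert x_hi == pytest.approx(e.x, abs=1e-6)
        assert x_lo == pytest.approx(e.x, abs=1e-6)
        assert y_hi == pytest.approx(e.y, abs=1e-6)
        assert y_lo == pytest.approx(e.y, abs=1e-6)

    def test_large_valid_epsilon_keeps_invariants(self, example):
        # the raw half-critical epsilon converges only like eps/n, but
        # monotone bracketing must hold at every round regardless
        eps = lg.choose_epsilon(example)
        seq = lg.iterate_bounds(example, n_max=300, epsilon=eps, tol=0.0)
        (e,) = lg.positive_equilibria(example)
        assert_monotone_bracketing(seq, e.x, e.y)

    def test_random_c3_sets_converge_to_equilibrium(self):
        rng = np.random.default_rng(8)

        def c3_holds(p):
            return check_conditions(p).c3.holds

        for _ in range(30):
            p = sample_parameters(rng, predicate=c3_holds)
            seq = lg.iterate_bounds(p)
            (e,) = lg.positive_equilibria(p)
            assert_monotone_bracketing(seq, e.x, e.y)
            for lim, target in zip(seq.limits, (e.x, e.x, e.y, e.y)):
                assert lim == pytest.approx(target, abs=1e-6 * max(1, target))

    def test_oversized_epsilon_surfaces_error(self, example):
        with pytest.raises(lg.CertificateError, match="not positive|too large"):
            lg.iterate_bounds(example, epsilon=10.0)

    def test_holling_tanner_certificate(self, example):
        # k2 = 0 mode: C4 (= C3 at k2=0) holds, same iteration converges
        p = example.replace(k2=0.0, holling_tanner=True)
        rep = check_conditions(p)
        assert rep.c4.holds and rep.c4.margin == rep.c3.margin
        seq = lg.iterate_bounds(p)
        (e,) = lg.positive_equilibria(p)
        assert_monotone_bracketing(seq, e.x, e.y)
        assert seq.limits[0] == pytest.approx(e.x, abs=1e-6)
        assert seq.limits[2] == pytest.approx(e.y, abs=1e-6)


class TestPermanence:
    def test_worked_example_box(self, example):
        x_lo, x_hi, y_lo, y_hi = lg.permanence_bounds(example)
        assert x_hi == pytest.approx(2.2, abs=1e-12)  # r1/b1
        assert 0 < x_lo < x_hi and 0 < y_lo < y_hi
        (e,) = lg.positive_equilibria(example)
        assert x_lo < e.x < x_hi
        assert y_lo < e.y < y_hi

    def test_full_refuge_limit_recovers_carrying_capacity(self, example):
        # as m -> 1 predation pressure vanishes and the prey lower
        # bound approaches the carrying capacity r1/b1
        x_lo, x_hi, _, _ = lg.permanence_bounds(example.replace(m=0.999))
        assert x_hi == 2.2
        assert x_lo == pytest.approx(2.2, abs=0.01)


class TestSuperfluousC2:
    def test_witness_found_and_certified(self):
        # a no-refuge parameter set satisfying C1 but violating C2:
        # the certificate needs only C1 and still converges, showing
        # the auxiliary condition C2 of the older theory is redundant
        found = lg.find_c1_without_c2(n_samples=50_000, seed=0)
        assert found is not None
        p, rep = found
        assert p.m == 0.0 and rep.c1.holds and not rep.c2.holds
        seq = lg.iterate_bounds(p)
        (e,) = lg.positive_equilibria(p)
        assert seq.limits[0] == pytest.approx(e.x, abs=1e-6 * max(1, e.x))
        assert seq.limits[2] == pytest.approx(e.y, abs=1e-6 * max(1, e.y))

    def test_default_epsilon_cap_keeps_tail_small(self, example):
        seq = lg.iterate_bounds(example)
        assert seq.epsilon <= EPSILON_CAP
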