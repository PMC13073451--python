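import math

import numpy as np
import pytest
from scipy.optimize import linprog

from capla.pla import (
    PLASizeTable,
    brute_force_min_segments,
    min_segments,
    pla_segments,
    pla_size_table,
    read_table_tsv,
    write_table_tsv,
)
from capla.spectrum import Spectrum, rank_array, spectrum_from_values

from conftest import make_random_spectrum


def line_spectrum(u):
    return Spectrum(k=0, u=u, keys=np.arange(u), counts=np.ones(u, dtype=int))


class TestMinSegments:
    def test_perfect_line_is_one_segment(self):
        assert min_segments(line_spectrum(8), 1) == 1

    def test_eps_at_least_N_is_one_segment(self, rng):
        for _ in range(10):
            sp = make_random_spectrum(rng)
            assert min_segments(sp, sp.N) == 1

    def test_two_point_step_needs_two_segments(self):
        sp = Spectrum(k=0, u=16, keys=np.array([0, 15]), counts=np.array([3, 3]))
        assert min_segments(sp, 1) == 2
        assert brute_force_min_segments(sp, 1) == 2

    def test_eps_below_one_errors(self):
        with pytest.raises(ValueError):
            min_segments(line_spectrum(8), 0)

    def test_oracle_equivalence_on_random_instances(self, rng):
        """Greedy maximal extension equals the exhaustive DP on >= 200
        random small multisets (duplicates and all epsilon in 1..8)."""
        for _ in range(220):
            sp = make_random_spectrum(rng, u_max=128, n_max=60)
            eps = int(rng.integers(1, 9))
            assert min_segments(sp, eps) == brute_force_min_segments(sp, eps)

    def test_monotone_nonincreasing_in_eps(self, rng):
        for _ in range(25):
            sp = make_random_spectrum(rng)
            b = [min_segments(sp, e) for e in range(1, 12)]
            assert all(x >= y for x, y in zip(b, b[1:]))

    def test_worst_case_upper_bound(self, rng):
        """1 <= b(eps) <= ceil(N / (2 eps)) on every generated instance."""
        for _ in range(40):
            sp = make_random_spectrum(rng)
            for eps in (1, 2, 4):
                b = min_segments(sp, eps)
                assert 1 <= b <= max(1, math.ceil(sp.N / (2 * eps)))

    def test_horizontal_scale_invariance_of_constraints(self, rng):
        """Stretching the x-axis of the constraint system by any factor
        leaves the minimum piece count unchanged: segment feasibility is
        affine-invariant in x.  (Note this maps each constant run [a, b] to
        [c*a, c*b]; re-deriving runs from a key-scaled *integer* spectrum
        instead shifts run right-endpoints from c*(k-1) to c*k - 1, which
        can genuinely change the optimum by a piece near adjacent keys.)"""
        from capla.pla import _runs, _segment_pass

        for _ in range(15):
            sp = make_random_spectrum(rng, u_max=64, n_max=30)
            ra, rb, rr = _runs(sp, "definition1")
            for c in (2.0, 7.0, 1000.0):
                for eps in (1.0, 2.0, 3.0):
                    work = [np.empty(2 * ra.size + 2) for _ in range(4)]
                    ends = np.empty(1, dtype=np.int64)
                    base = _segment_pass(ra, rb, rr, eps, *work, ends, False)
                    scaled = _segment_pass(
                        c * ra, c * rb, rr, eps, *work, ends, False
                    )
                    assert scaled == base

    def test_integer_rescaling_matches_oracle(self, rng):
        """Key-scaled integer spectra are still solved optimally (the DP
        oracle agrees), even where the piece count differs from the
        unscaled instance by the run-boundary effect above."""
        for _ in range(20):
            sp = make_random_spectrum(rng, u_max=64, n_max=30)
            for c in (2, 7):
                scaled = Spectrum(
                    k=0, u=c * sp.u, keys=c * sp.keys, counts=sp.counts
                )
                eps = int(rng.integers(1, 4))
                assert min_segments(scaled, eps) == brute_force_min_segments(
                    scaled, eps
                )

    def test_keys_only_mode_needs_no_more_segments(self, rng):
        """Constraining only the (key, rank) points is a relaxation of the
        every-integer semantics, so it can only lower the count."""
        for _ in range(30):
            sp = make_random_spectrum(rng)
            eps = int(rng.integers(1, 5))
            assert min_segments(sp, eps, mode="keys-only") <= min_segments(sp, eps)


class TestWitness:
    def test_line_witness(self):
        segs = pla_segments(line_spectrum(8), 1)
        assert len(segs) == 1
        assert segs[0].interval_start == 0 and segs[0].interval_end == 7
        # f(x) = x + 1 is exact; the witness must be within eps of it
        for x in range(8):
            assert abs(segs[0](x) - (x + 1)) <= 1 + 1e-9

    def test_partition_tiles_universe(self, rng):
        for _ in range(30):
            sp = make_random_spectrum(rng)
            segs = pla_segments(sp, int(rng.integers(1, 5)))
            assert segs[0].interval_start == 0
            assert segs[-1].interval_end == sp.u - 1
            for s1, s2 in zip(segs, segs[1:]):
                assert s2.interval_start == s1.interval_end + 1

    def test_every_segment_within_eps_everywhere(self, rng):
        """Exhaustive per-integer check of the approximation guarantee."""
        for _ in range(60):
            sp = make_random_spectrum(rng, u_max=128, n_max=60)
            eps = int(rng.integers(1, 6))
            segs = pla_segments(sp, eps)
            assert len(segs) == min_segments(sp, eps)
            R = rank_array(sp, np.arange(sp.u))
            for s in segs:
                xs = np.arange(s.interval_start, s.interval_end + 1)
                err = np.abs(s.slope * xs + s.intercept - R[xs])
                assert err.max() <= eps * (1 + 1e-9) + 1e-9


class TestSizeTable:
    def test_line_table_all_ones(self):
        t = pla_size_table(line_spectrum(8), [1, 2, 4])
        assert t.b_values.tolist() == [1, 1, 1]

    def test_last_entry_one_when_eps_reaches_N(self, rng):
        sp = make_random_spectrum(rng)
        t = pla_size_table(sp, [1, sp.N])
        assert t.b_values[-1] == 1

    def test_sweep_matches_oracle_pointwise(self, rng):
        sp = make_random_spectrum(rng, u_max=64, n_max=40)
        t = pla_size_table(sp, range(1, 17))
        assert np.all(np.diff(t.b_values) <= 0)
        for e, b in zip(t.eps_values, t.b_values):
            assert b == brute_force_min_segments(sp, int(e))

    def test_table_validation(self):
        with pytest.raises(ValueError):
            PLASizeTable(eps_values=[2, 1], b_values=[1, 1], n=5, N=5)
        with pytest.raises(ValueError):
            PLASizeTable(eps_values=[1, 2], b_values=[1, 0.5], n=5, N=5)

    def test_tsv_roundtrip_with_real_values(self, tmp_path):
        t = PLASizeTable(
            eps_values=[1, 2, 4], b_values=[10, 5.5, 2.75], n=100, N=200
        )
        path = tmp_path / "t.tsv"
        write_table_tsv(t, path)
        back = read_table_tsv(path)
        assert back.n == 100 and back.N == 200
        assert np.array_equal(back.eps_values, t.eps_values)
        assert np.array_equal(back.b_values, t.b_values)


class TestFeasibilityCriterion:
    def test_pairwise_criterion_agrees_with_linear_programming(self, rng):
        """The extreme-slope feasibility rule used by both solvers equals LP
        feasibility of the full constraint system on random intervals."""
        for _ in range(30):
            sp = make_random_spectrum(rng, u_max=48, n_max=30)
            eps = int(rng.integers(1, 4))
            R = rank_array(sp, np.arange(sp.u)).astype(float)
            i = int(rng.integers(0, sp.u - 1))
            j = int(rng.integers(i + 1, sp.u))
            xs = np.arange(i, j + 1, dtype=float)
            lo, hi = R[i : j + 1] - eps, R[i : j + 1] + eps
            # pairwise extreme slopes
            dx = xs[None, :] - xs[:, None]
            with np.errstate(divide="ignore", invalid="ignore"):
                G = np.nanmax(np.where(dx > 0, (lo[None, :] - hi[:, None]) / dx, -np.inf))
                S = np.nanmin(np.where(dx > 0, (hi[None, :] - lo[:, None]) / dx, np.inf))
            pairwise_feasible = G <= S + 1e-9
            # LP in (slope, intercept): lo <= m x + c <= hi
            A = np.vstack([np.column_stack([xs, np.ones_like(xs)]) * -1,
                           np.column_stack([xs, np.ones_like(xs)])])
            b = np.concatenate([-lo, hi])
            res = linprog(c=[0.0, 0.0], A_ub=A, b_ub=b,
                          bounds=[(None, None), (None, None)], method="highs")
            assert pairwise_feasible == res.success
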