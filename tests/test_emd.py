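import numpy as np
import pytest
from scipy.linalg import solve_banded

from hhtdenoise import (Decomposition, SiftConfig, Spectrum,
                        count_zero_crossings, emd, find_extrema, is_imf,
                        sift_one_imf, spline_envelopes)


def brute_force_extrema(v):
    """Neighbour comparison with the plateau-midpoint rule."""
    maxima, minima = [], []
    n = len(v)
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and v[j + 1] == v[i]:
            j += 1
        if j + 1 < n and i - 1 >= 0:
            mid = (i + j) // 2
            if v[i - 1] < v[i] and v[j + 1] < v[i]:
                maxima.append(mid)
            elif v[i - 1] > v[i] and v[j + 1] > v[i]:
                minima.append(mid)
        i = j + 1
    return np.array(maxima, dtype=int), np.array(minima, dtype=int)


def brute_force_zero_crossings(v):
    signs = []
    for i, x in enumerate(v):
        if x != 0:
            signs.append(np.sign(x))
        else:
            nxt = next((np.sign(y) for y in v[i + 1:] if y != 0), None)
            prv = signs[-1] if signs else None
            signs.append(nxt if nxt is not None else (prv or 0))
    return sum(1 for a, b in zip(signs, signs[1:]) if a != b)


def natural_spline_oracle(xk, yk, xq):
    """Natural cubic spline by an independent tridiagonal solve."""
    xk = np.asarray(xk, float)
    yk = np.asarray(yk, float)
    n = xk.size
    h = np.diff(xk)
    # second derivatives M solve a tridiagonal system; M[0]=M[-1]=0
    if n == 2:
        m = np.zeros(2)
    else:
        ab = np.zeros((3, n - 2))
        rhs = np.empty(n - 2)
        for i in range(1, n - 1):
            j = i - 1
            ab[1, j] = 2.0 * (h[i - 1] + h[i])
            if j > 0:
                ab[0, j] = h[i - 1]
            if j < n - 3:
                ab[2, j] = h[i]
            rhs[j] = 6.0 * ((yk[i + 1] - yk[i]) / h[i] - (yk[i] - yk[i - 1]) / h[i - 1])
        m = np.zeros(n)
        m[1:-1] = solve_banded((1, 1), ab, rhs)
    out = np.empty_like(np.asarray(xq, float))
    for q, x in enumerate(np.asarray(xq, float)):
        i = int(np.clip(np.searchsorted(xk, x) - 1, 0, n - 2))
        t = x - xk[i]
        hi = h[i]
        out[q] = (m[i] * (xk[i + 1] - x) ** 3 / (6 * hi)
                  + m[i + 1] * t ** 3 / (6 * hi)
                  + (yk[i] / hi - m[i] * hi / 6) * (xk[i + 1] - x)
                  + (yk[i + 1] / hi - m[i + 1] * hi / 6) * t)
    return out


class TestFindExtrema:
    def test_monotone_has_no_interior_extrema(self):
        mx, mn = find_extrema(np.array([1.0, 2, 3, 4, 5]))
        assert mx.size == 0 and mn.size == 0

    def test_single_peak(self):
        mx, mn = find_extrema(np.array([0.0, 1.0, 0.0]))
        np.testing.assert_array_equal(mx, [1])
        assert mn.size == 0

    def test_plateau_reports_midpoint_once(self):
        v = np.array([0.0, 1, 2, 2, 2, 1, 0])
        mx, mn = find_extrema(v)
        np.testing.assert_array_equal(mx, [3])
        assert mn.size == 0

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(20):
            v = np.round(rng.standard_normal(50), 1)  # rounding makes plateaus
            mx, mn = find_extrema(v)
            bmx, bmn = brute_force_extrema(v)
            np.testing.assert_array_equal(mx, bmx)
            np.testing.assert_array_equal(mn, bmn)


class TestZeroCrossings:
    def test_matches_brute_force_including_exact_zeros(self, rng):
        for _ in range(20):
            v = rng.standard_normal(60)
            v[rng.integers(0, 60, 6)] = 0.0  # force exact zeros
            assert count_zero_crossings(v) == brute_force_zero_crossings(v)

    def test_sine_crossing_count(self):
        t = np.arange(256)
        v = np.sin(2 * np.pi * 4 * t / 256)
        # starts at an exact zero (counted with the sign of the next sample):
        # 7 sign changes over four periods of the sampled record
        assert count_zero_crossings(v) == brute_force_zero_crossings(v) == 7


class TestSplineEnvelopes:
    def test_equal_maxima_give_constant_upper_envelope(self):
        t = np.arange(200)
        v = np.sin(2 * np.pi * 5 * t / 200) * 0.5 + 0.0
        mx, mn = find_extrema(v)
        upper, lower, mean = spline_envelopes(v, mx, mn)
        np.testing.assert_allclose(upper, 0.5, atol=1e-6)

    def test_antisymmetric_extrema_give_zero_mean(self):
        t = np.arange(300)
        v = np.sin(2 * np.pi * 6 * t / 300)
        mx, mn = find_extrema(v)
        upper, lower, mean = spline_envelopes(v, mx, mn)
        np.testing.assert_allclose(lower, -upper, atol=1e-9)
        np.testing.assert_allclose(mean, 0.0, atol=1e-9)

    def test_envelope_interpolates_every_knot(self, rng):
        v = rng.standard_normal(100).cumsum()
        v = v + 3 * np.sin(np.arange(100))
        mx, mn = find_extrema(v)
        upper, lower, _ = spline_envelopes(v, mx, mn)
        np.testing.assert_allclose(upper[mx], v[mx], atol=1e-10)
        np.testing.assert_allclose(lower[mn], v[mn], atol=1e-10)

    def test_matches_independent_tridiagonal_solve(self, rng):
        # 5 irregular knots, natural boundary: compare at 20 query points
        xk = np.sort(rng.choice(np.arange(1.0, 60.0), 5, replace=False))
        yk = rng.standard_normal(5)
        from scipy.interpolate import CubicSpline
        ours = CubicSpline(xk, yk, bc_type="natural")
        xq = np.linspace(xk[0], xk[-1], 20)
        np.testing.assert_allclose(ours(xq), natural_spline_oracle(xk, yk, xq),
                                   atol=1e-10)

    def test_too_few_extrema_is_an_error(self):
        with pytest.raises(ValueError, match="maximum"):
            spline_envelopes(np.arange(10.0), np.array([], dtype=int),
                             np.array([3], dtype=int))


class TestIsImf:
    def test_multi_period_sine_is_imf(self):
        t = np.arange(256)
        assert is_imf(np.sin(2 * np.pi * 4 * t / 256))

    def test_ramp_is_not_imf(self):
        assert not is_imf(np.linspace(0, 1, 64))

    def test_offset_oscillation_fails_envelope_mean(self):
        t = np.arange(256)
        assert not is_imf(np.sin(2 * np.pi * 4 * t / 256) + 0.5)


class TestSiftOneImf:
    def test_pure_sinusoid_sifts_to_itself(self):
        t = np.arange(256)
        v = np.sin(2 * np.pi * 8 * t / 256)
        imf, iterations, accepted = sift_one_imf(v)
        assert iterations <= 3
        # interior agreement; envelope end effects touch the edges only
        np.testing.assert_allclose(imf[10:-10], v[10:-10], atol=1e-3)
        assert np.linalg.norm(imf - v) / np.linalg.norm(v) < 1e-2

    def test_residual_plus_imf_reproduces_input_exactly(self, rng):
        v = rng.standard_normal(200).cumsum() + rng.standard_normal(200)
        imf, _, _ = sift_one_imf(v)
        residual = v - imf
        np.testing.assert_allclose(residual + imf, v, rtol=0, atol=1e-12)


class TestEmd:
    def test_linear_ramp_yields_no_imfs(self):
        s = Spectrum(np.arange(1.0, 51.0), np.linspace(0, 1, 50))
        d = emd(s)
        assert d.n_imfs == 0
        np.testing.assert_array_equal(d.residual, s.intensity)
        assert d.stop_reason in ("monotone_residual", "too_few_extrema")

    def test_completeness_on_random_inputs(self, rng):
        for _ in range(5):
            v = rng.standard_normal(256)
            d = emd(v)
            err = np.linalg.norm(d.reconstruct_full() - v) / np.linalg.norm(v)
            assert err < 1e-9

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="5"):
            emd(np.array([0.0, 1.0, 0.0, 1.0]))

    def test_determinism_bit_identical(self, rng):
        v = rng.standard_normal(300)
        d1, d2 = emd(v), emd(v)
        assert d1.n_imfs == d2.n_imfs
        for a, b in zip(d1.imfs, d2.imfs):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_array_equal(d1.residual, d2.residual)

    def test_imf_ordering_zero_crossings_non_increasing(self):
        from hhtdenoise import SynthParams, generate_noised
        ok = 0
        for seed in range(5):
            noisy, _, _ = generate_noised(SynthParams(seed=seed))
            d = emd(noisy)
            zc = [count_zero_crossings(imf) for imf in d.imfs]
            if all(a >= b for a, b in zip(zc, zc[1:])):
                ok += 1
        assert ok >= 4  # ties allowed; rare deep-order inversions tolerated

    def test_first_imf_oscillates_faster_than_second(self):
        from hhtdenoise import SynthParams, generate_noised
        noisy, _, _ = generate_noised(SynthParams(seed=1))
        d = emd(noisy)
        assert count_zero_crossings(d.imfs[0]) > count_zero_crossings(d.imfs[1])

    def test_max_imfs_cap_recorded(self, rng):
        v = rng.standard_normal(400)
        d = emd(v, SiftConfig(max_imfs=2))
        assert d.n_imfs == 2
        assert d.stop_reason == "max_imfs"

    def test_sift_metadata_lengths(self, rng):
        v = rng.standard_normal(300)
        d = emd(v)
        assert len(d.sift_iterations) == d.n_imfs == len(d.accepted_by)
        assert all(a in ("cauchy", "max_iterations", "lost_extrema")
                   for a in d.accepted_by)
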