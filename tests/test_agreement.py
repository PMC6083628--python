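"""Agreement statistics: two-way mixed ICC and log-scale Bland-Altman."""
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dietval.agreement import (
    MixedModelComponents,
    bland_altman_log,
    fit_two_way_mixed,
    icc_absolute,
)
from dietval.errors import InputError


def components(s2s, s2i, s2e, tau, methods=("a", "b")):
    return MixedModelComponents(
        methods=methods,
        sigma2_subject=s2s,
        sigma2_int={m: v for m, v in zip(methods, s2i)},
        sigma2_resid={m: v for m, v in zip(methods, s2e)},
        tau={m: t for m, t in zip(methods, tau)},
        grand_mean=0.0,
        n_subjects=10,
        n_occasions=3,
    )


def simulate_cube(rng, n, s2s=1.0, s2i=(0.0, 0.0), s2e=(1.0, 1.0), tau=(0.0, 0.0), k=3):
    b = rng.normal(0, math.sqrt(s2s), n)
    y = np.empty((n, 2, k))
    for m in range(2):
        g = rng.normal(0, math.sqrt(s2i[m]), n) if s2i[m] > 0 else np.zeros(n)
        y[:, m, :] = tau[m] + (b + g)[:, None] + rng.normal(0, math.sqrt(s2e[m]), (n, k))
    return y


class TestICCClosedForm:
    def test_equal_noise_no_shift_gives_half(self):
        c = components(1.0, (0.0, 0.0), (1.0, 1.0), (0.0, 0.0))
        assert icc_absolute(c).value == pytest.approx(0.5, rel=1e-12)

    def test_systematic_offset_penalizes_absolute_agreement(self):
        # residuals zero, sum tau^2/(M-1) = 1  ->  ICC = 1/(1+1)
        t = math.sqrt(0.5)
        c = components(1.0, (0.0, 0.0), (0.0, 0.0), (t, -t))
        assert icc_absolute(c).value == pytest.approx(0.5, rel=1e-12)

    def test_all_zero_components_rejected(self):
        with pytest.raises(InputError):
            icc_absolute(components(0.0, (0.0, 0.0), (0.0, 0.0), (0.0, 0.0)))


class TestTwoWayFit:
    def test_identical_methods_are_degenerate_with_icc_one(self):
        rng = np.random.default_rng(0)
        per_subject = rng.lognormal(4.0, 0.3, (50, 1, 1))
        vals = np.tile(per_subject, (1, 1, 3))  # identical across occasions too
        cube = np.concatenate([vals, vals], axis=1)
        comp = fit_two_way_mixed(np.log(cube))
        assert comp.method == "moments"
        assert all(v == pytest.approx(0.0, abs=1e-12) for v in comp.sigma2_resid.values())
        assert all(t == pytest.approx(0.0, abs=1e-12) for t in comp.tau.values())
        assert icc_absolute(comp).value == pytest.approx(1.0, abs=1e-9)

    def test_constant_shift_is_absorbed_by_the_fixed_effect(self):
        rng = np.random.default_rng(1)
        cube = simulate_cube(rng, 400)
        shifted = cube.copy()
        shifted[:, 1, :] += 0.7
        base = fit_two_way_mixed(cube)
        shift = fit_two_way_mixed(shifted)
        taus = list(shift.tau.values())
        assert taus[1] - taus[0] - (
            list(base.tau.values())[1] - list(base.tau.values())[0]
        ) == pytest.approx(0.7, abs=1e-6)
        assert shift.sigma2_subject == pytest.approx(base.sigma2_subject, rel=1e-5)
        for m in base.methods:
            assert shift.sigma2_resid[m] == pytest.approx(base.sigma2_resid[m], rel=1e-5)

    def test_variance_component_recovery(self):
        rng = np.random.default_rng(2)
        cube = simulate_cube(rng, 1500, s2s=1.0, s2i=(0.2, 0.1), s2e=(1.0, 0.5))
        comp = fit_two_way_mixed(cube)
        assert comp.converged
        assert comp.sigma2_subject == pytest.approx(1.0, abs=0.15)
        assert comp.sigma2_int[comp.methods[0]] == pytest.approx(0.2, abs=0.1)
        assert comp.sigma2_resid[comp.methods[0]] == pytest.approx(1.0, abs=0.08)
        assert comp.sigma2_resid[comp.methods[1]] == pytest.approx(0.5, abs=0.05)

    def test_requires_two_methods_and_subjects(self):
        with pytest.raises(InputError):
            fit_two_way_mixed(np.zeros((10, 1, 3)))
        with pytest.raises(InputError):
            fit_two_way_mixed(np.zeros((1, 2, 3)))

    def test_icc_invariance_and_offset_direction(self):
        rng = np.random.default_rng(3)
        cube = simulate_cube(rng, 600)
        base = icc_absolute(fit_two_way_mixed(cube)).value
        scaled = icc_absolute(fit_two_way_mixed(cube * 3.0)).value
        assert scaled == pytest.approx(base, rel=1e-4)
        offset = cube.copy()
        offset[:, 1, :] += 1.0
        assert icc_absolute(fit_two_way_mixed(offset)).value < base

    def test_bootstrap_ci_is_seed_deterministic(self):
        rng = np.random.default_rng(4)
        cube = simulate_cube(rng, 80)
        comp = fit_two_way_mixed(cube)
        a = icc_absolute(comp, data=cube, n_boot=20, seed=7)
        b = icc_absolute(comp, data=cube, n_boot=20, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert a.ci_low < a.value < a.ci_high


class TestBlandAltman:
    def test_identical_pairs(self):
        x = np.array([1.0, 2.0, 3.0])
        ba = bland_altman_log(x, x)
        assert ba.pct_difference == pytest.approx(0.0, abs=1e-12)
        assert ba.loa_lower == pytest.approx(0.0, abs=1e-12)
        assert ba.loa_upper == pytest.approx(0.0, abs=1e-12)

    def test_constant_ratio(self):
        y = np.array([1.0, 2.5, 7.0, 11.0])
        ba = bland_altman_log(1.1 * y, y)
        for v in (ba.pct_difference, ba.loa_lower, ba.loa_upper):
            assert v == pytest.approx(10.0, rel=1e-9)

    def test_hand_oracle_limits(self):
        # two pairs constructed to have sample mean ln(1.1) and sample sd 0.2
        m, s = math.log(1.1), 0.2
        d = np.array([m - s / math.sqrt(2), m + s / math.sqrt(2)])
        ba = bland_altman_log(np.exp(d), np.ones(2))
        assert ba.loa_lower == pytest.approx((math.exp(m - 1.959963984540054 * s) - 1) * 100, rel=1e-9)
        assert ba.loa_upper == pytest.approx((math.exp(m + 1.959963984540054 * s) - 1) * 100, rel=1e-9)
        assert ba.loa_lower == pytest.approx(-25.7, abs=0.05)
        assert ba.loa_upper == pytest.approx(62.8, abs=0.05)

    def test_input_validation(self):
        with pytest.raises(InputError):
            bland_altman_log([1.0], [1.0])
        with pytest.raises(InputError):
            bland_altman_log([1.0, -2.0], [1.0, 2.0])

    @given(
        st.lists(st.floats(0.1, 100.0), min_size=3, max_size=12),
        st.lists(st.floats(0.1, 100.0), min_size=3, max_size=12),
    )
    def test_antisymmetry_under_method_swap(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n]), np.array(ys[:n])
        fwd = bland_altman_log(x, y)
        rev = bland_altman_log(y, x)
        swap = lambda p: (1.0 / (1.0 + p / 100.0) - 1.0) * 100.0
        assert rev.pct_difference == pytest.approx(swap(fwd.pct_difference), rel=1e-9, abs=1e-9)
        assert rev.loa_lower == pytest.approx(swap(fwd.loa_upper), rel=1e-9, abs=1e-9)
        assert rev.loa_upper == pytest.approx(swap(fwd.loa_lower), rel=1e-9, abs=1e-9)
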