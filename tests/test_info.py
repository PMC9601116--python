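"""Information measures: Gaussian MI, transfer entropy, influence, crossovers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from politeia import (
    Architecture,
    QualiaParams,
    TransferEntropyPair,
    crossover_scan,
    finite_time_lag_covariance,
    gaussian_conditional_mutual_information,
    gaussian_mutual_information,
    influence,
    influence_analytic,
    influence_small_limit,
    params_from_asymmetries,
    transfer_entropy_analytic,
    transfer_entropy_empirical,
    transfer_entropy_pair_analytic,
)
from politeia.synthetic import gen_coupled_ou


class TestGaussianMI:
    def test_independent_blocks_have_zero_mi(self):
        cov = np.diag([1.0, 2.0, 3.0])
        assert gaussian_mutual_information(cov, [0], [1, 2]) == 0.0

    def test_bivariate_correlation_half(self):
        cov = np.array([[1.0, 0.5], [0.5, 1.0]])
        expected = -0.5 * math.log2(1 - 0.25)
        assert gaussian_mutual_information(cov, [0], [1]) == pytest.approx(expected)

    def test_symmetry_in_arguments(self, rng):
        m = rng.standard_normal((4, 4))
        cov = m @ m.T + 0.5 * np.eye(4)
        ab = gaussian_mutual_information(cov, [0, 1], [2, 3])
        ba = gaussian_mutual_information(cov, [2, 3], [0, 1])
        assert ab == pytest.approx(ba, rel=1e-10)

    def test_overlapping_index_sets_rejected(self):
        with pytest.raises(ValueError):
            gaussian_mutual_information(np.eye(3), [0, 1], [1, 2])

    def test_perfectly_redundant_variables_give_infinite_mi(self):
        cov = np.array([[1.0, 1.0], [1.0, 1.0]])
        assert gaussian_mutual_information(cov, [0], [1]) == math.inf

    def test_scale_invariance(self, rng):
        m = rng.standard_normal((3, 3))
        cov = m @ m.T + 0.5 * np.eye(3)
        d = np.diag([5.0, 0.2, 11.0])
        scaled = d @ cov @ d
        assert gaussian_mutual_information(cov, [0], [1, 2]) == pytest.approx(
            gaussian_mutual_information(scaled, [0], [1, 2]), rel=1e-9
        )


class TestTransferEntropyAnalytic:
    def test_symmetric_model_has_equal_flows(self, symmetric_params):
        arch = Architecture(3, 0.5)
        t21 = transfer_entropy_analytic(symmetric_params, arch, "2to1")
        t12 = transfer_entropy_analytic(symmetric_params, arch, "1to2")
        assert t21 == pytest.approx(t12, rel=1e-9)
        assert influence_analytic(symmetric_params, arch) == pytest.approx(0.0, abs=1e-9)

    def test_non_negativity_over_parameter_grid(self):
        for a in np.linspace(-0.8, 0.8, 5):
            for b in np.linspace(-0.8, 0.8, 5):
                p = params_from_asymmetries(a, b)
                for n in (1, 4):
                    for dt in (0.01, 1.0, 100.0):
                        pair = transfer_entropy_pair_analytic(p, Architecture(n, dt))
                        assert pair.te_1to2 >= 0 and pair.te_2to1 >= 0
                        assert np.isfinite(pair.te_1to2) and np.isfinite(pair.te_2to1)

    def test_matches_mi_difference_at_large_age(self, asym_params):
        """The conditional form equals the difference of two MIs (finite-age oracle)."""
        arch = Architecture(3, 0.7)
        n = arch.n
        own = list(range(1, n + 1))
        other = list(range(n + 1, 2 * n + 1))

        def te_eq2(age):
            raw = finite_time_lag_covariance(asym_params, arch, age=age)
            mi_both = gaussian_mutual_information(raw.matrix, [0], own + other)
            mi_own = gaussian_mutual_information(raw.matrix, [0], own)
            return mi_both - mi_own

        te = transfer_entropy_analytic(asym_params, arch, "2to1")
        young, old = te_eq2(300.0), te_eq2(3000.0)
        assert abs(te - old) < abs(te - young)  # converges with age
        assert te == pytest.approx(old, rel=1e-4)

    def test_degenerate_process_rejected_upstream(self):
        # a process with zero coupling and zero noise is frozen
        with pytest.raises(ValueError):
            QualiaParams(alpha1=1.0, alpha2=0.0, beta1=1.0, beta2=0.0)
        with pytest.raises(ValueError):
            QualiaParams(alpha1=1.0, alpha2=1.0, beta1=0.0, beta2=0.0)


class TestInfluence:
    def test_equal_flows_give_zero(self):
        v = influence(TransferEntropyPair(te_1to2=0.3, te_2to1=0.3))
        assert v.value == 0.0

    def test_one_sided_flow_saturates(self):
        assert influence(TransferEntropyPair(0.2, 0.0)).value == 1.0
        assert influence(TransferEntropyPair(0.0, 0.2)).value == -1.0

    def test_both_vanishing_defined_as_zero(self):
        assert influence(TransferEntropyPair(0.0, 0.0)).value == 0.0
        assert influence(TransferEntropyPair(1e-15, 0.0)).value == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(a=st.floats(-0.8, 0.8), b=st.floats(-0.8, 0.8),
           n=st.integers(1, 4), dt=st.floats(0.05, 20.0))
    def test_antisymmetric_under_label_swap(self, a, b, n, dt):
        p = params_from_asymmetries(a, b)
        arch = Architecture(n, dt)
        v = influence_analytic(p, arch)
        w = influence_analytic(p.swapped(), arch)
        assert abs(v) <= 1.0 + 1e-12
        assert v == pytest.approx(-w, abs=1e-9)


class TestSmallLimit:
    def test_symmetric_expansion_vanishes(self):
        for dt in (1e-3, 0.1, 1.0):
            assert influence_small_limit(0.01, 0.01, dt) == pytest.approx(
                -0.01 * 2 * dt / 4
            )
        assert influence_small_limit(0.0, 0.0, 0.5) == 0.0

    def test_expansion_root_matches_exact_influence_root(self):
        # a+b = 0.02 with b-a = 2e-4: expansion root 8(b-a)/(a+b) = 0.08
        s, d = 0.02, 2e-4
        a, b = (s - d) / 2, (s + d) / 2
        root_expected = 8 * d / s
        p = params_from_asymmetries(a, b)
        roots = crossover_scan(p, 1, np.logspace(-3, 1, 60))
        assert roots.size == 1
        assert roots[0] == pytest.approx(root_expected, rel=0.02)

    def test_slope_matches_finite_difference_of_exact_influence(self):
        a = b = 5e-4
        p = params_from_asymmetries(a, b)
        dt = 1e-3
        f1 = influence_analytic(p, Architecture(1, dt))
        f2 = influence_analytic(p, Architecture(1, 2 * dt))
        exact_slope = (f2 - f1) / dt
        expansion_slope = (
            influence_small_limit(a, b, 2 * dt) - influence_small_limit(a, b, dt)
        ) / dt
        assert exact_slope == pytest.approx(expansion_slope, rel=1e-3)
        assert exact_slope / (a + b) == pytest.approx(-0.25, rel=1e-3)

    def test_error_is_higher_order_in_the_asymmetry(self):
        """|exact - expansion| shrinks with log-log slope >= 3 along the regime path."""
        errs = []
        eps_list = [0.2, 0.1, 0.05, 0.025]
        for eps in eps_list:
            s, d, dt = eps, eps**2, eps**2
            a, b = (s - d) / 2, (s + d) / 2
            p = params_from_asymmetries(a, b)
            full = influence_analytic(p, Architecture(1, dt))
            errs.append(abs(full - influence_small_limit(a, b, dt)))
        slope = np.polyfit(np.log(eps_list), np.log(errs), 1)[0]
        assert slope >= 3.0


class TestEmpiricalEstimator:
    def test_matches_analytic_on_long_series(self):
        p = params_from_asymmetries(0.3, -0.2)
        x1, x2 = gen_coupled_ou(p, dt=1.0, n_points=100_000, seed=5)
        emp = transfer_entropy_empirical(x1, x2, n=2)
        ana = transfer_entropy_pair_analytic(p, Architecture(2, 1.0))
        assert emp.te_1to2 == pytest.approx(ana.te_1to2, abs=0.004)
        assert emp.te_2to1 == pytest.approx(ana.te_2to1, abs=0.004)

    def test_error_shrinks_with_series_length(self):
        p = params_from_asymmetries(0.3, -0.2)
        ana = transfer_entropy_pair_analytic(p, Architecture(2, 1.0))

        def err(n_pts, seed):
            x1, x2 = gen_coupled_ou(p, dt=1.0, n_points=n_pts, seed=seed)
            e = transfer_entropy_empirical(x1, x2, n=2)
            return abs(e.te_1to2 - ana.te_1to2) + abs(e.te_2to1 - ana.te_2to1)

        short = np.mean([err(20_000, s) for s in (1, 2, 3)])
        long = np.mean([err(80_000, s) for s in (4, 5, 6)])
        assert long < short

    def test_affine_invariance(self):
        p = params_from_asymmetries(0.2, 0.1)
        x1, x2 = gen_coupled_ou(p, dt=1.0, n_points=5_000, seed=8)
        base = transfer_entropy_empirical(x1, x2, n=3)
        moved = transfer_entropy_empirical(5.0 * x1 + 7.0, -2.0 * x2 + 1.0, n=3)
        assert moved.te_1to2 == pytest.approx(base.te_1to2, rel=1e-7)
        assert moved.te_2to1 == pytest.approx(base.te_2to1, rel=1e-7)

    def test_constant_series_rejected_with_block_name(self):
        x1 = np.random.default_rng(0).standard_normal(500)
        x2 = np.ones(500)
        with pytest.raises(ValueError, match="rank-deficient"):
            transfer_entropy_empirical(x1, x2, n=2)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            transfer_entropy_empirical(np.arange(20.0), np.arange(20.0), n=5)


class TestCrossoverScan:
    def test_single_signed_slices_have_no_crossing(self):
        dts = np.logspace(-3, 3, 60)
        for a in (-0.1, 0.5):
            p = params_from_asymmetries(a, 0.03)
            assert crossover_scan(p, 4, dts).size == 0

    def test_crossing_inside_band_is_found_and_refined(self):
        # stochastic asymmetry slightly above the deterministic one
        p = params_from_asymmetries(0.01, 0.03)
        dts = np.logspace(-3, 3, 60)
        roots = crossover_scan(p, 4, dts)
        assert roots.size == 1
        # bisection refinement: influence changes sign within +/-0.1% of the root
        lo = influence_analytic(p, Architecture(4, roots[0] * 0.999))
        hi = influence_analytic(p, Architecture(4, roots[0] * 1.001))
        assert lo * hi < 0

    def test_crossing_band_is_contiguous_in_a(self):
        dts = np.logspace(-3, 3, 30)
        has_crossing = []
        for a in np.arange(-0.02, 0.051, 0.005):
            p = params_from_asymmetries(float(a), 0.03)
            has_crossing.append(crossover_scan(p, 4, dts).size > 0)
        arr = np.array(has_crossing)
        idx = np.nonzero(arr)[0]
        assert idx.size > 0
        assert np.all(np.diff(idx) == 1)  # a contiguous band of crossing a values

    def test_fixed_window_direction_depends_on_discretisation(self):
        # same look-back window T = 1, different memory partitions
        p = params_from_asymmetries(0.7, 0.75)
        coarse = influence_analytic(p, Architecture(1, 1.0))
        fine = influence_analytic(p, Architecture(8, 1.0 / 8.0))
        assert coarse * fine < 0


def test_cmi_chain_consistency(rng):
    """I(A;B,C) = I(A;B) + I(A;C|B) on a random Gaussian."""
    m = rng.standard_normal((4, 4))
    cov = m @ m.T + 0.5 * np.eye(4)
    lhs = gaussian_mutual_information(cov, [0], [1, 2, 3])
    rhs = gaussian_mutual_information(cov, [0], [1]) + \
        gaussian_conditional_mutual_information(cov, [0], [2, 3], [1])
    assert lhs == pytest.approx(rhs, rel=1e-9)
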