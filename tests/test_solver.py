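"""Unit and property tests for the finite-volume density solver."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from popcolumn.solver import (
    ConfigurationError,
    DensityState,
    SolverError,
    build_grid,
    gaussian_init,
    leak_operator,
    step_density,
    synaptic_operator,
)


# ---------------------------------------------------------------------------
# grid
# ---------------------------------------------------------------------------

class TestGrid:
    def test_uniform_grid_geometry(self):
        g = build_grid(-5, 15, 200)
        assert g.n_bins == 200
        assert np.allclose(g.widths, 0.1)
        assert g.edges[0] == -5 and g.edges[-1] == 15
        # reset potential 0 lies inside the bin at reset_index
        assert g.edges[g.reset_index] <= 0 < g.edges[g.reset_index + 1]

    def test_reset_on_shared_edge_goes_to_upper_bin(self):
        # 0 is exactly the middle edge: half-open convention puts it above
        g = build_grid(-1, 1, 2)
        assert np.allclose(g.widths, [1.0, 1.0])
        assert g.reset_index == 1

    def test_widths_sum_to_domain_length(self):
        g = build_grid(-5, 15, 400)
        assert np.allclose(g.widths, 0.05)
        assert np.isclose(g.widths.sum(), 20.0)

    @pytest.mark.parametrize("bad", [(5, 15, 100), (-5, -1, 100), (0, 15, 100)])
    def test_non_monotone_or_nonneg_bounds_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            build_grid(*bad)

    def test_jump_exceeding_domain_rejected(self):
        g = build_grid(-1, 1, 20)
        with pytest.raises(ConfigurationError):
            synaptic_operator(g, 2.5)


# ---------------------------------------------------------------------------
# gaussian initialization
# ---------------------------------------------------------------------------

class TestGaussianInit:
    def test_normalized_and_peaked_at_reset(self):
        g = build_grid(-5, 15, 200)
        s = gaussian_init(g, 0.0, 5.0)
        assert np.isclose(s.total(), 1.0, atol=1e-12)
        assert abs(int(np.argmax(s.mass)) - g.reset_index) <= 1

    def test_delta_limit_concentrates_in_reset_bin(self):
        g = build_grid(-5, 15, 200)
        s = gaussian_init(g, 0.0, 1e-6)
        assert s.mass[g.reset_index] > 1.0 - 1e-12

    def test_asymmetric_domain_mass_split(self):
        # oracle: direct numerical integration of the Gaussian over each bin
        from scipy.stats import norm

        g = build_grid(-5, 15, 200)
        s = gaussian_init(g, 0.0, 5.0)
        above = s.mass[g.edges[:-1] >= 0].sum()
        below = s.mass[g.edges[1:] <= 0].sum()
        assert above > below
        expected = np.diff(norm.cdf(g.edges, 0.0, 5.0))
        expected /= expected.sum()
        assert np.allclose(s.mass, expected, atol=1e-12)

    def test_nonpositive_sd_rejected(self):
        g = build_grid(-5, 15, 200)
        with pytest.raises(ValueError):
            gaussian_init(g, 0.0, 0.0)


# ---------------------------------------------------------------------------
# flux operators
# ---------------------------------------------------------------------------

class TestOperators:
    def test_columns_conserve_mass(self):
        g = build_grid(-5, 15, 200)
        for op in (
            leak_operator(g, 10.0),
            synaptic_operator(g, 0.1756),
            synaptic_operator(g, -0.7024),
            synaptic_operator(g, 1.4996),
        ):
            cols = np.asarray(op.matrix.sum(axis=0)).ravel()
            assert np.max(np.abs(cols)) < 1e-12
            off = op.matrix.tocoo()
            mask = off.row != off.col
            if mask.any():
                assert off.data[mask].min() >= 0

    def test_leak_fixed_point_is_reset_bin(self):
        g = build_grid(-5, 15, 100)
        L = leak_operator(g, 10.0)
        state = gaussian_init(g, 3.0, 4.0)
        for _ in range(400):  # 200 ms of pure leak
            state, lam = step_density(state, L, [], 0.5)
        assert lam == 0.0
        assert state.mass[g.reset_index] > 0.999

    def test_leak_matches_exponential_decay(self):
        # closed-form LIF decay: mean voltage 10 exp(-t/10 ms)
        g = build_grid(-5, 15, 200)
        L = leak_operator(g, 10.0)
        mass = np.zeros(g.n_bins)
        start = int(np.searchsorted(g.edges, 10.0)) - 1
        mass[start] = 1.0
        state = DensityState(mass=mass)
        v0 = g.centers[start]
        for k in range(100):
            state, _ = step_density(state, L, [], 0.1)
        mean_v = float(state.mass @ g.centers)
        assert abs(mean_v - v0 * np.exp(-1.0)) <= g.widths[0]

    def test_integer_shift_moves_mass_exactly(self):
        g = build_grid(-5, 15, 200)
        op = synaptic_operator(g, 0.5)  # exactly 5 bins
        j = 50
        col = op.matrix[:, j].toarray().ravel()
        assert col[j] == -1.0 and col[j + 5] == 1.0
        assert np.count_nonzero(col) == 2

    def test_fractional_shift_splits_and_preserves_mean_jump(self):
        g = build_grid(-5, 15, 200)
        op = synaptic_operator(g, 0.15)  # 1.5 bins
        j = 50
        col = op.matrix[:, j].toarray().ravel()
        assert np.isclose(col[j + 1], 0.5) and np.isclose(col[j + 2], 0.5)
        # mean displacement over destinations = exactly the weight
        dest = col.copy()
        dest[j] += 1.0
        assert np.isclose(dest @ g.centers - g.centers[j], 0.15)

    def test_threshold_boundary_reinjects_at_reset(self):
        # all mass within one jump of threshold: one event's flux fires it all
        g = build_grid(-5, 15, 200)
        op = synaptic_operator(g, 1.0)
        near = g.n_bins - 5  # within 1 mV of threshold
        col = op.matrix[:, near].toarray().ravel()
        assert np.isclose(col[g.reset_index], 1.0)
        assert np.isclose(op.firing_row[near], 1.0)

    def test_inhibitory_wall_accumulates_in_lowest_bin(self):
        g = build_grid(-1, 1, 20)
        op = synaptic_operator(g, -0.55)
        # displacement from bin 2 would land below v_min: clamped to bin 0
        col = op.matrix[:, 2].toarray().ravel()
        assert np.isclose(col[0], 1.0)
        assert np.isclose(col[2], -1.0)
        assert np.isclose(col.sum(), 0.0, atol=1e-12)

    def test_zero_weight_rejected(self):
        g = build_grid(-5, 15, 200)
        with pytest.raises(ValueError):
            synaptic_operator(g, 0.0)


# ---------------------------------------------------------------------------
# time stepping
# ---------------------------------------------------------------------------

class TestStepDensity:
    def test_absorbing_state_with_zero_rates(self):
        g = build_grid(-5, 15, 200)
        L = leak_operator(g, 10.0)
        S = synaptic_operator(g, 0.5)
        mass = np.zeros(g.n_bins)
        mass[g.reset_index] = 1.0
        state = DensityState(mass=mass)
        new, lam = step_density(state, L, [(S, 0.0)], 0.1)
        assert lam == 0.0
        assert np.allclose(new.mass, mass)

    def test_taylor_matches_dense_expm(self):
        g = build_grid(-5, 15, 200)
        L = leak_operator(g, 10.0)
        ops = [
            (synaptic_operator(g, 0.1756), 12000.0),
            (synaptic_operator(g, -0.7024), 4000.0),
            (synaptic_operator(g, 1.4996), 1800.0),
        ]
        s_a = gaussian_init(g, 0, 5)
        s_b = gaussian_init(g, 0, 5)
        for _ in range(10):
            s_a, r_a = step_density(s_a, L, ops, 0.1, method="taylor")
            s_b, r_b = step_density(s_b, L, ops, 0.1, method="expm")
        assert np.max(np.abs(s_a.mass - s_b.mass)) < 1e-6
        assert abs(r_a - r_b) < 1e-6

    def test_negative_rate_rejected(self):
        g = build_grid(-5, 15, 200)
        L = leak_operator(g, 10.0)
        S = synaptic_operator(g, 0.5)
        with pytest.raises(ValueError):
            step_density(gaussian_init(g, 0, 5), L, [(S, -1.0)], 0.1)

    def test_mass_conserved_over_ten_thousand_steps(self):
        """Continuity-equation contract: total mass drift < 1e-10 over 1e4
        steps, with no bin dipping below -1e-12, under mixed drive."""
        g = build_grid(-5, 15, 200)
        L = leak_operator(g, 10.0)
        ops = [
            (synaptic_operator(g, 0.1756), 9000.0),
            (synaptic_operator(g, -0.7024), 3000.0),
        ]
        state = gaussian_init(g, 0, 5)
        for _ in range(10_000):
            state, _ = step_density(state, L, ops, 0.1)
        assert abs(state.total() - 1.0) < 1e-10
        assert state.mass.min() > -1e-12

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(
        weight=st.floats(-2.0, 2.0).filter(lambda w: abs(w) > 0.05),
        rate=st.floats(0.0, 20000.0),
        mean=st.floats(-3.0, 10.0),
        sd=st.floats(0.5, 6.0),
    )
    def test_conservation_and_positivity_under_arbitrary_drive(
        self, weight, rate, mean, sd
    ):
        g = build_grid(-5, 15, 100)
        L = leak_operator(g, 10.0)
        S = synaptic_operator(g, weight)
        state = gaussian_init(g, mean, sd)
        for _ in range(20):
            state, lam = step_density(state, L, [(S, rate)], 0.1)
            assert lam >= 0.0
        assert abs(state.total() - 1.0) < 1e-10
        assert state.mass.min() > -1e-12

    def test_halving_dt_changes_steady_rate_below_one_percent(self):
        g = build_grid(-5, 15, 100)
        L = leak_operator(g, 10.0)
        S = synaptic_operator(g, 1.4996)
        rates = {}
        for dt in (0.1, 0.05):
            state = gaussian_init(g, 0, 5)
            out = []
            for _ in range(int(250 / dt)):
                state, lam = step_density(state, L, [(S, 1500.0)], dt)
                out.append(lam)
            rates[dt] = np.mean(out[-int(50 / dt):])
        assert abs(rates[0.05] - rates[0.1]) / rates[0.1] < 0.01

    def test_grid_refinement_first_order_convergence(self):
        """Steady output rates at n and 2n bins differ by O(1/n)."""
        def steady(n_bins):
            g = build_grid(-5, 15, n_bins)
            L = leak_operator(g, 10.0)
            S = synaptic_operator(g, 1.4996)
            state = gaussian_init(g, 0, 5)
            out = []
            for _ in range(2500):
                state, lam = step_density(state, L, [(S, 1500.0)], 0.1)
                out.append(lam)
            return np.mean(out[-500:])

        r100, r200, r400 = steady(100), steady(200), steady(400)
        d1, d2 = abs(r200 - r100), abs(r400 - r200)
        assert d2 < d1  # successive differences shrink
        assert d1 / r200 < 0.05
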