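import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from grnfvm import (
    TruncatedGrid,
    burst_coefficients,
    cell_average,
    compute_cell_averages,
    degradation_face_rates,
    eval_regulation,
)
from tests.conftest import make_constant_model


def coeffs(h=1.0, b=1.0, N=10):
    grid = TruncatedGrid([N], [N * h])
    model = make_constant_model(b=b, L=N * h)
    return burst_coefficients(grid, model, 0)


class TestBurstCoefficients:
    def test_self_coefficient_closed_form(self):
        # (2/h) * (integral of omega over half a cell minus the Dirac mass)
        c = coeffs(h=1.0, b=1.0)
        assert c.self_coef == pytest.approx(-2 * np.exp(-0.5), rel=1e-14)
        assert c.self_coef == pytest.approx(-1.21306, abs=5e-6)

    def test_first_offset_closed_form(self):
        c = coeffs(h=1.0, b=1.0)
        assert c.beta_bar[0] == pytest.approx(np.exp(-0.5) - np.exp(-1.5), rel=1e-14)
        assert c.beta_bar[0] == pytest.approx(0.38340, abs=5e-6)

    def test_boundary_tail_closes_the_column(self):
        # tail at offset 1 is e^{-1/2}; the source one below the boundary
        # balances exactly: (h/2)(-2 e^{-1/2}) + h e^{-1/2} = 0
        c = coeffs(h=1.0, b=1.0)
        assert c.tail[0] == pytest.approx(np.exp(-0.5), rel=1e-14)
        assert 0.5 * c.self_coef + c.tail[0] == pytest.approx(0.0, abs=1e-15)

    @settings(derandomize=True, max_examples=40)
    @given(
        h=st.floats(min_value=0.01, max_value=10.0),
        b=st.floats(min_value=0.05, max_value=50.0),
    )
    def test_geometric_ratio(self, h, b):
        """Consecutive interior coefficients decay by exactly exp(-h/b)."""
        assume(h / b < 25.0)  # beyond that the far coefficients underflow
        c = coeffs(h=h, b=b, N=8)
        ratios = c.beta_bar[1:] / c.beta_bar[:-1]
        assert ratios == pytest.approx(np.full(ratios.size, np.exp(-h / b)), rel=1e-10)

    @settings(derandomize=True, max_examples=40)
    @given(
        h=st.floats(min_value=0.05, max_value=5.0),
        b=st.floats(min_value=0.1, max_value=30.0),
        N=st.integers(min_value=2, max_value=30),
    )
    def test_every_source_column_conserves(self, h, b, N):
        c = coeffs(h=h, b=b, N=N)
        for j in range(1, N + 1):
            assert c.column_sum(j) == pytest.approx(0.0, abs=1e-13)

    def test_matches_direct_per_pair_integrals(self):
        """Translation invariance: stored offsets equal the per-pair definition."""
        from scipy.integrate import quad

        h, b, N = 0.7, 2.3, 6
        c = coeffs(h=h, b=b, N=N)
        omega = lambda u: np.exp(-u / b) / b
        for i in range(2, N):  # receiver (1-based), interior
            for j in range(1, i):  # source
                xi = (i - 0.5) * h
                val, _ = quad(lambda y: omega(xi - y), (j - 1) * h, j * h)
                assert c.beta_bar[i - j - 1] == pytest.approx(val / h, rel=1e-9)


class TestCellAverage:
    def test_constant_field_exact(self):
        grid = TruncatedGrid([4], [2.0])
        f = lambda x: np.full(x.shape[:-1], 4e-4)
        assert cell_average(grid, f, [2], order=1) == 4e-4
        for order in (3, 5):
            assert cell_average(grid, f, [2], order=order) == pytest.approx(4e-4, rel=1e-14)

    def test_linear_field_exact_at_order_two(self):
        grid = TruncatedGrid([2], [2.0])
        f = lambda x: x[..., 0]
        assert cell_average(grid, f, [1], order=2) == pytest.approx(0.5, rel=1e-14)

    def test_hill_average_matches_riemann_oracle(self):
        """Order-5 Gauss average of a steep Hill function vs brute force."""
        hill = lambda x: 1.0 - 0.85 / (1.0 + (45.0 / np.maximum(x[..., 0], 1e-300)) ** 4)
        # a unit cell straddling the threshold: shift the field to [44.5, 45.5]
        grid = TruncatedGrid([1], [1.0])
        g = lambda x: hill(x + 44.5)
        val = cell_average(grid, g, [1], order=5)
        xs = 44.5 + (np.arange(10_000) + 0.5) / 10_000
        oracle = hill(xs[:, None]).mean()
        assert val == pytest.approx(oracle, abs=1e-6)

    def test_bulk_averages_match_per_cell(self):
        from grnfvm import load_example

        cfg = load_example("example5", N=[5, 4])
        av = compute_cell_averages(cfg.grid, cfg.model, order=3)
        k = cfg.grid.flat_index([3, 2])
        direct = cell_average(
            cfg.grid, lambda x: eval_regulation(cfg.model, 0, x), [3, 2], order=3
        )
        assert av.c[0][k] == pytest.approx(direct, rel=1e-12)


class TestDegradationFaceRates:
    def test_first_layer_has_no_outflow(self):
        grid = TruncatedGrid([4, 3], [4.0, 3.0])
        model = make_constant_model(n=2, L=(4.0, 3.0))
        av = compute_cell_averages(grid, model)
        for dim in range(2):
            out, _ = degradation_face_rates(grid, av, dim)
            nd = out.reshape(grid.N)
            first = [slice(None)] * 2
            first[dim] = 0
            assert np.all(nd[tuple(first)] == 0.0)

    def test_unit_gamma_outflow_is_lower_face(self):
        grid = TruncatedGrid([3], [3.0])  # h = 1
        model = make_constant_model()
        av = compute_cell_averages(grid, model)
        out, _ = degradation_face_rates(grid, av, 0)
        assert out == pytest.approx([0.0, 1.0, 2.0])

    def test_flux_pairing(self):
        """Inflow credited to a cell equals its upper neighbour's outflow."""
        from grnfvm import load_example

        cfg = load_example("example5", N=[6, 5])
        av = compute_cell_averages(cfg.grid, cfg.model)
        for dim in range(2):
            out, inflow = degradation_face_rates(cfg.grid, av, dim)
            out_nd = out.reshape(cfg.grid.N)
            in_nd = inflow.reshape(cfg.grid.N)
            sl_lo = [slice(None)] * 2
            sl_hi = [slice(None)] * 2
            sl_lo[dim] = slice(0, -1)
            sl_hi[dim] = slice(1, None)
            assert np.array_equal(in_nd[tuple(sl_lo)], out_nd[tuple(sl_hi)])
            last = [slice(None)] * 2
            last[dim] = -1
            assert np.all(in_nd[tuple(last)] == 0.0)
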