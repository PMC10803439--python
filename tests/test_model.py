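import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grnfvm import (
    DegradationSpec,
    GRNModel,
    RegulationSpec,
    eval_degradation,
    eval_regulation,
    load_example,
    validate_model,
)
from tests.conftest import make_constant_model


def hill_model(K=45.0, H=-4.0, eps=0.15):
    return GRNModel(
        n=1,
        km=(3.2e-3,),
        burst=(16.0,),
        regulation=(RegulationSpec("hill_univariate", regulators=(0,), K=(K,), H=(H,), eps=(eps,)),),
        degradation=(DegradationSpec("constant", rate=4e-4),),
        domain=(300.0,),
    )


class TestHillUnivariate:
    def test_half_saturation_value(self):
        """At the threshold x = K the Hill function equals (1 + eps)/2."""
        for H in (-4.0, 4.0, -2.0, 5.0):
            m = hill_model(H=H, eps=0.15)
            assert float(eval_regulation(m, 0, [45.0])) == pytest.approx((1 + 0.15) / 2, rel=1e-12)

    def test_activation_limits(self):
        """H < 0 (activation): c rises from the leakage at 0 toward 1."""
        m = hill_model(H=-4.0, eps=0.15)
        assert float(eval_regulation(m, 0, [0.0])) == pytest.approx(0.15, abs=1e-12)
        assert float(eval_regulation(m, 0, [1e6])) == pytest.approx(1.0, abs=1e-9)

    def test_repression_limits(self):
        """H > 0 (repression): c falls from 1 at zero regulator to the leakage."""
        m = hill_model(H=4.0, eps=0.15)
        assert float(eval_regulation(m, 0, [0.0])) == pytest.approx(1.0, abs=1e-12)
        assert float(eval_regulation(m, 0, [1e6])) == pytest.approx(0.15, rel=1e-6)

    @settings(derandomize=True, max_examples=60)
    @given(
        H=st.sampled_from([-6.0, -4.0, -2.0, 2.0, 4.0, 5.0]),
        eps=st.floats(min_value=0.0, max_value=0.9),
        K=st.floats(min_value=1.0, max_value=200.0),
    )
    def test_monotone_between_leakage_and_one(self, H, eps, K):
        m = hill_model(K=K, H=H, eps=eps)
        x = np.linspace(0.0, 5 * K, 200)[:, None]
        c = eval_regulation(m, 0, x)
        assert np.all(c <= 1.0 + 1e-12) and np.all(c >= eps - 1e-12)
        diffs = np.diff(c)
        if H < 0:
            assert np.all(diffs >= -1e-12)  # activation: increasing
        else:
            assert np.all(diffs <= 1e-12)  # repression: decreasing

    def test_negative_x_rejected(self):
        with pytest.raises(ValueError):
            eval_regulation(hill_model(), 0, [-1.0])


class TestHillGeneralized:
    def test_corner_leakages(self):
        """The two-regulator form interpolates the corner leakages.

        Gene 1 of the self/mutual-regulation network is activated by
        protein 1 (H = -4) and repressed by protein 2 (H = 2), so:
        no activator + no repressor -> 0.2; full activator + full
        repressor -> 0.02; no activator + full repressor -> 0.002
        (both Hill factors saturated); full activator alone -> 1.
        """
        m = load_example("example4").model
        big, tiny = 1e9, 0.0
        c = eval_regulation(
            m, 0, [[tiny, tiny], [big, big], [tiny, big], [big, tiny]]
        )
        assert c[0] == pytest.approx(0.2, abs=1e-9)
        assert c[1] == pytest.approx(0.02, rel=1e-6)
        assert c[2] == pytest.approx(0.002, abs=1e-9)
        assert c[3] == pytest.approx(1.0, rel=1e-6)

    def test_strictly_positive_on_grid(self):
        m = load_example("example4", N=16).model
        from grnfvm import TruncatedGrid

        pts = TruncatedGrid([16, 16], m.domain).midpoint_array()
        for gene in range(2):
            assert np.all(eval_regulation(m, gene, pts) > 0)


class TestDegradation:
    def test_constant(self):
        m = make_constant_model(gamma=4e-4)
        assert float(eval_degradation(m, 0, [123.0])) == 4e-4

    def test_competence_rational_at_origin(self):
        m = load_example("example5").model
        assert eval_degradation(m, 0, [[0.0, 0.0]])[0] == pytest.approx(0.0014, rel=1e-12)

    def test_competence_rational_direct_substitution(self):
        # delta*Gk*Gs/(Gk*Gs + Gs*x1 + Gk*x2) at x=(500, 0)
        m = load_example("example5").model
        expected = 0.0014 * (500 * 50) / (500 * 50 + 50 * 500)
        got = eval_degradation(m, 0, [[500.0, 0.0]])[0]
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(7e-4, rel=1e-12)

    def test_bounded_by_delta_and_positive(self):
        m = load_example("example5").model
        x = np.random.default_rng(0).uniform(0, 1500, size=(100, 2))
        g = eval_degradation(m, 0, x)
        assert np.all(g > 0) and np.all(g <= 0.0014)


class TestValidation:
    def test_example_fixtures_are_valid(self):
        for name in ("example1", "example2", "example3", "example4", "example5"):
            assert validate_model(load_example(name).model) == []

    def test_zero_burst_size_flagged(self):
        m = make_constant_model()
        bad = GRNModel(**{**m.__dict__, "burst": (0.0,)})
        violations = validate_model(bad)
        assert len(violations) == 1 and "burst" in violations[0]

    def test_leakage_out_of_range_flagged(self):
        bad = hill_model(eps=1.5)
        violations = validate_model(bad)
        assert len(violations) == 1 and "eps" in violations[0]

    def test_zero_leakage_accepted(self):
        assert validate_model(hill_model(H=5.0, eps=0.0)) == []
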