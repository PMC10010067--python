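"""Activating function, passive-current proxy, weights, exponential fits."""

import numpy as np
import pytest

from rgcstim import cable, field, morphology, predictors as P
from rgcstim.field import PulseWaveform


def uniform_fiber(n=400, dx=5.0, diameter=1.0, depth=-15.0):
    """Straight horizontal axon used as the uniform-cable reference."""
    x = (np.arange(n) + 0.5) * dx
    m = morphology.Morphology(
        x=x, y=np.zeros(n), z=np.full(n, depth),
        length=np.full(n, dx), d_prox=np.full(n, diameter),
        d_dist=np.full(n, diameter),
        region=np.array(["soma"] + ["axon"] * (n - 1), dtype=object),
        parent=np.arange(-1, n - 1), arc=x)
    return cable.assemble(m)


class TestActivatingFunction:
    def test_exact_for_quadratic(self):
        arc = np.linspace(0, 100, 51)
        pf = P.PathField(arc, arc ** 2, np.array(["axon"] * 51), np.arange(51))
        af = P.activating_function(pf)
        np.testing.assert_allclose(af, 2.0, rtol=1e-9)

    def test_zero_for_linear(self):
        arc = np.cumsum(np.random.default_rng(0).uniform(1, 3, 40))
        pf = P.PathField(arc, 3.0 * arc - 7.0, np.array(["axon"] * 40), np.arange(40))
        np.testing.assert_allclose(P.activating_function(pf), 0.0, atol=1e-10)

    def test_matches_analytic_point_source_second_derivative(self):
        sigma, h = 1.0, 50.0
        arc = np.arange(0.0, 2000.0, 1.0)
        pts = np.column_stack([arc, np.zeros_like(arc), np.zeros_like(arc)])
        ve = field.point_source_potential(pts, (1000.0, 0.0, h), sigma)
        pf = P.PathField(arc, ve, np.array(["axon"] * len(arc)), np.arange(len(arc)))
        af = P.activating_function(pf)
        x = arc - 1000.0
        exact = 1000.0 / (2 * np.pi * sigma) * (2 * x ** 2 - h ** 2) / (x ** 2 + h ** 2) ** 2.5
        err = np.max(np.abs(af[1:-1] - exact[1:-1])) / np.max(np.abs(exact))
        assert err < 0.01

    def test_linearity_in_potential(self):
        arc = np.linspace(0, 500, 101)
        ve = np.sin(arc / 40.0)
        pf1 = P.PathField(arc, ve, np.array(["axon"] * 101), np.arange(101))
        pf2 = P.PathField(arc, 2.5 * ve, np.array(["axon"] * 101), np.arange(101))
        np.testing.assert_allclose(P.activating_function(pf2),
                                   2.5 * P.activating_function(pf1), rtol=1e-9)

    def test_lobe_structure_under_disc(self):
        """Cathodic disc over a straight axon: a positive central lobe flanked
        by negative side lobes."""
        arc = np.arange(0.0, 2000.0, 2.0)
        pts = np.column_stack([arc, np.zeros_like(arc), np.full_like(arc, -15.0)])
        ve = -field.disc_electrode_potential(pts, (1000.0, 0, 50.0), 100.0)
        pf = P.PathField(arc, ve, np.array(["axon"] * len(arc)), np.arange(len(arc)))
        af = P.activating_function(pf)[1:-1]
        center = np.argmax(af)
        assert af[center] > 0
        assert af[:center].min() < 0 and af[center:].min() < 0

    def test_too_few_points_rejected(self):
        pf = P.PathField(np.array([0.0, 1.0]), np.zeros(2),
                         np.array(["axon", "axon"]), np.arange(2))
        with pytest.raises(ValueError):
            P.activating_function(pf)


class TestPassiveCurrent:
    def test_proportional_to_af_on_uniform_cable(self):
        sys_ = uniform_fiber()
        src = field.DiscElectrode(center=(1000.0, 0, 50))
        ve = src.unit_potentials(sys_.morph.centers)
        imem = P.passive_instantaneous_current(sys_, ve, PulseWaveform(30.0))
        pf = P.path_field(sys_.morph, ve * -30.0)
        af = P.activating_function(pf)
        interior = slice(10, -10)
        corr = np.corrcoef(imem[interior], af[interior])[0, 1]
        assert corr > 0.99
        # peak |current| coincides with peak |AF|
        assert abs(np.argmax(np.abs(imem[interior])) - np.argmax(np.abs(af[interior]))) <= 1

    def test_uniform_potential_gives_no_current(self):
        sys_ = uniform_fiber(n=50)
        imem = P.passive_instantaneous_current(sys_, np.ones(50), PulseWaveform(10.0))
        np.testing.assert_allclose(imem, 0.0, atol=1e-12)

    def test_area_weighted_sum_vanishes(self):
        sys_ = uniform_fiber(n=100)
        src = field.DiscElectrode(center=(250.0, 0, 50))
        ve = src.unit_potentials(sys_.morph.centers)
        imem = P.passive_instantaneous_current(sys_, ve, PulseWaveform(20.0))
        total = np.sum(imem * sys_.area_cm2)
        scale = np.sum(np.abs(imem) * sys_.area_cm2)
        assert abs(total) < 1e-6 * scale


class TestWeights:
    def test_self_weight_is_maximum(self, default_cell):
        w = P.compartment_weights(default_cell)
        socb = default_cell.landmark("socb")
        assert w[socb] == pytest.approx(w.max()) == pytest.approx(1.0)
        assert default_cell.morph.region[np.argmax(w)] == "socb"

    def test_weights_positive_and_bounded(self, default_cell):
        w = P.compartment_weights(default_cell)
        assert np.all(w > 0) and np.all(w <= 1.0)

    def test_monotone_decay_along_the_axon(self, default_cell):
        w = P.compartment_weights(default_cell)
        axon = default_cell.morph.region_index("axon")
        wa = w[axon]
        assert np.all(np.diff(wa) < 0)


class TestWeightedAf:
    def test_top_one_compartment(self):
        af = np.array([5.0, -2.0, 1.0])
        w = np.array([0.2, 1.0, 0.5])
        assert P.weighted_af(af, w, 1) == pytest.approx(-2.0)

    def test_all_compartments_unit_weights(self):
        af = np.array([1.0, 2.0, 3.0])
        assert P.weighted_af(af, np.ones(3), 3) == pytest.approx(6.0)

    def test_n_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            P.weighted_af(np.ones(3), np.ones(3), 0)


class TestExponentialFit:
    def test_recovers_noiseless_parameters(self):
        x = np.linspace(0.05, 1.0, 30)
        y = 2.0 * 10 ** (-3.0 * x) + 0.5
        a, b, c, r2 = P.fit_threshold_distance(y, x)
        assert a == pytest.approx(2.0, rel=0.01)
        assert b == pytest.approx(-3.0, rel=0.01)
        assert c == pytest.approx(0.5, rel=0.01)
        assert r2 > 0.999

    def test_constant_data_flagged_degenerate(self):
        x = np.linspace(0.1, 1.0, 10)
        a, b, c, r2 = P.fit_threshold_distance(np.full(10, 3.3), x)
        assert r2 == pytest.approx(0.0, abs=1e-6)

    def test_noise_degrades_fit_monotonically(self):
        rng = np.random.default_rng(42)
        x = np.linspace(0.05, 1.0, 80)
        clean = 2.0 * 10 ** (-3.0 * x) + 0.5
        r2s = []
        for noise in (0.01, 0.1, 0.5):
            y = clean + rng.normal(0, noise, len(x))
            r2s.append(P.fit_threshold_distance(y, x)[3])
        assert r2s[0] > r2s[1] > r2s[2]

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            P.fit_threshold_distance([1.0, 2.0, 3.0], [0.1, 0.2, 0.3])
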