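"""Chain mechanics, the stationary distance law, and the Langevin sampler."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, optimize, stats

from eptx import (
    Conformation,
    ConfigurationError,
    EPDistanceLaw,
    InputError,
    PolymerSpec,
    chain_potential,
    contact_probability,
    ep_equilibrium,
    ep_pdf,
    sample_ep,
    simulate_chain,
)


class TestPotential:
    def test_zero_displacement(self):
        spec = PolymerSpec(N=4, k_NN=1.0, k_EP=0.5, E=1, P=4)
        conf = Conformation(np.zeros((4, 3)))
        assert chain_potential(conf, spec) == 0.0

    def test_single_unit_spring(self):
        spec = PolymerSpec(N=2, k_NN=1.0, k_EP=0.0, E=1, P=2)
        conf = Conformation(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        assert chain_potential(conf, spec) == pytest.approx(0.5)

    def test_hand_evaluated_sum(self):
        # two k_NN=2 springs stretched by 1 plus the E-P spring stretched by 2
        spec = PolymerSpec(N=3, k_NN=2.0, k_EP=1.0, E=1, P=3)
        conf = Conformation(np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]]))
        assert chain_potential(conf, spec) == pytest.approx(4.0)

    def test_dimension_mismatch(self):
        spec = PolymerSpec(N=3, k_NN=1.0, k_EP=0.0, E=1, P=3)
        with pytest.raises(InputError):
            chain_potential(Conformation(np.zeros((4, 3))), spec)

    def test_quadratic_form_equivalence(self):
        # direct spring sums equal (1/2) sum_axis r.K.r
        rng = np.random.default_rng(0)
        spec = PolymerSpec(N=7, k_NN=1.3, k_EP=0.4, E=2, P=6)
        r = rng.standard_normal((7, 3))
        K = spec.spring_matrix()
        expected = 0.5 * sum(r[:, c] @ K @ r[:, c] for c in range(3))
        assert chain_potential(Conformation(r), spec) == pytest.approx(expected)


class TestDistanceLaw:
    def test_theta_unit_effective_stiffness(self):
        spec = PolymerSpec(N=2, k_NN=1.0, k_EP=0.0, E=1, P=2)
        assert ep_equilibrium(spec).theta == pytest.approx(1.0)

    def test_theta_stiff_ep_spring_collapses(self):
        spec = PolymerSpec(N=5, k_NN=1.0, k_EP=1e12, E=1, P=5)
        assert ep_equilibrium(spec).theta < 1e-5

    def test_theta_series_parallel(self, unit_theta_spec):
        # k_eff = k_NN/d_G + k_EP = 0.25 + 0.75 = 1
        assert ep_equilibrium(unit_theta_spec).theta == pytest.approx(1.0)

    @given(
        d_g1=st.integers(1, 50), d_g2=st.integers(1, 50),
        k_ep=st.floats(0.0, 10.0), dk=st.floats(0.01, 10.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_theta_monotone(self, d_g1, d_g2, k_ep, dk):
        def theta(d_g, kep):
            return PolymerSpec.from_genomic_distance(d_g, k_EP=kep).theta

        if d_g1 < d_g2:
            assert theta(d_g1, k_ep) < theta(d_g2, k_ep)
        assert theta(d_g1, k_ep) > theta(d_g1, k_ep + dk)

    def test_pdf_zero_at_origin(self):
        assert ep_pdf(0.0, EPDistanceLaw(2.3)) == 0.0

    @pytest.mark.parametrize("theta", [0.1, 1.0, 10.0])
    def test_pdf_normalization(self, theta):
        law = EPDistanceLaw(theta)
        total, _ = integrate.quad(law.pdf, 0, 12 * theta)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_pdf_mode_at_sqrt2_theta(self):
        law = EPDistanceLaw(1.7)
        res = optimize.minimize_scalar(
            lambda d: -law.pdf(d), bounds=(0.1, 10), method="bounded",
            options={"xatol": 1e-10},
        )
        assert res.x == pytest.approx(math.sqrt(2.0) * 1.7, abs=1e-6)

    def test_negative_distance_rejected(self):
        with pytest.raises(InputError):
            ep_pdf(-0.1, EPDistanceLaw(1.0))

    def test_cdf_boundaries(self):
        law = EPDistanceLaw(1.0)
        assert law.cdf(0.0) == 0.0
        assert law.cdf(12.0) > 1 - 1e-10

    def test_cdf_at_theta_matches_quadrature(self):
        law = EPDistanceLaw(1.0)
        ref, _ = integrate.quad(law.pdf, 0, 1.0)
        assert law.cdf(1.0) == pytest.approx(ref, abs=1e-10)
        assert law.cdf(1.0) == pytest.approx(0.1988, abs=5e-4)

    def test_quantile_99(self):
        law = EPDistanceLaw(1.0)
        # equals sqrt of the chi-square(3 dof) 0.99 quantile
        assert law.quantile(0.99) == pytest.approx(
            math.sqrt(stats.chi2(3).ppf(0.99)), abs=1e-9
        )
        assert law.quantile(0.99) == pytest.approx(3.3682, abs=1e-4)

    @pytest.mark.parametrize("q", [0.01, 0.25, 0.5, 0.9, 0.999])
    def test_cdf_quantile_roundtrip(self, q):
        law = EPDistanceLaw(0.37)
        assert law.cdf(law.quantile(q)) == pytest.approx(q, abs=1e-9)

    def test_quantile_domain(self):
        with pytest.raises(InputError):
            EPDistanceLaw(1.0).quantile(1.5)


class TestSampler:
    def test_sample_mean(self):
        law = EPDistanceLaw(1.0)
        x = sample_ep(law, 100_000, seed=1)
        assert x.mean() == pytest.approx(2 * math.sqrt(2 / math.pi), abs=0.01)

    def test_sample_distribution(self):
        law = EPDistanceLaw(2.0)
        x = sample_ep(law, 10_000, seed=2)
        ks = stats.kstest(x, law.cdf).statistic
        assert ks < 0.02

    def test_sample_determinism(self):
        law = EPDistanceLaw(1.0)
        assert np.array_equal(sample_ep(law, 100, seed=7), sample_ep(law, 100, seed=7))


class TestContactProbability:
    def test_limits(self):
        law = EPDistanceLaw(1.0)
        assert contact_probability(law, 1e6) == pytest.approx(1.0)
        assert contact_probability(law, 1e-9) == pytest.approx(0.0, abs=1e-12)

    def test_at_encounter_equal_theta(self):
        assert contact_probability(EPDistanceLaw(1.0), 1.0) == pytest.approx(
            0.1988, abs=5e-4
        )

    def test_decreasing_in_genomic_distance(self):
        ps = [
            contact_probability(
                ep_equilibrium(PolymerSpec.from_genomic_distance(dg, gamma=1.0)), 0.5
            )
            for dg in (2, 4, 8, 16, 32)
        ]
        assert np.all(np.diff(ps) < 0)

    def test_small_b_powerlaw_slope(self):
        # CDF ~ sqrt(2/pi) b^3/(3 theta^3) for b << theta, theta ~ d_G^(1/2)
        d_gs = np.array([8, 16, 32, 64])
        b = ep_equilibrium(PolymerSpec.from_genomic_distance(8)).theta / 10.0
        ps = [
            contact_probability(
                ep_equilibrium(PolymerSpec.from_genomic_distance(int(dg))), b
            )
            for dg in d_gs
        ]
        slope = np.polyfit(np.log(d_gs), np.log(ps), 1)[0]
        assert slope == pytest.approx(-1.5, abs=0.05)


class TestLangevin:
    def test_noise_free_fixed_point(self):
        spec = PolymerSpec(N=5, k_NN=1.0, k_EP=0.2, E=1, P=5, D=1e-300)
        traj = simulate_chain(
            spec, dt=0.01, n_samples=10, seed=0, init="coincident", burn_in_steps=0
        )
        assert np.allclose(traj.d_s, 0.0)

    def test_seeded_determinism(self, unit_theta_spec):
        a = simulate_chain(unit_theta_spec, n_samples=50, n_replicates=3, seed=11)
        b = simulate_chain(unit_theta_spec, n_samples=50, n_replicates=3, seed=11)
        assert np.array_equal(a.d_s, b.d_s)

    def test_stability_guard(self, unit_theta_spec):
        with pytest.raises(ConfigurationError, match="lambda_max"):
            simulate_chain(unit_theta_spec, dt=1.0, n_samples=10, seed=0)

    def test_stationary_component_variance(self, unit_theta_spec):
        # per-component variance of r_E - r_P equals theta^2 = 1
        traj = simulate_chain(
            unit_theta_spec, seed=3, n_samples=100, n_replicates=200, sample_stride=80
        )
        var = traj.separations.reshape(-1, 3).var(axis=0)
        assert np.allclose(var, 1.0, rtol=0.05)

    @pytest.mark.parametrize("k_ep,d_g", [(0.0, 4), (0.3, 4), (0.75, 8)])
    def test_stationary_distance_law(self, k_ep, d_g):
        spec = PolymerSpec.from_genomic_distance(d_g, k_EP=k_ep, flank=4)
        stride = max(1, int(2.0 * spec.gamma / spec.k_eff / 0.025))
        traj = simulate_chain(
            spec, dt=0.025, seed=4, n_samples=50, n_replicates=200,
            sample_stride=stride,
        )
        ref = sample_ep(ep_equilibrium(spec), 10_000, seed=5)
        ks = stats.ks_2samp(traj.d_s_flat, ref).statistic
        assert ks < 0.03
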