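"""Analytic stationary laws, the fast/slow mixture, and modality analysis."""

import numpy as np
import pytest
from scipy import stats

from eptx import (
    LinkSpec,
    Pmf,
    PolymerSpec,
    RateSet,
    omega,
    p_fast,
    p_slow,
    p_stationary,
    phase_diagram,
    poisson_beta_pmf,
    scan_expression,
    summarize_pmf,
)
from eptx.stationary import mode_sequence


def degenerate_link(alpha=0.5, mu=3.0, beta=1.0, delta=1.0) -> LinkSpec:
    return LinkSpec(
        alpha_min=alpha, alpha_max=alpha, mu_min=mu, mu_max=mu, beta=beta,
        delta=delta,
    )


@pytest.fixture
def spec() -> PolymerSpec:
    return PolymerSpec(N=23, k_NN=1.0, k_EP=0.75, E=10, P=14, b=1.0)


class TestOmega:
    def test_worked_example(self, spec):
        link = LinkSpec(
            alpha_min=0.1, alpha_max=1.0, mu_min=0.2, mu_max=1.0, beta=0.5
        )
        mw = omega(spec, link)
        assert mw.d_s99 == pytest.approx(3.3682, abs=1e-4)
        assert mw.v_max == pytest.approx(3.3682, abs=1e-4)
        assert mw.omega == pytest.approx(0.1 / 3.3682, abs=1e-5)
        assert mw.weight_fast + mw.weight_slow == pytest.approx(1.0)

    def test_linear_in_minimum_rate(self, spec):
        link1 = LinkSpec(alpha_min=0.1, alpha_max=1, mu_min=0.2, mu_max=1, beta=0.5)
        link2 = link1.replace(alpha_min=0.2)
        assert omega(spec, link2).omega == pytest.approx(
            2 * omega(spec, link1).omega
        )

    def test_friction_scaling(self, spec):
        # theta ~ sqrt(gamma) so v_max ~ 1/sqrt(gamma): omega ~ sqrt(gamma)
        link = LinkSpec(alpha_min=0.1, alpha_max=1, mu_min=0.2, mu_max=1, beta=0.5)
        om1 = omega(spec, link).omega
        om4 = omega(spec.replace(gamma=4.0), link).omega
        assert om4 == pytest.approx(2 * om1, rel=1e-9)


class TestLimitLaws:
    def test_fast_degenerate_equals_poisson_beta(self, spec):
        link = degenerate_link()
        ref = poisson_beta_pmf(RateSet(alpha=0.5, beta=1.0, mu=3.0), 30)
        assert np.abs(p_fast(spec, link, 30).p - ref.p).max() < 1e-12

    def test_fast_contact_limit(self, spec, tv):
        link = LinkSpec(
            alpha_min=0.1, alpha_max=1.0, mu_min=1.0, mu_max=6.0, beta=0.8
        )
        tight = spec.replace(k_EP=1e12)
        ref = poisson_beta_pmf(RateSet(alpha=1.0, beta=0.8, mu=6.0), 40)
        assert tv(p_fast(tight, link, 40).p, ref.p) < 1e-4

    def test_slow_degenerate_equals_poisson_beta(self, spec):
        link = degenerate_link()
        ref = poisson_beta_pmf(RateSet(alpha=0.5, beta=1.0, mu=3.0), 30)
        assert np.abs(p_slow(spec, link, 30).p - ref.p).max() < 1e-9

    def test_slow_quadrature_refinement(self, spec, timescale_link):
        a = p_slow(spec, timescale_link, 60, n_nodes=96)
        b = p_slow(spec, timescale_link, 60, n_nodes=192)
        assert np.abs(a.p - b.p).max() < 1e-6

    def test_mixture_zero_omega_is_fast(self, spec):
        link = LinkSpec(
            alpha_min=0.0, alpha_max=1.0, mu_min=1.0, mu_max=4.0, beta=0.5
        )
        pmf, mw = p_stationary(spec, link, 50)
        assert mw.omega == 0.0
        assert np.array_equal(pmf.p, p_fast(spec, link, 50).p)

    def test_mixture_large_omega_is_slow(self, spec, timescale_link):
        # enormous encounter distance makes chromatin velocity negligible
        slow_spec = spec.replace(b=1e9)
        pmf, mw = p_stationary(slow_spec, timescale_link, 60)
        assert mw.weight_slow > 1 - 1e-6
        assert np.abs(pmf.p - p_slow(slow_spec, timescale_link, 60).p).max() < 1e-6

    @pytest.mark.parametrize("gamma,k_ep", [(0.1, 0.3), (100.0, 0.1), (5.0, 0.3)])
    def test_emitted_pmfs_proper(self, gamma, k_ep, timescale_link):
        s = PolymerSpec(N=23, k_NN=1.0, k_EP=k_ep, E=10, P=14, gamma=gamma)
        pmf, _ = p_stationary(s, timescale_link)
        assert np.all(pmf.p >= 0)
        assert 1 - 1e-6 <= pmf.p.sum() <= 1 + 1e-9


class TestSummaries:
    def test_poisson_bimodality_coefficient(self):
        # K - S^2 = 3 exactly for any Poisson, so BC = 1/3
        for lam in (1.0, 4.0, 15.0):
            pmf = Pmf(stats.poisson.pmf(np.arange(120), lam))
            s = summarize_pmf(pmf)
            assert s.bc == pytest.approx(1 / 3, abs=1e-3)

    def test_symmetric_two_point(self):
        pmf = Pmf(np.array([0.5, 0.0, 0.5]))
        s = summarize_pmf(pmf)
        assert s.skewness == pytest.approx(0.0)
        assert s.kurtosis == pytest.approx(1.0)
        assert s.bc == pytest.approx(1.0)

    def test_bimodal_poisson_mixture_peaks(self):
        x = np.arange(80)
        p = 0.5 * stats.poisson.pmf(x, 2.0) + 0.5 * stats.poisson.pmf(x, 30.0)
        s = summarize_pmf(Pmf(p))
        # brute enumeration of local maxima
        brute = [
            i for i in range(1, 79)
            if p[i] > p[i - 1] and p[i] >= p[i + 1]
        ] + ([0] if p[0] > p[1] else [])
        assert s.n_peaks == len(brute) == 2
        assert s.mode_class == "B"
        assert any(abs(loc - 29) <= 2 for loc, _, _ in s.peaks)

    def test_degenerate_distribution_flagged(self):
        s = summarize_pmf(Pmf(np.array([1.0])))
        assert s.mode_class == "degenerate"
        assert s.bc is None

    def test_plateau_collapses_left(self):
        p = np.array([0.1, 0.3, 0.3, 0.3, 0.0])
        s = summarize_pmf(Pmf(p))
        assert s.peaks == ((1, 0.3, "NOP"),)


class TestScans:
    def test_degenerate_link_flat(self, spec):
        frame = scan_expression(spec, degenerate_link(), "d_G", [2, 8, 32])
        assert frame["mean"].std() < 1e-9
        diag = phase_diagram(spec, degenerate_link(), np.array([0.01, 0.1, 1.0]))
        assert len(set(diag.classes.ravel())) == 1

    def test_mean_monotone_in_both_knobs(self):
        tpl = PolymerSpec.from_genomic_distance(10, k_EP=0.01, gamma=50.0)
        link = LinkSpec(
            alpha_min=0.06, alpha_max=2.0, mu_min=0.3, mu_max=3.0, beta=0.20,
            delta=0.1, n_h=2.0, d0=25.0,
        )
        f = scan_expression(tpl, link, "d_G", [10, 40, 160])
        assert np.all(np.diff(f["mean"]) < 0)
        assert np.all(np.diff(f["cv"]) > 0)
        g = scan_expression(tpl, link, "k_EP", [0.1, 1.0, 10.0])
        assert np.all(np.diff(g["mean"]) > 0)
        assert np.all(np.diff(g["cv"]) < 0)

    def test_mode_sequence_collapse(self):
        s_u = summarize_pmf(Pmf(stats.poisson.pmf(np.arange(40), 8.0)))
        assert mode_sequence([s_u, s_u]) == ["U:NOP"]

    def test_phase_diagram_boundaries_mark_class_changes(self, spec, timescale_link):
        diag = phase_diagram(
            spec, timescale_link, np.geomspace(0.01, 1.0, 4), d_G_grid=[2, 8]
        )
        for (i1, j1), (i2, j2) in diag.boundaries:
            assert diag.classes[i1, j1] != diag.classes[i2, j2]
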