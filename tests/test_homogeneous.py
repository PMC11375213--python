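"""Stationary record-age theory: normalisations, differential and
integral identities, reign lengths, and the large-atom special case."""

import numpy as np
import pytest
from scipy import integrate

import recordage as ra

# finite-difference steps: first derivatives tolerate 1e-4; second
# differences amplify the ~1e-12 evaluation noise of the hypergeometric
# survival tail by 1/h^2, so they use 1e-3
H1, H2 = 1e-4, 1e-3


class TestStationaryLaw:
    def test_normalisation_gg(self, realistic_hom):
        hom = realistic_hom
        total, _ = integrate.quad(
            hom.stationary_density, 1e-9, 150.0, limit=400, points=[85.0, 90.0, 95.0]
        )
        assert total + hom.point_mass() == pytest.approx(1.0, abs=1e-8)

    def test_normalisation_world_scale(self):
        # reference-calibration law frozen at 2000 with the world birth
        # rate; the age cut-off must sit where lam * S1 is below 1e-9
        # (160 here), since the huge rate amplifies any truncated tail
        law = ra.MORTALITY_TRENDS[(0, 0.09)].law_at(2000.0)
        hom = ra.HomogeneousModel(lam=1.346e8, law=law, x_max=160.0)
        total, _ = integrate.quad(
            hom.stationary_density, 100.0, 160.0, limit=500, points=[128.0, 132.0, 136.0]
        )
        assert total + hom.point_mass() == pytest.approx(1.0, abs=1e-8)

    def test_exponential_lifespans_closed_form(self, exp_hom):
        # lam = mu = 1: atom e^{-lam/mu}, continuous mass 1 - e^{-lam/mu}
        assert exp_hom.point_mass() == pytest.approx(np.exp(-1.0), rel=1e-12)
        total, _ = integrate.quad(exp_hom.stationary_density, 0, np.inf, limit=200)
        assert total == pytest.approx(1.0 - np.exp(-1.0), abs=1e-9)

    def test_second_order_ode(self, realistic_hom):
        # plug-in residual of the equilibrium ODE for h, scale-free
        hom, law, lam = realistic_hom, realistic_hom.law, realistic_hom.lam
        for x in (86.0, 90.0, 96.0):
            H = hom.stationary_density
            d1 = (H(x + H2) - H(x - H2)) / (2 * H2)
            d2 = (H(x + H2) - 2 * H(x) + H(x - H2)) / H2**2
            f, sf = law.pdf(x), float(law.sf(x))
            fp = (law.pdf(x + H1) - law.pdf(x - H1)) / (2 * H1)
            t1 = d2
            t2 = (2 * f / sf - lam * sf) * d1
            t3 = (2 * f**2 / sf**2 + fp / sf) * H(x)
            assert abs(t1 + t2 + t3) / max(abs(t1), abs(t2), abs(t3)) <= 1e-6

    def test_equilibrium_balance(self, realistic_hom):
        # h'(x) + h(x) haz(x) = int_x^inf h(y) haz(y) j_y(x) dy
        hom, law = realistic_hom, realistic_hom.law
        for x in (86.0, 90.0, 96.0):
            d1 = (hom.stationary_density(x + H1) - hom.stationary_density(x - H1)) / (2 * H1)
            t2 = hom.stationary_density(x) * law.hazard(x)
            t3, _ = integrate.quad(
                lambda y: hom.stationary_density(y) * law.hazard(y) * hom.jump_density(y, x),
                x + 1e-9,
                150.0,
                epsabs=1e-14,
                limit=300,
            )
            assert abs(d1 + t2 - t3) / max(abs(d1), abs(t2), abs(t3)) <= 1e-5

    def test_point_mass_balance(self, exp_hom):
        # outflow of the atom equals the inflow of jumps to zero
        hom = exp_hom
        rhs, _ = integrate.quad(
            lambda y: hom.stationary_density(y) * hom.law.hazard(y) * hom.jump_density(y, 1e-12),
            1e-9,
            60.0,
            limit=200,
        )
        assert hom.point_mass() * hom.lam == pytest.approx(rhs, rel=1e-8)


class TestJumpLaw:
    def test_normalisation(self, realistic_hom):
        hom, y = realistic_hom, 95.0
        integral, _ = integrate.quad(
            lambda x: hom.jump_density(y, x), 1e-9, y - 1e-12, limit=300
        )
        assert integral + hom.jump_point_mass(y) == pytest.approx(1.0, abs=1e-8)

    def test_first_order_identity(self, realistic_hom):
        # d/dx j_y(x) = j_y(x) (lam (1-F(x)) - haz(x))
        hom, law, lam = realistic_hom, realistic_hom.law, realistic_hom.lam
        y = 95.0
        for x in (86.0, 90.0):
            fd = (hom.jump_density(y, x + H1) - hom.jump_density(y, x - H1)) / (2 * H1)
            rhs = hom.jump_density(y, x) * (lam * float(law.sf(x)) - law.hazard(x))
            assert fd == pytest.approx(rhs, rel=1e-5)

    def test_large_death_age_limit_is_stationary_density(self, realistic_hom):
        hom = realistic_hom
        for x in (86.0, 90.0):
            assert hom.jump_density(140.0, x) == pytest.approx(
                float(hom.stationary_density(x)), rel=1e-10
            )

    def test_domain_error(self, realistic_hom):
        with pytest.raises(ValueError):
            realistic_hom.jump_density(90.0, 95.0)


class TestPeaksProcess:
    def test_normalisation(self, realistic_hom):
        total, _ = integrate.quad(
            realistic_hom.peaks_density, 1e-9, 150.0, limit=400, points=[88.0, 92.0, 96.0]
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_second_order_ode_for_g(self, realistic_hom):
        # g = z/f solves g'' - lam (1-F) g' + lam f g = 0
        hom, law, lam = realistic_hom, realistic_hom.law, realistic_hom.lam
        g = lambda u: hom.peaks_density(u) / law.pdf(u)
        for x in (86.0, 90.0, 96.0):
            d1 = (g(x + H2) - g(x - H2)) / (2 * H2)
            d2 = (g(x + H2) - 2 * g(x) + g(x - H2)) / H2**2
            t1, t2, t3 = d2, -lam * float(law.sf(x)) * d1, lam * law.pdf(x) * g(x)
            assert abs(t1 + t2 + t3) / max(abs(t1), abs(t2), abs(t3)) <= 1e-6

    def test_integral_equation(self, realistic_hom):
        # one-step invariance of the peaks chain, by double quadrature
        hom, law = realistic_hom, realistic_hom.law

        def transported(x):
            def inner(w):
                val, _ = integrate.quad(
                    lambda y: hom.jump_density(w, y) * law.pdf(x) / float(law.sf(y)),
                    1e-9,
                    min(x, w) - 1e-12,
                    epsabs=1e-300,
                    epsrel=1e-10,
                    limit=300,
                )
                return hom.peaks_density(w) * val

            t1, _ = integrate.quad(inner, 80.0, 110.0, epsabs=1e-300, epsrel=1e-8, limit=300)
            t2, _ = integrate.quad(
                lambda w: hom.peaks_density(w) * hom.jump_point_mass(w) * law.pdf(x),
                80.0,
                110.0,
                limit=200,
            )
            return t1 + t2

        for x in (86.0, 90.0, 96.0):
            lhs = float(hom.peaks_density(x))
            assert abs(lhs - transported(x)) / lhs <= 1e-4


class TestReignLength:
    def test_density_normalises(self, realistic_hom):
        assert realistic_hom.reign_length_cdf(60.0, w_max=60.0) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_density_normalises_with_large_atom(self, exp_hom):
        total, _ = integrate.quad(exp_hom.reign_length_density, 0.0, 80.0, limit=300)
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_denominator_identity(self, realistic_hom):
        # int f exp(-lam S1) dy = int h (1-F) dy + m  (integration by parts)
        hom, law, lam = realistic_hom, realistic_hom.law, realistic_hom.lam
        lhs, _ = integrate.quad(
            lambda y: law.pdf(y) * np.exp(-lam * hom.survival_tail(y)),
            0.0,
            150.0,
            epsabs=1e-14,
            limit=400,
            points=[88.0, 92.0],
        )
        rhs, _ = integrate.quad(
            lambda y: hom.stationary_density(y) * float(law.sf(y)),
            0.0,
            150.0,
            epsabs=1e-14,
            limit=400,
            points=[88.0, 92.0],
        )
        rhs += hom.point_mass()
        assert lhs == pytest.approx(rhs, rel=1e-8)

    def test_not_the_remaining_reign_density(self, realistic_hom):
        # the reign-length law differs from the stationary remaining-
        # reign law, whose numerator divides by the survival at the
        # current age: their means disagree by several percent here
        hom, law = realistic_hom, realistic_hom.law
        ys = np.linspace(0.1, 140.0, 8000)
        hv = hom.stationary_density(ys)
        ws = np.linspace(0.0, 50.0, 2001)
        rem = np.array([np.trapezoid(hv * law.pdf(ys + w) / law.sf(ys), ys) for w in ws])
        rem /= np.trapezoid(rem, ws)
        rem_mean = np.trapezoid(ws * rem, ws)
        assert abs(hom.expected_reign_length() - rem_mean) / rem_mean > 0.02

    def test_exponential_lifespans_against_event_driven_simulation(self, exp_hom):
        # lam = mu = 1: record process simulated directly from its jumps
        expected = exp_hom.expected_reign_length()
        pop = ra.simulate_population(
            lambda t: np.full(np.shape(t), 1.0),
            ra.LifespanLaw(a=1.0, b=0.09, gamma=0.09),
            window=(0.0, 200_000.0),
            seed=11,
        )
        traj = ra.extract_record_trajectory(pop)
        reigns = traj.reign_lengths()
        reigns = reigns[: 100_000]
        se = reigns.std() / np.sqrt(len(reigns))
        assert abs(reigns.mean() - expected) < 3 * se
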