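import numpy as np
import pytest

from minflat.params import (
    HUANG_RATES,
    MIND_CONCENTRATION,
    MINE_CONCENTRATION,
    RateParameters,
)
from minflat.stability import (
    growth_spectrum,
    max_stable_half_wavelength,
    solve_steady_state,
)

SLAB_TOTALS = (MIND_CONCENTRATION * 0.4, MINE_CONCENTRATION * 0.4)


@pytest.fixture(scope="module")
def slab_ss():
    return solve_steady_state(HUANG_RATES, "slab", 0.4, SLAB_TOTALS)


class TestSteadyState:
    def test_zero_totals_give_zero_state(self):
        ss = solve_steady_state(HUANG_RATES, "slab", 0.4, (0.0, 0.0))
        assert np.all(ss.rho == 0) and np.all(ss.sigma == 0)

    def test_residual_and_totals(self, slab_ss):
        assert slab_ss.residual < 1e-8
        d = slab_ss.disc
        mind = (slab_ss.rho[0] + slab_ss.rho[1]) @ d.volumes + (
            slab_ss.sigma[0] + slab_ss.sigma[1]
        ) @ d.mem_weight
        mine = slab_ss.rho[2] @ d.volumes + slab_ss.sigma[1] @ d.mem_weight
        assert mind == pytest.approx(SLAB_TOTALS[0], rel=1e-9)
        assert mine == pytest.approx(SLAB_TOTALS[1], rel=1e-9)

    def test_membrane_occupied_at_steady_state(self, slab_ss):
        """k_D > 0 forces some MinD onto the membrane."""
        assert np.all(slab_ss.sigma.sum(axis=0) > 0)

    def test_steady_state_is_stationary_in_detsim(self):
        """Inserting the steady-state profile into the lattice integrator
        produces a negligible time derivative."""
        from minflat.detsim import _Lattice, _advance

        from conftest import make_box_geometry

        dx = 0.05
        nz = 8
        ss = solve_steady_state(HUANG_RATES, "slab", 0.4, SLAB_TOTALS, n_points=nz)
        g = make_box_geometry((3, 3, nz), dx, membrane="slab")
        lat = _Lattice(g)
        z = lat.idx[:, 2]
        arrs = [
            ss.rho[0][z].copy(), ss.rho[1][z].copy(), ss.rho[2][z].copy(),
            np.zeros(lat.n), np.zeros(lat.n),
        ]
        arrs[3][z == 0] = ss.sigma[0, 0]
        arrs[3][z == nz - 1] = ss.sigma[0, 1]
        arrs[4][z == 0] = ss.sigma[1, 0]
        arrs[4][z == nz - 1] = ss.sigma[1, 1]
        before = [a.copy() for a in arrs]
        dt = 1e-4
        nsteps = 1000
        _advance(
            nsteps, dt, dx, *arrs, lat.nbr, 1.0 / lat.v_dyn, lat.g, lat.is_mem,
            HUANG_RATES.D_D, HUANG_RATES.D_E, HUANG_RATES.k_exchange,
            HUANG_RATES.k_D, HUANG_RATES.k_dD, HUANG_RATES.k_de, HUANG_RATES.k_E,
        )
        scale = HUANG_RATES.k_de * max(np.max(b) for b in before)
        for a, b in zip(arrs, before):
            rate = np.max(np.abs(a - b)) / (nsteps * dt)
            assert rate < 1e-6 * scale


class TestGrowthSpectrum:
    def test_short_wavelengths_strongly_damped(self, slab_ss):
        """At q -> infinity every diffusing mode is crushed by -D q^2; the
        immobile membrane species keep finite but negative relaxation rates,
        so the system is stable."""
        from minflat.stability import _jacobian

        ev = np.sort(np.linalg.eigvals(_jacobian(slab_ss, np.pi / 0.02)).real)
        n_cyto = 3 * len(slab_ss.disc.volumes)
        assert np.all(ev[:n_cyto] < -1e3)   # -D q^2 asymptotics
        assert ev[-1] < 0                   # membrane modes relax too

    def test_all_rates_zero_gives_pure_diffusion_spectrum(self):
        p = RateParameters(k_exchange=0, k_D=0, k_dD=0, k_de=0, k_E=0)
        ss = solve_steady_state(p, "slab", 0.4, SLAB_TOTALS, well_mixed=True)
        q = np.pi / 1.7
        from minflat.stability import _jacobian

        ev = np.sort(np.linalg.eigvals(_jacobian(ss, q)).real)
        # three diffusing species at -D q^2, four immobile membrane fields
        # (two per face) at zero
        expect = np.sort([-2.5 * q * q] * 3 + [0.0] * 4)
        assert np.allclose(ev, expect, atol=1e-8)

    def test_stable_flags_match_sign(self, slab_ss):
        disp = growth_spectrum(slab_ss, HUANG_RATES, [1.0, 3.0])
        assert disp.stable[0] and not disp.stable[1]

    def test_eigenvalue_matches_measured_perturbation_growth(self):
        """Cross-check against the lattice integrator: seed a small harmonic
        perturbation in a thin no-flux strip (fundamental mode with
        half-wavelength equal to the strip length) and compare its measured
        envelope growth rate with the leading Jacobian eigenvalue."""
        from scipy.optimize import curve_fit

        from minflat.detsim import _Lattice, _advance

        from conftest import make_box_geometry

        dx = 0.1
        nz = 4
        L = 3.0
        ny = int(round(L / dx))
        ss = solve_steady_state(HUANG_RATES, "slab", 0.4, SLAB_TOTALS, n_points=nz)
        lead = growth_spectrum(ss, HUANG_RATES, [L]).leading_eigenvalues[0]

        g = make_box_geometry((3, ny, nz), dx, membrane="slab")
        lat = _Lattice(g)
        z = lat.idx[:, 2]
        y = (lat.idx[:, 1] + 0.5) * dx
        mode = np.cos(np.pi * y / L)
        arrs = [
            ss.rho[0][z] * (1 + 1e-4 * mode),
            ss.rho[1][z].copy(), ss.rho[2][z].copy(),
            np.zeros(lat.n), np.zeros(lat.n),
        ]
        for k, row in ((3, 0), (4, 1)):
            arrs[k][z == 0] = ss.sigma[row, 0]
            arrs[k][z == nz - 1] = ss.sigma[row, 1]
        dt = 2e-4
        amp = []
        t_obs = np.arange(0.0, 150.0, 1.0)
        for i, t in enumerate(t_obs):
            if i:
                _advance(
                    int(round(1.0 / dt)), dt, dx, *arrs, lat.nbr,
                    1.0 / lat.v_dyn, lat.g, lat.is_mem,
                    HUANG_RATES.D_D, HUANG_RATES.D_E, HUANG_RATES.k_exchange,
                    HUANG_RATES.k_D, HUANG_RATES.k_dD, HUANG_RATES.k_de,
                    HUANG_RATES.k_E,
                )
            dev = arrs[0] - ss.rho[0][z]
            amp.append((dev * mode).sum() / (mode**2).sum())
        amp = np.array(amp)

        def model(t, a, r, w, phi):
            return a * np.exp(r * t) * np.cos(w * t + phi)

        p0 = (amp[0], lead.real, abs(lead.imag), 0.0)
        popt, _ = curve_fit(model, t_obs[20:], amp[20:], p0=p0, maxfev=40000)
        assert popt[1] == pytest.approx(lead.real, rel=0.05)


class TestStabilityLimit:
    def test_resolved_and_well_mixed_slab_agree(self):
        a = max_stable_half_wavelength(HUANG_RATES, "slab", 0.4, SLAB_TOTALS)
        b = max_stable_half_wavelength(
            HUANG_RATES, "slab", 0.4, SLAB_TOTALS, well_mixed=True
        )
        assert abs(a - b) < 0.05

    def test_limit_insensitive_to_thin_dimension_resolution(self):
        vals = [
            max_stable_half_wavelength(
                HUANG_RATES, "slab", 0.4, SLAB_TOTALS, n_points=n
            )
            for n in (8, 24)
        ]
        assert abs(vals[0] - vals[1]) < 0.02

    def test_wavelengths_below_limit_are_stable(self):
        limit = max_stable_half_wavelength(HUANG_RATES, "slab", 0.4, SLAB_TOTALS)
        ss = solve_steady_state(HUANG_RATES, "slab", 0.4, SLAB_TOTALS)
        disp = growth_spectrum(
            ss, HUANG_RATES, [0.5 * limit, 0.9 * limit, 1.1 * limit]
        )
        assert disp.stable[0] and disp.stable[1] and not disp.stable[2]

    def test_no_sign_change_reported(self):
        with pytest.raises(RuntimeError, match="unconditionally"):
            max_stable_half_wavelength(
                HUANG_RATES, "slab", 0.4, SLAB_TOTALS, bracket=(0.6, 0.9)
            )

    def test_cylinder_limit_near_two_microns(self):
        limit = max_stable_half_wavelength(
            HUANG_RATES, "cylinder", 0.5, (1000.0, 350.0)
        )
        assert 1.9 < limit < 2.2
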