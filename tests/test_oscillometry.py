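import numpy as np
import pytest

from minflat.oscillometry import (
    cross_correlation,
    envelope_decay,
    fit_decoherence,
    polar_counts,
    polar_region_masks,
    track_maxima,
)
from minflat.optics import PSFParams

from conftest import settled_polar_series


class TestPolarRegions:
    def test_uniform_density_ratio_equals_volume_ratio(self, pill_coarse):
        class Uniform:
            times = np.array([0.0, 1.0])

            def __init__(self, geom):
                self.geom = geom

            def __iter__(self):
                for _ in self.times:
                    yield self[0]

            def __getitem__(self, i):
                g = self.geom

                class S:
                    rho_dadp = np.where(g.mask, 100.0, 0.0)
                    rho_datp = np.zeros(g.mask.shape)
                    rho_e = np.zeros(g.mask.shape)
                    sigma_d = np.zeros(g.mask.shape)
                    sigma_de = np.zeros(g.mask.shape)

                return S()

        g = pill_coarse
        ps = polar_counts(Uniform(g), g)
        top, bottom = polar_region_masks(g)
        v_top = g.volume[top].sum()
        v_bot = g.volume[bottom].sum()
        assert ps.n_top[0] / ps.n_bottom[0] == pytest.approx(v_top / v_bot)

    def test_regions_disjoint_and_bounded(self, pill_coarse):
        top, bottom = polar_region_masks(pill_coarse)
        assert not np.any(top & bottom)
        ps_frac = (
            pill_coarse.volume[top].sum() / pill_coarse.total_volume,
            pill_coarse.volume[bottom].sum() / pill_coarse.total_volume,
        )
        for f in ps_frac:
            assert 0.0 < f < 0.5


class TestCrossCorrelation:
    def test_antiphase_closed_form(self):
        t = np.arange(0, 400.0, 0.5)
        omega = 2 * np.pi / 40.0
        top = np.sin(omega * t)
        bottom = -np.sin(omega * t)
        lags, c = cross_correlation(top, bottom, stride=0.5)
        assert c[0] == pytest.approx(-1.0)
        half = np.argmin(np.abs(lags - 20.0))
        assert c[half] == pytest.approx(1.0, abs=0.02)

    def test_white_noise_stays_within_sampling_band(self):
        rng = np.random.default_rng(0)
        n = 4000
        a, b = rng.normal(size=n), rng.normal(size=n)
        lags, c = cross_correlation(a, b, stride=1.0)
        # c is normalized by |C(0)|, itself an O(1/sqrt(n)) quantity; compare
        # the raw correlation against the sampling bound instead
        raw = c * abs(
            np.mean((a - a.mean()) * (b - b.mean()))
        )
        assert np.max(np.abs(raw[: n // 4])) < 3.0 / np.sqrt(n // 2)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=100)
        b = rng.normal(size=100) + 0.3 * a
        lags, c = cross_correlation(a, b, stride=2.0)
        am, bm = a - a.mean(), b - b.mean()
        brute = []
        for k in range(51):
            s = sum(am[t] * bm[t + k] for t in range(100 - k))
            brute.append(s / (100 - k))
        brute = np.array(brute) / abs(brute[0])
        assert np.allclose(c, brute, atol=1e-10)
        assert np.allclose(lags, 2.0 * np.arange(51))

    def test_antisymmetric_under_region_swap_for_antiphase(self):
        t = np.arange(0, 600.0, 1.0)
        x = np.cos(2 * np.pi * t / 37.0)
        _, c1 = cross_correlation(x, -x, stride=1.0)
        _, c2 = cross_correlation(-x, x, stride=1.0)
        assert np.allclose(c1, c2, atol=1e-12)  # swap symmetric here
        _, auto = cross_correlation(x, x, stride=1.0)
        assert np.allclose(auto, -c1, atol=1e-12)

    def test_constant_series_reported(self):
        with pytest.raises(ValueError, match="constant"):
            cross_correlation(np.ones(100), np.ones(100), stride=1.0)


class TestDecoherenceFit:
    def test_noiseless_self_consistency(self):
        """Parameters of an exactly damped cosine are recovered to < 0.1%."""
        lags = np.arange(0, 900.0, 1.0)
        c = -np.cos(2 * np.pi * lags / 58.0) * np.exp(-lags / 306.0)
        fit = fit_decoherence(lags, c)
        assert fit.period == pytest.approx(58.0, rel=1e-3)
        assert fit.coherence_time == pytest.approx(306.0, rel=1e-3)

    def test_scale_invariance(self):
        lags = np.arange(0, 600.0, 1.0)
        c = -np.cos(2 * np.pi * lags / 41.0) * np.exp(-lags / 180.0)
        f1 = fit_decoherence(lags, c)
        f2 = fit_decoherence(lags, 2.0 * c)
        assert f1.period == pytest.approx(f2.period, rel=1e-9)
        assert f1.coherence_time == pytest.approx(f2.coherence_time, rel=1e-9)

    def test_too_short_record_flagged(self):
        lags = np.arange(0, 30.0, 1.0)
        c = -np.cos(2 * np.pi * lags / 58.0)
        with pytest.raises(ValueError, match="short"):
            fit_decoherence(lags, c)

    def test_pure_cosine_envelope_is_flat(self):
        lags = np.arange(0, 500.0, 1.0)
        c = -np.cos(2 * np.pi * lags / 50.0)
        assert envelope_decay(lags, c, 8, 50.0) == pytest.approx(0.0, abs=1e-9)


class TestMaximaTracking:
    def test_static_gaussian_yields_no_arrows(self, disc3):
        g = disc3

        class Static:
            times = np.arange(0.0, 30.0, 2.5)

            def __getitem__(self, i):
                shape = g.mask.shape
                x = np.arange(shape[0])[:, None, None]
                y = np.arange(shape[1])[None, :, None]
                blob = np.exp(
                    -((x - shape[0] / 2) ** 2 + (y - shape[1] / 2) ** 2) / 18.0
                )
                blob = np.where(g.mask, blob, 0.0)

                class S:
                    rho_dadp = blob
                    rho_datp = np.zeros(shape)
                    rho_e = np.zeros(shape)
                    sigma_d = np.zeros(shape)
                    sigma_de = np.zeros(shape)

                return S()

        track = track_maxima(Static(), g, PSFParams(pixel_size=g.dx))
        assert len(track.arrows) == 0
        assert len(set(map(tuple, np.round(track.locations, 6)))) == 1

    def test_agrees_with_exhaustive_argmax(self, disc3, disc3_trajectory):
        """The tracked maximum equals a brute-force argmax over every pixel
        of every sampled blurred frame."""
        from minflat.optics import blur, pad_margin, project, upsample

        g = disc3
        psf = PSFParams(pixel_size=g.dx)
        track = track_maxima(
            disc3_trajectory, g, psf, sampling_stride=100.0, min_displacement=0.5
        )
        pixel = g.dx
        factor = 1
        while pixel > psf.sigma / 2:
            factor *= 2
            pixel /= 2
        psf2 = PSFParams(pixel_size=pixel)
        k = 0
        for i, t in enumerate(disc3_trajectory.times):
            if k >= len(track.times) or abs(t - track.times[k]) > 1e-9:
                continue
            snap = disc3_trajectory[i]
            img = project(
                snap.rho_dadp + snap.rho_datp, g,
                membrane=snap.sigma_d + snap.sigma_de,
            )
            img = upsample(img, factor)
            img, pad = pad_margin(img, psf2)
            img = blur(img, psf2)
            best = None
            for ix in range(img.shape[0]):
                row = img[ix]
                iy = int(np.argmax(row))
                if best is None or row[iy] > best[0]:
                    best = (row[iy], ix, iy)
            x = g.origin[0] - g.dx / 2 + (best[1] - pad + 0.5) * pixel
            y = g.origin[1] - g.dx / 2 + (best[2] - pad + 0.5) * pixel
            assert np.allclose(track.locations[k], (x, y))
            k += 1
        assert k == len(track.times)

    def test_deterministic_pill_maxima_alternate_between_poles(
        self, pill_coarse, pill_trajectory
    ):
        """Wild-type deterministic oscillation is uniformly bipolar: every
        arrow head after the transient lies in a polar third."""
        track = track_maxima(
            pill_trajectory, pill_coarse,
            PSFParams(pixel_size=pill_coarse.dx),
            sampling_stride=2.5, min_displacement=0.5,
        )
        heads = track.arrows[:, 2:]
        times = track.times
        ymin = pill_coarse.origin[1]
        ymax = ymin + pill_coarse.mask.shape[1] * pill_coarse.dx
        third = (ymax - ymin) / 3
        settled = heads[-20:]
        assert len(settled) > 5
        in_polar = (settled[:, 1] < ymin + third) | (settled[:, 1] > ymax - third)
        assert np.all(in_polar)
        # and both poles are visited
        assert (settled[:, 1] < ymin + third).any()
        assert (settled[:, 1] > ymax - third).any()


class TestDeterministicCoherence:
    def test_pill_correlation_envelope_is_undamped(self, pill_coarse, pill_trajectory):
        """Deterministic wild-type dynamics are perfectly periodic: fitted
        coherence time enormous, envelope flat over 10 periods."""
        ps = settled_polar_series(pill_trajectory, pill_coarse, 200.0)
        lags, c = cross_correlation(ps)
        fit = fit_decoherence(lags, c)
        assert fit.coherence_time > 100 * fit.period
        assert envelope_decay(lags, c, 10, fit.period) < 0.05
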