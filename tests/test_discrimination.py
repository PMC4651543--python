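"""PCA -> DFA spectral-shape discrimination and the D2/D1 indicator."""

from datetime import date, datetime, timedelta

import numpy as np
import pytest

import hivevib as hv
from hivevib import discrimination as dc
from hivevib.distributions import ModeSeries
from hivevib.spectra_io import SpectrumFrame


def _frames(amps_list, start=datetime(2022, 4, 1, 0, 0)):
    n_bins = len(amps_list[0])
    freqs = np.arange(n_bins) * 3.125
    return [
        SpectrumFrame(
            timestamp=start + timedelta(minutes=3 * i),
            colony_id="C01",
            sensor="comb",
            freqs=freqs,
            amps=np.asarray(a, float),
        )
        for i, a in enumerate(amps_list)
    ]


class TestLabelExtrema:
    def test_sinusoid_extrema_at_analytic_phases(self):
        start = date(2022, 4, 1)
        t = np.arange(120)
        series = ModeSeries(
            "X",
            [start + timedelta(days=int(i)) for i in t],
            1e-6 + 3e-7 * np.cos(2 * np.pi * t / 23.0),
        )
        ex = dc.label_extrema(series, n_per_state=3)
        highs = [(d - start).days for d in ex["high_amplitude_state"]]
        lows = [(d - start).days for d in ex[dc.LOW_STATE]]
        assert all(min(abs(h - k * 23) for k in range(6)) <= 1 for h in highs)
        assert all(min(abs(l - (11.5 + 23 * k)) for k in range(6)) <= 1.5 for l in lows)

    def test_flat_series_raises(self):
        start = date(2022, 4, 1)
        series = ModeSeries(
            "X", [start + timedelta(days=i) for i in range(60)], np.full(60, 1e-6)
        )
        with pytest.raises(ValueError, match="flat|extrema"):
            dc.label_extrema(series)

    def test_labels_match_ground_truth_brood_extremes(self, apiary5):
        """Low-amplitude labels coincide with ground-truth brood maxima
        (and high with minima) to within two nights."""
        cid = "C01"
        sc = apiary5["scenarios"][cid]
        truth = hv.ground_truth(sc)
        ex = dc.label_extrema(apiary5["series"][cid])
        brood = truth["brood"]
        for d in ex[dc.LOW_STATE]:  # low amplitude = brood present
            window = brood.loc[d - timedelta(days=2) : d + timedelta(days=2)]
            assert window.max() > 0.8 * brood.max()
        for d in ex["high_amplitude_state"]:
            window = brood.loc[d - timedelta(days=2) : d + timedelta(days=2)]
            assert window.min() < 0.2 * brood.max()


class TestAverageSpectra:
    def test_identical_frames_average_to_the_frame(self):
        amps = np.linspace(1, 2, 40)
        frames = _frames([amps] * 10)
        avg = dc.average_spectra(frames, 30, normalize=False)
        np.testing.assert_allclose(avg.amps, amps)

    def test_normalized_max_exactly_one(self):
        rng = np.random.default_rng(0)
        frames = _frames(rng.uniform(1, 3, (20, 40)))
        avg = dc.average_spectra(frames, 60, normalize=True)
        assert avg.amps.max() == 1.0

    def test_insufficient_frames_error_names_need(self):
        frames = _frames(np.ones((5, 40)))
        with pytest.raises(ValueError, match="20"):
            dc.average_spectra(frames, 60, normalize=False)

    def test_averaging_reduces_noise_sd_as_sqrt_n(self):
        rng = np.random.default_rng(1)
        base = np.full(40, 2.0)
        sds = {}
        for n in (1, 16):
            vals = []
            for _ in range(300):
                frames = _frames(base + 0.1 * rng.standard_normal((n, 40)))
                vals.append(dc.average_spectra(frames, 3 * n, normalize=False).amps[7])
            sds[n] = np.std(vals)
        assert sds[16] == pytest.approx(sds[1] / 4, rel=0.25)


class TestPCA:
    def test_matches_brute_force_eigendecomposition(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(20, 30)) * np.linspace(3, 0.1, 30)
        mean, loadings, scores = dc.fit_pca(X, n_components=10)
        # independent oracle: eigenvectors of the covariance matrix
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        order = np.argsort(evals)[::-1][:10]
        for k in range(10):
            v = evecs[:, order[k]]
            v = v * np.sign(v[np.argmax(np.abs(v))])
            np.testing.assert_allclose(loadings[k], v, atol=1e-8)
        np.testing.assert_allclose(scores, Xc @ loadings.T, atol=1e-10)

    def test_loadings_orthonormal(self, trained_model):
        model, _ = trained_model
        G = model.pca_loadings @ model.pca_loadings.T
        np.testing.assert_allclose(G, np.eye(10), atol=1e-10)

    def test_two_dimensional_data_has_no_variance_beyond_two(self):
        rng = np.random.default_rng(3)
        basis = rng.normal(size=(2, 30))
        X = rng.normal(size=(15, 2)) @ basis
        _, _, scores = dc.fit_pca(X, n_components=10)
        assert scores[:, 2:].std() < 1e-10 * scores[:, :2].std()

    def test_score_variance_non_increasing(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(40, 25))
        _, _, scores = dc.fit_pca(X, n_components=10)
        v = scores.var(axis=0)
        assert np.all(np.diff(v) <= 1e-12)

    def test_too_few_spectra_rejected(self):
        with pytest.raises(ValueError, match="components"):
            dc.fit_pca(np.ones((5, 30)), n_components=10)


class TestDFA:
    def test_two_isotropic_groups_axis_aligns_with_mean_difference(self):
        rng = np.random.default_rng(5)
        mu = np.array([4.0, 1.0])
        a = rng.normal(size=(200, 2)) * 0.3 + mu
        b = rng.normal(size=(200, 2)) * 0.3 - mu
        W, cents, evals = dc.fit_dfa(np.vstack([a, b]), ["a"] * 200 + ["b"] * 200, n_functions=1)
        w = W[0] / np.linalg.norm(W[0])
        d = (a.mean(axis=0) - b.mean(axis=0))
        d = d / np.linalg.norm(d)
        angle = np.arccos(np.clip(abs(w @ d), 0, 1))
        assert angle < 0.05  # isotropic within-scatter: Fisher axis ~ mean difference

    def test_matches_brute_force_generalized_eigenproblem(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(60, 5))
        labels = ["g%d" % (i % 3) for i in range(60)]
        X[np.array(labels) == "g1"] += [2, 0, 0, 0, 0]
        X[np.array(labels) == "g2"] += [0, 3, 1, 0, 0]
        W, _, evals = dc.fit_dfa(X, labels, n_functions=2)
        # independent oracle: plain eig of inv(Sw) @ Sb
        overall = X.mean(axis=0)
        Sw = np.zeros((5, 5))
        Sb = np.zeros((5, 5))
        for g in set(labels):
            Xg = X[np.array(labels) == g]
            mu = Xg.mean(axis=0)
            Sw += (Xg - mu).T @ (Xg - mu)
            Sb += len(Xg) * np.outer(mu - overall, mu - overall)
        ev, evec = np.linalg.eig(np.linalg.inv(Sw) @ Sb)
        order = np.argsort(ev.real)[::-1][:2]
        np.testing.assert_allclose(np.sort(evals), np.sort(ev.real[order]), atol=1e-6)
        for k in range(2):
            v = evec[:, order[k]].real
            w = W[k]
            cosang = abs(v @ w) / (np.linalg.norm(v) * np.linalg.norm(w))
            assert np.arccos(np.clip(cosang, 0, 1)) < 1e-6

    def test_label_permutation_destroys_separation(self):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(50, 4)) + [6, 0, 0, 0]
        b = rng.normal(size=(50, 4)) - [6, 0, 0, 0]
        X = np.vstack([a, b])
        labels = ["a"] * 50 + ["b"] * 50
        _, _, ev_true = dc.fit_dfa(X, labels, n_functions=1)
        perm = rng.permutation(100)
        _, _, ev_perm = dc.fit_dfa(X, [labels[i] for i in perm], n_functions=1)
        assert ev_true[0] > 10 * ev_perm[0]

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="two groups"):
            dc.fit_dfa(np.ones((10, 3)), ["a"] * 10)


class TestDiscriminantFunctions:
    def test_cross_correlation_reproduces_scores(self, trained_model):
        """The composed functions' inner product with a mean-centred spectrum
        must equal the PCA->DFA score path to 1e-8."""
        model, training = trained_model
        X = training.matrix
        scores = (X - model.mean_spectrum) @ model.pca_loadings.T
        df_direct = scores @ model.df_weights.T
        df_via_functions = (X - model.mean_spectrum) @ model.discriminant_functions.T
        np.testing.assert_allclose(df_via_functions, df_direct, atol=1e-8)

    def test_functions_lie_in_pca_span(self, trained_model):
        model, _ = trained_model
        P = model.pca_loadings.T @ model.pca_loadings  # projector onto the span
        residual = model.discriminant_functions - model.discriminant_functions @ P
        assert np.abs(residual).max() < 1e-10

    def test_mean_spectrum_scores_zero(self, trained_model):
        model, _ = trained_model
        np.testing.assert_allclose(model.project(model.mean_spectrum), 0.0, atol=1e-12)


class TestIndicator:
    @staticmethod
    def _toy_model():
        n_bins = 30
        loadings = np.zeros((10, n_bins))
        loadings[np.arange(10), np.arange(10)] = 1.0
        W = np.zeros((3, 10))
        W[np.arange(3), np.arange(3)] = 1.0
        return dc.DiscriminantModel(
            freqs=np.arange(n_bins) * 3.125,
            mean_spectrum=np.zeros(n_bins),
            pca_loadings=loadings,
            df_weights=W,
            discriminant_functions=W @ loadings,
            centroid_low=np.array([1.0, 0.0, 0.0]),
            centroid_high=np.array([-1.0, 0.0, 0.0]),
            colony_centroids={},
            eigenvalues=np.ones(3),
            duration_minutes=60,
            normalized=True,
        )

    def _spectrum(self, point):
        amps = np.zeros(30)
        amps[:3] = point
        return amps

    def test_at_high_centroid_indicator_zero(self):
        m = self._toy_model()
        assert dc.indicator(self._spectrum([-1, 0, 0]), m) == 0.0

    def test_at_low_centroid_indicator_infinite(self):
        m = self._toy_model()
        assert np.isinf(dc.indicator(self._spectrum([1, 0, 0]), m))

    def test_midpoint_indicator_one(self):
        m = self._toy_model()
        assert dc.indicator(self._spectrum([0, 0, 0]), m) == pytest.approx(1.0)

    def test_model_round_trips_through_json(self, trained_model, tmp_path):
        model, _ = trained_model
        p = model.save(tmp_path / "model.json")
        back = dc.DiscriminantModel.load(p)
        np.testing.assert_allclose(back.discriminant_functions, model.discriminant_functions)
        np.testing.assert_allclose(back.centroid_low, model.centroid_low)
        assert back.colony_centroids.keys() == model.colony_centroids.keys()

    def test_normalized_pipeline_invariant_to_global_rescaling(self, apiary5, trained_model):
        model, _ = trained_model
        cid = "C03"
        d = sorted(apiary5["frames"][cid])[30]
        frames = sorted(apiary5["frames"][cid][d], key=lambda f: f.timestamp)[:20]
        scaled = [
            SpectrumFrame(
                timestamp=f.timestamp,
                colony_id=f.colony_id,
                sensor=f.sensor,
                freqs=f.freqs,
                amps=f.amps * 7.3,
            )
            for f in frames
        ]
        v1 = dc.indicator(dc.average_spectra(frames, 60, normalize=True), model)
        v2 = dc.indicator(dc.average_spectra(scaled, 60, normalize=True), model)
        assert v1 == pytest.approx(v2, rel=1e-12)


class TestIndicatorImage:
    def test_six_slots_per_full_night(self, apiary5, trained_model):
        model, _ = trained_model
        cid = "C02"
        sub = {d: apiary5["frames"][cid][d] for d in sorted(apiary5["frames"][cid])[:10]}
        ind = dc.indicator_image(sub, model, 60, True)
        assert ind.values.shape == (10, 6)
        assert np.isfinite(ind.values).all()

    def test_partial_night_flagged_missing(self, apiary5, trained_model):
        model, _ = trained_model
        cid = "C02"
        ds = sorted(apiary5["frames"][cid])[:3]
        sub = {d: apiary5["frames"][cid][d] for d in ds}
        sub[ds[1]] = sub[ds[1]][:25]  # one full slot + a fragment
        ind = dc.indicator_image(sub, model, 60, True)
        assert np.isnan(ind.values[1, 1:]).all()
        assert np.isfinite(ind.values[1, 0])

    def test_white_noise_spectra_do_not_track(self, trained_model):
        """Spectra with no load information produce an indicator series
        uncorrelated with any mode series."""
        model, _ = trained_model
        rng = np.random.default_rng(11)
        start = date(2022, 4, 1)
        n_bins = model.freqs.size
        nights, mode = {}, []
        for i in range(100):
            d = start + timedelta(days=i)
            amps = rng.uniform(0.5, 1.5, (20, n_bins)) * 1e-6
            nights[d] = _frames(amps, start=datetime(2022, 4, 1 + 0, 0, 0) + timedelta(days=i))
            mode.append(1e-6 * (1 + 0.3 * np.sin(2 * np.pi * i / 23)))
        series = ModeSeries("N", sorted(nights), np.array(mode))
        ind = dc.indicator_image(nights, model, 60, True)
        r = dc.tracking_correlation(ind, series)
        assert abs(r) < 0.2
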