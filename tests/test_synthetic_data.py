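import datetime as dt

import numpy as np
import pytest

from milkguard.data_model_io import ConfigError, FEATURES
from milkguard.drift_stats import SeasonBin
from milkguard.synthetic_data import (
    AdulterantSignature,
    SpectrumPeak,
    _fvec,
    default_adulterant_library,
    default_generator_config,
    generate_normal,
    generate_study,
    spike,
    synth_spectrum,
)

JAN_MAR_2020 = (dt.date(2020, 1, 1), dt.date(2020, 3, 31))


class TestConfigValidation:
    def test_non_psd_covariance_rejected(self):
        cov = np.eye(8)
        cov[0, 1] = cov[1, 0] = 2.0  # eigenvalue -1
        with pytest.raises(ConfigError, match="positive semi-definite"):
            default_generator_config(covariance=cov)

    def test_unsorted_concentrations_rejected(self):
        with pytest.raises(ConfigError, match="ascending"):
            default_generator_config(concentrations=(0.1, 0.05))

    def test_peak_outside_grid_rejected(self):
        with pytest.raises(ConfigError, match="outside grid"):
            default_generator_config(
                spectrum_peaks=(SpectrumPeak(900.0, 10.0, 0.5),))

    def test_signature_needs_a_nonzero_delta(self):
        with pytest.raises(ValueError, match="nonzero delta"):
            AdulterantSignature("ghost", _fvec())


class TestGenerateNormal:
    def test_same_seed_identical_output(self):
        cfg = default_generator_config(seed=5)
        a = generate_normal(cfg, 20, seed=123)
        b = generate_normal(cfg, 20, seed=123)
        for ra, rb in zip(a, b):
            assert ra.sample_id == rb.sample_id and ra.date == rb.date
            np.testing.assert_array_equal(ra.profile.as_array(),
                                          rb.profile.as_array())
            np.testing.assert_array_equal(ra.spectrum.absorbances,
                                          rb.spectrum.absorbances)

    def test_noiseless_spectrum_matches_gaussian_sum(self):
        cfg = default_generator_config(noise_sd=0.0, with_spectra=True)
        rec = generate_normal(cfg, 1, dates=JAN_MAR_2020, seed=1).records[0]
        w = cfg.wavenumbers
        vals = rec.profile.as_array()
        expected = np.zeros_like(w)
        for pk in cfg.spectrum_peaks:
            h = pk.height
            if pk.modulates:
                i = FEATURES.index(pk.modulates)
                h *= 1 + pk.mod_scale * (vals[i] / cfg.mean_profile[i] - 1)
            expected += h * np.exp(-0.5 * ((w - pk.center) / pk.width) ** 2)
        np.testing.assert_allclose(rec.spectrum.absorbances, expected,
                                   atol=1e-12)

    def test_large_sample_recovers_mean_and_covariance(self):
        cfg = default_generator_config(
            seed=2, with_spectra=False,
            seasonal_shift={s: _fvec() for s in SeasonBin})
        n = 5000
        sset = generate_normal(cfg, n, dates=JAN_MAR_2020, seed=2)
        X = sset.feature_matrix()
        se = np.sqrt(np.diag(cfg.covariance) / n)
        assert np.all(np.abs(X.mean(axis=0) - cfg.mean_profile) < 3 * se)
        S = np.cov(X, rowvar=False)
        rel = np.linalg.norm(S - cfg.covariance) / np.linalg.norm(cfg.covariance)
        assert rel < 0.10

    def test_seasonal_shift_applied_by_date(self):
        shift = _fvec(acidity=5.0)
        cfg = default_generator_config(
            seed=3, with_spectra=False, covariance=np.eye(8) * 1e-6,
            seasonal_shift={SeasonBin.JAN_MAR: _fvec(),
                            SeasonBin.APR_AUG: shift,
                            SeasonBin.SEP_DEC: _fvec()})
        summer = generate_normal(cfg, 50, dates=(dt.date(2020, 5, 1),
                                                 dt.date(2020, 7, 31)), seed=4)
        winter = generate_normal(cfg, 50, dates=JAN_MAR_2020, seed=4)
        diff = (summer.feature_matrix().mean(axis=0)
                - winter.feature_matrix().mean(axis=0))
        assert diff[-1] == pytest.approx(5.0, abs=0.01)


class TestSpike:
    def _record(self, cfg):
        return generate_normal(cfg, 1, dates=JAN_MAR_2020, seed=9).records[0]

    def test_zero_concentration_degenerate_but_relabelled(self):
        cfg = default_generator_config()
        rec = self._record(cfg)
        sig = cfg.adulterant_library["melamine"]
        with pytest.warns(UserWarning, match="degenerate"):
            spiked = spike(rec, sig, 0.0)
        assert spiked.label == "spiked" and spiked.concentration == 0.0
        np.testing.assert_array_equal(spiked.profile.as_array(),
                                      rec.profile.as_array())
        np.testing.assert_array_equal(spiked.spectrum.absorbances,
                                      rec.spectrum.absorbances)

    def test_linear_composition_rule_exact(self):
        cfg = default_generator_config(with_spectra=False)
        rec = self._record(cfg)
        sig = AdulterantSignature("acidifier", _fvec(acidity=1.0))
        spiked = spike(rec, sig, 0.1)
        assert (spiked.profile.acidity - rec.profile.acidity
                == pytest.approx(0.1, abs=1e-12))

    def test_perturbation_monotone_in_concentration(self):
        cfg = default_generator_config(seed=10)
        sig = cfg.adulterant_library["sucrose"]
        records = generate_normal(cfg, 100, dates=JAN_MAR_2020, seed=10)
        for rec in records:
            hi = spike(rec, sig, 0.2).profile.as_array() - rec.profile.as_array()
            lo = spike(rec, sig, 0.01).profile.as_array() - rec.profile.as_array()
            assert np.linalg.norm(hi) >= np.linalg.norm(lo)

    def test_expression_scales_the_applied_delta(self):
        cfg = default_generator_config(with_spectra=False)
        rec = self._record(cfg)
        sig = AdulterantSignature("acidifier", _fvec(acidity=1.0))
        half = spike(rec, sig, 0.2, expression=0.5)
        assert (half.profile.acidity - rec.profile.acidity
                == pytest.approx(0.1, abs=1e-12))
        assert half.concentration == 0.2  # nominal concentration recorded


class TestGenerateStudy:
    def test_held_out_never_in_training(self, default_study):
        train_adults = {r.adulterant for r in default_study["training"]
                        if r.label == "spiked"}
        assert train_adults.isdisjoint(
            {"hydrogen_peroxide", "sodium_hydroxide", "salt"})

    def test_counts_match_design(self, default_study):
        tr, cv = default_study["training"], default_study["crossval"]
        assert len(tr) == 372 + 19 * 15
        assert len(cv) == 65 + 6 * 15
        per = {}
        for r in tr:
            if r.label == "spiked":
                per[r.adulterant] = per.get(r.adulterant, 0) + 1
        assert set(per.values()) == {15}
        concs = sorted({r.concentration for r in tr if r.label == "spiked"})
        assert concs == [0.01, 0.02, 0.05, 0.1, 0.2]

    def test_overlap_between_held_out_and_training_rejected(self):
        with pytest.raises(ConfigError, match="held-out"):
            generate_study(default_generator_config(
                held_out_adulterants=("melamine",)))

    def test_crossval_normals_shifted_by_annual_vector(self):
        cfg = default_generator_config(
            seed=6, with_spectra=False,
            n_normal_training=400, n_normal_crossval=400,
            n_spikes_per_adulterant=5,
            seasonal_shift={s: _fvec() for s in SeasonBin})
        study = generate_study(cfg)
        tr = study["training"].subset(lambda r: r.label == "normal")
        cv = study["crossval"].subset(lambda r: r.label == "normal")
        diff = cv.feature_matrix().mean(axis=0) - tr.feature_matrix().mean(axis=0)
        shift = cfg.annual_shift[2021]
        se = np.sqrt(np.diag(cfg.covariance) * (1 / 400 + 1 / 400))
        assert np.all(np.abs(diff - shift) < 3 * se)

    def test_study_is_deterministic(self):
        a = generate_study(default_generator_config(
            seed=12, n_normal_training=30, n_normal_crossval=10,
            n_spikes_per_adulterant=5, with_spectra=False))
        b = generate_study(default_generator_config(
            seed=12, n_normal_training=30, n_normal_crossval=10,
            n_spikes_per_adulterant=5, with_spectra=False))
        fa = a["training"].to_frame()
        fb = b["training"].to_frame()
        assert fa.equals(fb)


def test_library_categories_and_coverage():
    lib = default_adulterant_library()
    cats = {s.category for s in lib.values()}
    assert cats == {"common chemical", "nitrogen-based", "carbohydrate-based",
                    "other"}
    cfg = default_generator_config()
    for name in cfg.training_adulterants + cfg.crossval_adulterants:
        assert name in lib
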