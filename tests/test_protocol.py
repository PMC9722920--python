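import numpy as np
import pytest

from milkguard.data_model_io import ConfigError, SampleSet
from milkguard.learners import LearnerConfig
from milkguard.protocol import (
    NOT_DETECTED,
    LeakageError,
    ProtocolConfig,
    blinded_crossval,
    build_feature_view,
    estimate_lod,
    leave_one_adulterant_out,
    run_model_selection,
)
from milkguard.synthetic_data import default_generator_config, generate_study, spike

# small ensembles for speed; XGBoost still needs enough rounds at the
# protocol's 0.01 learning rate to move the logit past the 0.5 threshold
FAST = ProtocolConfig(
    et_config=LearnerConfig(kind="extratrees", n_trees=40),
    xgb_config=LearnerConfig(kind="xgboost", n_boost_rounds=200),
    seed=0,
)


@pytest.fixture(scope="module")
def spectral_study():
    cfg = default_generator_config(
        seed=21, n_normal_training=120, n_normal_crossval=40,
        n_spikes_per_adulterant=5,
        training_adulterants=("melamine", "sucrose", "citric_acid",
                              "glucose", "fructose", "urea"),
        crossval_adulterants=("sodium_hydroxide", "salt", "glucose",
                              "fructose", "sucrose"),
    )
    return generate_study(cfg)


class TestFeatureViews:
    def test_combined_is_column_stack_of_single_views(self, spectral_study):
        tr = spectral_study["training"]
        comp = build_feature_view(tr, "compositional")
        spec = build_feature_view(tr, "spectral8")
        both = build_feature_view(tr, "combined16")
        assert both.X.shape[1] == 16
        np.testing.assert_array_equal(both.X,
                                      np.hstack([comp.X, spec.X]))
        assert both.feature_names[:8] == comp.feature_names

    def test_column_order_stable_across_calls(self, spectral_study):
        tr = spectral_study["training"]
        a = build_feature_view(tr, "combined16")
        b = build_feature_view(tr, "combined16")
        assert a.feature_names == b.feature_names
        np.testing.assert_array_equal(a.X, b.X)

    def test_missing_spectra_listed(self, small_study):
        with pytest.raises(ValueError, match="lack spectra"):
            build_feature_view(small_study["training"], "spectral8")

    def test_replicates_are_averaged(self, spectral_study):
        rec = spectral_study["training"].records[0]
        import copy
        rep2 = copy.deepcopy(rec)
        rep2.replicate_index = 2
        rep2.profile = type(rec.profile).from_array(
            rec.profile.as_array() + np.full(8, 0.2))
        duo = SampleSet([rec, rep2])
        fv = build_feature_view(duo, "compositional")
        assert fv.X.shape == (1, 8)
        np.testing.assert_allclose(
            fv.X[0], rec.profile.as_array() + 0.1, atol=1e-12)


class TestModelSelection:
    def test_all_candidates_reported_and_winner_is_argmax(self, spectral_study):
        sel = run_model_selection(spectral_study["training"], FAST,
                                  views=("combined16",))
        cands = sel.per_view["combined16"]
        assert set(cands) == {"md", "extratrees", "xgboost", "voting",
                              "weighting"}
        f1s = {c: (m.f1 if isinstance(m.f1, float) else -1.0)
               for c, m in cands.items()}
        best = sel.winner["combined16"]
        assert f1s[best] == max(f1s.values())

    def test_separable_study_ties_to_first_candidate(self):
        # spikes far above noise in one tight cluster -> every candidate
        # separates perfectly (a wide concentration spread would leave tree
        # split placement in the empty gap arbitrary)
        cfg = default_generator_config(
            seed=22, n_normal_training=60, n_spikes_per_adulterant=5,
            with_spectra=False,
            training_adulterants=("melamine", "citric_acid"),
            concentrations=(4.9, 4.95, 5.0, 5.05, 5.1))
        study = generate_study(cfg)
        sel = run_model_selection(study["training"], ProtocolConfig(seed=0),
                                  views=("compositional",))
        assert all(m.f1 == 1.0
                   for m in sel.per_view["compositional"].values())
        assert sel.winner["compositional"] == "md"


class TestBlindedCrossval:
    def test_exclude_mode_uses_no_crossval_records(self, spectral_study):
        res = blinded_crossval(spectral_study["training"],
                               spectral_study["crossval"],
                               drift_mode="exclude", config=FAST)
        n_unique_train = len({r.sample_id
                              for r in spectral_study["training"]})
        assert res.n_train == n_unique_train
        assert res.held_out == ("salt", "sodium_hydroxide")

    def test_include_sugars_augments_training(self, spectral_study):
        res = blinded_crossval(spectral_study["training"],
                               spectral_study["crossval"],
                               drift_mode="include_sugars", config=FAST)
        assert res.n_train > len({r.sample_id
                                  for r in spectral_study["training"]})

    def test_all_held_out_contradiction_rejected(self, spectral_study):
        with pytest.raises(ConfigError, match="held out"):
            blinded_crossval(
                spectral_study["training"], spectral_study["crossval"],
                drift_mode="include_sugars",
                held_out=("sodium_hydroxide", "salt", "glucose",
                          "fructose", "sucrose"),
                config=FAST)

    def test_held_out_in_training_batch_is_leakage(self, spectral_study):
        # sucrose appears in the training batch, so holding it out leaks
        with pytest.raises(LeakageError):
            blinded_crossval(spectral_study["training"],
                             spectral_study["crossval"],
                             held_out=("salt", "sucrose"), config=FAST)

    def test_rerun_with_same_seed_is_identical(self, spectral_study):
        a = blinded_crossval(spectral_study["training"],
                             spectral_study["crossval"],
                             drift_mode="include_sugars", config=FAST)
        b = blinded_crossval(spectral_study["training"],
                             spectral_study["crossval"],
                             drift_mode="include_sugars", config=FAST)
        assert a.test_flags == b.test_flags
        assert a.metrics.as_dict() == b.metrics.as_dict()


class TestLeaveOneOut:
    def test_holding_out_one_of_two_adulterants(self):
        cfg = default_generator_config(
            seed=23, n_normal_training=60, n_spikes_per_adulterant=5,
            with_spectra=False,
            training_adulterants=("melamine", "citric_acid"))
        study = generate_study(cfg)
        res = leave_one_adulterant_out(study["training"],
                                       view="compositional", config=FAST)
        assert set(res.metrics) == {"melamine", "citric_acid"}
        assert set(res.lod) == {"melamine", "citric_acid"}

    def test_absent_adulterant_rejected(self, spectral_study):
        with pytest.raises(ValueError, match="no samples"):
            leave_one_adulterant_out(spectral_study["training"],
                                     adulterants=["salt"], config=FAST)

    def test_strong_signature_detected_at_mid_concentrations(self,
                                                             default_study):
        sens = []
        for seed in range(3):
            res = leave_one_adulterant_out(
                default_study["training"], adulterants=["melamine"],
                config=ProtocolConfig(seed=seed))
            hi = [f for c, f in res.spike_flags["melamine"] if c >= 0.05]
            sens.append(np.mean(hi))
        assert np.mean(sens) >= 0.9


class TestLOD:
    def test_first_detected_rule(self):
        rep = estimate_lod("x", [0.01, 0.02, 0.05, 0.1, 0.2],
                           [0, 0, 1, 1, 1])
        assert rep.lod == 0.05

    def test_all_detected_gives_lowest(self):
        rep = estimate_lod("x", [0.01, 0.02, 0.05], [1, 1, 1])
        assert rep.lod == 0.01

    def test_none_detected(self):
        rep = estimate_lod("x", [0.01, 0.2], [0, 0])
        assert rep.lod == NOT_DETECTED
        assert "> 0.2" in str(rep)

    def test_any_replicate_counts_as_detected(self):
        rep = estimate_lod("x", [0.01, 0.01, 0.01, 0.05], [0, 1, 0, 0])
        assert rep.lod == 0.01
        assert rep.detected == (True, False)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            estimate_lod("x", [], [])
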