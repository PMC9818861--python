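from dataclasses import replace

import numpy as np
import pytest

from msfingerprint import cnn, ncv
from msfingerprint.dscore import (
    confusion_counts,
    fit_calibration,
    log_odds,
    mcc,
    transform,
)
from msfingerprint.matrixify import MatrixConfig, aggregate_to_integer_mass, znormalize_scans
from msfingerprint.simulate import SampleMeta, SimConfig, simulate_dataset


def metas_for(n_cultivars: int, n_replicates: int = 2) -> list[SampleMeta]:
    metas = []
    for cls in ("A", "B"):
        for ci in range(n_cultivars):
            cultivar = f"{cls}{ci + 1:02d}"
            for run in range(1, n_replicates + 1):
                metas.append(SampleMeta(f"{cultivar}_r{run}", cultivar, cls, run))
    return metas


class TestBuildFolds:
    def test_study_design_counts(self):
        folds = ncv.build_folds(metas_for(11))
        assert len(folds) == 11
        for fold in folds:
            assert len(fold.train_sample_ids) == 40
            assert len(fold.test_sample_ids) == 4

    def test_two_cultivar_design(self):
        folds = ncv.build_folds(metas_for(2))
        assert len(folds) == 2
        for fold in folds:
            assert len(fold.train_sample_ids) == 4
            assert len(fold.test_sample_ids) == 4

    def test_lexicographic_pairing(self):
        folds = ncv.build_folds(metas_for(3))
        assert [(f.held_out_cultivar_a, f.held_out_cultivar_b) for f in folds] == [
            ("A01", "B01"), ("A02", "B02"), ("A03", "B03"),
        ]

    def test_partition_property_each_cultivar_tested_once(self):
        metas = metas_for(5)
        folds = ncv.build_folds(metas)
        tested = [c for f in folds for c in (f.held_out_cultivar_a, f.held_out_cultivar_b)]
        assert sorted(tested) == sorted({m.cultivar for m in metas})
        for fold in folds:
            assert not set(fold.train_sample_ids) & set(fold.test_sample_ids)
            held = {fold.held_out_cultivar_a, fold.held_out_cultivar_b}
            train_cultivars = {m.cultivar for m in metas if m.sample_id in fold.train_sample_ids}
            assert not held & train_cultivars

    def test_random_pairing_keeps_partition(self):
        metas = metas_for(4)
        folds = ncv.build_folds(metas, rng=np.random.default_rng(0))
        tested = [c for f in folds for c in (f.held_out_cultivar_a, f.held_out_cultivar_b)]
        assert sorted(tested) == sorted({m.cultivar for m in metas})

    def test_single_cultivar_class_rejected(self):
        metas = [m for m in metas_for(2) if not (m.class_label == "B" and m.cultivar == "B02")]
        with pytest.raises(ValueError, match="need >= 2"):
            ncv.build_folds(metas)

    def test_requires_two_classes(self):
        metas = [m for m in metas_for(3) if m.class_label == "A"]
        with pytest.raises(ValueError, match="two classes"):
            ncv.build_folds(metas)


def _small_pipeline_inputs(sim_cfg: SimConfig):
    runs, metas = simulate_dataset(sim_cfg)
    mc = MatrixConfig(mz_min=sim_cfg.mz_min, mz_max=sim_cfg.mz_max, n_scans=sim_cfg.n_scans)
    matrices = {
        m.sample_id: znormalize_scans(aggregate_to_integer_mass(r, mc))
        for r, m in zip(runs, metas)
    }
    return matrices, metas


SMALL_CNN = cnn.CnnConfig(
    n_conv_layers=2, filters_per_layer=(3, 4), epochs=15, batch_size=4, seed=0
)


class TestInternalValidation:
    def test_every_sample_predicted_once_never_in_own_training_fold(self, tiny_sim_config):
        matrices, metas = _small_pipeline_inputs(tiny_sim_config)
        folds = ncv.build_folds(metas)
        result = ncv.run_internal_validation(folds, matrices, metas, SMALL_CNN)
        assert len(result.models) == len(folds)
        assert sorted(result.held_out_probability) == sorted(m.sample_id for m in metas)
        for fold in folds:
            for sid in fold.test_sample_ids:
                assert sid not in fold.train_sample_ids

    def test_missing_matrix_raises_naming_sample(self, tiny_sim_config):
        matrices, metas = _small_pipeline_inputs(tiny_sim_config)
        victim = metas[0].sample_id
        del matrices[victim]
        folds = ncv.build_folds(metas)
        with pytest.raises(KeyError, match=victim):
            ncv.run_internal_validation(folds, matrices, metas, SMALL_CNN)

    def test_null_class_effect_gives_mcc_near_zero(self, tiny_sim_config):
        """No class signal in, no class signal out: held-out MCC over a small
        seed batch stays well below 1 — systematic positive MCC would mean
        information leaks across the cultivar partition."""
        mccs = []
        for seed in (0, 1, 2):
            cfg = replace(tiny_sim_config, class_effect=0.0, seed=seed)
            matrices, metas = _small_pipeline_inputs(cfg)
            folds = ncv.build_folds(metas)
            result = ncv.run_internal_validation(
                folds, matrices, metas, replace(SMALL_CNN, seed=seed)
            )
            meta_by_id = {m.sample_id: m for m in metas}
            truths = [meta_by_id[sid].class_label for sid in result.held_out_probability]
            decisions = [
                "A" if p > 0.5 else "B" for p in result.held_out_probability.values()
            ]
            mccs.append(mcc(confusion_counts(truths, decisions, positive_class="A")))
        assert abs(float(np.mean(mccs))) < 0.5


class TestPredictExternal:
    def test_average_is_mean_of_log_odds_and_linear_in_d(self, tiny_sim_config):
        matrices, metas = _small_pipeline_inputs(tiny_sim_config)
        folds = ncv.build_folds(metas)[:2]
        result = ncv.run_internal_validation(folds, matrices, metas, SMALL_CNN)
        sample = matrices[metas[0].sample_id]
        probs, avg_lo = ncv.predict_external(result, sample)
        assert len(probs) == 2
        assert avg_lo == pytest.approx(np.mean([log_odds(p) for p in probs]), abs=1e-12)
        # averaging commutes with the affine D transform
        params = fit_calibration([1.0, 2.0], [-1.5, -0.5])
        mean_of_d = np.mean([transform(log_odds(p), params) for p in probs])
        assert transform(avg_lo, params) == pytest.approx(mean_of_d, abs=1e-12)

    def test_artificial_mix_follows_major_component(self, tiny_sim_config):
        """A 90/10 in-silico blend of a class-A and a class-B spectrum scores
        as class A across the fold models."""
        from msfingerprint.matrixify import (
            MatrixConfig,
            aggregate_to_integer_mass,
            make_artificial_mix,
            znormalize_scans,
        )

        cfg = replace(tiny_sim_config, class_effect=3.0)
        runs, metas = simulate_dataset(cfg)
        mc = MatrixConfig(mz_min=cfg.mz_min, mz_max=cfg.mz_max, n_scans=cfg.n_scans)
        raw = {m.sample_id: aggregate_to_integer_mass(r, mc) for r, m in zip(runs, metas)}
        matrices = {sid: znormalize_scans(m) for sid, m in raw.items()}
        folds = ncv.build_folds(metas)
        result = ncv.run_internal_validation(folds, matrices, metas, SMALL_CNN)

        a_id = next(m.sample_id for m in metas if m.class_label == "A")
        b_id = next(m.sample_id for m in metas if m.class_label == "B")
        mix = znormalize_scans(make_artificial_mix(raw[a_id], raw[b_id], 0.9))
        _, avg_lo = ncv.predict_external(result, mix)
        assert avg_lo > 0.0  # positive class A wins on the averaged log odds

    def test_empty_model_list_rejected(self, tiny_sim_config):
        matrices, _ = _small_pipeline_inputs(tiny_sim_config)
        empty = ncv.NcvResult(folds=[], models=[], held_out_probability={})
        with pytest.raises(ValueError, match="no models"):
            ncv.predict_external(empty, next(iter(matrices.values())))
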