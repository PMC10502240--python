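import numpy as np
import pytest

from epimodal.variant_effects import (
    EffectFeatures,
    SiameseClassifier,
    VariantBatch,
    _logit,
    effect_features,
    eqtl_crossval,
    fit_siamese,
    grouped_folds,
    zero_shot_score,
    zero_shot_scores,
)


class TestEffectFeatures:
    def test_identical_windows_give_zero_vectors(self, tiny_model, small_fixture):
        w = small_fixture.onehot[0]
        feats = effect_features(tiny_model, w, w.copy(), 0)
        np.testing.assert_array_equal(feats.delta_prob, 0)
        np.testing.assert_array_equal(feats.delta_logit, 0)

    def test_delta_logit_closed_form(self):
        # p 0.5 -> 0.75 shifts the log odds by ln 3
        assert _logit(np.array([0.75]))[0] - _logit(np.array([0.5]))[0] == (
            pytest.approx(np.log(3)))

    def test_event_mask_restricts_width(self, tiny_model, small_fixture):
        mask = np.zeros(6, dtype=bool)
        mask[:5] = True
        feats = effect_features(tiny_model, small_fixture.onehot[0],
                                small_fixture.onehot[2], 0, event_mask=mask)
        assert feats.delta_prob.shape == (5,)

    def test_antisymmetric_under_swap(self, tiny_model, small_fixture):
        a, b = small_fixture.onehot[0], small_fixture.onehot[2]
        f1 = effect_features(tiny_model, a, b, 1)
        f2 = effect_features(tiny_model, b, a, 1)
        np.testing.assert_allclose(f1.delta_prob, -f2.delta_prob, atol=1e-12)
        np.testing.assert_allclose(f1.delta_logit, -f2.delta_logit, atol=1e-12)


class TestZeroShotScore:
    def test_zero_features_score_zero_every_mode(self):
        feats = EffectFeatures(None, np.zeros(4), np.zeros(4))
        for mode in ("mean_abs", "max_abs", "l2"):
            assert zero_shot_score(feats, mode) == 0.0

    def test_aggregation_examples(self):
        feats = EffectFeatures(None, np.array([0.4, 0.0, 0.0, 0.0]), np.zeros(4))
        assert zero_shot_score(feats, "mean_abs") == pytest.approx(0.1)
        feats2 = EffectFeatures(None, np.array([0.1, -0.3]), np.zeros(2))
        assert zero_shot_score(feats2, "max_abs") == pytest.approx(0.3)

    def test_nonnegative_and_zero_iff_zero(self):
        rng = np.random.default_rng(0)
        d = rng.normal(size=8) * 0.1
        feats = EffectFeatures(None, d, d)
        assert zero_shot_score(feats) > 0


class TestGroupedFolds:
    def test_human_chromosomes_fill_five_folds(self):
        chroms = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
        folds = grouped_folds(chroms, n_folds=5, seed=0)
        per_fold = {}
        for g, f in folds.fold_of_chrom.items():
            per_fold.setdefault(f, []).append(g)
        assert set(per_fold) == set(range(5))
        # 23 groups over 5 folds: pigeonhole gives every fold >= 3 groups
        assert min(len(v) for v in per_fold.values()) >= 3

    def test_sex_chromosomes_share_a_fold(self):
        chroms = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]
        folds = grouped_folds(chroms, n_folds=5, seed=3)
        assert folds.fold_of("chrX") == folds.fold_of("chrY")

    def test_deterministic_given_seed(self):
        chroms = [f"chr{i}" for i in range(1, 11)]
        a = grouped_folds(chroms, n_folds=3, seed=7)
        b = grouped_folds(chroms, n_folds=3, seed=7)
        assert a.fold_of_chrom == b.fold_of_chrom

    def test_fewer_groups_than_folds_rejected(self):
        with pytest.raises(ValueError):
            grouped_folds(["chr1", "chrX", "chrY"], n_folds=3)


def _eqtl_data(n=2000, dim=6, separable=True, seed=0):
    rng = np.random.default_rng(seed)
    chroms = rng.choice([f"chr{i}" for i in range(1, 11)], size=n)
    features = rng.normal(size=(n, dim))
    if separable:
        labels = rng.integers(0, 2, n)
        features[:, 0] = np.where(labels, 2.0, -2.0) + rng.normal(0, 0.1, n)
    else:
        labels = rng.integers(0, 2, n)
    return features, labels, chroms


class TestEqtlCrossval:
    def test_separable_features_reach_perfect_auroc(self):
        features, labels, chroms = _eqtl_data(separable=True)
        folds = grouped_folds(chroms, n_folds=3, seed=0)
        result = eqtl_crossval(features, labels, chroms, folds,
                               tuning_chroms=("chr1",))
        assert result.mean_auroc == pytest.approx(1.0)

    def test_independent_labels_stay_near_chance(self):
        features, labels, chroms = _eqtl_data(separable=False)
        folds = grouped_folds(chroms, n_folds=3, seed=0)
        result = eqtl_crossval(features, labels, chroms, folds,
                               tuning_chroms=("chr1",))
        assert 0.45 <= result.mean_auroc <= 0.55

    def test_impossible_fold_change_filter_rejected(self):
        features, labels, chroms = _eqtl_data(n=200)
        folds = grouped_folds(chroms, n_folds=3, seed=0)
        with pytest.raises(ValueError, match="relax"):
            eqtl_crossval(features, labels, chroms, folds,
                          log2_fold_change=np.zeros(200), fold_change_cutoff=99.0)

    def test_fold_change_filter_reduces_evaluated_count(self):
        features, labels, chroms = _eqtl_data(n=400)
        folds = grouped_folds(chroms, n_folds=3, seed=0)
        l2fc = np.linspace(-4, 4, 400)
        full = eqtl_crossval(features, labels, chroms, folds,
                             tuning_chroms=("chr1",), log2_fold_change=l2fc,
                             fold_change_cutoff=0.0)
        cut = eqtl_crossval(features, labels, chroms, folds,
                            tuning_chroms=("chr1",), log2_fold_change=l2fc,
                            fold_change_cutoff=2.0)
        assert cut.n_used < full.n_used


def _variant_batch(fixture, n=8):
    rng = np.random.default_rng(0)
    idx = rng.choice(len(fixture.samples), n, replace=False)
    ref = fixture.onehot[idx]
    alt = ref.copy()
    alt[:, :, 500] = ref[:, [1, 0, 3, 2], 500]  # swap one column's channels
    return VariantBatch(ref, alt, fixture.sample_hic_bins[idx],
                        np.arange(n) % 2)


class TestSiamese:
    def test_output_invariant_to_input_swap(self, tiny_model, small_fixture):
        batch = _variant_batch(small_fixture)
        clf = SiameseClassifier(tiny_model, seed=0)
        a = clf.predict(batch.ref_onehot, batch.alt_onehot, batch.bins)
        b = clf.predict(batch.alt_onehot, batch.ref_onehot, batch.bins)
        np.testing.assert_array_equal(a, b)  # bit-identical

    def test_zero_training_size_falls_back_to_zero_shot(self, tiny_model, small_fixture):
        batch = _variant_batch(small_fixture)
        clf = fit_siamese(tiny_model, batch.subset(np.array([], dtype=int)),
                          batch, seed=0)
        scores = clf.predict(batch.ref_onehot, batch.alt_onehot, batch.bins)
        expected = zero_shot_scores(tiny_model, batch)
        np.testing.assert_allclose(scores, expected)
        assert clf.trained is False

    def test_training_does_not_mutate_the_pretrained_encoder(self, tiny_model,
                                                             small_fixture):
        batch = _variant_batch(small_fixture)
        before = {k: v.copy() for k, v in tiny_model.state_dict().items()}
        fit_siamese(tiny_model, batch, batch, max_epochs=2, patience=2, seed=0)
        for k, v in tiny_model.state_dict().items():
            np.testing.assert_array_equal(v, before[k])

    def test_untrained_head_ranks_by_aggregate_squared_difference(
            self, tiny_model, small_fixture):
        batch = _variant_batch(small_fixture)
        clf = SiameseClassifier(tiny_model, seed=0)
        scores = clf.predict(batch.ref_onehot, batch.alt_onehot, batch.bins)
        probs_ref = tiny_model.predict(batch.ref_onehot, batch.bins)
        probs_alt = tiny_model.predict(batch.alt_onehot, batch.bins)
        agg = ((probs_ref - probs_alt) ** 2).sum(axis=1)
        np.testing.assert_array_equal(np.argsort(scores), np.argsort(agg))
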