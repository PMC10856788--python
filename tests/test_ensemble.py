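"""One-hot encoding, surrogate ensemble contract, and top-k selection."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from dnasensor import (
    EnsemblePrediction,
    OracleSurrogate,
    ResponseEnsemble,
    encode_onehot,
    select_top_k,
)
from dnasensor.ensemble import (
    N_CLASSIFIERS,
    encode_batch,
    load_ensemble,
    predictions_to_frame,
    save_ensemble,
)
from dnasensor.sequences import FLANK, validate_sequence


def make_pred(bases, mean_r, votes_high=9):
    votes = (1,) * votes_high + (0,) * (9 - votes_high)
    return EnsemblePrediction(
        sequence=validate_sequence(bases),
        pred_min=mean_r,
        pred_max=mean_r,
        mean_r=mean_r,
        class_votes=votes,
        consistent_high=votes_high > 4,
    )


class TestEncoding:
    def test_all_adenine_sets_first_slot_of_each_block(self):
        vec = encode_onehot("A" * 18)
        assert np.array_equal(vec.reshape(18, 4)[:, 0], np.ones(18))
        assert vec.sum() == 18

    def test_every_sequence_sums_to_18_with_one_hot_blocks(self, full_library):
        X = encode_batch(full_library.members[:200])
        assert np.all(X.sum(axis=1) == 18)
        assert np.all(X.reshape(-1, 18, 4).sum(axis=2) == 1)

    def test_three_mutations_flip_six_coordinates(self, original, l114):
        a, b = encode_onehot(original), encode_onehot(l114)
        assert int(np.sum(a != b)) == 6


class TestEnsembleFit:
    def test_too_few_training_pairs_raise(self, original):
        with pytest.raises(ValueError, match="20"):
            ResponseEnsemble().fit([original] * 10, np.arange(10.0))

    def test_degenerate_labels_raise(self, full_library):
        seqs = full_library.members[:30]
        with pytest.raises(ValueError, match="degenerate"):
            ResponseEnsemble().fit(seqs, np.ones(30))

    def test_smoke_fit_predicts_finite_on_training_set(self, full_library, landscape):
        seqs = full_library.members[:20]
        labels = landscape.true_response_batch(seqs, "5HT")
        ens = ResponseEnsemble(random_state=1).fit(seqs, labels)
        assert np.all(np.isfinite(ens.predict(seqs)))

    def test_unfitted_predict_raises(self, original):
        with pytest.raises(Exception):
            ResponseEnsemble().predict([original])


class TestEnsemblePredictions:
    def test_min_mean_max_ordering_always_holds(self, trained_ensemble):
        ens, heldout, _ = trained_ensemble
        for pred in ens.predict_ensemble(heldout):
            assert pred.pred_min <= pred.mean_r <= pred.pred_max
            assert len(pred.class_votes) == N_CLASSIFIERS

    def test_heldout_rank_correlation_on_additive_landscape(self, trained_ensemble):
        ens, heldout, truth = trained_ensemble
        rho = spearmanr(ens.predict(heldout), truth).statistic
        assert rho >= 0.7

    def test_mean_of_two_regressor_outputs(self, trained_ensemble):
        ens, heldout, _ = trained_ensemble
        X = encode_batch(heldout)
        r1 = ens.regressors_[0].predict(X)
        r2 = ens.regressors_[1].predict(X)
        preds = ens.predict_ensemble(heldout)
        assert np.allclose([p.mean_r for p in preds], (r1 + r2) / 2)
        assert np.allclose([p.pred_min for p in preds], np.minimum(r1, r2))
        assert np.allclose([p.pred_max for p in preds], np.maximum(r1, r2))

    def test_invalid_prediction_record_rejected(self, original):
        with pytest.raises(ValueError):
            EnsemblePrediction(original, 2.0, 1.0, 1.5, (1,) * 9, True)
        with pytest.raises(ValueError):
            EnsemblePrediction(original, 0.0, 1.0, 0.5, (1,) * 5, True)

    def test_save_load_round_trip(self, trained_ensemble, tmp_path):
        ens, heldout, _ = trained_ensemble
        path = tmp_path / "ensemble.joblib"
        save_ensemble(ens, path)
        loaded = load_ensemble(path)
        assert np.array_equal(loaded.predict(heldout), ens.predict(heldout))


class TestSelection:
    def test_majority_vote_threshold(self):
        assert make_pred(FLANK + "A" * 18 + FLANK, 1.0, votes_high=5).consistent_high
        assert not make_pred(FLANK + "A" * 18 + FLANK, 1.0, votes_high=4).consistent_high

    def test_inconsistent_candidates_are_skipped_and_next_promoted(self):
        preds = [
            make_pred(FLANK + "A" * 18 + FLANK, 3.0, votes_high=2),
            make_pred(FLANK + "C" * 18 + FLANK, 2.0),
            make_pred(FLANK + "G" * 18 + FLANK, 1.0),
        ]
        top = select_top_k(preds, 2)
        assert [p.mean_r for p in top] == [2.0, 1.0]

    def test_ties_break_lexicographically(self):
        preds = [
            make_pred(FLANK + "T" * 18 + FLANK, 1.0),
            make_pred(FLANK + "A" * 18 + FLANK, 1.0),
            make_pred(FLANK + "G" * 18 + FLANK, 1.0),
        ]
        top = select_top_k(preds, 2)
        assert [p.sequence.variable_region[0] for p in top] == ["A", "G"]

    def test_permutation_invariance_and_subset(self, landscape, full_library):
        oracle = OracleSurrogate(landscape)
        sample = full_library.members[:500]
        preds = oracle.predict_ensemble(sample)
        rng = np.random.default_rng(3)
        shuffled = [preds[i] for i in rng.permutation(len(preds))]
        a = select_top_k(preds, 20)
        b = select_top_k(shuffled, 20)
        assert [p.sequence.bases for p in a] == [p.sequence.bases for p in b]
        assert set(p.sequence.bases for p in a) <= set(s.bases for s in sample)

    def test_k_larger_than_pool_returns_all_sorted(self):
        preds = [make_pred(FLANK + b * 18 + FLANK, v) for b, v in zip("ACGT", [1, 3, 2, 4])]
        top = select_top_k(preds, 10)
        assert [p.mean_r for p in top] == [4, 3, 2, 1]

    def test_oracle_top20_equals_brute_force(self, landscape, full_library):
        """With the exact landscape as surrogate, screening must reproduce
        the brute-force top 20 of the true response over the full library."""
        oracle = OracleSurrogate(landscape)
        preds = oracle.predict_ensemble(full_library.members)
        selected = [p.sequence.bases for p in select_top_k(preds, 20)]
        truth = landscape.true_response_batch(full_library.members, "5HT")
        order = sorted(
            range(len(truth)),
            key=lambda i: (-truth[i], full_library.members[i].bases),
        )
        brute = [full_library.members[i].bases for i in order[:20]]
        assert selected == brute

    def test_prediction_frame_is_rank_ordered(self):
        preds = [make_pred(FLANK + b * 18 + FLANK, v) for b, v in zip("ACGT", [1, 3, 2, 4])]
        frame = predictions_to_frame(preds)
        assert list(frame["rank"]) == [1, 2, 3, 4]
        assert frame["mean_r"].is_monotonic_decreasing
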