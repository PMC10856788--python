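"""Surrogate screening ensemble: two kernel regressors plus nine classifiers.

The screen mimics the published composition: support-vector regression with
radial-basis and sigmoid kernels predicts ΔF/F0 from a one-hot encoding of
the 18-nt variable region, and nine small feed-forward binary classifiers
(differing by seed and width) vote on whether a sequence is "high response".
Candidates are ranked by the ensemble-mean prediction (``mean_r``) and the
top k that the classifier majority also calls high are carried forward to
measurement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVR
from sklearn.utils.validation import check_is_fitted

from .sequences import ALPHABET, VARIABLE_LENGTH, SensorSequence

N_REGRESSORS = 2
N_CLASSIFIERS = 9

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}


def encode_onehot(seq: SensorSequence | str) -> np.ndarray:
    """Length-72 one-hot encoding of the variable region (base order ACGT).

    The flanks are fixed and carry no information, so only the 18 variable
    positions are encoded (18 positions x 4 bases).
    """
    var = seq.variable_region if isinstance(seq, SensorSequence) else seq
    if len(var) != VARIABLE_LENGTH:
        raise ValueError(f"expected an {VARIABLE_LENGTH}-nt variable region")
    vec = np.zeros(VARIABLE_LENGTH * 4)
    for i, b in enumerate(var):
        vec[i * 4 + _BASE_INDEX[b]] = 1.0
    return vec


def encode_batch(seqs) -> np.ndarray:
    return np.stack([encode_onehot(s) for s in seqs])


@dataclass(frozen=True)
class EnsemblePrediction:
    """Per-sequence ensemble output used for ranking and consistency checks."""

    sequence: SensorSequence
    pred_min: float
    pred_max: float
    mean_r: float
    class_votes: tuple[int, ...]
    consistent_high: bool

    def __post_init__(self) -> None:
        if not self.pred_min <= self.mean_r <= self.pred_max:
            raise ValueError("mean_r must lie between pred_min and pred_max")
        if len(self.class_votes) != N_CLASSIFIERS:
            raise ValueError(f"expected {N_CLASSIFIERS} classifier votes")

    @property
    def votes_high(self) -> int:
        return int(sum(self.class_votes))


class ResponseEnsemble(BaseEstimator, RegressorMixin):
    """Kernel-regression + classifier-consensus surrogate for ΔF/F0.

    Parameters
    ----------
    high_response_quantile : float
        Quantile of the training labels used as the "high response" cutoff
        for classifier training (top quartile by default).
    svr_c, svr_epsilon : float
        Shared SVR regularisation and tube width for both kernels.
    hidden_sizes : tuple of int
        Cycle of hidden-layer widths for the nine classifiers; combined with
        per-classifier seeds this diversifies the committee.
    random_state : int
        Base seed for the classifier committee.

    Attributes
    ----------
    regressors_ : list of fitted SVR (RBF and sigmoid kernels).
    classifiers_ : list of 9 fitted binary classifiers.
    high_response_threshold_ : ΔF/F0 cutoff defining the "high" class.
    """

    def __init__(
        self,
        high_response_quantile: float = 0.75,
        svr_c: float = 10.0,
        svr_epsilon: float = 0.01,
        hidden_sizes: tuple[int, ...] = (8, 16, 32),
        max_iter: int = 400,
        random_state: int = 0,
    ):
        self.high_response_quantile = high_response_quantile
        self.svr_c = svr_c
        self.svr_epsilon = svr_epsilon
        self.hidden_sizes = hidden_sizes
        self.max_iter = max_iter
        self.random_state = random_state

    def _as_features(self, X) -> np.ndarray:
        arr = np.asarray(X)
        if arr.ndim == 2 and arr.shape[1] == VARIABLE_LENGTH * 4:
            return arr.astype(float)
        return encode_batch(list(X))

    def fit(self, X, y):
        """Train the ensemble on (sequence, measured ΔF/F0) pairs.

        ``X`` may be sequences (``SensorSequence`` or 18-nt strings) or an
        already-encoded (n, 72) matrix.  At least 20 pairs are required and
        the labels must straddle the high-response threshold so the binary
        classifiers have both classes to learn.
        """
        features = self._as_features(X)
        labels = np.asarray(y, dtype=float).reshape(-1)
        if len(features) != len(labels):
            raise ValueError("X and y length mismatch")
        if len(labels) < 20:
            raise ValueError("need at least 20 training pairs")
        if not np.all(np.isfinite(labels)):
            raise ValueError("training labels must be finite")

        self.high_response_threshold_ = float(
            np.quantile(labels, self.high_response_quantile)
        )
        binary = (labels >= self.high_response_threshold_).astype(int)
        if len(np.unique(binary)) < 2:
            raise ValueError(
                "degenerate labels: all sequences fall in one response class"
            )

        self.regressors_ = [
            SVR(kernel="rbf", C=self.svr_c, epsilon=self.svr_epsilon, gamma="scale"),
            SVR(kernel="sigmoid", C=self.svr_c, epsilon=self.svr_epsilon,
                gamma=1.0 / features.shape[1], coef0=0.0),
        ]
        for reg in self.regressors_:
            reg.fit(features, labels)

        self.classifiers_ = []
        for i in range(N_CLASSIFIERS):
            clf = MLPClassifier(
                hidden_layer_sizes=(self.hidden_sizes[i % len(self.hidden_sizes)],),
                max_iter=self.max_iter,
                random_state=self.random_state + i,
            )
            clf.fit(features, binary)
            self.classifiers_.append(clf)
        self.n_features_in_ = features.shape[1]
        return self

    def predict(self, X) -> np.ndarray:
        """Ensemble-mean predicted ΔF/F0 (``mean_r``) per sequence."""
        check_is_fitted(self, "regressors_")
        features = self._as_features(X)
        preds = np.stack([reg.predict(features) for reg in self.regressors_])
        return preds.mean(axis=0)

    def predict_ensemble(self, seqs: list[SensorSequence]) -> list[EnsemblePrediction]:
        """Full per-sequence record: min/mean/max prediction and class votes."""
        check_is_fitted(self, "regressors_")
        features = encode_batch(seqs)
        preds = np.stack([reg.predict(features) for reg in self.regressors_])
        votes = np.stack([clf.predict(features) for clf in self.classifiers_])
        out = []
        for j, seq in enumerate(seqs):
            v = tuple(int(x) for x in votes[:, j])
            out.append(
                EnsemblePrediction(
                    sequence=seq,
                    pred_min=float(preds[:, j].min()),
                    pred_max=float(preds[:, j].max()),
                    mean_r=float(preds[:, j].mean()),
                    class_votes=v,
                    consistent_high=sum(v) > N_CLASSIFIERS // 2,
                )
            )
        return out


class OracleSurrogate(BaseEstimator, RegressorMixin):
    """Surrogate that answers with the landscape's exact saturating response.

    Used to isolate the selection logic from surrogate error: with this
    oracle, top-k screening must agree with a brute-force sort of the true
    landscape.  Every classifier vote is "high", so nothing is filtered.
    """

    def __init__(self, landscape, analyte: str = "5HT"):
        self.landscape = landscape
        self.analyte = analyte

    def fit(self, X=None, y=None):
        return self

    def predict(self, seqs) -> np.ndarray:
        return self.landscape.true_response_batch(list(seqs), self.analyte)

    def predict_ensemble(self, seqs: list[SensorSequence]) -> list[EnsemblePrediction]:
        values = self.predict(seqs)
        return [
            EnsemblePrediction(
                sequence=s,
                pred_min=float(v),
                pred_max=float(v),
                mean_r=float(v),
                class_votes=(1,) * N_CLASSIFIERS,
                consistent_high=True,
            )
            for s, v in zip(seqs, values)
        ]


def fit_ensemble(train_pairs, **params) -> ResponseEnsemble:
    """Thin wrapper: fit a :class:`ResponseEnsemble` on (sequence, ΔF/F0) pairs."""
    seqs, labels = zip(*train_pairs)
    return ResponseEnsemble(**params).fit(list(seqs), list(labels))


def predict_ensemble(ens, seqs: list[SensorSequence]) -> list[EnsemblePrediction]:
    return ens.predict_ensemble(seqs)


def select_top_k(preds: list[EnsemblePrediction], k: int) -> list[EnsemblePrediction]:
    """Top-k by mean_r with classifier-consistency filtering.

    Sequences the classifier majority does not call high are skipped and the
    next-ranked promoted; ties in mean_r break lexicographically by sequence
    string so the selection is reproducible and order-independent.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    eligible = [p for p in preds if p.consistent_high]
    eligible.sort(key=lambda p: (-p.mean_r, p.sequence.bases))
    return eligible[:k]


def save_ensemble(ens: ResponseEnsemble, path) -> None:
    """Persist a fitted ensemble; ``load_ensemble(save(...))`` predicts identically."""
    import joblib

    joblib.dump({"format_version": 1, "ensemble": ens}, path)


def load_ensemble(path) -> ResponseEnsemble:
    import joblib

    payload = joblib.load(path)
    if payload.get("format_version") != 1:
        raise ValueError("unrecognised ensemble archive version")
    return payload["ensemble"]


def predictions_to_frame(preds: list[EnsemblePrediction]) -> pd.DataFrame:
    """Ranked prediction table ready for CSV export."""
    ranked = sorted(preds, key=lambda p: (-p.mean_r, p.sequence.bases))
    return pd.DataFrame(
        {
            "sequence": [p.sequence.bases for p in ranked],
            "name": [p.sequence.name for p in ranked],
            "pred_min": [p.pred_min for p in ranked],
            "mean_r": [p.mean_r for p in ranked],
            "pred_max": [p.pred_max for p in ranked],
            "votes_high": [p.votes_high for p in ranked],
            "consistent_high": [p.consistent_high for p in ranked],
            "rank": np.arange(1, len(ranked) + 1),
        }
    )
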