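"""Risk classifiers over packed visit sequences.

Two sklearn-style estimators share one interface: ``LSTMRiskClassifier``, a
stacked-LSTM sequence model with early stopping on validation AUROC, and
``BagOfCodesLogisticClassifier``, a ridge-penalized logistic regression over
binary presence indicators of the same tokens (the conventional baseline that
discards within-window timing).  ``X`` is a list of packed samples — each a
list of visits, each visit a list of integer token ids (see
``encoding.pack_sample``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression

from .recurrent import LSTMNet

__all__ = [
    "auroc",
    "predict_risk",
    "LSTMRiskClassifier",
    "BagOfCodesLogisticClassifier",
    "EvalResult",
    "repeat_evaluate",
]


def auroc(scores, labels) -> float:
    """Area under the ROC curve in its Mann-Whitney form.

    The probability that a uniformly random case outscores a uniformly random
    control, with ties counted one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUROC requires both classes")
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _check_X(X):
    if len(X) == 0:
        raise ValueError("empty fold")
    for seq in X:
        if not isinstance(seq, (list, tuple)) or len(seq) == 0:
            raise ValueError("each sample must be a non-empty list of visits")
    return X


def _max_token(X) -> int:
    return max((tok for seq in X for visit in seq for tok in visit), default=0)


class LSTMRiskClassifier(BaseEstimator, ClassifierMixin):
    """Gated recurrent risk classifier over visit-token sequences.

    Token embeddings are sum-pooled per visit, the visit vectors run through a
    stacked LSTM, and the final hidden state maps to an event probability.
    Training minimizes binary cross-entropy with Adam; after each epoch the
    validation AUROC is measured and training stops once it has failed to
    improve for ``patience`` consecutive epochs, restoring the best weights.
    """

    def __init__(self, embed_dim: int = 128, hidden_size: int = 128,
                 n_layers: int = 2, dropout: float = 0.2,
                 learning_rate: float = 1e-3, batch_size: int = 64,
                 max_epochs: int = 50, patience: int = 3,
                 vocab_size: int | None = None, seed: int = 0):
        self.embed_dim = embed_dim
        self.hidden_size = hidden_size
        self.n_layers = n_layers
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.patience = patience
        self.vocab_size = vocab_size
        self.seed = seed

    def fit(self, X, y, X_val=None, y_val=None):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        X = _check_X(X)
        y = np.asarray(y, dtype=float)
        if len(np.unique(y)) < 2:
            raise ValueError("training fold must contain both classes")
        vocab_size = self.vocab_size or max(_max_token(X),
                                            _max_token(X_val or []))
        net = LSTMNet(vocab_size, self.embed_dim, self.hidden_size,
                      self.n_layers, self.dropout, seed=self.seed)
        rng = np.random.default_rng(self.seed + 1)
        n = len(X)
        best_auc, best_weights, best_epoch, since_best = -np.inf, None, -1, 0
        self.history_ = []
        for epoch in range(self.max_epochs):
            order = rng.permutation(n)
            losses = []
            for s in range(0, n, self.batch_size):
                idx = order[s:s + self.batch_size]
                loss, grads = net.loss_and_grads([X[i] for i in idx], y[idx],
                                                 rng=rng)
                net.adam_step(grads, lr=self.learning_rate)
                losses.append(loss)
            epoch_loss = float(np.mean(losses))
            if X_val is not None and len(X_val):
                val_auc = auroc(net.predict(X_val), y_val)
            else:
                val_auc = auroc(net.predict(X), y)
            self.history_.append({"epoch": epoch, "train_loss": epoch_loss,
                                  "val_auc": val_auc})
            if val_auc > best_auc:
                best_auc, best_weights, best_epoch = val_auc, net.get_weights(), epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        net.set_weights(best_weights)
        self.net_ = net
        self.best_epoch_ = best_epoch
        self.best_val_auc_ = best_auc
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        X = _check_X(X)
        p = self.net_.predict(X)
        return np.column_stack([1 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


def predict_risk(model, sample) -> float:
    """Event probability for one packed sample (inference mode)."""
    if not isinstance(sample, (list, tuple)) or not sample:
        raise ValueError("sample must be a packed, non-empty visit sequence")
    if not any(sample):
        raise ValueError("sample has no tokens after packing")
    return float(model.predict_proba([list(sample)])[0, 1])


class BagOfCodesLogisticClassifier(BaseEstimator, ClassifierMixin):
    """Ridge-logistic baseline on binary bag-of-codes indicators.

    A token's presence anywhere in the lookback window is one feature; all
    timing information is discarded.  The inverse regularization strength is
    chosen on validation AUROC from a fixed small grid.
    """

    def __init__(self, C_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0),
                 vocab_size: int | None = None, seed: int = 0):
        self.C_grid = C_grid
        self.vocab_size = vocab_size
        self.seed = seed

    def _featurize(self, X, vocab_size: int) -> sparse.csr_matrix:
        rows, cols = [], []
        for i, seq in enumerate(X):
            toks = {tok for visit in seq for tok in visit}
            rows.extend([i] * len(toks))
            cols.extend(sorted(toks))
        data = np.ones(len(rows))
        return sparse.csr_matrix((data, (rows, cols)),
                                 shape=(len(X), vocab_size + 1))

    def fit(self, X, y, X_val=None, y_val=None):
        X = _check_X(X)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training fold must contain both classes")
        vocab_size = self.vocab_size or max(_max_token(X),
                                            _max_token(X_val or []))
        self.vocab_size_ = vocab_size
        M = self._featurize(X, vocab_size)
        if X_val is not None and len(X_val):
            Mv = self._featurize(X_val, vocab_size)
            best = (-np.inf, None, None)
            for C in self.C_grid:
                clf = LogisticRegression(C=C, max_iter=2000,
                                         random_state=self.seed)
                clf.fit(M, y)
                a = auroc(clf.predict_proba(Mv)[:, 1], y_val)
                if a > best[0]:
                    best = (a, C, clf)
            self.best_val_auc_, self.C_, self.clf_ = best
        else:
            self.C_ = 1.0
            self.clf_ = LogisticRegression(C=1.0, max_iter=2000,
                                           random_state=self.seed).fit(M, y)
            self.best_val_auc_ = None
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X) -> np.ndarray:
        M = self._featurize(_check_X(X), self.vocab_size_)
        return self.clf_.predict_proba(M)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)


@dataclass
class EvalResult:
    """AUROC over repeated seeded re-trainings on fixed folds."""

    val_aucs: list[float] = field(default_factory=list)
    test_aucs: list[float] = field(default_factory=list)

    @property
    def n_repeats(self) -> int:
        return len(self.val_aucs)

    @property
    def val_mean(self) -> float:
        return float(np.mean(self.val_aucs))

    @property
    def val_std(self) -> float:
        return float(np.std(self.val_aucs, ddof=1)) if self.n_repeats > 1 else 0.0

    @property
    def test_mean(self) -> float:
        return float(np.mean(self.test_aucs))

    @property
    def test_std(self) -> float:
        return float(np.std(self.test_aucs, ddof=1)) if self.n_repeats > 1 else 0.0

    def as_dict(self) -> dict:
        return {
            "n_repeats": self.n_repeats,
            "val_aucs": self.val_aucs, "test_aucs": self.test_aucs,
            "val_mean": self.val_mean, "val_std": self.val_std,
            "test_mean": self.test_mean, "test_std": self.test_std,
        }


def repeat_evaluate(make_model, folds, n_repeats: int = 10,
                    base_seed: int = 0) -> EvalResult:
    """Re-train ``n_repeats`` times with seeds ``base_seed + 0..n-1`` on fixed
    folds and collect validation/test AUROC.

    ``make_model(seed)`` must return an unfitted estimator; ``folds`` is
    ``((X_tr, y_tr), (X_val, y_val), (X_te, y_te))``.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    (X_tr, y_tr), (X_val, y_val), (X_te, y_te) = folds
    result = EvalResult()
    for r in range(n_repeats):
        model = make_model(base_seed + r)
        model.fit(X_tr, y_tr, X_val=X_val, y_val=y_val)
        result.val_aucs.append(auroc(model.predict_proba(X_val)[:, 1], y_val))
        result.test_aucs.append(auroc(model.predict_proba(X_te)[:, 1], y_te))
    return result
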