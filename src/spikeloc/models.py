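"""Balanced classifiers over spike-train feature matrices.

Two model families predict a unit's anatomical class from its feature
vector:

* :class:`BalancedLogisticRegression` — multinomial logistic regression with
  L2 regularization and a 1e-4 stopping tolerance, on z-scored features
  (train-set statistics only);
* :class:`SpikeTrainMLP` — a single-hidden-layer rectified-linear perceptron
  trained with the Adam optimizer, with early stopping on validation
  balanced accuracy.

Class imbalance is corrected before fitting by resampling the training set;
the default is SMOTE (synthetic minority oversampling), which upsamples each
minority class to the majority count with convex combinations of minority
nearest neighbours.  Hyperparameters are tuned by seeded random search over
per-representation grids, maximizing validation balanced accuracy.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.utils.validation import check_X_y, check_array

from .metrics import balanced_accuracy

__all__ = [
    "smote_resample",
    "resample",
    "BalancedLogisticRegression",
    "SpikeTrainMLP",
    "HyperparameterSpace",
    "hyperparameter_space",
    "tune_hyperparameters",
    "ProbabilityTable",
    "predict_probabilities",
    "train_logistic",
    "train_mlp",
]

RESAMPLING_CHOICES = ("none", "undersample", "oversample", "smote")


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def smote_resample(X, y, k_neighbors: int = 5, seed: int | np.random.Generator = 0):
    """Upsample every class to the majority count with SMOTE.

    Synthetic samples are ``x + u * (x_nn - x)`` with ``u ~ Uniform(0, 1)``
    and ``x_nn`` one of the ``k_neighbors`` Euclidean nearest neighbours of
    ``x`` within its own class.  A class with a single sample cannot be
    interpolated and falls back to duplication with a warning.  Original
    rows are returned unchanged, followed by the synthetic rows.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    X_new, y_new = [X], [y]
    for cls, n in zip(classes, counts):
        deficit = int(target - n)
        if deficit == 0:
            continue
        Xc = X[y == cls]
        if n == 1:
            warnings.warn(f"SMOTE: class {cls!r} has one sample; duplicating")
            synth = np.repeat(Xc, deficit, axis=0)
        else:
            k = min(k_neighbors, n - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
            _, idx = nn.kneighbors(Xc)  # column 0 is the point itself
            base = rng.integers(n, size=deficit)
            pick = idx[base, rng.integers(1, k + 1, size=deficit)]
            u = rng.random((deficit, 1))
            synth = Xc[base] + u * (Xc[pick] - Xc[base])
        X_new.append(synth)
        y_new.append(np.full(deficit, cls, dtype=y.dtype))
    return np.vstack(X_new), np.concatenate(y_new)


def resample(X, y, method: str, seed: int | np.random.Generator = 0):
    """Apply one of the class-rebalancing strategies."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if method == "none":
        return X, y
    if method == "smote":
        return smote_resample(X, y, seed=rng)
    classes, counts = np.unique(y, return_counts=True)
    idx_out = []
    if method == "undersample":
        target = counts.min()
        for cls in classes:
            idx = np.flatnonzero(y == cls)
            idx_out.append(rng.choice(idx, size=target, replace=False))
    elif method == "oversample":
        target = counts.max()
        for cls in classes:
            idx = np.flatnonzero(y == cls)
            extra = rng.choice(idx, size=target - idx.size, replace=True)
            idx_out.append(np.concatenate([idx, extra]))
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    idx_all = np.concatenate(idx_out)
    return X[idx_all], y[idx_all]


# ---------------------------------------------------------------------------
# probability table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbabilityTable:
    """Per-unit class-probability vectors with a fixed class ordering."""

    unit_ids: tuple[str, ...]
    class_labels: tuple[str, ...]
    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (len(self.unit_ids), len(self.class_labels)):
            raise ValueError("probs shape mismatch")
        if p.size and (p.min() < -1e-9 or np.abs(p.sum(axis=1) - 1).max() > 1e-9):
            raise ValueError("rows must be probability vectors summing to 1")
        object.__setattr__(self, "probs", p)

    @property
    def predicted_labels(self) -> np.ndarray:
        """Winner-take-all labels; ties break to the lowest class index."""
        return np.asarray(self.class_labels, dtype=object)[
            np.argmax(self.probs, axis=1)
        ]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, index=list(self.unit_ids),
                          columns=list(self.class_labels))
        df.index.name = "unit_id"
        return df

    def subset(self, unit_ids) -> "ProbabilityTable":
        pos = {u: i for i, u in enumerate(self.unit_ids)}
        idx = [pos[u] for u in unit_ids]
        return ProbabilityTable(tuple(unit_ids), self.class_labels, self.probs[idx])


def predict_probabilities(model, X, unit_ids=None) -> ProbabilityTable:
    """Predict a :class:`ProbabilityTable`; rows sum to 1."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature dimension {X.shape} does not match model "
            f"({model.n_features_in_} features)"
        )
    probs = model.predict_proba(X)
    probs = probs / probs.sum(axis=1, keepdims=True)
    if unit_ids is None:
        unit_ids = tuple(f"row{i}" for i in range(len(X)))
    return ProbabilityTable(tuple(unit_ids), tuple(str(c) for c in model.classes_), probs)


# ---------------------------------------------------------------------------
# logistic regression
# ---------------------------------------------------------------------------

class BalancedLogisticRegression(BaseEstimator, ClassifierMixin):
    """Multinomial logistic regression with z-scoring and optional resampling.

    Features are standardized with train-set mean/SD; constant features are
    dropped with a warning.  The solver uses an L2 penalty and a 1e-4
    stopping tolerance.
    """

    def __init__(self, C: float = 1.0, tol: float = 1e-4, max_iter: int = 1000,
                 resampling: str = "none", seed: int = 0):
        self.C = C
        self.tol = tol
        self.max_iter = max_iter
        self.resampling = resampling
        self.seed = seed

    def fit(self, X, y):
        X, y = check_X_y(np.asarray(X, dtype=float), y)
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0)
        self.keep_ = sd > 0
        if not self.keep_.all():
            warnings.warn(f"dropping {int((~self.keep_).sum())} constant feature(s)")
        self.scale_ = np.where(self.keep_, sd, 1.0)
        self.n_features_in_ = X.shape[1]
        Xs = ((X - self.mean_) / self.scale_)[:, self.keep_]
        Xs, y = resample(Xs, y, self.resampling, self.seed)
        # sklearn's default penalty is L2; C and tol carry the contract
        self.model_ = LogisticRegression(
            C=self.C, tol=self.tol, max_iter=self.max_iter, random_state=self.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.model_.fit(Xs, y)
        self.classes_ = self.model_.classes_
        self.train_balanced_accuracy_ = balanced_accuracy(y, self.model_.predict(Xs))
        return self

    def _prep(self, X):
        X = check_array(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        return ((X - self.mean_) / self.scale_)[:, self.keep_]

    def predict_proba(self, X):
        return self.model_.predict_proba(self._prep(X))

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


# ---------------------------------------------------------------------------
# MLP
# ---------------------------------------------------------------------------

class SpikeTrainMLP(BaseEstimator, ClassifierMixin):
    """Single-hidden-layer ReLU perceptron trained with Adam.

    Training resamples classes (default SMOTE), then runs minibatch Adam for
    up to ``max_epochs`` epochs.  If a validation set is supplied to
    :meth:`fit`, training stops when validation balanced accuracy has not
    improved for ``patience`` epochs and the best-epoch weights are
    restored.
    """

    def __init__(self, hidden_nodes: int = 200, learning_rate: float = 1e-3,
                 batch_size: int = 125, alpha_l2: float = 1e-4, beta1: float = 0.9,
                 resampling: str = "smote", max_epochs: int = 200,
                 patience: int = 10, seed: int = 0):
        self.hidden_nodes = hidden_nodes
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.alpha_l2 = alpha_l2
        self.beta1 = beta1
        self.resampling = resampling
        self.max_epochs = max_epochs
        self.patience = patience
        self.seed = seed

    def fit(self, X, y, X_val=None, y_val=None):
        X, y = check_X_y(np.asarray(X, dtype=float), y)
        self.n_features_in_ = X.shape[1]
        rng = np.random.default_rng(self.seed)
        Xr, yr = resample(X, y, self.resampling, rng)
        classes = np.unique(yr)
        mlp = MLPClassifier(
            hidden_layer_sizes=(self.hidden_nodes,),
            activation="relu",
            solver="adam",
            alpha=self.alpha_l2,
            batch_size=min(self.batch_size, len(Xr)),
            learning_rate_init=self.learning_rate,
            beta_1=self.beta1,
            max_iter=1,
            shuffle=True,
            random_state=self.seed,
            warm_start=False,
        )
        if X_val is None:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                mlp.set_params(max_iter=self.max_epochs)
                mlp.fit(Xr, yr)
            self.n_epochs_ = mlp.n_iter_
            self.val_balanced_accuracy_ = None
        else:
            X_val = np.asarray(X_val, dtype=float)
            y_val = np.asarray(y_val)
            best_score, best_state, best_epoch = -np.inf, None, 0
            order = np.arange(len(Xr))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                mlp.partial_fit(Xr[:1], yr[:1], classes=classes)  # initialize shapes
            for epoch in range(self.max_epochs):
                rng.shuffle(order)
                bs = min(self.batch_size, len(Xr))
                for k in range(0, len(Xr), bs):
                    b = order[k:k + bs]
                    mlp.batch_size = len(b)  # avoid re-splitting the minibatch
                    mlp.partial_fit(Xr[b], yr[b])
                score = balanced_accuracy(y_val, mlp.predict(X_val))
                if not np.isfinite(mlp.loss_):
                    raise RuntimeError(
                        f"MLP diverged (non-finite loss) at epoch {epoch} "
                        f"with {self.get_params()!r}"
                    )
                if score > best_score:
                    best_score, best_epoch = score, epoch
                    best_state = (copy.deepcopy(mlp.coefs_),
                                  copy.deepcopy(mlp.intercepts_))
                elif epoch - best_epoch >= self.patience:
                    break
            if best_state is not None:
                mlp.coefs_, mlp.intercepts_ = best_state
            self.n_epochs_ = best_epoch + 1
            self.val_balanced_accuracy_ = float(best_score)
        if not np.all(np.isfinite(np.concatenate([c.ravel() for c in mlp.coefs_]))):
            raise RuntimeError(f"MLP diverged with {self.get_params()!r}")
        self.model_ = mlp
        self.classes_ = mlp.classes_
        self.train_balanced_accuracy_ = balanced_accuracy(y, mlp.predict(X))
        return self

    def predict_proba(self, X):
        X = check_array(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature dimension mismatch")
        return self.model_.predict_proba(X)

    def predict(self, X):
        proba = self.predict_proba(X)
        return self.classes_[np.argmax(proba, axis=1)]


# ---------------------------------------------------------------------------
# hyperparameter search
# ---------------------------------------------------------------------------

def _grid(lo, hi, step):
    return tuple(range(lo, hi + 1, step))


@dataclass(frozen=True)
class HyperparameterSpace:
    """Per-representation MLP search grids."""

    hidden_nodes: tuple[int, ...]
    learning_rate: tuple[float, ...]
    batch_size: tuple[int, ...]
    alpha_l2: tuple[float, ...]
    beta1: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9)
    resampling: tuple[str, ...] = ("smote",)

    def sample(self, rng: np.random.Generator) -> dict:
        return {
            "hidden_nodes": int(rng.choice(self.hidden_nodes)),
            "learning_rate": float(rng.choice(self.learning_rate)),
            "batch_size": int(rng.choice(self.batch_size)),
            "alpha_l2": float(rng.choice(self.alpha_l2)),
            "beta1": float(rng.choice(self.beta1)),
            "resampling": str(rng.choice(self.resampling)),
        }

    def all_points(self):
        from itertools import product

        for hn, lr, bs, a, b1, rs in product(
            self.hidden_nodes, self.learning_rate, self.batch_size,
            self.alpha_l2, self.beta1, self.resampling,
        ):
            yield {"hidden_nodes": hn, "learning_rate": lr, "batch_size": bs,
                   "alpha_l2": a, "beta1": b1, "resampling": rs}

    def __contains__(self, hp: dict) -> bool:
        return (
            hp["hidden_nodes"] in self.hidden_nodes
            and hp["learning_rate"] in self.learning_rate
            and hp["batch_size"] in self.batch_size
            and hp["alpha_l2"] in self.alpha_l2
            and hp["beta1"] in self.beta1
            and hp.get("resampling", "smote") in self.resampling
        )


def hyperparameter_space(representation: str) -> HyperparameterSpace:
    """The search grid for one representation."""
    if representation == "avg_psth":
        return HyperparameterSpace(
            hidden_nodes=_grid(30, 300, 50),
            learning_rate=(1e-5, 1e-4, 1e-3, 1e-2, 1e-1),
            batch_size=_grid(50, 600, 50),
            alpha_l2=(1e-4, 1e-3, 1e-2, 1e-1, 1.0),
        )
    if representation == "isi_dist":
        return HyperparameterSpace(
            hidden_nodes=_grid(50, 600, 50),
            learning_rate=(1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2, 1e-1),
            batch_size=_grid(25, 500, 50),
            alpha_l2=(1e-4, 1e-3, 1e-2, 1e-1, 1.0, 5.0, 10.0),
        )
    if representation in ("cat_psth", "metrics14"):
        return HyperparameterSpace(
            hidden_nodes=_grid(50, 600, 50),
            learning_rate=(1e-5, 1e-4, 1e-3, 1e-2, 1e-1),
            batch_size=_grid(50, 600, 50),
            alpha_l2=(1e-4, 1e-3, 1e-2, 1e-1, 1.0),
        )
    raise ValueError(f"unknown representation {representation!r}")


def tune_hyperparameters(
    space: HyperparameterSpace,
    X_train, y_train, X_val, y_val,
    budget: int = 25,
    seed: int = 0,
    strategy: str = "random",
    model_factory=None,
    max_epochs: int = 60,
) -> tuple[dict, pd.DataFrame]:
    """Search ``space`` for the point maximizing validation balanced accuracy.

    ``strategy='random'`` draws ``budget`` iid points from the grids;
    ``strategy='exhaustive'`` evaluates every point (small grids only).
    Returns the best point and the full trial log.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    if strategy == "random":
        points = [space.sample(rng) for _ in range(budget)]
    elif strategy == "exhaustive":
        points = list(space.all_points())
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    if model_factory is None:
        def model_factory(hp, trial_seed):
            return SpikeTrainMLP(max_epochs=max_epochs, seed=trial_seed, **hp)
    trials = []
    best_hp, best_score = None, -np.inf
    for t, hp in enumerate(points):
        trial_seed = int(rng.integers(2**31 - 1))
        try:
            model = model_factory(hp, trial_seed)
            model.fit(X_train, y_train, X_val=X_val, y_val=y_val)
            score = balanced_accuracy(y_val, model.predict(X_val))
        except RuntimeError:  # divergence under an extreme learning rate
            score = -np.inf
        trials.append({**hp, "trial": t, "objective": score})
        if score > best_score:
            best_hp, best_score = hp, score
    return best_hp, pd.DataFrame(trials)


# ---------------------------------------------------------------------------
# thin functional wrappers
# ---------------------------------------------------------------------------

def train_logistic(X, y, **kwargs) -> BalancedLogisticRegression:
    return BalancedLogisticRegression(**kwargs).fit(X, y)


def train_mlp(X, y, hp: dict | None = None, seed: int = 0,
              X_val=None, y_val=None, **kwargs) -> SpikeTrainMLP:
    model = SpikeTrainMLP(seed=seed, **(hp or {}), **kwargs)
    return model.fit(X, y, X_val=X_val, y_val=y_val)
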