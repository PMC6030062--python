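"""Scikit-learn style estimators wrapping the functional core.

* :class:`GammaPoissonMixture` — unsupervised batch-EM fit of the full
  Gamma-Poisson mixture; ``predict_proba`` returns exact class posteriors.
* :class:`GammaPoissonCircuit` — the online-learning neural circuit
  (Hebbian + intrinsic plasticity + copy weights); ``predict_proba`` returns
  soft-WTA responsibilities and :meth:`intensity` the stress readout.
* :class:`LabelMapClassifier` — the supervised responsibility-to-label
  Bayesian classifier used in semi-supervised evaluation.
* :class:`ShapeNormalizer` / :class:`BrightnessPreservingNormalizer` —
  stateless/statful preprocessing transformers composable in pipelines.

All estimators follow the ``fit`` / ``predict`` / ``get_params`` protocol,
validate inputs, and expose fitted state through trailing-underscore
attributes, so they compose with ``sklearn.pipeline`` and model selection.
"""

from __future__ import annotations

import numpy as np
from numpy.typing import ArrayLike, NDArray
from sklearn.base import BaseEstimator, ClassifierMixin, DensityMixin, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import plasticity
from .circuit import CircuitParams, responsibilities
from .datagen import PreprocConfig, normalize_shape_only
from .model import (
    Dataset,
    GammaPoissonParams,
    class_posterior_batch,
    log_marginal_likelihood,
    sample_dataset,
)
from .stress import fit_label_map, classify as _classify_s

__all__ = [
    "GammaPoissonMixture",
    "GammaPoissonCircuit",
    "LabelMapClassifier",
    "ShapeNormalizer",
    "BrightnessPreservingNormalizer",
]


def _as_Y(X) -> NDArray[np.float64]:
    Y = check_array(X, dtype=float, ensure_min_samples=1)
    if np.any(Y < 0):
        raise ValueError("stimuli must be non-negative")
    return Y


class GammaPoissonMixture(DensityMixin, BaseEstimator):
    """Gamma-Poisson mixture fitted by batch expectation-maximization.

    Each mixture component is a class prototype ``W_c`` (non-negative, sums
    to one) scaled by a ``Gamma(alpha_c, beta_c)`` intensity, with Poisson
    observation noise.  The E-step uses the closed-form class posterior; the
    M-step updates prototypes and mean intensities in closed form and the
    Gamma shape/rate by weighted method of moments on brightness.

    Parameters
    ----------
    n_classes : number of mixture components.
    max_iter, tol : EM iteration budget and relative-change stopping rule.
    n_init : EM restarts; the first spreads components over brightness
        quantiles, the rest use random stimuli, best likelihood wins.
    random_state : seed for the datapoint initializations.

    Attributes
    ----------
    params_ : fitted :class:`GammaPoissonParams`.
    W_, alpha_, beta_, prior_, lambda_ : views of the fitted parameters.
    n_iter_, log_likelihood_ : iterations run and log-marginal trace.
    """

    def __init__(self, n_classes: int = 2, max_iter: int = 200,
                 tol: float = 1e-9, n_init: int = 3,
                 random_state: int | None = 0):
        self.n_classes = n_classes
        self.max_iter = max_iter
        self.tol = tol
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None) -> "GammaPoissonMixture":
        Y = _as_Y(X)
        if Y.shape[0] < self.n_classes:
            raise ValueError("need at least one stimulus per component")
        seed = 0 if self.random_state is None else self.random_state
        params, trace = plasticity.batch_em(
            Y, self.n_classes, n_iter=self.max_iter, tol=self.tol, seed=seed,
            n_init=self.n_init)
        self.params_ = params
        self.n_iter_ = len(trace)
        self.log_likelihood_ = trace
        self.n_features_in_ = Y.shape[1]
        return self

    # fitted views -------------------------------------------------------
    @property
    def W_(self):
        return self.params_.W

    @property
    def alpha_(self):
        return self.params_.alpha

    @property
    def beta_(self):
        return self.params_.beta

    @property
    def prior_(self):
        return self.params_.prior

    @property
    def lambda_(self):
        return self.params_.lam

    def predict_proba(self, X) -> NDArray[np.float64]:
        check_is_fitted(self, "params_")
        return class_posterior_batch(_as_Y(X), self.params_)

    def predict(self, X) -> NDArray[np.int64]:
        """Most probable component per stimulus, 0-based, lowest index on ties."""
        return self.predict_proba(X).argmax(axis=1)

    def intensity(self, X) -> NDArray[np.float64]:
        """Posterior-mean intensity per stimulus."""
        check_is_fitted(self, "params_")
        Y = _as_Y(X)
        S = class_posterior_batch(Y, self.params_)
        yhat = Y.sum(axis=1)
        zc = (self.params_.alpha[None, :] + yhat[:, None]) / (self.params_.beta[None, :] + 1.0)
        return (S * zc).sum(axis=1)

    def score(self, X, y=None) -> float:
        """Mean log marginal likelihood per stimulus."""
        check_is_fitted(self, "params_")
        Y = _as_Y(X)
        return log_marginal_likelihood(Y, self.params_) / Y.shape[0]

    def sample(self, n: int, seed: int | None = None) -> Dataset:
        check_is_fitted(self, "params_")
        return sample_dataset(self.params_, n, seed=seed)


class GammaPoissonCircuit(BaseEstimator):
    """Online-learning soft-WTA circuit with Hebbian and intrinsic plasticity.

    Learns synapses ``W_``, excitabilities ``lam_`` and readout copy weights
    ``V_`` from unlabeled count stimuli by per-stimulus updates gated by
    soft-WTA responsibilities.  ``clamp_lambda`` freezes all excitabilities
    at a shared constant, turning the model into the shape-only control
    circuit that ignores brightness.

    Attributes after ``fit``: ``circuit_`` (:class:`CircuitParams`), views
    ``W_``, ``lam_``, ``V_``, ``beta_shared_``, ``K_``, and a per-epoch
    diagnostics table ``history_``.
    """

    def __init__(self, n_classes: int = 2, eps_w: float = 1e-5,
                 eps_lambda: float = 1e-4, eps_v: float = 1e-3,
                 epochs: int = 10, init_mode: str = "datapoint",
                 lambda_init: object = "datapoint", current_mode: str = "log",
                 shuffle_each_epoch: bool = True,
                 clamp_lambda: float | None = None,
                 random_state: int | None = 0):
        self.n_classes = n_classes
        self.eps_w = eps_w
        self.eps_lambda = eps_lambda
        self.eps_v = eps_v
        self.epochs = epochs
        self.init_mode = init_mode
        self.lambda_init = lambda_init
        self.current_mode = current_mode
        self.shuffle_each_epoch = shuffle_each_epoch
        self.clamp_lambda = clamp_lambda
        self.random_state = random_state

    def _config(self) -> plasticity.LearningConfig:
        return plasticity.LearningConfig(
            eps_W=self.eps_w, eps_lambda=self.eps_lambda, eps_V=self.eps_v,
            epochs=self.epochs, seed=0 if self.random_state is None else self.random_state,
            init_mode=self.init_mode, lambda_init=self.lambda_init,
            current_mode=self.current_mode,
            shuffle_each_epoch=self.shuffle_each_epoch,
            clamp_lambda=self.clamp_lambda,
        )

    def fit(self, X, y=None) -> "GammaPoissonCircuit":
        Y = _as_Y(X)
        state, history = plasticity.train(Y, self.n_classes, self._config())
        self.circuit_ = state
        self.history_ = history
        self.n_features_in_ = Y.shape[1]
        return self

    @property
    def W_(self):
        return self.circuit_.W

    @property
    def lam_(self):
        return self.circuit_.lam

    @property
    def V_(self):
        return self.circuit_.V

    @property
    def beta_shared_(self):
        return self.circuit_.beta_shared

    @property
    def K_(self):
        return self.circuit_.K

    def predict_proba(self, X) -> NDArray[np.float64]:
        check_is_fitted(self, "circuit_")
        return responsibilities(_as_Y(X), self.circuit_, self.current_mode)

    def predict(self, X) -> NDArray[np.int64]:
        """Winning class neuron per stimulus, 0-based, lowest index on ties."""
        return self.predict_proba(X).argmax(axis=1)

    def transform(self, X) -> NDArray[np.float64]:
        """Responsibility vectors, usable as features downstream."""
        return self.predict_proba(X)

    def intensity(self, X) -> NDArray[np.float64]:
        """Second-layer stress readout ``K (yhat - sum_c s_c V_c)`` per stimulus."""
        check_is_fitted(self, "circuit_")
        Y = _as_Y(X)
        S = self.predict_proba(Y)
        return self.circuit_.K * (Y.sum(axis=1) - S @ self.circuit_.V)


class LabelMapClassifier(ClassifierMixin, BaseEstimator):
    """Bayesian classifier on class-neuron responsibilities.

    ``fit`` receives responsibility vectors with labels and estimates the
    column-stochastic conditional P(label | neuron) with Laplace smoothing;
    ``predict_proba`` mixes the columns with the responsibilities.
    """

    def __init__(self, smoothing: float = 1e-6):
        self.smoothing = smoothing

    def fit(self, X, y) -> "LabelMapClassifier":
        S = check_array(X, dtype=float)
        self.label_map_ = fit_label_map(S, np.asarray(y), self.smoothing)
        self.classes_ = self.label_map_.label_values
        self.n_features_in_ = S.shape[1]
        return self

    def predict_proba(self, X) -> NDArray[np.float64]:
        check_is_fitted(self, "label_map_")
        return np.atleast_2d(_classify_s(check_array(X, dtype=float), self.label_map_))

    def predict(self, X):
        return self.classes_[self.predict_proba(X).argmax(axis=1)]


class ShapeNormalizer(TransformerMixin, BaseEstimator):
    """Stateless transformer applying the shape-only normalization: every
    image mapped to total mass ``A`` with an all-ones background."""

    def __init__(self, A: float = 500.0, D: int = 400):
        self.A = A
        self.D = D

    def fit(self, X, y=None):
        self.n_features_in_ = check_array(X, dtype=float).shape[1]
        return self

    def transform(self, X) -> NDArray[np.float64]:
        X = check_array(X, dtype=float)
        return normalize_shape_only(X, PreprocConfig(A=self.A, D=self.D))


class BrightnessPreservingNormalizer(TransformerMixin, BaseEstimator):
    """Normalization that preserves relative brightness.

    ``fit`` records the mean raw brightness of the training batch;``transform``
    scales each image's foreground by its brightness relative to that mean,
    so class-specific brightness structure survives the normalization.
    """

    def __init__(self, A: float = 450.0, D: int = 400):
        self.A = A
        self.D = D

    def fit(self, X, y=None):
        X = check_array(X, dtype=float)
        self.mean_brightness_ = float(X.sum(axis=1).mean())
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> NDArray[np.float64]:
        check_is_fitted(self, "mean_brightness_")
        X = check_array(X, dtype=float)
        cfg = PreprocConfig(A=self.A, D=self.D)
        y_sa = normalize_shape_only(X, cfg)
        f = X.sum(axis=1) / self.mean_brightness_
        return (y_sa - 1.0) * f[:, None] + 1.0
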