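"""Gamma-Poisson class/intensity generative model and exact inference.

The generative process for a stimulus ``y`` (a non-negative count vector of
dimension ``D``) is

1. draw a class ``c`` from the categorical prior ``P(c)``,
2. draw an intensity ``z ~ Gamma(alpha_c, rate=beta_c)``,
3. draw each element independently ``y_d ~ Poisson(z * W_cd)``,

where row ``W_c`` of the feature matrix is a non-negative prototype summing
to one.  Because the rows of ``W`` are normalized, the total brightness
``yhat = sum_d y_d`` is marginally negative-binomial,
``NB(yhat; alpha_c, 1/(beta_c+1))``, and the joint posterior over ``(c, z)``
is available in closed form: a categorical over classes times a conjugate
``Gamma(alpha_c + yhat, beta_c + 1)`` intensity posterior per class.

All likelihood computations are done in log space so inference stays finite
for brightnesses up to at least 1e6.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.special import gammaln, logsumexp

__all__ = [
    "W_FLOOR",
    "GammaPoissonParams",
    "Dataset",
    "PosteriorResult",
    "sample_dataset",
    "nb_log_pmf",
    "joint_posterior",
    "class_posterior",
    "posterior_mean_intensity",
    "log_marginal_likelihood",
]

#: Floor applied to feature entries before taking logarithms, so that a
#: stimulus with energy in a pixel where some class has zero weight yields a
#: very unlikely -- not NaN -- posterior for that class.
W_FLOOR = 1e-12


def _floor_and_renormalize(W: NDArray[np.float64]) -> NDArray[np.float64]:
    """Clip feature entries to ``W_FLOOR`` and renormalize each row to sum 1."""
    W = np.clip(np.asarray(W, dtype=float), W_FLOOR, None)
    return W / W.sum(axis=1, keepdims=True)


@dataclass
class GammaPoissonParams:
    """Full parameters of the Gamma-Poisson mixture.

    Parameters
    ----------
    W : (C, D) array
        Non-negative class feature prototypes; each row sums to one.
    alpha, beta : (C,) arrays
        Shape and rate of the class-specific Gamma intensity distributions.
    prior : (C,) array, optional
        Class prior on the simplex.  Defaults to uniform: the marginal class
        posterior contains no explicit prior term, so a uniform prior
        reproduces it exactly, while a non-uniform prior enters as an
        additive log term.
    """

    W: NDArray[np.float64]
    alpha: NDArray[np.float64]
    beta: NDArray[np.float64]
    prior: NDArray[np.float64] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        C = self.W.shape[0]
        if self.prior is None:
            self.prior = np.full(C, 1.0 / C)
        self.prior = np.atleast_1d(np.asarray(self.prior, dtype=float))
        if self.alpha.shape != (C,) or self.beta.shape != (C,):
            raise ValueError("alpha and beta must have one entry per class")
        if self.prior.shape != (C,):
            raise ValueError("prior must have one entry per class")
        if np.any(self.W < 0):
            raise ValueError("W entries must be non-negative")
        if np.any(self.alpha <= 0) or np.any(self.beta <= 0):
            raise ValueError("alpha and beta must be positive")
        if np.any(self.prior < 0) or self.prior.sum() <= 0:
            raise ValueError("prior must be non-negative with positive sum")
        self.prior = self.prior / self.prior.sum()
        row_sums = self.W.sum(axis=1)
        if np.any(row_sums <= 0):
            raise ValueError("each W row needs positive mass")
        if not np.allclose(row_sums, 1.0, atol=1e-9):
            raise ValueError(
                "W rows must sum to 1 (use GammaPoissonParams.create to "
                "renormalize raw prototypes)"
            )

    @classmethod
    def create(
        cls,
        W: ArrayLike,
        alpha: ArrayLike,
        beta: ArrayLike,
        prior: ArrayLike | None = None,
    ) -> "GammaPoissonParams":
        """Build parameters from raw prototypes, renormalizing W rows."""
        W = _floor_and_renormalize(np.atleast_2d(np.asarray(W, dtype=float)))
        return cls(W=W, alpha=np.asarray(alpha, float),
                   beta=np.asarray(beta, float), prior=prior)

    @property
    def n_classes(self) -> int:
        return self.W.shape[0]

    @property
    def n_dims(self) -> int:
        return self.W.shape[1]

    @property
    def lam(self) -> NDArray[np.float64]:
        """Mean intensity per class, ``lambda_c = alpha_c / beta_c``."""
        return self.alpha / self.beta

    # -- serialization --------------------------------------------------

    def to_json(self, path) -> None:
        obj = {
            "W": self.W.tolist(),
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
            "prior": self.prior.tolist(),
            "format_version": 1,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "GammaPoissonParams":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            W=np.asarray(obj["W"], float),
            alpha=np.asarray(obj["alpha"], float),
            beta=np.asarray(obj["beta"], float),
            prior=np.asarray(obj["prior"], float),
        )


@dataclass
class Dataset:
    """A matrix of stimuli with optional labels and ground-truth latents.

    ``Y`` has one stimulus per row.  ``labels`` (observed class labels) and
    ``true_c`` / ``true_z`` (generative ground truth, filled by the sampler)
    use 1-based class indices externally; internal computations are 0-based.
    """

    Y: NDArray
    labels: NDArray | None = None
    true_z: NDArray | None = None
    true_c: NDArray | None = None

    def __post_init__(self) -> None:
        self.Y = np.atleast_2d(np.asarray(self.Y))
        if np.any(self.Y < 0):
            raise ValueError("stimuli must be non-negative")
        for name in ("labels", "true_z", "true_c"):
            val = getattr(self, name)
            if val is not None:
                val = np.asarray(val)
                if val.shape != (self.Y.shape[0],):
                    raise ValueError(f"{name} must have one entry per stimulus")
                setattr(self, name, val)

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def n_dims(self) -> int:
        return self.Y.shape[1]

    @property
    def brightness(self) -> NDArray[np.float64]:
        """Row sums ``yhat = sum_d y_d``."""
        return self.Y.sum(axis=1).astype(float)

    def subset(self, idx: ArrayLike) -> "Dataset":
        idx = np.asarray(idx)
        pick = lambda a: None if a is None else a[idx]
        return Dataset(self.Y[idx], pick(self.labels),
                       pick(self.true_z), pick(self.true_c))


@dataclass
class PosteriorResult:
    """Closed-form joint posterior over class and intensity for one stimulus.

    ``s`` is the marginal class posterior.  Conditioned on class ``c`` the
    intensity posterior is ``Gamma(z_shape[c], rate=z_rate[c])`` with
    ``z_shape[c] = alpha_c + yhat`` and ``z_rate[c] = beta_c + 1``; ``z_mean``
    is the class-marginalized posterior-mean intensity.
    """

    s: NDArray[np.float64]
    z_shape: NDArray[np.float64]
    z_rate: NDArray[np.float64]
    z_mean: float


def sample_dataset(params: GammaPoissonParams, n: int, seed: int | None = None) -> Dataset:
    """Draw ``n`` stimuli from the generative model.

    Each stimulus draws a class from the prior, an intensity from the
    class-specific Gamma, and element-wise Poisson counts with mean
    ``z * W_cd``.  The returned dataset carries ``true_c`` (1-based) and
    ``true_z``; ``labels`` is set to ``true_c`` for convenience.
    """
    if n <= 0:
        raise ValueError("n must be a positive integer")
    rng = np.random.default_rng(seed)
    c = rng.choice(params.n_classes, size=n, p=params.prior)
    z = rng.gamma(shape=params.alpha[c], scale=1.0 / params.beta[c])
    Y = rng.poisson(z[:, None] * params.W[c])
    true_c = c + 1
    return Dataset(Y=Y, labels=true_c.copy(), true_z=z, true_c=true_c)


def nb_log_pmf(k: ArrayLike, alpha: ArrayLike, beta: ArrayLike) -> NDArray[np.float64] | float:
    """Log-pmf of the brightness marginal ``NB(k; alpha, 1/(beta+1))``.

    This is the negative binomial obtained by integrating the Gamma intensity
    out of the total-count Poisson:

        NB(k) = Gamma(k+alpha) / (k! Gamma(alpha))
                * (beta/(beta+1))^alpha * (1/(beta+1))^k

    evaluated via log-gamma so it stays finite for large ``k``.  ``k`` may be
    non-integral (continuous extension through the gamma function), which is
    used for gain-scaled spectrogram data before rounding.
    """
    k = np.asarray(k, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(k < 0):
        raise ValueError("counts must be non-negative")
    log1pb = np.log1p(beta)
    out = (
        gammaln(k + alpha)
        - gammaln(k + 1.0)
        - gammaln(alpha)
        + alpha * (np.log(beta) - log1pb)
        - k * log1pb
    )
    return out if out.ndim else float(out)


def _check_stimulus(y: ArrayLike, params: GammaPoissonParams) -> NDArray[np.float64]:
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != params.n_dims:
        raise ValueError(
            f"stimulus has {y.shape[0]} dims, model expects {params.n_dims}"
        )
    if np.any(y < 0):
        raise ValueError("stimulus must be non-negative")
    return y


def _log_class_weights(Y: NDArray, params: GammaPoissonParams) -> NDArray[np.float64]:
    """Unnormalized log posterior over classes for each row of ``Y`` (N x C)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    logW = np.log(_floor_and_renormalize(params.W))
    yhat = Y.sum(axis=1)
    shape_term = Y @ logW.T
    nb_term = nb_log_pmf(yhat[:, None], params.alpha[None, :], params.beta[None, :])
    return shape_term + nb_term + np.log(params.prior)[None, :]


def joint_posterior(y: ArrayLike, params: GammaPoissonParams) -> PosteriorResult:
    """Closed-form joint posterior ``P(c, z | y)``.

    The class marginal is proportional to
    ``prior_c * prod_d W_cd^{y_d} * NB(yhat; alpha_c, 1/(beta_c+1))`` and the
    per-class intensity posterior is ``Gamma(alpha_c + yhat, beta_c + 1)``.
    """
    y = _check_stimulus(y, params)
    logw = _log_class_weights(y[None, :], params)[0]
    s = np.exp(logw - logsumexp(logw))
    s /= s.sum()
    yhat = float(y.sum())
    z_shape = params.alpha + yhat
    z_rate = params.beta + 1.0
    z_mean = float(np.dot(s, z_shape / z_rate))
    return PosteriorResult(s=s, z_shape=z_shape, z_rate=z_rate, z_mean=z_mean)


def class_posterior(y: ArrayLike, params: GammaPoissonParams) -> NDArray[np.float64]:
    """Marginal class posterior ``P(c | y)`` (the ``s`` of :func:`joint_posterior`)."""
    return joint_posterior(y, params).s


def class_posterior_batch(Y: ArrayLike, params: GammaPoissonParams) -> NDArray[np.float64]:
    """Class posteriors for every row of ``Y`` at once (N x C)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[1] != params.n_dims:
        raise ValueError("dimension mismatch")
    logw = _log_class_weights(Y, params)
    logw -= logsumexp(logw, axis=1, keepdims=True)
    S = np.exp(logw)
    return S / S.sum(axis=1, keepdims=True)


def posterior_mean_intensity(y: ArrayLike, params: GammaPoissonParams) -> float:
    """Posterior-mean intensity ``<z> = sum_c s_c (alpha_c + yhat)/(beta_c + 1)``."""
    return joint_posterior(y, params).z_mean


def log_marginal_likelihood(data: Dataset | ArrayLike, params: GammaPoissonParams) -> float:
    """Total log marginal likelihood ``sum_n log P(y^(n) | theta)``.

    Per stimulus, ``log P(y) = logsumexp_c [log prior_c + log NB(yhat) +
    sum_d y_d log W_cd] + lgamma(yhat+1) - sum_d lgamma(y_d+1)``; the last two
    terms are the multinomial coefficient of splitting ``yhat`` events over
    dimensions.  Used for monitoring EM ascent.
    """
    Y = data.Y if isinstance(data, Dataset) else np.atleast_2d(np.asarray(data))
    Y = Y.astype(float)
    logw = _log_class_weights(Y, params)
    yhat = Y.sum(axis=1)
    multinom = gammaln(yhat + 1.0) - gammaln(Y + 1.0).sum(axis=1)
    return float(np.sum(logsumexp(logw, axis=1) + multinom))
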