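"""Online Hebbian + intrinsic-plasticity learning and its batch-EM reference.

The circuit learns from unlabeled stimuli, one at a time.  After computing
the soft-WTA responsibilities ``s`` for a stimulus, each neuron updates

    dW_cd   = eps_W  * s_c * (y_d  - lam_c * W_cd)      (Hebbian)
    dlam_c  = eps_lam * s_c * (yhat - lam_c)            (intrinsic)
    dV_c    = eps_V  * s_c * (e    - V_c),  e = yhat    (copy weights)

The Hebbian rule pulls the prediction ``lam_c W_cd`` toward the input; the
intrinsic-plasticity rule tracks the mean brightness of the neuron's class
in a negative feedback loop; the copy rule drives ``V_c`` toward ``lam_c``
(during learning the second layer is clamped to the feedforward drive
``yhat``).  These rules share their fixed points with the batch-EM M-step

    lam_c = sum_n s_c yhat^(n) / sum_n s_c
    W_cd  = sum_n s_c y_d^(n) / (lam_c sum_n s_c)

so the online circuit and the exact-model EM converge to the same solutions.
EM additionally fits the full per-class Gamma shape/rate by responsibility-
weighted method of moments on brightness, which the circuit does not carry.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.typing import NDArray
from scipy.special import gammaln, logsumexp

from .circuit import CircuitParams, responsibilities
from .model import (
    Dataset,
    GammaPoissonParams,
    _floor_and_renormalize,
    class_posterior_batch,
)

__all__ = [
    "LearningConfig",
    "online_update",
    "train",
    "batch_em_step",
    "batch_em",
    "check_fixed_point",
    "FixedPointReport",
]

logger = logging.getLogger(__name__)

#: Floor keeping excitabilities and copy weights positive during learning.
PARAM_FLOOR = 1e-6

#: Near-Poisson rate used when weighted brightness moments are under-dispersed
#: (the Gamma-Poisson marginal cannot have variance below its mean).
BETA_UNDERDISPERSED = 1e3


@dataclass
class LearningConfig:
    """Hyper-parameters of the online learning loop.

    The default learning rates are the ones used for intensity-preserving
    image data (``eps_W = 1e-5``, ``eps_lambda = 1e-4``); they should be
    scaled to the brightness range and size of the dataset at hand.
    ``init_mode`` selects weight initialization from randomly chosen data
    points or from the data mean plus scaled unit-rate Poisson noise;
    ``lambda_init`` is ``"datapoint"`` (brightness of the chosen
    initialization stimuli), ``"brightness_quantiles"`` (evenly spaced
    quantiles of the data brightness, spreading the neurons over the
    observed intensity range), or a ``(lo, hi)`` tuple of a uniform range.
    """

    eps_W: float = 1e-5
    eps_lambda: float = 1e-4
    eps_V: float = 1e-3
    epochs: int = 10
    seed: int = 0
    init_mode: str = "datapoint"  # or "mean_plus_poisson_noise"
    lambda_init: object = "datapoint"  # or (lo, hi)
    current_mode: str = "log"  # or "linear"
    shuffle_each_epoch: bool = True
    clamp_lambda: float | None = None  # shape-only control: fix lam_c
    record_every: int = 1

    def __post_init__(self) -> None:
        if min(self.eps_W, self.eps_lambda, self.eps_V) < 0:
            raise ValueError("learning rates must be non-negative")
        if self.epochs < 1:
            raise ValueError("epochs must be positive")
        if self.init_mode not in ("datapoint", "mean_plus_poisson_noise"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.current_mode not in ("log", "linear"):
            raise ValueError(f"unknown current_mode {self.current_mode!r}")
        if isinstance(self.lambda_init, str):
            if self.lambda_init not in ("datapoint", "brightness_quantiles"):
                raise ValueError(f"unknown lambda_init {self.lambda_init!r}")
        else:
            lo, hi = self.lambda_init
            if not lo < hi:
                raise ValueError("uniform lambda_init requires lo < hi")


def online_update(state: CircuitParams, y: NDArray, cfg: LearningConfig) -> CircuitParams:
    """Apply the three plasticity rules for a single stimulus, returning a new state.

    Responsibilities are computed from the current state with the configured
    current form; updates are gated by them.  Excitabilities and copy weights
    are floored at a small positive value, synapses at zero; underflow is
    clamped, never fatal.
    """
    y = np.asarray(y, dtype=float).ravel()
    s = responsibilities(y[None, :], state, cfg.current_mode)[0]
    return _apply_updates(state, y, s, cfg)


def _apply_updates(state: CircuitParams, y: NDArray, s: NDArray,
                   cfg: LearningConfig) -> CircuitParams:
    yhat = y.sum()
    W = state.W + cfg.eps_W * s[:, None] * (y[None, :] - state.lam[:, None] * state.W)
    np.clip(W, 0.0, None, out=W)
    if cfg.clamp_lambda is not None:
        lam = np.full_like(state.lam, cfg.clamp_lambda)
    else:
        lam = state.lam + cfg.eps_lambda * s * (yhat - state.lam)
        np.clip(lam, PARAM_FLOOR, None, out=lam)
    V = state.V + cfg.eps_V * s * (yhat - state.V)
    np.clip(V, PARAM_FLOOR, None, out=V)
    return CircuitParams(W=W, lam=lam, V=V, beta_shared=state.beta_shared)


def _init_state(Y: NDArray, C: int, cfg: LearningConfig,
                rng: np.random.Generator) -> CircuitParams:
    N, D = Y.shape
    if cfg.init_mode == "datapoint":
        idx = rng.choice(N, size=C, replace=False)
        # unit pseudocount mirrors initializing from preprocessed stimuli with
        # all elements >= 1: a zero pixel in the chosen stimulus must not
        # hard-veto the neuron for every input with energy there
        W = _floor_and_renormalize(Y[idx].astype(float) + 1.0)
        lam_dp = Y[idx].sum(axis=1).astype(float)
    else:
        mean = Y.mean(axis=0).astype(float)
        W = np.stack([mean + 0.1 * rng.poisson(1.0, size=D) for _ in range(C)])
        W = _floor_and_renormalize(W)
        lam_dp = np.full(C, float(Y.sum(axis=1).mean()))
    if cfg.lambda_init == "datapoint":
        lam = np.maximum(lam_dp, PARAM_FLOOR)
    elif cfg.lambda_init == "brightness_quantiles":
        q = (np.arange(C) + 0.5) / C
        lam = np.maximum(np.quantile(Y.sum(axis=1), q), PARAM_FLOOR)
    else:
        lo, hi = cfg.lambda_init
        lam = rng.uniform(lo, hi, size=C)
    if cfg.clamp_lambda is not None:
        lam = np.full(C, cfg.clamp_lambda)
    V = np.full(C, max(float(Y.sum(axis=1).mean()), PARAM_FLOOR))
    return CircuitParams(W=W, lam=lam, V=V, beta_shared=1.0)


def _poisson_mixture_loglik(Y: NDArray, state: CircuitParams) -> float:
    """Log-likelihood of the Poisson-limit mixture (uniform class prior)."""
    logWlam = np.log(_floor_and_renormalize(state.W) * state.lam[:, None])
    I = Y @ logWlam.T - state.lam
    const = -gammaln(Y + 1.0).sum() - Y.shape[0] * np.log(state.W.shape[0])
    return float(logsumexp(I, axis=1).sum() + const)


def _estimate_beta_shared(Y: NDArray, S: NDArray) -> float:
    """Responsibility-weighted average of per-class method-of-moments rates.

    Per class, ``beta_c = m_c / (v_c - m_c)`` from the weighted mean and
    variance of brightness; under-dispersed classes fall back to a
    near-Poisson rate.
    """
    yhat = Y.sum(axis=1).astype(float)
    Nc = S.sum(axis=0)
    keep = Nc > 1e-8
    m = np.where(keep, S.T @ yhat / np.where(keep, Nc, 1.0), 1.0)
    v = np.array([
        float(np.dot(S[:, c], (yhat - m[c]) ** 2) / Nc[c]) if keep[c] else 0.0
        for c in range(S.shape[1])
    ])
    beta = np.where(v > m, m / np.maximum(v - m, 1e-300), BETA_UNDERDISPERSED)
    beta = np.clip(beta, 1e-8, BETA_UNDERDISPERSED)
    w = np.where(keep, Nc, 0.0)
    return float(np.dot(w, beta) / w.sum())


def train(data: Dataset | NDArray, C: int, cfg: LearningConfig
          ) -> tuple[CircuitParams, "pd.DataFrame"]:
    """Online training loop over the dataset.

    Initializes per ``cfg``, then for each epoch visits every stimulus (in a
    freshly shuffled order when ``shuffle_each_epoch``) and applies
    :func:`online_update`.  After the loop, ``beta_shared`` is estimated from
    the training data via responsibility-weighted method of moments.

    Returns the trained state and a per-epoch diagnostics table with the
    excitability of each neuron and the Poisson-limit data log-likelihood.
    """
    import pandas as pd

    Y = data.Y if isinstance(data, Dataset) else np.atleast_2d(np.asarray(data))
    Y = Y.astype(float)
    N = Y.shape[0]
    if C > N:
        raise ValueError("need at least one stimulus per class neuron")
    rng = np.random.default_rng(cfg.seed)
    state = _init_state(Y, C, cfg, rng)
    rows = []
    for epoch in range(cfg.epochs):
        order = rng.permutation(N) if cfg.shuffle_each_epoch else np.arange(N)
        for i in order:
            state = online_update(state, Y[i], cfg)
        if (epoch + 1) % cfg.record_every == 0 or epoch == cfg.epochs - 1:
            rows.append({
                "epoch": epoch + 1,
                "log_likelihood": _poisson_mixture_loglik(Y, state),
                **{f"lambda_{c + 1}": state.lam[c] for c in range(C)},
            })
    S = responsibilities(Y, state, cfg.current_mode)
    state = CircuitParams(W=state.W, lam=state.lam, V=state.V,
                          beta_shared=_estimate_beta_shared(Y, S))
    return state, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Batch EM reference
# ---------------------------------------------------------------------------

def batch_em_step(data: Dataset | NDArray, params: GammaPoissonParams,
                  rng: np.random.Generator | None = None) -> GammaPoissonParams:
    """One EM iteration on the full Gamma-Poisson model.

    E-step: exact class posteriors.  M-step: ``lam_c`` is the responsibility-
    weighted mean brightness, ``W_cd`` the weighted mean stimulus divided by
    ``lam_c`` (rows then sum to one by construction), the Gamma shape/rate
    come from weighted method of moments on brightness with an
    under-dispersion guard, and the prior is the mean responsibility.  A class
    whose total responsibility collapses below 1e-8 is reinitialized from a
    random stimulus (logged as a warning).
    """
    Y = data.Y if isinstance(data, Dataset) else np.atleast_2d(np.asarray(data))
    Y = Y.astype(float)
    N, D = Y.shape
    C = params.n_classes
    rng = np.random.default_rng(0) if rng is None else rng
    S = class_posterior_batch(Y, params)
    yhat = Y.sum(axis=1)
    Nc = S.sum(axis=0)

    W = np.empty((C, D))
    lam = np.empty(C)
    alpha = np.empty(C)
    beta = np.empty(C)
    for c in range(C):
        if Nc[c] < 1e-8:
            logger.warning("class %d collapsed; reinitializing from a random stimulus", c + 1)
            i = int(rng.integers(N))
            W[c] = _floor_and_renormalize(Y[i][None, :])[0]
            lam[c] = max(yhat[i], PARAM_FLOOR)
            beta[c] = 1.0
            alpha[c] = beta[c] * lam[c]
            Nc[c] = 1.0 / N
            continue
        m = float(np.dot(S[:, c], yhat) / Nc[c])
        v = float(np.dot(S[:, c], (yhat - m) ** 2) / Nc[c])
        lam[c] = max(m, PARAM_FLOOR)
        W[c] = (S[:, c] @ Y) / (lam[c] * Nc[c])
        if v > m:
            beta[c] = m / (v - m)
        else:
            beta[c] = BETA_UNDERDISPERSED
        alpha[c] = beta[c] * lam[c]
    W = _floor_and_renormalize(np.clip(W, 0.0, None))
    prior = Nc / Nc.sum()
    return GammaPoissonParams(W=W, alpha=alpha, beta=beta, prior=prior)


def _quantile_datapoint_init(Y: NDArray, C: int) -> GammaPoissonParams:
    """Initialize each class from the stimulus at an evenly spaced brightness
    quantile, spreading components over the observed intensity range."""
    yhat = Y.sum(axis=1)
    order = np.argsort(yhat, kind="stable")
    picks = order[((np.arange(C) + 0.5) / C * len(order)).astype(int)]
    W = _floor_and_renormalize(Y[picks] + 1.0)
    lam0 = np.maximum(yhat[picks], 1.0)
    return GammaPoissonParams(W=W, alpha=lam0, beta=np.ones(C))


def batch_em(data: Dataset | NDArray, C: int, n_iter: int = 100,
             tol: float = 1e-10, seed: int = 0,
             init_params: GammaPoissonParams | None = None,
             n_init: int = 1) -> tuple[GammaPoissonParams, list[float]]:
    """Run batch EM until convergence, optionally with restarts.

    The first initialization places one component on the stimulus at each
    evenly spaced brightness quantile; further restarts (``n_init > 1``) use
    randomly chosen stimuli, and the run with the highest final log marginal
    likelihood wins.  Convergence is declared when the relative change of
    every lambda_c and the max-abs change of W drop below ``tol``.  Returns
    the winning parameters and their log-marginal-likelihood trace.
    """
    from .model import log_marginal_likelihood

    Y = data.Y if isinstance(data, Dataset) else np.atleast_2d(np.asarray(data))
    Y = Y.astype(float)
    rng = np.random.default_rng(seed)

    def _run(init: GammaPoissonParams):
        params, trace = init, []
        for _ in range(n_iter):
            new = batch_em_step(Y, params, rng=rng)
            trace.append(log_marginal_likelihood(Y, new))
            dlam = np.max(np.abs(new.lam - params.lam) / np.maximum(params.lam, 1e-12))
            dW = np.max(np.abs(new.W - params.W))
            params = new
            if dlam < tol and dW < tol:
                break
        return params, trace

    inits: list[GammaPoissonParams] = []
    if init_params is not None:
        inits.append(init_params)
    else:
        inits.append(_quantile_datapoint_init(Y, C))
    while len(inits) < max(n_init, 1):
        idx = rng.choice(Y.shape[0], size=C, replace=False)
        inits.append(GammaPoissonParams(
            W=_floor_and_renormalize(Y[idx] + 1.0),
            alpha=np.maximum(Y[idx].sum(axis=1), 1.0), beta=np.ones(C)))

    best: tuple[GammaPoissonParams, list[float]] | None = None
    for init in inits:
        params, trace = _run(init)
        if best is None or (trace and trace[-1] > best[1][-1]):
            best = (params, trace)
    return best  # type: ignore[return-value]


@dataclass
class FixedPointReport:
    """Expected online-update magnitudes over a dataset (learning rates excluded)."""

    mean_abs_dW: NDArray[np.float64]      # per class, mean_d |mean_n s_c (y_d - lam_c W_cd)|
    mean_dlam: NDArray[np.float64]        # per class, mean_n s_c (yhat - lam_c)
    rel_dW: NDArray[np.float64]           # mean_abs_dW / (lam_c * mean row weight)
    rel_dlam: NDArray[np.float64]         # |mean_dlam| / (lam_c * mean responsibility)


def check_fixed_point(data: Dataset | NDArray,
                      state: CircuitParams | GammaPoissonParams,
                      responsibility_mode: str = "exact") -> FixedPointReport:
    """Measure how far a parameter set is from a plasticity fixed point.

    Averages the bracketed terms of the Hebbian and intrinsic updates over the
    dataset.  With ``responsibility_mode="exact"`` the gating uses the exact
    class posterior (for a :class:`CircuitParams` the implied full model has
    ``alpha_c = lam_c * beta_shared`` and shared rate); ``"circuit"`` uses the
    soft-WTA responsibilities.  At a batch-EM fixed point both averages vanish.
    """
    Y = data.Y if isinstance(data, Dataset) else np.atleast_2d(np.asarray(data))
    Y = Y.astype(float)
    if isinstance(state, GammaPoissonParams):
        model = state
        W, lam = state.W, state.lam
        circ = CircuitParams(W=W, lam=lam, beta_shared=float(np.mean(state.beta)))
    else:
        circ = state
        W, lam = state.W, state.lam
        model = GammaPoissonParams(W=_floor_and_renormalize(W),
                                   alpha=lam * state.beta_shared,
                                   beta=np.full_like(lam, state.beta_shared))
    if responsibility_mode == "exact":
        S = class_posterior_batch(Y, model)
    elif responsibility_mode == "circuit":
        S = responsibilities(Y, circ, "log")
    else:
        raise ValueError("responsibility_mode must be 'exact' or 'circuit'")
    N = Y.shape[0]
    yhat = Y.sum(axis=1)
    Nc = S.sum(axis=0)
    dW = (S.T @ Y) / N - (Nc / N)[:, None] * lam[:, None] * W
    dlam = (S.T @ yhat) / N - (Nc / N) * lam
    mean_abs_dW = np.abs(dW).mean(axis=1)
    rel_dW = mean_abs_dW / (lam * np.maximum(Nc / N, 1e-300) / W.shape[1])
    rel_dlam = np.abs(dlam) / (lam * np.maximum(Nc / N, 1e-300))
    return FixedPointReport(mean_abs_dW=mean_abs_dW, mean_dlam=dlam,
                            rel_dW=rel_dW, rel_dlam=rel_dlam)
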