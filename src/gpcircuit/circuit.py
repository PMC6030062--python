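"""Two-layer soft winner-take-all circuit approximating exact inference.

The first layer holds one neuron per class.  Neuron ``c`` receives the input
through synapses ``W_c``, carries an intrinsic excitability ``lam_c`` (the
learned mean brightness of its preferred class), and competes with its
neighbours through a softmax (soft-WTA).  In the regime where the negative
binomial brightness marginal is well approximated by a Poisson (large
``alpha_c`` at fixed ``lam_c``), the resulting activities match the exact
class posterior.

A second, linear layer reads out the stimulus intensity relative to what is
typical for the inferred class — the contrastive-stress signal
``s_z = K (yhat - sum_c s_c lam_c)`` with ``K = 1/(beta+1)``.  To keep the
readout local, a copy of each excitability is maintained in the inter-layer
weights ``V_c``, learned by Hebbian plasticity and converging to ``lam_c``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .model import GammaPoissonParams, _floor_and_renormalize

__all__ = [
    "CircuitParams",
    "currents_log",
    "currents_linear",
    "soft_wta",
    "intensity_readout",
]


@dataclass
class CircuitParams:
    """Parameters of the two-layer circuit.

    ``W`` are the first-layer synapses (rows sum to one), ``lam`` the neuron
    excitabilities, ``V`` the copy weights to the intensity readout, and
    ``beta_shared`` a single Gamma rate shared across classes (the circuit
    assumes the per-class rates are similar); ``K = 1/(beta_shared+1)``.
    """

    W: NDArray[np.float64]
    lam: NDArray[np.float64]
    V: NDArray[np.float64] = field(default=None)  # type: ignore[assignment]
    beta_shared: float = 1.0

    def __post_init__(self) -> None:
        self.W = np.atleast_2d(np.asarray(self.W, dtype=float))
        self.lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        if self.V is None:
            self.V = self.lam.copy()
        self.V = np.atleast_1d(np.asarray(self.V, dtype=float))
        C = self.W.shape[0]
        if self.lam.shape != (C,) or self.V.shape != (C,):
            raise ValueError("lam and V must have one entry per class neuron")
        if np.any(self.lam <= 0) or np.any(self.V <= 0):
            raise ValueError("excitabilities and copy weights must be positive")
        if self.beta_shared <= 0:
            raise ValueError("beta_shared must be positive")

    @property
    def n_classes(self) -> int:
        return self.W.shape[0]

    @property
    def n_dims(self) -> int:
        return self.W.shape[1]

    @property
    def K(self) -> float:
        """Readout gain ``K = 1/(beta_shared + 1)``, in (0, 1)."""
        return 1.0 / (self.beta_shared + 1.0)

    @classmethod
    def from_model(cls, params: GammaPoissonParams) -> "CircuitParams":
        """Oracle circuit: excitabilities and copies set to the true lambda_c,
        shared rate set to the prior-weighted mean of beta_c."""
        lam = params.lam
        return cls(W=params.W.copy(), lam=lam.copy(), V=lam.copy(),
                   beta_shared=float(np.dot(params.prior, params.beta)))

    def copy(self) -> "CircuitParams":
        return CircuitParams(self.W.copy(), self.lam.copy(), self.V.copy(),
                             self.beta_shared)

    def to_json(self, path) -> None:
        obj = {
            "W": self.W.tolist(),
            "lambda": self.lam.tolist(),
            "V": self.V.tolist(),
            "beta_shared": self.beta_shared,
            "format_version": 1,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "CircuitParams":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(W=np.asarray(obj["W"], float),
                   lam=np.asarray(obj["lambda"], float),
                   V=np.asarray(obj["V"], float),
                   beta_shared=float(obj["beta_shared"]))


def _check_input(y: ArrayLike, params: CircuitParams) -> NDArray[np.float64]:
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != params.n_dims:
        raise ValueError(
            f"stimulus has {y.shape[0]} dims, circuit expects {params.n_dims}"
        )
    return y


def currents_log(y: ArrayLike, params: CircuitParams) -> NDArray[np.float64]:
    """Input currents ``I_c = sum_d y_d ln(W_cd lam_c) - lam_c``.

    This is the Poisson-limit form of the exact class posterior: passing the
    currents through :func:`soft_wta` approximates ``P(c|y)`` when the
    brightness marginal is close to Poisson.
    """
    y = _check_input(y, params)
    logWlam = np.log(_floor_and_renormalize(params.W) * params.lam[:, None])
    return logWlam @ y - params.lam


def currents_linear(y: ArrayLike, params: CircuitParams) -> NDArray[np.float64]:
    """Linearized currents ``I_c = sum_d W_cd y_d + yhat log lam_c - lam_c``.

    Removes the logarithmic nonlinearity on the synapses at the cost of an
    approximation; ``lam_c`` still acts mainly as a neuron-specific threshold.
    """
    y = _check_input(y, params)
    yhat = y.sum()
    return params.W @ y + yhat * np.log(params.lam) - params.lam


def soft_wta(I: ArrayLike) -> NDArray[np.float64]:
    """Soft winner-take-all: ``s_c = exp(I_c) / sum_c' exp(I_c')``.

    Computed with max-subtraction; invariant to adding a constant to all
    currents.
    """
    I = np.asarray(I, dtype=float)
    if np.any(np.isnan(I)):
        raise ValueError("currents contain NaN")
    e = np.exp(I - I.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def responsibilities(Y: ArrayLike, params: CircuitParams,
                     current_mode: str = "log") -> NDArray[np.float64]:
    """Soft-WTA class responsibilities for every row of ``Y`` (N x C)."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if current_mode == "log":
        logWlam = np.log(_floor_and_renormalize(params.W) * params.lam[:, None])
        I = Y @ logWlam.T - params.lam
    elif current_mode == "linear":
        I = Y @ params.W.T + Y.sum(axis=1, keepdims=True) * np.log(params.lam) - params.lam
    else:
        raise ValueError("current_mode must be 'log' or 'linear'")
    return soft_wta(I)


def intensity_readout(y_hat: float, s: ArrayLike, params: CircuitParams,
                      use_copy_weights: bool = True) -> float:
    """Second-layer intensity signal ``s_z = K (yhat - sum_c s_c V_c)``.

    With ``use_copy_weights=False`` ("oracle" mode) the excitabilities
    ``lam_c`` are used directly instead of their learned copies ``V_c``; the
    copies exist precisely so the readout only needs locally available
    synaptic weights.
    """
    s = np.asarray(s, dtype=float)
    if s.shape != (params.n_classes,):
        raise ValueError("s must have one entry per class neuron")
    ref = params.V if use_copy_weights else params.lam
    return params.K * (float(y_hat) - float(np.dot(s, ref)))
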