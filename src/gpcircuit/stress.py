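"""Contrastive-stress estimators and semi-supervised evaluation.

Contrastive stress formalizes "how emphasized is this utterance relative to
what is typical for its class": the posterior-mean intensity minus the
posterior-weighted class-mean intensity,

    E = <z>_{P(z|y)} - <lam_c>_{P(c|y)}.

Four estimators are compared:

* ``E_B``  — the exact Bayes-optimal estimate under full model parameters;
* ``E_IP`` — the neural-circuit readout ``K (yhat - sum_c s_c V_c)`` with
  soft-WTA responsibilities and learned copy weights (local operations only);
* ``E_N``  — the naive estimate, brightness minus the sentence-mean
  brightness, ignoring class structure entirely;
* ``E_EN`` — the enhanced naive estimate ``yhat - <lam_c>_{P(c|y)}``, which
  knows the class-mean intensities but conflates brightness with intensity.

The module also provides the responsibility-based Bayesian classifier used
to score learned representations semi-supervised: the representation is
learned without labels, and only ``L`` labeled examples calibrate a map from
class-neuron responses to labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike, NDArray

from .circuit import CircuitParams, intensity_readout, responsibilities
from .model import Dataset, GammaPoissonParams, class_posterior_batch, joint_posterior

__all__ = [
    "SentenceResult",
    "LabelMap",
    "stress_bayes",
    "stress_circuit",
    "stress_naive",
    "stress_enhanced_naive",
    "evaluate_sentence",
    "fit_label_map",
    "classify",
]


@dataclass
class SentenceResult:
    """Per-utterance stress estimates and their RMS distances to the Bayes
    estimate.  ``predicted_class`` is 1-based."""

    predicted_class: NDArray[np.int64]
    s: NDArray[np.float64]           # circuit responsibilities, N x C
    E_B: NDArray[np.float64]
    E_IP: NDArray[np.float64]
    E_N: NDArray[np.float64]
    E_EN: NDArray[np.float64]
    rms_IP: float
    rms_N: float
    rms_EN: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "class": self.predicted_class,
            "E_B": self.E_B,
            "E_IP": self.E_IP,
            "E_N": self.E_N,
            "E_EN": self.E_EN,
        })

    def summary(self) -> dict:
        return {"rms_IP": self.rms_IP, "rms_N": self.rms_N, "rms_EN": self.rms_EN}


@dataclass
class LabelMap:
    """Column-stochastic map P(label | class neuron), labels in rows."""

    conditional: NDArray[np.float64]
    label_values: NDArray

    def __post_init__(self) -> None:
        self.conditional = np.asarray(self.conditional, dtype=float)
        col_sums = self.conditional.sum(axis=0)
        if not np.allclose(col_sums, 1.0, atol=1e-9):
            raise ValueError("conditional columns must sum to 1")


def stress_bayes(y: ArrayLike, params: GammaPoissonParams) -> float:
    """Bayes-optimal contrastive stress under the full model."""
    post = joint_posterior(y, params)
    return post.z_mean - float(np.dot(post.s, params.lam))


def stress_circuit(y: ArrayLike, circuit: CircuitParams,
                   use_copy_weights: bool = True) -> float:
    """Circuit stress readout ``E_IP``: soft-WTA responsibilities feeding the
    linear second layer with learned copy weights."""
    y = np.asarray(y, dtype=float).ravel()
    s = responsibilities(y[None, :], circuit, "log")[0]
    return intensity_readout(float(y.sum()), s, circuit,
                             use_copy_weights=use_copy_weights)


def stress_naive(sentence: Dataset | ArrayLike) -> NDArray[np.float64]:
    """Naive stress ``E_N``: brightness minus the sentence-mean brightness.
    Sums to zero over the sentence by construction."""
    Y = sentence.Y if isinstance(sentence, Dataset) else np.atleast_2d(np.asarray(sentence))
    if Y.shape[0] < 1:
        raise ValueError("sentence must contain at least one utterance")
    yhat = Y.sum(axis=1).astype(float)
    return yhat - yhat.mean()


def stress_enhanced_naive(y: ArrayLike, params: GammaPoissonParams) -> float:
    """Enhanced naive stress ``E_EN = yhat - <lam_c>_{P(c|y)}``: treats the
    brightness itself as the intensity estimate."""
    y = np.asarray(y, dtype=float).ravel()
    s = joint_posterior(y, params).s
    return float(y.sum()) - float(np.dot(s, params.lam))


def evaluate_sentence(sentence: Dataset, params: GammaPoissonParams,
                      circuit: CircuitParams) -> SentenceResult:
    """Run all four stress estimators over a sentence.

    Classification is the argmax of the circuit responsibilities (lowest
    index on ties); the three RMS values measure the distance of each
    approximate estimator from ``E_B`` across utterances.
    """
    Y = np.asarray(sentence.Y, dtype=float)
    n = Y.shape[0]
    S = responsibilities(Y, circuit, "log")
    pred = S.argmax(axis=1) + 1
    E_B = np.array([stress_bayes(Y[i], params) for i in range(n)])
    E_IP = np.array([
        intensity_readout(Y[i].sum(), S[i], circuit, use_copy_weights=True)
        for i in range(n)
    ])
    E_N = stress_naive(sentence)
    E_EN = np.array([stress_enhanced_naive(Y[i], params) for i in range(n)])
    rms = lambda a: float(np.sqrt(np.mean((a - E_B) ** 2)))
    return SentenceResult(
        predicted_class=pred, s=S, E_B=E_B, E_IP=E_IP, E_N=E_N, E_EN=E_EN,
        rms_IP=rms(E_IP), rms_N=rms(E_N), rms_EN=rms(E_EN),
    )


def fit_label_map(responses: ArrayLike, labels: ArrayLike,
                  smoothing: float = 1e-6) -> LabelMap:
    """Estimate P(label | class neuron) from labeled responsibility vectors.

    ``conditional[l, c]`` is proportional to the summed responsibility of
    neuron ``c`` over examples with label ``l`` plus a Laplace smoothing
    term, normalized per neuron (column).
    """
    S = np.atleast_2d(np.asarray(responses, dtype=float))
    labels = np.asarray(labels)
    if labels.shape != (S.shape[0],):
        raise ValueError("need one label per response vector")
    if S.shape[0] == 0:
        raise ValueError("need at least one labeled example")
    values = np.unique(labels)
    counts = np.stack([S[labels == l].sum(axis=0) for l in values])
    counts = counts + smoothing
    conditional = counts / counts.sum(axis=0, keepdims=True)
    return LabelMap(conditional=conditional, label_values=values)


def classify(s: ArrayLike, label_map: LabelMap) -> NDArray[np.float64]:
    """Label posterior ``P(l | s) ∝ sum_c conditional[l, c] s_c``.

    Accepts a single responsibility vector or a batch (rows); the argmax
    with lowest-index tie-break is the predicted label.
    """
    s = np.asarray(s, dtype=float)
    single = s.ndim == 1
    S = np.atleast_2d(s)
    if S.shape[1] != label_map.conditional.shape[1]:
        raise ValueError("responsibility dimension does not match the label map")
    P = S @ label_map.conditional.T
    P = P / P.sum(axis=1, keepdims=True)
    return P[0] if single else P


def predict_labels(responses: ArrayLike, label_map: LabelMap) -> NDArray:
    """Hard label predictions from responsibility vectors."""
    P = np.atleast_2d(classify(responses, label_map))
    return label_map.label_values[P.argmax(axis=1)]


def semi_supervised_accuracy(
    train_responses: ArrayLike,
    train_labels: ArrayLike,
    test_responses: ArrayLike,
    test_labels: ArrayLike,
    n_labeled: int = 30,
    seed: int | None = None,
    smoothing: float = 1e-6,
) -> float:
    """The semi-supervised evaluation protocol for learned representations.

    Exactly ``n_labeled`` training examples (chosen at random, but covering
    every label when possible) reveal their labels to fit the label map; the
    returned number is the held-out classification accuracy.
    """
    train_responses = np.atleast_2d(np.asarray(train_responses, dtype=float))
    train_labels = np.asarray(train_labels)
    rng = np.random.default_rng(seed)
    n = train_responses.shape[0]
    if n_labeled > n:
        raise ValueError("cannot label more examples than available")
    values = np.unique(train_labels)
    chosen: list[int] = []
    if n_labeled >= len(values):
        for v in values:  # one guaranteed example per label
            chosen.append(int(rng.choice(np.flatnonzero(train_labels == v))))
    rest = np.setdiff1d(np.arange(n), np.asarray(chosen, dtype=int))
    extra = n_labeled - len(chosen)
    if extra > 0:
        chosen.extend(rng.choice(rest, size=extra, replace=False).tolist())
    idx = np.asarray(chosen[:n_labeled])
    lm = fit_label_map(train_responses[idx], train_labels[idx], smoothing)
    pred = predict_labels(test_responses, lm)
    return float(np.mean(pred == np.asarray(test_labels)))
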