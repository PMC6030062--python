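"""Independent oracles used by the test suite.

These deliberately avoid the closed-form inference code paths: the posterior
oracle integrates the unnormalized joint density on a dense intensity grid,
and the alignment helper scores a clustering against ground truth by brute
force over class permutations.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from scipy.special import gammaln

from gpcircuit.model import GammaPoissonParams


def grid_posterior(y: np.ndarray, params: GammaPoissonParams, n_points: int = 100_000):
    """Brute-force posterior over (class, intensity) on a dense z grid.

    Evaluates ``P(y|c,z) P(z|c) P(c)`` pointwise and integrates with the
    trapezoid rule.  Returns the class posterior and the posterior-mean
    intensity.
    """
    y = np.asarray(y, dtype=float)
    yhat = y.sum()
    # cover the conjugate posterior mass generously
    z_max = (params.alpha.max() + yhat) / (params.beta.min() + 1.0)
    z_max += 12.0 * np.sqrt(params.alpha.max() + yhat) / (params.beta.min() + 1.0)
    z = np.linspace(1e-9, z_max, n_points)
    logW = np.log(np.clip(params.W, 1e-12, None))
    log_joint = np.empty((params.n_classes, n_points))
    for c in range(params.n_classes):
        log_prior_z = (params.alpha[c] * np.log(params.beta[c])
                       - gammaln(params.alpha[c])
                       + (params.alpha[c] - 1.0) * np.log(z)
                       - params.beta[c] * z)
        log_lik_const = float(np.dot(y, logW[c]) - gammaln(y + 1.0).sum())
        log_lik = log_lik_const + yhat * np.log(z) - z
        log_joint[c] = log_prior_z + log_lik + np.log(params.prior[c])
    m = log_joint.max()
    f = np.exp(log_joint - m)
    mass = np.trapezoid(f, z, axis=1)
    s = mass / mass.sum()
    z_mean = float(np.trapezoid(f * z[None, :], z, axis=1).sum() / mass.sum())
    return s, z_mean


def best_permutation_match(estimated: np.ndarray, truth: np.ndarray,
                           n_classes: int):
    """Best relabeling of estimated cluster indices against 1-based truth.

    Returns ``(accuracy, perm)`` where ``perm[k]`` is the 1-based true class
    assigned to estimated cluster ``k``.
    """
    best_acc, best_perm = -1.0, None
    for perm in permutations(range(1, n_classes + 1)):
        acc = float(np.mean(np.asarray(perm)[estimated] == truth))
        if acc > best_acc:
            best_acc, best_perm = acc, perm
    return best_acc, best_perm


def align_params_to_truth(lam_est: np.ndarray, lam_true: np.ndarray):
    """Permutation of estimated classes minimizing total |lambda| mismatch."""
    C = len(lam_true)
    best_cost, best_perm = np.inf, None
    for perm in permutations(range(C)):
        cost = float(np.abs(lam_est[list(perm)] - lam_true).sum())
        if cost < best_cost:
            best_cost, best_perm = cost, list(perm)
    return best_perm
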