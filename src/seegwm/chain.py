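"""Exact inference on one-dimensional Ising chains.

A shank of N contacts carries labels ``z_i in {-1, +1}`` (-1 = gray matter,
+1 = white matter).  The prior couples neighbours through

    P(z) proportional to exp(beta * sum_i z_i z_{i+1})

so larger ``beta`` penalises gray/white transitions.  Combined with
per-contact log-likelihoods this is a two-state chain model on which the
partition function, posterior marginals and exact samples are all available
in O(N) by transfer-matrix / forward-backward recursions.  Everything here
works in log space so that couplings as large as beta ~ 50 stay finite.

State convention: axis index 0 <-> z = -1 (gray), index 1 <-> z = +1 (white).
An optional per-contact external field ``h`` contributes ``h_i * z_i`` to the
exponent; the inference prior never uses it (the field exists for the
synthetic generator only).
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "STATES",
    "ising_log_prior",
    "chain_log_partition",
    "chain_marginals",
    "chain_sample",
    "chain_log_posterior",
    "enumerate_labelings",
]

#: spin value of each state index
STATES = np.array([-1.0, 1.0])


def _pair_log_potential(beta: float) -> np.ndarray:
    """2x2 matrix M[a, b] = beta * z_a * z_b."""
    return beta * np.outer(STATES, STATES)


def _as_log_node(log_node, n: int | None) -> np.ndarray:
    if log_node is None:
        if n is None:
            raise ValueError("need log_node or n")
        return np.zeros((n, 2))
    log_node = np.asarray(log_node, dtype=float)
    if log_node.ndim != 2 or log_node.shape[1] != 2:
        raise ValueError("log_node must have shape (N, 2)")
    return log_node


def chain_log_partition(beta: float, log_node=None, n: int | None = None,
                        field=None) -> float:
    """Log partition function of the chain by transfer-matrix product.

    Parameters
    ----------
    beta : coupling strength (>= 0 for the tissue prior, any real accepted).
    log_node : (N, 2) per-contact log potentials (e.g. log-likelihoods);
        zeros give the bare prior normaliser.
    n : chain length, required when ``log_node`` is None.
    field : optional (N,) external field, adds ``field[i] * z_i``.
    """
    log_node = _as_log_node(log_node, n)
    if field is not None:
        log_node = log_node + np.outer(np.asarray(field, dtype=float), STATES)
    n = log_node.shape[0]
    if n == 0:
        raise ValueError("empty chain")
    pair = _pair_log_potential(beta)
    msg = log_node[0].copy()
    for i in range(1, n):
        msg = log_node[i] + logsumexp(msg[:, None] + pair, axis=0)
    return float(logsumexp(msg))


def ising_log_prior(labels, beta: float) -> tuple[float, float]:
    """Unnormalised log-prior of a labeling and the chain's log-partition.

    ``labels`` is a sequence over {-1, +1}.  Returns
    ``(beta * sum z_i z_{i+1}, log Z)`` so that the normalised log prior is
    their difference.
    """
    z = np.asarray(labels, dtype=float)
    if z.ndim != 1 or z.size < 1:
        raise ValueError("labels must be a non-empty 1-D sequence")
    if not np.all(np.isin(z, (-1.0, 1.0))):
        raise ValueError("labels must be -1 (gray) or +1 (white)")
    energy = float(beta * np.sum(z[:-1] * z[1:]))
    return energy, chain_log_partition(beta, n=z.size)


def _messages(beta: float, log_node: np.ndarray):
    """Forward and backward log messages (each (N, 2))."""
    n = log_node.shape[0]
    pair = _pair_log_potential(beta)
    fwd = np.empty((n, 2))
    bwd = np.empty((n, 2))
    fwd[0] = log_node[0]
    for i in range(1, n):
        fwd[i] = log_node[i] + logsumexp(fwd[i - 1][:, None] + pair, axis=0)
    bwd[n - 1] = 0.0
    for i in range(n - 2, -1, -1):
        bwd[i] = logsumexp(pair + (log_node[i + 1] + bwd[i + 1])[None, :],
                           axis=1)
    return fwd, bwd


def chain_marginals(beta: float, log_node, field=None) -> np.ndarray:
    """Exact posterior marginals P(z_i = +1) by forward-backward.

    ``log_node[i, k]`` is the log-likelihood of contact ``i`` under state
    ``k`` (0 = gray, 1 = white).  O(N); matches brute-force enumeration.
    """
    log_node = _as_log_node(log_node, None)
    if field is not None:
        log_node = log_node + np.outer(np.asarray(field, dtype=float), STATES)
    fwd, bwd = _messages(beta, log_node)
    log_marg = fwd + bwd
    log_marg -= logsumexp(log_marg, axis=1, keepdims=True)
    return np.exp(log_marg[:, 1])


def chain_log_posterior(labels, beta: float, log_node) -> float:
    """Normalised log posterior probability of one full labeling."""
    z = np.asarray(labels)
    log_node = _as_log_node(log_node, None)
    if z.size != log_node.shape[0]:
        raise ValueError("labels and log_node lengths differ")
    idx = (z > 0).astype(int)
    joint = float(beta * np.sum(z[:-1] * z[1:])
                  + log_node[np.arange(z.size), idx].sum())
    return joint - chain_log_partition(beta, log_node)


def chain_sample(beta: float, n: int, rng: np.random.Generator,
                 field=None, log_node=None) -> np.ndarray:
    """Draw one exact labeling from the chain distribution.

    Backward messages give the forward conditionals
    P(z_i | z_{i-1}), which are sampled left to right; the draw is exact,
    not MCMC.  Returns an (n,) array over {-1, +1}.
    """
    log_node = _as_log_node(log_node, n)
    if field is not None:
        log_node = log_node + np.outer(np.asarray(field, dtype=float), STATES)
    n = log_node.shape[0]
    pair = _pair_log_potential(beta)
    _, bwd = _messages(beta, log_node)
    z_idx = np.empty(n, dtype=int)
    logits = log_node[0] + bwd[0]
    p = np.exp(logits - logsumexp(logits))
    z_idx[0] = rng.random() < p[1]
    for i in range(1, n):
        logits = pair[z_idx[i - 1]] + log_node[i] + bwd[i]
        p = np.exp(logits - logsumexp(logits))
        z_idx[i] = rng.random() < p[1]
    return STATES[z_idx].copy()


def enumerate_labelings(n: int) -> np.ndarray:
    """All 2^n labelings over {-1, +1}, shape (2^n, n).  Brute-force helper."""
    if n < 1 or n > 20:
        raise ValueError("n out of enumerable range")
    grid = np.indices((2,) * n).reshape(n, -1).T
    return STATES[grid]
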