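"""Bayesian white/gray-matter classifier for SEEG contact chains.

The generative model, per electrode shank of N contacts:

* labels ``z in {-1, +1}^N`` follow a one-dimensional Ising-type prior
  ``P(z) prop. exp(beta * sum_i z_i z_{i+1})`` with no external field, so
  gray/white transitions are penalised but neither class is favoured a
  priori;
* given its label, each contact's 2-D feature vector ``x_i = (s_i, d_i)``
  (relative log-power shift, depth) is independent with class-conditional
  density a Gaussian-kernel KDE over the training contacts of that class,
  kernel widths ``alpha_c = (alpha_c1, alpha_c2)``.

The likelihood of a contact integrates the KDE over a depth interval
running from halfway to the previous contact position to halfway to the
next (closed-form Gaussian-CDF differences per kernel), so irregular
contact spacing rescales the density automatically.  Per-contact marginals
P(z_i = white) sum the posterior over all labelings of the other contacts;
on a chain this is exact forward-backward message passing.

The free hyperparameters (alpha_wm1, alpha_gm1, beta) get diffuse
exponential hyperpriors; their posterior is evaluated on a log-spaced
positive grid (leave-one-point-out KDE likelihood for the kernel widths,
normalised Ising probability of the observed labelings for beta), then
moment-matched by a positive-orthant truncated Gaussian.  Predictions
average the exact marginals over draws from that truncated Gaussian — the
posterior predictive, 100 samples by default.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import log_ndtr, logsumexp
from scipy.stats import truncnorm

from .chain import chain_log_posterior, chain_marginals
from .features import ShankRecord

logger = logging.getLogger(__name__)

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)
_LOG_FLOOR = -1e6          # stands in for -inf likelihoods; keeps chains finite

PARAM_NAMES = ("alpha_wm1", "alpha_gm1", "beta")

DEFAULT_ALPHA2 = (1.0, 1.0)       # (wm, gm): one inter-contact spacing
DEFAULT_HYPER_RATE = 0.01         # diffuse exponential hyperprior
DEFAULT_N_SAMPLES = 100           # posterior-predictive draws

ALPHA_GRID_RANGE = (0.01, 2.0)
BETA_GRID_RANGE = (0.01, 30.0)
DEFAULT_GRID_POINTS = 40


def _log_ndtr_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """log(Phi(b) - Phi(a)) for a < b, stable far into either tail."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    # reflect so the interval midpoint is <= 0, then work off log_ndtr(b)
    with np.errstate(invalid="ignore"):
        flip = (a + b) > 0          # (-inf, inf) stays unflipped; symmetric
    a_, b_ = np.where(flip, -b, a), np.where(flip, -a, b)
    la, lb = log_ndtr(a_), log_ndtr(b_)
    with np.errstate(divide="ignore"):
        out = lb + np.log1p(-np.exp(np.minimum(la - lb, -1e-300)))
    return out


@dataclass
class ModelParameters:
    """Kernel widths per class/dimension and the chain coupling beta."""

    alpha1: tuple[float, float]       # (wm, gm), feature-1 (log-power) units
    alpha2: tuple[float, float]       # (wm, gm), depth units
    beta: float                       # dimensionless, >= 0

    def __post_init__(self) -> None:
        vals = (*self.alpha1, *self.alpha2)
        if any(v <= 0 for v in vals):
            raise ValueError("kernel widths must be positive")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass
class ClassDensity:
    """Gaussian-kernel density of one tissue class in (s, depth) space."""

    points: np.ndarray                # (M, 2) training features
    alpha: tuple[float, float]        # kernel widths (feature-1, depth)
    tag: str = ""                     # "wm" | "gm"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[1] != 2 or self.points.shape[0] == 0:
            raise ValueError("points must be a non-empty (M, 2) array")
        if self.alpha[0] <= 0 or self.alpha[1] <= 0:
            raise ValueError("kernel widths must be positive")

    def log_density(self, s, d) -> np.ndarray:
        """Plain 2-D KDE log-density at feature points (s, d)."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        d = np.atleast_1d(np.asarray(d, dtype=float))
        a1, a2 = self.alpha
        z1 = (s[:, None] - self.points[None, :, 0]) / a1
        z2 = (d[:, None] - self.points[None, :, 1]) / a2
        logk = (-0.5 * z1 ** 2 - np.log(a1) - _LOG_SQRT_2PI
                - 0.5 * z2 ** 2 - np.log(a2) - _LOG_SQRT_2PI)
        return logsumexp(logk, axis=1) - np.log(self.points.shape[0])

    def log_likelihood(self, s, intervals) -> np.ndarray:
        """Log-likelihood of contacts: KDE at ``s``, integrated over depth.

        ``intervals`` is (N, 2) with rows [lo, hi]; each Gaussian kernel
        contributes pdf(s) * (Phi(hi) - Phi(lo)) in closed form.  Rows with
        lo = -inf, hi = +inf marginalise depth away exactly.
        """
        s = np.atleast_1d(np.asarray(s, dtype=float))
        intervals = np.atleast_2d(np.asarray(intervals, dtype=float))
        if intervals.shape != (s.size, 2):
            raise ValueError("intervals must be (N, 2)")
        if np.any(intervals[:, 0] >= intervals[:, 1]):
            raise ValueError("empty or inverted depth interval")
        a1, a2 = self.alpha
        z1 = (s[:, None] - self.points[None, :, 0]) / a1
        lo = (intervals[:, :1] - self.points[None, :, 1]) / a2
        hi = (intervals[:, 1:] - self.points[None, :, 1]) / a2
        logk = (-0.5 * z1 ** 2 - np.log(a1) - _LOG_SQRT_2PI
                + _log_ndtr_diff(lo, hi))
        return logsumexp(logk, axis=1) - np.log(self.points.shape[0])


def contact_log_likelihood(density: ClassDensity, s: float,
                           depth_interval) -> float:
    """Likelihood of a single contact under one class (scalar wrapper)."""
    return float(density.log_likelihood([s], [depth_interval])[0])


def class_points(records: list[ShankRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Pool labeled training contacts into (gm_points, wm_points)."""
    gm, wm = [], []
    for rec in records:
        if rec.labels is None:
            continue
        pts = np.column_stack([rec.s, rec.depth])
        gm.append(pts[rec.labels < 0])
        wm.append(pts[rec.labels > 0])
    gm_pts = np.vstack(gm) if gm else np.empty((0, 2))
    wm_pts = np.vstack(wm) if wm else np.empty((0, 2))
    return gm_pts, wm_pts


def class_densities(train_records: list[ShankRecord],
                    params: ModelParameters) -> tuple[ClassDensity, ClassDensity]:
    """Build the (gm, wm) class densities from labeled training shanks."""
    gm_pts, wm_pts = class_points(train_records)
    if len(gm_pts) == 0 or len(wm_pts) == 0:
        raise ValueError("training set must contain both tissue classes")
    gm = ClassDensity(gm_pts, (params.alpha1[1], params.alpha2[1]), "gm")
    wm = ClassDensity(wm_pts, (params.alpha1[0], params.alpha2[0]), "wm")
    return gm, wm


def shank_log_node(record: ShankRecord, gm: ClassDensity,
                   wm: ClassDensity) -> np.ndarray:
    """(N, 2) per-contact class log-likelihoods (column 0 gray, 1 white)."""
    iv = record.depth_intervals
    node = np.column_stack([gm.log_likelihood(record.s, iv),
                            wm.log_likelihood(record.s, iv)])
    return np.maximum(node, _LOG_FLOOR)


def shank_log_posterior(record: ShankRecord, labels, params: ModelParameters,
                        gm: ClassDensity, wm: ClassDensity) -> float:
    """Normalised log posterior of one full labeling of a shank."""
    labels = np.asarray(labels, dtype=float)
    if labels.size != len(record):
        raise ValueError("labels and shank length differ")
    node = shank_log_node(record, gm, wm)
    return chain_log_posterior(labels, params.beta, node)


def marginal_probabilities(record: ShankRecord, params: ModelParameters,
                           gm: ClassDensity, wm: ClassDensity) -> np.ndarray:
    """Exact per-contact P(z_i = white) by forward-backward on the chain."""
    return chain_marginals(params.beta, shank_log_node(record, gm, wm))


# ---------------------------------------------------------------------------
# Hyperparameter posterior
# ---------------------------------------------------------------------------

@dataclass
class ParameterPosterior:
    """Truncated-Gaussian approximation to p(alpha_wm1, alpha_gm1, beta | D).

    The three parameters touch disjoint likelihood terms, so the posterior
    factorises and the Gaussian has diagonal covariance.  Samples are
    rejected into the positive orthant.
    """

    mean: np.ndarray                  # (3,) ordered as PARAM_NAMES
    sd: np.ndarray                    # (3,) posterior standard deviations
    alpha2: tuple[float, float] = DEFAULT_ALPHA2
    hyper_rate: float = DEFAULT_HYPER_RATE
    names: tuple[str, ...] = PARAM_NAMES

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.mean.shape != (3,) or self.sd.shape != (3,):
            raise ValueError("mean and sd must have shape (3,)")
        if np.any(self.mean <= 0) or np.any(self.sd < 0):
            raise ValueError("posterior means must be positive, sds >= 0")

    @property
    def cov(self) -> np.ndarray:
        return np.diag(self.sd ** 2)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw n positive parameter vectors (rejection on positivity)."""
        if np.all(self.sd == 0):
            return np.tile(self.mean, (n, 1))
        out = np.empty((n, 3))
        got, tried = 0, 0
        while got < n:
            m = max(n - got, 64)
            draw = rng.normal(self.mean, self.sd, size=(m, 3))
            draw = draw[np.all(draw > 0, axis=1)]
            tried += m
            take = min(len(draw), n - got)
            out[got:got + take] = draw[:take]
            got += take
            if tried >= 100 * n and got < max(1, tried // 100):
                warnings.warn("truncated-Gaussian rejection rate > 99%; "
                              "falling back to coordinate-wise sampling",
                              stacklevel=2)
                for j in range(3):
                    if self.sd[j] == 0:
                        out[:, j] = self.mean[j]
                    else:
                        a = -self.mean[j] / self.sd[j]
                        out[:, j] = truncnorm.rvs(
                            a, np.inf, loc=self.mean[j], scale=self.sd[j],
                            size=n, random_state=rng)
                return out
        return out

    def mean_parameters(self) -> ModelParameters:
        return ModelParameters(alpha1=(self.mean[0], self.mean[1]),
                               alpha2=self.alpha2, beta=self.mean[2])


def loo_kde_log_likelihood(points: np.ndarray, a1: float, a2: float) -> float:
    """Leave-one-point-out KDE log-likelihood of one class's features.

    Each training point's density is evaluated from the other M-1 points;
    this removes the degenerate width->0 optimum of the plain in-sample
    likelihood.
    """
    pts = np.atleast_2d(points)
    m = pts.shape[0]
    if m < 2:
        raise ValueError("need at least 2 points per class")
    z1 = (pts[:, None, 0] - pts[None, :, 0]) / a1
    z2 = (pts[:, None, 1] - pts[None, :, 1]) / a2
    logk = (-0.5 * (z1 ** 2 + z2 ** 2)
            - np.log(a1) - np.log(a2) - 2 * _LOG_SQRT_2PI)
    np.fill_diagonal(logk, -np.inf)
    return float(np.sum(logsumexp(logk, axis=1) - np.log(m - 1)))


def _beta_log_likelihood(records: list[ShankRecord],
                         beta_grid: np.ndarray) -> np.ndarray:
    """Sum over shanks of the normalised Ising log-prob of the labeling.

    For a uniform chain the log-partition has the closed form
    log Z = log 2 + (N-1) log(2 cosh beta), equal to the transfer-matrix
    product.
    """
    agree = np.array([float(np.sum(r.labels[:-1] * r.labels[1:]))
                      for r in records])
    nm1 = np.array([len(r) - 1 for r in records], dtype=float)
    b = beta_grid[:, None]
    log_z = np.log(2.0) + nm1[None, :] * np.logaddexp(b, -b)
    return np.sum(b * agree[None, :] - log_z, axis=1)


def _grid_posterior_moments(grid: np.ndarray, loglik: np.ndarray,
                            rate: float) -> tuple[float, float]:
    logpost = loglik + np.log(rate) - rate * grid
    w = np.exp(logpost - logsumexp(logpost))
    mean = float(np.sum(w * grid))
    var = float(np.sum(w * (grid - mean) ** 2))
    return mean, np.sqrt(var)


def fit_parameter_posterior(train_records: list[ShankRecord],
                            alpha2: tuple[float, float] = DEFAULT_ALPHA2,
                            hyper_rate: float = DEFAULT_HYPER_RATE,
                            grid_points: int = DEFAULT_GRID_POINTS,
                            alpha_grid: np.ndarray | None = None,
                            beta_grid: np.ndarray | None = None,
                            ) -> ParameterPosterior:
    """Grid posterior over (alpha_wm1, alpha_gm1, beta), moment-matched.

    The kernel-width likelihood is the leave-one-point-out KDE likelihood
    of each class's pooled training features (depth width fixed at
    ``alpha2``); the beta likelihood is the product over training shanks of
    the normalised chain-prior probability of the observed labeling.  Each
    factor carries an exponential(``hyper_rate``) hyperprior.
    """
    labeled = [r for r in train_records if r.labels is not None]
    if not labeled:
        raise ValueError("no labeled training shanks")
    gm_pts, wm_pts = class_points(labeled)
    if len(gm_pts) < 2 or len(wm_pts) < 2:
        raise ValueError("training set must contain both tissue classes")
    if alpha_grid is None:
        alpha_grid = np.geomspace(*ALPHA_GRID_RANGE, grid_points)
    if beta_grid is None:
        beta_grid = np.geomspace(*BETA_GRID_RANGE, grid_points)

    ll_wm = np.array([loo_kde_log_likelihood(wm_pts, a, alpha2[0])
                      for a in alpha_grid])
    ll_gm = np.array([loo_kde_log_likelihood(gm_pts, a, alpha2[1])
                      for a in alpha_grid])
    ll_beta = _beta_log_likelihood(labeled, beta_grid)

    m_wm, s_wm = _grid_posterior_moments(alpha_grid, ll_wm, hyper_rate)
    m_gm, s_gm = _grid_posterior_moments(alpha_grid, ll_gm, hyper_rate)
    m_b, s_b = _grid_posterior_moments(beta_grid, ll_beta, hyper_rate)
    return ParameterPosterior(mean=np.array([m_wm, m_gm, m_b]),
                              sd=np.array([s_wm, s_gm, s_b]),
                              alpha2=tuple(alpha2), hyper_rate=hyper_rate)


# ---------------------------------------------------------------------------
# Posterior predictive
# ---------------------------------------------------------------------------

def posterior_predictive(test_records, posterior: ParameterPosterior,
                         train_records: list[ShankRecord],
                         n_samples: int = DEFAULT_N_SAMPLES,
                         rng: np.random.Generator | None = None,
                         beta_override: float | None = None):
    """P(z_i = white) per contact, averaged over hyperparameter draws.

    Draws ``n_samples`` parameter vectors from the truncated-Gaussian
    posterior, rebuilds the class densities for each draw, recomputes the
    exact chain marginals, and returns the per-contact sample mean.  With a
    zero-variance posterior this reduces to the marginals at the posterior
    mean.  ``beta_override`` pins beta to a fixed value (used for the
    beta = 0 ablation and the AUC-maximised-beta variant).

    Accepts one ShankRecord (returns one array) or a list (returns a list).
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    gm_pts, wm_pts = class_points(train_records)
    if len(gm_pts) == 0 or len(wm_pts) == 0:
        raise ValueError("training set must contain both tissue classes")
    return _predictive_from_points(test_records, posterior, gm_pts, wm_pts,
                                   n_samples=n_samples, rng=rng,
                                   beta_override=beta_override)


def classify(probabilities, threshold: float = 0.5):
    """Hard labels (+1 white iff p > threshold, ties -> gray) + confidence.

    Confidence is 2|p - 0.5|: 0 at maximal uncertainty, 1 at certainty.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    p = np.asarray(probabilities, dtype=float)
    labels = np.where(p > threshold, 1.0, -1.0)
    confidence = 2.0 * np.abs(p - 0.5)
    return labels, confidence


# ---------------------------------------------------------------------------
# Model artifact: training features + fitted posterior, one JSON file
# ---------------------------------------------------------------------------

@dataclass
class ModelArtifact:
    """Everything needed to classify new patients."""

    posterior: ParameterPosterior
    gm_points: np.ndarray
    wm_points: np.ndarray

    @classmethod
    def fit(cls, train_records: list[ShankRecord],
            **fit_kwargs) -> "ModelArtifact":
        post = fit_parameter_posterior(train_records, **fit_kwargs)
        gm_pts, wm_pts = class_points(train_records)
        return cls(posterior=post, gm_points=gm_pts, wm_points=wm_pts)

    def predict(self, records, n_samples: int = DEFAULT_N_SAMPLES,
                rng: np.random.Generator | None = None,
                beta_override: float | None = None):
        return _predictive_from_points(
            records, self.posterior, self.gm_points, self.wm_points,
            n_samples=n_samples, rng=rng, beta_override=beta_override)

    def save(self, path) -> None:
        payload = {
            "format": "seegwm-model-v1",
            "alpha2": list(self.posterior.alpha2),
            "hyper_rate": self.posterior.hyper_rate,
            "posterior": {"names": list(self.posterior.names),
                          "mean": self.posterior.mean.tolist(),
                          "sd": self.posterior.sd.tolist()},
            "training": {"gm_points": self.gm_points.tolist(),
                         "wm_points": self.wm_points.tolist()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def load(cls, path) -> "ModelArtifact":
        with open(path) as fh:
            payload = json.load(fh)
        post = ParameterPosterior(
            mean=np.array(payload["posterior"]["mean"]),
            sd=np.array(payload["posterior"]["sd"]),
            alpha2=tuple(payload["alpha2"]),
            hyper_rate=payload["hyper_rate"])
        return cls(posterior=post,
                   gm_points=np.array(payload["training"]["gm_points"]),
                   wm_points=np.array(payload["training"]["wm_points"]))


def _predictive_from_points(test_records, posterior, gm_pts, wm_pts,
                            n_samples=DEFAULT_N_SAMPLES, rng=None,
                            beta_override=None):
    single = isinstance(test_records, ShankRecord)
    records = [test_records] if single else list(test_records)
    if rng is None:
        rng = np.random.default_rng()
    draws = posterior.sample(n_samples, rng)
    if beta_override is not None:
        draws = draws.copy()
        draws[:, 2] = beta_override
    a2_wm, a2_gm = posterior.alpha2
    sums = [np.zeros(len(r)) for r in records]
    ivs = [r.depth_intervals for r in records]
    for a_wm, a_gm, beta in draws:
        gm = ClassDensity(gm_pts, (a_gm, a2_gm), "gm")
        wm = ClassDensity(wm_pts, (a_wm, a2_wm), "wm")
        for k, rec in enumerate(records):
            node = np.column_stack([gm.log_likelihood(rec.s, ivs[k]),
                                    wm.log_likelihood(rec.s, ivs[k])])
            node = np.maximum(node, _LOG_FLOOR)
            sums[k] += chain_marginals(beta, node)
    probs = [s / n_samples for s in sums]
    return probs[0] if single else probs


def write_probability_table(path, records: list[ShankRecord], probs,
                            threshold: float = 0.5) -> None:
    """Delimited output: patient, shank, contact, p_white, confidence."""
    import pandas as pd

    rows = []
    for rec, p in zip(records, probs):
        _, conf = classify(p, threshold)
        for i in range(len(rec)):
            rows.append(dict(patient=rec.patient, shank=rec.shank,
                             contact=rec.contacts[i],
                             p_white=f"{p[i]:.10f}",
                             confidence=f"{conf[i]:.10f}"))
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
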