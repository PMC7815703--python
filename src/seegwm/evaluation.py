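"""Evaluation harness: ROC/AUC, cross-validation, transition analysis.

AUC is reported per patient and then averaged across patients (matching a
cohort-level "average AUC"); pooled-contact AUC is available behind a flag.
The transition-distance analysis bins every contact on a shank that
contains at least one gray/white transition by its signed half-integer
distance from the nearest transition (+ into white matter, - into gray)
and summarises the white-matter probabilities per bin.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chain import chain_marginals
from .features import ShankRecord
from .model import (DEFAULT_ALPHA2, DEFAULT_HYPER_RATE, DEFAULT_N_SAMPLES,
                    class_densities, fit_parameter_posterior,
                    posterior_predictive, shank_log_node)

logger = logging.getLogger(__name__)


class UndefinedAUCError(ValueError):
    """ROC/AUC is undefined when the truth contains a single class."""


@dataclass
class ROCResult:
    """ROC curve from a full threshold sweep, plus the p=0.5 operating point."""

    thresholds: np.ndarray        # decreasing; curve runs (0,0) -> (1,1)
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    point_at_half: tuple[float, float]   # (fpr, tpr) when threshold = 0.5


def roc_auc(probabilities, labels) -> ROCResult:
    """ROC curve and trapezoid AUC for white-vs-gray probabilities.

    ``labels`` are -1 gray / +1 white; a contact is called white when its
    probability exceeds the threshold.  TPR = white called white / true
    white; FPR = gray called white / true gray.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probabilities and labels differ in length")
    n_white = int(np.sum(y > 0))
    n_gray = int(np.sum(y < 0))
    if n_white == 0 or n_gray == 0:
        raise UndefinedAUCError("both classes required for an ROC curve")
    thresholds = np.r_[1.0, np.unique(p)[::-1], -1.0]
    calls = p[None, :] > thresholds[:, None]
    tpr = np.sum(calls & (y > 0), axis=1) / n_white
    fpr = np.sum(calls & (y < 0), axis=1) / n_gray
    auc = float(np.trapezoid(tpr, fpr))
    at_half = (float(np.sum((p > 0.5) & (y < 0)) / n_gray),
               float(np.sum((p > 0.5) & (y > 0)) / n_white))
    return ROCResult(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc,
                     point_at_half=at_half)


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-patient ROC results with the cohort mean and SD of AUC."""

    per_patient: dict[str, ROCResult]
    folds: list[list[str]]            # test-patient ids per fold
    pooled: ROCResult | None = None

    @property
    def aucs(self) -> np.ndarray:
        return np.array([r.auc for r in self.per_patient.values()])

    @property
    def mean_auc(self) -> float:
        return float(self.aucs.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.aucs.std(ddof=1)) if len(self.aucs) > 1 else 0.0


def _group_by_patient(records: list[ShankRecord]) -> dict[str, list[ShankRecord]]:
    out: dict[str, list[ShankRecord]] = {}
    for rec in records:
        out.setdefault(rec.patient, []).append(rec)
    return out


def _make_folds(patients: list[str], mode, k: int | None,
                rng: np.random.Generator) -> list[list[str]]:
    if mode == "loo" or (mode == "kfold" and k == len(patients)):
        return [[p] for p in patients]
    if mode != "kfold":
        raise ValueError("mode must be 'loo' or 'kfold'")
    if k is None or not 2 <= k <= len(patients):
        raise ValueError("k must be in [2, n_patients]")
    order = list(patients)
    rng.shuffle(order)
    return [sorted(order[i::k]) for i in range(k)]


def cross_validate(records: list[ShankRecord], mode: str = "loo",
                   k: int | None = None, seed: int = 0,
                   alpha2=DEFAULT_ALPHA2, hyper_rate=DEFAULT_HYPER_RATE,
                   n_samples: int = DEFAULT_N_SAMPLES,
                   beta_override: float | None = None,
                   pooled: bool = False,
                   fit_kwargs: dict | None = None) -> CVResult:
    """Patient-level cross-validated evaluation of the full pipeline.

    For every fold the hyperparameter posterior and class densities are fit
    on the training patients only; held-out patients are scored with the
    posterior predictive and summarised by per-patient AUC.  Fold
    assignment (k-fold mode) and the predictive draws are seeded.
    """
    by_patient = _group_by_patient(records)
    patients = sorted(by_patient)
    if len(patients) < 2:
        raise ValueError("cross-validation needs at least 2 patients")
    rng = np.random.default_rng(seed)
    folds = _make_folds(patients, mode, k, rng)
    if mode == "kfold":
        folds = _stratify_folds(folds, by_patient, rng)

    per_patient: dict[str, ROCResult] = {}
    all_p, all_y = [], []
    for fold in folds:
        train = [r for pat in patients if pat not in fold
                 for r in by_patient[pat]]
        post = fit_parameter_posterior(train, alpha2=alpha2,
                                       hyper_rate=hyper_rate,
                                       **(fit_kwargs or {}))
        for pat in fold:
            test = by_patient[pat]
            probs = posterior_predictive(
                test, post, train, n_samples=n_samples,
                rng=np.random.default_rng(seed + 1 + patients.index(pat)),
                beta_override=beta_override)
            p = np.concatenate(probs)
            y = np.concatenate([r.labels for r in test])
            all_p.append(p)
            all_y.append(y)
            try:
                per_patient[pat] = roc_auc(p, y)
            except UndefinedAUCError:
                logger.warning("patient %s has a single class; AUC skipped",
                               pat)
    pooled_roc = roc_auc(np.concatenate(all_p),
                         np.concatenate(all_y)) if pooled else None
    return CVResult(per_patient=per_patient, folds=folds, pooled=pooled_roc)


def _stratify_folds(folds, by_patient, rng, max_tries: int = 100):
    """Reshuffle k-fold assignment until every training fold has both classes."""
    def ok(assignment):
        for fold in assignment:
            lab = np.concatenate(
                [r.labels for p, recs in by_patient.items()
                 if p not in fold for r in recs if r.labels is not None])
            if not ((lab > 0).any() and (lab < 0).any()):
                return False
        return True

    patients = sorted(by_patient)
    k = len(folds)
    for _ in range(max_tries):
        if ok(folds):
            return folds
        order = list(patients)
        rng.shuffle(order)
        folds = [sorted(order[i::k]) for i in range(k)]
    raise ValueError("could not stratify folds: a class is too rare")


def fit_beta_by_auc(train_records: list[ShankRecord], beta_grid,
                    alpha2=DEFAULT_ALPHA2, hyper_rate=DEFAULT_HYPER_RATE,
                    fit_kwargs: dict | None = None) -> float:
    """Pick the coupling beta that maximises mean training-set AUC.

    Kernel widths are pinned at their posterior means; for each grid value
    the exact marginals are computed on every training shank and the
    per-patient AUCs averaged.  Ties return the smallest beta.
    """
    beta_grid = np.asarray(beta_grid, dtype=float)
    if beta_grid.size == 0 or np.any(beta_grid < 0):
        raise ValueError("beta grid must be non-empty and >= 0")
    post = fit_parameter_posterior(train_records, alpha2=alpha2,
                                   hyper_rate=hyper_rate,
                                   **(fit_kwargs or {}))
    by_patient = _group_by_patient(train_records)
    gm, wm = class_densities(train_records, post.mean_parameters())
    nodes = {pat: [shank_log_node(r, gm, wm) for r in recs]
             for pat, recs in by_patient.items()}
    best_beta, best_auc = None, -np.inf
    for beta in np.sort(beta_grid):
        aucs = []
        for pat, recs in by_patient.items():
            p = np.concatenate([chain_marginals(float(beta), node)
                                for node in nodes[pat]])
            y = np.concatenate([r.labels for r in recs])
            try:
                aucs.append(roc_auc(p, y).auc)
            except UndefinedAUCError:
                continue
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:          # strict: ties keep the smaller beta
            best_beta, best_auc = float(beta), mean_auc
    return best_beta


# ---------------------------------------------------------------------------
# Transition-distance analysis
# ---------------------------------------------------------------------------

def signed_transition_distances(labels) -> np.ndarray:
    """Signed distance of each contact from the nearest label transition.

    The transition sits at x = 0 between two contacts; the first contact on
    the white side is at +0.5, the first on the gray side at -0.5, and so
    on in unit steps.  Ties between two transitions resolve toward the tip
    (lower index).  Returns NaN everywhere if the shank has no transition.
    """
    y = np.asarray(labels, dtype=float)
    trans = np.flatnonzero(y[:-1] != y[1:]) + 0.5
    if trans.size == 0:
        return np.full(y.shape, np.nan)
    idx = np.arange(y.size)
    dist = np.abs(idx[:, None] - trans[None, :])
    nearest = dist[np.arange(y.size), np.argmin(dist, axis=1)]
    return np.sign(y) * nearest


def transition_distance_analysis(probs_per_shank, records: list[ShankRecord]
                                 ) -> pd.DataFrame:
    """Quartile summary of p_white vs. signed distance from a transition.

    Only shanks containing at least one labeled gray/white transition
    contribute.  Returns a frame with columns distance, n, q1, median, q3.
    """
    dists, probs = [], []
    for p, rec in zip(probs_per_shank, records):
        if rec.labels is None:
            continue
        d = signed_transition_distances(rec.labels)
        ok = ~np.isnan(d)
        dists.append(d[ok])
        probs.append(np.asarray(p)[ok])
    if not dists or sum(len(d) for d in dists) == 0:
        warnings.warn("no labeled transitions found; empty summary",
                      stacklevel=2)
        return pd.DataFrame(columns=["distance", "n", "q1", "median", "q3"])
    d = np.concatenate(dists)
    p = np.concatenate(probs)
    rows = []
    for x in np.unique(d):
        sel = p[d == x]
        q1, med, q3 = np.percentile(sel, [25, 50, 75])
        rows.append(dict(distance=x, n=sel.size, q1=q1, median=med, q3=q3))
    return pd.DataFrame(rows)


def plot_roc(results: dict[str, ROCResult], path=None):
    """Per-patient ROC curves with the chance diagonal and p=0.5 dots."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for pat, roc in results.items():
        ax.plot(roc.fpr, roc.tpr, lw=1, alpha=0.7, label=pat)
        ax.plot(*roc.point_at_half, "r.", ms=8)
    ax.plot([0, 1], [0, 1], "k:", lw=1)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    mean_auc = np.mean([r.auc for r in results.values()])
    ax.set_title(f"mean AUC = {mean_auc:.3f}")
    if len(results) <= 10:
        ax.legend(fontsize=7)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
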