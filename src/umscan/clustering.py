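"""U/M-plane clustering: bivariate Gaussian mixtures and a dbscan K-caller.

Genotype classes (homozygotes and heterozygotes) form distinct clusters in
the plane of unmethylated vs methylated fluorescence.  Two complementary
tools operate on that plane:

* ``fit_bgmm`` -- an EM-fitted bivariate Gaussian mixture with a *known*
  number of components, used for targeted cluster assignment (e.g. before
  counting genotypes for allele-frequency estimation).
* ``k_call`` -- a density-based cluster counter (dbscan) for epigenome-wide
  scans where the number of clusters is unknown.  Points are first mapped to
  a scale-free unit square so that a single ``eps`` is meaningful across
  probes of very different brightness; the calibrated defaults are
  ``min_pts=12``, ``eps=0.035``.

Benchmark scores (twin assignment agreement and K-call accuracy) quantify
both tools against a genetically controlled cohort or simulation truth.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.metrics import f1_score

from .intensity import CohortDesign

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterModel",
    "KCallerParams",
    "fit_bgmm",
    "k_call",
    "preprocess_um",
    "calibrate_kcaller",
    "assignment_agreement",
    "k_accuracy",
    "DegenerateMixtureError",
]


class DegenerateMixtureError(RuntimeError):
    """Raised when every EM restart collapses a component."""


@dataclass
class ClusterModel:
    """Fitted K-component bivariate Gaussian mixture on (U, M) points.

    Components are relabeled by ascending centroid beta
    (M_c / (M_c + U_c + 100)), so label 0 is the most unmethylated-like
    cluster and label K-1 the most methylated-like; ``assignments`` holds
    hard maximum-posterior labels in that order.
    """

    K: int
    weights: np.ndarray
    means: np.ndarray  # (K, 2) as (U, M)
    covariances: np.ndarray  # (K, 2, 2)
    assignments: np.ndarray  # (n,) ints in 0..K-1
    loglik: float
    n_iter: int = 0

    def centroid_beta(self) -> np.ndarray:
        u, m = self.means[:, 0], self.means[:, 1]
        return m / (m + u + 100.0)


def _kmeanspp(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = points.shape[0]
    centers = [points[rng.integers(n)]]
    for _ in range(1, k):
        d2 = np.min(
            [((points - c) ** 2).sum(axis=1) for c in centers], axis=0
        )
        total = d2.sum()
        if total <= 0:  # all points coincide with existing centers
            centers.append(points[rng.integers(n)])
            continue
        centers.append(points[rng.choice(n, p=d2 / total)])
    return np.array(centers)


def _log_gauss(points: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log density of a bivariate normal at each point (Cholesky-based)."""
    chol = np.linalg.cholesky(cov)
    diff = points - mean
    sol = np.linalg.solve(chol, diff.T)
    maha = (sol**2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (maha + logdet + 2.0 * np.log(2.0 * np.pi))


def _em_once(
    points: np.ndarray,
    k: int,
    rng: np.random.Generator,
    max_iter: int,
    tol: float,
    ridge: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, float, int]:
    n = points.shape[0]
    centers = _kmeanspp(points, k, rng)
    labels = np.argmin(
        ((points[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    weights = np.full(k, 1.0 / k)
    means = centers.copy()
    global_cov = np.cov(points.T) + 1e-8 * np.eye(2)
    covs = np.empty((k, 2, 2))
    for c in range(k):
        sel = points[labels == c]
        covs[c] = np.cov(sel.T) if sel.shape[0] > 2 else global_cov
        covs[c] += (ridge * np.trace(covs[c]) + 1e-10) * np.eye(2)

    prev_ll = -np.inf
    log_resp = np.empty((n, k))
    for it in range(1, max_iter + 1):
        for c in range(k):
            log_resp[:, c] = np.log(weights[c]) + _log_gauss(points, means[c], covs[c])
        row_max = log_resp.max(axis=1, keepdims=True)
        log_norm = row_max[:, 0] + np.log(np.exp(log_resp - row_max).sum(axis=1))
        ll = float(log_norm.sum())
        # EM guarantees monotone likelihood; the covariance ridge makes the
        # M-step inexact by O(ridge) per point, so allow that much slack
        # before declaring a bug.
        if ll < prev_ll - 100.0 * ridge * max(1.0, abs(prev_ll)):
            raise AssertionError(
                f"EM log-likelihood decreased: {prev_ll:.6f} -> {ll:.6f}"
            )
        resp = np.exp(log_resp - log_norm[:, None])
        nk = resp.sum(axis=0)
        if np.any(nk < 1e-8):
            raise DegenerateMixtureError("vanishing mixture component")
        weights = nk / n
        means = (resp.T @ points) / nk[:, None]
        for c in range(k):
            d = points - means[c]
            cov = (resp[:, c][:, None] * d).T @ d / nk[c]
            covs[c] = cov + (ridge * np.trace(cov) + 1e-10) * np.eye(2)
        if np.isfinite(prev_ll) and (ll - prev_ll) < tol * max(1.0, abs(ll)):
            prev_ll = ll
            break
        prev_ll = ll
    # final E-step so assignments and loglik reflect the returned parameters
    for c in range(k):
        log_resp[:, c] = np.log(weights[c]) + _log_gauss(points, means[c], covs[c])
    row_max = log_resp.max(axis=1, keepdims=True)
    ll = float((row_max[:, 0] + np.log(np.exp(log_resp - row_max).sum(axis=1))).sum())
    labels = np.argmax(log_resp, axis=1)
    return weights, means, covs, labels, ll, it


def fit_bgmm(
    points: np.ndarray,
    k: int,
    n_restarts: int = 10,
    seed: int | np.random.Generator | None = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
    ridge: float = 1e-6,
) -> ClusterModel:
    """Fit a K-component bivariate Gaussian mixture to (U, M) points by EM.

    Each restart uses a fresh k-means++ initialization; the best restart by
    log-likelihood wins.  Covariances are full, with a ridge of
    ``ridge * trace`` added for stability; convergence at relative
    log-likelihood change below ``tol`` or ``max_iter`` iterations.  Restarts
    that collapse a component are retried; if all collapse, a
    ``DegenerateMixtureError`` is raised.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (U, M) pairs")
    if not np.isfinite(points).all():
        raise ValueError("points must be finite")
    n = points.shape[0]
    if k < 1 or n < 5 * k:
        raise ValueError(f"need at least 5*K={5 * k} points, got {n}")
    rng = np.random.default_rng(seed)

    best = None
    failures = 0
    for _ in range(n_restarts):
        try:
            fit = _em_once(points, k, rng, max_iter, tol, ridge)
        except (DegenerateMixtureError, np.linalg.LinAlgError):
            failures += 1
            continue
        if best is None or fit[4] > best[4]:
            best = fit
    if best is None:
        raise DegenerateMixtureError(
            f"all {n_restarts} EM restarts degenerated (K={k}, n={n})"
        )
    if failures:
        logger.debug("fit_bgmm: %d/%d degenerate restarts", failures, n_restarts)
    weights, means, covs, labels, ll, n_iter = best
    # relabel ascending by centroid beta for a reproducible genotype axis
    beta = means[:, 1] / (means[:, 1] + means[:, 0] + 100.0)
    order = np.argsort(beta, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return ClusterModel(
        K=k,
        weights=weights[order],
        means=means[order],
        covariances=covs[order],
        assignments=relabel[labels],
        loglik=ll,
        n_iter=n_iter,
    )


@dataclass(frozen=True)
class KCallerParams:
    """dbscan K-caller parameters; the defaults are the calibrated values."""

    min_pts: int = 12
    eps: float = 0.035
    scaling: str = "p99_total"  # divide axes by the 99th pct of U+M, clip
    clip_max: float = 1.5
    percentile: float = 99.0

    def __post_init__(self) -> None:
        if self.min_pts < 1 or self.eps <= 0:
            raise ValueError("min_pts must be >= 1 and eps > 0")


def preprocess_um(points: np.ndarray, params: KCallerParams = KCallerParams()) -> np.ndarray:
    """Map (U, M) points to a scale-free unit square.

    Both axes are divided by the 99th percentile of the total signal U + M
    across samples and clipped to [0, clip_max]; eps is then dimensionless
    and robust to bright outliers, and the K-call is invariant to a joint
    positive rescaling of the two channels.
    """
    points = np.asarray(points, dtype=float)
    if params.scaling != "p99_total":
        raise ValueError(f"unknown scaling {params.scaling!r}")
    scale = np.percentile(points.sum(axis=1), params.percentile)
    if scale <= 0:
        scale = 1.0
    return np.clip(points / scale, 0.0, params.clip_max)


def k_call(points: np.ndarray, params: KCallerParams = KCallerParams()) -> int:
    """Count U/M-plane clusters with dbscan; 0 when everything is noise.

    Noise points are excluded from the count (and should be excluded from any
    downstream genotype counting).
    """
    points = np.asarray(points, dtype=float)
    if points.shape[0] < params.min_pts:
        raise ValueError("need at least min_pts points")
    x = preprocess_um(points, params)
    labels = DBSCAN(eps=params.eps, min_samples=params.min_pts).fit(x).labels_
    return int(len(set(labels[labels >= 0])))


def k_call_labels(points: np.ndarray, params: KCallerParams = KCallerParams()) -> np.ndarray:
    """dbscan cluster labels on the preprocessed plane (-1 = noise)."""
    x = preprocess_um(np.asarray(points, dtype=float), params)
    return DBSCAN(eps=params.eps, min_samples=params.min_pts).fit(x).labels_


def calibrate_kcaller(
    training: Sequence[tuple[np.ndarray, int]],
    eps_grid: Iterable[float] = (0.02, 0.035, 0.05, 0.075),
    min_pts_grid: Iterable[int] = (6, 12, 20),
    base_params: KCallerParams = KCallerParams(),
) -> tuple[KCallerParams, float]:
    """Grid-search dbscan parameters as a K in {1,2,3} classification task.

    Each training item is a labeled point cloud (points, true K).  Calls and
    truths above 3 are binned as 3 and calls of 0 count as errors; the score
    is the macro F1 over classes 1..3.  Ties break toward smaller eps, then
    larger min_pts.  The training set must cover K = 1, 2 and 3.
    """
    truth = np.array([min(int(k), 3) for _, k in training])
    if not {1, 2, 3} <= set(truth.tolist()):
        raise ValueError("training must cover K = 1, 2 and 3")
    # preprocessing does not depend on (eps, min_pts): do it once per cloud
    clouds = [preprocess_um(p, base_params) for p, _ in training]
    best: tuple[float, float, int] | None = None
    for eps, min_pts in itertools.product(sorted(eps_grid), sorted(min_pts_grid)):
        calls = np.empty(len(clouds), dtype=int)
        for i, x in enumerate(clouds):
            labels = DBSCAN(eps=eps, min_samples=min_pts).fit(x).labels_
            calls[i] = min(len(set(labels[labels >= 0])), 3)
        score = f1_score(truth, calls, labels=[1, 2, 3], average="macro", zero_division=0.0)
        key = (score, -eps, min_pts)
        if best is None or key > (best[0], -best[1], best[2]):
            best = (score, eps, min_pts)
    assert best is not None
    score, eps, min_pts = best
    return replace(base_params, eps=eps, min_pts=min_pts), float(score)


def assignment_agreement(
    assignments: Sequence[np.ndarray] | pd.DataFrame,
    cohort: CohortDesign,
    sample_ids: Sequence[str] | None = None,
) -> float:
    """Correct-assignment coefficient: mean over probes of rho^2 between the
    cluster labels of twin A and twin B across pairs.

    Labels must be the centroid-beta-ordered integers of ``fit_bgmm`` (a
    Pearson rho on unordered categories would be ill-defined).  Probes where
    rho is undefined because labels are constant contribute 1 when twins
    agree everywhere and are otherwise excluded with a log entry.
    """
    if isinstance(assignments, pd.DataFrame):
        frame = assignments
    else:
        if sample_ids is None:
            raise ValueError("sample_ids required when passing raw label arrays")
        frame = pd.DataFrame(np.vstack(assignments), columns=list(sample_ids))
    pairs = [
        p for p in cohort.twin_pairs() if p[0] in frame.columns and p[1] in frame.columns
    ]
    if not pairs:
        raise ValueError("assignment_agreement requires twin pairs")
    a_ids, b_ids = zip(*pairs)
    a = frame[list(a_ids)].to_numpy(float)
    b = frame[list(b_ids)].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        va = a.var(axis=1)
        vb = b.var(axis=1)
        cov = ((a - a.mean(axis=1, keepdims=True)) * (b - b.mean(axis=1, keepdims=True))).mean(axis=1)
        rho2 = cov**2 / (va * vb)
    defined = (va > 0) & (vb > 0)
    concordant_const = ~defined & (a == b).all(axis=1)
    dropped = int((~defined & ~concordant_const).sum())
    if dropped:
        logger.info("assignment_agreement: %d probes with undefined rho excluded", dropped)
    scores = np.concatenate([rho2[defined], np.ones(concordant_const.sum())])
    if scores.size == 0:
        raise ValueError("no probe yields a defined agreement score")
    return float(scores.mean())


def k_accuracy(calls: Sequence[int], expected: Sequence[int]) -> float:
    """Fraction of exact K-call matches."""
    calls = np.asarray(calls)
    expected = np.asarray(expected)
    if calls.shape != expected.shape:
        raise ValueError("calls and expected must be aligned")
    return float((calls == expected).mean())
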