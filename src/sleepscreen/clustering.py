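"""Gaussian-mixture clustering of drivers in (ΔP(wake), ΔP(doze)) space.

Each driver contributes one control-corrected coordinate per phase; a full-
covariance Gaussian mixture is fit by EM for each candidate component count
k, points are hard-assigned by maximum posterior, and the k whose mean
silhouette coefficient is closest to one (i.e. maximal, since silhouette
is bounded above by one) is selected.  Cluster extents are reported as
n·σ ellipses from the component covariances.

The EM here keeps the full per-iteration log-likelihood trace (monotone
non-decreasing, a standing invariant) and per-component covariances for the
σ ellipses; restarts are seeded and the best of ``n_init`` runs by final
log-likelihood is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

DEFAULT_K_CANDIDATES = (3, 4, 5)


@dataclass
class GmmModel:
    """A fitted full-covariance Gaussian mixture."""

    k: int
    weights: np.ndarray  # (k,)
    means: np.ndarray  # (k, d)
    covariances: np.ndarray  # (k, d, d)
    log_likelihood: float
    ll_trace: np.ndarray = field(repr=False)
    converged: bool = True
    seed: int | None = None

    def log_prob(self, points: np.ndarray) -> np.ndarray:
        """Per-point, per-component weighted log density, shape (n, k)."""
        points = np.atleast_2d(points)
        n, d = points.shape
        out = np.empty((n, self.k))
        for j in range(self.k):
            out[:, j] = np.log(self.weights[j]) + _mvn_logpdf(
                points, self.means[j], self.covariances[j]
            )
        return out

    def predict(self, points: np.ndarray) -> np.ndarray:
        """Hard labels by maximum posterior."""
        return np.argmax(self.log_prob(points), axis=1)

    def score(self, points: np.ndarray) -> float:
        return float(logsumexp(self.log_prob(points), axis=1).sum())


def _mvn_logpdf(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    d = len(mean)
    L = np.linalg.cholesky(cov)
    diff = x - mean
    sol = np.linalg.solve(L, diff.T)
    maha = (sol**2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    return -0.5 * (d * np.log(2 * np.pi) + logdet + maha)


def _kmeanspp_init(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial means proportionally to squared distance."""
    n = len(points)
    centers = [points[rng.integers(n)]]
    for _ in range(k - 1):
        d2 = np.min(
            [((points - c) ** 2).sum(axis=1) for c in centers], axis=0
        )
        total = d2.sum()
        if total <= 0:
            centers.append(points[rng.integers(n)])
            continue
        centers.append(points[rng.choice(n, p=d2 / total)])
    return np.array(centers)


def _em_once(
    points: np.ndarray,
    k: int,
    rng: np.random.Generator,
    reg: float,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[float], bool]:
    n, d = points.shape
    means = _kmeanspp_init(points, k, rng)
    base_cov = np.cov(points.T) if n > 1 else np.eye(d)
    base_cov = np.atleast_2d(base_cov) + reg * np.eye(d)
    covs = np.tile(base_cov, (k, 1, 1))
    weights = np.full(k, 1.0 / k)
    trace: list[float] = []
    converged = False
    for _ in range(max_iter):
        # E step
        logp = np.empty((n, k))
        for j in range(k):
            logp[:, j] = np.log(weights[j]) + _mvn_logpdf(points, means[j], covs[j])
        lse = logsumexp(logp, axis=1)
        ll = float(lse.sum())
        resp = np.exp(logp - lse[:, None])
        if trace and ll - trace[-1] < tol:
            trace.append(max(ll, trace[-1]))
            converged = True
            break
        trace.append(ll)
        # M step
        nk = resp.sum(axis=0) + 1e-300
        weights = nk / n
        means = (resp.T @ points) / nk[:, None]
        for j in range(k):
            diff = points - means[j]
            covs[j] = (resp[:, j][:, None] * diff).T @ diff / nk[j] + reg * np.eye(d)
    return weights, means, covs, trace, converged


def fit_gmm(
    points: np.ndarray,
    k: int,
    seed: int | None = 0,
    n_init: int = 20,
    reg: float = 1e-6,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> GmmModel:
    """Fit a full-covariance k-component Gaussian mixture by EM.

    Runs ``n_init`` seeded k-means++ restarts and keeps the run with the
    highest final log-likelihood.  Covariances are regularized by ``reg·I``
    every M step, so identical points converge without numerical failure.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(points) <= k:
        raise ValueError(f"need more than k={k} points, got {len(points)}")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_init)):
        weights, means, covs, trace, conv = _em_once(points, k, rng, reg, tol, max_iter)
        if best is None or trace[-1] > best[3][-1]:
            best = (weights, means, covs, trace, conv)
    weights, means, covs, trace, conv = best
    return GmmModel(
        k=k,
        weights=weights,
        means=means,
        covariances=covs,
        log_likelihood=trace[-1],
        ll_trace=np.array(trace),
        converged=conv,
        seed=seed,
    )


def silhouette_mean(points: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient (Euclidean), singleton clusters scoring 0.

    For each point, a = mean distance to the rest of its own cluster, b = the
    smallest mean distance to any other cluster; s = (b − a)/max(a, b) (0 when
    both are 0).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette requires at least 2 clusters")
    dist = np.sqrt(((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=-1))
    svals = np.zeros(len(points))
    for i in range(len(points)):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            svals[i] = 0.0
            continue
        a = dist[i, own].sum() / (n_own - 1)
        b = min(dist[i, labels == lab].mean() for lab in uniq if lab != labels[i])
        denom = max(a, b)
        svals[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(svals.mean())


@dataclass(frozen=True)
class ClusterEllipse:
    center: tuple[float, float]
    semi_axes: tuple[float, float]  # descending
    angle_rad: float  # of the major axis, from +x


def cluster_ellipse(model: GmmModel, component: int, n_sigma: float = 1.0) -> ClusterEllipse:
    """The n·σ ellipse of one mixture component.

    Semi-axes are n_sigma·sqrt(eigenvalues) of the component covariance;
    the orientation comes from the leading eigenvector.
    """
    if not 0 <= component < model.k:
        raise ValueError(f"component must be in 0..{model.k - 1}")
    cov = model.covariances[component]
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    major = evecs[:, 0]
    return ClusterEllipse(
        center=tuple(model.means[component]),
        semi_axes=tuple(n_sigma * np.sqrt(np.clip(evals, 0, None))),
        angle_rad=float(np.arctan2(major[1], major[0])),
    )


class DeltaPClusterer(ClusterMixin, BaseEstimator):
    """Gaussian-mixture clustering with silhouette-based choice of k.

    Fits a full-covariance mixture for every candidate k, hard-assigns by
    maximum posterior, and keeps the k with the greatest mean silhouette.
    Candidates with too few points (n <= k) are skipped with a warning.

    Parameters
    ----------
    k_candidates : iterable of int, default (3, 4, 5)
    n_init, reg, tol, max_iter : EM settings (seeded restarts, covariance
        regularization, convergence tolerance, iteration cap).
    random_state : int, seed for all restarts.

    Attributes
    ----------
    chosen_k_ : int
    labels_ : hard assignments under the chosen model
    silhouettes_ : dict k -> mean silhouette
    models_ : dict k -> GmmModel
    model_ : the chosen GmmModel
    """

    def __init__(
        self,
        k_candidates=DEFAULT_K_CANDIDATES,
        n_init: int = 20,
        reg: float = 1e-6,
        tol: float = 1e-6,
        max_iter: int = 500,
        random_state: int = 0,
    ):
        self.k_candidates = k_candidates
        self.n_init = n_init
        self.reg = reg
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = check_array(X)
        if not list(self.k_candidates):
            raise ValueError("k_candidates must be non-empty")
        self.models_ = {}
        self.silhouettes_ = {}
        labels = {}
        for k in self.k_candidates:
            if len(X) <= k:
                warnings.warn(
                    f"skipping k={k}: needs more than {k} points, have {len(X)}",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            model = fit_gmm(
                X,
                k,
                seed=self.random_state,
                n_init=self.n_init,
                reg=self.reg,
                tol=self.tol,
                max_iter=self.max_iter,
            )
            lab = model.predict(X)
            self.models_[k] = model
            labels[k] = lab
            if len(np.unique(lab)) < 2:
                # All mass collapsed onto one component; silhouette undefined.
                self.silhouettes_[k] = float("-inf")
            else:
                self.silhouettes_[k] = silhouette_mean(X, lab)
        if not self.models_:
            raise ValueError("no candidate k could be fit (too few points)")
        self.chosen_k_ = max(sorted(self.silhouettes_), key=lambda k: self.silhouettes_[k])
        self.model_ = self.models_[self.chosen_k_]
        self.labels_ = labels[self.chosen_k_]
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return self.model_.predict(check_array(X))

    def ellipses(self, n_sigma: float = 1.0) -> list[ClusterEllipse]:
        check_is_fitted(self, "model_")
        return [cluster_ellipse(self.model_, j, n_sigma) for j in range(self.chosen_k_)]


def select_k(points, k_candidates=DEFAULT_K_CANDIDATES, seed: int = 0, **em_kwargs):
    """Functional wrapper: fit a DeltaPClusterer and return it."""
    return DeltaPClusterer(
        k_candidates=k_candidates, random_state=seed, **em_kwargs
    ).fit(np.asarray(points, dtype=float))
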