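"""Unsupervised reduction of U-Net bottleneck features.

The cohort's latent vectors form a patients x features matrix. Each
*feature* is treated as a point — its z-scored profile across patients —
and the feature set is clustered with k-medoids (classic PAM build+swap,
Euclidean distance between profiles). The mean silhouette over a k grid
selects the cluster count; the cluster medoids are the representative
features. An L1-penalized logistic regression on the medoid features then
retains the ones associated with a binary outcome, with the penalty chosen
by minimum cross-validated deviance.

For very wide panels a seeded subsample of features (default cap 4096)
precedes PAM; exact PAM over tens of thousands of points is not practical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import silhouette_samples
from sklearn.model_selection import StratifiedKFold


@dataclass
class FeaturePanel:
    """Cohort x latent-feature matrix with its standardization state."""

    matrix: np.ndarray                  # (n_patients, n_features), raw
    feature_ids: np.ndarray             # stable indices into the bottleneck
    mean_: np.ndarray | None = None
    sd_: np.ndarray | None = None

    @classmethod
    def from_latents(cls, latents, feature_ids=None) -> "FeaturePanel":
        m = np.asarray(latents, dtype=float)
        if m.ndim != 2:
            raise ValueError("latents must be 2-D (patients x features)")
        if not np.isfinite(m).all():
            raise ValueError("panel contains non-finite entries")
        ids = np.arange(m.shape[1]) if feature_ids is None \
            else np.asarray(feature_ids)
        return cls(matrix=m, feature_ids=ids)

    def fit_standardization(self) -> "FeaturePanel":
        self.mean_ = self.matrix.mean(axis=0)
        self.sd_ = self.matrix.std(axis=0)
        return self

    @property
    def nonconstant(self) -> np.ndarray:
        """Boolean flag per feature: has variance across patients."""
        sd = self.matrix.std(axis=0) if self.sd_ is None else self.sd_
        return sd > 0

    def zscored(self, matrix: np.ndarray | None = None) -> np.ndarray:
        """Z-score (stored constants), constant features mapped to 0."""
        if self.mean_ is None:
            self.fit_standardization()
        m = self.matrix if matrix is None else np.asarray(matrix, dtype=float)
        sd = np.where(self.sd_ > 0, self.sd_, 1.0)
        return (m - self.mean_) / sd


@dataclass
class MedoidSet:
    k: int
    medoid_feature_ids: np.ndarray      # ids in panel.feature_ids space
    medoid_columns: np.ndarray          # column indices into the panel
    assignments: np.ndarray             # feature -> cluster index
    mean_silhouette: float
    objective: float                    # total within-cluster dissimilarity


@dataclass
class LassoSelection:
    lam: float
    retained_feature_ids: np.ndarray
    retained_columns: np.ndarray
    coefficients: np.ndarray            # dense over input columns; 0 = dropped
    intercept: float
    cv_deviance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# PAM


def _pam(dist: np.ndarray, k: int, rng: np.random.Generator
         ) -> tuple[np.ndarray, np.ndarray, float]:
    """Classic PAM: greedy BUILD then best-improvement SWAP until no
    improving swap remains. Ties break to the lowest index. Returns
    (medoid indices sorted, assignments, objective)."""
    n = dist.shape[0]
    if k > n:
        raise ValueError("k exceeds the number of points")
    # BUILD: first medoid minimizes total distance; then greedy additions
    medoids = [int(np.argmin(dist.sum(axis=1)))]
    d_near = dist[medoids[0]].copy()
    for _ in range(1, k):
        gain = np.maximum(d_near[None, :] - dist, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        m = int(np.argmax(gain))    # argmax takes the first (lowest) index
        medoids.append(m)
        d_near = np.minimum(d_near, dist[m])
    medoids = sorted(medoids)
    # SWAP
    while True:
        med = np.asarray(medoids)
        dmed = dist[med]                          # (k, n)
        current = dmed.min(axis=0).sum()
        best = (0.0, None, None)
        order = np.argsort(dmed, axis=0)
        nearest = dmed[order[0], np.arange(n)]
        second = dmed[order[1], np.arange(n)] if k > 1 else np.full(n, np.inf)
        nearest_idx = order[0]
        for mi in range(len(med)):
            # removing medoid mi: points assigned to it fall back to second
            fallback = np.where(nearest_idx == mi, second, nearest)
            for h in range(n):
                if h in medoids:
                    continue
                new_cost = float(np.minimum(fallback, dist[h]).sum())
                delta = new_cost - current
                if delta < best[0] - 1e-12:
                    best = (delta, mi, h)
        if best[1] is None:
            break
        medoids[best[1]] = best[2]
        medoids = sorted(medoids)
    med = np.asarray(medoids)
    assignments = np.argmin(dist[med], axis=0)
    objective = float(dist[med].min(axis=0).sum())
    return med, assignments, objective


def cluster_features(panel: FeaturePanel, k: int, seed: int = 0,
                     max_features: int = 4096) -> MedoidSet:
    """k-medoids over z-scored feature profiles (Euclidean distance).

    Constant features are excluded; panels wider than ``max_features`` are
    first reduced to a seeded subsample of that size.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = np.random.default_rng(seed)
    z = panel.zscored()
    cols = np.flatnonzero(panel.nonconstant)
    if cols.size == 0:
        raise ValueError("all features are constant")
    if cols.size > max_features:
        cols = np.sort(rng.choice(cols, size=max_features, replace=False))
    if k > cols.size:
        raise ValueError(f"k={k} exceeds {cols.size} usable features")
    profiles = z[:, cols].T                       # feature profiles as points
    from scipy.spatial.distance import squareform, pdist
    dist = squareform(pdist(profiles))
    med, assign, obj = _pam(dist, k, rng)
    if 2 <= k <= len(cols) - 1 and np.unique(assign).size >= 2:
        sil = float(np.mean(silhouette_samples(dist, assign,
                                               metric="precomputed")))
    else:
        sil = 0.0
    return MedoidSet(k=k,
                     medoid_feature_ids=panel.feature_ids[cols[med]],
                     medoid_columns=cols[med],
                     assignments=assign, mean_silhouette=sil,
                     objective=obj)


def select_k_silhouette(panel: FeaturePanel, k_grid, seed: int = 0,
                        max_features: int = 4096) -> tuple[int, dict]:
    """k maximizing the mean silhouette over the grid; ties -> smallest k."""
    k_grid = sorted(set(int(k) for k in k_grid))
    if not k_grid:
        raise ValueError("empty k grid")
    scores = {}
    for k in k_grid:
        scores[k] = cluster_features(panel, k, seed=seed,
                                     max_features=max_features).mean_silhouette
    best = max(k_grid, key=lambda k: (scores[k], -k))
    return best, scores


# ---------------------------------------------------------------------------
# LASSO retention


def _newton_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-10,
                     max_iter: int = 100, ridge: float = 0.0
                     ) -> tuple[np.ndarray, float]:
    """Unpenalized (optionally ridge-stabilized) logistic MLE."""
    n, p = X.shape
    Xd = np.hstack([np.ones((n, 1)), X])
    beta = np.zeros(p + 1)
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = Xd.T @ (y - mu) - ridge * np.r_[0.0, beta[1:]]
        hess = (Xd * w[:, None]).T @ Xd + ridge * np.diag(np.r_[0.0, np.ones(p)])
        step = np.linalg.solve(hess + 1e-12 * np.eye(p + 1), grad)
        beta += step
        if np.linalg.norm(grad) < tol:
            break
    return beta[1:], float(beta[0])


def _binomial_deviance(y, p):
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return float(-2.0 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def lasso_select(X: np.ndarray, y: np.ndarray, lambda_grid=None,
                 cv_folds: int = 6, seed: int = 0,
                 feature_ids=None) -> LassoSelection:
    """L1-penalized logistic retention of outcome-associated features.

    The penalty is chosen as the grid value minimizing mean cross-validated
    binomial deviance (stratified, seeded folds); the model is refit on all
    rows at that penalty and features with nonzero coefficients are
    retained. ``lambda_grid`` entries are the multiplier on the L1 norm of
    the summed-deviance objective; 0 falls back to the unpenalized Newton
    MLE (every feature retained).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be (n, p) aligned with y")
    if X.shape[1] == 0:
        raise ValueError("empty feature matrix")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("y must contain both classes")
    ids = np.arange(X.shape[1]) if feature_ids is None \
        else np.asarray(feature_ids)
    if lambda_grid is None:
        lambda_grid = np.geomspace(1e-3, 10.0, 13)
    lambda_grid = sorted(float(l) for l in lambda_grid)

    def _fit(lam, Xtr, ytr):
        if lam == 0.0:
            coef, intercept = _newton_logistic(Xtr, ytr)
            return coef, intercept
        clf = LogisticRegression(l1_ratio=1.0, solver="liblinear",
                                 C=1.0 / lam, tol=1e-8, max_iter=2000,
                                 random_state=0)
        clf.fit(Xtr, ytr)
        return clf.coef_[0], float(clf.intercept_[0])

    cv_dev = {}
    n_splits = min(cv_folds, int(min(np.bincount(y.astype(int))).item()))
    if n_splits >= 2 and len(lambda_grid) > 1:
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True,
                              random_state=seed)
        folds = list(skf.split(X, y))
        for lam in lambda_grid:
            dev = 0.0
            for tr, va in folds:
                coef, b0 = _fit(lam, X[tr], y[tr])
                p = 1.0 / (1.0 + np.exp(-(X[va] @ coef + b0)))
                dev += _binomial_deviance(y[va], p) / len(va)
            cv_dev[lam] = dev / len(folds)
        lam_star = min(lambda_grid, key=lambda l: (cv_dev[l], l))
    else:
        lam_star = lambda_grid[0]
    coef, b0 = _fit(lam_star, X, y)
    coef = np.where(np.abs(coef) > 0, coef, 0.0)
    kept = np.flatnonzero(coef != 0)
    return LassoSelection(lam=lam_star, retained_feature_ids=ids[kept],
                         retained_columns=kept, coefficients=coef,
                         intercept=b0, cv_deviance=cv_dev)
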