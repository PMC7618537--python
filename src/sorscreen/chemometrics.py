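"""Multivariate analysis: PCA, confidence ellipses, outlier screening, PLS-DA.

PCA is computed from the singular value decomposition of the column-centered
spectra matrix; loadings are the right singular vectors, with each vector
oriented so its largest-magnitude element is positive (reproducible score
plots).  Class scatter in score space is summarised by confidence ellipses at
the χ²(2 d.f.) quantile.  Outlying spectra are screened with Hotelling's T²
(distance within the model plane, F-distribution limit) and the Q residual
(squared distance off the model plane, moment-matched χ² limit).

Classification uses PLS-DA: a NIPALS PLS1 regression of the spectra against
a 0/1 class code (1 = falsified), thresholded at 0.5 (ties called positive —
conservative for screening).  Performance is estimated by cross-validation
grouped by vial, so replicate measurements of one vial never straddle a
train/test split, with the number of latent variables chosen by an inner
cross-validation when not fixed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .dataset import DegenerateDataError, LabeledSpectraSet

__all__ = [
    "PcaModel",
    "EllipseSpec",
    "OutlierReport",
    "PlsdaModel",
    "CvReport",
    "pca_fit",
    "confidence_ellipse",
    "outlier_screen",
    "plsda_fit",
    "plsda_predict",
    "cross_validate",
    "confusion_metrics",
    "balanced_accuracy",
]


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, LabeledSpectraSet):
        return X.matrix
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D spectra matrix")
    return X


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaModel:
    """SVD-based principal component model of a spectra matrix.

    ``loadings`` has shape (n_components, n_channels), rows orthonormal;
    ``scores = (X − mean) @ loadings.T``.
    """

    mean: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    singular_values: np.ndarray

    @property
    def n_components(self) -> int:
        return int(self.loadings.shape[0])

    def transform(self, X) -> np.ndarray:
        X = _as_matrix(X)
        if X.shape[1] != self.mean.size:
            raise ValueError("channel count does not match the fitted model")
        return (X - self.mean) @ self.loadings.T


def pca_fit(X, n_components: int) -> PcaModel:
    """Fit a PCA model by SVD of the column-centered matrix.

    Components are ordered by decreasing singular value;
    ``explained_variance_ratio[i] = σ_i² / Σ_j σ_j²`` over all singular
    values of the centered matrix.
    """
    X = _as_matrix(X)
    n, ch = X.shape
    max_comp = min(n - 1, ch)
    if not 1 <= n_components <= max_comp:
        raise ValueError(
            f"n_components must be in [1, min(n-1, n_channels)] = [1, {max_comp}]"
        )
    mean = X.mean(axis=0)
    u, s, vt = np.linalg.svd(X - mean, full_matrices=False)
    # orient each loading so its largest-magnitude element is positive
    flip = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]
    u = u * flip[None, :]
    total = float(np.sum(s**2))
    ratio = s**2 / total if total > 0 else np.zeros_like(s)
    k = n_components
    return PcaModel(
        mean=mean,
        loadings=vt[:k],
        scores=(u * s)[:, :k],
        explained_variance=s[:k] ** 2 / (n - 1),
        explained_variance_ratio=ratio[:k],
        singular_values=s[:k],
    )


# ---------------------------------------------------------------------------
# Confidence ellipse
# ---------------------------------------------------------------------------

@dataclass
class EllipseSpec:
    """Confidence ellipse for a 2-D score cloud.

    The boundary is the set of points whose squared Mahalanobis distance from
    ``center`` (under ``covariance``) equals ``boundary_mahalanobis_sq``.
    """

    center: np.ndarray
    covariance: np.ndarray
    level: float
    boundary_mahalanobis_sq: float

    def mahalanobis_sq(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.center
        sol = np.linalg.solve(self.covariance, pts.T)
        return np.einsum("ij,ji->i", pts, sol)

    def contains(self, points) -> np.ndarray:
        return self.mahalanobis_sq(points) <= self.boundary_mahalanobis_sq

    def boundary_points(self, num: int = 200) -> np.ndarray:
        """Points on the ellipse boundary, for plotting."""
        theta = np.linspace(0.0, 2.0 * np.pi, num)
        circle = np.stack([np.cos(theta), np.sin(theta)])
        chol = np.linalg.cholesky(self.covariance)
        r = np.sqrt(self.boundary_mahalanobis_sq)
        return (self.center[:, None] + r * (chol @ circle)).T


def confidence_ellipse(scores, level: float = 0.95, form: str = "chi2") -> EllipseSpec:
    """Fit a confidence ellipse to n×2 score coordinates.

    ``chi2`` (default) places the boundary at the χ² quantile with 2 degrees
    of freedom — the population-covariance form; ``hotelling`` uses the
    F-based quantile 2(n−1)/(n−2)·F₂,ₙ₋₂, which widens the ellipse slightly
    at small n.  Needs at least 3 points and a nonsingular sample covariance.
    """
    pts = np.asarray(scores, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("scores must be an n×2 array")
    n = pts.shape[0]
    if n < 3:
        raise DegenerateDataError("confidence ellipse needs at least 3 points")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    cov = np.cov(pts, rowvar=False, ddof=1)
    if np.linalg.matrix_rank(cov, tol=1e-12 * max(1.0, float(np.abs(cov).max()))) < 2:
        raise DegenerateDataError("singular score covariance: points are collinear")
    if form == "chi2":
        m2 = float(stats.chi2.ppf(level, df=2))
    elif form == "hotelling":
        m2 = float(2.0 * (n - 1) / (n - 2) * stats.f.ppf(level, 2, n - 2))
    else:
        raise ValueError(f"unknown ellipse form {form!r}")
    return EllipseSpec(center=pts.mean(axis=0), covariance=cov,
                       level=level, boundary_mahalanobis_sq=m2)


# ---------------------------------------------------------------------------
# Outlier screening
# ---------------------------------------------------------------------------

@dataclass
class OutlierReport:
    """Per-row T² and Q statistics with their control limits; a row is
    flagged iff either statistic exceeds its limit."""

    t2: np.ndarray
    q: np.ndarray
    t2_limit: float
    q_limit: float
    flags: np.ndarray
    n_components: int
    confidence: float

    @property
    def flagged_rows(self) -> np.ndarray:
        return np.flatnonzero(self.flags)


def outlier_screen(X, n_components: int = 3, confidence: float = 0.99) -> OutlierReport:
    """Screen spectra against a PCA model with Hotelling T² and Q residuals.

    T² is the Mahalanobis distance of each row's scores under the retained
    components, limited at ``a(n−1)(n+1)/(n(n−a)) · F_{a,n−a}(confidence)``.
    Q is the squared reconstruction residual, limited by moment-matching the
    discarded eigenvalue spectrum to a scaled χ² distribution.
    """
    X = _as_matrix(X)
    n, ch = X.shape
    a = n_components
    if n <= a + 2:
        raise ValueError(f"need more than n_components+2 = {a + 2} rows, got {n}")
    Xc = X - X.mean(axis=0)
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eig = s**2 / (n - 1)
    scores = u * s
    if np.any(eig[:a] <= 0):
        raise DegenerateDataError("rank of data below n_components")
    t2 = np.sum(scores[:, :a] ** 2 / eig[:a], axis=1)
    t2_limit = float(
        a * (n - 1) * (n + 1) / (n * (n - a)) * stats.f.ppf(confidence, a, n - a)
    )
    q = np.sum(scores[:, a:] ** 2, axis=1)
    resid_eig = eig[a:]
    theta1 = float(np.sum(resid_eig))
    theta2 = float(np.sum(resid_eig**2))
    if theta1 <= 0 or theta2 <= 0:  # data exactly rank <= a
        q_limit = 0.0
    else:
        g = theta2 / theta1
        h = theta1**2 / theta2
        q_limit = float(g * stats.chi2.ppf(confidence, h))
    flags = (t2 > t2_limit) | (q > q_limit + 1e-12 * max(theta1, 1.0))
    return OutlierReport(t2=t2, q=q, t2_limit=t2_limit, q_limit=q_limit,
                         flags=flags, n_components=a, confidence=confidence)


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class PlsdaModel:
    """NIPALS PLS1 discriminant model on 0/1-coded class labels.

    Components are nested: ``coefficients_upto(k)`` returns the regression
    vector of the k-component model without refitting.  ``threshold`` is the
    decision cut on the predicted response; ties are called positive.
    """

    n_latent: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray       # (n_channels, n_latent)
    x_loadings: np.ndarray    # (n_channels, n_latent)
    y_loadings: np.ndarray    # (n_latent,)
    coefficients: np.ndarray  # regression vector of the full model
    threshold: float = 0.5

    def coefficients_upto(self, k: int) -> np.ndarray:
        if not 1 <= k <= self.n_latent:
            raise ValueError(f"k must be in [1, {self.n_latent}]")
        W = self.weights[:, :k]
        P = self.x_loadings[:, :k]
        c = self.y_loadings[:k]
        return W @ np.linalg.solve(P.T @ W, c)


def plsda_fit(X, y, n_latent: int) -> PlsdaModel:
    """Fit PLS1 by NIPALS on centered spectra and centered 0/1 class codes.

    Deflates X and y after each component.  Stops early (with fewer
    components than requested) only if the residual covariance vanishes, in
    which case the stored ``n_latent`` reflects the components actually
    extracted.
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if y.size != X.shape[0]:
        raise ValueError("X and y lengths differ")
    uniq = np.unique(y)
    if uniq.size < 2:
        raise ValueError("PLS-DA needs both classes present in y")
    if not set(np.round(uniq, 12)) <= {0.0, 1.0}:
        raise ValueError("y must be 0/1 coded (1 = falsified)")
    n, ch = X.shape
    if not 1 <= n_latent <= min(n - 1, ch):
        raise ValueError(
            f"n_latent must be in [1, min(n-1, n_channels)] = [1, {min(n - 1, ch)}]"
        )
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    scale = max(float(np.abs(Xc).max()), np.finfo(float).tiny)

    W, P, C = [], [], []
    for _ in range(n_latent):
        w = Xc.T @ yc
        wn = np.linalg.norm(w)
        if wn <= 1e-12 * scale:
            break
        w = w / wn
        t = Xc @ w
        tt = float(t @ t)
        if tt <= (1e-12 * scale) ** 2:
            break
        p = Xc.T @ t / tt
        c = float(t @ yc / tt)
        Xc = Xc - np.outer(t, p)
        yc = yc - c * t
        W.append(w)
        P.append(p)
        C.append(c)
    if not W:
        raise DegenerateDataError("no PLS component could be extracted (X'y = 0)")
    model = PlsdaModel(
        n_latent=len(W),
        x_mean=x_mean,
        y_mean=y_mean,
        weights=np.column_stack(W),
        x_loadings=np.column_stack(P),
        y_loadings=np.asarray(C),
        coefficients=np.zeros(ch),
    )
    model.coefficients = model.coefficients_upto(model.n_latent)
    return model


def plsda_predict(model: PlsdaModel, X, n_latent: int | None = None):
    """Predict continuous responses and class calls (True = falsified).

    A response equal to the threshold is called positive.
    """
    X = _as_matrix(X) if np.size(X) else np.empty((0, model.x_mean.size))
    if X.shape[1] != model.x_mean.size:
        raise ValueError("channel count does not match the fitted model")
    b = model.coefficients if n_latent is None else model.coefficients_upto(n_latent)
    resp = (X - model.x_mean) @ b + model.y_mean
    return resp, resp >= model.threshold


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvReport:
    """Cross-validated confusion counts with falsified as the positive class.

    ``sensitivity = 100·TP/(TP+FN)`` (falsified detected),
    ``specificity = 100·TN/(TN+FP)`` (genuine passed).
    """

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    scheme: str
    n_latent: list
    folds: list = field(default_factory=list)

    @property
    def balanced_accuracy(self) -> float:
        return 0.5 * (self.sensitivity + self.specificity)


def _lovo_folds(vials: np.ndarray):
    order = {}
    for v in vials:
        order.setdefault(v, None)
    return [np.flatnonzero(vials == v) for v in order]


def _stratified_folds(y: np.ndarray, n_folds: int, rng) -> list:
    folds = [[] for _ in range(n_folds)]
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i, row in enumerate(idx):
            folds[i % n_folds].append(row)
    return [np.sort(np.asarray(f)) for f in folds]


def _select_n_latent(X, y, vials, max_latent: int) -> int:
    """Inner leave-one-vial-out selection: smallest component count with the
    fewest misclassifications."""
    kmax = min(max_latent, X.shape[0] - 2, X.shape[1])
    errors = np.zeros(kmax)
    counted = np.zeros(kmax, dtype=bool)
    for test in _lovo_folds(vials):
        train = np.setdiff1d(np.arange(X.shape[0]), test)
        ytr = y[train]
        if np.unique(ytr).size < 2:
            continue
        model = plsda_fit(X[train], ytr, min(kmax, train.size - 1))
        for k in range(1, model.n_latent + 1):
            _, calls = plsda_predict(model, X[test], n_latent=k)
            errors[k - 1] += np.sum(calls != (y[test] == 1))
            counted[k - 1] = True
    if not counted.any():
        return 1
    errors[~counted] = np.inf
    return int(np.argmin(errors)) + 1  # ties -> fewest components


def cross_validate(
    X,
    y,
    n_latent: int | None = None,
    scheme: str = "leave-one-vial-out",
    vials: Sequence | None = None,
    n_folds: int = 5,
    seed=0,
    max_latent: int = 10,
) -> CvReport:
    """Cross-validated PLS-DA sensitivity/specificity.

    ``leave-one-vial-out`` holds out all replicates of one vial per fold
    (requires ``vials`` and at least two vials per class), so a vial never
    informs its own prediction; ``stratified-k-fold`` deals rows into
    ``n_folds`` class-balanced folds using ``seed``.  With ``n_latent=None``
    the component count is chosen per fold by an inner vial-grouped
    cross-validation over ``1..max_latent``.
    """
    X = _as_matrix(X)
    y = np.asarray(y, dtype=float).ravel()
    if y.size != X.shape[0]:
        raise ValueError("X and y lengths differ")
    if np.unique(y).size < 2:
        raise ValueError("cross-validation needs both classes present")

    if scheme == "leave-one-vial-out":
        if vials is None:
            raise ValueError("leave-one-vial-out requires vial ids")
        vials = np.asarray(vials, dtype=object)
        if vials.size != y.size:
            raise ValueError("vials and y lengths differ")
        for cls in np.unique(y):
            if np.unique(vials[y == cls]).size < 2:
                raise ValueError(
                    "leave-one-vial-out needs at least 2 vials per class"
                )
        folds = _lovo_folds(vials)
    elif scheme == "stratified-k-fold":
        if n_folds < 2:
            raise ValueError("need at least 2 folds")
        counts = [np.sum(y == cls) for cls in np.unique(y)]
        if min(counts) < n_folds:
            raise ValueError("n_folds exceeds the smallest class size")
        rng = np.random.default_rng(seed)
        folds = _stratified_folds(y, n_folds, rng)
        vials = np.asarray([f"row{i}" for i in range(y.size)], dtype=object)
    else:
        raise ValueError(f"unknown cross-validation scheme {scheme!r}")

    truth = y == 1
    tp = fp = tn = fn = 0
    fold_records: list = []
    used_latent: list = []
    all_idx = np.arange(X.shape[0])
    for test in folds:
        if test.size == 0:
            continue
        train = np.setdiff1d(all_idx, test)
        if np.unique(y[train]).size < 2:
            raise ValueError("a training fold lost one class entirely")
        if n_latent is None:
            k = _select_n_latent(X[train], y[train], vials[train], max_latent)
        else:
            k = int(n_latent)
        model = plsda_fit(X[train], y[train], min(k, train.size - 1))
        _, calls = plsda_predict(model, X[test])
        t = truth[test]
        ftp = int(np.sum(calls & t))
        ffp = int(np.sum(calls & ~t))
        ftn = int(np.sum(~calls & ~t))
        ffn = int(np.sum(~calls & t))
        tp, fp, tn, fn = tp + ftp, fp + ffp, tn + ftn, fn + ffn
        used_latent.append(model.n_latent)
        fold_records.append(
            {"test_rows": test.tolist(), "n_latent": model.n_latent,
             "tp": ftp, "fp": ffp, "tn": ftn, "fn": ffn}
        )
    sens, spec = confusion_metrics(
        np.concatenate([np.repeat(True, tp + fp), np.repeat(False, tn + fn)]),
        np.concatenate(
            [np.repeat(True, tp), np.repeat(False, fp),
             np.repeat(False, tn), np.repeat(True, fn)]
        ),
    )
    return CvReport(tp=tp, fp=fp, tn=tn, fn=fn,
                    sensitivity=sens, specificity=spec,
                    scheme=scheme, n_latent=used_latent, folds=fold_records)


def confusion_metrics(calls, truth):
    """Sensitivity and specificity in percent (falsified = positive).

    With no positive (or no negative) samples the corresponding rate is
    undefined and returned as NaN with a warning.
    """
    calls = np.asarray(calls, dtype=bool).ravel()
    truth = np.asarray(truth, dtype=bool).ravel()
    if calls.size != truth.size:
        raise ValueError("calls and truth lengths differ")
    pos = int(truth.sum())
    neg = int(truth.size - pos)
    if pos == 0:
        warnings.warn("no positive-class samples: sensitivity undefined",
                      RuntimeWarning, stacklevel=2)
        sens = float("nan")
    else:
        sens = 100.0 * float(np.sum(calls & truth)) / pos
    if neg == 0:
        warnings.warn("no negative-class samples: specificity undefined",
                      RuntimeWarning, stacklevel=2)
        spec = float("nan")
    else:
        spec = 100.0 * float(np.sum(~calls & ~truth)) / neg
    return sens, spec


def balanced_accuracy(calls, truth) -> float:
    """Mean of sensitivity and specificity, percent."""
    sens, spec = confusion_metrics(calls, truth)
    return 0.5 * (sens + spec)
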