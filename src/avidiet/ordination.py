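"""Correlation-matrix PCA with supplementary projection, linear discriminant
analysis with Gaussian posteriors, DAPC, and two-rater agreement kappa.

Fossil (supplementary) rows never influence the fitted rotation or the
discriminant axes: they are standardised by the training statistics and passed
through the trained transform only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateDataError, GroupError

__all__ = [
    "OrdinationResult",
    "DiscriminantResult",
    "AgreementResult",
    "pca_correlation",
    "lda",
    "dapc",
    "kappa",
]


@dataclass
class OrdinationResult:
    """PCA on the training correlation matrix with independent projection."""

    scores: pd.DataFrame
    loadings: pd.DataFrame            # variables x components, orthonormal columns
    percent_variance: np.ndarray
    center: pd.Series
    scale: pd.Series
    supplementary_scores: pd.DataFrame | None = None

    def project(self, rows: pd.DataFrame) -> pd.DataFrame:
        """Standardise by training mean/sd and rotate; training is unaffected."""
        Z = (rows[self.center.index] - self.center) / self.scale
        proj = Z.to_numpy() @ self.loadings.to_numpy()
        return pd.DataFrame(proj, index=rows.index, columns=self.loadings.columns)


def pca_correlation(X: pd.DataFrame, supplementary: pd.DataFrame | None = None) -> OrdinationResult:
    """Eigendecomposition of the correlation matrix of the training rows.

    Axis signs follow the convention that each component's largest-magnitude
    loading is positive.  Raises on zero-variance training columns (named).
    """
    if len(X) < 2:
        raise DegenerateDataError("need at least 2 training rows")
    center = X.mean()
    scale = X.std(ddof=1)
    dead = list(scale.index[scale == 0])
    if dead:
        raise DegenerateDataError(f"zero-variance columns: {dead}")
    Z = ((X - center) / scale).to_numpy()
    R = np.corrcoef(X.to_numpy(), rowvar=False)
    R = np.atleast_2d(R)
    w, V = np.linalg.eigh(R)
    order = np.argsort(w)[::-1]
    w, V = np.maximum(w[order], 0.0), V[:, order]
    # deterministic sign: largest |loading| positive
    for j in range(V.shape[1]):
        k = int(np.argmax(np.abs(V[:, j])))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    comps = [f"PC{i+1}" for i in range(V.shape[1])]
    loadings = pd.DataFrame(V, index=X.columns, columns=comps)
    scores = pd.DataFrame(Z @ V, index=X.index, columns=comps)
    pct = 100.0 * w / w.sum()
    result = OrdinationResult(scores=scores, loadings=loadings,
                              percent_variance=pct, center=center, scale=scale)
    if supplementary is not None:
        result.supplementary_scores = result.project(supplementary)
    return result


@dataclass
class DiscriminantResult:
    """Fisher discriminant axes plus shared-covariance Gaussian posteriors."""

    axes: pd.DataFrame                   # variables x LDs
    class_means: pd.DataFrame            # classes x variables
    pooled_cov: np.ndarray
    priors: pd.Series
    scores: pd.DataFrame                 # training rows x LDs
    posteriors: pd.DataFrame             # training rows x classes
    predictions: pd.Series
    percent_between_variance: np.ndarray
    supplementary_scores: pd.DataFrame | None = None
    supplementary_posteriors: pd.DataFrame | None = None
    supplementary_predictions: pd.Series | None = None
    ridge_applied: bool = False


def _posteriors(X: np.ndarray, means: np.ndarray, W_inv: np.ndarray,
                log_priors: np.ndarray) -> np.ndarray:
    """Gaussian class posteriors with a shared covariance (log-sum-exp safe)."""
    # discriminant: x' W^-1 mu_k - 0.5 mu_k' W^-1 mu_k + log pi_k
    WM = means @ W_inv                     # classes x vars
    lin = X @ WM.T
    const = -0.5 * np.sum(WM * means, axis=1) + log_priors
    scores = lin + const
    scores -= scores.max(axis=1, keepdims=True)
    e = np.exp(scores)
    return e / e.sum(axis=1, keepdims=True)


def lda(
    X: pd.DataFrame,
    groups: pd.Series,
    priors: str | dict = "proportional",
    supplementary: pd.DataFrame | None = None,
    ridge: float | None = None,
) -> DiscriminantResult:
    """Fisher LDA with shared-covariance Gaussian posterior prediction.

    Groups with fewer than 2 members are rejected by name (single-member
    categories distort discriminants).  A singular pooled within-group
    covariance triggers a ridge fallback (lambda = 1e-8 x trace/dim) with a
    warning.  ``priors`` is "proportional" (training class frequencies),
    "uniform", or an explicit mapping.
    """
    g = groups.reindex(X.index)
    if g.isna().any():
        raise GroupError(f"rows without group labels: {list(X.index[g.isna()])}")
    counts = g.value_counts()
    singles = sorted(counts.index[counts < 2])
    if singles:
        raise GroupError(f"groups with fewer than 2 members: {singles}")
    classes = sorted(counts.index)
    Xm = X.to_numpy(dtype=float)
    n, p = Xm.shape
    k = len(classes)

    means = np.vstack([Xm[(g == c).to_numpy()].mean(axis=0) for c in classes])
    grand = Xm.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for i, c in enumerate(classes):
        Xi = Xm[(g == c).to_numpy()]
        d = Xi - means[i]
        W += d.T @ d
        m = (means[i] - grand)[:, None]
        B += len(Xi) * (m @ m.T)
    W /= (n - k)
    B /= max(k - 1, 1)

    ridge_applied = False
    lam = ridge
    if lam is None:
        try:
            np.linalg.cholesky(W)
        except np.linalg.LinAlgError:
            lam = 1e-8 * np.trace(W) / p
            warnings.warn("singular pooled covariance; applying ridge fallback",
                          stacklevel=2)
            ridge_applied = True
    if lam:
        W = W + lam * np.eye(p)
        ridge_applied = True
    W_inv = np.linalg.inv(W)

    # Fisher axes: eigenvectors of W^-1 B (via symmetric whitened problem)
    evals_w, evecs_w = np.linalg.eigh(W)
    evals_w = np.maximum(evals_w, 1e-15)
    W_isqrt = evecs_w @ np.diag(1.0 / np.sqrt(evals_w)) @ evecs_w.T
    Bs = W_isqrt @ B @ W_isqrt
    evals, evecs = np.linalg.eigh(Bs)
    order = np.argsort(evals)[::-1]
    n_axes = min(k - 1, p)
    evals = np.maximum(evals[order][:n_axes], 0.0)
    A = W_isqrt @ evecs[:, order][:, :n_axes]
    for j in range(A.shape[1]):
        idx = int(np.argmax(np.abs(A[:, j])))
        if A[idx, j] < 0:
            A[:, j] = -A[:, j]
    ld_names = [f"LD{i+1}" for i in range(n_axes)]
    axes = pd.DataFrame(A, index=X.columns, columns=ld_names)

    if priors == "proportional":
        pr = counts.reindex(classes) / n
    elif priors == "uniform":
        pr = pd.Series(1.0 / k, index=classes)
    else:
        pr = pd.Series(priors).reindex(classes)
        pr = pr / pr.sum()
    log_priors = np.log(pr.to_numpy())

    post = _posteriors(Xm, means, W_inv, log_priors)
    posteriors = pd.DataFrame(post, index=X.index, columns=classes)
    predictions = posteriors.idxmax(axis=1)
    scores = pd.DataFrame((Xm - grand) @ A, index=X.index, columns=ld_names)
    pct_between = 100.0 * evals / evals.sum() if evals.sum() > 0 else np.zeros(n_axes)

    result = DiscriminantResult(
        axes=axes,
        class_means=pd.DataFrame(means, index=classes, columns=X.columns),
        pooled_cov=W,
        priors=pr,
        scores=scores,
        posteriors=posteriors,
        predictions=predictions,
        percent_between_variance=pct_between,
        ridge_applied=ridge_applied,
    )
    if supplementary is not None:
        S = supplementary[X.columns].to_numpy(dtype=float)
        sp = _posteriors(S, means, W_inv, log_priors)
        result.supplementary_posteriors = pd.DataFrame(sp, index=supplementary.index,
                                                       columns=classes)
        result.supplementary_predictions = result.supplementary_posteriors.idxmax(axis=1)
        result.supplementary_scores = pd.DataFrame(
            (S - grand) @ A, index=supplementary.index, columns=ld_names)
    return result


def dapc(
    X: pd.DataFrame,
    groups: pd.Series,
    n_pcs: int | None = None,
    supplementary: pd.DataFrame | None = None,
    priors: str | dict = "proportional",
    variance_kept: float = 99.0,
) -> DiscriminantResult:
    """LDA on correlation-matrix PCA scores (de-correlated inputs).

    ``n_pcs`` defaults to the number of components explaining
    ``variance_kept`` percent of variance.  Supplementary rows pass through
    the same PCA projection before prediction.
    """
    pca = pca_correlation(X)
    if n_pcs is None:
        cum = np.cumsum(pca.percent_variance)
        n_pcs = int(np.searchsorted(cum, variance_kept - 1e-9) + 1)
    n_pcs = min(n_pcs, pca.scores.shape[1])
    cols = pca.scores.columns[:n_pcs]
    sup = pca.project(supplementary)[cols] if supplementary is not None else None
    return lda(pca.scores[cols], groups, priors=priors, supplementary=sup)


@dataclass(frozen=True)
class AgreementResult:
    """Two-rater chance-corrected agreement."""

    kappa: float
    observed_agreement: float
    expected_agreement: float
    confusion: pd.DataFrame

    def __post_init__(self):
        if not (-1.0 - 1e-12 <= self.kappa <= 1.0 + 1e-12):
            raise ValueError("kappa outside [-1, 1]")


def kappa(true_labels, predicted_labels) -> AgreementResult:
    """Cohen's kappa: (p_o - p_e)/(1 - p_e), p_e from marginal products."""
    t = pd.Series(list(true_labels))
    p = pd.Series(list(predicted_labels))
    if len(t) == 0:
        raise ValueError("empty label sequences")
    if len(t) != len(p):
        raise ValueError("label sequences must have equal length")
    cats = sorted(set(t) | set(p))
    confusion = pd.crosstab(t, p).reindex(index=cats, columns=cats, fill_value=0)
    n = len(t)
    po = float(np.trace(confusion.to_numpy())) / n
    row = confusion.sum(axis=1).to_numpy() / n
    col = confusion.sum(axis=0).to_numpy() / n
    pe = float(np.dot(row, col))
    k = 0.0 if abs(1.0 - pe) < 1e-15 else (po - pe) / (1.0 - pe)
    return AgreementResult(kappa=float(k), observed_agreement=po,
                           expected_agreement=pe, confusion=confusion)
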