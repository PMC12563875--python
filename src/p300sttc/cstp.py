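"""Common spatiotemporal pattern (CSTP) filtering.

CSTP extends CSP by learning a spatial filter bank W (channels x M) and a
temporal filter bank V (time x K) jointly so that the ratio of projected
variance between two classes is maximized:

    max_{W,V}  tr(W' Sigma1(V) W) / tr(W' Sigma2(V) W)

where Sigma_c(V) is the class-average spatial covariance of the temporally
filtered trials Z = X V, and R_c(W) the analogous temporal covariance of
W' X.  The problem is solved by alternating generalized eigendecompositions:
given V, keep eigenvectors of Sigma1 w = lambda (Sigma1 + Sigma2) w from both
ends of the spectrum (the CSP convention, capturing variance increases for
either class); given W, the analogous temporal problem.  Each accepted update
is safeguarded so the recorded objective trace is non-decreasing.

Inside the alternation, per-trial covariances are normalized by the raw trial
energy tr(XX') (projection-independent), which makes both half-steps ascend
the same objective; the standalone :func:`class_covariances` defaults to
normalizing by the projected energy tr(ZZ').

Projected trials yield per-trial normalized log-variance features

    f_space^m = log( var(Z[m, :]) / sum_m' var(Z[m', :]) )
    f_time^k  = log( var(Z[:, k]) / sum_k' var(Z[:, k']) )

whose exponentials sum to 1 within each block.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.utils.validation import check_is_fitted

from .containers import EpochSet

__all__ = [
    "CSTP",
    "class_covariances",
    "fit_cstp",
    "project",
    "extract_features",
    "pca_project",
]


def _as_trials(ep) -> np.ndarray:
    if isinstance(ep, EpochSet):
        return ep.data
    X = np.asarray(ep, dtype=float)
    if X.ndim != 3:
        raise ValueError("expected trials x channels x time array")
    return X


def class_covariances(ep, labels, projector=None, kind: str = "spatial", normalize: str = "projected"):
    """Class-average covariance matrices of (optionally projected) trials.

    kind="spatial": per trial, Z = X V (V = ``projector``, time x K) and the
    covariance is Z Z' / norm, a channels x channels matrix.
    kind="temporal": per trial, U = W' X (W = ``projector``, channels x M) and
    the covariance is U' U / norm, a time x time matrix.

    ``normalize="projected"`` divides by the projected energy tr(ZZ') (resp.
    tr(U'U)); ``normalize="trial"`` divides by the raw trial energy tr(XX').
    Returns one matrix per class, ordered by sorted unique label.
    """
    X = _as_trials(ep)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError(f"exactly two classes required, got {classes.size}")
    out = []
    for cls in classes:
        trials = X[labels == cls]
        if trials.shape[0] < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 trials")
        acc = None
        for trial in trials:
            if kind == "spatial":
                Z = trial @ projector if projector is not None else trial
                cov = Z @ Z.T
            elif kind == "temporal":
                U = projector.T @ trial if projector is not None else trial
                cov = U.T @ U
            else:
                raise ValueError("kind must be 'spatial' or 'temporal'")
            denom = np.trace(cov) if normalize == "projected" else float(np.sum(trial**2))
            if denom <= 0:
                raise ValueError("all-zero trial encountered (zero energy)")
            acc = cov / denom if acc is None else acc + cov / denom
        cov = acc / trials.shape[0]
        out.append((cov + cov.T) / 2.0)
    return tuple(out)


def _shrink(S: np.ndarray, gamma: float) -> np.ndarray:
    c = S.shape[0]
    return (1.0 - gamma) * S + gamma * (np.trace(S) / c) * np.eye(c)


def _two_ended(eigvals: np.ndarray, eigvecs: np.ndarray, m: int) -> np.ndarray:
    """CSP selection: ceil(m/2) largest + floor(m/2) smallest eigenvectors."""
    order = np.argsort(eigvals)  # ascending
    n_hi = (m + 1) // 2
    n_lo = m // 2
    idx = list(order[::-1][:n_hi]) + list(order[:n_lo])
    W = eigvecs[:, idx]
    # canonical scaling: unit-norm columns (generalized eigenvectors come back
    # B-orthonormal, with arbitrary and possibly huge Euclidean norms),
    # sign fixed by making the largest-magnitude entry positive
    W = W / np.linalg.norm(W, axis=0, keepdims=True)
    for j in range(W.shape[1]):
        k = np.argmax(np.abs(W[:, j]))
        if W[k, j] < 0:
            W[:, j] = -W[:, j]
    return W


def _gev(S1: np.ndarray, S2: np.ndarray, m: int, gamma: float):
    """Solve S1 x = lambda (S1 + S2) x, return two-ended selection + eigvals."""
    S = _shrink(S1 + S2, gamma)
    try:
        vals, vecs = linalg.eigh(S1, S)
    except linalg.LinAlgError:
        warnings.warn("singular covariance sum; increasing shrinkage", RuntimeWarning)
        vals, vecs = linalg.eigh(S1, _shrink(S1 + S2, 1e-3))
    return _two_ended(vals, vecs, m), vals


class CSTP(BaseEstimator, TransformerMixin):
    """Common spatiotemporal pattern filter bank (scikit-learn estimator).

    Parameters
    ----------
    m_filters : int, default 6
        Number of spatial filters M (split evenly between the two eigenvalue
        extremes; odd M puts the extra filter on the large end).
    k_filters : int, default 6
        Number of temporal filters K, selected the same way.
    max_iter : int, default 20
        Maximum alternating iterations.
    tol : float, default 1e-6
        Relative objective-change convergence threshold.
    shrinkage : float, default 1e-6
        Diagonal shrinkage applied to the covariance sum before each
        generalized eigendecomposition.

    Attributes
    ----------
    W_ : ndarray (channels, M) — spatial filters.
    V_ : ndarray (time, K) — temporal filters.
    sigma1_, sigma2_ : spatial class covariances at the final V.
    r1_, r2_ : temporal class covariances at the final W.
    objective_trace_ : per-iteration objective values (non-decreasing).
    classes_ : the two labels, sorted; class 1 = ``classes_[0]``.
    converged_ : True if the relative change fell below ``tol``.
    """

    def __init__(self, m_filters: int = 6, k_filters: int = 6, max_iter: int = 20,
                 tol: float = 1e-6, shrinkage: float = 1e-6):
        self.m_filters = m_filters
        self.k_filters = k_filters
        self.max_iter = max_iter
        self.tol = tol
        self.shrinkage = shrinkage

    # -- internals -----------------------------------------------------------

    @staticmethod
    def _normalize_trials(X: np.ndarray) -> np.ndarray:
        energy = np.sqrt(np.sum(X**2, axis=(1, 2), keepdims=True))
        if np.any(energy == 0):
            raise ValueError("all-zero trial encountered")
        return X / energy

    @staticmethod
    def _spatial_covs(Xn, masks, V):
        out = []
        for mask in masks:
            Z = np.einsum("ict,tk->ick", Xn[mask], V)
            cov = np.einsum("ick,idk->cd", Z, Z) / mask.sum()
            out.append((cov + cov.T) / 2.0)
        return out

    @staticmethod
    def _temporal_covs(Xn, masks, W):
        out = []
        for mask in masks:
            U = np.einsum("cm,ict->imt", W, Xn[mask])
            cov = np.einsum("imt,ims->ts", U, U) / mask.sum()
            out.append((cov + cov.T) / 2.0)
        return out

    @staticmethod
    def _objective(W, S1, S2) -> float:
        num = float(np.trace(W.T @ S1 @ W))
        den = float(np.trace(W.T @ S2 @ W))
        if den <= 0:
            return np.inf
        return num / den

    # -- estimator API -------------------------------------------------------

    def fit(self, X, y):
        X = _as_trials(X)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("CSTP requires exactly two classes")
        n, C, T = X.shape
        if not (1 <= self.m_filters <= C):
            raise ValueError("m_filters must be in [1, n_channels]")
        if not (1 <= self.k_filters <= T):
            raise ValueError("k_filters must be in [1, n_times]")
        masks = [y == classes[0], y == classes[1]]
        if min(m.sum() for m in masks) < 2:
            raise ValueError("each class needs at least 2 trials")

        Xn = self._normalize_trials(X)

        # V init: top-K eigenvectors of the pooled temporal covariance
        R1, R2 = self._temporal_covs(Xn, masks, np.eye(C))
        vals, vecs = linalg.eigh(_shrink(R1 + R2, self.shrinkage))
        V = vecs[:, np.argsort(vals)[::-1][: self.k_filters]]
        V = V / np.linalg.norm(V, axis=0, keepdims=True)

        S1, S2 = self._spatial_covs(Xn, masks, V)
        W, eigvals = _gev(S1, S2, self.m_filters, self.shrinkage)
        J = self._objective(W, S1, S2)
        trace = [J]
        converged = False

        for _ in range(self.max_iter):
            # temporal half-step
            R1, R2 = self._temporal_covs(Xn, masks, W)
            V_cand, _ = _gev(R1, R2, self.k_filters, self.shrinkage)
            S1_cand, S2_cand = self._spatial_covs(Xn, masks, V_cand)
            J_v = self._objective(W, S1_cand, S2_cand)
            if J_v < J - 1e-12 * max(1.0, abs(J)):
                converged = True  # monotone safeguard: no improving update left
                break
            V, S1, S2, J = V_cand, S1_cand, S2_cand, J_v

            # spatial half-step
            W_cand, eigvals_cand = _gev(S1, S2, self.m_filters, self.shrinkage)
            J_w = self._objective(W_cand, S1, S2)
            if J_w < J - 1e-12 * max(1.0, abs(J)):
                trace.append(J)
                converged = True  # monotone safeguard
                break
            W, J, eigvals = W_cand, J_w, eigvals_cand
            trace.append(J)
            if len(trace) >= 2 and abs(trace[-1] - trace[-2]) <= self.tol * max(1.0, abs(trace[-2])):
                converged = True
                break

        if not converged:
            warnings.warn("CSTP alternation did not converge; returning best iterate",
                          RuntimeWarning)

        self.classes_ = classes
        self.W_ = W
        self.V_ = V
        self.spatial_eigvals_ = np.sort(eigvals)
        self.objective_trace_ = np.asarray(trace)
        self.converged_ = converged
        self.n_iter_ = len(trace)
        # spec-convention covariances at the final filters
        self.sigma1_, self.sigma2_ = class_covariances(X, y, projector=V, kind="spatial")
        self.r1_, self.r2_ = class_covariances(X, y, projector=W, kind="temporal")
        return self

    def project(self, X) -> np.ndarray:
        """Z_i = W' X_i V for every trial; returns trials x M x K."""
        check_is_fitted(self, "W_")
        X = _as_trials(X)
        if X.shape[1] != self.W_.shape[0] or X.shape[2] != self.V_.shape[0]:
            raise ValueError("trial shape incompatible with fitted filters")
        return np.einsum("cm,ict,tk->imk", self.W_, X, self.V_)

    def transform(self, X) -> np.ndarray:
        """Normalized log-variance features, trials x (M + K)."""
        Z = self.project(X)
        var_space = Z.var(axis=2)          # trials x M, variance along time
        var_time = Z.var(axis=1)           # trials x K, variance along space
        tot_s = var_space.sum(axis=1, keepdims=True)
        tot_t = var_time.sum(axis=1, keepdims=True)
        if np.any(tot_s <= 0) or np.any(tot_t <= 0):
            raise ValueError("zero total projected variance in some trial")
        return np.concatenate(
            [np.log(var_space / tot_s), np.log(var_time / tot_t)], axis=1
        )


# -- thin functional wrappers -------------------------------------------------

def fit_cstp(ep, labels, m_filters: int = 6, k_filters: int = 6,
             max_iter: int = 20, tol: float = 1e-6) -> CSTP:
    return CSTP(m_filters=m_filters, k_filters=k_filters,
                max_iter=max_iter, tol=tol).fit(_as_trials(ep), labels)


def project(model: CSTP, ep) -> np.ndarray:
    return model.project(_as_trials(ep))


def extract_features(model: CSTP, ep) -> np.ndarray:
    return model.transform(_as_trials(ep))


def pca_project(X, n_components: int = 2):
    """Column-centered SVD PCA; returns (scores, explained_variance_ratio)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    max_comp = min(X.shape)
    if n_components > max_comp:
        warnings.warn(
            f"n_components={n_components} exceeds rank bound {max_comp}; truncating",
            RuntimeWarning,
        )
        n_components = max_comp
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return scores, pca.explained_variance_ratio_
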