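"""NIPALS partial least squares and orthogonal PLS with fit statistics.

`NipalsPLS` implements PLS2 regression by the classical NIPALS iteration
with X and Y deflation; `OPLS` implements the orthogonal-signal-corrected
variant (one predictive component plus *k* orthogonal components, reported
as a "1+k" signature). Both centre X and Y internally and are scikit-learn
estimators, so they compose with `clone`, pipelines and model selection.

Model quality is summarized the way discriminant chemometrics does: R2Y
(fraction of response variance explained by the fit) and Q2Y (the same
fraction for cross-validated predictions, computed from PRESS over
stratified folds with scaling refit inside each fold). `autofit` grows the
component count greedily while Q2Y keeps improving; `vip` returns variable
influence on projection scores, whose squares average to 1 by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "NipalsPLS",
    "OPLS",
    "FitStatistics",
    "fit_pls",
    "fit_opls",
    "fit_statistics",
    "autofit",
    "vip",
    "ConvergenceError",
]

_EPS = 1e-12


class ConvergenceError(RuntimeError):
    """NIPALS failed to converge; carries the offending component index."""

    def __init__(self, component: int, message: str | None = None):
        self.component = component
        super().__init__(
            message or f"NIPALS did not converge for component {component}"
        )


def _as_2d(Y) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y[:, None] if Y.ndim == 1 else Y


class NipalsPLS(RegressorMixin, BaseEstimator):
    """PLS2 regression via NIPALS.

    Parameters
    ----------
    n_components : int
        Number of latent components A.
    max_iter : int
        Iteration cap per component.
    tol : float
        Convergence threshold on the relative change of the score vector.

    Attributes
    ----------
    x_weights_ : ndarray (p, A)
        Unit-norm weight vectors W.
    x_loadings_ : ndarray (p, A)
        Loadings P.
    x_scores_ : ndarray (n, A)
        Scores T (mutually orthogonal columns).
    y_loadings_ : ndarray (q, A)
        Response loadings C.
    coef_ : ndarray (p, q)
        Regression coefficients on centred data.
    ssy_ : ndarray (A,)
        Per-component explained Y sum of squares, (c_a'c_a)(t_a't_a).
    x_mean_, y_mean_ : ndarray
        Training means (centring is internal).
    """

    def __init__(
        self,
        n_components: int = 2,
        max_iter: int = 500,
        tol: float = 1e-10,
        strict_convergence: bool = False,
    ):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.strict_convergence = strict_convergence

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = _as_2d(Y)
        n, p = X.shape
        if Y.shape[0] != n:
            raise ValueError("X and Y row counts differ")
        A = int(self.n_components)
        if A < 1:
            raise ValueError("n_components must be >= 1")
        if A > min(n - 1, p):
            raise ValueError(
                f"n_components={A} exceeds the rank bound min(n-1, p)="
                f"{min(n - 1, p)}"
            )
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = Y.mean(axis=0)
        Xc = X - self.x_mean_
        Yc = Y - self.y_mean_
        W = np.empty((p, A))
        P = np.empty((p, A))
        T = np.empty((n, A))
        C = np.empty((Y.shape[1], A))
        ssy = np.empty(A)
        for a in range(A):
            u = Yc[:, 0].copy()
            t_old = None
            converged = False
            for _ in range(self.max_iter):
                w = Xc.T @ u
                nw = np.linalg.norm(w)
                if nw < _EPS:
                    raise ValueError(
                        f"component {a}: no X variance left (rank exceeded)"
                    )
                w /= nw
                t = Xc @ w
                tt = t @ t
                if tt < _EPS:
                    raise ValueError(
                        f"component {a}: degenerate score vector (rank exceeded)"
                    )
                c = Yc.T @ t / tt
                u = Yc @ c / (c @ c)
                if t_old is not None and np.linalg.norm(t - t_old) <= self.tol * (
                    1.0 + np.linalg.norm(t)
                ):
                    converged = True
                    break
                t_old = t
            if not converged:
                # Near-degenerate eigenpairs of X'YY'X make the score vector
                # rotate slowly inside the degenerate subspace; the fitted
                # subspace is still well determined, so by default accept
                # with a warning (raise only in strict mode).
                if self.strict_convergence:
                    raise ConvergenceError(a)
                warnings.warn(
                    f"NIPALS reached max_iter={self.max_iter} for component "
                    f"{a}; accepting current score vector",
                    RuntimeWarning,
                )
            pvec = Xc.T @ t / tt
            Xc = Xc - np.outer(t, pvec)
            Yc = Yc - np.outer(t, c)
            W[:, a], P[:, a], T[:, a], C[:, a] = w, pvec, t, c
            ssy[a] = (c @ c) * tt
        self.x_weights_, self.x_loadings_, self.x_scores_, self.y_loadings_ = W, P, T, C
        self.ssy_ = ssy
        # B = W (P'W)^-1 C'  so that  Yhat = (X - x_mean) B + y_mean
        R = W @ np.linalg.inv(P.T @ W)
        self.x_rotations_ = R
        self.coef_ = R @ C.T
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = np.asarray(X, dtype=float)
        one_d = X.ndim == 1
        if one_d:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} columns, got {X.shape[1]}"
            )
        Yhat = (X - self.x_mean_) @ self.coef_ + self.y_mean_
        if Yhat.shape[1] == 1:
            Yhat = Yhat[:, 0]
        return Yhat[0] if one_d else Yhat

    @property
    def signature(self) -> str:
        return str(self.n_components)


class OPLS(RegressorMixin, BaseEstimator):
    """Orthogonal PLS for a single response.

    Removes from X, sequentially, ``n_orthogonal`` components uncorrelated
    with y, then fits one predictive PLS component on the filtered matrix.
    The component signature is reported as ``"1+k"``.

    Attributes
    ----------
    x_weights_ : ndarray (p,)
        Predictive weight vector w (unit norm).
    x_scores_, x_loadings_ : ndarray
        Predictive score t and loading p.
    y_loading_ : float
        Predictive response loading c.
    ortho_weights_, ortho_scores_, ortho_loadings_ : ndarray (p or n, k)
        Orthogonal-component triplets (w_o, t_o, p_o).
    """

    def __init__(self, n_orthogonal: int = 0):
        self.n_orthogonal = n_orthogonal

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if y.ndim == 2:
            if y.shape[1] != 1:
                raise ValueError("OPLS supports a single response only")
            y = y[:, 0]
        n, p = X.shape
        k = int(self.n_orthogonal)
        if k < 0:
            raise ValueError("n_orthogonal must be >= 0")
        self.x_mean_ = X.mean(axis=0)
        self.y_mean_ = y.mean()
        Xf = X - self.x_mean_
        yc = y - self.y_mean_
        yy = yc @ yc
        if yy < _EPS:
            raise ValueError("degenerate response: zero variance")
        w = Xf.T @ yc / yy
        nw = np.linalg.norm(w)
        if nw < _EPS:
            raise ValueError("X carries no covariance with y")
        w /= nw
        W_o = np.empty((p, k))
        T_o = np.empty((n, k))
        P_o = np.empty((p, k))
        for j in range(k):
            t = Xf @ w
            pv = Xf.T @ t / (t @ t)
            w_o = pv - (w @ pv) * w
            norm_wo = np.linalg.norm(w_o)
            if norm_wo < _EPS:
                raise ValueError(
                    f"no orthogonal variation left at component {j + 1}; "
                    "use a smaller n_orthogonal"
                )
            w_o /= norm_wo
            t_o = Xf @ w_o
            p_o = Xf.T @ t_o / (t_o @ t_o)
            Xf = Xf - np.outer(t_o, p_o)
            W_o[:, j], T_o[:, j], P_o[:, j] = w_o, t_o, p_o
        # predictive component: 1-component PLS1 on the filtered matrix
        w_p = Xf.T @ yc
        w_p /= np.linalg.norm(w_p)
        t = Xf @ w_p
        tt = t @ t
        c = (yc @ t) / tt
        pv = Xf.T @ t / tt
        self.x_weights_ = w_p
        self.x_scores_ = t
        self.x_loadings_ = pv
        self.y_loading_ = float(c)
        self.ortho_weights_ = W_o
        self.ortho_scores_ = T_o
        self.ortho_loadings_ = P_o
        self.n_features_in_ = p
        return self

    def _filter(self, Xc: np.ndarray) -> np.ndarray:
        for j in range(self.ortho_weights_.shape[1]):
            t_o = Xc @ self.ortho_weights_[:, j]
            Xc = Xc - np.outer(t_o, self.ortho_loadings_[:, j])
        return Xc

    def predict(self, X):
        check_is_fitted(self, "x_weights_")
        X = np.asarray(X, dtype=float)
        one_d = X.ndim == 1
        if one_d:
            X = X[None, :]
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} columns, got {X.shape[1]}"
            )
        Xc = self._filter(X - self.x_mean_)
        yhat = (Xc @ self.x_weights_) * self.y_loading_ + self.y_mean_
        return yhat[0] if one_d else yhat

    @property
    def signature(self) -> str:
        return f"1+{int(self.n_orthogonal)}"


def fit_pls(X, Y, n_components: int) -> NipalsPLS:
    """Fit a :class:`NipalsPLS` model (thin wrapper)."""
    return NipalsPLS(n_components=n_components).fit(X, Y)


def fit_opls(X, y, n_orthogonal: int) -> OPLS:
    """Fit an :class:`OPLS` model (thin wrapper)."""
    return OPLS(n_orthogonal=n_orthogonal).fit(X, y)


@dataclass
class FitStatistics:
    """Goodness-of-fit (R2Y) and cross-validated predictability (Q2Y)."""

    r2y: float
    q2y: float
    r2y_increments: tuple[float, ...] = ()

    def __iter__(self):
        yield from (self.r2y, self.q2y)


def _press_folds(model, X, Y, cv, scaler, stratify, random_state):
    Y = _as_2d(Y)
    n = len(Y)
    labels = np.asarray(stratify) if stratify is not None else None
    if labels is not None:
        classes = np.unique(labels)
        skf = StratifiedKFold(n_splits=cv, shuffle=True, random_state=random_state)
        splits = skf.split(np.zeros(n), labels)
    else:
        from sklearn.model_selection import KFold

        classes = None
        splits = KFold(n_splits=cv, shuffle=True, random_state=random_state).split(
            np.zeros(n)
        )
    press = 0.0
    for train, test in splits:
        if classes is not None and len(np.unique(labels[train])) < len(classes):
            raise ValueError(
                "a cross-validation training fold lost an entire class; "
                "stratification required"
            )
        Xtr, Xte = X[train], X[test]
        if scaler is not None:
            s = clone(scaler).fit(Xtr)
            Xtr, Xte = s.transform(Xtr), s.transform(Xte)
        m = clone(model).fit(Xtr, Y[train] if Y.shape[1] > 1 else Y[train, 0])
        pred = _as_2d(m.predict(Xte))
        press += float(((Y[test] - pred) ** 2).sum())
    return press


def fit_statistics(
    model,
    X,
    Y,
    *,
    cv: int = 7,
    scaler=None,
    stratify=None,
    random_state: int = 0,
) -> FitStatistics:
    """R2Y of the full fit and Q2Y from fold-held-out predictions.

    Parameters
    ----------
    model : estimator
        Configured (unfitted) :class:`NipalsPLS` or :class:`OPLS`; cloned
        for every fold so the component structure is fixed.
    X : ndarray
        Feature matrix. If ``scaler`` is given, X is the *unscaled*
        (normalized) matrix and scaling is refit inside each fold as well as
        on the full data for R2Y.
    Y : ndarray
        Response vector or dummy matrix.
    cv : int
        Number of stratified folds (>= 2).
    stratify : array-like, optional
        Class labels driving the stratification.
    """
    if cv < 2:
        raise ValueError("cv must be >= 2")
    X = np.asarray(X, dtype=float)
    Y2 = _as_2d(Y)
    Xs = X
    if scaler is not None:
        Xs = clone(scaler).fit(X).transform(X)
    m = clone(model).fit(Xs, Y2 if Y2.shape[1] > 1 else Y2[:, 0])
    fitted = _as_2d(m.predict(Xs))
    tss = float(((Y2 - Y2.mean(axis=0)) ** 2).sum())
    r2y = 1.0 - float(((Y2 - fitted) ** 2).sum()) / tss
    press = _press_folds(model, X, Y2, cv, scaler, stratify, random_state)
    q2y = 1.0 - press / tss
    incr = ()
    if isinstance(m, NipalsPLS):
        incr = tuple(m.ssy_ / tss)
    return FitStatistics(r2y=r2y, q2y=q2y, r2y_increments=incr)


@dataclass
class AutofitResult:
    """Outcome of greedy component selection."""

    model: object
    statistics: FitStatistics
    signature: str
    q2_path: tuple[float, ...] = field(default_factory=tuple)


def autofit(
    X,
    Y,
    *,
    family: str = "pls",
    max_components: int = 10,
    min_increment: float = 0.01,
    cv: int = 7,
    scaler=None,
    stratify=None,
    random_state: int = 0,
) -> AutofitResult:
    """Grow the component count while Q2Y improves by more than a threshold.

    For ``family="pls"`` the search is over the number of latent components
    (starting at 1); for ``family="opls"`` it is over the number of
    orthogonal components k in the "1+k" signature (starting at 1+0). The
    first configuration is always kept, so at least one component is
    returned even for pure-noise responses.
    """
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    if family not in ("pls", "opls"):
        raise ValueError(f"unknown family {family!r}")

    def make(i):
        return NipalsPLS(n_components=i) if family == "pls" else OPLS(n_orthogonal=i)

    start = 1 if family == "pls" else 0
    kwargs = dict(cv=cv, scaler=scaler, stratify=stratify, random_state=random_state)
    best_i = start
    best = fit_statistics(make(start), X, Y, **kwargs)
    path = [best.q2y]
    i = start
    while i - start + 1 < max_components:
        i += 1
        try:
            stats = fit_statistics(make(i), X, Y, **kwargs)
        except (ValueError, ConvergenceError):
            break
        path.append(stats.q2y)
        if stats.q2y - best.q2y > min_increment:
            best, best_i = stats, i
        else:
            break
    model = make(best_i)
    return AutofitResult(
        model=model,
        statistics=best,
        signature=model.signature,
        q2_path=tuple(path),
    )


def vip(model) -> np.ndarray:
    """Variable influence on projection.

    For PLS2: ``VIP_j = sqrt(p * sum_a w_aj^2 SSY_a / sum_a SSY_a)`` with
    unit-norm weight vectors, so the squared VIPs average to 1. For OPLS the
    score is computed on the predictive component only, where the formula
    collapses to ``sqrt(p) * |w_j|``.
    """
    check_is_fitted(model)
    if isinstance(model, OPLS):
        w = model.x_weights_
        return np.sqrt(len(w)) * np.abs(w)
    W = model.x_weights_
    p = W.shape[0]
    share = model.ssy_ / model.ssy_.sum()
    return np.sqrt(p * (W**2 @ share))
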