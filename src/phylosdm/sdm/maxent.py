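"""L1-regularised maximum-entropy species distribution model.

``MaxEntSDM`` is a scikit-learn-style estimator: ``fit(X, y)`` takes raw
environmental values for presence rows (y = 1) and background rows
(y = 0), maximises the penalised presence log-likelihood of the Gibbs
distribution over the background

    l(lam) = mean_presence lam.f(x) - log sum_bg exp(lam.f(x))
             - RM * sum_j beta_j |lam_j|

by proximal gradient descent (FISTA with backtracking), and exposes raw,
logistic and cloglog output transforms. Feature regularisation weights
beta_j follow the sample-size-dependent class defaults scaled by the
feature standard deviation over presences.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from ..errors import ParameterError
from .features import FeatureSpec, Normalizer, build_features, feature_names

__all__ = ["MaxEntSDM"]

# MaxEnt default beta tables: (presence sample size, beta) breakpoints,
# linearly interpolated, constant outside the range.
_BETA_TABLES = {
    "LQP": [(0, 0.65), (10, 0.5), (17, 0.25), (30, 0.2), (100, 0.05)],
    "H": [(0, 0.5), (1, 0.5)],
    "T": [(0, 2.0), (100, 1.0)],
}


def _beta_default(table_key: str, m: int) -> float:
    pts = _BETA_TABLES[table_key]
    xs = [p[0] for p in pts]
    ys = [p[1] for p in pts]
    return float(np.interp(m, xs, ys))


class MaxEntSDM(BaseEstimator):
    """Maximum-entropy presence/background suitability model.

    Parameters
    ----------
    feature_classes : str
        Subset of "LQHPT" (e.g. ``"LQ"``, ``"LQHP"``).
    rm : float
        Regularisation multiplier scaling all beta weights.
    n_knots : int
        Hinge/threshold knots per layer per direction.
    transform : str
        Default output transform for :meth:`predict`:
        ``"raw"``, ``"logistic"`` or ``"cloglog"``.
    tol : float
        Convergence tolerance on the relative objective change.
    max_iter : int
        Proximal-gradient iteration cap.

    Attributes
    ----------
    coef_ : (n_features,) fitted coefficient vector.
    feature_names_ : names matching ``coef_``.
    entropy_ : entropy of the fitted raw distribution over the background.
    log_z_ : log-partition value over the training background.
    converged_ : whether the optimiser met ``tol`` within ``max_iter``.
    n_clamped_ : entries clamped to the training range in the last predict.
    """

    def __init__(
        self,
        feature_classes: str = "LQ",
        rm: float = 1.0,
        n_knots: int = 20,
        transform: str = "logistic",
        tol: float = 1e-7,
        max_iter: int = 1000,
    ):
        self.feature_classes = feature_classes
        self.rm = rm
        self.n_knots = n_knots
        self.transform = transform
        self.tol = tol
        self.max_iter = max_iter

    # -- fitting -----------------------------------------------------------

    def _betas(self, F_pres: np.ndarray) -> np.ndarray:
        m = F_pres.shape[0]
        spec = self.spec_
        std = F_pres.std(axis=0)
        # assemble per-column class labels in build_features column order
        labels: list[str] = []
        p = self.n_layers_
        n_var = p - len(self.constant_layers_)
        if spec.has("L"):
            labels += ["LQP"] * p
        if spec.has("Q"):
            labels += ["LQP"] * n_var
        if spec.has("H"):
            labels += ["H"] * (2 * spec.n_knots * n_var)
        if spec.has("P"):
            labels += ["LQP"] * (p * (p - 1) // 2)
        if spec.has("T"):
            labels += ["T"] * (spec.n_knots * n_var)
        base = np.array([_beta_default(lab, m) for lab in labels])
        # scale by the feature spread over presences; features are in [0,1]
        # so use std/sqrt(m) with a floor to keep every column penalised
        scale = np.maximum(std, 1e-3) / np.sqrt(max(m, 1))
        return base * scale

    def fit(self, X: np.ndarray, y: np.ndarray) -> "MaxEntSDM":
        """Fit from raw environmental values.

        ``y`` marks presences (1) vs background (0); normalisation bounds
        come from all rows, so presences always join the normalisation
        pool.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ParameterError("X must be 2-D (samples x layers)")
        pres, bg = X[y == 1], X[y == 0]
        if pres.shape[0] < 5:
            raise ParameterError("need >= 5 presence rows")
        if bg.shape[0] < pres.shape[0]:
            raise ParameterError("background must be at least as large as presences")
        self.spec_ = FeatureSpec(self.feature_classes, self.n_knots)
        self.n_layers_ = X.shape[1]
        self.normalizer_ = Normalizer.from_data(X)
        Z, _ = self.normalizer_(X)
        F, self.constant_layers_ = build_features(Z, self.spec_)
        F_pres, F_bg = F[y == 1], F[y == 0]
        self.feature_names_ = feature_names(
            [f"x{i}" for i in range(self.n_layers_)], self.spec_,
            self.constant_layers_,
        )
        beta = self._betas(F_pres)
        lam = np.zeros(F.shape[1])
        mean_pres = F_pres.mean(axis=0)
        n_bg = F_bg.shape[0]
        penalty_w = self.rm * beta

        def smooth_obj_grad(l: np.ndarray):
            eta = F_bg @ l
            lz = logsumexp(eta)
            q = np.exp(eta - lz)
            return lz - mean_pres @ l, F_bg.T @ q - mean_pres

        # FISTA with backtracking line search
        step = 1.0
        xk = lam.copy()
        yk = lam.copy()
        t_k = 1.0
        f_y, g_y = smooth_obj_grad(yk)
        obj_prev = f_y + penalty_w @ np.abs(yk)
        self.converged_ = False
        for _ in range(self.max_iter):
            while True:
                cand = yk - step * g_y
                cand = np.sign(cand) * np.maximum(
                    np.abs(cand) - step * penalty_w, 0.0
                )
                f_c, _ = smooth_obj_grad(cand)
                diff = cand - yk
                if f_c <= f_y + g_y @ diff + (diff @ diff) / (2 * step) + 1e-12:
                    break
                step *= 0.5
                if step < 1e-12:
                    break
            t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_k**2))
            x_next = cand
            yk = x_next + ((t_k - 1.0) / t_next) * (x_next - xk)
            xk, t_k = x_next, t_next
            f_y, g_y = smooth_obj_grad(yk)
            obj = f_c + penalty_w @ np.abs(cand)
            if abs(obj_prev - obj) <= self.tol * (abs(obj_prev) + 1.0):
                self.converged_ = True
                break
            obj_prev = obj
            step = min(step * 2.0, 1e6)
        self.coef_ = xk
        eta_bg = F_bg @ self.coef_
        self.log_z_ = float(logsumexp(eta_bg))
        q = np.exp(eta_bg - self.log_z_)
        with np.errstate(divide="ignore", invalid="ignore"):
            self.entropy_ = float(-(q * np.where(q > 0, np.log(q), 0.0)).sum())
        self.n_background_ = n_bg
        self.n_presence_ = pres.shape[0]
        self.n_clamped_ = 0
        return self

    # -- prediction --------------------------------------------------------

    @property
    def k_(self) -> int:
        """Number of nonzero coefficients."""
        return int(np.sum(self.coef_ != 0.0))

    def decision_function(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        """eta(x) = lam.f(x) - log Z over the training background."""
        Z, n_clamped = self.normalizer_(np.asarray(X, dtype=float), clamp=clamp)
        self.n_clamped_ = n_clamped
        F, _ = build_features(Z, self.spec_, self.constant_layers_)
        return F @ self.coef_ - self.log_z_

    def predict_raw(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        """Raw (relative occurrence rate) output; sums to 1 over the
        training background."""
        return np.exp(self.decision_function(X, clamp=clamp))

    def predict(
        self, X: np.ndarray, transform: str | None = None, clamp: bool = True
    ) -> np.ndarray:
        """Suitability under the requested output transform."""
        transform = transform or self.transform
        eta = self.decision_function(X, clamp=clamp)
        if transform == "raw":
            return np.exp(eta)
        c_eta = self.entropy_ + eta
        if transform == "logistic":
            return 1.0 / (1.0 + np.exp(-c_eta))
        if transform == "cloglog":
            return 1.0 - np.exp(-np.exp(c_eta))
        raise ParameterError(f"unknown transform {transform!r}")

    def log_likelihood(self, X_presence: np.ndarray, X_grid: np.ndarray) -> float:
        """Presence log-likelihood with raw output renormalised over a grid.

        This is the ENMTools convention used for AICc: ln L = sum over
        presences of ln(raw / sum of raw over all grid cells).
        """
        eta_p = self.decision_function(X_presence)
        eta_g = self.decision_function(X_grid)
        return float(np.sum(eta_p - logsumexp(eta_g)))
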