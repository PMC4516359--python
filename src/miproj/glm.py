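"""Maximum-likelihood Poisson regression with a log link and exposure offset.

The model: event counts :math:`y_i \\sim \\mathrm{Poisson}(t_i e^{\\eta_i})`
with linear predictor :math:`\\eta_i = \\beta_0 + x_i^\\top\\beta` and known
follow-up duration :math:`t_i` entering as an offset :math:`\\log t_i`.
Fitting is Newton–Raphson on the log-likelihood (equivalently IRLS; for the
canonical log link observed and expected information coincide), with the
coefficient covariance taken as the inverse Fisher information at the
optimum.  Wald standard errors, 95% intervals and p-values follow.

The fitter is deliberately written out rather than delegated: it is the
engine the rest of the package (projection gradients included) is built on.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin

from .cohort import TERMS, TERM_LABELS, ValidationError

Z975 = 1.959963984540054  # standard-normal 97.5% quantile


class ConvergenceError(RuntimeError):
    """Newton iterations failed to converge; carries the iteration trace."""

    def __init__(self, message: str, trace: list[float]):
        super().__init__(f"{message}; log-likelihood trace: {trace}")
        self.trace = trace


def _poisson_loglik(y, mu):
    # constant term -log(y!) omitted throughout (does not affect the MLE)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.where(y > 0, y * np.log(mu), 0.0) - mu
    return float(ll.sum())


class PoissonGLM(RegressorMixin, BaseEstimator):
    """Poisson rate regression (log link, log-exposure offset).

    Parameters
    ----------
    max_iter : int
        Newton iteration cap (default 100).
    score_tol : float
        Convergence when every score (gradient) coordinate is below this in
        absolute value (default 1e-8).
    loglik_rtol : float
        Alternative stop: relative log-likelihood change below this
        (default 1e-10).

    Attributes (after :meth:`fit`)
    ------------------------------
    intercept_ : float -- log baseline rate per unit exposure.
    coef_ : ndarray (p,) -- slope per design column.
    cov_ : ndarray (p+1, p+1) -- covariance of (intercept, slopes).
    se_, ci95_, p_ : Wald standard errors, intervals, p-values (same order).
    loglik_ : float -- log-likelihood at the optimum (up to the y! constant).
    n_, events_ : fit metadata.
    n_iter_ : Newton iterations used.
    feature_names_in_ : design column names.
    coding_mode_ : coding mode tag carried from the design, if present.
    """

    def __init__(self, max_iter: int = 100, score_tol: float = 1e-8,
                 loglik_rtol: float = 1e-10):
        self.max_iter = max_iter
        self.score_tol = score_tol
        self.loglik_rtol = loglik_rtol

    # ------------------------------------------------------------------ fit
    def fit(self, X, y, exposure=None) -> "PoissonGLM":
        X_df = X if isinstance(X, pd.DataFrame) else None
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        y = np.asarray(y, dtype=float)
        n, p = Xa.shape
        if y.shape != (n,):
            raise ValidationError(f"y has shape {y.shape}, expected ({n},)")
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise ValidationError("event counts must be non-negative integers")
        if exposure is None:
            t = np.ones(n)
        else:
            t = np.broadcast_to(np.asarray(exposure, dtype=float), (n,)).copy()
        if np.any(t <= 0):
            raise ValidationError("exposure must be strictly positive")
        if y.sum() < 1:
            raise ValidationError("no events in the data; cannot fit a rate model")

        names = list(X_df.columns) if X_df is not None else [f"x{j}" for j in range(p)]
        self._check_separation(Xa, y, names)

        D = np.column_stack([np.ones(n), Xa])  # intercept first
        if np.linalg.matrix_rank(D) < p + 1:
            raise ValidationError("design matrix is rank-deficient (collinear columns)")

        offset = np.log(t)
        theta = np.zeros(p + 1)
        theta[0] = np.log(y.sum() / t.sum())  # closed-form intercept-only start
        mu = np.exp(D @ theta + offset)
        ll = _poisson_loglik(y, mu)
        trace = [ll]
        converged = False
        for it in range(1, self.max_iter + 1):
            score = D.T @ (y - mu)
            info = (D * mu[:, None]).T @ D
            try:
                step = np.linalg.solve(info, score)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(f"singular information matrix at iteration {it}", trace) from exc
            # damped Newton: halve the step until the log-likelihood improves
            new_theta, new_ll = theta + step, -np.inf
            for _ in range(30):
                new_mu = np.exp(D @ new_theta + offset)
                new_ll = _poisson_loglik(y, new_mu)
                if new_ll >= ll - 1e-12:
                    break
                new_theta = theta + (new_theta - theta) / 2.0
            rel_change = abs(new_ll - ll) / (abs(ll) + 1e-300)
            theta, mu, ll = new_theta, np.exp(D @ new_theta + offset), new_ll
            trace.append(ll)
            score = D.T @ (y - mu)
            if np.max(np.abs(score)) < self.score_tol or rel_change < self.loglik_rtol:
                converged = True
                break
        if not converged:
            raise ConvergenceError(f"no convergence in {self.max_iter} iterations", trace)

        info = (D * mu[:, None]).T @ D
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
        self.intercept_ = float(theta[0])
        self.coef_ = theta[1:].copy()
        self.cov_ = cov
        self.se_ = se
        self.ci95_ = np.column_stack([theta - Z975 * se, theta + Z975 * se])
        self.p_ = 2.0 * stats.norm.sf(np.abs(theta / se))
        self.loglik_ = ll
        self.n_iter_ = it
        self.n_ = n
        self.events_ = int(y.sum())
        self.n_features_in_ = p
        self.feature_names_in_ = np.asarray(names, dtype=object)
        self.coding_mode_ = (X_df.attrs.get("coding_mode") if X_df is not None else None)
        return self

    @staticmethod
    def _check_separation(Xa: np.ndarray, y: np.ndarray, names: list[str]) -> None:
        """Error on a binary covariate level with zero events (MLE at infinity)."""
        for j in range(Xa.shape[1]):
            col = Xa[:, j]
            vals = np.unique(col)
            if len(vals) == 2 and set(vals) <= {0.0, 1.0}:
                for level in (0.0, 1.0):
                    mask = col == level
                    if mask.any() and y[mask].sum() == 0:
                        raise ValidationError(
                            f"separation: covariate {names[j]!r} level {int(level)} "
                            "has zero events; coefficient is not identifiable"
                        )

    # ------------------------------------------------------------- predict
    def _eta(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            mode = X.attrs.get("coding_mode")
            if mode is not None and self.coding_mode_ is not None and mode != self.coding_mode_:
                raise ValidationError(
                    f"coding-mode mismatch: model is {self.coding_mode_!r}, design is {mode!r}"
                )
            if list(X.columns) != list(self.feature_names_in_):
                X = X[list(self.feature_names_in_)]
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[None, :]
        return self.intercept_ + Xa @ self.coef_

    def predict_rate(self, X) -> np.ndarray:
        """Expected events per unit exposure: exp(intercept + beta.x)."""
        return np.exp(self._eta(X))

    def predict(self, X, exposure=1.0) -> np.ndarray:
        """Expected event count over the given exposure."""
        return np.exp(self._eta(X)) * np.asarray(exposure, dtype=float)

    # ------------------------------------------------------------- summary
    @property
    def params_(self) -> np.ndarray:
        """(intercept, slopes) in design order."""
        return np.concatenate([[self.intercept_], self.coef_])

    def wald_summary(self) -> pd.DataFrame:
        """Per-term coefficient table (coefficient, SE, 95% CI, p-value).

        Rows appear in the canonical term order (Sex, Age, Hypertension,
        Diabetes, Smoking, Waist circumference, Triglyceride, HDL, LDL) when
        the design used those names, with the intercept appended last;
        otherwise in design order after the intercept.
        """
        names = ["intercept"] + list(self.feature_names_in_)
        tab = pd.DataFrame(
            {
                "term": names,
                "coefficient": self.params_,
                "se": self.se_,
                "ci_low": self.ci95_[:, 0],
                "ci_high": self.ci95_[:, 1],
                "p": self.p_,
            }
        )
        known = [t for t in TERMS if t in set(self.feature_names_in_)]
        if known:
            order = known + [n for n in self.feature_names_in_ if n not in set(TERMS)] + ["intercept"]
            tab = tab.set_index("term").loc[order].reset_index()
        tab["label"] = tab["term"].map(lambda t: TERM_LABELS.get(t, t))
        return tab


def fit(design: pd.DataFrame, events, exposure=None, **kwargs) -> PoissonGLM:
    """Fit a Poisson rate model; thin wrapper over :class:`PoissonGLM`."""
    return PoissonGLM(**kwargs).fit(design, events, exposure=exposure)


def predict_rate(model: PoissonGLM, x) -> np.ndarray:
    """Rate prediction; thin wrapper over :meth:`PoissonGLM.predict_rate`."""
    return model.predict_rate(x)


def wald_summary(model: PoissonGLM) -> pd.DataFrame:
    """Coefficient table; thin wrapper over :meth:`PoissonGLM.wald_summary`."""
    return model.wald_summary()


def wald_ci(beta: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Wald interval beta +/- z * se at the given level."""
    z = stats.norm.ppf(0.5 + level / 2.0)
    return beta - z * se, beta + z * se
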