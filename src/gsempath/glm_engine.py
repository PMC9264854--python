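"""Maximum-likelihood fitting of the recursive equation system.

Each equation is a binary logit or a baseline-category multinomial logit and
is fit on its own complete cases by Newton-Raphson with step-halving.  Because
the system is recursive over fully observed variables with independently
specified residuals, the joint likelihood factorizes into the per-equation
likelihoods, so equation-by-equation ML *is* the joint ML; no joint optimizer
is needed and the system log-likelihood is the sum of the per-equation ones.

Numerical contract: convergence on score max-norm <= 1e-8 or relative
log-likelihood change <= 1e-10, at most 100 Newton iterations with at most 20
halvings per step; covariance is the inverse observed information (for the
canonical logit link, observed and expected information coincide); any
coefficient exceeding 15 in absolute value during iteration is treated as
complete or quasi-complete separation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .model_spec import DesignMatrix, EquationSpec, PathDiagram, encode_design

__all__ = [
    "EquationFit",
    "SystemFit",
    "FitError",
    "SingularDesignError",
    "SeparationError",
    "ConvergenceError",
    "fit_binary_logit",
    "fit_multinomial_logit",
    "fit_equation",
    "fit_system",
    "log_likelihood",
]

GRAD_TOL = 1e-8
LL_RELTOL = 1e-10
MAX_ITER = 100
MAX_HALVINGS = 20
SEPARATION_BOUND = 15.0
Z95 = 1.959964


class FitError(RuntimeError):
    """Base class for estimation failures."""


class SingularDesignError(FitError):
    pass


class SeparationError(FitError):
    pass


class ConvergenceError(FitError):
    pass


@dataclass
class EquationFit:
    """MLE of one equation: coefficients on the log-odds scale, their
    covariance, and fit bookkeeping.

    Parameters are laid out contrast-major: all terms of the first contrast,
    then all terms of the second, matching ``covariance`` rows/columns.
    """

    response: str
    contrasts: list[str]                 # response levels contrasted with baseline
    baseline: str
    terms: list[str]                     # design column names incl. Intercept
    params: np.ndarray                   # shape (n_contrasts, n_terms)
    covariance: np.ndarray               # shape (C*T, C*T)
    log_likelihood: float
    n_used: int
    rows_dropped: int
    converged: bool
    iterations: int
    family: str = "bernoulli"
    _ix: dict[tuple[str, str], int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._ix:
            self._ix = {
                (c, t): i * len(self.terms) + j
                for i, c in enumerate(self.contrasts)
                for j, t in enumerate(self.terms)
            }

    # -- lookups ------------------------------------------------------------
    def _index(self, contrast: Optional[str], term: str) -> int:
        if contrast is None:
            if len(self.contrasts) != 1:
                raise KeyError(f"{self.response}: contrast must be named (one of {self.contrasts})")
            contrast = self.contrasts[0]
        key = (contrast, term)
        if key not in self._ix:
            raise KeyError(f"{self.response}: no coefficient for contrast={contrast!r} term={term!r}")
        return self._ix[key]

    def has(self, contrast: Optional[str], term: str) -> bool:
        try:
            self._index(contrast, term)
            return True
        except KeyError:
            return False

    def coef(self, term: str, contrast: Optional[str] = None) -> float:
        i = self._index(contrast, term)
        return float(self.params.ravel()[i])

    def se(self, term: str, contrast: Optional[str] = None) -> float:
        i = self._index(contrast, term)
        return float(np.sqrt(self.covariance[i, i]))

    def cov(self, term_a: str, term_b: str,
            contrast_a: Optional[str] = None, contrast_b: Optional[str] = None) -> float:
        i = self._index(contrast_a, term_a)
        j = self._index(contrast_b, term_b)
        return float(self.covariance[i, j])

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Fitted category probabilities, baseline first then contrasts in
        order; rows sum to one."""
        X = np.asarray(X, dtype=float)
        eta = X @ self.params.T                       # n x C
        m = np.maximum(eta.max(axis=1), 0.0)
        denom = np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1)
        base = np.exp(-m) / denom
        rest = np.exp(eta - m[:, None]) / denom[:, None]
        return np.column_stack([base, rest])

    @property
    def coefficients(self) -> dict[tuple[str, str], float]:
        flat = self.params.ravel()
        return {key: float(flat[i]) for key, i in self._ix.items()}

    def to_frame(self) -> pd.DataFrame:
        """Long-format coefficient table with Wald SEs, 95% CIs, and p-values."""
        rows = []
        flat = self.params.ravel()
        for (contrast, term), i in self._ix.items():
            est = float(flat[i])
            se = float(np.sqrt(self.covariance[i, i]))
            z = est / se if se > 0 else np.inf * np.sign(est)
            rows.append(
                {
                    "equation": self.response,
                    "contrast": contrast,
                    "term": term,
                    "estimate": est,
                    "se": se,
                    "ci_low": est - Z95 * se,
                    "ci_high": est + Z95 * se,
                    "p": 2 * stats.norm.sf(abs(z)),
                    "n": self.n_used,
                }
            )
        return pd.DataFrame(rows)


@dataclass
class SystemFit:
    """The union of per-equation fits; total log-likelihood is their sum."""

    fits: dict[str, EquationFit]

    @property
    def total_log_likelihood(self) -> float:
        return float(sum(f.log_likelihood for f in self.fits.values()))

    def __getitem__(self, response: str) -> EquationFit:
        return self.fits[response]

    def to_frame(self) -> pd.DataFrame:
        return pd.concat([f.to_frame() for f in self.fits.values()], ignore_index=True)

    @classmethod
    def from_coefficient_table(cls, table: pd.DataFrame) -> "SystemFit":
        """Assemble a SystemFit from a long coefficient table (columns:
        equation, contrast, term, estimate and either se or ci_low/ci_high).

        Intended for decomposing a published coefficient set without refitting;
        cross-coefficient covariances are unavailable and set to zero, so
        delta-method variances use the diagonal only.
        """
        table = table.copy()
        if "se" not in table.columns:
            table["se"] = (table["ci_high"] - table["ci_low"]) / (2 * Z95)
        fits = {}
        for response, block in table.groupby("equation", sort=False):
            contrasts = list(dict.fromkeys(block["contrast"]))
            terms = list(dict.fromkeys(block["term"]))
            C, T = len(contrasts), len(terms)
            params = np.zeros((C, T))
            var = np.zeros(C * T)
            seen = np.zeros((C, T), dtype=bool)
            for _, row in block.iterrows():
                i, j = contrasts.index(row["contrast"]), terms.index(row["term"])
                params[i, j] = row["estimate"]
                var[i * T + j] = float(row["se"]) ** 2
                seen[i, j] = True
            if not seen.all():
                missing = [(contrasts[i], terms[j]) for i, j in zip(*np.where(~seen))]
                raise ValueError(f"{response}: coefficient table is ragged, missing {missing}")
            n = int(block["n"].iloc[0]) if "n" in block.columns else 0
            fits[response] = EquationFit(
                response=response,
                contrasts=contrasts,
                baseline="",
                terms=terms,
                params=params,
                covariance=np.diag(var),
                log_likelihood=np.nan,
                n_used=n,
                rows_dropped=0,
                converged=True,
                iterations=0,
                family="bernoulli" if C == 1 else "multinomial",
            )
        return cls(fits=fits)


# ---------------------------------------------------------------------------
# Newton-Raphson core

def _check_rank(X: np.ndarray, columns: Sequence[str]) -> None:
    _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        bad = sorted(columns[i] for i in piv[rank:])
        raise SingularDesignError(f"design is rank deficient; collinear column(s): {bad}")


def _newton(theta0, negloglik_grad_hess):
    """Maximize a log-likelihood by damped Newton steps.

    ``negloglik_grad_hess(theta)`` returns (ll, grad, hess) of the
    log-likelihood.  Log-likelihood never decreases across accepted steps;
    each proposed step is halved (up to MAX_HALVINGS) until it improves.
    """
    theta = theta0.copy()
    ll, grad, hess = negloglik_grad_hess(theta)
    converged = False
    it = 0
    for it in range(1, MAX_ITER + 1):
        if np.max(np.abs(grad)) <= GRAD_TOL:
            converged = True
            it -= 1
            break
        try:
            step = linalg.solve(-hess, grad, assume_a="sym")
        except linalg.LinAlgError as exc:  # pragma: no cover - guarded by rank check
            raise SingularDesignError(f"information matrix is singular: {exc}") from exc
        scale = 1.0
        for _ in range(MAX_HALVINGS + 1):
            cand = theta + scale * step
            ll_new, grad_new, hess_new = negloglik_grad_hess(cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise ConvergenceError(
                f"step-halving failed after {MAX_HALVINGS} halvings (ll={ll:.6g})"
            )
        theta, grad, hess = cand, grad_new, hess_new
        if np.max(np.abs(theta)) > SEPARATION_BOUND:
            raise SeparationError(
                "separation suspected: a coefficient exceeded "
                f"{SEPARATION_BOUND} on the log-odds scale during iteration"
            )
        rel_change = abs(ll_new - ll) / (abs(ll) + 1e-300)
        ll = ll_new
        if np.max(np.abs(grad)) <= GRAD_TOL or rel_change <= LL_RELTOL:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"no convergence in {MAX_ITER} iterations; "
            f"|grad|_max={np.max(np.abs(grad)):.3g}, ll={ll:.6g}"
        )
    cov = linalg.inv(-hess)
    return theta, ll, cov, it


def fit_binary_logit(
    X: np.ndarray,
    y: np.ndarray,
    columns: Sequence[str],
    weights: Optional[np.ndarray] = None,
    *,
    response: str = "y",
    contrast: str = "1",
    baseline: str = "0",
    rows_dropped: int = 0,
) -> EquationFit:
    """Newton-Raphson MLE of a binary logit; covariance is the inverse
    observed information.  ``y`` must be coded 0/1."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("X and y are not conformable")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binary response must be coded 0/1")
    if y.size == 0:
        raise FitError(f"{response}: no usable rows")
    events = float(w @ y)
    if events == 0 or events == float(w.sum()):
        raise SeparationError(f"{response}: response is constant; logit MLE does not exist")
    _check_rank(np.sqrt(w)[:, None] * X, columns)

    def llgh(beta):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        ll = float(w @ (y * eta - np.logaddexp(0.0, eta)))
        grad = X.T @ (w * (y - p))
        wvar = w * p * (1.0 - p)
        hess = -(X.T * wvar) @ X
        return ll, grad, hess

    theta, ll, cov, it = _newton(np.zeros(X.shape[1]), llgh)
    return EquationFit(
        response=response,
        contrasts=[contrast],
        baseline=baseline,
        terms=list(columns),
        params=theta[None, :],
        covariance=cov,
        log_likelihood=ll,
        n_used=int(len(y)),
        rows_dropped=rows_dropped,
        converged=True,
        iterations=it,
        family="bernoulli",
    )


def fit_multinomial_logit(
    X: np.ndarray,
    y_codes: np.ndarray,
    levels: Sequence[str],
    baseline: str,
    columns: Sequence[str],
    weights: Optional[np.ndarray] = None,
    *,
    response: str = "y",
    rows_dropped: int = 0,
) -> EquationFit:
    """Baseline-category multinomial logit: K-1 log-odds contrasts against the
    baseline, fit jointly.  ``y_codes`` indexes into ``levels``.  Levels
    observed zero times are dropped from the contrast set with a warning."""
    X = np.asarray(X, dtype=float)
    y_codes = np.asarray(y_codes, dtype=np.int64)
    w = np.ones(len(y_codes)) if weights is None else np.asarray(weights, dtype=float)
    levels = list(levels)
    if baseline not in levels:
        raise ValueError(f"baseline {baseline!r} not among levels")
    if y_codes.size == 0:
        raise FitError(f"{response}: no usable rows")

    observed = {levels[c] for c in np.unique(y_codes)}
    if baseline not in observed:
        raise SeparationError(f"{response}: baseline category {baseline!r} unobserved")
    contrasts = [l for l in levels if l != baseline and l in observed]
    dropped_levels = [l for l in levels if l != baseline and l not in observed]
    for lvl in dropped_levels:
        warnings.warn(
            f"{response}: category {lvl!r} observed zero times; contrast omitted",
            RuntimeWarning,
            stacklevel=2,
        )
    if not contrasts:
        raise SeparationError(f"{response}: response is constant; MLE does not exist")
    _check_rank(np.sqrt(w)[:, None] * X, columns)

    C, p = len(contrasts), X.shape[1]
    # indicator matrix n x C for the non-baseline observed contrasts
    code_of = {levels.index(l): k for k, l in enumerate(contrasts)}
    Y = np.zeros((len(y_codes), C))
    for code, k in code_of.items():
        Y[:, k] = y_codes == code

    def llgh(theta):
        B = theta.reshape(C, p)
        eta = X @ B.T                                   # n x C
        m = np.maximum(eta.max(axis=1), 0.0)
        denom = np.exp(-m) + np.exp(eta - m[:, None]).sum(axis=1)
        logdenom = m + np.log(denom)
        ll = float(w @ ((Y * eta).sum(axis=1) - logdenom))
        P = np.exp(eta - logdenom[:, None])             # n x C
        grad = ((w[:, None] * (Y - P)).T @ X).ravel()
        hess = np.empty((C * p, C * p))
        for a in range(C):
            for b in range(a, C):
                wab = w * P[:, a] * ((a == b) - P[:, b])
                block = -(X.T * wab) @ X
                hess[a * p:(a + 1) * p, b * p:(b + 1) * p] = block
                if b != a:
                    hess[b * p:(b + 1) * p, a * p:(a + 1) * p] = block
        return ll, grad, hess

    theta, ll, cov, it = _newton(np.zeros(C * p), llgh)
    return EquationFit(
        response=response,
        contrasts=contrasts,
        baseline=baseline,
        terms=list(columns),
        params=theta.reshape(C, p),
        covariance=cov,
        log_likelihood=ll,
        n_used=int(len(y_codes)),
        rows_dropped=rows_dropped,
        converged=True,
        iterations=it,
        family="multinomial",
    )


def fit_equation(
    diagram: PathDiagram,
    equation: EquationSpec,
    records: pd.DataFrame,
    weight_column: Optional[str] = None,
) -> EquationFit:
    """Encode one equation's design on its complete cases and fit it."""
    design: DesignMatrix = encode_design(records, diagram, equation, weight_column)
    resp = diagram.variable(equation.response)
    if equation.family == "bernoulli":
        y01 = (design.response != design.baseline_index).astype(float)
        contrast = resp.non_reference_levels[0]
        return fit_binary_logit(
            design.X,
            y01,
            design.columns,
            design.weights,
            response=equation.response,
            contrast=contrast,
            baseline=resp.reference_level,
            rows_dropped=design.rows_dropped,
        )
    return fit_multinomial_logit(
        design.X,
        design.response,
        design.response_levels,
        resp.reference_level,
        design.columns,
        design.weights,
        response=equation.response,
        rows_dropped=design.rows_dropped,
    )


def fit_system(
    diagram: PathDiagram,
    records: pd.DataFrame,
    weight_column: Optional[str] = None,
) -> SystemFit:
    """Fit every equation of the diagram, each on its own complete cases.

    Per-equation sample sizes may differ: a variable missing for most rows
    (e.g. one collected only in a survey subsample) shrinks only the equations
    it enters.
    """
    fits: dict[str, EquationFit] = {}
    for eq in diagram.equations:
        try:
            fits[eq.response] = fit_equation(diagram, eq, records, weight_column)
        except FitError as exc:
            raise type(exc)(f"equation {eq.response!r}: {exc}") from exc
    return SystemFit(fits=fits)


def log_likelihood(fit: EquationFit) -> float:
    """The maximized log-likelihood of a fitted equation (always <= 0)."""
    if not fit.converged:
        raise FitError(f"{fit.response}: fit did not converge")
    return fit.log_likelihood
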