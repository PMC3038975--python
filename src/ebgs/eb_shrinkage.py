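"""Empirical Bayes shrinkage estimation of all marker effects at once.

Model
-----
The plot-mean-adjusted record value is

    y_j = beta + sum_k Z_jk gamma_k + eps_j,      eps_j ~ N(0, sigma^2)

where the sum runs over all model terms (marker main effects and,
optionally, marker-pair epistatic effects; every Z column is +1/-1).
Each effect gets a normal prior gamma_k ~ N(0, sigma_k^2) with its own
variance component, and each sigma_k^2 a scaled inverse chi-square
hyperprior Inv-chi2(tau, omega).  The default (tau, omega) = (-2, 0)
makes that hyperprior flat: p(sigma_k^2) = 1.

Algorithm
---------
Iterative conditional-mode empirical Bayes.  With current variances the
marginal covariance of y is V = Z D Z' + sigma^2 I (D = diag(sigma_k^2)).
Each sweep visits every term once, computes the marginal posterior mean
and variance of its effect,

    gamma_hat_k = sigma_k^2 Z_k' V^{-1} (y - beta),
    V_k         = sigma_k^2 - sigma_k^4 Z_k' V^{-1} Z_k,

updates sigma_k^2 <- max(floor, (gamma_hat_k^2 + V_k + omega)/(tau + 3))
(= gamma_hat_k^2 + V_k under the flat hyperprior), and folds the change
into V^{-1} by a rank-one Sherman-Morrison update.  beta is re-estimated
by GLS and sigma^2 by its EM update once per sweep.  The iteration is a
monotone ECM ascent of the marginal posterior; fixed points satisfy
sigma_k^2 = gamma_hat_k^2 + V_k, so the reported per-term variance equals
effect^2 + (posterior standard error)^2.

Because replicate records of a line share its design row, all per-term
algebra is carried out on the line-level aggregation R' V^{-1} R (R the
record -> line incidence), an (n_lines x n_lines) matrix, which makes a
sweep over all m(m+1)/2 epistatic terms cheap.

Estimates are deterministic given the inputs: there is no randomised
initialisation (all sigma_k^2 start at 1e-4 var(y), sigma^2 at var(y)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .design_matrix import DesignMatrix, ModelTerm
from .errors import NumericalError, ValidationError
from .io_data import PhenotypeTable

logger = logging.getLogger(__name__)

# init / floor scales relative to var(y); see docs for rationale
_INIT_SIGMA2K_SCALE = 1e-4
_VAR_FLOOR_SCALE = 1e-12


@dataclass
class EBConfig:
    """Settings of the empirical Bayes fit.

    tau, omega
        Hyperprior parameters of Inv-chi2(tau, omega) on each effect
        variance.  The default (-2, 0) is the flat prior.
    max_sweeps, rel_tol
        Iteration cap and convergence tolerance on the maximum relative
        change of any variance component between sweeps.
    var_floor
        Smallest admissible sigma_k^2 (absolute).  ``None`` resolves to
        1e-12 * var(y) at fit time so standard errors stay defined while
        floored effects report as essentially zero.
    seed
        Unused; present to make the deterministic contract explicit.
    """

    tau: float = -2.0
    omega: float = 0.0
    max_sweeps: int = 200
    rel_tol: float = 1e-8
    var_floor: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.max_sweeps < 1:
            raise ValidationError("max_sweeps must be >= 1")
        if self.rel_tol <= 0:
            raise ValidationError("rel_tol must be > 0")
        if self.var_floor is not None and self.var_floor <= 0:
            raise ValidationError("var_floor must be > 0")
        if self.tau + 3.0 <= 0:
            raise ValidationError("tau must exceed -3 for a proper variance update")


@dataclass
class EBFit:
    """Converged empirical Bayes estimates for one design."""

    terms: list[ModelTerm]
    beta_hat: float
    gamma_hat: np.ndarray
    se_gamma: np.ndarray
    sigma2_k: np.ndarray
    sigma2_resid: float
    sweeps_run: int
    converged: bool
    config: EBConfig
    design: DesignMatrix | None = None
    degenerate: np.ndarray | None = None

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.terms]

    def term_index(self) -> dict[str, int]:
        return {t.label: i for i, t in enumerate(self.terms)}

    def to_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "kind": [t.kind for t in self.terms],
                "variance": self.sigma2_k,
                "effect": self.gamma_hat,
                "std_err": self.se_gamma,
            }
        )


# ---------------------------------------------------------------------------
# compact line-level representation
# ---------------------------------------------------------------------------


class _Compact:
    """Design collapsed to the distinct genotype rows actually referenced."""

    def __init__(self, y: np.ndarray, design: DesignMatrix):
        rec = design.record_index
        used, inv = np.unique(rec, return_inverse=True)
        self.Z = design.line_matrix[used].astype(np.float64)  # (L, p)
        self.rec = inv  # record -> compact row
        self.r = np.bincount(inv, minlength=used.size).astype(np.float64)
        self.y = np.asarray(y, dtype=np.float64)
        self.n = self.y.size
        self.L, self.p = self.Z.shape
        self.sy = np.bincount(inv, weights=self.y, minlength=used.size)

    def rebuild(self, sigma2_k: np.ndarray, sigma2: float):
        """Return (M, wy) = (R'V^-1 R, R'V^-1 y) for current variances."""
        G = (self.Z * sigma2_k) @ self.Z.T
        K = np.eye(self.L) + (G * self.r[None, :]) / sigma2
        try:
            B = scipy.linalg.solve(K, G, assume_a="gen") / sigma2
        except scipy.linalg.LinAlgError as exc:  # pragma: no cover - rare
            raise NumericalError(f"singular covariance: {exc}") from exc
        B = 0.5 * (B + B.T)
        rB = self.r[:, None] * B
        M = (np.diag(self.r) - rB * self.r[None, :]) / sigma2
        M = 0.5 * (M + M.T)
        wy = (self.sy - rB @ self.sy) / sigma2
        return M, B, wy

    def gls_beta(self, M: np.ndarray, wy: np.ndarray) -> float:
        denom = float(M.sum())
        if denom <= 0:
            raise NumericalError("non-positive GLS normaliser for the intercept")
        return float(wy.sum() / denom)


def _resolve_y(y) -> np.ndarray:
    if isinstance(y, PhenotypeTable):
        y = y.adjusted
    arr = np.asarray(y, dtype=float).ravel()
    if arr.size and not np.isfinite(arr).all():
        raise ValidationError("phenotype vector contains non-finite values")
    return arr


# ---------------------------------------------------------------------------
# fixed-variance BLUP / GLS solve
# ---------------------------------------------------------------------------


def blup_given_variances(
    y,
    design: DesignMatrix,
    sigma2_k: Sequence[float] | np.ndarray,
    sigma2_resid: float,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Posterior mean and sd of all effects with variances held fixed.

    Returns ``(beta_hat, gamma_hat, se_gamma)`` for the Gaussian model with
    known variance components: the GLS intercept, the BLUP/ridge-type
    effect solution ``D Z' V^{-1} (y - beta)`` and the marginal posterior
    standard deviations ``sqrt(sigma_k^2 - sigma_k^4 Z_k' V^{-1} Z_k)``.
    """
    y = _resolve_y(y)
    if y.size != design.n_records:
        raise ValidationError("length of y does not match design rows")
    sigma2_k = np.asarray(sigma2_k, dtype=float)
    if sigma2_k.shape != (design.n_terms,):
        raise ValidationError("sigma2_k length does not match number of terms")
    if (sigma2_k < 0).any():
        raise ValidationError("sigma2_k must be nonnegative")
    if sigma2_resid <= 0:
        raise NumericalError(
            "residual variance must be positive (singular covariance otherwise)"
        )
    c = _Compact(y, design)
    if c.p <= c.L:
        return _blup_primal(c, sigma2_k, float(sigma2_resid))
    M, _, wy = c.rebuild(sigma2_k, float(sigma2_resid))
    beta = c.gls_beta(M, wy)
    w = wy - beta * M.sum(axis=1)
    gamma = sigma2_k * (c.Z.T @ w)
    s = ((M @ c.Z) * c.Z).sum(axis=0)
    post_var = np.clip(sigma2_k - sigma2_k**2 * s, 0.0, None)
    return beta, gamma, np.sqrt(post_var)


def _blup_primal(
    c: _Compact, sigma2_k: np.ndarray, sigma2: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """p x p ridge-normal-equation route; stable for very large sigma_k^2."""
    active = sigma2_k > 0
    Za = c.Z[:, active]
    ZtZ = (Za * c.r[:, None]).T @ Za  # expanded Z'Z via replicate counts
    A = ZtZ / sigma2 + np.diag(1.0 / sigma2_k[active])
    try:
        Ainv = scipy.linalg.inv(A)
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError(f"singular posterior precision: {exc}") from exc
    # GLS intercept via Woodbury: V^-1 = (I - Z A^-1 Z'/s2)/s2 on records
    u1 = Za.T @ c.r  # Z' 1 over expanded records
    uy = Za.T @ c.sy  # Z' y
    one_v_one = (c.n - u1 @ Ainv @ u1 / sigma2) / sigma2
    one_v_y = (float(c.sy.sum()) - u1 @ Ainv @ uy / sigma2) / sigma2
    if one_v_one <= 0:
        raise NumericalError("non-positive GLS normaliser for the intercept")
    beta = float(one_v_y / one_v_one)
    gamma = np.zeros(c.p)
    gamma[active] = Ainv @ (uy - beta * u1) / sigma2
    post_var = np.zeros(c.p)
    post_var[active] = np.clip(np.diag(Ainv), 0.0, None)
    return beta, gamma, np.sqrt(post_var)


# ---------------------------------------------------------------------------
# marginal objective
# ---------------------------------------------------------------------------


def marginal_log_posterior(
    y,
    design: DesignMatrix,
    sigma2_k: Sequence[float] | np.ndarray,
    sigma2_resid: float,
    config: EBConfig | None = None,
) -> float:
    """Log marginal likelihood of y (effects integrated out) plus log prior.

    The Gaussian marginal is N(y | beta_hat * 1, Z D Z' + sigma^2 I) with
    beta profiled out by GLS.  The (unnormalised) hyperprior contributes
    ``sum_k [-(tau+2)/2 * log sigma_k^2 - omega/(2 sigma_k^2)]``, which is
    identically zero at the flat choice (tau, omega) = (-2, 0).
    """
    config = config or EBConfig()
    y = _resolve_y(y)
    sigma2_k = np.asarray(sigma2_k, dtype=float)
    if (sigma2_k < 0).any() or sigma2_resid < 0:
        raise ValidationError("variances must be nonnegative")
    c = _Compact(y, design)
    G = (c.Z * sigma2_k) @ c.Z.T
    V = G[c.rec][:, c.rec] + sigma2_resid * np.eye(c.n)
    try:
        L = scipy.linalg.cholesky(V, lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError(f"covariance not positive definite: {exc}") from exc
    ones = np.ones(c.n)
    Vi_y = scipy.linalg.cho_solve((L, True), y)
    Vi_1 = scipy.linalg.cho_solve((L, True), ones)
    beta = float(ones @ Vi_y / (ones @ Vi_1))
    e = y - beta
    quad = float(e @ (Vi_y - beta * Vi_1))
    logdet = 2.0 * float(np.log(np.diag(L)).sum())
    ll = -0.5 * (c.n * np.log(2.0 * np.pi) + logdet + quad)
    if config.tau == -2.0 and config.omega == 0.0:
        return ll
    with np.errstate(divide="ignore", invalid="ignore"):
        lp = -0.5 * (config.tau + 2.0) * np.log(sigma2_k) - config.omega / (
            2.0 * sigma2_k
        )
    return ll + float(np.sum(lp))


# ---------------------------------------------------------------------------
# the EB fit
# ---------------------------------------------------------------------------


def eb_fit(
    y,
    design: DesignMatrix,
    config: EBConfig | None = None,
    *,
    init_sigma2_k: np.ndarray | None = None,
    init_sigma2_resid: float | None = None,
    freeze_variances: bool = False,
) -> EBFit:
    """Fit all effects simultaneously by empirical Bayes shrinkage.

    Parameters other than the first three are escape hatches for testing
    and warm starts; with ``freeze_variances`` the sweep only re-solves the
    fixed-variance posterior (one sweep then reproduces
    :func:`blup_given_variances` exactly).
    """
    config = config or EBConfig()
    y = _resolve_y(y)
    if design.n_terms == 0:
        raise ValidationError("design has no terms")
    if y.size != design.n_records or y.size == 0:
        raise ValidationError("length of y does not match design rows (or empty)")
    p, n = design.n_terms, y.size
    if p > 60 * n:
        logger.warning(
            "model has %d effects for %d records (> 60n); estimates may be "
            "unreliable at this ratio",
            p,
            n,
        )

    vary = float(np.var(y))
    scale = vary if vary > 0 else 1.0
    floor = config.var_floor if config.var_floor is not None else _VAR_FLOOR_SCALE * scale
    resid_floor = _VAR_FLOOR_SCALE * scale

    c = _Compact(y, design)
    # degenerate (constant) columns are confounded with the intercept:
    # pin them at the floor and report effect ~ 0
    degenerate = np.array(
        [np.unique(col).size == 1 for col in c.Z.T], dtype=bool
    )
    if degenerate.any():
        logger.warning("%d constant design column(s) pinned at the variance floor",
                       int(degenerate.sum()))

    sigma2_k = (
        np.full(p, max(_INIT_SIGMA2K_SCALE * scale, floor))
        if init_sigma2_k is None
        else np.asarray(init_sigma2_k, dtype=float).copy()
    )
    sigma2_k[degenerate] = floor
    sigma2 = float(scale if init_sigma2_resid is None else init_sigma2_resid)

    if vary == 0.0:
        # degenerate response: everything is zero, nothing to iterate
        beta, gamma, se = blup_given_variances(y, design, np.full(p, floor), sigma2)
        return EBFit(list(design.terms), beta, gamma, se, np.full(p, floor),
                     sigma2, 0, True, config, design, degenerate)

    denom_update = config.tau + 3.0
    active = np.flatnonzero(~degenerate)
    sweeps = 0
    converged = False
    for sweep in range(config.max_sweeps):
        sweeps = sweep + 1
        M, B, wy = c.rebuild(sigma2_k, sigma2)
        beta = c.gls_beta(M, wy)
        w = wy - beta * M.sum(axis=1)
        prev_k = sigma2_k.copy()
        prev_resid = sigma2
        if not freeze_variances:
            for k in active:
                z = c.Z[:, k]
                t = M @ z
                s = float(z @ t)
                g = float(z @ w)
                sk = sigma2_k[k]
                gamma_k = sk * g
                post_v = max(sk - sk * sk * s, 0.0)
                new = max(floor, (gamma_k * gamma_k + post_v + config.omega)
                          / denom_update)
                delta = new - sk
                if delta != 0.0:
                    den = 1.0 + delta * s
                    if den <= 1e-300:
                        den = 1e-300
                    coef = delta / den
                    M -= coef * np.outer(t, t)
                    w -= (coef * g) * t
                    sigma2_k[k] = new
            # EM update of the residual variance from the quadratic form
            Bcur = np.diag(1.0 / c.r) - sigma2 * (M / np.outer(c.r, c.r))
            tr_vinv = (c.n - c.L) / sigma2 + float((np.diag(M) / c.r).sum())
            e = c.y - beta
            se_rows = np.bincount(c.rec, weights=e, minlength=c.L)
            u = (e - (Bcur @ se_rows)[c.rec]) / sigma2  # V^{-1} e
            ehat_ss = sigma2**2 * float(u @ u)
            sigma2 = max(
                resid_floor,
                (ehat_ss + sigma2 * (c.n - sigma2 * tr_vinv)) / c.n,
            )
        rel = np.abs(sigma2_k - prev_k) / np.maximum(prev_k, floor)
        rel_resid = abs(sigma2 - prev_resid) / max(prev_resid, resid_floor)
        if max(float(rel.max(initial=0.0)), rel_resid) < config.rel_tol:
            converged = True
            break

    if not converged and not freeze_variances:
        logger.warning(
            "empirical Bayes fit stopped at max_sweeps=%d without meeting "
            "rel_tol=%.1e", config.max_sweeps, config.rel_tol,
        )

    beta, gamma, se = blup_given_variances(y, design, sigma2_k, sigma2)
    return EBFit(
        terms=list(design.terms),
        beta_hat=beta,
        gamma_hat=gamma,
        se_gamma=se,
        sigma2_k=sigma2_k,
        sigma2_resid=sigma2,
        sweeps_run=sweeps,
        converged=converged,
        config=config,
        design=design,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# genomic-value prediction
# ---------------------------------------------------------------------------


def predict(
    fit: EBFit,
    design_new: DesignMatrix,
    included_terms: Sequence[ModelTerm | str] | None = None,
) -> np.ndarray:
    """Predicted genomic values: beta_hat + sum over included terms.

    ``included_terms`` selects a subset of the fitted terms (by term or
    label); the default uses all of them.  With an empty selection the
    prediction is the constant ``beta_hat``.
    """
    fit_idx = fit.term_index()
    new_idx = design_new.term_index()
    if included_terms is None:
        labels = fit.labels
    else:
        labels = [
            t.label if isinstance(t, ModelTerm) else str(t) for t in included_terms
        ]
    cols = []
    coefs = []
    for lab in labels:
        if lab not in fit_idx:
            raise ValidationError(f"term {lab!r} not present in the fit")
        if lab not in new_idx:
            raise ValidationError(f"term {lab!r} absent from the prediction design")
        cols.append(new_idx[lab])
        coefs.append(fit.gamma_hat[fit_idx[lab]])
    yhat = np.full(design_new.n_records, fit.beta_hat, dtype=float)
    if cols:
        Z = design_new.line_matrix[:, cols].astype(float)[design_new.record_index]
        yhat += Z @ np.asarray(coefs)
    return yhat
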