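"""Leave-one-line-out cross-validation for choosing the model size.

Effects are ranked once by LOD score from a fit on the full data and the
prediction model is grown along that ranking: for every candidate size
m* the top-m* effects are re-fitted from scratch on the 125 training
lines of each fold (all replicate records of the held-out line leave
together) and the held-out line's records are predicted from Eq.-style
genomic values beta + sum Z gamma.  The curve statistic is

    r^2 = 1 - SSE / (SSE + SSRp),
    SSE = sum (y_j - yhat_j)^2,   SSRp = sum (yhat_j - mean(yhat))^2,

the proportion of phenotypic variance explained by the predictions (not
the Pearson correlation); it lies in [0, 1] by construction.

A random-inclusion baseline grows the model in a uniformly random term
order instead.  Within a fold the selected subset is always fitted in
canonical term order, so membership - not inclusion order - defines the
model; at full size the ranked and random curves therefore coincide
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import association_stats as stats
from .design_matrix import DesignBuilder, DesignMatrix
from .eb_shrinkage import EBConfig, eb_fit
from .errors import ValidationError
from .io_data import GenotypeMatrix, PhenotypeTable, adjust_plot_means


@dataclass
class CVConfig:
    """Cross-validation settings.

    ordering: "lod_ranked" (rank once on the full data) or "random"
    (uniform term orders, averaged over ``n_random_orders``; a seed is
    then mandatory).  ``rank_per_fold`` switches to honest per-fold
    re-ranking (off by default, mirroring the study design).  ``center``
    picks the mean in SSRp: of the predictions (default) or of the
    observations.
    """

    ordering: str = "lod_ranked"
    m_star_grid: Sequence[int] | None = None
    n_random_orders: int = 1
    rng_seed: int | None = None
    eb: EBConfig = field(default_factory=EBConfig)
    rank_per_fold: bool = False
    center: str = "predictions"

    def __post_init__(self) -> None:
        if self.ordering not in ("lod_ranked", "random"):
            raise ValidationError(f"unknown ordering {self.ordering!r}")
        if self.n_random_orders < 1:
            raise ValidationError("n_random_orders must be >= 1")
        if self.ordering == "random" and self.rng_seed is None:
            raise ValidationError("random ordering requires rng_seed")
        if self.center not in ("predictions", "observations"):
            raise ValidationError(f"unknown center {self.center!r}")


@dataclass
class CVCurve:
    """r^2 as a function of the number of included effects."""

    m_star: np.ndarray
    r2: np.ndarray
    best_m_star: int
    predictions: pd.DataFrame  # out-of-fold record predictions at best_m_star
    ordering: str
    term_order: np.ndarray | None = None  # ranked order (lod_ranked only)
    r2_per_order: np.ndarray | None = None  # (n_orders, n_m) random baseline

    @property
    def peak_r2(self) -> float:
        return float(self.r2.max())


def loo_folds(pheno: PhenotypeTable) -> list[tuple[list[str], str]]:
    """One fold per line: (training line ids, held-out line id)."""
    lines = pheno.line_ids
    if len(lines) < 2:
        raise ValidationError("leave-one-line-out needs at least 2 lines")
    return [([l for l in lines if l != held], held) for held in lines]


def r_squared(y, y_hat, center: str = "predictions") -> float:
    """Proportion-of-variance r^2 between observed and predicted values."""
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size != y_hat.size:
        raise ValidationError("observed and predicted lengths differ")
    if y.size < 2:
        raise ValidationError("need at least 2 values")
    sse = float(np.sum((y - y_hat) ** 2))
    ybar = float(np.mean(y_hat if center == "predictions" else y))
    dev = y_hat - ybar
    # constant predictions carry no variance; snap summation noise to zero
    if np.max(np.abs(dev)) <= 1e-12 * max(1.0, abs(ybar)):
        dev = np.zeros_like(dev)
    ssrp = float(np.sum(dev**2))
    if sse == 0.0 and ssrp == 0.0:
        return 1.0
    return ssrp / (sse + ssrp)


def _default_grid(p: int) -> np.ndarray:
    if p <= 30:
        return np.arange(1, p + 1)
    grid = np.unique(np.round(np.geomspace(1, p, 30)).astype(int))
    return grid


def _rank_order(y: np.ndarray, design: DesignMatrix, eb: EBConfig) -> np.ndarray:
    fit = eb_fit(y, design, eb)
    return stats.rank_by_lod(stats.term_tests(fit)).order


def _fold_predictions(
    y: np.ndarray,
    design: DesignMatrix,
    folds: list[tuple[np.ndarray, np.ndarray, int]],
    orders_per_fold: list[np.ndarray],
    m_grid: np.ndarray,
    eb: EBConfig,
) -> np.ndarray:
    """Out-of-fold record predictions for every grid size.

    folds: (train record mask, test record indices, held line row).
    Returns array (n_m, n_records).
    """
    preds = np.empty((m_grid.size, y.size), dtype=float)
    for f, (train_mask, test_idx, held_row) in enumerate(folds):
        order = orders_per_fold[f]
        y_train = y[train_mask]
        for gi, m in enumerate(m_grid):
            sel = np.sort(order[:m])  # canonical order: membership defines the model
            sub = design.subset_terms(sel).subset_records(train_mask)
            fit = eb_fit(y_train, sub, eb)
            zrow = design.line_matrix[held_row, sel].astype(float)
            preds[gi, test_idx] = fit.beta_hat + zrow @ fit.gamma_hat
    return preds


def cv_curve(
    pheno: PhenotypeTable,
    geno: GenotypeMatrix,
    design_builder: DesignBuilder,
    config: CVConfig | None = None,
) -> CVCurve:
    """Leave-one-line-out r^2 curve over the model-size grid."""
    config = config or CVConfig()
    if not pheno.is_adjusted:
        pheno = adjust_plot_means(pheno)
    y = pheno.adjusted
    design = design_builder(geno, pheno)
    p = design.n_terms
    m_grid = (
        _default_grid(p)
        if config.m_star_grid is None
        else np.asarray(list(config.m_star_grid), dtype=int)
    )
    if m_grid.size == 0 or (np.diff(m_grid) <= 0).any():
        raise ValidationError("m_star_grid must be strictly increasing and nonempty")
    if m_grid[0] < 1 or m_grid[-1] > p:
        raise ValidationError(
            f"m_star_grid must lie in [1, {p}] for this design"
        )

    # record-level fold bookkeeping
    line_of_record = pheno.table["line_id"].to_numpy()
    row_of_line = {lid: i for i, lid in enumerate(design.row_ids)}
    folds = []
    for _, held in loo_folds(pheno):
        test = line_of_record == held
        folds.append((~test, np.flatnonzero(test), row_of_line[held]))

    def run_order(order_per_fold: list[np.ndarray]) -> np.ndarray:
        return _fold_predictions(y, design, folds, order_per_fold, m_grid, config.eb)

    ranked_order: np.ndarray | None = None
    if config.ordering == "lod_ranked":
        if config.rank_per_fold:
            orders = [
                _rank_order(y[tm], design.subset_records(tm), config.eb)
                for tm, _, _ in folds
            ]
        else:
            ranked_order = _rank_order(y, design, config.eb)
            orders = [ranked_order] * len(folds)
        preds = run_order(orders)
        r2 = np.array([r_squared(y, preds[gi], config.center) for gi in range(m_grid.size)])
        r2_per_order = None
        best_gi = int(np.argmax(r2))  # argmax returns the earliest maximiser
        best_preds = preds[best_gi]
    else:
        rng = np.random.default_rng(config.rng_seed)
        r2_per_order = np.empty((config.n_random_orders, m_grid.size))
        first_preds = None
        for rep in range(config.n_random_orders):
            order = rng.permutation(p)
            preds = run_order([order] * len(folds))
            r2_per_order[rep] = [
                r_squared(y, preds[gi], config.center) for gi in range(m_grid.size)
            ]
            if rep == 0:
                first_preds = preds
        r2 = r2_per_order.mean(axis=0)
        best_gi = int(np.argmax(r2))
        best_preds = first_preds[best_gi]

    pred_df = pheno.table[["line_id", "plot_id"]].copy()
    pred_df["observed_adjusted"] = y
    pred_df["predicted"] = best_preds
    return CVCurve(
        m_star=m_grid,
        r2=r2,
        best_m_star=int(m_grid[best_gi]),
        predictions=pred_df,
        ordering=config.ordering,
        term_order=ranked_order,
        r2_per_order=r2_per_order,
    )


def hyperparameter_search(
    pheno: PhenotypeTable,
    geno: GenotypeMatrix,
    design_builder: DesignBuilder,
    candidates: Sequence[tuple[float, float]] | None = None,
    config: CVConfig | None = None,
) -> tuple[tuple[float, float], pd.DataFrame]:
    """Choose (tau, omega) by peak cross-validated r^2.

    Evaluates the CV curve for every candidate hyperprior pair and returns
    the first candidate attaining the maximum peak r^2 (ties and
    duplicates resolve to the earliest listed).  The default candidate
    list holds only the flat hyperprior (-2, 0).
    """
    config = config or CVConfig()
    if candidates is None:
        candidates = [(-2.0, 0.0)]
    if len(candidates) == 0:
        raise ValidationError("candidate list must be nonempty")
    rows = []
    best: tuple[float, float] | None = None
    best_r2 = -np.inf
    for tau, omega in candidates:
        cand_cfg = replace(config, eb=replace(config.eb, tau=tau, omega=omega))
        curve = cv_curve(pheno, geno, design_builder, cand_cfg)
        rows.append(
            {
                "tau": tau,
                "omega": omega,
                "peak_r2": curve.peak_r2,
                "best_m_star": curve.best_m_star,
            }
        )
        if curve.peak_r2 > best_r2:
            best_r2 = curve.peak_r2
            best = (tau, omega)
    return best, pd.DataFrame(rows)
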