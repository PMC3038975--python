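"""Wald tests, LOD scores and effect ranking for fitted model terms.

For each term the Wald statistic is W = (effect / se)^2, compared with a
central chi-square with one degree of freedom: p = 1 - F_chi2(1, W).  The
same statistic converts to a LOD score as LOD = W / (2 ln 10).  Terms are
ranked by decreasing LOD (equivalently decreasing W) to choose which
effects enter the prediction model during cross-validation.

The per-term proportion of phenotypic variance ``h`` is reported as
sigma_k^2 * var(Z_k) / var(y): the estimated effect-variance component
scaled by the (population) variance of the term's +1/-1 column relative
to that of the adjusted phenotype.  This is a documented convention; see
the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .design_matrix import ModelTerm
from .eb_shrinkage import EBFit
from .errors import ValidationError
from .io_data import PhenotypeTable

TWO_LN_TEN = 2.0 * np.log(10.0)


def wald_statistic(effect, se):
    """W = (effect / se)^2; symmetric in the sign of the effect."""
    effect = np.asarray(effect, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValidationError("standard errors must be positive")
    out = (effect / se) ** 2
    return float(out) if out.ndim == 0 else out


def chisq_pvalue(w):
    """Upper-tail chi-square(1 df) probability of the Wald statistic."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValidationError("Wald statistic must be nonnegative")
    out = chi2.sf(w, df=1)
    return float(out) if out.ndim == 0 else out


def lod_score(w):
    """LOD = W / (2 ln 10)."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValidationError("Wald statistic must be nonnegative")
    out = w / TWO_LN_TEN
    return float(out) if out.ndim == 0 else out


@dataclass
class TermTest:
    """Wald/LOD summary of one model term."""

    term: ModelTerm
    W: float
    p_value: float
    lod: float
    h: float = float("nan")
    effect: float = float("nan")
    se: float = float("nan")
    variance: float = float("nan")


@dataclass
class RankedTerms:
    """Permutation of term indices, LOD descending."""

    order: np.ndarray
    tie_break: str = "larger |effect|, then canonical term order"


def variance_explained(fit: EBFit, term: ModelTerm | str, pheno: PhenotypeTable) -> float:
    """Proportion of phenotypic variance attributed to one term.

    h = sigma_k^2 * var(term column) / var(adjusted phenotype), population
    variances over the records.  A constant column yields h = 0 whatever
    its variance component.
    """
    if fit.design is None:
        raise ValidationError("fit carries no design; cannot locate term columns")
    label = term.label if isinstance(term, ModelTerm) else str(term)
    idx = fit.term_index()
    if label not in idx:
        raise ValidationError(f"term {label!r} not in fit")
    k = idx[label]
    y = pheno.adjusted
    vy = float(np.var(y))
    if vy <= 0:
        raise ValidationError("phenotypic variance is zero; h undefined")
    col = fit.design.line_matrix[:, k].astype(float)[fit.design.record_index]
    return float(fit.sigma2_k[k] * np.var(col) / vy)


def term_tests(fit: EBFit, pheno: PhenotypeTable | None = None) -> list[TermTest]:
    """Wald/p/LOD (and h when phenotypes are given) for every fitted term."""
    tests = []
    W = wald_statistic(fit.gamma_hat, np.maximum(fit.se_gamma, 1e-300))
    p = chisq_pvalue(W)
    lods = lod_score(W)
    for i, term in enumerate(fit.terms):
        h = variance_explained(fit, term, pheno) if pheno is not None else float("nan")
        tests.append(
            TermTest(
                term=term,
                W=float(W[i]),
                p_value=float(p[i]),
                lod=float(lods[i]),
                h=h,
                effect=float(fit.gamma_hat[i]),
                se=float(fit.se_gamma[i]),
                variance=float(fit.sigma2_k[i]),
            )
        )
    return tests


def rank_by_lod(tests: Sequence[TermTest]) -> RankedTerms:
    """Stable descending-LOD ranking.

    Ties break toward the larger absolute effect, then toward canonical
    (input) term order.
    """
    if len(tests) == 0:
        raise ValidationError("cannot rank an empty test list")
    lods = np.array([t.lod for t in tests])
    abs_eff = np.array([abs(t.effect) if np.isfinite(t.effect) else 0.0 for t in tests])
    idx = np.arange(len(tests))
    # np.lexsort: last key is primary
    order = np.lexsort((idx, -abs_eff, -lods))
    return RankedTerms(order=order)


def tests_table(tests: Sequence[TermTest]) -> pd.DataFrame:
    """Effect-table layout: markers, variance, effect, StdErr, LOD, p, H."""
    return pd.DataFrame(
        {
            "marker_1": [t.term.markers[0] for t in tests],
            "marker_2": [
                t.term.markers[1] if t.term.kind == "epistatic" else ""
                for t in tests
            ],
            "variance": [t.variance for t in tests],
            "effect": [t.effect for t in tests],
            "std_err": [t.se for t in tests],
            "lod": [t.lod for t in tests],
            "p_value": [t.p_value for t in tests],
            "h": [t.h for t in tests],
        }
    )


def write_effect_table(
    tests: Sequence[TermTest],
    path: str | Path,
    sep: str = "\t",
    header_lines: Sequence[str] = (),
) -> None:
    """Write tests sorted by descending LOD as delimited text."""
    order = rank_by_lod(tests).order
    df = tests_table([tests[i] for i in order])
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep=sep, index=False)
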