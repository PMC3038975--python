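"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd

from ebgs.design_matrix import DesignMatrix, ModelTerm
from ebgs.io_data import MarkerMap, PhenotypeTable


def design_from_codes(Z: np.ndarray, rec: np.ndarray | None = None) -> DesignMatrix:
    """Main-effect design directly from a +1/-1 matrix (rows = records)."""
    Z = np.asarray(Z, dtype=np.int8)
    if rec is None:
        rec = np.arange(Z.shape[0])
    terms = [ModelTerm("main", (f"M{j + 1}",)) for j in range(Z.shape[1])]
    return DesignMatrix(terms, Z, rec, [f"L{i + 1}" for i in range(Z.shape[0])])


def adjusted_pheno(values: np.ndarray, line_ids=None, plot_ids=None) -> PhenotypeTable:
    """Phenotype table whose adjusted values are set verbatim (no re-adjustment)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    if line_ids is None:
        line_ids = [f"L{i + 1}" for i in range(n)]
    if plot_ids is None:
        plot_ids = [f"P{i + 1}" for i in range(n)]  # unique -> no duplicate pairs
    return PhenotypeTable(
        pd.DataFrame(
            {
                "line_id": line_ids,
                "plot_id": plot_ids,
                "raw_value": values,
                "adjusted_value": values,
            }
        )
    )


def toy_marker_map(n: int = 5, spacing: float = 20.0) -> MarkerMap:
    """Small single-linkage-group map (last marker unmapped when n >= 3)."""
    rows = []
    for i in range(n):
        unmapped = i == n - 1 and n >= 3
        rows.append(
            {
                "marker_id": f"M{i + 1}",
                "marker_name": f"Sat_{i + 1:03d}",
                "position_cm": np.nan if unmapped else i * spacing,
                "linkage_group": np.nan if unmapped else 1,
            }
        )
    return MarkerMap(pd.DataFrame(rows))


def grid_best_log_posterior(
    y: np.ndarray,
    Z: np.ndarray,
    var_grid: np.ndarray,
    resid_grid: np.ndarray,
) -> float:
    """Independent grid-search oracle for the flat-hyperprior objective.

    Profiles the intercept by GLS and evaluates the Gaussian marginal
    log-likelihood of y under V = Z D Z' + s2 I over the Cartesian grid of
    per-column variances (var_grid each) and residual variances
    (resid_grid).  Vectorises the residual axis through an
    eigendecomposition of Z D Z'; entirely separate from the package's
    linear algebra.
    """
    from itertools import product

    n, p = Z.shape
    ones = np.ones(n)
    best = -np.inf
    for combo in product(var_grid, repeat=p):
        D = np.asarray(combo)
        lam, Q = np.linalg.eigh((Z * D) @ Z.T)
        lam = np.clip(lam, 0.0, None)
        yt = Q.T @ y
        ot = Q.T @ ones
        denom = lam[None, :] + resid_grid[:, None]  # (n_s2, n)
        w = 1.0 / denom
        beta = (w * ot * yt).sum(axis=1) / (w * ot * ot).sum(axis=1)
        e = yt[None, :] - beta[:, None] * ot[None, :]
        quad = (w * e * e).sum(axis=1)
        logdet = np.log(denom).sum(axis=1)
        ll = -0.5 * (n * np.log(2 * np.pi) + logdet + quad)
        best = max(best, float(ll.max()))
    return best
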