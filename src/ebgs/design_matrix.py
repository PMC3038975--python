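"""Regression designs for the main-effect and epistatic marker models.

The main-effect model regresses the plot-mean-adjusted phenotype on the
+1/-1 marker codes; the epistatic model adds one column per unordered
marker pair, equal to the elementwise product of the two parent columns
(still +1/-1 valued).  For ``m`` markers the full epistatic design has
``m(m+1)/2`` terms: ``m`` mains followed by ``m(m-1)/2`` pairs in
lexicographic order of marker indices.

Because every replicate record of a line shares that line's genotype, the
design stores one row per line plus a record -> line index instead of
materialising duplicate rows; ``DesignMatrix.columns`` exposes the fully
expanded matrix semantics.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_data import GenotypeMatrix, PhenotypeTable

PAIR_SEP = ":"  # canonical label separator for epistatic terms, e.g. "M3:M39"


@dataclass(frozen=True)
class ModelTerm:
    """One model effect: a single marker (main) or an unordered pair."""

    kind: str  # "main" | "epistatic"
    markers: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("main", "epistatic"):
            raise ValidationError(f"unknown term kind {self.kind!r}")
        n = {"main": 1, "epistatic": 2}[self.kind]
        if len(self.markers) != n:
            raise ValidationError(
                f"{self.kind} term needs {n} marker(s), got {self.markers}"
            )
        if self.kind == "epistatic" and self.markers[0] == self.markers[1]:
            raise ValidationError(f"self-pair {self.markers} not allowed")

    @property
    def label(self) -> str:
        return PAIR_SEP.join(self.markers)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass
class DesignMatrix:
    """Ordered model terms plus their +1/-1 columns.

    ``line_matrix``: (n_rows, n_terms) int8, one row per distinct genotype
    row referenced by the records.  ``record_index`` maps each phenotype
    record to its row.  ``row_ids`` names the rows (line ids).
    """

    terms: list[ModelTerm]
    line_matrix: np.ndarray
    record_index: np.ndarray
    row_ids: list[str]

    def __post_init__(self) -> None:
        self.line_matrix = np.asarray(self.line_matrix, dtype=np.int8)
        self.record_index = np.asarray(self.record_index, dtype=np.intp)
        if self.line_matrix.ndim != 2:
            raise ValidationError("line_matrix must be 2-D")
        if self.line_matrix.shape[1] != len(self.terms):
            raise ValidationError("line_matrix column count != number of terms")
        if not np.isin(self.line_matrix, (-1, 1)).all():
            raise ValidationError("design entries must be +1 or -1")
        if self.record_index.size and (
            self.record_index.min() < 0
            or self.record_index.max() >= self.line_matrix.shape[0]
        ):
            raise ValidationError("record_index out of range")
        labels = [t.label for t in self.terms]
        if len(set(labels)) != len(labels):
            raise ValidationError("duplicate terms in design")

    # -- shape -------------------------------------------------------------
    @property
    def n_records(self) -> int:
        return int(self.record_index.size)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    @property
    def labels(self) -> list[str]:
        return [t.label for t in self.terms]

    @property
    def columns(self) -> np.ndarray:
        """Expanded (n_records, n_terms) float design matrix."""
        return self.line_matrix[self.record_index].astype(float)

    def term_index(self) -> dict[str, int]:
        return {t.label: i for i, t in enumerate(self.terms)}

    # -- views -------------------------------------------------------------
    def subset_terms(self, indices: Sequence[int]) -> "DesignMatrix":
        idx = np.asarray(indices, dtype=np.intp)
        return DesignMatrix(
            [self.terms[i] for i in idx],
            self.line_matrix[:, idx],
            self.record_index.copy(),
            list(self.row_ids),
        )

    def subset_records(self, mask: np.ndarray) -> "DesignMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            rec = self.record_index[mask]
        else:
            rec = self.record_index[np.asarray(mask, dtype=np.intp)]
        return DesignMatrix(list(self.terms), self.line_matrix, rec, list(self.row_ids))

    def to_term_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "label": self.labels,
                "kind": [t.kind for t in self.terms],
                "marker_1": [t.markers[0] for t in self.terms],
                "marker_2": [
                    t.markers[1] if t.kind == "epistatic" else "" for t in self.terms
                ],
            }
        )


def term_count(m: int, epistatic: bool) -> int:
    """Number of model terms for ``m`` markers: m, or m(m+1)/2 with pairs."""
    if m < 1:
        raise ValidationError(f"need at least one marker, got m={m}")
    return m * (m + 1) // 2 if epistatic else m


def _record_index(geno: GenotypeMatrix, pheno: PhenotypeTable) -> np.ndarray:
    lookup = geno.line_index()
    idx = np.empty(pheno.n_records, dtype=np.intp)
    for i, lid in enumerate(pheno.table["line_id"]):
        if lid not in lookup:
            raise ValidationError(
                f"phenotype line {lid!r} missing from genotype matrix"
            )
        idx[i] = lookup[lid]
    return idx


def build_main_design(geno: GenotypeMatrix, pheno: PhenotypeTable) -> DesignMatrix:
    """One +1/-1 column per marker, rows replicated per phenotype record."""
    rec = _record_index(geno, pheno)
    terms = [ModelTerm("main", (mid,)) for mid in geno.marker_ids]
    return DesignMatrix(terms, geno.codes.copy(), rec, list(geno.line_ids))


def build_epistatic_design(geno: GenotypeMatrix, pheno: PhenotypeTable) -> DesignMatrix:
    """Main terms in marker order, then all pairs (k < k') lexicographically.

    The column of pair (k, k') is the elementwise product of the two main
    columns, hence still +1/-1 valued.
    """
    rec = _record_index(geno, pheno)
    m = geno.n_markers
    terms = [ModelTerm("main", (mid,)) for mid in geno.marker_ids]
    Z = geno.codes
    cols = np.empty((geno.n_lines, term_count(m, True)), dtype=np.int8)
    cols[:, :m] = Z
    pos = m
    for k, kp in combinations(range(m), 2):
        terms.append(
            ModelTerm("epistatic", (geno.marker_ids[k], geno.marker_ids[kp]))
        )
        np.multiply(Z[:, k], Z[:, kp], out=cols[:, pos])
        pos += 1
    return DesignMatrix(terms, cols, rec, list(geno.line_ids))


def write_term_list(design: DesignMatrix, path: str | Path, sep: str = "\t") -> None:
    design.to_term_table().to_csv(path, sep=sep, index=False)


DesignBuilder = Callable[[GenotypeMatrix, PhenotypeTable], DesignMatrix]
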