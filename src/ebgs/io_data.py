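"""Tabular input/output for replicated RIL marker-trait datasets.

Three plain-text tables describe a study: a marker map (marker id, locus
name, cM position, linkage group), a genotype matrix (one row per inbred
line, entries coded +1/-1 for the two parental alleles), and a phenotype
table (one record per line x replicate plot).  Files are comma- or
tab-delimited with mandatory headers; the delimiter is sniffed from the
header line unless given explicitly.

Replicate-plot block effects are removed by subtracting from every record
the mean of its plot (:func:`adjust_plot_means`); downstream model fitting
always operates on these plot-mean-adjusted values.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

MISSING_TOKENS = {"", "NA", "N/A", "NaN", "nan", "na", "n/a"}


def _sniff_delimiter(path: str | Path, dialect: str | None = None) -> str:
    """Return the field delimiter, auto-detected from the header line."""
    if dialect is not None:
        return dialect
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    if "\t" in header:
        return "\t"
    return ","


# ---------------------------------------------------------------------------
# Marker map
# ---------------------------------------------------------------------------

MARKER_MAP_COLUMNS = ("marker_id", "marker_name", "position_cm", "linkage_group")


@dataclass
class MarkerMap:
    """Genetic map of the markers: identity, cM position, linkage group.

    ``table`` has columns ``marker_id``, ``marker_name``, ``position_cm``
    (float, NaN when unmapped) and ``linkage_group`` (nullable integer).
    Markers missing both position and group are valid "unmapped" markers;
    a marker assigned to a linkage group must have a position.  Ties in
    position (co-located markers) are allowed.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MARKER_MAP_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValidationError(f"marker map missing columns: {missing}")
        df = self.table.loc[:, list(MARKER_MAP_COLUMNS)].reset_index(drop=True)
        df["marker_id"] = df["marker_id"].astype(str)
        df["marker_name"] = df["marker_name"].astype(str)
        df["position_cm"] = pd.to_numeric(df["position_cm"], errors="coerce")
        df["linkage_group"] = pd.to_numeric(
            df["linkage_group"], errors="coerce"
        ).astype("Int64")
        if len(df) < 1:
            raise ValidationError("marker map must contain at least one marker")
        dup = df["marker_id"][df["marker_id"].duplicated()].unique().tolist()
        if dup:
            raise ValidationError(f"duplicate marker_id values: {dup}")
        bad_pos = df["position_cm"].dropna() < 0
        if bad_pos.any():
            raise ValidationError("position_cm must be nonnegative")
        mapped_no_pos = df["linkage_group"].notna() & df["position_cm"].isna()
        if mapped_no_pos.any():
            ids = df.loc[mapped_no_pos, "marker_id"].tolist()
            raise ValidationError(
                f"markers assigned to a linkage group need a position: {ids}"
            )
        self.table = df

    # -- accessors ---------------------------------------------------------
    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> list[str]:
        return self.table["marker_id"].tolist()

    @property
    def mapped(self) -> pd.DataFrame:
        """Rows assigned to a linkage group."""
        return self.table[self.table["linkage_group"].notna()]

    @property
    def unmapped_ids(self) -> list[str]:
        return self.table.loc[
            self.table["linkage_group"].isna(), "marker_id"
        ].tolist()

    def linkage_groups(self) -> dict[int, pd.DataFrame]:
        """Mapping linkage group -> rows sorted by position (stable on ties)."""
        out: dict[int, pd.DataFrame] = {}
        for lg, sub in self.mapped.groupby("linkage_group", sort=True):
            out[int(lg)] = sub.sort_values("position_cm", kind="stable")
        return out


def read_marker_map(path: str | Path, dialect: str | None = None) -> MarkerMap:
    """Read and validate a marker-map table.

    ``N/A`` (or empty) position/group fields parse as missing, which marks
    a marker as unmapped.
    """
    sep = _sniff_delimiter(path, dialect)
    df = pd.read_csv(
        path, sep=sep, dtype=str, keep_default_na=False, skipinitialspace=True
    )
    missing = [c for c in MARKER_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"marker map file {path} lacks columns {missing}")
    for col in ("position_cm", "linkage_group"):
        df[col] = df[col].map(lambda v: np.nan if v.strip() in MISSING_TOKENS else v)
    return MarkerMap(df)


def write_marker_map(marker_map: MarkerMap, path: str | Path, sep: str = ",") -> None:
    df = marker_map.table.copy()
    df.to_csv(path, sep=sep, index=False, na_rep="N/A")


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Lines x markers matrix of inbred genotypes coded +1/-1.

    The two parental genotype classes map to +1 and -1; heterozygotes are
    not representable (the lines are inbred).  ``codes`` is an int8 array
    of shape ``(n_lines, n_markers)``.
    """

    line_ids: list[str]
    marker_ids: list[str]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = [str(x) for x in self.line_ids]
        self.marker_ids = [str(x) for x in self.marker_ids]
        codes = np.asarray(self.codes)
        if codes.ndim != 2 or codes.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValidationError(
                f"genotype codes shape {codes.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if not np.isin(codes, (-1, 1)).all():
            raise ValidationError("genotype codes must be exactly +1 or -1")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValidationError("duplicate line_id in genotype matrix")
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise ValidationError("duplicate marker_id in genotype matrix")
        self.codes = codes.astype(np.int8)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def line_index(self) -> dict[str, int]:
        return {lid: i for i, lid in enumerate(self.line_ids)}


DEFAULT_CODING: Mapping[str, int] = {"A": +1, "B": -1, "+1": +1, "-1": -1, "1": +1}


def read_genotypes(
    path: str | Path,
    coding: Mapping[str, int] | None = None,
    dialect: str | None = None,
) -> GenotypeMatrix:
    """Read a genotype table; first column is ``line_id``, the rest markers.

    ``coding`` maps file symbols to +1/-1 (default accepts A/B and numeric
    codes).  Any cell not covered by the mapping raises a
    :class:`FormatError` naming the offending row and column.
    """
    coding = dict(DEFAULT_CODING if coding is None else coding)
    sep = _sniff_delimiter(path, dialect)
    with open(path, "r", newline="") as fh:
        reader = csv.reader(fh, delimiter=sep)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"genotype file {path} is empty") from None
        header = [h.strip() for h in header]
        marker_ids = header[1:]
        if not marker_ids:
            raise FormatError(f"genotype file {path} has no marker columns")
        line_ids: list[str] = []
        rows: list[list[int]] = []
        for i, rec in enumerate(reader):
            if not rec:
                continue
            if len(rec) != len(header):
                raise FormatError(
                    f"{path}: ragged row {i + 2} has {len(rec)} fields, "
                    f"expected {len(header)}"
                )
            line_ids.append(rec[0].strip())
            coded = []
            for j, cell in enumerate(rec[1:]):
                sym = cell.strip()
                if sym not in coding:
                    raise FormatError(
                        f"{path}: unmappable genotype symbol {sym!r} at line "
                        f"{rec[0]!r} (row {i + 2}), marker {marker_ids[j]!r}"
                    )
                coded.append(int(coding[sym]))
            rows.append(coded)
    return GenotypeMatrix(line_ids, marker_ids, np.array(rows, dtype=np.int8))


def write_genotypes(
    geno: GenotypeMatrix,
    path: str | Path,
    symbols: Mapping[int, str] | None = None,
    sep: str = ",",
) -> None:
    symbols = {+1: "A", -1: "B"} if symbols is None else dict(symbols)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["line_id", *geno.marker_ids])
        for lid, row in zip(geno.line_ids, geno.codes):
            writer.writerow([lid, *(symbols[int(v)] for v in row)])


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


@dataclass
class PhenotypeTable:
    """Replicated phenotype records: one row per (line, plot).

    ``table`` columns: ``line_id``, ``plot_id``, ``raw_value`` and, once
    :func:`adjust_plot_means` has run, ``adjusted_value`` (raw value minus
    its plot mean).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy().reset_index(drop=True)
        for col in ("line_id", "plot_id", "raw_value"):
            if col not in df.columns:
                raise ValidationError(f"phenotype table missing column {col!r}")
        df["line_id"] = df["line_id"].astype(str)
        df["plot_id"] = df["plot_id"].astype(str)
        df["raw_value"] = pd.to_numeric(df["raw_value"])
        if "adjusted_value" not in df.columns:
            df["adjusted_value"] = np.nan
        dup = df.duplicated(subset=["line_id", "plot_id"])
        if dup.any():
            pairs = df.loc[dup, ["line_id", "plot_id"]].values.tolist()
            raise ValidationError(f"duplicated (line_id, plot_id) records: {pairs}")
        self.table = df[["line_id", "plot_id", "raw_value", "adjusted_value"]]

    @property
    def n_records(self) -> int:
        return len(self.table)

    @property
    def line_ids(self) -> list[str]:
        """Unique line ids in order of first appearance."""
        return self.table["line_id"].drop_duplicates().tolist()

    @property
    def is_adjusted(self) -> bool:
        return self.n_records == 0 or bool(
            self.table["adjusted_value"].notna().all()
        )

    @property
    def adjusted(self) -> np.ndarray:
        if not self.is_adjusted:
            raise ValidationError(
                "phenotypes not yet plot-mean adjusted; run adjust_plot_means"
            )
        return self.table["adjusted_value"].to_numpy(dtype=float)


def read_phenotypes(path: str | Path, dialect: str | None = None) -> PhenotypeTable:
    """Read a phenotype table with columns ``line_id``, ``plot_id``, ``value``."""
    sep = _sniff_delimiter(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in ("line_id", "plot_id", "value"):
        if col not in df.columns:
            raise FormatError(f"phenotype file {path} lacks column {col!r}")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = values.isna() & df["value"].astype(str).str.strip().ne("")
    if bad.any():
        idx = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"{path}: non-numeric value {df['value'].iloc[idx]!r} at record {idx}"
        )
    if values.isna().any():
        idx = int(np.flatnonzero(values.isna().to_numpy())[0])
        raise FormatError(f"{path}: missing value at record {idx}")
    out = pd.DataFrame(
        {"line_id": df["line_id"], "plot_id": df["plot_id"], "raw_value": values}
    )
    return PhenotypeTable(out)


def write_phenotypes(pheno: PhenotypeTable, path: str | Path, sep: str = ",") -> None:
    df = pheno.table.rename(columns={"raw_value": "value"})
    df[["line_id", "plot_id", "value"]].to_csv(path, sep=sep, index=False)


def adjust_plot_means(pheno: PhenotypeTable) -> PhenotypeTable:
    """Subtract from every record the mean of its plot.

    Removes replicate-plot block effects; the adjusted values have exactly
    zero mean within every plot.  All records enter their plot mean.  A
    single-record plot adjusts to 0.  Idempotent when the raw values
    already have zero plot means.
    """
    df = pheno.table.copy()
    if len(df):
        plot_means = df.groupby("plot_id")["raw_value"].transform("mean")
        df["adjusted_value"] = df["raw_value"] - plot_means
    return PhenotypeTable(df)
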