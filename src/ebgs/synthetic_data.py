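"""Synthetic replicated-RIL datasets with a known genetic architecture.

The original soybean dataset behind this pipeline is not deposited, so
every stage is exercised on simulated recombinant inbred lines instead.
Genotypes are simulated marker-by-marker along each linkage group as a
Markov chain: the first marker of a group is +1/-1 with probability 1/2
and adjacent markers recombine with the selfed-RIL-adjusted probability

    R = 2r / (1 + 2r),   r = (1 - exp(-2 d / 100)) / 2   (Haldane, d in cM),

which accounts for the recombination accumulated over repeated selfing.
Distinct linkage groups and unmapped markers segregate independently.
Residual heterozygosity of F5:6 lines is ignored (two-class +1/-1 coding).

Traits are generated from the same linear model the estimator assumes:
line genomic value beta + sum Z gamma (mains and pairs), plus one block
effect per replicate plot and iid Gaussian residual noise.  A Poisson
count mode (log link, each record the average of 10 simulated plants)
exists behind a flag for the count nature of embryo-number data.

Default sizes mirror the motivating study: 126 lines x 3 plots = 378
records on the packaged 80-marker map.  Default architecture scales
(effects drawn with |gamma| in [0.5, 1], residual sd 1.5, plot sd 1.0)
are the package's stated simulation world; see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import datasets
from .errors import ValidationError
from .io_data import (
    GenotypeMatrix,
    MarkerMap,
    PhenotypeTable,
    write_genotypes,
    write_marker_map,
    write_phenotypes,
)
import pandas as pd


@dataclass
class SimConfig:
    """Population design: map, number of lines, replicate plots, seed."""

    marker_map: MarkerMap | None = None  # None -> packaged 80-marker soybean map
    n_lines: int = 126
    n_plots: int = 3
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_lines < 2:
            raise ValidationError("n_lines must be >= 2")
        if self.n_plots < 1:
            raise ValidationError("n_plots must be >= 1")

    def resolved_map(self) -> MarkerMap:
        return self.marker_map if self.marker_map is not None else datasets.soybean_marker_map()


@dataclass
class TrueArchitecture:
    """The generative truth: effects, plot-block scale, residual scale."""

    beta: float = 10.0
    main_effects: dict[str, float] = field(default_factory=dict)
    epistatic_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    plot_effect_sd: float = 1.0
    resid_sd: float = 1.5

    def validate_against(self, marker_ids: list[str]) -> None:
        known = set(marker_ids)
        order = {m: i for i, m in enumerate(marker_ids)}
        for m in self.main_effects:
            if m not in known:
                raise ValidationError(f"unknown marker {m!r} in main effects")
        for a, b in self.epistatic_effects:
            if a not in known or b not in known:
                raise ValidationError(f"unknown marker in pair ({a!r}, {b!r})")
            if a == b:
                raise ValidationError(f"self-pair ({a!r}, {b!r})")
            if order[a] > order[b]:
                raise ValidationError(
                    f"pair ({a!r}, {b!r}) not in canonical marker order"
                )


def haldane_recombination(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Single-meiosis recombination fraction r for map distance d (cM)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def ril_recombination(d_cm: np.ndarray | float) -> np.ndarray | float:
    """Selfed-RIL effective recombination R = 2r/(1+2r)."""
    r = haldane_recombination(d_cm)
    return 2.0 * r / (1.0 + 2.0 * r)


def simulate_ril_genotypes(config: SimConfig) -> GenotypeMatrix:
    """Simulate +1/-1 RIL genotypes along the map; deterministic given seed."""
    mm = config.resolved_map()
    rng = np.random.default_rng(
        None if config.seed is None else [int(config.seed), 0]
    )
    n = config.n_lines
    ids = mm.marker_ids
    col_of = {m: i for i, m in enumerate(ids)}
    codes = np.empty((n, len(ids)), dtype=np.int8)
    filled = np.zeros(len(ids), dtype=bool)
    for _, sub in mm.linkage_groups().items():
        prev = None
        prev_pos = None
        for _, row in sub.iterrows():
            j = col_of[row["marker_id"]]
            if prev is None:
                col = rng.choice(np.array([-1, 1], dtype=np.int8), size=n)
            else:
                R = float(ril_recombination(row["position_cm"] - prev_pos))
                flip = rng.random(n) < R
                col = np.where(flip, -prev, prev).astype(np.int8)
            codes[:, j] = col
            filled[j] = True
            prev, prev_pos = col, row["position_cm"]
    for j in np.flatnonzero(~filled):  # unmapped markers: independent
        codes[:, j] = rng.choice(np.array([-1, 1], dtype=np.int8), size=n)
    line_ids = [f"L{i + 1:03d}" for i in range(n)]
    return GenotypeMatrix(line_ids, list(ids), codes)


def genetic_values(geno: GenotypeMatrix, truth: TrueArchitecture) -> np.ndarray:
    """Per-line genomic value beta + sum Z gamma over the true architecture."""
    truth.validate_against(geno.marker_ids)
    col = {m: i for i, m in enumerate(geno.marker_ids)}
    g = np.full(geno.n_lines, truth.beta, dtype=float)
    Z = geno.codes.astype(float)
    for m, eff in truth.main_effects.items():
        g += eff * Z[:, col[m]]
    for (a, b), eff in truth.epistatic_effects.items():
        g += eff * Z[:, col[a]] * Z[:, col[b]]
    return g


def simulate_trait(
    geno: GenotypeMatrix,
    truth: TrueArchitecture,
    config: SimConfig,
    family: str = "gaussian",
) -> PhenotypeTable:
    """Replicated phenotype records for every line; deterministic given seed."""
    rng = np.random.default_rng(
        None if config.seed is None else [int(config.seed), 1]
    )
    g = genetic_values(geno, truth)
    plot_ids = [f"P{p + 1}" for p in range(config.n_plots)]
    plot_effects = rng.normal(0.0, truth.plot_effect_sd, size=config.n_plots)
    lines, plots, values = [], [], []
    for p, pid in enumerate(plot_ids):
        mu = g + plot_effects[p]
        if family == "gaussian":
            vals = mu + rng.normal(0.0, truth.resid_sd, size=geno.n_lines)
        elif family == "poisson":
            # count trait: each record averages 10 simulated plants, log link
            lam = np.exp(np.clip(mu - mu.mean(), -10.0, 10.0))
            vals = rng.poisson(lam[None, :].repeat(10, axis=0)).mean(axis=0)
        else:
            raise ValidationError(f"unknown trait family {family!r}")
        lines.extend(geno.line_ids)
        plots.extend([pid] * geno.n_lines)
        values.extend(vals.tolist())
    return PhenotypeTable(
        pd.DataFrame({"line_id": lines, "plot_id": plots, "raw_value": values})
    )


def random_architecture(
    marker_map: MarkerMap,
    n_main: int = 3,
    n_epistatic: int = 3,
    effect_range: tuple[float, float] = (0.5, 1.0),
    beta: float = 10.0,
    plot_effect_sd: float = 1.0,
    resid_sd: float = 1.5,
    seed: int | None = None,
) -> TrueArchitecture:
    """Draw a sparse random architecture on the given map.

    Effect magnitudes are uniform on ``effect_range`` with random signs;
    main-effect markers are drawn without replacement and epistatic pairs
    are distinct, stored in canonical marker order.
    """
    rng = np.random.default_rng(None if seed is None else [int(seed), 2])
    ids = marker_map.marker_ids
    m = len(ids)
    if n_main > m or 2 * n_epistatic > m:
        raise ValidationError("architecture larger than the map allows")
    mains = rng.choice(m, size=n_main, replace=False)

    def draw_effect() -> float:
        mag = rng.uniform(*effect_range)
        return float(mag * rng.choice([-1.0, 1.0]))

    main_effects = {ids[i]: draw_effect() for i in sorted(mains)}
    pairs: dict[tuple[str, str], float] = {}
    while len(pairs) < n_epistatic:
        a, b = sorted(rng.choice(m, size=2, replace=False))
        key = (ids[a], ids[b])
        if key not in pairs:
            pairs[key] = draw_effect()
    return TrueArchitecture(
        beta=beta,
        main_effects=main_effects,
        epistatic_effects=pairs,
        plot_effect_sd=plot_effect_sd,
        resid_sd=resid_sd,
    )


@dataclass
class SimDataset:
    marker_map: MarkerMap
    genotypes: GenotypeMatrix
    phenotypes: PhenotypeTable
    truth: TrueArchitecture


def write_truth_manifest(truth: TrueArchitecture, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"beta={truth.beta!r}\n")
        fh.write(f"plot_effect_sd={truth.plot_effect_sd!r}\n")
        fh.write(f"resid_sd={truth.resid_sd!r}\n")
        for m, e in truth.main_effects.items():
            fh.write(f"main:{m}={e!r}\n")
        for (a, b), e in truth.epistatic_effects.items():
            fh.write(f"epistatic:{a}:{b}={e!r}\n")


def read_truth_manifest(path: str | Path) -> TrueArchitecture:
    truth = TrueArchitecture(main_effects={}, epistatic_effects={})
    with open(path) as fh:
        for line in fh:
            key, val = line.rstrip("\n").split("=", 1)
            if key == "beta":
                truth.beta = float(val)
            elif key == "plot_effect_sd":
                truth.plot_effect_sd = float(val)
            elif key == "resid_sd":
                truth.resid_sd = float(val)
            elif key.startswith("main:"):
                truth.main_effects[key[5:]] = float(val)
            elif key.startswith("epistatic:"):
                _, a, b = key.split(":")
                truth.epistatic_effects[(a, b)] = float(val)
    return truth


def make_dataset(
    config: SimConfig,
    truth: TrueArchitecture | None = None,
    outdir: str | Path | None = None,
) -> SimDataset:
    """Simulate a full dataset; optionally write the three tables + manifest.

    With ``truth=None`` a default sparse architecture (3 main + 3 epistatic
    effects) is drawn from the config seed.  Writing is deterministic:
    identical config and truth give byte-identical files.
    """
    mm = config.resolved_map()
    if truth is None:
        truth = random_architecture(mm, seed=config.seed)
    geno = simulate_ril_genotypes(config)
    pheno = simulate_trait(geno, truth, config)
    ds = SimDataset(mm, geno, pheno, truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_marker_map(mm, outdir / "marker_map.csv")
        write_genotypes(geno, outdir / "genotypes.csv")
        write_phenotypes(pheno, outdir / "phenotypes.csv")
        write_truth_manifest(truth, outdir / "truth.txt")
    return ds
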