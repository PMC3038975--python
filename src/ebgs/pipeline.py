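"""End-to-end runs: adjust -> design -> shrinkage fit -> stats -> rank / CV.

Thin orchestration over the library modules; the CLI wraps these
functions.  Every output table starts with comment lines naming the
package version and a hash of the run configuration, so re-runs with
identical inputs are byte-identical (logs may differ in timestamps).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from . import association_stats as stats
from .cross_validation import CVConfig, CVCurve, cv_curve
from .design_matrix import build_epistatic_design, build_main_design
from .eb_shrinkage import EBConfig, EBFit, eb_fit
from .errors import ValidationError
from .io_data import (
    GenotypeMatrix,
    PhenotypeTable,
    adjust_plot_means,
    read_genotypes,
    read_marker_map,
    read_phenotypes,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths, model choice and sub-configurations for one pipeline run."""

    genotypes: str
    phenotypes: str
    marker_map: str | None = None
    model: str = "main"  # "main" | "epistatic"
    eb: EBConfig = field(default_factory=EBConfig)
    cv: CVConfig = field(default_factory=CVConfig)
    outdir: str = "ebgs_out"

    def __post_init__(self) -> None:
        if self.model not in ("main", "epistatic"):
            raise ValidationError(f"model must be 'main' or 'epistatic', got {self.model!r}")

    def config_hash(self) -> str:
        blob = repr(dataclasses.asdict(self)).encode()
        return hashlib.md5(blob).hexdigest()[:12]


def _header(config: RunConfig) -> list[str]:
    return [f"ebgs {__version__}", f"config_hash={config.config_hash()}"]


def _load_inputs(config: RunConfig) -> tuple[GenotypeMatrix, PhenotypeTable]:
    geno = read_genotypes(config.genotypes)
    pheno = adjust_plot_means(read_phenotypes(config.phenotypes))
    if config.marker_map is not None:
        read_marker_map(config.marker_map)  # validated; ordering is by genotype file
    return geno, pheno


def _builder(model: str):
    return build_main_design if model == "main" else build_epistatic_design


@dataclass
class AnalysisResult:
    fit: EBFit
    tests: list
    outdir: Path


def run_analysis(config: RunConfig) -> AnalysisResult:
    """Fit the chosen model and write the effect and LOD-profile tables."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geno, pheno = _load_inputs(config)
    design = _builder(config.model)(geno, pheno)
    logger.info(
        "fitting %s model: %d records, %d terms", config.model,
        design.n_records, design.n_terms,
    )
    fit = eb_fit(pheno.adjusted, design, config.eb)
    logger.info(
        "fit %s after %d sweeps (converged=%s), residual variance %.4g",
        "converged" if fit.converged else "stopped",
        fit.sweeps_run, fit.converged, fit.sigma2_resid,
    )
    tests = stats.term_tests(fit, pheno)
    stats.write_effect_table(tests, outdir / "effects.tsv",
                             header_lines=_header(config))
    profile = pd.DataFrame(
        {
            "label": [t.term.label for t in tests],
            "kind": [t.term.kind for t in tests],
            "lod": [t.lod for t in tests],
        }
    )
    with open(outdir / "lod_profile.tsv", "w") as fh:
        for line in _header(config):
            fh.write(f"# {line}\n")
        profile.to_csv(fh, sep="\t", index=False)
    return AnalysisResult(fit=fit, tests=tests, outdir=outdir)


@dataclass
class CVResult:
    curve: CVCurve
    random_curve: CVCurve | None
    outdir: Path


def _write_curve(curve: CVCurve, path: Path, header: list[str]) -> None:
    df = pd.DataFrame(
        {"m_star": curve.m_star, "r2": curve.r2, "ordering": curve.ordering}
    )
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_cv(config: RunConfig, with_random: bool = False) -> CVResult:
    """Cross-validate model size; write curve tables and best predictions."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    geno, pheno = _load_inputs(config)
    builder = _builder(config.model)
    curve = cv_curve(pheno, geno, builder, config.cv)
    logger.info("ranked CV: best m*=%d, peak r2=%.4f", curve.best_m_star,
                curve.peak_r2)
    _write_curve(curve, outdir / "cv_ranked.tsv", _header(config))
    random_curve = None
    if with_random:
        rnd_cfg = dataclasses.replace(config.cv, ordering="random")
        random_curve = cv_curve(pheno, geno, builder, rnd_cfg)
        _write_curve(random_curve, outdir / "cv_random.tsv", _header(config))
    with open(outdir / "cv_predictions.tsv", "w") as fh:
        for line in _header(config):
            fh.write(f"# {line}\n")
        fh.write(f"# best_m_star={curve.best_m_star}\n")
        curve.predictions.to_csv(fh, sep="\t", index=False)
    return CVResult(curve=curve, random_curve=random_curve, outdir=outdir)


def plot_cv_curves(
    curve: CVCurve, random_curve: CVCurve | None, path: str | Path
) -> None:
    """Optional PNG of the ranked (black) and random (blue) r^2 curves."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.m_star, curve.r2, color="black", label="LOD-ranked inclusion")
    if random_curve is not None:
        ax.plot(
            random_curve.m_star, random_curve.r2, color="blue",
            label="random inclusion",
        )
    ax.axvline(curve.best_m_star, color="grey", ls=":", lw=0.8)
    ax.set_xlabel("number of effects in the model (m*)")
    ax.set_ylabel("cross-validated $r^2$")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
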