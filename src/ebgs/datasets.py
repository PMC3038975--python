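"""Packaged reference data.

The soybean somatic-embryogenesis RIL study that motivates this package
did not deposit its genotype/phenotype data, but its published report
includes the 80-marker SSR map (77 markers on 19 linkage groups, 3
unmapped) and the empirical Bayes effect estimates for the top 27 main
effects and top 66 epistatic effects.  Those printed tables ship here:
the map seeds the synthetic-data generator, and the effect tables serve
as consistency fixtures for the Wald/LOD/p-value chain.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io_data import MarkerMap, read_marker_map


def _data_path(name: str):
    return resources.files("ebgs").joinpath("data", name)


def soybean_marker_map() -> MarkerMap:
    """The 80-marker SSR map (M1-M80, markers Satt005...; 19 linkage groups)."""
    with resources.as_file(_data_path("soybean_marker_map.csv")) as path:
        return read_marker_map(path)


def reported_main_effects() -> pd.DataFrame:
    """Published top-27 main-effect estimates (variance, effect, StdErr, LOD, p, H)."""
    with resources.as_file(_data_path("soybean_main_effects.csv")) as path:
        return pd.read_csv(path)


def reported_epistatic_effects() -> pd.DataFrame:
    """Published top-66 epistatic-effect estimates."""
    with resources.as_file(_data_path("soybean_epistatic_effects.csv")) as path:
        return pd.read_csv(path)
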