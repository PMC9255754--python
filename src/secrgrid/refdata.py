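"""Loaders for the published reference tables shipped with the package.

Two small CSV tables from an 18-year salt-marsh harvest mouse grid-trapping
monitoring program (Suisun Marsh, CA) are bundled: annual SECR density
estimates with capture counts for the full 10x10 design and its subsampled
variants, and the per-year full-minus-reduced density differences. They
drive the design-comparison arithmetic and provide the default density
trajectory for the study emulator.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_annual_estimates", "load_design_differences", "DESIGN_COLUMNS"]

DESIGN_COLUMNS = ("9x9", "8x8", "7x7", "6x6", "half", "3day")


def _read(name: str) -> pd.DataFrame:
    with resources.files("secrgrid.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


def load_annual_estimates() -> pd.DataFrame:
    """Annual densities (ind/ha) and capture counts per design variant."""
    return _read("annual_density_estimates.csv")


def load_design_differences() -> pd.DataFrame:
    """Per-year density differences, full design minus each reduced design."""
    return _read("design_density_differences.csv")
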