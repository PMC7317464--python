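"""Subregion environments: mean-monthly-maximum SST baselines.

Every host node lives in a subregion, and each subregion carries the 2005
mean monthly maximum sea surface temperature (T_MMM, degC) — the climatological
baseline above which bleaching is expected. A packaged default table ships the
fourteen subregions of the global coral-symbiont network, grouped into three
ocean-basin regions.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["SubregionEnvironment", "load_default_environment", "read_environment_csv"]

#: Subregions with fewer links than this are excluded from resistance and
#: robustness reporting by default.
MIN_LINKS_FOR_REPORTING = 40


class EnvironmentLookupError(KeyError):
    """A subregion or region label is absent from the environment table."""


@dataclass
class SubregionEnvironment:
    """Maps subregion -> (region, T_MMM) and region -> member subregions."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"subregion", "region", "t_mmm_2005_c"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"environment table missing columns: {sorted(missing)}")
        dup = self.table["subregion"].duplicated()
        if dup.any():
            raise ValueError(
                f"duplicate subregions: {sorted(self.table.loc[dup, 'subregion'])}"
            )
        self._by_subregion = self.table.set_index("subregion")

    @property
    def subregions(self) -> list[str]:
        return list(self._by_subregion.index)

    @property
    def regions(self) -> list[str]:
        return list(dict.fromkeys(self.table["region"]))

    def t_mmm(self, subregion: str) -> float:
        try:
            return float(self._by_subregion.loc[subregion, "t_mmm_2005_c"])
        except KeyError:
            raise EnvironmentLookupError(f"unknown subregion: {subregion!r}") from None

    def region_of(self, subregion: str) -> str:
        try:
            return str(self._by_subregion.loc[subregion, "region"])
        except KeyError:
            raise EnvironmentLookupError(f"unknown subregion: {subregion!r}") from None

    def subregions_of(self, region: str) -> list[str]:
        out = list(self.table.loc[self.table["region"] == region, "subregion"])
        if not out:
            raise EnvironmentLookupError(f"unknown region: {region!r}")
        return out

    def __contains__(self, subregion: str) -> bool:
        return subregion in self._by_subregion.index


def read_environment_csv(path) -> SubregionEnvironment:
    """Read an environment table (columns subregion, region, t_mmm_2005_c)."""
    return SubregionEnvironment(pd.read_csv(path))


def load_default_environment() -> SubregionEnvironment:
    """The packaged default: fourteen subregions in three ocean basins."""
    ref = importlib.resources.files("coralnet") / "data" / "subregions.csv"
    with importlib.resources.as_file(ref) as path:
        return read_environment_csv(path)
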