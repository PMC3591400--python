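"""Gel-lane geometry: MW-calibrated, ordered gel bands.

In a GeLC experiment an SDS-PAGE lane is sliced into thin numbered bands
(top of the gel = band 1 = highest molecular weight), grouped into lettered
sections.  Proteins migrate to the band(s) matching their molecular weight,
so band position carries implicit MW information — that is what lets the
pipeline separate proteoforms (e.g. a protease precursor from its processed
form).  Calibration here is log-linear between the MW at the top and bottom
of the lane, the standard first-order model for SDS-PAGE migration.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass

import numpy as np

__all__ = ["GelBand", "GelLane", "default_lane"]


@dataclass(frozen=True)
class GelBand:
    """One gel slice.  ``mw_lo_kda``/``mw_hi_kda`` may be NaN when the lane is
    uncalibrated (e.g. evidence read without a lane definition)."""

    fraction: str
    index: int
    section: str = ""
    mw_lo_kda: float = math.nan
    mw_hi_kda: float = math.nan

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("band index starts at 1 (top of the gel)")
        if self.is_calibrated and not self.mw_lo_kda < self.mw_hi_kda:
            raise ValueError(
                f"band {self.index}: mw_lo must be < mw_hi "
                f"({self.mw_lo_kda}, {self.mw_hi_kda})"
            )

    @property
    def is_calibrated(self) -> bool:
        return math.isfinite(self.mw_lo_kda) and math.isfinite(self.mw_hi_kda)

    @property
    def mw_mid_kda(self) -> float:
        """Geometric midpoint of the band's MW window."""
        return math.sqrt(self.mw_lo_kda * self.mw_hi_kda)


@dataclass(frozen=True)
class GelLane:
    """Ordered bands of one fraction's lane, top (high MW) to bottom."""

    fraction: str
    bands: tuple[GelBand, ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError("a lane needs at least one band")
        for prev, cur in zip(self.bands, self.bands[1:]):
            if cur.index != prev.index + 1:
                raise ValueError("band indices must be consecutive from 1")
            if prev.is_calibrated and cur.is_calibrated and cur.mw_hi_kda > prev.mw_hi_kda + 1e-9:
                raise ValueError("MW windows must be non-increasing down the lane")
        if self.bands[0].index != 1:
            raise ValueError("first band must have index 1")

    @classmethod
    def log_linear(
        cls,
        fraction: str,
        n_bands: int,
        mw_top_kda: float = 250.0,
        mw_bottom_kda: float = 10.0,
        n_sections: int = 10,
    ) -> "GelLane":
        """Calibrate ``n_bands`` bands log-linearly between the MW at the top
        and bottom of the lane, splitting them into ``n_sections`` lettered
        sections (A nearest the top)."""
        if n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        if not mw_bottom_kda < mw_top_kda:
            raise ValueError("mw_bottom_kda must be < mw_top_kda")
        edges = np.geomspace(mw_top_kda, mw_bottom_kda, n_bands + 1)
        letters = string.ascii_uppercase
        section_of = np.repeat(
            np.arange(min(n_sections, len(letters))),
            math.ceil(n_bands / min(n_sections, len(letters))),
        )[:n_bands]
        bands = tuple(
            GelBand(
                fraction=fraction,
                index=i + 1,
                section=letters[section_of[i]],
                mw_lo_kda=float(edges[i + 1]),
                mw_hi_kda=float(edges[i]),
            )
            for i in range(n_bands)
        )
        return cls(fraction=fraction, bands=bands)

    @property
    def n_bands(self) -> int:
        return len(self.bands)

    @property
    def is_calibrated(self) -> bool:
        return all(b.is_calibrated for b in self.bands)

    def band(self, index: int) -> GelBand:
        if not 1 <= index <= len(self.bands):
            raise KeyError(f"band index {index} outside lane (1..{len(self.bands)})")
        return self.bands[index - 1]

    def band_for_mw(self, mw_kda: float) -> GelBand:
        """Band whose MW window contains ``mw_kda`` (clamped to lane ends)."""
        if not self.is_calibrated:
            raise ValueError(f"lane {self.fraction} is not MW-calibrated")
        if mw_kda >= self.bands[0].mw_hi_kda:
            return self.bands[0]
        for band in self.bands:
            if mw_kda >= band.mw_lo_kda:
                return band
        return self.bands[-1]


def default_lane(fraction: str) -> GelLane:
    """Default lane geometries for the two membrane fractions.

    F1: 65 bands in 11 sections (A-K); F2: 72 bands in 10 sections (A-J);
    both calibrated 250 kDa (top) to 10 kDa (bottom).
    """
    if fraction == "F1":
        return GelLane.log_linear("F1", n_bands=65, n_sections=11)
    if fraction == "F2":
        return GelLane.log_linear("F2", n_bands=72, n_sections=10)
    raise ValueError(f"unknown fraction {fraction!r} (expected 'F1' or 'F2')")
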