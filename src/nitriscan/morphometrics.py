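"""Cell surface-area-to-volume (SA/V) morphometrics.

SA/V (1/um) is the standard proxy for substrate-uptake affinity: small cells
with large SA/V scavenge dilute substrates (e.g. marine ammonia oxidizers)
better than large, low-SA/V cells.  Two idealized geometries are supported:

* sphere of diameter d:   SA = pi d^2, V = (pi/6) d^3  ->  SA/V = 6/d
* rod, a flat-capped cylinder of diameter d and length h:
  SA = pi d h + 2 pi (d/2)^2, V = pi (d/2)^2 h  ->  SA/V = 4/d + 2/h

Cell dimensions are means over literature-reported widths/lengths.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean

import pandas as pd

from .genome_io import StrainMetadata


@dataclass
class CellShape:
    strain_id: str
    shape: str  # 'sphere' | 'rod'
    d: float    # diameter, um
    h: float | None  # length, um (rod only)
    sav: float  # 1/um


def sav(shape: str, d: float, h: float | None = None) -> float:
    """SA/V ratio (1/um) for a sphere (6/d) or flat-capped rod (4/d + 2/h)."""
    if d <= 0:
        raise ValueError("diameter must be positive")
    if shape == "sphere":
        return 6.0 / d
    if shape == "rod":
        if h is None:
            raise ValueError("rod shape requires length h")
        if h <= 0:
            raise ValueError("length must be positive")
        return 4.0 / d + 2.0 / h
    raise ValueError(f"unknown shape {shape!r}")


def strain_sav(meta: StrainMetadata) -> CellShape:
    """SA/V from a strain's reported dimensions (means of widths/lengths)."""
    d = mean(meta.widths)
    h = mean(meta.lengths) if meta.lengths else None
    return CellShape(strain_id=meta.strain_id, shape=meta.shape, d=d, h=h,
                     sav=sav(meta.shape, d, h))


def sav_table(metadata: list[StrainMetadata]) -> pd.DataFrame:
    """Per-strain SA/V table ready for guild/habitat group comparisons."""
    rows = []
    for m in metadata:
        c = strain_sav(m)
        rows.append({"strain_id": m.strain_id, "guild": m.guild,
                     "habitat": m.habitat, "shape": c.shape,
                     "d_um": c.d, "h_um": c.h, "sav_per_um": c.sav})
    return pd.DataFrame(rows, columns=["strain_id", "guild", "habitat", "shape",
                                       "d_um", "h_um", "sav_per_um"])
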