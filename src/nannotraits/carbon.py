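"""Cellular carbon allometries.

Organic carbon per cell scales with biovolume (Prymnesiophyte fit):

    POC (pg C) = 0.228 · volume^0.899,   volume in μm³.

Inorganic carbon per coccolith follows the shape-factor approach:

    coccolith PIC (pg C) = dimension³ · Ks · 2.7 · 0.12,

where 2.7 pg μm⁻³ is the density of calcite and carbon is 12% of the mass
of CaCO₃ (fixed conversion constants — never recomputed from atomic
weights, for bit-compatibility of published estimates).  Cellular PIC is
coccolith PIC times C_N.  Both POC and PIC are pg of elemental carbon, so
the PIC:POC mass ratio equals the molar ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DomainError
from .params import KsEntry

__all__ = [
    "POC_COEF",
    "POC_EXP",
    "CALCITE_DENSITY",
    "CARBON_FRACTION",
    "CellCarbon",
    "sphere_volume",
    "poc_from_volume",
    "coccolith_pic",
    "cellular_pic",
    "pic_poc_ratio",
    "pic_dimension_from_length",
    "cell_carbon",
]

POC_COEF = 0.228      # pg C at unit biovolume
POC_EXP = 0.899       # sublinear biovolume exponent
CALCITE_DENSITY = 2.7  # pg CaCO3 per μm³ calcite
CARBON_FRACTION = 0.12  # mass fraction of C in CaCO3


@dataclass(frozen=True)
class CellCarbon:
    """Per-cell carbon content, pg C, and the PIC:POC molar ratio."""

    POC: float
    PIC: float

    def __post_init__(self):
        if not (self.POC > 0):
            raise ValueError("POC must be > 0 for a positive cell volume")
        if self.PIC < 0:
            raise ValueError("PIC must be >= 0")

    @property
    def pic_poc(self) -> float:
        return self.PIC / self.POC


def sphere_volume(cell_diameter):
    """Biovolume (μm³) of a spherical cell of diameter Θ: (π/6)Θ³."""
    theta = np.asarray(cell_diameter, dtype=float)
    if np.any(theta <= 0):
        raise DomainError("cell diameter must be > 0")
    v = (np.pi / 6.0) * theta ** 3
    return float(v) if v.ndim == 0 else v


def poc_from_volume(volume):
    """Cellular POC (pg C) from biovolume (μm³): 0.228 · V^0.899."""
    v = np.asarray(volume, dtype=float)
    if np.any(v < 0):
        raise DomainError("volume must be >= 0")
    poc = POC_COEF * v ** POC_EXP
    return float(poc) if poc.ndim == 0 else poc


def coccolith_pic(dimension, ks: KsEntry, dimension_kind: str | None = None):
    """PIC per coccolith (pg C) from the cubed characteristic dimension.

    ``dimension`` must be the length named by ``ks.dimension_kind``; a caller
    declaring a different ``dimension_kind`` is an error, not a conversion.
    """
    if dimension_kind is not None and dimension_kind != ks.dimension_kind:
        raise ConfigurationError(
            f"{ks.morphogroup}: Ks expects {ks.dimension_kind!r}, "
            f"caller supplied {dimension_kind!r}"
        )
    d = np.asarray(dimension, dtype=float)
    if np.any(d <= 0):
        raise DomainError("coccolith dimension must be > 0")
    pic = d ** 3 * ks.Ks * CALCITE_DENSITY * CARBON_FRACTION
    return float(pic) if pic.ndim == 0 else pic


def cellular_pic(lith_pic, coccoliths_per_cell):
    """PIC per cell: coccolith PIC × C_N."""
    lp = np.asarray(lith_pic, dtype=float)
    cn = np.asarray(coccoliths_per_cell, dtype=float)
    if np.any(lp < 0):
        raise DomainError("coccolith PIC must be >= 0")
    if np.any(cn < 1):
        raise DomainError("C_N must be >= 1")
    pic = lp * cn
    return float(pic) if pic.ndim == 0 else pic


def pic_poc_ratio(pic, poc):
    """PIC:POC (mol:mol; equals the mass ratio as both are pg of carbon)."""
    poc_arr = np.asarray(poc, dtype=float)
    if np.any(poc_arr <= 0):
        raise DomainError("POC must be > 0")
    r = np.asarray(pic, dtype=float) / poc_arr
    return float(r) if r.ndim == 0 else r


def pic_dimension_from_length(coccolith_length, ks: KsEntry,
                              height_base_ratio: float | None = None):
    """Map the size-model length to the dimension feeding the calcite cube.

    distal shield / base length feed directly; ray length is half the
    circumscribing-circle diameter (*Discoaster*); lith height is base
    length times the sample-mean height:base ratio (holococcoliths).
    """
    cl = np.asarray(coccolith_length, dtype=float)
    kind = ks.dimension_kind
    if kind in ("distal shield length", "base length"):
        out = cl
    elif kind == "ray length":
        out = cl / 2.0
    elif kind == "lith height":
        if height_base_ratio is None or not (height_base_ratio > 0):
            raise ConfigurationError(
                f"{ks.morphogroup}: lith-height Ks needs a positive "
                "height:base ratio"
            )
        out = cl * height_base_ratio
    else:  # pragma: no cover - closed set enforced by KsEntry
        raise ConfigurationError(f"unknown dimension kind {kind!r}")
    return float(out) if out.ndim == 0 else out


def cell_carbon(cell_diameter, coccolith_length, coccoliths_per_cell,
                ks: KsEntry, height_base_ratio: float | None = None) -> CellCarbon:
    """Full per-cell carbon budget for one (Θ, C_L, C_N) combination."""
    poc = poc_from_volume(sphere_volume(cell_diameter))
    dim = pic_dimension_from_length(coccolith_length, ks, height_base_ratio)
    pic = cellular_pic(coccolith_pic(dim, ks), coccoliths_per_cell)
    return CellCarbon(float(poc), float(pic))
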