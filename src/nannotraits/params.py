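"""Per-morphogroup model parameters and JSON registries.

Two parameterizations of the coccolith-geometry → cell-diameter link exist:

* ``placolith`` morphogroups carry the slope/intercept (α, β) of the
  log10-linear allometry between coccolith length and cell surface area
  per coccolith, fitted on intact fossil coccospheres.
* ``nonplacolith`` morphogroups (nannoliths and holococcoliths, which
  disarticulate before burial) instead carry a coverage factor C_O, a
  coccolith aspect ratio AR, and simulated coccoliths-per-cell (C_N)
  settings, because no intact coccospheres constrain them.

Every morphogroup also carries a calcite shape factor Ks and the coccolith
dimension that feeds the cubic mass term: the distal shield length for
placoliths, base length for *Sphenolithus*, ray length (half the
circumscribing-circle diameter) for *Discoaster*, and lith height for
*Z. bijugatus* (obtained from base length via a mean height:base ratio).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "RegressionParams",
    "NonPlacolithParams",
    "KsEntry",
    "MorphogroupParams",
    "DIMENSION_KINDS",
    "default_registry",
    "load_registry",
    "save_registry",
]

DIMENSION_KINDS = frozenset(
    {"distal shield length", "base length", "ray length", "lith height"}
)


@dataclass(frozen=True)
class RegressionParams:
    """Fitted log-log allometry for a placolith morphogroup.

    log10(C_L) = alpha * log10(cell surface area / C_N) + beta
    """

    morphogroup: str
    alpha: float
    beta: float
    n_spheres: int = 0

    def __post_init__(self):
        if not np.isfinite(self.alpha) or not np.isfinite(self.beta):
            raise ValueError("alpha and beta must be finite")
        if self.alpha == 0:
            raise ValueError("alpha must be non-zero (the allometry is invertible)")


@dataclass(frozen=True)
class NonPlacolithParams:
    """Coverage-factor parameterization for nannolith/holococcolith groups.

    ``C_O`` is the fraction of cell surface area represented by the summed
    coccolith areas (>1 for abutting liths with gaps, <1 for overlap), ``AR``
    the mean length:width aspect ratio of the lith, and ``cn_*`` the settings
    of the simulated Gaussian C_N distribution (mean, sd, inclusive range).
    ``height_base_ratio`` optionally maps base length to lith height for the
    calcite mass term (holococcoliths).
    """

    morphogroup: str
    C_O: float
    AR: float
    cn_mean: float
    cn_sd: float
    cn_range: tuple[int, int]
    height_base_ratio: float | None = None

    def __post_init__(self):
        if not (self.C_O > 0):
            raise ValueError("coverage factor C_O must be > 0")
        if not (self.AR >= 1):
            raise ValueError("aspect ratio AR must be >= 1 (length >= width)")
        lo, hi = self.cn_range
        if lo < 1 or lo >= hi or int(lo) != lo or int(hi) != hi:
            raise ValueError("cn_range must be integers with 1 <= min < max")
        if not (lo <= self.cn_mean <= hi):
            raise ValueError("cn_mean must lie within cn_range")
        if not (self.cn_sd > 0):
            raise ValueError("cn_sd must be > 0")


@dataclass(frozen=True)
class KsEntry:
    """Shape factor converting a coccolith dimension cubed to calcite volume."""

    morphogroup: str
    Ks: float
    dimension_kind: str = "distal shield length"

    def __post_init__(self):
        if not (self.Ks > 0):
            raise ValueError("Ks must be > 0")
        if self.dimension_kind not in DIMENSION_KINDS:
            raise ValueError(
                f"dimension_kind must be one of {sorted(DIMENSION_KINDS)}"
            )


@dataclass(frozen=True)
class MorphogroupParams:
    """Bundle of everything the size-trait model needs for one morphogroup."""

    morphogroup: str
    mode: str  # "placolith" | "nonplacolith"
    ks: KsEntry
    regression: RegressionParams | None = None
    nonplacolith: NonPlacolithParams | None = None

    def __post_init__(self):
        if self.mode not in ("placolith", "nonplacolith"):
            raise ValueError("mode must be 'placolith' or 'nonplacolith'")
        if self.mode == "placolith" and self.regression is None:
            raise ConfigurationError(
                f"{self.morphogroup}: placolith mode requires regression params"
            )
        if self.mode == "nonplacolith" and self.nonplacolith is None:
            raise ConfigurationError(
                f"{self.morphogroup}: nonplacolith mode requires C_O/AR params"
            )

    @property
    def size_params(self):
        return self.regression if self.mode == "placolith" else self.nonplacolith


def _cn_sd_default(lo: int, hi: int) -> float:
    # a +/-3 sigma window spanning the admitted range
    return (hi - lo) / 6.0


# Default shape factors (dimensionless) and the dimension feeding the cube.
_DEFAULT_KS = {
    "Chiasmolithus": ("distal shield length", 0.06),
    "Coccolithus": ("distal shield length", 0.06),
    "Clausicoccus": ("distal shield length", 0.05),
    "Cyclicargolithus": ("distal shield length", 0.08),
    "R. bisecta group": ("distal shield length", 0.07),
    "R. lockeri group": ("distal shield length", 0.05),
    "R. umbilicus group": ("distal shield length", 0.045),
    "Sphenolithus": ("base length", 0.05),
    "Discoaster": ("ray length", 0.22),
    "Z. bijugatus": ("lith height", 0.40),
}

# Default fitted allometries for the placolith morphogroups (site-specific
# values; refit whenever coccosphere geometry data are available).
_DEFAULT_REGRESSION = {
    "Chiasmolithus": (0.478, 0.151),
    "Coccolithus": (0.623, -0.122),
    "Clausicoccus": (0.513, -0.025),
    "Cyclicargolithus": (0.441, 0.275),
    "R. bisecta group": (0.574, 0.052),
    "R. lockeri group": (0.574, 0.052),
    "R. umbilicus group": (0.574, 0.052),
}

# Coverage factor, aspect ratio, simulated C_N settings, height:base ratio.
_DEFAULT_NONPLACOLITH = {
    "Sphenolithus": (1.18, 1.4, 42.5, None, (27, 60), None),
    "Discoaster": (0.80, 1.0, 20.0, None, (10, 31), None),
    "Z. bijugatus": (1.13, 1.3, 22.0, None, (9, 37), 0.7),
}

PLACOLITH_MORPHOGROUPS = tuple(_DEFAULT_REGRESSION)
NONPLACOLITH_MORPHOGROUPS = tuple(_DEFAULT_NONPLACOLITH)
ALL_MORPHOGROUPS = PLACOLITH_MORPHOGROUPS + NONPLACOLITH_MORPHOGROUPS


def default_registry() -> dict[str, MorphogroupParams]:
    """The preloaded 10-morphogroup parameter registry."""
    reg: dict[str, MorphogroupParams] = {}
    for mg, (kind, ks) in _DEFAULT_KS.items():
        ks_entry = KsEntry(mg, ks, kind)
        if mg in _DEFAULT_REGRESSION:
            a, b = _DEFAULT_REGRESSION[mg]
            reg[mg] = MorphogroupParams(
                mg, "placolith", ks_entry,
                regression=RegressionParams(mg, a, b),
            )
        else:
            co, ar, mean, sd, rng, hbr = _DEFAULT_NONPLACOLITH[mg]
            if sd is None:
                sd = _cn_sd_default(*rng)
            reg[mg] = MorphogroupParams(
                mg, "nonplacolith", ks_entry,
                nonplacolith=NonPlacolithParams(mg, co, ar, mean, sd, rng, hbr),
            )
    return reg


def save_registry(registry: dict[str, MorphogroupParams], path) -> None:
    """Write a registry to JSON keyed by morphogroup."""
    payload = {}
    for mg, p in registry.items():
        entry: dict = {
            "mode": p.mode,
            "Ks": p.ks.Ks,
            "ks_dimension": p.ks.dimension_kind,
        }
        if p.mode == "placolith":
            entry.update(alpha=p.regression.alpha, beta=p.regression.beta,
                         n_spheres=p.regression.n_spheres)
        else:
            np_ = p.nonplacolith
            entry.update(
                C_O=np_.C_O, AR=np_.AR, cn_mean=np_.cn_mean, cn_sd=np_.cn_sd,
                cn_range=list(np_.cn_range),
                height_base_ratio=np_.height_base_ratio,
            )
        payload[mg] = entry
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def load_registry(path) -> dict[str, MorphogroupParams]:
    """Load a JSON parameter registry keyed by morphogroup."""
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    reg = {}
    for mg, entry in payload.items():
        try:
            ks = KsEntry(mg, entry["Ks"], entry.get("ks_dimension",
                                                    "distal shield length"))
            if entry["mode"] == "placolith":
                reg[mg] = MorphogroupParams(
                    mg, "placolith", ks,
                    regression=RegressionParams(
                        mg, entry["alpha"], entry["beta"],
                        entry.get("n_spheres", 0)),
                )
            else:
                reg[mg] = MorphogroupParams(
                    mg, "nonplacolith", ks,
                    nonplacolith=NonPlacolithParams(
                        mg, entry["C_O"], entry["AR"], entry["cn_mean"],
                        entry["cn_sd"], tuple(entry["cn_range"]),
                        entry.get("height_base_ratio"),
                    ),
                )
        except (KeyError, ValueError) as exc:
            raise ConfigurationError(f"registry entry {mg!r}: {exc}") from exc
    return reg
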