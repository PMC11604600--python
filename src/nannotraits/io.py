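"""Tabular input/output and the age-depth model.

All tables are comma-delimited UTF-8 text with a single header row and "."
as the decimal separator.  Coccosphere geometry is one row per measured
coccosphere; coccolith-size and assemblage-count tables are long format
(one measurement, or one taxon count, per row) and are grouped on read.

Depths are metres composite core depth below sea floor (m-CCSF), ages are
Ma.  Ages between tie points assume a linear sedimentation rate; no
extrapolation beyond the outermost tie points is performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, RowValidationError, SchemaError

__all__ = [
    "CoccosphereRecord",
    "LithSizeSample",
    "AssemblageSample",
    "AgeModel",
    "read_coccosphere_table",
    "write_coccosphere_table",
    "read_lith_size_table",
    "write_lith_size_table",
    "read_assemblage_table",
    "write_assemblage_table",
    "read_age_model",
    "write_age_model",
    "age_from_depth",
    "sedimentation_rate",
]


@dataclass(frozen=True)
class CoccosphereRecord:
    """One measured intact fossil coccosphere.

    Attributes
    ----------
    morphogroup : str
        Genus-level morphogroup label.
    coccolith_length : float
        Maximum coccolith (distal shield) length C_L, μm.
    coccoliths_per_cell : int
        Number of coccoliths forming the coccosphere, C_N.
    coccosphere_diameter : float
        External diameter of the calcite covering ∅, μm.
    cell_diameter : float
        Internal (cell) diameter Θ, μm.
    source_sample : str or None
        Optional provenance label.
    """

    morphogroup: str
    coccolith_length: float
    coccoliths_per_cell: int
    coccosphere_diameter: float
    cell_diameter: float
    source_sample: str | None = None

    def __post_init__(self):
        if not self.morphogroup:
            raise ValueError("morphogroup label must be non-empty")
        if not (self.coccolith_length > 0):
            raise ValueError("coccolith length C_L must be > 0")
        cn = self.coccoliths_per_cell
        if not (isinstance(cn, (int, np.integer)) and not isinstance(cn, bool)):
            raise ValueError("coccoliths per cell C_N must be an integer")
        if cn < 1:
            raise ValueError("coccoliths per cell C_N must be >= 1")
        if not (self.cell_diameter > 0):
            raise ValueError("cell diameter Θ must be > 0")
        if self.coccosphere_diameter < self.cell_diameter:
            raise ValueError(
                "coccosphere diameter ∅ must be >= cell diameter Θ "
                "(the coccolith layer adds to the external diameter)"
            )


@dataclass(frozen=True)
class LithSizeSample:
    """Loose-coccolith length measurements for one morphogroup in one sample."""

    sample_id: str
    morphogroup: str
    lengths: tuple[float, ...]

    def __post_init__(self):
        if len(self.lengths) == 0:
            raise ValueError("lith-size sample must contain at least one length")
        if any(not (x > 0) for x in self.lengths):
            raise ValueError("all coccolith lengths must be > 0")


@dataclass(frozen=True)
class AssemblageSample:
    """Coccolith counts per taxon at one depth."""

    sample_id: str
    depth: float
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        for taxon, c in self.counts.items():
            if c < 0 or int(c) != c:
                raise ValueError(f"count for {taxon!r} must be a non-negative integer")
        if self.total < 1:
            raise ValueError("assemblage sample must contain at least one count")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def proportions(self) -> dict[str, float]:
        tot = self.total
        return {t: c / tot for t, c in self.counts.items()}


class AgeModel:
    """Piecewise-linear age-depth model over ordered tie points.

    Tie points are (depth m-CCSF, age Ma) pairs, strictly monotone in both
    coordinates.  Sample ages assume a linear sedimentation rate between
    the tie points; depths outside the tie-point span raise
    :class:`~nannotraits.errors.DomainError` rather than extrapolating.
    """

    def __init__(self, tie_points):
        pts = sorted((float(d), float(a)) for d, a in tie_points)
        if len(pts) < 2:
            raise ValueError("age model needs at least 2 tie points")
        depths = np.array([p[0] for p in pts])
        ages = np.array([p[1] for p in pts])
        if np.any(np.diff(depths) <= 0):
            raise ValueError("tie-point depths must be strictly monotone")
        if np.any(np.diff(ages) <= 0):
            raise ValueError("tie-point ages must be strictly monotone with depth")
        self.tie_points = tuple(pts)
        self._depths = depths
        self._ages = ages

    def __repr__(self):
        return f"AgeModel({len(self.tie_points)} tie points, " \
               f"{self._depths[0]:g}-{self._depths[-1]:g} m-CCSF)"

    def age_at(self, depth):
        return age_from_depth(self, depth)


def age_from_depth(model: AgeModel, depth) -> float:
    """Interpolate age (Ma) at ``depth`` (m-CCSF) on a linear age-depth model."""
    depth = np.asarray(depth, dtype=float)
    lo, hi = model._depths[0], model._depths[-1]
    if np.any(depth < lo) or np.any(depth > hi):
        raise DomainError(
            f"depth outside tie-point range [{lo:g}, {hi:g}] m-CCSF; "
            "no extrapolation is performed"
        )
    out = np.interp(depth, model._depths, model._ages)
    return float(out) if out.ndim == 0 else out


def sedimentation_rate(model: AgeModel) -> list[tuple[tuple[float, float], float]]:
    """Per-interval sedimentation rates, m/Myr, as ((depth_lo, depth_hi), rate)."""
    out = []
    for (d0, a0), (d1, a1) in zip(model.tie_points[:-1], model.tie_points[1:]):
        out.append(((d0, d1), (d1 - d0) / (a1 - a0)))
    return out


# ---------------------------------------------------------------------------
# table reading / writing

_COCCOSPHERE_COLS = [
    "morphogroup",
    "coccolith_length_um",
    "coccoliths_per_cell",
    "coccosphere_diameter_um",
    "cell_diameter_um",
]


def _read_csv(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def read_coccosphere_table(path) -> list[CoccosphereRecord]:
    """Read a coccosphere-geometry table (one row per intact coccosphere)."""
    df = _read_csv(path, _COCCOSPHERE_COLS)
    records = []
    for i, row in df.iterrows():
        try:
            cn_raw = float(row["coccoliths_per_cell"])
            if math.isnan(cn_raw) or cn_raw != int(cn_raw):
                raise ValueError("coccoliths per cell C_N must be an integer")
            rec = CoccosphereRecord(
                morphogroup=str(row["morphogroup"]),
                coccolith_length=float(row["coccolith_length_um"]),
                coccoliths_per_cell=int(cn_raw),
                coccosphere_diameter=float(row["coccosphere_diameter_um"]),
                cell_diameter=float(row["cell_diameter_um"]),
                source_sample=(
                    str(row["source_sample"])
                    if "source_sample" in df.columns and pd.notna(row["source_sample"])
                    else None
                ),
            )
        except (ValueError, TypeError) as exc:
            raise RowValidationError(int(i), str(exc)) from exc
        records.append(rec)
    return records


def write_coccosphere_table(records, path) -> None:
    rows = [
        {
            "morphogroup": r.morphogroup,
            "coccolith_length_um": r.coccolith_length,
            "coccoliths_per_cell": r.coccoliths_per_cell,
            "coccosphere_diameter_um": r.coccosphere_diameter,
            "cell_diameter_um": r.cell_diameter,
            "source_sample": r.source_sample if r.source_sample is not None else "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_COCCOSPHERE_COLS + ["source_sample"]).to_csv(
        path, index=False
    )


def read_lith_size_table(path) -> list[LithSizeSample]:
    """Read a long-format coccolith-length table (one measurement per row)."""
    df = _read_csv(path, ["sample_id", "morphogroup", "coccolith_length_um"])
    samples = []
    for (sid, mg), grp in df.groupby(["sample_id", "morphogroup"], sort=False):
        lengths = []
        for i, v in grp["coccolith_length_um"].items():
            x = float(v)
            if not (x > 0) or math.isnan(x):
                raise RowValidationError(int(i), "coccolith length must be > 0")
            lengths.append(x)
        samples.append(LithSizeSample(str(sid), str(mg), tuple(lengths)))
    return samples


def write_lith_size_table(samples, path) -> None:
    rows = [
        {"sample_id": s.sample_id, "morphogroup": s.morphogroup,
         "coccolith_length_um": x}
        for s in samples
        for x in s.lengths
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_assemblage_table(path) -> list[AssemblageSample]:
    """Read a long-format assemblage count table (one taxon count per row)."""
    df = _read_csv(path, ["sample_id", "depth_m_ccsf", "taxon", "count"])
    samples = []
    for sid, grp in df.groupby("sample_id", sort=False):
        depths = grp["depth_m_ccsf"].unique()
        if len(depths) != 1:
            raise SchemaError(f"sample {sid!r} has inconsistent depths {depths}")
        counts: dict[str, int] = {}
        for i, row in grp.iterrows():
            taxon = str(row["taxon"])
            if taxon in counts:
                raise RowValidationError(int(i), f"duplicate taxon {taxon!r}")
            c = float(row["count"])
            if c < 0 or c != int(c) or math.isnan(c):
                raise RowValidationError(
                    int(i), f"count for {taxon!r} must be a non-negative integer"
                )
            counts[taxon] = int(c)
        try:
            samples.append(AssemblageSample(str(sid), float(depths[0]), counts))
        except ValueError as exc:
            raise RowValidationError(int(grp.index[0]), str(exc)) from exc
    return samples


def write_assemblage_table(samples, path) -> None:
    rows = [
        {"sample_id": s.sample_id, "depth_m_ccsf": s.depth, "taxon": t, "count": c}
        for s in samples
        for t, c in s.counts.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_age_model(path) -> AgeModel:
    df = _read_csv(path, ["depth_m_ccsf", "age_ma"])
    return AgeModel(list(zip(df["depth_m_ccsf"], df["age_ma"])))


def write_age_model(model: AgeModel, path) -> None:
    pd.DataFrame(
        [{"depth_m_ccsf": d, "age_ma": a} for d, a in model.tie_points]
    ).to_csv(path, index=False)
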