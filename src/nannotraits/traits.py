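"""The size-trait model core: likelihood-weighted trait distributions.

For one morphogroup in one sample, every (C_L, C_N) combination on the
grid of observed coccolith lengths × coccoliths-per-cell values is scored
by its joint likelihood — the product of the two marginal frequency
distributions, which are treated as independent because only marginals are
observable — and the cell diameter, POC, PIC and PIC:POC implied by that
combination receive the node's weight.  Accumulating node weights into
fixed trait lattices yields binned distributions whose weighted sums are
exact (binning groups nodes, it never approximates their values).

Bin conventions (all overridable via :class:`BinSpec`): cell size 1 μm
bins centred on half-integers, POC and PIC 30 pg C bins centred on
15 + 30k pg C, PIC:POC 0.1 bins centred on 0.05 + 0.1k.  Bin membership is
half-open [lower, upper).  Coccolith-length histograms use 0.5 μm bins —
finer bins would be spurious given the ~0.26 μm optical resolution of the
light-microscope measurements they summarise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .allometry import (
    CnHistogram,
    cell_diameter_nonplacolith,
    cell_diameter_placolith,
)
from .carbon import (
    cellular_pic,
    coccolith_pic,
    pic_dimension_from_length,
    poc_from_volume,
    sphere_volume,
)
from .errors import ConfigurationError, InsufficientDataError, NannotraitsError
from .params import KsEntry, MorphogroupParams, NonPlacolithParams, RegressionParams

__all__ = [
    "BinSpec",
    "ClHistogram",
    "WeightGrid",
    "TraitDistribution",
    "build_cl_histogram",
    "build_weight_grid",
    "morphogroup_trait_distribution",
    "summarize_distribution",
]


@dataclass(frozen=True)
class BinSpec:
    """Bin widths for the four trait axes (bin edges at integer multiples)."""

    size_width: float = 1.0     # μm
    carbon_width: float = 30.0  # pg C, POC and PIC axes
    ratio_width: float = 0.1    # PIC:POC
    cl_width: float = 0.5       # μm, coccolith-length histograms

    def __post_init__(self):
        for w in (self.size_width, self.carbon_width, self.ratio_width,
                  self.cl_width):
            if not (w > 0):
                raise ValueError("bin widths must be > 0")


DEFAULT_BINS = BinSpec()


def bin_center(x, width: float):
    """Centre of the half-open bin [k·width, (k+1)·width) containing x."""
    c = (np.floor(np.asarray(x, dtype=float) / width) + 0.5) * width
    c = np.round(c, 9)  # stabilise float keys on the lattice
    return float(c) if c.ndim == 0 else c


@dataclass(frozen=True)
class ClHistogram:
    """Binned sample-specific coccolith-length distribution."""

    sample_id: str
    morphogroup: str
    bins: dict[float, float]
    bin_width: float

    def __post_init__(self):
        if not self.bins:
            raise ValueError("C_L histogram must be non-empty")
        centers = np.array(list(self.bins.keys()), dtype=float)
        if np.any(np.diff(np.sort(centers)) <= 0):
            raise ValueError("bin centers must be distinct")
        freqs = np.array(list(self.bins.values()), dtype=float)
        if np.any(freqs < 0) or abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must be >= 0 and sum to 1 within 1e-9")


def build_cl_histogram(lengths, bin_width: float = DEFAULT_BINS.cl_width,
                       sample_id: str = "", morphogroup: str = "") -> ClHistogram:
    """Histogram raw coccolith lengths on the 0.5 μm (default) lattice."""
    lengths = np.asarray(list(lengths), dtype=float)
    if lengths.size == 0:
        raise InsufficientDataError("no coccolith lengths to histogram")
    centers = bin_center(lengths, bin_width)
    values, counts = np.unique(centers, return_counts=True)
    total = counts.sum()
    bins = {float(v): float(c) / total for v, c in zip(values, counts)}
    return ClHistogram(sample_id, morphogroup, bins, bin_width)


@dataclass(frozen=True)
class WeightGrid:
    """Joint (C_L, C_N) likelihood grid: weight = freq(C_L) · freq(C_N)."""

    cl_values: tuple[float, ...]
    cn_values: tuple[int, ...]
    weights: np.ndarray  # shape (len(cl_values), len(cn_values))

    @property
    def n_nodes(self) -> int:
        return self.weights.size


def build_weight_grid(cl_hist: ClHistogram, cn_hist: CnHistogram) -> WeightGrid:
    """Outer product of the two normalized marginal histograms."""
    if not cl_hist.bins or not cn_hist.bins:
        raise InsufficientDataError("both marginal histograms must be non-empty")
    cl = sorted(cl_hist.bins)
    cn = sorted(cn_hist.bins)
    w_cl = np.array([cl_hist.bins[c] for c in cl], dtype=float)
    w_cn = np.array([cn_hist.bins[k] for k in cn], dtype=float)
    return WeightGrid(tuple(cl), tuple(int(k) for k in cn),
                      np.outer(w_cl, w_cn))


@dataclass(frozen=True)
class TraitDistribution:
    """Binned joint result of the size-trait model for one morphogroup/sample.

    ``*_bins`` map bin centre → accumulated weight (each axis sums to 1).
    ``poc_by_size_bin``/``pic_by_size_bin`` carry the weighted carbon mass
    Σ w·POC (pg C per cell of this morphogroup) grouped by *cell-size* bin,
    which is what community stacking needs to partition carbon by size.
    ``mean_ratio`` is the weighted mean of the per-combination PIC:POC —
    deliberately not ``mean_pic / mean_poc``, which differs on skewed
    distributions.
    """

    morphogroup: str
    sample_id: str
    size_bins: dict[float, float]
    poc_bins: dict[float, float]
    pic_bins: dict[float, float]
    ratio_bins: dict[float, float]
    poc_by_size_bin: dict[float, float]
    pic_by_size_bin: dict[float, float]
    mean_size: float
    mean_poc: float
    mean_pic: float
    mean_ratio: float
    bin_spec: BinSpec = field(default=DEFAULT_BINS)

    def __post_init__(self):
        for name in ("size_bins", "poc_bins", "pic_bins", "ratio_bins"):
            w = np.array(list(getattr(self, name).values()), dtype=float)
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be >= 0 and sum to 1 within 1e-9")

    @property
    def total_poc(self) -> float:
        """Per-cell expected POC, pg C (equals mean_poc by construction)."""
        return float(sum(self.poc_by_size_bin.values()))

    @property
    def total_pic(self) -> float:
        return float(sum(self.pic_by_size_bin.values()))

    def plot(self, ax=None):
        """Bar chart of the binned cell-size distribution."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        centers = sorted(self.size_bins)
        ax.bar(centers, [self.size_bins[c] for c in centers],
               width=self.bin_spec.size_width * 0.9)
        ax.set_xlabel("cell diameter (μm)")
        ax.set_ylabel("frequency")
        ax.set_title(f"{self.morphogroup} — {self.sample_id}")
        return ax


def _resolve_params(params, ks):
    if isinstance(params, MorphogroupParams):
        return params.size_params, params.ks if ks is None else ks
    if ks is None:
        raise ConfigurationError("a KsEntry is required alongside bare size params")
    return params, ks


def morphogroup_trait_distribution(
    grid: WeightGrid,
    params,
    ks: KsEntry | None = None,
    *,
    sample_id: str = "",
    bin_spec: BinSpec = DEFAULT_BINS,
    height_base_ratio: float | None = None,
) -> TraitDistribution:
    """Propagate the joint (C_L, C_N) weights through size and carbon models.

    ``params`` is a :class:`RegressionParams` (placolith mode), a
    :class:`NonPlacolithParams` (coverage-factor mode) or a full
    :class:`MorphogroupParams` bundle.  Each grid node's weight is added to
    the containing bin on every trait axis; weighted carbon is additionally
    grouped by cell-size bin for downstream community partitioning.
    """
    size_params, ks = _resolve_params(params, ks)

    cl = np.array(grid.cl_values, dtype=float)
    cn = np.array(grid.cn_values, dtype=float)
    cl_m, cn_m = np.meshgrid(cl, cn, indexing="ij")

    if isinstance(size_params, RegressionParams):
        theta = cell_diameter_placolith(cl_m, cn_m, size_params)
        hbr = height_base_ratio
    elif isinstance(size_params, NonPlacolithParams):
        theta = cell_diameter_nonplacolith(
            cl_m, size_params.AR, cn_m, size_params.C_O
        )
        hbr = (height_base_ratio if height_base_ratio is not None
               else size_params.height_base_ratio)
    else:
        raise ConfigurationError(
            f"unsupported size-parameter type {type(size_params).__name__}"
        )

    poc = poc_from_volume(sphere_volume(theta))
    dim = pic_dimension_from_length(cl_m, ks, hbr)
    pic = cellular_pic(coccolith_pic(dim, ks), cn_m)
    ratio = pic / poc

    morphogroup = ks.morphogroup
    w = grid.weights
    size_c = bin_center(theta, bin_spec.size_width)
    poc_c = bin_center(poc, bin_spec.carbon_width)
    pic_c = bin_center(pic, bin_spec.carbon_width)
    ratio_c = bin_center(ratio, bin_spec.ratio_width)

    size_bins: dict[float, float] = {}
    poc_bins: dict[float, float] = {}
    pic_bins: dict[float, float] = {}
    ratio_bins: dict[float, float] = {}
    poc_by_size: dict[float, float] = {}
    pic_by_size: dict[float, float] = {}
    mean_size = mean_poc = mean_pic = mean_ratio = 0.0

    # row-major accumulation (C_L outer, C_N inner) keeps the floating-point
    # sums identical to a naive per-node enumeration in the same order
    for i in range(w.shape[0]):
        for j in range(w.shape[1]):
            wij = w[i, j]
            sb = size_c[i, j]
            size_bins[sb] = size_bins.get(sb, 0.0) + wij
            pb = poc_c[i, j]
            poc_bins[pb] = poc_bins.get(pb, 0.0) + wij
            ib = pic_c[i, j]
            pic_bins[ib] = pic_bins.get(ib, 0.0) + wij
            rb = ratio_c[i, j]
            ratio_bins[rb] = ratio_bins.get(rb, 0.0) + wij
            poc_by_size[sb] = poc_by_size.get(sb, 0.0) + wij * poc[i, j]
            pic_by_size[sb] = pic_by_size.get(sb, 0.0) + wij * pic[i, j]
            mean_size += wij * theta[i, j]
            mean_poc += wij * poc[i, j]
            mean_pic += wij * pic[i, j]
            mean_ratio += wij * ratio[i, j]

    return TraitDistribution(
        morphogroup=morphogroup,
        sample_id=sample_id,
        size_bins=dict(sorted(size_bins.items())),
        poc_bins=dict(sorted(poc_bins.items())),
        pic_bins=dict(sorted(pic_bins.items())),
        ratio_bins=dict(sorted(ratio_bins.items())),
        poc_by_size_bin=dict(sorted(poc_by_size.items())),
        pic_by_size_bin=dict(sorted(pic_by_size.items())),
        mean_size=float(mean_size),
        mean_poc=float(mean_poc),
        mean_pic=float(mean_pic),
        mean_ratio=float(mean_ratio),
        bin_spec=bin_spec,
    )


def _binned_percentile(bins: dict[float, float], q: float) -> float:
    """First bin centre whose cumulative weight reaches q/100."""
    cum = 0.0
    centers = sorted(bins)
    for c in centers:
        cum += bins[c]
        if cum >= q / 100.0 - 1e-12:
            return c
    return centers[-1]


def summarize_distribution(dist: TraitDistribution,
                           percentiles=(5, 95)) -> dict[str, dict[str, float]]:
    """Mean and percentile band per trait axis, on the binned lattice.

    Percentiles are located on the binned cumulative weight and reported
    as bin centres (first bin whose cumulative weight reaches the target).
    """
    axes = {
        "size": (dist.size_bins, dist.mean_size),
        "poc": (dist.poc_bins, dist.mean_poc),
        "pic": (dist.pic_bins, dist.mean_pic),
        "ratio": (dist.ratio_bins, dist.mean_ratio),
    }
    out = {}
    for name, (bins, mean) in axes.items():
        w = np.array(list(bins.values()), dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise NannotraitsError(f"{name} axis is not normalized")
        entry = {"mean": float(mean)}
        for q in percentiles:
            entry[f"p{q:g}"] = _binned_percentile(bins, q)
        out[name] = entry
    return out
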