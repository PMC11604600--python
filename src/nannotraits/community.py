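"""Assemblage-level computation: from counts to community carbon budgets.

The chain is: per-sample relative abundances with binomial confidence
intervals → centred 5-point moving-average smoothing down-section →
conversion of coccolith proportions to *cell* proportions (dividing by
mean coccoliths per cell, since one cell sheds C_N coccoliths) → stacking
of abundance-weighted per-morphogroup trait distributions into a community
reconstruction for a fixed standing stock (100 cells by convention) →
partitioning of cells, POC and PIC across cell-size classes, assemblage
ecological indices, and hypothetical standing-stock scenarios.

"Community" throughout means the modelled morphogroups only; proportions
are renormalized over them before conversion, and every renormalization is
recorded on the module logger.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .allometry import (
    CoccolithAllometry,
    empirical_cn_histogram,
    simulate_cn_distribution,
)
from .errors import ConfigurationError, DomainError, NannotraitsError
from .io import AgeModel, AssemblageSample, age_from_depth
from .params import MorphogroupParams
from .traits import (
    DEFAULT_BINS,
    BinSpec,
    TraitDistribution,
    build_cl_histogram,
    build_weight_grid,
    morphogroup_trait_distribution,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceSeries",
    "CommunityReconstruction",
    "SizeClassPartition",
    "ScenarioReport",
    "relative_abundance_with_ci",
    "abundance_series",
    "smooth_abundance",
    "coccolith_to_cell_abundance",
    "stack_community",
    "partition_size_classes",
    "ecological_index",
    "scenario_totals",
    "implied_standing_stock",
    "reconstruct_communities",
]

DEFAULT_SIZE_CLASS_EDGES = (2.0, 5.0, 8.0, 11.0, 15.0, 20.0)
COLD_EUTROPHIC_TAXA = ("Chiasmolithus", "R. daviesii", "Cl. subdistichus")


@dataclass(frozen=True)
class AbundanceSeries:
    """Relative-abundance time series for one taxon, with 95% CIs."""

    taxon: str
    points: tuple  # of (sample_id, depth, proportion, ci_low, ci_high)
    smoothed: tuple | None = None


def relative_abundance_with_ci(sample: AssemblageSample, conf: float = 0.95,
                               method: str = "wald") -> dict[str, tuple]:
    """Per-taxon proportion and binomial CI for one assemblage sample.

    The default is the Wald interval p ± z·sqrt(p(1−p)/N) clamped to [0, 1]
    (degenerate at p = 0 or 1, where it collapses to a point); ``method=
    "wilson"`` selects the Wilson score interval instead.
    """
    n = sample.total
    if n < 1:
        raise DomainError("assemblage sample has zero total count")
    z = stats.norm.ppf(0.5 + conf / 2.0)
    out = {}
    for taxon, count in sample.counts.items():
        p = count / n
        if method == "wald":
            half = z * math.sqrt(p * (1.0 - p) / n)
            lo, hi = max(0.0, p - half), min(1.0, p + half)
        elif method == "wilson":
            denom = 1.0 + z * z / n
            center = (p + z * z / (2 * n)) / denom
            half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
            lo, hi = max(0.0, center - half), min(1.0, center + half)
        else:
            raise ConfigurationError(f"unknown CI method {method!r}")
        out[taxon] = (p, lo, hi)
    return out


def abundance_series(samples, conf: float = 0.95,
                     method: str = "wald") -> dict[str, AbundanceSeries]:
    """Depth-ordered per-taxon abundance series across assemblage samples."""
    samples = sorted(samples, key=lambda s: s.depth)
    taxa = sorted({t for s in samples for t in s.counts})
    series: dict[str, list] = {t: [] for t in taxa}
    for s in samples:
        cis = relative_abundance_with_ci(s, conf, method)
        for t in taxa:
            p, lo, hi = cis.get(t, (0.0, 0.0, 0.0))
            series[t].append((s.sample_id, s.depth, p, lo, hi))
    return {t: AbundanceSeries(t, tuple(pts)) for t, pts in series.items()}


def smooth_abundance(proportions: pd.DataFrame, window: int = 5,
                     renormalize: bool = True) -> pd.DataFrame:
    """Centred moving average down a depth-ordered samples × taxa table.

    The window is truncated *symmetrically* at the series ends (a point
    k rows from an end averages over 2k+1 rows), so endpoint values are
    less smoothed rather than biased.  Rows are renormalized to sum to 1
    afterwards unless ``renormalize=False``.
    """
    if window < 1 or window % 2 == 0:
        raise ConfigurationError("window must be a positive odd integer")
    n = len(proportions)
    half = (window - 1) // 2
    vals = proportions.to_numpy(dtype=float)
    out = np.empty_like(vals)
    for i in range(n):
        k = min(i, n - 1 - i, half)
        out[i] = vals[i - k: i + k + 1].mean(axis=0)
    result = pd.DataFrame(out, index=proportions.index,
                          columns=proportions.columns)
    if renormalize:
        rowsum = result.sum(axis=1)
        if (rowsum <= 0).any():
            raise DomainError("cannot renormalize a zero-sum sample row")
        if not np.allclose(rowsum, 1.0):
            logger.info("smooth_abundance: renormalizing %d rows (max |1-sum| "
                        "= %.3g)", n, float(abs(1 - rowsum).max()))
        result = result.div(rowsum, axis=0)
    return result


def coccolith_to_cell_abundance(lith_props: dict[str, float],
                                mean_cn: dict[str, float]) -> dict[str, float]:
    """Convert relative coccolith abundance to relative *cell* abundance.

    One cell of morphogroup i contributes mean C_N,i loose coccoliths to the
    sediment, so cell proportions are lith proportions divided by mean C_N,
    renormalized to 1.
    """
    missing = [m for m in lith_props if m not in mean_cn]
    if missing:
        raise ConfigurationError(
            f"no mean C_N for morphogroup(s): {', '.join(sorted(missing))}"
        )
    bad = [m for m, v in mean_cn.items() if m in lith_props and not v > 0]
    if bad:
        raise ConfigurationError(f"mean C_N must be > 0 for {bad}")
    raw = {m: p / mean_cn[m] for m, p in lith_props.items()}
    total = sum(raw.values())
    if total <= 0:
        raise DomainError("all coccolith proportions are zero")
    return {m: v / total for m, v in raw.items()}


@dataclass(frozen=True)
class CommunityReconstruction:
    """Stacked community size structure and carbon budget for one sample.

    Carbon is reported per fixed standing stock (``standing_stock`` cells,
    100 by convention); community PIC:POC = total PIC / total POC and is
    independent of the standing stock.
    """

    sample_id: str
    age: float
    cell_proportions: dict[str, float]
    size_structure: dict[float, float]
    poc_by_bin: dict[float, float]
    pic_by_bin: dict[float, float]
    mean_community_size: float
    total_poc: float
    total_pic: float
    community_pic_poc: float
    standing_stock: float = 100.0
    bin_spec: BinSpec = field(default=DEFAULT_BINS)

    def __post_init__(self):
        for name in ("cell_proportions", "size_structure"):
            w = np.array(list(getattr(self, name).values()), dtype=float)
            if abs(w.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1 within 1e-9")


def stack_community(dists: dict[str, TraitDistribution],
                    cell_props: dict[str, float],
                    standing_stock: float = 100.0,
                    *, sample_id: str = "", age: float = float("nan"),
                    ) -> CommunityReconstruction:
    """Abundance-weighted stack of per-morphogroup trait distributions."""
    missing = [m for m, p in cell_props.items() if p > 0 and m not in dists]
    if missing:
        raise ConfigurationError(
            f"no trait distribution for morphogroup(s): {', '.join(missing)}"
        )
    psum = sum(cell_props.values())
    if abs(psum - 1.0) > 1e-9:
        raise DomainError("cell proportions must sum to 1")

    size_structure: dict[float, float] = {}
    poc_by_bin: dict[float, float] = {}
    pic_by_bin: dict[float, float] = {}
    mean_size = total_poc = total_pic = 0.0
    bin_spec = next(iter(dists.values())).bin_spec
    for m, prop in sorted(cell_props.items()):
        if prop == 0:
            continue
        d = dists[m]
        for c, wgt in d.size_bins.items():
            size_structure[c] = size_structure.get(c, 0.0) + prop * wgt
        for c, v in d.poc_by_size_bin.items():
            poc_by_bin[c] = poc_by_bin.get(c, 0.0) + standing_stock * prop * v
        for c, v in d.pic_by_size_bin.items():
            pic_by_bin[c] = pic_by_bin.get(c, 0.0) + standing_stock * prop * v
        total_poc += standing_stock * prop * d.mean_poc
        total_pic += standing_stock * prop * d.mean_pic

    mean_size = sum(c * w for c, w in size_structure.items())
    return CommunityReconstruction(
        sample_id=sample_id,
        age=age,
        cell_proportions=dict(sorted(cell_props.items())),
        size_structure=dict(sorted(size_structure.items())),
        poc_by_bin=dict(sorted(poc_by_bin.items())),
        pic_by_bin=dict(sorted(pic_by_bin.items())),
        mean_community_size=float(mean_size),
        total_poc=float(total_poc),
        total_pic=float(total_pic),
        community_pic_poc=float(total_pic / total_poc),
        standing_stock=float(standing_stock),
        bin_spec=bin_spec,
    )


@dataclass(frozen=True)
class SizeClassPartition:
    """Cells, POC and PIC partitioned across cell-size classes.

    ``classes`` maps a label ("2-5" etc., plus overflow "<2" and ">=20")
    to a dict with cells_pct, poc_pct, pic_pct and pic_poc (None when the
    class holds no POC).  Percentages sum to 100 across classes including
    the overflow classes.
    """

    edges: tuple[float, ...]
    classes: dict[str, dict]


def partition_size_classes(recon: CommunityReconstruction,
                           edges=DEFAULT_SIZE_CLASS_EDGES) -> SizeClassPartition:
    """Partition a reconstruction into the cell-size classes given by edges."""
    edges = tuple(float(e) for e in edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ConfigurationError("size-class edges must be strictly increasing")

    labels = ([f"<{edges[0]:g}"]
              + [f"{a:g}-{b:g}" for a, b in zip(edges, edges[1:])]
              + [f">={edges[-1]:g}"])

    def class_of(center: float) -> str:
        if center < edges[0]:
            return labels[0]
        for a, b, lab in zip(edges, edges[1:], labels[1:-1]):
            if a <= center < b:
                return lab
        return labels[-1]

    cells = {lab: 0.0 for lab in labels}
    poc = {lab: 0.0 for lab in labels}
    pic = {lab: 0.0 for lab in labels}
    for c, w in recon.size_structure.items():
        cells[class_of(c)] += w
    for c, v in recon.poc_by_bin.items():
        poc[class_of(c)] += v
    for c, v in recon.pic_by_bin.items():
        pic[class_of(c)] += v

    total_poc, total_pic = recon.total_poc, recon.total_pic
    classes = {}
    for lab in labels:
        classes[lab] = {
            "cells_pct": 100.0 * cells[lab],
            "poc_pct": 100.0 * poc[lab] / total_poc if total_poc > 0 else 0.0,
            "pic_pct": 100.0 * pic[lab] / total_pic if total_pic > 0 else 0.0,
            "poc": poc[lab],
            "pic": pic[lab],
            "pic_poc": (pic[lab] / poc[lab]) if poc[lab] > 0 else None,
        }
    return SizeClassPartition(edges, classes)


def ecological_index(props: dict[str, float], taxa_list=COLD_EUTROPHIC_TAXA,
                     thresholds=(0.30, 0.10)) -> tuple[float, str]:
    """Percentage of indicator taxa and the interval label it implies.

    Returns (index %, label) with label "cooler" above the upper threshold,
    "warmer" below the lower, otherwise "intermediate".  Listed taxa absent
    from ``props`` contribute zero (with a warning).
    """
    hi, lo = thresholds
    unknown = [t for t in taxa_list if t not in props]
    if unknown:
        warnings.warn(f"indicator taxa absent from proportions: {unknown}; "
                      "treated as 0", stacklevel=2)
    index = 100.0 * sum(props.get(t, 0.0) for t in taxa_list)
    if index > 100.0 * hi:
        label = "cooler"
    elif index < 100.0 * lo:
        label = "warmer"
    else:
        label = "intermediate"
    return index, label


@dataclass(frozen=True)
class ScenarioReport:
    """Two-timepoint standing-stock scenario: absolute totals and changes."""

    poc_a: float  # pg C mL^-1
    poc_b: float
    pic_a: float
    pic_b: float
    stock_a: float  # cells mL^-1
    stock_b: float
    poc_change_pct: int
    pic_change_pct: int
    stock_change_pct: int


def _pct_change(a: float, b: float) -> int:
    return int(round(100.0 * (b / a - 1.0)))


def scenario_totals(recon_a: CommunityReconstruction,
                    recon_b: CommunityReconstruction,
                    stock_a: float, stock_b: float) -> ScenarioReport:
    """Hypothetical standing-stock scenario between two reconstructions.

    Total POC/PIC per mL = stock · (total per standing stock)/standing
    stock; percent changes are reported to the nearest integer.
    """
    if not (stock_a > 0 and stock_b > 0):
        raise DomainError("standing stocks must be > 0")
    if recon_a.bin_spec != recon_b.bin_spec:
        raise ConfigurationError("reconstructions use different bin conventions")
    poc_a = stock_a * recon_a.total_poc / recon_a.standing_stock
    poc_b = stock_b * recon_b.total_poc / recon_b.standing_stock
    pic_a = stock_a * recon_a.total_pic / recon_a.standing_stock
    pic_b = stock_b * recon_b.total_pic / recon_b.standing_stock
    return ScenarioReport(
        poc_a=poc_a, poc_b=poc_b, pic_a=pic_a, pic_b=pic_b,
        stock_a=float(stock_a), stock_b=float(stock_b),
        poc_change_pct=_pct_change(poc_a, poc_b),
        pic_change_pct=_pct_change(pic_a, pic_b),
        stock_change_pct=_pct_change(stock_a, stock_b),
    )


def implied_standing_stock(poc_budget: float,
                           recon: CommunityReconstruction) -> float:
    """Cells mL⁻¹ sustainable at a fixed POC budget (pg C mL⁻¹).

    budget / mean cellular POC, with mean cellular POC taken from the
    reconstruction's per-standing-stock total.
    """
    if not (poc_budget > 0):
        raise DomainError("POC budget must be > 0")
    mean_cellular_poc = recon.total_poc / recon.standing_stock
    return poc_budget / mean_cellular_poc


def load_pipeline_config(path) -> dict:
    """Read pipeline options from a YAML file.

    Recognised keys: bin widths (``size_bin_um``, ``carbon_bin_pg``,
    ``ratio_bin``, ``cl_bin_um``), ``size_class_edges_um``,
    ``cold_taxa_thresholds`` (fractions), ``ci_method``,
    ``smoothing_window``, ``standing_stock``.  Returns keyword arguments
    for :func:`reconstruct_communities` plus the reporting-side options
    ``size_class_edges`` / ``thresholds`` / ``ci_method`` for the
    partition, index and abundance-CI steps.
    """
    import yaml

    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    known = {"size_bin_um", "carbon_bin_pg", "ratio_bin", "cl_bin_um",
             "size_class_edges_um", "cold_taxa_thresholds", "ci_method",
             "smoothing_window", "standing_stock"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    out: dict = {}
    bins = {}
    if "size_bin_um" in raw:
        bins["size_width"] = float(raw["size_bin_um"])
    if "carbon_bin_pg" in raw:
        bins["carbon_width"] = float(raw["carbon_bin_pg"])
    if "ratio_bin" in raw:
        bins["ratio_width"] = float(raw["ratio_bin"])
    if "cl_bin_um" in raw:
        bins["cl_width"] = float(raw["cl_bin_um"])
    if bins:
        out["bin_spec"] = BinSpec(**bins)
    if "smoothing_window" in raw:
        out["smoothing_window"] = int(raw["smoothing_window"])
    if "ci_method" in raw:
        out["ci_method"] = str(raw["ci_method"])
    if "standing_stock" in raw:
        out["standing_stock"] = float(raw["standing_stock"])
    if "size_class_edges_um" in raw:
        out["size_class_edges"] = tuple(float(e)
                                        for e in raw["size_class_edges_um"])
    if "cold_taxa_thresholds" in raw:
        out["thresholds"] = tuple(float(t)
                                  for t in raw["cold_taxa_thresholds"])
    return out


# ---------------------------------------------------------------------------
# end-to-end driver

def reconstruct_communities(
    coccosphere_records,
    lith_samples,
    assemblage_samples,
    registry: dict[str, MorphogroupParams],
    age_model: AgeModel | None = None,
    *,
    standing_stock: float = 100.0,
    bin_spec: BinSpec = DEFAULT_BINS,
    smoothing_window: int = 5,
    cn_sim_draws: int = 10_000,
    cn_sim_seed: int = 0,
    refit_allometry: bool = True,
):
    """Run the full pipeline over a set of samples.

    Steps: fit the placolith allometries and empirical C_N histograms from
    the coccosphere data (unless ``refit_allometry=False``, which uses the
    registry's α/β as-is), simulate C_N for nonplacolith groups, convert
    assemblage counts to smoothed cell proportions over the modelled
    morphogroups, build per-sample per-morphogroup trait distributions from
    the loose-coccolith length data, and stack them into per-sample
    :class:`CommunityReconstruction` objects (depth-ordered).

    Returns ``(reconstructions, trait_distributions)`` where the latter
    maps (sample_id, morphogroup) → :class:`TraitDistribution`.
    """
    from dataclasses import replace

    # 1. per-morphogroup allometries and C_N histograms
    by_group: dict[str, list] = {}
    for r in coccosphere_records:
        by_group.setdefault(r.morphogroup, []).append(r)

    working = dict(registry)
    cn_hists = {}
    for mg, p in registry.items():
        if p.mode == "placolith":
            recs = by_group.get(mg, [])
            if not recs:
                raise ConfigurationError(
                    f"no coccosphere records for placolith morphogroup {mg!r}"
                )
            if refit_allometry:
                fit = CoccolithAllometry(recs).fit()
                working[mg] = replace(p, regression=fit.params)
            cn_hists[mg] = empirical_cn_histogram(recs)
        else:
            cn_hists[mg] = simulate_cn_distribution(
                p.nonplacolith, cn_sim_draws, seed=cn_sim_seed
            )
    mean_cn = {mg: h.mean() for mg, h in cn_hists.items()}

    # 2. assemblage proportions over modelled morphogroups, smoothed
    samples = sorted(assemblage_samples, key=lambda s: s.depth)
    modeled = sorted(registry)
    rows = []
    for s in samples:
        props = s.proportions()
        kept = {m: props.get(m, 0.0) for m in modeled}
        tot = sum(kept.values())
        if tot <= 0:
            raise DomainError(
                f"sample {s.sample_id!r} contains none of the modelled "
                "morphogroups"
            )
        if tot < 1.0 - 1e-12:
            logger.info("sample %s: renormalizing over modelled morphogroups "
                        "(coverage %.1f%%)", s.sample_id, 100 * tot)
        rows.append({m: v / tot for m, v in kept.items()})
    lith_props = pd.DataFrame(rows, index=[s.sample_id for s in samples])
    smoothed = smooth_abundance(lith_props, window=smoothing_window)

    # 3. lith-size histograms per (sample, morphogroup)
    lith_index = {(ls.sample_id, ls.morphogroup): ls for ls in lith_samples}

    reconstructions = []
    dists_out = {}
    for s in samples:
        cell_props = coccolith_to_cell_abundance(
            smoothed.loc[s.sample_id].to_dict(), mean_cn
        )
        dists = {}
        for mg in modeled:
            if cell_props.get(mg, 0.0) == 0:
                continue
            key = (s.sample_id, mg)
            if key not in lith_index:
                raise ConfigurationError(
                    f"no coccolith-length data for {mg!r} in sample "
                    f"{s.sample_id!r}"
                )
            cl_hist = build_cl_histogram(
                lith_index[key].lengths, bin_spec.cl_width,
                sample_id=s.sample_id, morphogroup=mg,
            )
            grid = build_weight_grid(cl_hist, cn_hists[mg])
            dists[mg] = morphogroup_trait_distribution(
                grid, working[mg], sample_id=s.sample_id, bin_spec=bin_spec,
            )
            dists_out[key] = dists[mg]
        age = (age_from_depth(age_model, s.depth)
               if age_model is not None else float("nan"))
        reconstructions.append(
            stack_community(dists, cell_props, standing_stock,
                            sample_id=s.sample_id, age=age)
        )
    return reconstructions, dists_out
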