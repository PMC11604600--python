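"""Synthetic data generator with known ground truth.

Emulates the statistical structure of the field datasets the pipeline
consumes, so every stage is testable end-to-end without external data:

* coccosphere geometry — integer C_N from a rounded, range-truncated
  Gaussian; right-skewed (log-normal) coccolith lengths; cell diameter
  from the exact placolith allometry inversion, with the multiplicative
  log-normal allometry noise applied on the coccolith-length side (the
  regression response), so ordinary least squares on the generated cloud
  is unbiased; coccosphere diameter a fixed fraction larger than the cell
  (the coccolith layer);
* per-sample loose-coccolith lengths — log-normal draws (n = 50 per
  morphogroup per sample by default), with an optional linear temporal
  drift in the median to emulate within-lineage size decline;
* assemblage counts — multinomial draws (≥ 300 per sample) around smooth
  true proportion paths (logistic rise of one dominant morphogroup, a
  transient acme, gradual declines).

Every bundle records its :class:`GroundTruth`: the generating parameters
plus per-sample *true* cell proportions, community PIC:POC and mean
community size, computed by dense numerical expectation over the true
C_L distribution and C_N probability mass function (independent of the
pipeline's histogramming, weighting and smoothing machinery).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import io as nio
from .allometry import cell_diameter_nonplacolith, cell_diameter_placolith
from .carbon import (
    cellular_pic,
    coccolith_pic,
    pic_dimension_from_length,
    poc_from_volume,
    sphere_volume,
)
from .errors import ConfigurationError
from .io import AgeModel, AssemblageSample, CoccosphereRecord, LithSizeSample
from .params import (
    KsEntry,
    MorphogroupParams,
    NonPlacolithParams,
    RegressionParams,
    default_registry,
    save_registry,
)

__all__ = [
    "TruthGroup",
    "TruthSample",
    "GroundTruth",
    "SyntheticBundle",
    "make_ground_truth",
    "gen_coccosphere_dataset",
    "gen_lith_size_samples",
    "gen_assemblage_series",
    "gen_ground_truth_bundle",
    "PRESETS",
]

DEFAULT_ALLOMETRY_NOISE_SD = 0.05  # log10 units around the exact inversion
LITH_LAYER_FRACTION = 0.15         # ∅ = Θ · (1 + fraction)


@dataclass(frozen=True)
class TruthGroup:
    """Generating parameters for one morphogroup."""

    params: MorphogroupParams          # true α/β or C_O/AR + Ks
    cn_mean: float
    cn_sd: float
    cn_range: tuple[int, int]
    cl_median: float                   # μm, at the oldest sample
    cl_sigma: float                    # sd of log10(C_L)
    cl_drift_total: float = 0.0        # fractional median change, old → young

    def cl_median_at(self, young_frac: float) -> float:
        return self.cl_median * (1.0 + self.cl_drift_total * young_frac)


@dataclass(frozen=True)
class TruthSample:
    """True per-sample composition and the community values it implies.

    ``lith_props`` is the raw generating proportion path; ``cell_props``
    and the community values are computed from the 5-point-smoothed path,
    because the community estimand is defined on smoothed relative
    abundances (the reconstruction smooths by design, so the recoverable
    truth at a sample is the smoothed composition).
    """

    sample_id: str
    depth: float
    young_frac: float                  # 0 at the oldest sample, 1 at youngest
    lith_props: dict[str, float]
    cell_props: dict[str, float]
    community_pic_poc: float
    mean_community_size: float


@dataclass(frozen=True)
class GroundTruth:
    preset: str
    groups: dict[str, TruthGroup]
    samples: tuple[TruthSample, ...]   # depth-ascending
    age_tie_points: tuple[tuple[float, float], ...]
    noise_sd: float = DEFAULT_ALLOMETRY_NOISE_SD

    @property
    def placolith_groups(self) -> list[str]:
        return [m for m, g in self.groups.items()
                if g.params.mode == "placolith"]

    def registry(self) -> dict[str, MorphogroupParams]:
        return {m: g.params for m, g in self.groups.items()}


# ---------------------------------------------------------------------------
# expectation oracle (independent of the pipeline's binning machinery)

def _cn_pmf(tg: TruthGroup):
    """pmf of rounded, range-truncated Normal C_N (exact renormalized masses)."""
    lo, hi = tg.cn_range
    ks = np.arange(lo, hi + 1)
    mass = (stats.norm.cdf(ks + 0.5, tg.cn_mean, tg.cn_sd)
            - stats.norm.cdf(ks - 0.5, tg.cn_mean, tg.cn_sd))
    total = mass.sum()
    if total < 1e-12:
        raise ConfigurationError("cn_range admits no probability mass")
    return ks, mass / total


def _group_expectations(tg: TruthGroup, cl_median: float) -> dict[str, float]:
    """E[Θ], E[POC], E[PIC], E[PIC:POC], E[C_N] under the true distributions."""
    zs = np.linspace(-6.0, 6.0, 601)
    wz = stats.norm.pdf(zs)
    wz = wz / wz.sum()
    cl = 10.0 ** (np.log10(cl_median) + tg.cl_sigma * zs)
    cns, wcn = _cn_pmf(tg)
    cl_m, cn_m = np.meshgrid(cl, cns.astype(float), indexing="ij")
    w = np.outer(wz, wcn)

    p = tg.params
    if p.mode == "placolith":
        theta = cell_diameter_placolith(cl_m, cn_m, p.regression)
        hbr = None
    else:
        theta = cell_diameter_nonplacolith(
            cl_m, p.nonplacolith.AR, cn_m, p.nonplacolith.C_O
        )
        hbr = p.nonplacolith.height_base_ratio
    poc = poc_from_volume(sphere_volume(theta))
    dim = pic_dimension_from_length(cl_m, p.ks, hbr)
    pic = cellular_pic(coccolith_pic(dim, p.ks), cn_m)
    return {
        "theta": float((w * theta).sum()),
        "poc": float((w * poc).sum()),
        "pic": float((w * pic).sum()),
        "ratio": float((w * pic / poc).sum()),
        "cn": float((cns * wcn).sum()),
    }


# ---------------------------------------------------------------------------
# presets

def _u1553_like_groups() -> dict[str, TruthGroup]:
    reg = default_registry()
    # (cn_mean, cn_sd, cn_range, cl_median, cl_sigma, drift); the C_L
    # medians and C_N means are calibrated so each group's expected cell
    # size and cellular PIC match the published morphogroup means
    placolith = {
        "Chiasmolithus": (8.0, 1.6, (4, 13), 12.48, 0.07, 0.0),
        "Coccolithus": (9.5, 1.9, (4, 15), 9.39, 0.08, 0.0),
        "Clausicoccus": (14.0, 2.8, (6, 22), 6.56, 0.06, 0.0),
        "Cyclicargolithus": (9.0, 1.8, (4, 14), 7.74, 0.08, 0.0),
        "R. bisecta group": (8.0, 1.6, (4, 13), 9.36, 0.07, 0.0),
        "R. lockeri group": (10.5, 2.1, (4, 17), 6.49, 0.07, 0.0),
        "R. umbilicus group": (6.0, 1.5, (4, 10), 9.30, 0.09, -0.45),
    }
    nonplacolith = {
        "Sphenolithus": (4.8, 0.08, 0.0),
        "Discoaster": (11.0, 0.09, 0.0),
        "Z. bijugatus": (8.6, 0.08, 0.0),
    }
    groups = {}
    for mg, (mean, sd, rng, med, sig, drift) in placolith.items():
        groups[mg] = TruthGroup(reg[mg], mean, sd, rng, med, sig, drift)
    for mg, (med, sig, drift) in nonplacolith.items():
        npp = reg[mg].nonplacolith
        groups[mg] = TruthGroup(reg[mg], npp.cn_mean, npp.cn_sd, npp.cn_range,
                                med, sig, drift)
    return groups


def _u1553_like_lith_props(young_frac: float) -> dict[str, float]:
    y = young_frac
    raw = {
        "Cyclicargolithus": 0.08 + 0.40 / (1.0 + np.exp(-(y - 0.45) * 8.0)),
        "R. umbilicus group": 0.16 * (1.0 - y) + 0.02,
        "R. lockeri group": 0.10,
        "R. bisecta group": 0.08 + 0.10 * y,
        "Coccolithus": 0.20 - 0.10 * y,
        "Chiasmolithus": 0.10 - 0.03 * y,
        "Clausicoccus": 0.03 + 0.09 * np.exp(-(((y - 0.25) / 0.12) ** 2)),
        "Sphenolithus": 0.02,
        "Discoaster": 0.01,
        "Z. bijugatus": 0.03,
    }
    total = sum(raw.values())
    return {m: float(v) / total for m, v in raw.items()}


def _minimal_groups() -> dict[str, TruthGroup]:
    mg = "Coccolithus"
    params = MorphogroupParams(
        mg, "placolith",
        KsEntry(mg, 0.06, "distal shield length"),
        regression=RegressionParams(mg, 0.623, -0.122),
    )
    return {mg: TruthGroup(params, 14, 3.5, (6, 26), 7.5, 0.08, 0.0)}


def _build_truth(preset: str, groups: dict[str, TruthGroup],
                 depths, tie_points, lith_props_fn) -> GroundTruth:
    from .community import smooth_abundance  # deferred: no import cycle

    depths = np.sort(np.asarray(depths, dtype=float))
    dmin, dmax = depths.min(), depths.max()
    span = dmax - dmin if dmax > dmin else 1.0
    young_fracs = [float(1.0 - (d - dmin) / span) for d in depths]
    lith_paths = [lith_props_fn(y) for y in young_fracs]
    import pandas as pd

    smoothed = smooth_abundance(pd.DataFrame(lith_paths))
    samples = []
    for i, d in enumerate(depths):
        y = young_fracs[i]
        lith = lith_paths[i]
        lith_sm = smoothed.iloc[i].to_dict()
        exps = {m: _group_expectations(g, g.cl_median_at(y))
                for m, g in groups.items() if m in lith}
        raw_cells = {m: lith_sm[m] / exps[m]["cn"] for m in lith}
        tot = sum(raw_cells.values())
        cells = {m: v / tot for m, v in raw_cells.items()}
        poc = sum(cells[m] * exps[m]["poc"] for m in cells)
        pic = sum(cells[m] * exps[m]["pic"] for m in cells)
        mean_size = sum(cells[m] * exps[m]["theta"] for m in cells)
        samples.append(TruthSample(
            sample_id=f"S{i + 1:02d}", depth=float(d), young_frac=y,
            lith_props=lith, cell_props=cells,
            community_pic_poc=float(pic / poc),
            mean_community_size=float(mean_size),
        ))
    return GroundTruth(preset, groups, tuple(samples), tuple(tie_points))


def make_ground_truth(preset: str, n_samples: int = 18) -> GroundTruth:
    """Construct the generating truth for a named preset.

    ``"U1553-like"`` — 10 morphogroups with the published α/β, Ks, C_O and
    simulated-C_N settings as the truth, smooth compositional trends over
    ``n_samples`` depths.  ``"minimal"`` — one placolith morphogroup, one
    sample (degenerate pipeline check).
    """
    if preset == "U1553-like":
        depths = np.linspace(6.0, 206.0, n_samples)
        ties = ((5.0, 26.5), (50.0, 28.0), (100.0, 29.5), (150.0, 31.5),
                (185.0, 33.3), (207.0, 34.7))
        return _build_truth(preset, _u1553_like_groups(), depths, ties,
                            _u1553_like_lith_props)
    if preset == "minimal":
        ties = ((0.0, 26.0), (100.0, 30.0))
        return _build_truth(preset, _minimal_groups(), [50.0], ties,
                            lambda y: {"Coccolithus": 1.0})
    raise ConfigurationError(f"unknown preset {preset!r}")


PRESETS = ("U1553-like", "minimal")


# ---------------------------------------------------------------------------
# generators

def _draw_cn(rng, mean, sd, lo, hi, size: int) -> np.ndarray:
    """Rounded Normal draws, redrawn (not clipped) when outside [lo, hi]."""
    out = np.empty(0, dtype=int)
    while out.size < size:
        draws = np.rint(rng.normal(mean, sd, size=max(2 * (size - out.size),
                                                      32))).astype(int)
        ok = draws[(draws >= lo) & (draws <= hi)]
        out = np.concatenate([out, ok[: size - out.size]])
    return out


def gen_coccosphere_dataset(truth: GroundTruth, n: int,
                            noise_sd: float | None = None,
                            seed=0) -> list[CoccosphereRecord]:
    """Generate ``n`` intact-coccosphere records across the placolith groups.

    Records are allocated round-robin over the truth's placolith
    morphogroups.  A latent coccolith length is drawn log-normally, the
    cell diameter is its exact allometry inversion, and the *recorded*
    coccolith length is the latent value times 10^ε with ε ~ Normal(0,
    noise_sd) — multiplicative scatter about the power law placed on the
    regression's response variable, where ordinary least squares assumes
    it.  The coccosphere diameter adds a fixed lith-layer fraction.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if noise_sd is None:
        noise_sd = truth.noise_sd
    groups = truth.placolith_groups
    if not groups:
        raise ConfigurationError("truth contains no placolith morphogroups")
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        mg = groups[i % len(groups)]
        tg = truth.groups[mg]
        cn = int(_draw_cn(rng, tg.cn_mean, tg.cn_sd, *tg.cn_range, size=1)[0])
        cl_latent = float(10.0 ** rng.normal(np.log10(tg.cl_median),
                                             tg.cl_sigma))
        theta = float(cell_diameter_placolith(cl_latent, cn,
                                              tg.params.regression))
        eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        records.append(CoccosphereRecord(
            morphogroup=mg,
            coccolith_length=cl_latent * 10.0 ** eps,
            coccoliths_per_cell=cn,
            coccosphere_diameter=theta * (1.0 + LITH_LAYER_FRACTION),
            cell_diameter=theta,
            source_sample="synthetic",
        ))
    return records


def gen_lith_size_samples(truth: GroundTruth, n_per_sample: int = 50,
                          seed=0) -> list[LithSizeSample]:
    """Per-sample log-normal coccolith lengths for every morphogroup.

    The log-normal median follows each group's (optional) linear temporal
    drift, emulating within-lineage coccolith size change.
    """
    if n_per_sample < 2:
        raise ConfigurationError("n_per_sample must be >= 2")
    rng = np.random.default_rng(seed)
    out = []
    for ts in truth.samples:
        for mg in sorted(truth.groups):
            tg = truth.groups[mg]
            med = tg.cl_median_at(ts.young_frac)
            lengths = 10.0 ** rng.normal(np.log10(med), tg.cl_sigma,
                                         size=n_per_sample)
            out.append(LithSizeSample(ts.sample_id, mg,
                                      tuple(float(x) for x in lengths)))
    return out


def gen_assemblage_series(truth: GroundTruth, total_count: int = 300,
                          seed=0) -> list[AssemblageSample]:
    """Multinomial assemblage counts around the true proportion paths."""
    if total_count < 1:
        raise ConfigurationError("total_count must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for ts in truth.samples:
        taxa = sorted(ts.lith_props)
        probs = np.array([ts.lith_props[t] for t in taxa], dtype=float)
        counts = rng.multinomial(total_count, probs / probs.sum())
        out.append(AssemblageSample(
            ts.sample_id, ts.depth,
            {t: int(c) for t, c in zip(taxa, counts)},
        ))
    return out


@dataclass(frozen=True)
class SyntheticBundle:
    """A complete generated input set plus its ground truth."""

    truth: GroundTruth
    coccospheres: list[CoccosphereRecord]
    lith_samples: list[LithSizeSample]
    assemblages: list[AssemblageSample]
    age_model: AgeModel
    registry: dict[str, MorphogroupParams] = field(default_factory=dict)
    seed: int = 0

    def write(self, outdir) -> None:
        """Write all inputs as delimited text plus a JSON metadata sidecar."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        nio.write_coccosphere_table(self.coccospheres,
                                    outdir / "coccospheres.csv")
        nio.write_lith_size_table(self.lith_samples, outdir / "lith_sizes.csv")
        nio.write_assemblage_table(self.assemblages, outdir / "assemblages.csv")
        nio.write_age_model(self.age_model, outdir / "age_model.csv")
        save_registry(self.registry, outdir / "registry.json")
        meta = {
            "preset": self.truth.preset,
            "seed": self.seed,
            "noise_sd": self.truth.noise_sd,
            "samples": [
                {
                    "sample_id": ts.sample_id,
                    "depth_m_ccsf": ts.depth,
                    "true_cell_proportions": ts.cell_props,
                    "true_community_pic_poc": ts.community_pic_poc,
                    "true_mean_community_size_um": ts.mean_community_size,
                }
                for ts in self.truth.samples
            ],
        }
        with open(outdir / "metadata.json", "w", encoding="utf-8") as fh:
            json.dump(meta, fh, indent=2)


def gen_ground_truth_bundle(preset: str, seed=0, *, n_samples: int = 18,
                            n_coccospheres: int = 375,
                            n_liths_per_sample: int = 50,
                            total_count: int = 300,
                            noise_sd: float | None = None,
                            outdir=None) -> SyntheticBundle:
    """Generate the full input set for a preset, with ground truth attached.

    A single seed drives three child streams (coccospheres, lith sizes,
    assemblage counts) via ``numpy`` seed spawning; the seed is recorded in
    the bundle and its metadata sidecar.
    """
    truth = make_ground_truth(preset, n_samples=n_samples)
    if noise_sd is not None:
        truth = GroundTruth(truth.preset, truth.groups, truth.samples,
                            truth.age_tie_points, noise_sd=noise_sd)
    s1, s2, s3 = np.random.SeedSequence(seed).spawn(3)
    bundle = SyntheticBundle(
        truth=truth,
        coccospheres=gen_coccosphere_dataset(truth, n_coccospheres, seed=s1),
        lith_samples=gen_lith_size_samples(truth, n_liths_per_sample, seed=s2),
        assemblages=gen_assemblage_series(truth, total_count, seed=s3),
        age_model=AgeModel(truth.age_tie_points),
        registry=truth.registry(),
        seed=int(seed) if np.isscalar(seed) else 0,
    )
    if outdir is not None:
        bundle.write(outdir)
    return bundle
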