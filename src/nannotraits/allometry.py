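"""Coccolith geometry → cell diameter.

Placolith-bearing morphogroups leave intact fossil coccospheres, so the
link between coccolith length C_L, coccoliths per cell C_N and cell
diameter Θ can be *fitted*: a log10-linear regression of C_L on cell
surface area per coccolith,

    log10(C_L) = α · log10(π Θ² / C_N) + β,

treating the cell as a sphere of diameter Θ (surface area π Θ²).  The
fitted line is then inverted to predict Θ for any (C_L, C_N) pair:

    Θ = sqrt( C_N · 10^((log10 C_L − β)/α) / π ).

Nannolith and holococcolith groups disarticulate before burial, so their
cell diameter is instead modelled from the coverage factor C_O relating
summed (elliptical) coccolith area to cell surface area:

    Θ = (C_LP / 2) · sqrt( C_O · C_N / AR ),

with C_LP the proximal/base length and AR the lith aspect ratio.  Their
C_N distributions are simulated as rounded, range-truncated Gaussians.

The fit is exposed statsmodels-style: :class:`CoccolithAllometry` is the
model object, its :meth:`~CoccolithAllometry.fit` returns an
:class:`AllometryResult` carrying estimates, standard errors, confidence
intervals, diagnostics, ``summary()`` and plotting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateFitError,
    DomainError,
    InsufficientDataError,
)
from .io import CoccosphereRecord
from .params import NonPlacolithParams, RegressionParams

__all__ = [
    "CnHistogram",
    "CoccolithAllometry",
    "AllometryResult",
    "fit_loglog_regression",
    "cell_diameter_placolith",
    "cell_diameter_nonplacolith",
    "simulate_cn_distribution",
    "empirical_cn_histogram",
]


@dataclass(frozen=True)
class CnHistogram:
    """Normalized frequency distribution of coccoliths per cell (integer C_N)."""

    morphogroup: str
    bins: dict[int, float]

    def __post_init__(self):
        if not self.bins:
            raise ValueError("C_N histogram must be non-empty")
        freqs = np.array(list(self.bins.values()), dtype=float)
        if np.any(freqs < 0):
            raise ValueError("C_N frequencies must be non-negative")
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError("C_N frequencies must sum to 1 within 1e-9")

    def mean(self) -> float:
        return float(sum(k * w for k, w in self.bins.items()))

    def support(self) -> tuple[int, int]:
        keys = [k for k, w in self.bins.items() if w > 0]
        return min(keys), max(keys)


def _sphere_surface_area(theta):
    # sphere of diameter Θ: SA = 4π(Θ/2)² = πΘ²
    return np.pi * np.asarray(theta, dtype=float) ** 2


class CoccolithAllometry:
    """OLS model of the placolith Θ–C_L–C_N allometry.

    Regresses log10(C_L) on log10(cell surface area / C_N) across measured
    intact coccospheres of one morphogroup.  Cell surface area is that of a
    sphere of diameter Θ.

    Parameters
    ----------
    records : sequence of CoccosphereRecord
        The training coccospheres (all one morphogroup; mixing groups is
        the caller's responsibility and almost certainly a mistake).
    """

    def __init__(self, records):
        records = list(records)
        if len(records) < 3:
            raise InsufficientDataError(
                f"allometry fit needs >= 3 coccospheres, got {len(records)}"
            )
        self.records = records
        self.morphogroup = records[0].morphogroup
        cl = np.array([r.coccolith_length for r in records], dtype=float)
        cn = np.array([r.coccoliths_per_cell for r in records], dtype=float)
        theta = np.array([r.cell_diameter for r in records], dtype=float)
        self._x = np.log10(_sphere_surface_area(theta) / cn)
        self._y = np.log10(cl)
        if np.unique(self._x).size < 2:
            raise DegenerateFitError(
                "zero variance in log10(cell surface area / C_N); "
                "the slope is unidentifiable"
            )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CoccolithAllometry":
        """Build from a coccosphere-geometry DataFrame (canonical columns)."""
        recs = [
            CoccosphereRecord(
                morphogroup=str(r["morphogroup"]),
                coccolith_length=float(r["coccolith_length_um"]),
                coccoliths_per_cell=int(r["coccoliths_per_cell"]),
                coccosphere_diameter=float(r["coccosphere_diameter_um"]),
                cell_diameter=float(r["cell_diameter_um"]),
            )
            for _, r in df.iterrows()
        ]
        return cls(recs)

    def fit(self) -> "AllometryResult":
        """Ordinary least squares on the log10-transformed variables."""
        X = sm.add_constant(self._x)
        res = sm.OLS(self._y, X).fit()
        return AllometryResult(self, res)


class AllometryResult:
    """Fitted placolith allometry: estimates, uncertainties, diagnostics."""

    def __init__(self, model: CoccolithAllometry, sm_result):
        self.model = model
        self._res = sm_result
        self.beta = float(sm_result.params[0])   # intercept
        self.alpha = float(sm_result.params[1])  # slope
        if self.alpha == 0:
            raise DegenerateFitError("fitted slope alpha is exactly zero")

    # -- estimates ---------------------------------------------------------
    @property
    def params(self) -> RegressionParams:
        return RegressionParams(
            self.model.morphogroup, self.alpha, self.beta,
            n_spheres=len(self.model.records),
        )

    @property
    def bse(self) -> dict[str, float]:
        return {"beta": float(self._res.bse[0]), "alpha": float(self._res.bse[1])}

    def conf_int(self, alpha: float = 0.05) -> dict[str, tuple[float, float]]:
        ci = self._res.conf_int(alpha)
        return {"beta": (float(ci[0][0]), float(ci[0][1])),
                "alpha": (float(ci[1][0]), float(ci[1][1]))}

    @property
    def rsquared(self) -> float:
        return float(self._res.rsquared)

    @property
    def nobs(self) -> int:
        return int(self._res.nobs)

    def summary(self):
        return self._res.summary(
            yname="log10(C_L)", xname=["beta (intercept)", "alpha (slope)"],
            title=f"Coccolith allometry: {self.model.morphogroup}",
        )

    # -- prediction --------------------------------------------------------
    def predict_cell_diameter(self, coccolith_length, coccoliths_per_cell):
        """Invert the fitted line: Θ (μm) for given C_L (μm) and C_N."""
        return cell_diameter_placolith(
            coccolith_length, coccoliths_per_cell, self.params
        )

    def plot(self, ax=None):
        """Scatter of the log-log data with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x, y = self.model._x, self.model._y
        ax.scatter(x, y, s=12, alpha=0.6, label="coccospheres")
        xs = np.linspace(x.min(), x.max(), 50)
        ax.plot(xs, self.alpha * xs + self.beta, color="k",
                label=f"α={self.alpha:.3f}, β={self.beta:.3f}")
        ax.set_xlabel("log10(cell surface area / C_N)  [μm²]")
        ax.set_ylabel("log10(C_L)  [μm]")
        ax.set_title(self.model.morphogroup)
        ax.legend()
        return ax


def fit_loglog_regression(records) -> RegressionParams:
    """Fit the placolith allometry and return (α, β) for the records' group."""
    return CoccolithAllometry(records).fit().params


def cell_diameter_placolith(coccolith_length, coccoliths_per_cell,
                            params: RegressionParams):
    """Cell diameter Θ (μm) from the inverted placolith allometry.

    Θ = sqrt( C_N · 10^((log10 C_L − β)/α) / π ).
    """
    cl = np.asarray(coccolith_length, dtype=float)
    cn = np.asarray(coccoliths_per_cell, dtype=float)
    if np.any(cl <= 0):
        raise DomainError("coccolith length C_L must be > 0")
    if np.any(cn < 1):
        raise DomainError("coccoliths per cell C_N must be >= 1")
    surface_area = cn * 10.0 ** ((np.log10(cl) - params.beta) / params.alpha)
    theta = np.sqrt(surface_area / np.pi)
    return float(theta) if theta.ndim == 0 else theta


def cell_diameter_nonplacolith(base_length, aspect_ratio, coccoliths_per_cell,
                               coverage_factor):
    """Cell diameter Θ (μm) for nannolith/holococcolith morphogroups.

    Summed elliptical lith area (π/4 · C_LP · C_LP/AR per lith) times the
    coverage factor C_O gives the cell (sphere) surface area, hence
    Θ = (C_LP/2) · sqrt(C_O · C_N / AR).
    """
    clp = np.asarray(base_length, dtype=float)
    ar = np.asarray(aspect_ratio, dtype=float)
    cn = np.asarray(coccoliths_per_cell, dtype=float)
    co = np.asarray(coverage_factor, dtype=float)
    if np.any(clp <= 0) or np.any(ar <= 0) or np.any(cn <= 0) or np.any(co <= 0):
        raise DomainError("all geometric inputs must be > 0")
    lith_area = (np.pi / 4.0) * clp * (clp / ar)
    surface_area = cn * lith_area * co
    theta = 2.0 * np.sqrt(surface_area / (4.0 * np.pi))
    return float(theta) if theta.ndim == 0 else theta


def simulate_cn_distribution(params: NonPlacolithParams, n_draws: int,
                             seed) -> CnHistogram:
    """Simulated C_N histogram: rounded Normal draws, redrawn outside range.

    Out-of-range draws are rejected and redrawn (truncation), not clipped,
    so no artificial mass piles up on the range bounds.  Reproducible for a
    given seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    lo, hi = params.cn_range
    # admissible mass of the rounding cells [lo-0.5, hi+0.5] under the Normal
    mass = (stats.norm.cdf(hi + 0.5, params.cn_mean, params.cn_sd)
            - stats.norm.cdf(lo - 0.5, params.cn_mean, params.cn_sd))
    if mass < 1e-12:
        raise ConfigurationError(
            f"{params.morphogroup}: cn_range {params.cn_range} admits no mass "
            f"under Normal({params.cn_mean}, {params.cn_sd})"
        )
    rng = np.random.default_rng(seed)
    accepted = np.empty(0, dtype=int)
    while accepted.size < n_draws:
        need = n_draws - accepted.size
        draws = np.rint(rng.normal(params.cn_mean, params.cn_sd,
                                   size=max(need * 2, 64))).astype(int)
        ok = draws[(draws >= lo) & (draws <= hi)]
        accepted = np.concatenate([accepted, ok[:need]])
    values, counts = np.unique(accepted, return_counts=True)
    total = counts.sum()
    return CnHistogram(params.morphogroup,
                       {int(v): float(c) / total for v, c in zip(values, counts)})


def empirical_cn_histogram(records) -> CnHistogram:
    """Normalized integer-count histogram of C_N from measured coccospheres."""
    records = list(records)
    if not records:
        raise InsufficientDataError("no coccosphere records for C_N histogram")
    values, counts = np.unique(
        [r.coccoliths_per_cell for r in records], return_counts=True
    )
    total = counts.sum()
    return CnHistogram(records[0].morphogroup,
                       {int(v): float(c) / total for v, c in zip(values, counts)})
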