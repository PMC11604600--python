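# Methods

## Model overview and assumptions

The package reconstructs the biogeochemical trait structure of fossil
calcareous nannoplankton communities from two kinds of observable:
morphometrics of the calcite plates (coccoliths) that survive in the
sediment, and counts of those plates by taxon. The central assumptions
are:

* **Spherical cells.** Cell surface area is that of a sphere of diameter
  Θ (`SA = πΘ²`) and biovolume is `(π/6)Θ³`. Fossil cells leave no direct
  volume record; the sphere is the standard minimal geometry and is the
  same shape assumed when the allometry was fitted, so the inversion is
  self-consistent.
* **Placolith allometry.** For morphogroups with intact fossil
  coccospheres, `log10(C_L)` is linear in `log10(SA/C_N)` with slope α
  and intercept β, fitted by unweighted OLS (no errors-in-variables
  correction). The relation is inverted analytically to predict Θ from
  any coccolith length `C_L` and coccolith count `C_N`.
* **Coverage-factor geometry for non-placoliths.** Nannolith and
  holococcolith morphogroups disarticulate before burial, so `SA =
  C_N · (π/4)·C_LP·(C_LP/AR) · C_O`, where the coverage factor `C_O`
  absorbs gaps between abutting liths (`C_O > 1`) or overlap
  (`C_O < 1`). Their `C_N` distributions are simulated as rounded
  Gaussians truncated by redrawing (not clipping, which would pile
  artificial mass on the range bounds).
* **Independent marginals.** The joint likelihood of a `(C_L, C_N)`
  combination is the product of the two marginal histograms. Only
  marginals are observable for loose coccoliths, so no joint structure
  can be estimated; within-morphogroup covariance between lith size and
  lith number is thereby assumed away.
* **Fixed carbon conversions.** `POC = 0.228·V^0.899` pg C (Prymnesiophyte
  biovolume fit) and `coccolith PIC = d³·Ks·2.7·0.12` pg C, with 2.7 pg
  μm⁻³ the density of calcite and 0.12 the carbon mass fraction of CaCO₃.
  The constants are used verbatim (never recomputed from atomic weights)
  so that estimates are bit-compatible with published values.
* **Fixed standing stock.** Community totals are reported per 100 cells.
  Community PIC:POC (= ΣPIC/ΣPOC) is independent of the stock; absolute
  standing stocks enter only through the explicit scenario calculator.

## Parameters that matter

| parameter | units | default | rationale |
|---|---|---|---|
| α, β per placolith morphogroup | – | published site-specific fits | refitted from coccosphere data whenever available (`refit_allometry=True`) |
| `Ks` shape factor | – | 0.045–0.40 by morphogroup | published morphogroup values; converts dimension³ to calcite volume |
| Ks dimension routing | – | shield/base length direct; ray = `C_L/2`; height = base × height:base | the characteristic dimension differs by lith architecture |
| height:base ratio (*Z. bijugatus*) | – | 0.7 | implied by the published mean cellular PIC (604 pg), `C_N` (22), `Ks` (0.40 on height) and mean cell size (18.9 μm ⇒ base ≈ 8.6 μm ⇒ height ≈ 6 μm) |
| `C_O`, `AR` | – | 1.18/0.80/1.13; 1.4/1.0/1.3 | published coverage factors; aspect ratios are registry defaults, overridable |
| simulated `C_N` mean/range | – | 42.5 (27–60), 20 (10–31), 22 (9–37) | published simulation settings; `cn_sd` defaults to (range)/6 so a ±3σ window reproduces the stated ranges |
| `C_L` histogram bin width | μm | 0.5 | light-microscope optical resolution ~0.26 μm makes finer bins spurious |
| cell-size bins | μm | width 1, centres on half-integers | granularity of published percentile tables |
| POC/PIC bins | pg C | width 30, centres 15+30k | same |
| PIC:POC bins | – | width 0.1, centres 0.05+0.1k | same |
| smoothing window | samples | 5 (centred) | the named statistic in the source protocol |
| CI method | – | Wald, z = 1.960, clamped | matches the cited assemblage-counting practice; Wilson selectable |
| size-class edges | μm | 2, 5, 8, 11, 15, 20 | standard plankton size fractions; overflow classes `<2` and `≥20` are tracked explicitly so percentages always total 100 |

## The synthetic-data generator

The generator emulates the statistical structure of the field datasets —
right-skewed (log-normal) coccolith lengths, Gaussian-like integer
coccolith counts, a power-law length–cell-size allometry with
multiplicative scatter, multinomial assemblage counts (≥300 per sample)
around smooth compositional trends (a logistic rise of the dominant
small, heavily calcified morphogroup; a transient acme; a within-lineage
coccolith size decline) — with every generating parameter recorded as
ground truth.

Two generator design points deserve emphasis:

* **Noise placement.** The allometric scatter (default 0.05 log10 units)
  multiplies the *coccolith length* about the power law, i.e. the
  regression's response, with the cell diameter computed exactly from the
  latent length. Placing the same noise on Θ instead would put it in the
  OLS predictor `log10(πΘ²/C_N)` and attenuate the fitted slope by ~40%
  at realistic coccolith-length spreads — a biased generator that no
  consistent fitting procedure could recover. With response-side noise,
  the fit is unbiased and its 95% confidence intervals cover the
  generating values at the nominal rate.
* **The recoverable estimand.** Per-sample ground-truth community values
  are computed from the *5-point-smoothed* true proportion paths, because
  the reconstruction (like the source protocol) is defined on smoothed
  relative abundances. Comparing against the raw path would charge the
  pipeline with a smoothing bias (up to ~3% in community PIC:POC at a
  steep compositional transition) that is part of the estimand's
  definition, not an estimation error. Truth expectations are evaluated
  by dense numerical integration over the exact log-normal `C_L` law and
  the exact truncated-Gaussian `C_N` mass function — independent of the
  pipeline's histogramming and weighting machinery.

The `"U1553-like"` preset uses the published morphogroup registry (α, β,
`Ks`, `C_O`, simulated-`C_N` settings) as its truth; the unpublished
`C_L` medians and placolith `C_N` means were calibrated once so that each
morphogroup's expected cell size *and* expected cellular PIC match the
published morphogroup means (both are printed; the raw distributions are
only in the archived datasets). The resulting synthetic record spans
community PIC:POC ≈ 1.4–1.9 rising through time and mean community size
≈ 9.5–11.3 μm — the same regime as the published record.

What passing tests show: the pipeline is a consistent estimator of the
generator's community quantities (record-mean community PIC:POC recovered
within 5%, mean community size within half a size bin, errors shrinking
toward zero as sample sizes grow), and every deterministic contract
(weight conservation, enumeration equivalence, scenario arithmetic)
holds exactly. What they do not show: fidelity to real fossil data —
the generator has no preservation/dissolution bias, no taxonomic
misidentification, no joint `C_L`–`C_N` covariance, no non-lognormal
size structure, and its compositional trends are smooth by construction.

## Numerical choices

* Bin membership is half-open `[lower, upper)`; bin centres are
  `(floor(x/w)+0.5)·w`, rounded to 9 decimals to stabilise float keys on
  the lattice.
* Weight accumulation iterates grid nodes in row-major order so that
  accumulated sums are bit-identical to a naive per-node enumeration
  (exploited by the oracle-equivalence tests).
* Binned percentiles: first bin whose cumulative weight reaches the
  target (with a 1e-12 tolerance); reported as bin centres.
* `mean_ratio` is the weight-average of per-combination PIC:POC, *not*
  `mean_pic/mean_poc`; the two differ on skewed distributions and both
  are exposed.
* Moving-average smoothing truncates its window symmetrically at the
  series ends (a point k rows from an end averages 2k+1 rows), then
  renormalizes each sample's proportions to 1; every renormalization is
  logged.
* Degenerate inputs fail loudly: fewer than 3 coccospheres or zero
  predictor variance abort the fit; zero-total assemblages, non-monotone
  tie points and out-of-range depths (no extrapolation) raise domain
  errors; a Wald interval at p = 0 collapses to a point, documented.
* Problem sizes in the test and acceptance runs — 375 coccospheres, 18
  samples × 50 lengths × 10 morphogroups, 300 counts per sample, 200
  replicate fits — mirror a single-site study and keep the full suite
  under a few seconds.

## Known limitations

* The spherical-cell assumption biases biovolume for elongated cells
  (notably *Sphenolithus*); no alternative geometry is provided.
* Regression-parameter uncertainty is quantified (standard errors,
  confidence intervals) but not propagated into the trait distributions.
* Percent abundances are closed compositions; confidence intervals are
  per-taxon binomial, ignoring the multinomial covariance.
* The scenario calculator does linear bookkeeping between two
  reconstructions; it models no ecology (no growth-rate or nutrient
  dynamics).
* Absolute paleo-productivity, carbonate-system feedbacks and
  preservation biases are out of scope.
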