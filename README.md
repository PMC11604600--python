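# nannotraits

Size-trait modelling of calcareous nannoplankton communities: from
coccolith morphometrics and assemblage counts to the distribution of cell
size, organic carbon (POC), inorganic carbon (PIC) and the PIC:POC
calcification ratio across a fossil plankton community.

## The problem

Calcareous nannoplankton (coccolithophores and allied groups) build a
calcite cell covering — the coccosphere — out of `C_N` individual plates
(coccoliths) of length `C_L`. Their fossil record preserves loose
coccoliths in vast numbers and, occasionally, intact coccospheres. Because
cell size controls carbon content, and coccolith geometry controls calcite
mass, a community's mix of morphotypes sets how much organic and inorganic
carbon a fixed standing stock of cells represents — a quantity (the
community PIC:POC ratio) that matters for the biological carbon pump and
marine carbonate chemistry on geological timescales.

`nannotraits` implements the full reconstruction chain for deep-time
assemblages, with a synthetic-data generator (known ground truth) standing
in for field datasets:

1. **Cell size from coccolith geometry.** For placolith-bearing
   morphogroups with intact fossil coccospheres, an OLS allometry

   `log10(C_L) = α · log10(π Θ² / C_N) + β`

   links coccolith length to cell surface area per coccolith (cell of
   diameter Θ treated as a sphere); inverting it predicts
   `Θ = sqrt(C_N · 10^((log10 C_L − β)/α) / π)` for any combination.
   Groups that disarticulate before burial (nannoliths, holococcoliths)
   instead use a coverage factor `C_O` relating summed elliptical lith
   area to cell surface area: `Θ = (C_LP/2)·sqrt(C_O · C_N / AR)`, with
   simulated Gaussian `C_N` distributions.
2. **Carbon per cell.** `POC = 0.228 · V^0.899` pg C from biovolume
   `V = (π/6)Θ³`; `PIC = C_N · d³ · Ks · 2.7 · 0.12` pg C from a
   morphogroup-specific calcite shape factor `Ks` and characteristic
   dimension `d`.
3. **Likelihood weighting.** Every `(C_L, C_N)` combination is weighted by
   the product of the observed `C_L` histogram (n ≈ 50 loose coccoliths
   per sample) and the `C_N` histogram (measured or simulated), producing
   binned per-morphogroup distributions of cell size, POC, PIC and
   PIC:POC.
4. **Community stacking.** Assemblage counts (≥ 300 coccoliths per
   sample) become relative abundances with binomial confidence intervals,
   are smoothed down-section (centred 5-point moving average), converted
   from coccolith to *cell* proportions (dividing by mean `C_N`), and used
   to stack the per-morphogroup distributions into a community size
   structure, size-class carbon partition and community PIC:POC per time
   slice, on a piecewise-linear age-depth model.

## Worked example

```python
from nannotraits import (CoccolithAllometry, gen_ground_truth_bundle,
                         reconstruct_communities, partition_size_classes)

# a complete synthetic input set with known ground truth
bundle = gen_ground_truth_bundle("U1553-like", seed=1)

# fit one morphogroup's allometry from its intact coccospheres
records = [r for r in bundle.coccospheres if r.morphogroup == "Coccolithus"]
fit = CoccolithAllometry(records).fit()
print(f"Coccolithus allometry: alpha = {fit.alpha:.3f} +/- {fit.bse['alpha']:.3f}, "
      f"beta = {fit.beta:.3f}, R^2 = {fit.rsquared:.2f}, n = {fit.nobs}")
print(f"predicted cell diameter at C_L = 8 um, C_N = 12: "
      f"{fit.predict_cell_diameter(8.0, 12):.2f} um")

# the full pipeline: counts -> smoothed cell abundances -> stacked traits
recons, _ = reconstruct_communities(
    bundle.coccospheres, bundle.lith_samples, bundle.assemblages,
    bundle.registry, bundle.age_model)
for r in (recons[-1], recons[0]):          # oldest and youngest samples
    print(f"{r.sample_id} ({r.age:.2f} Ma): mean cell size "
          f"{r.mean_community_size:.1f} um, community PIC:POC "
          f"{r.community_pic_poc:.2f}, total POC {r.total_poc:,.0f} pg C/100 cells")

cls = partition_size_classes(recons[0]).classes["8-11"]
print(f"8-11 um class holds {cls['cells_pct']:.0f}% of cells, "
      f"{cls['poc_pct']:.0f}% of POC, PIC:POC {cls['pic_poc']:.2f}")
```

prints

```
Coccolithus allometry: alpha = 0.610 +/- 0.052, beta = -0.097, R^2 = 0.72, n = 54
predicted cell diameter at C_L = 8 um, C_N = 12: 12.89 um
S18 (34.64 Ma): mean cell size 11.2 um, community PIC:POC 1.47, total POC 10,864 pg C/100 cells
S01 (26.53 Ma): mean cell size 10.1 um, community PIC:POC 1.79, total POC 8,309 pg C/100 cells
8-11 um class holds 40% of cells, 26% of POC, PIC:POC 2.14
```

The fitted slope/intercept recover the generating allometry within their
standard errors; across the record the community shifts toward smaller,
more heavily calcified cells, raising community PIC:POC from ~1.5 to ~1.8
while total biomass per 100 cells falls — the intermediate size classes
carry less of the carbon than their share of cells would suggest.

A command-line interface mirrors the library
(`nannotraits simulate | validate | fit-allometry | cell-carbon | traits |
assemblage | reconstruct | scenario`); see `nannotraits --help`.

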