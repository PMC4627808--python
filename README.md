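# rootpatch

Tools for analysing the **small-scale spatial distribution of insect root
herbivores** (wireworms and other soil-dwelling larvae) along grassland
transects, and for asking what determines it: the functional composition of
the plant community, soil water, or land-use intensity.

The package reimplements a complete field-study analysis chain as a tested,
reusable library with a synthetic-data generator in place of field records,
so that every stage can be verified against known ground truth:

1. **Community metrics** — Shannon diversity `H' = −Σ pᵢ ln pᵢ`, Pielou
   evenness `J' = H'/ln S`, leaf traits (SLA = area/dry mass,
   LDMC = dry/fresh mass, leaf density), community-weighted mean traits
   `CWM = Σ cᵢ · traitᵢ` with an 80 % trait-coverage omission rule, the
   land-use intensity index `LUI = F/F_R + M/M_R + G/G_R`, and gravimetric
   soil water content / water-holding capacity.
2. **Spatial statistics** — Bray-Curtis / Euclidean distance matrices,
   Sturges-rule distance classes (a 30-plot transect at 0.3 m spacing gives
   exactly 10 classes, 0–0.72 m … 7.44–8.28 m), Mantel correlograms with a
   permutation null and progressive Holm correction, pattern classification
   (*patchy* / *autocorrelated* / *none*), and global Moran's I with
   inverse-distance weights.
3. **Mixed models** — zero-inflation mitigation by summing counts over
   blocks of three adjacent cores; per-predictor Poisson GLMMs
   `log μ = region + β₁·z(x) + u_site`, `u_site ~ N(0, σ²)`, fitted by a
   Laplace-approximated marginal likelihood (adaptive Gauss–Hermite as a
   cross-check); Nakagawa–Schielzeth conditional R²; parametric-bootstrap
   likelihood-ratio p-values; predictor ranking by |slope|; Gaussian LMMs of
   Mantel coefficients vs LUI/WHC/distance with backward selection; and
   site-level OLS against land-use intensity.
4. **Synthetic transects** — 28 sites in 3 regions, 30 plots per 9 m
   transect, a ~190-species pool with 10 functional traits, patchy species
   composition built from Gaussian patch kernels, and zero-inflated Poisson
   counts whose log-mean follows a community-weighted mean trait with a site
   random intercept.

## Worked example

```python
import rootpatch as rp

cfg = rp.RunConfig(sim=rp.SimConfig(seed=42), out_dir="results",
                   n_perm=199, n_boot=99, seed=7)
bundle = rp.run_full(cfg)

fam, share = bundle["family"]
print(fam, round(share, 1))
print(bundle["patterns"]["species_composition"].value_counts())
print(bundle["ranking_total"].head(3)[["predictor", "slope", "chi2", "r2"]])
```

prints (seed 42):

```
Elateridae 43.3
species_composition
patchy    28
Name: count, dtype: int64
               predictor     slope       chi2        r2
0                cwm_sla  0.325378  27.490678  0.402952
1                     wc -0.257037   5.588804  0.403031
2  cwm_vegetative_spread -0.086058   2.105193  0.410884
```

Elaterid (click-beetle) larvae are the dominant family (43.3 % of the 619
simulated individuals); plant species composition is classified *patchy*
at all 28 sites (significant positive Mantel coefficients in the shortest
distance classes that decay to negative at long range); and the
community-weighted mean specific leaf area — the trait the counts were
coupled to — tops the predictor ranking with a standardized slope of 0.33,
i.e. a block on plots one standard deviation richer in high-SLA plants is
expected to hold e^0.33 ≈ 1.4 times as many root herbivores.

The same chain runs from the command line on generated or user-supplied
delimited-text tables:

```bash
rootpatch simulate --seed 42 --out fixtures/
rootpatch full --input-dir fixtures/ --out-dir results/
```

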