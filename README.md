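# rnahsi — road-network-adjusted settlement mapping of urban populations

`rnahsi` builds fine-scale (100 m) gridded population maps for cities by
combining three things a census cannot provide on its own: nighttime-light
(NTL) radiance, a vegetation-index composite, and the density of the
classified road network. It is aimed at spatial demographers and
epidemiologists who need a population denominator layer at sub-district
resolution, where coarse global products and zone-level census counts are
both too blunt.

## The model

Raw NTL digital numbers are first calibrated to radiance,

    L = 10⁻¹⁰ · DN^(3/2)        [W/(m²·sr·µm)]

and min–max normalized over the study area to `LJ_nor`. The annual maximum
composite of the per-period vegetation layers gives `EVI_max`. The human
settlement index combines the two so that bright, unvegetated (built-up)
cells score high:

    HSI = (1 − EVI_max + LJ_nor) / ((1 − LJ_nor) + EVI_max + LJ_nor·EVI_max)

HSI alone systematically underestimates population where human activity is
invisible to the sensor — underground malls, transit, heavily shadowed
high-rise cores — which are exactly the places with dense road networks.
The package therefore builds a road-network density (RND) surface: each of
six road classes (expressway, trunk, secondary trunk, branch, railway,
other) is rasterized by quartic-kernel line density

    K(u) = (3/π)(1 − u²)²/h²,   u = d/h < 1

with the bandwidth *h* selected by sweeping 100–5000 m against the
correlation between per-zone density sums and census counts (3000 m is the
stable default), and the class layers are combined with PCA-derived
weights. Zone-mean population density and zone-mean RND follow a power law,
fitted in log space:

    density = a · RND^b

and the road-adjusted index is

    RNAHSI = HSI · RND^b .

Zonal RNAHSI sums are calibrated linearly against census counts, the
overall bias is removed with a correction factor (actual total / estimated
total), and population is disaggregated to the grid (regression mode by
default; proportional and per-zone proportional modes guarantee exact
finer-grained mass conservation). Accuracy is scored per zone with

    MRE   = (100/n) Σ |PE_i − P_i| / P_i
    %RMSE = 100 · √(Σ(PE_i − P_i)²/n) / mean(P)

plus R² between zonal estimates and census.

Because the original satellite, road and census datasets are not
redistributable, the package ships a seeded synthetic-city generator
(`rnahsi.synthetic`) that reproduces the statistical structure the method
relies on — multi-centre density, roads tracking density with a power-law
link, NTL blooming and underground-activity deficit, saturating
anti-correlated vegetation — so every stage is testable end to end.

## Worked example

Generate a synthetic city and run the full pipeline:

```
$ rnahsi make-fixtures scene --seed 7 --rows 120 --cols 120 --zones 49
scene written to scene: 720 roads, 49 zones, total population 2000000

$ rnahsi run config.yaml       # config listing the scene files, bandwidth 2000 m
INFO rnahsi.pipeline: power fit: a=2.311e+07 b=1.2094 R2=0.991 (49 zones, 0 dropped)
INFO rnahsi.popmap: correction factor (actual/estimated): 1.3060
outputs written to out
MRE 20.57%  %RMSE 18.93%  R² 0.989  (49 zones)
```

The power-law exponent `b = 1.2094` is the fitted elasticity of population
density with respect to road density (the generator's true value is
1.2322); the correction factor 1.306 says the uncorrected regression map
underestimated the city total by ~23% before rescaling; the final line is
the zone-level accuracy of the finished 100 m population map. `out/`
contains the HSI, RND, RNAHSI, population and density GeoTIFFs, the
bandwidth-sweep table, PCA weights, fit diagnostics and the per-zone
residual table.

Any external gridded population product can be scored against the same
census with:

```
$ rnahsi assess out/population.tif scene/zones.geojson --census scene/census.csv
{
  "mre_pct": 20.566503511342052,
  "n_zones": 49,
  "pct_rmse": 18.92959396694375,
  "r_squared": 0.9887175280245257,
  ...
}
```

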