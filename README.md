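# habiquant

Habitat-quality modelling for raster landscapes: distance-decay threat
kernels, land-use transition accounting, spatial hotspot statistics, and a
latent-variable path model of natural and anthropogenic drivers.

`habiquant` is aimed at landscape ecologists who score habitat condition
from categorical land-use maps — the workflow used to monitor ecologically
fragile regions such as the Songnen Plain of Northeast China, where an
eastern forest belt, a central cropland/urban core and a western
grassland/saline mosaic produce strongly heterogeneous habitat patterns.
The package ships a synthetic-landscape generator with that spatial
template, so every stage runs and is testable without any external rasters.

## The model

**Habitat quality.** Each land-use class *j* has an intrinsic habitat
suitability $H_j \in [0,1]$ and a sensitivity $S_{jr} \in [0,1]$ to each
threat factor *r* (urban land, arable land, rural settlements, industrial
and mining land, saline-alkali land, bare ground). A threat radiates from
its source cells with a distance-decay kernel truncated at a maximum reach
$d_{r\max}$:

$$i_r(d) = 1 - d/d_{r\max} \quad\text{(linear)},\qquad
  i_r(d) = \exp(-2.99\, d/d_{r\max}) \quad\text{(exponential)}.$$

Degradation at cell *x* accumulates the decayed pressure of every source
cell of every threat, weighted by the normalised threat weight
$\omega_r/\sum\omega$, accessibility $\beta_x$ and the sensitivity of the
cell's own class:

$$D_x = \sum_r \sum_{y \in Y_r} \frac{\omega_r}{\sum_r \omega_r}\,
        i_r(d_{xy})\, \beta_x\, S_{jr},$$

and quality discounts suitability through a saturating penalty with
half-saturation constant *k* and exponent *z*:

$$Q_x = H_j \left(1 - \frac{D_x^z}{D_x^z + k^z}\right).$$

Quality surfaces are classified into five grades
([0,0.2), [0.2,0.4), [0.4,0.6), [0.6,0.8), [0.8,1]) and, between dates,
into improved/unchanged/degraded change maps.

**Change accounting.** Transition matrices $T_{ij}$ cross-tabulate the
area moving from class *i* to class *j* between two dates, with row and
column sums conserving per-date class areas.

**Spatial statistics.** Global Moran's *I* (with expectation $-1/(n-1)$
and the randomization-assumption z-score) measures clustering of the
quality surface; per-cell Getis-Ord $G_i^*$ z-scores classify hotspots and
coldspots at the 90/95/99% confidence tiers.

**Driver analysis.** A covariance-based structural equation model links
latent Topography (elevation, slope), Climate (precipitation, temperature)
and Human Disturbance (nighttime light, population density) to NDVI and
habitat quality: measurement model $Y = \Lambda_y \eta + \epsilon$,
structural model $\eta = B\eta + \Gamma\xi + \zeta$, estimated by maximum
likelihood with fit indices CFI, GFI, RMSEA and SRMR. Because the
structural graph is acyclic, each driver's effect decomposes exactly into
a direct coefficient plus products of standardized coefficients along
directed paths (indirect effects); their sum is the total effect.

## Worked example

```python
import habiquant as hqp

legend, threats = hqp.default_parameter_tables()
params = hqp.LandscapeParams(nrows=120, ncols=120, seed=1)
lu = hqp.generate_landscape_series(params, 1)[0]

d = hqp.degradation(lu, threats, legend)
q = hqp.quality(lu, d, legend)
print(round(q.valid_values().mean(), 3))     # 0.246

res = hqp.morans_i(q)
print(round(res.I, 3), round(res.z, 1))      # 0.877 208.8

_, grades = hqp.classify_quality(q)
print(grades.percents.round(2).to_dict())
# {'lowest': 67.23, 'lower': 3.01, 'medium': 9.41, 'higher': 11.78, 'highest': 8.56}
```

The mean quality of 0.246 reflects a cropland-dominated landscape (dry
farmland has suitability 0.40 and is itself an arable-land threat source);
Moran's *I* of 0.877 says quality is strongly spatially clustered, as the
zoned east-forest/central-cropland layout implies; two thirds of the area
falls in the lowest grade because urban, saline and heavily degraded
cropland cells score below 0.2.

The same pipeline runs from the shell:

```
habiquant run --config run.yml        # full analysis from one seeded config
habiquant simulate / transitions / hq / hotspots / sem   # individual stages
```

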