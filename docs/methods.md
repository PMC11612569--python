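# Methods

This note documents the models, the numerical choices, and what the
synthetic data do and do not establish.

## Habitat-quality model

Quality is scored per cell as $Q_x = H_j (1 - D_x^z/(D_x^z + k^z))$, with
degradation $D_x$ the sum over threats and their source cells of the
normalised threat weight times a distance-decay kernel times accessibility
times the cell class's sensitivity. Conventions and parameter choices:

- **Units.** Cell size and threat distances are kilometres throughout;
  distances are centre-to-centre Euclidean.
- **z and k.** Defaults `z = 2.5`, `k = 0.5`, the customary defaults for
  this model family; both are exposed on `HQConfig`. `k` is on the scale
  of `D`, so if a landscape's degradation range differs strongly from
  O(1), setting `k` to half the observed maximum degradation is a
  reasonable alternative; the package computes with whatever is supplied.
- **Decay kernels.** Linear `1 − d/d_rmax` and exponential
  `exp(−2.99·d/d_rmax)`, both truncated to zero strictly beyond
  `d_rmax`, both 1 at distance zero. The exponential rate is written so
  that the kernel decays to `exp(−2.99) ≈ 0.05` at the maximum distance,
  the dimensionally consistent exponential analogue of the linear form.
- **Degradation is an unnormalised sum over source cells** (no division
  by the number of sources): a cell surrounded by more sources is more
  degraded, and `k` absorbs overall scale.
- **Self-exposure.** A source cell whose own class has nonzero
  sensitivity to its threat receives that threat at distance 0 (i = 1);
  nothing in the model excludes self-threatening classes, and the
  packaged tables contain one (saline-alkali land is both a habitat with
  H = 0.5 and a threat source).
- **Accessibility β** defaults to 1 everywhere (scalar) and may be a
  raster; no accessibility data are bundled.
- **Implementation.** Per threat, the sum over source cells is a direct
  (non-FFT) 2-D convolution of the binary source map with the kernel
  sampled on the cell-offset lattice. This is algebraically identical to
  the quadruple loop over (cell, source, threat); tests assert agreement
  to 1e-12.
- **Grades.** Five bins, left-closed/right-open, with 1.0 included in
  "highest". The open-interval notation sometimes used for these bands
  leaves boundaries ambiguous; left-closed binning is total and
  deterministic, and bin edges are compared with `numpy.digitize` so the
  floating-point representations of 0.2/0.4/0.6/0.8 classify exactly.
- **Change maps.** "Unchanged" means |ΔQ| ≤ eps with `eps = 0.01` by
  default — one quality unit at the usual two-decimal reporting
  precision.
- **Threat source classes.** The packaged threat table maps threat names
  to legend codes as: arable → paddy fields + dry farmland; urban → urban
  area; rural settlements → rural settlements; industrial/mining → other
  construction land; saline-alkali → saline-alkali land; bare ground →
  bare land + bare rock texture. The mapping is the package's own
  reading of the class legend and is editable via the threats CSV.

## Transition accounting

Cells nodata at either date are excluded from the matrix entirely rather
than assigned a pseudo-class, so row sums equal first-date class areas and
column sums second-date areas exactly. Conversion rates are row-normalised
percentages of the matrix.

## Spatial statistics

- **Weights.** Queen contiguity by default (rook available),
  row-standardized for Moran's I, binary with self included for Gi*.
  These are the most common defaults in desktop GIS tools and are stated
  explicitly so results are reproducible; no distance-band scheme is
  implemented. Nodata cells are removed from the weights graph entirely.
- **Moran's I** uses the closed-form expectation −1/(n−1) and the
  randomization-assumption variance for its z-score.
- **Gi\*** classifies by fixed normal quantiles ±1.645/±1.960/±2.576
  (90/95/99%), with no multiple-testing correction — matching the
  three-tier confidence semantics of standard hotspot maps. Exactly at a
  threshold a cell stays in the lower tier.

## Driver path model

- **Form.** All-y LISREL: every structural node is a construct; real
  indicators get free loadings (first fixed to 1 for identification) and
  free measurement-error variances; directly observed structural nodes
  (NDVI, HQ) are their own constructs with loading 1 and zero error.
- **Estimation.** Maximum-likelihood discrepancy
  `F = log|Σ(θ)| + tr(SΣ⁻¹) − log|S| − p`, minimised by L-BFGS-B with
  finite-difference gradients, `ftol = 1e-8`, variance parameters bounded
  below at 1e-6, and up to 5 seeded jittered restarts. Non-convergence
  raises with the best-so-far discrepancy.
- **Standardization.** Standardized coefficients are derived after
  fitting from the model-implied construct and indicator variances.
- **Fit indices.** χ² = (n−1)F; CFI against the independence baseline
  Σ = diag(S); GFI = 1 − tr[(Σ⁻¹S − I)²]/tr[(Σ⁻¹S)²];
  RMSEA = √(max(χ²−df,0)/(df(n−1))); SRMR as the root mean square
  correlation-scale residual over the lower triangle including the
  diagonal.
- **Normalisation.** Variables are passed through a rank-based
  inverse-normal transform (Blom offsets) and z-standardized before the
  covariance is formed. A rank-normal transform is used rather than a
  parametric Johnson-family fit: it serves the same purpose (meeting the
  normality assumption), is fully deterministic, and needs no family
  selection.
- **Effect decomposition.** Direct = coefficient on the driver→response
  edge; each indirect contribution = product of standardized coefficients
  along one simple directed path of length ≥ 2, enumerated exhaustively
  (the graph is acyclic); total = direct + sum of indirect. An
  independent reduced-form route, (I−B)⁻¹ − I, is used as a cross-check
  in tests.
- **Per-year coefficient tables.** `data/path_coefficients.csv` stores
  one standardized edge set per study year (2000/2010/2018/2020) for the
  driver models. Where a mediator's edge to HQ is known the table uses
  it directly; upstream edges of two-edge indirect channels are stored as
  the channel product divided by that mediator coefficient, so path
  enumeration over the table reconstructs the per-channel indirect
  contributions and totals. These tables parameterise reporting and
  examples; they are not estimated from data at run time.
- **Sampling.** The pipeline fits the SEM to a seeded uniform random
  sample of valid cells (default 10,000) rather than all cells, keeping
  n explicit in the fit indices.

## Synthetic data

- **Landscape.** A neutral-landscape construction: one smoothed Gaussian
  noise field per realisation, thresholded at per-zone class quantiles.
  Three longitudinal zones (west 30%, centre 40%, east 30% of columns by
  default) receive class mixes computed by iterative proportional
  fitting from the global class budgets and fixed zone affinities
  (forest east, cropland/urban centre, grassland/saline west), so the
  realised class shares match the requested budgets to within rounding.
  Default budgets (cropland 0.59, forest 0.12, grassland 0.08, water
  0.05, urban 0.045, saline 0.045, swamp 0.06) follow the approximate
  year-2000 composition of the kind of agriculturally dominated plain
  the generator emulates.
- **Dynamics.** Cell-independent Bernoulli conversions per step, default
  rates emulating cropland expansion (grassland→cropland 0.06,
  swamp→cropland 0.04, forest→cropland 0.015, cropland→urban 0.01) —
  the simplest mechanism that yields testable transition matrices.
- **Covariates.** Smooth latent fields — topography rising eastwards,
  climate and human disturbance driven by topography with the truth's
  structural coefficients, NDVI driven by all three plus a land-class
  greenness boost — observed through noisy indicator rasters with the
  truth's loadings.
- **What this does not show.** The generator has no realistic
  geomorphology, climate gradients beyond a linear trend, autocorrelated
  measurement error, or calibrated regional class budgets. Passing tests
  demonstrate the correctness of the algorithms and the recoverability of
  known signals under the stated generating process — not the empirical
  values any real landscape would produce.

## Problem sizes

Tests and the acceptance script use landscapes between 9×9 and 120×120
cells, brute-force oracles up to 25×30, and SEM samples of n = 5000
(50,000 for the law-of-large-numbers check). These sizes give stable
statistics while keeping the full suite to a few seconds.

## Known limitations

- Rasters must share one grid; no reprojection or resampling.
- Only rook/queen contiguity weights; no distance-band neighbourhoods.
- The SEM is covariance-only: no mean structure, categorical indicators,
  or bootstrap standard errors.
- Nodata handling assumes a sentinel value that never collides with a
  valid class code or measurement.
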