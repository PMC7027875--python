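# Methods

This note records the models, the defaults and the numerical choices
behind `traitscape`, and what the synthetic experiments do and do not
demonstrate about real airborne campaigns.

## The trait–landscape model

Every foliar trait (N %, P %, N:P, SLA mm²/mg) is treated as a linear
function of disturbance history (logged vs. old-growth), elevation and
top-of-canopy height (TCH) with all two- and three-way interactions —
eight terms.  Elevation and TCH enter standardized against a reference
stand of 30 m tall forest at 200 m a.s.l.:

    z_e = (elevation − 200 m) / 155 m
    z_t = (TCH − 30 m) / 7.3 m

so the intercept is the expected trait of the reference stand and the
continuous coefficients are per standard deviation of the predictor.
The bundled default coefficient table (`REFERENCE_COEFFICIENTS`) holds
bootstrapped SAR estimates published for a logged-forest landscape in
Sabah, Borneo; it serves both as the worked-example calculator's input
and as the generative truth for parameter-recovery experiments, which
makes those experiments self-describing (the recovery target is the
shipped table).  One published value is internally inconsistent — the
N:P TCH row's mean (−1.80) lies outside its own printed interval
(−0.40, 0.03), presumably a misprint — we carry the printed mean
verbatim; no conclusion in this package depends on it.

Model error is simultaneous-autoregressive (SAR, error form):
u = λWu + ε with ε i.i.d. normal.  The *generator* uses the
row-standardized first-order (rook) grid neighbourhood for W; the
*estimator* uses a 2 km distance-band neighbourhood, mirroring the
field workflow where the band is chosen from residual semivariograms
rather than known a priori.  This deliberate mismatch is why fitted λ
values on synthetic data are not comparable to the generative λ — the
regression coefficients, which are what the bootstrap summarizes, remain
unbiased under any fixed weighting because the spatially filtered
estimator is linear in y.

## Synthetic campaign: what it emulates

* **Landscape** — elevation and TCH are Gaussian-kernel-smoothed white
  noise (defaults: σ = 5 and 3 cells), elevation scaled to 100–1,000 m
  a.s.l., TCH mean 27 m, SD 9 m.  Disturbance thresholds a third smooth
  field (σ = 6 cells) at the 50% quantile, giving contiguous logged
  blocks like a reserve/coupe mosaic; logged stands lose 8 m of canopy
  height on average, so TCH and disturbance are correlated, as in
  logged landscapes.  Cells are 100 m (1 ha).
* **Crowns** — discs of radius 4–8 m placed without overlap (an
  `overlap_fraction` forces overlaps to exercise the assignment rule).
  Each tree's trait is the local surface value plus a normal tree-level
  deviation (defaults: 0.15 N %, 0.012 P %, 1.0 N:P, 0.8 SLA — chosen
  to mimic the large within-plot trait variation seen in field data);
  the deviation is recorded so tests can verify the sampling model.
* **Spectra** — pixel reflectance is a smooth green-vegetation baseline
  (chlorophyll trough, red edge, NIR plateau, water-dominated SWIR)
  times a log-normal brightness factor (SD 0.10), minus one Gaussian
  absorption feature per trait (depth linear in the trait; defaults at
  1510/1680/2210/1240 nm for N/P/N:P/SLA, all inside the retained trim
  windows), plus a shared within-crown offset (SD 0.015) and i.i.d.
  pixel noise (SD 0.010), clipped to [0, 1].  Non-vegetated pixels
  (TCH < 4 m, or outside crowns when no landscape is supplied) get a
  bright, spectrally flat soil curve whose NDVI sits well below the
  0.75 vegetation threshold.  The 12 nm dialect is the 6 nm grid
  decimated to every second band.  The sensor grid defaults to
  380–2,500 nm at 6 nm so that band averaging and dialect resampling
  have sensor margin outside the retained trim windows, as a real
  instrument does.
* **Noise magnitudes** are not field-calibrated: no within-plot spectral
  noise decomposition was available to copy.  The defaults are set so
  that the clustered structure (shared crown offsets ≫ pixel noise)
  makes the LOPO/LOTO divergence visible, which is the behaviour the
  cross-validation design exists to expose.

What passing tests therefore show: the estimators recover the truth
under the model's own assumptions, the preprocessing is arithmetically
correct, and the cross-validation machinery has the expected
leakage/holdout behaviour.  What they do not show: robustness to
atmospheric/BRDF residuals, crown misregistration, non-linear
trait–spectrum links, or sensor noise structure — all absent from the
generator.

## Preprocessing conventions

* Band averaging groups 3 adjacent bands below 1,100 nm and 2 at or
  above; trailing incomplete groups are averaged as-is rather than
  dropped (conserves coverage); a region smaller than one group passes
  through with a warning.
* Trimming keeps the closed interval [420, 2400] nm and removes three
  *open* windows (900–1000, 1350–1480, 1780–2032 nm): boundary bands are
  retained.  A convention had to be fixed; it is tested.
* Dialect resampling is piecewise-linear and refuses extrapolation.  In
  the pipeline the coarse dialect is resampled onto the fine flight's
  averaged-then-trimmed grid, because the averaged coarse grid's
  endpoints sit inside the averaged fine grid's — only bands the trim
  step discards anyway would ever need extrapolating.
* Brightness normalization divides each spectrum by its Euclidean norm.
  NDVI (defaults: red 650 nm, NIR 860 nm, nearest retained band) is
  scale-invariant, so its position relative to normalization is
  immaterial.
* Pixel filtering runs height → NDVI → zenith → crown coverage, in that
  order, with per-stage exclusion counts; the counts always sum to
  input − retained.  The solar-zenith rule defaults to *excluding*
  scenes beyond 50° (the physically plausible reading); the literal
  inclusion reading is available via `zenith_rule="include_above"`.
  A pixel sufficiently covered by several crowns goes to the larger
  coverage, then the larger crown, then the lexicographically smallest
  tree id — deterministic output.

## PLSR choices

scikit-learn's NIPALS `PLSRegression` (no column scaling) is the fitter;
per-component regression vectors are sliced from the rotation/loading
matrices so one fit per fold serves the whole component curve.  N, P and
SLA are fitted on log responses and back-transformed by exponentiation;
N:P on the identity scale.  Repeat spectra of a tree from different
flights enter as separate rows, never pre-averaged.  The CV error curve
is RMSE on the original trait scale; the one-SE rule takes the smallest
component count within one standard error (across folds, at the best
count) of the minimum, and can select zero components — a mean-only
model, for which R²/%RMSE are suppressed as meaningless.  Mosaicking is
an unweighted cellwise mean across flight lines; cells with no
vegetation pixels are missing, never zero.  `predict_map` refuses cubes
whose wavelength grid or recorded processing history differ from the
model's training table (SHA-256 of the step list).

## SAR fitting and the bootstrap

The SAR error model is fitted by maximum likelihood: for candidate λ the
regression is spatially filtered ((I − λW)y on (I − λW)X), and the
profile log-likelihood log|I − λW| − (n/2)·log(SSR/n) is maximized by
bounded scalar search (tolerance 1e−6).  The log-determinant uses the
eigenvalues of the symmetrized weights D^(−1/2)BD^(−1/2), which share
the row-standardized matrix's spectrum; isolates contribute zeros.  With
λ fixed at 0 the estimator is exactly OLS (tested against statsmodels).

The bootstrap draws cell samples *without* replacement (subsampling;
with-replacement available), rebuilds the neighbourhood among sampled
cells, refits, and reports per-term means, 2.5/97.5 percentile
intervals and zero-exclusion significance.  Samples are drawn from
cells in a canonical coordinate order, so results depend only on the
seed, not on array layout.  Failed replicate fits are redrawn and
counted.

Two properties of subsample-percentile intervals matter for
interpretation and shaped the experiments:

* their width reflects the estimator's dispersion at the *sample* size,
  so when the sample is a large fraction of the raster the interval
  understates landscape-level uncertainty — coverage experiments
  therefore keep the sampling fraction small (320 of 1,600 cells),
  as in the field workflow (1,000 of tens of thousands);
* a single landscape realization of a strongly autocorrelated error
  field carries substantial realization error on the logged/old-growth
  contrast (few contiguous blocks → small effective n), so the
  acceptance recovery experiment averages bootstrap means over five
  independent landscape realizations rather than trusting one draw.

## Semivariograms

Classical (Matheron) estimator on OLS residuals, four directions
(0/45/90/135°, ±22.5° tolerance), ten lag bins to a 4 km maximum.  The
practical range per direction comes from an exponential-model fit
γ(h) = c₀ + c₁(1 − e^(−3h/r)) (`curve_fit`, non-negative bounds); when
the fit fails the range is NaN rather than a guess.  The pipeline's
neighbourhood band stays fixed at 2 km by default rather than being
re-estimated per run.

## Worked-example calculator

`predict_at` evaluates the plain linear predictor — no bootstrap-draw
averaging — and rounds only at reporting (2 decimals for N, 3 for P, 1
for N:P and SLA).  The published narrative values it reproduces exactly
are the tall-logged N (1.82%) and P (0.115%), short-logged N (2.07%)
and SLA (10.5 mm²/mg), and the 35% logging-associated P reduction.  A
few other published narrative numbers (old-growth N:P at 200 m quoted as
14.8 vs. the table's 15.1 reference; a logged N:P increase of 2.26 vs.
the 2.14 coefficient; 1.76% N at 800 m vs. 1.91 by linear arithmetic)
differ from the plain predictor, consistent with those figures having
been averaged over bootstrap draws in an unstated way; the calculator
documents rather than imitates this.

## Problem sizes and determinism

Desk-scale defaults: pipeline demo landscapes of 40×40 (default config)
to 60×60 cells (examples), 4 m calibration pixels restricted to crown
neighbourhoods, 10–20 m mapping pixels, bootstrap 50×400; the test
suite uses 16×16 to 50×50 landscapes, and the coverage experiment runs
200 landscapes at 40×40 with 40 refits of 320 cells.  Every random
stage takes an explicit seed (`numpy.random.default_rng`); the pipeline
manifest hashes all artefacts, and reruns at fixed configuration are
byte-identical.

## Known limitations

* No radiative-transfer realism (PROSPECT/SAIL-class optics), no
  topographic illumination, no atmospheric or BRDF residuals, no
  georeferencing error: the generator's trait–spectrum link is linear
  by construction.
* The SAR fitter supports the error specification only (no spatial-lag
  model), dense eigendecomposition limits single fits to a few thousand
  cells — comfortable for the bootstrap's subsamples, and adequate for
  full-raster fits to ~50×50 landscapes.
* Planar metric geometry throughout; no geodesy.
* The co-limitation band treats [14, 16] as closed; the boundary
  convention is a choice, tested as such.
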