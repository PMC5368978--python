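# Methods

This note records the models implemented in `redoxflim`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data generator does and does not emulate.

## Decay model and incomplete-decay treatment

A TCSPC histogram collects photon arrival times modulo the laser period
T = 1000/rep_rate ns (12.5 ns at the default 80 MHz).  The underlying decay
is bi-exponential, F(t) = A(α₁e^(−t/τ₁) + α₂e^(−t/τ₂)) + C with α₁+α₂ = 1.
When a lifetime is comparable to or longer than T, emission from previous
pulses overlaps the current period; in steady state the summed tails form a
geometric series, giving each exponential the closed-form wrap factor
1/(1 − e^(−T/τ)).  This is the unique steady state of periodic excitation,
and it is exact — the package's tests verify it against a brute-force
10⁴-pulse summation to 1e−10 relative error and against numerical
quadrature of the per-bin integrals.  A useful identity the tests also
exercise: the integral of the wrapped decay over one period equals the full
single-pulse integral A(α₁τ₁ + α₂τ₂), because the wrap factor cancels
against truncation of the integration window.

The instrument response is treated as ideal (δ-like): the exciting pulses
are ~85 fs, five orders of magnitude below the default bin width
(12.5 ns / 256 ≈ 49 ps), so IRF convolution would be far below shot noise
at any realistic photon budget.

## Fitting

Bin counts are Poisson, so the fitter minimizes the Poisson deviance
Σᵢ (μᵢ − nᵢ log μᵢ) where μᵢ is the per-bin integral of the wrapped decay.
Parameters are optimized as (log A, α₂, log τ₁, log τ₂ [, C]) with L-BFGS-B
under bounds (τ₁ ∈ [0.05, 12.5] ns, τ₂ ∈ [0.05, 2000] ns, α₂ ∈ [0, 1],
C ≥ 0), initialized from log-linear slope fits of the early and late bins,
with deterministic multi-start perturbations; a damped Newton polish on the
analytic gradient (finite-difference Hessian) sharpens the optimum to
~1e−9 relative error on noiseless input and doubles as a convergence
certificate (a negligible projected Newton step) that is robust to
line-search breakdown at float precision.  Lifetimes are reported ordered
(τ₁ ≤ τ₂) with amplitudes swapped accordingly.  `stderr_tau2` is the
observed-information (inverse-Hessian) standard error mapped from log τ₂.

**Offset convention.**  C is a free parameter by default, but for slow
lifetimes the wrapped decay is nearly flat across the window and trades off
against a constant, so quantitative τ₂ recovery fixes C (the package's
simulations use `fix_offset=0`; real acquisitions would fix it to a
measured dark level).  This mirrors standard TCSPC practice of calibrating
the baseline once per study rather than refitting it per pixel.

**Identifiability.**  With T = 12.5 ns, τ₂ ≳ T is intrinsically
ill-determined: the only signal is the residual slope of the quasi-flat
wrapped tail.  Three consequences are built in and tested:

1. `stderr_tau2` grows monotonically with τ₂ at fixed photons — the fit
   honestly reports when it no longer constrains the lifetime.
2. When the fast component itself has τ₁ ≈ 5–6 ns (unreacted probe), its
   wrapped tail is confusable with the slow pedestal and a free
   bi-exponential fit leaves τ₂ with very wide spread even at 10⁷ photons.
   Reliable per-cell positivity therefore needs the fast pool to complete
   within the window (the fully-reacted scenario below) or very high
   photon counts.
3. On effectively mono-exponential data a second component fits noise with
   arbitrary τ₂ at negligible α₂.  `fit_histogram_auto`, used by the map
   fitter and the per-cell ROI path, fits both 1- and 2-component models
   and keeps the lower-AIC one, additionally requiring the minor amplitude
   fraction to exceed 0.05 for the bi-exponential to be accepted.  An
   unreacted cell is thus reported at its short mono lifetime instead of a
   spurious slow component.

Per-histogram fits below `min_photons` (default 100) are masked, not
fitted.  Optional square spatial binning (radius b pools (2b+1)² pixels)
trades resolution for photons, as TCSPC analysis software does.

## Synthetic scenes

The generator plants round cells (discs, 32–46 px diameter by default,
non-touching, away from the border) on a dim autofluorescent background and
renders a Poisson photon-count cube: each pixel's expected photons
(per-cell intensity inside cells, `background_level` outside) are
distributed over time bins by the periodic-decay profile of the pixel's
true parameters.  Three templates encode the experimental arms: *control*
(one bright GSH population, low ROS), *injury* (two GSH subpopulations,
both dimmer than control, elevated ROS), *treated* (a single recovered GSH
population, reduced ROS).  Each template parameterizes both a GSH and an
ROS channel so parallel scenes for the OSI come from one template; a stated
fraction of cells is probe-negative in every template.

Key defaults, with rationale:

- **Probe lifetimes** (packaged table): unreacted/reacted 6/225 ns (P-GSH),
  5.5/146 ns (P-HP), 4.3/90.5 ns (P-HA); autofluorescence 2.5 ns (midpoint
  of the 2–3 ns tissue range), 15% of cell photons.
- **Dose response**: reacted fraction is linear in analyte concentration up
  to the probe's linear limit and reaches 1 at its saturation
  concentration (one continuous ramp; the shape between limit and
  saturation is not otherwise constrained).
- **Reacted fraction of positive cells: 1.0.**  Intracellular GSH is
  millimolar and injury-level ROS tens of micromolar — orders of magnitude
  above the probes' 20–100 μM saturation — so probe molecules in a
  probe-positive cell are fully converted.  This also determines the decay
  mixture's fast pool (2.5 ns autofluorescence only), which completes
  within the window and keeps the slow lifetime identifiable.  Partial
  reacted fractions remain available (`reacted_frac`, `mix_decay`) for
  dose-response studies.
- **Photon budget**: cell intensities of 1 200–6 000 expected photons/pixel,
  i.e. ~4×10⁶ photons per cell ROI.  At this budget the fitted slow
  lifetime of a reacted cell clears the 100 ns positivity threshold with
  wide margin even for the shortest reacted lifetime in scope (146 ns for
  P-HP), while single pixels (needing ≳3×10⁵ photons for a reliable call)
  do not — which is why the pipeline pools ROIs by default (below).
- **Image size 320×320 px, 18 cells per scene**: desk-scale runtimes with
  enough positive cells (≥10) for per-scene mixture modeling.

What the generator does **not** emulate: optical PSF blur, depth-dependent
scattering and attenuation, respiratory motion, photobleaching, spectral
bleed-through beyond the lumped fast background, and within-cell intensity
texture (cells are uniform discs).  Passing tests therefore demonstrate the
correctness of the analysis chain under the stated photophysics and noise
model, not robustness to these instrumental effects.

## Segmentation

Gaussian smoothing (σ = 2 px) → global Otsu threshold → hole filling →
connected components → keep objects with equivalent circular diameter
2√(area/π) ∈ [30, 70] px and circularity 4πA/P² ≥ 0.6; border-touching
objects are removed (their diameter is undefined) and touching cells are
not split by default (optional watershed `declump`).  The Otsu value
returned is the midpoint between the two classes' nearest observed gray
levels — same partition, but strictly between the class extremes.  For
images whose cells span a wide dynamic range above a dim background
(exactly what turn-on probes produce), thresholding the log1p-compressed
image keeps a single global cut below every cell; the pipeline uses
`transform="log"` for this reason, and the choice is recorded in the label
map's provenance block.

## Per-cell quantification and positivity

`quantify_cells` joins a label map with the intensity image and per-pixel
lifetime maps: per cell it reports mean intensity and the photon-weighted
mean τ₂ over unmasked pixels (unweighted median available), flags cells
with <50% unmasked pixels as unclassifiable, and calls a cell positive when
the aggregate slow lifetime exceeds 100 ns — the criterion that separates
reacted probes (90–225 ns) from every fast source, and the mechanism by
which intensity-bright but unreacted "false positive" cells are rejected
(tested explicitly).  The per-cell aggregation rule (mean τ₂ with a 100 ns
cut) is a package convention; the threshold and statistic are parameters.

`quantify_cells_roi` is the pooled alternative: each cell's pixels are
summed into one decay histogram and fitted once (`fit_histogram_auto`), so
`mean_tau2` is the ROI's fitted slow lifetime.  Pooling concentrates the
cell's entire photon budget into a single well-conditioned fit, which is
both statistically stronger and ~10³× faster than per-pixel mapping; it is
the pipeline default (`fit_scope="roi"`), with per-pixel maps available via
`fit_scope="pixel"`.

## Subpopulation modeling

Per-cell intensities of positive cells are modeled with Gaussian mixtures:
k = 1 uses the closed-form MLE; k = 2 uses EM (log-domain responsibilities)
with a median-split initialization plus 5 seeded random restarts, an SD
floor of 1e−3 × data range against single-point collapse, and components
reported sorted by mean.  The likelihood is computed on the raw values, not
binned counts.  AIC with p = 3k − 1 free parameters selects k; ties go to
k = 1; reported densities are renormalized to unit trapezoid area on their
grid.  A known property of this selection rule, reproduced by the package's
simulations: on single-Gaussian samples (n = 1000) a fully-converged EM
finds mild spurious two-component optima often enough that AIC overfits in
roughly 5–8% of replicates — AIC's fixed 2-per-parameter penalty is not
calibrated for the non-regular mixture family.  Users who need stricter
null behavior should apply a stronger penalty (e.g. BIC) on top of the
reported log-likelihoods; the package deliberately reports the
fully-optimized likelihoods rather than relying on early EM termination to
mask the effect.

## OSI and statistics

OSI = mean per-cell ROS intensity / mean per-cell GSH intensity, over
FLIM-confirmed positive cells by default, with ROS and GSH taken from
parallel scenes of the same experimental arm (the probes cannot be
co-injected).  If an arm has no positive cells the index is undefined and
reported as such rather than computed over all cells.  Group comparisons
are two-sided Student's t tests (equal-variance classic form; Welch by
flag), Bonferroni-adjusted by the number of pairs tested (overridable when
the reported pairs are a subset of a larger family), significant at
adjusted p < 0.05.  Type-I calibration of this procedure is verified by
simulation in the test suite.

## Pipeline and reproducibility

`run_pipeline` composes simulate → segment → fit → quantify → subpop → OSI
for one template and writes every artifact (TIFF stacks + JSON sidecars,
label maps, cell tables, mixture JSON, densities) plus the resolved config
and a manifest with SHA-256 checksums of all data artifacts.  All
randomness flows from the single config seed through
`numpy.random.SeedSequence` spawning; identical configs produce
byte-identical artifacts and manifests (tested).  Any stage failure aborts
with the stage named, retaining partial outputs.

## Known limitations

- Lifetimes beyond ~10× the laser period are detected (the positivity call
  is robust) but not precisely quantified; the inflated `stderr_tau2` is
  the honest statement of this limit.  Phosphorescence-mode acquisition
  with longer windows would be the instrumental fix.
- No IRF deconvolution, phasor analysis, or image-wide shared-lifetime
  (global) fitting.
- Segmentation does not split touching cells by default and is validated
  on disc-like objects only.
- The t tests treat cells or scenes as exchangeable replicates; the
  hierarchical (per-animal) structure of real experiments is respected
  only insofar as the caller aggregates to per-scene means first, which is
  the intended usage.
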