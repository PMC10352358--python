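# Methods

## Decay model and fitting

Per-pixel TCSPC histograms are modelled as a two-component exponential
decay, f(t) = α₁e^(−t/τ₁) + α₂e^(−t/τ₂), sampled at bin centres over one
80 MHz repetition period (12.5 ns). Incomplete decay is handled
analytically: summing the geometric series over all preceding pulses
multiplies each component by 1/(1 − e^(−T/τᵢ)). This wrap is on by
default because τ₂ of a few nanoseconds leaves several percent of the
signal in the next period; with it, the tail of the histogram settles on
a plateau that carries real information about the long component. The
model is circularly convolved with the instrument response function
(IRF) over the period, which preserves total counts.

The IRF default is a discretized Gaussian of 100 ps FWHM, a round figure
for a 70 ps excitation pulse plus hybrid-detector transit-time spread.
The true instrument IRF of any given device is neither Gaussian nor
fixed; for real data the `Irf` container accepts an arbitrary measured
curve on the histogram's bin grid.

Fitting maximizes the Poisson likelihood (minimizes the deviance) over
(τ₁, τ₂, α-fraction), with the overall amplitude profiled from the
photon total; Neyman-weighted least squares is available as an option
for comparison with conventional software. Bounds are τ₁ ∈ [10, 1500] ps
and τ₂ ∈ [300, 7000] ps, bracketing the 100–300 ps mean-lifetime regime
of the healthy fundus and typical nanosecond long components. The
optimizer (L-BFGS-B on log/logit-transformed parameters) is run from
three starting points — a data-driven estimate (log-linear tail fit for
τ₂, early-residual fit for τ₁) plus two generic fundus-regime starts —
and the best deviance is kept; a single start was observed to land in
local minima when initialized adversarially. Components are reordered to
τ₁ ≤ τ₂ after fitting. A constant-baseline term exists but is off by
default, matching the two-term model. Pixels below 100 photons (after
binning) raise a low-signal error and are masked, not zero-filled;
masked pixels never enter regional means.

Spatial binning follows SPCImage semantics: binning factor b replaces
each pixel's histogram by the sum over its (2b+1)×(2b+1) neighbourhood,
truncated at image edges so no photons are invented. The study pipeline
this mirrors used b = 1 (3×3). Whether that vendor setting means exactly
a 3×3 box sum is not documented publicly; the kernel here is the box
sum, and the factor is configurable.

A brute-force verification oracle evaluates the same Poisson deviance on
an explicit (τ₁, τ₂, α-fraction) grid and returns the global grid
minimum. It is deliberately independent of the gradient path and is used
in tests to bound the fitter's error: at the foveal photon budget
(1000 photons, ×9 after 3×3 binning) the fitter's median relative τ_m
error is ~2%, below the ≈5% resolution floor of the verification grid
itself, and noise-free histograms are recovered to better than 1%.

One empirical note: the amplitude-weighted mean τ_m is more stable than
τ₁ on replicate fits (errors in τ₁ and its amplitude are anticorrelated
and partially cancel), but the long component τ₂ is *more* stable than
τ_m in this regime — the period-wrap plateau pins it almost
independently. Claims that τ_m is the most robust parameter should be
read as relative to the short component.

## ETDRS grid

Masks are built from the foveal centre by pixel-centre radial distance:
C for r < 0.5 mm, inner ring 0.5–1.5 mm, outer ring 1.5–3 mm (diameters
1/3/6 mm), quadrants split at the two 45° diagonals. Pixels exactly on a
diagonal are assigned clockwise-first (S, T, I, N) so ties are
deterministic. No area-weighting of boundary pixels is attempted; at the
default raster (≈34 µm/pixel) the pixel count of the 6 mm disc matches
the analytic area within 1% and the C-to-grid area ratio matches (1/6)²
within 2%. For right eyes, temporal is image-left and nasal image-right;
left eyes are mirrored. The fovea centre is an input — there is no
automatic fovea detection. IR and OR aggregates pool the member pixels
of their four quadrant subfields rather than averaging subfield means,
which matters when subfield areas or valid-pixel counts differ.

## Synthetic cohort

The generator emulates the structure of a two-group observational study
of smoking and fundus fluorescence lifetimes: 26 non-smokers and 28
smokers aged 20–40. Covariates are drawn from the published group
summaries — age, BMI and IOP as truncated normals per group; sex
Bernoulli at the published group frequencies; years smoked as a
truncated normal (12.0 ± 4.9 years, minimum 2); pack-years log-normal
with median 7.11 and log-σ 0.485, which reproduces the published mean of
8.0 (the published SD of 6.1 implies a heavier tail than a two-parameter
log-normal matching median and mean; the tail was not chased). Retinal
thickness per ETDRS subfield uses typical healthy Spectralis values,
identical for both groups, since no group difference was found in the
study design this emulates.

Ground-truth decay parameters are drawn per (eye, channel, region). The
regional mean-lifetime distributions are the published group summaries
(e.g. SSC inner ring 210 ± 17.7 ps in non-smokers vs 220 ± 15.2 ps in
smokers; LSC outer ring 242 ± 11.2 vs 236 ± 15.4 ps), so the configured
group effects carry the published directions: longer inner-ring SSC τ_m
and shorter outer-ring LSC τ_m in smokers. τ₁ is drawn around 0.55·τ_m
(the published component tables for τ₁/τ₂ are not publicly deposited;
this ratio puts τ₁ near 70–135 ps, plausible for the fundus), τ₂ around
a per-channel mean (2200 ps SSC, 2400 ps LSC, SD 150 ps), and the
amplitude fraction is then solved from the τ_m identity, making every
subject's truth exactly representable by the fitted model family and the
regional τ_m equal to the configured mean in expectation. Each item is a
bivariate (OD, OS) normal draw with correlation ρ = 0.9, reproducing the
high between-eye symmetry of healthy fundi (all 18 parameter × region ×
channel correlations > 0.8 at n = 54). In the regional shortcut mode the
inner- and outer-ring aggregates are drawn directly from their own
published distributions as first-class items; in the pixel mode they
arise from pooling rendered subfield pixels.

Photon cubes are simulated by rendering piecewise-constant parameter
maps on the grid (background outside the 6 mm disc: a longer-lifetime,
dimmer decay; optional vessel/disc overlays exist but are off by
default, as the emulated analysis does not exclude vessels), computing
each pixel's IRF-convolved wrapped decay profile, and drawing
independent Poisson counts. The clinical stopping rule is honoured
exactly rather than approximately: the exposure is the maximum over the
two channels of the first-passage time to 1000 foveal photons (gamma
distributed), so the foveal-centre pixel always reaches the target in
both channels, the limiting channel holding exactly 1000 at its own
passage time plus the extra accrued while the other channel finishes.

What the generator does **not** model: eye motion and tracking residue,
lens autofluorescence, macular-pigment absorption spectra, detector
afterpulsing and dead time, vessel shadows (by default), spatial
correlation of noise. Passing tests therefore demonstrate correctness of
the pipeline under the stated statistical model, not robustness to every
artifact of clinical data.

## Cohort statistics

Two-group metric comparisons use the unpaired t-test with pooled
variance by default (the default of common point-and-click statistics
packages; Welch is a switch). Sex uses the Pearson chi-square test of
independence without continuity correction — with the published 2×2
counts (13/13 vs 15/13) this reproduces the printed p = 0.793 exactly,
which is how the flavor was pinned down. The three-arm analysis splits
smokers at their median pack-year (strictly below → light, at or above →
heavy) and runs one-way between-subjects ANOVA per region with Tukey HSD
pairwise tests; the "repeated measures" phrasing in the emulated design
is interpreted as per-region one-way testing, since the reported post
hoc structure (G0 vs G1, G0 vs G2, G1 vs G2 per region) is exactly what
that produces. Tukey p-values come from the table-interpolated
studentized-range routine (`statsmodels`' `psturng`) with the
Tukey–Kramer standard error; the quadrature-based scipy equivalent was
~50× slower at identical results to ~1e-3. A Shapiro–Wilk screen at
α = 0.05 per cell stands in for visual Q–Q inspection and routes
violating cells to Kruskal–Wallis with Dunn's rank-sum pairwise tests
(tie-corrected, unadjusted), with the routing logged. Correlations are
Pearson r with two-sided p and Cohen labels on left-closed bands
(|r| < 0.1 negligible, [0.1, 0.3) small, [0.3, 0.5) medium, ≥ 0.5
large). No multiplicity correction is applied across regions by default,
matching the emulated analysis; a Benjamini–Hochberg switch exists.
Between-eye agreement reports the paired t-test and the OD–OS Pearson r
for the three main regions, three parameters and two channels (18
items).

## Numerical and design choices

- Time axis: bin centres, width = period / n_bins; default 256 bins
  (tests use 64). Amplitudes are in counts per bin at t = 0.
- Default raster 256×256 over ≈8.8 mm (30°), ≈34 µm/pixel — a
  convention, not a device fact; all geometry is configurable.
- Reduced χ² is the Pearson statistic over all bins with 4 model
  parameters; it averages ≈1 on data from the fitted family at the
  simulated budgets.
- Degenerate inputs: empty or flat histograms raise a degenerate-input
  error before optimization; all-zero pixels are reported as low-signal.
- Determinism: every stochastic stage takes a seed or Generator;
  identical configuration and seed reproduce cohorts, cubes, maps and
  tables byte-for-byte.
- Problem sizes in the test suite (64-bin histograms, 64×64 or smaller
  rasters, 120–200 replicate fits, 12-cohort calibration loops, 1000
  replicate null tests) were chosen as the smallest that leave the
  checked contrasts well outside sampling noise.

## Known limitations

- The fitter assumes the IRF is known; it is not estimated from data.
- Three-exponential models, stretched exponentials and phasor analysis
  are out of scope.
- No mixed-effects modelling of eye nesting, and no age/BMI-adjusted
  models — group comparisons are unadjusted, as in the emulated design.
- The pack-year distribution matches the published median and mean but
  not the published SD (see above).
- The τ₁/τ₂ population defaults are consistent with, but not uniquely
  determined by, the published mean-lifetime tables.
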