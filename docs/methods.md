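# Methods

This note documents the models behind `metaboscope`, the choices that were
genuinely open, and what the synthetic-data tests do and do not establish
about real data.

## Biosensor and trace model

Intracellular glucose `G` (mM) in one cell evolves as

    dG/dt = Vup · G_ext/(K_media + G_ext) − Vcon · G/(Km + G)

with a piecewise-constant extracellular schedule `G_ext(t)`. Uptake
saturates with the medium (half-saturation `K_media = 1 mM`) and vanishes
in glucose-free medium; consumption is Michaelis–Menten in the
intracellular pool (`Km = 2 mM`), which produces the curved wash-out decays
characteristic of biosensor traces. Integration is fixed-step RK4 with 20
substeps per frame; the medium level is held constant within each substep
so schedule switches aligned to the frame grid are integrated exactly.
Against adaptive integration at `rtol = 1e-11` the sampled ratio agrees to
better than 1e-9, far below every fitting tolerance used downstream.

The emitted ratio is a Hill response
`R(G) = R_min + (R_max − R_min)·G^h/(Kd^h + G^h)` plus i.i.d. Gaussian read
noise per frame. The sensor's true `Kd` and dynamic range are
construct-specific and not publicly tabulated for this configuration, so
the defaults (`R` from 1.0 to 3.0, `Kd = 0.6 mM`, `h = 1`) are explicit
placeholders, configurable on `BiosensorModel`. Any saturating monotone
response would serve the same testing purpose; Hill is the standard form
for periplasmic-binding-protein sensors.

## Wash-out/wash-in cohort design

The demonstration cohort initializes every cell at its steady state in
25 mM medium (uptake balancing consumption), so the pre-wash-out baseline
is flat and the decay starts from a defined operating point. Consumption
Vmax is drawn from U(0.30, 0.65) mM/min and steady-state glucose from
U(0.30, 0.60) mM, independently; uptake follows from the balance
condition. These ranges put the wash-out half-life at roughly 3–9 minutes
— the regime this assay is designed for, in which the glucose drop
completes well inside the 30-minute wash-out window and the one-phase rate
is well identified. Slower cells (half-life beyond ~10 min) leave the decay
under-resolved within the window and the fitted rate poorly determined;
they are a real limitation of the protocol, not of the estimator.

The truth channel for kinetic recovery records the *instantaneous* slopes
of the noiseless ratio at the two medium switches (chain rule through the
sensor response), i.e. the same estimands the 3-minute OLS windows target,
in ratio units/min. The initial-slope window defaults to the 3 minutes
immediately after wash-out (minutes 10–13 of the protocol); a two-point
difference mode is available for replication of slope-by-differencing
conventions. The decay fit leaves the plateau free rather than pinning it
to the 0 mM sensor floor.

## Lineage and heritability

Cohorts branch with exponentially distributed lifetimes
(`division_rate = 0.055/h` by default; 3,000-min movies at 5-min frames).
A daughter's standardized state is `ρ·parent + √(1−ρ²)·ε`; founder states
come from a high/low mixture standardized to mean 0, SD 1, so the
correlation readout is exactly ρ (and ρ² over two generations) regardless
of the mixture. Baseline ratio is an affine map of the state
(center 2.0, scale 0.25 ratio units); traces are flat at baseline plus
read noise. This deliberately omits within-lifetime state drift — the
generator models a *stable* heritable state, which is what makes the
closed-form AR(1) predictions exact. Per-cell summaries for correlations
are the mean ratio over the last 2 h before division (configurable); both
daughters contribute pairs by default, with a one-per-family subsampling
option for strictly independent pairs (sister pairs share a parent, which
inflates the variance but not the expectation of r).

Return-to-mean of sorted subpopulations is modeled as an
Ornstein–Uhlenbeck state with configurable relaxation time; the analysis
fits an exponential to the per-day median distance from the reference and
flags trajectories that re-expand (non-monotone beyond 1.5× the running
minimum) as unreliable.

## Dose–response cohort

The stepped schedule is 0, 0.05, 0.1, 0.5 μM at 0, 1, 2, 3 h, assayed at
the end of each dwell (mean of frames within ±5 min). Responses approach
each step's target fractional shift exponentially (τ = 10 min). Class
profiles (strong −0.35/−0.45/−0.55; weak −0.08/−0.17/−0.25; non
−0.005/−0.012/−0.02) are scaled per cell by one positive factor
(SD 0.12), which keeps each cell's per-dose response monotone. The
classification thresholds (strong ≤ −0.2 at the first nonzero dose; non
≥ −0.05 at the final dose) are package defaults — exemplar-based sources
give no numeric cutoffs — and are exposed in the API.

Refractory cells are constitutively high (baseline 2.40 ± 0.07 against a
control population of 2.00 ± 0.15) and unresponsive, so they remain above
the control median at every dose. Non-refractory non-responders are
generated with *low* baselines (1.80 ± 0.06): mechanistically, cells with
little inhibitor-sensitive uptake have little signal to lose, and this
choice keeps the median rule identifiable — an unresponsive cell whose
baseline were drawn from the control distribution would be flagged
"refractory" half the time by construction, and no generating fraction
could be recovered by any estimator. This is a modeling commitment of the
generator, stated here so its consequences are not mistaken for a property
of real cohorts.

## Spatial profiling

The interactive "circle the tumor, straighten, re-slice, sum-project"
procedure is implemented as distance-transform banding: each pixel inside
the region gets its Euclidean distance to the boundary (inward positive),
pixels are binned every 100 μm (50 μm mode for stain profiles), and the
band statistic is `Σ acceptor / Σ donor` — sums first, then one division,
which is exactly what a sum-slice projection followed by a ratio computes.
A pixel-loop oracle in the tests enforces the equivalence exactly. The
μm-per-pixel scale is a required argument with no default. Kymographs
measure distance from the current wound edge (boundary of the cell-occupied
mask per frame) and report the mean ratio over cell pixels per band — a
different statistic from the tumor profile, matching how each readout is
produced upstream. Wound closure is `100·(A₀ − A₂₄)/A₀`; negative closure
is allowed and flagged.

## FLIM fitting

Decay cubes are 3×3 box-averaged per time bin (edge pixels average over
available neighbors only), masked at strictly greater than 100 integrated
photons, and fitted per pixel with

    m(t) = scale · [IRF(t − shift) ⊛ (f₁ e^(−t/τ₁) + (1−f₁) e^(−t/τ₂))] + bg

under Neyman weights `1/√(counts+1)`. The nonlinear parameters are
(log τ₁, log τ₂, logit f₁, shift); scale and background are linear and
solved in closed form at each step, which keeps per-pixel fits to a few
milliseconds. Initial guesses are deterministic and data-driven: the slow
lifetime from a log-linear fit to the tail (last 30% after the peak), the
fast one from the first 15%. τ₁ ≤ τ₂ is enforced by sorting;
`mean_tau = a₁τ₁ + a₂τ₂`. Fits with τ₂/τ₁ < 1.05 are collapsed to a
mono-exponential and flagged. The IRF time shift is a fit parameter by
default in single-decay fits and off in map mode (the simulated IRF is
already on the data's bin grid). Demonstration maps are 32–64 pixels
square at 256 bins over an 11.1 ns window (90 MHz excitation) and ~10⁴
photons/pixel; at that photon budget the recovered amplitude-weighted mean
lifetime is within a fraction of a percent of truth after smoothing.

## Isotope correction

The forward model is lower-triangular: column `j` is the binomial mass-
shift distribution of the `n − j` unlabeled carbons at abundance
`q = 0.0107`. Correction solves `M·x = observed` by non-negative least
squares and renormalizes; the raw solution and residual are kept. Only the
carbon skeleton is corrected — derivatization-atom (TMS/Si) corrections
are a separate concern handled by dedicated GC-MS software and are out of
scope here. `percent_labeled` refuses uncorrected MIDs unless explicitly
overridden.

## Statistics

Distribution comparisons use the two-sample Kolmogorov–Smirnov test
(exact/asymptotic p per sample size). Its null calibration is checked
empirically (type-I error within [0.03, 0.07] at α = 0.05 over 2000
simulations) and its statistic against a brute-force ECDF sup-distance.
Refractory fractions carry Wilson binomial confidence intervals.

## Determinism and problem sizes

All generators take explicit seeds; the pipeline expands one global seed
into per-stage seeds via `SeedSequence([seed, stage_index])`, so stages
can be rerun independently with identical outputs (verified by checksum in
the tests). Demonstration sizes — 200-cell kinetic cohorts, 60-founder
lineages (~1,400 parent–daughter pairs), 600-cell dose cohorts, 300-px
spatial fields, 32–48 px lifetime maps — were chosen so every analysis
runs in seconds to a couple of minutes on one CPU while leaving the
statistical tolerances comfortably resolvable.

## What the synthetic tests do not show

The generators emulate the *structure* of the real experiments, not their
nuisance processes: no photobleaching, spectral crosstalk, focus drift or
flat-field error; disk-shaped cells with small random walks instead of
real morphology and migration (tracking is therefore validated only on
well-separated cells); Gaussian read noise on ratios rather than full
shot-noise propagation through both channels (shot noise is exercised
separately in the rendering tests); dose responses with a single
exponential approach rather than pharmacokinetics. Passing recovery tests
demonstrates that the estimators are correct and well-calibrated under the
stated models; performance on real microscopy additionally depends on
segmentation quality and the nuisance processes above.
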