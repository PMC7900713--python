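# metaboscope

Single-cell metabolic-imaging analysis for ratiometric glucose FRET
biosensor experiments: per-cell FRET quantification from two-channel
time-lapse stacks, kinetic decomposition of glucose uptake versus
consumption, lineage heritability of the glycolytic state, single-cell
dose–response classification with refractory-cell detection, spatial
(kymograph and center–periphery) profiling, TCSPC fluorescence-lifetime
fitting, and ¹³C label-incorporation computation.

The package is written for imaging groups who quantify intracellular
glucose with a genetically encoded FRET biosensor (donor + sensitized
emission) and need the downstream statistics as tested, reusable code.
Because such experiments rarely ship with public raw data, every analysis
stage is paired with a synthetic-data generator that records its ground
truth, so the whole pipeline is verifiable end to end by parameter
recovery.

## The core quantities

**FRET ratio.** For each segmented cell, `R = (A − bg_A) / (D − bg_D)`
where `D` and `A` are the mean pixel intensities of the donor and
sensitized-emission channels over the cell mask (ratio of means, not mean
of ratios). `R` increases with intracellular glucose through a saturable
(Hill) sensor response.

**Kinetic decomposition.** Switching the medium to 0 mM glucose halts
uptake, so the trace decays at the consumption rate; switching back
restores uptake. With a one-phase fit `R(t) = plateau + span·e^(−k(t−t₀))`
(half-life `t½ = ln2/k`) and 3-minute initial slopes after each switch,

    uptake = consumption + refill_slope        (exact identity)

**Heritability.** Daughter baseline states follow an AR(1) process on the
standardized glycolytic state, `z_child = ρ·z_parent + √(1−ρ²)·ε`, which
predicts parent–daughter correlation ρ and grandparent–granddaughter
correlation ρ² — a correlation that declines across generations.

**Dose response.** Per-step fractional shifts `s_i = (R_i − R_0)/R_0`
classify cells as strong (`s₁ ≤ −0.2` at the lowest nonzero dose), non
(`s_final ≥ −0.05`) or weak (in between); a treated cell is *refractory*
when its final ratio stays strictly above the untreated control
population's median.

**Spatial profiles.** Center–periphery profiles use distance-transform
banding with ratio-of-sums per band (`Σ A / Σ D`, the sum-slice
projection); scratch kymographs report mean ratio per
(distance-from-wound-edge, time) band.

**FLIM.** Per pixel, photon-count decays are 3×3 smoothed, masked at
>100 integrated photons, and fitted with an IRF-convolved double
exponential under Poisson weights; the amplitude-weighted mean lifetime is
`τ_m = a₁τ₁ + a₂τ₂` (FRET shortens the donor lifetime).

**¹³C labeling.** Observed mass-isotopomer distributions are corrected for
natural ¹³C abundance (q = 1.07%) by inverting the binomial forward model
with non-negative least squares; label incorporation is `100·(1 − M+0)`,
the percent of the pool with at least one tracer carbon.

## Worked example

The numbered scripts under `analysis/` run each stage on synthetic data and
print what they find. For example, the kinetic decomposition:

```bash
$ python analysis/01_simulate_inputs.py            # renders the demo movie
$ python analysis/03_kinetic_decomposition.py
200 cells; median t1/2 = 4.18 min (IQR [3.50, 5.33])
consumption rank recovery: Spearman r = 0.923
uptake rank recovery:      Spearman r = 0.971
flux identity violations: 0
```

Each of the 200 simulated cells was wash-out/wash-in cycled (0 mM at
10 min, 25 mM at 40 min) with read noise of 0.02 ratio units; the fitted
half-lives sit in the few-minute range the assay is designed for, and the
estimated consumption and uptake rates rank the cells almost exactly as the
generating rates do. Likewise:

```bash
$ python analysis/05_dose_response.py
class counts: {'non': 229, 'weak': 203, 'strong': 168}
class accuracy vs truth: 100.0%
refractory: 9.5% (95% CI [7.4, 12.1]; generated 11%)
```

i.e. with an 11% refractory subpopulation generated, the median rule
recovers 9.5% with a confidence interval covering the truth. The other
drivers (`02` quantification + KS comparison, `04` heritability, `06`
spatial, `07` FLIM, `08` isotopes) follow the same pattern and write their
tables under `results/`.

The same functionality is exposed as a CLI (`metaboscope simulate|quantify|
kinetics|dose|flim|isotopes|run`) for file-to-file use.

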