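# Methods

`gamfoci` estimates the rate of spontaneous DNA double-strand breaks
(DSBs) per cell division in bacteria from fluorescent-focus data, the
way microfluidic GamGFP experiments measure it. GamGFP binds
double-strand ends, marking each break with a diffraction-limited focus,
and traps the ends so that a focus-bearing cell stops dividing. Three
quantities anchor everything: the probability *p* that a true break is
seen as a focus (detection efficiency), the focus rate per division *f*,
and the true break rate per division *r* = *f*/*p*.

## Detection-efficiency calibration

Gamma rays deliver breaks at a known yield *y* (0.031 DSBs·cell⁻¹·Gy⁻¹
for *E. coli*, from sucrose-sedimentation measurements). Focus counts
are linear in dose over 0–140 Gy, so an ordinary least-squares fit of
mean foci/cell on dose gives a slope in foci·cell⁻¹·Gy⁻¹ and

  p = slope / y.

The default fit is unweighted OLS on per-dose means; an inverse-variance
weighted option (weights n/sd²) exists for strongly heteroskedastic
tables. With exactly two doses the fit degenerates to the two-point
subtraction (slope = Δmean/Δdose) and r² is reported as absent — this
two-point path is exactly the printed-number arithmetic
(3.12 − 0.043)/140 = 0.022, 0.022/0.031 = 0.71. Efficiencies above 1 are
returned unclamped with a warning flag, since they indicate an
inconsistent yield rather than a computational fault.

Uncertainty on *p* comes from a percentile bootstrap (default 2,000
replicates). The natural resampling unit is the cell within each dose,
but the table stores per-dose summaries (mean, sd, n) rather than raw
counts, so cell resampling is applied in its Gaussian limit: each
replicate draws mean*ᵢ ~ Normal(meanᵢ, sdᵢ/√nᵢ) and refits. A
zero-variance table therefore produces a zero-width interval at the
point estimate, and the interval scales exactly as 1/yield.

## Rate inference from microcolony traces

A trace records one founder cell growing into a microcolony: frames of
(time, n_cells, cumulative divisions, cumulative foci) plus an event
log. Every division satisfies n_cells = 1 + cum_divisions (binary
fission from one founder).

The headline estimator is colony-level: each colony contributes
fᵢ = final foci / final divisions; *f* is the mean of fᵢ with its SEM
across colonies (this is the "mean ± SEM over six microcolonies"
convention; how the original SEM was pooled is not stated, so the
colony-level convention is adopted and used consistently). A pooled
Wilson 95% interval on Σfoci/Σdivisions is reported alongside — Wilson
because it behaves at small counts. Colonies whose founder never
divided are excluded with a warning.

The efficiency correction is r = f/p with r_sem = f_sem/p by default:
the efficiency is treated as a known constant, which reproduces the
convention of quoting ±(0.006/0.71) ≈ 0.008 on the corrected rate.
Full delta-method propagation including the efficiency SE is available
(`propagate_efficiency=True`) and reported as `r_sem_full`.

Legacy frequency-based estimates (a rate *F* of cells acquiring ≥1
break per generation, from flow-cytometric detection) convert to break
rates as F × (total foci / focus-carrying cells), i.e. scaled by the
observed mean breaks per break-carrying cell (108/98 ≈ 1.1 under
minimal-glucose growth).

### Generation-dependence diagnostic

If breaks are replication-coupled, foci per division is invariant when
the division rate changes, while foci per hour is not. The diagnostic
partitions traces at regime boundaries (e.g. glucose withdrawal at
9 h), pools foci and division counts per regime over colonies, and
reports the first-vs-last-regime per-division rate ratio with a Katz
log-ratio interval (0.5 continuity correction on zero counts, flagged),
plus the per-hour Poisson rate ratio using trapezoid-integrated
cell-hours as exposure. Generation-dependence is "supported" when the
per-division ratio interval covers 1 and the per-hour interval does
not. The fluorescence-exposure control (repeatedly pulsed vs
first-imaged-late colonies) is a Welch two-sample comparison of focus
means with a 95% t interval.

## Synthetic-data generator

The generator is the study model, not a fixture factory; its defaults
are the study conditions.

* **Microcolonies** grow as a continuous-time Markov branching process.
  Interdivision times are exponential with piecewise-constant mean
  `tau_schedule`; the default ((0 h, 1 h), (9 h, 12 h)) emulates
  log-phase growth in glucose followed by near-halted division after
  glucose withdrawal at 9 h. Starved divisions are described only
  qualitatively in the source experiments (slowed, then halted); the
  1 h log-phase mean matches
  minimal-glucose doubling, and the memoryless waiting time keeps the
  process analytically checkable (regime switches simply re-draw the
  clock).
* Each division carries an independent Bernoulli(q) detected focus,
  q = r·p, with defaults r = 0.021 and p = 0.71. A focus formed at
  division is scored once and arrests **both** products of that division
  (the broken, Gam-bound chromosome cannot complete segregation). This
  is a model choice: whether focus appearance is scored at or between
  divisions is not observable in the source data, and tying breaks to
  divisions encodes the generation-dependence conclusion by
  construction. An alternative time-driven process (`foci_per_hour`)
  generates the null-breaking hypothesis for power checks.
* Founders that fully arrest before reaching the target colony size
  (e.g. a focus at the first division) are not scoreable microcolonies;
  `simulate_microcolonies(require_growth=True)` draws founders until the
  requested number reach size. The induced conditioning bias on *f* is
  ≈ −q/(divisions per colony) (~1% at 100 cells), negligible against
  the Monte-Carlo error of 20-colony experiments.
* **Dose–response**: true breaks ~ Poisson(y·D) per cell, detected by
  binomial thinning with p, plus a Bernoulli(b) spontaneous background
  (b = 0.043 foci/cell, the M9-glucose zero-dose level; b < 1 in every
  observed regime, so Bernoulli vs Poisson background differs only at
  second order in b).
* **Cut foci**: copies per cell from a discrete distribution (log-phase
  cells carry two or four ori:ter regions), each copy cut with
  `cut_prob`, each cut detected with p.
* **Focus pairs**: one red (chromosome-label) and one green (break)
  focus per cell; displacement distance ~ Gamma(shape 4, mean μ(g)) in a
  uniform direction, with μ(g) = plateau·(1 − exp(−g/g₀)) a saturating
  function of genomic separation g. Defaults plateau = 0.57 µm (the
  measured 2.4 Mb distance) and g₀ = 35 kb (so the 55 kb and 80 kb
  means fall near the measured 0.45/0.52 µm); the source data give four
  points and no functional form, so the saturating exponential and the
  Gamma shape are generator choices.
* **Images**: 2-D Gaussian spots (amplitude = peak photons, sigma = PSF
  width) on a constant background with per-pixel Poisson shot noise.
  Pixel (row, col) centers at (x, y) = (col, row)·pixel_size.

The generator emulates the stochastic structure of the experiments —
thinning, arrest, regime switches, copy-number mixtures, saturating
geometry — but not cell shape, segmentation error, focus photobleaching,
chromatic aberration, or 3-D distances. Passing recovery tests on this
data shows the estimators are consistent under the stated model, not
that real images segment correctly.

## Spot calling

Difference-of-Gaussians band-pass at the PSF scale (σ and 1.6σ),
threshold = median + k·1.4826·MAD of the filtered image (robust to
sparse spots; k = 5 by default), 3×3 local maxima with plateau ties
resolved to the lowest (row, col) index, and sub-pixel centers by
intensity-weighted centroid in the 3×3 window. Because a constant
offset passes through both blurs and cancels, detection is exactly
invariant under uniform background shifts. Measured performance on
synthetic fields at SNR 10 (peak/√background) and ≥5σ spot separation:
recall and precision ≥ 0.95. The original study's focus-counting
software is unspecified; this module is the package's own tested
operator, not a numerical mimic.

## Co-localization

Within each cell, green and red calls (sorted by (x, y) so ties resolve
deterministically) are paired by minimum-total-distance assignment
(Hungarian algorithm); for the 1:1 and 1:2 ratio classes this coincides
with mutual nearest-neighbour matching. Cells are classified 1:1, 1:2
(one green, two red — the single green focus contributes a near and a
far distance), or other; other-class cells are excluded from distance
summaries but counted. Overlap calls use a configurable threshold
(default 0.2 µm ≈ the diffraction limit; the original yellow-overlap
criterion is unstated, so the threshold is surfaced in all reports).
The overlap fraction is per cell (SEM across experiments when labels
are provided, binomial otherwise); the three-category count
(A-only/B-only/both) is per focus, with a pooled denominator in which a
matched pair counts once (per-channel denominators behind a flag).

## qPCR copy number

ΔCt per sample = mean Ct(ter-locus) − mean Ct(ori-locus), replicates
averaged on the Ct scale; ratio = E^(ΔCt − ΔCt_reference) with the
stationary-phase culture as the 1:1 reference and E the per-cycle
amplification (default 2; per-locus efficiencies assumed equal, which
the 1:1 normalisation makes the faithful reading). The forward model
P(>1 focus) = mixture over copies c of Binomial(c, cut_prob·p){>1} is
exact; it is exposed forward-only because the per-site cleavage
efficiency is unknown, so observed multi-focus fractions cannot be
inverted without a free parameter — only the direction (more copies →
more multi-focus cells) is testable.

## Numerical and design notes

* Randomness: one run seed fans out to per-stage PCG64 streams keyed by
  stable string labels (CRC-32 of the label into a SeedSequence), so
  fixed seed ⇒ byte-identical outputs and stages never share streams.
* Reported figures use full-precision arithmetic; summaries format to
  3–4 significant digits.
* Problem sizes in the test suite are chosen to bound Monte-Carlo error
  via 3-standard-error bands: thinning checks use 1,500 colonies × 100
  divisions, recovery checks 20 colonies and 5,000 cells/dose (the
  study-scale design), coverage checks 100 outer replicates × 2,000
  bootstrap refits (vectorised).
* Degenerate inputs: zero-division traces are excluded with warnings
  (error if all are); empty dose lists, identical doses, empty
  channels, zero-variance Welch pairs and missing loci raise or flag as
  documented per function.

## Known limitations

* The branching model scores breaks only at divisions; truly
  division-independent breakage during growth is representable only via
  the time-driven alternative generator.
* The r² of the original multi-dose regression cannot be reproduced:
  per-dose values exist only in a figure. The two-point arithmetic and
  synthetic multi-dose recovery stand in for it.
* Interfocal geometry is 2-D and aberration-free; absolute overlap
  percentages therefore depend on the configured threshold, and only
  their ordering with genomic distance is treated as meaningful.
* The arrest-on-focus absorbing state is immediate; any lag between
  break formation and division arrest is not modelled.
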