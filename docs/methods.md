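# Methods

This note documents the models behind `fltscreen`, the defaults and why
they were chosen, what the synthetic plates do and do not emulate, and the
numerical choices that matter when reading results.

## Measurement model

Each well of a lifetime plate reader yields a histogram of photon arrival
times. We model it as a single-exponential donor decay convolved with the
instrument response function (IRF) plus a constant background:

    m(t) = A · (h ⊛ e^(−t/τ))(t) + b

For a Gaussian IRF with center μ and width σ the convolution has the
closed exponentially-modified-Gaussian form

    (h ⊛ e^(−t/τ))(t) = ½ exp(σ²/2τ² − (t−μ)/τ) · erfc((σ/τ − (t−μ)/σ)/√2)

evaluated in two numerically stable branches: the scaled complementary
error function (`erfcx`) where the erfc argument is positive (rising edge)
and the plain exponential form in the tail. A tabulated IRF is supported
through discrete convolution on the waveform grid.

FRET efficiency is the fractional donor-lifetime shortening,
E = 1 − τ_DA/τ_D, with τ_D taken as the mean over converged DMSO wells of
a paired donor-only plate — matching the practice of running a donor-only
control transfection alongside each screening day. Slightly negative E
values produced by noise are deliberately retained: clipping at zero would
skew the null distribution that the SD-threshold statistics assume.

## Lifetime fitting

Fits minimize Poisson-weighted squared residuals with
`scipy.optimize.least_squares` (bounded trust-region). Key choices:

- **Weights.** Counting statistics give Var(c_i) = λ_i. Weighting by the
  *observed* counts (1/max(c,1)) over-weights downward fluctuations and
  biases τ̂ low by ≈1% at 10⁵ photons/well. The fit therefore starts from
  observed-count weights and performs two reweighting passes using the
  fitted model's expected counts; the procedure stays a weighted
  least-squares minimization throughout and reduces the bias to <0.1%.
- **Initialization** is deterministic (no random restarts): τ₀ from a
  log-linear regression on post-peak bins above 5% of the maximum,
  baseline from the last 2% of bins, amplitude from the peak.
- **Bounds.** τ ∈ [0.1, 10] ns, amplitude ≥ 0, baseline ≥ 0. A solution at
  the τ bound is flagged non-converged, never silently clamped.
- **Modes.** `reconvolution` fits the full window; `tail` fits a bare
  exponential starting 3 IRF widths past the histogram peak. For an IRF
  much narrower than τ the two agree within ~2%.
- **Failure isolation.** All-zero or near-empty waveforms (<20 nonzero
  bins) raise in single-well fitting and are flagged `converged = False`
  in plate fitting so one dead well cannot abort a plate.
- **Errors.** τ standard errors come from the Gauss–Newton covariance
  (JᵀJ)⁻¹ scaled by reduced χ². Reduced χ² uses n_bins − 3 degrees of
  freedom; on correct-model Poisson data at 10⁵ counts it sits in
  [0.8, 1.2].

Fits are per-well and independent; the plate-level element shared across
wells (the "global" ingredient) is the IRF and the fit bounds. No
amplitude or baseline tying across wells is assumed.

## Screening decision layer

- **Hit statistic.** Hits are called on τ_DA itself, not on E: for a fixed
  donor reference the two are affinely related, and τ_DA is the quantity
  the plate reader delivers per well. The baseline is the *same plate's*
  DMSO wells (256 of them in the 1536-well LOPAC layout), so plate-to-plate
  drifts cancel; μ and σ use the sample SD. A compound is a hit when
  |τ_DA − μ| > k·σ with k = 4 by default (3 and 5 as standard
  alternatives). Calling is two-sided — FRET increases and decreases are
  both biologically informative — with the τ-shift direction recorded.
- **Interference screen** (mandatory before hit calling). The donor-only
  plate shares the compound layout. A compound is excluded when its
  donor-only lifetime deviates > 3 DMSO SDs (two-sided), or when its
  spectral score exceeds the DMSO score mean by > 3 DMSO-score SDs. The
  spectral score is the log10 of the cosine dissimilarity between the
  well's emission-band vector and the DMSO mean vector. The log scaling is
  a variance-stabilizing choice: the raw dissimilarity's null is
  chi-square-like, and a mean + 3 SD cut on it would falsely flag ~2% of
  clean wells (enough to eat real hits), while on the log scale the null
  is near-symmetric and genuine contamination moves the score by orders of
  magnitude. The spectral cut is one-sided (the score is a dissimilarity;
  "more similar than controls" is not interference), the lifetime cut
  two-sided.
- **Reproducibility.** For plate p and level m, the repeated-hit
  percentage is 100·|{hits of p that are hits on ≥ m plates, p included}| /
  |hits of p| — each plate's own hit count is the denominator — aggregated
  as mean ± SEM across plates. Percentages are undefined (NaN) for plates
  with zero hits.
- **Z′.** Z′ = 1 − 3(σ_DMSO + σ_Tool)/|μ_DMSO − μ_Tool| with sample SDs,
  computed on τ_DA. Equal group means raise an explicit error (no window).
  Z′ is invariant under affine rescaling of all lifetimes.
- **Triage.** A primary hit is a `candidate` when its counter-screen
  |Δσ| stays below the counter threshold (default: the counter's own hit
  threshold) and `undesired` otherwise; compounds absent from the counter
  screen are reported `unclassified`, never silently dropped.

## Hill dose–response

The four-parameter logistic
`y = bottom + (top − bottom)/(1 + (EC50/c)^n)` is fitted in log10(EC50)
space with deterministic initialization: plateaus from the extreme-
concentration means, slope sign from the data trend, EC50 from the first
grid crossing of the half-response. The slope is signed (negative for
responses that fall with concentration), so `bottom ≤ top` always names
the plateaus and the curve passes (top+bottom)/2 at EC50 in either
direction. `fix_top` / `fix_bottom` pin plateaus for DMSO-relative data.
Flat responses are flagged non-converged with NaN EC50 rather than
returning an arbitrary number; an EC50 at the search bound (3 decades
outside the tested range) is likewise flagged. EC50 standard errors use
the delta method from the log-space covariance. Fits require ≥ 4 distinct
concentrations spanning ≥ 1.5 decades. Replicate summaries report plain
mean and SD of EC50 and flag any plate deviating > 3 leave-one-out SDs.

## Secondary assays

Cosedimentation arithmetic follows the supernatant-depletion logic: the
acceptor-peptide bound fraction is 1 − F_sample/F_no-actin (the no-actin
spin defines 100% unbound); values outside [0,1] are retained and flagged.
ABD binding uses bound = total − unbound, with the total lane either
supplied (no-spin reference) or calibrated from DMSO lanes assuming the
assay's near-saturated control binding (default 0.9 bound under DMSO).
Aggregation is a one-sided comparison of no-actin pellet fractions against
DMSO. Group comparisons are unpaired two-sample t-tests at p < 0.05, with
significance reported as unavailable (not false) for single replicates;
the test suite cross-checks the flags against an exhaustive permutation
test on small tables away from the decision boundary, where the two tests
must agree.

## Synthetic plates

The simulator emulates the screen's statistical structure, not its optics:

- **Defaults as study conditions.** Donor lifetime 2.60 ns and IRF σ
  0.15 ns are plausible GFP/plate-reader values (the screen design itself
  fixes no absolute lifetimes), fully configurable. 10⁵ expected photons
  per well on a 0–25 ns window with 0.05 ns bins. Baseline efficiencies
  default to the assay's DMSO controls: total FRET 0.123 for
  donor + Lifeact-acceptor wells and 0.059 nonspecific FRET for
  donor + free-acceptor (counter) wells, so simulated effect magnitudes
  are realistic.
- **Noise.** Per-bin independent Poisson draws around the IRF-convolved
  expectation — photon-counting physics, and the source of the per-well τ̂
  scatter the SD thresholds are calibrated against. Emission spectra are
  three band intensities (donor ~510 nm, contaminant ~560 nm, acceptor
  ~600 nm) with 2% multiplicative Gaussian noise.
- **Effect classes.** `modulator` removes up to `max_fret_change` of the
  *specific* FRET with Hill concentration dependence; `cytotoxic` /
  `aggregator` scale both specific and nonspecific FRET toward zero
  (lysis abolishes both); `interferer` shifts the apparent donor lifetime
  and mixes a contaminant profile into the spectrum; `inert` is the null.
  Effects ramp in time as 1 − e^(−t/t_c) to reproduce the observed growth
  of hit counts between the 20- and 120-min reads.
- **Titration.** Specific FRET saturates exponentially in acceptor
  expression to a 0.12 plateau; the nonspecific component is linear
  through the origin.
- **Fitted-τ shortcut.** `simulate_fitted_tau_plate` draws per-well
  fitted lifetimes directly from the Gaussian well-noise approximation.
  At 10⁵ counts the fitted τ̂ of the full simulate-and-fit path is Gaussian
  to excellent approximation, so million-well null-calibration studies
  use this generator with its SD calibrated from a Monte-Carlo of full
  fits; waveform-level synthesis at that scale would add hours of compute
  and no statistical content to the hit-calling question.

What the simulator does **not** emulate — and what passing tests therefore
do not establish about real plates: multi-exponential donor populations
and autofluorescence decay, detector afterpulsing and dead time, spatial
plate gradients and edge effects, day-to-day transfection variability,
compound carryover, and real interferer spectra (a two-parameter
contaminant stands in). Results on real data still depend on instrument-
specific QC that is out of scope here.

## Problem sizes in tests

The test suite runs plates at 96- and 384-well scale for full
waveform-level pipelines (a 384-well trio fits in seconds), 10⁶ wells at
the fitted-τ level for null calibration, 100 curves for EC50 recovery,
and 768 + 768 wells for Z′ — sizes chosen so each statistical check has
enough power to be meaningful while the whole suite stays quick. The
1536-well LOPAC layout itself is exercised end-to-end by the layout, IO
and interference tests.

## Known limitations

- One-exponential decays only; no lifetime distributions or
  multi-exponential unmixing, and no IRF estimation from data.
- No κ² orientation modeling in the Förster arithmetic.
- No FDR-style multiple-testing control beyond the SD thresholds — by
  design, since the thresholds are the assay's established decision rule.
- The ABD "total lane" calibration assumes near-saturated control binding;
  assays run far from saturation should pass an explicit `total_signal`.
- Whether interference thresholds should be one- or two-sided on the
  spectral score is an open convention; the one-sided choice here is
  argued above but is a package decision, not an instrument standard.
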