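# Methods

This note records the models, conventions and default constants the
package uses, the design choices made where the underlying protocols
are silent, and the limits of what the synthetic forward models can
demonstrate.

## Spectra and Q-band features

Spectra are stored as wavelength-indexed arrays (`Spectrum`) with kind
absorption / emission / transmittance. Preprocessing subtracts a
solvent baseline and resamples by linear interpolation onto a uniform
grid (default 0.5 nm, the same step used for absorbed-light
integration, so spectra, filter profiles and the I_aT sum share a
grid).

Q-band detection uses prominence-based local-maxima search
(`scipy.signal.find_peaks`) in a configurable window (default
550–800 nm). Up to two maxima are retained; the second requires a
prominence of ≥ 20% of the window maximum and ≥ 5 nm separation —
thresholds that are declared package defaults, since published
descriptions of band splitting are qualitative. Ties for the primary
maximum break toward longer wavelength. The extinction coefficient is
Beer–Lambert at the *global* window maximum (for split bands either
maximum is defensible; the choice is flagged in the result so
downstream users can see it).

The aggregation index is 1 − A(λ_mono)/A_ref(λ_mono) against a
concentration-matched monomeric reference spectrum: 0 for fully
monomeric, → 1 as the monomer band vanishes into the H-aggregate.
Without a reference, a band-width proxy (1 − FWHM_mono/FWHM_obs, with
FWHM_mono defaulting to the 18 nm monomer band width) is used and
flagged; the proxy saturates and should be treated as ordinal only.

## Quantum yields

The absorbed-light integrand uses the exponent constant **2.3 exactly
as conventionally printed**, not ln 10 ≈ 2.3026; a `use_ln10` switch
provides the exact conversion (off by default). The difference is
≤ 0.1% in I_a and cancels almost entirely in the comparative ratio.
Negative post-baseline absorbances are clipped to zero inside the
absorbed-light sum only (absorbed intensity is physically
nonnegative); they are preserved everywhere else.

The bleach-slope regression keeps a **free intercept** by default.
Forcing the line through the origin is the literal reading of
ln(A₀/A_t) = k·t, but it makes the slope hostage to a single A₀
reading; the free intercept is robust to that error and identical on
noise-free data. A `force_zero_intercept` mode is provided.

Yield uncertainties default to the comparative method's blanket
relative errors (±10% for Φ_Δ, ±15% for Φ_F); when ≥ 3 replicate
yields are supplied their sample SD replaces the blanket value.
Yields above 1 are flagged, never clamped — they indicate a forward-
model or input error that should stay visible.

Refractive indices for common solvents (DMF 1.4305, THF 1.4050, …)
are bundled; anything in [1.2, 1.7] is accepted explicitly.

## Lifetimes

Tail fits only: the fit starts at the histogram peak bin and no
instrument-response deconvolution is attempted (appropriate when the
IRF is much narrower than the shortest lifetime of interest; sub-0.2 ns
components are not trustworthy under this scheme). Weights are
Poisson, σ_j = sqrt(max(count_j, 1)). Initialization takes τ guesses
from the 1/e and 1/e² crossing times, with up to 5 jittered restarts
(seeded) on failure.

Model selection between one and two components is an F-test at
α = 0.05 on the weighted residual sums of squares of the nested fits,
plus a separability guard: two lifetimes closer than a factor of 1.2
collapse to the one-component model, since tail fits cannot resolve
them (a pair like 4.1/5.6 ns is genuinely unfittable without an IRF
and is reported mono-exponential).

Component percentages are **relative amplitudes** 100·aᵢ/Σa. Published
tables rarely state which convention they use; the generator uses the
same convention, so round trips are self-consistent, and an
intensity-fraction mode (aᵢτᵢ/Σaⱼτⱼ) is available and flagged in the
output.

## log P

log₁₀ of the ratio of integrated emission areas of the octanol and
PBS layers, both aliquots diluted into the same solvent before
measurement. The integration range defaults to the full recorded
emission range (the published protocol does not state one) and is
configurable. Replicates are averaged on the log scale — each run
yields its own log P — matching the per-measurement formula; a single
replicate reports no SD rather than zero.

## Dose–response

Fluence (J/cm²) = irradiance (mW/cm²) × time (s) / 1000, reported to
3 significant figures. Viability is anchored exactly at the untreated
(100%) and killed (0%) controls; values outside [0, 100] are kept and
flagged rather than truncated. The 4PL is fit on log₁₀ concentration
with a free Hill slope, initialized at the 50%-crossing of the data.
Concentration 0 never enters the fit; it only defines the untreated
anchor. The default report is the mean ± sample SD of per-experiment
EC50s (each independent experiment fit separately), which is the
standard "mean ± SD of n ≥ 3 experiments" convention; the pooled-fit
alternative reports the asymptotic SE of the EC50 instead and is
flagged as such. An EC50 outside the tested concentration range is
flagged as extrapolated.

## BSA titration classifier

The published response categories are verbal ("partial", "slight"), so
the decision thresholds are declared package defaults, all
configurable: Q-band shift ≥ 3 nm for a bathochromic component;
emission fold ≥ 1.5 together with an aggregation-index drop ≥ 0.5 for
disaggregation (final index ≤ 0.1 upgrades partial to complete);
emission fold ≤ 0.75 with a stable band position for quenching;
precedence disaggregation > shift > quenching > no change. The band
position is tracked as the longest-wavelength retained maximum, which
is robust to the blue-shifted aggregate band dominating early
titration points.

## SAR statistics

Group comparisons are Welch (unequal-variance) t tests on
log₁₀(EC50): panel activities span ~5 orders of magnitude, so raw-scale
tests would be dominated by the least active compounds. No
multiple-testing correction is applied by default (per-panel tests are
reported individually, as is conventional for exploratory SAR panels);
a Holm-adjusted report is available (`holm_adjust`). Any comparison in
which either group has ≤ 2 members carries `small_group_flag`. Two
degenerate identical groups (zero variance, equal means) return
t = 0, p = 1 explicitly rather than the NaN a naive Welch computation
produces.

## Synthetic forward models

The generators emulate: monomeric Q-bands as Gaussians (FWHM 18 nm)
with a 20%-height vibronic shoulder 60 nm to the blue; H-aggregation
as a broad (FWHM 30 nm) band 40 nm to the blue whose weight trades off
against the monomer band, with emission scaled by the monomer fraction
(aggregates treated as dark); mirror-image emission at a ~10 nm Stokes
shift; first-order DPBF bleaching with the sample rate obtained by
inverting the comparative Φ_Δ formula (same 2.3 convention as the
analysis, so the loop closes exactly); TCSPC decays as amplitude-
weighted multi-exponentials with Poisson noise; plates as 4PL
viabilities with additive Gaussian noise in percentage points
(default σ = 5), back-transformed through the control anchors;
partition pairs sharing one band shape so the area ratio is exact;
BSA titrations per category with margins of roughly twice each
classifier threshold (the aggregation-drop margin for *partial*
disaggregation is capped by the index's [0, 1] range and the
requirement that the final index stay above the "complete" boundary,
so that schedule uses a 0.6 drop); and log-normal EC50 panels
(σ = 0.2 dex) with tag-dependent shifts.

They do **not** emulate: vibronic progression beyond a single
shoulder, instrument response functions or detector afterpulsing,
scattering baselines, inner-filter curvature, plate-edge effects, or
compound-specific aggregation equilibria. Passing round-trip tests
therefore demonstrates the correctness and self-consistency of the
estimators under the stated noise models — not robustness to every
artifact of real instrument data.

All generators are deterministic given their configuration (seed
included); identical configurations produce byte-identical outputs.

## Problem sizes and numerical choices

Default sizes keep every analysis interactive: spectra on a 0.5 nm
grid over 300–900 nm (1201 points), TCSPC histograms of 4096 bins
over 50 ns at 10⁴ peak counts, DPBF series of 13 time points over
120 s, plates of 8 half-log concentrations × 3 experiments × 3
replicates. Seeded replicate studies in the test suite use 40–60
decay fits, 50 titrations per category and 500 panel seeds for the
null calibration of the group t test; these sizes give the binomial /
KS checks comfortable power while the whole suite runs in seconds.
Nonlinear fits use `lmfit`/`scipy.optimize.curve_fit` with bounded
parameters; tolerances are library defaults, which on noise-free
inputs recover generating parameters to well below 10⁻⁶ relative.

## Known limitations

* Tail fitting without an IRF biases sub-nanosecond components; the
  short component of a biexponential is recovered less precisely than
  the long one.
* The aggregation-index FWHM proxy is ordinal, not quantitative.
* DPBF absorbance at 415 nm is not corrected for dye absorption
  overlapping the trap band; strongly blue-absorbing dyes would bias
  the bleach slope.
* Rose-Bengal-referenced yields require the user to supply the
  reference yield explicitly — literature values for Φ_Δ(RB) in DMF
  disagree, so no default is shipped for it (the ZnPc defaults,
  Φ_Δ = 0.56 and Φ_F = 0.32, are bundled in `RunConfig`).
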