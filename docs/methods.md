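# Methods

This note documents the models, conventions, parameter defaults and known
limitations behind `nirsox`. Everything quantitative stated here is computed
by the test suite or by `scripts/acceptance.py`; nothing is asserted that the
code does not itself verify.

## Conventions and optical constants

Concentrations are µM, distances cm, extinction coefficients cm⁻¹·µM⁻¹ in
the **base-10 (decadic)** convention, attenuation in optical density
A = −log₁₀(I/I₀). Tissue oxygen saturation is
StO₂ = 100·HbO/(HbO+Hb) %.

The shipped extinction table (`nirsox/data/extinction_gratzer.csv`) carries
the Gratzer/Prahl hemoglobin-spectrum compilation at 730/800/850 nm,
converted to the units above. Loading is versioned through a CSV so a user
can substitute any tabulation; construction validates the spectral shape
(Hb dominant at 730 nm, HbO at 850 nm, 800 nm near-isosbestic) to catch
unit or column mix-ups. Both StO₂ estimators are ratios of sums of log
terms, hence invariant to the logarithm base; base 10 is fixed throughout
and an explicit natural-log path exists for cross-checking.

The differential pathlength factor defaults to 6.0 (a typical adult-forehead
value) and is assumed equal across the three wavelengths; all estimators
accept per-wavelength values. Note the single-separation estimator and the
SRS saturation are DPF-independent under their respective model assumptions;
DPF only scales the modified-Beer–Lambert concentration changes.

## The single-separation estimator

The calibration constants are interpreted as **emitted-intensity ratios**,
k₁ = I₀(λ₁)/I₀(λ₂) and k₂ = I₀(λ₃)/I₀(λ₂). Under this reading each log term
is a pairwise attenuation difference, and for the homogeneous equal-DPF
Beer–Lambert model with wavelength-independent coupling loss the estimator
is *algebraically exact*: the Hb cross-products cancel in the numerator and
numerator/denominator share the common factor, leaving HbO/(HbO+Hb)
identically. This cancellation was verified symbolically (computer algebra)
and is enforced numerically by the acceptance grid (worst error ≤ 1e-6
percentage points over StO₂ ∈ {0,…,100} %, THb ∈ {30, 60, 120} µM, coupling
loss ∈ {0, 1, 3} OD, d ∈ {3, 4} cm). The alternative reading of k as
*detected* baseline ratios would make the formula 0/0 at baseline and was
rejected. The grouping of the typeset third terms is
log(k₂·I(λ₁)/(k₁·I(λ₃))) and its reciprocal — the only grouping under which
the exactness identity holds.

Two calibration routes are provided: `source_spec` (declared emitted
intensities, as carried in the raw-worksheet metadata) and
`baseline_assumed_sto2` (back-solve k from a baseline epoch plus an assumed
baseline chromophore state; with a wrong assumption the estimate acquires a
systematic, monotone offset, asserted qualitatively in tests).

Out-of-range StO₂ values are reported **unclamped** with an
`out_of_physio_range` QC flag; a |denominator| below 1e-12 (configurable)
yields NaN with `denominator_near_zero`, never a fabricated number.

## The SRS comparator

The textbook diffusion-asymptote form: slope of attenuation across the two
separations (ln units/cm), minus the geometric 2/ρ̄ term (ρ̄ = mean
separation, 3.5 cm for the default geometry), squared, over 3μs′(λ), gives a
relative absorption spectrum whose two-chromophore inversion yields StO₂ —
common scales, source power, and shared detector gains cancel. μs′ is
wavelength-independent (10 cm⁻¹) by default; only its spectral shape matters
downstream. A far/near relative-gain constant (default 1.0) is exposed
because a detector gain mismatch biases the slope. Samples with slope
≤ 2/ρ̄ are flagged invalid rather than inverted.

On noiseless diffusion-model tissue the recovery bias is monotone and
bounded by 3 percentage points over 50–80 % StO₂ (−0.7 at 50 % to −2.7 at
80 %); this band was established with the diffusion forward model before the
estimator tests were frozen and is the documented tolerance for SRS
recovery. The proprietary implementations in commercial oximeters are not
public; matching any particular device output is explicitly not a goal.

## Modified Beer–Lambert pipeline

ΔA per wavelength relative to a reference epoch (default: the 5 s preceding
task onset, matching the statistical baseline) is inverted by least squares
over all three wavelengths simultaneously. The reference epoch mean defines
I₀ per channel, so constant channel gains cancel and the output is zero over
the reference epoch by construction. Non-positive samples are flagged and
linearly interpolated only across gaps ≤ 0.1 s; longer gaps propagate NaN.

Under the diffusion forward model the effective pathlength is
wavelength-dependent and larger than DPF·d, so MBLL with a fixed DPF
rescales and mixes the true concentration changes (visible in the group
example: recovered ΔHbO peak ≈ 0.13 µM for a generated 0.021 µM when the
co-occurring Hb decrease is large). The pipeline's statistics operate on
baseline-subtracted window means, which are insensitive to static bias but
not to this rescaling; absolute concentration fidelity on real tissue is a
known limitation of single-DPF MBLL, not of this implementation.

## Synthetic data generator

The generator emulates a wearable two-separation, three-wavelength probe at
120 Hz with per-recording ground truth (true concentrations, saturation,
all generating parameters, seed — sufficient to recompute every intermediate
quantity).

**Forward modes.** `mbll-exact` (I = I₀·10^(−DPF·d·μa−G)) is the mode on
which the single-separation estimator is provably exact — the unit-test
mode; `diffusion` is the physically realistic mode: steady-state reflectance
of a semi-infinite homogeneous medium, extrapolated-boundary two-dipole
solution with the Groenhuis internal-reflection parameter (n = 1.4), checked
against an independent finite-difference flux computation to ≤1e-6 relative.
SRS is only meaningful on the diffusion mode (the exact mode has no ρ²
geometric decay, so the SRS slope falls below its validity bound there).

**Breath-hold response.** A shape-preserving monotone cubic (PCHIP) passes
through zero up to onset, the dip, the peak, and exponential-decay knots
(τ = 18 s) back toward baseline. PCHIP was chosen over a two-gamma-kernel
difference because the kernels' cross-talk displaces the extrema by several
seconds at the canonical amplitudes, whereas the analysis contracts require
the dip and peak to sit exactly at their configured times; with PCHIP they
are knots with zero slope and monotone flanks on both sides. Canonical
timing: dip 10 s and peak 27.5 s after onset. Canonical amplitudes are the
group-mean magnitudes of the study conditions the generator emulates:
ΔHbO −0.002/+0.021 µM; ΔStO₂ −0.04/+1.22 % (single-separation scale, the
default) or −0.10/+0.48 % (SRS scale, via `canonical_srs_scale()`). The HbO
trajectory follows ΔHbO directly and Hb is solved so saturation follows
ΔStO₂ — both curves are honored simultaneously, with THb absorbing the
difference. These amplitudes conflate inter-subject variability into a group
mean; the generator is a calibrated stand-in, not a claim of fidelity to any
individual physiology.

**Noise.** Cardiac (1.1 Hz, 0.02 µM), respiratory (0.25 Hz, 0.01 µM) and
Mayer-wave (0.1 Hz, 0.01 µM) oscillations act on HbO concentration — where
they physically arise — with random phases; white noise (0.1 % relative per
sample) and slow linear drift (0.05 %/min sd) act multiplicatively on
detected intensities; oscillation amplitudes are scaled to the scenario's
signal magnitude so single trials are visibly noisy while group means are
clean, the SNR regime the pipeline is designed for. Motion spikes (default
**off**; group statistics model screened, good-SNR recordings) share event
times across the 4 cm channels with per-wavelength amplitude jitter — a
perfectly wavelength-common transient would cancel in the intensity ratios
and never reach StO₂, contradicting the observed artifact sharing. Holds
longer than 60 s additionally receive low-frequency saturation fluctuation
(0.3 % sd, ~1 s correlation) during the hold.

**Cohort.** 19 subjects, 3 holds each except 2 for the last (56 trials).
Between-subject spread: baseline StO₂ sd 3 %, THb sd 8 µM, lognormal
amplitude factor (sd 0.3); hold durations from a truncated lognormal
calibrated at runtime so the truncated mean/sd are 41.4/22.4 s on
[17.5, 120] s (verified by Monte Carlo to within 1 s over 10⁴ draws).
Identical seeds produce bit-identical worksheets.

## Statistical pipeline

Half-open 5-s windows over −5…45 s (ten windows; half-open to avoid
double-counting boundary samples), QC-flagged samples excluded from means,
baseline window subtracted (hence exactly zero). Trials — not subjects — are
the pooled observations. The ANOVA treats the ten windows as independent
groups with no repeated-measures correction, which matches the field
convention for this task and is flagged in the report notes; post hoc
one-sample t-tests cover post-onset windows only (the baseline window has
zero variance by construction) and are uncorrected by default, with
Bonferroni/FDR options. Correlations default to the group-mean window series
(10 points per signal); a pooled per-trial mode is exposed because either
reading of "correlations among responses" is defensible. ANOVA, t-tests and
correlations delegate to scipy.stats behind this module's validation layer;
tests verify them against explicit sums-of-squares and closed-form values to
1e-10. The SNR screen (channel mean over detrended high-frequency residual
sd, threshold 20) is a stated, configurable stand-in — no standard criterion
exists for these devices.

At the canonical noise and variability defaults, the initial dip is the
smallest feature in the pipeline (group-mean ≈ −0.05 % StO₂ against a
group-mean noise SE ≈ 0.02 %, dominated by long-hold fluctuations): a
simulated cohort localizes the dip in the 5–10 s window with roughly 2σ
margin over the adjacent 0–5 s window, so occasional cohorts place it one
window early. The peak (≈ 25× larger) and the ANOVA significance are robust
far beyond seed choice.

## Numerical choices

Least-squares inversions go through the pseudoinverse with a condition
number ceiling (1e8) on the extinction matrix; rank-deficient systems raise
a dedicated error rather than returning garbage. The SSDS denominator
tolerance is 1e-12 in log-OD·extinction units. Degenerate inputs (zero
within-group variance, zero-variance correlations, empty windows, empty
files) raise validation errors naming the offending quantity.

## Known limitations

Homogeneous semi-infinite tissue only: no scalp/skull layering, no partial
pathlength correction, no short-channel regression, and no motion-artifact
*correction* (spikes are flagged or excluded, not repaired). The generator
has no systemic physiology model (CO₂ dynamics, blood pressure); response
timing does not adapt to hold duration. Passing tests demonstrate
correctness of the algorithms on their stated forward models, and robustness
of the pipeline under the documented synthetic noise — not fidelity to any
particular commercial device's proprietary processing or to human
inter-subject variability.
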