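# Methods

## Sequence model

A GraSE multi-echo acquisition excites once per RR interval and plays a
train of refocusing pulses spaced ΔTE apart; every spin echo is read out
with an EPI train of `epi_factor` phase-encode lines and reconstructed
as a separate image at its effective echo time. Echo times are
`TE_k = first_te + (k−1)·ΔTE`; with one start-up echo (acquired, never
imaged) `first_te = 2·ΔTE`. The shot count per slice is
`ceil(matrix_phase / (sense_factor · epi_factor))` imaging heartbeats
plus the dummy TRs (default 1), which fixes the breath-hold at a given
RR interval. Shot duration is defined as `(n_echoes + n_startup)·ΔTE`,
the span of the refocusing train per excitation.

The dual-inversion black-blood delay uses the cyclic-steady-state null:
with one inversion per RR, inverted blood magnetization crosses zero at
`TI = T1·ln(2 / (1 + exp(−RR/T1)))`, with blood T1 = 1200 ms at 1.5 T by
default. This closed form is the standard dual-IR prescription; it tends
to `T1·ln 2` for long RR and is monotone increasing in RR.

## Echo-train simulation

The extended-phase-graph (EPG) recursion tracks configuration states
`F(k)`, `Z(k)` through the pulse train: each half-interval applies
relaxation (`E2` transverse, `E1` longitudinal with regrowth on `Z(0)`)
and one unit of gradient dephasing; each refocusing pulse applies the
standard three-state rotation mixing `F(+k)`, `F(−k)*` and `Z(k)`.
Excitation is an ideal 90° with the CPMG phase condition (refocusing
axis along the excited magnetization); crushers are assumed perfectly
balanced. States are truncated at order `n_pulses + 2`, which no pathway
can reach, so truncation is exact. The echo amplitude is `|F(0)|` at the
midpoint between pulses. At 180° the recursion reduces to
`exp(−TE_k/T2)` for any T1; for arbitrary constant flip angles it is
validated in the tests against an independent isochromat (Bloch
rotation-matrix) simulation on a uniform 500-spin dephasing grid, which
annihilates all nonzero Fourier orders exactly and therefore must agree
to numerical precision.

Slice-profile effects enter as a weighted sum of per-position EPG trains
over a `RefocusingProfile` (flip angle + quadrature weight per sub-slice
position, 33 positions). Actual vendor pulse shapes are unpublished, so
the two non-ideal profiles are synthetic stand-ins chosen once for their
qualitative behaviour:

- `slr_optimized`: near-rectangular, >95% of quadrature weight between
  170° and 180° (flip `60 + 120·exp(−(x/0.95)^12)` with cos²-shaped
  excitation weights). Emulates optimized Shinnar–Le-Roux-type
  refocusing.
- `suboptimal`: Gaussian flip distribution peaking at 180° with wings
  near 60° (`60 + 120·exp(−x²/(2·0.4²))`, uniform weights).

These reproduce the expected ordering — fitted T2(suboptimal) ≥ fitted
T2(slr_optimized) ≥ true T2, severe overestimation without a start-up
echo, near-exact recovery with the optimized profile — but only the
directions, not the magnitudes, should be read as quantitative.

EPI readout T2\* weighting is modelled as a centre-profile attenuation:
per-echo offsets attenuate each image by `exp(−|t_k|/T2*)`; a shared
readout yields one effective factor for the whole train. With an
identical readout per echo the factor is constant, so a mono-exponential
fit changes only in S0 — producing an actual T2 underestimation requires
echo-varying centre-profile timing, which is why the shared-readout
property is stated as "never raises" rather than "lowers" the fitted T2.

## Noise model and estimation

Root-sum-of-squares combination of L coil channels with per-channel
Gaussian noise σ gives the noncentral-chi magnitude density
`f(m|a,σ,L) = m^L/(σ²a^(L−1)) · exp(−(m²+a²)/(2σ²)) · I_{L−1}(ma/σ²)`
(Rician at L = 1, central chi at a = 0). Log-densities are evaluated
with exponentially scaled Bessel functions; beyond Bessel argument 1e8
(where `scipy.special.ive` fails) the large-argument asymptotic
`log I_ν(z) ≈ z − ½log(2πz) + log1p(−(4ν²−1)/(8z))` is used, accurate
there to < 1e-7. σ is estimated from a signal-free background region via
the second moment `E[m²] = 2Lσ²` (≥ 50 samples required). The effective
channel count L is a user parameter (default 1): real phased-array noise
is spatially varying and g-factor-modulated, which is not modelled.

The per-pixel estimator maximizes the joint log-likelihood over
(S0, T2), T2 bounded in [1, 1000] ms, initialized from an unweighted
log-linear fit with magnitudes floored at σ/2 and refined by bounded
L-BFGS-B. The optimizer never returns a point worse than its
initializer; an all-zero series is flagged non-converged (T2 = 0) rather
than raised, and map-level fitting falls back to nonlinear least squares
on failures so maps stay complete. Least-squares baselines ("log" and
"nonlinear") are kept because their noise-floor bias at low SNR is the
motivation for ML fitting; Monte-Carlo tests verify both the bias
direction (LSQ above MLE) and the MLE bias bound (< 2% at first-echo
SNR ≥ 20 for T2 = 52 ms).

SNR is defined throughout as first-echo signal over σ:
`snr = S0·exp(−TE₁/T2_ref)/σ` with `T2_ref = median(T2)` of the phantom
compartments. ML fits agree with an exhaustive (0.25 ms, 0.25 unit) grid
search to within one grid cell in the tests.

## Phantoms

The tube phantom places six discs (2×3 grid, radius scaled to the
matrix) on the protocol's acquisition matrix (176×168 by default) with
T2 = {40, 50, 55, 60, 80, 120} ms and T1 = 10×T2, emulating MnCl₂-doped
water at 1.5 T. The T2 set is a documented stand-in spanning the
myocardium-relevant range (healthy ≈ 52 ms through acute edema
≈ 80–90 ms). The cardiac phantom is an annulus (endo/epi radii 9.5% and
18% of the matrix) with per-AHA-segment T2, zero-amplitude blood pool
(black blood) and no fat signal; myocardial T1 is 1000 ms. Ground truth
(label, T2 and S0 maps, 64-gon contours, RV insertion at display angle
150°) is returned alongside the noisy stack. Echo trains come from the
slice-profile EPG model; noise is drawn per pixel from the same
noncentral-chi law the likelihood assumes (verified by a KS test), with
a mandatory seed for bit-reproducibility.

What the phantoms do not emulate: motion and misregistration between
echoes, partial-volume mixing beyond pixelation, spatially varying coil
sensitivity and noise, B0/B1 inhomogeneity, flow. Passing recovery tests
therefore demonstrates correctness of the estimator chain under the
stated noise model, not robustness to in-vivo confounders.

## Segmental analysis

Myocardial pixels are those whose centre (0-based integer coordinates)
lies inside the epicardial and outside the endocardial polygon
(matplotlib point-in-polygon). Angles are measured about the centroid of
the endocardial contour, counterclockwise in a standard short-axis
display (anterior up, septum image-left), starting at the ray through
the anterior RV insertion and proceeding through the septum. Basal and
mid slices use six 60° sectors ordered anterior, anteroseptal,
inferoseptal, inferior, inferolateral, anterolateral; apical slices use
four 90° sectors (anterior, septal, inferior, lateral) with the septal
sector centred 120° past the RV ray (the mid-septum). Boundary pixels
belong to the sector that starts at the boundary (lower AHA index wins).
The apical cap (segment 17) is not used.

Global T2 is reported under two rules: the primary rule is the
unweighted mean of segment means with the population SD (÷n) of segment
means — the convention that reproduces the worked example exactly — and
a pixel-weighted mean/SD over all valid myocardial pixels is kept
alongside, since "global" is ambiguous when segments differ in size.
Empty segments are excluded and flagged.

## Agreement statistics

Bland–Altman limits of agreement use the 1.96 multiplier on the sample
SD (n−1) of paired differences, the standard convention. Pearson R is
flagged undefined (None) for zero-variance input while the limits are
still returned. The synthetic inter-study experiment images each
subject's cardiac phantom twice with independent noise seeds, runs the
full generate → fit → report pipeline per visit and feeds the global-T2
pairs to the Bland–Altman analysis; subject-level pairing is the
default, segmental pairing is available by reporting per-segment means.

## Problem sizes and numerical choices

The shipped tests and the acceptance script use the full 176×168
acquisition matrix for the tube phantom (~2800 fitted pixels, about half
a minute), 72–96 px matrices for cardiac pipeline tests, 500 replicates
for bias Monte-Carlo, and 500-spin isochromat oracles for ≤12-pulse EPG
checks — sizes chosen so the whole suite runs in a few minutes while
keeping Monte-Carlo error well below the tested tolerances. The CPMG
reference is simulated with ideal 180° refocusing, 32 echoes at
ΔTE = 10 ms (a documented stand-in for unpublished reference-sequence
parameters) and fitted by nonlinear least squares on a tube-ROI-averaged
series. T2 values are clipped to [1, 1000] ms; 0 marks non-fitted
pixels; all of this is recorded in output metadata.

## Known limitations

- Refocusing profiles and CPMG parameters are qualitative stand-ins.
- The EPI/T2\* model has no echo-structure detail beyond centre-profile
  attenuation; no off-resonance, flow or motion simulation.
- A single effective σ and L per image; no spatially varying noise maps.
- The estimator reproduces the definition of on-scanner ML map
  generation, not any vendor's exact optimizer.
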