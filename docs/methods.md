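# Methods

## Physical model

A chromophore embedded in a matrix has its (0,0) electronic transition at
`nu0 = nu_vac + nu_s`, where `nu_vac` is the vacuum frequency and `nu_s`
the matrix ("solvent") shift. In the linear elastic picture a hydrostatic
pressure `p` compresses the matrix uniformly and the line moves as
`nu_p = nu0 + 2 (nu0 - nu_vac) kappa p`, with `kappa` the isothermal
compressibility. Applied to a normal distribution of (0,0) energies (the
inhomogeneous distribution function, IDF) this gives a linear center shift
`nu00(p) = nu00 + 2 kappa p nu0s` and a linear broadening
`sigma(p) = (1 + 2 kappa p) sigma0`. No higher-order pressure terms are
used. The code never assumes a sign for `nu0s`; in the hemoglobin fixtures
it is negative (the matrix red-shifts the transition), so pressure shifts
the IDF to lower wavenumbers while broadening it.

`kappa` connects to equilibrium volume fluctuations through
`<(V - <V>)^2> = kappa kB T <V>` (computed in `volume_fluctuation_variance`;
all spectroscopic quantities are in cm^-1 / GPa, SI conversion happens only
inside this one function). For a monomer-sized volume of 2.1e4 A^3 at 300 K
and kappa = 0.17/GPa the rms volume fluctuation is about 1.2e2 A^3.

The vacuum frequency of the chromophore inside the protein is not
measurable and is never hard-coded: it enters only as a configuration or
fit parameter. The width-based kappa estimator needs no `nu_vac` at all,
which is why it is primary (below).

## Generative model (simulator)

Excitation at `nu_exc` through vibronic level m selects molecules with
(0,0) energy `nu_exc - dnu_m`; the resonant emission line sits at that
position with peak amplitude `gain * B_m * n'_p(nu_exc - dnu_m) *
laser_width`, where `n'_p` is the pressure-transformed IDF density and
`B_m` the relative absorption strength of the mode. Lines are Gaussian
with the instrumental width (0.5 cm^-1) and the 0.7 cm^-1 FWHM laser
width added in quadrature. Vibrational energies and strengths are treated
as pressure independent.

Defaults emulate the measurement conditions of the hemoglobin study:

| parameter | default | why |
| --- | --- | --- |
| detection window | 16700-17200 cm^-1 | CCD range of the spectrograph |
| grid step | 0.5 cm^-1 | instrument resolution better than 1 cm^-1 |
| pressures | 8 points, 0-1.2 GPa | measured series range (cell limit 1.5 GPa) |
| excitations | 25 points, 17550-18100 cm^-1 | see below |
| IDF | N(17000, 60) cm^-1 | strongest line positions at low pressure |
| `nu0s` | -200 cm^-1 | window-consistency bound, see below |
| vibronic modes | 973 (B=1.0); 750, 1130, 1220, 1375 cm^-1 | 973 cm^-1 is the attested dominant mode of Zn-protoporphyrin in this system; the others are synthetic defaults with typical porphyrin skeletal energies, present so multi-mode pooling is exercised |
| background | Gaussian (0.25 x max line, center 16950, width 200) + 0.05 offset | simplest broad non-resonant background the baseline stage must defeat |
| noise | Gaussian, SD = 5% of the largest p=0 line amplitude | constant detector noise floor for the whole experiment |

Two defaults deserve justification. The excitation grid is wider than the
range used to trace one line at a single low pressure, because a fixed
grid must keep the strongest mode's emission sweeping the whole detection
window while pressure moves the IDF; 25 points over 550 cm^-1 samples the
IDF every ~23 cm^-1 through every mode. The solvent-shift default is
bounded by an observable consistency argument: the measured IDF center
stayed inside the fixed CCD window across the entire 0-1.2 GPa series even
for the most compressible condition (kappa ~ 0.36/GPa), and since the
total center shift is `2 kappa p_max |nu0s|`, that caps `|nu0s|` at
roughly 230 cm^-1. We use -200 cm^-1. (Closed-form unit checks that
specify a different `nu0s` are run with exactly that value; they are
independent of this default.)

Noise streams are per-(pressure, excitation) children of one seed
(`SeedSequence` spawn keys), so experiments are reproducible and spectra
statistically independent.

What the generator does **not** emulate: phonon side bands, vibronic
progressions of the excited state, photon-counting (Poisson) statistics,
wavenumber-calibration drift, pressure-cell artifacts, or non-Gaussian
(multi-site) IDFs. Passing tests therefore demonstrate correctness of the
evaluation chain under the stated model, not robustness to every artifact
of real spectra.

## Spectral evaluation

Per pressure:

1. **Baseline.** Asymmetric least squares locates the sharp peaks; a
   second, peak-masked symmetric Whittaker smoothing pass then tracks the
   *mean* background instead of the lower noise envelope, so the corrected
   spectrum is offset free (an offset would bias every amplitude and the
   fitted widths). Smoothness `lam = 1e6` in grid-index units puts the
   smoothing length near 16 cm^-1: far above the ~1 cm^-1 lines, far
   below the ~200 cm^-1 background.
2. **Line detection.** Local maxima above 4x a robust (MAD-of-differences)
   noise SD with 3x prominence, refined by a Gaussian-plus-offset fit over
   a +/-3-width window; fits narrower than 0.25 cm^-1 or broader than
   6 cm^-1 are rejected as noise spikes or background remnants, as are
   peaks within 5 cm^-1 of the window edge.
3. **Vibronic assignment.** A peak's vibrational energy is
   `nu_exc - center`; it joins the nearest table mode within 3 cm^-1
   (laser width plus resolution with headroom), ties toward the lower
   energy.
4. **Amplitude tracking.** Detection alone cannot follow a line into the
   IDF tails, and keeping only detections biases the faint end of a trace
   upward (a near-threshold line is seen only when noise pushes it up).
   So each established mode's vibrational energy and line width are fixed
   to the medians over its detections, and the amplitude at the predicted
   position is then read from *every* spectrum by a linear least-squares
   fit of a fixed-shape Gaussian plus constant. Negative readings are kept:
   they are what makes the tail statistics unbiased.
5. **Normalization and pooling.** Each mode's (position, amplitude) trace
   samples the same IDF up to the factor `B_m`. When a trace spans
   essentially the whole distribution, dividing by its trapezoid area
   removes that factor (this literal inverse-area weighting is available
   as `weighting="area"`, and the area-weighted trace integrates to one
   by construction). With a fixed detection window and realistic pressure
   shifts, however, different modes see different *partial* slices of the
   IDF, and inverse-area weighting then scales a tail-only trace wildly.
   The default `weighting="prefit"` therefore divides each trace by the
   amplitude of its own Gaussian prefit — identical to area weighting in
   the full-coverage limit, consistent under truncation. The prefit also
   sigma-clips stray points (outliers that survived assignment by
   coincidence) at 4 robust scales.
6. **Pooled IDF fit.** One Gaussian is fit to the union of normalized
   traces. Because the detector noise floor is constant in raw units, a
   point's uncertainty after normalization is proportional to the inverse
   of its trace scale; the fit weights points accordingly (inverse
   variance). The unweighted fit remains available
   (`weighted_idf_fit=False`). Initialization is deterministic: weighted
   moments and a log-quadratic fit (exact on noiseless Gaussian samples
   and the only stable start on truncated tails); the lower-SSR solution
   wins. A fit whose samples do not flank the fitted center by at least
   0.6 sigma on both sides is rejected — a width estimated from a
   one-sided slice is not trustworthy — and that pressure is skipped
   rather than contaminating the regression.

On noiseless, background-free simulations this chain reproduces the
closed-form IDF transform to machine-level accuracy (the acceptance test
requires kappa to four decimals), which pins down that every stage is
exact rather than merely approximate.

## Compressibility inference

The IDF estimates are regressed against pressure with straight lines,
weighted by the inverse squared standard errors when available (plain
least squares otherwise, and automatically when errors are degenerate).
`kappa_width = slope / (2 x intercept)` of the width trend is the primary
estimator: it requires no knowledge of `nu_vac`. The center trend yields
the solvent-shift estimate `nu0s_est = slope_c / (2 kappa_width)`; when an
independent `nu0s` is supplied, it instead yields a second estimator
`kappa_center = slope_c / (2 nu0s)` and the combined value is their
inverse-variance mean (their correlation through the shared spectra is
neglected; on noiseless data the two agree to six digits).

Reported uncertainty: delta-method propagation of the weighted-fit
slope/intercept covariance (scale never below chi2/dof), multiplied by the
small-sample t quantile (68.3%, df = n_pressures - 2), and floored by a
leave-one-pressure-out jackknife SD. The plain delta-method SE was found
against simulation to be anti-conservative — it cannot see
between-pressure systematics of the spectral evaluation — and the
calibration of this convention is itself measured by the acceptance
sweep's coverage check. Propagating the ~0.02 GPa pressure-calibration
accuracy was examined and contributes negligibly (< 0.005/GPa); it is not
included.

Condition comparison is by pairwise z statistics with two-sided normal
p-values, reported raw — with ~15 pairs per survey a multiple-testing
correction would be appropriate before making claims about any single
pair, and the outputs say so. The effector-strength correlation (Pearson r
between the effector-induced kappa decrease and user-supplied strength
scores) is computed only when scores are supplied; no strength scale is
bundled. Unit-height Gaussian summary curves (center kappa, width SD) are
exported for plotting.

## Interaction radius

With a pairwise `r^-n` interaction (n = 6 for dispersion-type forces)
integrated over a homogeneous isotropic shell from the effective
chromophore radius `R0 = (3 V0 / 4 pi)^(1/3)` outward, the fraction of the
total shift arising beyond radius R is `(R/R0)^-(n-3)`; inverting,
`R_(1-P) = R0 * P^(-1/(n-3))`. The implementation is generalized to any
n > 3 (the shell integral of `r^(2-n)` diverges otherwise); a quadrature
oracle in the tests verifies the closed form. Radii are reported at one
decimal (R0) or the nearest angstrom, with full precision retained.

## Problem sizes and determinism

The stochastic acceptance checks use the study-scale experiment (8
pressures x 25 excitations, ~1000 grid points per spectrum) with 20 seeded
replicates per grid point of the kappa sweep and 50 paired replicates for
the subunit-asymmetry check; one full simulate-and-evaluate cycle takes
well under a second, and the entire suite a few minutes. All randomness is
seeded; reruns are bit-reproducible.

## Known limitations

- The two-stage procedure (per-pressure Gaussian, then straight lines) is
  the classical evaluation; a global fit tying all pressures together
  would extract more information from window-truncated high-pressure data
  but is deliberately out of scope.
- Only Gaussian line shapes and single-Gaussian IDFs are supported;
  multi-site distributions and Voigt profiles are not.
- The closed effector vocabulary (none, Cl, IHP, IHP+Cl, BZF, BZF+Cl)
  keeps results tables joinable; free-form labels are rejected.
- High pressures whose IDF center leaves the detection window are skipped
  by design; with large `|nu0s|` this can reduce an eight-pressure series
  to the minimum of three usable pressures.
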