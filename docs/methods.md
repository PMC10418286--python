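# Methods

`specklesim` predicts what a pixel-array camera measures when it images
dynamic, diffuse laser speckle — the signal underlying speckle contrast
optical spectroscopy and tomography (SCOS/SCOT) blood-flow instruments —
so that accuracy, precision and SNR of the squared speckle contrast
(kappa^2) can be studied before hardware is built. This note records the
model, the numerical choices, and what the simulator does and does not
capture.

## Model overview

The pipeline has six stages, each a separate module:

1. **Semi-infinite correlation diffusion theory** (`theory`). The
   normalized electric-field autocorrelation of diffuse speckle at
   source-detector separation rho is the two-term Green's function of the
   correlation diffusion equation,

       g1(rho, tau) = [exp(-K(tau) r1)/r1 - exp(-K(tau) rb)/rb] /
                      [exp(-K(0) r1)/r1 - exp(-K(0) rb)/rb],
       K(tau)^2 = 3 mu_a mu_s' + 6 mu_s'^2 k0^2 alphaDb tau,

   with a real isotropic source at depth ltr = 1/(mu_a + mu_s') and an
   image source behind the extrapolated boundary at
   zb = 2 ltr (1 + Reff)/(3 (1 - Reff)); Reff comes from the standard
   polynomial in the refractive index. The decorrelation time tau_c is
   defined throughout as the lag where g1 = 0.5 (not the more common 1/e
   point), found by Brent root bracketing to |g1 - 0.5| < 1e-9. The
   detected photon rate Phi(rho) uses the matching steady-state fluence
   with attenuation mu_eff = sqrt(3 mu_a (mu_a + mu_s')), multiplied by
   the pixel area and divided by the photon energy hc/lambda. The
   theoretical contrast is the exposure integral
   kappa^2(T) = (2 beta / T) Int_0^T (1 - tau/T) g1(tau)^2 dtau,
   evaluated by adaptive quadrature (relative tolerance 1e-10).
   The g1 provider is pluggable (`kappa2_from_g1` accepts any decay);
   only the semi-infinite solution is implemented.

2. **Copula speckle generator** (`copula`). Frames of speckle are
   simulated so that the field autocorrelation between frame 1 and frame
   k follows

       g1_bar(k) = exp{-((2 pi m)^2 / 6) [1 - cos((pi/2)(k-1)/(f_N-1))]},

   with m fixed by inverting this law at the frame index of tau_c so
   that g1_bar(tau_c) = 0.5 exactly. Internally each object-plane pixel
   is a circular-complex-Gaussian process over the frame index with the
   stationary covariance C(dk) = exp(-sigma^2 [1 - cos(omega dk)]),
   sigma = 2 pi m / sqrt(6), omega = (pi/2)/(f_N - 1) — the stationary
   extension of the frame-1 law. C is periodic with period 4(f_N - 1)
   and positive definite on that ring, so frames are drawn exactly by
   circulant spectral synthesis (FFT eigenvalues of C, independent
   Gaussian mode fields, FFT mixing along the frame axis); when the
   covariance support is much shorter than the stack, a just-long-enough
   embedding ring is used instead of the full period (wrapped lags carry
   covariance below 1e-16). Imaging is a circular Fourier-plane pupil
   whose diameter sets the speckle size to Ø pixels. This construction
   guarantees three contractual properties: every frame is exactly fully
   developed speckle (unit contrast for beta = 1); the spatial
   autocorrelation width is ~Ø; and the frame-1 correlation equals
   g1_bar(k) with pair correlations stationary in lag, so integrating an
   exposure keeps decorrelating at the proper rate through the whole
   stack. Partial coherence beta < 1 is emulated by averaging ~1/beta
   independent speckle intensity patterns per frame; when 1/beta is not
   an integer the last pattern enters with the fractional weight solving
   (n-1+w^2) = beta (n-1+w)^2, which reproduces kappa^2(T->0) = beta
   exactly in expectation.

3. **Photometry** (`photometry`). Copula units are rescaled so the grand
   mean equals Phi (photons/s); N = T/t_frame consecutive rate-frames are
   summed and multiplied by t_frame to give photons per exposure (so the
   mean photon count is Phi*T — the bin width must enter or absolute
   shot-noise levels would depend on an arbitrary discretization); and
   photons become mean photo-electrons via the quantum efficiency. All
   three steps are linear, so kappa^2 is invariant under them.

4. **Detector noise** (`noise`). Photon shot noise replaces each pixel
   with a Poisson draw of its mean electron count. Dark frames are
   synthesized independently: per-pixel logistic dark-signal means
   (DSNU; shape parameter sqrt(3 var)/pi, negatives clamped to zero
   before serving as Poisson means), Poisson dark shot noise about those
   means, and T-independent normal read-out noise (signed; real cameras
   report it about an offset). A dark frame is dark shot + read-out, and
   the noisy frame is the shot-noised signal plus one independent dark
   frame per exposure. Three camera presets carry specification-sheet
   values: `orca_fusion` (DSNU per exposure; QE folded into the measured
   electron rate), `orca_flash` (DSNU specified as a rate in e-/s,
   multiplied by T), and `basler_daA1920` (DSNU per exposure). Gain is
   1 e-/DN and quantization is not modeled.

5. **Contrast estimation and correction** (`contrast`). Spatial kappa^2
   is var/mean^2 over a pixel window per experiment; temporal kappa^2 is
   the per-pixel ratio over repeated experiments. Population variance
   (divide by the count) is used in both windows. The correction first
   subtracts a *fresh* dark-frame realization (subtracting the very
   frame that was added is rejected as a contract violation — no real
   calibration can do it), then removes the shot variance (estimated by
   the window mean, the Poisson property) and the dark-frame variance
   (window variance of the correction frame):
   kappa^2_corr = (var_signal - mean - var_df) / mean^2. Corrections are
   only applied for noise stages actually present; negative corrected
   values at very low signal are kept (not clipped) so averages stay
   unbiased, and flagged. Note the corrected frame contains *two*
   dark-frame variance contributions (added + subtracted) while the
   correction removes one; the residual +var_df is a property of this
   correction scheme and is what ultimately limits accuracy at low count
   rates (see the count-rate study below).

6. **Model bias and metrics.** Because the copula decay law is a single
   stationary family while the semi-infinite g1 is a double exponential,
   simulated kappa^2 differs from the theoretical value by a model bias.
   The bias gamma = mean(noise-free kappa^2) - mean(noisy kappa^2) over
   experiments transfers the simulated noise offset onto the theoretical
   kappa^2: model-corrected values are normal draws with mean
   kappa^2_hat + gamma and the simulated inter-experiment variance
   (500 draws by default). The printed sign convention is the default; a
   `bias-added` switch (kappa^2_hat - gamma) is provided because the
   opposite convention is also defensible. Accuracy is the percent error
   against kappa^2_hat, precision the coefficient of variation over
   experiments, SNR its reciprocal.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| mu_a, mu_s' | 1/cm | 0.1, 10 | tissue-mimicking optical properties |
| n | — | 1.33 | aqueous tissue refractive index |
| alphaDb | cm^2/s | 1e-8 | typical tissue blood-flow index |
| lambda | nm | 785 | common near-infrared source |
| Ø | px | 3 | Nyquist sampling of the speckle (>= 2 enforced) |
| beta | — | 0.5 | unpolarized detection; T->0 limit of kappa^2 |
| t_frame | s | tau_c/10 | resolves the g1 decay; the generator must sample several frames per tau_c |
| epsilon_N | — | 100 | experiments per condition for variance estimates |
| n_draws | — | 500 | model-corrected kappa^2 sample size |

`t_frame` is the one resolution knob with no physical counterpart: it
sets how finely the decay is sampled. Ten frames per tau_c keeps the
discretization error of the exposure integral well below the
inter-experiment noise; the count-rate design study uses the same value.

## Problem sizes used by the test suite and the acceptance script

Statistical tests run on 64–100 px square grids with 40–120 repeated
experiments — enough that 2–3-sigma assertions are stable at fixed
seeds. The count-rate design study reproduces its full stated
conditions: tau_c = 14.6 us, T = 5 ms (3425 frames of tau_c/10), 5-px
speckles, beta = 0.2 (five averaged patterns), a 33x33 = 1089-px ROI
(~44 independent speckles), 100 experiments, and 16 log-spaced detected
count rates from 1e3 to 1e6 e-/pixel/s. Because the photometric chain
is linear, each experiment's exposure-integrated copula pattern is
computed once and rescaled per count rate before the stochastic
detector stages — exactly equivalent to rerunning the chain per rate.

## What the generator emulates — and does not

The generator reproduces the *statistics* a camera sees: negative-
exponential intensity, a prescribed speckle size, a prescribed field
decorrelation law, and partial coherence. It does not model photon
transport explicitly (no Monte Carlo), does not preserve spatial
correlation between consecutive frames (a known property of copula-type
generators; spatio-temporal speckle maps are out of scope), and the
decay within one stack follows the single stationary copula family
rather than the semi-infinite double exponential — the model-bias
correction exists precisely to bridge that gap. Passing tests therefore
show the detection/noise/correction chain behaves correctly for
speckle with the right second-order statistics; they do not validate a
particular light-transport model against real tissue. Quantization,
pixel fill factor, vignetting, saturation, hot pixels and rolling
shutter are not modeled. Only the semi-infinite homogeneous geometry is
implemented; layered or heterogeneous media would enter as alternative
g1 providers.

## Numerical choices and degenerate inputs

- tau_c root finding: Brent on [1e-12, 10] s; g1 monotone, so the
  bracket is safe; a non-bracketing configuration raises.
- Exposure quadrature: `scipy.integrate.quad`, relative 1e-10; a
  non-convergent integral raises rather than returning a stale value.
- Exposure times snap to integer multiples of t_frame (recorded in the
  output), so photon bookkeeping is exact.
- Circulant eigenvalues are clipped at zero (they are analytically
  nonnegative on the full ring; the shortened embedding can produce
  roundoff-scale negatives) and modes below 1e-14 of the maximum are
  skipped.
- Zero-mean windows, single-frame correlation requests, out-of-range
  QE/beta/speckle sizes and reversed unit ordering all raise typed
  `ParameterError`s; grids holding fewer than ~25 speckles warn.
- Every stochastic stage derives its seed from the master seed plus
  (sweep index, exposure index, experiment index, stage id) via
  `numpy.random.SeedSequence`, so identical configs give byte-identical
  CSV output.

## Known limitations

- Absolute Phi(rho) depends on the source term S (W/cm^3), which users
  must supply; relative behavior in rho and T is what the tests pin
  down. Measured electron rates can be supplied directly instead.
- The noise-corrected kappa^2 keeps a +var(dark frame) residual by
  construction of the correction scheme; for cameras whose specified
  dark signal is large (e.g. the `basler_daA1920` preset at 130.9 e-),
  this residual — with the dark signal modeled as Poisson — dominates
  the low-count error budget and pushes the 5%-accuracy count rate
  well above the shot-noise-only expectation.
- The DSNU clamp (negatives to zero before Poisson) biases the realized
  mean dark current upward when the specified DSNU variance is much
  larger than its mean, as for the `orca_flash` preset; the rate model
  itself (mean = rate x T) is exact.
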