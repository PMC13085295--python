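# Methods

This note documents the models, the synthetic data they are exercised on,
the numerical choices, and the limits of what the test suite demonstrates.

## Problem setting

Four analytes — bupropion (BUP), dextromethorphan (DEX) and their process
impurities 3-chlorobenzoic acid (CBA) and N,N-dimethylaniline (DMA) —
absorb in the same UV region, so their mixture spectrum is a bilinear
Beer-Lambert superposition `D = C S^T + E`: rows of `D` are mixture
spectra (AU), `C` holds concentrations (ug/mL), columns of `S` are molar
(here mass-basis) absorptivity profiles, `E` is instrument noise.
Calibration inverts this map from a designed training set.

## Calibration design

A five-level, four-factor design with 25 runs: run 1 is the all-centre
point (15, 12, 6, 6 ug/mL) and, in coded units (-2..+2), every subsequent
factor's level sequence over runs 2-25 is the cyclic left shift of the
previous factor's.  This yields exact balance — each factor visits each of
its five levels exactly five times and coded columns sum to zero — while
spreading level combinations over the hypercube.  Eight runs (1, 3, 6, 7,
10, 13, 21, 23) are held out for validation, 17 calibrate.  Component
ranges: BUP 5-25, DEX 8-16, CBA 2-10, DMA 2-10 ug/mL.  The canonical
25-row table is embedded as a fixture; `build_multilevel_design`
regenerates the same family for arbitrary five-level grids and reproduces
the fixture with the default seed sequence.

## Synthetic spectra

The measured spectra are not published, so the generator emulates the
regime they create:

- **Pure profiles.** Each component is a sum of two Gaussian bands on the
  200-400 nm grid (1 nm step), parameterized (center, width, height in AU
  per ug/mL).  The defaults place all four components' absorption inside
  the 224-330 nm working window with heavy overlap — maximum pairwise
  cosine similarity 0.73, minimum 0.37 — which is the regime that defeats
  single-wavelength quantification.  The band parameters were chosen once
  so that the workflow's validation statistics land in the precision range
  the method is designed for (mean recoveries within ~2% of 100%, RSD
  roughly 0.5-2.5% at the default noise); a near-collinear alternative
  (cosine > 0.95) degrades every model far beyond that regime and would
  not represent a system on which this workflow is used.
- **Noise.** Additive i.i.d. Gaussian noise, default `sd_frac = 0.005`
  (0.5% of the maximum clean absorbance, about 0.008 AU here), a typical
  UV-Vis photometric noise level; absolute `sd_au` is also accepted.  The
  seed fully determines the realization.
- **Not modelled:** absorbance saturation, stray light, baseline drift,
  wavelength registration error, inter-day variation.  Passing tests
  therefore demonstrate correctness of the algorithms under the bilinear
  model with white noise, not robustness to real-instrument artifacts.

## Preprocessing

The working window is the closed interval 224.0-330.0 nm at 1 nm, i.e.
107 points.  (Part of the source material states 224-320 nm, but the
107-point count stated three times is only consistent with an inclusive
224-330 nm window; the window stays configurable.)  Spectra and
concentrations are mean-centered on the calibration set; validation and
test spectra are centered with the stored calibration means and predicted
concentrations get the means added back.

## PCR and PLS

PCR computes the SVD of the centered calibration spectra and regresses the
centered concentrations on the leading score columns; requesting more
components than the numerical rank is an error.  PLS is NIPALS PLS2: per
latent variable, the inner loop alternates weight/score/loading updates
(tolerance 1e-10 on the u-vector, cap 500 iterations), then deflates both
X (by `t p^T`) and Y (by `t q^T`); coefficients are
`W (P^T W)^{-1} Q^T`.  With as many components as the rank both reduce to
ordinary least squares, which the tests exploit as an oracle; the NIPALS
path is additionally cross-checked against an independent implementation.

Latent-variable counts are selected by leave-one-out cross-validation:
each sample is excluded in turn, the model (including re-centering) is
refit, and RMSECV pools squared errors over all samples and the four
components equally (one LV count per model, per-component curves exposed).
Ties within 1e-12 resolve to the smaller count.  Defaults: 6 (PCR) and
5 (PLS).  On the noiseless synthetic system LOOCV selects 4, the true
chemical rank; the larger defaults simply absorb noise directions and are
retained as the shipped configuration.

## MCR-ALS

Each iteration solves row-wise least squares for `C` given `S`, applies
the active C-constraints, solves for `S` given `C`, applies the
S-constraints, and evaluates the lack of fit.

- **Non-negativity** is imposed by solving each row/column subproblem with
  NNLS rather than clipping, preserving the least-squares contract.
- **Horizontal unimodality** (optional) flattens secondary peaks to the
  running bound on each side of the global maximum, with a 5% tolerance
  factor before a violation is corrected; the correction is idempotent and
  preserves the maximum's position.  It is off by default because the
  design deliberately randomizes concentration levels across mixtures, so
  concentration columns are not unimodal sequences and flattening them
  destroys the inner calibration; it is appropriate for evolving systems
  (chromatographic/kinetic profiles) and is fully supported for them.
- **Correlation constraint.** For each component, the resolved calibration
  entries `c` are regressed against the known references
  (`ref ~ a c + b`) and the whole column is passed through that line, so
  calibration entries become the fitted references and test entries land
  in real ug/mL.  This both fixes the intensity ambiguity and implements
  the quantification step.
- **Convergence** when the relative change in lof between consecutive
  iterations falls below 0.1% (denominator floored at 1e-9% so an exactly
  bilinear matrix registers as converged); cap 50 iterations.  The best
  (lowest-lof) iterate is retained, making the accepted-lof sequence
  non-increasing by construction even though constrained iterations are
  not guaranteed monotone.  Rank-deficient unconstrained solves fall back
  to a ridge with 1e-10 jitter and a warning.
- **Initialization**: supplied pure spectra restricted to the window when
  available, otherwise the k most dissimilar data rows (greedy Gram-
  determinant maximization over normalized rows, seeded with the
  largest-norm row).

Unknowns are quantified one by one: the calibration matrix is augmented
with a single test spectrum, ALS runs with the correlation constraint
masked to the calibration rows, and the test row of `C` is read off.
Results are independent of test-row order by construction.

On the noiseless synthetic system the resolution is exact (lof ~ 1e-14,
per-component spectral cosines 1.0, validation errors < 1e-12 ug/mL); at
0.5% noise lof is about 1.0-1.1% with convergence in 2-3 iterations.

## Linear network with Levenberg-Marquardt

The network is 107-10-4 with linear transfer in both layers — algebraically
the affine map `y = (W2 W1) x + (W2 b1 + b2)` of rank at most 10 (the
tests verify the collapsed map reproduces the network to 1e-10).  Training
still follows the classical LM procedure rather than a closed-form fit,
because the training trajectory (damping schedule, early stopping,
best-validation snapshot) is part of the modelled procedure: per epoch the
step `delta = -(J^T J + mu I)^{-1} J^T r` is computed on the training
partition — solved in residual space via
`delta = -J^T (J J^T + mu I)^{-1} r`, exact for `mu > 0` and much cheaper
when parameters (1124) outnumber residuals — accepted if it lowers the
training MSE (mu /= 10), otherwise mu *= 10 and retried.  Stopping:
validation MSE not improving for 6 consecutive epochs, mu overflowing
1e10, 1000 epochs, or the MSE goal; the best-validation snapshot is
returned.  Data are split 70/15/15 train/validation/test by a seeded
shuffle; weights initialize uniform in +-0.5 scaled by fan-in, seeded.
On noiseless data LM reaches machine-zero MSE in about a dozen epochs and
the validation predictions are exact, because an exact linear target
representable by the network is interpolated on a training set that spans
the 4-dimensional spectral subspace.

## Validation statistics

- Recovery % = 100 predicted/nominal; summaries report mean and
  RSD = 100 sd/mean (n-1 denominator) after optional Dixon Q screening.
- **Dixon Q** uses the r10 gap/range statistic on the more extreme tail,
  one rejection per pass (a sequential mode repeats while n >= 3), with
  the classical analytical-chemistry critical table for n = 3-10 at the
  95% confidence level (0.941, 0.765, 0.642, 0.560, 0.507, 0.468, 0.437,
  0.412) plus a stricter 99% table.
- **EJCR**: from OLS of predicted on nominal, the joint region
  `{beta : (beta - b)^T X^T X (beta - b) <= 2 s^2 F(alpha; 2, n-2)}`;
  the model is unbiased at level alpha when (intercept 0, slope 1) lies
  inside.  The boundary is returned as 360 parametric points from the
  eigendecomposition of `X^T X`.  Monte-Carlo replicates confirm the
  nominal 95% coverage.
- **t/F comparisons**: one-sample t of mean recovery vs 100%; pooled-
  variance two-sample t (df n1+n2-2) and variance-ratio F with the larger
  variance in the numerator against an official method.  Critical values
  come from the inverse t/F distributions and are reported at 3 dp.
- **Titration utility**: molar masses from the embedded IUPAC 2021
  conventional atomic weights; equivalent mass (mg) =
  molarity x volume(mL) x M / stoichiometry.

## Problem sizes and determinism

The shipped workflows run on the 25-mixture design with 107-point spectra;
the test suite and the acceptance script complete in well under a minute.
EJCR coverage uses 500 replicates (binomial standard error ~ 1%).  A
single master seed derives per-stage seeds (stable name hash folded in,
kept below 2^31), so every report is byte-reproducible.

## Known limitations

- Rotational ambiguity of bilinear factorization is controlled only by
  the implemented constraints; no band-boundary (feasible-region)
  analysis is provided.
- The Q-test tables cover n = 3-10 only, matching its intended use on
  small validation sets.
- The generator's printed-figure realism is qualitative: band positions
  and intensities are plausible for these chromophores but are not fits
  to measured spectra, so published figures of merit that depend on the
  real instrument (e.g. a specific lof value) are not reproduction
  targets.
- Trace-level impurity quantification (sub-ug/mL) is outside the modelled
  concentration ranges.
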