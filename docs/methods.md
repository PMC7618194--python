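# Methods

This note documents the statistical models the package implements, the
choices made where a method is under-determined by convention, what the
synthetic generator does and does not emulate, and the problem sizes used in
the validation suite.

## ROI-level robust regression

"Robust linear regression" is implemented as Huber M-estimation: IRLS with
weights w(u) = min(1, c/|u|), tuning constant c = 1.345 (95% efficiency at
the Gaussian), and scale re-estimated each iteration as the normalized MAD
of the residuals (median |r| / 0.6745). Iteration stops when the largest
coefficient change falls below 1e-8 or after 50 iterations; non-converged
fits are flagged and their results withheld. Inference is asymptotic: the
reported "t-score" is coefficient/SE referred to the standard normal, with
the Huber H1 sandwich covariance (small-sample degrees of freedom for
M-estimators are not well defined, and the normal reference reproduces the
kind of coefficient table these studies print). `statsmodels.RLM` provides
the single-response fit; the mass-univariate fit below is an independent
vectorized implementation of the same estimator and the two are verified
against each other to ~1e-9 in the tests.

Categorical confounders are expanded to indicators against declared
reference levels (smoking: current/past vs never; sex: male vs female;
group: patient vs control). Rows with missing modelled values are dropped
with a warning. Moderation models center the predictor and moderator before
forming their product; the interaction coefficient and its test are
invariant to this reparametrization (asserted in tests), centering only
conditions the design numerically.

Cohen's d uses the pooled-SD definition with the normal-approximation CI,
SE = sqrt((n1+n2)/(n1 n2) + d²/(2(n1+n2))); this reproduces printed CI
bounds of the form (-0.98, -0.34) for d = -0.66 at n = 80/79 exactly, which
is why it was adopted over the noncentral-t construction. The Steiger test
for two dependent overlapping correlations uses the back-transformed average
correlation variant (the default of the standard comparison toolkits);
Fisher's r-to-z comparison handles the independent case. BH-FDR is the
standard step-up procedure via statsmodels.

## Voxelwise inference

Per-voxel fits use the identical Huber estimator, vectorized: all voxels'
weighted normal equations are assembled from two GEMMs per IRLS pass and
solved as a batched p×p system. The voxelwise convergence tolerance is 1e-6
on coefficients (a numerical choice: t-values move at the fourth decimal
between 1e-6 and 1e-8, far below permutation resolution, and the looser
tolerance roughly halves iteration counts at mass-univariate scale).
Censoring marks individual subject-voxel observations outside the
whole-sample 1st/99th percentile bounds as missing — not winsorized and not
whole-voxel exclusion — so each voxel's fit keeps its remaining
observations; winsorizing is available by flag. Voxels with fewer than 10
observations, degenerate response, or non-converged fits are dropped and
counted.

Smoothing is a discrete Gaussian with per-axis sigma = sigma_mm/voxel_size,
zero-padded and renormalized by the smoothed lattice indicator (constant
volumes stay constant at edges; NaNs are treated as zero-weight).

TFCE sums extent^E · h^H · dh over thresholds h = dh, 2dh, … with E = 0.5,
H = 2 and dh = max|t|/100 (the conventional defaults), 26-connectivity,
positive and negative tails enhanced separately. All threshold levels are
labelled in a single 4D connected-component pass (no connectivity across
the threshold axis) — a pure implementation optimization, bit-identical to
the per-threshold loop.

Permutation inference uses Freedman-Lane: the response is re-assembled as
(nuisance fit + permuted nuisance residuals) and the full robust model is
refit, which respects the covariates under the null. Simple label
permutation is available by flag. Each voxel's two-sided p compares |TFCE|
against its own permutation distribution, p = (1 + #{≥}) / (1 + n_perm);
BH-FDR at q = 0.05 then runs across mask voxels, and surviving voxels are
grouped into 26-connected clusters reported with peak t and mm coordinates.
The alternative of FDR over cluster-level statistics is intentionally not
chosen as the default: voxel-level p with BH matches the "FDR-corrected
voxels grouped into clusters" reading and is the better calibrated of the
two on the synthetic phantoms. The spatial-extent variant forms clusters at
a two-sided uncorrected p < 0.001 by default (configurable; the primary
threshold is not fixed by convention) and compares observed extents with
the permutation null of the maximum extent.

Permutations are processed in batches: a batch of permuted datasets is fit
as one wide mass-univariate problem. With 500 phantom voxels this sustains
roughly 70 permutations/second on one CPU, which is what makes the
100-dataset × 500-permutation calibration practical.

## PLS brain-map association

One latent pair is extracted by NIPALS (tolerance 1e-10, max 500
iterations; the weight vector equals the leading left singular vector of
Xcᵀ Yc up to sign, asserted against direct SVD and scikit-learn). Note that
PLS maximizes cross-block covariance, not correlation: when the response
block is literally one of the predictor columns the score correlation is
close to but not exactly 1 — the tests reflect this.

Cross-validation: per repeat, a random 10-fold assignment; each fold's
subjects are projected with the model fit on the complement using the
training fold's centering vectors (no leakage); pooled out-of-sample
(x, y) scores give one Pearson r; the statistic is the mean over repeats.
Two implementation routes exist and are tested for equivalence: a direct
per-fold NIPALS fit, and a subject-space (Gram matrix) evaluation of the
identical model in which the x-score direction is the leading eigenvector
of the product of the train-centered Gram matrices. The kernel route makes
the cost independent of voxel counts and is the default.

Fold orientation matters for pooling. The x side follows a fixed sum(w) > 0
convention. The response side applies the sign-reversal rule *per training
fold*: if the training score correlation's direction disagrees with the
training-fold ROI-mean correlation, the fold's response scores are negated.
Without this, each fold's response orientation follows the sign of the
training cross-block fit, which under permutation is random per fold: the
pooled null SD inflates from ≈0.145 to ≈0.23 at n = 40 and the permutation
test loses most of its power. With the rule, the returned out-of-sample
correlation also directly carries the sign of the underlying association
(negative for an inverse susceptibility-Ki coupling).

The permutation test permutes subject rows of the response block and
re-runs the identical CV machinery; permutation repeats default to 5 per
permutation for tractability (a config knob; calibration tests use equal
observed/permutation repeat counts, under which the p-value is exact by
exchangeability). p = (1 + #{|null| ≥ |observed|})/(1 + n_perm).

VIP with one component reduces to sqrt(p)·|w_j|/||w|| (mean-square 1 over
predictors); response-side importance is the analogously normalized |q|.
Bootstrap error resamples response voxels with replacement and refits the
whole model — perturbing both sides, which is how a response-voxel
bootstrap can yield predictor-side error at all; voxels never drawn in a
replicate are excluded from that replicate's statistics, and
z_j = sign(w_j or q_j) · mean_boot/sd_boot. A subject-level bootstrap is
available by flag.

## Patlak-Gjedde analysis

The graphical estimator regresses y(t) = C_t/C_ref on
x(t) = ∫₀ᵗ C_ref dτ / C_ref over frames with mid-time ≥ t*; the slope is
Ki (min⁻¹), the intercept the apparent distribution volume. Integration is
trapezoidal on frame mid-times with a zero-activity anchor at t = 0.
Defaults: t* = 20 min (not dictated by convention; the fit reports
per-frame linearity deviations as a diagnostic), unweighted OLS
(frame-duration weighting by flag). The estimator is invariant to common
rescaling of both curves and equivariant under target-curve scaling;
for generator TACs, which satisfy the discrete model exactly, the fit is
exact at any t*.

## The synthetic generator

The generator emulates the statistical structure the analyses assume, not
images: group sizes 80/79; demographic marginals (≈70% male; current/past
smoking 15%/18% in controls vs 37%/11% in patients; ≈24% THC-positive; ages
≈31±7 truncated to 18-45); PANSS subscales sharing a latent severity factor
(loading 0.62, chosen so the total-score SD is ≈14 as in such cohorts) with
total = sum of subscales; gamma-distributed antipsychotic doses with ≈25%
unmedicated. ROI measures follow a per-group latent Gaussian model:
susceptibility = mean + SD·(age_r·z_age + √(1−age_r²)·u) + SD·d·I(patient),
with the latent block correlation matrix dilution-corrected so the observed
within-group correlations land on their targets (group d = −0.66; age
r = 0.19 within group; susceptibility-NM-CNR r = 0.25 in controls vs −0.19
in patients; susceptibility-Ki r = −0.44 in patients, concentrated in the
associative/sensorimotor subregions with a weak limbic share). Positive
definiteness of every implied covariance is checked at construction. The
within-group susceptibility SD is a free scale, default 22 ppb on a 90 ppb
mean, consistent with published coefficient scales; Ki is 0.013 ± 0.0015
min⁻¹.

Voxel maps live on exact-count ellipsoidal phantom masks (1790 SN-VTA
voxels, 2967 striatal voxels, 1 mm grid, MNI-like mm offsets). Each
subject's map is ROI scalar + smooth noise + focal field, where noise
(white noise smoothed with a 2-voxel sigma, standardized) and the focal
field both have zero mean over the mask — so the mask mean reproduces the
tabulated ROI scalar exactly, and the group effect is *redistributed*
spatially into a contiguous ventral-pole cluster (default 327/1790 of the
mask) rather than added on top. Smooth noise is essential: TFCE calibration
on white noise would be meaningless. Striatal Ki maps concentrate the
susceptibility-linked signal in a dorsal subset via a zero-mean modulation
field.

For PLS validation, `generate_latent_pair_blocks` builds two voxel blocks
loading on a correlated latent pair. By default the latent correlation is
planted *exactly in sample* (the innovation is orthogonalized against the
predictor factor): the recovery experiments then test estimation of a known
realized association rather than compounding it with sampling error in the
latent draw. Null-calibration simulations must pass
`exact_sample_correlation=False` — an exactly-zero-correlation draw is
atypical under exchangeability and makes permutation p-values conservative.

TACs are built to satisfy the irreversible-uptake model *in the discrete
sense*: the target is Ki·(trapezoidal cumulative reference integral) +
V·C_ref on the frame grid, so the Patlak fit recovers Ki exactly in the
noiseless case. The reference curve is bi-exponential (≈2 min uptake,
60 min washout, peak ≈20 kBq/mL): a sharply peaked gamma variate decays to
numerically zero over a 95-min acquisition and destroys the Patlak
ordinates by cancellation. Framing: 8×15 s, 3×1 min, 5×2 min, 16×5 min.

What the generator does not emulate: spatial normalization error,
scanner-specific noise spectra, partial-volume effects, motion, metabolite
kinetics, or any raw-image physics. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the assumed structure,
not that the pipeline is robust to real-data artifacts.

## Validation problem sizes

The long-running checks use these scales, chosen to exercise each claim at
meaningful power on a single CPU: case-control recovery over 200 cohorts of
159 subjects; voxelwise null calibration over 100 datasets × 500
permutations on a 500-voxel phantom (n = 40), with planted-cluster recovery
(300 voxels at 1.2 SD, n = 159, 1000 permutations); PLSR recovery over 20
seeds at the study's block sizes (1790/2967 voxels, n = 40, 500
permutations, 10 CV repeats observed / 5 per permutation) and null
calibration over 100 datasets × 200 permutations; Patlak bias over 1000
noisy replicates. `scripts/acceptance.py` re-runs the same experiments at
moderately reduced replicate counts and records the measured values.

## Known limitations

- Asymptotic-normal inference for the robust fits is anticonservative at
  very small n; no small-sample df correction is attempted.
- Permutation p-values are granular at 1/(n_perm+1); BH-FDR across voxels
  cannot reject at all until enough voxels share small p.
- The spatial-extent variant's primary threshold (p < 0.001) is a
  convention, and its results are threshold-dependent in the usual way.
- One PLS component only; no model selection across components, by design.
- The kernel CV route assumes voxels ≫ subjects is the regime of interest;
  it is exact regardless, but confers no advantage for tiny blocks.
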