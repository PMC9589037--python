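# Methods

`taskconn` analyzes dynamic functional connectivity in widely spaced
event-related task fMRI. This note documents the model, the estimators, the
statistical procedure, the synthetic data generator that stands in for
scanner data, and the numerical and design choices a maintainer would want
to know about.

## Phase-aligned connectivity estimation

In a widely spaced design, stimuli are separated by ~20 s, so the BOLD
response to one trial decays before the next begins. With a TR of 2.5 s,
each trial covers 8 frames; frame *f* of every trial samples the same point
in the hemodynamic evolution of the task. Stacking frame *f* across trials
of one stimulus class gives a regions × frames matrix (a *replica-frame
stack*) that is an i.i.d.-across-columns sample of the brain state at that
task phase — there are 16 such stacks per participant (8 frames × 2
stimulus classes).

Trials enter a stack only if they run the full 8 frames before the next
onset and the preceding trial started at least 20 s earlier; catch trials
(shortened inter-trial intervals of 5/7.5/10 s) and their immediate
successors are thereby excluded. One literal consequence worth noting: a
catch trial in the final position of a run does keep its full 8 frames and
is eligible. Frames with frame displacement (FD) at or above the threshold
(default 0.3 mm; the comparison is strict and configurable) are censored,
with the first frame of each run fixed at FD 0. Rotations are converted to
arc displacement on the conventional 50 mm sphere. A participant is
analyzed only if all 16 conditions retain at least 40 frames, and each
stack is then subsampled to exactly 40 frames, uniformly at random (not
lowest-FD, to avoid motion-correlated selection bias), with a
per-(participant, condition) seed derived by hashing so that adding a
participant never reshuffles another's selection.

## The connectotype

Each region's signal is modeled as a weighted sum of all the other
regions:

x_i = Σ_{j≠i} β_ij x_j + e_i,  with ridge penalty λ‖β_i‖².

The collected rows form a directed region × region matrix with zero
diagonal. Regions are z-scored within the stack before fitting (so the
penalty treats regions symmetrically) and the betas are mapped back to the
input scale (β_ij·σ_i/σ_j), which keeps exact linear relations in raw data
recoverable as their raw coefficients. No autocorrelation pre-whitening is
applied: in phase-aligned task data the temporal structure is part of the
signal, not a nuisance.

All rows are solved at once through the regularized precision matrix: with
M = (XᵀX + λI)⁻¹, block inversion gives β_ij = −M_ij/M_ii exactly. This is
stable in both the overdetermined (frames ≫ regions, λ→0 reduces to
per-row OLS, verified to 1e-6) and the underdetermined 40-frame ×
hundreds-of-regions regime. An earlier kernel-form (dual) implementation
was abandoned for numerical reasons; the identity above is exact.

**What the estimator identifies.** If data are generated as
x = (I − B)⁻¹η with isotropic η, the population regression of region i on
the rest has coefficients −P_ij/P_ii with P ∝ (I−B)ᵀ(I−B). For symmetric B
this is B up to a small quadratic correction (elementwise correlation
≈ 0.99 in the 10-region recovery check); a strictly asymmetric B is only
identified up to the symmetrization implied by the joint precision
(correlation ≈ 1/√2 for i.i.d. entries). Parameter-recovery claims in the
tests therefore use symmetric generative matrices, and a directed planted
perturbation is expected to appear in both orientations of the perturbed
network pair.

**Penalty selection.** λ is chosen from a log-spaced grid (default 10⁻⁴ …
10⁴, 13 points) by 5-fold cross-validation over frames (frames are
exchangeable within a stack: they come from different trials), minimizing
held-out prediction MSE summed over regions, ties broken toward heavier
regularization. By default one λ is selected for the whole cohort from the
pooled CV error of all stacks (`penalty_scope="cohort"`): every stack has
the same 40 × regions geometry by construction, so the optimal penalty is
a property of the design, and re-selecting it per participant or per
condition lets the effective shrinkage — hence the scale of every beta —
vary across exactly the units the downstream ANOVA compares.
Per-participant and per-condition scopes are available for sensitivity
analysis, as is per-region λ sharing within a stack.

The Pearson-correlation baseline is computed on the identical sampled
stacks, so estimator comparisons differ in nothing but the connectivity
measure.

## Network-pair statistics

The Gordon-style parcellation has 333 ROIs in 12 named networks plus 47
unassigned ROIs. All regions enter every fit as predictors; statistics are
computed on the 129 ROIs of the six higher-order networks (CiP, Def, DoA,
FrP, Sal, VeA), grouped into the 36 ordered network pairs. Pair (A, B)
collects β with the modeled (target) region in A and the predictor
(source) region in B; (A, B) and (B, A) are distinct, which is why the
pair listing shows symmetric-looking counts twice (e.g. 205 for both
Def/CiP orientations), and a network of n regions has n(n−1) within-pair
connections. The counts total 16,512 = 129·128.

Per pair, the connectivity values form a complete (participant,
connection, frame, stimulus) table. Processing:

1. **Box-cox normalization**, fitted per pair over all its values. Betas
   can be negative, so a shift of ε − min is applied first with
   ε = 10⁻³ × range. The exponent maximizes the profile log-likelihood via
   L-BFGS-B (matches scipy's Brent MLE to 1e-3); λ→0 is the log limit.
2. **Two-stage ANOVA**: connection-level values are adjusted for
   participant effects and aggregated to a participant × 16-condition
   matrix of cell means (with balanced complete tables the adjustment
   changes nothing the within-subject ANOVA doesn't already remove; both
   the fit-then-aggregate and the plain participant-mean mode are exposed
   and tested to give identical F). The matrix is then tested with a
   classical two-way repeated-measures ANOVA; the quantity of interest is
   the frame × stimulus interaction, F with nominal df (7, 7(n−1)).
3. **Sphericity**: Greenhouse–Geisser ε is estimated from the orthonormal
   interaction contrasts (normalized Helmert ⊗ stimulus difference),
   clamped to [1/7, 1]; Huynh–Feldt optional. The ε-adjusted p is always
   applied and reported as `p_uncorrected`; Mauchly's test is reported but
   gates nothing (adjust-only-if-significant would make the pipeline
   discontinuous). The sphericity-unadjusted p is also kept
   (`p_unadjusted`): under compound symmetry — which holds for the
   synthetic nulls by construction — the unadjusted F is exactly
   calibrated, while ε̂'s small-sample downward bias makes the adjusted
   test deliberately conservative. Calibration checks therefore read
   `p_unadjusted`; reported inference uses the adjusted value.
4. **Family-wise correction** across the 36 pairs, default a
   studentized-range adjustment (each p is converted to its two-sided
   normal quantile z and corrected as the survival probability of z√2
   under the studentized range with k = 36 groups); Holm, Bonferroni and
   Šidák are available. Significance threshold 0.05.
5. **Post-hoc**: per frame, a paired t-test of word vs pseudoword
   participant-level means (8 two-sided p-values; a frame with identical
   values reports t = 0, p = 1).
6. **Marginal means** per (frame, stimulus) over participants ×
   connections, with dispersion bars of 1.15 × the standard deviation (or
   standard error) — the plotting convention used for trajectory figures.

## Synthetic cohorts

No scanner data ships with the package; the generator reproduces the
statistical structure the analysis assumes.

**Design**: TR 2.5 s; 10 runs × 24 trials (18 pseudowords, 6 words);
non-catch onsets exactly 20 s apart; 3 catch trials per run (either
stimulus class) with ITI drawn from {5, 7.5, 10} s; runs extend one trial
length past the last onset.

**Signal**: at a frame of phase f and stimulus s the region vector is
x = (I − B(f,s))⁻¹η, η ~ N(hrf(offset)·a·gain_s, σ²I), so the frame-wise
covariance embeds the condition's connectivity and the connectotype model
is correctly specified. B(f,s) equals a base matrix B₀ (dense
within-network blocks, sparse background, spectral radius rescaled to 0.6
over all conditions) except for a planted network-pair block scaled by
g(f,s). The default interaction profile raises the word-condition CiP→FrP
block by amplitude × [0, .25, 1, 1, .25, 0, 0, 0] across frames 1–8,
concentrating the word/pseudoword difference at frames 3–4 (around the
hemodynamic peak); g ≡ 1 is the null configuration. The double-gamma HRF
peaks at 5.4 s and is within 5% of baseline by 20 s. Evoked means use a
stimulus gain so that cohorts with *activation-only* differences (mean
shift, no connectivity change) exist — the specificity control for
co-activation vs connectivity. Frames are conditionally independent given
their phase (matching the estimand of phase-aligned stacking); an optional
AR(1) innovation stream across within-trial frames is available for
stress-testing. Participants get multiplicative N(1, 0.1²) jitter on the
nonzero B₀ cells, creating between-subject variability for the RM-ANOVA.

**Motion** is simulated directly as an FD-like trace (lognormal body,
median 0.1 mm, log-sd 0.5, plus 5% spikes around 0.6 mm), tuned so that
~94% of frames survive the 0.3 mm threshold; a six-parameter random-walk
mode exercises the FD computation. Real studies lose participants to
censoring, and so does this design: with 6 words per run and catch-trial
exclusions, word conditions hover near the 40-frame floor, and roughly
half of simulated candidates fail the inclusion rule even at modest
motion. The cohort generator therefore screens candidates until the
requested number of *survivors* is reached (the analyzed sample size is
what the defaults specify: 15), drawing candidate seeds deterministically
from the master seed; unscreened cohorts are available, and the FD-0.25
sweep still drops participants, as stricter censoring should.

**What passing tests do and do not show.** The generator matches the
analysis' assumptions exactly (correct model specification, independent
replica frames, Gaussian innovations). Real BOLD data add autocorrelation,
non-Gaussian noise, preprocessing artifacts and parcellation mismatch, so
calibration and power measured here are best-case statements about the
procedure, not about any scanner dataset.

## Simulation studies and problem sizes

Type-I error, power, localization, specificity and the estimator contrast
are measured over 20-repetition studies of 15-participant cohorts on a
reduced 40-ROI analogue of the atlas (six included networks of 3–8
regions, a visual network, 6 unassigned), keeping full studies at
desk scale; atlas bookkeeping and the estimator oracles run at full size.
The planted amplitude for power studies is 0.8 (word-block scaling peaks
at 1.8×), chosen so the connectotype pipeline detects in a clear majority
of repetitions while the Pearson baseline trails — the regime in which the
estimator contrast is informative. At this setting a seeded reference run
gives: null per-pair rejection 0.054 (nominal 0.05), zero family-corrected
false positives in 20 null cohorts, planted-pair localization 20/20,
detection 19/20 (connectotype) vs 12/20 (Pearson), and no detections on
activation-only cohorts. `scripts/acceptance.py` recomputes all of these
from scratch for any seed.

## Numerical notes and limitations

- Ridge grids must be strictly positive; λ→0 limits are taken as 10⁻⁸ on
  the grid, not 0.
- Mauchly's chi-square uses the standard Anderson correction factor;
  pingouin's variant differs in the third decimal of the p-value. GG ε
  matches pingouin to 1e-10. With fewer participants than contrasts the
  contrast covariance is singular; ε falls back to its lower bound with a
  warning rather than failing.
- The studentized-range family correction treats the 36 tests as a
  comparison family; it is an interpretation of a correction whose exact
  mechanics are not recoverable for this setting, hence the documented
  alternatives.
- Connection-level (edge-wise) inference, sliding-window dynamics, seed
  regressions and volumetric/surface atlas handling are out of scope; the
  parcellation is a pure labeling.
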