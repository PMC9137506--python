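# Methods

`permbold` implements a nonparametric analysis chain for event-related
Go/NoGo fMRI: voxelwise subject-level GLM contrast maps, a robust
(median) group map, permutation-based familywise-error thresholds with
cluster extraction, and a PCA / sparse-PCA comparison of two groups'
activation patterns.  A synthetic cohort generator with known ground
truth makes every stage testable end to end.

## Subject-level model

For each subject the BOLD series at voxel v is modelled as
`y_v = X b_v + e_v` with an n x 11 design matrix containing, in fixed
order: the first principal component of the in-mask data (a global
nuisance signal), the six rigid-body motion series, and the four event
regressors `h * z_j` obtained by convolving the one-hot outcome columns
of the performance matrix Z (correct Go, correct NoGo, omission,
commission) with a gamma HRF.  One trial occurs per volume, so event
regressors live on the TR grid; no sub-TR timing or slice-timing model
is used.

Estimation uses the Moore-Penrose pseudo-inverse `G = (X'X)^+` (relative
singular-value cutoff 1e-10), and the inhibition contrast
C = (0, ..., -1, +1, 0, 0)' — correct NoGo minus correct Go — yields

    t_v = C'b_v / sqrt(s2_v C'GC),  s2_v = RSS_v / df,
    df = n - 1 - rank(X'X).

Both y and the columns of X are mean-centred before fitting.  No
explicit intercept is present; the centring together with the extra -1
in the df plays that role, and for the standard full-rank 200 x 11
design df = 188.  Voxels with zero residual variance (possible only in
noise-free synthetic data) are flagged, counted, and set to t = 0
rather than propagated as NaN.  Ordinary least squares is used
deliberately: no prewhitening or autocorrelation model.

The permutation engine solves an algebraically equivalent reduced
problem: data and event regressors are residualised against the
centred nuisance block (Frisch-Waugh), so each permutation run only
refits four columns.  Equality with the full 11-column solve is
enforced by test to 1e-10.

## Group map

Subject t-maps (already voxel-aligned; the generator produces subjects
in a common space, so no registration step exists here) are smoothed
with an isotropic Gaussian of 3 mm standard deviation — per-axis sigma
in voxels is `3 mm / voxel size`, kernel truncated at 4 SD.  The volume
is zero-padded and the kernel renormalised over the in-grid (and
in-mask) support, which avoids attenuation at edges.  The group map is
the voxelwise median (midpoint of the two central order statistics for
even subject counts), preferred over the mean for outlier robustness.
The pipeline order is fixed: smooth, then median.

## Permutation familywise-error thresholds

Each permutation run shuffles the rows of every subject's Z
independently (one permutation per subject per run, shared across that
subject's voxels), preserving outcome counts while destroying event
timing, and recomputes subject maps, smoothing, and the median map.
The global maximum and minimum of each of the B permuted group maps
form two empirical distributions, from which six thresholds are read at
alpha in {0.001, 0.01, 0.05}.

The upper threshold is the smallest observed value t with
`#{maxima > t}/B` strictly below alpha, i.e. the (B - ceil(alpha B) + 1)-th
ascending order statistic; lower thresholds are symmetric on the
minima.  The strict inequality is the defining property; when alpha*B
is an integer the naive `ceil((1-alpha)B)` index would violate it, so
the index above is used and verified against a brute-force threshold
scan.  With B = 199 and alpha = 0.05 this is the 190th order statistic.
B below `1/min(alpha)` triggers a warning, since the empirical tail
probability has resolution 1/B.

Each tail controls its own familywise error: by exchangeability of the
true and permuted orderings, the probability that any voxel of the true
map exceeds the upper threshold is just below alpha, and likewise for
the lower tail; the two-sided union is therefore close to 2*alpha by
construction.  Calibration is validated per tail on replicate null
studies (no activation, no group effect) at a reduced scale chosen to
keep the check cheap: 200 replicates of 12-subject cohorts on the
default 16 x 16 x 12 grid with B = 199, with the hit count required to
sit in the exact binomial 95% interval around 0.05.

Significance labels encode the most stringent tier passed (+-1, +-2,
+-3).  Clusters are connected components among positive and negative
labels separately (signs never merge), with 18-connectivity by default
(6 and 26 available), retained when strictly larger than 100 mm^3 —
with the default anisotropic 2.5 x 2.5 x 3.5 mm voxels that is five or
more voxels.  The peak is the largest-|statistic| member voxel.

## Group comparison

The response matrix R has one row per subject and one column per voxel
significant at the 0.05 tier or stricter, filled with the smoothed
subject-map values.  Columns are mean-centred before the SVD; voxel
variances are *not* standardised (the normalisation contract applies to
scores, not columns).  PC scores u_k are the projections scaled to
sample mean 0 and variance 1 (ddof = 1); d_k is the sample SD of the
projections, and explained-variance fractions are d_k^2 over the total.
Signs are fixed by making the largest-magnitude loading element
positive, so score directions are reproducible; the group test is
sign-invariant anyway.

Mann-Whitney U tests compare the two groups on u_1..u_10.  U counts
pairs where the first group's value is lower (plus half-ties); the
p-value is exact when n1*n2 <= 400 with no ties and a tie-corrected
normal approximation otherwise (delegated to scipy with the method
chosen by that rule).  The ten raw p-values are reported without
multiplicity correction — the procedure treats u_1 as the primary
omnibus direction and u_2..u_10 as descriptive — so roughly one in
twenty components flags by chance under the null, which the suite
checks explicitly.

Sparse PCA localises the discriminating pattern: rank-1 penalised
matrix decomposition maximising `u'Rv` subject to ||u||_2 <= 1,
||v||_2 <= 1, ||v||_1 <= c, by alternating power steps with
soft-thresholding of v (threshold level found by binary search so the
l1 bound holds), initialised from the dense first right-singular vector
and stopped at relative objective change below 1e-6 or 200 iterations.
c must be >= 1 (no unit-l2 vector has a smaller l1 norm); c >= sqrt(p)
leaves the constraint inactive and reproduces the dense PC; c = 1
leaves a single voxel.  Alternatively a target nonzero fraction can be
requested, in which case the soft-threshold is set each iteration to
the order statistic that keeps exactly that many loadings, and the
realised c = ||v||_1 is reported.  Only the first sparse component is
computed.  Support recovery is scored against the generator's
true-effect voxels with a hypergeometric enrichment test — equivalent
to randomising the support placement among the significant voxels.

## Cohort summary statistics

Two-sample t-tests are computed directly from per-group (n, mean, SD)
triples: pooled (df = n1 + n2 - 2) and Welch (Satterthwaite df), with a
two-sided F pretest of variance homogeneity (alpha = 0.05) selecting
between them, Pearson correlation for raw paired samples, and
Bonferroni adjustment min(1, m p).  A bundled reference table describes
a 60-participant abstinent-AUD vs control Go/NoGo cohort; its printed
t and df values reproduce from the triples to two decimals under the
variant implied by each row's df, with two caveats: fractional df can
be recovered only to the precision the 2-dp rounding of the printed SDs
supports, and the Go and NoGo accuracy rows yield each other's
tabulated statistics — the two rows' test statistics appear
interchanged in the source table, so they are flagged and excluded from
validation rather than silently "corrected".

## Synthetic cohort generator

The generator reproduces the study conditions the pipeline assumes:
200-volume runs at TR 2 s, one 500-ms trial per volume, 80/20 Go/NoGo
proportions with exactly `round(n * fraction)` NoGo trials at uniformly
random positions, and four mutually exclusive outcomes drawn per trial
from group-specific accuracies (defaults: Go 0.89 / NoGo 0.94 for the
control group, Go 0.91 / NoGo 0.85 for the deficit group, matching the
reference cohort's group means).

Each subject's BOLD run is built on a 16 x 16 x 12 grid of
2.5 x 2.5 x 3.5 mm voxels (the anisotropic EPI voxel size, so mm^3
cluster thresholds are genuinely exercised): an ellipsoidal "brain" at
baseline 100 against a background of 1 (so the intensity-threshold mask
— voxels above 0.4 x the 99th-percentile of the mean volume — recovers
it exactly); gamma-HRF responses to correct-NoGo events in three
ellipsoidal regions (two positive "activation" blobs carrying the group
deficit, one negative "deactivation" blob common to both groups); a
slow half-cycle cosine drift (amplitude 1, random phase) that is
deliberately absent from the design; a motion-correlated nuisance
(AR(1) motion series, SD 0.1, times per-voxel random weights of SD
0.5); and i.i.d. Gaussian noise of SD 1.  The default activation
amplitude equals one noise SD, which puts single-subject peak t values
around 6-8 — a strong, reliably detectable activation, as appropriate
for a task contrast that produces large significant clusters.  The
injected NoGo-minus-Go amplitude is recorded per voxel as ground truth.

Per-subject randomness comes from `numpy.random.SeedSequence(master
seed)` spawned once per subject, so cohorts are bit-reproducible while
subjects stay independent; every trial schedule is drawn fresh per
subject.

What the generator does **not** emulate: scanner physics and k-space,
susceptibility distortion, actual head-motion resampling (motion enters
only as nuisance time series plus correlated signal), spatial noise
correlation, physiological noise spectra, and intersubject anatomical
variability (subjects are generated directly in a common space, so the
registration step of a real study has no counterpart here).  Passing
tests therefore demonstrate the statistical machinery under idealised
noise, not robustness to registration error or structured artefacts.

## Problem sizes and runtime choices

The validation suite runs at reduced but honest scales chosen as the
package's own study conditions: FWER calibration uses 200 replicate
null studies (12 subjects, B = 199); parameter recovery uses 25
replicate 30-subject cohorts with a 0.5-noise-SD group amplitude
deficit and B = 199, requiring cluster coverage of at least 80% of
truly active voxels, u1 group separation with the deficit group lower,
and sparse-support enrichment, in at least 80% of replicates.  A
full-scale run (B = 1000, the default) is what `run-study` performs:
B + 1 group-map computations in total, one of them with the true event
timing.

## Known limitations

- OLS residual variance ignores temporal autocorrelation; the
  permutation null inherits whatever autocorrelation the data carry, so
  FWER control is unaffected, but subject-level t values are not
  calibrated individually.
- The maxima/minima are taken within the intersection brain mask;
  voxels outside any subject's mask are never tested.
- The median group map has no parametric reference distribution — all
  inference flows through the permutation null.
- Sparse-PCA support size is controlled, not inferred; the choice of
  sparsity (default: keep 50% of loadings) is a localisation dial, and
  no significance is attached to individual surviving voxels.
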