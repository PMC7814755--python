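# Methods

`paintract` re-creates, on fully synthetic data, an analysis chain used to
relate white-matter tract microstructure to self-reported pain: global
tractography of a multi-shell diffusion acquisition, exhaustive ROI-combination
bundle selection, fiber-density mapping with group aggregation and threshold
masks, supervised posterior-mean estimation of the intra-axonal signal fraction
(v_intra), and covariate-adjusted nonparametric association of per-tract
v_intra with a 0-10 pain score under Bonferroni and Benjamini-Hochberg (BH)
control. This note documents the models, the defaults and why they were
chosen, and what the synthetic data can and cannot show.

## Signal model and units

Voxel signals follow the three-compartment "standard model" of white matter:
an intra-axonal stick with zero radial diffusivity, an axially symmetric
extra-axonal zeppelin, and an isotropic free-water ball,

    A(b, g) = v_intra exp(-b d_a (g.n)^2)
            + v_extra exp(-b [d_e_perp + (d_e_par - d_e_perp)(g.n)^2])
            + v_csf  exp(-b d_csf),

with fractions on the simplex and diffusivities in um^2/ms. b-values are kept
internally in ms/um^2 (1000 s/mm^2 = 1.0 ms/um^2) so that b*d is
dimensionless; FSL-dialect bval/bvec text is converted on load. The free-water
diffusivity is fixed at the usual 3.0 um^2/ms. Shells are inferred by
clustering b-values within +-50 s/mm^2; b <= 50 s/mm^2 counts as b0. Synthetic
schemes use antipodally symmetric electrostatic-repulsion direction sets
(seeded, deterministic); with 60 directions per shell the powder average of a
stick matches the closed form sqrt(pi/(4bd)) erf(sqrt(bd)) to better than
1e-3.

## Phantom and cohort generator

The phantom is a 40x40x40 grid at 1.5 mm with spherical ROIs (closed balls in
world mm, the center+radius dialect commonly used to define small brainstem
nuclei) and tubular bundles (radius 3 mm) around polyline
centerlines. The default layout mimics the four tract families of interest: a
curved three-ROI bundle ("AP"), a second bundle crossing it at 90 degrees
("DP"), two further straight bundles ("CS", "PN"), and a negative-control ROI
pair joined by no bundle. Tube voxels carry (v_intra, v_extra, v_csf) =
(0.60, 0.30, 0.10) with the local centerline tangent; crossing voxels mix the
contributions of both tubes with weights proportional to tube membership (no
exchange); background is pure free water. Rician noise is applied per volume
with sigma = s0/SNR. The white-matter tracking mask is the tube union dilated
by one voxel.

The cohort generator draws age, sex and pain marginals matching the study
descriptors: age mean 29 y, sd 3.7, range [22, 40]; 64% female (exact
composition at n = 100); pain mean 1.63, sd 1.85 on the 0-10 NTPIS scale.
Because truncation shifts moments, the truncated-normal parameters are
moment-matched numerically so the *truncated* distribution reproduces the
printed mean (and sd where feasible — a sample sd of 1.85 at mean 1.63 on
[0, 10] exceeds what any truncated normal can reach, so the pain sd is fit in
least squares and the mean is matched exactly; the generated pain
distribution is therefore slightly less dispersed than the real survey,
which is zero-inflated and right-skewed). Per-tract ground-truth v_intra is
v0 + beta*z(pain) + eps with eps ~ N(0, 0.05), clipped to [0.05, 0.95]; the
default beta = 0.0185 gives a population Spearman correlation of ~0.30 in
coupled tracts, a detectable-but-not-trivial effect at n = 100. All anatomy
is shared across subjects — only microstructure amplitudes vary — which
deliberately isolates the v_intra-pain statistical machinery from
registration.

## Global tractography

The tracker fits a configuration of short oriented segments (half length
0.67 voxel) to the data at once. The data term is the squared residual
between the measured anisotropy contrast — b0-normalized attenuation on the
weighted volumes minus its per-shell mean, which is identically zero for
isotropic voxels — and a superposition of per-segment, mean-removed stick
kernels (d_a = 2.0) deposited with trilinear weights at the segment center.
The internal term is

    E_int = mu * n_segments + p * n_free_endpoints - b * n_links
          + c * sum_links (1 - |cos(theta_link)|),

with defaults mu = 1.0 (per-segment potential; the point-process prior that
keeps segments out of voxels with no anisotropy to explain), p = 0.15,
b = 0.30, c = 0.30. Links are admissible between free endpoints within
2.25 mm, with axes within 60 degrees, and only continuing outward (each
partner's segment lies beyond the other's endpoint), which prevents chains
from folding back onto themselves. These constants are this package's own
surrogate: the original toolbox's preset values are not public, so the
architecture is reproduced with an explicit, configurable functional.

Optimization is Metropolis-Hastings with proposals {birth, death,
move/rotate, link, unlink, extend, retract} and geometric cooling. Birth
proposals are uniform over the mask volume and the orientation half-sphere,
with the exact reference-measure Hastings ratio; extend/retract grow or trim
chain ends (a new segment born already linked to a free endpoint, entry point
uniform in the link-radius ball and orientation uniform in the bending cone),
which is what lets chains span whole bundles at desk-scale iteration counts.
Move steps scale with sqrt(T) so the chain refines geometry as it cools. Each
proposal pair satisfies detailed balance at fixed temperature; a test
verifies the Boltzmann distribution against exhaustive enumeration on a
three-segment toy state space. The desk-scale default schedule is
t: 0.1 -> 0.001 over 2x10^5 proposals, then reheat to t = 0.1 (kept from the
source strategy) for 5x10^4 proposals per accumulation round, five rounds,
concatenating the extracted streamlines of every round; end-to-end runs use
a further-reduced schedule (5-6x10^4 cooling proposals) to keep a full
multi-seed study within minutes on one CPU. Chains become polylines with a
point at each link midpoint; isolated segments are not streamlines; cycles
are broken at an arbitrary link with a warning.

## Bundle selection

A streamline connects an ROI combination iff, for every ROI, at least one
*supporting point* lies inside it (closed ball; label volumes by the voxel
containing the point). The rule is deliberately point-wise: a segment that
crosses a sphere between two outside points does not count. All ROI subsets of
size 2..4 are enumerated and combinations with at least one connecting
streamline are kept; correctness is pinned to a brute-force double-loop oracle
in the tests. Whether supporting points must hit ROIs in anatomical order is
not specified by the design this follows; the implemented rule is the
unordered conjunction.

## Density maps, probability maps, masks

Streamlines are discretized at arc-length steps of 0.25 voxel; each step
deposits its exact length (scalar map) or length-weighted tangent outer
product (rank-1 directional map) via trilinear weights on the 1.5 mm grid, so
total mass equals total streamline length and trace(directional) equals the
scalar map identically. Indicator images threshold the density at 1 mm
streamline length per voxel (closed, >=); group probability maps are the
voxel-wise mean of indicator images across subjects; tract-core masks keep
voxels with occurrence probability >= the lower limit (default 0.8), with the
maximal observed probability recorded as the upper limit. A tract is retained
only if some voxel reaches 40% occurrence — the rule that drops weak or
highly variable tracts. All threshold comparisons are closed (>=) for
determinism at boundaries.

Tensor fields are mapped through spatial-normalization warps (dense
template-to-subject displacement, mm) by resampling at the warped coordinate
and reorienting with the local warp Jacobian (central differences): by default
with the rotation factor of its polar decomposition, which preserves
eigenvalue ratios; the full-Jacobian mode J T J^T is available. An all-zero
displacement is a bit-exact no-op. The pipeline itself runs with the identity
warp: nonlinear inter-subject registration is out of scope, and the warp
machinery exists so that externally supplied deformation fields slot in.

## FACT tracking

Bundle-specific visualization tracts are obtained by seeding uniformly at
random in voxels whose directional-density trace exceeds 1e-1 and following
the per-voxel principal eigenvector bidirectionally (nearest-voxel lookup, the
FACT convention; trilinear direction interpolation is available) at 0.75 mm
steps, stopping below a trace of 1e-8, beyond 60 degrees of turning, or
outside the grid. The 1e-1/1e-8 thresholds apply to the trace of the group
directional field in mm-per-voxel units (the field is an additive length
density, so its trace is directly interpretable); directions are sign-free.

## Microstructure estimation

v_intra is estimated by a supervised Bayesian (posterior-mean) approach:
parameters are drawn from a broad prior — Dirichlet(1,1,1) fractions,
d_a ~ U[1.5, 2.5], d_e_par ~ U[1.0, 2.5], d_e_perp ~ U[0.3, min(1.5, d_e_par)],
b0 SNR ~ U[20, 200] — signals are simulated with the forward model, Rician
noise is applied per volume, and a degree-3 polynomial (full interactions) is
fit by least squares from the per-shell spherical means (b0-normalized) to
(v_intra, v_extra, v_csf, d_a). Least-squares regression onto a sampled prior
approximates the posterior mean under squared loss, keeping the compartment
model itself unconstrained; the spherical-mean features make the estimator
rotation invariant, so no per-voxel fiber direction is needed, and prediction
is a closed-form polynomial evaluation (whole-volume maps in seconds, training
in a few seconds at the default 5x10^4 samples). Predicted fractions are
clipped to [0, 1] and renormalized to the simplex. Voxels with non-positive b0
are flagged invalid and excluded from mask means. At SNR 50 on the default
three-shell scheme the v_intra RMSE over the prior is ~0.05 with |bias| ~0.01
(the acceptance suite enforces <= 0.10 and <= 0.03). The prior ranges and
training-set size are this package's defaults; the originating method's exact
basis functions and priors are in its own reference and are not reproduced.

## Statistics

"Nonparametric multiple linear regression" is implemented as rank-transformed
OLS: response rank(v_intra), predictors rank(pain), rank(age) and a sex
indicator. Inference on the pain coefficient uses Freedman-Lane permutation
(B = 9,999 default; 999 in the pipeline loop for speed): the response is
residualized on the covariates, residuals are permuted, and
p = (1 + #{|t*| >= |t|}) / (1 + B). Parametric t p-values are reported as a
diagnostic column. Either regression direction (v_intra on pain or pain on
v_intra) yields the same permutation test for the pain term; v_intra is the
response here. Subjects are sorted by id before fitting, making the result
invariant to input row order. Across tracts, Bonferroni (p <= alpha/m) and
BH step-up FDR at q = 0.05 are applied (via statsmodels, pinned to a
hand-rolled step-up oracle in the tests), and the FDR decision boundary is
reported as log10 of the largest rejected p-value. Empirical size of the
permutation test over 500 null cohorts lies in [0.03, 0.07], and power at a
population Spearman of 0.5 (n = 100) exceeds 90%.

## Pipeline

`run_pipeline` chains the stages with a single master seed fanned out to
per-stage seeds by fixed offsets (tracking +1, cohort +2, estimator +3,
subject noise +4, bootstrap +5, FACT +6, permutations +7). The estimator seed
is intentionally *not* tied to the master seed: the same trained estimator is
applied to every subject and can be shared across runs, exactly as one
trained model would be applied to a whole cohort. Because anatomy is shared,
tractography runs once on a noise-free reference DWI; inter-subject density
variability is emulated by a seeded 70% bootstrap of each tract's streamlines
per subject before indicator aggregation; per-subject signals (subject tract
v_intra, SNR 50) are synthesized only at tract-mask voxels. Artifacts (NIfTI
maps, TCK tractograms, bval/bvec, cohort and results TSV) and a manifest
(seeds, per-stage counts, file list) are written per run; re-running a config
with the same master seed reproduces the results exactly.

## What the synthetic data does not show

Passing tests demonstrate internal correctness and statistical calibration,
not performance on real brains: the phantom has no orientation dispersion,
gradient nonlinearity, susceptibility distortion, motion, or inter-subject
anatomical variability; bundles are smooth tubes far apart except for one
controlled crossing; the pain distribution is a truncated normal rather than
the zero-inflated survey distribution; and registration (the template-warp
machinery) is exercised only with identity and synthetic linear warps.
Desk-scale annealing (1-4x10^5 proposals on ~10^3 mask voxels) stands in for
cluster-scale runs (10^7 iterations on whole-brain masks); the architecture,
temperatures and round structure are the same, the scale is not.
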