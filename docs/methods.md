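# Methods

## Signal model and fitting

CSF signal attenuation at low b-values is modelled as a
single-compartment isotropic mono-exponential,
S(b) = S(0)·exp(−b·D\*), where D\* (mm²/s) is the pseudodiffusivity of
incoherently moving fluid. Only volumes with b ≤ `b_max` (default
200 s/mm²) enter the fit: above that cutoff thermal diffusion, not
IVIM, dominates the decay. D\* is estimated per voxel as minus the
slope of an ordinary least-squares fit of ln S on b. Every volume is a
separate point — the three gradient directions per nonzero b (CSF is
assumed isotropic, so replicates differ only by noise) and every b = 0
volume. A nonlinear two-parameter exponential fit is kept in the test
suite as an independent oracle only; on clean exponentials the
log-linear estimator is exact, and under 2 % Rician noise its median
agrees with the nonlinear oracle to within 2 %.

Numerical conventions: non-positive signals are dropped pointwise
(their logarithm is undefined) rather than failing the voxel; a voxel
is marked missing when fewer than two distinct b-values survive. A
constant signal yields D\* = 0. Fitted D\* may be negative under noise
and is deliberately not clamped, so regional medians remain unbiased.

## Eligibility and the free-water comparator

Voxels enter the CSF analysis when their free-water fraction passes a
threshold of 0.8 **and** they carry a ventricle or subarachnoid label.
One configurable comparator (`ge` by default, `gt` available) is shared
between the CSF mask and fit eligibility, so the two stages can never
disagree about a voxel sitting exactly at the threshold. The strict
variant is exercised in the tests.

## Parcellation

Each subarachnoid CSF voxel takes the label of the gray-matter atlas
voxel nearest in physical millimetres, honouring the anisotropic
2×2×4 mm grid (a voxel three in-plane steps away, 3 mm with 1 mm
in-plane spacing, beats one slice away at 4 mm). Ties at exactly equal
distance go to the lowest label code — a deterministic, documented
convention. The implementation (one KD-tree per label, canonical
squared-distance recomputation, first-minimum argmin) is required to
equal a brute-force all-pairs scan voxel for voxel, and is tested
against one on random phantoms. Ventricle labels from the anatomical
segmentation always take precedence over propagation. Whether distances
should be measured in millimetres or voxel steps is an open convention
in the field; millimetres are the default here and the spacing is an
explicit argument.

Bilateral regions are merged at the summary level: the MPD of a paired
region is the volume-weighted average of the left and right medians,
the weights being each side's fitted-voxel volume. A region with fewer
than 10 voxels in at least 50 % of subjects is dropped cohort-wide;
where it is small in fewer subjects it is kept and marked missing for
exactly those subjects.

## Fine mapping along the ventricles

The "start of the third ventricle" seed is the overlap between the
third-ventricle mask and the lateral-ventricle mask dilated by 3
voxels. The structuring element is face-connected (6-neighbour) by
default and configurable to full 26-connectivity; the choice is a
convention, not a fitted parameter. Distances from the seed are exact
Euclidean distance-transform values in mm. Zone bins are half-open
[lo, hi) over edges {0, 5, 10, 15, 20} mm — a voxel at exactly 5.0 mm
falls in the second bin — which makes "within 5 mm" and "between 5 and
10 mm" consistent under a single rule. Zone numbering runs away from
the seed for the third ventricle (0–5 mm = zone 1) and toward it for
the lateral ventricles (15–20 mm = zone 1); voxels beyond 20 mm are not
analysed. Geodesic (within-CSF) distances are out of scope.

## Statistics

All continuous variables are z-scored (mean 0, sd 1 with the n−1
denominator, over non-missing entries); sex stays binary (male = 1,
reference female) and is analysed with the two-sided Wilcoxon rank-sum
test (exact null when both groups have ≤ 25 untied observations,
tie-corrected normal approximation otherwise). Associations between
regional MPD and cognition are ordinary least squares of the outcome on
the region's z-scored MPD plus age, sex and years of education, with
listwise deletion; associations with age are unadjusted. The reported
R is the marginal Pearson correlation on the rows used (not the partial
correlation — a deliberate, flagged choice). Multiplicity control is
Benjamini–Hochberg within each stated family: all unique region pairs
for the correlation matrix, all regions (or all zones) per outcome for
the associations.

Reproducibility of a regional MPD is the coefficient of variation
(sd/mean) of the median over 100 draws of ⌊0.95·n⌋ voxels without
replacement. The cohort bootstrap draws ⌊0.95·n⌋ subjects without
replacement ten times, averages each pair's correlations, and combines
the ten Pearson p-values with the aggregated Cauchy association test
using equal weights, T = (1/k)·Σ tan((0.5 − pᵢ)π),
p = 0.5 − arctan(T)/π; exact 0/1 inputs are clamped to [1e−15,
1 − 1e−15]. The per-participant MPD–CBF profile correlation is the
Pearson R across regions between a subject's MPD vector and matched
regional-CBF vector (≥ 3 complete pairs required), subsequently
regressed on age; a constant profile or fewer than four complete
subjects makes that regression degenerate and it is reported as absent
rather than fabricated.

## The phantom: what it emulates and what it does not

The phantom is a procedural head on the acquisition grid (default
24×34×16 voxels at 2×2×4 mm, the smallest geometry that keeps every
anatomical class, all eight atlas labels and all four distance zones of
both ventricles populated): an ellipsoidal head with a ~2-voxel
subarachnoid shell, a 2-voxel cortical GM ribbon carrying eight
sulcus/cistern atlas labels (four bilateral pairs, painted by octant),
a WM core, two lateral-ventricle blobs, a narrow midline
third-ventricle channel running posteriorly from beneath them (so the
dilation-overlap seed exists by construction), and a small fourth
ventricle. Per-subject geometry is jittered without changing topology.

Generating pseudodiffusivities (mm²/s) are fixed per merged region —
cisterns 5.5–6.5×10⁻³, third ventricle 6×10⁻³, fourth 5×10⁻³, lateral
4×10⁻³, cortical sulci 2.2–2.4×10⁻³ — reproducing the in-vivo ordering
(fast near the skull base and ventricles, slow over the convexity).
Parenchyma decays mono-exponentially at 0.8×10⁻³ mm²/s. The acquisition
emulates the 16-b-value scheme (0–1500 s/mm², triplicate directions for
nonzero b) plus five b = 0 volumes. Noise is Rician (magnitude MRI) by
default with σ = 0.02·S(0) — a choice made here, since low-b SNR is
rarely reported; it yields regional CoVs well below 0.05, consistent
with reproducible MPD estimates. Gaussian and noise-free variants exist
for analytic checks.

Covariates are drawn from realistic population moments (age ≈ N(68, 9),
38.3 % male, education ≈ 12 y, five cognitive scores loaded on one
latent factor). A *planted effect* sets a subject's regional D\* to
base·(1 + rel_sd·u) with u = slope·z_cov + √(1 − slope²)·ε, making the
standardized regression slope of regional D\* on the covariate equal to
`slope` by construction (rel_sd defaults to 0.1, i.e. 10 %
between-subject variation). Cognitive scores are generated independent
of age/sex/education, so the covariate-adjusted slope targets the same
value. An optional age-modulated gain couples regional CBF to the D\*
profile for the MPD–CBF analyses, and an optional linear D\* gradient
along the third ventricle orders the fine-mapping zones.

The phantom does **not** emulate cortical folding, EPI distortion,
motion, partial-volume mixing beyond linear fractions, or realistic
covariance between CSF regions. Passing tests therefore demonstrate
the correctness of the algorithms and statistics under the stated
model, not robustness to those real-data effects.

## Problem sizes and runtimes

The test suite and acceptance script run on one CPU in a few minutes.
Monte-Carlo checks use 50 replicate cohorts of 60 subjects on the
default grid for slope recovery and null calibration; the parcellation
oracle uses 20 random phantoms of up to 20³ voxels; the noisy-fit
oracle uses 1000 voxels. These sizes were chosen as the smallest runs
that make the statistical assertions sharp (e.g. a ±2-binomial-SD band
around the nominal 5 % rejection rate).

## Known limitations

* The WM split is a deterministic two-means soft clustering of
  corrected FA, a simple stand-in for a full EM segmentation; it is
  exact on well-separated bimodal inputs and degrades gracefully
  (all-zero WM plus a warning) on constant ones.
* Free-water estimation, skull-stripping, anatomical segmentation and
  nonlinear atlas registration are upstream of this package: their
  outputs are inputs here, assumed co-registered (a rigid
  nearest-neighbor resampling hook is provided).
* Bi-exponential IVIM (perfusion fraction) and diffusion-tensor
  modelling are out of scope; only the low-b mono-exponential D\* is
  fitted.
* Missing data are handled by listwise deletion per analysis, with
  counts reported; no imputation is attempted.
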