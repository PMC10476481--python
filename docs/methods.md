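# Methods

## Problem setting

Structural MR studies of Alzheimer's disease report two early, measurable
signals: atrophy of medial temporal structures (the hippocampus above
all) and a gradual change of the brain's normal left–right asymmetry
from normal controls (NC) through mild cognitive impairment (MCI) to AD.
`hemisym` operationalizes the second signal: it quantifies each
hemisphere separately over four bilateral structures (gray matter, white
matter, cerebrospinal fluid, hippocampus), derives asymmetry features
from the left/right pairs, and classifies subject pairs (NC-vs-AD,
NC-vs-MCI) with a kernel SVM after wrapper feature selection.

Because no public clinical cohort accompanies this method, the package
includes a synthetic phantom cohort generator as a first-class, tested
component. All quantitative claims made by the test suite are claims
about phantoms, not about patients; what carries over to real data is the
correctness of the feature definitions, the asymmetry algebra and the
leakage-free evaluation protocol, not any particular accuracy number.

## The phantom cohort

Each subject is a 64³ voxel volume at 1.5 mm isotropic spacing (the
defaults mirror the emulated acquisition; any grid size works and the
geometry scales proportionally). The eight regions are mirror-symmetric
axis-aligned ellipsoids — deliberately not atlas-based: ellipsoids are
sufficient to carry volume and texture signal and avoid external atlas
dependencies. Overlaps are resolved by the fixed precedence hippocampus >
gray matter > white matter > CSF, so the hippocampus is always carved out
of surrounding tissue.

Sources of variation, all driven by one integer seed:

- **Inter-subject anatomy.** One lognormal volume factor per structure
  (log-sd 0.05, i.e. ±5 % volume) applied identically to both
  hemispheres. Keeping the jitter mirror-symmetric preserves the exact
  left/right null for control subjects; real anatomical fluctuating
  asymmetry is therefore *not* modeled, which makes the asymmetry
  features cleaner than they would be in patients.
- **Texture.** Each structure is filled with a stationary correlated
  random field: unit white noise smoothed by an isotropic Gaussian of
  width equal to the structure's correlation length (in voxels),
  renormalized to unit variance, scaled by an amplitude and added to the
  structure's base intensity. The right hemisphere samples the field at
  mirrored coordinates, so with identity effects the image is exactly
  mirror-symmetric voxel-for-voxel.
- **Noise.** Rician magnitude noise, out = √((I+n₁)² + n₂²) with n₁, n₂
  zero-mean Gaussians; σ defaults to 2 % of the gray-matter base
  intensity. This is the appropriate model for magnitude MR images and
  has the testable property E[out | I=0] = σ√(π/2).

Disease enters through per-class `ClassEffect`s. A volume scale s
multiplies the affected ellipsoid's radii by s^(1/3), so the parameter
reads directly as a volume ratio. The shipped conditions are graded and
left-lateralized:

| class | left-HC volume | left-GM correlation length |
|-------|----------------|----------------------------|
| NC    | 1.00           | ×1.00                      |
| MCI   | 0.85           | ×1.25                      |
| AD    | 0.70           | ×1.50                      |

MCI is the componentwise midpoint of NC and AD, giving the monotonicity
analysis a known ground truth. The magnitudes are a design choice — the
emulated study reports no quantitative effect sizes — picked once to be
physiologically plausible (≈30 % hippocampal volume loss in AD) and to
reproduce the qualitative orderings (NC-AD easier than NC-MCI; left
features more informative than right), not any specific percentage.

## Feature definitions and numerical choices

Intensities are min–max normalized to [0, 1] over the labeled brain
before texture extraction (min–max rather than z-scoring so gray-level
bins mean the same thing across subjects). Gray levels: uniform
quantization of the in-mask range into Z = 32 levels (max maps to Z−1;
constant regions map to level 0). Z, the offset distance d = 1 and the
13-direction set are recorded in the feature CSV's JSON sidecar; none is
canonical, and all are configurable.

- **GLCM.** Ordered co-occurrences over the 13 unique 26-neighborhood
  directions with symmetric closure (each pair counted both ways),
  aggregated into a single matrix before normalization — simpler and
  deterministic compared with per-direction averaging. Entropy uses
  log₂ with 0·log 0 = 0. Correlation uses the classical marginal
  means/standard deviations and returns 0 (not NaN) when a marginal
  variance vanishes, so constant regions still yield finite feature
  vectors.
- **Run-length matrix.** Maximal collinear runs of equal level strictly
  inside the mask (a mask gap ends a run), accumulated over the same 13
  directions (a direction and its negation define the same runs). The
  gray-level weights of the emphasis features use the 1-based level
  index, so level 0 never divides by zero.
- **First-order.** Mean and population variance of the raw in-mask
  intensities; histogram energy/entropy over 32 uniform bins. In-mask
  values are sorted before reduction — mathematically a no-op, but it
  makes mirror-image regions reduce in the same floating-point order, so
  the left/right null is exact to the last bit.
- **Asymmetry.** The difference feature defaults to |L − R| (the
  magnitude is what the classifier consumes); the signed form is
  available by flag. Ratio features L/R drop the whole column if any
  subject's denominator is within 1e−12 of zero, rather than imputing.

Both texture matrices are verified against independent brute-force
enumeration oracles (naive per-voxel loops) to < 1e−12 on random masked
volumes; this, not any printed example, is the binding correctness
property.

## Selection and evaluation

The emulated study never specifies its feature-selection algorithm, so
the selector here is a standard, explicitly documented stand-in — the
package's largest inferred component:

1. **Filter:** Fisher score
   F = Σ_c n_c(μ_c − μ)² / Σ_c n_c σ_c² per feature; perfect separation
   (zero within-class variance, positive between) gets a +∞ sentinel
   ranked above all finite scores; features constant in both classes
   score 0. Only the top 40 ranked features enter the wrapper — a
   tractability knob that also stabilizes the greedy search.
2. **Wrapper:** sequential forward selection maximizing stratified
   5-fold CV accuracy of an RBF-SVM (C = 1, width = median pairwise
   distance), stopping at max_k = 15 features or when the best
   improvement drops below delta_min = 0.002. Ties break by higher
   Fisher score, then lexicographic name, making the procedure fully
   deterministic given the seed.

Monotone flags are strict (ties do not count) and are computed from
class means only — on training data when used inside an evaluation.

Classification uses the soft-margin kernel SVM; the dual is solved by
scikit-learn's SVC and the model stores support vectors, dual
coefficients βₒyₒ and bias q*, from which the decision function
sgn(Σ βₒyₒK(xₒ, x) + q*) is reconstructed and checked against the solver
to < 1e−8. RBF is the default kernel (the usual choice for this problem
and the best performer among the three offered); the polynomial and
sigmoid kernels are available.

Evaluation is stratified nested cross-validation: by default 5 outer
folds × 5 repeats, with standardization (train-fold mean/sd), feature
selection and the (C, u) grid search — C ∈ {0.1, 1, 10, 100}, RBF width
∈ {0.25, 0.5, 1, 2, 4} × median pairwise distance — all performed inside
each outer training fold. The emulated study does not state its
validation protocol; nesting is a deliberate divergence that prevents
selection leakage, at the cost of reporting more conservative numbers
than a leaky protocol would. A no-selection mode provides the
"before selection" comparison arm. Inner loops reuse the outer fold's
standardization rather than re-standardizing per inner fold; with
min–max-bounded features the difference is negligible and the code is
simpler.

## Problem sizes

The full shipped conditions (50 subjects per class, 64³) are the
`RunConfig` defaults. The stochastic test suite and the acceptance
script run the same pipeline at a reduced size — 30 subjects per class
on a 48³ grid, single-repeat outer CV — which preserves every qualitative
property while keeping a full run in tens of seconds. Reported metrics
at that size: NC-vs-AD is typically separated perfectly (the phantom's
volume channel carries no measurement noise, so a 30 % left-HC deficit
against a 5 % jitter is an easy margin), NC-vs-MCI slightly less so, and
the right-hemisphere variant falls to near chance — the expected ordering
for a left-lateralized ground truth.

## Known limitations

- Ellipsoid geometry has no cortical folding, no partial-volume mixing,
  no bias field, and no k-space physics; the phantom validates the
  pipeline, not radiological realism.
- Control subjects are exactly symmetric: natural fluctuating asymmetry
  is absent, so difference/ratio features are far cleaner than in real
  cohorts and phantom accuracies overstate what clinical data would give.
- Real-scan preprocessing (rigid registration, skull stripping, tissue
  segmentation) is out of scope; label maps are inputs.
- Three-class classification is not provided; the study design is the
  two pairwise problems NC-vs-AD and NC-vs-MCI.
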