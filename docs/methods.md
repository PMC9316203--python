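# Methods

This note records what stylemorph computes, the choices made where the
design was genuinely open, and what the synthetic data can and cannot show.

## Outline model and standardization

A specimen is a single closed, counterclockwise 2D contour of the larval
head capsule together with both stylets, in arbitrary but consistent length
units.  The anterior–posterior midline is the y axis, anterior up.  The
digitization protocol mirrors standard practice for these larvae: only the
better-accessible body half is traced (fossil inclusions rarely show both
sides equally), the stylet is rigidly rotated to a straightened pose, the
half is mirrored across the midline, and the result is resampled at equal
arc length.

Open choices resolved here:

* **Rotation center for straightening.** The protocol does not specify a
  pivot; we rotate the blade about the innermost *proximal* landmark (its
  articulation end), which leaves head-capsule geometry exactly untouched
  and preserves all pairwise distances within the blade (verified to 1e-9).
* **Landmark detection.** The innermost distal/proximal points may be given
  explicitly per specimen; a heuristic detector (sharpest post-tip corner on
  the midline-facing margin) is provided, and explicit indices always win.
* **Resampling.** Equal arc-length resampling is iterated to its fixed
  point, because a single pass equalizes spacing only along the *source*
  polygon; after iteration consecutive spacing is uniform to 1e-6 relative
  and the operation is idempotent at that tolerance.  The first sample is
  placed at the topmost midline crossing (the head's anterior pole) so the
  starting point is consistent across specimens by construction.  Default
  512 points for file-based input; the synthetic study uses 256, which
  leaves the cumulative harmonic power at 20 harmonics above 0.999.

## Elliptic Fourier coding

Coefficients are the exact Fourier integrals of the piecewise-linear
contour (the classical polygon closed form), not an FFT — so they match a
dense quadrature of the defining integrals to ~1e-11 and carry no sampling
assumptions beyond the polygon itself.  Chain-code input is converted to a
polygon first, keeping grid quantization out of the main path.

Normalization is the first-harmonic procedure: the starting point is moved
to the first-harmonic ellipse's semi-major axis, the shape rotated so that
axis lies along +x, and all coefficients divided by the semi-major length
(stored as `size_scalar`, so size remains recoverable).  After this
`a1 = 1`, `b1 = c1 = 0`, and `d1 > 0` for counterclockwise contours.  Two
canonical forms remain (the two ends of the major axis); we keep the
lexicographically larger coefficient vector, a shape-intrinsic rule that is
invariant under similarity transforms and reduces to the identity for
180-degree-symmetric shapes.  Shapes whose first harmonic is nearly
circular have no stable orientation; none of the head outlines are in that
regime.  Note that under the arc-length parametrization even a perfect
ellipse is not a pure first harmonic — examples and tests account for this.

Default 20 harmonics (the conventional SHAPE-style default; the harmonic
power sweep shows >99.9% of power captured on head outlines), recorded in
every output manifest.

## Morphospace

The coefficient matrix drops `a1, b1, c1` (constants after normalization)
and keeps `d1`, giving `4H − 3` columns.  PCA is a centered,
*unstandardized* covariance decomposition (computed by SVD for stability);
z-scoring is available but off by default, matching outline-morphometrics
convention where coefficients share a scale.  Loadings' signs are fixed so
each one's largest-magnitude entry is positive.

"Effective" components follow the mean-eigenvalue rule (eigenvalue strictly
above the mean), with a cumulative-90% alternative behind a config switch.
If all eigenvalues tie (an isotropic cloud) the rule is uninformative and
the pipeline falls back to k = 2 with a warning.

## Disparity

Both metrics are computed on the effective-PC scores only:

* **Sum of variances** (occupied size): per-component sample variance with
  the n−1 denominator (matching R's `var()` as used by the dispRity
  ecosystem), summed; equals the trace of the group covariance.
* **Average displacement** (position): mean over members of
  ‖x‖ / ‖x − centroid‖.  Members exactly at the centroid are excluded with
  a warning; a group entirely at its centroid is an error.

Bootstrap: 1000 replicates by default, drawing with replacement; rarefaction
draws a fixed common size inside each replicate.  The default rarefaction
target is the smallest group with n ≥ 3 (the Miocene slice, n = 9, in the
study design).  Groups with n < 3 are reported but flagged "too small for
disparity"; rarefying below 3 is refused because a 2-point variance is
maximally unstable.

## Tests

* **PERMANOVA** — one-way pseudo-F on squared Euclidean distances,
  F = (SSB/(g−1)) / (SSW/(N−g)), null by free permutation of labels
  (9999 by default).  When the number of distinct relabelings is at most
  the requested permutation count the null is enumerated exhaustively and
  the p-value marked exact; otherwise p = (1 + #{F* ≥ F}) / (1 + B), which
  cannot be zero.  Verified against brute-force enumeration, scikit-bio's
  implementation (statistic), and a 1000-simulation type-I-error study
  (rejection rate at α = 0.05 inside the 95% binomial band).
* **Pairwise disparity tests** — the protocol names "bootstrapped,
  Bonferroni-corrected random sampling tests" without a null construction;
  we resample both pseudo-groups from the *pooled* pair, each at the
  smaller group's size, which is exchangeability-valid under the no-
  difference null, and compare |metric(S1) − metric(S2)| to the observed
  full-sample difference.  Bonferroni correction counts only the pairs
  actually tested; pairs with a group under 3 specimens are reported as
  untestable (the n = 2 Eocene case) instead of contributing a correction
  factor.
* Two grouping schemes ship: coarse fossil-vs-extant (the headline
  comparison) and the four time slices.

## Synthetic data: what it emulates, and what it does not

The generator builds each head as one closed curve: a superellipse head
capsule (exponent 2.5), a circular-arc posterior rim whose signed sagitta
is `posterior_rim_curvature × head_width`, and two tapered quadratic-Bézier
stylet blades fused to the anterior rim, optionally bowed and with cosmetic
tooth bumps on the inner margin.  Specimen noise enters through the shape
*parameters* (Gaussian around group means, invalid draws rejected with a
100-retry cap), never through vertices, so the generating truth of every
specimen is recoverable; per-vertex jitter exists only as an explicit
robustness flag.  Antennae and palps are omitted: they are tiny and slender
in these larvae and would be invisible at outline resolution.

The default design reproduces the study's composition — 243 extant, 46
Cretaceous, 9 Miocene, 2 Eocene — and its qualitative structure:

* three dominant factors of decreasing variance (relative stylet length,
  posterior-rim curvature, stylet thickness: extant SDs 0.16, 0.10, 0.020),
  so the mean-eigenvalue rule returns three effective PCs;
* extant dispersion twice the Cretaceous on every parameter (the extant
  fauna shows the larger occupied morphospace);
* a Cretaceous mean offset on the low-variance thickness axis
  (0.19 vs 0.12, plus a slight rim shift), placing many Cretaceous
  specimens outside the extant range on that axis;
* the two Eocene larvae offset even further on the thickness axis (0.24)
  with slightly longer stylets — an outlier morphology beyond the
  Cretaceous range, as in the source fauna;
* Miocene specimens drawn inside the extant cloud.

Magnitudes were fixed once, during generator design, so that these
qualitative statements hold with comfortable statistical margin across
seeded replicates of the full pipeline; they are defaults of the artifact,
not estimates of the real fauna.  Passing tests on this design show that
the *pipeline* recovers known structure of the stated kind — they say
nothing about real owllion larvae, whose outlines involve drawing choices,
preservation artifacts, allometry and phylogenetic structure that the
generator does not model.  The printed explained-variance percentages of a
synthetic run (e.g. 79/11/6) are likewise properties of the generator, not
of the published morphospace (72.4/17.9/3.4); the report module compares
published-style rounded percentages only for within-rounding consistency
(tolerance 0.15 percentage points), never for equality.

## Numerical choices and problem sizes

* EFA oracle agreement: 1e-8 budget, measured ~4e-11 on random polygons.
* Similarity invariance of normalized coefficients: 1e-6 budget, measured
  ~1e-14; the lexicographic tie-break uses a 1e-12 floor.
* PCA uses SVD with a relative rank cutoff of 1e-12 on singular values.
* Permutation p-values use a 1e-12 tie tolerance on F comparisons.
* The simulation-based checks run the full pipeline at 256 outline points,
  20 harmonics, 999 permutations/resamples, 100 replicate datasets — sizes
  chosen to make replicate studies routine on a laptop while keeping every
  stage identical to a full-size run.

## Known limitations

* The chain-code writer quantizes off-grid outlines (bounded by about one
  grid unit in Hausdorff distance); its dialect targets the common
  `name x0 y0 n codes…` layout and the reader is lenient on whitespace.
* The canonical orientation is undefined for first-harmonic-circular
  shapes (inherent to first-harmonic normalization).
* Average displacement is undefined for groups collapsed onto their
  centroid; such groups are reported with an `undefined` flag.
* No between-group PCA, phylogenetic correction, disparity-through-time
  binning, or open-curve Fourier variants.
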