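# stylemorph

Outline morphometrics for the head capsules of antlion- and owlfly-type
lacewing larvae ("owllions"): elliptic Fourier shape coding of closed
head+stylet outlines, a PCA morphospace, group disparity with bootstrap and
rarefaction, and permutation tests comparing fossil time slices (Cretaceous,
Eocene, Miocene amber inclusions) against the extant fauna.

The package is aimed at paleobiologists and morphometricians who work with
digitized 2D outlines of stylet-bearing larval heads and want a reproducible,
scriptable version of the classic SHAPE + dispRity workflow in Python:

1. **Standardization** — half-outlines are drawn from the better-accessible
   body side; the stylet (the piercing blade formed by the coupled mandible
   and maxilla) is rigidly rotated about its proximal articulation so the
   line through its innermost proximal and distal points parallels the
   anterior–posterior midline; the half is mirrored into one closed contour
   and resampled at equal arc length from the anterior pole.
2. **Elliptic Fourier analysis** — each closed contour `(x(t), y(t))` with
   perimeter `T` is decomposed as

   ```
   x(t) = A0 + Σₙ aₙ cos(2πnt/T) + bₙ sin(2πnt/T)
   y(t) = C0 + Σₙ cₙ cos(2πnt/T) + dₙ sin(2πnt/T)
   ```

   with the exact piecewise-linear closed form (no quadrature or FFT error),
   then normalized to the first harmonic so translation, rotation, scale and
   starting point are removed (`a₁ = 1`, `b₁ = c₁ = 0`).
3. **Morphospace** — PCA of the normalized coefficient matrix; the
   *effective* components are those with eigenvalues above the mean
   eigenvalue.
4. **Disparity** — occupied *size* as the sum of variances of a group's
   scores across the effective PCs, and *position* as the average
   displacement (mean ratio of each specimen's distance from the morphospace
   origin to its distance from the group centroid), both with bootstrap CIs
   and rarefaction to a common sample size.
5. **Inference** — one-way PERMANOVA (pseudo-F on Euclidean distances, free
   label permutation, exact enumeration for tiny designs) and bootstrapped,
   Bonferroni-corrected pairwise tests of disparity differences with a
   pooled-resampling null.

Because the original study's hand-drawn outlines are not available in
machine-readable form, the package ships a first-class synthetic generator
(`stylemorph.synthetic`) that emulates the study design: 300 specimens split
243 extant / 46 Cretaceous / 9 Miocene / 2 Eocene, with group structure
expressed in posterior-rim concavity, relative stylet length and stylet
thickness — the three interpretable shape axes of such a morphospace.

## Worked example

Run the full synthetic study from the shell:

```sh
stylemorph run --seed 1 --out results/study
stylemorph report --eigen results/study/eigen.json
```

which prints (seed 1):

```
PC1: 79.1% of overall variation
PC2: 11.0% of overall variation
PC3: 6.0% of overall variation
cumulative over 3 components: 96.1%
```

Three effective principal components emerge; PC1 tracks relative stylet
length, PC2 the posterior-rim curvature and PC3 stylet thickness.  The
results tree also contains per-group disparity (`disparity.csv` — the extant
fauna occupies the largest region: sum of variances 0.0144 vs 0.0026 for the
Cretaceous slice at seed 1) and the fossil-vs-extant tests (`tests.json`):

```
PERMANOVA F=12.12 p=0.0001       # position difference, very significant
size test     p_bonferroni=0.001 # occupied-size difference
position test p_bonferroni=0.001 # average-displacement difference
```

The n=2 Eocene group is carried through but flagged `too small for
disparity` rather than silently tested.

The same pipeline runs on real data: `stylemorph run --config my.json` with
`"synthetic": false` and an `input_path` pointing at XY-coordinate CSV, TPS
outline records, or SHAPE-style Freeman chain-code files (see
`stylemorph.outlines`), plus a `specimen_id,group` labels CSV.  Each stage
(`simulate`, `preprocess`, `efa`, `pca`, `disparity`, `test`, `report`) is
also available as its own subcommand operating on intermediate files.

From Python:

```python
from stylemorph import (default_study_groups, generate_dataset, compute_efa,
                        normalize, assemble_matrix, pca)

ds = generate_dataset(default_study_groups(), n_points=256, seed=1)
coeffs = [normalize(compute_efa(o, 20)) for o in ds.outlines]
emb = pca(*assemble_matrix(coeffs), groups=[c.group for c in coeffs])
print(emb.effective_k, emb.proportions[:3].round(3))  # 3 [0.791 0.11 0.06]
```

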