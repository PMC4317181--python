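# Methods

This note documents the statistical models, numerical choices and known
limitations of `shouldergm`, and states exactly what the synthetic-data
generator does and does not emulate.

## Shape model and superimposition

A specimen is an ordered set of `k` named 3D landmarks. Shape is the
equivalence class of a configuration under translation, isotropic scaling
and rotation. We remove these nuisance parameters by centring, scaling to
unit centroid size (`CS = sqrt(Σ ‖x_j − x̄‖²)`), and rotating with the
Kabsch/SVD solution. Reflections are disallowed by default: the data model
assumes anatomical (chiral) structures with left elements explicitly
mirrored at load time, so an alignment that silently reflects would hide a
digitising error. `allow_reflection=True` is available for symmetry
checks.

**Procrustes distance.** The default is the full Procrustes distance: after
reducing both configurations to unit preshapes and rotating optimally, the
target is also optimally scaled (`β = Σ singular values`) and the distance
is the root summed squared coordinate difference of the superimposed
forms, equal to `sqrt(1 − β²)`. We evaluate it from the residual rather
than the analytic shortcut because `sqrt(1 − β²)` loses all precision for
near-identical shapes. A rotation-only (partial) variant is available via
`scale=False`. The full distance is a metric on shape space; the test
suite checks the triangle inequality on random triples.

**GPA.** Iterative: rotate every unit-size configuration to the running
consensus, replace the consensus by the normalised mean, repeat. The
objective `Σ_i ‖X_i − mean‖²` is non-increasing by construction (each
rotation step minimises its own term; the mean minimises the sum over
consensus choices) and the suite asserts this on every run. Convergence is
declared when the consensus root-mean-square change drops below `tol`
(default `1e-10`, `max_iter=100`); non-convergence is flagged, not fatal.
The consensus orientation is arbitrary (initialised from the first
specimen); all reported statistics are invariant to it, which the
rigid-motion invariance tests verify to `1e-8`.

**Tangent projection.** Aligned flat configurations `x` are projected onto
the affine hyperplane through the unit consensus `c` orthogonal to it:
`x_t = x + (1 − x·c) c`. The consensus is a fixed point, the map is
idempotent, and the correction is `O(d²)` in the Procrustes distance, so
for biological-scale variation tangent and Procrustes coordinates are
nearly identical. The orthogonal (rather than stereographic) projection
follows common practice in the major GM packages.

## Sliding semilandmarks

Semilandmarks on anchored curves carry no along-curve homology. Each outer
iteration runs GPA, then for every specimen and every semilandmark
independently computes the local unit tangent as the normalised difference
of the two curve neighbours (an anchor counts as a neighbour) and moves
the point along that tangent line by the closed-form step
`s = (consensus_point − point)·t`, the exact 1D minimiser of the
specimen's squared distance to the consensus; then re-runs GPA. Slid
positions are mapped back through the inverse of each specimen's
similarity transform, so homologous (type-II) landmark coordinates are
preserved bit for bit. The loop stops at relative objective improvement
below `1e-8` or after 10 outer iterations, and aborts with a diagnostic if
the objective ever increases.

Defaults per protocol: the four humeral articular-arc semilandmarks slide;
the eight glenoid semilandmarks do not (their sliding status is
protocol-configurable, and `--slide all|none` overrides). Sliding is along
straight tangent lines without re-projection onto the curve polyline.

*Known limitation.* Pure Procrustes-distance sliding along unbounded
tangent lines is degenerate in the long-iteration limit: semilandmarks can
drift collectively off the anatomy while the unit-size constraint shrinks
the remainder of the configuration, so the objective keeps creeping
downward without a meaningful fixed point. With the default cap of 10
outer iterations this effect is negligible (the jittered-arc recovery test
shows along-curve error reduced in 100/100 replicates, RMS ≈ 0.049 →
0.012 rad), but the iteration cap should not be raised casually; a
bending-energy criterion or curve re-projection would be the principled
fix and is out of scope here.

## Between-group PCA

The between-group covariance is the covariance (denominator `g − 1`) of
the `g` group-mean tangent vectors, each group weighted equally regardless
of its sample size; the grand mean is the unweighted mean of group means.
Specimens are scored by projecting their deviation from the grand mean
onto the eigenvectors. Exactly `min(g − 1, dim)` components have nonzero
variance, and percent variance is reported over those retained components,
so the cumulative column ends at 100. Singleton fossil specimens are
carried through GPA (configurable) but never enter the group means or the
eigendecomposition; they are projected post hoc, so adding or removing a
fossil leaves the axes bit-identical (tested).

bgPCA is known to exaggerate group separation when the number of variables
is large relative to samples; this implementation reproduces the classic
method deliberately and leaves cross-validated variants out of scope.
Scores, not just group centroids, are reported because the scatter of
individuals around the group structure is the object of interest.

**Equal-frequency ellipses.** Under a bivariate Gaussian model the squared
Mahalanobis radius is χ²(2), so the ellipse containing a fraction `level`
of the distribution has semi-axes `sqrt(λ_i · χ²_level(2))` along the
score-covariance eigenvectors (default level 0.95).

## Shape regressions

Shape (all `3k` tangent coordinates jointly) is regressed on one scalar by
per-coordinate OLS; with a single predictor the coefficient vector is
`cov(x, y_j)/var(x)`. Percent variance explained is the predicted sum of
squares over the total, summed across coordinates; the decomposition
`SS_total = SS_pred + SS_resid` is asserted to `1e-8` relative. The
regression score of a specimen is the projection of its centred shape on
the unit coefficient vector. Significance uses a seeded permutation test
on %variance with the add-one correction; the default 10,000 permutations
resolve p down to ~1e-4, and the null distribution of p is verified
uniform by a KS test over 200 replicates. Covariates are used raw (not
log-transformed): predicted shapes are stated at natural covariate values
(e.g. CS 40 vs 160), and a log option would change only the covariate
handed in. Fossils never enter the fit but receive residuals and scores
against the extant model.

Humeral torsion enters as a per-specimen scalar covariate in degrees under
the 90°-offset convention for posteriorly facing humeral heads; measuring
torsion on 3D models is out of scope. The torsion summary table reports
per-group mean, N and sample SD (denominator `n − 1`), an overall row, and
fossils individually.

## Affinity structures

Group centroid shapes are arithmetic means of aligned Procrustes
coordinates; fossils are their own singletons. The distance matrix between
centroids uses pairwise Procrustes superimposition of the centroid shapes
(default), with a Euclidean-tangent option for comparison with packages
that skip re-superimposition; for data of this kind the two differ by well
under the between-group signal. The MST is Kruskal over edges sorted by
(weight, lexicographic label pair), making ties deterministic; the test
suite verifies minimal total weight against exhaustive enumeration of all
`n^(n−2)` spanning trees (Prüfer decoding) up to `n = 8`. Ward clustering
uses the Ward.D2 convention (Lance–Williams on squared distances, via
scipy's linkage); a `variant="D"` option recurses on raw distances. Merge
heights are exported as a newick string with branch lengths
`parent_height − child_height`, hence ultrametric.

## Synthetic data: what it emulates, what it does not

The generator draws each specimen as

```
group mean + allometric_vector · (CS − CS_mid) + N(0, σ²) per coordinate,
```

normalised to unit size, scaled to its target CS, and placed at a random
rotation and translation; a stated fraction is emitted mirrored as
left-sided. Group means are a common anatomical template (a hemisphere
with four insertion-facet clusters for the 25-point humerus protocol, a
shallow oval dish for the 13-point glenoid, a deterministic spherical
spiral otherwise) displaced by seeded random directions of magnitude
`mean_offset_magnitude`. Fossils are convex combinations of group means
plus the same noise. All randomness flows from one integer seed through
independent named streams, so identical specs give bit-identical datasets.

Default study conditions mirror the comparative samples this toolkit was
built around: 7 extant genus-level groups with n = (20, 9, 18, 20, 15, 17,
34) humeri (N = 133) or (11, 6, 16, 16, 14, 14, 19) glenoids (N = 96),
within-group σ = 0.02 shape units, separation 0.1, CS spanning ~40–160 mm
(humerus) or ~15–60 mm (glenoid), and per-group torsion means/SDs at the
published per-genus values (e.g. Lagothrix 94.17° ± 5.86, Gorilla 152.71°
± 7.11). The allometric displacement is injected in the tangent space at
the template (orthogonal to translations, scale, and the template itself),
because only that component is identifiable to any Procrustes-based
analysis; recovery tests compare the fitted coefficient vector with the
injected vector's shape-tangent component after rotating frames together.

What the generator does **not** emulate: correlated (anatomically
structured) landmark covariance, measurement error that varies by landmark
type, missing landmarks, allometric curvature, group-specific allometries,
or phylogenetic covariance among group means. Passing recovery tests
therefore demonstrate correctness of the algorithms under an idealised
isotropic model, not robustness to real digitising error structure.

## Tolerances and degenerate inputs

- GPA: `tol 1e-10` on consensus RMS change, `max_iter 100`.
- Sliding: relative objective tolerance `1e-8`, `max_outer 10`,
  divergence abort at relative increase `1e-9`.
- Eigenvalue floor `1e-12` (relative to the largest) for counting nonzero
  components and truncating PCA bases.
- Degenerate configurations (all points coincident) and zero-variance
  covariates raise immediately; singular score covariances warn and return
  a degenerate ellipse; empty torsion groups are dropped with a warning.
- Specimens failing protocol validation (wrong landmark count, non-finite
  coordinates) are reported per specimen; file readers refuse datasets
  whose point counts contradict the protocol.

## Problem sizes used in the shipped checks

The structural acceptance computation runs the full chain on 123-specimen
(25 landmarks) and 85-specimen (13 landmarks) simulations — the
seven-group dimensionality result is analytic, so these sizes exercise it
at realistic scale while keeping a full run under a minute. Recovery
checks use n = 100 specimens at σ = 0.01 (allometry), 100 seeded
replicates (fossil assignment, sliding recovery), and 200 replicates
(permutation-p calibration).
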