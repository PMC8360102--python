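# Methods

## Object-symmetry model

A palatal configuration is a matrix of 41 landmarks × 3 coordinates with an
internal midline. The template schema fixes the bilateral structure: the
pairing map is an involution (2↔3, 6–9↔10–13, 14–25↔26–37 in order) whose
fixed points are the seven midline landmarks {1, 4, 5, 38–41}. The
reflected, relabelled copy of a configuration is `x → −x` followed by the
pairing permutation. Because reflection in *any* plane produces the same
mirror shape up to a rigid motion, the raw digitising frame does not need
to be midsagittal for the analysis; a midsagittal frame (best-fit plane
through the midline landmarks rotated to x = 0, total least squares) is
constructed only where the literal x-negation must be meaningful —
template completion by mirroring, and symmetry checks of outputs.

Superimposition is full generalized Procrustes analysis: centre each
configuration, scale to centroid size 1, then iterate optimal rotation to
the consensus (the arithmetic mean of aligned configurations) until the
consensus root-mean-square change is below 1e-10 or 100 iterations.
Rotations come from the SVD of the cross-covariance with the determinant
sign corrected along the smallest singular direction, so they are always
proper: reflected copies must not be silently un-reflected, or the entire
asymmetric signal would vanish. The final solution is rotated so the
consensus optimally aligns with the first configuration's input
orientation; this makes outputs reproducible across runs. It also means a
global rotation of all inputs rotates the outputs by the same amount —
all shape-space quantities (distances, DA/FA scalars) are invariant, and
the test suite checks frame-dependent quantities up to one global
rotation.

Originals and reflected copies are pooled into a single joint GPA by
default (366 configurations for the full design): between-group DA/FA
comparisons need a common shape space. A per-group mode
(`RunConfig.gpa_mode = "per_group"`) is provided for within-group analyses
that prefer local superimpositions.

## Semilandmarks

The thin-plate-spline kernel is U(r) = −r (the sign that is conditionally
positive definite in 3D, making bending energy nonnegative on the subspace
orthogonal to affine functions of the reference). The bending-energy
matrix is the upper-left block of the inverted TPS system; its null space
is exactly [1, x, y, z] of the reference, so affine maps cost nothing.

Sliding solves, per iteration, the joint linear least-squares displacement
of all semilandmarks along their tangent directions that minimises
trace((Y+ΔY)ᵀ B (Y+ΔY)) with B from the reference (the consensus, during
GPA), then projects slid points back onto their geometry: curve
semilandmarks get one tangent from the polyline (central difference of the
neighbouring vertices, one-sided at endpoints) and are re-projected to the
nearest polyline point; surface semilandmarks get a tangent plane from the
face normal at the nearest mesh point and are re-projected onto the mesh
by an exact point-to-triangle query (Eberly's algorithm, brute force over
faces — template-scale meshes do not need a spatial index). Fixed
landmarks never move. Because projection can undo part of a descent step,
an iteration that fails to decrease the energy is rolled back, so the
reported energy trace is non-increasing by construction. Default: at most
5 inner iterations, relative-decrease tolerance 1e-8, sliding active in
the first 3 GPA outer iterations.

## DA and FA

With aligned original O<sub>i</sub> and reflected copy RR<sub>i</sub>:

- a<sub>i</sub> = O<sub>i</sub> − RR<sub>i</sub>; d<sub>k</sub> = group
  mean of a<sub>i</sub>; DA<sub>k</sub> = ‖d<sub>k</sub>‖;
  FA<sub>i</sub> = ‖a<sub>i</sub> − d<sub>k</sub>‖.
- Per-landmark values are the Euclidean norms over the 3 coordinates at
  each landmark, one scalar per landmark (so the six-group design yields
  6 × 41 = 246 DA observations and 183 × 41 = 7503 FA observations, and
  the scalars satisfy DA² = Σ per-landmark DA²).
- Sign convention: both DA and FA are built from a<sub>i</sub> = O − RR
  and d<sub>k</sub> = mean(a<sub>i</sub>), which makes FA deviations
  exactly centred per group. A mixed convention that defines the group
  vector as mean(RR) − mean(O) merely flips signs and changes no norm; it
  is available for audit via `decompose(..., literal_signs=True)`.
- The symmetric component (O<sub>i</sub> + RR<sub>i</sub>)/2 is an exact
  fixed point of reflect/relabel once expressed in its own midsagittal
  frame; symmetric component ± a<sub>i</sub>/2 reconstructs O and RR
  exactly.

The plain norm ‖d̄‖ is biased upward under within-group noise:
E‖d̄‖² = ‖δ‖² + tr(Σ)/n. `da_magnitude_bias_corrected` subtracts the
plug-in estimate Σᵢ FA²ᵢ / (n(n−1)) before taking the square root (clipped
at zero). The pipeline tables keep the conventional uncorrected DA — it is
the field's standard statistic — and the corrected estimator is used when
comparing estimates against known injected magnitudes.

## Statistical battery

- **Procrustes ANOVA (within group).** Individuals × reflection two-way
  decomposition of the flattened shape coordinates: df (n−1, 1, n−1), F
  ratios against the interaction mean square. p values by residual
  randomisation under the reduced model (RRPP, 999 permutations by
  default): the reflection effect permutes individual-centred residuals,
  which reduces to random O/RR sign flips per individual (an exact group
  symmetry of the null); the individual effect permutes reflection-centred
  residuals across all 2n observations. Permutation p values are
  (count + 1)/(n_perm + 1), so the attainable floor is 1/(n_perm + 1).
- **Between-group ANOVA on per-landmark DA/FA values** is classical
  one-way with a parametric F p value (the reported p values at these
  sample sizes are far below any permutation floor), with Tukey–Kramer
  HSD intervals from the studentized-range distribution. No additional
  Bonferroni is stacked on Tukey-adjusted p values — the double correction
  is statistically redundant. Landmark-level observations are treated as
  exchangeable replicates here, deliberately mirroring common practice in
  the field despite their spatial autocorrelation; a caveat is logged.
- **PERMANOVA** computes the pseudo-F from the Gower-centred decomposition
  of squared distances and permutes group labels; on univariate Euclidean
  distances it equals the classical one-way F exactly (tested).
- **Dispersion homogeneity** embeds the distance matrix by principal
  coordinates, keeping negative-eigenvalue axes as imaginary parts
  (squared embedded distances subtract the imaginary contribution,
  clipped at zero), measures each point's distance to its group centroid
  (centroid, not spatial median), and permutes labels with full
  recomputation of centroid distances.
- **Rank tests.** Kruskal–Wallis (tie-corrected, chi-square p), Dunn's
  post-hoc Z from mean midranks with tie-corrected variance and Bonferroni
  over all pairs, Spearman as Pearson on midranks, Mann–Whitney exact by
  enumeration when both n ≤ 8 without ties and otherwise the normal
  approximation with tie and continuity corrections. All-tied inputs
  return H = 0 with a warning instead of failing.
- Every stochastic routine takes an explicit seed; the pipeline spawns
  per-stage seeds deterministically from the run seed.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes, on
an analytic stand-in for the palate: a triangulated half-ellipsoid dome
(default semi-axes 25 × 30 × 12 mm, so the vault spans ~50 mm), two
alveolar-ridge polylines and a median-suture polyline, with the 41
template points placed exactly on their assigned geometry (curve
semilandmarks at 20/40/60/80% arc length, surface semilandmarks on a
parametric grid of the right hemi-dome mirrored exactly to the left).

An individual in group k is

    mean_k + symmetric deviation + ½·δ_k + ½·φ_i + measurement noise,

then a random rigid motion plus ±3% scale jitter. `mean_k` is the template
under isotropic growth scaling (0.55–1.0 across the six age groups) with
mild vault deepening — a deliberately simple, non-biological growth model.
δ_k (the group DA field) and φ_i (individual FA draws) are antisymmetrised
(via (v − mirror(v))/2) **and projected orthogonal to the similarity
tangent space** at the group mean: superimposition removes net
translation/rotation/scale components of any displacement field, so only
the projected part is recoverable as shape asymmetry — injecting pure
shape displacements is what makes the serialized ground-truth norms
meaningful (recovery is then within ~1% in the noise-free linear regime).
Default DA magnitudes are 0.15–0.45 mm (Frobenius norm), placed on the
anterior surface semilandmarks (14–16/26–28) or the posterior ento-molar
landmarks (2, 3) depending on the group; σ_fa = 0.15 mm,
σ_sym = 0.5 mm, and σ_noise = 0.05 mm, the accuracy of a structured-light
surface scanner. Injected asymmetry above 2% of centroid size triggers a
warning (the Procrustes projection is no longer near-linear there).

What the generator does **not** emulate: biomechanical loading, spatially
correlated FA, age-dependent FA variance, antisymmetry (bimodal
asymmetry is out of scope throughout), digitisation error correlated
along curves, or real palatal shape. Passing tests therefore demonstrate
the correctness and calibration of the machinery, not biological claims
about real palates.

## Problem sizes and calibration choices

The test suite and acceptance script run: the full six-group design (183
individuals, 999 permutations; ~2 s end to end), DA recovery at injected
magnitudes 0.25/0.5/1.0 mm with n = 30 and 20 replicates, and type-I
calibration of the reflection, PERMANOVA, dispersion and Kruskal–Wallis
tests from 500 null simulations of an 18-individual group with 199
permutations each. 500 null draws put the ±0.02 acceptance band at about
two binomial standard errors around 0.05; at 200 draws the same band is
only ~1.3σ and an exactly calibrated test would still miss it ~8% of the
time.

## Known limitations

- FA estimates absorb a small rotational leakage term of order
  (symmetric deviation × asymmetry)/centroid size — a property of
  object-symmetry Procrustes decomposition, visible in the generator as
  imperfect per-individual direction recovery when symmetric variation is
  large.
- Sliding against per-configuration geometry inside GPA assumes the
  geometry is expressed in each configuration's raw frame; with no
  geometry supplied, GPA runs without sliding (synthetic landmarks are
  geometrically homologous by construction).
- The occlusal-plane-based midsagittal convention used in some digitising
  protocols is replaced by the best-fit midline plane; the two coincide
  for symmetric configurations.
- Tukey intervals use the pooled-variance Tukey–Kramer form; no
  heteroscedasticity-robust variant is provided.
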