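# Methods and design notes

This note records the models, conventions and numerical choices behind
`conglobe`, and the rationale for each default. Notation follows standard
geometric-morphometrics and cladistics usage.

## 1. Landmark data and semilandmark resampling

Outlines of three traits are analysed in 2-D: **head**, **pronotum** and
**elytra**. Digitised curves are resampled to fixed numbers of equally
spaced points by arc length (linear interpolation along the polyline):

| trait    | semilandmarks | rationale                                    |
|----------|---------------|----------------------------------------------|
| head     | 30            | shorter, simpler outline                     |
| pronotum | 50            | strongly curved in conglobating taxa         |
| elytra   | 50            | main dorsal shield, highest shape variance   |

Open curves keep both endpoints (n points, n−1 equal segments); closed
curves use n points with spacing L/n so the first point is not duplicated.
TPS files follow the usual `LM=`/`CURVES=`/`POINTS=`/`ID=`/`IMAGE=`/`SCALE=`
conventions; `SCALE` multiplies all coordinates. Character matrices use
TNT `xread` (dimensions as *nchar ntax*) or NEXUS, with `?` = missing and
`-` = inapplicable.

## 2. Generalized Procrustes analysis

GPA centres each configuration, scales it to unit centroid size, and
iteratively rotates all configurations onto their mean (tolerance 1e-10,
at most 100 iterations). Rotations are constrained to be proper
(det = +1, via the sign-corrected SVD of the cross-covariance), so
specimens are never reflected. After convergence the whole dataset is
rotated into a **canonical frame** — principal axes of the consensus, with
a deterministic sign rule — so the result is exactly invariant to the
orientation, position and scale of the inputs and GPA is idempotent.

## 3. Ordination and permutation tests

PCA uses the SVD of the centred data; components with eigenvalues below
`max(λ₁, 1)·1e-12` are dropped, and each axis's sign is fixed by making its
largest-magnitude loading positive.

Mahalanobis distances use the pooled within-group covariance
(divisor n−g). Because landmark data usually have p ≫ n, distances are
computed in a within-group principal subspace: components are kept while
the covariance condition number stays below 1e8, capped at
min(n−g, 20) dimensions. The cap keeps the metric stable at the study's
sample sizes; it is a bias/variance trade-off, not a mathematical
requirement. CVA whitens by the pooled within-group covariance and
extracts at most g−1 canonical axes.

Permutation tests permute group labels as a whole and compare the
permuted statistic to the observed one with ≥ tie handling. Monte-Carlo
mode uses +1 smoothing, p = (1 + X)/(N + 1), with N = 10,000 rounds and
seed 20220806 by default. For small samples an **exact mode** enumerates
every distinct label arrangement and reports the exceedance fraction
directly (the identity arrangement is included, so p > 0 without
smoothing). When p ≫ n the data are first reduced to their row space via
PCA; this is an isometry of the specimens, so Mahalanobis distances and
permutation p-values are unchanged.

## 4. Parsimony

Tree length is computed by the **Sankoff dynamic programme** (exact for any
tree, including polytomies, and any unordered state set); `?` and `-`
contribute zero cost everywhere. The consistency index is CI = m/s and the
retention index RI = (g−s)/(g−m), with m the minimum and g the maximum
conceivable steps per character (missing cells excluded); published values
are compared after rounding to two decimals.

Heuristic search uses random-addition starting trees followed by **TBR**
branch swapping to a local optimum, keeping all equally optimal trees
(default 1,000 replicates, tree buffer 10,000). Lengths during search are
computed by a vectorised Fitch pass over bitmask-encoded characters with
duplicate columns collapsed into weights. Exhaustive search is available
up to 9 taxa. Bremer supports are computed from the exhaustive tree pool
when feasible, otherwise from a bounded suboptimal sweep (flagged as
capped). Strict consensus keeps exactly the bipartitions shared by all
input trees.

Discrete ancestral states use exact down/up dynamic programming to obtain
**MPR sets** (every state that appears at that node in some
most-parsimonious labelling). One concrete resolution is produced by
backtracking with deterministic tie-breaking (prefer the parent's state,
then the smallest symbol). A branch change is annotated only when the two
endpoint MPR sets are disjoint, and called *unambiguous* when both are
singletons — on fully binary trees with binary characters, changes can
usually slide along a path, so disjoint sets typically require extra
pinning (e.g. polytomies).

## 5. Ancestral shape reconstruction

Internal-node shapes minimise the **squared-change parsimony** objective
Σ ‖xᵢ − x_parent(i)‖²/lᵢ over branches. The optimum solves a weighted
graph-Laplacian linear system; zero-length branches are contracted first
(with a warning). Each reconstructed ancestor is then compared to the
mean shapes of the three conglobation archetypes (*straight*,
*incomplete*, *complete*) computed from the labelled tips. The three
distances are normalised to sum to one and inverted into similarities
(so e.g. raw distances (1, 2, 2) give similarities (5, 2.5, 2.5)).
Trends along a root-to-tip backbone are summarised by the Spearman rank
correlation of similarity against node order.

## 6. Biomechanics

Compression curves are analysed on engineering strain
ε = displacement / original height.

- **Breaking point**: the first sample whose force falls below 95% of the
  running maximum — i.e. an instantaneous drop of *more than* 5%. A drop
  of exactly 5% is not a break; a monotone curve never breaks.
- **Defensive strength**: the force at ε = 0.10 (linear interpolation
  between bracketing samples) or the pre-drop maximum at the breaking
  point, whichever occurs at the smaller deformation. Records that end
  before 10% deformation without breaking are rejected rather than
  extrapolated. When a projected area is supplied, the force is normalised
  to a pressure.
- **Thickness ratio**: (elytra + pronotum) / (ventrites + metasternum),
  outer shell over inner sclerites.
- **Oliver–Pharr**: E_r from S = 2βE_r√(A/π) with β = 1.034, and the
  sample modulus from 1/E_r = (1−ν_s²)/E_s + (1−ν_i²)/E_i using a diamond
  indenter (E_i = 1141 GPa, ν_i = 0.07) and ν_s = 0.3; results in MPa.
- Group comparisons use two-tailed t-tests (Welch by default).

Width/length body ratios use exact decimal arithmetic
(`Decimal(str(x))` division, so 1.8/1.6 is exactly 1.125) and
**half-to-even** rounding to one decimal. At one decimal place 1.125 is
not a tie (it is 0.025 below the midpoint 1.15), so it rounds down to 1.1;
all 13 published ratio/measurement pairs are reproduced exactly under this
convention.

## 7. Synthetic data as study conditions

The generator defaults *are* the study conditions, not tuning knobs:

- group sizes 14 straight / 22 incomplete / 38 complete (74 specimens);
- archetype outlines parameterised by a single morphing parameter
  t ∈ [0, 1] (head superellipse exponent 6−5t; pronotum arc of chord
  2−0.9t and height 0.25+0.85t; elytra arc of chord 2 and height
  0.35+1.05t), with Gaussian landmark noise σ = 0.02;
- regime trees: pectinate backbones whose internal nodes carry a monotone
  0→1 conglobation parameter, with the complete-conglobation tips forming
  a nested clade;
- character matrices: random multistate, or *compatible* (binary clade
  markers, CI = 1) for controlled tests;
- compression curves: F = s·(ε/0.1)^1.5 so the strength at 10%
  deformation equals the requested value exactly; the sample grid always
  contains ε = 0.10 and the requested break strain, and post-break force
  is flat at (1−drop)·F_break, so sub-threshold drops are constructible.

## 8. Verification strategy

Every non-trivial algorithm is checked against an independent oracle:
Fitch/Sankoff length against brute-force enumeration over all internal
(and missing-tip) assignments; heuristic search against exhaustive search;
squared-change parsimony against an unconstrained least-squares solve of
the branch-residual system and against a black-box numerical minimiser;
permutation p-values against full enumeration; Oliver–Pharr against
round-tripping a known modulus; t-tests against SciPy. The null
calibration of the Monte-Carlo permutation test is exact by construction
(with a continuous statistic, p is uniform on {1/(N+1), …, 1}), and is
confirmed empirically over 200 seeds.

## 9. Limitations and open points

- The published 76-taxon character matrix behind the reported tree
  statistics (length 564, CI 0.21, RI 0.67) is not archived in a
  machine-readable supplementary file. The corresponding acceptance test
  runs the full 1,000-replicate search when `data/published_matrix.tnt`
  is present and otherwise fails with an explanatory message; it is
  deliberately not skipped, so the data gap stays visible.
- Bremer supports above the suboptimality cap are reported as capped
  lower bounds on large matrices.
- The within-subspace cap (min(n−g, 20)) and the condition-number bound
  (1e8) are pragmatic regularisation choices for p ≫ n landmark data.
- Semilandmark sliding (bending-energy or perpendicular-projection) is not
  implemented; outlines are equally spaced by arc length.
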