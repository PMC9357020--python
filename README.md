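# conglobe

Quantitative tools for studying the evolution of **conglobation** — the
ability of some pill scarab beetles (Scarabaeoidea: Hybosoridae:
Ceratocanthinae) to roll into a near-perfect, tightly interlocking ball.
The package covers the full analysis chain used in comparative work on this
syndrome: 2-D outline morphometrics of the head, pronotum and elytra,
maximum-parsimony phylogenetics, ancestral shape reconstruction along the
tree, and compression/indentation biomechanics of the rolled-up ball.

## What it does

- **`morpho_io`** — read/write TPS landmark files (including curves, `SCALE`
  and `ID`/`IMAGE` keys), resample digitised outlines to fixed numbers of
  equally spaced semilandmarks, and read/write Newick trees and TNT/NEXUS
  character matrices (`?` missing, `-` inapplicable).
- **`superimposition`** — generalized Procrustes analysis (GPA): centring,
  unit centroid-size scaling and iterative rotational alignment, with a
  deterministic canonical orientation so repeated runs agree exactly.
- **`ordination`** — PCA of aligned shapes, pooled within-group covariances,
  Mahalanobis distances, canonical variates analysis (CVA), and permutation
  tests of pairwise group separation (Monte-Carlo with +1 smoothing, or
  exact enumeration of all label arrangements for small samples).
- **`parsimony`** — exact Fitch/Sankoff tree length via dynamic programming,
  consistency and retention indices, heuristic search (random-addition
  sequences + TBR branch swapping), exhaustive search for small matrices,
  strict consensus, Bremer (decay) support, and discrete ancestral-state
  reconstruction with MPR sets and unambiguous-change annotation.
- **`ancestral_shapes`** — squared-change parsimony for continuous shape
  reconstruction at internal nodes, sum-to-one normalised distances of each
  ancestor to the three conglobation archetypes (*straight*, *incomplete*,
  *complete*), reciprocal similarities, and root-to-tip trend summaries.
- **`biomech`** — force–deformation curve analysis: breaking-point detection
  (an instantaneous force drop of more than 5% of the running maximum),
  defensive strength at 10% deformation or at the breaking point (whichever
  comes first), cuticle thickness ratios (outer shell vs inner sclerites),
  Oliver–Pharr elastic moduli from nanoindentation, and Welch/Student
  t-tests for group comparisons.
- **`synthetic_data`** — a first-class generator for study-shaped data:
  archetype outlines on a straight→complete morphing parameter, labelled
  landmark datasets (default design 14 straight / 22 incomplete /
  38 complete specimens), regime trees with a known conglobation gradient,
  Brownian tip simulation, compatible or random character matrices, and
  compression curves calibrated so the strength at 10% deformation equals a
  chosen value exactly.
- **`pipeline` / `cli`** — a YAML-configured end-to-end pipeline and a
  `conglobe` command-line interface, with a provenance record (seed,
  parameters, SHA-256 input hashes) written next to every result set.

Width/length body ratios are computed with exact decimal arithmetic and
half-to-even rounding, matching the convention used in taxonomic
descriptions (`conglobe wl 1.8 1.6` → `1.1`).

## Quick start

Command line:

```console
$ conglobe wl 1.8 1.6
1.1
$ conglobe simulate landmarks --seed 3 --out .
wrote 74 specimens
$ conglobe cva landmarks.tps labels.csv --n-perm 999 --seed 3 --out pvals.csv
complete vs incomplete: p = 0.00100
complete vs straight: p = 0.00100
incomplete vs straight: p = 0.00100
```

Python — reconstruct ancestral shapes along a simulated conglobation
gradient and summarise the archetype-similarity trajectory:

```python
from conglobe.synthetic_data import generate_regime_tree, simulate_gradient_tips
from conglobe.superimposition import gpa
from conglobe.ancestral_shapes import (
    reconstruct_ancestral_configurations, archetype_similarity, trajectory_trend)

tree, truth = generate_regime_tree(12, seed=1)
configs = simulate_gradient_tips(tree, truth, seed=1)
labels = [truth.tip_archetype[c.specimen_id] for c in configs]
aligned = gpa(configs, group_labels=labels)
asr = reconstruct_ancestral_configurations(aligned, tree)
traj = archetype_similarity(asr, aligned, truth.backbone)
for t in trajectory_trend(traj):
    print(f"{t.archetype:>10}: rho = {t.rho:+.2f} ({t.direction})")
```

Output:

```
  straight: rho = -0.95 (decreasing)
incomplete: rho = +0.45 (increasing)
  complete: rho = +0.96 (increasing)
```

Similarity to the straight archetype decays and similarity to the complete
ball grows from root to tip — the expected signature of a gradual
evolutionary acquisition of conglobation.

## Testing and reproducing the results

Run the test suite:

```sh
python -m pytest -q tests/
```

One acceptance test (`test_criterion_2_published_matrix_statistics`)
requires the original 76-taxon published character matrix, which is not
archived in machine-readable form; without `data/published_matrix.tnt` it
fails with an explanatory message rather than being skipped. All other
tests pass. See `docs/methods.md` for the analysis details and design
decisions.

The headline numeric checks can be rerun end to end:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

This writes a JSON report (about 30 s) covering, among others: exact
reproduction of the 13 published width/length ratio pairs, agreement of the
parsimony engine with brute-force and exhaustive oracles on 100 random
cases each, squared-change parsimony vs an independent least-squares
oracle (max error ~1e-14), permutation-test calibration under the null
(rejection rate at α = 0.05 over 200 seeds), CVA separation of the default
synthetic design, trajectory-direction and single-origin recovery over 50
simulated trees, and breaking-point/strength calibration of the
biomechanics module.
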