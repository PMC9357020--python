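"""Synthetic-data generators with known ground truth.

Every generator is a pure function of its seed.  The landmark generator
draws the three conglobation archetypes from a one-parameter outline family
per trait (morph parameter t = 0 / 0.5 / 1 for straight body / incomplete /
complete conglobation):

* head (dorsal outline): anterior margin morphs from subrectangular to
  triangular via a superellipse exponent;
* pronotum (lateral outline): from long and flat to short and strongly
  convex circular arcs;
* elytra (lateral outline): from weakly convex to greatly curved arcs.

Default group sizes mirror the study design (straight 14, incomplete 22,
complete 38 species) so permutation tests run at realistic n; default
semilandmark counts are 30 (head), 50 (pronotum), 50 (elytra).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, InsufficientDataError
from .morpho_io import DEFAULT_SEMILANDMARKS, CharacterMatrix, Curve, LandmarkConfiguration, resample_curve
from .biomech import BREAK_DROP_FRACTION, ForceCurve
from .phylogeny import Phylogeny

DEFAULT_GROUP_SIZES = {"straight": 14, "incomplete": 22, "complete": 38}
ARCHETYPE_PARAMS = {"straight": 0.0, "incomplete": 0.5, "complete": 1.0}


# ---------------------------------------------------------------------------
# archetype outline families
# ---------------------------------------------------------------------------


def archetype_outline(trait: str, t: float, n: int | None = None) -> np.ndarray:
    """Template outline for a trait at morph parameter ``t`` in [0, 1].

    Returns ``n`` semilandmarks equally spaced by arc length along the
    template polyline (defaults: head 30, pronotum 50, elytra 50).
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError("morph parameter t must lie in [0, 1]")
    if trait not in DEFAULT_SEMILANDMARKS:
        raise ValueError(f"unknown trait {trait!r}")
    n = n if n is not None else DEFAULT_SEMILANDMARKS[trait]
    u = np.linspace(-1.0, 1.0, 256)
    if trait == "head":
        # anterior head margin: superellipse exponent 6 (subrectangular)
        # down to 1 (triangular)
        m = 6.0 - 5.0 * t
        y = (1.0 - np.abs(u) ** m) ** (1.0 / m)
        pts = np.column_stack([u, y])
    elif trait == "pronotum":
        # lateral pronotum: chord shortens, convexity (sagitta) grows
        chord = 2.0 - 0.9 * t
        height = 0.25 + 0.85 * t
        pts = _arc(chord, height)
    elif trait == "elytra":
        # lateral elytra: from weakly convex to greatly curved
        chord = 2.0
        height = 0.35 + 1.05 * t
        pts = _arc(chord, height)
    else:
        raise ValueError(f"unknown trait {trait!r}")
    return resample_curve(Curve(pts), n)


def _arc(chord: float, height: float) -> np.ndarray:
    """Circular arc with the given chord length and sagitta (height)."""
    r = (chord / 2.0) ** 2 / (2.0 * height) + height / 2.0
    half_angle = np.arcsin(min(1.0, (chord / 2.0) / r))
    if height > r:  # more than a semicircle
        half_angle = np.pi - half_angle
    theta = np.linspace(-half_angle, half_angle, 256)
    x = r * np.sin(theta)
    y = r * np.cos(theta) - (r - height)
    return np.column_stack([x, y])


def generate_archetype_dataset(
    group_sizes: dict[str, int] | None = None,
    trait: str = "elytra",
    noise_sd: float = 0.02,
    seed: int = 0,
    n_semilandmarks: int | None = None,
) -> tuple[list[LandmarkConfiguration], list[str]]:
    """Labelled landmark configurations for the three archetype groups.

    Each specimen is its archetype's template outline plus isotropic Gaussian
    landmark noise with standard deviation ``noise_sd`` (in template units,
    where outlines span about 2 units).
    """
    sizes = dict(DEFAULT_GROUP_SIZES if group_sizes is None else group_sizes)
    if any(v < 2 for v in sizes.values()):
        raise InsufficientDataError("each group needs at least 2 specimens")
    if noise_sd < 0:
        raise DegenerateInputError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    configs, labels = [], []
    for group in ("straight", "incomplete", "complete"):
        template = archetype_outline(trait, ARCHETYPE_PARAMS[group], n_semilandmarks)
        for i in range(sizes[group]):
            pts = template + rng.normal(0.0, noise_sd, template.shape) if noise_sd > 0 else template.copy()
            configs.append(
                LandmarkConfiguration(f"{group}_{i + 1}", pts, trait=trait, view=None)
            )
            labels.append(group)
    return configs, labels


# ---------------------------------------------------------------------------
# regime trees
# ---------------------------------------------------------------------------


@dataclass
class SimulationTruth:
    """Ground truth recorded alongside a generated tree."""

    tip_archetype: dict[str, str]  # taxon -> archetype label
    node_parameter: dict[int, float]  # node -> true morph parameter
    backbone: list[int] = field(default_factory=list)  # root-to-tip internal nodes
    seed: int | None = None


def generate_regime_tree(n_tips: int, seed: int = 0) -> tuple[Phylogeny, SimulationTruth]:
    """A tree whose morph parameter increases monotonically along a backbone.

    Straight-body tips branch off at the base, incomplete-conglobation tips
    in the middle, and complete-conglobation tips form a nested clade — the
    single-origin regime layout.  Tips split evenly into the three grades
    (remainder to the straight grade).  Branch lengths are all 1.
    """
    if n_tips < 6:
        raise InsufficientDataError("regime tree needs at least 6 tips")
    rng = np.random.default_rng(seed)
    per = n_tips // 3
    sizes = {"straight": n_tips - 2 * per, "incomplete": per, "complete": per}
    names = {
        g: [f"{g}_{i + 1}" for i in range(sizes[g])] for g in sizes
    }
    for g in names:
        rng.shuffle(names[g])

    # pectinate backbone: straight tips branch off first, then incomplete;
    # complete tips form a terminal clade
    backbone_tips = names["straight"] + names["incomplete"]
    complete_clade = names["complete"][0]
    for t in names["complete"][1:]:
        complete_clade = (complete_clade, t)
    nested = complete_clade
    for t in reversed(backbone_tips[1:]):
        nested = (t, nested)
    nested = (backbone_tips[0], nested)
    tree = Phylogeny.from_nested(nested)

    tip_arch = {t: g for g in names for t in names[g]}
    node_param: dict[int, float] = {}
    backbone: list[int] = []
    clusters = tree.clusters()
    for node in tree.preorder():
        if tree.is_tip(node):
            node_param[node] = ARCHETYPE_PARAMS[tip_arch[tree.taxon(node)]]
        else:
            # an ancestor's true grade is the most basal grade beneath it
            grades = {tip_arch[t] for t in clusters[node]}
            if "straight" in grades:
                node_param[node] = 0.0
            elif "incomplete" in grades:
                node_param[node] = 0.5
            else:
                node_param[node] = 1.0
            backbone.append(node)
    truth = SimulationTruth(tip_arch, node_param, backbone, seed)
    return tree, truth


# ---------------------------------------------------------------------------
# Brownian landmark evolution
# ---------------------------------------------------------------------------


def simulate_brownian_tips(
    tree: Phylogeny,
    root_config: np.ndarray,
    rate: float,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Brownian evolution of each coordinate along the tree.

    Every coordinate gains an independent Gaussian increment of variance
    ``rate x branch_length`` on each branch.  Returns taxon -> configuration.
    """
    if rate <= 0:
        raise DegenerateInputError("Brownian rate must be positive")
    rng = np.random.default_rng(seed)
    root = np.asarray(root_config, float)
    values: dict[int, np.ndarray] = {tree.root: root}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder():
        par = tree.parent(node)
        if par is not None:
            sd = np.sqrt(rate * tree.branch_length(node))
            values[node] = values[par] + rng.normal(0.0, sd, root.shape)
        if tree.is_tip(node):
            out[tree.taxon(node)] = values[node]
    return out


def simulate_gradient_tips(
    tree: Phylogeny,
    truth: SimulationTruth,
    trait: str = "elytra",
    noise_sd: float = 0.02,
    seed: int = 0,
    n_semilandmarks: int | None = None,
) -> list[LandmarkConfiguration]:
    """Tip shapes drawn from each tip's true archetype template plus noise —
    the terminal morphology implied by a regime tree."""
    rng = np.random.default_rng(seed)
    configs = []
    for tip in tree.tips():
        taxon = tree.taxon(tip)
        template = archetype_outline(trait, truth.node_parameter[tip], n_semilandmarks)
        pts = template + rng.normal(0.0, noise_sd, template.shape)
        configs.append(LandmarkConfiguration(taxon, pts, trait=trait))
    return configs


# ---------------------------------------------------------------------------
# character matrices
# ---------------------------------------------------------------------------


def generate_character_matrix(
    tree: Phylogeny,
    n_chars: int,
    change_prob: float,
    seed: int = 0,
    n_states: int = 3,
    missing_rate: float = 0.0,
    compatible: bool = False,
) -> CharacterMatrix:
    """Discrete characters evolved on the tree by Markov state changes.

    Each branch changes state with probability ``change_prob`` (new state
    uniform among the others).  With ``compatible=True`` the characters are
    instead perfectly hierarchical clade markers (one binary character per
    internal node), so parsimony search can recover the generating topology
    with CI = 1.  ``missing_rate`` masks cells as '?' after simulation.
    """
    if n_chars < 1:
        raise InsufficientDataError("need at least one character")
    if not 0.0 < change_prob < 1.0 and not compatible:
        raise ValueError("change_prob must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    taxa = tree.taxa()
    tip_index = {t: i for i, t in enumerate(taxa)}
    cells = np.full((len(taxa), n_chars), "0", dtype="<U1")

    if compatible:
        internals = [n for n in tree.internal_nodes() if n != tree.root]
        clusters = tree.clusters()
        for j in range(n_chars):
            node = internals[j % len(internals)]
            for t in clusters[node]:
                cells[tip_index[t], j] = "1"
    else:
        for j in range(n_chars):
            state: dict[int, int] = {tree.root: int(rng.integers(n_states))}
            for node in tree.preorder():
                par = tree.parent(node)
                if par is not None:
                    s = state[par]
                    if rng.random() < change_prob:
                        others = [x for x in range(n_states) if x != s]
                        s = others[int(rng.integers(len(others)))]
                    state[node] = s
                if tree.is_tip(node):
                    cells[tip_index[tree.taxon(node)], j] = str(state[node])
    if missing_rate > 0:
        mask = rng.random(cells.shape) < missing_rate
        cells[mask] = "?"
    return CharacterMatrix(list(taxa), cells)


# ---------------------------------------------------------------------------
# force curves
# ---------------------------------------------------------------------------


def generate_force_curve(
    strength_at_10pct: float,
    break_epsilon: float | None = None,
    drop_fraction: float = 0.06,
    original_height: float = 1000.0,
    max_strain: float = 0.5,
    n_samples: int = 201,
    seed: int | None = None,
    noise_sd: float = 0.0,
) -> ForceCurve:
    """Smooth rising compression curve calibrated so the interpolated force
    at 10% deformation equals ``strength_at_10pct``; optionally a single-step
    force drop of ``drop_fraction`` at ``break_epsilon``."""
    if break_epsilon is not None and not 0.0 < drop_fraction < 1.0:
        raise ValueError("drop_fraction must lie in (0, 1)")
    # note: drops of at most BREAK_DROP_FRACTION are generatable on purpose,
    # so the detection threshold can be probed from both sides
    eps = np.linspace(0.0, max_strain, n_samples)
    # make sure the 10% point and any breaking point are exact grid samples
    eps = np.unique(np.concatenate([eps, [0.10] + ([break_epsilon] if break_epsilon else [])]))
    force = strength_at_10pct * (eps / 0.10) ** 1.5
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        force = np.clip(force + rng.normal(0.0, noise_sd, force.shape), 0.0, None)
        i10 = int(np.argmin(np.abs(eps - 0.10)))
        force[i10] = strength_at_10pct
    if break_epsilon is not None:
        if break_epsilon >= eps[-1]:
            raise DegenerateInputError("break_epsilon beyond the curve range")
        idx = int(np.argmin(np.abs(eps - break_epsilon)))
        post = (1.0 - drop_fraction) * force[idx]
        force[idx + 1 :] = post
    return ForceCurve(eps * original_height, force, original_height)
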