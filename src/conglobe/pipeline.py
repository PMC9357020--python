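"""Reproducible orchestration of the full analysis chain.

A declarative config (dict or YAML file) names the inputs; every stage whose
inputs are present runs, the others are skipped with an explicit log entry.
All outputs are CSV/TPS/Newick text files plus a provenance log recording
input hashes, parameters and the seed, so identical config + seed reproduce
identical outputs.
"""
from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import ancestral_shapes, biomech, morpho_io, ordination, parsimony, superimposition
from .errors import ConglobeError

logger = logging.getLogger(__name__)

DEFAULTS = {
    "n_permutations": 10000,
    "seed": ordination.DEFAULT_SEED,
    "subspace_dim": None,
    "semilandmarks": dict(morpho_io.DEFAULT_SEMILANDMARKS),
    "search_replicates": 1000,
    "nodes": [],
}


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConglobeError("pipeline config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict[str, Any] | str | Path, out_dir: str | Path) -> dict[str, Any]:
    """Run every stage whose inputs are configured; return the result bundle.

    Recognised config keys: ``landmarks`` (mapping trait -> TPS path),
    ``labels`` (CSV: specimen_id, archetype), ``tree`` (Newick path),
    ``matrix`` (TNT path), ``curves`` (CSV: displacement, force) with
    ``original_height``, ``thickness`` (CSV: region, value), plus the
    parameters in ``DEFAULTS``.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = {**DEFAULTS, **config}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    provenance: dict[str, Any] = {"seed": seed, "parameters": {}, "inputs": {}, "stages": {}}
    for key in ("n_permutations", "subspace_dim", "semilandmarks", "search_replicates", "nodes"):
        provenance["parameters"][key] = cfg[key]
    for key in ("landmarks", "labels", "tree", "matrix", "curves", "thickness"):
        value = cfg.get(key)
        if isinstance(value, (str, Path)):
            provenance["inputs"][key] = _sha256(Path(value))
        elif isinstance(value, dict):
            provenance["inputs"][key] = {k: _sha256(Path(v)) for k, v in value.items()}

    bundle: dict[str, Any] = {}
    labels_map: dict[str, str] | None = None
    if cfg.get("labels"):
        df = pd.read_csv(cfg["labels"])
        labels_map = dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(str)))

    # -- morphometrics -------------------------------------------------------
    aligned_by_trait: dict[str, superimposition.AlignedDataset] = {}
    if cfg.get("landmarks"):
        for trait, tps_path in cfg["landmarks"].items():
            configs = morpho_io.read_tps(tps_path)
            if configs and configs[0].curves and configs[0].n_points == 0:
                configs = morpho_io.semilandmarks_from_tps(
                    configs, trait, cfg["semilandmarks"].get(trait)
                )
            else:
                configs = [c.with_points(c.points) for c in configs]
                for c in configs:
                    c.trait = trait
            group_labels = (
                [labels_map[c.specimen_id] for c in configs] if labels_map else None
            )
            aligned = superimposition.gpa(configs, group_labels=group_labels)
            aligned_by_trait[trait] = aligned
            rows = []
            for i, sid in enumerate(aligned.specimen_ids):
                for j, (x, y) in enumerate(aligned.coords[i]):
                    rows.append((sid, j, x, y))
            pd.DataFrame(rows, columns=["specimen_id", "point", "x", "y"]).to_csv(
                out / f"aligned_{trait}.csv", index=False
            )
            result = ordination.pca(aligned)
            pd.DataFrame(
                result.scores,
                index=aligned.specimen_ids,
                columns=[f"PC{i + 1}" for i in range(result.n_components)],
            ).to_csv(out / f"pca_scores_{trait}.csv")
            if group_labels:
                cva_res = ordination.cva(
                    aligned,
                    subspace_dim=cfg["subspace_dim"],
                    n_permutations=int(cfg["n_permutations"]),
                    seed=seed,
                )
                pd.DataFrame(
                    cva_res.pairwise_mahalanobis,
                    index=cva_res.group_names,
                    columns=cva_res.group_names,
                ).to_csv(out / f"cva_mahalanobis_{trait}.csv")
                pd.DataFrame(
                    cva_res.p_matrix(), index=cva_res.group_names, columns=cva_res.group_names
                ).to_csv(out / f"cva_pvalues_{trait}.csv")
                bundle[f"cva_{trait}"] = cva_res
            bundle[f"aligned_{trait}"] = aligned
            bundle[f"pca_{trait}"] = result
        provenance["stages"]["morphometrics"] = sorted(aligned_by_trait)
    else:
        provenance["stages"]["morphometrics"] = "skipped: no landmarks configured"
        logger.info("morphometrics skipped: no landmarks configured")

    # -- parsimony -----------------------------------------------------------
    tree = morpho_io.read_newick(cfg["tree"]) if cfg.get("tree") else None
    if cfg.get("matrix"):
        matrix = morpho_io.read_matrix(cfg["matrix"])
        search = parsimony.heuristic_search(
            matrix, n_replicates=int(cfg["search_replicates"]), seed=seed
        )
        consensus = search.strict_consensus()
        morpho_io.write_newick(consensus, out / "strict_consensus.nwk")
        scores = [parsimony.tree_score(t, matrix) for t in search.trees]
        pd.DataFrame(
            [(i + 1, s.length, s.ci, s.ri) for i, s in enumerate(scores)],
            columns=["tree", "length", "ci", "ri"],
        ).to_csv(out / "tree_scores.csv", index=False)
        bundle["search"] = search
        bundle["tree_scores"] = scores
        provenance["stages"]["parsimony"] = {
            "best_length": search.best_length,
            "n_trees": len(search.trees),
        }
        if tree is None and search.trees:
            tree = search.trees[0]
    else:
        provenance["stages"]["parsimony"] = "skipped: no matrix configured"
        logger.info("parsimony skipped: no matrix configured")

    # -- ancestral shapes ----------------------------------------------------
    trait_for_asr = next(iter(aligned_by_trait), None)
    if tree is not None and trait_for_asr and labels_map:
        aligned = aligned_by_trait[trait_for_asr]
        asr = ancestral_shapes.reconstruct_ancestral_configurations(aligned, tree)
        nodes = [int(n) for n in cfg["nodes"]] or [
            n for n in tree.internal_nodes()
        ]
        trajectory = ancestral_shapes.archetype_similarity(
            asr, aligned, nodes, subspace_dim=cfg["subspace_dim"]
        )
        rows = []
        for i, node in enumerate(trajectory.node_ids):
            row: dict[str, Any] = {"node_id": node, "trait": trait_for_asr}
            for j, a in enumerate(trajectory.archetypes):
                row[f"d_raw_{a}"] = trajectory.raw_distances[i, j]
                row[f"d_norm_{a}"] = trajectory.normalized_distances[i, j]
                row[f"similarity_{a}"] = trajectory.similarities[i, j]
            rows.append(row)
        pd.DataFrame(rows).to_csv(out / "similarity_trajectory.csv", index=False)
        bundle["asr"] = asr
        bundle["trajectory"] = trajectory
        provenance["stages"]["ancestral_shapes"] = {"nodes": nodes}
    else:
        reason = "no tree" if tree is None else "no aligned landmarks or labels"
        provenance["stages"]["ancestral_shapes"] = f"skipped: {reason}"
        logger.info("ancestral shapes skipped: %s", reason)

    # -- biomechanics --------------------------------------------------------
    if cfg.get("curves"):
        df = pd.read_csv(cfg["curves"])
        curve = biomech.ForceCurve(
            df["displacement"].to_numpy(),
            df["force"].to_numpy(),
            original_height=float(cfg.get("original_height", 1.0)),
            projected_area=cfg.get("projected_area"),
        )
        strength = biomech.defensive_strength(curve)
        pd.DataFrame(
            [(strength.force, strength.event, strength.strain_at_event)],
            columns=["force", "event", "strain"],
        ).to_csv(out / "defensive_strength.csv", index=False)
        bundle["strength"] = strength
        provenance["stages"]["biomech_strength"] = strength.event
    if cfg.get("thickness"):
        df = pd.read_csv(cfg["thickness"])
        profiles = [
            biomech.ThicknessProfile(region, grp.iloc[:, 1].to_numpy())
            for region, grp in df.groupby(df.columns[0])
        ]
        ratio = biomech.thickness_ratio(profiles)
        (out / "thickness_ratio.txt").write_text(f"{ratio:.6f}\n")
        bundle["thickness_ratio"] = ratio
        provenance["stages"]["biomech_thickness"] = ratio

    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True, default=str)
    bundle["provenance"] = provenance
    return bundle
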