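"""End-to-end screening funnel: filter → cluster → rank → rescore.

The pipeline consumes per-ligand, per-target pose sets, applies the
docking-energy cutoff, clusters each pose set adaptively, gates on the
largest-cluster population, ranks ligands by consensus over targets,
and optionally re-ranks by externally supplied MM-PBSA energies.  The
output is a deterministic report (a DataFrame, optionally written as
CSV and JSON): a pure function of inputs, configuration and seed.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .clustering import cluster_adaptive, pose_rmsd_matrix, representative_cluster
from .core import Pose, RunConfig
from .ranking import LigandTargetResult, consensus_rank, rerank_by_mmpbsa
from .scoring import score_pose

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "summarize_poses"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def summarize_poses(ligand: str, target: str, poses: Sequence[Pose],
                    config: RunConfig) -> Optional[LigandTargetResult]:
    """Cluster one pose set and summarise its representative cluster."""
    energies = np.array([p.docking_energy for p in poses], dtype=float)
    if len(poses) == 1:
        sol_fraction = 1.0
        rep_energy = float(energies[0])
    else:
        dist = pose_rmsd_matrix(poses)
        sol = cluster_adaptive(
            dist, k_range=(config.cluster_k_min, config.cluster_k_max),
            energies=energies)
        rep = representative_cluster(sol, energies,
                                     min_population=config.min_cluster_population)
        sol_fraction = float(sol.populations.max() / sol.n)
        if rep is None:
            logger.info("ligand %s target %s: largest cluster %.0f%% fails "
                        "the population gate", ligand, target,
                        100 * sol_fraction)
            return LigandTargetResult(ligand=ligand, target=target,
                                      largest_cluster_fraction=sol_fraction,
                                      representative_energy=float(energies.min()))
        rep_energy = rep[1]
    return LigandTargetResult(ligand=ligand, target=target,
                              largest_cluster_fraction=sol_fraction,
                              representative_energy=rep_energy)


def run_pipeline(config: RunConfig,
                 poses: Optional[Dict[str, Dict[str, List[Pose]]]] = None,
                 receptors: Optional[Dict] = None,
                 scoring_params=None,
                 mmpbsa_energies: Optional[Dict[str, float]] = None,
                 out_csv=None, out_json=None) -> pd.DataFrame:
    """Run the screening funnel and return the ranked hit report.

    ``poses`` maps ligand id → target id → pose list; when absent, pose
    files are read from ``config.paths["poses"]`` (same nesting, file
    paths as leaves).  Poses without a docking energy are rescored with
    the empirical function against ``receptors[target]`` when provided.
    ``mmpbsa_energies`` (ligand → kcal/mol) triggers the re-ranking
    stage.  Stage order: energy filter → adaptive clustering + gate →
    consensus rank → MM-PBSA re-rank.
    """
    if poses is None:
        from .io import read_poses
        try:
            spec = config.paths["poses"]
        except KeyError:
            raise StageError("input stage: no poses given and no "
                             "config.paths['poses'] entry") from None
        poses = {lig: {tgt: read_poses(path) for tgt, path in targets.items()}
                 for lig, targets in spec.items()}

    # stage 1: ensure energies, apply the docking-energy cutoff per pose
    filtered: Dict[str, Dict[str, List[Pose]]] = {}
    n_in = n_kept = 0
    for ligand, per_target in sorted(poses.items()):
        for target, pose_list in sorted(per_target.items()):
            kept = []
            for pose in pose_list:
                n_in += 1
                if pose.docking_energy is None:
                    if receptors is None or target not in receptors:
                        raise StageError(
                            f"filter stage: pose of ligand {ligand!r} has no "
                            f"docking energy and no receptor for {target!r} "
                            "to rescore against")
                    pose.docking_energy = score_pose(
                        pose, receptors[target], params=scoring_params).total
                if pose.docking_energy <= config.energy_cutoff:
                    kept.append(pose)
                    n_kept += 1
            if kept:
                filtered.setdefault(ligand, {})[target] = kept
    logger.info("filter stage: %d/%d poses within cutoff %.2f kcal/mol",
                n_kept, n_in, config.energy_cutoff)

    # stage 2: adaptive clustering + population gate per (ligand, target)
    results: List[LigandTargetResult] = []
    for ligand, per_target in sorted(filtered.items()):
        for target, pose_list in sorted(per_target.items()):
            try:
                res = summarize_poses(ligand, target, pose_list, config)
            except Exception as exc:
                raise StageError(f"cluster stage ({ligand}/{target}): {exc}"
                                 ) from exc
            if res is not None:
                results.append(res)
    logger.info("cluster stage: %d ligand-target summaries", len(results))

    # stage 3: consensus ranking across targets
    try:
        hits = consensus_rank(results,
                              min_population=config.min_cluster_population)
    except Exception as exc:
        raise StageError(f"rank stage: {exc}") from exc
    logger.info("rank stage: %d ligands ranked", len(hits))

    # stage 4: optional MM-PBSA re-ranking
    if mmpbsa_energies is not None:
        for h in hits:
            if h.ligand not in mmpbsa_energies:
                raise StageError(
                    f"rescore stage: no MM-PBSA energy for ligand {h.ligand!r}")
            h.mmpbsa_energy = float(mmpbsa_energies[h.ligand])
        hits = rerank_by_mmpbsa(hits)
        logger.info("rescore stage: re-ranked %d ligands by MM-PBSA energy",
                    len(hits))

    best_pop = {}
    for res in results:
        cur = best_pop.get(res.ligand, 0.0)
        if res.largest_cluster_fraction >= config.min_cluster_population:
            best_pop[res.ligand] = max(cur, res.largest_cluster_fraction)

    rows = []
    for h in hits:
        rows.append({
            "ligand": h.ligand,
            "best_cluster_population": round(best_pop.get(h.ligand, 0.0), 6),
            "preliminary_energy": round(h.preliminary_energy, 6),
            "preliminary_rank": h.preliminary_rank,
            "mmpbsa_energy": (round(h.mmpbsa_energy, 6)
                              if h.mmpbsa_energy is not None else None),
            "mmpbsa_rank": h.mmpbsa_rank,
        })
    report = pd.DataFrame(rows, columns=[
        "ligand", "best_cluster_population", "preliminary_energy",
        "preliminary_rank", "mmpbsa_energy", "mmpbsa_rank"])

    if out_csv is not None:
        Path(out_csv).write_text(report.to_csv(index=False, float_format="%.6f"))
    if out_json is not None:
        Path(out_json).write_text(
            json.dumps(rows, indent=2, sort_keys=True) + "\n")
    return report
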