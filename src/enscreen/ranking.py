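"""Consensus ranking across receptor conformations and MM-PBSA re-ranking.

In the relaxed-complex scheme one ligand is docked against every member
of a receptor ensemble and clustered per target.  A ligand's
representative energy is the minimum over the targets whose largest
pose cluster passes the population gate (25 % by default); ligands with
no surviving target are dropped.  Hits retained after this preliminary
(docking-score) ranking can be re-ranked by their MM-PBSA binding free
energies, which typically reshuffles the list substantially.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Dict, List, Optional, Sequence

import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "LigandTargetResult",
    "RankedHit",
    "consensus_rank",
    "rank_single_target",
    "rerank_by_mmpbsa",
    "ranking_agreement",
    "load_published_rescoring_table",
]


@dataclass
class LigandTargetResult:
    """Per-(ligand, target) clustering summary."""

    ligand: str
    target: str
    largest_cluster_fraction: float
    representative_energy: float  # kcal/mol, min energy of largest cluster

    def __post_init__(self) -> None:
        if not (0.0 <= self.largest_cluster_fraction <= 1.0):
            raise ValueError("largest_cluster_fraction must be in [0, 1]")


@dataclass
class RankedHit:
    """One ligand in a ranked hit list (ranks 1-based, dense)."""

    ligand: str
    preliminary_energy: float
    preliminary_rank: int = 0
    mmpbsa_energy: Optional[float] = None
    mmpbsa_rank: Optional[int] = None


def consensus_rank(results: Sequence[LigandTargetResult],
                   min_population: float = 0.25) -> List[RankedHit]:
    """Gate-then-min consensus ranking over receptor conformations.

    Per ligand: drop targets whose largest-cluster fraction is below
    ``min_population`` (inclusive gate), take the minimum representative
    energy over the survivors, exclude ligands with no survivor, and
    rank ascending by that energy (ties broken by ligand id).
    Independent of the order the per-target results arrive in.
    """
    per_ligand: Dict[str, List[LigandTargetResult]] = {}
    for res in results:
        per_ligand.setdefault(res.ligand, []).append(res)
    hits: List[RankedHit] = []
    for ligand, entries in per_ligand.items():
        surviving = [e for e in entries
                     if e.largest_cluster_fraction >= min_population]
        if not surviving:
            continue
        energy = min(e.representative_energy for e in surviving)
        hits.append(RankedHit(ligand=ligand, preliminary_energy=energy))
    hits.sort(key=lambda h: (h.preliminary_energy, h.ligand))
    for rank, hit in enumerate(hits, start=1):
        hit.preliminary_rank = rank
    return hits


def rank_single_target(results: Sequence[LigandTargetResult],
                       min_population: float = 0.25) -> List[RankedHit]:
    """Single-target ranking: lowest energy of the most populated cluster.

    Same gate semantics as :func:`consensus_rank`; kept as a separate
    entry point for the first (single-conformation) screening phase.
    """
    return consensus_rank(results, min_population=min_population)


def rerank_by_mmpbsa(hits: Sequence[RankedHit]) -> List[RankedHit]:
    """Stable re-sort of hits by MM-PBSA energy; preliminary ranks kept.

    Idempotent; equal energies preserve the incoming order.
    """
    for h in hits:
        if h.mmpbsa_energy is None:
            raise ValueError(f"hit {h.ligand!r} has no MM-PBSA energy")
    out = [replace(h) for h in hits]
    out.sort(key=lambda h: h.mmpbsa_energy)  # stable
    for rank, hit in enumerate(out, start=1):
        hit.mmpbsa_rank = rank
    return out


def ranking_agreement(hits: Sequence[RankedHit]) -> float:
    """Spearman rank correlation between the two rankings (reported,
    never asserted: the two scoring schemes are expected to differ)."""
    pre = [h.preliminary_rank for h in hits]
    post = [h.mmpbsa_rank for h in hits]
    rho, _ = spearmanr(pre, post)
    return float(rho)


def load_published_rescoring_table() -> pd.DataFrame:
    """The published 14-compound rescoring table (packaged data).

    Columns: compound, mmpbsa_rank, autodock_rank, mmpbsa_be_kcal_mol,
    logp.  The docking-rank column refers to the preliminary empirical
    score; the BE column is the MM-PBSA binding free energy.
    """
    with resources.files("enscreen.data").joinpath(
            "table1_rescoring.csv").open() as fh:
        return pd.read_csv(fh)
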