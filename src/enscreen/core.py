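"""Shared domain types for the ensemble-screening toolkit.

Coordinates are Ångström everywhere internally; partial charges are in
elementary charge units; energies are kcal/mol.  Nanometre values appear
only at presentation time (ensemble RMSD reports).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "ReceptorConformation",
    "Pose",
    "RunConfig",
    "COULOMB_CONSTANT",
]

#: Coulomb constant in kcal·Å/(mol·e²).
COULOMB_CONSTANT = 332.0636


@dataclass
class AtomRecord:
    """One atom of a receptor or ligand structure.

    ``atom_type`` is the scoring-parameter key (AutoDock-4 convention,
    e.g. ``"OA"``, ``"HD"``); ``radius`` is used by the PB and SASA
    stages and may be unset (``None``) for atoms that never reach them.
    """

    serial: int
    name: str
    residue_name: str
    residue_number: int
    chain: str
    position: np.ndarray
    charge: float = 0.0
    atom_type: str = ""
    radius: Optional[float] = None

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for atom serial {self.serial}")
        if self.radius is not None and self.radius <= 0:
            raise ValueError(f"radius must be > 0 (atom serial {self.serial})")

    def copy(self) -> "AtomRecord":
        return replace(self, position=self.position.copy())


# ordered (chain, residue_number, atom_name) triples naming binding-site atoms
SiteSelection = Sequence[tuple]


@dataclass
class ReceptorConformation:
    """One member of a receptor ensemble with a binding-site selection.

    ``site_selection`` is an ordered list of ``(chain, residue_number,
    atom_name)`` triples; the same selection must resolve in every member
    of an ensemble so that RMSDs are computed over corresponding atoms.
    """

    atoms: list
    site_selection: SiteSelection = ()

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def site_atoms(self) -> list:
        """Resolve the selection, preserving its order.

        Raises ``KeyError`` listing every triple that does not resolve.
        """
        index = {(a.chain, a.residue_number, a.name): a for a in self.atoms}
        missing = [key for key in self.site_selection if tuple(key) not in index]
        if missing:
            raise KeyError(f"binding-site atoms not found: {missing}")
        return [index[tuple(key)] for key in self.site_selection]

    def site_coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.site_atoms()], dtype=float)


@dataclass
class Pose:
    """One docked ligand geometry.

    ``docking_energy`` is the engine-reported binding energy (kcal/mol)
    when the pose came from a docking log; ``n_rotatable_bonds`` feeds
    the torsional-entropy term of the empirical score.
    """

    ligand_atoms: list
    docking_energy: Optional[float] = None
    n_rotatable_bonds: int = 0
    source_target: str = ""
    run_id: int = 0
    ligand_id: str = ""

    def __post_init__(self) -> None:
        if len(self.ligand_atoms) < 1:
            raise ValueError("a pose needs at least one atom")
        if self.n_rotatable_bonds < 0:
            raise ValueError("n_rotatable_bonds must be >= 0")

    def coordinates(self) -> np.ndarray:
        return np.array([a.position for a in self.ligand_atoms], dtype=float)


@dataclass
class RunConfig:
    """Stage parameters for the screening pipeline.

    Defaults mirror the study conditions: a −5 kcal/mol docking-energy
    cutoff, a 25 % largest-cluster population gate, 300 K, and a 10 ns⁻¹
    fluorophore lifetime τ0 = 1e−8 s.
    """

    energy_cutoff: float = -5.0          # kcal/mol
    min_cluster_population: float = 0.25  # fraction of poses
    cluster_k_min: int = 2
    cluster_k_max: int = 20
    pb_grid_spacing: float = 0.5          # Å
    temperature: float = 300.0            # K
    tau0: float = 1e-8                    # s
    ci_effect_level: float = 0.95
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.min_cluster_population <= 1):
            raise ValueError("min_cluster_population must be in (0, 1]")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.tau0 <= 0:
            raise ValueError("tau0 must be > 0")
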