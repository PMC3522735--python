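"""AutoDock-4-type empirical free-energy rescoring of rigid docked poses.

The score of a receptor–pose pair is a weighted sum of five terms:

* a Lennard-Jones 12-6 dispersion/repulsion term,
* a directional 12-10 hydrogen-bond term (directional weight ``E(t)``),
* a screened Coulomb electrostatic term with a distance-dependent
  dielectric (sigmoidal Mehler–Solmajer form by default),
* a pairwise Gaussian-weighted volume desolvation term, and
* a torsional-entropy penalty proportional to the number of rotatable
  bonds of the ligand.

Only intermolecular (receptor × ligand) pair interactions enter the
score: in a rescoring context the pose geometry is fixed, so the
intramolecular ligand energy is a constant offset and is excluded.
Pairs beyond the nonbonded cutoff (default 20.48 Å, the conventional
nonbond-table extent) contribute exactly zero to every term.

Weights default to the published AutoDock 4.0 free-energy coefficient
set shipped as packaged data (``data/ad4_params.tsv`` holds the per-type
parameters).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import COULOMB_CONSTANT, Pose, ReceptorConformation

__all__ = [
    "AtomTypeParameters",
    "ScoringParameters",
    "ScoreBreakdown",
    "sigmoidal_dielectric",
    "directional_weight",
    "score_pose",
    "filter_by_energy",
]

#: AutoDock 4.0 free-energy model coefficients (vdW, hbond, elec, tor, desolv).
AD4_WEIGHTS = {
    "vdw": 0.1560,
    "hbond": 0.0974,
    "elec": 0.1465,
    "tor": 0.2744,
    "desolv": 0.1159,
}


@dataclass
class AtomTypeParameters:
    """Per-type nonbonded parameters (AutoDock-4 convention)."""

    Rii: float        # like-pair equilibrium distance, Å
    epsii: float      # well depth, kcal/mol
    vol: float        # fragmental volume, Å³
    solpar: float     # atomic solvation parameter
    hbond: str        # "0", "D" (donor H), "A1"/"A2" (acceptor)
    Rij_hb: float = 0.0
    epsij_hb: float = 0.0

    @property
    def is_donor_hydrogen(self) -> bool:
        return self.hbond == "D"

    @property
    def is_acceptor(self) -> bool:
        return self.hbond in ("A1", "A2")


def sigmoidal_dielectric(r: np.ndarray,
                         eps0: float = 78.4,
                         A: float = -8.5525,
                         lam: float = 0.003627,
                         k: float = 7.7839) -> np.ndarray:
    """Mehler–Solmajer distance-dependent dielectric ε(r)."""
    B = eps0 - A
    return A + B / (1.0 + k * np.exp(-lam * B * np.asarray(r, dtype=float)))


def directional_weight(angle_deg: float, exponent: float = 2.0) -> float:
    """Hydrogen-bond directionality ramp E(t).

    ``angle_deg`` is the deviation from ideal hydrogen-bond geometry;
    the weight is ``cos(t)**exponent`` and clamps to zero beyond 90°.
    """
    if angle_deg >= 90.0:
        return 0.0
    return math.cos(math.radians(angle_deg)) ** exponent


@dataclass
class ScoringParameters:
    """Weights, per-type tables and functional-form knobs for the score."""

    weights: Dict[str, float] = field(default_factory=lambda: dict(AD4_WEIGHTS))
    atom_types: Dict[str, AtomTypeParameters] = field(default_factory=dict)
    sigma: float = 3.5                     # desolvation Gaussian width, Å
    dielectric: object = "sigmoidal"       # "sigmoidal" or a constant float
    hbond_exponent: float = 2.0
    nonbonded_cutoff: Optional[float] = 20.48  # Å; pair terms vanish beyond it

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.nonbonded_cutoff is not None and self.nonbonded_cutoff <= 0:
            raise ValueError("nonbonded_cutoff must be > 0 or None")
        for name, w in self.weights.items():
            if not np.isfinite(w):
                raise ValueError(f"non-finite weight {name}")

    @classmethod
    def autodock4(cls, **overrides) -> "ScoringParameters":
        """Parameters of the published AutoDock 4.0 force field."""
        table: Dict[str, AtomTypeParameters] = {}
        text = resources.files("enscreen.data").joinpath("ad4_params.tsv").read_text()
        for line in text.splitlines():
            if not line.strip() or line.startswith("#") or line.startswith("atom_type"):
                continue
            f = line.split("\t")
            table[f[0]] = AtomTypeParameters(
                Rii=float(f[1]), epsii=float(f[2]), vol=float(f[3]),
                solpar=float(f[4]), hbond=f[5],
                Rij_hb=float(f[6]), epsij_hb=float(f[7]))
        return cls(atom_types=table, **overrides)

    def lookup(self, atom_type: str) -> AtomTypeParameters:
        try:
            return self.atom_types[atom_type]
        except KeyError:
            raise KeyError(f"unknown atom type {atom_type!r}: "
                           "not present in the scoring parameter table") from None

    def epsilon_of_r(self, r: np.ndarray) -> np.ndarray:
        if self.dielectric == "sigmoidal":
            return sigmoidal_dielectric(r)
        return np.full_like(np.asarray(r, dtype=float), float(self.dielectric))


@dataclass
class ScoreBreakdown:
    """Per-term decomposition of the empirical score (kcal/mol)."""

    vdw: float
    hbond: float
    elec: float
    desolv: float
    torsional: float
    total: float

    @classmethod
    def from_components(cls, vdw, hbond, elec, desolv, torsional):
        return cls(vdw=vdw, hbond=hbond, elec=elec, desolv=desolv,
                   torsional=torsional,
                   total=vdw + hbond + elec + desolv + torsional)


def _is_hbond_pair(pi: AtomTypeParameters, pj: AtomTypeParameters) -> bool:
    return ((pi.is_donor_hydrogen and pj.is_acceptor)
            or (pj.is_donor_hydrogen and pi.is_acceptor))


def score_pose(pose: Pose, receptor: ReceptorConformation,
               params: Optional[ScoringParameters] = None,
               hbond_weight_fn: Optional[Callable] = None) -> ScoreBreakdown:
    """Evaluate the empirical score of one rigid pose against a receptor.

    ``hbond_weight_fn(rec_atom, lig_atom) -> E(t)`` supplies the
    directional weight when donor geometry is known; without it the
    ideal-geometry weight 1.0 is used (rescoring default — poses carry
    no bond topology).
    """
    if params is None:
        params = ScoringParameters.autodock4()
    rec_atoms = receptor.atoms
    lig_atoms = pose.ligand_atoms
    prec = [params.lookup(a.atom_type) for a in rec_atoms]
    plig = [params.lookup(a.atom_type) for a in lig_atoms]

    xr = np.array([a.position for a in rec_atoms], dtype=float)
    xl = np.array([a.position for a in lig_atoms], dtype=float)
    qr = np.array([a.charge for a in rec_atoms], dtype=float)
    ql = np.array([a.charge for a in lig_atoms], dtype=float)

    diff = xr[:, None, :] - xl[None, :, :]
    r = np.sqrt(np.sum(diff * diff, axis=2))
    if np.any(r == 0.0):
        i, j = np.argwhere(r == 0.0)[0]
        raise ValueError(
            f"zero distance between receptor atom {rec_atoms[i].serial} "
            f"and ligand atom {lig_atoms[j].serial}")

    cutoff = params.nonbonded_cutoff
    within = np.ones_like(r, dtype=bool) if cutoff is None else (r <= cutoff)

    # electrostatics: screened Coulomb
    eps = params.epsilon_of_r(r)
    elec_pair = COULOMB_CONSTANT * np.outer(qr, ql) / (eps * r)
    elec_pair[~within] = 0.0

    # desolvation: Gaussian-weighted fragmental volumes
    s_r = np.array([p.solpar for p in prec])
    v_r = np.array([p.vol for p in prec])
    s_l = np.array([p.solpar for p in plig])
    v_l = np.array([p.vol for p in plig])
    gauss = np.exp(-(r * r) / (2.0 * params.sigma ** 2))
    desolv_pair = (np.outer(s_r, v_l) + np.outer(v_r, s_l)) * gauss
    desolv_pair[~within] = 0.0

    vdw_sum = 0.0
    hbond_sum = 0.0
    for i, pi in enumerate(prec):
        for j, pj in enumerate(plig):
            if not within[i, j]:
                continue
            rij = r[i, j]
            if _is_hbond_pair(pi, pj):
                acceptor = pj if pi.is_donor_hydrogen else pi
                r0, epsm = acceptor.Rij_hb, acceptor.epsij_hb
                c12 = 5.0 * epsm * r0 ** 12
                c10 = 6.0 * epsm * r0 ** 10
                et = 1.0 if hbond_weight_fn is None else float(
                    hbond_weight_fn(rec_atoms[i], lig_atoms[j]))
                hbond_sum += et * (c12 / rij ** 12 - c10 / rij ** 10)
            else:
                r0 = 0.5 * (pi.Rii + pj.Rii)
                epsm = math.sqrt(pi.epsii * pj.epsii)
                a12 = epsm * r0 ** 12
                b6 = 2.0 * epsm * r0 ** 6
                vdw_sum += a12 / rij ** 12 - b6 / rij ** 6

    w = params.weights
    return ScoreBreakdown.from_components(
        vdw=w["vdw"] * vdw_sum,
        hbond=w["hbond"] * hbond_sum,
        elec=w["elec"] * float(elec_pair.sum()),
        desolv=w["desolv"] * float(desolv_pair.sum()),
        torsional=w["tor"] * pose.n_rotatable_bonds,
    )


def filter_by_energy(hits: Sequence[Tuple[object, float]],
                     cutoff: float = -5.0) -> List[Tuple[object, float]]:
    """Keep ``(ligand, energy)`` entries with energy ≤ cutoff, order kept.

    The default −5 kcal/mol is the screening triage threshold.
    """
    out = []
    for ligand, energy in hits:
        if not np.isfinite(energy):
            raise ValueError(f"non-finite energy for {ligand!r}")
        if energy <= cutoff:
            out.append((ligand, energy))
    return out
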