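"""Seeded synthetic-data generators with known ground truth.

Every input class the pipeline consumes can be generated here: NMR-like
receptor ensembles with a planted medoid, docked-pose clouds with
planted clusters and energies, toy bonded complexes for the MM-PBSA
stage, fluorescence titrations from a known binding constant, and
median-effect dose-response curves with known (Dm, m).  Each generator
takes an explicit seed, uses its own random stream, and returns the
ground truth alongside the data so recovery can be tested without
peeking at the data itself.

Default parameter values mirror the reference screening study: 10
ensemble members with binding-site RMSDs in the 1.0–2.8 Å band, 100
docking trials per ligand, a 20 µM peptide titrated over
0–320 µM ligand with K_b = 1.5×10⁴ M⁻¹, and dose grids matching the
UV-survival experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import AtomRecord, Pose, ReceptorConformation
from .mmpbsa import AngleTerm, BondTerm, Snapshot, TorsionTerm
from .quenching import TitrationSeries
from .synergy import DoseResponse, MedianEffectFit

__all__ = [
    "FixtureSpec",
    "make_ensemble",
    "make_pose_cloud",
    "make_toy_complex",
    "make_born_ion",
    "make_titration",
    "make_dose_response",
    "make_additive_combo",
]


@dataclass
class FixtureSpec:
    """Declarative description of one fixture (same spec ⇒ same data)."""

    seed: int
    kind: str   # ensemble | pose_cloud | toy_complex | titration | dose_response
    params: Dict = field(default_factory=dict)

    def generate(self):
        makers = {
            "ensemble": make_ensemble,
            "pose_cloud": make_pose_cloud,
            "toy_complex": make_toy_complex,
            "titration": make_titration,
            "dose_response": make_dose_response,
        }
        try:
            maker = makers[self.kind]
        except KeyError:
            raise ValueError(f"unknown fixture kind {self.kind!r}") from None
        return maker(self.seed, **self.params)


def _atom(serial, position, name="CA", resnum=None, chain="A", charge=0.0,
          atom_type="C", radius=1.7):
    return AtomRecord(serial=serial, name=name, residue_name="ALA",
                      residue_number=resnum if resnum is not None else serial,
                      chain=chain, position=position, charge=charge,
                      atom_type=atom_type, radius=radius)


def make_ensemble(seed: int, n: int = 10, site_size: int = 10,
                  spread: float = 1.2
                  ) -> Tuple[List[ReceptorConformation], int]:
    """NMR-like receptor ensemble with a planted medoid.

    One member receives the smallest perturbation of a common base
    geometry, making it the medoid; with ``spread = 0`` all members
    coincide and the medoid defaults to index 0 (tie-break).  The
    default spread puts pairwise binding-site RMSDs in the 1–3 Å
    (0.1–0.3 nm) range typical of a relaxed NMR ensemble.
    """
    if n < 2:
        raise ValueError("ensemble needs at least 2 members")
    rng = np.random.default_rng(seed)
    base = rng.uniform(-6.0, 6.0, size=(site_size, 3))
    planted = int(rng.integers(n)) if spread > 0 else 0
    ensemble = []
    selection = [("A", i + 1, "CA") for i in range(site_size)]
    for i in range(n):
        scale = 0.25 * spread if i == planted else spread
        disp = rng.normal(0.0, 1.0, size=(site_size, 3))
        disp -= disp.mean(axis=0)
        coords = base + scale * disp
        atoms = [_atom(j + 1, coords[j], resnum=j + 1)
                 for j in range(site_size)]
        ensemble.append(ReceptorConformation(atoms=atoms,
                                             site_selection=selection))
    return ensemble, planted


def make_pose_cloud(seed: int, k_true: int = 3, n: int = 100,
                    intra_spread: float = 0.5, separation: float = 10.0,
                    energy_offsets: Optional[Sequence[float]] = None,
                    fractions: Optional[Sequence[float]] = None,
                    n_atoms: int = 5) -> Dict:
    """Gaussian pose clusters with planted labels and energies.

    Returns a dict with ``poses``, ``labels`` (planted assignment),
    ``energies`` (kcal/mol, lower for earlier clusters by default) and
    ``per_cluster_min_energy``.  ``fractions`` fixes cluster sizes
    (e.g. a largest cluster at exactly 25 % for gate tests).
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    rng = np.random.default_rng(seed)
    if energy_offsets is None:
        energy_offsets = [-7.0 - 0.5 * c for c in range(k_true)]
    if fractions is None:
        sizes = np.full(k_true, n // k_true)
        sizes[: n % k_true] += 1
    else:
        if len(fractions) != k_true or not math.isclose(sum(fractions), 1.0):
            raise ValueError("fractions must sum to 1 with one entry per cluster")
        sizes = np.floor(np.asarray(fractions) * n).astype(int)
        sizes[0] += n - sizes.sum()
    template = rng.uniform(-2.0, 2.0, size=(n_atoms, 3))
    centers = np.zeros((k_true, 3))
    for c in range(k_true):
        centers[c, c % 3] = separation * (1 + c // 3)
    poses, labels, energies = [], [], []
    for c in range(k_true):
        for _ in range(int(sizes[c])):
            jitter = rng.normal(0.0, intra_spread, size=(n_atoms, 3))
            coords = template + centers[c] + jitter
            atoms = [_atom(j + 1, coords[j], name="C", resnum=1, chain="L")
                     for j in range(n_atoms)]
            poses.append(Pose(ligand_atoms=atoms, run_id=len(poses) + 1))
            labels.append(c)
            energies.append(energy_offsets[c] + rng.uniform(0.0, 0.5))
    order = rng.permutation(len(poses))
    poses = [poses[i] for i in order]
    labels = np.asarray(labels)[order]
    energies = np.asarray(energies)[order]
    for i, p in enumerate(poses):
        p.run_id = i + 1
        p.docking_energy = float(energies[i])
    per_min = np.array([energies[labels == c].min() for c in range(k_true)])
    return {"poses": poses, "labels": labels, "energies": energies,
            "per_cluster_min_energy": per_min, "k_true": k_true}


def _zigzag_chain(n: int, origin: np.ndarray, bond: float = 1.5,
                  angle: float = math.radians(109.5)) -> np.ndarray:
    coords = np.zeros((n, 3))
    step = bond * math.sin(angle / 2.0)
    rise = bond * math.cos(angle / 2.0)
    for i in range(n):
        coords[i] = origin + np.array([i * step, rise * (i % 2), 0.12 * (i % 3)])
    return coords


def make_toy_complex(seed: int, n_rec: int = 4, n_lig: int = 3,
                     n_snapshots: int = 1, jitter: float = 0.03,
                     noninteracting: bool = False,
                     ligand_offset: float = 4.0) -> List[Snapshot]:
    """Toy bonded receptor–ligand trajectory with full parameters.

    Two short zigzag chains with harmonic bonds/angles, one torsion per
    4-atom stretch, Lennard-Jones and Coulomb terms.  The
    ``noninteracting`` switch zeroes the ligand's charges, LJ depths
    and PB radii so every cross term vanishes (the ΔE_MM = 0,
    ΔG_polar = 0 limit of the single-trajectory scheme).
    """
    if n_rec < 1 or n_lig < 1:
        raise ValueError("need at least one atom per species")
    rng = np.random.default_rng(seed)
    rec = _zigzag_chain(n_rec, np.zeros(3))
    lig = _zigzag_chain(n_lig, np.array([0.5, ligand_offset, 0.3]))
    pos0 = np.vstack([rec, lig])
    n = n_rec + n_lig
    charges = np.array([0.2 * (-1) ** i for i in range(n)], dtype=float)
    radii = np.full(n, 1.6)
    masses = np.full(n, 12.0)
    lj_rmin_half = np.full(n, 1.7)
    lj_eps = np.full(n, 0.10)
    lig_slice = slice(n_rec, n)
    if noninteracting:
        charges[lig_slice] = 0.0
        lj_eps[lig_slice] = 0.0
        radii[lig_slice] = 0.0

    def chain_terms(start, count):
        bonds = [BondTerm(i, i + 1, k=300.0, r0=1.5)
                 for i in range(start, start + count - 1)]
        angles = [AngleTerm(i, i + 1, i + 2, kf=50.0,
                            theta0=math.radians(109.5))
                  for i in range(start, start + count - 2)]
        torsions = [TorsionTerm(i, i + 1, i + 2, i + 3, vn=2.0, n=3,
                                gamma=0.0)
                    for i in range(start, start + count - 3)]
        return bonds, angles, torsions

    b1, a1, t1 = chain_terms(0, n_rec)
    b2, a2, t2 = chain_terms(n_rec, n_lig)
    snapshots = []
    for _ in range(n_snapshots):
        pos = pos0 + rng.normal(0.0, jitter, size=pos0.shape)
        snapshots.append(Snapshot(
            positions=pos, charges=charges.copy(), radii=radii.copy(),
            masses=masses.copy(),
            receptor_index=np.arange(n_rec),
            ligand_index=np.arange(n_rec, n),
            bonds=b1 + b2, angles=a1 + a2, torsions=t1 + t2,
            lj_rmin_half=lj_rmin_half.copy(), lj_epsilon=lj_eps.copy()))
    return snapshots


def make_born_ion(q: float = 1.0, radius: float = 2.0) -> Snapshot:
    """Single-ion snapshot whose polar solvation has a closed form.

    The Born formula gives G_polar = −(332.0636/(2a))·q²·(1 − 1/ε_out)
    for a charge q in a sphere of radius a transferred from ε = 1 to
    ε_out.
    """
    return Snapshot(positions=np.zeros((1, 3)), charges=np.array([q]),
                    radii=np.array([radius]), masses=np.array([20.0]),
                    receptor_index=np.array([0]),
                    ligand_index=np.array([], dtype=int))


#: ligand-concentration grid (µM) of the reference compound-12 titration
DEFAULT_TITRATION_GRID = (0.0, 10.0, 20.0, 40.0, 60.0, 80.0, 160.0, 320.0)


def make_titration(seed: int, k_b: float = 1.5e4, dfi_max: float = 100.0,
                   noise_sd: float = 0.0,
                   concs: Sequence[float] = DEFAULT_TITRATION_GRID,
                   peptide_conc: float = 20.0,
                   inner_filter_alpha: float = 0.0) -> Tuple[TitrationSeries, Dict]:
    """Titration from the 1:1 saturable-binding model, K_b in M⁻¹.

    Multiplicative Gaussian noise (fractional ``noise_sd``) applies to
    the modelled quenching response ΔFI; ``inner_filter_alpha`` (per
    µM) adds exponential inner-filter attenuation to both the sample
    and a generated tryptophan-control series.
    """
    if k_b <= 0:
        raise ValueError("k_b must be positive")
    rng = np.random.default_rng(seed)
    conc = np.asarray(concs, dtype=float)
    conc_M = conc * 1e-6
    dfi = dfi_max * k_b * conc_M / (1.0 + k_b * conc_M)
    if noise_sd > 0:
        dfi = dfi * (1.0 + rng.normal(0.0, noise_sd, size=dfi.shape))
    fi0 = 1.2 * dfi_max
    intensity = fi0 - dfi
    control = None
    if inner_filter_alpha > 0:
        atten = np.exp(-inner_filter_alpha * conc)
        intensity = intensity * atten
        control = 1000.0 * atten
    series = TitrationSeries(ligand_conc=conc, intensity=intensity,
                             peptide_conc=peptide_conc,
                             control_intensity=control)
    truth = {"k_b": k_b, "dfi_max": dfi_max, "fi0": fi0}
    return series, truth


#: UV-survival dose grid (J/m²) of the reference cell assay
DEFAULT_UV_DOSES = (0.0, 20.0, 40.0, 80.0)


def make_dose_response(seed: int, dm: float = 5.0, m: float = 1.5,
                       noise_sd: float = 0.0,
                       doses: Optional[Sequence[float]] = None,
                       agent: str = "") -> Tuple[DoseResponse, Dict]:
    """Dose-response curve from the median-effect model.

    Viability = 1 − fa + additive Gaussian noise, clipped to [0, 1];
    the default dose grid is geometric around Dm so the fit is well
    conditioned.
    """
    if dm <= 0 or m <= 0:
        raise ValueError("dm and m must be positive")
    rng = np.random.default_rng(seed)
    if doses is None:
        doses = dm * 2.0 ** np.arange(-3, 4)
        doses = np.concatenate(([0.0], doses))
    doses = np.asarray(doses, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(doses > 0, (doses / dm) ** m, 0.0)
    fa = ratio / (1.0 + ratio)
    viability = 1.0 - fa
    if noise_sd > 0:
        viability = viability + rng.normal(0.0, noise_sd, size=viability.shape)
    viability = np.clip(viability, 0.0, 1.0)
    dr = DoseResponse(dose=doses, viability=viability, agent=agent)
    return dr, {"dm": dm, "m": m}


def make_additive_combo(seed: int, fit_a: MedianEffectFit,
                        fit_b: MedianEffectFit, ratio: Tuple[float, float],
                        noise_sd: float = 0.0,
                        doses: Optional[Sequence[float]] = None
                        ) -> Tuple[DoseResponse, Dict]:
    """Exactly Loewe-additive mixture of two agents with equal slope m.

    For equal m the additive mixture is itself median-effect with
    1/Dm_mix = p_a/Dm_a + p_b/Dm_b (p the dose-ratio fractions), so its
    combination index is 1 at every effect level — the identity used to
    validate the CI computation.
    """
    if not math.isclose(fit_a.m, fit_b.m, rel_tol=1e-9):
        raise ValueError("additive construction requires equal slopes")
    ra, rb = float(ratio[0]), float(ratio[1])
    p_a, p_b = ra / (ra + rb), rb / (ra + rb)
    dm_mix = 1.0 / (p_a / fit_a.dm + p_b / fit_b.dm)
    return make_dose_response(seed, dm=dm_mix, m=fit_a.m, noise_sd=noise_sd,
                              doses=doses, agent="combo")
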