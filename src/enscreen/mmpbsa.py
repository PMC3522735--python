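"""Single-trajectory MM-PBSA binding free energies.

For each snapshot of a complex trajectory the binding free energy is
estimated as

    G = E_MM + G_polar + G_nonpolar − T·S_solute

with ``E_MM`` the gas-phase molecular-mechanics energy (harmonic bonds
and angles, periodic torsions, Lennard-Jones 12-6, Coulomb with ε = 1),
``G_polar`` the electrostatic solvation free energy from a
finite-difference Poisson solver, ``G_nonpolar`` a linear function of
the Shrake–Rupley solvent-accessible surface area, and the solute
entropy from normal-mode analysis.  In the single-trajectory scheme the
receptor and ligand energies are evaluated on sub-selections of the
complex snapshot, so internal (bonded) contributions cancel exactly in
the difference

    ΔX = X_complex − X_receptor − X_ligand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .core import COULOMB_CONSTANT

__all__ = [
    "BondTerm", "AngleTerm", "TorsionTerm", "Snapshot",
    "EnergyComponents", "BindingEnergyResult",
    "mm_energy", "pb_solvation", "shrake_rupley_sasa", "sasa_nonpolar",
    "normal_mode_entropy", "binding_free_energy",
]

# physical constants (CODATA)
_KCAL = 4184.0                     # J per kcal
_NA = 6.02214076e23                # 1/mol
_KB = 1.380649e-23                 # J/K
_H = 6.62607015e-34                # J s
_HBAR = _H / (2 * math.pi)
_R_KCAL = _KB * _NA / _KCAL        # gas constant, kcal/(mol K)
_AMU = 1.66053906660e-27           # kg
# (kcal/mol/Å²/amu) -> s⁻² for mass-weighted Hessian eigenvalues
_OMEGA2 = _KCAL / (_NA * 1e-20 * _AMU)


@dataclass
class BondTerm:
    i: int
    j: int
    k: float       # kcal/mol/Å²
    r0: float      # Å


@dataclass
class AngleTerm:
    i: int
    j: int          # central atom
    k: int
    kf: float       # kcal/mol/rad²
    theta0: float   # rad


@dataclass
class TorsionTerm:
    i: int
    j: int
    k: int
    l: int
    vn: float       # barrier, kcal/mol (E = vn/2 (1 + cos(n φ − γ)))
    n: int
    gamma: float    # rad


@dataclass
class Snapshot:
    """One trajectory frame of a complex with its toy force field.

    ``receptor_index`` and ``ligand_index`` are disjoint index sets
    whose union covers all atoms.  Lennard-Jones parameters are
    per-atom ``(rmin_half Å, epsilon kcal/mol)`` combined by
    Lorentz–Berthelot rules; 1-2 and 1-3 pairs are excluded from the
    nonbonded sums.
    """

    positions: np.ndarray            # (n, 3) Å
    charges: np.ndarray              # (n,) e
    radii: np.ndarray                # (n,) Å (PB/SASA)
    masses: np.ndarray               # (n,) amu
    receptor_index: np.ndarray
    ligand_index: np.ndarray
    bonds: List[BondTerm] = field(default_factory=list)
    angles: List[AngleTerm] = field(default_factory=list)
    torsions: List[TorsionTerm] = field(default_factory=list)
    lj_rmin_half: Optional[np.ndarray] = None
    lj_epsilon: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.receptor_index = np.asarray(self.receptor_index, dtype=int)
        self.ligand_index = np.asarray(self.ligand_index, dtype=int)
        n = self.positions.shape[0]
        both = set(self.receptor_index) & set(self.ligand_index)
        if both:
            raise ValueError(f"receptor/ligand index sets overlap: {sorted(both)}")
        if set(self.receptor_index) | set(self.ligand_index) != set(range(n)):
            raise ValueError("receptor and ligand index sets must cover all atoms")
        if self.lj_rmin_half is None:
            self.lj_rmin_half = np.zeros(n)
        if self.lj_epsilon is None:
            self.lj_epsilon = np.zeros(n)
        self.lj_rmin_half = np.asarray(self.lj_rmin_half, dtype=float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def with_positions(self, positions: np.ndarray) -> "Snapshot":
        return Snapshot(positions=np.asarray(positions, dtype=float),
                        charges=self.charges, radii=self.radii,
                        masses=self.masses,
                        receptor_index=self.receptor_index,
                        ligand_index=self.ligand_index,
                        bonds=self.bonds, angles=self.angles,
                        torsions=self.torsions,
                        lj_rmin_half=self.lj_rmin_half,
                        lj_epsilon=self.lj_epsilon)

    def exclusions(self) -> set:
        """1-2 and 1-3 atom pairs excluded from nonbonded sums."""
        excl = set()
        for b in self.bonds:
            excl.add(frozenset((b.i, b.j)))
        for a in self.angles:
            excl.add(frozenset((a.i, a.k)))
        return excl


# ---------------------------------------------------------------------------
# molecular-mechanics gas-phase energy


def _angle(p0, p1, p2) -> float:
    v1, v2 = p0 - p1, p2 - p1
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return math.acos(max(-1.0, min(1.0, cosang)))


def _dihedral(p0, p1, p2, p3) -> float:
    b0, b1, b2 = p1 - p0, p2 - p1, p3 - p2
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x, y = np.dot(n1, n2), np.dot(m1, n2)
    return math.atan2(y, x)


def mm_energy(s: Snapshot, dielectric: float = 1.0,
              subset: Optional[Sequence[int]] = None,
              positions: Optional[np.ndarray] = None) -> Dict[str, float]:
    """Gas-phase MM energy breakdown (kcal/mol).

    ``subset`` restricts the evaluation to a sub-selection of atoms
    (bonded terms only when every participating atom is in the subset)
    — this is how receptor and ligand energies are carved out of a
    complex snapshot in the single-trajectory scheme.
    """
    x = s.positions if positions is None else np.asarray(positions, dtype=float)
    if subset is None:
        subset_set = set(range(s.n_atoms))
        idx = np.arange(s.n_atoms)
    else:
        idx = np.asarray(subset, dtype=int)
        subset_set = set(int(i) for i in idx)

    e_bond = sum(b.k * (np.linalg.norm(x[b.i] - x[b.j]) - b.r0) ** 2
                 for b in s.bonds if {b.i, b.j} <= subset_set)
    e_angle = sum(a.kf * (_angle(x[a.i], x[a.j], x[a.k]) - a.theta0) ** 2
                  for a in s.angles if {a.i, a.j, a.k} <= subset_set)
    e_tors = sum(0.5 * t.vn * (1.0 + math.cos(t.n * _dihedral(
        x[t.i], x[t.j], x[t.k], x[t.l]) - t.gamma))
        for t in s.torsions if {t.i, t.j, t.k, t.l} <= subset_set)

    excl = s.exclusions()
    e_vdw = 0.0
    e_elec = 0.0
    m = len(idx)
    for a in range(m):
        for b in range(a + 1, m):
            i, j = int(idx[a]), int(idx[b])
            if frozenset((i, j)) in excl:
                continue
            r = float(np.linalg.norm(x[i] - x[j]))
            if r == 0.0:
                raise ValueError(f"zero distance between atoms {i} and {j}")
            eps = math.sqrt(s.lj_epsilon[i] * s.lj_epsilon[j])
            if eps > 0.0:
                rmin = s.lj_rmin_half[i] + s.lj_rmin_half[j]
                sr6 = (rmin / r) ** 6
                e_vdw += eps * (sr6 * sr6 - 2.0 * sr6)
            e_elec += COULOMB_CONSTANT * s.charges[i] * s.charges[j] / (
                dielectric * r)
    total = e_bond + e_angle + e_tors + e_vdw + e_elec
    return {"bond": float(e_bond), "angle": float(e_angle),
            "torsion": float(e_tors), "vdw": float(e_vdw),
            "elec": float(e_elec), "total": float(total)}


# ---------------------------------------------------------------------------
# finite-difference Poisson solver (linearized PB, κ = 0 by default)


try:
    import numba as _numba
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _numba = None

if _numba is not None:
    @_numba.njit(cache=True)
    def _sor_kernel(phi, ex, ey, ez, src, omega, tol, max_iter):
        nx, ny, nz = phi.shape
        for it in range(max_iter):
            maxd = 0.0
            for color in range(2):
                for i in range(1, nx - 1):
                    for j in range(1, ny - 1):
                        k0 = 1 + ((color - i - j - 1) % 2)
                        for k in range(k0, nz - 1, 2):
                            exm = ex[i - 1, j, k]
                            exp_ = ex[i, j, k]
                            eym = ey[i, j - 1, k]
                            eyp = ey[i, j, k]
                            ezm = ez[i, j, k - 1]
                            ezp = ez[i, j, k]
                            nb = (exm * phi[i - 1, j, k] + exp_ * phi[i + 1, j, k]
                                  + eym * phi[i, j - 1, k] + eyp * phi[i, j + 1, k]
                                  + ezm * phi[i, j, k - 1] + ezp * phi[i, j, k + 1])
                            diag = exm + exp_ + eym + eyp + ezm + ezp
                            new = (nb + src[i, j, k]) / diag
                            d = omega * (new - phi[i, j, k])
                            phi[i, j, k] += d
                            if d < 0.0:
                                d = -d
                            if d > maxd:
                                maxd = d
            if maxd < tol:
                return it + 1
        return -1


def _solve_poisson(phi, eps_x, eps_y, eps_z, source, omega, tol, max_iter):
    """Red-black SOR for ∇·(ε∇φ) = −4πkρ on a uniform grid.

    ``source`` is ``4πk·q_node/h`` at interior nodes; boundary values of
    ``phi`` are held fixed (Dirichlet).  Uses a compiled kernel when
    numba is importable, otherwise a vectorised sweep.
    """
    if _numba is not None:
        iters = _sor_kernel(phi, eps_x, eps_y, eps_z, source,
                            float(omega), float(tol), int(max_iter))
        if iters < 0:
            raise RuntimeError(
                f"Poisson solver did not converge in {max_iter} iterations")
        return phi, iters
    return _solve_poisson_numpy(phi, eps_x, eps_y, eps_z, source, omega,
                                tol, max_iter)


def _solve_poisson_numpy(phi, eps_x, eps_y, eps_z, source, omega, tol,
                         max_iter):
    nx, ny, nz = phi.shape
    ii, jj, kk = np.meshgrid(np.arange(1, nx - 1), np.arange(1, ny - 1),
                             np.arange(1, nz - 1), indexing="ij")
    parity = (ii + jj + kk) % 2
    masks = [parity == 0, parity == 1]
    # face dielectrics seen from each interior node
    e_xm = eps_x[:-1, 1:-1, 1:-1]
    e_xp = eps_x[1:, 1:-1, 1:-1]
    e_ym = eps_y[1:-1, :-1, 1:-1]
    e_yp = eps_y[1:-1, 1:, 1:-1]
    e_zm = eps_z[1:-1, 1:-1, :-1]
    e_zp = eps_z[1:-1, 1:-1, 1:]
    diag = e_xm + e_xp + e_ym + e_yp + e_zm + e_zp
    src = source[1:-1, 1:-1, 1:-1]
    for it in range(max_iter):
        max_delta = 0.0
        for mask in masks:
            interior = phi[1:-1, 1:-1, 1:-1]
            nb = (e_xm * phi[:-2, 1:-1, 1:-1] + e_xp * phi[2:, 1:-1, 1:-1]
                  + e_ym * phi[1:-1, :-2, 1:-1] + e_yp * phi[1:-1, 2:, 1:-1]
                  + e_zm * phi[1:-1, 1:-1, :-2] + e_zp * phi[1:-1, 1:-1, 2:])
            new = (nb + src) / diag
            delta = omega * (new - interior)
            interior[mask] += delta[mask]
            max_delta = max(max_delta, float(np.abs(delta[mask]).max()))
        if max_delta < tol:
            return phi, it + 1
    raise RuntimeError(
        f"Poisson solver did not converge in {max_iter} iterations "
        f"(last update {max_delta:.3e})")


def _grid_energy(positions, charges, radii, h, eps_in, eps_out,
                 box_lo, shape, tol, max_iter):
    """0.5 Σ q φ on the grid for a given dielectric environment."""
    nx, ny, nz = shape
    # trilinear (cloud-in-cell) charge assignment
    q_grid = np.zeros(shape)
    frac = (positions - box_lo) / h
    base = np.floor(frac).astype(int)
    t = frac - base
    for d, q in enumerate(charges):
        i, j, k = base[d]
        tx, ty, tz = t[d]
        for di, wx in ((0, 1 - tx), (1, tx)):
            for dj, wy in ((0, 1 - ty), (1, ty)):
                for dk, wz in ((0, 1 - tz), (1, tz)):
                    q_grid[i + di, j + dj, k + dk] += q * wx * wy * wz

    # dielectric on cell edges: harmonic mean of eps over the fraction of
    # the edge lying inside any atom sphere (smooth dielectric boundary)
    def face_eps(axis):
        sh = list(shape)
        sh[axis] -= 1
        if eps_in == eps_out:
            return np.full(sh, eps_out)
        axes = [np.arange(sh[a]) * h + box_lo[a] for a in range(3)]
        mid = axes[axis] + 0.5 * h
        gx, gy, gz = np.meshgrid(*[mid if a == axis else axes[a]
                                   for a in range(3)], indexing="ij",
                                 sparse=True)
        # fraction of the edge [-h/2, +h/2] around the midpoint inside the
        # solute, accumulated as the max over atoms (spheres may overlap)
        frac = np.zeros(sh)
        grids = (gx, gy, gz)
        for c, r in zip(positions, radii):
            if r <= 0:
                continue
            d2_perp = sum((grids[a] - c[a]) ** 2 for a in range(3)
                          if a != axis)
            t = grids[axis] - c[axis]       # along-edge offset of midpoint
            half_chord = np.sqrt(np.maximum(0.0, r * r - d2_perp))
            lo = np.maximum(-half_chord - t, -0.5 * h)
            hi = np.minimum(half_chord - t, 0.5 * h)
            f = np.clip((hi - lo) / h, 0.0, 1.0)
            frac = np.maximum(frac, np.broadcast_to(f, sh))
        return 1.0 / (frac / eps_in + (1.0 - frac) / eps_out)

    eps_x, eps_y, eps_z = face_eps(0), face_eps(1), face_eps(2)

    # Dirichlet boundary: analytic Coulomb in the outer dielectric; the
    # same field (distance-capped near the charges) seeds the interior,
    # which cuts the relaxation count substantially
    coords = [np.arange(n) * h + box_lo[a] for a, n in enumerate(shape)]
    eps_bc = eps_out
    gx, gy, gz = np.meshgrid(*coords, indexing="ij", sparse=True)
    phi = np.zeros(shape)
    for c, q in zip(positions, charges):
        if q == 0.0:
            continue
        r = np.sqrt((gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2)
        phi += COULOMB_CONSTANT * q / (eps_bc * np.maximum(r, 0.5 * h))

    source = 4.0 * math.pi * COULOMB_CONSTANT * q_grid / h
    omega = 2.0 / (1.0 + math.sin(math.pi / max(shape)))
    phi, _ = _solve_poisson(phi, eps_x, eps_y, eps_z, source, omega,
                            tol, max_iter)
    return 0.5 * float(np.sum(q_grid * phi))


def pb_solvation(s: Snapshot, grid_spacing: float = 0.5,
                 eps_in: float = 1.0, eps_out: float = 80.0,
                 subset: Optional[Sequence[int]] = None,
                 margin: float = 10.0, tol: float = 1e-5,
                 max_iter: int = 20000,
                 box: Optional[tuple] = None) -> float:
    """Polar solvation free energy G_polar (kcal/mol).

    Two finite-difference solves on the same grid — solute dielectric
    ``eps_in`` embedded in ``eps_out``, minus a homogeneous ``eps_in``
    reference — so the grid self-energy of the spread charges cancels.
    The grid covers the solute with a ``margin`` (Å) on every side;
    pass ``box=(lo, hi)`` to force a common grid across sub-selections
    of one snapshot (exact cancellation in single-trajectory Δ values).
    """
    idx = np.arange(s.n_atoms) if subset is None else np.asarray(subset, int)
    pos = s.positions[idx]
    charges = s.charges[idx]
    radii = s.radii[idx]
    if np.any(radii < 0):
        raise ValueError("PB radii must be >= 0")
    if not np.any(charges != 0.0):
        return 0.0
    if box is None:
        pad = margin + float(radii.max(initial=0.0))
        lo = pos.min(axis=0) - pad
        hi = pos.max(axis=0) + pad
    else:
        lo, hi = (np.asarray(b, dtype=float) for b in box)
    h = float(grid_spacing)
    shape = tuple(int(math.ceil((hi[a] - lo[a]) / h)) + 1 for a in range(3))
    e_solv = _grid_energy(pos, charges, radii, h, eps_in, eps_out,
                          lo, shape, tol, max_iter)
    e_ref = _grid_energy(pos, charges, radii, h, eps_in, eps_in,
                         lo, shape, tol, max_iter)
    return e_solv - e_ref


# ---------------------------------------------------------------------------
# nonpolar solvation from solvent-accessible surface area


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = math.pi * (3.0 - math.sqrt(5.0)) * i
    z = 1.0 - 2.0 * i / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack((r * np.cos(phi), r * np.sin(phi), z))


def shrake_rupley_sasa(positions: np.ndarray, radii: np.ndarray,
                       probe: float = 1.4, n_points: int = 960) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake–Rupley."""
    positions = np.asarray(positions, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = len(radii)
    unit = _sphere_points(n_points)
    expanded = radii + probe
    areas = np.zeros(n)
    for i in range(n):
        ri = expanded[i]
        pts = positions[i] + ri * unit
        accessible = np.ones(n_points, dtype=bool)
        for j in range(n):
            if j == i:
                continue
            d2 = np.sum((pts - positions[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        areas[i] = 4.0 * math.pi * ri * ri * accessible.mean()
    return areas


def sasa_nonpolar(s: Snapshot, gamma: float = 0.00542, beta: float = 0.92,
                  probe: float = 1.4,
                  subset: Optional[Sequence[int]] = None,
                  n_points: int = 960) -> float:
    """Nonpolar solvation term G_nonpolar = γ·SASA + β (kcal/mol)."""
    idx = np.arange(s.n_atoms) if subset is None else np.asarray(subset, int)
    sasa = shrake_rupley_sasa(s.positions[idx], s.radii[idx],
                              probe=probe, n_points=n_points).sum()
    return gamma * float(sasa) + beta


# ---------------------------------------------------------------------------
# normal-mode solute entropy


def _minimize_subset(s: Snapshot, idx: np.ndarray, gtol: float) -> np.ndarray:
    from scipy.optimize import minimize

    x_full = s.positions.copy()

    def fun(flat):
        x = x_full.copy()
        x[idx] = flat.reshape(-1, 3)
        return mm_energy(s, subset=idx, positions=x)["total"]

    res = minimize(fun, s.positions[idx].ravel(), method="L-BFGS-B",
                   options={"gtol": gtol, "ftol": 1e-14, "maxiter": 2000})
    x_full[idx] = res.x.reshape(-1, 3)
    return x_full


def _hessian(s: Snapshot, idx: np.ndarray, x_full: np.ndarray,
             step: float = 1e-3) -> np.ndarray:
    m = 3 * len(idx)

    def energy(flat):
        x = x_full.copy()
        x[idx] = flat.reshape(-1, 3)
        return mm_energy(s, subset=idx, positions=x)["total"]

    x0 = x_full[idx].ravel().copy()
    hess = np.zeros((m, m))
    e0 = energy(x0)
    for a in range(m):
        ea_p = x0.copy(); ea_p[a] += step
        ea_m = x0.copy(); ea_m[a] -= step
        hess[a, a] = (energy(ea_p) - 2 * e0 + energy(ea_m)) / step ** 2
        for b in range(a + 1, m):
            xpp = x0.copy(); xpp[a] += step; xpp[b] += step
            xpm = x0.copy(); xpm[a] += step; xpm[b] -= step
            xmp = x0.copy(); xmp[a] -= step; xmp[b] += step
            xmm = x0.copy(); xmm[a] -= step; xmm[b] -= step
            val = (energy(xpp) - energy(xpm) - energy(xmp) + energy(xmm)) / (
                4 * step ** 2)
            hess[a, b] = hess[b, a] = val
    return hess


def _rigid_body_modes(x: np.ndarray, masses: np.ndarray) -> np.ndarray:
    n = len(masses)
    sqrtm = np.sqrt(masses)
    com = np.average(x, axis=0, weights=masses)
    modes = []
    for axis in range(3):
        v = np.zeros((n, 3))
        v[:, axis] = sqrtm
        modes.append(v.ravel())
    for axis in range(3):
        e = np.zeros(3)
        e[axis] = 1.0
        v = np.cross(x - com, e) * sqrtm[:, None]
        modes.append(v.ravel())
    q = []
    for v in modes:
        for u in q:
            v = v - np.dot(v, u) * u
        norm = np.linalg.norm(v)
        if norm > 1e-8:
            q.append(v / norm)
    return np.array(q)


def _translational_entropy(mass_amu: float, T: float) -> float:
    m = mass_amu * _AMU
    p = 101325.0
    v = _KB * T / p
    q = (2 * math.pi * m * _KB * T / _H ** 2) ** 1.5 * v
    return _R_KCAL * (math.log(q) + 2.5)


def _rotational_entropy(x: np.ndarray, masses: np.ndarray, T: float) -> float:
    com = np.average(x, axis=0, weights=masses)
    d = x - com
    inertia = np.zeros((3, 3))
    for pos, m in zip(d, masses):
        inertia += m * (np.dot(pos, pos) * np.eye(3) - np.outer(pos, pos))
    # amu Å² -> kg m²
    moments = np.sort(np.linalg.eigvalsh(inertia)) * _AMU * 1e-20
    moments = moments[moments > 1e-53]
    if moments.size == 0:
        return 0.0
    if moments.size < 3 or moments[0] / moments[-1] < 1e-6:
        # linear rotor
        i_lin = moments[-1]
        q = 8 * math.pi ** 2 * i_lin * _KB * T / _H ** 2
        return _R_KCAL * (math.log(q) + 1.0)
    q = math.sqrt(math.pi * np.prod(moments)) * (
        8 * math.pi ** 2 * _KB * T / _H ** 2) ** 1.5
    return _R_KCAL * (math.log(q) + 1.5)


def _vibrational_entropy(omega: np.ndarray, T: float) -> float:
    x = _HBAR * omega / (_KB * T)
    return float(_R_KCAL * np.sum(x / np.expm1(x) - np.log1p(-np.exp(-x))))


def normal_mode_entropy(s: Snapshot, T: float = 300.0,
                        subset: Optional[Sequence[int]] = None,
                        minimize: bool = True, gtol: float = 1e-8,
                        freq_floor: float = 1e-4) -> float:
    """T·S_solute (kcal/mol) from harmonic normal-mode analysis.

    The structure is minimised internally unless already at a minimum;
    rigid-body translation/rotation is projected out of the
    mass-weighted Hessian; the vibrational entropy uses harmonic-
    oscillator statistical mechanics, plus ideal-gas translational and
    rigid-rotor rotational terms at temperature ``T`` (1 atm standard
    state).
    """
    idx = np.arange(s.n_atoms) if subset is None else np.asarray(subset, int)
    masses = s.masses[idx]
    if np.any(masses <= 0):
        raise ValueError("all atoms need positive masses")
    x_full = _minimize_subset(s, idx, gtol) if minimize else s.positions.copy()
    x = x_full[idx]
    n = len(idx)
    s_total = _translational_entropy(float(masses.sum()), T)
    if n > 1:
        s_total += _rotational_entropy(x, masses, T)
        hess = _hessian(s, idx, x_full)
        sqrtm = np.repeat(np.sqrt(masses), 3)
        hess_mw = hess / np.outer(sqrtm, sqrtm)
        modes = _rigid_body_modes(x, masses)
        proj = np.eye(3 * n) - modes.T @ modes
        hess_proj = proj @ hess_mw @ proj
        eig = np.linalg.eigvalsh(hess_proj)
        n_rigid = modes.shape[0]
        expected_internal = 3 * n - n_rigid
        vib = eig[np.abs(eig) > freq_floor]
        if vib.size > expected_internal:
            vib = vib[-expected_internal:]
        if np.any(vib < 0):
            raise ValueError("negative curvature after projection: "
                             "structure is not at a minimum")
        if vib.size < expected_internal:
            raise ValueError("more than the rigid-body count of near-zero "
                             "frequencies: structure is not at a minimum")
        omega = np.sqrt(vib * _OMEGA2)
        s_total += _vibrational_entropy(omega, T)
    return T * s_total


# ---------------------------------------------------------------------------
# binding free energy over a trajectory


@dataclass
class EnergyComponents:
    """MM-PBSA decomposition of one species (kcal/mol)."""

    e_mm: float
    g_polar: float
    g_nonpolar: float
    ts_solute: float

    @property
    def g_total(self) -> float:
        return self.e_mm + self.g_polar + self.g_nonpolar - self.ts_solute


@dataclass
class BindingEnergyResult:
    """ΔG_bind and its component deltas, averaged over snapshots."""

    dg_bind: float
    delta_e_mm: float
    delta_g_polar: float
    delta_g_nonpolar: float
    minus_t_delta_s: float
    per_snapshot: List[float]
    stderr: float


def binding_free_energy(traj: Sequence[Snapshot], T: float = 300.0,
                        grid_spacing: float = 0.5,
                        eps_in: float = 1.0, eps_out: float = 80.0,
                        gamma: float = 0.00542, beta: float = 0.92,
                        probe: float = 1.4,
                        entropy_stride: int = 10,
                        include_entropy: bool = True,
                        pb_margin: float = 10.0) -> BindingEnergyResult:
    """Single-trajectory MM-PBSA binding free energy.

    Receptor and ligand quantities come from sub-selections of each
    complex snapshot (all three PB solves share the complex grid so the
    reference self-energies cancel); the entropy is evaluated on every
    ``entropy_stride``-th snapshot, with internal minimisation.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    deltas = {"e_mm": [], "g_polar": [], "g_nonpolar": []}
    per_snapshot = []
    for s in traj:
        all_idx = np.arange(s.n_atoms)
        pad = pb_margin + float(s.radii.max(initial=0.0))
        box = (s.positions.min(axis=0) - pad, s.positions.max(axis=0) + pad)
        subsets = {"complex": all_idx, "receptor": s.receptor_index,
                   "ligand": s.ligand_index}
        comp = {}
        for name, idx in subsets.items():
            e_mm = mm_energy(s, dielectric=eps_in, subset=idx)["total"]
            g_pol = pb_solvation(s, grid_spacing=grid_spacing, eps_in=eps_in,
                                 eps_out=eps_out, subset=idx, box=box)
            g_np = sasa_nonpolar(s, gamma=gamma, beta=beta, probe=probe,
                                 subset=idx)
            comp[name] = (e_mm, g_pol, g_np)
        d = [comp["complex"][i] - comp["receptor"][i] - comp["ligand"][i]
             for i in range(3)]
        deltas["e_mm"].append(d[0])
        deltas["g_polar"].append(d[1])
        deltas["g_nonpolar"].append(d[2])
        per_snapshot.append(sum(d))

    minus_tds = 0.0
    if include_entropy:
        ent_frames = list(traj[::max(1, entropy_stride)])
        tds_deltas = []
        for s in ent_frames:
            tds = {}
            for name, idx in (("complex", np.arange(s.n_atoms)),
                              ("receptor", s.receptor_index),
                              ("ligand", s.ligand_index)):
                tds[name] = normal_mode_entropy(s, T=T, subset=idx)
            tds_deltas.append(tds["complex"] - tds["receptor"] - tds["ligand"])
        minus_tds = -float(np.mean(tds_deltas))

    delta_e_mm = float(np.mean(deltas["e_mm"]))
    delta_g_polar = float(np.mean(deltas["g_polar"]))
    delta_g_nonpolar = float(np.mean(deltas["g_nonpolar"]))
    dg = delta_e_mm + delta_g_polar + delta_g_nonpolar + minus_tds
    arr = np.asarray(per_snapshot)
    stderr = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return BindingEnergyResult(
        dg_bind=dg, delta_e_mm=delta_e_mm, delta_g_polar=delta_g_polar,
        delta_g_nonpolar=delta_g_nonpolar, minus_t_delta_s=minus_tds,
        per_snapshot=[float(v) for v in per_snapshot], stderr=stderr)
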