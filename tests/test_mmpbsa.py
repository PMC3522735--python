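"""MM-PBSA components: MM energy, PB solver, SASA, entropy, composition."""

import math

import numpy as np
import pytest

from enscreen.core import COULOMB_CONSTANT
from enscreen.mmpbsa import (BondTerm, AngleTerm, Snapshot, TorsionTerm,
                             binding_free_energy, mm_energy,
                             normal_mode_entropy, pb_solvation, sasa_nonpolar,
                             shrake_rupley_sasa)
from enscreen.simulate import make_born_ion, make_toy_complex

from conftest import random_rotation

KB_KCAL = 1.380649e-23 * 6.02214076e23 / 4184.0   # kcal/(mol K)


def free_atoms(positions, charges=None, radii=None, masses=None):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return Snapshot(
        positions=positions,
        charges=np.zeros(n) if charges is None else np.asarray(charges, float),
        radii=np.full(n, 1.5) if radii is None else np.asarray(radii, float),
        masses=np.full(n, 12.0) if masses is None else np.asarray(masses, float),
        receptor_index=np.arange(n), ligand_index=np.array([], dtype=int))


def test_harmonic_bond_at_rest_length():
    s = free_atoms([[0, 0, 0], [1.5, 0, 0]])
    s.bonds = [BondTerm(0, 1, k=300.0, r0=1.5)]
    assert mm_energy(s)["bond"] == pytest.approx(0.0, abs=1e-12)


def test_coulomb_closed_form_minus_100():
    r = 3.320636
    s = free_atoms([[0, 0, 0], [r, 0, 0]], charges=[1.0, -1.0])
    assert mm_energy(s, dielectric=1.0)["elec"] == pytest.approx(-100.0,
                                                                 abs=1e-9)


def test_mm_energy_direct_sum_oracle(rng):
    # independent term-by-term evaluation of a 4-atom system
    pos = np.array([[0.0, 0, 0], [1.4, 0.2, 0], [2.5, 1.3, 0.4],
                    [3.9, 1.1, 1.0]])
    s = free_atoms(pos, charges=[0.3, -0.3, 0.2, -0.2])
    s.lj_rmin_half = np.full(4, 1.7)
    s.lj_epsilon = np.full(4, 0.1)
    s.bonds = [BondTerm(0, 1, 250.0, 1.4), BondTerm(1, 2, 250.0, 1.5)]
    s.angles = [AngleTerm(0, 1, 2, 40.0, math.radians(110.0))]
    s.torsions = [TorsionTerm(0, 1, 2, 3, vn=1.5, n=3, gamma=0.0)]
    got = mm_energy(s, dielectric=1.0)

    def norm(a, b):
        return float(np.linalg.norm(pos[a] - pos[b]))

    e_bond = 250.0 * (norm(0, 1) - 1.4) ** 2 + 250.0 * (norm(1, 2) - 1.5) ** 2
    v1 = pos[0] - pos[1]
    v2 = pos[2] - pos[1]
    theta = math.acos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    e_angle = 40.0 * (theta - math.radians(110.0)) ** 2
    b0, b1, b2 = pos[1] - pos[0], pos[2] - pos[1], pos[3] - pos[2]
    n1, n2 = np.cross(b0, b1), np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    phi = math.atan2(np.dot(m1, n2), np.dot(n1, n2))
    e_tors = 0.75 * (1.0 + math.cos(3 * phi))
    charges = [0.3, -0.3, 0.2, -0.2]
    excluded = {(0, 1), (1, 2), (0, 2)}
    e_elec = e_vdw = 0.0
    for i in range(4):
        for j in range(i + 1, 4):
            if (i, j) in excluded:
                continue
            r = norm(i, j)
            e_elec += COULOMB_CONSTANT * charges[i] * charges[j] / r
            sr6 = (3.4 / r) ** 6
            e_vdw += 0.1 * (sr6 * sr6 - 2 * sr6)
    assert got["bond"] == pytest.approx(e_bond, abs=1e-10)
    assert got["angle"] == pytest.approx(e_angle, abs=1e-10)
    assert got["torsion"] == pytest.approx(e_tors, abs=1e-10)
    assert got["elec"] == pytest.approx(e_elec, abs=1e-10)
    assert got["vdw"] == pytest.approx(e_vdw, abs=1e-10)
    assert got["total"] == pytest.approx(
        e_bond + e_angle + e_tors + e_elec + e_vdw, abs=1e-9)


def test_mm_energy_subset_drops_cross_terms():
    s = free_atoms([[0, 0, 0], [1.5, 0, 0], [8, 0, 0]],
                   charges=[0.5, -0.5, 0.2])
    s.bonds = [BondTerm(0, 1, 300.0, 1.0)]
    sub = mm_energy(s, subset=[0, 2])
    # bond excluded (atom 1 outside), elec only between 0 and 2
    assert sub["bond"] == 0.0
    assert sub["elec"] == pytest.approx(COULOMB_CONSTANT * 0.5 * 0.2 / 8.0,
                                        abs=1e-10)


def test_mm_rigid_invariance(rng):
    snaps = make_toy_complex(4)
    s = snaps[0]
    base = mm_energy(s)["total"]
    rot = random_rotation(rng)
    moved = s.with_positions(s.positions @ rot.T + np.array([3.0, 1.0, -2.0]))
    assert mm_energy(moved)["total"] == pytest.approx(base, abs=1e-9)


def test_pb_zero_charges():
    s = free_atoms([[0, 0, 0]], charges=[0.0], radii=[2.0])
    assert pb_solvation(s) == 0.0


def born_closed_form(q=1.0, a=2.0, eps_out=80.0):
    return -(COULOMB_CONSTANT / (2 * a)) * q * q * (1.0 - 1.0 / eps_out)


def test_born_ion_half_angstrom_grid():
    got = pb_solvation(make_born_ion(), grid_spacing=0.5)
    ref = born_closed_form()
    assert abs(got - ref) / abs(ref) < 0.02


def test_born_convergence_monotone():
    ref = born_closed_form()
    errors = [abs(pb_solvation(make_born_ion(), grid_spacing=h) - ref)
              for h in (1.0, 0.5, 0.25)]
    assert errors[0] > errors[1] > errors[2]


def test_kirkwood_dipole_oracle():
    # two opposite charges inside a 4 Å spherical cavity (the boundary
    # comes from a third, chargeless atom); the Kirkwood multipole
    # series gives the closed-form reference
    d = 1.0
    radius = 4.0
    eps_out = 80.0
    s = Snapshot(positions=np.array([[-d / 2, 0, 0], [d / 2, 0, 0],
                                     [0.0, 0, 0]]),
                 charges=np.array([1.0, -1.0, 0.0]),
                 radii=np.array([0.0, 0.0, radius]),
                 masses=np.array([12.0, 12.0, 12.0]),
                 receptor_index=np.array([0, 1, 2]),
                 ligand_index=np.array([], dtype=int))
    got = pb_solvation(s, grid_spacing=0.4)
    charges = [1.0, -1.0]
    pos = [-d / 2, d / 2]
    ref = 0.0
    for ell in range(40):
        coeff = -(COULOMB_CONSTANT / (2 * radius)) * (
            (ell + 1) * (eps_out - 1)
            / (eps_out * (ell + 1) + ell)) / radius ** (2 * ell)
        series = sum(charges[i] * charges[j] * (pos[i] * pos[j]) ** ell
                     for i in range(2) for j in range(2))
        ref += coeff * series
    assert abs(got - ref) / abs(ref) < 0.05


def test_pb_nonconvergence_errors():
    with pytest.raises(RuntimeError, match="converge"):
        pb_solvation(make_born_ion(), grid_spacing=1.0, max_iter=3)


def test_pb_translation_invariance_within_grid_noise():
    base = pb_solvation(make_born_ion(), grid_spacing=0.5)
    s = make_born_ion()
    moved = s.with_positions(s.positions + np.array([0.27, -0.13, 0.41]))
    shifted = pb_solvation(moved, grid_spacing=0.5)
    assert abs(shifted - base) <= 0.5


def test_sasa_single_atom_closed_form():
    areas = shrake_rupley_sasa(np.zeros((1, 3)), np.array([1.6]))
    assert areas[0] == pytest.approx(4 * math.pi * 3.0 ** 2, rel=1e-12)


def test_sasa_buried_atom_zero():
    # central atom enclosed by a tight shell of large neighbours
    shell_dirs = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                           [0, 0, 1], [0, 0, -1]], dtype=float)
    positions = np.vstack([np.zeros(3), 2.0 * shell_dirs])
    radii = np.array([1.0] + [3.0] * 6)
    areas = shrake_rupley_sasa(positions, radii)
    assert areas[0] == 0.0


def test_sasa_two_spheres_vs_integration_oracle():
    # analytic: two equal spheres of expanded radius R at distance d;
    # exposed fraction of each = (1 + d/(2R))/2 (spherical-cap formula)
    r_atom, probe, d = 1.6, 1.4, 2.5
    big_r = r_atom + probe
    positions = np.array([[0.0, 0, 0], [d, 0, 0]])
    areas = shrake_rupley_sasa(positions, np.array([r_atom, r_atom]),
                               probe=probe)
    exposed_fraction = (1.0 + d / (2 * big_r)) / 2.0
    expected = 4 * math.pi * big_r ** 2 * exposed_fraction
    assert areas[0] == pytest.approx(expected, rel=0.01)
    assert areas[1] == pytest.approx(expected, rel=0.01)


def test_sasa_nonpolar_affine():
    s = free_atoms([[0, 0, 0]], radii=[1.6])
    sasa = 4 * math.pi * 3.0 ** 2
    assert sasa_nonpolar(s) == pytest.approx(0.00542 * sasa + 0.92, rel=1e-9)


def sackur_tetrode(mass_amu, T):
    kb, h, na, amu = 1.380649e-23, 6.62607015e-34, 6.02214076e23, 1.66053906660e-27
    m = mass_amu * amu
    lam = h / math.sqrt(2 * math.pi * m * kb * T)
    p = 101325.0
    v = kb * T / p
    return kb * na / 4184.0 * (math.log(v / lam ** 3) + 2.5)


def test_entropy_single_free_atom():
    s = free_atoms([[0, 0, 0]], masses=[20.0])
    got = normal_mode_entropy(s, T=300.0, minimize=False)
    assert got == pytest.approx(300.0 * sackur_tetrode(20.0, 300.0), rel=1e-9)


def test_entropy_diatomic_vibrational_closed_form():
    k, r0, m = 400.0, 1.2, 12.0
    s = free_atoms([[0, 0, 0], [r0, 0, 0]], masses=[m, m])
    s.bonds = [BondTerm(0, 1, k=k, r0=r0)]
    T = 300.0
    got = normal_mode_entropy(s, T=T, minimize=False)
    # textbook harmonic oscillator: E = k(r−r0)² so force constant 2k,
    # reduced mass m/2, ω = sqrt(2k/(m/2)) in mass-weighted units
    omega2_conv = 4184.0 / (6.02214076e23 * 1e-20 * 1.66053906660e-27)
    omega = math.sqrt(2 * k / (m / 2.0) * omega2_conv)
    hbar, kb, na = 6.62607015e-34 / (2 * math.pi), 1.380649e-23, 6.02214076e23
    x = hbar * omega / (kb * T)
    s_vib = kb * na / 4184.0 * (x / math.expm1(x) - math.log1p(-math.exp(-x)))
    # rotational entropy of a linear rotor, moment of inertia μ r0²
    mu = (m / 2.0) * 1.66053906660e-27
    inertia = mu * (r0 * 1e-10) ** 2
    theta_rot = hbar ** 2 / (2 * inertia * kb)
    s_rot = kb * na / 4184.0 * (math.log(T / theta_rot) + 1.0)
    expected = T * (sackur_tetrode(2 * m, T) + s_rot + s_vib)
    assert got == pytest.approx(expected, rel=1e-6)


def test_entropy_translation_invariance():
    snaps = make_toy_complex(8)
    s = snaps[0]
    a = normal_mode_entropy(s, subset=s.ligand_index)
    moved = s.with_positions(s.positions + np.array([5.0, -3.0, 2.0]))
    b = normal_mode_entropy(moved, subset=moved.ligand_index)
    assert b == pytest.approx(a, rel=1e-6)


def test_entropy_not_at_minimum_errors():
    # two free atoms with no bonded coupling: 6 atom DOF but 12 expected
    # rigid+internal structure cannot satisfy the mode count
    s = free_atoms([[0, 0, 0], [4.0, 0, 0]], masses=[12.0, 12.0])
    with pytest.raises(ValueError):
        normal_mode_entropy(s, minimize=False)


def test_noninteracting_deltas_vanish():
    traj = make_toy_complex(5, noninteracting=True)
    res = binding_free_energy(traj, include_entropy=False)
    assert res.delta_e_mm == pytest.approx(0.0, abs=1e-9)
    assert res.delta_g_polar == pytest.approx(0.0, abs=1e-9)
    assert res.dg_bind == pytest.approx(res.delta_g_nonpolar, abs=1e-9)


def test_binding_free_energy_composition_oracle():
    traj = make_toy_complex(6, n_snapshots=1)
    s = traj[0]
    res = binding_free_energy(traj, include_entropy=False, grid_spacing=0.6)
    pad = 10.0 + float(s.radii.max())
    box = (s.positions.min(axis=0) - pad, s.positions.max(axis=0) + pad)
    manual = {}
    for name, idx in (("complex", np.arange(s.n_atoms)),
                      ("receptor", s.receptor_index),
                      ("ligand", s.ligand_index)):
        manual[name] = (mm_energy(s, subset=idx)["total"]
                        + pb_solvation(s, grid_spacing=0.6, subset=idx, box=box)
                        + sasa_nonpolar(s, subset=idx))
    expected = manual["complex"] - manual["receptor"] - manual["ligand"]
    assert res.dg_bind == pytest.approx(expected, abs=1e-9)


def test_component_additivity():
    traj = make_toy_complex(7, n_snapshots=2, jitter=0.01)
    res = binding_free_energy(traj, include_entropy=False, grid_spacing=0.8)
    assert res.dg_bind == pytest.approx(
        res.delta_e_mm + res.delta_g_polar + res.delta_g_nonpolar
        + res.minus_t_delta_s, abs=1e-9)
    # averaging linearity: mean of per-snapshot totals equals the total
    assert res.dg_bind == pytest.approx(float(np.mean(res.per_snapshot)),
                                        abs=1e-9)


def test_empty_trajectory_errors():
    with pytest.raises(ValueError, match="empty"):
        binding_free_energy([])


def test_snapshot_index_validation():
    with pytest.raises(ValueError, match="cover"):
        Snapshot(positions=np.zeros((2, 3)), charges=np.zeros(2),
                 radii=np.ones(2), masses=np.ones(2),
                 receptor_index=np.array([0]),
                 ligand_index=np.array([], dtype=int))
    with pytest.raises(ValueError, match="overlap"):
        Snapshot(positions=np.zeros((2, 3)), charges=np.zeros(2),
                 radii=np.ones(2), masses=np.ones(2),
                 receptor_index=np.array([0, 1]),
                 ligand_index=np.array([1]))
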