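"""Representative-conformation selection for receptor ensembles.

An NMR (or MD-derived) ensemble is reduced to a single docking target by
computing binding-site RMSDs between members and picking the medoid —
the member with minimal total RMSD to all others, the standard
operationalisation of "the centroid" of an ensemble.  Hydrogens are
excluded by default because NMR hydrogen placement is model-dependent.
"""

from __future__ import annotations

from typing import List, Sequence

import numpy as np

from .core import ReceptorConformation

__all__ = [
    "kabsch_superpose",
    "binding_site_rmsd",
    "rmsd_matrix",
    "rmsd_to_reference",
    "select_representative",
]


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Optimal rigid-body superposition of ``mobile`` onto ``target``.

    Returns the transformed mobile coordinates.  Standard SVD solution
    with the proper-rotation (det = +1) correction.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    p, q = mobile - cm, target - ct
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    return p @ rot.T + ct


def _site_coords(conf: ReceptorConformation, heavy_only: bool) -> np.ndarray:
    atoms = conf.site_atoms() if conf.site_selection else list(conf.atoms)
    if heavy_only:
        atoms = [a for a in atoms if not a.name.startswith("H")]
    if not atoms:
        raise ValueError("binding-site selection resolves to no atoms")
    return np.array([a.position for a in atoms], dtype=float)


def binding_site_rmsd(a: ReceptorConformation, b: ReceptorConformation,
                      superpose: bool = True, heavy_only: bool = True) -> float:
    """RMSD (Å) over the binding-site atoms of two conformations.

    With ``superpose`` the selected atoms of ``a`` are first Kabsch-fitted
    onto those of ``b``, so any proper rigid motion between the inputs is
    removed before the deviation is measured.
    """
    xa, xb = _site_coords(a, heavy_only), _site_coords(b, heavy_only)
    if xa.shape != xb.shape:
        raise ValueError(
            f"selection mismatch: {xa.shape[0]} vs {xb.shape[0]} site atoms")
    if superpose:
        xa = kabsch_superpose(xa, xb)
    return float(np.sqrt(np.mean(np.sum((xa - xb) ** 2, axis=1))))


def rmsd_matrix(ensemble: Sequence[ReceptorConformation],
                superpose: bool = True) -> np.ndarray:
    """Symmetric pairwise binding-site RMSD matrix (Å) for an ensemble."""
    n = len(ensemble)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = binding_site_rmsd(ensemble[i], ensemble[j], superpose=superpose)
            mat[i, j] = mat[j, i] = r
    return mat


def rmsd_to_reference(ensemble: Sequence[ReceptorConformation],
                      reference_index: int = 0,
                      superpose: bool = True) -> List[float]:
    """RMSD of every ensemble member to one reference member (Å)."""
    n = len(ensemble)
    if n < 2:
        raise ValueError("need at least 2 conformations")
    if not (0 <= reference_index < n):
        raise IndexError(f"reference_index {reference_index} out of range")
    ref = ensemble[reference_index]
    return [binding_site_rmsd(conf, ref, superpose=superpose)
            for conf in ensemble]


def select_representative(ensemble: Sequence[ReceptorConformation],
                          superpose: bool = True) -> int:
    """Index of the ensemble medoid (minimal total RMSD to all others).

    Ties break toward the lowest index, which makes the choice
    deterministic and permutation-equivariant.
    """
    n = len(ensemble)
    if n < 1:
        raise ValueError("empty ensemble")
    if n == 1:
        return 0
    totals = rmsd_matrix(ensemble, superpose=superpose).sum(axis=1)
    return int(np.argmin(totals))
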