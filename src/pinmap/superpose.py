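"""Rigid-body superposition and RMSD.

Least-squares superposition uses the SVD form of the Kabsch algorithm with
the usual determinant sign correction, so reflections are never returned.
RMSD between two models is computed over atoms paired by
(chain, residue number, insertion code, atom name); hydrogens are excluded
by default because predicted models do not carry them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import SelectionSpec, StructureModel, equivalent_atom_map, select

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "kabsch_fit",
    "apply_transform",
    "superpose_models",
    "rename_chain",
]

_ORTHO_TOL = 1e-8


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-6):
            raise ValueError("rotation is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation has negative determinant (reflection)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.asarray(coords, dtype=float)
        return coords @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)


@dataclass(frozen=True)
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_atoms: int

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")
        if self.n_atoms < 1:
            raise ValueError("superposition must report at least one atom")


def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid transform mapping ``mobile`` onto
    ``reference`` (equal-length point sets, n >= 3, not collinear)."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")
    cm = mobile.mean(axis=0)
    cr = reference.mean(axis=0)
    X = mobile - cm
    Y = reference - cr
    H = X.T @ Y
    # rank of the covariance detects collinear/degenerate inputs
    U, S, Vt = np.linalg.svd(H)
    if np.sum(S > S[0] * 1e-10 if S[0] > 0 else S > 0) < 2:
        raise ValueError("degenerate (collinear) point set; rotation is not determined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cr - R @ cm
    assert np.allclose(R.T @ R, np.eye(3), atol=_ORTHO_TOL * 100)
    return RigidTransform(R, t)


def apply_transform(model: StructureModel, transform: RigidTransform) -> StructureModel:
    """Return a copy of ``model`` with every atom mapped x -> R x + t."""
    out = model.copy()
    for _, _, atom in out.iter_atoms():
        atom.coords = transform.apply(atom.coords)
    return out


def _paired_coords(mobile: StructureModel, reference: StructureModel,
                   spec: SelectionSpec) -> tuple[np.ndarray, np.ndarray]:
    sub_m = select(mobile, spec)
    sub_r = select(reference, spec)
    pairs = equivalent_atom_map(sub_m, sub_r, heavy_only=True)
    xm = np.array([p[1].coords for p in pairs])
    xr = np.array([p[2].coords for p in pairs])
    return xm, xr


def rename_chain(model: StructureModel, mapping: dict[str, str]) -> StructureModel:
    """Relabel chains (e.g. to compare a monomer against one chain of a
    dimer); chain correspondence is always explicit, never guessed."""
    out = model.copy()
    for chain in out.chains:
        chain.chain_id = mapping.get(chain.chain_id, chain.chain_id)
    seen = [c.chain_id for c in out.chains]
    if len(seen) != len(set(seen)):
        raise ValueError(f"chain renaming produces duplicate ids: {seen}")
    return out


def superpose_models(
    mobile: StructureModel,
    reference: StructureModel,
    fit_on: SelectionSpec | None = None,
    report_on: SelectionSpec | None = None,
) -> SuperpositionResult:
    """Fit ``mobile`` onto ``reference`` and report RMSD.

    The transform is fitted on the ``fit_on`` selection and the RMSD is
    evaluated over the ``report_on`` selection; both default to all
    equivalent heavy atoms.
    """
    fit_on = fit_on or SelectionSpec()
    report_on = report_on or SelectionSpec()
    fit_m, fit_r = _paired_coords(mobile, reference, fit_on)
    transform = kabsch_fit(fit_m, fit_r)
    rep_m, rep_r = _paired_coords(mobile, reference, report_on)
    moved = transform.apply(rep_m)
    rmsd = float(np.sqrt(np.mean(np.sum((moved - rep_r) ** 2, axis=1))))
    return SuperpositionResult(transform=transform, rmsd=rmsd,
                               n_atoms=rep_m.shape[0])
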