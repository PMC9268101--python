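"""Simplified CoMFA-style grid-field 3D-QSAR.

Pre-aligned 3D molecules are surrounded by a shared rectangular grid
(default 1.4 Angstrom spacing, 3 Angstrom margin). At every grid point two
probe interaction energies are evaluated per molecule:

* steric — Lennard-Jones 6-12 energy of a carbon probe (radius 1.73 A),
  with per-element well depths combined by Lorentz-Berthelot rules;
* electrostatic — Coulomb energy of a +1 point charge with a
  distance-dependent dielectric eps(r) = r, i.e. 332.0637 * q_i / r^2.

Energies are truncated to +/- 30 kcal/mol (the classic field convention).
Near-constant grid columns are dropped before a partial-least-squares
regression on activity; the PLS coefficient vector is mapped back through
the drop mask to grid coordinates for contour export.

Alignment is the caller's responsibility: the module expects molecules on a
common frame and offers only rigid least-squares superposition onto a
user-supplied atom mapping as a convenience (`align_rigid`). Partial
charges default to Gasteiger.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.cross_decomposition import PLSRegression

from .chem_io import MolecularGraph

__all__ = [
    "FieldGrid",
    "FieldBlock",
    "PLSModel",
    "COULOMB_K",
    "build_grid",
    "steric_field",
    "electrostatic_field",
    "field_matrix",
    "assemble_and_filter",
    "fit_pls",
    "loo_q2_pls",
    "contour_coefficients",
    "assign_gasteiger",
    "align_rigid",
]

COULOMB_K = 332.0637  # kcal * Angstrom / (mol * e^2)
ENERGY_CAP = 30.0  # kcal/mol
PROBE_RADIUS = 1.73  # Angstrom
DEFAULT_SPACING = 1.4
DEFAULT_MARGIN = 3.0


@lru_cache(maxsize=None)
def _lj_params() -> dict:
    ref = importlib.resources.files("qsarligand.data").joinpath("lj_params.yaml")
    return yaml.safe_load(ref.read_text())


@lru_cache(maxsize=None)
def _vdw_radii() -> dict:
    ref = importlib.resources.files("qsarligand.data").joinpath("vdw_radii.yaml")
    return yaml.safe_load(ref.read_text())


@dataclass(frozen=True)
class FieldGrid:
    origin: tuple[float, float, float]
    spacing: float
    extents: tuple[int, int, int]  # nx, ny, nz

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.extents
        return nx * ny * nz

    def points(self) -> np.ndarray:
        """All grid point coordinates, shape (n_points, 3), x fastest last."""
        nx, ny, nz = self.extents
        ax = [np.arange(n) * self.spacing + o for n, o in zip(self.extents, self.origin)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])


def _coords(mol: MolecularGraph) -> np.ndarray:
    if not mol.has_coords():
        raise ValueError(f"molecule {mol.id!r} has no 3D coordinates")
    return np.array([a.coords for a in mol.atoms], dtype=float)


def build_grid(
    molecules: Sequence[MolecularGraph],
    spacing: float = DEFAULT_SPACING,
    margin: float = DEFAULT_MARGIN,
) -> FieldGrid:
    """Shared grid covering the union bounding box of all molecules plus a
    margin on every side."""
    if not molecules:
        raise ValueError("no molecules")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    all_xyz = np.vstack([_coords(m) for m in molecules])
    lo = all_xyz.min(axis=0) - margin
    hi = all_xyz.max(axis=0) + margin
    extents = tuple(int(np.ceil((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
    return FieldGrid(origin=tuple(lo), spacing=spacing, extents=extents)


def steric_field(
    molecule: MolecularGraph,
    grid: FieldGrid,
    probe_radius: float = PROBE_RADIUS,
    cap: float = ENERGY_CAP,
) -> np.ndarray:
    """Lennard-Jones 6-12 probe energy (kcal/mol) at every grid point.

    Per atom i: E = eps_ij * ((r*/r)^12 - 2 (r*/r)^6) with r* = R_i + R_probe
    and eps_ij = sqrt(eps_i * eps_probe); the summed energy is truncated to
    +/- cap. A probe at distance r = r* from a single atom sits at the
    potential minimum -eps_ij.
    """
    params = _lj_params()
    radii = _vdw_radii()
    eps_tab = params["epsilon"]
    eps_probe = params["probe"]["epsilon"]
    xyz = _coords(molecule)
    pts = grid.points()
    energy = np.zeros(len(pts))
    for atom, pos in zip(molecule.atoms, xyz):
        if atom.element not in eps_tab or atom.element not in radii:
            raise ValueError(f"no LJ parameters for element {atom.element}")
        r_min = radii[atom.element] + probe_radius
        eps = np.sqrt(eps_tab[atom.element] * eps_probe)
        r = np.linalg.norm(pts - pos, axis=1)
        r = np.maximum(r, 1e-6)
        ratio6 = (r_min / r) ** 6
        energy += eps * (ratio6**2 - 2.0 * ratio6)
    return np.clip(energy, -cap, cap)


def electrostatic_field(
    molecule: MolecularGraph,
    grid: FieldGrid,
    probe_charge: float = 1.0,
    cap: float = ENERGY_CAP,
) -> np.ndarray:
    """Coulomb probe energy with distance-dependent dielectric eps(r) = r:
    E = sum_i 332.0637 * q_i * q_probe / r_i^2, truncated to +/- cap."""
    charges = [a.partial_charge for a in molecule.atoms]
    if any(q is None for q in charges):
        raise ValueError(
            f"molecule {molecule.id!r} lacks partial charges; "
            "call assign_gasteiger first"
        )
    xyz = _coords(molecule)
    pts = grid.points()
    energy = np.zeros(len(pts))
    for q, pos in zip(charges, xyz):
        r = np.linalg.norm(pts - pos, axis=1)
        r = np.maximum(r, 1e-6)
        energy += COULOMB_K * q * probe_charge / r**2
    return np.clip(energy, -cap, cap)


def assign_gasteiger(molecule: MolecularGraph) -> MolecularGraph:
    """Attach Gasteiger partial charges (heavy atoms carry their hydrogens'
    charges) computed from the parsed molecule."""
    from rdkit.Chem import AllChem

    if molecule.rdmol is None:
        raise ValueError("Gasteiger charges need the parsed molecule (rdmol)")
    mol = molecule.rdmol
    AllChem.ComputeGasteigerCharges(mol)
    for idx, atom in enumerate(molecule.atoms):
        a = mol.GetAtomWithIdx(idx)
        q = a.GetDoubleProp("_GasteigerCharge") + a.GetDoubleProp("_GasteigerHCharge")
        atom.partial_charge = float(q)
    return molecule


def align_rigid(
    mobile: MolecularGraph,
    reference: MolecularGraph,
    atom_map: Sequence[tuple[int, int]],
) -> MolecularGraph:
    """Rigid least-squares (Kabsch) superposition of ``mobile`` onto
    ``reference`` using a caller-supplied (mobile_idx, ref_idx) atom map.
    Returns the mobile graph with transformed coordinates."""
    mob = _coords(mobile)
    ref = _coords(reference)
    mi = np.array([m for m, _ in atom_map])
    ri = np.array([r for _, r in atom_map])
    P, Q = mob[mi], ref[ri]
    Pc, Qc = P - P.mean(0), Q - Q.mean(0)
    U, _, Vt = np.linalg.svd(Pc.T @ Qc)
    d = np.sign(np.linalg.det(U @ Vt))
    R = U @ np.diag([1.0, 1.0, d]) @ Vt
    moved = (mob - P.mean(0)) @ R + Q.mean(0)
    for atom, xyz in zip(mobile.atoms, moved):
        atom.coords = tuple(xyz)
    return mobile


def field_matrix(
    molecules: Sequence[MolecularGraph], grid: FieldGrid, field: str, **kwargs
) -> np.ndarray:
    """n_molecules x n_gridpoints energy matrix for one field type."""
    func = {"steric": steric_field, "electrostatic": electrostatic_field}[field]
    return np.vstack([func(m, grid, **kwargs) for m in molecules])


@dataclass
class FieldBlock:
    """Filtered, concatenated field matrix ready for PLS.

    ``columns`` records (field name, grid point index) per retained column so
    coefficients can be mapped back to grid coordinates.
    """

    matrix: np.ndarray  # n_molecules x n_retained_columns
    columns: list[tuple[str, int]]
    grid: FieldGrid
    cap: float = ENERGY_CAP
    min_sd: float = 0.05


def assemble_and_filter(
    blocks: dict[str, np.ndarray], grid: FieldGrid, min_sd: float = 0.05
) -> FieldBlock:
    """Concatenate per-field energy matrices and drop near-constant columns
    (standard deviation below ``min_sd``), recording the mask."""
    if not blocks:
        raise ValueError("no field blocks")
    n_mols = next(iter(blocks.values())).shape[0]
    if n_mols < 2:
        raise ValueError("need at least 2 molecules")
    cols, mats = [], []
    for fname, mat in blocks.items():
        sd = mat.std(axis=0)
        keep = np.where(sd >= min_sd)[0]
        for j in keep:
            cols.append((fname, int(j)))
        mats.append(mat[:, keep])
    matrix = np.hstack(mats) if mats else np.empty((n_mols, 0))
    if matrix.shape[1] == 0:
        raise ValueError(
            "all grid columns dropped by the variance filter; "
            "molecules may be identical or min_sd too large"
        )
    return FieldBlock(matrix=matrix, columns=cols, grid=grid, min_sd=min_sd)


class _MeanOnly:
    """Degenerate stand-in used when y is orthogonal to every column."""

    def __init__(self, mean: float, p: int) -> None:
        self._mean = mean
        self.coef_ = np.zeros((1, p))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.full((len(X), 1), self._mean)


@dataclass
class PLSModel:
    n_components: int
    pls: PLSRegression = field(repr=False)
    columns: list[tuple[str, int]]
    grid: FieldGrid
    r2_train: float
    q2_loo: Optional[float] = None

    def predict(self, matrix: np.ndarray) -> np.ndarray:
        return self.pls.predict(matrix).ravel()

    @property
    def coefficients(self) -> np.ndarray:
        return self.pls.coef_.ravel()


def fit_pls(field_block: FieldBlock, y: Sequence[float], n_components: int) -> PLSModel:
    """Partial-least-squares (NIPALS) regression of activity on field
    energies. With components equal to the rank of X the predictions
    coincide with the OLS fit."""
    y = np.asarray(y, float)
    n, p = field_block.matrix.shape
    if n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={n_components} exceeds min(n-1={n - 1}, columns={p})"
        )
    Xc = field_block.matrix - field_block.matrix.mean(axis=0)
    yc = y - y.mean()
    if np.allclose(Xc.T @ yc, 0.0):
        # response orthogonal to every column: NIPALS has no direction to
        # extract; the best linear predictor is the mean (R^2 = 0)
        pls = _MeanOnly(y.mean(), p)
        return PLSModel(
            n_components=n_components,
            pls=pls,
            columns=list(field_block.columns),
            grid=field_block.grid,
            r2_train=0.0,
        )
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(field_block.matrix, y)
    yhat = pls.predict(field_block.matrix).ravel()
    tss = ((y - y.mean()) ** 2).sum()
    r2 = float(1.0 - ((y - yhat) ** 2).sum() / tss)
    return PLSModel(
        n_components=n_components,
        pls=pls,
        columns=list(field_block.columns),
        grid=field_block.grid,
        r2_train=r2,
    )


def loo_q2_pls(field_block: FieldBlock, y: Sequence[float], n_components: int) -> float:
    """Leave-one-out Q^2 = 1 - PRESS/TSS with a per-fold PLS refit."""
    y = np.asarray(y, float)
    n = len(y)
    if n < 4:
        raise ValueError("need at least 4 molecules for LOO")
    preds = np.empty(n)
    X = field_block.matrix
    for i in range(n):
        mask = np.arange(n) != i
        ncomp = min(n_components, mask.sum() - 1)
        pls = PLSRegression(n_components=ncomp, scale=False)
        pls.fit(X[mask], y[mask])
        preds[i] = pls.predict(X[[i]]).ravel()[0]
    press = ((y - preds) ** 2).sum()
    tss = ((y - y.mean()) ** 2).sum()
    return float(1.0 - press / tss)


def contour_coefficients(model: PLSModel) -> pd.DataFrame:
    """PLS regression coefficients mapped back to grid coordinates.

    One row per retained grid column: x, y, z, field, coefficient. Positive
    coefficients mark regions where larger field values increase predicted
    activity, negative the reverse (the blue/red and green/yellow contour
    convention)."""
    pts = model.grid.points()
    coefs = model.coefficients
    rows = [
        {
            "x": pts[j, 0],
            "y": pts[j, 1],
            "z": pts[j, 2],
            "field": fname,
            "coefficient": float(c),
        }
        for (fname, j), c in zip(model.columns, coefs)
    ]
    return pd.DataFrame(rows, columns=["x", "y", "z", "field", "coefficient"])
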