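"""Formula-level 2D molecular descriptors for the five-term TLR7 model.

Every building block is implemented from its defining formula on the
molecular graph:

* ``VE3sign_D_Dt`` — (n/10)*log10 |sum of coefficients| of the eigenvector
  belonging to the smallest (most negative) eigenvalue of the
  distance/detour ratio matrix. The distance matrix holds shortest
  topological distances (bond counts); the detour matrix holds longest
  simple-path distances. For acyclic graphs the two coincide and all
  off-diagonal ratios are 1.
* ``SpMin2_Bh_s`` — second-smallest eigenvalue of the Burden matrix of the
  hydrogen-filled graph, diagonal-weighted by Kier–Hall intrinsic states
  I = ((2/N)^2 * dv + 1) / d (dv: valence electrons, d: sigma/heavy-atom
  degree, N: principal quantum number; hydrogens get I = 5). Off-diagonal
  entries are the bond order pi_b (plus 0.001 when an endpoint is terminal)
  for bonded pairs, 0.001 for non-bonded pairs — the printed convention,
  kept literally (classical Burden matrices use 0.1*pi_b instead).
* ``P_VSA_logP_5`` — sum of per-atom Van der Waals surface areas (sphere
  area minus bonded-neighbor spherical caps, with bond-order-corrected
  reference bond lengths) over atoms whose Ghose–Crippen atomic logP
  contribution lies in (0, 0.25].
* ``Eig02_EA_dm`` — second-largest eigenvalue of the edge-adjacency matrix
  (bonds sharing an atom) with bond dipole moments on the diagonal.
* ``CATS2D_09_AA`` — number of hydrogen-bond-acceptor atom pairs at
  shortest-path distance exactly nine bonds.

All descriptors are invariant under atom/bond reindexing.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass
from functools import lru_cache

import networkx as nx
import numpy as np
import yaml
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors

from .chem_io import MolecularGraph

__all__ = [
    "DescriptorVector",
    "DESCRIPTOR_NAMES",
    "DescriptorError",
    "topological_distance_matrix",
    "detour_matrix",
    "ve3sign_d_dt",
    "estate_intrinsic",
    "burden_matrix",
    "hfilled_burden_matrix",
    "spmin2_bh_s",
    "atomic_logp",
    "vdw_surface_area",
    "p_vsa_logp_5",
    "eig02_ea_dm",
    "cats2d_09_aa",
    "acceptor_atoms",
    "descriptor_vector",
    "descriptor_table",
]

DESCRIPTOR_NAMES = (
    "VE3sign_D_Dt",
    "SpMin2_Bh_s",
    "P_VSA_logP_5",
    "Eig02_EA_dm",
    "CATS2D_09_AA",
)

DETOUR_ATOM_CAP = 60


class DescriptorError(ValueError):
    """Raised when a descriptor cannot be computed for a graph."""


@dataclass(frozen=True)
class DescriptorVector:
    """The five descriptor values of the published activity model."""

    VE3sign_D_Dt: float
    SpMin2_Bh_s: float
    P_VSA_logP_5: float  # Angstrom^2
    Eig02_EA_dm: float
    CATS2D_09_AA: int

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in DESCRIPTOR_NAMES}


@lru_cache(maxsize=None)
def _load_table(name: str) -> dict:
    ref = importlib.resources.files("qsarligand.data").joinpath(name)
    return yaml.safe_load(ref.read_text())


def _heavy_nx(graph: MolecularGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_atoms))
    g.add_edges_from((b.i, b.j) for b in graph.bonds)
    return g


def _require_connected(graph: MolecularGraph) -> nx.Graph:
    g = _heavy_nx(graph)
    if graph.n_atoms and not nx.is_connected(g):
        raise DescriptorError(f"disconnected graph {graph.id!r}")
    return g


# ---------------------------------------------------------------------------
# distance / detour matrices and VE3sign
# ---------------------------------------------------------------------------


def topological_distance_matrix(graph: MolecularGraph) -> np.ndarray:
    """Shortest-path distances in bond counts between all heavy-atom pairs."""
    g = _require_connected(graph)
    n = graph.n_atoms
    dist = np.zeros((n, n))
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, d in lengths.items():
            dist[src, dst] = d
    return dist


def detour_matrix(graph: MolecularGraph, atom_cap: int = DETOUR_ATOM_CAP) -> np.ndarray:
    """Longest simple-path distances (bond counts) between all atom pairs.

    Longest-path search is exponential in the worst case, so graphs above
    ``atom_cap`` heavy atoms are rejected; raise the cap explicitly for
    larger (sparsely cyclic) molecules.
    """
    g = _require_connected(graph)
    n = graph.n_atoms
    if n > atom_cap:
        raise DescriptorError(
            f"{graph.id!r} has {n} heavy atoms > detour cap {atom_cap}; "
            "pass a larger atom_cap if the ring topology is sparse"
        )
    adj = [list(g.neighbors(v)) for v in range(n)]
    det = np.zeros((n, n), dtype=float)

    # Exhaustive iterative DFS from every source; each simple path updates
    # the best length seen for its endpoint. Feasible because molecular
    # graphs are sparse and only ring systems multiply the path count.
    for src in range(n):
        best = det[src]
        visited = [False] * n
        visited[src] = True
        stack = [(src, 0, iter(adj[src]))]
        while stack:
            node, depth, it = stack[-1]
            advanced = False
            for nxt in it:
                if not visited[nxt]:
                    visited[nxt] = True
                    if depth + 1 > best[nxt]:
                        best[nxt] = depth + 1
                    stack.append((nxt, depth + 1, iter(adj[nxt])))
                    advanced = True
                    break
            if not advanced:
                stack.pop()
                visited[node] = False
                visited[src] = True
    det = np.maximum(det, det.T)
    return det


def distance_detour_ratio(graph: MolecularGraph, atom_cap: int = DETOUR_ATOM_CAP) -> np.ndarray:
    """Symmetric matrix of shortest/longest path-length ratios (diagonal 0)."""
    dist = topological_distance_matrix(graph)
    det = detour_matrix(graph, atom_cap=atom_cap)
    n = graph.n_atoms
    ratio = np.zeros((n, n))
    off = ~np.eye(n, dtype=bool)
    ratio[off] = dist[off] / det[off]
    return ratio


def ve3sign_d_dt(graph: MolecularGraph, atom_cap: int = DETOUR_ATOM_CAP) -> float:
    """(n/10)*log10 |sum l_i| over the eigenvector of the smallest eigenvalue
    of the distance/detour matrix.

    Eigenvalues are sorted ascending and "last" means the most negative one;
    the eigenvector's arbitrary global sign is fixed by making its largest-
    magnitude coefficient positive, and the coefficients are summed signed.
    Returns NaN (with a warning) when the coefficient sum vanishes.
    """
    n = graph.n_atoms
    if n < 2:
        raise DescriptorError("VE3sign needs at least 2 heavy atoms")
    ratio = distance_detour_ratio(graph, atom_cap=atom_cap)
    eigvals, eigvecs = np.linalg.eigh(ratio)
    vec = eigvecs[:, 0]  # smallest (most negative) eigenvalue
    vec = vec * np.sign(vec[np.argmax(np.abs(vec))] or 1.0)
    s = float(vec.sum())
    if abs(s) < 1e-12:
        warnings.warn(
            f"VE3sign undefined for {graph.id!r}: eigenvector coefficient sum is 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return n / 10.0 * math.log10(abs(s))


# ---------------------------------------------------------------------------
# E-state intrinsic values and the Burden matrix
# ---------------------------------------------------------------------------

_PT = Chem.GetPeriodicTable()


def estate_intrinsic(graph: MolecularGraph) -> np.ndarray:
    """Kier–Hall intrinsic state I = ((2/N)^2 * dv + 1) / d per heavy atom.

    d is the heavy-atom (sigma skeleton) degree, dv the valence-electron
    count minus attached hydrogens, N the principal quantum number (periodic
    table row). Reference values: pyridine-type N 3.00, tertiary amine N
    2.00, ether O 3.50.
    """
    degrees = np.zeros(graph.n_atoms, dtype=int)
    for b in graph.bonds:
        degrees[b.i] += 1
        degrees[b.j] += 1
    out = np.empty(graph.n_atoms)
    for idx, atom in enumerate(graph.atoms):
        znum = _PT.GetAtomicNumber(atom.element)
        if znum <= 1:
            raise DescriptorError(
                "hydrogen is not part of the H-depleted intrinsic-state view"
            )
        period = _PT.GetRow(znum)
        if period < 1:
            raise DescriptorError(f"no principal quantum number for {atom.element}")
        dv = _PT.GetNOuterElecs(znum) - atom.attached_h
        d = int(degrees[idx])
        if d < 1:
            raise DescriptorError(
                f"atom {idx} ({atom.element}) is unbonded; intrinsic state needs d >= 1"
            )
        out[idx] = ((2.0 / period) ** 2 * dv + 1.0) / d
    return out


H_INTRINSIC = 5.0  # I for hydrogen: d = dv = N = 1 -> ((2/1)^2*1 + 1)/1


def burden_matrix(
    adjacency_orders: np.ndarray, weights: np.ndarray
) -> np.ndarray:
    """Burden matrix from a bond-order adjacency matrix and diagonal weights.

    ``adjacency_orders[i, j]`` is the bond order pi_b for bonded pairs and 0
    otherwise. Bonded entries keep pi_b literally (with +0.001 when either
    endpoint is terminal, i.e. degree 1); non-bonded off-diagonal entries
    are 0.001.
    """
    orders = np.asarray(adjacency_orders, dtype=float)
    w = np.asarray(weights, dtype=float)
    n = orders.shape[0]
    if orders.shape != (n, n):
        raise DescriptorError("adjacency matrix must be square")
    if w.shape != (n,):
        raise DescriptorError(
            f"weight vector length {w.shape} does not match {n} atoms"
        )
    degree = (orders > 0).sum(axis=1)
    terminal = degree == 1
    mat = np.full((n, n), 0.001)
    bonded = orders > 0
    mat[bonded] = orders[bonded]
    term_pair = bonded & (terminal[:, None] | terminal[None, :])
    mat[term_pair] += 0.001
    np.fill_diagonal(mat, w)
    return mat


def hfilled_burden_matrix(graph: MolecularGraph) -> np.ndarray:
    """Burden matrix of the hydrogen-filled graph weighted by intrinsic state.

    Heavy atoms come first in input order, followed by their hydrogens
    (order 1 bonds to the parent atom, weight I = 5).
    """
    n_heavy = graph.n_atoms
    n_total = n_heavy + graph.total_h()
    orders = np.zeros((n_total, n_total))
    for b in graph.bonds:
        orders[b.i, b.j] = orders[b.j, b.i] = b.order
    h_idx = n_heavy
    for idx, atom in enumerate(graph.atoms):
        for _ in range(atom.attached_h):
            orders[idx, h_idx] = orders[h_idx, idx] = 1.0
            h_idx += 1
    weights = np.concatenate(
        [estate_intrinsic(graph), np.full(n_total - n_heavy, H_INTRINSIC)]
    )
    return burden_matrix(orders, weights)


def spmin2_bh_s(graph: MolecularGraph) -> float:
    """Second-smallest eigenvalue of the intrinsic-state Burden matrix of the
    hydrogen-filled graph."""
    if graph.n_atoms + graph.total_h() < 2:
        raise DescriptorError("SpMin2 needs at least 2 atoms in the H-filled graph")
    mat = hfilled_burden_matrix(graph)
    eigvals = np.linalg.eigvalsh(mat)
    return float(eigvals[1])


# ---------------------------------------------------------------------------
# atomic logP, Van der Waals surface areas and P_VSA
# ---------------------------------------------------------------------------


def atomic_logp(graph: MolecularGraph) -> np.ndarray:
    """Ghose–Crippen atomic logP contribution per heavy atom.

    Atoms are typed with the Crippen atom-centred fragment scheme (RDKit's
    implementation); contributions of attached hydrogens are folded into
    their heavy atom so the per-atom values sum to the whole-molecule logP.
    """
    if graph.rdmol is None:
        raise DescriptorError(
            f"atomic logP needs the parsed molecule for {graph.id!r} "
            "(build the graph via parse_smiles/read_sdf)"
        )
    molh = Chem.AddHs(graph.rdmol)
    contribs = rdMolDescriptors._CalcCrippenContribs(molh)
    per_heavy = np.zeros(graph.n_atoms)
    for atom in molh.GetAtoms():
        c = contribs[atom.GetIdx()][0]
        if atom.GetAtomicNum() == 1:
            per_heavy[atom.GetNeighbors()[0].GetIdx()] += c
        else:
            per_heavy[atom.GetIdx()] += c
    return per_heavy


def vdw_surface_area(graph: MolecularGraph) -> np.ndarray:
    """Per-atom Van der Waals surface area (Angstrom^2).

    VSA_i = 4*pi*R_i^2 - pi*R_i * sum_j a_ij * (R_j^2 - (R_i - d_ij)^2)/d_ij
    over bonded neighbours j, where d_ij = min(max(|R_i - R_j|, b_ij),
    R_i + R_j) clips the working distance, b_ij = r_ij - c_ij is the
    reference bond length (sum of covalent radii) shortened by the bond-order
    correction c_ij (0 single, 0.1 aromatic, 0.2 double, 0.3 triple).
    Negative areas are clamped to zero; an isolated atom gives the full
    sphere 4*pi*R^2.
    """
    radii = _load_table("vdw_radii.yaml")
    cov = _load_table("covalent_radii.yaml")
    c_corr = {1: 0.0, 1.5: 0.1, 2: 0.2, 3: 0.3}
    R = np.empty(graph.n_atoms)
    for idx, atom in enumerate(graph.atoms):
        if atom.element not in radii:
            raise DescriptorError(f"no Van der Waals radius for element {atom.element}")
        if atom.element not in cov:
            raise DescriptorError(f"no covalent radius for element {atom.element}")
        R[idx] = radii[atom.element]
    vsa = 4.0 * math.pi * R**2
    for b in graph.bonds:
        ri, rj = R[b.i], R[b.j]
        r_ref = cov[graph.atoms[b.i].element] + cov[graph.atoms[b.j].element]
        bij = r_ref - c_corr[b.order]
        dij = min(max(abs(ri - rj), bij), ri + rj)
        vsa[b.i] -= math.pi * ri * (rj**2 - (ri - dij) ** 2) / dij
        vsa[b.j] -= math.pi * rj * (ri**2 - (rj - dij) ** 2) / dij
    return np.maximum(vsa, 0.0)


def p_vsa_logp_5(graph: MolecularGraph) -> float:
    """Sum of Van der Waals surface areas over atoms with atomic logP in
    (0, 0.25] (Angstrom^2); 0 when no atom qualifies."""
    logp = atomic_logp(graph)
    vsa = vdw_surface_area(graph)
    mask = (logp > 0.0) & (logp <= 0.25)
    return float(vsa[mask].sum())


# ---------------------------------------------------------------------------
# edge adjacency / dipole eigenvalue descriptor
# ---------------------------------------------------------------------------


def _bond_dipole(graph: MolecularGraph, bond) -> float:
    table = _load_table("bond_dipoles.yaml")
    e1, e2 = sorted(
        (graph.atoms[bond.i].element, graph.atoms[bond.j].element)
    )
    order = int(bond.order) if bond.order != 1.5 else 1.5
    key = f"{e1}-{e2}:{order}"
    if key not in table:
        warnings.warn(
            f"no bond dipole tabulated for {key}; using 0",
            RuntimeWarning,
            stacklevel=3,
        )
        return 0.0
    return float(table[key])


def eig02_ea_dm(graph: MolecularGraph) -> float:
    """Second-largest eigenvalue of the dipole-weighted edge adjacency matrix.

    The |E| x |E| matrix has 1 where two bonds share an atom and the bond
    dipole moment (Debye) on the diagonal; eigenvalues are sorted descending.
    """
    m = graph.n_bonds
    if m < 2:
        raise DescriptorError("Eig02_EA needs at least 2 bonds")
    mat = np.zeros((m, m))
    for a in range(m):
        ba = graph.bonds[a]
        mat[a, a] = _bond_dipole(graph, ba)
        for b in range(a + 1, m):
            bb = graph.bonds[b]
            if len({ba.i, ba.j} & {bb.i, bb.j}) == 1:
                mat[a, b] = mat[b, a] = 1.0
    eigvals = np.sort(np.linalg.eigvalsh(mat))[::-1]
    return float(eigvals[1])


# ---------------------------------------------------------------------------
# CATS2D acceptor-acceptor pair count
# ---------------------------------------------------------------------------


def acceptor_atoms(graph: MolecularGraph) -> list[int]:
    """Hydrogen-bond acceptor atoms under the CATS typing rules.

    Oxygens are acceptors unless positively charged. Nitrogens are acceptors
    unless positively charged, amide-type (bonded to a carbonyl carbon), or
    pyrrole-type (aromatic with an attached hydrogen or three ring
    neighbours, i.e. the lone pair is part of the aromatic sextet).
    """
    carbonyl_c = set()
    for b in graph.bonds:
        if b.order == 2:
            ei, ej = graph.atoms[b.i].element, graph.atoms[b.j].element
            if ei == "C" and ej == "O":
                carbonyl_c.add(b.i)
            elif ei == "O" and ej == "C":
                carbonyl_c.add(b.j)
    out = []
    for idx, atom in enumerate(graph.atoms):
        if atom.formal_charge > 0:
            continue
        if atom.element == "O":
            out.append(idx)
        elif atom.element == "N":
            nbrs = graph.neighbors(idx)
            if atom.is_aromatic and (atom.attached_h > 0 or len(nbrs) == 3):
                continue  # pyrrole-type: lone pair in the ring
            if any(nb in carbonyl_c for nb in nbrs):
                continue  # amide nitrogen
            out.append(idx)
    return out


def cats2d_09_aa(graph: MolecularGraph) -> int:
    """Number of unordered acceptor-acceptor pairs at shortest-path distance
    exactly nine bonds."""
    acceptors = acceptor_atoms(graph)
    if len(acceptors) < 2:
        return 0
    dist = topological_distance_matrix(graph)
    count = 0
    for a_pos, a in enumerate(acceptors):
        for b in acceptors[a_pos + 1 :]:
            if dist[a, b] == 9:
                count += 1
    return count


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def descriptor_vector(graph: MolecularGraph, atom_cap: int = DETOUR_ATOM_CAP) -> DescriptorVector:
    """Compute all five model descriptors for one molecule."""
    values = {}
    for name, func in (
        ("VE3sign_D_Dt", lambda g: ve3sign_d_dt(g, atom_cap=atom_cap)),
        ("SpMin2_Bh_s", spmin2_bh_s),
        ("P_VSA_logP_5", p_vsa_logp_5),
        ("Eig02_EA_dm", eig02_ea_dm),
        ("CATS2D_09_AA", cats2d_09_aa),
    ):
        try:
            values[name] = func(graph)
        except DescriptorError as exc:
            raise DescriptorError(f"{name} failed for {graph.id!r}: {exc}") from exc
    return DescriptorVector(**values)


def descriptor_table(graphs, atom_cap: int = DETOUR_ATOM_CAP):
    """Descriptor DataFrame (index: compound id, columns: the five names)."""
    import pandas as pd

    rows = {g.id: descriptor_vector(g, atom_cap=atom_cap).as_dict() for g in graphs}
    return pd.DataFrame.from_dict(rows, orient="index")[list(DESCRIPTOR_NAMES)]
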