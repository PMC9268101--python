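"""Shared fixtures: fixture molecules, permutation helpers, small datasets."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from qsarligand.chem_io import Atom, Bond, MolecularGraph
from qsarligand.synthetic_data import SyntheticSpec, fixture_molecules, generate_2d_dataset


@pytest.fixture(scope="session")
def fixtures():
    """The bundled ~20 drug-like fixture molecules."""
    return fixture_molecules()


@pytest.fixture(scope="session")
def synthetic_54():
    """One default 54-compound synthetic dataset (seed 0)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return generate_2d_dataset(SyntheticSpec(seed=0))


@pytest.fixture(scope="session")
def linear_design():
    """Small exactly-linear regression problem: y affine in 3 columns."""
    rng = np.random.default_rng(42)
    X = pd.DataFrame(
        rng.normal(size=(20, 3)), columns=["a", "b", "c"],
        index=[f"c{i}" for i in range(20)],
    )
    beta = np.array([1.5, -2.0, 0.7])
    y = 0.3 + X.to_numpy() @ beta
    return X, y, 0.3, beta


def permute_graph(graph: MolecularGraph, rng: np.random.Generator) -> MolecularGraph:
    """Relabel atoms (and shuffle bond order) under a random permutation."""
    n = graph.n_atoms
    perm = rng.permutation(n)
    inv = np.empty(n, dtype=int)
    inv[perm] = np.arange(n)
    atoms = [graph.atoms[perm[i]] for i in range(n)]
    bonds = [Bond(int(inv[b.i]), int(inv[b.j]), b.order) for b in graph.bonds]
    rng.shuffle(bonds)
    return MolecularGraph(atoms=atoms, bonds=bonds, id=graph.id + "_perm", rdmol=None)


@pytest.fixture
def chain_graph():
    """Hand-built 4-atom chain (n-butane) without an RDKit backing mol."""
    atoms = [Atom("C", attached_h=3), Atom("C", attached_h=2),
             Atom("C", attached_h=2), Atom("C", attached_h=3)]
    bonds = [Bond(0, 1, 1), Bond(1, 2, 1), Bond(2, 3, 1)]
    return MolecularGraph(atoms=atoms, bonds=bonds, id="butane_manual")
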