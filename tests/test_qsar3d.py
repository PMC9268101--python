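"""Grid construction, probe fields, column filtering, PLS and contours."""

import math

import numpy as np
import pytest

from qsarligand.chem_io import Atom, Bond, MolecularGraph
from qsarligand.qsar3d import (
    COULOMB_K,
    FieldGrid,
    assemble_and_filter,
    build_grid,
    contour_coefficients,
    electrostatic_field,
    fit_pls,
    loo_q2_pls,
    steric_field,
    align_rigid,
)
from qsarligand.synthetic_data import generate_3d_toy


def _atom_mol(element="C", xyz=(0.0, 0.0, 0.0), q=0.0, mol_id="a"):
    return MolecularGraph(
        atoms=[Atom(element, coords=tuple(xyz), partial_charge=q)], bonds=[], id=mol_id
    )


def test_build_grid_single_atom_extents():
    g = build_grid([_atom_mol()], spacing=1.4, margin=3.0)
    # 6 A span per axis at 1.4 A spacing -> ceil(6/1.4)+1 = 6 points
    assert all(n >= 5 for n in g.extents)
    pts = g.points()
    assert pts.min() <= -3.0 + 1e-9 and pts.max() >= 3.0 - 1.4


def test_build_grid_covers_all_molecules():
    m1 = _atom_mol(xyz=(0, 0, 0), mol_id="a")
    m2 = _atom_mol(xyz=(8, -4, 2), mol_id="b")
    g = build_grid([m1, m2], margin=2.0)
    pts = g.points()
    for m in (m1, m2):
        xyz = np.array(m.atoms[0].coords)
        assert np.all(pts.min(axis=0) <= xyz) and np.all(pts.max(axis=0) >= xyz)


def test_grid_halved_spacing_scales_points():
    mols = [_atom_mol(xyz=(0, 0, 0)), _atom_mol(xyz=(60, 60, 60), mol_id="b")]
    n1 = build_grid(mols, spacing=1.4).n_points
    n2 = build_grid(mols, spacing=0.7).n_points
    assert 6.0 < n2 / n1 < 10.0  # ~8x within rounding


def test_steric_singularity_clamp_and_decay():
    mol = _atom_mol()
    grid = FieldGrid(origin=(0.0, 0.0, 0.0), spacing=20.0, extents=(2, 1, 1))
    e = steric_field(mol, grid, cap=30.0)
    assert e[0] == 30.0            # probe at the atom centre: clamped
    assert abs(e[1]) < 1e-3        # 20 A away: decayed to ~0


def test_steric_minimum_matches_closed_form():
    """Probe at r = R_C + R_probe from a single carbon sits at -eps_comb."""
    r_min = 1.70 + 1.73
    eps_comb = math.sqrt(0.0860 * 0.1094)
    mol = _atom_mol()
    grid = FieldGrid(origin=(r_min, 0.0, 0.0), spacing=1.0, extents=(1, 1, 1))
    e = steric_field(mol, grid)
    assert e[0] == pytest.approx(-eps_comb, abs=1e-9)


def test_electrostatic_closed_form_and_symmetry():
    mol = _atom_mol(q=1.0)
    r = 5.0
    grid = FieldGrid(origin=(r, 0.0, 0.0), spacing=1.0, extents=(1, 1, 1))
    e = electrostatic_field(mol, grid)
    assert e[0] == pytest.approx(COULOMB_K / r**2, abs=1e-6)

    pair = MolecularGraph(
        atoms=[
            Atom("C", coords=(-1.0, 0, 0), partial_charge=0.5),
            Atom("C", coords=(1.0, 0, 0), partial_charge=-0.5),
        ],
        bonds=[Bond(0, 1, 1)],
        id="dipole",
    )
    mid = FieldGrid(origin=(0.0, 4.0, 0.0), spacing=1.0, extents=(1, 1, 1))
    assert electrostatic_field(pair, mid)[0] == pytest.approx(0.0, abs=1e-12)


def test_electrostatic_zero_charges():
    mol = _atom_mol(q=0.0)
    grid = FieldGrid(origin=(3.0, 0, 0), spacing=1.0, extents=(4, 1, 1))
    assert np.all(electrostatic_field(mol, grid) == 0.0)


def test_fields_translation_covariant():
    rng = np.random.default_rng(3)
    atoms = [
        Atom("C", coords=tuple(rng.normal(size=3)), partial_charge=float(q))
        for q in rng.uniform(-0.3, 0.3, 5)
    ]
    bonds = [Bond(i, i + 1, 1) for i in range(4)]
    mol = MolecularGraph(atoms=atoms, bonds=bonds, id="m")
    grid = build_grid([mol], spacing=1.4, margin=2.0)
    s0, e0 = steric_field(mol, grid), electrostatic_field(mol, grid)
    shift = np.array([5.0, -2.0, 1.0])
    moved = MolecularGraph(
        atoms=[
            Atom("C", coords=tuple(np.array(a.coords) + shift), partial_charge=a.partial_charge)
            for a in atoms
        ],
        bonds=bonds,
        id="m2",
    )
    grid2 = FieldGrid(
        origin=tuple(np.array(grid.origin) + shift),
        spacing=grid.spacing,
        extents=grid.extents,
    )
    assert steric_field(moved, grid2) == pytest.approx(s0, abs=1e-8)
    assert electrostatic_field(moved, grid2) == pytest.approx(e0, abs=1e-8)


def test_filter_drops_constant_columns_and_errors_when_identical():
    grid = FieldGrid(origin=(0, 0, 0), spacing=1.0, extents=(3, 1, 1))
    varying = np.array([[1.0, 5.0, 0.0], [2.0, 5.0, 0.0], [3.0, 5.0, 0.0]])
    fb = assemble_and_filter({"steric": varying}, grid)
    assert fb.matrix.shape == (3, 1)
    assert fb.columns == [("steric", 0)]

    identical = np.tile(varying[0], (3, 1))
    with pytest.raises(ValueError, match="dropped"):
        assemble_and_filter({"steric": identical}, grid)

    fb_all = assemble_and_filter({"steric": varying}, grid, min_sd=0.0)
    assert fb_all.matrix.shape == (3, 3)


def test_pls_full_rank_equals_ols():
    rng = np.random.default_rng(7)
    X = rng.normal(size=(12, 3))
    y = X @ np.array([1.0, -0.5, 2.0]) + rng.normal(scale=0.1, size=12)
    grid = FieldGrid(origin=(0, 0, 0), spacing=1.0, extents=(3, 1, 1))
    fb = assemble_and_filter({"steric": X}, grid, min_sd=0.0)
    model = fit_pls(fb, y, n_components=3)
    A = np.column_stack([np.ones(12), X])
    beta = np.linalg.pinv(A) @ y
    assert model.predict(X) == pytest.approx(A @ beta, abs=1e-8)


def test_pls_orthogonal_response_r2_zero():
    X = np.array([[1.0, 0.0], [-1.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
    y = np.array([1.0, 1.0, -1.0, -1.0])  # orthogonal to both columns
    grid = FieldGrid(origin=(0, 0, 0), spacing=1.0, extents=(2, 1, 1))
    fb = assemble_and_filter({"steric": X}, grid, min_sd=0.0)
    model = fit_pls(fb, y, n_components=1)
    assert model.r2_train == pytest.approx(0.0, abs=1e-10)


def test_pls_rank_one_exact_recovery():
    rng = np.random.default_rng(15)
    t = rng.normal(size=10)
    p = rng.normal(size=6)
    X = np.outer(t, p)
    y = 2.0 * t
    grid = FieldGrid(origin=(0, 0, 0), spacing=1.0, extents=(6, 1, 1))
    fb = assemble_and_filter({"steric": X}, grid, min_sd=0.0)
    model = fit_pls(fb, y, n_components=1)
    assert model.predict(X) == pytest.approx(y, abs=1e-8)
    with pytest.raises(ValueError, match="n_components"):
        fit_pls(fb, y, n_components=11)


def test_loo_q2_noiseless_and_bounded_by_r2():
    mols, y, _ = generate_3d_toy(n=30, seed=5, sigma=0.0)
    from qsarligand.qsar3d import field_matrix

    grid = build_grid(mols)
    fb = assemble_and_filter({"electrostatic": field_matrix(mols, grid, "electrostatic")}, grid)
    model = fit_pls(fb, y, 3)
    q2 = loo_q2_pls(fb, y, 3)
    assert q2 > 0.95
    assert q2 <= model.r2_train + 1e-9


def test_loo_q2_permuted_response_near_zero():
    rng = np.random.default_rng(2)
    mols, y, _ = generate_3d_toy(n=20, seed=2, sigma=0.1)
    from qsarligand.qsar3d import field_matrix

    grid = build_grid(mols)
    fb = assemble_and_filter({"electrostatic": field_matrix(mols, grid, "electrostatic")}, grid)
    q2s = [loo_q2_pls(fb, rng.permutation(y), 2) for _ in range(20)]
    assert np.mean(q2s) < 0.2


def test_contour_export_designated_column_dominates():
    mols, y, truth = generate_3d_toy(n=24, seed=11, sigma=0.0)
    from qsarligand.qsar3d import field_matrix

    grid = build_grid(mols)
    E = field_matrix(mols, grid, "electrostatic")
    fb = assemble_and_filter({"electrostatic": E}, grid)
    model = fit_pls(fb, y, 3)
    table = contour_coefficients(model)
    assert set(table["field"]) == {"electrostatic"}
    assert len(table) == fb.matrix.shape[1]
    # the designated signal points should carry leading coefficient weight
    retained = [j for _, j in fb.columns]
    mags = table["coefficient"].abs().to_numpy()
    top = {retained[i] for i in np.argsort(mags)[::-1][:10]}
    assert top & set(truth["signal_points"])


def test_align_rigid_recovers_rotation():
    rng = np.random.default_rng(23)
    xyz = rng.normal(size=(6, 3))
    theta = 0.7
    R = np.array(
        [
            [math.cos(theta), -math.sin(theta), 0],
            [math.sin(theta), math.cos(theta), 0],
            [0, 0, 1],
        ]
    )
    moved = xyz @ R.T + np.array([1.0, -2.0, 0.5])
    ref = MolecularGraph(
        atoms=[Atom("C", coords=tuple(p)) for p in xyz],
        bonds=[Bond(i, i + 1, 1) for i in range(5)],
        id="ref",
    )
    mob = MolecularGraph(
        atoms=[Atom("C", coords=tuple(p)) for p in moved],
        bonds=[Bond(i, i + 1, 1) for i in range(5)],
        id="mob",
    )
    out = align_rigid(mob, ref, [(i, i) for i in range(6)])
    got = np.array([a.coords for a in out.atoms])
    assert got == pytest.approx(xyz, abs=1e-8)
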