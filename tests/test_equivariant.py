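"""Spherical harmonics, Clebsch–Gordan tables, tensor products and
Wigner-D blocks — each checked against an independent construction."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from nemp.equivariant import (CGTable, EquivariantFeatureBlock,
                              cg_table, clebsch_gordan_complex, lm_slices,
                              real_sph_harm, real_sph_harm_ad,
                              rotate_features, tensor_product,
                              tensor_product_values, wigner_d_real)
import nemp.autodiff as ad


def random_unit(rng, n=1):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


# ---------------------------------------------------------------- harmonics

def test_y00_is_constant(rng):
    Y = real_sph_harm(0, random_unit(rng, 20))
    np.testing.assert_allclose(Y[:, 0], 0.28209479177387814, rtol=1e-12)


def test_l1_addition_theorem(rng):
    Y = real_sph_harm(1, random_unit(rng, 20))
    np.testing.assert_allclose((Y[:, 1:4] ** 2).sum(axis=1), 3 / (4 * np.pi),
                               rtol=1e-12)


def test_numerical_orthonormality_by_quadrature():
    """∫ Y_lm Y_l'm' dΩ = δ δ via Gauss–Legendre × uniform-φ quadrature."""
    l_max = 3
    nt, nphi = 40, 80
    x, w = np.polynomial.legendre.leggauss(nt)    # x = cosθ
    phi = (np.arange(nphi) + 0.5) * 2 * np.pi / nphi
    ct = np.repeat(x, nphi)
    st = np.sqrt(1 - ct ** 2)
    ph = np.tile(phi, nt)
    dirs = np.stack([st * np.cos(ph), st * np.sin(ph), ct], axis=1)
    weights = np.repeat(w, nphi) * (2 * np.pi / nphi)
    Y = real_sph_harm(l_max, dirs)
    G = (Y * weights[:, None]).T @ Y
    np.testing.assert_allclose(G, np.eye((l_max + 1) ** 2), atol=1e-6)


def test_zero_vector_rejected():
    with pytest.raises(ValueError):
        real_sph_harm(2, np.array([[0.0, 0.0, 0.0]]))


def test_differentiable_harmonics_match_reference(rng):
    u = random_unit(rng, 30)
    ref = real_sph_harm(3, u)
    got = real_sph_harm_ad(3, ad.constant(u)).data
    np.testing.assert_allclose(got, ref, atol=1e-13)


# ------------------------------------------------------------------- CG

def test_scalar_coupling_is_single_unit_entry():
    tbl = cg_table(0)
    assert tbl.paths == [(0, 0, 0)]
    assert list(tbl.entries) == [(0, 0, 0, 0, 0, 0)]
    assert tbl.entries[(0, 0, 0, 0, 0, 0)] == pytest.approx(1.0)


def test_racah_value_and_sympy_cross_check():
    assert clebsch_gordan_complex(1, 0, 1, 0, 2, 0) == pytest.approx(
        np.sqrt(2 / 3), abs=1e-14)
    sympy = pytest.importorskip("sympy.physics.quantum.cg")
    rng = np.random.default_rng(4)
    for _ in range(20):
        j1, j2 = int(rng.integers(0, 4)), int(rng.integers(0, 4))
        J = int(rng.integers(abs(j1 - j2), j1 + j2 + 1))
        m1 = int(rng.integers(-j1, j1 + 1))
        m2 = int(rng.integers(-j2, j2 + 1))
        if abs(m1 + m2) > J:
            continue
        ref = float(sympy.CG(j1, m1, j2, m2, J, m1 + m2).doit())
        assert clebsch_gordan_complex(j1, m1, j2, m2, J, m1 + m2) == \
            pytest.approx(ref, abs=1e-13)


def test_real_basis_orthogonality_to_machine_precision():
    tbl = cg_table(3)
    for (l1, l2, lf), blk in tbl.blocks.items():
        G = np.einsum("mnr,mns->rs", blk, blk)
        np.testing.assert_allclose(G, np.eye(2 * lf + 1), atol=1e-12)


def test_selection_rules():
    tbl = cg_table(3)
    for (l1, m1, l2, m2, lf, mf), v in tbl.entries.items():
        assert abs(l1 - l2) <= lf <= l1 + l2
        assert abs(v) > 1e-14
    assert all(abs(l1 - l2) <= lf <= min(l1 + l2, 3) for l1, l2, lf in tbl.paths)


# ------------------------------------------------------------ tensor product

def _blocks(rng, n, l_max, c):
    return (EquivariantFeatureBlock(rng.normal(size=(n, (l_max + 1) ** 2, c)), l_max),
            EquivariantFeatureBlock(rng.normal(size=(n, (l_max + 1) ** 2, c)), l_max))


def test_scalar_b_acts_as_identity_on_0l_paths(rng):
    cg = cg_table(2)
    a, b = _blocks(rng, 4, 2, 3)
    b.values[:] = 0.0
    b.values[:, 0, :] = 1.0
    w = {(l, 0, l): np.ones(3) for l in range(3)}
    out = tensor_product(a, b, cg, w)
    # each (l, 0) -> l block is the identity coupling, so a passes through
    np.testing.assert_allclose(out.values, a.values, atol=1e-10)


def test_zero_inputs_give_zero(rng):
    cg = cg_table(2)
    a, b = _blocks(rng, 3, 2, 2)
    a.values[:] = 0.0
    b.values[:] = 0.0
    w = {p: np.ones(2) for p in cg.paths}
    assert np.all(tensor_product(a, b, cg, w).values == 0.0)


def test_tensor_product_equivariance(rng):
    cg = cg_table(2)
    a, b = _blocks(rng, 5, 2, 4)
    w = {p: rng.normal(size=4) for p in cg.paths}
    R = Rotation.random(random_state=11).as_matrix()
    out = tensor_product_values(a.values, b.values, cg, w)
    out_rot = tensor_product_values(rotate_features(a.values, R, 2),
                                    rotate_features(b.values, R, 2), cg, w)
    np.testing.assert_allclose(rotate_features(out, R, 2), out_rot, atol=1e-10)


def test_lmax0_product_is_scalar_multiplication(rng):
    cg = cg_table(0)
    a, b = _blocks(rng, 6, 0, 5)
    w = {(0, 0, 0): np.ones(5)}
    out = tensor_product(a, b, cg, w)
    # the scalar-scalar coupling coefficient is exactly 1
    np.testing.assert_allclose(out.values, a.values * b.values, atol=1e-12)


# ---------------------------------------------------------------- Wigner-D

def test_identity_rotation_gives_identity_blocks():
    for l, D in enumerate(wigner_d_real(3, np.eye(3))):
        np.testing.assert_allclose(D, np.eye(2 * l + 1), atol=1e-12)


def test_d1_is_rotation_in_yzx_order(rng):
    R = Rotation.random(random_state=2).as_matrix()
    P = np.zeros((3, 3))
    P[0, 1] = P[1, 2] = P[2, 0] = 1.0       # (x,y,z) -> (y,z,x)
    D1 = wigner_d_real(1, R)[1]
    np.testing.assert_allclose(D1, P @ R @ P.T, atol=1e-12)


def test_harmonics_equivariance_under_wigner_blocks(rng):
    u = random_unit(rng, 15)
    for state in range(5):
        R = Rotation.random(random_state=state).as_matrix()
        D = wigner_d_real(3, R)
        Yr = real_sph_harm(3, u @ R.T)
        Y = real_sph_harm(3, u)
        for l, sl in enumerate(lm_slices(3)):
            np.testing.assert_allclose(Yr[:, sl], Y[:, sl] @ D[l].T, atol=1e-10)


def test_wigner_homomorphism():
    R1 = Rotation.random(random_state=8).as_matrix()
    R2 = Rotation.random(random_state=9).as_matrix()
    D12 = wigner_d_real(3, R1 @ R2)
    D1 = wigner_d_real(3, R1)
    D2 = wigner_d_real(3, R2)
    for l in range(4):
        np.testing.assert_allclose(D12[l], D1[l] @ D2[l], atol=1e-10)


def test_wigner_vs_sympy_small_d():
    sympy_spin = pytest.importorskip("sympy.physics.quantum.spin")
    from sympy import Float
    beta = 0.731
    R = Rotation.from_euler("y", beta).as_matrix()
    from nemp.equivariant import _wigner_small_d
    for l in (1, 2, 3):
        for mp in range(-l, l + 1):
            for m in range(-l, l + 1):
                ref = complex(sympy_spin.Rotation.d(l, mp, m, Float(beta)).doit()).real
                assert _wigner_small_d(l, mp, m, beta) == pytest.approx(ref, abs=1e-12)


def test_non_rotation_rejected():
    with pytest.raises(ValueError):
        wigner_d_real(1, np.diag([1.0, 1.0, -1.0]))   # improper
    with pytest.raises(ValueError):
        wigner_d_real(1, np.eye(3) * 2.0)


# --------------------------------------------------------- property tests

from hypothesis import given, settings, strategies as st


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10 ** 6), l=st.integers(0, 3))
def test_property_addition_theorem(seed, l):
    """Σ_m Y_lm(u)² = (2l+1)/4π for every l and direction."""
    r = np.random.default_rng(seed)
    u = r.normal(size=(4, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    Y = real_sph_harm(l, u)
    sl = lm_slices(l)[l]
    np.testing.assert_allclose((Y[:, sl] ** 2).sum(axis=1),
                               (2 * l + 1) / (4 * np.pi), rtol=1e-10)
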