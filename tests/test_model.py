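"""The potential's exact symmetries, force consistency, smoothness at the
cutoff, layer-state contracts and checkpointing."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import nemp.autodiff as ad
from nemp.equivariant import rotate_features
from nemp.model import (ModelConfig, NempModel, RadialBasis, initial_layer,
                        mp_layer, radial_basis_eval, _recorded_states)
from nemp.systems_io import AtomicSystem
from tests.conftest import random_cluster


# ------------------------------------------------------------ radial basis

def test_radial_basis_vanishes_beyond_cutoff():
    rb = RadialBasis(n_basis=6, r_c=4.0)
    vals = radial_basis_eval(np.array([4.0, 4.8]), rb)
    np.testing.assert_allclose(vals, 0.0, atol=1e-14)
    # first derivative vanishes at r_c too
    h = 1e-6
    below = radial_basis_eval(np.array([4.0 - h]), rb)
    np.testing.assert_allclose(below / h, 0.0, atol=1e-4)


def test_radial_basis_derivative_matches_finite_differences(rng):
    rb = RadialBasis(n_basis=8, r_c=5.0)
    r = rng.uniform(0.5, 4.9, size=50)
    rt = ad.tensor(r, requires_grad=True)
    out = radial_basis_eval(rt, rb)
    g, = ad.grad(ad.sum_(out), [rt])
    h = 1e-6
    fd = (radial_basis_eval(r + h, rb) - radial_basis_eval(r - h, rb)) / (2 * h)
    np.testing.assert_allclose(g.data, fd.sum(axis=1), rtol=1e-6, atol=1e-9)


def test_radial_basis_rejects_nonpositive_r():
    rb = RadialBasis(n_basis=4, r_c=5.0)
    with pytest.raises(ValueError):
        radial_basis_eval(np.array([0.0, 1.0]), rb)


# ----------------------------------------------------------- exact symmetries

def test_translation_leaves_energy_unchanged(small_model, rng):
    """Energies depend on displacement vectors only: when a translation
    preserves those bitwise (coarse-mantissa positions and shift), the
    energy is bit-identical; for arbitrary shifts it matches to machine
    precision."""
    s = random_cluster(rng)
    # dyadic grid: translated coordinates remain exactly representable
    s.positions = np.round(s.positions * 2 ** 20) / 2 ** 20
    E0, _ = small_model.energy(s)
    t_exact = np.array([1.5, -2.25, 3.0])
    s_t = AtomicSystem(s.elements, s.positions + t_exact)
    assert small_model.energy(s_t)[0] == E0
    t_any = rng.normal(scale=30.0, size=3)
    s_t2 = AtomicSystem(s.elements, s.positions + t_any)
    assert small_model.energy(s_t2)[0] == pytest.approx(E0, abs=1e-12)


def test_permutation_invariance_is_bitwise(small_model, rng):
    s = random_cluster(rng)
    E0, Ei = small_model.energy(s)
    for _ in range(5):
        perm = rng.permutation(s.n_atoms)
        s_p = AtomicSystem(s.elements[perm], s.positions[perm])
        E1, Ei_p = small_model.energy(s_p)
        assert E1 == E0
        np.testing.assert_array_equal(Ei_p, Ei[perm])


def test_rotation_invariance_of_energy(small_model, rng):
    s = random_cluster(rng)
    E0, _ = small_model.energy(s)
    for state in range(5):
        R = Rotation.random(random_state=state).as_matrix()
        s_r = AtomicSystem(s.elements, s.positions @ R.T)
        assert small_model.energy(s_r)[0] == pytest.approx(E0, abs=1e-10)


def test_layer_states_transform_correctly(small_model, rng):
    """Every ψ block follows the Wigner-D oracle; every invariant feature
    and every edge coefficient is unchanged by rotation."""
    s = random_cluster(rng)
    R = Rotation.random(random_state=3).as_matrix()
    s_r = AtomicSystem(s.elements, s.positions @ R.T)
    states = _recorded_states(s, small_model)
    states_r = _recorded_states(s_r, small_model)
    L = small_model.config.l_max
    for (node, edge), (node_r, edge_r) in zip(states, states_r):
        np.testing.assert_allclose(rotate_features(node.psi.data, R, L),
                                   node_r.psi.data, atol=1e-10)
        np.testing.assert_allclose(node.rho.data, node_r.rho.data, atol=1e-10)
        np.testing.assert_allclose(edge.chi.data, edge_r.chi.data, atol=1e-10)


def test_initial_layer_functional_surface(small_model, rng):
    s = random_cluster(rng)
    nl = small_model.neighbor_list(s)
    node, edge = initial_layer(s, nl, small_model)
    assert node.psi.shape == (s.n_atoms, 9, small_model.config.n_channels)
    assert node.layer_index == 0
    node1, edge1 = mp_layer(s, small_model, 1)
    assert node1.layer_index == 1
    assert edge1.chi.shape[1] == small_model.config.l_max + 3
    # the ψ/ρ/virtual subsets partition the EC slot axis
    L = small_model.config.l_max
    assert edge1.chi_psi(L).shape[1] == L + 1
    assert edge1.chi_rho(L).ndim == 2
    assert edge1.chi_virtual(L).ndim == 2
    with pytest.raises(ValueError):
        edge.chi_virtual(L)   # initial layer has no virtual subset


def test_isolated_atom_zero_features_finite_energy(small_model):
    s = AtomicSystem([8], [[0.0, 0.0, 0.0]])
    states = _recorded_states(s, small_model)
    node0, _ = states[0]
    assert np.all(node0.psi.data == 0.0)
    assert np.all(node0.rho.data == 0.0)
    E, Ei = small_model.energy(s)
    assert np.isfinite(E) and len(Ei) == 1
    assert np.all(small_model.forces(s) == 0.0)


def test_size_consistency_at_infinite_separation(small_model, rng):
    s = random_cluster(rng, n=4)
    E1, _ = small_model.energy(s)
    two = AtomicSystem(np.concatenate([s.elements, s.elements]),
                       np.concatenate([s.positions, s.positions + 100.0]))
    E2, _ = small_model.energy(two)
    assert E2 == pytest.approx(2 * E1, abs=1e-12)


# ------------------------------------------------------------------ forces

def test_forces_match_central_differences(small_model, rng):
    s = random_cluster(rng, n=6)
    _, F = small_model.energy_forces(s)
    h = 1e-4
    for _ in range(6):
        i = int(rng.integers(s.n_atoms))
        d = int(rng.integers(3))
        pp = s.positions.copy()
        pp[i, d] += h
        Ep, _ = small_model.energy(AtomicSystem(s.elements, pp))
        pp[i, d] -= 2 * h
        Em, _ = small_model.energy(AtomicSystem(s.elements, pp))
        fd = -(Ep - Em) / (2 * h)
        assert F[i, d] == pytest.approx(fd, rel=1e-5, abs=1e-9)


def test_force_sum_vanishes(small_model, rng):
    for _ in range(3):
        s = random_cluster(rng)
        _, F = small_model.energy_forces(s)
        np.testing.assert_allclose(F.sum(axis=0), 0.0, atol=1e-8)


def test_energy_continuous_across_cutoff(small_model):
    """Move one neighbor across r_c in a 1e-6 Å step: ΔE below 1e-8 eV."""
    rc = small_model.config.r_c
    for offset in (-5e-7, 5e-7):
        s1 = AtomicSystem([1, 8], [[0, 0, 0], [rc + offset, 0.0, 0.0]])
        s2 = AtomicSystem([1, 8], [[0, 0, 0], [rc + offset + 1e-6, 0.0, 0.0]])
        dE = abs(small_model.energy(s1)[0] - small_model.energy(s2)[0])
        assert dE <= 1e-8


# ------------------------------------------------------- structure / plumbing

def test_tp_operands_are_node_space(small_model, rng):
    """The tensor-product operands in every layer have exactly three axes
    (atoms, lm, channels) — no neighbor axis — and their element counts
    equal N_atom · (l_max+1)² · N_c regardless of coordination."""
    c = small_model.config
    for n in (4, 9):
        s = random_cluster(rng, n=n)
        small_model.energy(s)
        shapes = small_model.last_tp_operand_shapes
        assert len(shapes) == c.n_layers
        for a_shape, b_shape in shapes:
            assert len(a_shape) == len(b_shape) == 3
            assert a_shape == b_shape == (n, (c.l_max + 1) ** 2, c.n_channels)


def test_linear_edge_map_variant(rng):
    cfg = ModelConfig(elements=(1,), l_max=1, n_layers=1, n_channels=4,
                      hidden=8, edge_map_kind="linear")
    m = NempModel.create(cfg, seed=1)
    s = random_cluster(rng, n=5, elements=(1,))
    E, F = m.energy_forces(s)
    assert np.isfinite(E) and np.all(np.isfinite(F))
    R = Rotation.random(random_state=1).as_matrix()
    assert m.energy(AtomicSystem(s.elements, s.positions @ R.T))[0] == \
        pytest.approx(E, abs=1e-10)


def test_unknown_element_rejected(small_model):
    s = AtomicSystem([79], [[0.0, 0.0, 0.0]])
    with pytest.raises(ValueError, match="not covered"):
        small_model.energy(s)


def test_checkpoint_roundtrip_bit_exact(small_model, rng, tmp_path):
    s = random_cluster(rng)
    E0, _ = small_model.energy(s)
    path = tmp_path / "model.npz"
    small_model.save(path)
    loaded = NempModel.load(path)
    assert loaded.config == small_model.config
    for k in small_model.params:
        np.testing.assert_array_equal(loaded.params[k], small_model.params[k])
    assert loaded.energy(s)[0] == E0


def test_parameter_count_reported(small_model):
    n = small_model.n_parameters
    assert n == sum(v.size for v in small_model.params.values()) > 0
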