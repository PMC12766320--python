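"""The MD engine: analytic limits (free particle, harmonic dimer), energy
conservation, thermostat bookkeeping and RDF normalisation."""

import numpy as np
import pytest

from nemp.md import (KB, KE_CONV, MDConfig, Trajectory, compute_rdf, run_md,
                     thermostat_check)
from nemp.synthetic import ToyPotential, ToyPotentialSpec
from nemp.systems_io import AtomicSystem


class ZeroPotential:
    def energy_forces(self, s):
        return 0.0, np.zeros_like(s.positions)


LJ_AR = ToyPotentialSpec(
    terms=[{"kind": "lennard_jones", "epsilon": 0.0104, "sigma": 3.4}], r_c=5.0)


def test_free_particle_moves_in_a_straight_line():
    s = AtomicSystem([18], [[0.0, 0.0, 0.0]])
    cfg = MDConfig(timestep=1.0, n_steps=100, ensemble="nve", stride=10)
    v0 = np.array([[0.01, -0.02, 0.005]])
    traj = run_md(s, ZeroPotential(), cfg, velocities=v0)
    for step, p in zip(traj.steps, traj.positions):
        np.testing.assert_allclose(p, v0 * step * 1.0, atol=1e-12)
    assert np.ptp(traj.e_kin) == 0.0


def test_harmonic_dimer_period():
    """Small oscillations of a Morse dimer: period 2π√(μ/k) with
    k = 2 D_e a², matched to 1% over ten periods."""
    De, a, re = 0.5, 1.5, 2.0
    spec = ToyPotentialSpec(terms=[{"kind": "morse", "D_e": De, "a": a,
                                    "r_e": re}], r_c=8.0, smooth=False)
    m_ar = 39.948
    mu = m_ar / 2
    k = 2 * De * a * a                       # eV/Å²
    period = 2 * np.pi * np.sqrt(mu * KE_CONV / k)   # fs
    amp = 0.01
    s = AtomicSystem([18, 18], [[0, 0, 0], [re + amp, 0, 0]])
    dt = period / 400
    n_per = 10
    cfg = MDConfig(timestep=dt, n_steps=int(400 * n_per), ensemble="nve", stride=1)
    traj = run_md(s, ToyPotential(spec), cfg)
    bond = np.array([p[1, 0] - p[0, 0] for p in traj.positions])
    # count the mean spacing of maxima via zero crossings of (bond - re)
    x = bond - re
    crossings = np.nonzero(np.diff(np.sign(x)))[0]
    half_periods = np.diff(crossings) * dt
    measured = 2 * half_periods.mean()
    assert measured == pytest.approx(period, rel=0.01)


def test_nve_energy_conservation_short():
    rng = np.random.default_rng(0)
    r0 = 2 ** (1 / 6) * 3.4
    pos = np.array([[0, 0, 0], [r0, 0, 0], [r0 / 2, r0 * 0.866, 0],
                    [r0 / 2, r0 * 0.289, r0 * 0.816]])
    s = AtomicSystem([18] * 4, pos + rng.normal(scale=0.05, size=(4, 3)))
    cfg = MDConfig(timestep=0.5, n_steps=2000, ensemble="nve",
                   temperature=30.0, seed=2, stride=20)
    traj = run_md(s, ToyPotential(LJ_AR), cfg)
    total = np.asarray(traj.conserved)
    assert np.ptp(total) / s.n_atoms < 1e-4


def test_halving_timestep_reduces_drift_fourfold():
    rng = np.random.default_rng(1)
    r0 = 2 ** (1 / 6) * 3.4
    pos = np.array([[0, 0, 0], [r0, 0, 0], [r0 / 2, r0 * 0.866, 0],
                    [r0 / 2, r0 * 0.289, r0 * 0.816]])
    s = AtomicSystem([18] * 4, pos + rng.normal(scale=0.05, size=(4, 3)))

    def drift(dt, n):
        cfg = MDConfig(timestep=dt, n_steps=n, ensemble="nve",
                       temperature=40.0, seed=3, stride=10)
        traj = run_md(s, ToyPotential(LJ_AR), cfg)
        c = np.asarray(traj.conserved)
        return np.abs(c - c[0]).max()

    d1 = drift(1.0, 2000)
    d2 = drift(0.5, 4000)     # same physical time
    assert d2 < d1 / 2.5      # second-order integrator: ideally 4x

def test_frozen_lattice_has_zero_temperature():
    s = AtomicSystem([18] * 4, np.diag([3.4, 3.4, 3.4, 0])[:, :3] + 5.0)
    cfg = MDConfig(timestep=0.5, n_steps=40, ensemble="nve", stride=1)
    traj = run_md(s, ZeroPotential(), cfg)
    assert np.all(np.asarray(traj.temperature) == 0.0)
    mean, se = thermostat_check(traj, cfg, burn_in=0.0, n_blocks=5)
    assert mean == 0.0 and se == 0.0


def test_fixed_interval_refresh_reproduces_auto_bitwise():
    rng = np.random.default_rng(4)
    L = 11.45
    # jittered 2x2x2 simple-cubic sublattice: no unphysical close contacts
    frac = (np.stack(np.meshgrid(*[[0.1, 0.6]] * 3, indexing="ij"), axis=-1)
            .reshape(-1, 3))
    frac = np.concatenate([frac, frac + 0.25])
    pos = frac * L + rng.normal(scale=0.15, size=(16, 3))
    s = AtomicSystem([18] * 16, pos, np.eye(3) * L, np.ones(3, bool))
    kw = dict(timestep=0.5, n_steps=300, ensemble="nve", temperature=30.0,
              seed=5, stride=10, skin=1.0)
    t_auto = run_md(s, ToyPotential(LJ_AR), MDConfig(nl_refresh="auto", **kw))
    t_fix = run_md(s, ToyPotential(LJ_AR), MDConfig(nl_refresh=5, **kw))
    for a, b in zip(t_auto.positions, t_fix.positions):
        np.testing.assert_array_equal(a, b)
    assert t_auto.e_pot == t_fix.e_pot


def test_nonfinite_force_aborts_with_step_index():
    class ExplodingPotential:
        def energy_forces(self, s):
            return 0.0, np.full_like(s.positions, np.nan)

    s = AtomicSystem([18], [[0.0, 0.0, 0.0]])
    with pytest.raises(RuntimeError, match="step 1"):
        run_md(s, ExplodingPotential(), MDConfig(timestep=0.5, n_steps=5))


def test_nvt_requires_temperature():
    with pytest.raises(ValueError):
        MDConfig(ensemble="nvt")


# ------------------------------------------------------------------- RDF

def _uniform_trajectory(rng, n_frames=60, n=64, L=12.0):
    traj = Trajectory(np.full(n, 18), np.eye(3) * L, np.ones(3, bool),
                      stride=1, timestep=1.0)
    for _ in range(n_frames):
        traj.positions.append(rng.uniform(0, L, size=(n, 3)))
    return traj


def test_ideal_gas_rdf_is_flat(rng):
    # 100 frames x 64 atoms at 0.15 Å bins: per-bin sampling error ~1.3%,
    # so the ±0.05 band sits at ~3.5 sigma
    traj = _uniform_trajectory(rng, n_frames=100)
    r, g = compute_rdf(traj, (18, 18), r_max=5.5, n_bins=37)
    sel = r >= 3.0
    assert np.all(np.abs(g[sel] - 1.0) < 0.05)


def test_frozen_dimer_rdf_single_bin():
    d = 3.0
    traj = Trajectory(np.array([18, 18]), np.eye(3) * 20.0, np.ones(3, bool),
                      stride=1, timestep=1.0,
                      positions=[np.array([[5.0, 5, 5], [5.0 + d, 5, 5]])])
    r, g = compute_rdf(traj, (18, 18), r_max=5.0, n_bins=50)
    occupied = np.nonzero(g)[0]
    assert len(occupied) == 1
    assert r[occupied[0]] == pytest.approx(d, abs=0.05)


def test_rdf_bin_count_conservation(rng):
    from nemp.neighbors import brute_force_neighbors
    traj = _uniform_trajectory(rng, n_frames=5, n=20)
    r_max = 5.0
    r, g = compute_rdf(traj, (18, 18), r_max=r_max, n_bins=25)
    # reconstruct total counts from the normalisation and compare with a
    # direct enumeration of ordered pairs within r_max
    L, n = 12.0, 20
    V = L ** 3
    edges = np.linspace(0, r_max, 26)
    shell = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    counts = g * len(traj.positions) * n * ((n - 1) / V) * shell
    direct = 0
    for p in traj.positions:
        s = AtomicSystem(traj.elements, p, traj.cell, traj.pbc)
        direct += brute_force_neighbors(s, r_max).n_pairs
    assert counts.sum() == pytest.approx(direct, abs=1e-6)


def test_rdf_rejects_rmax_beyond_half_cell():
    traj = _uniform_trajectory(np.random.default_rng(0), n_frames=1)
    with pytest.raises(ValueError, match="half the minimum cell height"):
        compute_rdf(traj, (18, 18), r_max=6.5, n_bins=10)
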