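"""Molecular dynamics: NVE velocity Verlet, Nose–Hoover NVT, buffered
neighbor-list refresh, radial distribution functions.

Units are Å, fs, amu and eV throughout; the kinetic-energy conversion
1 amu Å² fs⁻² = 103.642696 eV links them.  The thermostat is a single
Nose–Hoover chain (length 1) with mass Q = g·kB·T·τ², integrated with the
symmetric half/quarter-step splitting around a velocity-Verlet core; its
conserved quantity E_pot + E_kin + ½Qξ² + g·kB·T·η is logged for drift
monitoring.

The neighbor list is the skin-buffered list from :mod:`nemp.neighbors`:
rebuilt either automatically when an atom moves more than skin/2, or every
fixed n steps with a hard safety check — the desk-scale embodiment of
pipelined neighbor-list updates, where force evaluation runs on a slightly
stale but provably sufficient list.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .neighbors import BufferedNeighborList, brute_force_neighbors
from .systems_io import ATOMIC_MASSES, AtomicSystem

__all__ = ["MDConfig", "Trajectory", "run_md", "compute_rdf", "thermostat_check"]

KB = 8.617333262e-5            # eV/K
KE_CONV = 1.0364269656262e2    # amu Å²/fs² in eV


@dataclass
class MDConfig:
    timestep: float = 0.5            # fs
    n_steps: int = 1000
    ensemble: str = "nve"            # "nve" | "nvt"
    temperature: float | None = None  # K; Maxwell-Boltzmann init and NVT target
    tau: float | None = None         # thermostat coupling time, fs (default 100·dt)
    nl_refresh: str | int = "auto"   # skin/2 rule, or fixed interval n
    skin: float = 0.5                # Å
    seed: int = 0
    stride: int = 10                 # log/snapshot every this many steps

    def __post_init__(self):
        if self.timestep <= 0:
            raise ValueError("timestep must be positive")
        if self.ensemble not in ("nve", "nvt"):
            raise ValueError("ensemble must be 'nve' or 'nvt'")
        if self.ensemble == "nvt" and (self.temperature is None or self.temperature <= 0):
            raise ValueError("NVT requires a positive target temperature")
        if self.tau is None:
            self.tau = 100.0 * self.timestep


@dataclass
class Trajectory:
    elements: np.ndarray
    cell: np.ndarray | None
    pbc: np.ndarray
    stride: int
    timestep: float
    positions: list = field(default_factory=list)    # snapshots, (N,3) Å
    velocities: list = field(default_factory=list)   # (N,3) Å/fs
    steps: list = field(default_factory=list)
    e_pot: list = field(default_factory=list)        # eV
    e_kin: list = field(default_factory=list)        # eV
    temperature: list = field(default_factory=list)  # K
    conserved: list = field(default_factory=list)    # eV

    def thermo(self) -> dict[str, np.ndarray]:
        return {k: np.asarray(getattr(self, k))
                for k in ("steps", "e_pot", "e_kin", "temperature", "conserved")}


def _kinetic(m: np.ndarray, v: np.ndarray) -> float:
    return 0.5 * KE_CONV * float(np.sum(m[:, None] * v * v))


def maxwell_boltzmann(masses: np.ndarray, T: float, rng) -> np.ndarray:
    v = rng.normal(size=(len(masses), 3)) * np.sqrt(KB * T / (KE_CONV * masses))[:, None]
    # remove center-of-mass drift
    v -= (masses[:, None] * v).sum(axis=0) / masses.sum()
    return v


def run_md(s: AtomicSystem, potential, cfg: MDConfig,
           velocities: np.ndarray | None = None) -> Trajectory:
    """Integrate and return a :class:`Trajectory`.

    ``potential`` provides ``cutoff`` and ``energy_forces_nl(system, nl)``
    (or plain ``energy_forces(system)``).  Initial velocities default to a
    seeded Maxwell–Boltzmann draw at ``cfg.temperature`` (zero if no
    temperature is set) with center-of-mass motion removed.
    """
    n = s.n_atoms
    try:
        m = np.array([ATOMIC_MASSES[int(z)] for z in s.elements])
    except KeyError as e:
        raise ValueError(f"no mass tabulated for Z={e.args[0]}") from None
    dt = cfg.timestep
    pos = s.positions.copy()
    if velocities is not None:
        v = np.asarray(velocities, dtype=float).copy()
    elif cfg.temperature:
        v = maxwell_boltzmann(m, cfg.temperature, np.random.default_rng(cfg.seed))
    else:
        v = np.zeros((n, 3))

    work = s.copy()
    use_nl = hasattr(potential, "energy_forces_nl") and hasattr(potential, "cutoff")
    if use_nl:
        buffered = BufferedNeighborList(s, potential.cutoff, cfg.skin, cfg.nl_refresh)

        def eval_pf(p):
            work.positions = p
            return potential.energy_forces_nl(work, buffered.current(p))
    else:
        def eval_pf(p):
            work.positions = p
            return potential.energy_forces(work)

    g_dof = max(3 * n - 3, 1)
    nvt = cfg.ensemble == "nvt"
    if nvt:
        kT = KB * cfg.temperature
        Q = g_dof * kT * cfg.tau ** 2     # eV fs²
        xi, eta = 0.0, 0.0

    def thermostat_half(v, xi, eta):
        K = _kinetic(m, v)
        xi += 0.25 * dt * (2.0 * K - g_dof * kT) / Q
        sc = np.exp(-xi * 0.5 * dt)
        v = v * sc
        eta += xi * 0.5 * dt
        K = _kinetic(m, v)
        xi += 0.25 * dt * (2.0 * K - g_dof * kT) / Q
        return v, xi, eta

    E, F = eval_pf(pos)
    traj = Trajectory(s.elements.copy(),
                      None if s.cell is None else s.cell.copy(),
                      s.pbc.copy(), cfg.stride, dt)

    def log(step, E, v):
        K = _kinetic(m, v)
        traj.steps.append(step)
        traj.positions.append(pos.copy())
        traj.velocities.append(v.copy())
        traj.e_pot.append(E)
        traj.e_kin.append(K)
        traj.temperature.append(2.0 * K / (g_dof * KB))
        cons = E + K
        if nvt:
            cons += 0.5 * Q * xi * xi + g_dof * kT * eta
        traj.conserved.append(cons)

    log(0, E, v)
    acc = F / (KE_CONV * m[:, None])      # Å/fs²
    for step in range(1, cfg.n_steps + 1):
        if nvt:
            v, xi, eta = thermostat_half(v, xi, eta)
        v = v + 0.5 * dt * acc
        pos = pos + dt * v
        E, F = eval_pf(pos)
        if not np.all(np.isfinite(F)):
            raise RuntimeError(f"non-finite force at step {step}")
        acc = F / (KE_CONV * m[:, None])
        v = v + 0.5 * dt * acc
        if nvt:
            v, xi, eta = thermostat_half(v, xi, eta)
        if step % cfg.stride == 0:
            log(step, E, v)
    return traj


def compute_rdf(traj: Trajectory, species_pair: tuple[int, int],
                r_max: float, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Radial distribution function g(r) for an element pair.

    Histogram of ordered A→B pair distances over all frames, normalised by
    the ideal-gas shell expectation N_A · (N_B − δ_AB)/V · 4π r² dr per
    frame.  Returns (bin centers, g).  Requires periodic frames and
    r_max below half the smallest cell height.
    """
    if traj.cell is None or not np.any(traj.pbc):
        raise ValueError("RDF requires periodic frames")
    inv = np.linalg.inv(traj.cell)
    heights = 1.0 / np.linalg.norm(inv, axis=0)
    if r_max >= heights.min() / 2.0:
        raise ValueError(f"r_max={r_max} exceeds half the minimum cell "
                         f"height {heights.min() / 2:.3f}")
    za, zb = species_pair
    sel_a = traj.elements == za
    sel_b = traj.elements == zb
    n_a, n_b = int(sel_a.sum()), int(sel_b.sum())
    if n_a == 0 or n_b == 0:
        raise ValueError("species not present in the trajectory")
    V = abs(np.linalg.det(traj.cell))
    edges = np.linspace(0.0, r_max, n_bins + 1)
    hist = np.zeros(n_bins)
    for p in traj.positions:
        s = AtomicSystem(traj.elements, p, traj.cell, traj.pbc)
        nl = brute_force_neighbors(s, r_max, 0.0)
        keep = sel_a[nl.pairs[:, 0]] & sel_b[nl.pairs[:, 1]]
        hist += np.histogram(nl.distances[keep], bins=edges)[0]
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = n_a * ((n_b - (1 if za == zb else 0)) / V) * shell
    g = hist / (len(traj.positions) * ideal)
    centers = 0.5 * (edges[1:] + edges[:-1])
    return centers, g


def thermostat_check(traj: Trajectory, cfg: MDConfig,
                     burn_in: float = 0.2, n_blocks: int = 20) -> tuple[float, float]:
    """Time-averaged temperature after burn-in, with blocked standard error."""
    T = np.asarray(traj.temperature)
    start = int(round(burn_in * len(T)))
    T = T[start:]
    if len(T) < n_blocks:
        raise ValueError("trajectory shorter than burn-in + blocking window")
    usable = len(T) - len(T) % n_blocks
    blocks = T[:usable].reshape(n_blocks, -1).mean(axis=1)
    return float(T.mean()), float(blocks.std(ddof=1) / np.sqrt(n_blocks))
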