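"""Analytic toy potentials and configuration samplers.

Labeled datasets with exactly known energies and forces stand in for
first-principles reference data, so that training, evaluation and dynamics
can be exercised without any external download.  Pairwise terms
(Lennard-Jones, Morse) probe radial learning; the Axilrod–Teller
triple-dipole term adds a genuinely three-body (angular) contribution that
no pairwise model can represent, which makes it a sharp probe for the
angular (l ≥ 1) machinery of the potential.

All terms are smoothly truncated by the same polynomial envelope the model
uses, so the labels live in the same finite-cutoff function class as the
learner and the fit has no irreducible truncation floor.  Forces are exact
derivatives: closed-form for pair terms, via the autodiff tape for the
three-body term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .model import cutoff_envelope
from .neighbors import brute_force_neighbors, cell_list_neighbors
from .systems_io import AtomicSystem, Dataset

__all__ = [
    "ToyPotentialSpec", "SamplerSpec", "toy_energy_forces", "sample_dataset",
    "make_benchmark_suite", "ToyPotential", "sample_star_cluster",
]


@dataclass
class ToyPotentialSpec:
    """Sum of analytic terms, truncated at r_c.

    terms: list of dicts with a ``kind`` key:
      - {"kind": "lennard_jones", "epsilon": eV, "sigma": Å}
      - {"kind": "morse", "D_e": eV, "a": 1/Å, "r_e": Å}
      - {"kind": "axilrod_teller", "C9": eV·Å⁹}   (non-periodic systems only;
        hub-localised: summed over hub atoms and neighbor pairs within r_c,
        with the third side unconstrained — see _axilrod_teller_energy)
    smooth: multiply every term by the polynomial cutoff envelope (default),
    making energy and forces C²-continuous at r_c.  shift: subtract the
    value at r_c instead (sharp-cutoff alternative; forces then jump at r_c).
    """

    terms: list = field(default_factory=list)
    r_c: float = 5.0
    smooth: bool = True
    shift: bool = False

    def __post_init__(self):
        if self.r_c <= 0:
            raise ValueError("r_c must be positive")
        for t in self.terms:
            if t["kind"] not in ("lennard_jones", "morse", "axilrod_teller"):
                raise ValueError(f"unknown term kind {t['kind']!r}")


def _pair_potential(term: dict, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(V(r), dV/dr) for a pair term."""
    if term["kind"] == "lennard_jones":
        eps, sig = term["epsilon"], term["sigma"]
        s6 = (sig / r) ** 6
        V = 4.0 * eps * (s6 * s6 - s6)
        dV = 4.0 * eps * (-12.0 * s6 * s6 + 6.0 * s6) / r
        return V, dV
    if term["kind"] == "morse":
        De, a, re = term["D_e"], term["a"], term["r_e"]
        ex = np.exp(-a * (r - re))
        V = De * (1.0 - ex) ** 2 - De
        dV = 2.0 * De * a * ex * (1.0 - ex)
        return V, dV
    raise ValueError(term["kind"])


def _envelope(r: np.ndarray, r_c: float) -> tuple[np.ndarray, np.ndarray]:
    """(f_cut, df_cut/dr) of the degree-6 polynomial envelope."""
    p = 6
    u = r / r_c
    c1 = (p + 1) * (p + 2) / 2.0
    c2 = p * (p + 2.0)
    c3 = p * (p + 1) / 2.0
    f = 1.0 - c1 * u ** p + c2 * u ** (p + 1) - c3 * u ** (p + 2)
    df = (-c1 * p * u ** (p - 1) + c2 * (p + 1) * u ** p
          - c3 * (p + 2) * u ** (p + 1)) / r_c
    inside = u < 1.0
    return np.where(inside, f, 0.0), np.where(inside, df, 0.0)


def _hub_triplets(s: AtomicSystem, r_c: float) -> np.ndarray:
    """(hub i, j, k) with j<k and r_ij, r_ik <= r_c (open boundaries).

    The j–k separation is deliberately unconstrained: the term lives in the
    hub's local environment, and the third side may reach beyond the
    cutoff.  Pairs of neighbors that are mutually unconnected in the graph
    are exactly the configurations where the hub angle carries information
    that no invariant (l = 0) message-passing scheme can recover.
    """
    d = np.linalg.norm(s.positions[:, None, :] - s.positions[None, :, :], axis=-1)
    n = s.n_atoms
    out = []
    for i in range(n):
        nbrs = [j for j in range(n) if j != i and d[i, j] <= r_c]
        for a in range(len(nbrs)):
            for b in range(a + 1, len(nbrs)):
                out.append((i, nbrs[a], nbrs[b]))
    return np.array(out, dtype=int).reshape(-1, 3)


def _axilrod_teller_energy(pos, trip: np.ndarray, C9: float, r_c: float, smooth: bool):
    """Hub-localised triple-dipole energy on the autodiff tape.

    For each (hub i, neighbor pair j, k) the canonical Axilrod–Teller form
    C9·(1 + 3 cosθ_i cosθ_j cosθ_k)/(r_ij r_ik r_jk)³ is evaluated (r_jk by
    the law of cosines, not cutoff-limited) and gated by the smooth cutoff
    envelope of the two hub-adjacent sides.
    """
    if len(trip) == 0:
        return ad.constant(0.0)
    pi, pj, pk = (ad.gather(pos, trip[:, 0]), ad.gather(pos, trip[:, 1]),
                  ad.gather(pos, trip[:, 2]))
    rij = pj - pi
    rik = pk - pi
    rjk = pk - pj
    d2ij = ad.sum_(rij * rij, axis=1)
    d2ik = ad.sum_(rik * rik, axis=1)
    d2jk = ad.sum_(rjk * rjk, axis=1)
    dij, dik, djk = ad.sqrt(d2ij), ad.sqrt(d2ik), ad.sqrt(d2jk)
    # 3 cosθi cosθj cosθk expressed through scalar products
    ci = ad.sum_(rij * rik, axis=1)
    cj = ad.sum_(rij * rjk, axis=1) * (-1.0)     # angle at j uses r_ji, r_jk
    ck = ad.sum_(rik * rjk, axis=1)
    prod_r2 = d2ij * d2ik * d2jk
    prod_r = dij * dik * djk
    e = C9 * (1.0 + 3.0 * ci * cj * ck / prod_r2) / (prod_r * prod_r2)
    if smooth:
        for dd in (dij, dik):          # gate only the hub-adjacent sides
            e = e * cutoff_envelope(dd * (1.0 / r_c))
    return ad.sum_(e)


def toy_energy_forces(s: AtomicSystem, spec: ToyPotentialSpec) -> tuple[float, np.ndarray]:
    """Exact energy (eV) and forces (eV Å⁻¹) of the toy potential."""
    has_at = any(t["kind"] == "axilrod_teller" for t in spec.terms)
    periodic = s.cell is not None and np.any(s.pbc)
    if has_at and periodic:
        raise ValueError("the three-body term supports non-periodic systems only")
    build = brute_force_neighbors if s.n_atoms <= 64 else cell_list_neighbors
    nl = build(s, spec.r_c, 0.0)
    r = nl.distances
    if len(r) and r.min() < 1e-8:
        raise ValueError("atoms at zero separation")
    E = 0.0
    F = np.zeros_like(s.positions)
    if len(r):
        fc, dfc = _envelope(r, spec.r_c)
        for term in spec.terms:
            if term["kind"] == "axilrod_teller":
                continue
            V, dV = _pair_potential(term, r)
            if spec.smooth:
                V, dV = V * fc, dV * fc + V * dfc
            elif spec.shift:
                Vc, _ = _pair_potential(term, np.array([spec.r_c]))
                V = V - Vc[0]
            E += 0.5 * float(V.sum())
            # each directed pair (i,j) carries the full dV/dr pull on atom i
            contrib = (dV / r)[:, None] * nl.vectors
            np.add.at(F, nl.pairs[:, 0], contrib)
    for term in spec.terms:
        if term["kind"] != "axilrod_teller":
            continue
        trip = _hub_triplets(s, spec.r_c)
        pos_t = ad.tensor(s.positions, requires_grad=True)
        e_at = _axilrod_teller_energy(pos_t, trip, term["C9"], spec.r_c, spec.smooth)
        g, = ad.grad(e_at, [pos_t])
        E += float(e_at.data)
        F -= g.data
    return E, F


class ToyPotential:
    """Energy/force provider over a fixed :class:`ToyPotentialSpec`,
    exposing the same calculator surface as the learned model."""

    def __init__(self, spec: ToyPotentialSpec):
        self.spec = spec

    @property
    def cutoff(self) -> float:
        return self.spec.r_c

    def energy_forces(self, s: AtomicSystem) -> tuple[float, np.ndarray]:
        return toy_energy_forces(s, self.spec)

    def energy_forces_nl(self, s: AtomicSystem, nl) -> tuple[float, np.ndarray]:
        # pair terms can reuse the provided filtered list
        has_at = any(t["kind"] == "axilrod_teller" for t in self.spec.terms)
        if has_at:
            return toy_energy_forces(s, self.spec)
        r = nl.distances
        if len(r) and r.min() < 1e-8:
            raise ValueError("atoms at zero separation")
        E = 0.0
        F = np.zeros_like(s.positions)
        if len(r):
            fc, dfc = _envelope(r, self.spec.r_c)
            for term in self.spec.terms:
                V, dV = _pair_potential(term, r)
                if self.spec.smooth:
                    V, dV = V * fc, dV * fc + V * dfc
                elif self.spec.shift:
                    Vc, _ = _pair_potential(term, np.array([self.spec.r_c]))
                    V = V - Vc[0]
                E += 0.5 * float(V.sum())
                contrib = (dV / r)[:, None] * nl.vectors
                np.add.at(F, nl.pairs[:, 0], contrib)
        return E, F


# ---------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------

@dataclass
class SamplerSpec:
    base_positions: np.ndarray            # (N, 3) Å seed structure
    elements: np.ndarray                  # (N,) atomic numbers
    n_samples: int = 100
    displacement_scale: float = 0.1       # Å, Gaussian per-coordinate
    seed: int = 0
    cell: np.ndarray | None = None
    pbc: np.ndarray | None = None
    min_distance: float = 0.3             # Å, resample below this
    max_retries: int = 100

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")


def _min_separation(pos: np.ndarray) -> float:
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    return float(d.min())


def sample_dataset(pspec: ToyPotentialSpec, sspec: SamplerSpec) -> Dataset:
    """Gaussian displacements of the base geometry, each labeled with the
    exact toy energy and forces.  Deterministic for a fixed seed."""
    rng = np.random.default_rng(sspec.seed)
    base = np.asarray(sspec.base_positions, dtype=float)
    systems = []
    for _ in range(sspec.n_samples):
        for attempt in range(sspec.max_retries + 1):
            pos = base + rng.normal(scale=sspec.displacement_scale, size=base.shape) \
                if sspec.displacement_scale > 0 else base.copy()
            if len(base) == 1 or _min_separation(pos) >= sspec.min_distance:
                break
        else:
            raise RuntimeError(
                f"sampler failed to avoid overlaps below {sspec.min_distance} Å "
                f"after {sspec.max_retries} retries")
        s = AtomicSystem(sspec.elements, pos, sspec.cell,
                         sspec.pbc if sspec.pbc is not None else np.zeros(3, bool))
        s.energy, s.forces = toy_energy_forces(s, pspec)
        systems.append(s)
    return Dataset(systems)


def sample_star_cluster(rng, n_shell: int = 7, r_lo: float = 2.65,
                        r_hi: float = 2.95, min_sep: float = 3.0,
                        max_restarts: int = 500) -> np.ndarray:
    """A hub atom at the origin plus ``n_shell`` atoms at independent
    random radii and directions, with every shell–shell separation at or
    above ``min_sep``.

    With ``min_sep`` equal to the model cutoff, the only within-cutoff
    distances are the hub–shell radii, while the angles between shell
    directions vary freely at fixed radii (seven directions with pairwise
    angles ≳70° fit comfortably under the N=7 spherical-packing bound).  A
    three-body term at the hub therefore carries angular information that
    is not a function of any visible distance — the configuration class on
    which distance-only (invariant) models are information-limited by
    geometry, not merely by capacity.
    """
    for _ in range(max_restarts):
        shell: list[np.ndarray] = []
        for _ in range(n_shell):
            for _ in range(400):
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                p = v * rng.uniform(r_lo, r_hi)
                if all(np.linalg.norm(p - q) >= min_sep for q in shell):
                    shell.append(p)
                    break
            else:
                break
        if len(shell) == n_shell:
            return np.concatenate([[np.zeros(3)], shell], axis=0)
    raise RuntimeError("star-cluster sampler failed to place shell atoms")


def _split(ds: Dataset, n_train: int, n_valid: int, n_test: int) -> Dataset:
    labels = (["train"] * n_train + ["valid"] * n_valid + ["test"] * n_test)
    if len(labels) != len(ds):
        raise ValueError("split sizes do not match dataset length")
    return Dataset(ds.systems, labels)


# study conditions of the synthetic benchmark suite
LJ_DIMER = ToyPotentialSpec(
    terms=[{"kind": "lennard_jones", "epsilon": 0.1, "sigma": 2.5}], r_c=5.0)
MORSE_TRIMER = ToyPotentialSpec(
    terms=[{"kind": "morse", "D_e": 0.5, "a": 1.5, "r_e": 2.0}], r_c=5.0)
# The cluster cutoff (3.0 Å) keeps only nearest neighbors connected, so
# most hub neighbor-pairs are mutually unconnected and the triple-dipole
# term carries angular information no distance-only model can see.  C9 is
# set so the three-body share of the force standard deviation is ≈30%.
AT_CLUSTER = ToyPotentialSpec(
    terms=[{"kind": "lennard_jones", "epsilon": 0.05, "sigma": 2.2},
           {"kind": "axilrod_teller", "C9": 2800.0}], r_c=3.0)
LJ_BOX = ToyPotentialSpec(
    terms=[{"kind": "lennard_jones", "epsilon": 0.0104, "sigma": 3.4}], r_c=5.0)


def make_benchmark_suite(seed: int = 0) -> dict[str, Dataset]:
    """Fixed four-dataset suite with train/valid/test splits.

    - ``lj_dimer_scan``: radial curve of an Ar-like dimer (60 frames).
    - ``morse_trimer``: displaced triangles, angular content (300 frames).
    - ``at_cluster_8``: 8-atom cluster with a three-body term (625 frames).
    - ``lj_box_periodic``: 32 LJ atoms in a periodic cubic box (100 frames).
    """
    rng = np.random.default_rng(seed)
    suite: dict[str, Dataset] = {}

    # dimer scan: deterministic radial grid
    rr = np.linspace(0.95 * 2.5, 4.8, 60)
    systems = []
    for r in rr:
        s = AtomicSystem([18, 18], [[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
        s.energy, s.forces = toy_energy_forces(s, LJ_DIMER)
        systems.append(s)
    order = rng.permutation(60)
    suite["lj_dimer_scan"] = _split(
        Dataset([systems[k] for k in order]), 40, 10, 10)

    # trimer: equilateral Morse triangle, displaced
    a = 2.0
    tri = np.array([[0, 0, 0], [a, 0, 0], [a / 2, a * np.sqrt(3) / 2, 0.0]])
    ds = sample_dataset(MORSE_TRIMER, SamplerSpec(
        tri, np.array([8, 8, 8]), n_samples=300, displacement_scale=0.15,
        seed=int(rng.integers(2 ** 31))))
    suite["morse_trimer"] = _split(ds, 240, 30, 30)

    # 8-atom star clusters: hub + 7 shell atoms, angular three-body probe
    rng_star = np.random.default_rng(int(rng.integers(2 ** 31)))
    systems = []
    for _ in range(625):
        pos = sample_star_cluster(rng_star)
        s = AtomicSystem(np.full(8, 18), pos)
        s.energy, s.forces = toy_energy_forces(s, AT_CLUSTER)
        systems.append(s)
    suite["at_cluster_8"] = _split(Dataset(systems), 500, 62, 63)

    # periodic box: 2x2x2 fcc argon at liquid-like density
    L = 11.45
    cellf = np.array([[0, 0, 0], [0.5, 0.5, 0], [0.5, 0, 0.5], [0, 0.5, 0.5]])
    frac = np.concatenate([(cellf + np.array([i, j, k])) / 2.0
                           for i in (0, 1) for j in (0, 1) for k in (0, 1)])
    ds = sample_dataset(LJ_BOX, SamplerSpec(
        frac * L, np.full(32, 18), n_samples=100, displacement_scale=0.1,
        seed=int(rng.integers(2 ** 31)), cell=np.eye(3) * L,
        pbc=np.ones(3, bool)))
    suite["lj_box_periodic"] = _split(ds, 80, 10, 10)
    return suite


def write_suite(suite: dict[str, Dataset], directory) -> None:
    """Write every dataset as extended XYZ plus a plain-text manifest."""
    import os

    from .systems_io import write_extxyz
    os.makedirs(directory, exist_ok=True)
    lines = ["name\tn_frames\tn_train\tn_valid\tn_test"]
    for name, ds in suite.items():
        write_extxyz(ds, os.path.join(directory, f"{name}.extxyz"))
        lab = ds.split_labels or []
        lines.append(f"{name}\t{len(ds)}\t{lab.count('train')}"
                     f"\t{lab.count('valid')}\t{lab.count('test')}")
    with open(os.path.join(directory, "manifest.tsv"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
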