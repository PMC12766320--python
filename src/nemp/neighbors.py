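"""Directed neighbor lists under open or periodic boundaries.

Two constructions are provided: an exhaustive image-enumeration search
(:func:`brute_force_neighbors`, the oracle) and a spatially binned search
(:func:`cell_list_neighbors`) that must produce the identical pair set.
Both return *directed* lists — (i, j, S) and (j, i, −S) are stored
separately — because all message sums in the potential run over ordered
(central, neighbor) pairs.

A Verlet skin buffer supports infrequent rebuilds: a list built at
``r_c + skin`` remains a superset of the true ``r_c`` list until some atom
has moved more than ``skin / 2`` from its position at build time
(:func:`needs_refresh`), at which point it must be rebuilt.
:class:`BufferedNeighborList` packages that contract for molecular
dynamics, either with the automatic displacement criterion or with a fixed
refresh interval plus a hard safety check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .systems_io import AtomicSystem

__all__ = [
    "NeighborList", "brute_force_neighbors", "cell_list_neighbors",
    "needs_refresh", "filter_to_cutoff", "BufferedNeighborList",
]


@dataclass
class NeighborList:
    pairs: np.ndarray                # (P, 2) int, directed (i, j)
    shifts: np.ndarray               # (P, 3) int lattice-image triplets
    vectors: np.ndarray              # (P, 3) r_ij = pos_j + S·cell - pos_i, Å
    distances: np.ndarray            # (P,) Å
    cutoff: float                    # r_c, Å
    skin: float                      # buffer width, Å
    reference_positions: np.ndarray  # positions at last (re)build
    cell: np.ndarray | None = None
    pbc: np.ndarray | None = None

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def _sort_pairs(pairs, shifts, vectors, distances):
    if len(pairs) == 0:
        return pairs, shifts, vectors, distances
    order = np.lexsort((shifts[:, 2], shifts[:, 1], shifts[:, 0], pairs[:, 1], pairs[:, 0]))
    return pairs[order], shifts[order], vectors[order], distances[order]


def _shift_ranges(cell: np.ndarray, pbc: np.ndarray, frac_span: np.ndarray,
                  cut: float) -> list[np.ndarray]:
    """Per-axis integer shift candidates covering every displacement of
    norm <= cut, for arbitrary (possibly skewed, possibly small) cells."""
    inv = np.linalg.inv(cell)
    heights = 1.0 / np.linalg.norm(inv, axis=0)   # distance between lattice planes
    ranges = []
    for k in range(3):
        if not pbc[k]:
            ranges.append(np.array([0]))
        else:
            m = int(np.ceil(cut / heights[k] + frac_span[k])) + 1
            ranges.append(np.arange(-m, m + 1))
    return ranges


def _candidate_shifts(pos: np.ndarray, cell: np.ndarray, pbc: np.ndarray,
                      cut: float) -> np.ndarray:
    """Integer lattice shifts that can bring any image within `cut` of any
    central atom: per-axis ranges from the lattice-plane spacings, pruned by
    |S·cell| <= cut + system diameter."""
    frac = pos @ np.linalg.inv(cell)
    span = frac.max(axis=0) - frac.min(axis=0)
    ranges = _shift_ranges(cell, pbc, span, cut)
    n_cand = int(np.prod([len(r) for r in ranges], dtype=float))
    if n_cand > 2_000_000:
        raise ValueError(
            f"periodic image enumeration needs {n_cand} candidate shifts; "
            "the positions span far too many cells — wrap or sanity-check them")
    grids = np.stack(np.meshgrid(*ranges, indexing="ij"), axis=-1).reshape(-1, 3)
    diam = float(np.linalg.norm(pos.max(axis=0) - pos.min(axis=0)))
    norms = np.linalg.norm(grids @ cell, axis=1)
    return grids[norms <= cut + diam + 1e-9]


def brute_force_neighbors(s: AtomicSystem, r_c: float, skin: float = 0.0) -> NeighborList:
    """All directed pairs with |r_ij| <= r_c + skin, by exhaustive image
    enumeration.  Quadratic in atoms and images; the reference oracle."""
    if r_c <= 0:
        raise ValueError("cutoff must be positive")
    pos = np.asarray(s.positions, dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("non-finite positions")
    n = len(pos)
    cut = r_c + skin
    periodic = s.cell is not None and np.any(s.pbc)

    if periodic:
        grids = _candidate_shifts(pos, s.cell, s.pbc, cut)
        shift_vecs = grids @ s.cell
    else:
        grids = np.zeros((1, 3), dtype=int)
        shift_vecs = np.zeros((1, 3))

    d = pos[None, :, :] - pos[:, None, :]                       # (n, n, 3)
    disp = d[:, :, None, :] + shift_vecs[None, None, :, :]       # (n, n, S, 3)
    dist = np.linalg.norm(disp, axis=-1)
    mask = dist <= cut
    iz = np.arange(n)
    self_zero = (iz[:, None, None] == iz[None, :, None]) & \
        np.all(grids == 0, axis=1)[None, None, :]
    mask &= ~self_zero
    ii, jj, ss = np.nonzero(mask)
    pairs = np.stack([ii, jj], axis=1)
    shifts = grids[ss].astype(int)
    vectors = disp[ii, jj, ss]
    distances = dist[ii, jj, ss]
    pairs, shifts, vectors, distances = _sort_pairs(pairs, shifts, vectors, distances)
    return NeighborList(pairs, shifts, vectors, distances, r_c, skin, pos.copy(),
                        None if s.cell is None else s.cell.copy(), s.pbc.copy())


def cell_list_neighbors(s: AtomicSystem, r_c: float, skin: float = 0.0) -> NeighborList:
    """Same pair set as :func:`brute_force_neighbors`, via spatial binning.

    Ghost images of all atoms within reach of the central atoms are
    generated first, then binned on a Cartesian grid of box edge
    ``r_c + skin``; only neighboring bins are searched.
    """
    if r_c <= 0:
        raise ValueError("cutoff must be positive")
    pos = np.asarray(s.positions, dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("non-finite positions")
    n = len(pos)
    cut = r_c + skin
    periodic = s.cell is not None and np.any(s.pbc)

    if periodic:
        grids = _candidate_shifts(pos, s.cell, s.pbc, cut)
    else:
        grids = np.zeros((1, 3), dtype=int)
    shift_vecs = grids @ s.cell if s.cell is not None else np.zeros((1, 3))

    # ghost atoms: (source index, image shift, cartesian position)
    g_pos = (pos[None, :, :] + shift_vecs[:, None, :]).reshape(-1, 3)
    g_src = np.tile(np.arange(n), len(grids))
    g_shift = np.repeat(grids, n, axis=0)
    # prune ghosts that cannot be within `cut` of any central atom
    lo, hi = pos.min(axis=0) - cut, pos.max(axis=0) + cut
    keep = np.all((g_pos >= lo) & (g_pos <= hi), axis=1)
    g_pos, g_src, g_shift = g_pos[keep], g_src[keep], g_shift[keep]

    origin = g_pos.min(axis=0) - 1e-9
    bins_g = np.floor((g_pos - origin) / cut).astype(int)
    bins_c = np.floor((pos - origin) / cut).astype(int)
    from collections import defaultdict
    bucket: dict[tuple, list[int]] = defaultdict(list)
    for k, b in enumerate(map(tuple, bins_g)):
        bucket[b].append(k)

    offsets = np.stack(np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1],
                                   indexing="ij"), axis=-1).reshape(-1, 3)
    P_i, P_j, P_s, P_v, P_d = [], [], [], [], []
    for i in range(n):
        cand: list[int] = []
        bi = bins_c[i]
        for off in offsets:
            cand.extend(bucket.get((bi[0] + off[0], bi[1] + off[1], bi[2] + off[2]), ()))
        if not cand:
            continue
        cand = np.asarray(cand)
        vec = g_pos[cand] - pos[i]
        dist = np.linalg.norm(vec, axis=1)
        ok = dist <= cut
        ok &= ~((g_src[cand] == i) & np.all(g_shift[cand] == 0, axis=1))
        cand = cand[ok]
        P_i.append(np.full(len(cand), i))
        P_j.append(g_src[cand])
        P_s.append(g_shift[cand])
        P_v.append(vec[ok])
        P_d.append(dist[ok])
    if P_i and sum(map(len, P_i)):
        pairs = np.stack([np.concatenate(P_i), np.concatenate(P_j)], axis=1)
        shifts = np.concatenate(P_s).astype(int)
        vectors = np.concatenate(P_v)
        distances = np.concatenate(P_d)
    else:
        pairs = np.zeros((0, 2), dtype=int)
        shifts = np.zeros((0, 3), dtype=int)
        vectors = np.zeros((0, 3))
        distances = np.zeros(0)
    pairs, shifts, vectors, distances = _sort_pairs(pairs, shifts, vectors, distances)
    return NeighborList(pairs, shifts, vectors, distances, r_c, skin, pos.copy(),
                        None if s.cell is None else s.cell.copy(), s.pbc.copy())


def _max_displacement(current: np.ndarray, nl: NeighborList) -> float:
    d = current - nl.reference_positions
    if nl.cell is not None and nl.pbc is not None and np.any(nl.pbc):
        frac = d @ np.linalg.inv(nl.cell)
        frac[:, nl.pbc] -= np.round(frac[:, nl.pbc])
        d = frac @ nl.cell
    return float(np.linalg.norm(d, axis=1).max(initial=0.0))


def needs_refresh(current: np.ndarray, nl: NeighborList) -> bool:
    """True iff some atom moved more than skin/2 since the last rebuild.

    While this returns False, the buffered list is guaranteed to contain
    every pair currently within ``nl.cutoff``.
    """
    current = np.asarray(current, dtype=float)
    if current.shape != nl.reference_positions.shape:
        raise ValueError("atom count mismatch with the stored reference positions")
    return _max_displacement(current, nl) > nl.skin / 2.0


def filter_to_cutoff(nl: NeighborList, current: np.ndarray) -> NeighborList:
    """Recompute displacements for the stored (i, j, shift) triplets at the
    given positions and drop pairs beyond ``r_c``; the result has skin 0."""
    current = np.asarray(current, dtype=float)
    i, j = nl.pairs[:, 0], nl.pairs[:, 1]
    sv = nl.shifts @ nl.cell if nl.cell is not None else np.zeros((len(nl.pairs), 3))
    vec = current[j] + sv - current[i]
    dist = np.linalg.norm(vec, axis=1)
    keep = dist <= nl.cutoff
    return NeighborList(nl.pairs[keep], nl.shifts[keep], vec[keep], dist[keep],
                        nl.cutoff, 0.0, current.copy(), nl.cell, nl.pbc)


class BufferedNeighborList:
    """Skin-buffered list with an explicit refresh contract.

    ``refresh='auto'`` rebuilds when any atom has moved more than skin/2.
    ``refresh=n`` (int) rebuilds every n steps — the pipelined fixed-interval
    mode — and raises if the skin guarantee was violated in between.
    """

    def __init__(self, system: AtomicSystem, r_c: float, skin: float,
                 refresh: str | int = "auto", builder=cell_list_neighbors):
        if skin < 0:
            raise ValueError("skin must be nonnegative")
        self.r_c, self.skin, self.refresh = r_c, skin, refresh
        self._builder = builder
        self._template = system
        self.n_rebuilds = 0
        self._step = 0
        self.nl = self._build(system.positions)

    def _build(self, positions) -> NeighborList:
        s = self._template.copy()
        s.positions = np.asarray(positions, dtype=float)
        self.n_rebuilds += 1
        return self._builder(s, self.r_c, self.skin)

    def current(self, positions) -> NeighborList:
        """Neighbor list filtered to r_c at the given positions, rebuilding
        the buffered list according to the refresh policy."""
        if self.refresh == "auto":
            if needs_refresh(positions, self.nl):
                self.nl = self._build(positions)
        else:
            if self._step > 0 and self._step % int(self.refresh) == 0:
                self.nl = self._build(positions)
            elif needs_refresh(positions, self.nl):
                raise RuntimeError(
                    f"skin guarantee violated at step {self._step}: an atom moved "
                    f"more than skin/2 = {self.skin / 2:.3f} Å between fixed-interval "
                    "refreshes; increase the skin or shorten the interval")
        self._step += 1
        return filter_to_cutoff(self.nl, positions)
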