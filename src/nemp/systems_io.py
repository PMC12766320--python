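"""Atomic configurations and lossless extended-XYZ input/output.

An :class:`AtomicSystem` holds atomic numbers, Cartesian positions (Å), an
optional periodic cell (rows are lattice vectors, Å) and optional reference
labels: total energy (eV) and per-atom forces (eV Å⁻¹).  Datasets are
ordered collections of systems with optional train/valid/test split labels.

The on-disk format is extended XYZ: a per-frame comment line carrying
``Lattice=...``, ``Properties=...``, ``energy=...`` and ``pbc=...`` keys.
Floats are emitted with ``repr``-level precision so write → read is an
identity on every stored field.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = ["AtomicSystem", "Dataset", "read_extxyz", "write_extxyz", "validate_system"]

_SYMBOLS = [
    "X", "H", "He", "Li", "Be", "B", "C", "N", "O", "F", "Ne", "Na", "Mg",
    "Al", "Si", "P", "S", "Cl", "Ar", "K", "Ca", "Sc", "Ti", "V", "Cr",
    "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se", "Br", "Kr",
    "Rb", "Sr", "Y", "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd",
    "In", "Sn", "Sb", "Te", "I", "Xe",
]
_Z_FROM_SYMBOL = {s: z for z, s in enumerate(_SYMBOLS)}

# standard atomic weights (amu), indexed like _SYMBOLS; enough for toy work
ATOMIC_MASSES = {
    1: 1.008, 2: 4.002602, 3: 6.94, 4: 9.0121831, 5: 10.81, 6: 12.011,
    7: 14.007, 8: 15.999, 9: 18.998403163, 10: 20.1797, 11: 22.98976928,
    12: 24.305, 13: 26.9815385, 14: 28.085, 15: 30.973761998, 16: 32.06,
    17: 35.45, 18: 39.948, 19: 39.0983, 20: 40.078, 29: 63.546, 47: 107.8682,
}


def symbol_of(z: int) -> str:
    return _SYMBOLS[z]


def z_of(symbol: str) -> int:
    try:
        return _Z_FROM_SYMBOL[symbol]
    except KeyError:
        raise ValueError(f"unknown element symbol {symbol!r}") from None


@dataclass
class AtomicSystem:
    """One atomic configuration with optional reference labels."""

    elements: np.ndarray                 # (N,) int atomic numbers
    positions: np.ndarray                # (N, 3) Å
    cell: np.ndarray | None = None       # (3, 3) Å, rows = lattice vectors
    pbc: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=bool))
    energy: float | None = None          # eV
    forces: np.ndarray | None = None     # (N, 3) eV/Å

    def __post_init__(self):
        self.elements = np.asarray(self.elements, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float)
        self.pbc = np.asarray(self.pbc, dtype=bool)
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
        if self.energy is not None:
            self.energy = float(self.energy)

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def copy(self) -> "AtomicSystem":
        return AtomicSystem(
            self.elements.copy(), self.positions.copy(),
            None if self.cell is None else self.cell.copy(),
            self.pbc.copy(), self.energy,
            None if self.forces is None else self.forces.copy())


@dataclass
class Dataset:
    systems: list[AtomicSystem] = field(default_factory=list)
    split_labels: list[str] | None = None

    def __len__(self):
        return len(self.systems)

    def __iter__(self):
        return iter(self.systems)

    def __getitem__(self, i):
        if isinstance(i, slice):
            labels = None if self.split_labels is None else self.split_labels[i]
            return Dataset(self.systems[i], labels)
        return self.systems[i]

    def subset(self, label: str) -> "Dataset":
        if self.split_labels is None:
            raise ValueError("dataset has no split labels")
        keep = [s for s, lab in zip(self.systems, self.split_labels) if lab == label]
        return Dataset(keep, [label] * len(keep))


class ExtxyzParseError(ValueError):
    pass


def validate_system(s: AtomicSystem) -> AtomicSystem:
    """Check the structural invariants; return ``s`` unchanged if they hold."""
    problems = []
    if s.n_atoms < 1:
        problems.append("elements: at least one atom required")
    if np.any(s.elements < 1):
        problems.append("elements: atomic numbers must be >= 1")
    if s.positions.shape != (s.n_atoms, 3):
        problems.append(f"positions: shape {s.positions.shape} != ({s.n_atoms}, 3)")
    elif not np.all(np.isfinite(s.positions)):
        problems.append("positions: non-finite entries")
    if s.forces is not None and s.forces.shape != (s.n_atoms, 3):
        problems.append(f"forces length: shape {s.forces.shape} != ({s.n_atoms}, 3)")
    if np.any(s.pbc):
        if s.cell is None:
            problems.append("cell: missing although pbc is set")
        elif s.cell.shape != (3, 3):
            problems.append(f"cell: shape {s.cell.shape} != (3, 3)")
        elif abs(np.linalg.det(s.cell)) < 1e-12:
            problems.append("cell singular")
    if problems:
        raise ValueError("invalid AtomicSystem: " + "; ".join(problems))
    return s


# ---------------------------------------------------------------------
# extended-XYZ comment line key=value parsing
# ---------------------------------------------------------------------

_KV_RE = re.compile(r'(\S+)=(?:"([^"]*)"|(\S+))')


def _parse_comment(line: str) -> dict[str, str]:
    return {m.group(1): m.group(2) if m.group(2) is not None else m.group(3)
            for m in _KV_RE.finditer(line)}


def _fmt(x: float) -> str:
    return repr(float(x))


def read_extxyz(path) -> Dataset:
    """Read every frame of an extended-XYZ file into a :class:`Dataset`."""
    systems = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i, frame = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].strip())
        except ValueError:
            raise ExtxyzParseError(
                f"frame {frame}: line {i + 1}: expected atom count, got {lines[i]!r}")
        if i + 1 + nat >= len(lines) + 1:
            raise ExtxyzParseError(
                f"frame {frame}: declared {nat} atoms but file ends early")
        info = _parse_comment(lines[i + 1])
        props = info.get("Properties", "species:S:1:pos:R:3")
        cols, c = [], 0
        toks = props.split(":")
        for k in range(0, len(toks), 3):
            name, kind, width = toks[k], toks[k + 1], int(toks[k + 2])
            cols.append((name, kind, c, width))
            c += width
        has_forces = any(name == "forces" for name, *_ in cols)
        elements = np.empty(nat, dtype=int)
        positions = np.empty((nat, 3))
        forces = np.empty((nat, 3)) if has_forces else None
        for a in range(nat):
            ln = i + 2 + a
            if ln >= len(lines) or not lines[ln].strip() or _looks_like_header(lines, ln):
                raise ExtxyzParseError(
                    f"frame {frame}: declared {nat} atoms but line {ln + 1} is missing")
            fields = lines[ln].split()
            for name, kind, start, width in cols:
                vals = fields[start:start + width]
                if len(vals) < width:
                    raise ExtxyzParseError(
                        f"frame {frame}: line {ln + 1}: too few columns")
                try:
                    if name == "species":
                        elements[a] = z_of(vals[0])
                    elif name == "pos":
                        positions[a] = [float(v) for v in vals]
                    elif name == "forces":
                        forces[a] = [float(v) for v in vals]
                except ValueError as e:
                    raise ExtxyzParseError(
                        f"frame {frame}: line {ln + 1}: {e}") from None
        cell = None
        pbc = np.zeros(3, dtype=bool)
        if "Lattice" in info:
            cell = np.array([float(v) for v in info["Lattice"].split()]).reshape(3, 3)
            pbc = np.ones(3, dtype=bool)
        if "pbc" in info:
            pbc = np.array([v in ("T", "True", "1") for v in info["pbc"].split()])
        energy = float(info["energy"]) if "energy" in info else None
        systems.append(AtomicSystem(elements, positions, cell, pbc, energy, forces))
        i += 2 + nat
        frame += 1
    return Dataset(systems)


def _looks_like_header(lines, ln):
    """Heuristic guard: an atom-count line followed by a Properties= line."""
    try:
        int(lines[ln].strip())
    except ValueError:
        return False
    return ln + 1 < len(lines) and "Properties=" in lines[ln + 1]


def write_extxyz(data: Dataset, path) -> None:
    """Write a dataset as extended XYZ with full float precision."""
    with open(path, "w") as fh:
        for s in data:
            validate_system(s)
            props = "species:S:1:pos:R:3"
            if s.forces is not None:
                props += ":forces:R:3"
            parts = []
            if s.cell is not None:
                parts.append('Lattice="' + " ".join(_fmt(x) for x in s.cell.ravel()) + '"')
            parts.append(f"Properties={props}")
            if s.energy is not None:
                parts.append(f"energy={_fmt(s.energy)}")
            parts.append('pbc="' + " ".join("T" if b else "F" for b in s.pbc) + '"')
            fh.write(f"{s.n_atoms}\n")
            fh.write(" ".join(parts) + "\n")
            for a in range(s.n_atoms):
                row = [symbol_of(int(s.elements[a]))]
                row += [_fmt(x) for x in s.positions[a]]
                if s.forces is not None:
                    row += [_fmt(x) for x in s.forces[a]]
                fh.write(" ".join(row) + "\n")
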