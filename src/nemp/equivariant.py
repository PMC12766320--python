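"""Real spherical harmonics, Clebsch–Gordan tables, tensor products and
Wigner-D rotation blocks.

Conventions
-----------
* Real spherical harmonics in the standard Condon–Shortley-free real form
  (built from the complex harmonics as ``√2·(−1)^m Re/Im``), ordered
  m = −l..l inside each l block; slot ``l² + l + m`` of a flattened
  (l_max+1)²-long feature vector.
* Real-basis Clebsch–Gordan blocks are obtained from the complex
  coefficients (Racah closed form, exact rational arithmetic under the
  square root) conjugated by the complex→real change-of-basis matrices;
  blocks whose conjugation lands on the imaginary axis (l1+l2+lf odd) are
  rotated back to the real axis by a fixed −i phase.  Each (l1,l2)→lf block
  is orthonormal: Σ_{m1,m2} C_{m1 m2 Mf} C_{m1 m2 Mf'} = δ.
* ``wigner_d_real`` satisfies Y(R·u) = D(R)·Y(u) for the harmonics above,
  which makes it the oracle for every equivariance test in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from math import atan2, factorial, prod, sqrt

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "real_sph_harm", "real_sph_harm_ad", "clebsch_gordan_complex",
    "CGTable", "cg_table", "EquivariantFeatureBlock", "tensor_product",
    "tensor_product_values", "wigner_d_real", "rotate_features", "lm_slices",
]

SQRT2 = sqrt(2.0)


def lm_slices(l_max: int) -> list[slice]:
    """Slice of the flattened (l_max+1)² axis occupied by each l block."""
    return [slice(l * l, (l + 1) * (l + 1)) for l in range(l_max + 1)]


# ---------------------------------------------------------------------
# real spherical harmonics
# ---------------------------------------------------------------------

def real_sph_harm(l_max: int, vectors: np.ndarray) -> np.ndarray:
    """Real orthonormal spherical harmonics for (possibly non-unit) input
    vectors, shape (n, (l_max+1)²).  Zero-length vectors are an error."""
    from scipy.special import sph_harm_y

    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    norms = np.linalg.norm(v, axis=1)
    if np.any(norms < 1e-300):
        raise ValueError("zero-length direction vector")
    u = v / norms[:, None]
    theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
    phi = np.arctan2(u[:, 1], u[:, 0])
    out = np.empty((len(u), (l_max + 1) ** 2))
    for l in range(l_max + 1):
        for m in range(0, l + 1):
            Y = sph_harm_y(l, m, theta, phi)
            if m == 0:
                out[:, l * l + l] = Y.real
            else:
                out[:, l * l + l + m] = SQRT2 * (-1) ** m * Y.real
                out[:, l * l + l - m] = SQRT2 * (-1) ** m * Y.imag
    return out


_AD_LMAX = 3


def real_sph_harm_ad(l_max: int, unit: Tensor) -> Tensor:
    """Differentiable real spherical harmonics (closed-form Cartesian
    polynomials, l ≤ 3) of unit vectors, built on the autodiff tape.

    Matches :func:`real_sph_harm` to machine precision; the polynomial form
    keeps the tape short for force evaluation.
    """
    if l_max > _AD_LMAX:
        raise ValueError(f"differentiable harmonics implemented up to l={_AD_LMAX}")
    x = unit[:, 0]
    y = unit[:, 1]
    z = unit[:, 2]
    cols = [ad.constant(np.full(x.shape, 0.28209479177387814)) + 0.0 * x]
    if l_max >= 1:
        c1 = 0.4886025119029199
        cols += [c1 * y, c1 * z, c1 * x]
    if l_max >= 2:
        c2a, c2b, c2c = 1.0925484305920792, 0.31539156525252005, 0.5462742152960396
        cols += [c2a * x * y, c2a * y * z, c2b * (3.0 * z * z - 1.0),
                 c2a * x * z, c2c * (x * x - y * y)]
    if l_max >= 3:
        cols += [0.5900435899266435 * y * (3.0 * x * x - y * y),
                 2.890611442640554 * x * y * z,
                 0.4570457994644658 * y * (5.0 * z * z - 1.0),
                 0.3731763325901154 * z * (5.0 * z * z - 3.0),
                 0.4570457994644658 * x * (5.0 * z * z - 1.0),
                 1.445305721320277 * z * (x * x - y * y),
                 0.5900435899266435 * x * (x * x - 3.0 * y * y)]
    return ad.stack(cols, axis=1)


# ---------------------------------------------------------------------
# Clebsch–Gordan coefficients
# ---------------------------------------------------------------------

def clebsch_gordan_complex(j1: int, m1: int, j2: int, m2: int, J: int, M: int) -> float:
    """Complex-basis CG coefficient ⟨j1 m1 j2 m2 | J M⟩ by the Racah closed
    form, evaluated in exact rational arithmetic under the square root."""
    if M != m1 + m2 or J < abs(j1 - j2) or J > j1 + j2:
        return 0.0
    if abs(m1) > j1 or abs(m2) > j2 or abs(M) > J:
        return 0.0
    f = factorial
    pre = Fraction(2 * J + 1) * Fraction(
        f(J + j1 - j2) * f(J - j1 + j2) * f(j1 + j2 - J), f(j1 + j2 + J + 1))
    pre *= Fraction(f(J + M) * f(J - M) * f(j1 - m1) * f(j1 + m1)
                    * f(j2 - m2) * f(j2 + m2))
    s = Fraction(0)
    for k in range(0, j1 + j2 - J + 1):
        t = [k, j1 + j2 - J - k, j1 - m1 - k, j2 + m2 - k,
             J - j2 + m1 + k, J - j1 - m2 + k]
        if any(x < 0 for x in t):
            continue
        s += Fraction((-1) ** k, prod(f(x) for x in t))
    return float(s) * sqrt(float(pre))


@lru_cache(maxsize=None)
def _u_complex_to_real(l: int) -> np.ndarray:
    """Unitary matrix mapping complex harmonics (m=-l..l) to the real ones."""
    U = np.zeros((2 * l + 1, 2 * l + 1), dtype=complex)
    U[l, l] = 1.0
    for m in range(1, l + 1):
        U[l + m, l + m] = (-1) ** m / SQRT2
        U[l + m, l - m] = 1.0 / SQRT2
        U[l - m, l + m] = -1j * (-1) ** m / SQRT2
        U[l - m, l - m] = 1j / SQRT2
    return U


@lru_cache(maxsize=None)
def _real_cg_block(l1: int, l2: int, lf: int) -> np.ndarray:
    C = np.zeros((2 * l1 + 1, 2 * l2 + 1, 2 * lf + 1), dtype=complex)
    for m1 in range(-l1, l1 + 1):
        for m2 in range(-l2, l2 + 1):
            M = m1 + m2
            if abs(M) <= lf:
                C[m1 + l1, m2 + l2, M + lf] = clebsch_gordan_complex(l1, m1, l2, m2, lf, M)
    U1 = _u_complex_to_real(l1)
    U2 = _u_complex_to_real(l2)
    Uf = _u_complex_to_real(lf)
    Cr = np.einsum("rp,abp,ma,nb->mnr", Uf, C, U1.conj(), U2.conj())
    if np.abs(Cr.imag).max() > np.abs(Cr.real).max():   # odd l1+l2+lf parity
        Cr = 1j * Cr
    if np.abs(Cr.imag).max() > 1e-12:
        raise AssertionError("real CG block is neither real nor imaginary")
    return np.ascontiguousarray(Cr.real)


@dataclass
class CGTable:
    """Nonzero real-basis Clebsch–Gordan coefficients up to ``l_max``."""

    l_max: int
    paths: list[tuple[int, int, int]]                      # (l1, l2) -> lf
    blocks: dict[tuple[int, int, int], np.ndarray]         # dense per-path blocks
    entries: dict[tuple[int, int, int, int, int, int], float] = field(repr=False,
                                                                      default_factory=dict)


def cg_table(l_max: int) -> CGTable:
    """All couplings (l1, l2) → lf with |l1−l2| ≤ lf ≤ min(l1+l2, l_max)."""
    if l_max < 0:
        raise ValueError("l_max must be >= 0")
    paths, blocks, entries = [], {}, {}
    for l1 in range(l_max + 1):
        for l2 in range(l_max + 1):
            for lf in range(abs(l1 - l2), min(l1 + l2, l_max) + 1):
                blk = _real_cg_block(l1, l2, lf)
                paths.append((l1, l2, lf))
                blocks[(l1, l2, lf)] = blk
                nz = np.nonzero(np.abs(blk) > 1e-14)
                for a, b, r in zip(*nz):
                    entries[(l1, a - l1, l2, b - l2, lf, r - lf)] = float(blk[a, b, r])
    return CGTable(l_max, paths, blocks, entries)


# ---------------------------------------------------------------------
# feature blocks and tensor products
# ---------------------------------------------------------------------

@dataclass
class EquivariantFeatureBlock:
    """Per-node features indexed (node, lm-slot, channel)."""

    values: np.ndarray    # (n, (l_max+1)², n_channels)
    l_max: int

    def __post_init__(self):
        vals = self.values.data if isinstance(self.values, Tensor) else self.values
        if vals.shape[1] != (self.l_max + 1) ** 2:
            raise ValueError(
                f"lm axis {vals.shape[1]} != (l_max+1)² = {(self.l_max + 1) ** 2}")

    @property
    def n_channels(self) -> int:
        vals = self.values.data if isinstance(self.values, Tensor) else self.values
        return vals.shape[2]


def _is_tensor(x) -> bool:
    return isinstance(x, Tensor)


def tensor_product_values(a, b, cg: CGTable, path_weights: dict):
    """Channel-wise CG tensor product on raw (n, N_lmc, c) arrays or Tensors.

    out[n, (lf,mf), c] = Σ_paths w[path][c] Σ_{m1,m2} C · a[n,(l1,m1),c] · b[n,(l2,m2),c]

    ``path_weights`` maps (l1, l2, lf) to a per-channel weight vector; paths
    absent from the mapping are skipped.
    """
    use_ad = _is_tensor(a) or _is_tensor(b) or any(
        _is_tensor(w) for w in path_weights.values())
    sl = lm_slices(cg.l_max)
    shape = (a.shape[0], (cg.l_max + 1) ** 2, a.shape[2])
    if a.shape != b.shape or a.shape[1] != shape[1]:
        raise ValueError(f"operand shapes {a.shape} vs {b.shape} incompatible "
                         f"with l_max={cg.l_max}")
    if use_ad:
        at = a if _is_tensor(a) else ad.constant(a)
        bt = b if _is_tensor(b) else ad.constant(b)
        pieces = {}
        for (l1, l2, lf) in cg.paths:
            w = path_weights.get((l1, l2, lf))
            if w is None:
                continue
            wt = w if _is_tensor(w) else ad.constant(w)
            C = ad.constant(cg.blocks[(l1, l2, lf)])
            t1 = ad.einsum("npc,pqr->nqrc", at[:, sl[l1], :], C)
            t2 = ad.einsum("nqrc,nqc->nrc", t1, bt[:, sl[l2], :])
            t2 = t2 * ad.reshape(wt, (1, 1, -1))
            pieces[lf] = t2 if lf not in pieces else pieces[lf] + t2
        cols = []
        for lf in range(cg.l_max + 1):
            cols.append(pieces.get(lf) if lf in pieces else
                        ad.constant(np.zeros((shape[0], 2 * lf + 1, shape[2]))))
        return ad.concat(cols, axis=1)
    out = np.zeros(shape)
    for (l1, l2, lf) in cg.paths:
        w = path_weights.get((l1, l2, lf))
        if w is None:
            continue
        blk = np.einsum("npc,pqr,nqc->nrc", a[:, sl[l1], :],
                        cg.blocks[(l1, l2, lf)], b[:, sl[l2], :])
        out[:, sl[lf], :] += blk * np.asarray(w)[None, None, :]
    return out


def tensor_product(a: EquivariantFeatureBlock, b: EquivariantFeatureBlock,
                   cg: CGTable, path_weights: dict) -> EquivariantFeatureBlock:
    if a.l_max != b.l_max or a.l_max != cg.l_max:
        raise ValueError("l_max mismatch between operands and CG table")
    if a.n_channels != b.n_channels:
        raise ValueError("channel-count mismatch")
    out = tensor_product_values(a.values, b.values, cg, path_weights)
    return EquivariantFeatureBlock(out, cg.l_max)


# ---------------------------------------------------------------------
# Wigner-D rotation blocks (real basis)
# ---------------------------------------------------------------------

def _euler_zyz(R: np.ndarray) -> tuple[float, float, float]:
    beta = atan2(sqrt(R[0, 2] ** 2 + R[1, 2] ** 2), R[2, 2])
    if abs(beta) < 1e-12:
        return atan2(R[1, 0], R[0, 0]), 0.0, 0.0
    if abs(beta - np.pi) < 1e-12:
        return atan2(R[1, 0], -R[0, 0]), np.pi, 0.0
    return atan2(R[1, 2], R[0, 2]), beta, atan2(R[2, 1], -R[2, 0])


def _wigner_small_d(j: int, mp: int, m: int, beta: float) -> float:
    f = factorial
    pre = sqrt(f(j + mp) * f(j - mp) * f(j + m) * f(j - m))
    s = 0.0
    c, sn = np.cos(beta / 2.0), np.sin(beta / 2.0)
    for k in range(max(0, m - mp), min(j + m, j - mp) + 1):
        den = f(j + m - k) * f(k) * f(mp - m + k) * f(j - mp - k)
        s += (-1) ** (mp - m + k) * c ** (2 * j + m - mp - 2 * k) * sn ** (mp - m + 2 * k) / den
    return pre * s


def wigner_d_real(l_max: int, R: np.ndarray) -> list[np.ndarray]:
    """Real-basis Wigner-D blocks D_l(R), l = 0..l_max, satisfying
    ``real_sph_harm(R·u) = D_l(R) · real_sph_harm(u)`` blockwise."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or np.abs(R.T @ R - np.eye(3)).max() > 1e-10 \
            or abs(np.linalg.det(R) - 1.0) > 1e-10:
        raise ValueError("input is not a proper rotation matrix")
    a, b, g = _euler_zyz(R)
    out = []
    for l in range(l_max + 1):
        D = np.empty((2 * l + 1, 2 * l + 1), dtype=complex)
        for mp in range(-l, l + 1):
            for m in range(-l, l + 1):
                D[mp + l, m + l] = (np.exp(-1j * mp * a)
                                    * _wigner_small_d(l, mp, m, b)
                                    * np.exp(-1j * m * g))
        U = _u_complex_to_real(l)
        Dr = U @ D.conj() @ U.conj().T
        if np.abs(Dr.imag).max() > 1e-10:
            raise AssertionError("real Wigner-D block has imaginary residue")
        out.append(Dr.real)
    return out


def rotate_features(values: np.ndarray, R: np.ndarray, l_max: int) -> np.ndarray:
    """Apply block-diagonal D(R) along the lm axis of a (n, N_lmc, c) array."""
    D = wigner_d_real(l_max, R)
    out = np.empty_like(values)
    for l, sl in enumerate(lm_slices(l_max)):
        out[:, sl, :] = np.einsum("pq,nqc->npc", D[l], values[:, sl, :])
    return out
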