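"""Real-basis O(3) representation algebra for ranks ℓ ≤ 2.

Conventions
-----------
ℓ=1 components are ordered (x, y, z), so the ℓ=1 Wigner matrix of a rotation
R is R itself.  ℓ=2 components live in an orthonormal (Frobenius) basis of
symmetric traceless 3×3 matrices, and the ℓ=2 Wigner matrix is obtained by
conjugation, D₂(R) v = vec(R mat(v) Rᵀ).  Clebsch–Gordan couplings between
these real bases are generated numerically as the (one-dimensional) space of
rotation-equivariant bilinear maps, normalised to unit Frobenius norm with a
fixed sign convention — any fixed normalisation works downstream because
learned weights absorb scales.

A 3×3 Cartesian tensor P (e.g. an atomic polar tensor) decomposes into
  scalar   s = tr(P)/√3                      (ℓ=0),
  vector   w, from the antisymmetric part     (ℓ=1, axial),
  deviator v, the symmetric traceless part    (ℓ=2),
with ‖P‖²_F = s² + ‖w‖² + ‖v‖² (the map is orthogonal), so mean-squared
errors agree between Cartesian components and irreducible components.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from scipy.linalg import null_space

__all__ = [
    "SYM_BASIS",
    "sym2vec",
    "vec2sym",
    "wigner_d",
    "spherical_harmonics",
    "clebsch_gordan",
    "tensor_to_irreps",
    "irreps_to_tensor",
    "random_rotation",
]

_SQRT2 = np.sqrt(2.0)


def _build_sym_basis() -> np.ndarray:
    b = np.zeros((5, 3, 3))
    b[0, 0, 1] = b[0, 1, 0] = 1 / _SQRT2                      # xy
    b[1, 1, 2] = b[1, 2, 1] = 1 / _SQRT2                      # yz
    b[2] = np.diag([-1.0, -1.0, 2.0]) / np.sqrt(6.0)          # 3z² − r²
    b[3, 0, 2] = b[3, 2, 0] = 1 / _SQRT2                      # xz
    b[4] = np.diag([1.0, -1.0, 0.0]) / _SQRT2                 # x² − y²
    return b


#: orthonormal basis of symmetric traceless matrices, shape (5, 3, 3)
SYM_BASIS = _build_sym_basis()

#: Levi-Civita symbol
EPS = np.zeros((3, 3, 3))
EPS[0, 1, 2] = EPS[1, 2, 0] = EPS[2, 0, 1] = 1.0
EPS[0, 2, 1] = EPS[2, 1, 0] = EPS[1, 0, 2] = -1.0


def sym2vec(m: np.ndarray) -> np.ndarray:
    """Project symmetric traceless matrices (..., 3, 3) onto the 5-vector basis."""
    return np.einsum("kab,...ab->...k", SYM_BASIS, m)


def vec2sym(v: np.ndarray) -> np.ndarray:
    """Inverse of :func:`sym2vec`."""
    return np.einsum("...k,kab->...ab", v, SYM_BASIS)


def wigner_d(l: int, rot: np.ndarray) -> np.ndarray:
    """Real Wigner matrix of a (proper) rotation for ℓ ∈ {0, 1, 2}."""
    rot = np.asarray(rot, dtype=float)
    if l == 0:
        return np.ones((1, 1))
    if l == 1:
        return rot.copy()
    if l == 2:
        return np.einsum("kab,ac,bd,lcd->kl", SYM_BASIS, rot, rot, SYM_BASIS)
    raise ValueError("only ℓ ≤ 2 supported")


def spherical_harmonics(l: int, vectors: np.ndarray) -> np.ndarray:
    """Real spherical harmonics of unit-normalised input vectors (..., 3).

    Normalised so that |Y_ℓ(u)| = 1 for every unit vector u.  Parity is
    (−1)^ℓ: Y₁ is odd, Y₀ and Y₂ even.
    """
    v = np.asarray(vectors, dtype=float)
    u = v / np.linalg.norm(v, axis=-1, keepdims=True)
    if l == 0:
        return np.ones(u.shape[:-1] + (1,))
    if l == 1:
        return u
    if l == 2:
        outer = u[..., :, None] * u[..., None, :]
        outer -= np.eye(3) / 3.0
        return np.sqrt(1.5) * sym2vec(outer)
    raise ValueError("only ℓ ≤ 2 supported")


def random_rotation(rng: np.random.Generator, proper: bool = True) -> np.ndarray:
    """Haar-ish random rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1.0
    if not proper:
        q = -q
    return q


@lru_cache(maxsize=None)
def clebsch_gordan(l1: int, l2: int, l3: int) -> np.ndarray:
    """Real-basis coupling coefficients C with shape (2ℓ₃+1, 2ℓ₁+1, 2ℓ₂+1).

    Defined (up to the fixed normalisation) by equivariance:
    Σ C[k,m,n] (D₁a)ₘ (D₂b)ₙ = Σ D₃[k,j] (Σ C[j,p,q] aₚ b_q) for all
    rotations.  Raises if the coupling is forbidden by the triangle rule.
    """
    if not abs(l1 - l2) <= l3 <= l1 + l2:
        raise ValueError(f"coupling {l1}⊗{l2}→{l3} violates the triangle rule")
    d1, d2, d3 = 2 * l1 + 1, 2 * l2 + 1, 2 * l3 + 1
    rng = np.random.default_rng(987654321)
    blocks = []
    for _ in range(4):
        rot = random_rotation(rng)
        D1, D2, D3 = (wigner_d(l, rot) for l in (l1, l2, l3))
        # constraint: C·(D1⊗D2) − D3·C = 0 acting on vec(C)
        op = np.einsum("mp,nq->mnpq", D1, D2).reshape(d1 * d2, d1 * d2)
        a = np.kron(np.eye(d3), op.T) - np.kron(D3, np.eye(d1 * d2))
        blocks.append(a)
    ns = null_space(np.vstack(blocks), rcond=1e-10)
    if ns.shape[1] != 1:
        raise RuntimeError(
            f"expected 1-dim coupling space for {l1}⊗{l2}→{l3}, got {ns.shape[1]}"
        )
    c = ns[:, 0].reshape(d3, d1, d2)
    c /= np.linalg.norm(c)
    flat = c.ravel()
    lead = flat[np.argmax(np.abs(flat) > 1e-8)]
    if lead < 0:
        c = -c
    c[np.abs(c) < 1e-12] = 0.0
    return c


def tensor_to_irreps(p: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split 3×3 tensors (..., 3, 3) into (scalar, axial 3-vector, deviator 5-vector).

    The decomposition is orthogonal: the sum of squares of the nine returned
    components equals the squared Frobenius norm of the input.
    """
    p = np.asarray(p, dtype=float)
    s = np.einsum("...aa->...", p) / np.sqrt(3.0)
    w = np.einsum("abc,...ab->...c", EPS, p) / _SQRT2
    sym = 0.5 * (p + np.swapaxes(p, -1, -2))
    iso = np.einsum("...aa->...", p)[..., None, None] / 3.0 * np.eye(3)
    v = sym2vec(sym - iso)
    return s[..., None], w, v


def irreps_to_tensor(
    s: np.ndarray, w: np.ndarray, v: np.ndarray
) -> np.ndarray:
    """Inverse of :func:`tensor_to_irreps`."""
    s = np.asarray(s, dtype=float)
    if s.ndim and s.shape[-1] == 1:
        s = s[..., 0]
    anti = np.einsum("abc,...c->...ab", EPS, np.asarray(w, dtype=float)) / _SQRT2
    iso = s[..., None, None] * np.eye(3) / np.sqrt(3.0)
    return iso + anti + vec2sym(np.asarray(v, dtype=float))
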