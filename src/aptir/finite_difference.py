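"""Atomic polar tensors by central finite differences of a dipole backend.

The APT of atom *i* is the 3×3 matrix P with P[ξ, ζ] = ∂M_ξ/∂r_{iζ}, the
derivative of the total dipole moment M with respect to that atom's
Cartesian position.  A backend is anything exposing
``evaluate(configuration) -> 3-vector`` (total dipole, e·Å) that is
deterministic and — for periodic systems where the dipole is defined only
modulo a lattice quantum — branch-consistent under sub-displacement
perturbations.  Central (two-sided) differences with displacement h need six
backend evaluations per atom and carry an O(h²) truncation error; the
default h = 0.01 Å is a convergence parameter that should be audited per
system with :func:`displacement_check`.

Displaced geometries are never re-wrapped into the cell: wrapping would hop
between dipole branches and corrupt the derivative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from .io import APTFrame, AtomicConfiguration

__all__ = [
    "DipoleBackend",
    "CountingBackend",
    "FDSettings",
    "compute_apt_atom",
    "compute_apt_config",
    "displacement_check",
]


@runtime_checkable
class DipoleBackend(Protocol):
    """Contract for total-dipole providers."""

    def evaluate(self, config: AtomicConfiguration) -> np.ndarray: ...


class CountingBackend:
    """Wrap a backend (or bare callable) and count evaluations."""

    def __init__(self, backend):
        self._inner = backend
        self.call_count = 0

    def evaluate(self, config: AtomicConfiguration) -> np.ndarray:
        self.call_count += 1
        inner = getattr(self._inner, "evaluate", self._inner)
        return np.asarray(inner(config), dtype=float)

    def __getattr__(self, name):
        # delegate capabilities (e.g. analytic_apt) to the wrapped backend
        return getattr(self._inner, name)


@dataclass
class FDSettings:
    """Central-difference protocol: displacement h in Å."""

    displacement: float = 0.01

    def __post_init__(self) -> None:
        if self.displacement <= 0:
            raise ValueError("displacement must be positive")


def _evaluate(backend, config) -> np.ndarray:
    inner = getattr(backend, "evaluate", backend)
    m = np.asarray(inner(config), dtype=float)
    if m.shape != (3,):
        raise ValueError(f"backend returned shape {m.shape}, expected (3,)")
    return m


def compute_apt_atom(
    config: AtomicConfiguration,
    atom_index: int,
    backend,
    settings: FDSettings | None = None,
) -> np.ndarray:
    """APT of one atom (3×3, units e): exactly 6 backend evaluations.

    Column ζ is [M(r_iζ + h) − M(r_iζ − h)] / 2h.  The unperturbed geometry
    is never evaluated — central differences do not need it.
    """
    settings = settings or FDSettings()
    if not 0 <= atom_index < config.n_atoms:
        raise IndexError(f"atom index {atom_index} out of range")
    h = settings.displacement
    apt = np.empty((3, 3))
    for zeta in range(3):
        mp, mm = [], []
        for sign, store in ((+1.0, mp), (-1.0, mm)):
            shifted = config.copy()
            shifted.positions[atom_index, zeta] += sign * h
            m = _evaluate(backend, shifted)
            if not np.all(np.isfinite(m)):
                raise ValueError(
                    f"backend returned non-finite dipole for atom {atom_index} "
                    f"displaced by {sign * h:+g} Å along axis {zeta}"
                )
            store.append(m)
        apt[:, zeta] = (mp[0] - mm[0]) / (2.0 * h)
    return apt


def compute_apt_config(
    config: AtomicConfiguration,
    backend,
    settings: FDSettings | None = None,
    analytic: bool = False,
) -> APTFrame:
    """APTs of every atom: 6 × n_atoms backend evaluations.

    With ``analytic=True`` and a backend exposing ``analytic_apt(config,
    atom_index)`` (a DFPT-style capability), finite differences are bypassed;
    the FD path remains the reference path.
    """
    if analytic:
        fn = getattr(backend, "analytic_apt", None)
        if fn is None:
            raise ValueError("backend does not provide analytic APTs")
        tensors = np.stack([fn(config, i) for i in range(config.n_atoms)])
        return APTFrame(tensors)
    settings = settings or FDSettings()
    tensors = np.stack(
        [compute_apt_atom(config, i, backend, settings) for i in range(config.n_atoms)]
    )
    return APTFrame(tensors)


def displacement_check(
    config: AtomicConfiguration, backend, h1: float, h2: float
) -> np.ndarray:
    """Per-atom max-abs deviation between APTs at two displacements.

    A convergence audit: on a dipole surface that is linear in positions the
    deviation vanishes at any pair (h1, h2); on smooth nonlinear surfaces it
    scales as |h1² − h2²|.
    """
    if h1 <= 0 or h2 <= 0:
        raise ValueError("displacements must be positive")
    a1 = compute_apt_config(config, backend, FDSettings(h1))
    a2 = compute_apt_config(config, backend, FDSettings(h2))
    return np.max(np.abs(a1.tensors - a2.tensors), axis=(1, 2))
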