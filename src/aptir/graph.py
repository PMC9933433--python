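"""Neighbor graphs with periodic boundary handling.

Edges connect ordered atom pairs closer than the radial cutoff.  Two exact
construction paths exist: the minimum-image convention (valid only when the
cutoff is below half the smallest cell height) and explicit enumeration of
periodic images (valid for any cutoff, and the only correct choice for small
cells where an atom may see several images of the same neighbor, or its own).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AtomicConfiguration

__all__ = ["NeighborGraph", "build_graph", "cell_heights"]


@dataclass
class NeighborGraph:
    """Directed edge list: ``vectors[e]`` points from ``src[e]`` to ``dst[e]``.

    Each edge carries the image-resolved displacement (Å); ``src`` is the
    neighbor supplying a message, ``dst`` the receiving atom.
    """

    n_nodes: int
    species: list[str]
    src: np.ndarray
    dst: np.ndarray
    vectors: np.ndarray
    cutoff: float

    @property
    def n_edges(self) -> int:
        return len(self.src)

    @property
    def distances(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=1)


def cell_heights(cell: np.ndarray) -> np.ndarray:
    """Perpendicular heights of the cell along its three lattice directions."""
    inv = np.linalg.inv(cell)
    # rows of cell are lattice vectors; columns of inv are reciprocal vectors
    return 1.0 / np.linalg.norm(inv, axis=0)


def build_graph(
    config: AtomicConfiguration, cutoff: float, method: str = "auto"
) -> NeighborGraph:
    """Build the neighbor graph within ``cutoff`` (Å).

    method:
      ``"mic"``    minimum-image convention; raises if the cutoff exceeds the
                   half-cell bound (naming the limiting lattice vector),
      ``"images"`` explicit periodic-image enumeration (always exact),
      ``"auto"``   minimum image when valid, otherwise image enumeration.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pos = config.positions
    n = config.n_atoms

    if not config.periodic:
        delta = pos[None, :, :] - pos[:, None, :]
        dist = np.linalg.norm(delta, axis=-1)
        dst, src = np.nonzero((dist < cutoff) & ~np.eye(n, dtype=bool))
        return NeighborGraph(
            n, list(config.species), src, dst, delta[dst, src], cutoff
        )

    cell = config.cell
    heights = cell_heights(cell)
    half_ok = cutoff < 0.5 * np.min(heights)
    if method == "mic" and not half_ok:
        k = int(np.argmin(heights))
        raise ValueError(
            f"cutoff {cutoff} Å exceeds half the cell height "
            f"{heights[k]:.3f} Å along lattice vector {k}; "
            "use image enumeration instead"
        )
    use_mic = method == "mic" or (method == "auto" and half_ok)
    if method not in ("mic", "images", "auto"):
        raise ValueError(f"unknown method {method!r}")

    if use_mic:
        frac = pos @ np.linalg.inv(cell)
        dfrac = frac[None, :, :] - frac[:, None, :]
        dfrac -= np.round(dfrac)
        delta = dfrac @ cell
        dist = np.linalg.norm(delta, axis=-1)
        dst, src = np.nonzero((dist < cutoff) & ~np.eye(n, dtype=bool))
        return NeighborGraph(
            n, list(config.species), src, dst, delta[dst, src], cutoff
        )

    # explicit images: enough layers per axis to cover the cutoff sphere
    layers = np.maximum(1, np.ceil(cutoff / heights).astype(int))
    src_l, dst_l, vec_l = [], [], []
    base = pos[None, :, :] - pos[:, None, :]  # base[i, j] = r_j - r_i
    for sa in range(-layers[0], layers[0] + 1):
        for sb in range(-layers[1], layers[1] + 1):
            for sc in range(-layers[2], layers[2] + 1):
                shift = np.array([sa, sb, sc], dtype=float) @ cell
                delta = base + shift
                dist = np.linalg.norm(delta, axis=-1)
                mask = dist < cutoff
                if sa == 0 and sb == 0 and sc == 0:
                    mask &= ~np.eye(n, dtype=bool)
                d_idx, s_idx = np.nonzero(mask)
                src_l.append(s_idx)
                dst_l.append(d_idx)
                vec_l.append(delta[d_idx, s_idx])
    src = np.concatenate(src_l)
    dst = np.concatenate(dst_l)
    vec = np.concatenate(vec_l)
    # stable deterministic ordering: by (dst, src, then vector lexicographic)
    order = np.lexsort((vec[:, 2], vec[:, 1], vec[:, 0], src, dst))
    return NeighborGraph(
        n, list(config.species), src[order], dst[order], vec[order], cutoff
    )
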