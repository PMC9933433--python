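"""E(3)-equivariant message-passing network predicting per-atom 3×3 tensors.

Atoms are nodes carrying features that are direct sums of real O(3) irreps
(ℓ ≤ 2, both parities).  A message-passing layer sends, along every edge
within the radial cutoff, the tensor product of the neighbor's features with
spherical harmonics of the edge direction, weighted by learned radial
profiles; messages are summed on the receiving node, mixed linearly per
irrep together with a self connection, and passed through a gated
nonlinearity (silu on even scalars, tanh on odd scalars, sigmoid gates on
everything with ℓ > 0).  A final equivariant linear readout emits one even
scalar, one even axial vector and one even deviator per atom — the
irreducible parts of a parity-even rank-2 Cartesian tensor such as the
atomic polar tensor ∂M/∂r.

Equivariance is structural: every operation commutes with rotations by
construction (Clebsch–Gordan contractions, invariant radial profiles), so
predictions transform as R P Rᵀ under proper and improper rotations, are
translation invariant, and permute with the atoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..graph import NeighborGraph
from .autodiff import SegmentIndex, Tape, Var
from .o3 import clebsch_gordan, spherical_harmonics

__all__ = ["NetworkArchitecture", "GraphTensors", "radial_basis"]

Irrep = tuple[int, int]  # (ℓ, parity); parity +1 even, −1 odd

_FILTER_LS = (0, 1, 2)
_LMAX = 2


def radial_basis(r: np.ndarray, cutoff: float, n_basis: int) -> np.ndarray:
    """Gaussian radial shells under a smooth cosine cutoff envelope, (E, n_basis)."""
    centers = np.linspace(0.0, cutoff, n_basis)
    width = cutoff / n_basis
    env = 0.5 * (np.cos(np.pi * np.clip(r / cutoff, 0.0, 1.0)) + 1.0)
    return np.exp(-0.5 * ((r[:, None] - centers[None, :]) / width) ** 2) * env[:, None]


@dataclass
class GraphTensors:
    """Per-configuration constants consumed by the network forward pass.

    ``tp_cache`` holds the Clebsch–Gordan ⊗ spherical-harmonic edge kernels,
    filled lazily on first use and reused across epochs.
    """

    n_nodes: int
    species_idx: np.ndarray
    src_seg: SegmentIndex
    dst_seg: SegmentIndex
    rbf: np.ndarray
    sh: dict[int, np.ndarray]
    tp_cache: dict[tuple[int, int, int], np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_graph(
        cls,
        graph: NeighborGraph,
        species_to_idx: dict[str, int],
        n_basis: int,
    ) -> "GraphTensors":
        try:
            sp_idx = np.array([species_to_idx[s] for s in graph.species])
        except KeyError as exc:
            raise ValueError(f"species {exc.args[0]!r} not in model vocabulary") from None
        dist = graph.distances
        rbf = radial_basis(dist, graph.cutoff, n_basis)
        sh = {l: spherical_harmonics(l, graph.vectors) for l in _FILTER_LS}
        return cls(
            graph.n_nodes,
            sp_idx,
            SegmentIndex.build(graph.src, graph.n_nodes),
            SegmentIndex.build(graph.dst, graph.n_nodes),
            rbf,
            sh,
        )

    def species_segment(self, n_species: int) -> SegmentIndex:
        key = ("species_seg", n_species)
        if key not in self.tp_cache:
            self.tp_cache[key] = SegmentIndex.build(self.species_idx, n_species)
        return self.tp_cache[key]

    def tp_kernel(self, l1: int, l2: int, l3: int) -> np.ndarray:
        key = (l1, l2, l3)
        if key not in self.tp_cache:
            cg = clebsch_gordan(l1, l2, l3)
            self.tp_cache[key] = np.ascontiguousarray(
                np.einsum("kmn,en->ekm", cg, self.sh[l2])
            )
        return self.tp_cache[key]


@dataclass
class _Path:
    in_key: Irrep
    filter_l: int
    out_key: Irrep
    name: str


@dataclass
class _Layer:
    in_keys: list[Irrep]
    out_keys: list[Irrep]
    paths: list[_Path]
    lin_in_channels: dict[Irrep, int] = field(default_factory=dict)


class NetworkArchitecture:
    """Static architecture: path/parameter layout for given hyperparameters.

    Hidden features hold ``mult`` channels of every irrep reachable from
    scalar species embeddings at each depth (unreachable irreps would be
    identically zero and are omitted).
    """

    def __init__(
        self,
        species: list[str],
        n_layers: int = 2,
        mult: int = 20,
        n_basis: int = 8,
        avg_neighbors: float = 20.0,
    ):
        self.species = list(species)
        self.species_to_idx = {s: i for i, s in enumerate(self.species)}
        self.n_layers = n_layers
        self.mult = mult
        self.n_basis = n_basis
        self.avg_neighbors = float(avg_neighbors)
        self.layers: list[_Layer] = []
        current: list[Irrep] = [(0, 1)]
        for li in range(n_layers):
            # the last layer only produces what the parity-even rank-2
            # readout consumes; earlier layers keep every reachable irrep
            allowed = {(0, 1), (1, 1), (2, 1)} if li == n_layers - 1 else None
            paths = []
            out_set: set[Irrep] = set()
            for (l1, p1) in current:
                for l2 in _FILTER_LS:
                    p2 = (-1) ** l2
                    for l3 in range(abs(l1 - l2), min(_LMAX, l1 + l2) + 1):
                        key = (l3, p1 * p2)
                        if allowed is not None and key not in allowed:
                            continue
                        paths.append(
                            _Path((l1, p1), l2, key, f"L{li}.tp.{l1}{p1:+d}.f{l2}.{l3}{p1*p2:+d}")
                        )
                        out_set.add(key)
            out_keys = sorted(out_set, key=lambda k: (k[0], -k[1]))
            layer = _Layer(list(current), out_keys, paths)
            for key in out_keys:
                n_in = sum(1 for p in paths if p.out_key == key)
                if key in current:
                    n_in += 1  # self connection
                layer.lin_in_channels[key] = n_in * mult
            self.layers.append(layer)
            current = out_keys
        self.final_keys = current
        # readout: parity-even scalar / axial vector / deviator
        self.readout_keys = [k for k in [(0, 1), (1, 1), (2, 1)] if k in current]

    # -- parameters ---------------------------------------------------------

    def init_params(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        p: dict[str, np.ndarray] = {}
        p["embed"] = rng.standard_normal((len(self.species), self.mult))
        for li, layer in enumerate(self.layers):
            for path in layer.paths:
                p[path.name] = rng.standard_normal((self.mult, self.n_basis))
            for key in layer.out_keys:
                cin = layer.lin_in_channels[key]
                p[f"L{li}.lin.{key[0]}{key[1]:+d}"] = rng.standard_normal(
                    (self.mult, cin)
                )
                if key[0] > 0:
                    c0 = layer.lin_in_channels.get((0, 1), 0)
                    if c0:
                        p[f"L{li}.gate.{key[0]}{key[1]:+d}"] = rng.standard_normal(
                            (self.mult, c0)
                        )
        for key in self.readout_keys:
            p[f"out.{key[0]}{key[1]:+d}"] = rng.standard_normal((1, self.mult))
        return p

    # -- forward ------------------------------------------------------------

    def forward(
        self,
        g: GraphTensors,
        params: dict[str, Var],
        tape: Tape,
    ) -> Var:
        """Predict normalised irrep components, shape (n_atoms, 9).

        Component order: [scalar, axial x,y,z, deviator (5)] in the bases of
        :mod:`aptir.equivariant.o3`.
        """
        mult = self.mult
        edge_norm = 1.0 / np.sqrt(self.avg_neighbors * self.n_basis)
        ones1 = np.ones(1)

        x: dict[Irrep, Var] = {}
        emb = tape.gather(
            params["embed"], g.species_segment(params["embed"].value.shape[0])
        )                                                           # (N, mult)
        x[(0, 1)] = tape.einsum("nc,k->nck", emb, ones1)            # (N, mult, 1)

        for li, layer in enumerate(self.layers):
            gathered = {k: tape.gather(x[k], g.src_seg) for k in layer.in_keys}
            contrib: dict[Irrep, list[Var]] = {k: [] for k in layer.out_keys}
            for path in layer.paths:
                l1, _ = path.in_key
                l3, _ = path.out_key
                a = gathered[path.in_key]                           # (E, mult, 2l1+1)
                t = g.tp_kernel(l1, path.filter_l, l3)              # (E, 2l3+1, 2l1+1)
                msg = tape.bmm_const(a, t)                          # (E, mult, 2l3+1)
                w = tape.radial_weights(params[path.name], g.rbf)   # (E, mult)
                wmsg = tape.edge_scale(msg, w)
                agg = tape.scatter_add(wmsg, g.dst_seg)
                contrib[path.out_key].append(tape.scale(agg, edge_norm))
            for key in layer.in_keys:
                if key in contrib:
                    contrib[key].append(x[key])

            new_x: dict[Irrep, Var] = {}
            cat0 = tape.concat(contrib[(0, 1)], axis=1) if (0, 1) in contrib else None
            for key in layer.out_keys:
                cat = cat0 if key == (0, 1) else tape.concat(contrib[key], axis=1)
                cin = layer.lin_in_channels[key]
                lin = tape.channel_linear(
                    params[f"L{li}.lin.{key[0]}{key[1]:+d}"], cat
                )
                lin = tape.scale(lin, 1.0 / np.sqrt(cin))
                if key == (0, 1):
                    new_x[key] = tape.silu(lin)
                elif key == (0, -1):
                    new_x[key] = tape.tanh(lin)
                else:
                    if cat0 is None:
                        new_x[key] = lin
                    else:
                        s0 = tape.einsum("nck,k->nc", cat0, ones1)
                        gpre = tape.einsum(
                            "nc,oc->no", s0, params[f"L{li}.gate.{key[0]}{key[1]:+d}"]
                        )
                        gpre = tape.scale(gpre, 1.0 / np.sqrt(layer.lin_in_channels[(0, 1)]))
                        gate = tape.sigmoid(gpre)
                        new_x[key] = tape.node_scale(lin, gate)
            x = new_x

        parts: list[Var] = []
        for key in [(0, 1), (1, 1), (2, 1)]:
            dim = 2 * key[0] + 1
            if key in x and key in self.readout_keys:
                out = tape.channel_linear(params[f"out.{key[0]}{key[1]:+d}"], x[key])
                out = tape.scale(out, 1.0 / np.sqrt(mult))
                flat = tape.einsum("nok,o->nk", out, ones1)
            else:
                flat = tape.var(np.zeros((g.n_nodes, dim)))
            parts.append(flat)
        return tape.concat(parts, axis=1)                           # (N, 9)
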