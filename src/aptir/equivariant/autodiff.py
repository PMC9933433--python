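"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Supports exactly the operations the equivariant network needs: a generic
two-operand einsum (restricted so that every index of each operand appears
in the output or in the other operand — no implicit diagonals), BLAS-backed
specialisations for the hot paths (batched matmul against constant kernels,
channel-mixing linear maps, per-edge scaling), segment-sum gather/scatter
between node and edge arrays, concatenation, and the silu/sigmoid/tanh
nonlinearities.  Gradients are verified against central finite differences
in the test suite.

Gradient buffers are reference-shared until a second contribution arrives
(copy-on-accumulate), which keeps single-consumer chains allocation-free.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Tape", "Var", "SegmentIndex"]


class Var:
    __slots__ = ("value", "grad", "_own", "_backward", "_tape")

    def __init__(self, value: np.ndarray, tape: "Tape | None" = None):
        self.value = np.asarray(value, dtype=float)
        self.grad: np.ndarray | None = None
        self._own = False
        self._backward = None
        self._tape = tape

    @property
    def shape(self):
        return self.value.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g
            self._own = False
        elif self._own:
            self.grad += g
        else:
            self.grad = self.grad + g
            self._own = True


@dataclass
class SegmentIndex:
    """Edge↔node index bundle for one direction of an edge list.

    ``idx`` maps edge → node.  ``perm`` sorts edges by node, ``starts`` are
    the segment offsets into the sorted order, and ``nodes`` the node ids
    owning each segment (nodes without edges are simply absent).  When
    ``presorted`` the edge list itself is already node-sorted and ``perm``
    is not applied.
    """

    idx: np.ndarray
    n_nodes: int
    perm: np.ndarray
    starts: np.ndarray
    nodes: np.ndarray
    presorted: bool

    @classmethod
    def build(cls, idx: np.ndarray, n_nodes: int) -> "SegmentIndex":
        idx = np.asarray(idx)
        presorted = bool(np.all(np.diff(idx) >= 0)) if len(idx) else True
        perm = np.arange(len(idx)) if presorted else np.argsort(idx, kind="stable")
        sorted_idx = idx if presorted else idx[perm]
        counts = np.bincount(sorted_idx, minlength=n_nodes)
        nodes = np.nonzero(counts)[0]
        starts = np.concatenate([[0], np.cumsum(counts)])[:-1][nodes]
        return cls(idx, n_nodes, perm, starts, nodes, presorted)

    def segment_sum(self, x: np.ndarray) -> np.ndarray:
        out = np.zeros((self.n_nodes,) + x.shape[1:])
        if len(self.idx):
            data = x if self.presorted else x[self.perm]
            out[self.nodes] = np.add.reduceat(data, self.starts, axis=0)
        return out


class Tape:
    """Records operations in execution order; backward replays them reversed."""

    def __init__(self) -> None:
        self._ops: list[Var] = []

    def var(self, value: np.ndarray) -> Var:
        return Var(value, self)

    def _record(self, out: Var, backward) -> Var:
        out._backward = backward
        self._ops.append(out)
        return out

    def backward(self, loss: Var) -> None:
        if loss.value.shape != ():
            raise ValueError("backward expects a scalar loss")
        loss.accumulate(np.ones(()))
        for node in reversed(self._ops):
            if node.grad is not None and node._backward is not None:
                node._backward(node.grad)

    # -- generic einsum -----------------------------------------------------

    def einsum(self, spec: str, a: Var, b) -> Var:
        """C = einsum(spec, a, b); ``b`` may be a constant ndarray."""
        ins, out_sub = spec.split("->")
        sa, sb = ins.split(",")
        b_val = b.value if isinstance(b, Var) else np.asarray(b, dtype=float)
        if not set(sa) <= set(out_sub) | set(sb):
            raise ValueError(f"unsupported einsum for autodiff: {spec}")
        if isinstance(b, Var) and not set(sb) <= set(out_sub) | set(sa):
            raise ValueError(f"unsupported einsum for autodiff: {spec}")
        out = Var(np.einsum(spec, a.value, b_val), self)

        def backward(g):
            a.accumulate(np.einsum(f"{out_sub},{sb}->{sa}", g, b_val))
            if isinstance(b, Var):
                b.accumulate(np.einsum(f"{out_sub},{sa}->{sb}", g, a.value))

        return self._record(out, backward)

    # -- BLAS-backed specialisations ---------------------------------------

    def bmm_const(self, a: Var, kernel: np.ndarray) -> Var:
        """out[e,c,k] = Σ_m a[e,c,m] · kernel[e,k,m] (kernel constant)."""
        out = Var(np.einsum("ecm,ekm->eck", a.value, kernel), self)
        out._backward = lambda g: a.accumulate(np.einsum("eck,ekm->ecm", g, kernel))
        self._ops.append(out)
        return out

    def channel_linear(self, w: Var, x: Var) -> Var:
        """out[n,o,k] = Σ_c w[o,c] · x[n,c,k]."""
        out = Var(np.matmul(w.value, x.value), self)

        def backward(g):
            w.accumulate(np.tensordot(g, x.value, axes=([0, 2], [0, 2])))
            x.accumulate(np.matmul(w.value.T, g))

        return self._record(out, backward)

    def radial_weights(self, w: Var, rbf: np.ndarray) -> Var:
        """out[e,c] = Σ_b w[c,b] · rbf[e,b] (rbf constant)."""
        out = Var(rbf @ w.value.T, self)
        out._backward = lambda g: w.accumulate(g.T @ rbf)
        self._ops.append(out)
        return out

    def edge_scale(self, x: Var, w: Var) -> Var:
        """out[e,c,k] = x[e,c,k] · w[e,c]."""
        out = Var(x.value * w.value[:, :, None], self)

        def backward(g):
            x.accumulate(g * w.value[:, :, None])
            w.accumulate(np.einsum("eck,eck->ec", g, x.value))

        return self._record(out, backward)

    def node_scale(self, x: Var, w: Var) -> Var:
        """out[n,o,k] = x[n,o,k] · w[n,o]."""
        out = Var(x.value * w.value[:, :, None], self)

        def backward(g):
            x.accumulate(g * w.value[:, :, None])
            w.accumulate(np.einsum("nok,nok->no", g, x.value))

        return self._record(out, backward)

    # -- node/edge indexing -------------------------------------------------

    def gather(self, x: Var, seg: SegmentIndex) -> Var:
        """Edge-indexed view x[seg.idx]; backward is a segment sum."""
        out = Var(x.value[seg.idx], self)
        out._backward = lambda g: x.accumulate(seg.segment_sum(g))
        self._ops.append(out)
        return out

    def scatter_add(self, x: Var, seg: SegmentIndex) -> Var:
        """Sum edge rows onto nodes; backward is a gather."""
        out = Var(seg.segment_sum(x.value), self)
        out._backward = lambda g: x.accumulate(g[seg.idx])
        self._ops.append(out)
        return out

    # -- elementwise --------------------------------------------------------

    def add(self, a: Var, b: Var) -> Var:
        out = Var(a.value + b.value, self)

        def backward(g):
            a.accumulate(g)
            b.accumulate(g)

        return self._record(out, backward)

    def scale(self, a: Var, c: float) -> Var:
        out = Var(a.value * c, self)
        out._backward = lambda g: a.accumulate(g * c)
        self._ops.append(out)
        return out

    def concat(self, parts: list[Var], axis: int = 1) -> Var:
        out = Var(np.concatenate([p.value for p in parts], axis=axis), self)
        sizes = [p.value.shape[axis] for p in parts]
        splits = np.cumsum(sizes)[:-1]

        def backward(g):
            for p, piece in zip(parts, np.split(g, splits, axis=axis)):
                p.accumulate(piece)

        return self._record(out, backward)

    def silu(self, a: Var) -> Var:
        sig = 1.0 / (1.0 + np.exp(-a.value))
        out = Var(a.value * sig, self)
        out._backward = lambda g: a.accumulate(g * sig * (1.0 + a.value * (1.0 - sig)))
        self._ops.append(out)
        return out

    def sigmoid(self, a: Var) -> Var:
        sig = 1.0 / (1.0 + np.exp(-a.value))
        out = Var(sig, self)
        out._backward = lambda g: a.accumulate(g * sig * (1.0 - sig))
        self._ops.append(out)
        return out

    def tanh(self, a: Var) -> Var:
        th = np.tanh(a.value)
        out = Var(th, self)
        out._backward = lambda g: a.accumulate(g * (1.0 - th * th))
        self._ops.append(out)
        return out

    def mse(self, a: Var, target: np.ndarray) -> Var:
        """Mean squared deviation over all entries."""
        diff = a.value - target
        out = Var(np.asarray((diff * diff).mean()), self)
        out._backward = lambda g: a.accumulate(g * 2.0 * diff / diff.size)
        self._ops.append(out)
        return out
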