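"""Model/Results API for atomic-polar-tensor regression.

`AtomicPolarTensorModel` wraps a labelled dataset plus hyperparameters;
`fit()` trains the equivariant network (Adam, initial learning rate 0.01,
reduced by 0.1 when the validation MSE plateaus for 10 epochs) and returns
an `APTModelResults` carrying the learned weights, the per-epoch history,
normalisers and provenance; prediction, evaluation and plotting hang off the
results object, in the spirit of statsmodels.

Targets are conditioned per species in an equivariance-preserving way: the
isotropic mean (species-mean trace/3 times the identity) is subtracted and a
single scalar standard deviation per species divides all components.  Both
are computed on the training split only, stored with the results, and
inverted at prediction time, so the composed predictor remains exactly
equivariant.  Reported MSEs are always in raw units of e².
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..graph import build_graph
from ..io import APTDataset, APTFrame, AtomicConfiguration
from .autodiff import Tape, Var
from .network import GraphTensors, NetworkArchitecture
from .o3 import irreps_to_tensor, tensor_to_irreps

__all__ = [
    "ModelHyperparams",
    "TrainConfig",
    "AtomicPolarTensorModel",
    "APTModelResults",
    "EvaluationReport",
]


@dataclass
class ModelHyperparams:
    """Architecture knobs.

    cutoff (Å) bounds the neighbor graph; mult is the channel multiplicity
    per irrep (the reference configuration uses 20 channels of each of
    ranks 0, 1, 2 in both parities); n_layers message-passing layers.
    """

    cutoff: float = 6.0
    n_layers: int = 2
    mult: int = 20
    n_basis: int = 8
    seed: int = 0
    graph_method: str = "auto"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        if self.n_layers < 1:
            raise ValueError("need at least one message-passing layer")
        if self.mult < 1 or self.n_basis < 1:
            raise ValueError("multiplicities must be >= 1")


@dataclass
class TrainConfig:
    """Optimisation protocol (Adam + reduce-on-plateau)."""

    initial_lr: float = 0.01
    plateau_factor: float = 0.1
    plateau_patience: int = 10
    max_epochs: int = 100
    min_lr: float = 1e-6
    seed: int | None = None  # defaults to the model seed

    def __post_init__(self) -> None:
        if not 0.0 < self.plateau_factor < 1.0:
            raise ValueError("plateau_factor must lie in (0, 1)")
        if self.plateau_patience < 1:
            raise ValueError("plateau_patience must be >= 1")


@dataclass
class _Normalizer:
    """Per-species isotropic shift (e) and scalar scale (e)."""

    species: list[str]
    mean_iso: np.ndarray
    scale: np.ndarray

    def encode(self, tensors: np.ndarray, sp_idx: np.ndarray) -> np.ndarray:
        centred = tensors - self.mean_iso[sp_idx, None, None] * np.eye(3)
        s, w, v = tensor_to_irreps(centred)
        return np.concatenate([s, w, v], axis=1) / self.scale[sp_idx, None]

    def decode(self, comp9: np.ndarray, sp_idx: np.ndarray) -> np.ndarray:
        scaled = comp9 * self.scale[sp_idx, None]
        p = irreps_to_tensor(scaled[:, :1], scaled[:, 1:4], scaled[:, 4:])
        return p + self.mean_iso[sp_idx, None, None] * np.eye(3)


def _dataset_hash(ds: APTDataset) -> str:
    h = hashlib.sha256()
    for cfg, apt in ds.records:
        h.update(np.ascontiguousarray(cfg.positions).tobytes())
        h.update(np.ascontiguousarray(apt.tensors).tobytes())
    return h.hexdigest()[:16]


@dataclass
class EvaluationReport:
    """Component-wise errors of predicted against reference tensors (e)."""

    mse: float
    rmse: float
    per_species_rmse: dict[str, float]
    scatter: dict[str, tuple[np.ndarray, np.ndarray]]

    def __repr__(self) -> str:  # pragma: no cover
        sp = ", ".join(f"{k}: {v:.3e}" for k, v in self.per_species_rmse.items())
        return f"EvaluationReport(rmse={self.rmse:.4e} e, per-species {{{sp}}})"


class AtomicPolarTensorModel:
    """Equivariant regression of per-atom polar tensors from local structure."""

    def __init__(self, dataset: APTDataset, hyperparams: ModelHyperparams | None = None):
        if not any(s == "train" for s in dataset.split_labels):
            raise ValueError("dataset has no 'train' split; call split_dataset first")
        if not any(s == "validation" for s in dataset.split_labels):
            raise ValueError("dataset has no 'validation' split")
        self.dataset = dataset
        self.hp = hyperparams or ModelHyperparams()
        self.species = dataset.species_vocabulary()

        self._train = dataset.subset("train")
        self._val = dataset.subset("validation")
        self._graphs: dict[str, list[GraphTensors]] = {}
        self._targets: dict[str, list[np.ndarray]] = {}
        self._sp_idx: dict[str, list[np.ndarray]] = {}

        # degree normalisation: a fixed constant taken from the training data,
        # so predictions stay strictly local (no global graph statistics)
        degs = []
        sp_map = {s: i for i, s in enumerate(self.species)}
        for name, sub in (("train", self._train), ("validation", self._val)):
            gts, tgts, spi = [], [], []
            for cfg, apt in sub.records:
                graph = build_graph(cfg, self.hp.cutoff, self.hp.graph_method)
                gts.append(GraphTensors.from_graph(graph, sp_map, self.hp.n_basis))
                tgts.append(apt.tensors)
                spi.append(np.array([sp_map[s] for s in cfg.species]))
                degs.append(graph.n_edges / max(graph.n_nodes, 1))
            self._graphs[name] = gts
            self._targets[name] = tgts
            self._sp_idx[name] = spi
        avg_neighbors = max(float(np.mean(degs)), 1.0)

        self.arch = NetworkArchitecture(
            self.species,
            n_layers=self.hp.n_layers,
            mult=self.hp.mult,
            n_basis=self.hp.n_basis,
            avg_neighbors=avg_neighbors,
        )
        self.normalizer = self._fit_normalizer()

    def _fit_normalizer(self) -> _Normalizer:
        n_sp = len(self.species)
        mean_iso = np.zeros(n_sp)
        scale = np.ones(n_sp)
        all_t = np.concatenate(self._targets["train"])
        all_s = np.concatenate(self._sp_idx["train"])
        for i in range(n_sp):
            t = all_t[all_s == i]
            mean_iso[i] = np.einsum("naa->n", t).mean() / 3.0
            dev = t - mean_iso[i] * np.eye(3)
            scale[i] = max(np.sqrt((dev**2).mean()), 1e-12)
        return _Normalizer(list(self.species), mean_iso, scale)

    # -- fitting ------------------------------------------------------------

    def fit(self, train_config: TrainConfig | None = None) -> "APTModelResults":
        tc = train_config or TrainConfig()
        seed = self.hp.seed if tc.seed is None else tc.seed
        rng = np.random.default_rng(seed)
        params = self.arch.init_params(rng)
        norm = self.normalizer
        enc = {
            name: [
                norm.encode(t, s)
                for t, s in zip(self._targets[name], self._sp_idx[name])
            ]
            for name in ("train", "validation")
        }

        adam_m = {k: np.zeros_like(v) for k, v in params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in params.items()}
        adam_t = 0
        lr = tc.initial_lr
        best_val = np.inf
        stale = 0
        history = []
        n_train = len(self._graphs["train"])

        for epoch in range(tc.max_epochs):
            order = rng.permutation(n_train)
            train_se = 0.0
            train_n = 0
            for j in order:
                g = self._graphs["train"][j]
                tape = Tape()
                pvars = {k: Var(v, tape) for k, v in params.items()}
                pred = self.arch.forward(g, pvars, tape)
                loss = tape.mse(pred, enc["train"][j])
                if not np.isfinite(loss.value):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}, batch {j}"
                    )
                tape.backward(loss)
                adam_t += 1
                b1, b2, eps = 0.9, 0.999, 1e-8
                for k in params:
                    gk = pvars[k].grad
                    if gk is None:
                        continue
                    adam_m[k] = b1 * adam_m[k] + (1 - b1) * gk
                    adam_v[k] = b2 * adam_v[k] + (1 - b2) * gk * gk
                    mhat = adam_m[k] / (1 - b1**adam_t)
                    vhat = adam_v[k] / (1 - b2**adam_t)
                    params[k] = params[k] - lr * mhat / (np.sqrt(vhat) + eps)
                # raw-unit squared error of this batch (e²)
                err = (pred.value - enc["train"][j]) * norm.scale[
                    self._sp_idx["train"][j], None
                ]
                train_se += (err**2).sum()
                train_n += err.size
            val_mse = self._raw_mse(params, "validation")
            history.append(
                {"epoch": epoch, "train_mse": train_se / train_n,
                 "val_mse": val_mse, "lr": lr}
            )
            if val_mse < best_val:
                best_val = val_mse
                stale = 0
            else:
                stale += 1
                if stale > tc.plateau_patience:
                    lr = max(lr * tc.plateau_factor, tc.min_lr)
                    stale = 0

        return APTModelResults(
            model=self,
            params=params,
            history=pd.DataFrame(history),
            train_config=tc,
            provenance={
                "dataset_hash": _dataset_hash(self.dataset),
                "seed": seed,
                "n_train_configs": n_train,
                "n_train_apts": int(self._train.n_apts),
            },
        )

    def _raw_mse(self, params: dict[str, np.ndarray], which: str) -> float:
        norm = self.normalizer
        se, n = 0.0, 0
        for g, t, s in zip(
            self._graphs[which], self._targets[which], self._sp_idx[which]
        ):
            tape = Tape()
            pvars = {k: Var(v, tape) for k, v in params.items()}
            pred = self.arch.forward(g, pvars, tape).value
            err = (pred - norm.encode(t, s)) * norm.scale[s, None]
            se += (err**2).sum()
            n += err.size
        return se / n

    @classmethod
    def from_dataset(cls, dataset: APTDataset, **hyper) -> "AtomicPolarTensorModel":
        return cls(dataset, ModelHyperparams(**hyper))


class APTModelResults:
    """Fitted model: weights, history, normalisers, prediction and scoring."""

    def __init__(self, model, params, history, train_config, provenance):
        self.model = model
        self.params = params
        self.history = history
        self.train_config = train_config
        self.provenance = provenance

    # -- inference ----------------------------------------------------------

    def predict(self, config: AtomicConfiguration) -> APTFrame:
        """Predict one 3×3 polar tensor (e) per atom of a configuration."""
        arch = self.model.arch
        graph = build_graph(config, self.model.hp.cutoff, self.model.hp.graph_method)
        g = GraphTensors.from_graph(graph, arch.species_to_idx, arch.n_basis)
        tape = Tape()
        pvars = {k: Var(v, tape) for k, v in self.params.items()}
        comp9 = arch.forward(g, pvars, tape).value
        sp_idx = np.array([arch.species_to_idx[s] for s in config.species])
        return APTFrame(self.model.normalizer.decode(comp9, sp_idx))

    def predict_trajectory(self, frames) -> list[APTFrame]:
        return [self.predict(f) for f in frames]

    def evaluate(self, records) -> EvaluationReport:
        """Component-wise MSE/RMSE (e) of predictions against reference APTs.

        ``records`` is an APTDataset or an iterable of (configuration,
        APTFrame) pairs; the RMSE is over all nine Cartesian components of
        all atoms, and scatter data are grouped by species as in a
        predicted-vs-reference component plot.
        """
        if isinstance(records, APTDataset):
            records = records.records
        records = list(records)
        if not records:
            raise ValueError("cannot evaluate on an empty record set")
        per_sp_pred: dict[str, list[np.ndarray]] = {}
        per_sp_ref: dict[str, list[np.ndarray]] = {}
        se, n = 0.0, 0
        for cfg, apt in records:
            pred = self.predict(cfg).tensors
            err = pred - apt.tensors
            se += (err**2).sum()
            n += err.size
            for sp in set(cfg.species):
                mask = np.array([s == sp for s in cfg.species])
                per_sp_pred.setdefault(sp, []).append(pred[mask].reshape(-1, 9))
                per_sp_ref.setdefault(sp, []).append(apt.tensors[mask].reshape(-1, 9))
        scatter = {
            sp: (np.concatenate(per_sp_pred[sp]), np.concatenate(per_sp_ref[sp]))
            for sp in per_sp_pred
        }
        per_rmse = {
            sp: float(np.sqrt(((p - r) ** 2).mean())) for sp, (p, r) in scatter.items()
        }
        mse = se / n
        return EvaluationReport(float(mse), float(np.sqrt(mse)), per_rmse, scatter)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        hp = self.model.hp
        h = self.history
        lines = [
            "Atomic polar tensor regression results",
            "=" * 54,
            f"species vocabulary : {', '.join(self.model.species)}",
            f"cutoff / layers    : {hp.cutoff} Å / {hp.n_layers}",
            f"channels per irrep : {hp.mult} (radial basis {hp.n_basis})",
            f"parameters         : {sum(v.size for v in self.params.values())}",
            f"training APTs      : {self.provenance['n_train_apts']}",
            f"epochs             : {len(h)}",
            f"final train MSE    : {h['train_mse'].iloc[-1]:.6e} e²",
            f"final val MSE      : {h['val_mse'].iloc[-1]:.6e} e²",
            f"final lr           : {h['lr'].iloc[-1]:.2e}",
            f"dataset hash       : {self.provenance['dataset_hash']}",
            f"seed               : {self.provenance['seed']}",
        ]
        return "\n".join(lines)

    def plot_history(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy(self.history["epoch"], self.history["train_mse"], label="train")
        ax.semilogy(self.history["epoch"], self.history["val_mse"], label="validation")
        ax.set_xlabel("epoch")
        ax.set_ylabel(r"MSE / e$^2$")
        ax.legend()
        return ax

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "hyperparams": {
                "cutoff": self.model.hp.cutoff,
                "n_layers": self.model.hp.n_layers,
                "mult": self.model.hp.mult,
                "n_basis": self.model.hp.n_basis,
                "seed": self.model.hp.seed,
                "graph_method": self.model.hp.graph_method,
            },
            "species": self.model.species,
            "avg_neighbors": self.model.arch.avg_neighbors,
            "provenance": self.provenance,
        }
        arrays = {f"param::{k}": v for k, v in self.params.items()}
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            norm_mean_iso=self.model.normalizer.mean_iso,
            norm_scale=self.model.normalizer.scale,
            history=self.history.to_numpy(),
            history_cols=np.array(list(self.history.columns), dtype="U16"),
            **arrays,
        )

    @staticmethod
    def load(path) -> "APTModelResults":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(bytes(f["__meta__"].tolist()).decode())
            params = {
                k[len("param::"):]: f[k] for k in f.files if k.startswith("param::")
            }
            history = pd.DataFrame(f["history"], columns=list(f["history_cols"]))
            norm = _Normalizer(
                list(meta["species"]), f["norm_mean_iso"], f["norm_scale"]
            )
        hp = ModelHyperparams(**meta["hyperparams"])
        shell = _PredictorShell(meta["species"], hp, norm, meta["avg_neighbors"])
        return APTModelResults(
            model=shell,
            params=params,
            history=history,
            train_config=None,
            provenance=meta["provenance"],
        )


class _PredictorShell:
    """Stand-in model for checkpoints loaded without their training dataset."""

    def __init__(self, species, hp, normalizer, avg_neighbors):
        self.species = list(species)
        self.hp = hp
        self.normalizer = normalizer
        self.arch = NetworkArchitecture(
            self.species,
            n_layers=hp.n_layers,
            mult=hp.mult,
            n_basis=hp.n_basis,
            avg_neighbors=avg_neighbors,
        )
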