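"""Shared fixtures and independent numerical oracles."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings as _hyp_settings

_hyp_settings.register_profile("deterministic", derandomize=True, deadline=None)
_hyp_settings.load_profile("deterministic")

from aptir import (
    APTDataset,
    AtomicPolarTensorModel,
    ModelHyperparams,
    TrainConfig,
    split_dataset,
)
from aptir.synthetic import (
    ToyDipoleModel,
    generate_water_box,
    make_dipole_backend,
    make_labelled_dataset,
)


def richardson_derivative(f, x0: float, h: float = 0.02, levels: int = 4) -> float:
    """High-order numerical derivative of a scalar function (Richardson
    extrapolation of central differences); independent oracle for all
    finite-difference code paths."""
    table = np.empty((levels, levels))
    for i in range(levels):
        hi = h / 2**i
        table[i, 0] = (f(x0 + hi) - f(x0 - hi)) / (2 * hi)
    for j in range(1, levels):
        for i in range(levels - j):
            table[i, j] = (4**j * table[i + 1, j - 1] - table[i, j - 1]) / (4**j - 1)
    return table[0, levels - 1]


def brute_force_edges(config, cutoff: float, n_images: int = 2):
    """Naive neighbor enumeration over (2n+1)³ periodic images; the
    independent oracle for graph construction."""
    pos = config.positions
    n = config.n_atoms
    edges = set()
    shifts = range(-n_images, n_images + 1)
    for i in range(n):
        for j in range(n):
            for sa in shifts:
                for sb in shifts:
                    for sc in shifts:
                        if config.cell is None and (sa, sb, sc) != (0, 0, 0):
                            continue
                        shift = (
                            np.array([sa, sb, sc]) @ config.cell
                            if config.cell is not None
                            else np.zeros(3)
                        )
                        if i == j and (sa, sb, sc) == (0, 0, 0):
                            continue
                        d = pos[j] + shift - pos[i]
                        if np.linalg.norm(d) < cutoff:
                            edges.add((i, j, round(d[0], 9), round(d[1], 9), round(d[2], 9)))
    return edges


@pytest.fixture(scope="session")
def small_box():
    return generate_water_box(4, seed=10)


@pytest.fixture(scope="session")
def fluct_backend():
    return make_dipole_backend(ToyDipoleModel())


@pytest.fixture(scope="session")
def fixed_backend():
    return make_dipole_backend(ToyDipoleModel(variant="fixed"))


@pytest.fixture(scope="session")
def tiny_dataset() -> APTDataset:
    ds = make_labelled_dataset(6, 8, seed=21)
    return split_dataset(ds, 0.8, seed=21)


@pytest.fixture(scope="session")
def trained_results(tiny_dataset):
    """One modest fit shared by the prediction-contract tests."""
    model = AtomicPolarTensorModel(
        tiny_dataset, ModelHyperparams(cutoff=3.5, mult=6, n_basis=6, seed=3)
    )
    return model.fit(TrainConfig(max_epochs=30))
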