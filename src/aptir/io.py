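"""Core data types and file formats.

Geometry travels as extended XYZ (``Lattice=...`` and ``Properties=...`` keys
on the comment line, optional velocity columns); per-atom polar tensor
datasets are stored in a self-describing HDF5 container.  Everything else in
the package works on the in-memory types defined here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "AtomicConfiguration",
    "Trajectory",
    "APTFrame",
    "APTDataset",
    "IRSpectrumParams",
    "IRSpectrum",
    "read_trajectory",
    "write_trajectory",
    "read_apts",
    "write_apts",
    "split_dataset",
]


@dataclass
class AtomicConfiguration:
    """One snapshot: element symbols, Cartesian positions (Å), optional cell.

    ``cell`` holds the lattice vectors as rows; ``periodic_flags`` marks the
    periodic axes.  Positions are raw Cartesian coordinates — they are never
    wrapped implicitly, because wrapping is not a no-op for dipole surfaces.
    """

    species: list[str]
    positions: np.ndarray
    cell: np.ndarray | None = None
    periodic_flags: tuple[bool, bool, bool] = (False, False, False)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_atoms, 3)")
        if len(self.species) != len(self.positions):
            raise ValueError(
                f"species length {len(self.species)} != atom count {len(self.positions)}"
            )
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions contain non-finite entries")
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float)
            if self.cell.shape != (3, 3):
                raise ValueError("cell must be a 3x3 matrix")
            if any(self.periodic_flags) and abs(np.linalg.det(self.cell)) < 1e-12:
                raise ValueError("periodic cell is singular")

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    @property
    def periodic(self) -> bool:
        return self.cell is not None and any(self.periodic_flags)

    def copy(self) -> "AtomicConfiguration":
        return AtomicConfiguration(
            list(self.species),
            self.positions.copy(),
            None if self.cell is None else self.cell.copy(),
            tuple(self.periodic_flags),
        )


@dataclass
class Trajectory:
    """Time-ordered configurations with a uniform timestep (fs).

    ``velocities`` (Å/fs), when present, has shape (n_frames, n_atoms, 3) and
    comes from whatever produced the trajectory (an integrator, or a file's
    velocity columns).
    """

    frames: list[AtomicConfiguration]
    dt: float
    velocities: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.frames:
            raise ValueError("trajectory needs at least one frame")
        ref = self.frames[0].species
        for k, fr in enumerate(self.frames):
            if fr.species != ref:
                raise ValueError(
                    f"frame {k} has inconsistent species ordering or atom count"
                )
        if self.velocities is not None:
            self.velocities = np.asarray(self.velocities, dtype=float)
            expected = (len(self.frames), len(ref), 3)
            if self.velocities.shape != expected:
                raise ValueError(
                    f"velocities shape {self.velocities.shape} != {expected}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms

    def positions_array(self) -> np.ndarray:
        return np.stack([f.positions for f in self.frames])


@dataclass
class APTFrame:
    """Per-atom 3×3 atomic polar tensors (units of e) for one configuration."""

    tensors: np.ndarray
    config_id: str = ""

    def __post_init__(self) -> None:
        self.tensors = np.asarray(self.tensors, dtype=float)
        if self.tensors.ndim != 3 or self.tensors.shape[1:] != (3, 3):
            raise ValueError("tensors must have shape (n_atoms, 3, 3)")
        if not np.all(np.isfinite(self.tensors)):
            raise ValueError("APT tensors contain non-finite entries")

    @property
    def n_atoms(self) -> int:
        return self.tensors.shape[0]


@dataclass
class APTDataset:
    """Labelled records: (configuration, APT frame) pairs plus split tags.

    ``split_labels[i]`` is one of ``"train"``, ``"validation"``, ``"test"``
    or ``""`` (unassigned).  Splitting always acts on whole configurations.
    """

    records: list[tuple[AtomicConfiguration, APTFrame]] = field(default_factory=list)
    split_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.split_labels:
            self.split_labels = [""] * len(self.records)
        if len(self.split_labels) != len(self.records):
            raise ValueError("one split label per record required")
        for k, (cfg, apt) in enumerate(self.records):
            if cfg.n_atoms != apt.n_atoms:
                raise ValueError(
                    f"record {k}: {cfg.n_atoms} atoms but {apt.n_atoms} tensors"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_apts(self) -> int:
        return sum(cfg.n_atoms for cfg, _ in self.records)

    def subset(self, label: str) -> "APTDataset":
        recs = [r for r, s in zip(self.records, self.split_labels) if s == label]
        return APTDataset(recs, [label] * len(recs))

    def species_vocabulary(self) -> list[str]:
        seen: set[str] = set()
        for cfg, _ in self.records:
            seen.update(cfg.species)
        return sorted(seen)


@dataclass
class IRSpectrumParams:
    """Thermodynamic inputs of the absorption prefactor.

    temperature in K, volume in Å³.  When provided, spectra carry absolute
    n(ω)α(ω) in cm⁻¹; n(ω) is never separated from α(ω).
    """

    temperature: float
    volume: float

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.volume <= 0:
            raise ValueError("volume must be positive")


@dataclass
class IRSpectrum:
    """Wavenumber grid (cm⁻¹) against n(ω)α(ω)."""

    wavenumbers: np.ndarray
    intensity: np.ndarray
    absolute_units: bool = False

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.wavenumbers.shape != self.intensity.shape:
            raise ValueError("wavenumber and intensity grids differ in shape")
        if np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity contains non-finite values")

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.wavenumbers, self.intensity, **kwargs)
        ax.set_xlabel(r"wavenumber $\tilde\nu$ / cm$^{-1}$")
        ax.set_ylabel(
            r"$n(\omega)\alpha(\omega)$ / cm$^{-1}$"
            if self.absolute_units
            else "intensity / arb. u."
        )
        return ax


# ---------------------------------------------------------------------------
# extended XYZ
# ---------------------------------------------------------------------------

_KV_RE = re.compile(r'(\S+?)=(?:"([^"]*)"|(\S+))')


def _parse_comment(line: str) -> dict[str, str]:
    return {m.group(1): m.group(2) if m.group(2) is not None else m.group(3)
            for m in _KV_RE.finditer(line)}


def _parse_properties(spec: str) -> list[tuple[str, str, int]]:
    toks = spec.split(":")
    if len(toks) % 3:
        raise ValueError(f"malformed Properties spec: {spec!r}")
    out = []
    for i in range(0, len(toks), 3):
        out.append((toks[i], toks[i + 1], int(toks[i + 2])))
    return out


def read_trajectory(path, dt: float) -> Trajectory:
    """Read a (multi-frame) extended-XYZ file.

    The comment line of each frame may carry ``Lattice="ax ay az bx ..."``
    (row-major lattice vectors), ``pbc="T T F"`` and a ``Properties`` key;
    columns named ``vel`` or ``velo`` populate velocities (Å/fs).
    """
    frames: list[AtomicConfiguration] = []
    vels: list[np.ndarray] = []
    have_vel = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    idx = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            nat = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"frame {idx}: bad atom-count line {lines[i]!r}") from exc
        if i + 2 + nat > len(lines):
            raise ValueError(f"frame {idx}: truncated (expected {nat} atom lines)")
        keys = _parse_comment(lines[i + 1])
        cell = None
        pbc = (False, False, False)
        if "Lattice" in keys:
            vals = np.fromstring(keys["Lattice"], sep=" ")
            if vals.size != 9:
                raise ValueError(f"frame {idx}: Lattice needs 9 numbers")
            cell = vals.reshape(3, 3)
            pbc = (True, True, True)
        if "pbc" in keys:
            flags = keys["pbc"].replace('"', "").split()
            pbc = tuple(f.upper().startswith("T") for f in flags)
        props = _parse_properties(keys.get("Properties", "species:S:1:pos:R:3"))
        cols: dict[str, slice] = {}
        off = 0
        for name, _kind, width in props:
            cols[name] = slice(off, off + width)
            off += width
        body = [lines[i + 2 + k].split() for k in range(nat)]
        try:
            species = [row[cols["species"]][0] for row in body]
            pos = np.array(
                [[float(x) for x in row[cols["pos"]]] for row in body]
            )
        except (KeyError, IndexError, ValueError) as exc:
            raise ValueError(f"frame {idx}: malformed atom lines") from exc
        vel_key = "vel" if "vel" in cols else ("velo" if "velo" in cols else None)
        if have_vel is None:
            have_vel = vel_key is not None
        if (vel_key is not None) != have_vel:
            raise ValueError(f"frame {idx}: velocity columns present in some frames only")
        if vel_key:
            vels.append(
                np.array([[float(x) for x in row[cols[vel_key]]] for row in body])
            )
        frames.append(AtomicConfiguration(species, pos, cell, pbc))
        i += 2 + nat
        idx += 1
    if not frames:
        raise ValueError("no frames found")
    return Trajectory(frames, dt, np.stack(vels) if have_vel else None)


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory as extended XYZ (velocities included when present)."""
    with open(path, "w") as fh:
        for k, cfg in enumerate(traj.frames):
            fh.write(f"{cfg.n_atoms}\n")
            keys = []
            if cfg.cell is not None:
                flat = " ".join(f"{x:.12g}" for x in cfg.cell.ravel())
                keys.append(f'Lattice="{flat}"')
                keys.append(
                    'pbc="%s"' % " ".join("T" if f else "F" for f in cfg.periodic_flags)
                )
            props = "species:S:1:pos:R:3"
            if traj.velocities is not None:
                props += ":vel:R:3"
            keys.append(f"Properties={props}")
            fh.write(" ".join(keys) + "\n")
            for a in range(cfg.n_atoms):
                row = f"{cfg.species[a]:<2s} " + " ".join(
                    f"{x: .12e}" for x in cfg.positions[a]
                )
                if traj.velocities is not None:
                    row += " " + " ".join(f"{x: .12e}" for x in traj.velocities[k, a])
                fh.write(row + "\n")


# ---------------------------------------------------------------------------
# APT container (HDF5)
# ---------------------------------------------------------------------------

_FORMAT = "aptir-apt-container"


def write_apts(dataset: APTDataset, path) -> None:
    """Persist an APT dataset losslessly (geometry + tensors + split labels)."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = _FORMAT
        f.attrs["version"] = 1
        f.attrs["n_records"] = len(dataset)
        for k, ((cfg, apt), label) in enumerate(
            zip(dataset.records, dataset.split_labels)
        ):
            g = f.create_group(f"record_{k:06d}")
            g.create_dataset("species", data=np.array(cfg.species, dtype="S4"))
            g.create_dataset("positions", data=cfg.positions)
            if cfg.cell is not None:
                g.create_dataset("cell", data=cfg.cell)
                g.attrs["pbc"] = np.array(cfg.periodic_flags, dtype=bool)
            g.create_dataset("tensors", data=apt.tensors)
            g.attrs["split"] = label
            g.attrs["config_id"] = apt.config_id


def read_apts(path) -> APTDataset:
    records = []
    labels = []
    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != _FORMAT:
            raise ValueError(f"{path} is not an APT container file")
        n = int(f.attrs["n_records"])
        for k in range(n):
            g = f[f"record_{k:06d}"]
            species = [s.decode() for s in g["species"][...]]
            cell = g["cell"][...] if "cell" in g else None
            pbc = tuple(bool(x) for x in g.attrs.get("pbc", (False,) * 3))
            cfg = AtomicConfiguration(species, g["positions"][...], cell, pbc)
            apt = APTFrame(g["tensors"][...], str(g.attrs.get("config_id", "")))
            records.append((cfg, apt))
            labels.append(str(g.attrs.get("split", "")))
    return APTDataset(records, labels)


def split_dataset(
    dataset: APTDataset, train_fraction: float = 0.9, seed: int = 0
) -> APTDataset:
    """Assign train/validation labels by whole configuration.

    Deterministic for a given seed.  With ``n`` records, ``round(n * f)``
    (clipped so both sides are non-empty) go to training; the remainder is
    the held-out validation set.  Atoms never straddle splits — the split is
    configuration-wise, matching how snapshots are labelled in practice.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    n = len(dataset)
    if n < 2:
        raise ValueError("need at least 2 configurations to split")
    n_train = int(round(n * train_fraction))
    n_train = min(max(n_train, 1), n - 1)
    order = np.random.default_rng(seed).permutation(n)
    labels = [""] * n
    for j in order[:n_train]:
        labels[j] = "train"
    for j in order[n_train:]:
        labels[j] = "validation"
    return APTDataset(list(dataset.records), labels)
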