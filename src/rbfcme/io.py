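"""Serialization of runs, distributions and fixtures.

Runs are stored in a single HDF5 file (NPZ fallback when the ``.npz``
suffix is used): a manifest group with the model name, parameters, seeds
and software version; a per-step table of time / degrees of freedom /
mass / rejections; support masks; and the final distribution with its box
bounds.  The manifest is meant to suffice for re-running the experiment.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__ as _version
from .fullgrid import LatticeBox, LatticeDistribution
from .geometry import SupportMask
from .models import build_birth_death

__all__ = [
    "RunManifest",
    "write_run",
    "read_run",
    "save_basis",
    "load_basis",
    "make_fixture",
]


@dataclass
class RunManifest:
    """Reproducibility metadata for a stored run."""

    model: str
    params: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    version: str = _version
    extra: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def default(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return dataclasses.asdict(o)
            if isinstance(o, np.generic):
                return o.item()
            if isinstance(o, np.ndarray):
                return o.tolist()
            raise TypeError(f"cannot serialize {type(o)}")

        return json.dumps(dataclasses.asdict(self), default=default, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        data = json.loads(text)
        return cls(
            model=data["model"],
            params=data.get("params", {}),
            seeds=data.get("seeds", {}),
            version=data.get("version", ""),
            extra=data.get("extra", {}),
        )


def _log_table(log) -> np.ndarray:
    rows = [(r.t, r.dof, r.mass, r.discrepancy, r.rejects, r.components) for r in log.records]
    return np.array(rows, dtype=float).reshape(len(rows), 6)


def write_run(
    path: str | Path,
    manifest: RunManifest,
    log=None,
    distributions: dict[str, LatticeDistribution] | None = None,
    masks: dict[str, SupportMask] | None = None,
) -> Path:
    """Write a run bundle (HDF5, or NPZ if the path ends in .npz)."""
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"directory does not exist: {path.parent}")
    distributions = distributions or {}
    masks = masks or {}

    if path.suffix == ".npz":
        payload = {"manifest": np.bytes_(manifest.to_json().encode())}
        if log is not None:
            payload["log_table"] = _log_table(log)
        for name, dist in distributions.items():
            payload[f"dist_{name}_values"] = dist.values
            payload[f"dist_{name}_lower"] = np.array(dist.box.lower)
            payload[f"dist_{name}_upper"] = np.array(dist.box.upper)
        for name, m in masks.items():
            payload[f"mask_{name}_values"] = m.mask
            payload[f"mask_{name}_lower"] = np.array(m.box.lower)
            payload[f"mask_{name}_upper"] = np.array(m.box.upper)
        np.savez_compressed(path, **payload)
        return path

    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["manifest"] = manifest.to_json()
        f.attrs["config_hash"] = manifest.config_hash
        if log is not None:
            tbl = f.create_dataset("log/table", data=_log_table(log))
            tbl.attrs["columns"] = "t,dof,mass,discrepancy,rejects,components"
            f["log"].attrs["threshold_reductions"] = log.threshold_reductions
            f["log"].attrs["stationary"] = log.stationary
        for name, dist in distributions.items():
            g = f.create_group(f"distributions/{name}")
            g.create_dataset("values", data=dist.values)
            g.attrs["lower"] = dist.box.lower
            g.attrs["upper"] = dist.box.upper
        for name, m in masks.items():
            g = f.create_group(f"masks/{name}")
            g.create_dataset("values", data=m.mask)
            g.attrs["lower"] = m.box.lower
            g.attrs["upper"] = m.box.upper
    return path


def read_run(path: str | Path):
    """Read back a bundle written by :func:`write_run`.

    Returns (manifest, log_table or None, distributions, masks).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such run file: {path}")

    dists: dict[str, LatticeDistribution] = {}
    masks: dict[str, SupportMask] = {}
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as data:
            manifest = RunManifest.from_json(bytes(data["manifest"]).decode())
            table = data["log_table"] if "log_table" in data else None
            names = {k[5:-7] for k in data.files if k.startswith("dist_") and k.endswith("_values")}
            for name in names:
                box = LatticeBox(
                    tuple(int(v) for v in data[f"dist_{name}_lower"]),
                    tuple(int(v) for v in data[f"dist_{name}_upper"]),
                )
                dists[name] = LatticeDistribution(box, data[f"dist_{name}_values"])
            mnames = {k[5:-7] for k in data.files if k.startswith("mask_") and k.endswith("_values")}
            for name in mnames:
                box = LatticeBox(
                    tuple(int(v) for v in data[f"mask_{name}_lower"]),
                    tuple(int(v) for v in data[f"mask_{name}_upper"]),
                )
                masks[name] = SupportMask(box, data[f"mask_{name}_values"].reshape(box.shape))
        return manifest, table, dists, masks

    import h5py

    with h5py.File(path, "r") as f:
        manifest = RunManifest.from_json(f.attrs["manifest"])
        table = f["log/table"][...] if "log" in f else None
        if "distributions" in f:
            for name, g in f["distributions"].items():
                box = LatticeBox(
                    tuple(int(v) for v in g.attrs["lower"]),
                    tuple(int(v) for v in g.attrs["upper"]),
                )
                dists[name] = LatticeDistribution(box, g["values"][...])
        if "masks" in f:
            for name, g in f["masks"].items():
                box = LatticeBox(
                    tuple(int(v) for v in g.attrs["lower"]),
                    tuple(int(v) for v in g.attrs["upper"]),
                )
                masks[name] = SupportMask(box, g["values"][...].reshape(box.shape))
    return manifest, table, dists, masks


def save_basis(path: str | Path, basis) -> Path:
    """Store a basis system (centres and shape parameters, no factorization)."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez_compressed(path, centres=basis.centres, sigma=basis.sigma)
        return path
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("centres", data=basis.centres)
        f.create_dataset("sigma", data=basis.sigma)
    return path


def load_basis(path: str | Path):
    """Rebuild (and re-factorize) a basis stored by :func:`save_basis`."""
    from .rbf import make_basis

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such basis file: {path}")
    if path.suffix == ".npz":
        with np.load(path) as data:
            return make_basis(data["centres"], sigma=data["sigma"])
    import h5py

    with h5py.File(path, "r") as f:
        return make_basis(f["centres"][...], sigma=f["sigma"][...])


def make_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Deterministic test inputs.

    ``birth_death``: network + box + truncated-Poisson reference
    (params: lam, mu, N).
    ``gaussian_ic``: a lattice Gaussian distribution (params: box upper
    bound ``upper``, ``centre``, ``scale``).
    ``translating_mask``: a sequence of masks rigidly translated one cell
    per step (params: ``shape``, ``radius``, ``steps``, ``axis``).
    """
    from scipy import stats

    from .fullgrid import lattice_gaussian

    params = dict(params or {})

    if kind == "birth_death":
        lam = float(params.get("lam", 5.0))
        mu = float(params.get("mu", 1.0))
        N = int(params.get("N", 30))
        network = build_birth_death(lam, mu)
        box = LatticeBox((0,), (N,))
        k = np.arange(N + 1)
        ref = stats.poisson.pmf(k, lam / mu)
        ref = ref / ref.sum()
        return network, box, LatticeDistribution(box, ref)

    if kind == "gaussian_ic":
        upper = int(params.get("upper", 300))
        d = int(params.get("d", 2))
        centre = params.get("centre", (133,) * d)
        scale = float(params.get("scale", 266.0))
        box = LatticeBox.cube(len(tuple(centre)), upper)
        return lattice_gaussian(box, centre, scale, normalize=params.get("normalize", True))

    if kind == "translating_mask":
        shape = tuple(params.get("shape", (40, 40)))
        radius = float(params.get("radius", 4.0))
        steps = int(params.get("steps", 3))
        axis = int(params.get("axis", 0))
        start = params.get("start")
        box = LatticeBox(tuple(0 for _ in shape), tuple(s - 1 for s in shape))
        if start is None:
            start = tuple(int(s // 4) for s in shape)
        grid = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
        masks = []
        for step in range(steps):
            c = list(start)
            c[axis] += step
            r2 = sum((g - ci) ** 2 for g, ci in zip(grid, c))
            masks.append(SupportMask(box, r2 <= radius**2))
        return masks

    raise ValueError(f"unknown fixture kind: {kind!r}")
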