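"""Reading and writing the package's artifacts.

Connectivity matrices travel as Matrix Market sparse coordinate files
(1-based indices per the standard) plus a JSON sidecar carrying the
structural metadata (population labels, generator, seed, weight scale).
Covariance matrices are written as dense CSV or HDF5; stimulus models as
compact JSON (factor seed and strengths rather than raw vectors).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import scipy.io
import scipy.sparse

from .exceptions import ValidationError
from .linear_response import StimulusModel
from .networks import ConnectivityMatrix

__all__ = [
    "save_connectivity", "load_connectivity",
    "save_covariance", "load_covariance",
    "save_stimulus", "load_stimulus",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def save_connectivity(conn: ConnectivityMatrix, path) -> Path:
    """Write weights as .mtx plus a JSON metadata sidecar."""
    path = Path(path)
    scipy.io.mmwrite(str(path.with_suffix(".mtx")),
                     scipy.sparse.coo_matrix(conn.weights))
    meta = {
        "n_neurons": conn.n_neurons,
        "population": "".join(conn.population.tolist()),
        "generator": conn.generator,
        "seed": conn.seed,
        "meta": _jsonable(conn.meta),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path.with_suffix(".mtx")


def load_connectivity(path) -> ConnectivityMatrix:
    path = Path(path)
    W = np.asarray(scipy.io.mmread(str(path.with_suffix(".mtx"))).todense()) \
        if path.with_suffix(".mtx").exists() else None
    if W is None:
        raise ValidationError(f"no matrix market file at {path}")
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        pop = np.array(list(meta["population"]))
        return ConnectivityMatrix(weights=W, population=pop,
                                  generator=meta.get("generator", "unknown"),
                                  seed=meta.get("seed"),
                                  meta=meta.get("meta", {}))
    return ConnectivityMatrix(weights=W,
                              population=np.full(W.shape[0], "E", "<U1"))


def save_covariance(path, **matrices) -> Path:
    """Write named covariance matrices to .h5 (or a single one to .csv)."""
    path = Path(path)
    if path.suffix == ".csv":
        if len(matrices) != 1:
            raise ValidationError("CSV output holds exactly one matrix")
        (name, M), = matrices.items()
        np.savetxt(path, M, delimiter=",")
        return path
    import h5py
    with h5py.File(path, "w") as f:
        for name, M in matrices.items():
            f.create_dataset(name, data=np.asarray(M), compression="gzip")
    return path


def load_covariance(path, name: str | None = None):
    path = Path(path)
    if path.suffix == ".csv":
        return np.loadtxt(path, delimiter=",")
    import h5py
    with h5py.File(path, "r") as f:
        if name is not None:
            return f[name][()]
        return {k: f[k][()] for k in f}


def save_stimulus(stim: StimulusModel, path, seed: int | None = None,
                  n_neurons: int | None = None) -> Path:
    """JSON stimulus description.

    If the factors came from :meth:`StimulusModel.random`, pass the seed to
    store the compact (seed, strengths) form; otherwise raw vectors are
    stored.
    """
    path = Path(path)
    doc: dict = {"strengths": stim.strengths.tolist()}
    if seed is not None:
        doc.update({"seed": seed, "n_neurons": n_neurons
                    or stim.factors.shape[1],
                    "n_factors": stim.n_factors})
    else:
        doc["factors"] = stim.factors.tolist()
    path.write_text(json.dumps(doc))
    return path


def load_stimulus(path) -> StimulusModel:
    doc = json.loads(Path(path).read_text())
    strengths = np.asarray(doc["strengths"], dtype=float)
    if "factors" in doc:
        return StimulusModel(factors=np.asarray(doc["factors"]),
                             strengths=strengths)
    return StimulusModel.random(doc["n_neurons"], doc["n_factors"],
                                strengths, seed=doc["seed"])


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
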