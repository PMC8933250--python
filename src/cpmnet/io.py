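"""Readers and writers for the pipeline's plain-text file formats.

All formats are UTF-8 delimited text (comma by default) with mandatory
header rows.  Node indices are 1-based in files and converted to the
package's 0-based internal convention on read.  ``write(read(x))`` is
value-identical for every format; malformed files are rejected with
messages naming the offending line, cell or column.

Formats
-------
matrix        square numeric table; node labels as header row and first column
time series   one row per volume, one column per node; optional ``fd`` column
phenotypes    one row per subject; ``subject_id`` and ``score`` mandatory
partition     two columns: 1-based node index, network label
model         JSON with masks (1-based edge lists), coefficients, metadata
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ._exceptions import ConfigError, InputError
from .anatomy import NetworkPartition
from .connectome import ConnectivityMatrix, ParcelTimeSeries
from .cpm import CpmModel, EdgeMask

__all__ = [
    "RunConfig",
    "read_matrix",
    "write_matrix",
    "read_timeseries",
    "write_timeseries",
    "read_phenotypes",
    "write_phenotypes",
    "read_partition",
    "write_partition",
    "read_model",
    "write_model",
    "write_manifest",
]

MODEL_FORMAT_VERSION = 1
_SYMMETRY_TOL = 1e-8


@dataclass
class RunConfig:
    """One pipeline run's inputs, parameters and output location.

    Serialized as YAML key-value text; ``validate`` checks that every
    referenced path exists and that a seed is present whenever a stochastic
    step (permutation) is enabled.
    """

    matrices_dir: str | None = None
    timeseries_dir: str | None = None
    phenotypes: str | None = None
    partition: str | None = None
    output_dir: str = "."
    covariates: list[str] = field(
        default_factory=lambda: ["age", "gender", "duration"]
    )
    fd_threshold: float = 0.2
    min_volumes: int = 120
    p_threshold: float | None = None
    n_perm: int = 0
    seed: int | None = None

    def validate(self) -> None:
        for name in ("matrices_dir", "timeseries_dir", "phenotypes", "partition"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                raise ConfigError(f"{name}: path {value!r} does not exist")
        if self.fd_threshold <= 0:
            raise ConfigError("fd_threshold must be positive")
        if self.n_perm > 0 and self.seed is None:
            raise ConfigError("seed is required when permutation is enabled")

    def to_yaml(self, path) -> None:
        data = {k: v for k, v in self.__dict__.items() if v is not None}
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: run config is not a key-value mapping")
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(f"{path}: unrecognized run config field: {exc}") from exc


def _node_labels(n: int) -> list[str]:
    return [f"n{k + 1:04d}" for k in range(n)]


def write_matrix(matrix: ConnectivityMatrix, path, sep: str = ",") -> None:
    labels = _node_labels(matrix.n_nodes)
    df = pd.DataFrame(matrix.z, index=labels, columns=labels)
    df.to_csv(path, sep=sep)


def read_matrix(path, subject_id: str | None = None, sep: str = ",") -> ConnectivityMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise InputError(
            f"{path}: matrix is {df.shape[0]}x{df.shape[1]}, expected square"
        )
    z = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(z)):
        bad = np.argwhere(~np.isfinite(z))[0]
        raise InputError(f"{path}: non-finite value at cell ({bad[0] + 1}, {bad[1] + 1})")
    asym = np.abs(z - z.T)
    if asym.max() > _SYMMETRY_TOL:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise InputError(
            f"{path}: asymmetric beyond {_SYMMETRY_TOL} at cell "
            f"({i + 1}, {j + 1}): {z[i, j]} vs {z[j, i]}"
        )
    sid = subject_id if subject_id is not None else Path(path).stem
    return ConnectivityMatrix(sid, (z + z.T) / 2.0)


def write_timeseries(ts: ParcelTimeSeries, path, sep: str = ",") -> None:
    labels = ts.node_labels or _node_labels(ts.n_nodes)
    df = pd.DataFrame(ts.signal, columns=labels)
    df["fd"] = ts.fd
    df.to_csv(path, sep=sep, index=False)


def read_timeseries(
    path, subject_id: str | None = None, fd_path=None, sep: str = ","
) -> ParcelTimeSeries:
    """Read a time-series table; FD comes from an ``fd`` column or a companion file."""
    df = pd.read_csv(path, sep=sep)
    if df.shape[0] == 0:
        raise InputError(f"{path}: time series has no volumes")
    if "fd" in df.columns:
        fd = df.pop("fd").to_numpy(dtype=float)
    elif fd_path is not None:
        fd_df = pd.read_csv(fd_path, sep=sep)
        if fd_df.shape[1] != 1:
            raise InputError(f"{fd_path}: FD companion file must have one column")
        fd = fd_df.iloc[:, 0].to_numpy(dtype=float)
        if fd.size != df.shape[0]:
            raise InputError(
                f"{fd_path}: {fd.size} FD rows for {df.shape[0]} volumes"
            )
    else:
        raise InputError(f"{path}: no 'fd' column and no companion FD file given")
    sid = subject_id if subject_id is not None else Path(path).stem
    return ParcelTimeSeries(sid, df.to_numpy(dtype=float), fd,
                            node_labels=list(df.columns))


REQUIRED_PHENOTYPE_COLUMNS = ("subject_id", "score")


def write_phenotypes(df: pd.DataFrame, path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


def read_phenotypes(path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep)
    for col in REQUIRED_PHENOTYPE_COLUMNS:
        if col not in df.columns:
            raise InputError(f"{path}: missing required column {col!r}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise InputError(
            f"{path}: duplicate subject_id {dup.iloc[0]!r} "
            f"at line {dup.index[0] + 2}"
        )
    if df["score"].isna().any():
        line = int(df.index[df["score"].isna()][0]) + 2
        raise InputError(f"{path}: missing score at line {line}")
    return df


def write_partition(partition: NetworkPartition, path, sep: str = "\t") -> None:
    df = pd.DataFrame(
        {"node": np.arange(1, partition.n_nodes + 1), "network": partition.labels}
    )
    df.to_csv(path, sep=sep, index=False)


def read_partition(path, sep: str = "\t") -> NetworkPartition:
    df = pd.read_csv(path, sep=sep)
    for col in ("node", "network"):
        if col not in df.columns:
            raise InputError(f"{path}: missing required column {col!r}")
    nodes = df["node"].to_numpy(dtype=int)
    expected = np.arange(1, nodes.size + 1)
    if not np.array_equal(np.sort(nodes), expected):
        raise InputError(
            f"{path}: node column must cover 1..{nodes.size} exactly once"
        )
    labels = np.empty(nodes.size, dtype=object)
    labels[nodes - 1] = df["network"].to_numpy(dtype=object)
    return NetworkPartition(labels)


def _mask_to_json(mask: EdgeMask) -> list[list[int]]:
    return [[i + 1, j + 1] for i, j in mask.edges]


def _mask_from_json(n_nodes: int, pairs, polarity: str) -> EdgeMask:
    return EdgeMask.from_pairs(n_nodes, [(i - 1, j - 1) for i, j in pairs], polarity)


def write_model(model: CpmModel, path) -> None:
    data = {
        "format_version": MODEL_FORMAT_VERSION,
        "n_nodes": model.n_nodes,
        "positive_edges": _mask_to_json(model.positive_mask),
        "negative_edges": _mask_to_json(model.negative_mask),
        "a1": model.a1,
        "a2": model.a2,
        "b": model.b,
        "p_threshold": model.p_threshold,
        "covariates_used": list(model.covariates_used),
        "n_train": model.n_train,
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_model(path) -> CpmModel:
    with open(path) as fh:
        data = json.load(fh)
    version = data.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise InputError(f"{path}: unsupported model format version {version!r}")
    n = int(data["n_nodes"])
    return CpmModel(
        positive_mask=_mask_from_json(n, data["positive_edges"], "positive"),
        negative_mask=_mask_from_json(n, data["negative_edges"], "negative"),
        a1=float(data["a1"]),
        a2=float(data["a2"]),
        b=float(data["b"]),
        p_threshold=float(data["p_threshold"]),
        covariates_used=tuple(data.get("covariates_used", ())),
        n_train=int(data.get("n_train", 0)),
    )


def write_manifest(out_dir, command: str, params: dict, inputs: dict, seed=None) -> Path:
    """Machine-readable run record: command, parameters, input hashes, seed.

    The manifest alone (plus the referenced inputs) suffices to rerun the
    command identically.
    """
    from importlib.metadata import PackageNotFoundError, version

    try:
        pkg_version = version("cpmnet")
    except PackageNotFoundError:
        pkg_version = "unknown"
    hashes = {}
    for name, p in inputs.items():
        p = Path(p)
        if p.is_file():
            hashes[name] = hashlib.sha256(p.read_bytes()).hexdigest()
        else:
            hashes[name] = str(p)
    manifest = {
        "command": command,
        "parameters": {k: _jsonable(v) for k, v in params.items()},
        "inputs": hashes,
        "seed": seed,
        "cpmnet_version": pkg_version,
    }
    out = Path(out_dir) / "manifest.json"
    with open(out, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, Path):
        return str(v)
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v
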