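"""From parcellated node time series to scrubbed Fisher-z connectivity matrices.

Inputs are node-level signals (voxel-to-node averaging, nuisance regression
and temporal filtering are assumed to have happened upstream; the first
non-equilibrium volumes are assumed already dropped).  This module censors
high-motion volumes ("scrubbing"), builds the Pearson-correlation /
Fisher r-to-z connectivity matrix, and runs the motion sanity check used
to verify that head motion does not drive the behavioral association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._exceptions import ConstantInputError, InputError, SampleSizeError

__all__ = [
    "ParcelTimeSeries",
    "ConnectivityMatrix",
    "ScrubReport",
    "scrub",
    "build_connectivity",
    "count_edges",
    "motion_association_check",
    "FD_THRESHOLD_MM",
    "MIN_VOLUMES",
]

#: Volumes with framewise displacement at or above this value (mm) are censored.
FD_THRESHOLD_MM = 0.2

#: Subjects retaining fewer volumes than this after scrubbing are excluded
#: (4 min of data at a repetition time of 2 s).
MIN_VOLUMES = 120

# Pearson r is clamped to +/- (1 - _R_CLAMP_EPS) before atanh so a duplicated
# signal yields a large finite z instead of +/- inf.
_R_CLAMP_EPS = 1e-7


@dataclass
class ParcelTimeSeries:
    """One subject's node-level signal table with its motion trace.

    Attributes
    ----------
    subject_id : str
        Unique subject identifier.
    signal : ndarray, shape (n_volumes, n_nodes)
        Node signal values, one row per retained volume.
    fd : ndarray, shape (n_volumes,)
        Framewise displacement per volume, in mm, nonnegative.
    node_labels : list of str, optional
        Node names; defaults to ``n0001 ...`` on file output.
    """

    subject_id: str
    signal: np.ndarray
    fd: np.ndarray
    node_labels: list[str] | None = None

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.fd = np.asarray(self.fd, dtype=float)
        if self.signal.ndim != 2:
            raise InputError("signal must be a 2-D (volumes x nodes) array")
        if self.fd.shape != (self.signal.shape[0],):
            raise InputError(
                f"fd length {self.fd.shape} does not match "
                f"{self.signal.shape[0]} volumes"
            )
        if np.any(self.fd < 0):
            raise InputError("framewise displacement must be nonnegative")

    @property
    def n_volumes(self) -> int:
        return self.signal.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.signal.shape[1]


@dataclass
class ConnectivityMatrix:
    """Square symmetric Fisher-z edge-strength matrix over atlas nodes.

    The diagonal is zero by convention and never enumerated as an edge.
    """

    subject_id: str
    z: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if self.z.ndim != 2 or self.z.shape[0] != self.z.shape[1]:
            raise InputError("connectivity matrix must be square")
        if not np.all(np.isfinite(self.z)):
            raise InputError("connectivity matrix contains non-finite values")
        if not np.allclose(self.z, self.z.T, atol=1e-8):
            raise InputError("connectivity matrix is not symmetric")

    @property
    def n_nodes(self) -> int:
        return self.z.shape[0]

    def upper_triangle(self) -> np.ndarray:
        """Edge strengths in row-major upper-triangle order (i < j)."""
        i, j = np.triu_indices(self.n_nodes, k=1)
        return self.z[i, j]


@dataclass
class ScrubReport:
    """Book-keeping for one subject's motion censoring."""

    subject_id: str
    n_input_volumes: int
    n_removed: int
    n_retained: int
    mean_fd: float
    excluded: bool

    def __post_init__(self):
        if self.n_retained != self.n_input_volumes - self.n_removed:
            raise InputError("scrub report volume counts are inconsistent")


def scrub(
    ts: ParcelTimeSeries,
    fd_threshold: float = FD_THRESHOLD_MM,
    min_volumes: int = MIN_VOLUMES,
) -> tuple[ParcelTimeSeries, ScrubReport]:
    """Censor high-motion volumes and flag subjects with too little data left.

    Volumes with FD >= ``fd_threshold`` are removed (the threshold itself is
    removed); surviving volumes keep their original temporal order.  A subject
    retaining fewer than ``min_volumes`` volumes is flagged ``excluded``.
    ``mean_fd`` is computed over all input volumes, before censoring.
    """
    if ts.n_volumes == 0:
        raise InputError("cannot scrub an empty time series")
    if fd_threshold <= 0:
        raise InputError("fd_threshold must be positive")
    keep = ts.fd < fd_threshold
    retained = ParcelTimeSeries(
        ts.subject_id, ts.signal[keep], ts.fd[keep], node_labels=ts.node_labels
    )
    n_removed = int(np.sum(~keep))
    report = ScrubReport(
        subject_id=ts.subject_id,
        n_input_volumes=ts.n_volumes,
        n_removed=n_removed,
        n_retained=ts.n_volumes - n_removed,
        mean_fd=float(np.mean(ts.fd)),
        excluded=(ts.n_volumes - n_removed) < min_volumes,
    )
    return retained, report


def build_connectivity(ts: ParcelTimeSeries) -> ConnectivityMatrix:
    """Pearson-correlate every node pair and Fisher r-to-z transform.

    Both positive and negative correlations are retained.  Perfect
    correlations (|r| = 1, e.g. duplicated signals) are clamped just inside
    the open interval before ``atanh`` with a warning, since the transform
    diverges there.
    """
    if ts.n_volumes < 3:
        raise InputError("need at least 3 retained volumes to correlate")
    sd = ts.signal.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        raise InputError(f"node {dead[0]} has zero variance; correlation undefined")
    r = np.corrcoef(ts.signal, rowvar=False)
    np.fill_diagonal(r, 0.0)
    limit = 1.0 - _R_CLAMP_EPS
    if np.any(np.abs(r) > limit):
        warnings.warn(
            f"subject {ts.subject_id}: |r| = 1 encountered; "
            f"clamping to +/-{limit} before Fisher transform",
            RuntimeWarning,
            stacklevel=2,
        )
        r = np.clip(r, -limit, limit)
    z = np.arctanh(r)
    z = (z + z.T) / 2.0  # enforce exact symmetry against float round-off
    np.fill_diagonal(z, 0.0)
    return ConnectivityMatrix(ts.subject_id, z)


def count_edges(n_nodes: int) -> int:
    """Number of unordered node pairs, n(n-1)/2 (35,778 for 268 nodes)."""
    if n_nodes < 2:
        raise InputError("need at least 2 nodes to have an edge")
    return n_nodes * (n_nodes - 1) // 2


def motion_association_check(phenotypes, scores) -> tuple[float, float]:
    """Spearman correlation of per-subject mean FD against a score vector.

    ``phenotypes`` may be a DataFrame with a ``mean_fd`` column or a plain
    vector of mean FD values.  Used to verify that neither observed nor
    predicted behavioral scores track head motion.
    """
    if isinstance(phenotypes, pd.DataFrame):
        if "mean_fd" not in phenotypes.columns:
            raise InputError("phenotype table has no 'mean_fd' column")
        fd = phenotypes["mean_fd"].to_numpy(dtype=float)
    else:
        fd = np.asarray(phenotypes, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if fd.shape != scores.shape or fd.ndim != 1:
        raise InputError("mean FD and score vectors must be 1-D and aligned")
    if fd.size < 4:
        raise SampleSizeError("need at least 4 subjects for the motion check")
    if np.ptp(fd) == 0 or np.ptp(scores) == 0:
        raise ConstantInputError("constant input: rank correlation undefined")
    res = stats.spearmanr(fd, scores)
    return float(res.statistic), float(res.pvalue)
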