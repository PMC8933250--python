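"""Network anatomy of consensus connections and computational lesioning.

Nodes are grouped into a small set of named functional networks (the
canonical seven-network split of the 268-node functional atlas: frontoparietal,
default mode, motor, visual-related, limbic, basal ganglia, cerebellum).
Consensus edges are counted within and between networks, normalized by the
number of possible connections per network pair (reported per mille), and
each network's necessity is probed by deleting all of its nodes and re-running
the whole selection-and-fit pipeline on the reduced matrix ("lesioned model").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._exceptions import InputError
from .cpm import (
    CpmModel,
    EdgeMask,
    EvaluationResult,
    as_edge_table,
    external_validate,
    train_model,
)
from .comparison import compare_predictions

__all__ = [
    "NetworkPartition",
    "AnatomyReport",
    "LesionResult",
    "canonical_partition",
    "pair_counts",
    "per_mille_proportions",
    "network_contribution",
    "restrict_mask",
    "lesion_model",
    "compare_lesioned",
]

#: The canonical seven functional networks of the 268-node atlas and their
#: node counts (sum = 268).
CANONICAL_NETWORK_SIZES = {
    "frontoparietal": 63,
    "default_mode": 20,
    "motor": 50,
    "visual": 45,
    "limbic": 30,
    "basal_ganglia": 29,
    "cerebellum": 31,
}


@dataclass
class NetworkPartition:
    """Assignment of every node to exactly one named functional network."""

    labels: np.ndarray  # one label string per node

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.ndim != 1 or self.labels.size == 0:
            raise InputError("partition labels must be a nonempty 1-D sequence")

    @property
    def n_nodes(self) -> int:
        return self.labels.size

    @property
    def networks(self) -> list[str]:
        """Network names in first-appearance order."""
        seen = {}
        for lab in self.labels:
            seen.setdefault(lab, None)
        return list(seen)

    @property
    def network_sizes(self) -> dict[str, int]:
        return {net: int(np.sum(self.labels == net)) for net in self.networks}

    def nodes_of(self, network: str) -> np.ndarray:
        idx = np.flatnonzero(self.labels == network)
        if idx.size == 0:
            raise InputError(f"no network named {network!r} in the partition")
        return idx

    @classmethod
    def from_sizes(cls, sizes: dict[str, int]) -> "NetworkPartition":
        """Contiguous block partition: the first n1 nodes get the first label, etc."""
        labels = np.concatenate(
            [np.full(n, name, dtype=object) for name, n in sizes.items()]
        )
        return cls(labels)


def canonical_partition() -> NetworkPartition:
    """Synthetic stand-in for the seven-network split of the 268-node atlas.

    Real atlas assignments are interleaved anatomically; this fixture assigns
    contiguous node blocks with the canonical network sizes, which is all the
    counting and lesioning machinery depends on.
    """
    return NetworkPartition.from_sizes(CANONICAL_NETWORK_SIZES)


@dataclass
class AnatomyReport:
    """Edge counts and possible-edge counts per unordered network pair.

    Both tables are square, symmetric DataFrames indexed by network name;
    the diagonal holds within-network values.
    """

    counts: pd.DataFrame
    possible: pd.DataFrame
    mask_size: int

    def __post_init__(self):
        if (self.counts.to_numpy() > self.possible.to_numpy()).any():
            raise InputError("pair count exceeds possible count")


def _pair_possible(partition: NetworkPartition) -> pd.DataFrame:
    nets = partition.networks
    sizes = partition.network_sizes
    poss = pd.DataFrame(0, index=nets, columns=nets, dtype=int)
    for a_i, a in enumerate(nets):
        for b in nets[a_i:]:
            if a == b:
                v = sizes[a] * (sizes[a] - 1) // 2
            else:
                v = sizes[a] * sizes[b]
            poss.loc[a, b] = v
            poss.loc[b, a] = v
    return poss


def pair_counts(mask: EdgeMask, partition: NetworkPartition) -> AnatomyReport:
    """Count mask edges per unordered network pair.

    Within-network possible counts are n(n-1)/2; between-network possible
    counts are n_a * n_b.  Summed over all pairs, counts equal the mask size
    and possibles equal the total whole-brain edge count.
    """
    if mask.n_nodes != partition.n_nodes:
        raise InputError(
            f"mask spans {mask.n_nodes} nodes but partition has {partition.n_nodes}"
        )
    nets = partition.networks
    counts = pd.DataFrame(0, index=nets, columns=nets, dtype=int)
    for i, j in mask.edges:
        a, b = partition.labels[i], partition.labels[j]
        counts.loc[a, b] += 1
        if a != b:
            counts.loc[b, a] += 1
    return AnatomyReport(counts=counts, possible=_pair_possible(partition),
                         mask_size=len(mask))


def per_mille_proportions(
    report: AnatomyReport, aggregate: str = "pool"
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Size-normalized connection proportions, in per mille.

    Per network pair: 1000 * count / possible.  The aggregate within- and
    between-network values either pool counts over pooled possibles
    (``aggregate="pool"``, default) or average the per-pair ratios
    (``aggregate="average"``).
    """
    counts = report.counts.to_numpy(dtype=float)
    poss = report.possible.to_numpy(dtype=float)
    if (poss[np.triu_indices_from(poss)] <= 0).any():
        raise InputError("every network pair must have a positive possible count")
    ratios = 1000.0 * counts / poss
    table = pd.DataFrame(ratios, index=report.counts.index,
                         columns=report.counts.columns)
    diag = np.diag_indices_from(counts)
    off = np.triu_indices_from(counts, k=1)
    if aggregate == "pool":
        within = 1000.0 * counts[diag].sum() / poss[diag].sum()
        between = 1000.0 * counts[off].sum() / poss[off].sum()
    elif aggregate == "average":
        within = float(np.mean(ratios[diag]))
        between = float(np.mean(ratios[off]))
    else:
        raise InputError("aggregate must be 'pool' or 'average'")
    return table, {"within": float(within), "between": float(between)}


def network_contribution(
    positive_mask: EdgeMask, negative_mask: EdgeMask, partition: NetworkPartition
) -> pd.DataFrame:
    """Per-network contribution of the combined consensus masks.

    A network's raw weight is the number of combined-mask edges incident to
    it (a between-network edge credits both endpoint networks).  The
    normalized weight divides by the number of possible edges incident to
    the network, n_k(n_k - 1)/2 + n_k(N - n_k).
    """
    for mask in (positive_mask, negative_mask):
        if mask.n_nodes != partition.n_nodes:
            raise InputError("mask and partition disagree on n_nodes")
    nets = partition.networks
    sizes = partition.network_sizes
    N = partition.n_nodes
    raw = dict.fromkeys(nets, 0)
    for mask in (positive_mask, negative_mask):
        for i, j in mask.edges:
            a, b = partition.labels[i], partition.labels[j]
            raw[a] += 1
            if b != a:
                raw[b] += 1
    rows = []
    for net in nets:
        nk = sizes[net]
        possible = nk * (nk - 1) // 2 + nk * (N - nk)
        rows.append((net, nk, raw[net], raw[net] / possible))
    return pd.DataFrame(
        rows, columns=["network", "n_nodes", "raw", "normalized"]
    ).set_index("network")


def restrict_mask(mask: EdgeMask, keep_nodes: np.ndarray) -> EdgeMask:
    """Reindex a mask onto the subgraph of ``keep_nodes`` (sorted order).

    Edges with either endpoint outside ``keep_nodes`` are dropped.
    """
    keep = np.asarray(sorted(set(int(v) for v in keep_nodes)))
    new_index = {old: new for new, old in enumerate(keep)}
    kept_pairs = [
        (new_index[i], new_index[j])
        for i, j in mask.edges
        if i in new_index and j in new_index
    ]
    return EdgeMask.from_pairs(keep.size, kept_pairs, mask.polarity)


@dataclass
class LesionResult:
    """Outcome of removing one functional network and rebuilding the model."""

    removed_network: str
    kept_nodes: np.ndarray
    n_nodes_reduced: int
    model: CpmModel
    train_eval: EvaluationResult
    validation_eval: EvaluationResult | None = None


def lesion_model(
    matrices,
    scores,
    covariates,
    partition: NetworkPartition,
    removed_network: str,
    p_threshold: float,
    validation: tuple | None = None,
    n_nodes=None,
) -> LesionResult:
    """Delete one network's nodes and rerun the full pipeline.

    All nodes of ``removed_network`` (and every incident edge) are removed,
    the matrix reindexed, and consensus selection + fitting rerun at the
    supplied fixed threshold (the full model's optimum; no re-optimization).
    ``validation`` may supply ``(matrices, scores)`` of a frozen held-out
    cohort, evaluated with the lesioned model.
    """
    edge_table, n = as_edge_table(matrices, n_nodes)
    if partition.n_nodes != n:
        raise InputError("partition does not match matrix dimension")
    removed = partition.nodes_of(removed_network)
    keep = np.setdiff1d(np.arange(n), removed)
    if keep.size < 2:
        raise InputError("lesioning leaves fewer than 2 nodes")

    lut = np.full((n, n), -1, dtype=np.int64)
    iu, ju = np.triu_indices(n, k=1)
    lut[iu, ju] = np.arange(iu.size)
    ki, kj = np.triu_indices(keep.size, k=1)
    sub_cols = lut[keep[ki], keep[kj]]
    sub_table = edge_table[:, sub_cols]

    model, train_eval, _ = train_model(
        sub_table, scores, covariates, p_threshold, n_nodes=keep.size
    )
    val_eval = None
    if validation is not None:
        val_mats, val_scores = validation
        val_table, vn = as_edge_table(val_mats, n_nodes)
        if vn != n:
            raise InputError("validation matrices do not match training dimension")
        val_eval = external_validate(
            model, val_table[:, sub_cols], val_scores, n_nodes=keep.size
        )
    return LesionResult(
        removed_network=removed_network,
        kept_nodes=keep,
        n_nodes_reduced=keep.size,
        model=model,
        train_eval=train_eval,
        validation_eval=val_eval,
    )


def compare_lesioned(
    full_predictions,
    lesioned_predictions,
    observed,
    n_comparisons: int = 14,
) -> tuple[float, float, float]:
    """Steiger comparison of full vs lesioned predictions, Bonferroni-adjusted.

    The default correction spans 14 comparisons (seven lesioned models in
    each of two cohorts).  Returns (z, p, p_bonferroni).
    """
    if n_comparisons < 1:
        raise InputError("n_comparisons must be at least 1")
    cmp = compare_predictions(full_predictions, lesioned_predictions, observed)
    return cmp.z, cmp.p, min(1.0, cmp.p * n_comparisons)
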