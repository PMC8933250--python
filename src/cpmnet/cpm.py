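"""Consensus edge selection and the two-feature linear connectome model.

The pipeline: for each leave-one-out fold, every edge's strength across the
training subjects is correlated with the behavioral score by partial Spearman
correlation (nuisance covariates residualized out on ranks).  Edges that pass
the significance threshold in *every* fold form the positive / negative
consensus masks.  Each subject's two features are the summed Fisher-z strength
over each mask, and an ordinary least-squares fit

    predicted score = a1 * x1 + a2 * x2 + b

maps them to the score.  Model performance is the Spearman correlation
(``r_true``) and mean squared error between predicted and observed scores;
significance comes from a score-shuffling permutation test that reruns the
entire selection-and-fit pipeline per permutation.

Internals are vectorized across edges and permutations: ranked edge tables
are residualized once per fold, after which every permutation is a single
matrix product.  All public functions accept a list of
:class:`~cpmnet.connectome.ConnectivityMatrix`, a 3-D ``(subjects, nodes,
nodes)`` array, or a precomputed ``(subjects, edges)`` upper-triangle table.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata

from ._exceptions import (
    ConfigError,
    ConstantInputError,
    EmptyModelError,
    InputError,
    SampleSizeError,
    SingularFitError,
)
from .connectome import ConnectivityMatrix

__all__ = [
    "EdgeMask",
    "CpmModel",
    "EvaluationResult",
    "PermutationResult",
    "partial_rank_correlation",
    "select_candidates",
    "loocv_consensus",
    "summed_strength",
    "summed_strengths",
    "fit_model",
    "predict",
    "predict_many",
    "evaluate",
    "permutation_test",
    "optimize_threshold",
    "external_validate",
    "covariate_adjusted_evaluation",
    "train_model",
    "default_threshold_grid",
    "as_edge_table",
    "edge_pairs",
]

#: Sentinel evaluation statistic for degenerate permutation iterations
#: (empty consensus): worst possible rank correlation, keeping the
#: permutation denominator fixed.
DEGENERATE_PERM_R = -1.0


# ---------------------------------------------------------------------------
# edge bookkeeping
# ---------------------------------------------------------------------------

def edge_pairs(n_nodes: int) -> np.ndarray:
    """Upper-triangle node pairs (i < j), row-major, 0-based. Shape (E, 2)."""
    i, j = np.triu_indices(n_nodes, k=1)
    return np.column_stack([i, j])


def _flat_index_lookup(n_nodes: int) -> np.ndarray:
    lut = np.full((n_nodes, n_nodes), -1, dtype=np.int64)
    i, j = np.triu_indices(n_nodes, k=1)
    lut[i, j] = np.arange(i.size)
    return lut


@dataclass(frozen=True)
class EdgeMask:
    """A set of unordered node pairs with one sign of score association.

    Edges are stored as 0-based ``(i, j)`` tuples with ``i < j``; file formats
    use 1-based indices.  ``polarity`` records whether the edges' strengths
    correlate positively or negatively with the behavioral score.
    """

    n_nodes: int
    edges: tuple[tuple[int, int], ...]
    polarity: str

    def __post_init__(self):
        if self.polarity not in ("positive", "negative"):
            raise ConfigError(f"polarity must be positive/negative, got {self.polarity!r}")
        seen = set()
        for i, j in self.edges:
            if not (0 <= i < j < self.n_nodes):
                raise InputError(f"edge ({i}, {j}) invalid for {self.n_nodes} nodes")
            if (i, j) in seen:
                raise InputError(f"duplicate edge ({i}, {j})")
            seen.add((i, j))
        object.__setattr__(self, "edges", tuple(sorted(self.edges)))

    @classmethod
    def from_pairs(cls, n_nodes: int, pairs, polarity: str) -> "EdgeMask":
        return cls(n_nodes, tuple((int(i), int(j)) for i, j in pairs), polarity)

    @classmethod
    def from_flat(cls, n_nodes: int, flat_idx, polarity: str) -> "EdgeMask":
        pairs = edge_pairs(n_nodes)[np.asarray(flat_idx, dtype=int)]
        return cls.from_pairs(n_nodes, pairs, polarity)

    def flat_indices(self) -> np.ndarray:
        """Positions of this mask's edges in upper-triangle vector order."""
        if not self.edges:
            return np.empty(0, dtype=np.int64)
        lut = _flat_index_lookup(self.n_nodes)
        arr = np.asarray(self.edges)
        return lut[arr[:, 0], arr[:, 1]]

    def as_set(self) -> frozenset:
        return frozenset(self.edges)

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.as_set()


@dataclass
class CpmModel:
    """Frozen consensus-connection model: two masks and a line.

    ``a1`` weights the positive-mask strength sum, ``a2`` the negative-mask
    sum, ``b`` is the intercept (score units).  ``covariates_used`` records
    the nuisance variables partialled out during edge selection; they do not
    enter the prediction itself.
    """

    positive_mask: EdgeMask
    negative_mask: EdgeMask
    a1: float
    a2: float
    b: float
    p_threshold: float
    covariates_used: tuple[str, ...] = ()
    n_train: int = 0

    def __post_init__(self):
        if self.positive_mask.n_nodes != self.negative_mask.n_nodes:
            raise InputError("positive and negative masks disagree on n_nodes")
        if self.positive_mask.as_set() & self.negative_mask.as_set():
            raise InputError("positive and negative masks must be disjoint")
        if not (0 < self.p_threshold <= 0.05):
            raise ConfigError(f"p_threshold {self.p_threshold} outside (0, .05]")

    @property
    def n_nodes(self) -> int:
        return self.positive_mask.n_nodes


@dataclass
class EvaluationResult:
    """Spearman r between predicted and observed scores, and the MSE."""

    r_true: float
    p: float
    mse: float
    p_permu: float | None = None

    def __post_init__(self):
        if not -1.0000001 <= self.r_true <= 1.0000001:
            raise InputError("r_true outside [-1, 1]")
        if self.mse < 0:
            raise InputError("mse must be nonnegative")
        if self.p_permu is not None and not 0 <= self.p_permu <= 1:
            raise InputError("p_permu outside [0, 1]")


@dataclass
class PermutationResult:
    """Outcome of the score-shuffling permutation test."""

    p_permu: float
    r_true: float
    null_r: np.ndarray
    n_degenerate: int = 0


# ---------------------------------------------------------------------------
# input coercion
# ---------------------------------------------------------------------------

def as_edge_table(matrices, n_nodes: int | None = None) -> tuple[np.ndarray, int]:
    """Coerce connectivity input to an (n_subjects, n_edges) strength table.

    Accepts a sequence of :class:`ConnectivityMatrix`, a 3-D array of square
    matrices, or an already-flat 2-D edge table (requires ``n_nodes``).
    Edge order is row-major over the upper triangle (i < j).
    """
    if isinstance(matrices, np.ndarray) and matrices.ndim == 2:
        if n_nodes is None:
            raise InputError("n_nodes required when passing a flat edge table")
        expected = n_nodes * (n_nodes - 1) // 2
        if matrices.shape[1] != expected:
            raise InputError(
                f"edge table has {matrices.shape[1]} columns, expected {expected}"
            )
        return np.asarray(matrices, dtype=float), n_nodes
    if isinstance(matrices, np.ndarray) and matrices.ndim == 3:
        n = matrices.shape[1]
        if matrices.shape[2] != n:
            raise InputError("stacked matrices must be square")
        i, j = np.triu_indices(n, k=1)
        return np.asarray(matrices[:, i, j], dtype=float), n
    mats = list(matrices)
    if not mats:
        raise InputError("no connectivity matrices supplied")
    n = mats[0].n_nodes
    if any(m.n_nodes != n for m in mats):
        raise InputError("connectivity matrices disagree on n_nodes")
    i, j = np.triu_indices(n, k=1)
    return np.stack([m.z[i, j] for m in mats]), n


def _as_covariate_array(covariates) -> tuple[np.ndarray | None, tuple[str, ...]]:
    if covariates is None:
        return None, ()
    if isinstance(covariates, pd.DataFrame):
        if covariates.shape[1] == 0:
            return None, ()
        return covariates.to_numpy(dtype=float), tuple(covariates.columns)
    arr = np.asarray(covariates, dtype=float)
    if arr.size == 0:
        return None, ()
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, tuple(f"cov{k}" for k in range(arr.shape[1]))


# ---------------------------------------------------------------------------
# partial Spearman correlation
# ---------------------------------------------------------------------------

def _design_q(cov_ranks: np.ndarray | None, n: int) -> np.ndarray:
    """Orthonormal basis of the span of [1, ranked covariates]."""
    if cov_ranks is None:
        x = np.ones((n, 1))
    else:
        x = np.column_stack([np.ones(n), cov_ranks])
    q, _ = np.linalg.qr(x)
    return q


def _t_pvalue(rho: np.ndarray, df: int) -> np.ndarray:
    rho_c = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho_c * np.sqrt(df / np.maximum(1.0 - rho_c**2, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df)


def partial_rank_correlation(x, y, covariates=None) -> tuple[float, float]:
    """Spearman correlation of ``x`` and ``y`` controlling for covariates.

    All variables are rank-transformed (average ranks for ties); ``x`` and
    ``y`` are residualized on the ranked covariates (plus intercept) by least
    squares, and the Pearson correlation of the residuals is returned with a
    two-sided p from ``t = rho * sqrt((n - 2 - k) / (1 - rho^2))`` on
    ``n - 2 - k`` degrees of freedom.  With no covariates this is the plain
    Spearman correlation.

    If either variable is fully explained by the covariates the correlation
    is degenerate: the function warns and returns ``(0.0, 1.0)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov, _ = _as_covariate_array(covariates)
    n = x.size
    k = 0 if cov is None else cov.shape[1]
    if y.shape != x.shape or x.ndim != 1:
        raise InputError("x and y must be aligned 1-D vectors")
    if cov is not None and cov.shape[0] != n:
        raise InputError("covariate rows do not match x/y length")
    if n < k + 4:
        raise SampleSizeError(f"need at least {k + 4} observations with {k} covariates")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("constant input: rank correlation undefined")

    rx = rankdata(x)
    ry = rankdata(y)
    q = _design_q(rankdata(cov, axis=0) if cov is not None else None, n)
    rx_res = rx - q @ (q.T @ rx)
    ry_res = ry - q @ (q.T @ ry)
    nx, ny = np.linalg.norm(rx_res), np.linalg.norm(ry_res)
    if nx < 1e-10 * n or ny < 1e-10 * n:
        warnings.warn(
            "variable fully collinear with covariates; partial correlation "
            "degenerate, returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0, 1.0
    rho = float(np.dot(rx_res, ry_res) / (nx * ny))
    rho = float(np.clip(rho, -1.0, 1.0))
    p = float(_t_pvalue(np.array(rho), n - 2 - k))
    return rho, p


def _edge_stats(
    edge_table: np.ndarray, y: np.ndarray, cov: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized partial Spearman of every edge column against ``y``.

    Returns (rho, p) arrays over edges.  Zero-variance edges (or edges fully
    absorbed by the covariates) get rho = 0, p = 1 and are therefore never
    selected.
    """
    n, _ = edge_table.shape
    k = 0 if cov is None else cov.shape[1]
    ranks = rankdata(edge_table, axis=0)
    ry = rankdata(y)
    q = _design_q(rankdata(cov, axis=0) if cov is not None else None, n)
    r_res = ranks - q @ (q.T @ ranks)
    y_res = ry - q @ (q.T @ ry)
    norms = np.linalg.norm(r_res, axis=0)
    ynorm = np.linalg.norm(y_res)
    if ynorm < 1e-10 * n:
        raise ConstantInputError("scores fully collinear with covariates")
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (r_res.T @ y_res) / (norms * ynorm)
    dead = norms < 1e-10 * n
    rho = np.where(dead, 0.0, np.clip(rho, -1.0, 1.0))
    p = _t_pvalue(rho, n - 2 - k)
    p[dead] = 1.0
    return rho, p


def select_candidates(
    matrices, scores, covariates=None, p_threshold: float = 0.01, n_nodes=None
) -> tuple[EdgeMask, EdgeMask]:
    """Pick candidate edges whose strength tracks the score across subjects.

    Every upper-triangle edge is tested with
    :func:`partial_rank_correlation`; edges with ``p < p_threshold`` enter
    the positive mask when rho > 0 and the negative mask when rho < 0.
    """
    edge_table, n = as_edge_table(matrices, n_nodes)
    y = np.asarray(scores, dtype=float)
    cov, _ = _as_covariate_array(covariates)
    k = 0 if cov is None else cov.shape[1]
    if edge_table.shape[0] != y.size:
        raise InputError("number of matrices does not match number of scores")
    if edge_table.shape[0] < k + 4:
        raise SampleSizeError("too few training subjects for the covariate count")
    if not 0 < p_threshold < 1:
        raise InputError(f"p_threshold {p_threshold} outside (0, 1)")
    rho, p = _edge_stats(edge_table, y, cov)
    sig = p < p_threshold
    pos = np.flatnonzero(sig & (rho > 0))
    neg = np.flatnonzero(sig & (rho < 0))
    return (
        EdgeMask.from_flat(n, pos, "positive"),
        EdgeMask.from_flat(n, neg, "negative"),
    )


# ---------------------------------------------------------------------------
# LOOCV fold cache and consensus
# ---------------------------------------------------------------------------

class _FoldCache:
    """Per-fold ranked-and-residualized edge tables for fast reruns.

    Edge ranks and covariate projections depend only on the connectomes and
    covariates, so they are computed once per leave-one-out fold and reused
    for the observed scores, every candidate threshold, and every score
    permutation.
    """

    def __init__(self, edge_table: np.ndarray, cov: np.ndarray | None):
        self.n, self.m = edge_table.shape
        self.k = 0 if cov is None else cov.shape[1]
        if self.n < self.k + 5:
            raise SampleSizeError(
                f"LOOCV needs at least covariates + 5 = {self.k + 5} subjects"
            )
        self.folds = []
        for f in range(self.n):
            idx = np.concatenate([np.arange(f), np.arange(f + 1, self.n)])
            sub = edge_table[idx]
            ranks = rankdata(sub, axis=0)
            q = _design_q(
                rankdata(cov[idx], axis=0) if cov is not None else None, self.n - 1
            )
            r_res = ranks - q @ (q.T @ ranks)
            norms = np.linalg.norm(r_res, axis=0)
            self.folds.append((idx, q, r_res, norms))

    def fold_stats(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-fold (rho, p) matrices for one score vector.  Shape (n, m)."""
        rho_all = np.empty((self.n, self.m))
        p_all = np.empty((self.n, self.m))
        df = self.n - 1 - 2 - self.k
        for f, (idx, q, r_res, norms) in enumerate(self.folds):
            ry = rankdata(y[idx])
            y_res = ry - q @ (q.T @ ry)
            ynorm = np.linalg.norm(y_res)
            if ynorm < 1e-10 * self.n:
                raise ConstantInputError(
                    f"fold {f}: scores fully collinear with covariates"
                )
            with np.errstate(divide="ignore", invalid="ignore"):
                rho = (r_res.T @ y_res) / (norms * ynorm)
            dead = norms < 1e-10 * self.n
            rho = np.where(dead, 0.0, np.clip(rho, -1.0, 1.0))
            p = _t_pvalue(rho, df)
            p[dead] = 1.0
            rho_all[f] = rho
            p_all[f] = p
        return rho_all, p_all

    def consensus_over_scores(
        self, y_cols: np.ndarray, p_threshold: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """Consensus masks for many score vectors at once.

        ``y_cols`` has one score vector per column (n x P); returns boolean
        (m x P) positive and negative consensus indicators.
        """
        df = self.n - 1 - 2 - self.k
        m, P = self.m, y_cols.shape[1]
        # p < threshold is equivalent to |rho| > rho_crit (the t transform is
        # monotone in |rho|), so one inverse-t call replaces m x P tail areas
        t_crit = stats.t.isf(p_threshold / 2.0, df)
        rho_crit = t_crit / np.sqrt(df + t_crit**2)
        pos = np.ones((m, P), dtype=bool)
        neg = np.ones((m, P), dtype=bool)
        for idx, q, r_res, norms in self.folds:
            ry = rankdata(y_cols[idx], axis=0)
            y_res = ry - q @ (q.T @ ry)
            ynorms = np.linalg.norm(y_res, axis=0)
            ynorms = np.where(ynorms < 1e-12, np.inf, ynorms)
            rho = (r_res.T @ y_res) / (norms[:, None] * ynorms[None, :])
            rho = np.where(norms[:, None] < 1e-10 * self.n, 0.0, rho)
            pos &= rho > rho_crit
            neg &= rho < -rho_crit
            if not pos.any() and not neg.any():
                break
        return pos, neg


def loocv_consensus(
    matrices, scores, covariates=None, p_threshold: float = 0.01, n_nodes=None
) -> tuple[EdgeMask, EdgeMask, list[tuple[frozenset, frozenset]]]:
    """Leave-one-out consensus edge selection.

    Runs :func:`select_candidates` once per fold (each subject held out in
    turn) and intersects the per-fold candidate sets: only edges selected in
    *every* fold — the consensus connections — survive.  The per-fold
    candidate sets are returned for audit.
    """
    edge_table, n = as_edge_table(matrices, n_nodes)
    y = np.asarray(scores, dtype=float)
    cov, _ = _as_covariate_array(covariates)
    if edge_table.shape[0] != y.size:
        raise InputError("number of matrices does not match number of scores")
    if not 0 < p_threshold < 1:
        raise InputError(f"p_threshold {p_threshold} outside (0, 1)")
    cache = _FoldCache(edge_table, cov)
    rho_all, p_all = cache.fold_stats(y)
    sig = p_all < p_threshold
    pos_fold = sig & (rho_all > 0)
    neg_fold = sig & (rho_all < 0)
    pairs = edge_pairs(n)
    fold_sets = [
        (
            frozenset(map(tuple, pairs[pos_fold[f]])),
            frozenset(map(tuple, pairs[neg_fold[f]])),
        )
        for f in range(cache.n)
    ]
    pos_idx = np.flatnonzero(pos_fold.all(axis=0))
    neg_idx = np.flatnonzero(neg_fold.all(axis=0))
    return (
        EdgeMask.from_flat(n, pos_idx, "positive"),
        EdgeMask.from_flat(n, neg_idx, "negative"),
        fold_sets,
    )


# ---------------------------------------------------------------------------
# features, fitting, prediction, evaluation
# ---------------------------------------------------------------------------

def summed_strength(matrix: ConnectivityMatrix, mask: EdgeMask) -> float:
    """Sum of Fisher-z strengths over the mask edges (each counted once)."""
    if matrix.n_nodes != mask.n_nodes:
        raise InputError(
            f"matrix has {matrix.n_nodes} nodes but mask expects {mask.n_nodes}"
        )
    if not mask.edges:
        return 0.0
    arr = np.asarray(mask.edges)
    return float(matrix.z[arr[:, 0], arr[:, 1]].sum())


def summed_strengths(matrices, mask: EdgeMask, n_nodes=None) -> np.ndarray:
    """Vectorized :func:`summed_strength` over a cohort."""
    edge_table, n = as_edge_table(matrices, n_nodes)
    if n != mask.n_nodes:
        raise InputError(f"matrices have {n} nodes but mask expects {mask.n_nodes}")
    idx = mask.flat_indices()
    if idx.size == 0:
        return np.zeros(edge_table.shape[0])
    return edge_table[:, idx].sum(axis=1)


def _fit_two_features(
    x1: np.ndarray, x2: np.ndarray, y: np.ndarray
) -> tuple[float, float, float]:
    """OLS of y on (x1, x2, intercept), dropping degenerate feature columns.

    A constant feature (typically an all-zero sum from an empty mask) is
    dropped with its coefficient reported as 0.  Returns (a1, a2, b).
    """
    n = y.size
    use1 = np.ptp(x1) > 1e-12
    use2 = np.ptp(x2) > 1e-12
    cols, which = [np.ones(n)], []
    if use1:
        cols.append(x1)
        which.append(1)
    if use2:
        cols.append(x2)
        which.append(2)
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularFitError("sum features are collinear; cannot fit the model")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    a1 = a2 = 0.0
    b = float(beta[0])
    for pos, w in enumerate(which, start=1):
        if w == 1:
            a1 = float(beta[pos])
        else:
            a2 = float(beta[pos])
    return a1, a2, b


def fit_model(
    matrices,
    scores,
    positive_mask: EdgeMask,
    negative_mask: EdgeMask,
    p_threshold: float,
    covariates_used: tuple[str, ...] = (),
    n_nodes=None,
) -> CpmModel:
    """OLS of observed score on the two consensus strength sums.

    If one polarity's mask is empty (or its sum feature is constant) that
    column is dropped with a warning and its coefficient set to zero; the
    model degrades gracefully to a single-feature fit.
    """
    edge_table, n = as_edge_table(matrices, n_nodes)
    y = np.asarray(scores, dtype=float)
    if y.size < 4:
        raise SampleSizeError("need at least 4 subjects to fit the model")
    x1 = summed_strengths(edge_table, positive_mask, n_nodes=n)
    x2 = summed_strengths(edge_table, negative_mask, n_nodes=n)
    if np.ptp(x1) <= 1e-12 or np.ptp(x2) <= 1e-12:
        warnings.warn(
            "a sum feature is constant (empty mask?); dropping it from the fit",
            RuntimeWarning,
            stacklevel=2,
        )
    a1, a2, b = _fit_two_features(x1, x2, y)
    return CpmModel(
        positive_mask=positive_mask,
        negative_mask=negative_mask,
        a1=a1,
        a2=a2,
        b=b,
        p_threshold=p_threshold,
        covariates_used=tuple(covariates_used),
        n_train=y.size,
    )


def predict(model: CpmModel, matrix: ConnectivityMatrix) -> float:
    """Apply the frozen linear model to one subject's matrix."""
    x1 = summed_strength(matrix, model.positive_mask)
    x2 = summed_strength(matrix, model.negative_mask)
    return model.a1 * x1 + model.a2 * x2 + model.b


def predict_many(model: CpmModel, matrices, n_nodes=None) -> np.ndarray:
    """Vectorized :func:`predict` over a cohort."""
    edge_table, n = as_edge_table(matrices, n_nodes)
    if n != model.n_nodes:
        raise InputError(f"matrices have {n} nodes but model expects {model.n_nodes}")
    x1 = summed_strengths(edge_table, model.positive_mask, n_nodes=n)
    x2 = summed_strengths(edge_table, model.negative_mask, n_nodes=n)
    return model.a1 * x1 + model.a2 * x2 + model.b


def evaluate(predicted, observed) -> EvaluationResult:
    """Spearman r (``r_true``) with parametric two-sided p, plus the MSE.

    If either vector is constant the correlation is undefined; a
    :class:`ConstantInputError` carrying the (still well-defined) MSE is
    raised.
    """
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1:
        raise InputError("predicted and observed must be aligned 1-D vectors")
    if pred.size < 4:
        raise SampleSizeError("need at least 4 subjects to evaluate")
    mse = float(np.mean((pred - obs) ** 2))
    if np.ptp(pred) == 0 or np.ptp(obs) == 0:
        raise ConstantInputError(
            "constant prediction or observation: r_true undefined", mse=mse
        )
    res = stats.spearmanr(pred, obs)
    return EvaluationResult(
        r_true=float(res.statistic), p=float(res.pvalue), mse=mse
    )


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------

def permutation_pvalue(r_true: float, null_r: np.ndarray) -> float:
    """Fraction of permuted statistics greater than or equal to ``r_true``.

    Strict empirical proportion with denominator ``len(null_r)`` — no +1
    smoothing — so a statistic above every permuted value yields exactly 0.
    """
    null_r = np.asarray(null_r, dtype=float)
    return float(np.mean(null_r >= r_true))


def _spearman_stat(pred: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(pred) == 0 or np.ptp(y) == 0:
        return DEGENERATE_PERM_R
    rp, ry = rankdata(pred), rankdata(y)
    rp = rp - rp.mean()
    ry = ry - ry.mean()
    den = np.linalg.norm(rp) * np.linalg.norm(ry)
    if den == 0:
        return DEGENERATE_PERM_R
    return float(np.dot(rp, ry) / den)


def _pipeline_r(
    edge_table: np.ndarray,
    y: np.ndarray,
    cache: _FoldCache,
    p_threshold: float,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Consensus -> fit -> in-sample Spearman r for one score vector."""
    pos, neg = cache.consensus_over_scores(y[:, None], p_threshold)
    pos_idx, neg_idx = np.flatnonzero(pos[:, 0]), np.flatnonzero(neg[:, 0])
    if pos_idx.size == 0 and neg_idx.size == 0:
        return DEGENERATE_PERM_R, pos_idx, neg_idx
    x1 = edge_table[:, pos_idx].sum(axis=1) if pos_idx.size else np.zeros(y.size)
    x2 = edge_table[:, neg_idx].sum(axis=1) if neg_idx.size else np.zeros(y.size)
    try:
        a1, a2, b = _fit_two_features(x1, x2, y)
    except SingularFitError:
        return DEGENERATE_PERM_R, pos_idx, neg_idx
    pred = a1 * x1 + a2 * x2 + b
    return _spearman_stat(pred, y), pos_idx, neg_idx


def permutation_test(
    matrices,
    scores,
    covariates=None,
    p_threshold: float = 0.01,
    n_perm: int = 1000,
    seed: int | None = None,
    n_nodes=None,
) -> PermutationResult:
    """Score-shuffling significance test for the whole pipeline.

    ``r_true`` is computed on the unpermuted scores.  For each of ``n_perm``
    permutations the scores are shuffled (covariate rows stay aligned with
    the connectomes) and the entire consensus-selection-and-fit pipeline is
    rerun; ``p_permu`` is the fraction of permuted statistics >= ``r_true``.
    Permutations whose consensus is empty contribute the sentinel statistic
    -1 so the denominator stays fixed.  A seed is mandatory.
    """
    if seed is None:
        raise ConfigError("seed is required for the permutation test")
    if n_perm < 1:
        raise ConfigError("n_perm must be at least 1")
    edge_table, n = as_edge_table(matrices, n_nodes)
    y = np.asarray(scores, dtype=float)
    cov, _ = _as_covariate_array(covariates)
    cache = _FoldCache(edge_table, cov)
    rng = np.random.default_rng(seed)

    r_true, _, _ = _pipeline_r(edge_table, y, cache, p_threshold)

    perms = np.stack([rng.permutation(y) for _ in range(n_perm)], axis=1)
    pos, neg = cache.consensus_over_scores(perms, p_threshold)
    null_r = np.empty(n_perm)
    n_degenerate = 0
    nsub = y.size
    for p_i in range(n_perm):
        pos_idx = np.flatnonzero(pos[:, p_i])
        neg_idx = np.flatnonzero(neg[:, p_i])
        yp = perms[:, p_i]
        if pos_idx.size == 0 and neg_idx.size == 0:
            null_r[p_i] = DEGENERATE_PERM_R
            n_degenerate += 1
            continue
        x1 = edge_table[:, pos_idx].sum(axis=1) if pos_idx.size else np.zeros(nsub)
        x2 = edge_table[:, neg_idx].sum(axis=1) if neg_idx.size else np.zeros(nsub)
        try:
            a1, a2, b = _fit_two_features(x1, x2, yp)
        except SingularFitError:
            null_r[p_i] = DEGENERATE_PERM_R
            n_degenerate += 1
            continue
        null_r[p_i] = _spearman_stat(a1 * x1 + a2 * x2 + b, yp)
    if n_degenerate:
        logging.getLogger(__name__).info(
            "%d of %d permutations had an empty consensus; scored as r = %s",
            n_degenerate, n_perm, DEGENERATE_PERM_R,
        )
    return PermutationResult(
        p_permu=permutation_pvalue(r_true, null_r),
        r_true=r_true,
        null_r=null_r,
        n_degenerate=n_degenerate,
    )


# ---------------------------------------------------------------------------
# threshold optimization, training, validation
# ---------------------------------------------------------------------------

def default_threshold_grid() -> np.ndarray:
    """The 50 candidate selection thresholds: .001, .002, ..., .050."""
    return np.round(np.arange(1, 51) * 0.001, 3)


def optimize_threshold(
    matrices, scores, covariates=None, grid=None, n_nodes=None
) -> tuple[float, pd.DataFrame]:
    """Scan selection thresholds and keep the one with the highest r_true.

    Per-fold edge statistics are computed once; each threshold then only
    re-intersects the candidate sets and refits the two-feature model.
    Thresholds whose consensus is empty get ``r_true = NaN`` and are skipped.
    Ties are broken toward the smaller (more stringent) threshold.
    """
    grid = default_threshold_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise InputError("threshold grid is empty")
    if np.any((grid <= 0) | (grid >= 1)):
        raise InputError("thresholds must lie strictly inside (0, 1)")
    edge_table, n = as_edge_table(matrices, n_nodes)
    y = np.asarray(scores, dtype=float)
    cov, _ = _as_covariate_array(covariates)
    cache = _FoldCache(edge_table, cov)
    rho_all, p_all = cache.fold_stats(y)
    rows = []
    for thr in np.sort(grid):
        sig = p_all < thr
        pos_idx = np.flatnonzero((sig & (rho_all > 0)).all(axis=0))
        neg_idx = np.flatnonzero((sig & (rho_all < 0)).all(axis=0))
        if pos_idx.size == 0 and neg_idx.size == 0:
            rows.append((thr, np.nan, np.nan, 0, 0))
            continue
        x1 = edge_table[:, pos_idx].sum(axis=1) if pos_idx.size else np.zeros(y.size)
        x2 = edge_table[:, neg_idx].sum(axis=1) if neg_idx.size else np.zeros(y.size)
        try:
            a1, a2, b = _fit_two_features(x1, x2, y)
        except SingularFitError:
            rows.append((thr, np.nan, np.nan, pos_idx.size, neg_idx.size))
            continue
        pred = a1 * x1 + a2 * x2 + b
        r = _spearman_stat(pred, y)
        mse = float(np.mean((pred - y) ** 2))
        rows.append((thr, r, mse, pos_idx.size, neg_idx.size))
    table = pd.DataFrame(
        rows, columns=["p_threshold", "r_true", "mse", "n_positive", "n_negative"]
    )
    if table["r_true"].isna().all():
        raise EmptyModelError("no threshold in the grid yields any consensus edge")
    best_r = table["r_true"].max()
    best = table.loc[table["r_true"] == best_r, "p_threshold"].min()
    return float(best), table


def train_model(
    matrices,
    scores,
    covariates=None,
    p_threshold: float = 0.01,
    n_nodes=None,
) -> tuple[CpmModel, EvaluationResult, list[tuple[frozenset, frozenset]]]:
    """Consensus selection + final fit + in-sample evaluation in one call.

    Note the final coefficients are fit on *all* training subjects and the
    evaluation is in-sample; the honest out-of-sample variant is the
    per-fold model in :mod:`cpmnet.comparison`.
    """
    _, names = _as_covariate_array(covariates)
    pos, neg, folds = loocv_consensus(
        matrices, scores, covariates, p_threshold, n_nodes=n_nodes
    )
    if len(pos) == 0 and len(neg) == 0:
        raise EmptyModelError(f"no consensus connections at threshold {p_threshold}")
    model = fit_model(
        matrices, scores, pos, neg, p_threshold,
        covariates_used=names, n_nodes=n_nodes,
    )
    preds = predict_many(model, matrices, n_nodes=n_nodes)
    result = evaluate(preds, scores)
    return model, result, folds


def external_validate(model: CpmModel, matrices, observed_scores, n_nodes=None) -> EvaluationResult:
    """Apply a frozen model to an independent cohort and evaluate.

    No re-selection or refitting happens here; the masks and coefficients are
    used exactly as trained.
    """
    preds = predict_many(model, matrices, n_nodes=n_nodes)
    return evaluate(preds, observed_scores)


def covariate_adjusted_evaluation(predicted, observed, covariates) -> tuple[float, float]:
    """Partial Spearman correlation of predictions and observations,
    controlling for clinical covariates."""
    return partial_rank_correlation(predicted, observed, covariates)
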