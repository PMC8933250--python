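"""Model variants, Steiger's Z for dependent correlations, and edge overlap.

Three reduced variants of the full consensus model are built for comparison:
a positive-only model (M1), a negative-only model (M2), and a per-fold
model (M3) in which each subject's prediction comes from a model fit without
that subject — the honest out-of-sample estimate.  Differences between
correlated predictive correlations are tested with Steiger's Z for two
dependent correlations sharing one variable (the observed score).  A hybrid
model augments the two connectome features with clinical covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.stats import rankdata

from ._exceptions import (
    EmptyModelError,
    InputError,
    SampleSizeError,
    SingularFitError,
)
from .cpm import (
    EdgeMask,
    EvaluationResult,
    _as_covariate_array,
    _edge_stats,
    _fit_two_features,
    _FoldCache,
    _spearman_stat,
    as_edge_table,
    default_threshold_grid,
    evaluate,
    fit_model,
    loocv_consensus,
    predict_many,
)

__all__ = [
    "ModelComparison",
    "HybridModel",
    "build_variant",
    "optimize_variant_threshold",
    "steiger_z",
    "compare_predictions",
    "edge_overlap",
    "fit_hybrid",
]

VARIANTS = ("positive_only", "negative_only", "per_fold")


@dataclass
class ModelComparison:
    """Two dependent predictive correlations and their Steiger comparison."""

    model_a_r: float
    model_b_r: float
    r_ab: float
    n: int
    z: float
    p: float


@dataclass
class HybridModel:
    """Linear model on the two strength sums plus clinical covariates."""

    positive_mask: EdgeMask
    negative_mask: EdgeMask
    coefficients: dict[str, float]
    covariate_names: tuple[str, ...]

    def predict(self, matrices, covariates, n_nodes=None) -> np.ndarray:
        from .cpm import summed_strengths

        cov, names = _as_covariate_array(covariates)
        if tuple(names) != self.covariate_names:
            raise InputError(
                f"hybrid model expects covariates {self.covariate_names}, got {names}"
            )
        x1 = summed_strengths(matrices, self.positive_mask, n_nodes=n_nodes)
        x2 = summed_strengths(matrices, self.negative_mask, n_nodes=n_nodes)
        pred = (
            self.coefficients["intercept"]
            + self.coefficients["positive_sum"] * x1
            + self.coefficients["negative_sum"] * x2
        )
        for k, name in enumerate(self.covariate_names):
            pred = pred + self.coefficients[name] * cov[:, k]
        return pred


def build_variant(
    matrices,
    scores,
    covariates=None,
    variant: str = "per_fold",
    p_threshold: float = 0.01,
    n_nodes=None,
) -> tuple[np.ndarray, EvaluationResult]:
    """Build one reduced model variant and return its predictions.

    ``positive_only`` / ``negative_only``: consensus selection as usual, but
    the linear model uses only the requested polarity's strength sum; an
    empty consensus of that polarity raises :class:`EmptyModelError`.

    ``per_fold``: within each leave-one-out fold, candidates are selected and
    the model fit on the training subjects only, and the held-out subject is
    predicted by that fold's model; a fold with no candidates predicts the
    training-score mean.
    """
    if variant not in VARIANTS:
        raise InputError(f"variant must be one of {VARIANTS}, got {variant!r}")
    edge_table, n = as_edge_table(matrices, n_nodes)
    y = np.asarray(scores, dtype=float)
    cov, names = _as_covariate_array(covariates)

    if variant in ("positive_only", "negative_only"):
        pos, neg, _ = loocv_consensus(edge_table, y, cov, p_threshold, n_nodes=n)
        mask = pos if variant == "positive_only" else neg
        if len(mask) == 0:
            raise EmptyModelError(
                f"no {mask.polarity} consensus connections at threshold {p_threshold}"
            )
        empty = EdgeMask(n, (), "negative" if variant == "positive_only" else "positive")
        if variant == "positive_only":
            model = fit_model(edge_table, y, mask, empty, p_threshold,
                              covariates_used=names, n_nodes=n)
        else:
            model = fit_model(edge_table, y, empty, mask, p_threshold,
                              covariates_used=names, n_nodes=n)
        preds = predict_many(model, edge_table, n_nodes=n)
        return preds, evaluate(preds, y)

    # per-fold (out-of-sample) variant
    nsub = y.size
    k = 0 if cov is None else cov.shape[1]
    if nsub < k + 5:
        raise SampleSizeError(f"per-fold variant needs at least {k + 5} subjects")
    preds = np.empty(nsub)
    for f in range(nsub):
        idx = np.concatenate([np.arange(f), np.arange(f + 1, nsub)])
        rho, p = _edge_stats(
            edge_table[idx], y[idx], cov[idx] if cov is not None else None
        )
        sig = p < p_threshold
        pos_idx = np.flatnonzero(sig & (rho > 0))
        neg_idx = np.flatnonzero(sig & (rho < 0))
        if pos_idx.size == 0 and neg_idx.size == 0:
            preds[f] = y[idx].mean()
            continue
        x1 = edge_table[idx][:, pos_idx].sum(axis=1) if pos_idx.size else np.zeros(idx.size)
        x2 = edge_table[idx][:, neg_idx].sum(axis=1) if neg_idx.size else np.zeros(idx.size)
        try:
            a1, a2, b = _fit_two_features(x1, x2, y[idx])
        except SingularFitError:
            preds[f] = y[idx].mean()
            continue
        h1 = edge_table[f, pos_idx].sum() if pos_idx.size else 0.0
        h2 = edge_table[f, neg_idx].sum() if neg_idx.size else 0.0
        preds[f] = a1 * h1 + a2 * h2 + b
    return preds, evaluate(preds, y)


def optimize_variant_threshold(
    matrices,
    scores,
    covariates=None,
    variant: str = "per_fold",
    grid=None,
    n_nodes=None,
):
    """Scan selection thresholds for one reduced variant.

    Each variant is optimized on its own, mirroring how the full model's
    threshold is chosen: the per-fold edge statistics are computed once and
    each threshold re-intersects (or, for the per-fold variant, re-selects
    and refits within each fold).  Returns the best threshold (ties to the
    stricter one) and the full r_true/MSE table.
    """
    import pandas as pd

    from ._exceptions import EmptyModelError as _Empty

    if variant not in VARIANTS:
        raise InputError(f"variant must be one of {VARIANTS}, got {variant!r}")
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
    nsub = y.size
    rows = []
    for thr in np.sort(grid):
        sig = p_all < thr
        if variant in ("positive_only", "negative_only"):
            fold_masks = sig & (rho_all > 0) if variant == "positive_only" \
                else sig & (rho_all < 0)
            idx_sel = np.flatnonzero(fold_masks.all(axis=0))
            if idx_sel.size == 0:
                rows.append((thr, np.nan, np.nan, 0))
                continue
            x = edge_table[:, idx_sel].sum(axis=1)
            if np.ptp(x) <= 1e-12:
                rows.append((thr, np.nan, np.nan, idx_sel.size))
                continue
            X = np.column_stack([np.ones(nsub), x])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            pred = X @ beta
            rows.append((thr, _spearman_stat(pred, y),
                         float(np.mean((pred - y) ** 2)), idx_sel.size))
        else:  # per_fold
            preds = np.empty(nsub)
            n_sel = 0
            for f in range(nsub):
                idx = np.concatenate([np.arange(f), np.arange(f + 1, nsub)])
                pos_idx = np.flatnonzero(sig[f] & (rho_all[f] > 0))
                neg_idx = np.flatnonzero(sig[f] & (rho_all[f] < 0))
                n_sel += pos_idx.size + neg_idx.size
                if pos_idx.size == 0 and neg_idx.size == 0:
                    preds[f] = y[idx].mean()
                    continue
                x1 = edge_table[idx][:, pos_idx].sum(axis=1) if pos_idx.size \
                    else np.zeros(idx.size)
                x2 = edge_table[idx][:, neg_idx].sum(axis=1) if neg_idx.size \
                    else np.zeros(idx.size)
                try:
                    a1, a2, b = _fit_two_features(x1, x2, y[idx])
                except SingularFitError:
                    preds[f] = y[idx].mean()
                    continue
                h1 = edge_table[f, pos_idx].sum() if pos_idx.size else 0.0
                h2 = edge_table[f, neg_idx].sum() if neg_idx.size else 0.0
                preds[f] = a1 * h1 + a2 * h2 + b
            if np.ptp(preds) <= 1e-12:
                rows.append((thr, np.nan, np.nan, n_sel))
                continue
            rows.append((thr, _spearman_stat(preds, y),
                         float(np.mean((preds - y) ** 2)), n_sel))
    table = pd.DataFrame(rows, columns=["p_threshold", "r_true", "mse", "n_selected"])
    if table["r_true"].isna().all():
        raise _Empty(f"no threshold in the grid yields a usable {variant} model")
    best_r = table["r_true"].max()
    best = table.loc[table["r_true"] == best_r, "p_threshold"].min()
    return float(best), table


def steiger_z(r_jk: float, r_jh: float, r_kh: float, n: int) -> tuple[float, float]:
    """Steiger's Z for two dependent correlations sharing variable j.

    Tests whether corr(j, k) differs from corr(j, h) given corr(k, h), for
    correlations estimated on the same ``n`` subjects.  Both compared
    correlations are Fisher-z transformed; their covariance is estimated by
    plugging the pooled correlation ``rbar = (r_jk + r_jh) / 2`` into the
    asymptotic covariance of dependent correlations (Steiger's Z1* with the
    pooled estimate), and the statistic

        Z = (z_jk - z_jh) * sqrt((n - 3) / (2 - 2 * s))

    is referred to the standard normal, two-sided.
    """
    for name, r in (("r_jk", r_jk), ("r_jh", r_jh), ("r_kh", r_kh)):
        if not -1 <= r <= 1:
            raise InputError(f"{name} = {r} outside [-1, 1]")
        if name != "r_kh" and abs(r) == 1:
            raise InputError(f"{name} = {r}: Fisher transform diverges at |r| = 1")
    if n < 4:
        raise SampleSizeError("Steiger's Z needs at least 4 subjects")
    z_jk = np.arctanh(r_jk)
    z_jh = np.arctanh(r_jh)
    rbar = (r_jk + r_jh) / 2.0
    psi = r_kh * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r_kh**2)
    s = psi / (1 - rbar**2) ** 2
    denom = 2.0 - 2.0 * s
    if denom <= 0:
        raise InputError("correlation triple is inconsistent (non-PSD)")
    z = (z_jk - z_jh) * np.sqrt((n - 3) / denom)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def compare_predictions(
    pred_a, pred_b, observed, method: str = "spearman"
) -> ModelComparison:
    """Steiger comparison of two models' predictive correlations.

    Computes corr(observed, pred_a), corr(observed, pred_b) and
    corr(pred_a, pred_b) (Spearman by default, matching the pipeline's
    evaluation statistic) and runs :func:`steiger_z` on the triple.
    """
    a = np.asarray(pred_a, dtype=float)
    b = np.asarray(pred_b, dtype=float)
    y = np.asarray(observed, dtype=float)
    if not (a.shape == b.shape == y.shape) or a.ndim != 1:
        raise InputError("prediction and observation vectors must be aligned")
    if method == "spearman":
        a, b, y = rankdata(a), rankdata(b), rankdata(y)
    elif method != "pearson":
        raise InputError("method must be 'spearman' or 'pearson'")
    r_ya = float(np.corrcoef(y, a)[0, 1])
    r_yb = float(np.corrcoef(y, b)[0, 1])
    r_ab = float(np.corrcoef(a, b)[0, 1])
    if abs(r_ab) >= 1.0 or r_ya == r_yb:
        # identical (or rank-identical) prediction vectors: no difference
        z, p = 0.0, 1.0
    else:
        z, p = steiger_z(r_ya, r_yb, r_ab, y.size)
    return ModelComparison(
        model_a_r=r_ya, model_b_r=r_yb, r_ab=r_ab, n=y.size, z=z, p=p
    )


def edge_overlap(mask_a: EdgeMask, mask_b: EdgeMask, method: str = "reference") -> float:
    """Percentage overlap of two edge masks.

    ``reference`` (default): 100 * |a intersect b| / |a|, i.e. how much of the
    reference mask ``a`` reappears in ``b``.  ``jaccard``: symmetric
    100 * |a intersect b| / |a union b|.
    """
    if mask_a.n_nodes != mask_b.n_nodes:
        raise InputError("masks disagree on n_nodes")
    sa, sb = mask_a.as_set(), mask_b.as_set()
    if method == "reference":
        if not sa:
            raise InputError("overlap undefined: reference mask is empty")
        return 100.0 * len(sa & sb) / len(sa)
    if method == "jaccard":
        if not (sa | sb):
            raise InputError("overlap undefined: both masks are empty")
        return 100.0 * len(sa & sb) / len(sa | sb)
    raise InputError("method must be 'reference' or 'jaccard'")


def fit_hybrid(
    matrices,
    scores,
    positive_mask: EdgeMask,
    negative_mask: EdgeMask,
    clinical_covariates,
    n_nodes=None,
) -> tuple[HybridModel, EvaluationResult]:
    """Augment the two-feature connectome model with clinical factors.

    Ordinary least squares of the score on (positive sum, negative sum,
    clinical covariates, intercept).  Covariate columns must be complete and
    the design full rank.
    """
    from .cpm import summed_strengths

    edge_table, n = as_edge_table(matrices, n_nodes)
    y = np.asarray(scores, dtype=float)
    cov, names = _as_covariate_array(clinical_covariates)
    if cov is None:
        raise InputError("hybrid model requires at least one clinical covariate")
    if np.any(~np.isfinite(cov)):
        raise InputError("clinical covariates contain missing values")
    if cov.shape[0] != y.size:
        raise InputError("covariate rows do not match the number of subjects")
    x1 = summed_strengths(edge_table, positive_mask, n_nodes=n)
    x2 = summed_strengths(edge_table, negative_mask, n_nodes=n)
    X = np.column_stack([np.ones(y.size), x1, x2, cov])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise SingularFitError("hybrid design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    coefs = {"intercept": float(beta[0]), "positive_sum": float(beta[1]),
             "negative_sum": float(beta[2])}
    for k, name in enumerate(names):
        coefs[name] = float(beta[3 + k])
    model = HybridModel(positive_mask, negative_mask, coefs, tuple(names))
    preds = X @ beta
    return model, evaluate(preds, y)
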