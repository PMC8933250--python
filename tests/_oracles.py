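"""Independent brute-force reimplementations used as test oracles.

Everything here is deliberately written from first principles — explicit
rank loops, normal equations, exhaustive edge enumeration — and stays
independent of the package's vectorized code paths it is used to check.
Only scipy distribution functions (t / normal tail probabilities) are
shared, since those are textbook special functions, not pipeline logic.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def manual_ranks(values) -> list[float]:
    """Average ranks (1-based) computed by explicit sorting and tie groups."""
    values = list(map(float, values))
    order = sorted(range(len(values)), key=lambda k: values[k])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0  # mean of 1-based positions i..j
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def _normal_equations_residuals(y: list[float], covs: list[list[float]]) -> list[float]:
    """Residual of y on [1, covs] solved via explicit normal equations."""
    n = len(y)
    X = [[1.0] + [c[k] for c in covs] for k in range(n)]
    p = len(X[0])
    XtX = [[sum(X[a][i] * X[a][j] for a in range(n)) for j in range(p)] for i in range(p)]
    Xty = [sum(X[a][i] * y[a] for a in range(n)) for i in range(p)]
    beta = np.linalg.solve(np.array(XtX), np.array(Xty))
    return [y[a] - sum(beta[i] * X[a][i] for i in range(p)) for a in range(n)]


def partial_spearman_oracle(x, y, covariates=None) -> tuple[float, float]:
    """Rank everything, residualize on ranked covariates, correlate residuals."""
    n = len(x)
    rx = manual_ranks(x)
    ry = manual_ranks(y)
    if covariates is None or len(covariates) == 0:
        covs = []
    else:
        covs = [manual_ranks(col) for col in np.asarray(covariates, dtype=float).T]
    ex = _normal_equations_residuals(rx, covs)
    ey = _normal_equations_residuals(ry, covs)
    sxy = sum(a * b for a, b in zip(ex, ey))
    sxx = sum(a * a for a in ex)
    syy = sum(b * b for b in ey)
    rho = sxy / math.sqrt(sxx * syy)
    k = len(covs)
    df = n - 2 - k
    t = rho * math.sqrt(df / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df)
    return rho, p


def select_oracle(edge_table, y, covariates, threshold) -> tuple[set, set]:
    """Exhaustive per-edge loop returning flat-index candidate sets."""
    pos, neg = set(), set()
    for e in range(edge_table.shape[1]):
        rho, p = partial_spearman_oracle(list(edge_table[:, e]), list(y), covariates)
        if p < threshold and rho > 0:
            pos.add(e)
        elif p < threshold and rho < 0:
            neg.add(e)
    return pos, neg


def loocv_consensus_oracle(edge_table, y, covariates, threshold):
    """Leave-one-out loop, explicit intersection of per-fold candidate sets."""
    n = edge_table.shape[0]
    pos_sets, neg_sets = [], []
    for held_out in range(n):
        keep = [k for k in range(n) if k != held_out]
        cov_sub = None if covariates is None else np.asarray(covariates)[keep]
        p_set, n_set = select_oracle(
            edge_table[keep], [y[k] for k in keep], cov_sub, threshold
        )
        pos_sets.append(p_set)
        neg_sets.append(n_set)
    pos = set.intersection(*pos_sets)
    neg = set.intersection(*neg_sets)
    return pos, neg, pos_sets, neg_sets


def ols_oracle(y, features) -> list[float]:
    """[intercept, coefs...] via explicit normal equations."""
    n = len(y)
    X = [[1.0] + [f[k] for f in features] for k in range(n)]
    p = len(X[0])
    XtX = [[sum(X[a][i] * X[a][j] for a in range(n)) for j in range(p)] for i in range(p)]
    Xty = [sum(X[a][i] * y[a] for a in range(n)) for i in range(p)]
    return list(np.linalg.solve(np.array(XtX), np.array(Xty)))


def spearman_oracle(a, b) -> float:
    ra, rb = manual_ranks(a), manual_ranks(b)
    ma = sum(ra) / len(ra)
    mb = sum(rb) / len(rb)
    num = sum((x - ma) * (y - mb) for x, y in zip(ra, rb))
    den = math.sqrt(
        sum((x - ma) ** 2 for x in ra) * sum((y - mb) ** 2 for y in rb)
    )
    return num / den


def steiger_oracle(r_jk, r_jh, r_kh, n) -> tuple[float, float]:
    """Independent transcription of the dependent-correlation Z statistic
    (two correlations sharing one variable, pooled-correlation covariance)."""
    zjk = 0.5 * math.log((1 + r_jk) / (1 - r_jk))
    zjh = 0.5 * math.log((1 + r_jh) / (1 - r_jh))
    rbar = 0.5 * (r_jk + r_jh)
    psi = r_kh * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r_kh**2)
    sbar = psi / (1 - rbar**2) ** 2
    z = (zjk - zjh) * math.sqrt((n - 3) / (2 - 2 * sbar))
    p = 2.0 * stats.norm.sf(abs(z))
    return z, p


def summed_strength_oracle(z_matrix, edges) -> float:
    total = 0.0
    for i, j in edges:
        total += z_matrix[i][j]
    return total


def pipeline_oracle(edge_table, y, covariates, threshold):
    """Full brute-force pipeline: consensus -> sums -> OLS -> Spearman r."""
    pos, neg, pos_sets, neg_sets = loocv_consensus_oracle(
        edge_table, y, covariates, threshold
    )
    n = edge_table.shape[0]
    x1 = [sum(edge_table[s, e] for e in sorted(pos)) for s in range(n)]
    x2 = [sum(edge_table[s, e] for e in sorted(neg)) for s in range(n)]
    feats = []
    if len(set(x1)) > 1:
        feats.append(x1)
    if len(set(x2)) > 1:
        feats.append(x2)
    if not feats:  # empty consensus: no model to evaluate
        return {
            "pos": pos, "neg": neg, "pos_sets": pos_sets, "neg_sets": neg_sets,
            "beta": None, "pred": None, "r_true": None,
        }
    beta = ols_oracle(list(y), feats)
    pred = []
    for s in range(n):
        v = beta[0]
        for f_i, f in enumerate(feats):
            v += beta[1 + f_i] * f[s]
        pred.append(v)
    r = spearman_oracle(pred, list(y))
    return {
        "pos": pos,
        "neg": neg,
        "pos_sets": pos_sets,
        "neg_sets": neg_sets,
        "beta": beta,
        "pred": pred,
        "r_true": r,
    }
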