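"""Synthetic cohorts with planted brain-behavior structure.

Emulates the statistical shape of a drug-naive Parkinson's disease cohort:
a right-skewed motor-severity score (UPDRS III range), clinical covariates
(age and disease duration correlated with the score, gender as pure noise),
per-subject mean head motion, and 268-node Fisher-z connectivity matrices in
which a known set of "planted" edges carries a controlled positive or
negative rank correlation with the score.  Because the planted edge sets are
known, every downstream stage (selection, consensus, permutation inference,
lesioning) has a ground-truth test surface.

The edge model is the simplest monotone coupling consistent with rank-based
selection: planted strength = baseline + beta * standardized(score) + noise,
with beta calibrated through the Gaussian-copula relation between Pearson
and Spearman correlation so the *rank* correlation hits the configured
effect size in expectation.  Voxel-level BOLD, scanner noise and
hemodynamics are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from ._exceptions import ConfigError
from .connectome import ConnectivityMatrix, ParcelTimeSeries
from .cpm import EdgeMask

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_null_cohort",
    "generate_timeseries_cohort",
]

#: Baseline Fisher-z edge strength around which all edges fluctuate.
BASE_EDGE_MEAN = 0.2

_AGE_MEAN, _AGE_SD = 57.7, 10.1          # years, matches the modeled cohort
_DURATION_LOG_MU, _DURATION_LOG_SD = 0.6, 0.9   # lognormal disease duration, years
_FD_LOG_MU, _FD_LOG_SD = np.log(0.08), 0.45     # lognormal mean FD, mm


def _spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula conversion: latent Pearson r giving Spearman rho_s."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort generator.

    Parameters
    ----------
    n_subjects, n_nodes : int
        Cohort and parcellation size.  Defaults mirror the modeled study:
        47 drug-naive subjects on a 268-node atlas.
    n_planted_positive, n_planted_negative : int
        How many edges are coupled to the score with each sign.  Defaults
        mirror the 57 positive / 58 negative consensus connections of the
        modeled study.
    effect_size : float in [0, 1)
        Target Spearman correlation magnitude between a planted edge's
        strength and the score.
    noise_sd : float > 0
        Standard deviation of the Gaussian edge noise (Fisher-z units).
    score_range : (low, high)
        Behavioral score range; scores are a scaled right-skewed Beta on it.
    score_beta : (a, b)
        Beta shape parameters; (2, 5) gives pronounced right skew.
    covariate_effects : mapping
        Target Spearman correlation of each continuous covariate with the
        score (age ~ .40, duration ~ .53 by default).
    seed : int
        Root seed; identical seeds reproduce identical cohorts bit-for-bit.
    """

    n_subjects: int = 47
    n_nodes: int = 268
    n_planted_positive: int = 57
    n_planted_negative: int = 58
    effect_size: float = 0.6
    noise_sd: float = 0.25
    score_range: tuple[float, float] = (4.0, 68.0)
    score_beta: tuple[float, float] = (2.0, 5.0)
    covariate_effects: dict = field(
        default_factory=lambda: {"age": 0.40, "duration": 0.53}
    )
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 4:
            raise ConfigError("n_subjects must be at least 4")
        if self.n_nodes < 2:
            raise ConfigError("n_nodes must be at least 2")
        max_edges = self.n_nodes * (self.n_nodes - 1) // 2
        if self.n_planted_positive < 0 or self.n_planted_negative < 0:
            raise ConfigError("n_planted_positive/n_planted_negative must be >= 0")
        if self.n_planted_positive + self.n_planted_negative > max_edges:
            raise ConfigError(
                f"n_planted_positive + n_planted_negative exceeds the "
                f"{max_edges} available edges"
            )
        if not 0 <= self.effect_size < 1:
            raise ConfigError("effect_size must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        lo, hi = self.score_range
        if not lo < hi:
            raise ConfigError("score_range must be (low, high) with low < high")
        for name, r in self.covariate_effects.items():
            if not -1 < r < 1:
                raise ConfigError(f"covariate_effects[{name!r}] must lie in (-1, 1)")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed must be an integer")

    def to_yaml(self, path) -> None:
        data = {
            "n_subjects": self.n_subjects,
            "n_nodes": self.n_nodes,
            "n_planted_positive": self.n_planted_positive,
            "n_planted_negative": self.n_planted_negative,
            "effect_size": float(self.effect_size),
            "noise_sd": float(self.noise_sd),
            "score_range": [float(v) for v in self.score_range],
            "score_beta": [float(v) for v in self.score_beta],
            "covariate_effects": {k: float(v) for k, v in self.covariate_effects.items()},
            "seed": int(self.seed),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError("simulation config file is not a key-value mapping")
        for tup in ("score_range", "score_beta"):
            if tup in data:
                data[tup] = tuple(data[tup])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(f"unrecognized simulation config field: {exc}") from exc


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth that generated it."""

    matrices: list[ConnectivityMatrix]
    phenotypes: pd.DataFrame
    truth_positive: EdgeMask
    truth_negative: EdgeMask
    config: SimulationConfig

    @property
    def scores(self) -> np.ndarray:
        return self.phenotypes["score"].to_numpy(dtype=float)

    def covariates(self, names=("age", "gender", "duration")) -> pd.DataFrame:
        return self.phenotypes.loc[:, list(names)]


def _draw_phenotypes(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_subjects
    z_score = rng.standard_normal(n)
    u = stats.norm.cdf(z_score)
    a, b = config.score_beta
    lo, hi = config.score_range
    score = lo + (hi - lo) * stats.beta.ppf(u, a, b)

    # Gaussian copula: each covariate's latent shares rho_latent with the
    # score latent, so its rank correlation with the score hits the target.
    cov_cols = {}
    for name, rho_s in config.covariate_effects.items():
        rho_l = _spearman_to_pearson(rho_s)
        z = rho_l * z_score + np.sqrt(1 - rho_l**2) * rng.standard_normal(n)
        cov_cols[name] = z
    age = _AGE_MEAN + _AGE_SD * cov_cols.get("age", rng.standard_normal(n))
    duration = np.exp(
        _DURATION_LOG_MU
        + _DURATION_LOG_SD * cov_cols.get("duration", rng.standard_normal(n))
    )
    gender = rng.integers(0, 2, size=n)
    mean_fd = np.exp(_FD_LOG_MU + _FD_LOG_SD * rng.standard_normal(n))
    # ordinal clinical stage: coarse discretization of severity
    lo_t, hi_t = lo + (hi - lo) / 4, lo + (hi - lo) / 2
    hy_stage = 1 + (score > lo_t).astype(int) + (score > hi_t).astype(int)
    return pd.DataFrame(
        {
            "subject_id": [f"sub-{k + 1:03d}" for k in range(n)],
            "score": score,
            "age": age,
            "gender": gender,
            "duration": duration,
            "hy_stage": hy_stage,
            "mean_fd": mean_fd,
        }
    )


def _pick_truth(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[EdgeMask, EdgeMask]:
    m = config.n_nodes * (config.n_nodes - 1) // 2
    total = config.n_planted_positive + config.n_planted_negative
    chosen = rng.choice(m, size=total, replace=False)
    pos = np.sort(chosen[: config.n_planted_positive])
    neg = np.sort(chosen[config.n_planted_positive:])
    return (
        EdgeMask.from_flat(config.n_nodes, pos, "positive"),
        EdgeMask.from_flat(config.n_nodes, neg, "negative"),
    )


def generate_cohort(
    config: SimulationConfig,
    truth: tuple[EdgeMask, EdgeMask] | None = None,
) -> SyntheticCohort:
    """Generate connectivity matrices and phenotypes with planted structure.

    Planted positive edges increase (and negative edges decrease) with the
    behavioral score at the configured rank-correlation effect size; all
    other edges are independent noise around the same baseline.  Passing
    ``truth`` reuses an existing pair of planted masks, e.g. to generate an
    independent validation cohort sharing the training cohort's ground truth.
    """
    rng = np.random.default_rng(config.seed)
    pheno = _draw_phenotypes(config, rng)
    if truth is None:
        truth_pos, truth_neg = _pick_truth(config, rng)
    else:
        truth_pos, truth_neg = truth
        if truth_pos.n_nodes != config.n_nodes or truth_neg.n_nodes != config.n_nodes:
            raise ConfigError("supplied truth masks do not match n_nodes")
        if truth_pos.as_set() & truth_neg.as_set():
            raise ConfigError("truth masks must be disjoint")
        # keep the generator's random stream identical whether or not the
        # planted positions were reused
        _pick_truth(config, rng)

    n, n_nodes = config.n_subjects, config.n_nodes
    m = n_nodes * (n_nodes - 1) // 2
    score = pheno["score"].to_numpy()
    s_std = (score - score.mean()) / score.std()

    if config.effect_size > 0:
        rho_p = _spearman_to_pearson(config.effect_size)
        beta = config.noise_sd * rho_p / np.sqrt(1 - rho_p**2)
    else:
        beta = 0.0

    edges = BASE_EDGE_MEAN + config.noise_sd * rng.standard_normal((n, m))
    if beta:
        edges[:, truth_pos.flat_indices()] += beta * s_std[:, None]
        edges[:, truth_neg.flat_indices()] -= beta * s_std[:, None]

    i, j = np.triu_indices(n_nodes, k=1)
    matrices = []
    for k in range(n):
        z = np.zeros((n_nodes, n_nodes))
        z[i, j] = edges[k]
        z += z.T
        matrices.append(ConnectivityMatrix(pheno["subject_id"].iloc[k], z))
    return SyntheticCohort(matrices, pheno, truth_pos, truth_neg, config)


def generate_null_cohort(config: SimulationConfig) -> SyntheticCohort:
    """As :func:`generate_cohort` with all score structure removed.

    The planted edge effect *and* the covariate-score correlations are forced
    to zero, so the score is exchangeable across subjects — the exact null
    hypothesis of the score-shuffling permutation test.  (With covariates
    still correlated with the score, the score-only shuffle is conservative,
    not calibrated: observed consensus edges are selected against the
    covariate-residualized score while permuted ones are not.)  Truth masks
    are empty.
    """
    null_cfg = replace(
        config,
        effect_size=0.0,
        covariate_effects={k: 0.0 for k in config.covariate_effects},
    )
    cohort = generate_cohort(null_cfg)
    empty_pos = EdgeMask(config.n_nodes, (), "positive")
    empty_neg = EdgeMask(config.n_nodes, (), "negative")
    return SyntheticCohort(
        cohort.matrices, cohort.phenotypes, empty_pos, empty_neg, null_cfg
    )


def generate_timeseries_cohort(
    config: SimulationConfig,
    n_volumes: int = 195,
    fd_spike_rate: float = 0.05,
    factor_loading: float = 0.6,
    fd_spike_floor: float = 0.2,
) -> tuple[list[ParcelTimeSeries], pd.DataFrame]:
    """Node time series from a latent-factor model, with motion spikes.

    Each planted edge's node pair shares a latent factor with loading
    ``factor_loading``, giving the pair a controlled signal correlation
    (exactly 1 at loading 1).  The FD trace is a low lognormal baseline with
    spikes at or above ``fd_spike_floor`` (the scrub threshold) occurring
    independently per volume at ``fd_spike_rate``.  The default volume count
    matches a 205-volume acquisition after dropping 10 equilibration volumes.
    """
    if n_volumes < 1:
        raise ConfigError("n_volumes must be at least 1")
    if not 0 <= fd_spike_rate <= 1:
        raise ConfigError("fd_spike_rate must lie in [0, 1]")
    if not 0 <= factor_loading <= 1:
        raise ConfigError("factor_loading must lie in [0, 1]")
    rng = np.random.default_rng(config.seed)
    pheno = _draw_phenotypes(config, rng)
    truth_pos, truth_neg = _pick_truth(config, rng)
    pairs = list(truth_pos.edges) + list(truth_neg.edges)

    lam = factor_loading
    idio = np.sqrt(max(1.0 - lam**2, 0.0))
    out = []
    for k in range(config.n_subjects):
        signal = idio * rng.standard_normal((n_volumes, config.n_nodes))
        if pairs:
            factors = rng.standard_normal((n_volumes, len(pairs)))
            for p_i, (a, b) in enumerate(pairs):
                signal[:, a] += lam * factors[:, p_i]
                signal[:, b] += lam * factors[:, p_i]
        fd = np.exp(_FD_LOG_MU + 0.3 * rng.standard_normal(n_volumes))
        fd = np.minimum(fd, fd_spike_floor * 0.95)  # baseline stays sub-threshold
        spikes = rng.random(n_volumes) < fd_spike_rate
        fd[spikes] = fd_spike_floor + rng.exponential(0.1, size=spikes.sum())
        out.append(
            ParcelTimeSeries(pheno["subject_id"].iloc[k], signal, fd)
        )
    return out, pheno
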