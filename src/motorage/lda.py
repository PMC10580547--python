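"""Hyperspherical projection and GA axis search (the LDA-value machinery).

The normalized feature vector c = (c1..cn) of each participant (all entries
in [0.1, 1.1], hence strictly positive) is written in hyperspherical form

    p = ||c||,   theta_k = arctan( c_{k+1} / ||(c_1..c_k)|| ),  k = 1..n-1,

and projected onto a rotated one-dimensional axis by

    LDA-value = p * prod_k cos(theta_k + theta_hat_k),

where theta_hat is the rotation-angle vector of an imaginary axis.  A
real-coded genetic algorithm searches for the theta_hat that maximizes the
between-group separability

    E_z = sum_{i<j} | (mean_i - mean_j) / sqrt(var_i + var_j) |

summed over all unordered group pairs (population variances).  Features
whose removal changes E_z by less than 1% are then discarded and the axis
is re-optimized on the survivors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NORMALIZATION_OFFSET = 0.1
TWO_PI = 2.0 * np.pi


@dataclass
class GAConfig:
    """Genetic-algorithm hyperparameters (production defaults of the method)."""

    epochs: int = 50_000
    s: int = 50                       # population size (number of axes)
    xi: int = 8                       # number of classes
    p_mutation: float = 0.1
    p_crossover: float = 0.8
    seed: int | None = None
    relevance_threshold: float = 0.01
    ez_epsilon: float = 1e-12
    elitism: bool = True

    def __post_init__(self) -> None:
        if self.s < 2:
            raise ValueError("population size must be >= 2")
        if not (0 <= self.p_mutation <= 1 and 0 <= self.p_crossover <= 1):
            raise ValueError("probabilities must lie in [0, 1]")


# ---------------------------------------------------------------------------
# representation


def normalize_columns(features: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalize each column to [0, 1] and add a 0.1 offset.

    The offset keeps every entry strictly positive so the hyperspherical
    angles are well defined.  A constant column maps to all-0.1.
    """
    values = features.to_numpy(dtype=float)
    lo = values.min(axis=0)
    rng_ = values.max(axis=0) - lo
    safe = np.where(rng_ == 0.0, 1.0, rng_)
    normed = (values - lo) / safe + NORMALIZATION_OFFSET
    if (rng_ == 0.0).any():
        logger.info("constant columns normalized to %.1f", NORMALIZATION_OFFSET)
    return pd.DataFrame(normed, index=features.index, columns=features.columns)


def to_hyperspherical(c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Radius and angle vector of positive vectors (rows).

    Accepts one vector of length n or a matrix (n_obs, n); returns
    (p, theta) with theta of length n-1 per observation.  Satisfies the
    reconstruction identity p * prod(cos(theta_k)) = c_1.
    """
    c = np.asarray(c, dtype=float)
    single = c.ndim == 1
    C = c[None, :] if single else c
    if (C <= 0).any():
        raise ValueError("hyperspherical representation requires strictly positive entries")
    sq = np.cumsum(C**2, axis=1)
    p = np.sqrt(sq[:, -1])
    theta = np.arctan(C[:, 1:] / np.sqrt(sq[:, :-1]))
    if single:
        return float(p[0]), theta[0]
    return p, theta


def project_lda_value(p, theta: np.ndarray, axis: np.ndarray) -> np.ndarray | float:
    """p * prod_k cos(theta_k + axis_k).

    ``theta`` may be one angle vector or a matrix (n_obs, n-1); ``axis`` a
    single rotation vector or a stack (s, n-1).  Output shapes follow:
    scalar, (n_obs,), (s,) or (s, n_obs).
    """
    theta = np.asarray(theta, dtype=float)
    axis = np.asarray(axis, dtype=float)
    single_obs = theta.ndim == 1
    single_axis = axis.ndim == 1
    T = theta[None, :] if single_obs else theta          # (n_obs, k)
    A = axis[None, :] if single_axis else axis           # (s, k)
    if T.shape[1] != A.shape[1]:
        raise ValueError("angle-vector length mismatch")
    prod = np.prod(np.cos(T[None, :, :] + A[:, None, :]), axis=2)  # (s, n_obs)
    out = np.asarray(p, dtype=float) * prod
    if single_axis and single_obs:
        return float(out[0, 0])
    if single_axis:
        return out[0]
    if single_obs:
        return out[:, 0]
    return out


# ---------------------------------------------------------------------------
# separability


def _group_indices(groups) -> list[np.ndarray]:
    groups = np.asarray(groups)
    return [np.nonzero(groups == g)[0] for g in np.unique(groups)]


def separability_ez(values, groups, ez_epsilon: float = 1e-12) -> float:
    """Sum over group pairs of |standardized mean difference| (pop. variance)."""
    values = np.asarray(values, dtype=float)
    idx = _group_indices(groups)
    if len(idx) < 2:
        raise ValueError("need at least 2 groups")
    if any(ix.size < 2 for ix in idx):
        raise ValueError("every group needs at least 2 members")
    means = np.array([values[ix].mean() for ix in idx])
    var = np.array([values[ix].var() for ix in idx])
    total = 0.0
    for i in range(len(idx)):
        for j in range(i + 1, len(idx)):
            denom = np.sqrt(max(var[i] + var[j], ez_epsilon))
            total += abs((means[i] - means[j]) / denom)
    return float(total)


def _ez_batch(values: np.ndarray, idx: list[np.ndarray], ez_epsilon: float) -> np.ndarray:
    """E_z for each row of ``values`` (s, n_obs); vectorized over axes."""
    means = np.stack([values[:, ix].mean(axis=1) for ix in idx], axis=1)
    var = np.stack([values[:, ix].var(axis=1) for ix in idx], axis=1)
    g = len(idx)
    total = np.zeros(values.shape[0])
    for i in range(g):
        for j in range(i + 1, g):
            denom = np.sqrt(np.maximum(var[:, i] + var[:, j], ez_epsilon))
            total += np.abs((means[:, i] - means[:, j]) / denom)
    return total


# ---------------------------------------------------------------------------
# genetic algorithm


def init_population(cfg: GAConfig, n_angles: int, rng: np.random.Generator) -> np.ndarray:
    """s axes with angles drawn uniformly on [0, 2*pi)."""
    if n_angles < 1:
        raise ValueError("need at least one angle")
    return rng.uniform(0.0, TWO_PI, size=(cfg.s, n_angles))


def evolve_generation(
    population: np.ndarray,
    fitness: np.ndarray,
    cfg: GAConfig,
    rng: np.random.Generator,
    eval_fn,
) -> tuple[np.ndarray, np.ndarray]:
    """One GA generation: roulette selection, arithmetic crossover, mutation.

    Parents are the roulette-selected matrix K traversed in consecutive
    pairs.  Each pair spawns three children (1.5*p1-0.5*p2, the midpoint,
    and -0.5*p1+1.5*p2, wrapped to [0, 2*pi)); with probability
    ``p_crossover`` the two fittest children replace the pair, otherwise
    the parents pass through.  Every gene then mutates to a fresh uniform
    angle with probability ``p_mutation``.  ``eval_fn`` maps a stack of
    axes to their fitness.  Returns (new_population, new_fitness) with the
    new fitness evaluated after mutation.
    """
    s, n_angles = population.shape
    total = fitness.sum()
    if total > 0:
        probs = fitness / total
    else:
        probs = np.full(s, 1.0 / s)  # degenerate fitness: uniform selection
    K = population[rng.choice(s, size=s, p=probs)]

    new = K.copy()
    n_pairs = s // 2
    if n_pairs:
        cross = rng.random(n_pairs) < cfg.p_crossover
        if cross.any():
            p1 = K[0 : 2 * n_pairs : 2][cross]
            p2 = K[1 : 2 * n_pairs : 2][cross]
            children = np.concatenate(
                [1.5 * p1 - 0.5 * p2, 0.5 * p1 + 0.5 * p2, -0.5 * p1 + 1.5 * p2]
            ) % TWO_PI
            cfit = eval_fn(children).reshape(3, -1)          # (3, n_cross)
            order = np.argsort(-cfit, axis=0)                # best children first
            nc = p1.shape[0]
            kids = children.reshape(3, nc, n_angles)
            slots = np.nonzero(cross)[0]
            for w, slot in enumerate(slots):
                new[2 * slot] = kids[order[0, w], w]
                new[2 * slot + 1] = kids[order[1, w], w]

    mut = rng.random(new.shape) < cfg.p_mutation
    if mut.any():
        new[mut] = rng.uniform(0.0, TWO_PI, size=int(mut.sum()))
    return new, eval_fn(new)


@dataclass
class GAInternals:
    """Audit trail of one GA run."""

    best_axis: np.ndarray
    best_ez: float
    ez_trace: np.ndarray              # best-so-far per epoch
    projections: np.ndarray           # best axis applied to all participants
    final_population: np.ndarray
    final_fitness: np.ndarray         # E_zVec of the last generation
    last_selection: np.ndarray | None = None


def run_ga(
    p: np.ndarray,
    theta: np.ndarray,
    groups,
    cfg: GAConfig,
    rng: np.random.Generator | None = None,
) -> GAInternals:
    """Search rotation angles maximizing E_z over ``cfg.epochs`` generations.

    ``p``/``theta`` are the hyperspherical coordinates of all participants;
    the best axis ever seen is kept (and, with elitism, re-injected into
    the population each generation), so the best-so-far trace is monotone.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    theta = np.asarray(theta, dtype=float)
    idx = _group_indices(groups)
    if any(ix.size < 2 for ix in idx):
        raise ValueError("every group needs at least 2 members")

    def eval_fn(axes: np.ndarray) -> np.ndarray:
        values = project_lda_value(p, theta, axes)
        return _ez_batch(np.atleast_2d(values), idx, cfg.ez_epsilon)

    pop = init_population(cfg, theta.shape[1], rng)
    fit = eval_fn(pop)
    best_i = int(np.argmax(fit))
    best_axis = pop[best_i].copy()
    best_ez = float(fit[best_i])
    trace = np.empty(cfg.epochs)
    for epoch in range(cfg.epochs):
        pop, fit = evolve_generation(pop, fit, cfg, rng, eval_fn)
        if cfg.elitism:
            worst = int(np.argmin(fit))
            pop[worst] = best_axis
            fit[worst] = best_ez
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_ez:
            best_ez = float(fit[gen_best])
            best_axis = pop[gen_best].copy()
        trace[epoch] = best_ez
    return GAInternals(
        best_axis=best_axis,
        best_ez=best_ez,
        ez_trace=trace,
        projections=project_lda_value(p, theta, best_axis),
        final_population=pop,
        final_fitness=fit,
    )


# ---------------------------------------------------------------------------
# relevance filtering


def relevance_filter(
    C: pd.DataFrame,
    groups,
    best_axis: np.ndarray,
    cfg: GAConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Score each feature by the E_z change when it is held at its mean.

    relevance_k = |E_z(all) - E_z(feature k frozen)| / E_z(all); features
    below ``cfg.relevance_threshold`` (1% by default) are irrelevant.
    Returns (mask, relevance).  If nothing clears the threshold the single
    most relevant feature is kept, with a warning.
    """
    values = C.to_numpy(dtype=float)
    p, theta = to_hyperspherical(values)
    ez_full = separability_ez(
        project_lda_value(p, theta, best_axis), groups, cfg.ez_epsilon
    )
    n = values.shape[1]
    relevance = np.empty(n)
    col_means = values.mean(axis=0)
    for k in range(n):
        frozen = values.copy()
        frozen[:, k] = col_means[k]
        pk, tk = to_hyperspherical(frozen)
        ez_k = separability_ez(
            project_lda_value(pk, tk, best_axis), groups, cfg.ez_epsilon
        )
        relevance[k] = abs(ez_full - ez_k) / max(ez_full, cfg.ez_epsilon)
    mask = relevance >= cfg.relevance_threshold
    if not mask.any():
        logger.warning("no feature cleared the relevance threshold; keeping the best one")
        mask[int(np.argmax(relevance))] = True
    return mask, relevance


# ---------------------------------------------------------------------------
# the published axis


@dataclass(frozen=True)
class PublishedAxis:
    """The 46 rotation-angle offsets printed for the study's final axis.

    The offsets are shipped as constants for evaluating new data on the
    published axis; they are not re-derivable without the original cohort.
    ``feature_info`` maps each feature letter to its (task, parameter) row
    in the published relevant-feature table (the sensor column is not
    recoverable from the table).  Note the printed equation pairs 46
    features with 46 angles, although n features define n-1 hyperspherical
    angles; the evaluator follows the printed form literally.
    """

    offsets: tuple = (
        2.33, 2.85, 2.21, 2.08, 3.03, 2.50, 2.70, 0.31, 2.62, 2.70,
        2.78, 2.98, 3.03, 3.06, 2.96, 0.18, 3.02, 3.09, 3.20, 8.73,
        -0.16, -6.55, 0.10, 2.89, 2.98, 2.60, 2.90, 2.91, 0.05, 3.41,
        2.55, 2.96, 3.14, 0.18, -3.33, -0.33, 0.34, 0.05, 0.14, 3.02,
        -0.21, 2.82, 2.93, 3.06, 3.07, 0.02,
    )
    feature_labels: tuple = tuple("abcdefghijklmnopqrstuvwxyz") + tuple("ABCDEFGHIJKLMNOPQSTU")

    @property
    def feature_info(self) -> dict:
        rows = {
            1: {"MAV": "af", "MAVFD": "bgkx", "Peak": "cly", "ZC": "ds",
                "FMean": "ehm", "FPeak": "iot", "F50": "p", "F80": "q",
                "Power3.5_7.5": "nuz", "ApEn": "rvA", "VAR": "w", "SKEWNESS": "j"},
            2: {"ZC": "BEI", "FMean": "F", "FPeak": "CK", "F50": "GJL",
                "ApEn": "H", "SKEWNESS": "DM"},
            3: {"ZC": "OS", "FPeak": "N", "ApEn": "PT", "SKEWNESS": "Q",
                "KURTOSIS": "U"},
        }
        return {
            letter: (task, param)
            for task, params in rows.items()
            for param, letters in params.items()
            for letter in letters
        }


PUBLISHED_AXIS = PublishedAxis()


def evaluate_published_axis(
    theta: np.ndarray, R, axis: PublishedAxis | None = None
) -> np.ndarray | float:
    """R * prod_k cos(theta_k + offset_k) with the 46 published offsets."""
    axis = axis or PUBLISHED_AXIS
    theta = np.asarray(theta, dtype=float)
    offsets = np.asarray(axis.offsets, dtype=float)
    if theta.shape[-1] != offsets.size:
        raise ValueError(f"expected {offsets.size} angles, got {theta.shape[-1]}")
    prod = np.prod(np.cos(theta + offsets), axis=-1)
    out = np.asarray(R, dtype=float) * prod
    return float(out) if np.isscalar(R) or np.ndim(out) == 0 else out
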