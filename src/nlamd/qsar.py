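"""Descriptor thinning, GA-driven MLR model selection and validation.

The workflow follows the classical MobyDigs-style recipe:

1. thin the descriptor table — keep the top descriptors by Shannon entropy,
   drop extreme-magnitude columns (|value| outside 10^-5..10^5), then prune
   highly correlated / low-entropy columns;
2. search 3-9 variable MLR models with a steady-state genetic algorithm
   whose fitness is Q2_loo (leave-one-out cross-validated explained
   variance);
3. validate the top candidates by bootstrap (Q2_boot, out-of-bag pooling)
   and Y-scrambling (a(Q2), the chance-correlation intercept), and pick the
   model minimizing f = (1 - Q2_boot) + |a(Q2)|;
4. measure generalization on an external test set (Q2_ext, SDEP).

The published search configuration is 500,000 GA iterations, population
100, reproduction/mutation trade-off 0.5 and a selection bias that switches
from random to tournament parent selection at 80 % of the iterations;
bootstrap uses 5000 repetitions and Y-scrambling 300.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GAConfig",
    "RegressionModel",
    "entropy_filter",
    "magnitude_filter",
    "correlation_filter",
    "thin_table",
    "fit_mlr",
    "q2_loo",
    "ga_select",
    "q2_bootstrap",
    "y_scrambling",
    "model_quality_f",
    "external_validation",
    "stepwise_select",
    "select_best_model",
    "write_report",
    "read_report",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm search configuration (published defaults)."""

    iterations: int = 500_000
    population_size: int = 100
    crossover_prob: float = 0.5  # reproduction/mutation trade-off
    bias_switch_fraction: float = 0.8  # random selection before, tournament after
    min_size: int = 3
    max_size: int = 9
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.min_size <= self.max_size:
            raise ValueError("infeasible model size range")


@dataclass
class RegressionModel:
    """A selected MLR model with its validation statistics."""

    descriptors: tuple[str, ...]
    intercept: float = float("nan")
    coefficients: tuple[float, ...] = ()
    std_errors: tuple[float, ...] = ()
    intercept_se: float = float("nan")
    r2: float = float("nan")
    q2_loo: float = float("nan")
    q2_boot: float = float("nan")
    a_q2: float = float("nan")
    f_value: float = float("nan")
    q2_ext: float = float("nan")
    sdep_ext: float = float("nan")
    n_train: int = 0

    @property
    def size(self) -> int:
        return len(self.descriptors)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xm = np.asarray(X[list(self.descriptors)], dtype=float)
        return self.intercept + Xm @ np.asarray(self.coefficients)


# ---------------------------------------------------------------------------
# descriptor thinning


def _column_entropy(values: np.ndarray, bins: int) -> float:
    """Shannon entropy (bits) of an equal-width histogram of one column."""
    v = np.asarray(values, dtype=float)
    if np.ptp(v) == 0:
        return 0.0
    counts, _ = np.histogram(v, bins=bins)
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def entropy_filter(table: pd.DataFrame, top_k: int = 1000, bins: int | None = None) -> pd.DataFrame:
    """Keep the ``top_k`` descriptors with highest Shannon entropy.

    ``bins`` defaults to the number of molecules. Ties are broken by column
    name so the result is deterministic.
    """
    if bins is None:
        bins = len(table)
    if bins < 2:
        raise ValueError("need at least 2 histogram bins")
    ent = {c: _column_entropy(table[c].to_numpy(), bins) for c in table.columns}
    if all(e == 0 for e in ent.values()):
        log.warning("all descriptor entropies are zero; keeping first %d by name", top_k)
    ranked = sorted(table.columns, key=lambda c: (-ent[c], c))
    return table[ranked[: min(top_k, len(ranked))]]


def magnitude_filter(table: pd.DataFrame, exp_limit: int = 5) -> pd.DataFrame:
    """Drop descriptors containing values with |exponent| beyond ``exp_limit``.

    A column is removed if any |value| > 10^limit or any 0 < |value| <
    10^-limit; exact zeros are not small-exponent values and are retained.
    """
    hi = 10.0 ** exp_limit
    lo = 10.0 ** (-exp_limit)
    keep = []
    for c in table.columns:
        v = np.abs(table[c].to_numpy(dtype=float))
        if np.any(v > hi) or np.any((v > 0) & (v < lo)):
            continue
        keep.append(c)
    return table[keep]


def correlation_filter(table: pd.DataFrame, r_threshold: float = 0.95,
                       entropy_floor: float = 0.3, bins: int | None = None) -> pd.DataFrame:
    """Drop low-standardized-entropy columns, then prune correlated pairs.

    Standardized entropy is H/log2(bins).  Pairs with |Pearson r| at or
    above the threshold lose their lower-entropy member (greedy, scanning
    columns in decreasing entropy order).
    """
    if len(table) < 2:
        raise ValueError("need at least two molecules")
    if bins is None:
        bins = len(table)
    ent = {c: _column_entropy(table[c].to_numpy(), bins) / np.log2(bins)
           for c in table.columns}
    cols = [c for c in table.columns if ent[c] >= entropy_floor]
    cols.sort(key=lambda c: (-ent[c], c))
    if not cols:
        return table[cols]
    X = table[cols].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        R = np.corrcoef(X, rowvar=False)
    R = np.atleast_2d(np.nan_to_num(R))
    kept: list[int] = []
    for j in range(len(cols)):
        if all(abs(R[j, i]) < r_threshold for i in kept):
            kept.append(j)
    survivors = [cols[j] for j in kept]
    return table[[c for c in table.columns if c in set(survivors)]]


def thin_table(table: pd.DataFrame, top_k: int = 1000, exp_limit: int = 5,
               r_threshold: float = 0.95, entropy_floor: float = 0.3) -> pd.DataFrame:
    """Entropy -> magnitude -> correlation thinning, in that order."""
    out = entropy_filter(table, top_k=top_k)
    out = magnitude_filter(out, exp_limit=exp_limit)
    return correlation_filter(out, r_threshold=r_threshold, entropy_floor=entropy_floor)


# ---------------------------------------------------------------------------
# ordinary least squares and cross-validation


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0]), X])


def fit_mlr(X, y, names: tuple[str, ...] | None = None) -> RegressionModel:
    """Ordinary least squares with intercept; coefficients and their SEs."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more rows ({n}) than predictors+1 ({p + 1})")
    A = _design(X)
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix (collinear descriptors)")
    resid = y - A @ beta
    dof = n - p - 1
    sigma2 = resid @ resid / dof
    cov = sigma2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(np.diag(cov))
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - (resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    return RegressionModel(
        descriptors=tuple(names) if names is not None else tuple(f"x{j}" for j in range(p)),
        intercept=float(beta[0]),
        coefficients=tuple(float(b) for b in beta[1:]),
        std_errors=tuple(float(s) for s in se[1:]),
        intercept_se=float(se[0]),
        r2=float(r2),
        n_train=n,
    )


def q2_loo(X, y) -> float:
    """Leave-one-out cross-validated explained variance, 1 - PRESS/SS_tot.

    Uses the hat-matrix identity e_loo,i = e_i / (1 - h_ii), which equals
    the n explicit refits exactly for OLS.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n < p + 2:
        raise ValueError("need at least p + 2 rows for leave-one-out")
    A = _design(X)
    Q, _ = np.linalg.qr(A)
    h = np.sum(Q ** 2, axis=1)
    if np.any(h >= 1.0 - 1e-12):
        raise ValueError("leverage of 1 encountered: a left-out point is unpredictable")
    beta, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    resid = y - A @ beta
    press = np.sum((resid / (1.0 - h)) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return float(1.0 - press / ss_tot)


def _safe_q2_loo(X: np.ndarray, y: np.ndarray) -> float:
    try:
        return q2_loo(X, y)
    except (ValueError, np.linalg.LinAlgError):
        return -np.inf


# ---------------------------------------------------------------------------
# genetic algorithm variable selection


def ga_select(table: pd.DataFrame, y, cfg: GAConfig) -> list[RegressionModel]:
    """Steady-state GA over descriptor subsets with Q2_loo fitness.

    Chromosomes are descriptor subsets of size ``cfg.min_size`` ..
    ``cfg.max_size``.  Each iteration creates one offspring by crossover
    (probability ``crossover_prob``) or mutation, repairs its size, and
    replaces the current worst individual when it improves on it.  Parent
    selection is uniformly random until ``bias_switch_fraction`` of the
    iterations, then switches to tournament selection (pressure ramp-up).
    Returns the final population sorted by decreasing fitness.
    """
    names = list(table.columns)
    p = len(names)
    if cfg.min_size > p:
        raise ValueError(f"min model size {cfg.min_size} exceeds descriptor count {p}")
    Xall = table.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    rng = np.random.default_rng(cfg.seed)

    def fitness(support: tuple[int, ...]) -> float:
        return _safe_q2_loo(Xall[:, list(support)], yv)

    def random_support() -> tuple[int, ...]:
        size = int(rng.integers(cfg.min_size, min(cfg.max_size, p) + 1))
        return tuple(sorted(rng.choice(p, size=size, replace=False)))

    def repair(sup: set[int]) -> tuple[int, ...]:
        while len(sup) > cfg.max_size:
            sup.remove(int(rng.choice(sorted(sup))))
        while len(sup) < cfg.min_size:
            sup.add(int(rng.choice([j for j in range(p) if j not in sup])))
        return tuple(sorted(sup))

    def mutate(sup: tuple[int, ...]) -> tuple[int, ...]:
        s = set(sup)
        move = rng.random()
        outside = [j for j in range(p) if j not in s]
        if (move < 0.4 or len(s) >= cfg.max_size) and len(s) > cfg.min_size:
            s.remove(int(rng.choice(sorted(s))))
        elif move < 0.8 and outside and len(s) < cfg.max_size:
            s.add(int(rng.choice(outside)))
        elif outside:  # swap one member
            s.remove(int(rng.choice(sorted(s))))
            s.add(int(rng.choice(outside)))
        return repair(s)

    def crossover(a: tuple[int, ...], b: tuple[int, ...]) -> tuple[int, ...]:
        union = sorted(set(a) | set(b))
        target = int(rng.integers(min(len(a), len(b)), max(len(a), len(b)) + 1))
        target = min(max(target, cfg.min_size), cfg.max_size)
        take = rng.choice(len(union), size=min(target, len(union)), replace=False)
        return repair({union[t] for t in take})

    if p == cfg.min_size == cfg.max_size:
        sup = tuple(range(p))
        pop = [(sup, fitness(sup))]
    else:
        pop = []
        seen = set()
        while len(pop) < cfg.population_size:
            sup = random_support()
            if sup in seen:
                continue
            seen.add(sup)
            pop.append((sup, fitness(sup)))
        switch_at = int(cfg.bias_switch_fraction * cfg.iterations)
        for it in range(cfg.iterations):
            if it < switch_at:
                i1, i2 = rng.integers(0, len(pop), size=2)
            else:  # tournament of 3
                cand = rng.integers(0, len(pop), size=3)
                best2 = sorted(cand, key=lambda c: -pop[c][1])[:2]
                i1, i2 = best2[0], best2[1]
            if rng.random() < cfg.crossover_prob:
                child = crossover(pop[i1][0], pop[i2][0])
            else:
                child = mutate(pop[i1][0])
            if child in seen:
                child = mutate(child)
                if child in seen:
                    continue
            fit = fitness(child)
            worst = min(range(len(pop)), key=lambda c: pop[c][1])
            if fit > pop[worst][1]:
                seen.discard(pop[worst][0])
                seen.add(child)
                pop[worst] = (child, fit)
    pop.sort(key=lambda sf: -sf[1])
    models = []
    for sup, fit in pop:
        sel = tuple(names[j] for j in sup)
        try:
            m = fit_mlr(Xall[:, list(sup)], yv, names=sel)
        except (ValueError, np.linalg.LinAlgError):
            m = RegressionModel(descriptors=sel)
        m.q2_loo = float(fit)
        models.append(m)
    return models


# ---------------------------------------------------------------------------
# resampling validation


def q2_bootstrap(X, y, reps: int = 5000, seed: int = 0) -> float:
    """Bootstrap validation with pooled out-of-bag prediction errors.

    Each repetition resamples n rows with replacement as a training set,
    fits, and predicts the left-out rows; Q2_boot pools squared errors and
    squared deviations from each repetition's training mean.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n = len(y)
    rng = np.random.default_rng(seed)
    sse = 0.0
    sst = 0.0
    skipped = 0
    for _ in range(reps):
        idx = rng.integers(0, n, size=n)
        oob = np.setdiff1d(np.arange(n), idx)
        if oob.size == 0:
            skipped += 1
            continue
        A = _design(X[idx])
        beta, _, rank, _ = np.linalg.lstsq(A, y[idx], rcond=None)
        if rank < A.shape[1]:
            skipped += 1
            continue
        pred = _design(X[oob]) @ beta
        sse += float(np.sum((y[oob] - pred) ** 2))
        sst += float(np.sum((y[oob] - y[idx].mean()) ** 2))
    if skipped > 0.01 * reps:
        log.warning("bootstrap skipped %d/%d degenerate repetitions", skipped, reps)
    if sst == 0:
        raise ValueError("no usable bootstrap repetitions")
    return 1.0 - sse / sst


def y_scrambling(X, y, reps: int = 300, seed: int = 0, mode: str = "intercept") -> float:
    """Chance-correlation level a(Q2) from response permutation.

    Each repetition permutes y, refits and records the scrambled Q2_loo and
    r = |corr(y_perm, y)|.  ``mode="intercept"`` (default) returns the
    intercept of the least-squares line of Q2 on r, i.e. the r -> 0
    extrapolation; ``mode="mean"`` returns the mean scrambled Q2.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if reps < 2:
        raise ValueError("reps must be >= 2")
    rng = np.random.default_rng(seed)
    q2s = np.empty(reps)
    rs = np.empty(reps)
    for i in range(reps):
        yp = rng.permutation(y)
        q2s[i] = _safe_q2_loo(X, yp)
        rs[i] = abs(np.corrcoef(yp, y)[0, 1])
    ok = np.isfinite(q2s)
    q2s, rs = q2s[ok], rs[ok]
    if mode == "mean":
        return float(np.mean(q2s))
    if np.ptp(rs) == 0:
        return float(np.mean(q2s))
    slope, intercept = np.polyfit(rs, q2s, 1)
    return float(intercept)


def model_quality_f(model: RegressionModel | None = None, q2_boot: float | None = None,
                    a_q2: float | None = None) -> float:
    """Model-choice score f = (1 - Q2_boot) + |a(Q2)|; smaller is better."""
    if model is not None:
        q2_boot, a_q2 = model.q2_boot, model.a_q2
    if q2_boot is None or a_q2 is None or np.isnan(q2_boot) or np.isnan(a_q2):
        raise ValueError("model needs Q2_boot and a(Q2) before scoring")
    return (1.0 - q2_boot) + abs(a_q2)


def external_validation(model: RegressionModel, X_test: pd.DataFrame, y_test,
                        y_train_mean: float) -> tuple[float, float]:
    """(Q2_ext, SDEP) on an external test set.

    The Q2_ext denominator is taken about the *training* mean, so a model
    predicting worse than that mean scores negative.
    """
    y_test = np.asarray(y_test, dtype=float)
    if y_test.size < 1:
        raise ValueError("empty test set")
    pred = model.predict(X_test)
    sse = float(np.sum((y_test - pred) ** 2))
    sst = float(np.sum((y_test - y_train_mean) ** 2))
    if sst == 0:
        raise ValueError("test responses have zero variance about the training mean")
    return 1.0 - sse / sst, float(np.sqrt(sse / y_test.size))


# ---------------------------------------------------------------------------
# convenience selection


def stepwise_select(table: pd.DataFrame, y, p_enter: float = 0.05,
                    p_remove: float = 0.10, max_vars: int | None = None) -> list[str]:
    """Forward/backward stepwise pre-selection on coefficient t-test p-values."""
    y = np.asarray(y, dtype=float)
    selected: list[str] = []
    remaining = list(table.columns)
    max_vars = max_vars or min(len(remaining), len(y) // 3)

    def pvalues(cols: list[str]) -> np.ndarray:
        X = table[cols].to_numpy(dtype=float)
        m = fit_mlr(X, y, names=tuple(cols))
        t = np.asarray(m.coefficients) / np.asarray(m.std_errors)
        dof = len(y) - len(cols) - 1
        return 2 * stats.t.sf(np.abs(t), dof)

    improved = True
    while improved and len(selected) < max_vars:
        improved = False
        best_p, best_c = 1.0, None
        for c in remaining:
            try:
                pv = pvalues(selected + [c])[-1]
            except (ValueError, np.linalg.LinAlgError):
                continue
            if pv < best_p:
                best_p, best_c = pv, c
        if best_c is not None and best_p < p_enter:
            selected.append(best_c)
            remaining.remove(best_c)
            improved = True
            while len(selected) > 1:
                pv = pvalues(selected)
                worst = int(np.argmax(pv))
                if pv[worst] > p_remove:
                    remaining.append(selected.pop(worst))
                else:
                    break
    return selected


def select_best_model(table: pd.DataFrame, y, cfg: GAConfig, top_n: int = 50,
                      boot_reps: int = 5000, scramble_reps: int = 300) -> RegressionModel:
    """GA search, then bootstrap + scrambling on the top models, then f-choice.

    The ``top_n`` models by Q2_loo from the final GA population are
    validated; the one minimizing f = (1 - Q2_boot) + |a(Q2)| is returned
    (with all statistics filled in).
    """
    yv = np.asarray(y, dtype=float)
    pop = ga_select(table, yv, cfg)
    candidates = [m for m in pop if np.isfinite(m.q2_loo)][:top_n]
    if not candidates:
        raise ValueError("GA produced no finite-fitness model")
    best, best_f = None, np.inf
    for rank, m in enumerate(candidates):
        X = table[list(m.descriptors)].to_numpy(dtype=float)
        m.q2_boot = q2_bootstrap(X, yv, reps=boot_reps, seed=cfg.seed + 1000 + rank)
        m.a_q2 = y_scrambling(X, yv, reps=scramble_reps, seed=cfg.seed + 2000 + rank)
        m.f_value = model_quality_f(m)
        if m.f_value < best_f:
            best, best_f = m, m.f_value
    return best


# ---------------------------------------------------------------------------
# model report I/O


def write_report(model: RegressionModel, path) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(model), fh, indent=2)


def read_report(path) -> RegressionModel:
    with open(path) as fh:
        d = json.load(fh)
    for key in ("descriptors", "coefficients", "std_errors"):
        d[key] = tuple(d[key])
    return RegressionModel(**d)
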