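"""Multiple linear regression core: OLS fitting, the frozen published
five-descriptor model, genetic-algorithm variable subset selection, the
similarity/inter-correlation descriptor pre-filter, and the sorted-response
training/test split.

The activity model is affine in the descriptors,

    pIC50 = b0 + sum_j b_j * x_j,

fit by ordinary least squares. Subset selection searches descriptor subsets
of size 1..max maximizing leave-one-out Q^2 (computed with the exact OLS
hat-matrix identity), discarding subsets whose coefficients fail a
per-coefficient t-test at the configured significance level.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MLRModel",
    "GAConfig",
    "GAResult",
    "fit_mlr",
    "predict",
    "published_tlr7_model",
    "coefficient_pvalues",
    "loo_q2_ols",
    "ga_vss",
    "exhaustive_vss",
    "descriptor_prefilter",
    "split_sorted_response",
]

PUBLISHED_INTERCEPT = -6.2155
PUBLISHED_COEFFICIENTS = {
    "VE3sign_D_Dt": 0.1409,
    "SpMin2_Bh_s": 4.1832,
    "P_VSA_logP_5": 0.0366,
    "Eig02_EA_dm": -0.9329,
    "CATS2D_09_AA": -0.1016,
}


@dataclass
class MLRModel:
    """An OLS multiple-linear-regression model with training metadata.

    ``y_mean_train`` and ``tss_train`` (total sum of squares about the
    training mean) are carried so external-validation statistics that
    reference the training distribution can be computed later without the
    training responses.
    """

    intercept: float
    coefficients: dict[str, float]
    training_ids: list[str] = field(default_factory=list)
    y_mean_train: Optional[float] = None
    tss_train: Optional[float] = None
    n_train: Optional[int] = None

    @property
    def k(self) -> int:
        return len(self.coefficients)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "MLRModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        return cls(**json.loads(text))


def _design(X: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
    missing = [n for n in names if n not in X.columns]
    if missing:
        raise KeyError(f"missing descriptor columns: {missing}")
    return np.column_stack([np.ones(len(X)), X[list(names)].to_numpy(dtype=float)])


def fit_mlr(X: pd.DataFrame, y: Sequence[float]) -> MLRModel:
    """Ordinary-least-squares fit of y on the descriptor table X.

    Requires n > k + 1 and a full-column-rank design; rank deficiency is
    reported with the offending (collinear or constant) columns.
    """
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    n, k = len(X), len(names)
    if n != len(y):
        raise ValueError("X and y length mismatch")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 observations (n={n}, k={k})")
    A = _design(X, names)
    rank = np.linalg.matrix_rank(A)
    if rank < k + 1:
        culprits = _collinear_columns(X)
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {k + 1}); "
            f"suspect columns: {culprits}"
        )
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    ids = [str(i) for i in X.index]
    return MLRModel(
        intercept=float(beta[0]),
        coefficients={name: float(b) for name, b in zip(names, beta[1:])},
        training_ids=ids,
        y_mean_train=float(y.mean()),
        tss_train=float(((y - y.mean()) ** 2).sum()),
        n_train=n,
    )


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    out = [c for c in X.columns if X[c].nunique() <= 1]
    corr = X.corr().abs()
    for i, ci in enumerate(X.columns):
        for cj in X.columns[i + 1 :]:
            if corr.loc[ci, cj] > 0.9999:
                out.extend([ci, cj])
    return sorted(set(out))


def predict(model: MLRModel, X: pd.DataFrame) -> np.ndarray:
    """Evaluate the affine model on a descriptor table (column-name matched)."""
    names = list(model.coefficients)
    A = _design(X, names)
    beta = np.array([model.intercept] + [model.coefficients[n] for n in names])
    return A @ beta


def published_tlr7_model() -> MLRModel:
    """The frozen published five-descriptor TLR7 antagonism model."""
    return MLRModel(
        intercept=PUBLISHED_INTERCEPT,
        coefficients=dict(PUBLISHED_COEFFICIENTS),
        n_train=38,
    )


def coefficient_pvalues(X: pd.DataFrame, y: Sequence[float]) -> pd.Series:
    """Two-sided t-test p-values for each OLS coefficient (excl. intercept)."""
    y = np.asarray(y, dtype=float)
    names = list(X.columns)
    A = _design(X, names)
    n, p = A.shape
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    dof = n - p
    if dof <= 0:
        raise ValueError("no residual degrees of freedom")
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    tvals = beta / np.sqrt(np.diag(cov))
    pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    return pd.Series(pvals[1:], index=names)


def loo_q2_ols(X: pd.DataFrame, y: Sequence[float]) -> float:
    """Leave-one-out Q^2 for an OLS fit via the exact hat-matrix identity
    (LOO residual = e_i / (1 - h_ii))."""
    y = np.asarray(y, dtype=float)
    A = _design(X, list(X.columns))
    if np.linalg.matrix_rank(A) < A.shape[1]:
        return -np.inf
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    h = np.einsum("ij,ji->i", A, np.linalg.pinv(A))
    denom = 1.0 - h
    if np.any(denom < 1e-10):
        return -np.inf
    press = float(((resid / denom) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / tss


@dataclass
class GAConfig:
    """Genetic-algorithm settings for variable subset selection.

    The search runs once per subset size from 1 to ``max_subset_size``.
    Fitness is leave-one-out Q^2; subsets with any coefficient p-value at or
    above ``significance`` are discarded from the final ranking. Ties are
    broken by fewer descriptors, then by training R^2.
    """

    max_subset_size: int = 5
    generations: int = 10_000
    significance: float = 0.05
    population: int = 50
    crossover_rate: float = 0.5
    mutation_rate: Optional[float] = None  # default 1/n_descriptors
    tournament: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.max_subset_size, self.generations, self.population) < 1:
            raise ValueError("GA sizes must be positive")
        if not 0 < self.significance < 1:
            raise ValueError("significance must be in (0, 1)")


@dataclass
class GAResult:
    subset: tuple[str, ...]
    model: MLRModel
    fitness: float  # LOO Q^2
    r2: float
    seed: int


def _training_r2(X: pd.DataFrame, y: np.ndarray) -> float:
    A = _design(X, list(X.columns))
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    tss = ((y - y.mean()) ** 2).sum()
    return float(1.0 - resid @ resid / tss)


def _ga_single_size(
    X: pd.DataFrame, y: np.ndarray, size: int, cfg: GAConfig, rng: np.random.Generator
) -> tuple[tuple[int, ...], float]:
    """Tournament GA over fixed-size index subsets maximizing LOO Q^2."""
    n_desc = X.shape[1]
    mut = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / n_desc
    cache: dict[tuple[int, ...], float] = {}

    def fitness(subset: tuple[int, ...]) -> float:
        if subset not in cache:
            cache[subset] = loo_q2_ols(X.iloc[:, list(subset)], y)
        return cache[subset]

    def random_subset() -> tuple[int, ...]:
        return tuple(sorted(rng.choice(n_desc, size=size, replace=False)))

    def repair(genes: set[int]) -> tuple[int, ...]:
        genes = set(genes)
        pool = [g for g in range(n_desc) if g not in genes]
        rng.shuffle(pool)
        while len(genes) > size:
            genes.remove(rng.choice(sorted(genes)))
        while len(genes) < size:
            genes.add(pool.pop())
        return tuple(sorted(genes))

    pop = [random_subset() for _ in range(cfg.population)]
    best = max(pop, key=fitness)
    for _ in range(cfg.generations):
        new_pop = [best]  # elitism
        while len(new_pop) < cfg.population:
            parents = []
            for _ in range(2):
                contenders = [pop[i] for i in rng.integers(0, len(pop), cfg.tournament)]
                parents.append(max(contenders, key=fitness))
            if rng.random() < cfg.crossover_rate:
                union = list(set(parents[0]) | set(parents[1]))
                child = repair({g for g in union if rng.random() < 0.5} or set(union[:1]))
            else:
                child = parents[0]
            genes = set(child)
            for g in list(genes):
                if rng.random() < mut:
                    genes.discard(g)
            child = repair(genes)
            new_pop.append(child)
        pop = new_pop
        cand = max(pop, key=fitness)
        if fitness(cand) > fitness(best):
            best = cand
    return best, fitness(best)


def ga_vss(
    X: pd.DataFrame, y: Sequence[float], cfg: GAConfig
) -> list[GAResult]:
    """Genetic-algorithm variable subset selection.

    Runs one GA per subset size 1..max, ranks all size-winners by LOO Q^2
    (ties: fewer descriptors, then higher R^2) and drops subsets with any
    coefficient p-value >= the significance threshold. Deterministic for a
    given config seed.
    """
    y = np.asarray(y, dtype=float)
    if X.shape[1] < 1:
        raise ValueError("need at least one candidate descriptor")
    if len(X) <= cfg.max_subset_size + 1:
        raise ValueError("need n > max_subset_size + 1")
    rng = np.random.default_rng(cfg.seed)
    winners: list[GAResult] = []
    for size in range(1, min(cfg.max_subset_size, X.shape[1]) + 1):
        subset_idx, fit = _ga_single_size(X, y, size, cfg, rng)
        if not np.isfinite(fit):
            continue
        names = tuple(X.columns[list(subset_idx)])
        sub = X[list(names)]
        pvals = coefficient_pvalues(sub, y)
        if (pvals >= cfg.significance).any():
            continue
        winners.append(
            GAResult(
                subset=names,
                model=fit_mlr(sub, y),
                fitness=fit,
                r2=_training_r2(sub, y),
                seed=cfg.seed,
            )
        )
    if not winners:
        raise ValueError("no feasible subset passed rank and significance checks")
    winners.sort(key=lambda r: (-r.fitness, len(r.subset), -r.r2))
    return winners


def exhaustive_vss(
    X: pd.DataFrame, y: Sequence[float], size: int
) -> tuple[tuple[str, ...], float]:
    """Exhaustive best-Q^2 subset of a fixed size (oracle for the GA)."""
    from itertools import combinations

    y = np.asarray(y, dtype=float)
    best: tuple[tuple[str, ...], float] = ((), -np.inf)
    for combo in combinations(X.columns, size):
        q2 = loo_q2_ols(X[list(combo)], y)
        if q2 > best[1]:
            best = (combo, q2)
    return best


def descriptor_prefilter(
    table: pd.DataFrame, similarity: float = 0.80, correlation: float = 0.95
) -> pd.DataFrame:
    """Drop near-constant and highly inter-correlated descriptor columns.

    A column is near-constant when more than ``similarity`` of its values are
    identical. From every pair with |Pearson r| above ``correlation`` the
    later column (input order) is dropped.
    """
    keep = []
    for col in table.columns:
        top_frac = table[col].value_counts(normalize=True).iloc[0]
        if top_frac > similarity:
            continue
        keep.append(col)
    kept: list[str] = []
    for col in keep:
        redundant = False
        for prev in kept:
            r = np.corrcoef(table[prev].to_numpy(float), table[col].to_numpy(float))[0, 1]
            if np.isfinite(r) and abs(r) > correlation:
                redundant = True
                break
        if not redundant:
            kept.append(col)
    return table[kept]


def split_sorted_response(
    records: Sequence[tuple[str, float]] | pd.DataFrame,
    test_fraction: float = 0.30,
) -> tuple[list[str], list[str]]:
    """Sorted-response 70:30 training/test split.

    Records are ordered by increasing activity (pIC50; ties broken by id).
    The least- and most-active compounds are forced into training; the rest
    are assigned train, train, test cyclically until the test quota
    floor(test_fraction * n) is filled, the remainder going to training.
    For 54 compounds this yields the 38/16 split whose PRESS/RMSE algebra
    the published statistics satisfy.
    """
    if isinstance(records, pd.DataFrame):
        pairs = [(str(i), float(v)) for i, v in zip(records.index, records.iloc[:, 0])]
    else:
        pairs = [(str(i), float(v)) for i, v in records]
    n = len(pairs)
    if n < 5:
        raise ValueError("need at least 5 records to split")
    pairs.sort(key=lambda t: (t[1], t[0]))
    quota = max(1, int(np.floor(test_fraction * n)))
    train = [pairs[0][0], pairs[-1][0]]
    test: list[str] = []
    for pos, (cid, _) in enumerate(pairs[1:-1]):
        if pos % 3 == 2 and len(test) < quota:
            test.append(cid)
        else:
            train.append(cid)
    return train, test
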