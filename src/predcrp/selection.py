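"""Wrapper feature selection with an inheritable bi-objective combinatorial
genetic algorithm (IBCGA) around an RBF-kernel SVM.

The bi-objective problem C(n, m): choose m of n features minimising m while
maximising k-fold cross-validation accuracy of the SVM restricted to those
features.  One IBCGA run sweeps subset sizes r = r_start..r_end, evolving a
population of exactly-r-ones masks for a fixed number of generations at
each r and seeding size r+1 by adding one random unselected feature to each
individual.  S_m is the best solution over the sweep, ties broken toward
smaller r (parsimony).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

#: repressor is the positive class throughout
POSITIVE_CLASS = "repressor"

DEFAULT_GAMMA_GRID = tuple(2.0**e for e in range(-9, 2, 2))
DEFAULT_C_GRID = tuple(2.0**e for e in range(-3, 8, 2))


@dataclass
class GAConfig:
    r_start: int = 5
    r_end: int = 30
    population_size: int = 50
    generations_per_r: int = 30
    mutation_rate: float = 0.05
    crossover: str = "uniform"  # "uniform" | "intelligent" (hook)
    seed: int = 0
    cv_folds: int = 24
    gamma_grid: tuple = DEFAULT_GAMMA_GRID
    c_grid: tuple = DEFAULT_C_GRID

    def __post_init__(self) -> None:
        if not 1 <= self.r_start <= self.r_end:
            raise ValueError("need 1 <= r_start <= r_end")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")


@dataclass
class SelectionResult:
    per_r: dict  # r -> {"mask": bool array, "fitness": float}
    best_r: int
    best_mask: np.ndarray
    svm_params: tuple[float, float]  # (gamma, C)
    history: list  # (r, generation, best fitness)

    def to_json(self) -> dict:
        return {
            "per_r": {
                str(r): {
                    "mask": np.asarray(v["mask"]).astype(int).tolist(),
                    "fitness": v["fitness"],
                }
                for r, v in self.per_r.items()
            },
            "best_r": self.best_r,
            "best_mask": np.asarray(self.best_mask).astype(int).tolist(),
            "svm_params": {"gamma": self.svm_params[0], "C": self.svm_params[1]},
            "history": self.history,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=2)


def _effective_folds(y: np.ndarray, folds: int) -> int:
    min_class = min(int((y == c).sum()) for c in np.unique(y))
    if min_class < folds:
        warnings.warn(
            f"smallest class has {min_class} members; reducing folds "
            f"from {folds} to {min_class}",
            stacklevel=3,
        )
        return max(2, min_class)
    return folds


def cv_fitness(
    X: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray,
    folds: int = 24,
    gamma: float = 0.125,
    C: float = 8.0,
    seed: int = 0,
) -> float:
    """Pooled stratified k-fold CV accuracy of an RBF SVM on masked columns.

    With 24 repressors and folds=24 each fold holds exactly one repressor,
    maximising the repressors available for training.  Deterministic under
    ``seed`` (which shuffles the fold assignment).
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() == 0:
        raise ValueError("mask selects no features")
    X = np.asarray(X, dtype=float)[:, mask]
    y = np.asarray(y)
    folds = _effective_folds(y, folds)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    correct = 0
    for train_idx, test_idx in skf.split(X, y):
        clf = SVC(kernel="rbf", gamma=gamma, C=C)
        clf.fit(X[train_idx], y[train_idx])
        correct += int((clf.predict(X[test_idx]) == y[test_idx]).sum())
    return correct / len(y)


def grid_search_svm(
    X: np.ndarray,
    y: np.ndarray,
    mask: np.ndarray | None = None,
    gamma_grid=DEFAULT_GAMMA_GRID,
    c_grid=DEFAULT_C_GRID,
    folds: int = 24,
    seed: int = 0,
) -> tuple[float, float]:
    """Grid search for (gamma, C) maximising CV accuracy; ties go to the
    smallest C, then the smallest gamma."""
    if len(gamma_grid) == 0 or len(c_grid) == 0:
        raise ValueError("empty grid")
    if mask is None:
        mask = np.ones(np.asarray(X).shape[1], dtype=bool)
    best = None
    for C in sorted(c_grid):
        for gamma in sorted(gamma_grid):
            fit = cv_fitness(X, y, mask, folds=folds, gamma=gamma, C=C, seed=seed)
            if best is None or fit > best[0]:
                best = (fit, gamma, C)
    return best[1], best[2]


def _repair(mask: np.ndarray, r: int, rng: np.random.Generator) -> np.ndarray:
    """Force a mask to exactly r ones by random add/remove."""
    ones = np.flatnonzero(mask)
    zeros = np.flatnonzero(~mask)
    if len(ones) > r:
        drop = rng.choice(ones, size=len(ones) - r, replace=False)
        mask[drop] = False
    elif len(ones) < r:
        add = rng.choice(zeros, size=r - len(ones), replace=False)
        mask[add] = True
    return mask


def ibcga_select(X, y, cfg: GAConfig) -> SelectionResult:
    """Run the IBCGA sweep over subset sizes r_start..r_end.

    Uniform crossover with repair to exactly r ones; mutation swaps one
    selected index with one unselected; tournament selection with elitism.
    Fitness values are memoized per mask within the run.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[1]
    if cfg.r_end > n:
        raise ValueError(f"r_end={cfg.r_end} exceeds feature count {n}")
    rng = np.random.default_rng(cfg.seed)
    gamma, C = grid_search_svm(
        X,
        y,
        gamma_grid=cfg.gamma_grid,
        c_grid=cfg.c_grid,
        folds=cfg.cv_folds,
        seed=cfg.seed,
    )

    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = np.packbits(mask).tobytes()
        if key not in cache:
            cache[key] = cv_fitness(
                X, y, mask, folds=cfg.cv_folds, gamma=gamma, C=C, seed=cfg.seed
            )
        return cache[key]

    def random_mask(r: int) -> np.ndarray:
        m = np.zeros(n, dtype=bool)
        m[rng.choice(n, size=r, replace=False)] = True
        return m

    pop = [random_mask(cfg.r_start) for _ in range(cfg.population_size)]
    per_r: dict[int, dict] = {}
    history: list = []

    for r in range(cfg.r_start, cfg.r_end + 1):
        fits = np.array([fitness(m) for m in pop])
        for gen in range(cfg.generations_per_r):
            elite = int(np.argmax(fits))
            new_pop = [pop[elite].copy()]
            while len(new_pop) < cfg.population_size:
                # binary tournaments
                i, j = rng.integers(cfg.population_size, size=2)
                a = pop[i] if fits[i] >= fits[j] else pop[j]
                i, j = rng.integers(cfg.population_size, size=2)
                b = pop[i] if fits[i] >= fits[j] else pop[j]
                take_a = rng.random(n) < 0.5
                child = np.where(take_a, a, b)
                child = _repair(child.copy(), r, rng)
                if rng.random() < cfg.mutation_rate:
                    ones = np.flatnonzero(child)
                    zeros = np.flatnonzero(~child)
                    if len(zeros):
                        child[rng.choice(ones)] = False
                        child[rng.choice(zeros)] = True
                new_pop.append(child)
            pop = new_pop
            fits = np.array([fitness(m) for m in pop])
            history.append((r, gen, float(fits.max())))
        best_i = int(np.argmax(fits))
        per_r[r] = {"mask": pop[best_i].copy(), "fitness": float(fits[best_i])}
        if r < cfg.r_end:
            # inheritance: seed size r+1 by adding one unselected feature
            pop = [m.copy() for m in pop]
            for m in pop:
                zeros = np.flatnonzero(~m)
                m[rng.choice(zeros)] = True

    best_r = min(per_r, key=lambda r: (-per_r[r]["fitness"], r))
    return SelectionResult(
        per_r=per_r,
        best_r=best_r,
        best_mask=per_r[best_r]["mask"],
        svm_params=(gamma, C),
        history=history,
    )


# ---------------------------------------------------------------------------
# Final model


@dataclass
class PredictorModel:
    """RBF SVM restricted to the selected feature mask."""

    svc: SVC
    mask: np.ndarray
    feature_names: list[str]
    gamma: float
    C: float

    def predict(self, X: pd.DataFrame | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Labels plus decision scores oriented so larger = more
        repressor-like (usable for ROC with repressor positive)."""
        Xa = self._columns(X)
        labels = self.svc.predict(Xa)
        scores = self.svc.decision_function(Xa)
        if list(self.svc.classes_)[-1] != POSITIVE_CLASS:
            scores = -scores
        return labels, scores

    def _columns(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.selected_features if f not in X.columns]
            if missing:
                raise ValueError(f"feature columns missing: {missing}")
            return X[self.selected_features].to_numpy(dtype=float)
        Xa = np.asarray(X, dtype=float)
        if Xa.shape[1] == len(self.mask):
            return Xa[:, self.mask]
        if Xa.shape[1] == int(self.mask.sum()):
            return Xa
        raise ValueError(
            f"expected {len(self.mask)} or {int(self.mask.sum())} columns, "
            f"got {Xa.shape[1]}"
        )

    @property
    def selected_features(self) -> list[str]:
        return [f for f, m in zip(self.feature_names, self.mask) if m]

    def save(self, path) -> None:
        joblib.dump(self, path)
        sidecar = {
            "mask": self.mask.astype(int).tolist(),
            "selected_features": self.selected_features,
            "gamma": self.gamma,
            "C": self.C,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=2)

    @staticmethod
    def load(path) -> "PredictorModel":
        return joblib.load(path)


def train_model(
    X: pd.DataFrame,
    y,
    mask: np.ndarray,
    gamma: float,
    C: float,
) -> PredictorModel:
    mask = np.asarray(mask, dtype=bool)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"f{i}" for i in range(np.asarray(X).shape[1])
    ]
    Xa = np.asarray(X, dtype=float)[:, mask]
    svc = SVC(kernel="rbf", gamma=gamma, C=C)
    svc.fit(Xa, np.asarray(y))
    return PredictorModel(svc=svc, mask=mask, feature_names=names, gamma=gamma, C=C)
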