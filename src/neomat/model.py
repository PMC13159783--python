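"""Functional-maturation-age estimation: GA feature selection + ensemble.

The estimator maps a segment's HRV features (optionally with gestational
age appended) to a functional maturation age (FMA) in weeks. It averages
two components that capture linear-saturating and non-linear dynamics:

* a generalized-logistic (bounded sigmoid) regression
  ``FMA = A + (K - A) · expit(b0 + w·z)`` with growth bounds A, K fitted
  inside the physiologic range 22–45 weeks — the natural growth-curve
  reading of a "logistic" component with a continuous age target; and
* a random-forest regression.

Feature subsets are chosen by a genetic algorithm whose fitness is the
grouped cross-validated mean absolute error of the ensemble; final
evaluation uses leave-one-out cross-validation grouped by patient, so no
patient contributes segments to both the training and the test side of a
fold.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit, logit
from sklearn.ensemble import RandomForestRegressor

__all__ = [
    "GAConfig",
    "MaturationModel",
    "ga_select",
    "fit_ensemble",
    "predict_fma",
    "loocv",
    "LoocvResult",
    "fma_by_patient_week",
]

FMA_BOUNDS = (22.0, 45.0)
META_COLUMNS = ("patient_id", "pma_weeks", "ga_weeks", "segment_start_s", "quality")


def candidate_features(table: pd.DataFrame) -> list[str]:
    """Feature columns of a table (everything that is not metadata)."""
    return [c for c in table.columns if c not in META_COLUMNS]


def _check_table(table: pd.DataFrame, feature_names: Sequence[str]) -> pd.DataFrame:
    for col in ("patient_id", "pma_weeks"):
        if col not in table.columns:
            raise ValueError(f"feature table must have a {col!r} column")
    missing = [c for c in feature_names if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    bad = [
        c
        for c in feature_names
        if not np.all(np.isfinite(table[c].to_numpy(dtype=float)))
    ]
    if bad:
        raise ValueError(f"non-finite values in feature columns {bad}")
    if table["patient_id"].nunique() < 2:
        raise ValueError("feature table must contain at least 2 patients")
    return table


# ---------------------------------------------------------------------------
# Sigmoid (generalized-logistic) component
# ---------------------------------------------------------------------------


@dataclass
class _SigmoidFit:
    lower: float  # A
    upper: float  # K
    bias: float  # b0
    weights: np.ndarray  # w, on standardized features

    def predict(self, z: np.ndarray) -> np.ndarray:
        return self.lower + (self.upper - self.lower) * expit(
            self.bias + z @ self.weights
        )


def _fit_sigmoid(z: np.ndarray, y: np.ndarray, seed: int) -> _SigmoidFit:
    lo, hi = FMA_BOUNDS
    a0 = float(np.clip(y.min() - 1.0, lo, hi - 1.0))
    k0 = float(np.clip(y.max() + 1.0, a0 + 1.0, hi))
    # linear initialisation of the score through the logit link
    frac = np.clip((y - a0) / (k0 - a0), 0.02, 0.98)
    eta = logit(frac)
    design = np.column_stack([np.ones(len(z)), z])
    coef, *_ = np.linalg.lstsq(design, eta, rcond=None)
    p0 = np.concatenate([[a0, k0], coef])

    def resid(p):
        a, k, b0 = p[0], p[1], p[2]
        return a + (k - a) * expit(b0 + z @ p[3:]) - y

    def jac(p):
        a, k = p[0], p[1]
        s = expit(p[2] + z @ p[3:])
        ds = (k - a) * s * (1.0 - s)
        return np.column_stack([1.0 - s, s, ds, ds[:, None] * z])

    nf = z.shape[1]
    lower = np.concatenate([[lo, lo], np.full(nf + 1, -np.inf)])
    upper = np.concatenate([[hi, hi], np.full(nf + 1, np.inf)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sol = least_squares(
            resid, p0, jac=jac, bounds=(lower, upper), max_nfev=80, method="trf",
            ftol=1e-7, xtol=1e-7,
        )
    p = sol.x
    return _SigmoidFit(lower=float(p[0]), upper=float(p[1]), bias=float(p[2]),
                       weights=np.asarray(p[3:], dtype=float))


# ---------------------------------------------------------------------------
# Ensemble model
# ---------------------------------------------------------------------------


@dataclass
class MaturationModel:
    """Fitted FMA estimator (sigmoid + random forest, convex combination)."""

    feature_names: list[str]
    ga_included: bool
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    sigmoid: _SigmoidFit
    forest: RandomForestRegressor = field(repr=False)
    weights: tuple[float, float] = (0.5, 0.5)
    seed: int = 0

    @property
    def input_names(self) -> list[str]:
        return self.feature_names + (["ga_weeks"] if self.ga_included else [])

    def _matrix(self, data) -> np.ndarray:
        if isinstance(data, pd.DataFrame):
            missing = [c for c in self.input_names if c not in data.columns]
            if missing:
                raise KeyError(f"missing required feature(s) {missing}")
            X = data[self.input_names].to_numpy(dtype=float)
        else:
            missing = [c for c in self.input_names if c not in data]
            if missing:
                raise KeyError(f"missing required feature(s) {missing}")
            X = np.array([[float(data[c]) for c in self.input_names]])
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite feature values in prediction input")
        return X

    def predict(self, data) -> np.ndarray:
        """Predict FMA (weeks, clipped to [22, 45]) for rows or one mapping."""
        X = self._matrix(data)
        z = (X - self.scaler_mean) / self.scaler_sd
        c1 = self.sigmoid.predict(z)
        c2 = self.forest.predict(X)
        pred = self.weights[0] * c1 + self.weights[1] * c2
        return np.clip(pred, *FMA_BOUNDS)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "wb") as fh:
            pickle.dump({"format": "neomat-maturation-model", "version": 1,
                         "model": self}, fh)
        return path

    @staticmethod
    def load(path: str | Path) -> "MaturationModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        if payload.get("format") != "neomat-maturation-model":
            raise ValueError(f"{path} is not a maturation model archive")
        return payload["model"]


def fit_ensemble(
    table: pd.DataFrame,
    feature_names: Sequence[str],
    ga_included: bool = True,
    weights: tuple[float, float] = (0.5, 0.5),
    n_trees: int = 100,
    seed: int = 0,
) -> MaturationModel:
    """Fit the sigmoid + random-forest ensemble on segment rows.

    The target is ``pma_weeks``. Rows are sorted deterministically before
    fitting so the model is invariant to input row order. Requires at
    least 10 training rows and fully finite features.
    """
    feature_names = list(feature_names)
    _check_table(table, feature_names)
    if len(table) < 10:
        raise ValueError(f"need at least 10 training rows, got {len(table)}")
    cols = ["patient_id", "pma_weeks"] + feature_names
    data = table.sort_values(cols, kind="mergesort").reset_index(drop=True)
    inputs = feature_names + (["ga_weeks"] if ga_included else [])
    if ga_included and "ga_weeks" not in data.columns:
        raise ValueError("ga_included=True requires a ga_weeks column")
    X = data[inputs].to_numpy(dtype=float)
    y = data["pma_weeks"].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    z = (X - mean) / sd
    sigmoid = _fit_sigmoid(z, y, seed)
    forest = RandomForestRegressor(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    ).fit(X, y)
    return MaturationModel(
        feature_names=feature_names,
        ga_included=ga_included,
        scaler_mean=mean,
        scaler_sd=sd,
        sigmoid=sigmoid,
        forest=forest,
        weights=weights,
        seed=seed,
    )


def predict_fma(model: MaturationModel, vector: Mapping[str, float]) -> float:
    """FMA (weeks) for a single feature mapping; errors list absent names."""
    return float(model.predict(vector)[0])


# ---------------------------------------------------------------------------
# Genetic-algorithm feature selection
# ---------------------------------------------------------------------------


@dataclass
class GAConfig:
    """Genetic-algorithm settings for feature-subset search.

    Fitness is the grouped ``cv_folds``-fold cross-validated MAE of the
    ensemble (with a reduced ``fitness_trees``-tree forest for speed);
    lower is better. ``subset_size`` is the number of features per
    candidate subset.
    """

    subset_size: int = 15
    population_size: int = 30
    n_generations: int = 20
    crossover_rate: float = 0.9
    mutation_rate: float = 0.3
    tournament_k: int = 3
    cv_folds: int = 5
    fitness_trees: int = 25
    elitism: int = 1
    ga_included: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be at least 2")
        for name in ("crossover_rate", "mutation_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.subset_size < 1:
            raise ValueError("subset_size must be at least 1")


def _grouped_folds(patients: np.ndarray, n_folds: int, rng: np.random.Generator):
    """Assign patients to folds (shuffled round-robin); yields test masks."""
    unique = np.array(sorted(pd.unique(patients)))
    order = rng.permutation(len(unique))
    fold_of = {unique[idx]: i % n_folds for i, idx in enumerate(order)}
    assignment = np.array([fold_of[p] for p in patients])
    for f in range(min(n_folds, len(unique))):
        yield assignment == f


def _cv_mae(
    table: pd.DataFrame,
    subset: tuple[str, ...],
    config: GAConfig,
    fold_masks: list[np.ndarray],
) -> float:
    errs: list[np.ndarray] = []
    for test_mask in fold_masks:
        train, test = table[~test_mask], table[test_mask]
        if len(train) < 10 or len(test) == 0 or train["patient_id"].nunique() < 2:
            continue
        model = fit_ensemble(
            train,
            list(subset),
            ga_included=config.ga_included,
            n_trees=config.fitness_trees,
            seed=config.seed,
        )
        pred = model.predict(test)
        errs.append(np.abs(pred - test["pma_weeks"].to_numpy(dtype=float)))
    if not errs:
        return float("inf")
    return float(np.mean(np.concatenate(errs)))


def ga_select(
    table: pd.DataFrame,
    config: GAConfig,
    candidates: Sequence[str] | None = None,
) -> tuple[list[str], list[float]]:
    """Search feature subsets with a genetic algorithm.

    Returns the best subset found (sorted names) and the per-generation
    trace of the best-so-far fitness (non-increasing MAE). Deterministic
    under ``config.seed``. Fitness values are memoized per subset.
    """
    config.validate()
    cands = sorted(candidates) if candidates is not None else sorted(
        candidate_features(table)
    )
    _check_table(table, cands)
    if config.subset_size > len(cands):
        raise ValueError(
            f"subset_size {config.subset_size} exceeds the {len(cands)} "
            "candidate features"
        )
    rng = np.random.default_rng(config.seed)
    patients = table["patient_id"].to_numpy()
    fold_masks = list(_grouped_folds(patients, config.cv_folds, rng))
    cache: dict[tuple[str, ...], float] = {}

    def fitness(subset: tuple[str, ...]) -> float:
        if subset not in cache:
            cache[subset] = _cv_mae(table, subset, config, fold_masks)
        return cache[subset]

    def random_subset() -> tuple[str, ...]:
        idx = rng.choice(len(cands), size=config.subset_size, replace=False)
        return tuple(sorted(cands[i] for i in idx))

    def mutate(subset: tuple[str, ...]) -> tuple[str, ...]:
        inside = list(subset)
        outside = [c for c in cands if c not in subset]
        if not outside:
            return subset
        inside[int(rng.integers(len(inside)))] = outside[int(rng.integers(len(outside)))]
        return tuple(sorted(inside))

    def crossover(a: tuple[str, ...], b: tuple[str, ...]) -> tuple[str, ...]:
        union = sorted(set(a) | set(b))
        if len(union) <= config.subset_size:
            pool = union + [c for c in cands if c not in union]
            return tuple(sorted(pool[: config.subset_size]))
        idx = rng.choice(len(union), size=config.subset_size, replace=False)
        return tuple(sorted(union[i] for i in idx))

    population = [random_subset() for _ in range(config.population_size)]
    scores = [fitness(s) for s in population]
    best_idx = int(np.argmin(scores))
    best, best_score = population[best_idx], scores[best_idx]
    trace = [best_score]

    def tournament() -> tuple[str, ...]:
        picks = rng.integers(len(population), size=config.tournament_k)
        winner = min(picks, key=lambda i: scores[int(i)])
        return population[int(winner)]

    for _ in range(config.n_generations):
        next_pop: list[tuple[str, ...]] = [best] * config.elitism
        while len(next_pop) < config.population_size:
            pa, pb = tournament(), tournament()
            child = crossover(pa, pb) if rng.random() < config.crossover_rate else pa
            if rng.random() < config.mutation_rate:
                child = mutate(child)
            next_pop.append(child)
        population = next_pop
        scores = [fitness(s) for s in population]
        gen_best = int(np.argmin(scores))
        if scores[gen_best] < best_score:
            best, best_score = population[gen_best], scores[gen_best]
        trace.append(best_score)
    return list(best), trace


# ---------------------------------------------------------------------------
# Grouped leave-one-out cross-validation
# ---------------------------------------------------------------------------


@dataclass
class LoocvResult:
    """Out-of-fold FMA predictions and overall MAE from grouped LOOCV."""

    predictions: pd.DataFrame  # patient_id, pma_weeks, fma_pred
    mae_weeks: float
    n_folds: int
    excluded_patients: list[str] = field(default_factory=list)


def loocv(
    table: pd.DataFrame,
    feature_names: Sequence[str] | None = None,
    ga_included: bool = True,
    n_trees: int = 100,
    seed: int = 0,
) -> LoocvResult:
    """Leave-one-patient-out cross-validation of the ensemble.

    Each fold trains on all segments of every other patient and predicts
    the held-out patient's segments; a patient is never on both sides of a
    fold. Patients whose feature rows are all non-finite are excluded and
    listed in the result.
    """
    feature_names = (
        list(feature_names) if feature_names is not None else candidate_features(table)
    )
    work = table.copy()
    finite = np.all(
        np.isfinite(work[feature_names].to_numpy(dtype=float)), axis=1
    )
    excluded: list[str] = []
    for pid, grp in work.groupby("patient_id"):
        if not finite[work["patient_id"] == pid].any():
            excluded.append(str(pid))
    work = work[finite]
    work = work[~work["patient_id"].isin(excluded)]
    patients = sorted(work["patient_id"].unique())
    if len(patients) < 3:
        raise ValueError(f"grouped LOOCV needs at least 3 patients, got {len(patients)}")
    if excluded:
        warnings.warn(f"excluded patients with no usable rows: {excluded}", stacklevel=2)
    preds = []
    for pid in patients:
        test = work[work["patient_id"] == pid]
        train = work[work["patient_id"] != pid]
        model = fit_ensemble(
            train, feature_names, ga_included=ga_included, n_trees=n_trees, seed=seed
        )
        fold = test[["patient_id", "pma_weeks"]].copy()
        fold["fma_pred"] = model.predict(test)
        preds.append(fold)
    out = pd.concat(preds, ignore_index=True)
    mae = float(np.mean(np.abs(out["fma_pred"] - out["pma_weeks"])))
    return LoocvResult(
        predictions=out,
        mae_weeks=mae,
        n_folds=len(patients),
        excluded_patients=excluded,
    )


def fma_by_patient_week(predictions: pd.DataFrame) -> pd.DataFrame:
    """Per-patient-week FMA: median of segment predictions for that week.

    Robust to patients contributing different numbers of segments per
    recording week.
    """
    out = (
        predictions.groupby(["patient_id", "pma_weeks"], as_index=False)["fma_pred"]
        .median()
        .rename(columns={"fma_pred": "fma_weeks"})
    )
    return out
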