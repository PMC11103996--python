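"""Curative-efficacy classification: GA-selected kNN peak panels.

The model mirrors the classic serum-peptidome classifier recipe: a genetic
algorithm searches over small peak subsets and over the neighbour count k of
a k-nearest-neighbour classifier, scoring each candidate by repeated
stratified-holdout cross-validation (20% omitted, 10 iterations by default).
Features are z-scored with training statistics before Euclidean distances,
since peak areas span two orders of magnitude.  A nearest-class-centroid
classifier is included as an analogue of the "quick classifier" family.

Everything is exposed both as sklearn-style estimators
(:class:`PeakKnnClassifier`, :class:`NearestCentroidPeakClassifier`,
:class:`GAKnnClassifier`) and as thin module functions over the serialisable
:class:`ClassifierModel` artifact.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.utils.validation import check_is_fitted

from .spectra import PROGRESSION, RESPONSE, PeakMatrix

__all__ = [
    "ClassifierModel",
    "CVReport",
    "GAConfig",
    "PeakKnnClassifier",
    "NearestCentroidPeakClassifier",
    "GAKnnClassifier",
    "knn_predict",
    "centroid_predict",
    "cross_validate",
    "ga_select_features",
]


@dataclass
class ClassifierModel:
    """A trained peak-panel kNN model: panel, k, prototypes, standardisation."""

    selected_mzs: list[float]
    k: int
    training_areas: np.ndarray          # samples x selected peaks (raw areas)
    training_labels: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray

    def __post_init__(self) -> None:
        self.training_areas = np.asarray(self.training_areas, dtype=float)
        self.feature_means = np.asarray(self.feature_means, dtype=float)
        self.feature_sds = np.asarray(self.feature_sds, dtype=float)
        if not self.selected_mzs:
            raise ValueError("at least one selected peak required")
        if self.k < 1 or self.k > len(self.training_labels):
            raise ValueError("k must be in [1, n_train]")
        if np.any(self.feature_sds <= 0):
            raise ValueError("standardisation SDs must be positive")

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.feature_means) / self.feature_sds

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        for key in ("training_areas", "feature_means", "feature_sds"):
            d[key] = np.asarray(d[key]).tolist()
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClassifierModel":
        d = json.loads(Path(path).read_text())
        return cls(**d)


@dataclass
class CVReport:
    """Repeated-holdout cross-validation and resubstitution accuracy, in %."""

    cross_validation_rate: float
    recognition_rate: float
    per_iteration_rates: list[float]


@dataclass
class GAConfig:
    """Genetic-algorithm and cross-validation settings.

    The holdout scheme (fraction omitted 0.20, 10 iterations) follows the
    classic ClinPro-style random cross-validation; the GA hyperparameters are
    this package's defaults for a small (<= 44 feature) search space.

    ``feature_penalty`` (percentage points of cross-validation rate per
    selected peak) regularises the search: a peak stays in the panel only if
    it buys more holdout accuracy than the penalty, which keeps peaks that
    merely fit the fixed split schedule out of the winning model.
    """

    population_size: int = 64
    generations: int = 50
    crossover_rate: float = 0.9
    mutation_rate: float = 0.05
    max_panel_size: int = 8
    k_candidates: tuple[int, ...] = (1, 3, 5, 7, 9)
    elitism_count: int = 2
    tournament_size: int = 3
    seed: int = 0
    holdout_fraction: float = 0.20
    holdout_iterations: int = 10
    feature_penalty: float = 0.5

    def __post_init__(self) -> None:
        for r in (self.crossover_rate, self.mutation_rate):
            if not (0 <= r <= 1):
                raise ValueError("GA rates must be in [0, 1]")
        if not (0 < self.holdout_fraction < 1):
            raise ValueError("holdout_fraction must be in (0, 1)")
        if self.holdout_iterations < 1:
            raise ValueError("holdout_iterations must be >= 1")
        if self.elitism_count > self.population_size:
            raise ValueError("population smaller than elitism_count")
        if any(k % 2 == 0 for k in self.k_candidates):
            raise ValueError("k candidates must be odd")


# ---------------------------------------------------------------------------
# kNN / centroid cores (vectorised; used by estimators, CV and the GA loop)
# ---------------------------------------------------------------------------

def _knn_vote(
    train_X: np.ndarray,
    train_y01: np.ndarray,
    test_X: np.ndarray,
    k: int,
) -> np.ndarray:
    """Majority vote among the k nearest training rows (Euclidean).

    ``train_y01`` holds 0/1 class codes.  A tied vote (possible with even k)
    falls back to the label of the single nearest neighbour.
    """
    D = cdist(np.atleast_2d(test_X), train_X)
    k = min(k, train_X.shape[0])
    nn = np.argpartition(D, k - 1, axis=1)[:, :k]
    votes = train_y01[nn].sum(axis=1)
    pred = (votes * 2 > k).astype(int)
    tie = votes * 2 == k
    if tie.any():
        nearest = np.argmin(D[tie], axis=1)
        pred[tie] = train_y01[nearest]
    return pred


def _labels_to01(labels) -> tuple[np.ndarray, list[str]]:
    """Map labels to 0/1 codes with a fixed (progression, response) order
    when those domain labels are present, else sorted order.  A single-class
    training set is allowed (every prediction returns that class)."""
    labels = np.asarray(labels, dtype=object)
    uniq = sorted(set(labels))
    if set(uniq) == {RESPONSE, PROGRESSION}:
        uniq = [PROGRESSION, RESPONSE]
    if not (1 <= len(uniq) <= 2):
        raise ValueError("at most two classes supported")
    code = np.array([uniq.index(l) for l in labels])
    return code, uniq


def knn_predict(model: ClassifierModel, sample_areas: np.ndarray) -> np.ndarray | str:
    """Predict label(s) for one sample (1-D) or a matrix of samples (2-D)."""
    X = np.asarray(sample_areas, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != len(model.selected_mzs):
        raise ValueError("sample must provide a value for every selected peak")
    y01, classes = _labels_to01(model.training_labels)
    pred = _knn_vote(model.standardize(model.training_areas), y01,
                     model.standardize(X), model.k)
    out = np.array([classes[i] for i in pred], dtype=object)
    return out[0] if single else out


def centroid_predict(model: ClassifierModel, sample_areas: np.ndarray) -> np.ndarray | str:
    """Nearest class-centroid prediction on standardised features.

    An exact midpoint goes to the response class by fixed convention.
    """
    X = np.asarray(sample_areas, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != len(model.selected_mzs):
        raise ValueError("sample must provide a value for every selected peak")
    y01, classes = _labels_to01(model.training_labels)
    if len(classes) == 1:
        return classes[0] if single else np.array([classes[0]] * len(X), dtype=object)
    Z = model.standardize(model.training_areas)
    cents = np.vstack([Z[y01 == c].mean(axis=0) for c in (0, 1)])
    D = cdist(model.standardize(X), cents)
    pref = classes.index(RESPONSE) if RESPONSE in classes else 0
    pred = np.where(D[:, 0] < D[:, 1], 0, np.where(D[:, 1] < D[:, 0], 1, pref))
    out = np.array([classes[i] for i in pred], dtype=object)
    return out[0] if single else out


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return mu, sd


def holdout_schedule(y01: np.ndarray, cfg: GAConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """The fixed stratified-holdout split schedule for one run.

    All candidate models in a GA run are scored on these identical splits,
    so fitness differences reflect the models, not the splits.
    """
    sss = StratifiedShuffleSplit(
        n_splits=cfg.holdout_iterations,
        test_size=cfg.holdout_fraction,
        random_state=cfg.seed % (2**31),
    )
    return [(tr, te) for tr, te in sss.split(np.zeros(len(y01)), y01)]


def _cv_rates(
    X: np.ndarray,
    y01: np.ndarray,
    k: int,
    splits: list[tuple[np.ndarray, np.ndarray]],
) -> list[float]:
    rates = []
    for tr, te in splits:
        mu, sd = _standardize_fit(X[tr])
        pred = _knn_vote((X[tr] - mu) / sd, y01[tr], (X[te] - mu) / sd, k)
        rates.append(100.0 * float(np.mean(pred == y01[te])))
    return rates


def _recognition_rate(X: np.ndarray, y01: np.ndarray, k: int) -> float:
    mu, sd = _standardize_fit(X)
    Z = (X - mu) / sd
    pred = _knn_vote(Z, y01, Z, k)
    return 100.0 * float(np.mean(pred == y01))


def cross_validate(
    panel,
    k: int,
    matrix,
    labels=None,
    cfg: GAConfig | None = None,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
) -> CVReport:
    """Repeated stratified-holdout CV plus resubstitution for one panel/k.

    ``panel`` holds column indices when ``matrix`` is an array, or reference
    m/z values when ``matrix`` is a :class:`PeakMatrix` (then ``labels`` may
    be omitted).  ``splits`` optionally pins an explicit split schedule;
    otherwise one is derived from ``cfg.seed``.
    """
    cfg = cfg or GAConfig()
    if isinstance(matrix, PeakMatrix):
        cols = [int(np.argmin(np.abs(matrix.reference_mzs - mz))) for mz in panel]
        X = matrix.areas[:, cols]
        labels = matrix.group_labels if labels is None else labels
    else:
        X = np.asarray(matrix, dtype=float)[:, list(panel)]
    if len(X) < 5:
        raise ValueError("need at least 5 training samples")
    y01, _ = _labels_to01(labels)
    if splits is None:
        splits = holdout_schedule(y01, cfg)
    rates = _cv_rates(X, y01, k, splits)
    return CVReport(
        cross_validation_rate=float(np.mean(rates)),
        recognition_rate=_recognition_rate(X, y01, k),
        per_iteration_rates=rates,
    )


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------

def _repair(bits: np.ndarray, rng: np.random.Generator, max_size: int) -> np.ndarray:
    on = np.flatnonzero(bits)
    if len(on) > max_size:
        off = rng.choice(on, size=len(on) - max_size, replace=False)
        bits = bits.copy()
        bits[off] = False
    elif len(on) == 0:
        bits = bits.copy()
        bits[rng.integers(len(bits))] = True
    return bits


def _ga_search(
    X: np.ndarray,
    y01: np.ndarray,
    cfg: GAConfig,
) -> tuple[np.ndarray, int, float, list[float]]:
    """Generational GA over (feature subset, k); returns the best individual.

    Fitness is the mean holdout accuracy on a split schedule fixed for the
    whole run; evaluations are cached per (subset, k).
    """
    p = X.shape[1]
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0x6A]))
    splits = holdout_schedule(y01, cfg)
    cache: dict[tuple[bytes, int], float] = {}

    def fitness(bits: np.ndarray, k: int) -> float:
        key = (bits.tobytes(), k)
        if key not in cache:
            cache[key] = float(np.mean(_cv_rates(X[:, bits], y01, k, splits)))
        return cache[key]

    def score(i: int):
        # complexity-penalised objective, panel size as the tie-break
        return (fits[i] - cfg.feature_penalty * int(pop[i][0].sum()),
                -int(pop[i][0].sum()))

    def random_individual():
        size = rng.integers(1, min(cfg.max_panel_size, p) + 1)
        bits = np.zeros(p, dtype=bool)
        bits[rng.choice(p, size=size, replace=False)] = True
        return bits, int(rng.choice(cfg.k_candidates))

    pop = [random_individual() for _ in range(cfg.population_size)]
    fits = [fitness(b, k) for b, k in pop]
    best_trace: list[float] = []

    for _ in range(cfg.generations):
        order = sorted(range(cfg.population_size), key=score, reverse=True)
        elites = [(pop[i][0].copy(), pop[i][1]) for i in order[: cfg.elitism_count]]
        new_pop = list(elites)
        while len(new_pop) < cfg.population_size:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, cfg.population_size, cfg.tournament_size)
                parents.append(pop[max(contenders, key=score)])
            (b1, k1), (b2, k2) = parents
            if rng.random() < cfg.crossover_rate:
                mask = rng.random(p) < 0.5
                child_bits = np.where(mask, b1, b2)
                child_k = k1 if rng.random() < 0.5 else k2
            else:
                child_bits, child_k = b1.copy(), k1
            flip = rng.random(p) < cfg.mutation_rate
            child_bits = child_bits ^ flip
            if rng.random() < cfg.mutation_rate:
                child_k = int(rng.choice(cfg.k_candidates))
            child_bits = _repair(child_bits, rng, cfg.max_panel_size)
            new_pop.append((child_bits, child_k))
        pop = new_pop
        fits = [fitness(b, k) for b, k in pop]
        best_trace.append(max(fits))

    i_best = max(range(cfg.population_size), key=score)
    bits, k = pop[i_best]
    return bits, k, fits[i_best], best_trace


def ga_select_features(
    matrix,
    labels=None,
    cfg: GAConfig | None = None,
    feature_mzs=None,
) -> tuple[ClassifierModel, CVReport]:
    """GA feature selection + k tuning; returns the refit model and its CV
    report (cross-validation rate = the winning fitness; recognition rate =
    resubstitution accuracy of the refit model)."""
    cfg = cfg or GAConfig()
    if isinstance(matrix, PeakMatrix):
        X = matrix.areas
        labels = matrix.group_labels if labels is None else labels
        mzs = matrix.reference_mzs
    else:
        X = np.asarray(matrix, dtype=float)
        mzs = (
            np.asarray(feature_mzs, dtype=float)
            if feature_mzs is not None
            else np.arange(X.shape[1], dtype=float)
        )
    if X.shape[1] < 1:
        raise ValueError("empty peak panel")
    y01, classes = _labels_to01(labels)
    bits, k, best_fit, _ = _ga_search(X, y01, cfg)
    sel = np.flatnonzero(bits)
    Xs = X[:, sel]
    mu, sd = _standardize_fit(Xs)
    model = ClassifierModel(
        selected_mzs=[float(mzs[j]) for j in sel],
        k=k,
        training_areas=Xs,
        training_labels=[str(l) for l in np.asarray(labels, dtype=object)],
        feature_means=mu,
        feature_sds=sd,
    )
    splits = holdout_schedule(y01, cfg)
    report = CVReport(
        cross_validation_rate=best_fit,
        recognition_rate=_recognition_rate(Xs, y01, k),
        per_iteration_rates=_cv_rates(Xs, y01, k, splits),
    )
    return model, report


# ---------------------------------------------------------------------------
# sklearn estimators
# ---------------------------------------------------------------------------

class PeakKnnClassifier(BaseEstimator, ClassifierMixin):
    """k-nearest-neighbour classifier on z-scored peak areas.

    Euclidean distances on features standardised with training mean/SD;
    majority vote of the k nearest training samples, ties broken by the
    single nearest neighbour.
    """

    def __init__(self, k: int = 5):
        self.k = k

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y01, classes = _labels_to01(y)
        if self.k < 1 or self.k > len(y01):
            raise ValueError("k must be in [1, n_train]")
        self.classes_ = np.array(classes, dtype=object)
        mu, sd = _standardize_fit(X)
        self.mean_, self.scale_ = mu, sd
        self.X_train_ = (X - mu) / sd
        self.y_train_ = y01
        self.model_ = ClassifierModel(
            selected_mzs=list(range(X.shape[1])) or [0],
            k=self.k,
            training_areas=X,
            training_labels=[classes[i] for i in y01],
            feature_means=mu,
            feature_sds=sd,
        )
        return self

    def predict(self, X):
        check_is_fitted(self, "X_train_")
        X = np.asarray(X, dtype=float)
        pred = _knn_vote(self.X_train_, self.y_train_,
                         (X - self.mean_) / self.scale_, self.k)
        return self.classes_[pred]


class NearestCentroidPeakClassifier(BaseEstimator, ClassifierMixin):
    """Nearest class-centroid on z-scored peak areas ("quick" baseline)."""

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y01, classes = _labels_to01(y)
        self.classes_ = np.array(classes, dtype=object)
        self.mean_, self.scale_ = _standardize_fit(X)
        Z = (X - self.mean_) / self.scale_
        self.centroids_ = np.vstack([Z[y01 == c].mean(axis=0) for c in (0, 1)])
        return self

    def predict(self, X):
        check_is_fitted(self, "centroids_")
        Z = (np.asarray(X, dtype=float) - self.mean_) / self.scale_
        D = cdist(Z, self.centroids_)
        classes = list(self.classes_)
        pref = classes.index(RESPONSE) if RESPONSE in classes else 0
        pred = np.where(D[:, 0] < D[:, 1], 0, np.where(D[:, 1] < D[:, 0], 1, pref))
        return self.classes_[pred]


class GAKnnClassifier(BaseEstimator, ClassifierMixin):
    """GA feature selection wrapped around :class:`PeakKnnClassifier`.

    ``fit`` runs the genetic search and refits the winning panel/k on the
    full training data.  Fitted attributes: ``selected_idx_``,
    ``selected_mzs_``, ``k_``, ``cv_report_``, ``model_``.
    """

    def __init__(
        self,
        population_size: int = 64,
        generations: int = 50,
        crossover_rate: float = 0.9,
        mutation_rate: float = 0.05,
        max_panel_size: int = 8,
        k_candidates: tuple[int, ...] = (1, 3, 5, 7, 9),
        elitism_count: int = 2,
        tournament_size: int = 3,
        seed: int = 0,
        holdout_fraction: float = 0.20,
        holdout_iterations: int = 10,
    ):
        self.population_size = population_size
        self.generations = generations
        self.crossover_rate = crossover_rate
        self.mutation_rate = mutation_rate
        self.max_panel_size = max_panel_size
        self.k_candidates = k_candidates
        self.elitism_count = elitism_count
        self.tournament_size = tournament_size
        self.seed = seed
        self.holdout_fraction = holdout_fraction
        self.holdout_iterations = holdout_iterations

    def _config(self) -> GAConfig:
        return GAConfig(
            population_size=self.population_size,
            generations=self.generations,
            crossover_rate=self.crossover_rate,
            mutation_rate=self.mutation_rate,
            max_panel_size=self.max_panel_size,
            k_candidates=tuple(self.k_candidates),
            elitism_count=self.elitism_count,
            tournament_size=self.tournament_size,
            seed=self.seed,
            holdout_fraction=self.holdout_fraction,
            holdout_iterations=self.holdout_iterations,
        )

    def fit(self, X, y, feature_mzs=None):
        X = np.asarray(X, dtype=float)
        model, report = ga_select_features(
            X, y, self._config(), feature_mzs=feature_mzs
        )
        self.model_ = model
        self.cv_report_ = report
        self.selected_mzs_ = np.array(model.selected_mzs)
        mzs = (
            np.asarray(feature_mzs, dtype=float)
            if feature_mzs is not None
            else np.arange(X.shape[1], dtype=float)
        )
        self.selected_idx_ = np.array(
            [int(np.argmin(np.abs(mzs - mz))) for mz in model.selected_mzs]
        )
        self.k_ = model.k
        _, classes = _labels_to01(y)
        self.classes_ = np.array(classes, dtype=object)
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)[:, self.selected_idx_]
        return np.asarray(knn_predict(self.model_, X), dtype=object)
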