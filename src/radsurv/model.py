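"""Integrated feature selection and model training (IFSMT).

A binary survival-status classifier (death at 3 years = positive class) is
built in two stages:

1. *Feature selection* — a genetic algorithm evolves binary feature-inclusion
   templates ("chromosomes"). Each chromosome is scored by the held-out
   balanced accuracy of a linear soft-margin SVM run in leave-one-out
   cross-validation (standardization re-estimated inside every fold). The
   best chromosome of each generation is collected, and the best of that
   group is the selected feature set.
2. *Model training* — with the feature set fixed, the SVM regularization C is
   chosen by exhaustive search on a log grid (LOOCV on the training cohort,
   ties broken toward smaller C), and a final linear SVM is trained on the
   full training cohort.

The decision variable is the signed distance to the hyperplane,
(w . x_std + b) / ||w||; ROC curves are swept over it.

The statsmodels-style front door is :class:`GeneticSVM` (model) whose
``fit`` returns a :class:`GeneticSVMResults` carrying the selected features,
hyperplane, LOOCV score and diagnostics; the stage functions
(:func:`loocv_score`, :func:`evolve`, :func:`grid_search_svm`,
:func:`train_final`, :func:`decision_values`, :func:`roc_auc`) remain usable
on their own.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import balanced_accuracy_score, roc_curve
from sklearn.svm import SVC

from .errors import ConfigError, DomainError, SchemaError

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class SVMConfig:
    """Linear-kernel SVM hyperparameters.

    ``epsilon`` is used as the optimizer stopping tolerance; ``gamma`` is
    inert for a linear kernel and recorded for completeness only.
    """

    kernel: str = "linear"
    C: float = 1.0
    epsilon: float = 1e-3
    gamma: float | str = "scale"

    def __post_init__(self):
        if self.kernel != "linear":
            raise ConfigError("only the linear kernel is supported")
        if self.C <= 0:
            raise ConfigError("C must be positive")


@dataclass
class GAConfig:
    """Genetic-algorithm settings for feature-template evolution."""

    population_size: int = 50
    generations: int = 100
    mutation_rate: float = 0.02
    crossover_rate: float = 0.8
    elite_fraction: float = 0.1
    stagnation: int = 20          # early stop after this many flat generations
    init_prob: float = 0.5        # per-bit inclusion probability at init
    local_search: bool = False    # optional greedy bit-flip refinement of the best
    max_features: int | None = None
    seed: int | None = None

    def __post_init__(self):
        for name in ("mutation_rate", "crossover_rate", "init_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 < self.elite_fraction < 1.0:
            raise ConfigError("elite_fraction must be in (0, 1)")
        if self.population_size < 2 or self.generations < 1:
            raise ConfigError("population_size >= 2 and generations >= 1 required")
        self.n_elite = max(1, int(round(self.elite_fraction * self.population_size)))
        if self.n_elite >= self.population_size:
            raise ConfigError("population too small for the elite fraction")


@dataclass
class Chromosome:
    """A binary feature-inclusion template with its LOOCV fitness."""

    include: np.ndarray
    score: float | None = None

    def __post_init__(self):
        self.include = np.asarray(self.include, dtype=bool)

    @property
    def n_features(self) -> int:
        return int(self.include.sum())

    def key(self) -> bytes:
        return np.packbits(self.include).tobytes()


@dataclass
class LinearSVMModel:
    """A trained linear SVM: hyperplane in standardized feature space."""

    weights: np.ndarray
    bias: float
    selected: list[str]
    center: np.ndarray
    scale: np.ndarray
    config: SVMConfig = field(default_factory=SVMConfig)

    def __post_init__(self):
        if len(self.weights) != len(self.selected):
            raise ConfigError("one weight per selected feature required")


@dataclass
class ROCCurve:
    """ROC by threshold sweep over the decision variable."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


# ---------------------------------------------------------------------------
# validation helpers
# ---------------------------------------------------------------------------

def _as_matrix(table, columns=None) -> tuple[np.ndarray, list[str]]:
    if isinstance(table, pd.DataFrame):
        if columns is not None:
            missing = [c for c in columns if c not in table.columns]
            if missing:
                raise SchemaError(f"missing feature columns: {missing}")
            table = table[list(columns)]
        return table.to_numpy(dtype=float), list(table.columns)
    X = np.asarray(table, dtype=float)
    names = [f"f{i}" for i in range(X.shape[1])]
    return X, names


def _check_labels(y) -> np.ndarray:
    y = np.asarray(y).astype(int)
    if set(np.unique(y)) - {0, 1}:
        raise DomainError("labels must be binary 0/1 (death = 1)")
    if len(np.unique(y)) < 2:
        raise DomainError("both classes must be present")
    return y


def _fit_svc(X: np.ndarray, y: np.ndarray, svm: SVMConfig) -> SVC:
    clf = SVC(kernel="linear", C=svm.C, tol=svm.epsilon)
    clf.fit(X, y)
    return clf


# ---------------------------------------------------------------------------
# LOOCV scoring
# ---------------------------------------------------------------------------

def _fold_predict(Xtr, ytr, xte, svm: SVMConfig) -> int:
    """Fit a linear SVC on one fold and predict one held-out sample.

    Uses scikit-learn's low-level libsvm binding when available (verified
    prediction-identical to SVC; skips per-fit validation overhead, which
    dominates on LOOCV-sized folds), falling back to SVC otherwise.
    """
    global _LIBSVM
    if _LIBSVM is None:
        try:
            from sklearn.svm import _libsvm

            _libsvm.set_verbosity_wrap(0)
            _LIBSVM = _libsvm
        except Exception:
            _LIBSVM = False
    if _LIBSVM:
        try:
            fit = _LIBSVM.fit(
                np.ascontiguousarray(Xtr), ytr.astype(np.float64),
                svm_type=0, kernel="linear", C=svm.C, tol=svm.epsilon, gamma=1.0,
            )
            support, sv, n_sv, coef, intercept = fit[:5]
            pred = _LIBSVM.predict(
                np.ascontiguousarray(xte[None, :]), support, sv, n_sv, coef,
                intercept, svm_type=0, kernel="linear", gamma=1.0,
            )
            return int(pred[0])
        except Exception:
            pass
    clf = _fit_svc(Xtr, ytr, svm)
    return int(clf.predict(xte[None, :])[0])


_LIBSVM = None


def loocv_predictions(X: np.ndarray, y: np.ndarray, svm: SVMConfig) -> np.ndarray:
    """Held-out prediction for every sample, standardization re-estimated
    inside each fold. A fold whose training part is single-class predicts
    that class."""
    n = len(y)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Xtr, ytr = X[keep], y[keep]
        if len(np.unique(ytr)) < 2:
            preds[i] = int(ytr[0])
            continue
        mu = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0)
        sd[sd == 0] = 1.0
        preds[i] = _fold_predict((Xtr - mu) / sd, ytr, (X[i] - mu) / sd, svm)
    return preds


def loocv_score(table, labels, chrom: Chromosome | np.ndarray, svm: SVMConfig | None = None) -> float:
    """LOOCV fitness of a feature template: held-out balanced accuracy."""
    svm = svm or SVMConfig()
    y = _check_labels(labels)
    if len(y) < 3:
        raise DomainError("LOOCV needs at least 3 samples")
    include = chrom.include if isinstance(chrom, Chromosome) else np.asarray(chrom, bool)
    if include.sum() == 0:
        raise DomainError("chromosome selects no feature")
    X, _ = _as_matrix(table)
    if X.shape[0] != len(y):
        raise SchemaError("feature table and labels have different lengths")
    if X.shape[1] != include.size:
        raise SchemaError("chromosome length does not match the feature table")
    preds = loocv_predictions(X[:, include], y, svm)
    return float(balanced_accuracy_score(y, preds))


# ---------------------------------------------------------------------------
# genetic algorithm
# ---------------------------------------------------------------------------

def _repair(include: np.ndarray, rng: np.random.Generator, max_features: int | None):
    if not include.any():
        include[rng.integers(include.size)] = True
    if max_features is not None and include.sum() > max_features:
        on = np.flatnonzero(include)
        drop = rng.choice(on, size=int(include.sum()) - max_features, replace=False)
        include[drop] = False
    return include


def _rank_key(chrom: Chromosome) -> tuple[float, int]:
    # higher score first; at equal score prefer fewer features (parsimony)
    return (-chrom.score, chrom.n_features)


def evolve(
    table,
    labels,
    ga: GAConfig | None = None,
    svm: SVMConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[Chromosome, list[dict]]:
    """Evolve feature templates; return the best chromosome and the
    per-generation history.

    Each generation scores the whole population by LOOCV, retains the elites,
    and builds offspring from tournament-selected (higher-scoring) parents by
    uniform crossover and per-bit mutation, replacing the lower scorers. The
    best chromosome of every generation is collected into a group; the best
    of that group (parsimony tie-break) is returned. Fully reproducible from
    the seed; scores of revisited templates are memoized.
    """
    ga = ga or GAConfig()
    svm = svm or SVMConfig()
    if rng is None:
        rng = np.random.default_rng(ga.seed)
    X, names = _as_matrix(table)
    y = _check_labels(labels)
    p = X.shape[1]
    cache: dict[bytes, float] = {}

    def score(ch: Chromosome) -> Chromosome:
        k = ch.key()
        if k not in cache:
            cache[k] = loocv_score(X, y, ch, svm)
        ch.score = cache[k]
        return ch

    population = [
        Chromosome(_repair(rng.random(p) < ga.init_prob, rng, ga.max_features))
        for _ in range(ga.population_size)
    ]
    history: list[dict] = []
    group: list[Chromosome] = []
    best_so_far = -np.inf
    stagnant = 0
    for generation in range(ga.generations):
        population = [score(ch) for ch in population]
        population.sort(key=_rank_key)
        gen_best = population[0]
        group.append(Chromosome(gen_best.include.copy(), gen_best.score))
        history.append(
            {
                "generation": generation,
                "best_score": gen_best.score,
                "best_n_features": gen_best.n_features,
                "mean_score": float(np.mean([c.score for c in population])),
            }
        )
        if gen_best.score > best_so_far + 1e-12:
            best_so_far = gen_best.score
            stagnant = 0
        else:
            stagnant += 1
        if stagnant >= ga.stagnation or generation == ga.generations - 1:
            break
        elites = [Chromosome(c.include.copy(), c.score) for c in population[: ga.n_elite]]
        offspring: list[Chromosome] = []
        while len(offspring) < ga.population_size - ga.n_elite:
            pa = min(rng.integers(ga.population_size, size=2))  # tournament of 2
            pb = min(rng.integers(ga.population_size, size=2))
            inc_a = population[pa].include
            inc_b = population[pb].include
            if rng.random() < ga.crossover_rate:
                mask = rng.random(p) < 0.5
                child = np.where(mask, inc_a, inc_b)
            else:
                child = inc_a.copy()
            flip = rng.random(p) < ga.mutation_rate
            child = np.logical_xor(child, flip)
            offspring.append(Chromosome(_repair(child, rng, ga.max_features)))
        population = elites + offspring
    best = min(group, key=_rank_key)
    if ga.local_search:
        best = _hill_climb(best, score, p, rng, ga.max_features)
    return best, history


def _hill_climb(best: Chromosome, score, p: int, rng, max_features, max_passes: int = 3):
    """Memetic refinement: accept single-bit flips that improve the LOOCV
    score (or match it with fewer features), until a full pass is flat."""
    best = score(Chromosome(best.include.copy()))
    for _ in range(max_passes):
        improved = False
        for j in rng.permutation(p):
            trial = best.include.copy()
            trial[j] = ~trial[j]
            if not trial.any():
                continue
            if max_features is not None and trial.sum() > max_features:
                continue
            cand = score(Chromosome(trial))
            if _rank_key(cand) < _rank_key(best):
                best = cand
                improved = True
        if not improved:
            break
    return best


# ---------------------------------------------------------------------------
# hyperparameter search and final training
# ---------------------------------------------------------------------------

def grid_search_svm(
    table, labels, selected: list[str], c_grid=DEFAULT_C_GRID, epsilon: float = 1e-3
) -> tuple[SVMConfig, float]:
    """Exhaustive LOOCV search over the C lattice; ties go to the smaller C."""
    grid = sorted(c_grid)
    if not grid:
        raise ConfigError("empty hyperparameter grid")
    X, _ = _as_matrix(table, selected)
    y = _check_labels(labels)
    include = np.ones(X.shape[1], dtype=bool)
    best_cfg, best_score = None, -np.inf
    for C in grid:
        cfg = SVMConfig(C=C, epsilon=epsilon)
        s = loocv_score(X, y, include, cfg)
        if s > best_score + 1e-12:  # strict: earlier (smaller) C wins ties
            best_cfg, best_score = cfg, s
    return best_cfg, float(best_score)


def train_final(table, labels, selected: list[str], svm: SVMConfig | None = None) -> LinearSVMModel:
    """Fit the final soft-margin linear SVM on standardized selected features."""
    svm = svm or SVMConfig()
    X, names = _as_matrix(table, selected)
    y = _check_labels(labels)
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    clf = _fit_svc((X - center) / scale, y, svm)
    return LinearSVMModel(
        weights=clf.coef_.ravel().copy(),
        bias=float(clf.intercept_[0]),
        selected=list(names),
        center=center,
        scale=scale,
        config=svm,
    )


def decision_values(model: LinearSVMModel, table) -> np.ndarray:
    """Signed distance to the hyperplane for every row of the table."""
    X, _ = _as_matrix(table, model.selected)
    Xs = (X - model.center) / model.scale
    norm = float(np.linalg.norm(model.weights))
    if norm == 0:
        norm = 1.0
    return (Xs @ model.weights + model.bias) / norm


def predict(model: LinearSVMModel, table) -> np.ndarray:
    """Positive (death) iff the signed distance is > 0."""
    return (decision_values(model, table) > 0).astype(int)


def roc_auc(scores, labels) -> ROCCurve:
    """ROC by sweeping a threshold over the decision variable; trapezoidal
    AUC (ties at midpoint, equivalent to the Mann-Whitney U statistic)."""
    y = _check_labels(labels)
    scores = np.asarray(scores, dtype=float)
    fpr, tpr, thresholds = roc_curve(y, scores, drop_intermediate=False)
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=float(_sk_auc(fpr, tpr)))


# ---------------------------------------------------------------------------
# statsmodels-style front door
# ---------------------------------------------------------------------------

class GeneticSVM:
    """Survival-status model: GA feature selection + LOOCV linear SVM.

    Parameters
    ----------
    features : pandas.DataFrame
        One row per patient, one column per radiomic feature.
    labels : array-like of {0, 1}
        3-year survival status, death = 1 (the positive class).
    ga_config, svm_config : optional
        Evolution settings and the SVM configuration used during selection.
    c_grid : sequence of float
        C lattice for the post-selection exhaustive search.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        labels,
        ga_config: GAConfig | None = None,
        svm_config: SVMConfig | None = None,
        c_grid=DEFAULT_C_GRID,
    ):
        if not isinstance(features, pd.DataFrame):
            features = pd.DataFrame(np.asarray(features, dtype=float))
            features.columns = [f"f{i}" for i in range(features.shape[1])]
        self.features = features
        self.labels = _check_labels(labels)
        if len(self.features) != len(self.labels):
            raise SchemaError("features and labels have different lengths")
        self.ga_config = ga_config or GAConfig()
        self.svm_config = svm_config or SVMConfig()
        self.c_grid = tuple(c_grid)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str = "event", **kwargs) -> "GeneticSVM":
        if label_col not in df.columns:
            raise SchemaError(f"label column '{label_col}' not in table")
        features = df.drop(columns=[label_col]).select_dtypes(include=[np.number])
        return cls(features, df[label_col].to_numpy(), **kwargs)

    def fit(self, seed: int | None = None) -> "GeneticSVMResults":
        """Run selection, hyperparameter search and final training."""
        ga = self.ga_config
        if seed is not None:
            ga = replace_seed(ga, seed)
        rng = np.random.default_rng(ga.seed)
        best, history = evolve(self.features, self.labels, ga, self.svm_config, rng)
        selected = [c for c, keep in zip(self.features.columns, best.include) if keep]
        svm_cfg, grid_score = grid_search_svm(
            self.features, self.labels, selected, self.c_grid, self.svm_config.epsilon
        )
        model = train_final(self.features, self.labels, selected, svm_cfg)
        return GeneticSVMResults(
            model=self,
            chromosome=best,
            history=history,
            selected_features=selected,
            svm_config=svm_cfg,
            linear_model=model,
            loocv_score_=float(grid_score),
        )


def replace_seed(ga: GAConfig, seed: int) -> GAConfig:
    return replace(ga, seed=seed)


class GeneticSVMResults:
    """Fit results: selected features, hyperplane, and diagnostics."""

    def __init__(self, model, chromosome, history, selected_features, svm_config,
                 linear_model, loocv_score_):
        self.model = model
        self.chromosome = chromosome
        self.history = history
        self.selected_features = selected_features
        self.svm_config = svm_config
        self.linear_model = linear_model
        self.loocv_score_ = loocv_score_

    # -- prediction ---------------------------------------------------------
    def decision_values(self, table=None) -> np.ndarray:
        table = self.model.features if table is None else table
        return decision_values(self.linear_model, table)

    def predict(self, table=None) -> np.ndarray:
        table = self.model.features if table is None else table
        return predict(self.linear_model, table)

    def roc(self, table=None, labels=None) -> ROCCurve:
        table = self.model.features if table is None else table
        labels = self.model.labels if labels is None else labels
        return roc_auc(decision_values(self.linear_model, table), labels)

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        train_auc = self.roc().auc
        lines = [
            "Survival-status SVM (GA-selected features, linear kernel)",
            "=" * 60,
            f"n patients:            {len(self.model.labels)}",
            f"n candidate features:  {self.model.features.shape[1]}",
            f"n selected features:   {len(self.selected_features)}",
            f"GA LOOCV fitness:      {self.chromosome.score:.4f}",
            f"LOOCV (best C):        {self.loocv_score_:.4f}",
            f"C (exhaustive search): {self.svm_config.C:g}",
            f"training AUC:          {train_auc:.4f}",
            "-" * 60,
            f"{'feature':<40}{'weight':>12}",
        ]
        order = np.argsort(-np.abs(self.linear_model.weights))
        for i in order:
            lines.append(
                f"{self.linear_model.selected[i]:<40}"
                f"{self.linear_model.weights[i]:>12.4f}"
            )
        lines.append("=" * 60)
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "selected_features": self.selected_features,
            "weights": self.linear_model.weights.tolist(),
            "bias": self.linear_model.bias,
            "center": self.linear_model.center.tolist(),
            "scale": self.linear_model.scale.tolist(),
            "svm_config": {
                "kernel": self.svm_config.kernel,
                "C": self.svm_config.C,
                "epsilon": self.svm_config.epsilon,
            },
            "ga_config": {
                "population_size": self.model.ga_config.population_size,
                "generations": self.model.ga_config.generations,
                "mutation_rate": self.model.ga_config.mutation_rate,
                "crossover_rate": self.model.ga_config.crossover_rate,
                "elite_fraction": self.model.ga_config.elite_fraction,
                "seed": self.model.ga_config.seed,
            },
            "loocv_score": self.loocv_score_,
            "history": self.history,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def load_model_json(path) -> LinearSVMModel:
    """Rehydrate the trained hyperplane from a results JSON."""
    with open(path) as fh:
        payload = json.load(fh)
    cfg = payload["svm_config"]
    return LinearSVMModel(
        weights=np.asarray(payload["weights"], dtype=float),
        bias=float(payload["bias"]),
        selected=list(payload["selected_features"]),
        center=np.asarray(payload["center"], dtype=float),
        scale=np.asarray(payload["scale"], dtype=float),
        config=SVMConfig(C=cfg["C"], epsilon=cfg["epsilon"]),
    )
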