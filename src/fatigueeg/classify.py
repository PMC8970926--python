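"""Classifiers: ELM, hierarchical ELM, PSO-tuned H-ELM, and KNN/SVM baselines.

An extreme learning machine (ELM) is a single-hidden-layer network whose
input weights are random and fixed; only the output weights are learned, by
ridge-regularised least squares against one-hot labels:

    H = g(X W + b),   beta = (H^T H + C I)^(-1) H^T T

The hierarchical ELM (H-ELM) first learns a stack of sparse ELM
autoencoders -- each layer reconstructs its input through a random hidden
expansion with l1-regularised output weights (solved by FISTA) and the
learned weights project the data forward -- then classifies the last
encoding with a plain ELM.

PSO-H-ELM wraps H-ELM in a particle swarm search over the architecture
(layer sizes, final hidden width) and log10 of the ridge constant, scored by
stratified k-fold cross-validation accuracy on the training data only.

All trainers standardise features internally (statistics estimated on the
training data and stored in the model) and are deterministic under seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ParameterError
from .features import FeatureMatrix

__all__ = [
    "ELMModel",
    "HELMModel",
    "PSOConfig",
    "elm_train",
    "helm_train",
    "pso_optimize",
    "pso_helm_train",
    "knn_train",
    "svm_train",
    "predict",
    "save_model",
    "load_model",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


_ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "sigmoid": _sigmoid,
    "relu": lambda z: np.maximum(z, 0.0),
}


@dataclass
class _Scaler:
    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "_Scaler":
        std = X.std(axis=0, ddof=0)
        std[std == 0] = 1.0
        return cls(mean=X.mean(axis=0), std=std)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean) / self.std


@dataclass
class ELMModel:
    """Trained single-hidden-layer extreme learning machine."""

    W: np.ndarray  # features x hidden
    b: np.ndarray  # hidden
    beta: np.ndarray  # hidden x classes
    classes: np.ndarray
    activation: str
    C: float
    seed: int
    scaler: _Scaler | None = None

    def decision(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        H = _ACTIVATIONS[self.activation](X @ self.W + self.b)
        return H @ self.beta


def _one_hot(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes, idx = np.unique(y, return_inverse=True)
    T = -np.ones((len(y), len(classes)))
    T[np.arange(len(y)), idx] = 1.0
    return T, classes


def _solve_ridge(H: np.ndarray, T: np.ndarray, C: float) -> np.ndarray:
    n_hidden = H.shape[1]
    A = H.T @ H + C * np.eye(n_hidden)
    return np.linalg.solve(A, H.T @ T)


def elm_train(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray | None = None,
    n_hidden: int = 500,
    C: float = 1e-3,
    activation: str = "sigmoid",
    seed: int = 0,
    standardize: bool = True,
) -> ELMModel:
    """Train an ELM; ``X`` may be a FeatureMatrix (labels implied) or an array."""
    X, y = _unpack(X, y)
    if n_hidden < 1:
        raise ParameterError("n_hidden must be >= 1")
    if C < 0:
        raise ParameterError("ridge constant C must be >= 0")
    if activation not in _ACTIVATIONS:
        raise ParameterError(f"unknown activation {activation!r}")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ParameterError("training data must contain at least 2 classes")
    scaler = _Scaler.fit(X) if standardize else None
    Xs = scaler.transform(X) if scaler else X
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, (X.shape[1], n_hidden))
    b = rng.uniform(-1.0, 1.0, n_hidden)
    H = _ACTIVATIONS[activation](Xs @ W + b)
    T, classes = _one_hot(y)
    beta = _solve_ridge(H, T, C)
    if not np.all(np.isfinite(beta)):
        raise ParameterError("output weights are non-finite; increase C")
    return ELMModel(
        W=W, b=b, beta=beta, classes=classes, activation=activation,
        C=C, seed=seed, scaler=scaler,
    )


# --------------------------------------------------------------------- H-ELM

def _fista_l1(
    H: np.ndarray, X: np.ndarray, alpha: float, n_iter: int = 50
) -> np.ndarray:
    """l1-regularised least squares ``min ||H B - X||^2 + alpha ||B||_1``."""
    L = np.linalg.norm(H, 2) ** 2  # Lipschitz constant of the gradient
    if L == 0:
        return np.zeros((H.shape[1], X.shape[1]))
    B = np.zeros((H.shape[1], X.shape[1]))
    Z = B.copy()
    t = 1.0
    HtH, HtX = H.T @ H, H.T @ X
    step = 1.0 / L
    thr = alpha * step
    for _ in range(n_iter):
        G = Z - step * (HtH @ Z - HtX)
        B_new = np.sign(G) * np.maximum(np.abs(G) - thr, 0.0)
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        Z = B_new + ((t - 1.0) / t_new) * (B_new - B)
        B, t = B_new, t_new
    return B


@dataclass
class HELMModel:
    """Stacked sparse-ELM-autoencoder representation plus a final ELM."""

    layers: list[np.ndarray]  # projection matrices, input_dim -> layer_size
    final: ELMModel
    layer_sizes: list[int]
    C: float
    seed: int
    scaler: _Scaler | None = None
    activation: str = "sigmoid"

    def encode(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.scaler is not None:
            X = self.scaler.transform(X)
        g = _ACTIVATIONS[self.activation]
        for P in self.layers:
            X = g(X @ P)
        return X

    def decision(self, X: np.ndarray) -> np.ndarray:
        return self.final.decision(self.encode(X))


def helm_train(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray | None = None,
    layer_sizes: tuple[int, ...] = (100, 100),
    n_hidden: int = 500,
    C: float = 1e-3,
    l1_alpha: float = 1e-3,
    activation: str = "sigmoid",
    seed: int = 0,
) -> HELMModel:
    """Train the hierarchical ELM.

    Each autoencoder expands its input through a random hidden layer, learns
    sparse reconstruction weights B by FISTA, and projects forward with B^T;
    the final classifier is a plain ELM with ``n_hidden`` units on the last
    encoding.
    """
    X, y = _unpack(X, y)
    if not layer_sizes:
        raise ParameterError("layer_sizes must be non-empty")
    scaler = _Scaler.fit(X)
    Z = scaler.transform(X)
    rng = np.random.default_rng(seed)
    g = _ACTIVATIONS[activation]
    layers = []
    for size in layer_sizes:
        if size < 1:
            raise ParameterError("every layer size must be >= 1")
        A = rng.uniform(-1.0, 1.0, (Z.shape[1], size))
        H = g(Z @ A + rng.uniform(-1.0, 1.0, size))
        B = _fista_l1(H, Z, alpha=l1_alpha)  # size x input_dim
        P = B.T  # input_dim -> size projection
        Z = g(Z @ P)
        layers.append(P)
    final = elm_train(
        Z, y, n_hidden=n_hidden, C=C, activation=activation,
        seed=seed + 1, standardize=False,
    )
    return HELMModel(
        layers=layers, final=final, layer_sizes=list(layer_sizes),
        C=C, seed=seed, scaler=scaler, activation=activation,
    )


# ----------------------------------------------------------------------- PSO

@dataclass
class PSOConfig:
    """Canonical particle swarm settings and per-dimension search bounds."""

    bounds: list[tuple[float, float]] = field(default_factory=list)
    swarm_size: int = 15
    iterations: int = 30
    inertia: float = 0.7
    cognitive: float = 1.5
    social: float = 1.5
    velocity_clamp: float = 0.5  # fraction of each dimension's range
    seed: int = 0
    fitness_folds: int = 3
    init_positions: list | None = None  # warm-start particles (e.g. the incumbent)

    def validate(self) -> None:
        if self.swarm_size < 2:
            raise ParameterError("swarm_size must be >= 2")
        if not 0 < self.inertia < 1.5:
            raise ParameterError("inertia must be in (0, 1.5)")
        if not self.bounds:
            raise ParameterError("bounds must be non-empty")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ParameterError("every bound must satisfy lo < hi")


def pso_optimize(
    fitness: Callable[[np.ndarray], float], cfg: PSOConfig
) -> tuple[np.ndarray, float, list[float]]:
    """Maximise ``fitness`` over the box; returns (gbest, score, trace).

    Velocity update ``v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x)``;
    positions are clipped to the box, velocities clamped per dimension.
    Non-finite fitness values are treated as -inf.  The trace of the best
    score per iteration is non-decreasing by construction.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lo = np.array([b[0] for b in cfg.bounds])
    hi = np.array([b[1] for b in cfg.bounds])
    span = hi - lo
    vmax = cfg.velocity_clamp * span
    ndim = len(cfg.bounds)

    def safe_fitness(p: np.ndarray) -> float:
        val = fitness(p)
        if not np.isfinite(val):
            return float("-inf")
        return float(val)

    pos = rng.uniform(lo, hi, (cfg.swarm_size, ndim))
    if cfg.init_positions:
        for i, p in enumerate(cfg.init_positions[: cfg.swarm_size]):
            pos[i] = np.clip(np.asarray(p, dtype=float), lo, hi)
    vel = rng.uniform(-vmax, vmax, (cfg.swarm_size, ndim))
    pbest = pos.copy()
    pbest_score = np.array([safe_fitness(p) for p in pos])
    g_idx = int(np.argmax(pbest_score))
    gbest, gbest_score = pbest[g_idx].copy(), float(pbest_score[g_idx])
    trace = [gbest_score]
    for _ in range(cfg.iterations):
        r1 = rng.uniform(size=(cfg.swarm_size, ndim))
        r2 = rng.uniform(size=(cfg.swarm_size, ndim))
        vel = (
            cfg.inertia * vel
            + cfg.cognitive * r1 * (pbest - pos)
            + cfg.social * r2 * (gbest - pos)
        )
        vel = np.clip(vel, -vmax, vmax)
        pos = np.clip(pos + vel, lo, hi)
        for i in range(cfg.swarm_size):
            s = safe_fitness(pos[i])
            if s > pbest_score[i]:
                pbest[i], pbest_score[i] = pos[i].copy(), s
                if s > gbest_score:
                    gbest, gbest_score = pos[i].copy(), s
        trace.append(gbest_score)
    return gbest, gbest_score, trace


DEFAULT_PSO_BOUNDS = [
    (20.0, 300.0),   # autoencoder layer 1
    (20.0, 300.0),   # autoencoder layer 2
    (100.0, 1000.0),  # final ELM hidden width
    (-4.0, 4.0),      # log10 ridge constant
]


def pso_helm_train(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray | None = None,
    cfg: PSOConfig | None = None,
) -> tuple[HELMModel, dict]:
    """H-ELM with PSO-tuned hyperparameters.

    The swarm searches (layer1, layer2, final hidden, log10 C); each particle
    is scored by mean stratified k-fold CV accuracy on the *training* rows
    only (integer dimensions rounded at evaluation time), and the final model
    is retrained on all training rows at the best position.  The swarm is
    warm-started at the default H-ELM configuration, so the search moves off
    the incumbent only when cross-validation favours another candidate.
    """
    X, y = _unpack(X, y)
    cfg = cfg or PSOConfig(bounds=list(DEFAULT_PSO_BOUNDS))
    if not cfg.bounds:
        cfg.bounds = list(DEFAULT_PSO_BOUNDS)
    if cfg.init_positions is None and len(cfg.bounds) == 4:
        cfg.init_positions = [np.array([100.0, 100.0, 500.0, -3.0])]
    if len(np.unique(y)) < 2:
        raise ParameterError("training data must contain at least 2 classes")
    min_class = np.min(np.unique(y, return_counts=True)[1])
    folds = int(min(cfg.fitness_folds, min_class))
    if folds < 2:
        raise ParameterError("too few samples per class for CV fitness")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=cfg.seed)
    splits = list(skf.split(X, y))

    def decode(p: np.ndarray) -> dict:
        return dict(
            layer_sizes=(int(round(p[0])), int(round(p[1]))),
            n_hidden=int(round(p[2])),
            C=10.0 ** p[3],
        )

    def fitness(p: np.ndarray) -> float:
        kw = decode(p)
        accs = []
        for tr, te in splits:
            try:
                m = helm_train(X[tr], y[tr], seed=cfg.seed, **kw)
            except (ParameterError, np.linalg.LinAlgError):
                return float("-inf")
            accs.append(float(np.mean(predict(m, X[te]) == y[te])))
        return float(np.mean(accs))

    gbest, score, trace = pso_optimize(fitness, cfg)
    best_kw = decode(gbest)
    model = helm_train(X, y, seed=cfg.seed, **best_kw)
    return model, {"best_position": gbest, "cv_accuracy": score, "trace": trace,
                   "hyperparameters": best_kw}


# ------------------------------------------------------------------ baselines

def knn_train(
    X: FeatureMatrix | np.ndarray, y: np.ndarray | None = None, k: int = 5
):
    """K-nearest-neighbour baseline (Euclidean metric, standardised features)."""
    X, y = _unpack(X, y)
    pipe = Pipeline(
        [("scale", StandardScaler()), ("knn", KNeighborsClassifier(n_neighbors=k))]
    )
    pipe.fit(X, y)
    return pipe


def svm_train(
    X: FeatureMatrix | np.ndarray,
    y: np.ndarray | None = None,
    C: float = 1.0,
    gamma: str | float = "scale",
):
    """RBF-kernel support vector machine baseline (standardised features)."""
    X, y = _unpack(X, y)
    pipe = Pipeline(
        [("scale", StandardScaler()), ("svm", SVC(C=C, gamma=gamma, kernel="rbf"))]
    )
    pipe.fit(X, y)
    return pipe


def predict(model, X: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Labels from any trained model under the uniform contract."""
    if isinstance(X, FeatureMatrix):
        X = X.values
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        return np.array([], dtype=object)
    if isinstance(model, (ELMModel, HELMModel)):
        expected = (
            model.W.shape[0] if isinstance(model, ELMModel)
            else model.layers[0].shape[0]
        )
        if X.shape[1] != expected:
            raise ParameterError(
                f"model expects {expected} features, got {X.shape[1]}"
            )
        scores = model.decision(X)
        classes = model.classes if isinstance(model, ELMModel) else model.final.classes
        return classes[np.argmax(scores, axis=1)]
    return model.predict(X)


def _unpack(X, y):
    if isinstance(X, FeatureMatrix):
        if y is None:
            y = X.labels
        X = X.values
    X = np.asarray(X, dtype=float)
    if y is None:
        raise ParameterError("labels are required")
    y = np.asarray(y)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ParameterError("X must be 2-D with one label per row")
    return X, y


# ------------------------------------------------------------- serialisation

_FORMAT_VERSION = 1


def save_model(model, path: str) -> None:
    """Serialise any trained model to a versioned binary container."""
    import pickle

    with open(path, "wb") as fh:
        pickle.dump({"version": _FORMAT_VERSION, "model": model}, fh)


def load_model(path: str):
    import pickle

    with open(path, "rb") as fh:
        payload = pickle.load(fh)
    if payload.get("version") != _FORMAT_VERSION:
        raise ParameterError(f"unsupported model container version: {payload.get('version')}")
    return payload["model"]
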