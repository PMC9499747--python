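"""Binary particle-swarm feature selection.

A swarm of particles explores a real-valued search space; each particle keeps
its personal best position (p_best) and the swarm shares a global best
(g_best). Per iteration the velocity and position update as

    v <- w*v + c1*r1*(p_best - x) + c2*r2*(g_best - x)   (clamped to +-v_max)
    x <- x + v

with inertia w and cognitive/social coefficients c1, c2. For feature
selection each coordinate is squashed through a sigmoid and thresholded at
0.5 to yield a boolean mask (binary-PSO transfer convention; an empty mask is
repaired by selecting the highest-scoring coordinate). Selection fitness is
the stratified 3-fold cross-validated accuracy of a nearest-centroid
classifier on the masked features minus a sparsity penalty proportional to
the selected fraction — cheap, deterministic given the folds, and decoupled
from the downstream network.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.neighbors import NearestCentroid
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted, check_X_y


@dataclass
class SwarmConfig:
    n_particles: int = 30
    n_iterations: int = 60
    inertia: float = 0.72
    c1: float = 1.49
    c2: float = 1.49
    v_max: float = 4.0
    sparsity_weight: float = 0.02
    cv_folds: int = 3
    seed: int | None = None

    def validate(self):
        if self.n_particles < 1 or self.n_iterations < 1:
            raise ValueError("n_particles and n_iterations must be >= 1")
        for c in (self.inertia, self.c1, self.c2):
            if c < 0:
                raise ValueError("PSO coefficients must be >= 0")


class Swarm:
    """Generic maximising PSO engine over R^dim.

    ``objective`` maps a position vector to a scalar fitness (higher is
    better). :meth:`step` performs one velocity/position update and refreshes
    p_best/g_best; ``gbest_trace`` is therefore non-decreasing.
    """

    def __init__(self, objective, dim, cfg: SwarmConfig, rng,
                 init_range=(-1.0, 1.0)):
        self.objective = objective
        self.cfg = cfg
        self.rng = rng
        lo, hi = init_range
        self.x = rng.uniform(lo, hi, size=(cfg.n_particles, dim))
        self.v = rng.uniform(-abs(hi - lo), abs(hi - lo),
                             size=(cfg.n_particles, dim)) * 0.1
        self.pbest_x = self.x.copy()
        self.pbest_f = np.array([objective(p) for p in self.x])
        g = int(np.argmax(self.pbest_f))
        self.gbest_x = self.pbest_x[g].copy()
        self.gbest_f = float(self.pbest_f[g])
        self.gbest_trace = [self.gbest_f]

    def step(self):
        cfg, rng = self.cfg, self.rng
        r1 = rng.random(self.x.shape)
        r2 = rng.random(self.x.shape)
        self.v = (cfg.inertia * self.v
                  + cfg.c1 * r1 * (self.pbest_x - self.x)
                  + cfg.c2 * r2 * (self.gbest_x - self.x))
        np.clip(self.v, -cfg.v_max, cfg.v_max, out=self.v)
        self.x = self.x + self.v
        f = np.array([self.objective(p) for p in self.x])
        improved = f > self.pbest_f
        self.pbest_x[improved] = self.x[improved]
        self.pbest_f[improved] = f[improved]
        g = int(np.argmax(self.pbest_f))
        if self.pbest_f[g] > self.gbest_f:
            self.gbest_f = float(self.pbest_f[g])
            self.gbest_x = self.pbest_x[g].copy()
        self.gbest_trace.append(self.gbest_f)
        return self

    def run(self):
        for _ in range(self.cfg.n_iterations):
            self.step()
        return self


def optimize(objective, dim, cfg: SwarmConfig | None = None, seed=None,
             init_range=(-5.0, 5.0), maximize=True):
    """Continuous PSO on an arbitrary objective (selection mapping disabled).

    Returns ``(best_x, best_f, trace)``; with ``maximize=False`` the
    objective is negated internally and the returned best_f/trace are on the
    original (minimisation) scale.
    """
    cfg = cfg or SwarmConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    sign = 1.0 if maximize else -1.0
    swarm = Swarm(lambda p: sign * objective(p), dim, cfg, rng, init_range)
    swarm.run()
    trace = [sign * f for f in swarm.gbest_trace]
    return swarm.gbest_x, sign * swarm.gbest_f, trace


def sigmoid(z):
    from scipy.special import expit

    return expit(z)


def position_to_mask(position) -> np.ndarray:
    """Binary transfer: feature selected iff sigmoid(position) > 0.5.

    Repairs an all-empty mask by selecting the highest-position feature, so
    the mask is never empty.
    """
    position = np.asarray(position, dtype=np.float64)
    mask = sigmoid(position) > 0.5
    if not mask.any():
        mask[int(np.argmax(position))] = True
    return mask


class PSOFeatureSelector(SelectorMixin, BaseEstimator):
    """Binary-PSO feature selector with a scikit-learn selector surface.

    Attributes
    ----------
    support_ : boolean ndarray of shape (n_features,)
        The selected-feature mask (never empty).
    gbest_trace_ : list of float
        Global-best fitness per iteration; non-decreasing.
    best_fitness_ : float
    n_iter_ : int
    """

    def __init__(self, n_particles=30, n_iterations=60, inertia=0.72,
                 c1=1.49, c2=1.49, v_max=4.0, sparsity_weight=0.02,
                 cv_folds=3, random_state=None):
        self.n_particles = n_particles
        self.n_iterations = n_iterations
        self.inertia = inertia
        self.c1 = c1
        self.c2 = c2
        self.v_max = v_max
        self.sparsity_weight = sparsity_weight
        self.cv_folds = cv_folds
        self.random_state = random_state

    def _mask_fitness_factory(self, X, y):
        n_features = X.shape[1]
        cv = StratifiedKFold(n_splits=self.cv_folds, shuffle=False)
        clf = make_pipeline(StandardScaler(), NearestCentroid())
        cache: dict = {}

        def fitness(mask: np.ndarray) -> float:
            key = mask.tobytes()
            if key not in cache:
                acc = cross_val_score(clf, X[:, mask], y, cv=cv).mean()
                cache[key] = float(
                    acc - self.sparsity_weight * mask.sum() / n_features
                )
            return cache[key]

        return fitness

    def fit(self, X, y):
        X, y = check_X_y(X, y)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("feature selection needs at least two classes")
        if X.shape[1] < 2:
            raise ValueError("feature selection needs at least two features")
        if counts.min() < self.cv_folds:
            raise ValueError(
                f"every class needs >= cv_folds={self.cv_folds} samples"
            )
        cfg = SwarmConfig(
            n_particles=self.n_particles, n_iterations=self.n_iterations,
            inertia=self.inertia, c1=self.c1, c2=self.c2, v_max=self.v_max,
            sparsity_weight=self.sparsity_weight, cv_folds=self.cv_folds,
            seed=self.random_state,
        )
        cfg.validate()
        rng = np.random.default_rng(cfg.seed)
        mask_fitness = self._mask_fitness_factory(X, y)
        swarm = Swarm(lambda p: mask_fitness(position_to_mask(p)),
                      X.shape[1], cfg, rng, init_range=(-1.0, 1.0)).run()

        self.n_features_in_ = X.shape[1]
        self.support_ = position_to_mask(swarm.gbest_x)
        self.best_fitness_ = swarm.gbest_f
        self.gbest_trace_ = list(swarm.gbest_trace)
        self.n_iter_ = cfg.n_iterations
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_")
        return self.support_


def run_pso(X, y, cfg: SwarmConfig | None = None):
    """Functional wrapper: returns ``(mask, trace)`` for a feature table."""
    cfg = cfg or SwarmConfig()
    sel = PSOFeatureSelector(
        n_particles=cfg.n_particles, n_iterations=cfg.n_iterations,
        inertia=cfg.inertia, c1=cfg.c1, c2=cfg.c2, v_max=cfg.v_max,
        sparsity_weight=cfg.sparsity_weight, cv_folds=cfg.cv_folds,
        random_state=cfg.seed,
    ).fit(np.asarray(X, dtype=np.float64), np.asarray(y))
    return sel.support_, sel.gbest_trace_
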