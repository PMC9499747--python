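"""Genetic-algorithm clustering segmentation.

Segments a preprocessed greyscale slice into K intensity clusters with a
real-coded GA. Each chromosome encodes K scalar cluster centres; evaluating a
chromosome assigns every pixel to its nearest centre by absolute intensity
distance, replaces each centre by its cluster's mean (a Lloyd step, so the GA
is Lamarckian), and scores the clustering metric

    M = sum_j sum_{r in C_j} |r - G_j|

whose reciprocal f = 1/(M + eps) is the fitness. Parents are drawn by
fitness-proportional roulette-wheel selection; genes recombine by arithmetic
blend crossover and mutate by Michalewicz non-uniform mutation, whose step
size decays to zero as the generation count approaches its maximum. The best
chromosome is carried over unchanged (elitism), so best fitness never
regresses. The tumor is read off the final labelling as the cluster with the
highest (configurable: lowest) mean intensity.

Clustering is deliberately 1-D — pixels and centres live in intensity space;
no spatial regularisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .image import ImageSlice, as_image

_EPS_FITNESS = 1e-9


@dataclass
class GAConfig:
    n_clusters: int = 3
    population_size: int = 20
    max_generations: int = 100          # K_max
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    blend_a: float = 0.7                # crossover blend weight a in [0, 1]
    shape_d: float = 2.0                # mutation shape parameter d
    elitism: int = 1
    stall_generations: int = 10         # fitness-stability stop window
    stall_rel_tol: float = 1e-6
    tumor_cluster: str = "brightest"    # or "darkest"
    clean_mask: bool = True             # closing + hole fill + largest CC
    seed: int | None = None

    def validate(self):
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")
        for p in (self.crossover_prob, self.mutation_prob, self.blend_a):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities and blend_a must lie in [0, 1]")
        if self.tumor_cluster not in ("brightest", "darkest"):
            raise ValueError("tumor_cluster must be 'brightest' or 'darkest'")


@dataclass
class Chromosome:
    """Ordered list of K cluster centres with bounds and fitness."""

    centres: np.ndarray
    fitness: float = np.nan
    bounds: tuple = (0.0, 255.0)


@dataclass
class Segmentation:
    labels: np.ndarray       # per-pixel cluster index, image-shaped
    tumor_mask: np.ndarray
    centres: np.ndarray
    metric: float            # clustering metric M of the winning chromosome
    history: list = field(default_factory=list)  # (generation, best M, best f)


# ---------------------------------------------------------------- primitives


def assign_clusters(pixels, centres, rng=None, weights=None):
    """Assign each pixel to the nearest centre by |r_i - z_j|.

    Ties (a pixel exactly equidistant from two or more centres) are broken
    uniformly at random under ``rng``; with no rng the lowest index wins.
    """
    pixels = np.asarray(pixels, dtype=np.float64).ravel()
    centres = np.asarray(centres, dtype=np.float64).ravel()
    if centres.size == 0:
        raise ValueError("at least one centre is required")
    if pixels.size == 0:
        return np.empty(0, dtype=np.intp)
    d = np.abs(pixels[:, None] - centres[None, :])
    if rng is None:
        return d.argmin(axis=1)
    is_min = d == d.min(axis=1, keepdims=True)
    # random key on the tied minima only -> uniform choice among them
    key = np.where(is_min, rng.random(d.shape), -1.0)
    return key.argmax(axis=1)


def update_centres(pixels, labels, n_clusters, prev_centres=None, weights=None):
    """Replace each centre by the mean of its members (empty keeps previous)."""
    pixels = np.asarray(pixels, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    w = np.ones_like(pixels) if weights is None else np.asarray(weights, float)
    sums = np.bincount(labels, weights=pixels * w, minlength=n_clusters)
    counts = np.bincount(labels, weights=w, minlength=n_clusters)
    centres = np.empty(n_clusters, dtype=np.float64)
    nonempty = counts > 0
    centres[nonempty] = sums[nonempty] / counts[nonempty]
    if not nonempty.all():
        if prev_centres is None:
            raise ValueError("empty cluster with no previous centres to keep")
        centres[~nonempty] = np.asarray(prev_centres, float)[~nonempty]
    return centres


def clustering_metric(pixels, labels, centres, weights=None):
    """M = total absolute deviation of pixels from their assigned centres."""
    pixels = np.asarray(pixels, dtype=np.float64).ravel()
    centres = np.asarray(centres, dtype=np.float64).ravel()
    dev = np.abs(pixels - centres[np.asarray(labels).ravel()])
    if weights is not None:
        dev = dev * np.asarray(weights, float)
    return float(dev.sum())


def fitness(metric, eps: float = _EPS_FITNESS) -> float:
    """f = 1/(M + eps); strictly decreasing in M, finite at M = 0."""
    if metric < 0:
        raise ValueError("clustering metric must be non-negative")
    return 1.0 / (metric + eps)


def roulette_select(fitnesses, rng, size: int = 2):
    """Fitness-proportional sampling of ``size`` parent indices."""
    f = np.asarray(fitnesses, dtype=np.float64)
    if (f < 0).any():
        raise ValueError("fitness values must be non-negative")
    total = f.sum()
    if total <= 0:
        warnings.warn(
            "all fitness values are zero; falling back to uniform selection",
            stacklevel=2,
        )
        p = np.full(f.size, 1.0 / f.size)
    else:
        p = f / total
    return rng.choice(f.size, size=size, p=p)


def mutate(genes, bounds, generation, cfg: GAConfig, rng):
    """Non-uniform mutation with a step that decays over generations.

    For each gene hit with probability ``mutation_prob``: draw p_l, p_2
    uniform on [0, 1] and move up toward the upper bound d_i if p_l < 0.5,
    else down toward the lower bound c_i, by the fraction
    ``f(K) = (p_2 * (1 - K/K_max))**d`` of the remaining headroom. The result
    always stays inside [c_i, d_i]; at K = K_max the step is zero.
    """
    x = np.asarray(genes, dtype=np.float64).copy()
    c, d = bounds
    hit = rng.random(x.size) < cfg.mutation_prob
    for i in np.nonzero(hit)[0]:
        p_l = rng.random()
        p_2 = rng.random()
        f_k = (p_2 * (1.0 - generation / cfg.max_generations)) ** cfg.shape_d
        if p_l < 0.5:
            x[i] = x[i] + (d - x[i]) * f_k
        else:
            x[i] = x[i] - (x[i] - c) * f_k
    return np.clip(x, c, d)


def crossover(parent_m, parent_n, a: float, rng=None, crossover_prob: float = 1.0):
    """Arithmetic blend: M' = a*M + (1-a)*N, N' = (1-a)*M + a*N, per gene.

    Applied gene-wise with probability ``crossover_prob`` (untouched genes are
    copied). Gene-wise sums are preserved: M' + N' = M + N for any a.
    """
    m = np.asarray(parent_m, dtype=np.float64)
    n = np.asarray(parent_n, dtype=np.float64)
    if m.shape != n.shape:
        raise ValueError("parents must have the same number of genes")
    if not 0.0 <= a <= 1.0:
        raise ValueError("blend weight a must lie in [0, 1]")
    if crossover_prob >= 1.0 or rng is None:
        hit = np.ones(m.shape, dtype=bool)
    else:
        hit = rng.random(m.shape) < crossover_prob
    m2, n2 = m.copy(), n.copy()
    m2[hit] = a * m[hit] + (1.0 - a) * n[hit]
    n2[hit] = (1.0 - a) * m[hit] + a * n[hit]
    return m2, n2


def clean_tumor_mask(mask: np.ndarray) -> np.ndarray:
    """Morphological cleanup of a raw cluster mask into one tumor region.

    Closing bridges gaps in enhancing rims, hole filling turns a closed rim
    into a solid region, and largest-connected-component selection drops
    scattered same-intensity pixels elsewhere in the tissue. Helps compact
    high-contrast tumors; cannot rescue a cluster dominated by tissue noise.
    """
    m = np.asarray(mask, bool)
    if not m.any():
        return m
    m = ndimage.binary_closing(m, structure=np.ones((3, 3)), iterations=2)
    m = ndimage.binary_fill_holes(m)
    labels, n = ndimage.label(m)
    if n > 1:
        m = labels == (np.bincount(labels.ravel())[1:].argmax() + 1)
    return m


# ------------------------------------------------------------------ full GA


def _evaluate(centres, values, weights, rng):
    """Lloyd-step evaluation: assign, recentre, score. Returns (centres, M)."""
    labels = assign_clusters(values, centres, rng=rng)
    new_centres = update_centres(values, labels, centres.size,
                                 prev_centres=centres, weights=weights)
    labels = assign_clusters(values, new_centres, rng=rng)
    m = clustering_metric(values, labels, new_centres, weights=weights)
    return new_centres, m


class GAClusterSegmenter(ClusterMixin, BaseEstimator):
    """GA intensity clustering with a scikit-learn estimator surface.

    Parameters mirror :class:`GAConfig`. ``fit`` expects ``X`` of shape
    ``(n_pixels, 1)`` (flattened intensities); :meth:`segment` accepts an
    image directly and returns a :class:`Segmentation`.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (n_clusters,)
        Centres of the winning chromosome, sorted ascending.
    labels_ : ndarray of shape (n_pixels,)
        Cluster index of each training pixel.
    metric_ : float
        Final clustering metric M.
    history_ : list of (generation, best_M, best_fitness)
    n_iter_ : int
        Generations actually run.
    """

    def __init__(self, n_clusters=3, population_size=20, max_generations=100,
                 crossover_prob=0.8, mutation_prob=0.1, blend_a=0.7,
                 shape_d=2.0, elitism=1, stall_generations=10,
                 stall_rel_tol=1e-6, tumor_cluster="brightest",
                 clean_mask=True, random_state=None):
        self.n_clusters = n_clusters
        self.population_size = population_size
        self.max_generations = max_generations
        self.crossover_prob = crossover_prob
        self.mutation_prob = mutation_prob
        self.blend_a = blend_a
        self.shape_d = shape_d
        self.elitism = elitism
        self.stall_generations = stall_generations
        self.stall_rel_tol = stall_rel_tol
        self.tumor_cluster = tumor_cluster
        self.clean_mask = clean_mask
        self.random_state = random_state

    def _config(self) -> GAConfig:
        cfg = GAConfig(
            n_clusters=self.n_clusters,
            population_size=self.population_size,
            max_generations=self.max_generations,
            crossover_prob=self.crossover_prob,
            mutation_prob=self.mutation_prob,
            blend_a=self.blend_a,
            shape_d=self.shape_d,
            elitism=self.elitism,
            stall_generations=self.stall_generations,
            stall_rel_tol=self.stall_rel_tol,
            tumor_cluster=self.tumor_cluster,
            clean_mask=self.clean_mask,
            seed=self.random_state,
        )
        cfg.validate()
        return cfg

    def fit(self, X, y=None):
        cfg = self._config()
        pixels = np.asarray(X, dtype=np.float64).reshape(-1)
        rng = np.random.default_rng(cfg.seed)

        # evaluate on the weighted histogram of unique intensities; Eqs. over
        # scalar intensities make this exactly equivalent and much faster
        values, weights = np.unique(pixels, return_counts=True)
        if values.size < cfg.n_clusters:
            raise ValueError(
                f"need at least as many distinct intensities "
                f"({values.size}) as clusters ({cfg.n_clusters})"
            )
        lo, hi = float(values.min()), float(values.max())
        weights = weights.astype(np.float64)

        pop = rng.uniform(lo, hi, size=(cfg.population_size, cfg.n_clusters))
        history = []
        best_centres, best_m = None, np.inf
        stall = 0
        gen = 0
        for gen in range(1, cfg.max_generations + 1):
            metrics = np.empty(cfg.population_size)
            for k in range(cfg.population_size):
                pop[k], metrics[k] = _evaluate(pop[k], values, weights, rng)
            fits = np.array([fitness(m) for m in metrics])
            order = np.argsort(metrics)
            gen_best_m = metrics[order[0]]
            if gen_best_m < best_m:
                if np.isfinite(best_m):
                    rel = (best_m - gen_best_m) / max(best_m, _EPS_FITNESS)
                    stall = 0 if rel > cfg.stall_rel_tol else stall + 1
                else:
                    stall = 0
                best_m = gen_best_m
                best_centres = pop[order[0]].copy()
            else:
                stall += 1
            history.append((gen, float(best_m), fitness(best_m)))
            if stall >= cfg.stall_generations:
                break
            if gen == cfg.max_generations:
                break

            elite = pop[order[: cfg.elitism]].copy()
            children = list(elite)
            while len(children) < cfg.population_size:
                i, j = roulette_select(fits, rng, size=2)
                c1, c2 = crossover(pop[i], pop[j], cfg.blend_a, rng=rng,
                                   crossover_prob=cfg.crossover_prob)
                c1 = mutate(c1, (lo, hi), gen, cfg, rng)
                c2 = mutate(c2, (lo, hi), gen, cfg, rng)
                children.extend([c1, c2])
            pop = np.array(children[: cfg.population_size])

        order = np.argsort(best_centres)
        self.cluster_centers_ = best_centres[order]
        self.labels_ = assign_clusters(pixels, self.cluster_centers_, rng=rng)
        self.metric_ = clustering_metric(pixels, self.labels_, self.cluster_centers_)
        self.history_ = history
        self.n_iter_ = gen
        return self

    def predict(self, X):
        check_is_fitted(self, "cluster_centers_")
        return assign_clusters(np.asarray(X).reshape(-1), self.cluster_centers_)

    def segment(self, image, brain_mask=None) -> Segmentation:
        """Cluster an image's intensities and extract the tumor mask.

        If ``brain_mask`` is given, only pixels inside it are clustered;
        outside pixels get label -1 and cannot belong to the tumor.
        """
        img = as_image(image)
        px = img.pixels
        flat_mask = (np.ones(px.shape, bool) if brain_mask is None
                     else np.asarray(brain_mask, bool))
        self.fit(px[flat_mask].reshape(-1, 1))
        labels = np.full(px.shape, -1, dtype=np.intp)
        labels[flat_mask] = self.labels_
        tumor_idx = (self.cluster_centers_.argmax()
                     if self.tumor_cluster == "brightest"
                     else self.cluster_centers_.argmin())
        tumor_mask = labels == tumor_idx
        if self.clean_mask:
            tumor_mask = clean_tumor_mask(tumor_mask)
        return Segmentation(labels, tumor_mask, self.cluster_centers_.copy(),
                            self.metric_, list(self.history_))


def run_ga(image, cfg: GAConfig | None = None, brain_mask=None) -> Segmentation:
    """Functional wrapper over :class:`GAClusterSegmenter`."""
    cfg = cfg or GAConfig()
    cfg.validate()
    est = GAClusterSegmenter(
        n_clusters=cfg.n_clusters, population_size=cfg.population_size,
        max_generations=cfg.max_generations, crossover_prob=cfg.crossover_prob,
        mutation_prob=cfg.mutation_prob, blend_a=cfg.blend_a,
        shape_d=cfg.shape_d, elitism=cfg.elitism,
        stall_generations=cfg.stall_generations,
        stall_rel_tol=cfg.stall_rel_tol, tumor_cluster=cfg.tumor_cluster,
        clean_mask=cfg.clean_mask, random_state=cfg.seed,
    )
    return est.segment(image, brain_mask=brain_mask)
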