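"""Geometric binary PSO wrapper selection with SVM cross-validation fitness.

Particles are bit masks over the filtered genes. Geometric PSO replaces the
velocity update of real-valued PSO with a three-parent crossover in Hamming
space: each offspring bit is copied from the particle's current position, its
personal best, or the global best with probabilities (w_self, w_pbest,
w_gbest), followed by independent bit-flip mutation. With zero mutation the
offspring always lies in the parents' Hamming convex hull.

A candidate mask's fitness is the mean stratified K-fold cross-validated
accuracy of a polynomial-kernel SVM trained on the masked genes; the fold
split is fixed for the whole run so every particle is scored on identical
data partitions. The empty mask has fitness 0 by convention. Ties between
equal-fitness masks prefer fewer selected genes, then the lexicographically
smaller mask — the point of the wrapper is a small subset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .dataset import ExpressionDataset

__all__ = [
    "SvmConfig",
    "GbpsoConfig",
    "SelectionResult",
    "subset_fitness",
    "gbpso_move",
    "run_gbpso",
]


@dataclass
class SvmConfig:
    """Polynomial-kernel SVM and CV settings used for wrapper fitness."""

    degree: int = 1
    C: float = 1.0
    cv_folds: int = 10
    cv_seed: int = 0

    def __post_init__(self) -> None:
        if self.degree < 1:
            raise ValueError("degree must be >= 1")
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")

    def classifier(self) -> SVC:
        return SVC(kernel="poly", degree=self.degree, C=self.C, gamma="scale", coef0=0.0)


@dataclass
class GbpsoConfig:
    """Swarm settings for geometric binary PSO.

    ``mutation_rate=None`` means 1/L, L the gene count. The three crossover
    weights must be non-negative and sum to 1.
    """

    population: int = 20
    iterations: int = 100
    w_self: float = 1.0 / 3.0
    w_pbest: float = 1.0 / 3.0
    w_gbest: float = 1.0 / 3.0
    mutation_rate: float | None = None
    init_inclusion_prob: float = 0.5
    seed: int = 0
    svm: SvmConfig = field(default_factory=SvmConfig)

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        w = (self.w_self, self.w_pbest, self.w_gbest)
        if any(x < 0 for x in w) or not np.isclose(sum(w), 1.0):
            raise ValueError("crossover weights must be non-negative and sum to 1")
        for p in (self.init_inclusion_prob,) + (
            (self.mutation_rate,) if self.mutation_rate is not None else ()
        ):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class SelectionResult:
    """Outcome of a swarm run over the filtered gene set."""

    best_mask: np.ndarray
    best_fitness: float
    fitness_trace: list[float]
    selected_gene_ids: list[str]

    def trace_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("iteration\tbest_fitness\n")
            for i, f in enumerate(self.fitness_trace):
                fh.write(f"{i}\t{f:.6g}\n")


def _cv_splitter(labels: np.ndarray, folds: int, seed: int) -> StratifiedKFold:
    min_class = int(min(np.sum(labels == 0), np.sum(labels == 1)))
    if folds > min_class:
        warnings.warn(f"reducing CV folds from {folds} to {min_class}")
        folds = min_class
    return StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)


def subset_fitness(mask, ds: ExpressionDataset, svm: SvmConfig | None = None) -> float:
    """Mean stratified K-fold CV accuracy of the SVM on the masked genes."""
    svm = svm or SvmConfig()
    mask = np.asarray(mask, dtype=bool)
    if mask.size != ds.n_genes:
        raise ValueError("mask length must equal the gene count")
    if not mask.any():
        return 0.0
    X = ds.values[mask, :].T
    y = ds.labels
    skf = _cv_splitter(y, svm.cv_folds, svm.cv_seed)
    accs = []
    for train_idx, test_idx in skf.split(X, y):
        clf = svm.classifier()
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        accs.append(float(np.mean(pred == y[test_idx])))
    return float(np.mean(accs))


def gbpso_move(
    current, pbest, gbest, cfg: GbpsoConfig, rng: np.random.Generator
) -> np.ndarray:
    """One geometric-PSO position update: 3-parent crossover then mutation."""
    current = np.asarray(current, dtype=bool)
    pbest = np.asarray(pbest, dtype=bool)
    gbest = np.asarray(gbest, dtype=bool)
    if not (current.size == pbest.size == gbest.size):
        raise ValueError("mask lengths differ")
    L = current.size
    choice = rng.random(L)
    out = np.where(
        choice < cfg.w_self,
        current,
        np.where(choice < cfg.w_self + cfg.w_pbest, pbest, gbest),
    )
    rate = cfg.mutation_rate if cfg.mutation_rate is not None else 1.0 / L
    flip = rng.random(L) < rate
    return out ^ flip


def _better(fitness_a: float, mask_a: np.ndarray, fitness_b: float, mask_b: np.ndarray) -> bool:
    """Is (a) strictly preferable to (b)? Fitness, then parsimony, then lex order."""
    if fitness_a != fitness_b:
        return fitness_a > fitness_b
    ka, kb = int(mask_a.sum()), int(mask_b.sum())
    if ka != kb:
        return ka < kb
    return mask_a.astype(np.uint8).tobytes() < mask_b.astype(np.uint8).tobytes()


def run_gbpso(ds_filtered: ExpressionDataset, cfg: GbpsoConfig | None = None) -> SelectionResult:
    """Run the swarm over the filtered dataset; reproducible under cfg.seed.

    Fitness values are cached per mask (particles revisit positions). The
    returned trace holds the global-best fitness after initialization and
    after every iteration; it is non-decreasing by construction.
    """
    cfg = cfg or GbpsoConfig()
    if ds_filtered.n_genes == 0:
        raise ValueError("filtered dataset has no genes")
    L = ds_filtered.n_genes
    rng = np.random.default_rng(cfg.seed)
    cache: dict[bytes, float] = {}

    def fitness(mask: np.ndarray) -> float:
        key = np.packbits(mask).tobytes()
        if key not in cache:
            cache[key] = subset_fitness(mask, ds_filtered, cfg.svm)
        return cache[key]

    positions = rng.random((cfg.population, L)) < cfg.init_inclusion_prob
    fits = np.array([fitness(positions[i]) for i in range(cfg.population)])
    pbest = positions.copy()
    pbest_fit = fits.copy()
    g = 0
    for i in range(1, cfg.population):
        if _better(pbest_fit[i], pbest[i], pbest_fit[g], pbest[g]):
            g = i
    gbest = pbest[g].copy()
    gbest_fit = float(pbest_fit[g])
    trace = [gbest_fit]

    for _ in range(cfg.iterations):
        for i in range(cfg.population):
            positions[i] = gbpso_move(positions[i], pbest[i], gbest, cfg, rng)
            f = fitness(positions[i])
            if _better(f, positions[i], pbest_fit[i], pbest[i]):
                pbest[i] = positions[i].copy()
                pbest_fit[i] = f
                if _better(f, positions[i], gbest_fit, gbest):
                    gbest = positions[i].copy()
                    gbest_fit = f
        trace.append(gbest_fit)

    selected = [g_id for g_id, bit in zip(ds_filtered.gene_ids, gbest) if bit]
    return SelectionResult(gbest, gbest_fit, trace, selected)
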