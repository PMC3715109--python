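"""Genetic-algorithm search for small discriminative bin subsets.

Mirrors GALGO-style variable selection: chromosomes are small sets of bin
indices scored by cross-validated accuracy of a simple classifier (nearest
centroid by default); many short independent searches are run and bins are
ranked by how often they appear in the searches' best chromosomes. Selected
bins are presented via PCA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold

from .plsda import CvReport, _as_array, _confusion, encode_labels


@dataclass(frozen=True)
class GaParams:
    """Hyperparameters of the GA search (published GALGO-practice defaults)."""

    chromosome_length: int = 5
    population_size: int = 30
    max_generations: int = 200
    fitness_goal: float = 0.90
    n_searches: int = 100
    kfold: int = 5
    mutation_rate: float = 0.02
    seed: int = 0
    classifier: str = "nearest_centroid"  # or "knn3"

    def __post_init__(self) -> None:
        if self.chromosome_length < 1:
            raise ValueError("chromosome_length must be >= 1")
        if not 0 < self.fitness_goal <= 1:
            raise ValueError("fitness_goal must be in (0, 1]")
        for name in ("population_size", "max_generations", "n_searches", "kfold"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must be in [0, 1]")


@dataclass
class GaRun:
    """Best chromosome per search plus aggregate bin-selection frequencies."""

    solutions: list[tuple[tuple[int, ...], float]]
    bin_frequency: dict[int, int]
    params: GaParams
    bin_centers: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "solutions": [
                {"chromosome": [int(b) for b in c], "fitness": float(f)}
                for c, f in self.solutions
            ],
            "bin_frequency": {str(k): int(v) for k, v in
                              sorted(self.bin_frequency.items())},
            "params": {k: (v if not isinstance(v, float) else float(v))
                       for k, v in vars(self.params).items()},
        }


def stratified_folds(y01: np.ndarray, kfold: int, seed: int) -> list[np.ndarray]:
    """Stratified K-fold test-index lists (both classes in every train fold)."""
    counts = np.bincount(y01)
    if kfold > counts.min():
        raise ValueError(
            f"kfold={kfold} exceeds the smallest class size ({counts.min()}); "
            "stratification impossible"
        )
    skf = StratifiedKFold(n_splits=kfold, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(y01.size), y01)]


def _predict_folds(Xsub: np.ndarray, y01: np.ndarray, folds: list[np.ndarray],
                   classifier: str = "nearest_centroid") -> np.ndarray:
    """Held-out class predictions over all folds."""
    n = y01.size
    pred = np.zeros(n, dtype=np.int64)
    mask = np.zeros(n, dtype=bool)
    for test in folds:
        mask[:] = False
        mask[test] = True
        Xtr, ytr, Xte = Xsub[~mask], y01[~mask], Xsub[test]
        if classifier == "nearest_centroid":
            c0 = Xtr[ytr == 0].mean(axis=0)
            c1 = Xtr[ytr == 1].mean(axis=0)
            d0 = np.sum((Xte - c0) ** 2, axis=1)
            d1 = np.sum((Xte - c1) ** 2, axis=1)
            pred[test] = (d1 < d0).astype(np.int64)
        elif classifier == "knn3":
            d = np.sum((Xte[:, None, :] - Xtr[None, :, :]) ** 2, axis=2)
            nn = np.argsort(d, axis=1)[:, :3]
            pred[test] = (ytr[nn].sum(axis=1) >= 2).astype(np.int64)
        else:
            raise ValueError(f"unknown classifier {classifier!r}")
    return pred


def fitness(chromosome, X, y, kfold: int = 5, seed: int = 0,
            classifier: str = "nearest_centroid") -> float:
    """Mean held-out accuracy of the chromosome's bins under seeded K-fold."""
    Xa = _as_array(X)
    chrom = sorted(int(b) for b in chromosome)
    if any(b < 0 or b >= Xa.shape[1] for b in chrom):
        raise IndexError(f"chromosome bins out of range for {Xa.shape[1]} bins")
    coded, _ = encode_labels(y)
    y01 = (coded > 0).astype(np.int64)
    folds = stratified_folds(y01, kfold, seed)
    pred = _predict_folds(Xa[:, chrom], y01, folds, classifier)
    return float(np.mean(pred == y01))


def _random_chromosome(rng: np.random.Generator, p: int, length: int
                       ) -> tuple[int, ...]:
    return tuple(sorted(rng.choice(p, size=length, replace=False).tolist()))


def _mutate(rng: np.random.Generator, chrom: tuple[int, ...], p: int,
            rate: float) -> tuple[int, ...]:
    genes = list(chrom)
    in_use = set(genes)
    for i in range(len(genes)):
        if rng.random() < rate:
            candidates = [b for b in range(p) if b not in in_use]
            if not candidates:
                continue
            new = int(candidates[rng.integers(len(candidates))])
            in_use.discard(genes[i])
            in_use.add(new)
            genes[i] = new
    return tuple(sorted(genes))


def _crossover(rng: np.random.Generator, a: tuple[int, ...], b: tuple[int, ...]
               ) -> tuple[int, ...]:
    """Single-point crossover on the sorted index lists, repaired to a set."""
    length = len(a)
    if length == 1:
        return a if rng.random() < 0.5 else b
    point = int(rng.integers(1, length))
    child = list(a[:point])
    for g in b[point:]:
        if g not in child:
            child.append(g)
    # parents jointly carry >= length distinct genes, so the child always fills
    pool = [g for g in (a[point:] + b[:point]) if g not in child]
    while len(child) < length:
        child.append(pool.pop(0))
    return tuple(sorted(child[:length]))


def evolve(X, y, params: GaParams) -> GaRun:
    """Run ``n_searches`` independent GA searches; record the best of each.

    Tournament selection (size 2) with single-point crossover and per-gene
    mutation to a random unused bin; one elite chromosome survives each
    generation. A search stops when its best fitness reaches
    ``fitness_goal`` or after ``max_generations``.
    """
    Xa = _as_array(X)
    n, p = Xa.shape
    if p < params.chromosome_length:
        raise ValueError("fewer bins than chromosome_length")
    coded, _ = encode_labels(y)
    y01 = (coded > 0).astype(np.int64)

    master = np.random.default_rng(params.seed)
    search_seeds = master.integers(0, 2**31 - 1, size=params.n_searches)
    solutions: list[tuple[tuple[int, ...], float]] = []
    for s_seed in search_seeds:
        rng = np.random.default_rng(int(s_seed))
        folds = stratified_folds(y01, params.kfold, int(rng.integers(2**31 - 1)))
        cache: dict[tuple[int, ...], float] = {}

        def score(chrom: tuple[int, ...]) -> float:
            if chrom not in cache:
                pred = _predict_folds(Xa[:, list(chrom)], y01, folds,
                                      params.classifier)
                cache[chrom] = float(np.mean(pred == y01))
            return cache[chrom]

        population = [_random_chromosome(rng, p, params.chromosome_length)
                      for _ in range(params.population_size)]
        best_chrom, best_fit = None, -1.0
        for _ in range(params.max_generations):
            fits = [score(c) for c in population]
            gen_best = int(np.argmax(fits))
            if fits[gen_best] > best_fit:
                best_chrom, best_fit = population[gen_best], fits[gen_best]
            if best_fit >= params.fitness_goal:
                break
            nxt = [best_chrom]
            while len(nxt) < params.population_size:
                i, j = rng.integers(params.population_size, size=2)
                pa = population[i] if fits[i] >= fits[j] else population[j]
                i, j = rng.integers(params.population_size, size=2)
                pb = population[i] if fits[i] >= fits[j] else population[j]
                child = _crossover(rng, pa, pb)
                child = _mutate(rng, child, p, params.mutation_rate)
                nxt.append(child)
            population = nxt
        solutions.append((best_chrom, best_fit))

    freq: dict[int, int] = {}
    for chrom, _ in solutions:
        for b in chrom:
            freq[b] = freq.get(b, 0) + 1
    centers = X.bin_centers if hasattr(X, "bin_centers") else None
    return GaRun(solutions, freq, params, centers)


def rank_bins(run: GaRun, n_top: int = 20) -> pd.DataFrame:
    """Bins ranked by selection frequency across the searches' solutions.

    Ties break by the mean fitness of the solutions containing the bin,
    then by bin index.
    """
    if not run.solutions:
        raise ValueError("GA run has no solutions")
    fit_sum: dict[int, float] = {}
    for chrom, f in run.solutions:
        for b in chrom:
            fit_sum[b] = fit_sum.get(b, 0.0) + f
    rows = []
    for b, count in run.bin_frequency.items():
        rows.append((b, count, fit_sum[b] / count))
    rows.sort(key=lambda r: (-r[1], -r[2], r[0]))
    if n_top > len(rows):
        warnings.warn(
            f"n_top={n_top} exceeds the {len(rows)} distinct selected bins; "
            "returning all", stacklevel=2,
        )
    rows = rows[:n_top]
    idx = np.array([r[0] for r in rows], dtype=int)
    centers = (run.bin_centers[idx] if run.bin_centers is not None
               else idx.astype(float))
    return pd.DataFrame(
        {
            "bin_index": idx,
            "bin_center": centers,
            "frequency": [r[1] for r in rows],
            "mean_fitness": [r[2] for r in rows],
        }
    )


def pca_of_selected(X, bins, n_components: int = 2
                    ) -> tuple[np.ndarray, np.ndarray]:
    """PCA scores and variance fractions of the centered selected columns."""
    Xa = _as_array(X)[:, list(bins)]
    if np.all(np.std(Xa, axis=0) < 1e-15):
        raise ValueError("selected columns are constant; PCA undefined")
    n_components = min(n_components, Xa.shape[0], Xa.shape[1])
    pca = PCA(n_components=n_components)
    scores = pca.fit_transform(Xa - Xa.mean(axis=0))
    return scores, pca.explained_variance_ratio_


def cross_validated_accuracy(
    X, y, bins, kfold: int = 5, n_repeats: int = 10, seed: int = 0,
    positive_class=None, classifier: str = "nearest_centroid",
) -> CvReport:
    """Repeated seeded K-fold nearest-centroid evaluation of a fixed bin set.

    Reports the mean sensitivity/specificity across repeats and the pooled
    confusion counts.
    """
    Xa = _as_array(X)[:, list(bins)]
    coded, positive_class = encode_labels(y, positive_class)
    y01 = (coded > 0).astype(np.int64)
    rng = np.random.default_rng(seed)
    tp = fp = tn = fn = 0
    sens, spec = [], []
    last_folds = None
    for _ in range(n_repeats):
        folds = stratified_folds(y01, kfold, int(rng.integers(2**31 - 1)))
        last_folds = folds
        pred = _predict_folds(Xa, y01, folds, classifier)
        t_p, f_p, t_n, f_n = _confusion(y01 == 1, pred == 1)
        tp, fp, tn, fn = tp + t_p, fp + f_p, tn + t_n, fn + f_n
        sens.append(t_p / (t_p + f_n) if t_p + f_n else np.nan)
        spec.append(t_n / (t_n + f_p) if t_n + f_p else np.nan)
    assignment = np.zeros(y01.size, dtype=int)
    for f, test in enumerate(last_folds):
        assignment[test] = f
    return CvReport(
        tp, fp, tn, fn, float(np.nanmean(sens)), float(np.nanmean(spec)),
        positive_class, assignment,
        params={"kfold": kfold, "n_repeats": n_repeats,
                "classifier": classifier, "scheme": "stratified_kfold"},
    )
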