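"""Relevant-feature selection for the texture descriptor tables.

Four selectors are provided, mirroring the classical feature-selection
toolbox used with co-occurrence descriptors:

* correlation-based feature selection (CFS) merit, searched by a genetic
  algorithm over feature subsets;
* consistency-based subset evaluation, searched the same way;
* information-gain and gain-ratio single-feature rankers over
  entropy/MDL-discretized features.

The final relevant set is the union of the best CFS subset, the best
consistency subset, and the ranker features scoring above 0.3 bits.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SelectionResult",
    "cfs_merit",
    "consistency_score",
    "genetic_search",
    "ranker_scores",
    "select_relevant",
    "mdl_discretize",
]


@dataclass
class SelectionResult:
    """Outcome of one selection method."""

    method: str
    selected: set[str]
    scores: dict[str, float]


def _as_matrix(data: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
    return data.loc[:, list(names)].to_numpy(dtype=float)


def _binary_labels(y: Sequence) -> np.ndarray:
    classes = sorted(set(y))
    if len(classes) > 2:
        raise ValueError("binary labels expected")
    lut = {c: i for i, c in enumerate(classes)}
    return np.array([lut[v] for v in y], dtype=float)


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    # zero-variance columns contribute zero correlation by convention
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def cfs_merit(subset: Sequence[str], data: pd.DataFrame, y: Sequence) -> float:
    """CFS subset merit ``k r_cf / sqrt(k + k (k-1) r_ff)``.

    ``r_cf`` is the mean absolute feature-class correlation (point-biserial
    against the binary label) and ``r_ff`` the mean absolute pairwise
    feature-feature Pearson correlation. High merit rewards subsets that
    track the class while being mutually non-redundant.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    X = _as_matrix(data, subset)
    yb = _binary_labels(y)
    k = len(subset)
    r_cf = float(np.mean([abs(_safe_corr(X[:, j], yb)) for j in range(k)]))
    if k == 1:
        return r_cf
    r_ff_vals = [
        abs(_safe_corr(X[:, i], X[:, j])) for i in range(k) for j in range(i + 1, k)
    ]
    r_ff = float(np.mean(r_ff_vals))
    return k * r_cf / math.sqrt(k + k * (k - 1) * r_ff)


def _equal_frequency_bins(x: np.ndarray, n_bins: int = 10) -> np.ndarray:
    edges = np.unique(np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1]))
    return np.searchsorted(edges, x, side="right")


def consistency_score(
    subset: Sequence[str], data: pd.DataFrame, y: Sequence, n_bins: int = 10
) -> float:
    """Consistency of the class given the (discretized) feature subset.

    Features are equal-frequency discretized into ``n_bins`` bins; the
    score is ``1 - sum_patterns (count - majority_count) / n`` -- the
    fraction of rows *not* in conflict with the majority class of their
    feature-value pattern. 1.0 means the subset determines the class.
    """
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    X = _as_matrix(data, subset)
    yb = _binary_labels(y).astype(int)
    n = len(yb)
    binned = np.column_stack([_equal_frequency_bins(X[:, j], n_bins) for j in range(X.shape[1])])
    patterns: dict[tuple, np.ndarray] = {}
    for row, lab in zip(map(tuple, binned), yb):
        patterns.setdefault(row, np.zeros(2, dtype=int))[lab] += 1
    inconsistency = sum(int(c.sum() - c.max()) for c in patterns.values())
    return 1.0 - inconsistency / n


def genetic_search(
    evaluator: Callable[[Sequence[str]], float],
    feature_names: Sequence[str],
    generations: int = 20,
    population: int = 20,
    crossover_prob: float = 0.6,
    mutation_prob: float = 0.033,
    elitism: int = 1,
    seed: int = 0,
) -> set[str]:
    """Generational GA over feature-subset bit masks.

    Fitness-proportionate selection, single-point crossover, per-bit
    mutation and one elite; the best subset ever seen is returned.
    ``generations = 0`` evaluates only the initial random population.
    Deterministic given the seed.
    """
    names = list(feature_names)
    n = len(names)
    if n == 0:
        raise ValueError("no features to search over")
    rng = np.random.default_rng(seed)

    def fitness(mask: np.ndarray) -> float:
        sel = [names[i] for i in range(n) if mask[i]]
        if not sel:
            return -np.inf
        return evaluator(sel)

    pop = rng.integers(0, 2, size=(population, n)).astype(bool)
    fits = np.array([fitness(m) for m in pop])
    best_mask = pop[int(np.argmax(fits))].copy()
    best_fit = float(np.max(fits))

    for _ in range(generations):
        # fitness-proportionate selection on shifted fitness
        finite = np.where(np.isfinite(fits), fits, np.nanmin(fits[np.isfinite(fits)]) if np.isfinite(fits).any() else 0.0)
        shifted = finite - finite.min() + 1e-12
        probs = shifted / shifted.sum()
        order = np.argsort(-fits, kind="stable")
        next_pop = [pop[i].copy() for i in order[:elitism]]
        while len(next_pop) < population:
            i, j = rng.choice(population, size=2, p=probs)
            a, b = pop[i].copy(), pop[j].copy()
            if rng.random() < crossover_prob and n > 1:
                point = int(rng.integers(1, n))
                a[point:], b[point:] = b[point:].copy(), a[point:].copy()
            for child in (a, b):
                flips = rng.random(n) < mutation_prob
                child[flips] = ~child[flips]
                if len(next_pop) < population:
                    next_pop.append(child)
        pop = np.array(next_pop)
        fits = np.array([fitness(m) for m in pop])
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_mask = pop[gen_best].copy()

    return {names[i] for i in range(n) if best_mask[i]}


# ---------------------------------------------------------------------------
# entropy rankers


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-np.sum(p * np.log2(p)))


def _class_entropy(y: np.ndarray) -> float:
    return _entropy(np.bincount(y))


def mdl_discretize(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Entropy-based discretization with the MDL stopping criterion.

    Recursively picks the boundary minimizing the class-conditional entropy
    and keeps it only if the information gain beats the minimum description
    length cost (the Fayyad-Irani criterion). Returns integer bin ids; a
    feature that never splits gets a single bin.
    """
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    cut_points: list[float] = []

    def recurse(lo: int, hi: int) -> None:
        n = hi - lo
        if n < 2:
            return
        seg_x, seg_y = xs[lo:hi], ys[lo:hi]
        ent_full = _class_entropy(seg_y)
        # candidate boundaries: midpoints between adjacent distinct values
        distinct = np.nonzero(np.diff(seg_x) > 0)[0]
        if distinct.size == 0:
            return
        best = None
        for idx in distinct:
            left, right = seg_y[: idx + 1], seg_y[idx + 1 :]
            ent = (len(left) * _class_entropy(left) + len(right) * _class_entropy(right)) / n
            if best is None or ent < best[0]:
                best = (ent, idx)
        ent_split, idx = best
        gain = ent_full - ent_split
        left, right = seg_y[: idx + 1], seg_y[idx + 1 :]
        k = len(np.unique(seg_y))
        k1, k2 = len(np.unique(left)), len(np.unique(right))
        delta = math.log2(3.0**k - 2.0) - (
            k * ent_full - k1 * _class_entropy(left) - k2 * _class_entropy(right)
        )
        threshold = (math.log2(n - 1) + delta) / n
        if gain <= threshold:
            return
        cut = (seg_x[idx] + seg_x[idx + 1]) / 2.0
        cut_points.append(cut)
        recurse(lo, lo + idx + 1)
        recurse(lo + idx + 1, hi)

    recurse(0, len(xs))
    return np.searchsorted(sorted(cut_points), x, side="right")


def ranker_scores(
    data: pd.DataFrame, y: Sequence, criterion: str = "information_gain"
) -> dict[str, float]:
    """Per-feature information gain or gain ratio (bits), sorted descending.

    Continuous features are MDL-discretized against the binary label first.
    ``IG(f) = H(class) - H(class | f)``; ``GR(f) = IG(f) / H(f)`` with 0
    when ``H(f) = 0``. Single-class data scores 0 everywhere.
    """
    if criterion not in ("information_gain", "gain_ratio"):
        raise ValueError(f"unknown criterion: {criterion}")
    yb = _binary_labels(y).astype(int)
    h_class = _class_entropy(yb)
    scores: dict[str, float] = {}
    for name in data.columns:
        if h_class == 0.0:
            scores[name] = 0.0
            continue
        bins = mdl_discretize(data[name].to_numpy(dtype=float), yb)
        n = len(bins)
        cond = 0.0
        for v in np.unique(bins):
            sel = yb[bins == v]
            cond += len(sel) / n * _class_entropy(sel)
        ig = h_class - cond
        if criterion == "information_gain":
            scores[name] = ig
        else:
            h_f = _entropy(np.bincount(bins))
            scores[name] = ig / h_f if h_f > 0 else 0.0
    return dict(sorted(scores.items(), key=lambda kv: -kv[1]))


def select_relevant(
    data: pd.DataFrame,
    y: Sequence,
    score_threshold: float = 0.3,
    generations: int = 20,
    seed: int = 0,
) -> SelectionResult:
    """Union of the relevant features found by all four selectors.

    The CFS-GA and consistency-GA contribute their best subsets wholly; the
    information-gain and gain-ratio rankers contribute every feature
    scoring above ``score_threshold``. If the union comes out empty
    (degenerate data) all features are kept, with a warning.
    """
    if len(set(y)) < 2:
        raise ValueError("need at least two classes")
    # canonical name order so the result is invariant to column order
    names = sorted(data.columns)

    cfs_best = genetic_search(
        lambda s: cfs_merit(s, data, y), names, generations=generations, seed=seed
    )
    cons_best = genetic_search(
        lambda s: consistency_score(s, data, y), names, generations=generations, seed=seed + 1
    )
    ig = ranker_scores(data, y, "information_gain")
    gr = ranker_scores(data, y, "gain_ratio")
    ig_sel = {f for f, s in ig.items() if s > score_threshold}
    gr_sel = {f for f, s in gr.items() if s > score_threshold}

    union = cfs_best | cons_best | ig_sel | gr_sel
    if not union:
        warnings.warn("no selector retained any feature; keeping all features")
        union = set(names)
    return SelectionResult(method="union", selected=union, scores=ig)
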