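"""Training/target subsample construction and the swap-resampling series.

The far end of the decay curve is a pair of minimally related subsamples
obtained by 2-means clustering of the standardized genotypes (Euclidean
distance on standardized counts is monotone in kinship, so the clusters are
maximally differentiated).  Pairs at intermediate genetic distance are then
produced by swapping m randomly chosen individuals between the two sides:
the larger m, the more mixed, and the smaller the between-subsample F_ST.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .exceptions import DegenerateSplitError, ValidationError
from .fst import fst_beta_binomial
from .genotype_io import GenotypeMatrix, StandardizedMatrix


@dataclass
class SubsetPair:
    """A disjoint training/target partition, with swap count and seed."""

    train_idx: np.ndarray
    target_idx: np.ndarray
    m: int = 0
    seed: int = 0

    def __post_init__(self):
        self.train_idx = np.asarray(self.train_idx, dtype=int)
        self.target_idx = np.asarray(self.target_idx, dtype=int)
        if np.intersect1d(self.train_idx, self.target_idx).size:
            raise ValidationError("training and target sets overlap")
        if self.m < 0:
            raise ValidationError("swap count m must be >= 0")

    @property
    def n_train(self) -> int:
        return self.train_idx.size

    @property
    def n_target(self) -> int:
        return self.target_idx.size


@dataclass
class SwapSeries:
    """All subsample pairs of a swap schedule, plus their F_ST estimates."""

    pairs: list
    schedule: list
    reps_per_m: int
    fst_values: list  # parallel to pairs
    mean_fst_by_m: dict


def split_minimally_related(
    x: StandardizedMatrix, seed: int, restarts: int = 25
) -> SubsetPair:
    """k-means (k=2) split into maximally differentiated subsamples.

    Best of ``restarts`` seeded initializations by within-cluster sum of
    squares.  The larger cluster becomes the training subsample; on a tie the
    cluster containing the lowest sample index does.
    """
    if x.n_samples < 4:
        raise ValidationError("need >= 4 samples to split")
    km = KMeans(n_clusters=2, n_init=restarts, random_state=seed)
    labels = km.fit_predict(x.values)
    idx0 = np.flatnonzero(labels == 0)
    idx1 = np.flatnonzero(labels == 1)
    if idx0.size == 0 or idx1.size == 0:
        raise DegenerateSplitError("k-means produced an empty cluster")
    if idx0.size > idx1.size:
        train, target = idx0, idx1
    elif idx1.size > idx0.size:
        train, target = idx1, idx0
    else:  # tie: training is the cluster holding the lowest sample index
        train, target = (idx0, idx1) if 0 in idx0 else (idx1, idx0)
    return SubsetPair(train_idx=train, target_idx=target, m=0, seed=seed)


def rebalance(
    pair: SubsetPair, g: GenotypeMatrix, n_target_required: int
) -> SubsetPair:
    """Shrink the target subsample to ``n_target_required`` members.

    Greedy: each step moves to the training side the target individual whose
    transfer leaves the largest Beta-Binomial F_ST between the sides, so the
    pair stays as differentiated as possible while the training side grows.
    Deterministic (ties broken by lowest index).
    """
    if n_target_required > pair.n_target:
        raise ValidationError("n_target_required exceeds current target size")
    if n_target_required < 10:
        warnings.warn(
            "target subsample below 10 individuals: predictive-correlation "
            "estimates will be noisy",
            stacklevel=2,
        )
    train = pair.train_idx.copy()
    target = pair.target_idx.copy()
    while target.size > n_target_required:
        best_fst, best_j = -np.inf, None
        for j in range(target.size):
            cand_train = np.append(train, target[j])
            cand_target = np.delete(target, j)
            est = fst_beta_binomial(g, cand_train, cand_target)
            if est.value > best_fst + 1e-15:
                best_fst, best_j = est.value, j
        train = np.append(train, target[best_j])
        target = np.delete(target, best_j)
    return SubsetPair(train_idx=np.sort(train), target_idx=np.sort(target),
                      m=pair.m, seed=pair.seed)


def swap(pair: SubsetPair, m: int, seed: int) -> SubsetPair:
    """Exchange m uniformly chosen individuals between the two sides."""
    if m > min(pair.n_train, pair.n_target):
        raise ValidationError("m exceeds the smaller subsample size")
    if m == 0:
        return SubsetPair(
            train_idx=pair.train_idx.copy(),
            target_idx=pair.target_idx.copy(),
            m=0,
            seed=seed,
        )
    rng = np.random.default_rng(seed)
    out_train = rng.choice(pair.n_train, size=m, replace=False)
    out_target = rng.choice(pair.n_target, size=m, replace=False)
    train_mask = np.ones(pair.n_train, dtype=bool)
    train_mask[out_train] = False
    target_mask = np.ones(pair.n_target, dtype=bool)
    target_mask[out_target] = False
    new_train = np.sort(
        np.concatenate([pair.train_idx[train_mask], pair.target_idx[out_target]])
    )
    new_target = np.sort(
        np.concatenate([pair.target_idx[target_mask], pair.train_idx[out_train]])
    )
    return SubsetPair(train_idx=new_train, target_idx=new_target, m=m, seed=seed)


def auto_step(n_min: int, max_points: int = 30) -> int:
    """Smallest step in [2, 20] giving at most ``max_points`` schedule points."""
    for step in range(2, 21):
        if n_min // step <= max_points:
            return step
    return 20


def generate_swap_series(
    x: StandardizedMatrix,
    g: GenotypeMatrix,
    pair0: SubsetPair,
    step: int | None = None,
    reps_per_m: int = 40,
    fst_stop: float = 0.005,
    seed: int = 0,
) -> SwapSeries:
    """Swap-resampling series m = 0, step, 2*step, ... with F_ST per pair.

    For each m > 0, ``reps_per_m`` independent swapped pairs are generated
    and their Beta-Binomial F_ST estimated; the schedule stops after the
    first m whose mean F_ST drops to ``fst_stop`` or below.  m = 0 (the
    clustering split itself) appears once.  Mixing is maximal at
    m = min(n_TR, n_TA)/2 -- swapping m and n-m individuals produce
    mirror-image mixtures -- so the schedule never steps beyond that point;
    if the stopping threshold is still unmet there, the series ends with a
    warning (the threshold needs n_TR large enough that the ~1/(2 n_TR)
    plug-in bias of the estimator sits below it).
    """
    n_min = min(pair0.n_train, pair0.n_target) // 2
    if step is None:
        step = auto_step(n_min)
    if not (2 <= step <= 20):
        raise ValidationError("step must lie in [2, 20]")
    fst0 = fst_beta_binomial(g, pair0.train_idx, pair0.target_idx).value
    pairs = [SubsetPair(pair0.train_idx.copy(), pair0.target_idx.copy(), 0, seed)]
    fst_values = [fst0]
    schedule = [0]
    mean_by_m = {0: fst0}
    if fst0 <= fst_stop:
        return SwapSeries(pairs, schedule, reps_per_m, fst_values, mean_by_m)
    ss = np.random.SeedSequence(seed)
    m = step
    reached = False
    while m <= n_min:
        sub_seeds = ss.spawn(1)[0].generate_state(reps_per_m) % (2**31 - 1)
        block = []
        for r in range(reps_per_m):
            p = swap(pair0, m, int(sub_seeds[r]))
            est = fst_beta_binomial(g, p.train_idx, p.target_idx)
            pairs.append(p)
            fst_values.append(est.value)
            block.append(est.value)
        schedule.append(m)
        mean_by_m[m] = float(np.mean(block))
        if mean_by_m[m] <= fst_stop:
            reached = True
            break
        m += step
    if not reached:
        warnings.warn(
            f"swap schedule exhausted at m = {schedule[-1]} with mean F_ST "
            f"{mean_by_m[schedule[-1]]:.4f} > {fst_stop}",
            stacklevel=2,
        )
    return SwapSeries(pairs, schedule, reps_per_m, fst_values, mean_by_m)


def write_pair_csv(pair: SubsetPair, g: GenotypeMatrix, path) -> None:
    """Two-column CSV (id, role) for a subsample pair."""
    with open(path, "w") as fh:
        fh.write("id,role\n")
        for i in pair.train_idx:
            fh.write(f"{g.sample_ids[i]},train\n")
        for i in pair.target_idx:
            fh.write(f"{g.sample_ids[i]},target\n")
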