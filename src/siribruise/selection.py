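"""Random-frog feature selection scored by cross-validated PLS-DA.

The random-frog search is an MCMC-like walk over feature subsets: from
the current subset a candidate of normally perturbed size is proposed by
adding or removing features (alternating coefficient-guided and uniform
random moves), scored by stratified k-fold cross-validated PLS-DA error,
and accepted either outright (score no worse than one cross-validated
sample) or with probability ``eta * err_current / err_candidate``.
A feature's selection probability is the fraction of iterations whose
accepted subset contains it.

Because the selected subset depends on how the data are split, the walk
is repeated over (by default) 30 stratified 7:3 partitions of the data;
each partition's top-10 features earn one count, and the final subset is
the ten features with the highest counts.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .classify import _pls1_coefs, _pls1_components

__all__ = [
    "FrogConfig",
    "SelectionTally",
    "plsda_cv_error",
    "random_frog",
    "tally_over_partitions",
]


@dataclass(frozen=True)
class FrogConfig:
    """Random-frog tuning knobs; defaults follow the original algorithm's range."""

    n_iterations: int = 1000
    init_subset_size: int = 10
    perturb_factor: float = 0.3
    accept_factor: float = 0.1
    cv_folds: int = 5
    rng_seed: int = 0
    max_lv: int = 10
    #: "guided" ranks candidate features by |PLS coefficient| when growing or
    #: shrinking a subset (the original algorithm's proposal); "uniform"
    #: adds/removes uniformly at random.
    proposal: str = "guided"

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.init_subset_size < 1:
            raise ValueError("init_subset_size must be >= 1")
        if self.perturb_factor <= 0:
            raise ValueError("perturb_factor must be > 0")
        if not (0 < self.accept_factor <= 1):
            raise ValueError("accept_factor must lie in (0, 1]")


@dataclass
class SelectionTally:
    """Per-feature selection counts over partitions and the top-k subset."""

    feature_names: list[str]
    counts: np.ndarray
    mean_probabilities: np.ndarray
    top_subset: list[str]
    n_partitions: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.feature_names,
                "count": self.counts,
                "mean_probability": self.mean_probabilities,
                "selected": [f in self.top_subset for f in self.feature_names],
            }
        )


def plsda_cv_error(
    x: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    seed: int = 0,
    max_lv: int = 10,
) -> float:
    """Stratified k-fold misclassification rate of PLS-DA on a feature subset.

    The latent-variable count is fixed per subset by the same
    cross-validation: predictions are computed for every component count up
    to ``min(max_lv, n_features)`` in one pass per fold and the best CV
    error over component counts is returned.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 2 or x.shape[1] < 1:
        raise ValueError("feature subset must be nonempty")
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    max_lv = min(max_lv, x.shape[1])
    folds = max(2, min(folds, int(np.bincount(y.astype(int)).min())))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    errors = np.zeros(max_lv)
    total = 0
    for tr, te in skf.split(x, y):
        xm = x[tr].mean(axis=0)
        ym = y[tr].mean()
        w, p, q = _pls1_components(x[tr] - xm, y[tr] - ym, max_lv)
        avail = q.size
        total += len(te)
        for lv in range(1, max_lv + 1):
            k = min(lv, avail)
            if k == 0:
                pred = np.full(len(te), ym)
            else:
                coefs = _pls1_coefs(w, p, q, k)
                pred = (x[te] - xm) @ coefs + ym
            errors[lv - 1] += ((pred > 0.5) != (y[te] > 0.5)).sum()
    return float(errors.min() / total)


def random_frog(x: np.ndarray, y: np.ndarray, config: FrogConfig) -> np.ndarray:
    """Per-feature selection probabilities from one random-frog run.

    Starts from a random subset of ``init_subset_size`` features; each
    iteration draws a candidate size ``round(N(Q, max(1, theta*Q)))``
    (clipped to [1, n_features]) and mutates the current subset toward it,
    alternating coefficient-guided and uniform random adds/removals.
    Candidates whose CV error is lower, equal, or worse by at most one
    cross-validated sample are accepted outright; other candidates with
    probability ``eta * err_cur / err_cand`` (capped at 1; ratio defined
    as 1 when the candidate error is 0).  The probability of feature j is
    the fraction of iterations whose post-decision subset contains j.
    Fully reproducible from ``config.rng_seed``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n_feat = x.shape[1]
    if n_feat < 2:
        raise ValueError("need at least 2 features")
    q0 = min(config.init_subset_size, n_feat)
    rng = np.random.default_rng(config.rng_seed)
    cache: dict[tuple, float] = {}

    def score(subset: np.ndarray) -> float:
        key = tuple(subset)
        if key not in cache:
            cache[key] = plsda_cv_error(
                x[:, subset],
                y,
                folds=config.cv_folds,
                seed=config.rng_seed,
                max_lv=config.max_lv,
            )
        return cache[key]

    def rank_by_coefficient(subset: np.ndarray, keep: int) -> np.ndarray:
        """The ``keep`` features of ``subset`` with largest |PLS coefficient|."""
        xs = x[:, subset]
        w, p, q_load = _pls1_components(
            xs - xs.mean(axis=0), y - y.mean(), min(config.max_lv, len(subset))
        )
        if q_load.size == 0:
            return subset[:keep]
        coefs = np.abs(_pls1_coefs(w, p, q_load, q_load.size))
        order = np.lexsort((subset, -coefs))
        return subset[order[:keep]]

    current = np.sort(rng.choice(n_feat, size=q0, replace=False))
    err_cur = score(current)
    hits = np.zeros(n_feat)
    for _ in range(config.n_iterations):
        q = len(current)
        # std floored at one feature: theta*Q alone freezes the walk once the
        # subset shrinks to a couple of members
        scale = max(1.0, config.perturb_factor * q)
        q_star = int(np.clip(round(rng.normal(q, scale)), 1, n_feat))
        # guided moves alternate with uniform ones: coefficient ranking finds
        # informative features quickly, while uniform churn keeps the walk
        # from locking onto whichever spurious features it met first
        guided = config.proposal == "guided" and rng.random() < 0.5
        if q_star < q:
            if guided:
                candidate = np.sort(rank_by_coefficient(current, q_star))
            else:
                candidate = np.sort(rng.choice(current, size=q_star, replace=False))
        elif q_star > q:
            pool = np.setdiff1d(np.arange(n_feat), current)
            n_extra = q_star - q
            if guided:
                # over-draw candidates, then keep the best q_star by coefficient
                drawn = rng.choice(pool, size=min(3 * n_extra, len(pool)), replace=False)
                union = np.concatenate([current, drawn])
                candidate = np.sort(rank_by_coefficient(union, q_star))
            else:
                extra = rng.choice(pool, size=n_extra, replace=False)
                candidate = np.sort(np.concatenate([current, extra]))
        else:
            candidate = current
        err_cand = score(candidate)
        # near-ties (within one cross-validated sample) accepted outright: on
        # an error plateau this lets spurious features churn while features
        # whose removal genuinely costs accuracy persist in every subset
        if err_cand <= err_cur + 1.0 / len(y) + 1e-12:
            accept = True
        else:
            ratio = 1.0 if err_cand == 0 else err_cur / err_cand
            accept = rng.random() < min(1.0, config.accept_factor * ratio)
        if accept:
            current, err_cur = candidate, err_cand
        hits[current] += 1.0
    return hits / config.n_iterations


def _top_k(probs: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k largest values; ties resolve to lower feature index."""
    order = np.lexsort((np.arange(len(probs)), -probs))
    return order[:k]


def tally_over_partitions(
    x: np.ndarray,
    y: np.ndarray,
    feature_names,
    n_partitions: int = 30,
    split_ratio: float = 0.7,
    subset_size: int = 10,
    config: FrogConfig = FrogConfig(),
) -> SelectionTally:
    """Count top-k memberships of random-frog runs over repeated partitions.

    For each stratified ``split_ratio`` partition the frog runs on the
    training portion and its top-``subset_size`` features (by selection
    probability) earn one count.  The final subset is the ``subset_size``
    features with the highest counts, ties broken by higher mean selection
    probability and then by fixed feature order.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    feature_names = list(feature_names)
    if len(feature_names) != x.shape[1]:
        raise ValueError("feature_names length must match the feature count")
    if n_partitions < 1:
        raise ValueError("n_partitions must be >= 1")
    n_feat = x.shape[1]
    counts = np.zeros(n_feat)
    prob_sum = np.zeros(n_feat)
    sss = StratifiedShuffleSplit(
        n_splits=n_partitions, train_size=split_ratio, random_state=config.rng_seed
    )
    for part, (tr, _) in enumerate(sss.split(x, y)):
        run_cfg = replace(config, rng_seed=(config.rng_seed + 7919 * (part + 1)) % 2**31)
        probs = random_frog(x[tr], y[tr], run_cfg)
        counts[_top_k(probs, subset_size)] += 1.0
        prob_sum += probs
    mean_probs = prob_sum / n_partitions
    order = np.lexsort((np.arange(n_feat), -mean_probs, -counts))
    top = order[:subset_size]
    return SelectionTally(
        feature_names=feature_names,
        counts=counts.astype(int),
        mean_probabilities=mean_probs,
        top_subset=[feature_names[i] for i in top],
        n_partitions=n_partitions,
    )
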