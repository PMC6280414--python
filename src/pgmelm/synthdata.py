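"""Seeded generator of small, imbalanced, biomedical-like feature tables.

Emulates the regime of typical CAD benchmark tables: tens to a few hundred
samples, 8-30 real-valued features of which only some are informative,
correlated feature blocks, and a minority:majority ratio between roughly
0.1 and 0.6.  Two Gaussian classes are separated along the informative
axes; redundant features are noisy linear mixes of informative ones (so a
PCA front end has structure to find) and noise features are pure N(0,1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Dataset


@dataclass
class SynthSpec:
    """Recipe for one synthetic imbalanced table.

    ``class_separation`` is the Euclidean distance between the two class
    means in the informative subspace (identity-variance classes, so a
    separation of ~3 is comfortably learnable and 0 is indistinguishable).
    ``correlation`` in [0, 1) is the pairwise correlation of informative
    features within a class.
    """

    n_min: int = 40
    n_maj: int = 160
    n_informative: int = 6
    n_redundant: int = 3
    n_noise: int = 1
    class_separation: float = 3.0
    correlation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_min > self.n_maj:
            raise ValueError("n_min must be <= n_maj (minority is rarer)")
        if min(self.n_min, self.n_maj) < 1:
            raise ValueError("class counts must be >= 1")
        if self.n_informative < 1:
            raise ValueError("need >= 1 informative feature")
        if min(self.n_redundant, self.n_noise) < 0:
            raise ValueError("feature counts must be >= 0")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must be in [0, 1)")
        if self.class_separation < 0:
            raise ValueError("class_separation must be >= 0")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


def make_imbalanced(spec: SynthSpec) -> Dataset:
    """Draw one table per the spec; same seed gives identical matrices."""
    rng = np.random.default_rng(spec.seed)
    d = spec.n_informative
    # equicorrelated within-class covariance for the informative block
    cov = np.full((d, d), spec.correlation)
    np.fill_diagonal(cov, 1.0)
    L = np.linalg.cholesky(cov)
    shift = spec.class_separation / np.sqrt(d)

    def draw(n, mean):
        return rng.standard_normal((n, d)) @ L.T + mean

    X_maj = draw(spec.n_maj, 0.0)
    X_min = draw(spec.n_min, shift)
    X_inf = np.vstack([X_maj, X_min])
    blocks = [X_inf]
    if spec.n_redundant:
        mix = rng.standard_normal((d, spec.n_redundant))
        mix /= np.linalg.norm(mix, axis=0)
        blocks.append(X_inf @ mix
                      + 0.1 * rng.standard_normal((X_inf.shape[0], spec.n_redundant)))
    if spec.n_noise:
        blocks.append(rng.standard_normal((X_inf.shape[0], spec.n_noise)))
    X = np.hstack(blocks)
    y = np.concatenate([np.zeros(spec.n_maj, int), np.ones(spec.n_min, int)])
    perm = rng.permutation(len(y))
    names = ([f"inf{i + 1}" for i in range(d)]
             + [f"red{i + 1}" for i in range(spec.n_redundant)]
             + [f"noise{i + 1}" for i in range(spec.n_noise)])
    return Dataset(X[perm], y[perm], names)


def split(ds: Dataset, n_train: int, seed: int = 0,
          stratified: bool = True) -> tuple[Dataset, Dataset]:
    """Random disjoint train/test partition (stratified by default).

    Stratified mode keeps the training class ratio within one sample of the
    full-table ratio; both splits must contain both classes.
    """
    if not 0 < n_train < ds.n:
        raise ValueError(f"n_train must be in (0, {ds.n}), got {n_train}")
    rng = np.random.default_rng(seed)
    if stratified:
        idx_train = []
        for cls in (0, 1):
            cls_idx = np.flatnonzero(ds.y == cls)
            take = int(round(n_train * len(cls_idx) / ds.n))
            take = min(max(take, 1), len(cls_idx) - 1)
            idx_train.append(rng.permutation(cls_idx)[:take])
        train_idx = np.concatenate(idx_train)
        # adjust to the exact requested size, preserving both classes
        while len(train_idx) > n_train:
            counts = np.bincount(ds.y[train_idx], minlength=2)
            drop_cls = int(np.argmax(counts))
            pos = np.flatnonzero(ds.y[train_idx] == drop_cls)
            train_idx = np.delete(train_idx, pos[-1])
        while len(train_idx) < n_train:
            pool = np.setdiff1d(np.arange(ds.n), train_idx)
            extra = pool[rng.integers(len(pool))]
            train_idx = np.append(train_idx, extra)
    else:
        train_idx = rng.permutation(ds.n)[:n_train]
    train_mask = np.zeros(ds.n, bool)
    train_mask[train_idx] = True
    if stratified:
        for part, name in ((train_mask, "train"), (~train_mask, "test")):
            if len(np.unique(ds.y[part])) < 2:
                raise ValueError(f"{name} split would be single-class")
    train = Dataset(ds.X[train_mask], ds.y[train_mask], ds.feature_names)
    test = Dataset(ds.X[~train_mask], ds.y[~train_mask], ds.feature_names)
    return train, test
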