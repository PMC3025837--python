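"""C-SVC training, hyperparameter grids and nested cross-validated selection.

Model selection searches jointly over the feature-block combination (15
non-empty subsets of the four encoders), the kernel (linear, Gaussian,
polynomial) and its parameters, and the soft-margin cost C.  Selection by
plain cross-validation is optimistically biased because the CV error is
itself minimised; nested k-fold CV separates the two concerns: an inner loop
picks hyperparameters by stratified CV accuracy on each outer-training
portion, the outer held-out folds estimate generalisation error, and their
mean is the reported estimate.  The deployable model is then chosen by one
final grid search on all data.

The quadratic-programming SVM solver is scikit-learn's ``SVC`` (libsvm);
everything around it — the grid, the joint mask/kernel search, the nested
protocol, tie-breaking — lives here.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .encoders import (
    CANONICAL_FEATURES,
    FEATURE_DIMS,
    FeatureVector,
    encode_record,
)
from .sequences import PSSMProfile, SequenceRecord

KERNELS = ("linear", "gaussian", "polynomial")
# tie-break order: simpler kernels preferred
_KERNEL_RANK = {"linear": 0, "gaussian": 1, "polynomial": 2}
_SKLEARN_KERNEL = {"linear": "linear", "gaussian": "rbf", "polynomial": "poly"}

#: Default grids (powers of two, the usual coarse SVM search).
DEFAULT_C_GRID = tuple(2.0 ** e for e in range(-5, 16, 2))        # 11 values
DEFAULT_GAMMA_GRID = tuple(2.0 ** e for e in range(-15, 4, 2))    # 10 values
DEFAULT_DEGREE_GRID = (2, 3, 4, 5)


@dataclass(frozen=True)
class HyperParams:
    """One grid point: kernel, its parameters, cost, and feature-block mask.

    Kernel-irrelevant parameters must be ``None``: a linear kernel carries
    only C; gamma applies to gaussian and polynomial; degree and coef0 to
    polynomial only.
    """

    kernel: str
    C: float
    feature_mask: frozenset[str]
    gamma: float | None = None
    degree: int | None = None
    coef0: float = 0.0

    def __post_init__(self) -> None:
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.C <= 0:
            raise ValueError("C must be positive")
        mask = frozenset(self.feature_mask)
        if not mask or not mask <= set(CANONICAL_FEATURES):
            raise ValueError(f"invalid feature mask {sorted(self.feature_mask)}")
        object.__setattr__(self, "feature_mask", mask)
        if self.kernel == "linear" and (self.gamma is not None or self.degree is not None):
            raise ValueError("linear kernel takes only C")
        if self.kernel == "gaussian":
            if self.gamma is None or self.gamma <= 0:
                raise ValueError("gaussian kernel needs gamma > 0")
            if self.degree is not None:
                raise ValueError("gaussian kernel takes no degree")
        if self.kernel == "polynomial":
            if self.gamma is None or self.gamma <= 0:
                raise ValueError("polynomial kernel needs gamma > 0")
            if self.degree is None or self.degree < 1:
                raise ValueError("polynomial kernel needs degree >= 1")

    def sort_key(self) -> tuple:
        """Deterministic preference order for accuracy ties.

        Lower C first, then simpler kernel (linear < gaussian < polynomial),
        then smaller feature mask; remaining fields only stabilise ordering.
        """
        return (
            self.C,
            _KERNEL_RANK[self.kernel],
            len(self.feature_mask),
            tuple(sorted(self.feature_mask)),
            self.gamma if self.gamma is not None else -1.0,
            self.degree if self.degree is not None else -1,
        )

    def to_dict(self) -> dict:
        d = {
            "kernel": self.kernel,
            "C": self.C,
            "feature_mask": sorted(self.feature_mask),
        }
        if self.gamma is not None:
            d["gamma"] = self.gamma
        if self.degree is not None:
            d["degree"] = self.degree
            d["coef0"] = self.coef0
        return d

    def make_svc(self) -> SVC:
        kwargs: dict = {"kernel": _SKLEARN_KERNEL[self.kernel], "C": self.C}
        if self.gamma is not None:
            kwargs["gamma"] = self.gamma
        if self.degree is not None:
            kwargs["degree"] = self.degree
            kwargs["coef0"] = self.coef0
        return SVC(**kwargs)


def all_feature_masks(
    features: Sequence[str] = CANONICAL_FEATURES,
) -> list[frozenset[str]]:
    """The 2^m - 1 non-empty subsets of the available blocks (15 for all four)."""
    masks = []
    for r in range(1, len(features) + 1):
        for combo in itertools.combinations(features, r):
            masks.append(frozenset(combo))
    return masks


def default_grid(
    masks: Iterable[frozenset[str]] | None = None,
    kernels: Sequence[str] = KERNELS,
    C_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    degree_grid: Sequence[int] = DEFAULT_DEGREE_GRID,
) -> list[HyperParams]:
    """Cartesian hyperparameter grid over masks x kernels x parameters.

    With the defaults (15 masks; 11 C values; 10 gammas; 4 degrees) this is
    15 * (11 + 110 + 440) = 8 415 candidate models.
    """
    grid: list[HyperParams] = []
    mask_list = list(masks) if masks is not None else all_feature_masks()
    for mask in mask_list:
        for C in C_grid:
            if "linear" in kernels:
                grid.append(HyperParams("linear", C, mask))
            if "gaussian" in kernels:
                grid.extend(
                    HyperParams("gaussian", C, mask, gamma=g) for g in gamma_grid
                )
            if "polynomial" in kernels:
                grid.extend(
                    HyperParams("polynomial", C, mask, gamma=g, degree=d)
                    for g in gamma_grid
                    for d in degree_grid
                )
    return grid


@dataclass
class EncodedDataset:
    """Per-block feature matrices plus labels for a set of sequences.

    ``blocks`` maps encoder name to an (n, dim) matrix; ``y`` holds +1/-1
    labels.  Any feature mask can be materialised as a single design matrix
    with :meth:`matrix`, blocks concatenated in canonical order.
    """

    ids: list[str]
    y: np.ndarray
    blocks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=int)
        n = len(self.ids)
        if self.y.shape != (n,):
            raise ValueError("labels and ids disagree in length")
        if not set(np.unique(self.y)) <= {-1, 1}:
            raise ValueError("labels must be +1/-1")
        for name, mat in self.blocks.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (n, FEATURE_DIMS[name]):
                raise ValueError(
                    f"block {name!r}: expected {(n, FEATURE_DIMS[name])}, got {mat.shape}"
                )
            self.blocks[name] = mat

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(n for n in CANONICAL_FEATURES if n in self.blocks)

    def matrix(self, mask: Iterable[str]) -> np.ndarray:
        names = [n for n in CANONICAL_FEATURES if n in set(mask)]
        missing = set(mask) - set(self.blocks)
        if missing:
            raise ValueError(f"dataset lacks feature blocks {sorted(missing)}")
        return np.hstack([self.blocks[n] for n in names])

    def subset(self, indices: np.ndarray) -> "EncodedDataset":
        return EncodedDataset(
            ids=[self.ids[i] for i in indices],
            y=self.y[indices],
            blocks={k: v[indices] for k, v in self.blocks.items()},
        )

    @classmethod
    def from_records(
        cls,
        records: Sequence[SequenceRecord],
        labels: Sequence[int],
        profiles: Mapping[str, PSSMProfile] | None = None,
        features: Sequence[str] = ("frequencies", "dipeptides", "factors"),
    ) -> "EncodedDataset":
        """Encode records with the requested blocks (pssm needs ``profiles``)."""
        if len(records) != len(labels):
            raise ValueError("records and labels disagree in length")
        columns: dict[str, list[np.ndarray]] = {f: [] for f in features}
        for rec in records:
            profile = profiles.get(rec.id) if profiles else None
            encoded = encode_record(rec, features=features, profile=profile)
            for name in features:
                columns[name].append(encoded[name].values)
        return cls(
            ids=[r.id for r in records],
            y=np.asarray(labels, dtype=int),
            blocks={name: np.vstack(cols) for name, cols in columns.items()},
        )


def train_svm(X: np.ndarray, y: np.ndarray, params: HyperParams) -> SVC:
    """Fit a C-SVC at one grid point; deterministic for fixed input."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data contains a single class")
    expected = sum(FEATURE_DIMS[f] for f in params.feature_mask)
    if X.shape[1] != expected:
        raise ValueError(
            f"design matrix has {X.shape[1]} columns but mask "
            f"{sorted(params.feature_mask)} implies {expected}"
        )
    return params.make_svc().fit(X, y)


def predict(model: SVC, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Return (labels, decision scores); label = sign of the decision score."""
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        return np.empty(0, dtype=int), np.empty(0)
    if X.shape[1] != model.n_features_in_:
        raise ValueError(
            f"schema mismatch: model expects {model.n_features_in_} features, "
            f"got {X.shape[1]}"
        )
    scores = model.decision_function(X)
    labels = np.where(scores >= 0, 1, -1)
    return labels, scores


def _canonical_order(dataset: EncodedDataset) -> EncodedDataset:
    """Sort examples by id so fold assignment depends on the seed, not on the
    order records happened to arrive in."""
    order = np.array(sorted(range(len(dataset)), key=lambda i: dataset.ids[i]))
    return dataset.subset(order)


def _check_class_counts(y: np.ndarray, k: int) -> None:
    values, counts = np.unique(y, return_counts=True)
    if values.size < 2:
        raise ValueError("need both classes for stratified cross-validation")
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} examples, fewer than k={k} folds"
        )


def grid_search(
    dataset: EncodedDataset,
    grid: Sequence[HyperParams],
    k: int = 5,
    seed: int = 0,
) -> tuple[HyperParams, float]:
    """Pick the grid point with the highest stratified k-fold CV accuracy.

    All grid points are scored on the same fold assignment (derived from
    ``seed``).  Ties are broken by lower C, then simpler kernel
    (linear < gaussian < polynomial), then smaller feature mask.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not grid:
        raise ValueError("empty hyperparameter grid")
    _check_class_counts(dataset.y, k)
    dataset = _canonical_order(dataset)

    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    dummy = np.zeros(len(dataset))
    folds = list(splitter.split(dummy, dataset.y))

    matrices = {
        mask: dataset.matrix(mask)
        for mask in {p.feature_mask for p in grid}
    }
    best: tuple[float, tuple, HyperParams] | None = None
    for params in grid:
        X = matrices[params.feature_mask]
        correct = 0
        for train_idx, test_idx in folds:
            model = train_svm(X[train_idx], dataset.y[train_idx], params)
            labels, _ = predict(model, X[test_idx])
            correct += int(np.sum(labels == dataset.y[test_idx]))
        accuracy = correct / len(dataset)
        key = (-accuracy, params.sort_key())
        if best is None or key < (best[0], best[1]):
            best = (key[0], key[1], params)
    assert best is not None
    return best[2], -best[0]


def nested_cv_folds(
    dataset: EncodedDataset,
    grid: Sequence[HyperParams],
    k_outer: int = 5,
    k_inner: int = 5,
    seed: int = 0,
) -> list[dict]:
    """Run the outer loop of nested CV; one result dict per outer fold.

    Each dict carries the inner-loop winner (``params``), its inner CV
    accuracy, and the accuracy of that model retrained on the full
    outer-training portion and scored on the held-out fold.  Fold assignment
    depends only on ``seed`` and the label vector, not on input order beyond
    the stratified splitter's contract.
    """
    if k_outer < 2 or k_inner < 2:
        raise ValueError("k_outer and k_inner must be >= 2")
    _check_class_counts(dataset.y, k_outer)
    dataset = _canonical_order(dataset)
    splitter = StratifiedKFold(n_splits=k_outer, shuffle=True, random_state=seed)
    dummy = np.zeros(len(dataset))
    results = []
    for fold, (train_idx, test_idx) in enumerate(splitter.split(dummy, dataset.y)):
        train = dataset.subset(train_idx)
        inner_seed = seed * 131 + fold + 1  # one stream per fold, reproducible
        params, inner_acc = grid_search(train, grid, k=k_inner, seed=inner_seed)
        X_train = train.matrix(params.feature_mask)
        model = train_svm(X_train, train.y, params)
        test = dataset.subset(test_idx)
        labels, _ = predict(model, test.matrix(params.feature_mask))
        outer_acc = float(np.mean(labels == test.y))
        results.append(
            {
                "fold": fold,
                "params": params,
                "inner_accuracy": float(inner_acc),
                "outer_accuracy": outer_acc,
                "n_train": len(train),
                "n_test": len(test),
            }
        )
    return results
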