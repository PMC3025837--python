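"""Model/Results interface over nested-cross-validated SVM selection.

:class:`SecretionClassifier` is the model object: built from encoded
sequence data (or directly from records via :meth:`from_records`), it holds
the candidate hyperparameter grid and the CV geometry.  :meth:`fit` runs the
full nested protocol and returns a :class:`SelectionResults`, which carries
the per-outer-fold choices and accuracies, the generalisation-error
estimate, the final hyperparameters chosen on all data, and the deployable
fitted classifier; ``summary()`` renders the usual text table and
``predict``/``decision_scores``/``roc`` operate on new data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from . import selection as _sel
from .evaluation import RocCurve, confusion, metrics, roc
from .selection import EncodedDataset, HyperParams
from .sequences import PSSMProfile, SequenceRecord


class SecretionClassifier:
    """SVM secretion classifier selected by nested k-fold cross-validation.

    Parameters
    ----------
    dataset : EncodedDataset
        Encoded training sequences with +1 (secreted) / -1 (not) labels.
    grid : sequence of HyperParams, optional
        Candidate models.  Defaults to the full grid over every non-empty
        combination of the dataset's feature blocks, three kernels, and
        powers-of-two C/gamma ranges.
    k_outer, k_inner : int
        Fold counts of the outer (error-estimation) and inner (selection)
        loops; both default to 5.

    Examples
    --------
    >>> from secpred.simulate import FixtureSpec, generate
    >>> from secpred.selection import EncodedDataset
    >>> records, labels = generate(FixtureSpec(n_pos=20, n_neg=20, separation=0.3))
    >>> ds = EncodedDataset.from_records(records, labels, features=("frequencies",))
    >>> res = SecretionClassifier(ds).fit(seed=0)   # doctest: +SKIP
    """

    def __init__(
        self,
        dataset: EncodedDataset,
        grid: Sequence[HyperParams] | None = None,
        k_outer: int = 5,
        k_inner: int = 5,
    ):
        if k_outer < 2 or k_inner < 2:
            raise ValueError("k_outer and k_inner must be >= 2")
        self.dataset = dataset
        self.grid = (
            list(grid)
            if grid is not None
            else _sel.default_grid(masks=_sel.all_feature_masks(dataset.features))
        )
        self.k_outer = k_outer
        self.k_inner = k_inner

    @classmethod
    def from_records(
        cls,
        records: Sequence[SequenceRecord],
        labels: Sequence[int],
        profiles: Mapping[str, PSSMProfile] | None = None,
        features: Sequence[str] = ("frequencies", "dipeptides", "factors"),
        **kwargs,
    ) -> "SecretionClassifier":
        dataset = EncodedDataset.from_records(
            records, labels, profiles=profiles, features=features
        )
        return cls(dataset, **kwargs)

    def fit(self, seed: int = 0) -> "SelectionResults":
        """Run nested CV, then select and train the deployable model on all data."""
        folds = _sel.nested_cv_folds(
            self.dataset, self.grid, self.k_outer, self.k_inner, seed
        )
        final_params, final_acc = _sel.grid_search(
            self.dataset, self.grid, k=self.k_inner, seed=seed
        )
        final_model = _sel.train_svm(
            self.dataset.matrix(final_params.feature_mask),
            self.dataset.y,
            final_params,
        )
        return SelectionResults(
            model_spec=self,
            folds=folds,
            final_params=final_params,
            final_inner_accuracy=float(final_acc),
            final_model=final_model,
            seed=seed,
        )


@dataclass
class SelectionResults:
    """Outcome of one nested-CV selection run."""

    model_spec: SecretionClassifier
    folds: list[dict]
    final_params: HyperParams
    final_inner_accuracy: float
    final_model: SVC
    seed: int

    @property
    def outer_accuracies(self) -> np.ndarray:
        return np.array([f["outer_accuracy"] for f in self.folds])

    @property
    def inner_accuracies(self) -> np.ndarray:
        return np.array([f["inner_accuracy"] for f in self.folds])

    @property
    def mean_outer_accuracy(self) -> float:
        """Nested-CV estimate of generalisation accuracy."""
        return float(self.outer_accuracies.mean())

    def fold_table(self) -> pd.DataFrame:
        rows = []
        for f in self.folds:
            d = f["params"].to_dict()
            rows.append(
                {
                    "fold": f["fold"],
                    "kernel": d["kernel"],
                    "C": d["C"],
                    "features": "+".join(d["feature_mask"]),
                    "inner_cv_acc": f["inner_accuracy"],
                    "outer_acc": f["outer_accuracy"],
                    "n_test": f["n_test"],
                }
            )
        return pd.DataFrame(rows)

    # -- prediction -------------------------------------------------------

    def _design(self, dataset: EncodedDataset) -> np.ndarray:
        return dataset.matrix(self.final_params.feature_mask)

    def predict(self, dataset: EncodedDataset) -> np.ndarray:
        labels, _ = _sel.predict(self.final_model, self._design(dataset))
        return labels

    def decision_scores(self, dataset: EncodedDataset) -> np.ndarray:
        _, scores = _sel.predict(self.final_model, self._design(dataset))
        return scores

    def evaluate(self, dataset: EncodedDataset) -> dict:
        """Confusion-derived metrics plus ROC AUC on a labelled dataset."""
        labels, scores = _sel.predict(self.final_model, self._design(dataset))
        m = metrics(confusion(labels, dataset.y))
        m["auc"] = self.roc(dataset).auc
        return m

    def roc(self, dataset: EncodedDataset) -> RocCurve:
        return roc(self.decision_scores(dataset), dataset.y)

    # -- reporting --------------------------------------------------------

    def to_dict(self) -> dict:
        """JSON-safe selection report (no fitted-model internals)."""
        return {
            "seed": self.seed,
            "k_outer": self.model_spec.k_outer,
            "k_inner": self.model_spec.k_inner,
            "n_grid_points": len(self.model_spec.grid),
            "folds": [
                {
                    "fold": f["fold"],
                    "params": f["params"].to_dict(),
                    "inner_accuracy": f["inner_accuracy"],
                    "outer_accuracy": f["outer_accuracy"],
                    "n_train": f["n_train"],
                    "n_test": f["n_test"],
                }
                for f in self.folds
            ],
            "mean_outer_accuracy": self.mean_outer_accuracy,
            "final_params": self.final_params.to_dict(),
            "final_inner_accuracy": self.final_inner_accuracy,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def summary(self) -> str:
        d = self.final_params.to_dict()
        lines = [
            "Nested cross-validated SVM selection",
            "=" * 58,
            f"examples: {len(self.model_spec.dataset)} "
            f"(+{int(np.sum(self.model_spec.dataset.y == 1))} / "
            f"-{int(np.sum(self.model_spec.dataset.y == -1))})",
            f"grid points: {len(self.model_spec.grid)}   "
            f"k_outer={self.model_spec.k_outer} k_inner={self.model_spec.k_inner} "
            f"seed={self.seed}",
            "-" * 58,
            self.fold_table().to_string(index=False),
            "-" * 58,
            f"mean outer accuracy: {self.mean_outer_accuracy:.4f}",
            f"final model: {d['kernel']} kernel, C={d['C']:g}"
            + (f", gamma={d['gamma']:g}" if "gamma" in d else "")
            + (f", degree={d['degree']}" if "degree" in d else ""),
            f"final features: {'+'.join(d['feature_mask'])}",
            f"final inner CV accuracy: {self.final_inner_accuracy:.4f}",
        ]
        return "\n".join(lines)
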