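"""End-to-end pipeline: simulate/load -> curate -> encode -> select -> evaluate.

``run_pipeline`` wires the library modules behind one :class:`RunConfig` and
writes every artifact (resolved config, selection report, fold table, model,
predictions, metrics, log counts) next to the configured output directory, so
a run is fully reproducible from the config and its seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib

from . import redundancy, selection, sequences
from .model import SecretionClassifier
from .sequences import DEFAULT_EXCLUSION_WORDS, SequenceRecord
from .simulate import FixtureSpec, generate, generate_profiles, write_profiles

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully-resolved configuration of one pipeline run."""

    out_dir: str = "secpred_run"
    # inputs: either simulate=True, or fasta+labels paths
    simulate: bool = True
    fixture: FixtureSpec = field(default_factory=FixtureSpec)
    fasta: str | None = None
    labels: str | None = None
    pssm_dir: str | None = None
    annotations: str | None = None
    # curation
    min_len: int = 50
    max_len: int = 10000
    exclusion_words: tuple[str, ...] = DEFAULT_EXCLUSION_WORDS
    identity_threshold: float | None = None  # None skips culling
    strip_signals: bool = True
    # encoding / selection
    features: tuple[str, ...] = ("frequencies", "dipeptides", "factors")
    grid: Sequence[selection.HyperParams] | None = None
    k_outer: int = 5
    k_inner: int = 5
    seed: int = 0
    float_format: str = "{:.6f}"

    def validate(self) -> None:
        if self.k_outer < 2 or self.k_inner < 2:
            raise ValueError("k_outer and k_inner must be >= 2")
        if not self.simulate and (self.fasta is None or self.labels is None):
            raise ValueError("non-simulated runs need fasta and labels paths")
        if "pssm" in self.features and not self.simulate and self.pssm_dir is None:
            raise ValueError("pssm features need a pssm_dir")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = None if self.grid is None else [p.to_dict() for p in self.grid]
        return d


def read_labels(path: str | Path) -> dict[str, int]:
    """Read ``id<TAB>label`` (+1/-1) lines."""
    table = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        rid, label = line.split("\t")
        table[rid] = int(label)
    return table


def write_labels(records: Sequence[SequenceRecord], labels: Sequence[int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r, y in zip(records, labels):
            fh.write(f"{r.id}\t{y:+d}\n")


def _stage(counts: dict, name: str, records: list) -> list:
    counts[name] = len(records)
    logger.info("stage %-22s %d records", name, len(records))
    return records


def run_pipeline(config: RunConfig) -> dict:
    """Execute the whole pipeline; returns a summary dict of artifact paths."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    # --- inputs ---------------------------------------------------------
    profiles = None
    if config.simulate:
        records, labels = generate(config.fixture)
        sequences.write_fasta(records, out / "sequences.fasta")
        write_labels(records, labels, out / "labels.tsv")
        if "pssm" in config.features:
            profiles = generate_profiles(records, seed=config.fixture.seed)
            write_profiles(profiles, out / "pssm")
    else:
        records = sequences.read_fasta(config.fasta)
        label_table = read_labels(config.labels)
        labels = [label_table[r.id] for r in records]
        if config.annotations:
            records = sequences.attach_annotations(
                records, sequences.read_annotations(config.annotations)
            )
        if "pssm" in config.features:
            profiles = {
                r.id: sequences.read_pssm(Path(config.pssm_dir) / f"{r.id}.pssm", r.id)
                for r in records
            }
    _stage(counts, "input", records)
    label_of = {r.id: y for r, y in zip(records, labels)}

    # --- curation -------------------------------------------------------
    records = _stage(
        counts, "length_filter", sequences.length_filter(records, config.min_len, config.max_len)
    )
    records = _stage(
        counts, "annotation_filter", sequences.annotation_filter(records, config.exclusion_words)
    )
    if config.strip_signals:
        records = _stage(counts, "strip_signal", sequences.strip_signal_regions(records))
    if config.identity_threshold is not None:
        records = _stage(
            counts, "identity_cull", redundancy.cull(records, config.identity_threshold)
        )
    labels = [label_of[r.id] for r in records]

    # --- encode + select ------------------------------------------------
    dataset = selection.EncodedDataset.from_records(
        records, labels, profiles=profiles, features=config.features
    )
    counts["encoded"] = len(dataset)
    clf = SecretionClassifier(
        dataset, grid=config.grid, k_outer=config.k_outer, k_inner=config.k_inner
    )
    results = clf.fit(seed=config.seed)

    # --- predictions + metrics on the training set ----------------------
    pred_labels = results.predict(dataset)
    scores = results.decision_scores(dataset)
    counts["predictions"] = len(pred_labels)
    with open(out / "predictions.tsv", "w") as fh:
        for rid, lab, score in zip(dataset.ids, pred_labels, scores):
            fh.write(f"{rid}\t{lab:+d}\t{config.float_format.format(score)}\n")
    train_metrics = results.evaluate(dataset)

    # --- artifacts ------------------------------------------------------
    (out / "config.json").write_text(
        json.dumps(config.to_dict(), indent=2, sort_keys=True) + "\n"
    )
    (out / "selection_report.json").write_text(results.to_json() + "\n")
    (out / "metrics.json").write_text(
        json.dumps(train_metrics, indent=2, sort_keys=True) + "\n"
    )
    (out / "stage_counts.json").write_text(
        json.dumps(counts, indent=2, sort_keys=True) + "\n"
    )
    joblib.dump(
        {"params": results.final_params, "model": results.final_model,
         "features": config.features},
        out / "model.joblib",
    )
    (out / "summary.txt").write_text(results.summary() + "\n")

    return {
        "out_dir": str(out),
        "counts": counts,
        "mean_outer_accuracy": results.mean_outer_accuracy,
        "final_params": results.final_params.to_dict(),
        "metrics": train_metrics,
        "results": results,
    }
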