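"""Evaluation protocols: repeated stratified splits, accuracy aggregation,
per-sample misjudgment analysis, training-fraction sweeps and
hyperparameter grids.

The central protocol draws a fresh stratified train/test split per repeat
(default 8:2), fits a fresh forest, and aggregates: the per-repeat and
mean accuracies, a predicted×actual confusion matrix summed over repeats,
and for every sample how often it was drawn into a test set versus how
often it was then misclassified — the per-sample error rate that exposes
systematically confusable samples.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .classify import OriginRandomForestClassifier, RfConfig, accuracy

__all__ = [
    "LabeledDataset",
    "SplitSpec",
    "EvalReport",
    "split_dataset",
    "repeated_eval",
    "proportion_sweep",
    "hyperparameter_grid",
    "TABLE_GRID",
]

#: The five (n_trees, mtry) combinations of the hyperparameter study.
TABLE_GRID = ((1000, 50), (2000, 50), (3000, 50), (2000, 40), (2000, 60))

# offset decorrelating forest seeds from split seeds within one master seed
_RF_SEED_OFFSET = 100_003


@dataclass
class LabeledDataset:
    """Aligned feature matrix, class labels and sample identifiers."""

    X: np.ndarray
    y: np.ndarray
    ids: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y)
        self.ids = np.asarray(self.ids)
        n = self.X.shape[0]
        if not (len(self.y) == len(self.ids) == n):
            raise ValueError("X, y and ids must have the same length")

    def __len__(self) -> int:
        return self.X.shape[0]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.y)

    def subset(self, idx) -> "LabeledDataset":
        return LabeledDataset(self.X[idx], self.y[idx], self.ids[idx])


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split specification (default the study's 8:2)."""

    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")


def split_dataset(ds: LabeledDataset, spec: SplitSpec) -> tuple[LabeledDataset, LabeledDataset]:
    """Disjoint, exhaustive (optionally stratified) train/test split.

    Stratification keeps per-class proportions, so a 4×90 dataset at 8:2
    yields 288 training and 72 test samples with 18 test samples per class.
    """
    idx = np.arange(len(ds))
    stratify = ds.y if spec.stratified else None
    train_idx, test_idx = train_test_split(
        idx,
        train_size=spec.train_fraction,
        random_state=spec.seed,
        stratify=stratify,
        shuffle=True,
    )
    train, test = ds.subset(train_idx), ds.subset(test_idx)
    if len(np.unique(train.y)) < len(ds.classes):
        raise ValueError("split left a class without training samples")
    return train, test


@dataclass
class EvalReport:
    """Aggregate of a repeated train/test experiment."""

    mean_accuracy: float  # percent
    per_repeat_accuracy: list
    confusion: pd.DataFrame  # predicted (rows) × actual (columns) counts
    per_sample: pd.DataFrame  # id, label, times_drawn, times_wrong, error_rate
    repeats: int
    spec: SplitSpec
    rf: RfConfig

    def per_class_error_rates(self) -> pd.Series:
        """Mean per-sample error rate by true class, in percent."""
        drawn = self.per_sample.groupby("label")["times_drawn"].sum()
        wrong = self.per_sample.groupby("label")["times_wrong"].sum()
        return 100.0 * wrong / drawn

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "per_repeat_accuracy": list(map(float, self.per_repeat_accuracy)),
            "repeats": self.repeats,
            "train_fraction": self.spec.train_fraction,
            "seed": self.spec.seed,
            "n_trees": self.rf.n_trees,
            "mtry": self.rf.mtry,
            "confusion": {
                "classes": list(map(str, self.confusion.columns)),
                "predicted_by_actual": self.confusion.to_numpy().tolist(),
            },
            "per_sample": self.per_sample.to_dict(orient="records"),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def repeated_eval(
    ds: LabeledDataset,
    spec: SplitSpec = SplitSpec(),
    cfg: RfConfig = RfConfig(),
    repeats: int = 200,
) -> EvalReport:
    """Repeat split→train→test ``repeats`` times and aggregate.

    Repeat r uses split seed ``spec.seed + r`` and an independently offset
    forest seed, so the whole report is a deterministic function of the
    master seed.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    classes = ds.classes
    class_pos = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((len(classes), len(classes)), dtype=np.int64)
    drawn = pd.Series(0, index=ds.ids, dtype=np.int64)
    wrong = pd.Series(0, index=ds.ids, dtype=np.int64)
    accs = []

    for r in range(repeats):
        train, test = split_dataset(ds, SplitSpec(spec.train_fraction, spec.seed + r, spec.stratified))
        model = OriginRandomForestClassifier(
            n_trees=cfg.n_trees, mtry=cfg.mtry, seed=(cfg.seed or 0) + _RF_SEED_OFFSET + r
        ).fit(train.X, train.y)
        pl = model.predict(test.X)
        accs.append(accuracy(pl, test.y))
        for pred, act in zip(pl, test.y):
            confusion[class_pos[pred], class_pos[act]] += 1
        drawn[test.ids] += 1
        wrong[test.ids[pl != test.y]] += 1

    labels = pd.Series(ds.y, index=ds.ids)
    with np.errstate(invalid="ignore"):
        err = (wrong / drawn.replace(0, np.nan)).fillna(0.0)
    per_sample = pd.DataFrame(
        {
            "id": ds.ids,
            "label": labels.values,
            "times_drawn": drawn.values,
            "times_wrong": wrong.values,
            "error_rate": err.values,
        }
    )
    return EvalReport(
        mean_accuracy=float(np.mean(accs)),
        per_repeat_accuracy=accs,
        confusion=pd.DataFrame(confusion, index=classes, columns=classes),
        per_sample=per_sample,
        repeats=repeats,
        spec=spec,
        rf=cfg,
    )


def proportion_sweep(
    ds: LabeledDataset,
    fractions,
    cfg: RfConfig = RfConfig(),
    repeats: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean accuracy as a function of the training-set fraction."""
    rows = []
    for frac in fractions:
        report = repeated_eval(ds, SplitSpec(train_fraction=float(frac), seed=seed), cfg, repeats)
        rows.append({"train_fraction": float(frac), "mean_accuracy": report.mean_accuracy})
    return pd.DataFrame(rows)


def hyperparameter_grid(
    ds: LabeledDataset,
    grid=TABLE_GRID,
    spec: SplitSpec = SplitSpec(),
    repeats: int = 1,
) -> pd.DataFrame:
    """Mean accuracy per (n_trees, mtry) combination under the 8:2 protocol.

    Returns one row per combination plus a ``best`` flag; ties are broken
    toward smaller n_trees, then smaller mtry.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    n_features = ds.X.shape[1]
    rows = []
    for n_trees, mtry in grid:
        if not 1 <= mtry <= n_features:
            raise ValueError(f"mtry={mtry} must lie in [1, {n_features}]")
        report = repeated_eval(ds, spec, RfConfig(n_trees=n_trees, mtry=mtry), repeats)
        rows.append({"n_trees": n_trees, "mtry": mtry, "mean_accuracy": report.mean_accuracy})
    table = pd.DataFrame(rows)
    best_idx = table.sort_values(
        ["mean_accuracy", "n_trees", "mtry"], ascending=[False, True, True]
    ).index[0]
    table["best"] = False
    table.loc[best_idx, "best"] = True
    return table
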