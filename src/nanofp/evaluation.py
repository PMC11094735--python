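"""Split-based validation of probe-to-fingerprint prediction models.

Materials are repeatedly split at random into 70% training / 30% testing
sets (shuffle-split semantics: independent draws, not disjoint folds).
For each split a model is fit on the training materials' probe free
energies and scored per response molecule on both sets with the
coefficient of determination

    R2 = 1 - sum (y_MetaD - y_ML)^2 / sum (y_MetaD - y_mean)^2

and the mean absolute error (kJ/mol).  Aggregates are the mean over
response molecules within a split, then mean +/- sd over splits.

The leakage-free variant repeats molecule clustering and probe selection
inside each split using only the training-material columns, so the test
materials are never seen at any stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import ShuffleSplit

from . import regression
from .clustering import cut_tree, select_representatives, ward_linkage_molecules
from .matrix_io import FreeEnergyMatrix
from .regression import RegressorSpec

__all__ = [
    "SplitScheme",
    "EvaluationReport",
    "make_splits",
    "r2_score",
    "mae",
    "evaluate",
    "evaluate_leakage_free",
]


@dataclass
class SplitScheme:
    """Repeated random train/test splitting over materials."""

    test_fraction: float = 0.3
    n_repeats: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


def make_splits(material_ids: list[str], scheme: SplitScheme) -> list[tuple[list[str], list[str]]]:
    """Independent uniform random (train_ids, test_ids) pairs; seeded."""
    n = len(material_ids)
    if n < 4:
        raise ValueError("need at least 4 materials to split")
    ss = ShuffleSplit(
        n_splits=scheme.n_repeats, test_size=scheme.test_fraction, random_state=scheme.seed
    )
    ids = np.asarray(material_ids, dtype=object)
    out = []
    for train_idx, test_idx in ss.split(ids):
        if len(train_idx) == 0 or len(test_idx) == 0:
            raise ValueError("empty train or test set after rounding")
        out.append((list(ids[train_idx]), list(ids[test_idx])))
    return out


def r2_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination; NaN (with a warning) for constant y_true."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise ValueError("need equal-length vectors with at least 2 entries")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        warnings.warn("R2 undefined: y_true is constant", stacklevel=2)
        return float("nan")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def mae(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Mean absolute error, kJ/mol."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 1:
        raise ValueError("need equal-length non-empty vectors")
    return float(np.mean(np.abs(y_true - y_pred)))


@dataclass
class EvaluationReport:
    """Per-molecule x split scores plus Table-style aggregates.

    ``per_split`` is a tidy frame with columns
    (split, molecule, set, r2, mae); aggregates average first over
    response molecules within a split, then report mean +/- sd over splits.
    """

    per_split: pd.DataFrame
    feature_ids_per_split: list[list[str]]
    errors: list[str] = field(default_factory=list)

    def aggregate(self) -> dict[str, dict[str, float]]:
        """{'train'|'test': {'r2_mean', 'r2_sd', 'mae_mean', 'mae_sd'}} over splits."""
        out = {}
        for which in ("train", "test"):
            sub = self.per_split[self.per_split["set"] == which]
            by_split = sub.groupby("split")[["r2", "mae"]].mean()
            out[which] = {
                "r2_mean": float(by_split["r2"].mean()),
                "r2_sd": float(by_split["r2"].std(ddof=0)),
                "mae_mean": float(by_split["mae"].mean()),
                "mae_sd": float(by_split["mae"].std(ddof=0)),
            }
        return out

    def per_molecule(self) -> pd.DataFrame:
        """Mean and sd of r2/mae per molecule and set, over splits."""
        g = self.per_split.groupby(["molecule", "set"])[["r2", "mae"]]
        return g.agg(["mean", "std"])


def _score_split(
    m: FreeEnergyMatrix,
    feature_ids: list[str],
    response_ids: list[str],
    spec: RegressorSpec,
    train: list[str],
    test: list[str],
    split_index: int,
    rows: list,
) -> None:
    col = {c: j for j, c in enumerate(m.material_ids)}
    tr = [col[c] for c in train]
    te = [col[c] for c in test]
    F = m.select_molecules(feature_ids)  # features x materials
    R = m.select_molecules(response_ids)
    model = regression.fit(
        spec, F[:, tr].T, R[:, tr].T, feature_ids=feature_ids, response_ids=response_ids
    )
    for which, idx in (("train", tr), ("test", te)):
        pred = regression.predict(model, F[:, idx].T)  # materials x responses
        truth = R[:, idx].T
        for j, mol in enumerate(response_ids):
            rows.append(
                {
                    "split": split_index,
                    "molecule": mol,
                    "set": which,
                    "r2": r2_score(truth[:, j], pred[:, j]),
                    "mae": mae(truth[:, j], pred[:, j]),
                }
            )


def evaluate(
    m: FreeEnergyMatrix,
    feature_ids: list[str],
    spec: RegressorSpec,
    scheme: SplitScheme,
) -> EvaluationReport:
    """Fixed probe set: fit/score the model over repeated material splits.

    Responses are all molecules not in ``feature_ids``.  Per-split model
    seeds derive deterministically from ``spec.seed + split index``.
    """
    unknown = [f for f in feature_ids if f not in m.molecule_ids]
    if unknown:
        raise KeyError(f"feature molecules not in matrix: {unknown}")
    response_ids = [mol for mol in m.molecule_ids if mol not in feature_ids]
    splits = make_splits(m.material_ids, scheme)
    rows: list = []
    errors: list[str] = []
    for i, (train, test) in enumerate(splits):
        split_spec = RegressorSpec(spec.family, dict(spec.hyperparameters), spec.seed + i)
        try:
            _score_split(m, feature_ids, response_ids, split_spec, train, test, i, rows)
        except Exception as exc:  # recorded, not fatal
            errors.append(f"split {i}: {exc}")
    return EvaluationReport(
        per_split=pd.DataFrame(rows),
        feature_ids_per_split=[list(feature_ids)] * len(splits),
        errors=errors,
    )


def evaluate_leakage_free(
    m: FreeEnergyMatrix,
    k: int,
    spec: RegressorSpec,
    scheme: SplitScheme,
    extra_feature_ids: list[str] | None = None,
) -> EvaluationReport:
    """Hold-out protocol with clustering inside each split.

    For every split, molecules are Ward-clustered using only the training
    materials' columns, one representative per cluster is selected (plus
    optional named extras), the model is fit on the training materials and
    tested on materials never seen at the clustering or training stage.
    """
    extra = list(extra_feature_ids or [])
    unknown = [f for f in extra if f not in m.molecule_ids]
    if unknown:
        raise KeyError(f"extra feature molecules not in matrix: {unknown}")
    splits = make_splits(m.material_ids, scheme)
    rows: list = []
    feats_per_split: list[list[str]] = []
    errors: list[str] = []
    col = {c: j for j, c in enumerate(m.material_ids)}
    for i, (train, test) in enumerate(splits):
        tr = [col[c] for c in train]
        m_train = FreeEnergyMatrix(
            molecule_ids=m.molecule_ids, material_ids=train, values=m.values[:, tr]
        )
        tree = ward_linkage_molecules(m_train)
        part = cut_tree(tree, k)
        reps = select_representatives(m_train, part)
        feature_ids = reps + [f for f in extra if f not in reps]
        response_ids = [mol for mol in m.molecule_ids if mol not in feature_ids]
        feats_per_split.append(feature_ids)
        split_spec = RegressorSpec(spec.family, dict(spec.hyperparameters), spec.seed + i)
        try:
            _score_split(m, feature_ids, response_ids, split_spec, train, test, i, rows)
        except Exception as exc:
            errors.append(f"split {i}: {exc}")
    return EvaluationReport(
        per_split=pd.DataFrame(rows),
        feature_ids_per_split=feats_per_split,
        errors=errors,
    )
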