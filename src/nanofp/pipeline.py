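"""End-to-end orchestration: matrix -> probes -> model -> validation -> grouping.

Thin glue over the library modules, shared by the command-line front end,
the analysis drivers and the acceptance script.  All numerical work lives
in the individual modules.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import materials, regression
from .clustering import (
    cut_tree,
    elbow_curve,
    kmeans_partition,
    pca_variance,
    select_representatives,
    ward_linkage_molecules,
)
from .evaluation import SplitScheme, evaluate, evaluate_leakage_free
from .matrix_io import FreeEnergyMatrix
from .regression import RegressorSpec

__all__ = ["choose_features", "fit_on_all_materials", "run_pipeline"]


def choose_features(
    m: FreeEnergyMatrix, k: int = 3, extra: list[str] | None = None
) -> tuple[list[str], dict]:
    """Cluster molecules at k and return probe ids (+ optional named extras).

    Returns the feature list and a report dict (partition members,
    representatives, PCA component estimate, K-means agreement).
    """
    tree = ward_linkage_molecules(m)
    part = cut_tree(tree, k)
    reps = select_representatives(m, part)
    features = reps + [x for x in (extra or []) if x not in reps]
    var = pca_variance(m)
    km_part, inertia = kmeans_partition(m, k)
    from sklearn.metrics import adjusted_rand_score

    report = {
        "k": k,
        "representatives": reps,
        "features": features,
        "clusters": {str(c): part.members(c) for c in range(part.k)},
        "pca_components_estimate": var.n_components_estimate,
        "kmeans_inertia": inertia,
        "kmeans_vs_ward_ari": float(adjusted_rand_score(part.labels, km_part.labels)),
        "newick": tree.to_newick(),
    }
    return features, report


def fit_on_all_materials(
    m: FreeEnergyMatrix, feature_ids: list[str], spec: RegressorSpec
) -> regression.FittedModel:
    """Fit one model on every material (used for the predicted-matrix stage)."""
    response_ids = [mol for mol in m.molecule_ids if mol not in feature_ids]
    F = m.select_molecules(feature_ids).T
    R = m.select_molecules(response_ids).T
    return regression.fit(spec, F, R, feature_ids=feature_ids, response_ids=response_ids)


def run_pipeline(
    m: FreeEnergyMatrix,
    k: int = 3,
    extra_features: list[str] | None = None,
    spec: RegressorSpec | None = None,
    scheme: SplitScheme | None = None,
    leakage_free: bool = True,
) -> dict:
    """Full analysis on one matrix; returns a JSON-serializable summary."""
    spec = spec or RegressorSpec("LR")
    scheme = scheme or SplitScheme()
    features, cluster_report = choose_features(m, k=k, extra=extra_features)

    report = evaluate(m, features, spec, scheme)
    agg = report.aggregate()

    model = fit_on_all_materials(m, features, spec)
    full_tree = materials.cluster_materials(m)
    predicted = materials.build_predicted_matrix(m, model)
    pred_tree = materials.cluster_materials(predicted.matrix)
    agreement = materials.compare_groupings(full_tree, pred_tree, k)
    mat_part = cut_tree(full_tree, k)

    out = {
        "features": features,
        "clustering": cluster_report,
        "evaluation": agg,
        "material_groups": {str(c): mat_part.members(c) for c in range(mat_part.k)},
        "material_grouping_agreement": {
            "ari": agreement.ari,
            "cophenetic_correlation": agreement.cophenetic_correlation,
        },
        "model_errors": report.errors,
    }
    if leakage_free:
        lf = evaluate_leakage_free(m, k, spec, scheme, extra_feature_ids=extra_features)
        stable = sum(f == features for f in lf.feature_ids_per_split)
        out["leakage_free"] = {
            "evaluation": lf.aggregate(),
            "representative_stability": stable / max(len(lf.feature_ids_per_split), 1),
            "features_per_split": lf.feature_ids_per_split,
        }
    return out


def write_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report, indent=2, default=_json_default) + "\n")
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
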