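"""Grouping of nanomaterials from full or model-predicted fingerprints.

A nanomaterial's "biological fingerprint" is its column of biomolecule
adsorption free energies.  Materials are Ward-clustered on Euclidean
distances between fingerprints, both for the measured matrix and for a
matrix in which all non-probe rows are replaced by model predictions; the
agreement between the two groupings is quantified with the adjusted Rand
index of the k-cuts and the cophenetic correlation of the trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cophenet
from sklearn.metrics import adjusted_rand_score

from . import regression
from .clustering import LinkageTree, cut_tree, molecule_distance_matrix, ward_linkage
from .matrix_io import FreeEnergyMatrix
from .regression import FittedModel

__all__ = [
    "PredictedMatrix",
    "PartitionAgreement",
    "cluster_materials",
    "build_predicted_matrix",
    "compare_groupings",
]


@dataclass
class PredictedMatrix:
    """A free-energy matrix whose non-probe rows are model predictions.

    Probe (feature) rows are copied bit-identically from the source; the
    provenance of every row is recorded in ``measured`` flags.
    """

    matrix: FreeEnergyMatrix
    measured: dict[str, bool]

    def __post_init__(self) -> None:
        missing = set(self.matrix.molecule_ids) - set(self.measured)
        if missing:
            raise ValueError(f"missing provenance flags for {sorted(missing)}")


@dataclass
class PartitionAgreement:
    """Agreement between two material groupings."""

    ari: float
    cophenetic_correlation: float


def cluster_materials(m: FreeEnergyMatrix) -> LinkageTree:
    """Ward tree over material fingerprint columns."""
    return ward_linkage(molecule_distance_matrix(m.transpose()))


def build_predicted_matrix(m: FreeEnergyMatrix, model: FittedModel) -> PredictedMatrix:
    """Replace response rows by model predictions; keep probe rows measured."""
    ids = set(m.molecule_ids)
    unknown = [x for x in model.feature_ids + model.response_ids if x not in ids]
    if unknown:
        raise KeyError(f"model molecules not in matrix: {unknown}")
    X = m.select_molecules(model.feature_ids).T  # materials x features
    pred = regression.predict(model, X)  # materials x responses
    values = m.values.copy()
    row = {mol: i for i, mol in enumerate(m.molecule_ids)}
    for j, mol in enumerate(model.response_ids):
        values[row[mol], :] = pred[:, j]
    measured = {mol: mol not in model.response_ids for mol in m.molecule_ids}
    out = FreeEnergyMatrix(
        molecule_ids=list(m.molecule_ids), material_ids=list(m.material_ids), values=values
    )
    return PredictedMatrix(matrix=out, measured=measured)


def compare_groupings(t1: LinkageTree, t2: LinkageTree, k: int) -> PartitionAgreement:
    """ARI between the k-cuts and cophenetic correlation between the trees."""
    if t1.leaf_ids != t2.leaf_ids:
        raise ValueError("trees are over different leaf sets")
    p1, p2 = cut_tree(t1, k), cut_tree(t2, k)
    ari = float(adjusted_rand_score(p1.labels, p2.labels))
    c1, c2 = cophenet(t1.Z), cophenet(t2.Z)
    if np.std(c1) == 0 or np.std(c2) == 0:
        coph = 1.0 if np.allclose(c1, c2) else float("nan")
    else:
        coph = float(np.corrcoef(c1, c2)[0, 1])
    return PartitionAgreement(ari=ari, cophenetic_correlation=coph)
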