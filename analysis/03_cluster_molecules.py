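"""Cluster biomolecules, estimate the cluster count, and pick probe molecules.

Reads results/synthetic/matrix.csv (run 01 first), builds the Ward
dendrogram over molecule adsorption profiles, cross-checks the cluster
count with PCA (Minka MLE) and the K-means inertia elbow, cuts at k=3,
and selects one representative molecule per cluster.  Outputs under
results/clustering/.
"""

import json
from pathlib import Path

import pandas as pd

from nanofp.matrix_io import read_matrix
from nanofp.pipeline import choose_features
from nanofp.clustering import elbow_curve

IN = Path("results/synthetic/matrix.csv")
OUT = Path("results/clustering")


def main() -> None:
    m = read_matrix(IN)
    features, report = choose_features(m, k=3)
    curve = elbow_curve(m, k_max=8)
    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "molecules.nwk").write_text(report.pop("newick") + "\n")
    pd.DataFrame({"k": curve.k_values, "inertia": curve.inertia}).to_csv(
        OUT / "inertia.csv", index=False
    )
    (OUT / "clusters.json").write_text(json.dumps(report, indent=2, default=str) + "\n")

    sizes = {c: len(v) for c, v in report["clusters"].items()}
    print(f"Ward k=3 cluster sizes: {sizes}")
    print(f"PCA (MLE) component estimate: {report['pca_components_estimate']}")
    print(f"K-means elbow suggests k = {curve.suggest_k()}")
    print(f"K-means vs Ward agreement (ARI): {report['kmeans_vs_ward_ari']:.2f}")
    print(f"probe molecules (closest to cluster centroids): {', '.join(features)}")


if __name__ == "__main__":
    main()
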