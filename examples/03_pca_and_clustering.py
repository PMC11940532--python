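"""Explore spectral similarity among the 14 pesticides with PCA and HCA.

Averages preprocessed replicates per pesticide, then runs covariance PCA
and Ward/correlation hierarchical clustering on the 14 mean spectra.
"""

from ramanid import (
    SyntheticConfig,
    cut_clusters,
    hca,
    pca,
    run_pipeline,
    simulate_dataset,
)
from ramanid.library import load_library
from ramanid.workflow import average_by_class

pipe = run_pipeline(simulate_dataset(load_library(),
                                     SyntheticConfig(seed=42, n_per_class=8)))
X, names = average_by_class(pipe.spectra)
print(f"averaged matrix: {X.shape[0]} pesticides x {X.shape[1]} wavenumbers")

res = pca(X, n_components=3)
for i in range(3):
    print(f"PC{i + 1}: eigenvalue {res.eigenvalues[i]:.5f}, "
          f"explains {res.explained_pct[i]:5.2f}% (cumulative "
          f"{res.cumulative_pct[i]:5.2f}%)")
# Variance is spread over many components (PC1-PC3 together explain well
# under half of it): no single axis separates all 14 compounds, which is
# why the supervised classifier is needed on top of PCA.

tree = hca(X, metric="correlation", linkage="ward", labels=names)
clusters = cut_clusters(tree, 4)
print("\nfour-cluster cut of the Ward/correlation dendrogram:")
for c in range(4):
    members = [n for n, g in zip(names, clusters) if g == c]
    print(f"  cluster {c + 1}: {', '.join(members)}")
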