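"""Cross-dataset harmonization: batch adjustment, z-scoring, clustering.

Simulates ortholog expression from three datasets ("pig", "human",
"mouse") with dataset-level shifts, removes them with the location-scale
batch adjustment, z-scores rows and clusters the profiles into expression
pattern groups.
"""

import numpy as np
import pandas as pd

from omnifiber import batch_adjust, cluster_profiles, zscore_rows

rng = np.random.default_rng(11)
n_genes, n_timepoints = 300, 4
protos = rng.normal(0, 1.5, size=(3, n_timepoints))  # three expression archetypes
truth = rng.integers(0, 3, n_genes)

cols, batch = {}, {}
for species, shift in (("pig", 0.0), ("human", 2.5), ("mouse", -1.5)):
    for t in range(n_timepoints):
        s = f"{species}_t{t}"
        cols[s] = protos[truth, t] + shift + rng.normal(0, 0.2, n_genes)
        batch[s] = species
x = pd.DataFrame(cols, index=[f"OG{i:04d}" for i in range(n_genes)])

adjusted = batch_adjust(x, pd.Series(batch))
gap_before = x.filter(like="human").mean().mean() - x.filter(like="pig").mean().mean()
gap_after = (
    adjusted.filter(like="human").mean().mean() - adjusted.filter(like="pig").mean().mean()
)
print(f"human-vs-pig dataset offset: {gap_before:+.3f} before, {gap_after:+.3e} after")

z, n_dropped = zscore_rows(adjusted)
result = cluster_profiles(z, k=3, seed=2, column_groups=batch)
print(f"cluster sizes: {result.labels.value_counts().to_dict()} "
      f"({n_dropped} constant rows dropped)")
print("\npig mean trajectory per cluster:")
print(result.group_curves["pig"].round(2).to_string())
print(
    "\nAfter adjustment the dataset offsets vanish while the planted\n"
    "archetype structure drives the clusters."
)
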