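"""Bulk-sample scoring and stratification: score pseudo-bulk samples
against a subnetwork eigensystem, split them into top/bottom groups, and
label drug response from IC50 values.

The top/bottom groups are what a survival comparison (e.g. a log-rank
test) would consume; the resistant/sensitive labels accompany the
feature matrix for downstream regression.
"""

import numpy as np
import pandas as pd

from coac import (
    SyntheticSpec,
    feature_matrix,
    generate,
    label_drug_response,
    mine_filtered_subnetworks,
    stratify_samples,
    subnetwork_eigensystem,
)
from coac.matrix import ExpressionMatrix, log_tpm_transform

# train subnetworks on single-cell data
sc_matrix, truth = generate(SyntheticSpec(seed=2))
training = log_tpm_transform(sc_matrix)
decomposition, subnetworks = mine_filtered_subnetworks(sc_matrix, seed=2)
eigensystem = subnetwork_eigensystem(subnetworks[0], training, name="subnet_0")

# pseudo-bulk samples: averages of random cell subsets
rng = np.random.default_rng(2)
n_samples = 120
bulk = np.stack([
    training.dense()[rng.choice(training.n_cells, 40, replace=False)].mean(axis=0)
    for _ in range(n_samples)
])
bulk_matrix = ExpressionMatrix(
    bulk, training.gene_ids, [f"sample_{i:03d}" for i in range(n_samples)],
    transform=training.transform,
)

scores = feature_matrix(bulk_matrix, [eigensystem])["subnet_0"]
top, bottom = stratify_samples(scores, k=16)
print(f"scored {n_samples} bulk samples against subnetwork "
      f"({len(eigensystem.gene_ids)} genes)")
print(f"group 1 (top 16): {top[:4]} ... mean score {scores[top].mean():.3f}")
print(f"group 2 (bottom 16): {bottom[:4]} ... mean score {scores[bottom].mean():.3f}")

# drug-response labels: resistant iff IC50 > 10 uM
ic50 = pd.Series(rng.lognormal(1.5, 1.2, n_samples), index=scores.index)
labels = label_drug_response(ic50, cutoff=10.0)
print(f"drug response: {(labels == 'resistant').sum()} resistant, "
      f"{(labels == 'sensitive').sum()} sensitive cell lines")
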