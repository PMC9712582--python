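"""End-to-end convenience: counts -> SOM -> Ward labels in one call."""

from __future__ import annotations

import pandas as pd

from .io import drop_empty_samples, log_transform
from .som import SelfOrganizingMap, SOMConfig, lattice_size
from .zoning import cluster_neurons, label_samples

__all__ = ["assemblage_states"]


def assemblage_states(matrix: pd.DataFrame, k_clusters: int = 2,
                      k_subclusters: int = 4, seed: int = 0,
                      dims=None, config: SOMConfig | None = None):
    """Classify non-empty samples into assemblage states.

    Drops barren samples, log-transforms, trains the SOM (lattice sized by
    the 5*sqrt(n) heuristic unless ``dims`` is given), Ward-clusters the
    codebook at the two cut levels and propagates labels through BMU
    assignment.  Returns ``(labels, som_results, removed_codes)`` where
    ``labels`` has one row per non-empty sample (neuron, cluster,
    subcluster).
    """
    kept, removed = drop_empty_samples(matrix)
    transformed = log_transform(kept)
    som = SelfOrganizingMap(transformed, dims=dims, config=config)
    results = som.fit(seed=seed)
    clustering = cluster_neurons(results, k_clusters, k_subclusters)
    labels = label_samples(clustering, results.assign(transformed))
    return labels, results, removed
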