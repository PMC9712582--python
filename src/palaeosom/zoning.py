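"""Neuron clustering, sample labelling and stratigraphic zonation.

The trained codebook vectors are clustered with Ward's method on Euclidean
distances; a single dendrogram is cut at two levels (default 2 clusters and
4 subclusters, nested by construction).  Every non-empty sample inherits
the labels of its best-matching neuron.  Subclusters are then ordered by
their number of significantly associated indicator taxa — a gradient from
unfavourable to favourable conditions — and each core's depth sequence is
collapsed into contiguous zones of one label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

__all__ = [
    "NeuronClustering",
    "cluster_neurons",
    "label_samples",
    "order_subclusters",
    "core_zonation",
]


@dataclass
class NeuronClustering:
    linkage_matrix: np.ndarray
    cluster_labels: np.ndarray     # k_clusters-cut label per neuron
    subcluster_labels: np.ndarray  # k_subclusters-cut label per neuron

    @property
    def n_neurons(self) -> int:
        return len(self.cluster_labels)


def cluster_neurons(som_results, k_clusters: int = 2,
                    k_subclusters: int = 4) -> NeuronClustering:
    """Ward/Euclidean tree over codebook vectors, cut at two levels.

    Neurons without assigned samples are clustered like any other (their
    codebooks are valid virtual samples); they simply contribute no samples
    downstream.  Subclusters nest within clusters because both partitions
    are cuts of the same dendrogram (asserted).
    """
    codebook = som_results.codebook.to_numpy()
    n = codebook.shape[0]
    if not 1 <= k_clusters <= k_subclusters <= n:
        raise ValueError("require 1 <= k_clusters <= k_subclusters <= n_neurons")
    if n == 1:
        return NeuronClustering(np.empty((0, 4)), np.zeros(1, int), np.zeros(1, int))
    Z = linkage(codebook, method="ward", metric="euclidean")
    clusters = fcluster(Z, t=k_clusters, criterion="maxclust") - 1
    subclusters = fcluster(Z, t=k_subclusters, criterion="maxclust") - 1
    # nesting: each subcluster lies in exactly one cluster
    for s in np.unique(subclusters):
        assert len(np.unique(clusters[subclusters == s])) == 1, \
            "dendrogram cuts failed to nest"
    return NeuronClustering(Z, clusters, subclusters)


def label_samples(clustering: NeuronClustering, bmu: pd.Series) -> pd.DataFrame:
    """Propagate neuron labels to samples through their BMU assignment.

    Returns a DataFrame indexed by sample code with columns ``neuron``,
    ``cluster`` and ``subcluster``.
    """
    neurons = bmu.to_numpy(dtype=int)
    if neurons.min() < 0 or neurons.max() >= clustering.n_neurons:
        raise ValueError("sample mapped to a neuron outside the clustering")
    return pd.DataFrame({
        "neuron": neurons,
        "cluster": clustering.cluster_labels[neurons],
        "subcluster": clustering.subcluster_labels[neurons],
    }, index=bmu.index)


def order_subclusters(labels: pd.DataFrame, indval_results) -> tuple[list, dict]:
    """Order subclusters by their indicator-taxon counts (ascending).

    A taxon counts for its best (argmax-IndVal) subcluster when its
    permutation p-value is <= 0.05.  Ties are broken by the subcluster's
    total IndVal sum.  Returns ``(ordered_ids, name_map)`` where the name
    map assigns cluster letters in gradient order (X, Y, ...) and numbers
    within each cluster (X1, X2, Y1, Y2 for the default 2 + 4 cuts).
    """
    subs = sorted(pd.unique(labels["subcluster"]))
    sig = indval_results.pvalues <= 0.05
    counts = {j: int(((indval_results.best_group == j) & sig).sum()) for j in subs}
    if all(v == 0 for v in counts.values()):
        import warnings
        warnings.warn("no significant indicators in any subcluster; "
                      "ordering falls back to total IndVal and input order",
                      stacklevel=2)
    totals = {j: float(indval_results.indval.loc[j].sum())
              if j in indval_results.indval.index else 0.0 for j in subs}
    ordered = sorted(subs, key=lambda j: (counts[j], totals[j], j))

    sub_to_cluster = (labels.drop_duplicates("subcluster")
                      .set_index("subcluster")["cluster"].to_dict())
    # clusters ordered by their least-indicative subcluster's position
    cluster_rank: dict = {}
    for j in ordered:
        cluster_rank.setdefault(sub_to_cluster[j], len(cluster_rank))
    letters = "XYZWVU"
    name_map, within = {}, {}
    for j in ordered:
        c = sub_to_cluster[j]
        within[c] = within.get(c, 0) + 1
        name_map[j] = f"{letters[cluster_rank[c] % len(letters)]}{within[c]}"
    return ordered, name_map


def core_zonation(labels: pd.DataFrame, meta: pd.DataFrame,
                  name_map: dict | None = None) -> pd.DataFrame:
    """Collapse each core's depth sequence into contiguous label zones.

    ``labels`` covers the non-empty samples; samples present in ``meta``
    but absent from ``labels`` are emitted as explicit ``"barren"`` zones
    so that mostly-empty cores remain interpretable.  Zones partition the
    sampled depths of each core without overlap.
    """
    missing = labels.index.difference(meta.index)
    if len(missing):
        raise ValueError(f"samples missing from metadata: {list(missing)}")
    rows = []
    for core, grp in meta.groupby("core_id", sort=True):
        grp = grp.sort_values("depth_cm_bgl")
        zone_lab, top, bottom, ages = None, None, None, []
        for code, r in grp.iterrows():
            if code in labels.index:
                lab = labels.loc[code, "subcluster"]
                lab = name_map.get(lab, lab) if name_map else lab
            else:
                lab = "barren"
            if lab != zone_lab and zone_lab is not None:
                rows.append((core, top, bottom, zone_lab,
                             min(ages), max(ages)))
                top, ages = None, []
            if top is None:
                top = int(r["depth_cm_bgl"])
            zone_lab = lab
            bottom = int(r["depth_cm_bgl"])
            ages.append(float(r["age_mean_AD"]))
        if zone_lab is not None:
            rows.append((core, top, bottom, zone_lab, min(ages), max(ages)))
    return pd.DataFrame(rows, columns=["core_id", "top_depth_cm",
                                       "bottom_depth_cm", "label",
                                       "age_min_AD", "age_max_AD"])
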