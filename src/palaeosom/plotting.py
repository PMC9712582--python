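"""Matplotlib views of the fitted objects: component planes, the clustered
lattice, and the CCA biplot.  Shading of a component plane is scaled
independently per taxon."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_component_plane", "plot_lattice_clusters", "plot_cca_biplot"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _fig, ax = plt.subplots()
    return ax


def plot_component_plane(som_results, taxon: str, ax=None):
    """Greyness-gradient plane of one taxon over the lattice."""
    ax = _ax(ax)
    plane = som_results.component_plane(taxon)
    im = ax.imshow(plane, cmap="Greys", origin="upper")
    ax.set_title(taxon)
    ax.set_xticks([]), ax.set_yticks([])
    return im


def plot_lattice_clusters(som_results, clustering, bmu_map=None, ax=None):
    """Lattice shaded by subcluster, optionally annotated with sample codes."""
    ax = _ax(ax)
    dims = som_results.dims
    grid = clustering.subcluster_labels.reshape(dims.rows, dims.cols)
    im = ax.imshow(grid, cmap="Greys", origin="upper",
                   vmin=-0.5, vmax=grid.max() + 0.5)
    if bmu_map:
        for k, codes in bmu_map.items():
            if codes:
                r, c = divmod(k, dims.cols)
                ax.text(c, r, "\n".join(codes), ha="center", va="center",
                        fontsize=5)
    ax.set_xticks([]), ax.set_yticks([])
    return im


def plot_cca_biplot(cca_results, ax=None, arrow_scale: float | None = None):
    """Taxa as triangles, samples as circles, variables as arrows."""
    ax = _ax(ax)
    sp = cca_results.species_scores.iloc[:, :2].to_numpy()
    si = cca_results.site_scores.iloc[:, :2].to_numpy()
    bp = cca_results.biplot_scores.iloc[:, :2].to_numpy()
    if arrow_scale is None:
        arrow_scale = 0.9 * max(np.abs(si).max(), np.abs(sp).max()) \
            / max(np.abs(bp).max(), 1e-12)
    ax.scatter(sp[:, 0], sp[:, 1], marker="^", s=14, label="taxa")
    ax.scatter(si[:, 0], si[:, 1], marker="o", s=14, label="samples")
    for name, (x, y) in zip(cca_results.biplot_scores.index, bp):
        ax.annotate("", xy=(x * arrow_scale, y * arrow_scale), xytext=(0, 0),
                    arrowprops={"arrowstyle": "->", "color": "red"})
        ax.text(x * arrow_scale * 1.05, y * arrow_scale * 1.05, name,
                color="red", fontsize=8)
    pct = cca_results.prop_species_variance
    ax.set_xlabel(f"CCA1 ({pct[0]:.1f}%)")
    if len(pct) > 1:
        ax.set_ylabel(f"CCA2 ({pct[1]:.1f}%)")
    ax.legend(loc="best", fontsize=8)
    return ax
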