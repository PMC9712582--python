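"""Batch-trained Kohonen self-organising map for assemblage data.

The output layer is a two-dimensional rectangular lattice of neurons, each
holding one codebook vector of the same length as the input (one entry per
taxon) — a "virtual core sample".  Training uses the batch algorithm: per
epoch every sample is assigned to its best-matching unit (BMU), then every
codebook vector is replaced by the neighbourhood-kernel-weighted mean of
all samples.  No learning-rate factor is involved.

Lattice sizing follows the usual heuristic that the number of output
neurons should be close to ``5 * sqrt(n_samples)``, factored into the most
nearly square admissible grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

__all__ = [
    "LatticeDims",
    "SOMConfig",
    "SelfOrganizingMap",
    "SOMResults",
    "lattice_size",
]


@dataclass(frozen=True)
class LatticeDims:
    """Rectangular output lattice; neuron index = row * cols + col (row-major)."""

    rows: int
    cols: int

    def __post_init__(self):
        if not self.rows >= self.cols >= 1:
            raise ValueError("require rows >= cols >= 1")

    @property
    def n_neurons(self) -> int:
        return self.rows * self.cols

    def coordinates(self) -> np.ndarray:
        """(n_neurons, 2) integer (row, col) grid coordinates, row-major."""
        r, c = np.divmod(np.arange(self.n_neurons), self.cols)
        return np.column_stack([r, c]).astype(float)


def lattice_size(n_samples: int, aspect_cap: float = 1.5) -> LatticeDims:
    """Choose lattice dimensions for ``n_samples`` input samples.

    The target neuron count is ``round(5 * sqrt(n))``.  Among factor pairs
    ``rows >= cols`` with aspect ratio ``rows/cols <= aspect_cap``, the pair
    minimising ``|rows*cols - target|`` wins; ties go to the smaller
    product, then the smaller row count.

    >>> lattice_size(79)
    LatticeDims(rows=7, cols=6)
    """
    if n_samples < 4:
        raise ValueError("need at least 4 samples to size a lattice")
    target = int(np.floor(5.0 * np.sqrt(n_samples) + 0.5))
    best = None
    c_max = int(np.ceil(np.sqrt(2.0 * target))) + 2
    for c in range(1, c_max + 1):
        for r in range(c, int(np.floor(c * aspect_cap)) + 1):
            key = (abs(r * c - target), r * c, r)
            if best is None or key < best[0]:
                best = (key, LatticeDims(r, c))
    return best[1]


@dataclass
class SOMConfig:
    """Training schedule.

    Two phases of batch epochs: a rough phase with the neighbourhood radius
    shrinking linearly from ``radius_initial`` (default max(rows, cols)/4)
    to 1, then a fine phase from 1 to ``radius_final``.
    """

    n_epochs_rough: int = 10
    n_epochs_fine: int = 40
    radius_initial: float | None = None
    radius_final: float = 0.5
    init: str = "linear"  # "linear" (principal-axis) or "random"


@dataclass
class SOMResults:
    """Trained map: codebook, geometry, and query methods."""

    dims: LatticeDims
    codebook: pd.DataFrame  # n_neurons x n_taxa, index = neuron id
    config: SOMConfig
    seed: int

    @property
    def input_taxa(self) -> list[str]:
        return list(self.codebook.columns)

    def _check_taxa(self, data: pd.DataFrame) -> np.ndarray:
        if list(data.columns) != self.input_taxa:
            raise ValueError("taxon order of data does not match the trained map")
        return data.to_numpy(dtype=float)

    def assign(self, data: pd.DataFrame) -> pd.Series:
        """Best-matching neuron per sample (Euclidean; ties -> lowest index)."""
        X = self._check_taxa(data)
        d = cdist(X, self.codebook.to_numpy())
        return pd.Series(d.argmin(axis=1), index=data.index, name="neuron")

    def bmu_map(self, data: pd.DataFrame) -> dict[int, list[str]]:
        """Per neuron, the list of assigned sample codes (possibly empty)."""
        bmu = self.assign(data)
        out = {k: [] for k in range(self.dims.n_neurons)}
        for code, k in bmu.items():
            out[int(k)].append(code)
        return out

    def component_plane(self, taxon: str) -> np.ndarray:
        """Codebook values of one taxon arranged on the (rows x cols) lattice."""
        if taxon not in self.codebook.columns:
            raise KeyError(f"unknown taxon {taxon!r}")
        return (self.codebook[taxon].to_numpy()
                .reshape(self.dims.rows, self.dims.cols))

    def quality(self, data: pd.DataFrame) -> tuple[float, float]:
        """(quantization error, topographic error).

        Quantization error is the mean sample-to-BMU distance; topographic
        error the fraction of samples whose two nearest neurons are not
        lattice neighbours (0 by convention on a single-neuron map).
        """
        X = self._check_taxa(data)
        d = cdist(X, self.codebook.to_numpy())
        order = np.argsort(d, axis=1, kind="stable")
        qe = float(d[np.arange(len(X)), order[:, 0]].mean())
        if self.dims.n_neurons == 1:
            return qe, 0.0
        coords = self.dims.coordinates()
        gd = np.abs(coords[order[:, 0]] - coords[order[:, 1]]).max(axis=1)
        return qe, float((gd > 1).mean())


class SelfOrganizingMap:
    """Model object: transformed assemblage data plus lattice geometry.

    Parameters
    ----------
    data : DataFrame
        Non-empty samples x taxa, already log-transformed.
    dims : LatticeDims, optional
        Defaults to ``lattice_size(n_samples)``.
    config : SOMConfig, optional
    """

    def __init__(self, data: pd.DataFrame, dims: LatticeDims | None = None,
                 config: SOMConfig | None = None):
        if data.shape[0] == 0:
            raise ValueError("empty training data")
        X = data.to_numpy(dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("non-finite values in training data")
        self.data = data
        self.dims = dims if dims is not None else lattice_size(data.shape[0])
        self.config = config if config is not None else SOMConfig()

    def _initial_codebook(self, rng: np.random.Generator) -> np.ndarray:
        """Linear initialisation spanning the first two principal axes."""
        X = self.data.to_numpy(dtype=float)
        mean = X.mean(axis=0)
        coords = self.dims.coordinates()
        if self.config.init == "random" or min(X.shape) < 2:
            lo, hi = X.min(axis=0), X.max(axis=0)
            return rng.uniform(lo, hi, size=(self.dims.n_neurons, X.shape[1]))
        Xc = X - mean
        _u, s, vt = np.linalg.svd(Xc, full_matrices=False)
        # scale grid coordinates to [-1, 1] per axis, span the two leading axes
        span = np.zeros((self.dims.n_neurons, 2))
        for ax, extent in enumerate((self.dims.rows, self.dims.cols)):
            if extent > 1:
                span[:, ax] = 2.0 * coords[:, ax] / (extent - 1) - 1.0
        sd = s[:2] / np.sqrt(max(X.shape[0] - 1, 1))
        basis = vt[:2] * sd[:, None] if len(s) >= 2 else np.zeros((2, X.shape[1]))
        return mean + span @ basis

    def fit(self, seed: int = 0) -> SOMResults:
        """Train with the two-phase batch schedule; deterministic given seed."""
        cfg = self.config
        X = self.data.to_numpy(dtype=float)
        rng = np.random.default_rng(seed)
        codebook = self._initial_codebook(rng)
        coords = self.dims.coordinates()
        grid_d2 = cdist(coords, coords) ** 2

        r0 = cfg.radius_initial
        if r0 is None:
            r0 = max(self.dims.rows, self.dims.cols) / 4.0
        r0 = max(r0, cfg.radius_final)
        schedule = []
        for e in range(cfg.n_epochs_rough):
            t = e / max(cfg.n_epochs_rough - 1, 1)
            schedule.append(r0 + t * (max(1.0, cfg.radius_final) - r0))
        for e in range(cfg.n_epochs_fine):
            t = e / max(cfg.n_epochs_fine - 1, 1)
            schedule.append(1.0 + t * (cfg.radius_final - 1.0))

        for radius in schedule:
            codebook = _batch_step(X, codebook, grid_d2, radius)
        cb = pd.DataFrame(codebook, columns=self.data.columns)
        cb.index.name = "neuron"
        return SOMResults(self.dims, cb, cfg, seed)


def _batch_step(X: np.ndarray, codebook: np.ndarray, grid_d2: np.ndarray,
                radius: float) -> np.ndarray:
    """One batch update: BMU assignment, then kernel-weighted means.

    A Gaussian kernel on lattice distance is used; in the radius -> 0 limit
    the kernel collapses to an indicator and the step equals one k-means
    Lloyd iteration on neuron cells (cells left empty keep their vector).
    """
    bmu = cdist(X, codebook).argmin(axis=1)
    sigma2 = 2.0 * radius * radius
    with np.errstate(under="ignore"):
        h = np.exp(-grid_d2 / sigma2) if sigma2 > 0 else (grid_d2 == 0).astype(float)
    w = h[:, bmu]  # (n_neurons, n_samples) weight of each sample for each neuron
    denom = w.sum(axis=1)
    new = codebook.copy()
    nz = denom > 0
    new[nz] = (w[nz] @ X) / denom[nz, None]
    return new
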