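"""Geochemical ratio indices and their interpretation flags.

Classic sediment-geochemistry ratios: Na/K (weathering/salinity), Fe/Mn
(redox), Cu/Zn (pollution/redox), Ca/Mg (carbonate source) and TOC/N
(organic-matter source; values below 20 point to algal phytoplankton
rather than terrestrial plants).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["geochem_ratios", "DEFAULT_REFERENCE_MEANS", "TOC_N_ALGAL_THRESHOLD"]

#: site-level reference means the boolean flags are computed against
DEFAULT_REFERENCE_MEANS = {"Na/K": 0.12, "Fe/Mn": 60.0, "Cu/Zn": 0.27}

TOC_N_ALGAL_THRESHOLD = 20.0

_RATIOS = {
    "Na/K": ("Na", "K"),
    "Fe/Mn": ("Fe", "Mn"),
    "Cu/Zn": ("Cu", "Zn"),
    "Ca/Mg": ("Ca", "Mg"),
    "TOC/N": ("TOC", "TN"),
}


def geochem_ratios(geochem: pd.DataFrame,
                   reference_means: dict | None = None) -> pd.DataFrame:
    """Per-sample element ratios with reference and source flags.

    A zero denominator yields NaN plus a ``<ratio> undefined`` flag (never
    an exception).  For each ratio with a reference mean an
    ``<ratio> above_ref`` boolean is added; ``TOC/N`` also gets an
    ``algal_source`` flag (true when the ratio is below 20).
    """
    ref = dict(DEFAULT_REFERENCE_MEANS)
    if reference_means:
        ref.update(reference_means)
    out = pd.DataFrame(index=geochem.index)
    for name, (num, den) in _RATIOS.items():
        if num not in geochem.columns or den not in geochem.columns:
            continue
        d = geochem[den].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d != 0, geochem[num].to_numpy(dtype=float) / d, np.nan)
        out[name] = ratio
        out[f"{name} undefined"] = d == 0
        if name in ref:
            out[f"{name} above_ref"] = ratio > ref[name]
    if "TOC/N" in out.columns:
        out["algal_source"] = out["TOC/N"] < TOC_N_ALGAL_THRESHOLD
    return out
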