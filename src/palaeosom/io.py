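"""Reading, writing and validation of assemblage and environment tables.

The assemblage matrix is a samples x taxa table of integer head-capsule
counts.  Sample codes carry the sediment core symbol and the depth of the
slice: two non-digit characters (the core), an optional hyphen, and an
integer depth in cm below ground level, e.g. ``"W2-95"`` or ``"W295"``.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_assemblage",
    "write_assemblage",
    "parse_sample_code",
    "drop_empty_samples",
    "log_transform",
    "read_environment",
    "write_environment",
]

# core symbol = 2 characters, the first non-numeric ("W2", "F2", "aa");
# then an optional hyphen and the slice depth in cm
_SAMPLE_CODE_RE = re.compile(r"^([A-Za-z]\w)-?(\d+)$")

#: columns that belong to the per-sample metadata table
SAMPLE_COLUMNS = ["core_id", "depth_cm_bgl", "age_mean_AD", "age_sd", "volume_cm3"]


def parse_sample_code(code: str) -> tuple[str, int]:
    """Split a sample code into ``(core_id, depth_cm_bgl)``.

    >>> parse_sample_code("W2-95")
    ('W2', 95)
    >>> parse_sample_code("F267")
    ('F2', 67)
    """
    m = _SAMPLE_CODE_RE.match(str(code))
    if m is None:
        raise ValueError(f"malformed sample code {code!r}: expected a "
                         "2-character core symbol (first character not a "
                         "digit), optional '-', integer depth")
    return m.group(1), int(m.group(2))


def _delimiter_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def read_assemblage(path) -> pd.DataFrame:
    """Read a taxon-by-sample count table (CSV or TSV).

    First column holds sample codes, the header row taxon names.  Cells
    must be non-negative integers.  Returns a DataFrame indexed by sample
    code with one integer column per taxon.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), index_col=0)
    if df.empty and df.shape[1] == 0:
        raise ValueError(f"{path}: empty assemblage file")
    return validate_assemblage(df)


def validate_assemblage(df: pd.DataFrame) -> pd.DataFrame:
    """Check count-matrix invariants and coerce counts to integers."""
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate sample codes: {dup}")
    dup = df.columns[df.columns.duplicated()].unique().tolist()
    if dup:
        raise ValueError(f"duplicate taxon names: {dup}")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
        raise ValueError(f"non-numeric counts in columns: {list(bad)}")
    if np.any(values < 0):
        raise ValueError("negative counts in assemblage matrix")
    if not np.allclose(values, np.round(values)):
        raise ValueError("non-integer counts in assemblage matrix")
    out = df.astype(np.int64)
    out.index = out.index.astype(str)
    out.index.name = "sample_code"
    return out


def write_assemblage(df: pd.DataFrame, path) -> None:
    path = Path(path)
    df.to_csv(path, sep=_delimiter_for(path))


def drop_empty_samples(df: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Remove all-zero (barren) samples; report their codes.

    Empty slices carry no assemblage information and are excluded from the
    SOM and from indicator analysis; they reappear later as explicit barren
    zones in the stratigraphic zonation.
    """
    empty = df.sum(axis=1) == 0
    removed = df.index[empty].tolist()
    kept = df.loc[~empty]
    if kept.shape[0] == 0:
        raise ValueError("all samples are empty; nothing to analyse")
    return kept, removed


def log_transform(df: pd.DataFrame, base: str = "ln") -> pd.DataFrame:
    """Zero-safe log transform log(x + 1) of a count matrix.

    ``base`` is ``"ln"`` (default) or ``"log10"``; the SOM is invariant to
    the choice up to a uniform rescaling of the codebook.
    """
    if df.shape[0] == 0:
        raise ValueError("empty matrix")
    if base == "ln":
        return pd.DataFrame(np.log1p(df.to_numpy(dtype=float)),
                            index=df.index, columns=df.columns)
    if base == "log10":
        return pd.DataFrame(np.log10(df.to_numpy(dtype=float) + 1.0),
                            index=df.index, columns=df.columns)
    raise ValueError(f"unknown log base {base!r}")


#: geochemistry columns recognised in environment tables (units in header
#: comments of the written CSV: OM %, pH unitless, TOC/TN %, Na..Pb mg/g
#: or ug/g as produced upstream, grain-size fractions %)
GEOCHEM_COLUMNS = [
    "OM_percent", "pH", "TOC", "TN",
    "Na", "K", "Ca", "Mg", "Fe", "Mn", "Cu", "Zn", "Pb",
    "sand_percent", "silt_percent", "clay_percent",
]


def read_environment(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the joint sample-metadata + geochemistry CSV.

    Returns ``(sample_table, geochem_table)``, both indexed by sample code.
    The sample table carries core id, depth, modelled age mean and 1-sigma,
    and sample volume; the geochemistry table whatever recognised columns
    the file provides.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_delimiter_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "sample_code"
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing sample columns {missing}")
    sample = df[SAMPLE_COLUMNS].copy()
    if (sample["volume_cm3"] <= 0).any():
        bad = sample.index[sample["volume_cm3"] <= 0].tolist()
        raise ValueError(f"non-positive sample volume for {bad}")
    geo_cols = [c for c in GEOCHEM_COLUMNS if c in df.columns]
    geochem = df[geo_cols].copy()
    if "pH" in geochem and ((geochem["pH"] <= 0) | (geochem["pH"] >= 14)).any():
        bad = geochem.index[(geochem["pH"] <= 0) | (geochem["pH"] >= 14)].tolist()
        raise ValueError(f"pH outside (0, 14) for {bad}")
    for code in sample.index:
        parse_sample_code(code)
    return sample, geochem


def write_environment(sample: pd.DataFrame, geochem: pd.DataFrame, path) -> None:
    pd.concat([sample, geochem], axis=1).to_csv(Path(path))


def match_samples(matrix: pd.DataFrame, sample: pd.DataFrame) -> dict[str, list[str]]:
    """Report sample codes present on one side only (orphans)."""
    a, b = set(matrix.index), set(sample.index)
    return {"matrix_only": sorted(a - b), "environment_only": sorted(b - a)}
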