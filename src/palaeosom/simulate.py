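"""Synthetic multi-core stratigraphic assemblage generator with known truth.

Real subfossil head-capsule tables of this kind are rarely deposited, so
every downstream stage of the pipeline (SOM clustering, indicator-value
analysis, CCA, count modelling) is exercised here against data with planted
ecological states.  The generator emulates the study design the pipeline is
aimed at: a handful of sediment cores sampled in contiguous 2-4 cm slices,
~100 taxa, 50-100 head capsules per non-empty slice, a minority of barren
slices, four ecological states ordered from unfavourable to favourable
(increasing taxon richness), indicator taxa of varying specificity and
fidelity, and geochemical covariates correlated with state.

Count model: per non-empty sample the total head-capsule count is drawn
uniformly from ``total_count_range`` (fixed counting effort) and allocated
multinomially by the sample's state profile, optionally with
Dirichlet-multinomial overdispersion.  Fidelity acts as the per-sample
presence probability of an indicator taxon inside its own state;
specificity as the fraction of the taxon's expected abundance mass inside
its state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TruthProfiles",
    "CoreSpec",
    "CoreLayout",
    "generate_truth_profiles",
    "generate_dataset",
    "inject_empty_samples",
    "default_layout",
    "default_scenario",
    "layout_from_config",
]


@dataclass
class TruthProfiles:
    """Planted per-state taxon profiles.

    state_mean_abundance has one row per state (rows sum to 1); the
    indicator_assignment entry for a taxon is ``None`` or a
    ``(state, specificity, fidelity)`` triple with both knobs in [0, 1].
    """

    n_states: int
    n_taxa: int
    state_mean_abundance: np.ndarray
    indicator_assignment: list
    taxon_names: list

    def __post_init__(self):
        rows = self.state_mean_abundance.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("state_mean_abundance rows must sum to 1")

    @property
    def indicator_taxa(self) -> list[int]:
        return [i for i, a in enumerate(self.indicator_assignment) if a is not None]


@dataclass
class CoreSpec:
    core_id: str
    n_samples: int
    state_runs: list  # [(state, n_samples)] listed from the core top downward
    depth_step_cm: int = 2
    depth_top_cm: int = 21
    age_at_top_AD: float = 1900.0
    years_per_cm: float = 4.0
    age_noise_sd: float = 8.0
    age_sd_years: float = 15.0

    def __post_init__(self):
        if sum(n for _, n in self.state_runs) != self.n_samples:
            raise ValueError(f"core {self.core_id}: state runs must cover "
                             f"{self.n_samples} samples")

    def depths(self) -> np.ndarray:
        return self.depth_top_cm + self.depth_step_cm * np.arange(self.n_samples)

    def states(self) -> np.ndarray:
        return np.concatenate([np.full(n, s, dtype=int) for s, n in self.state_runs])


@dataclass
class CoreLayout:
    cores: list
    empty_fraction: float = 0.0
    total_count_range: tuple = (50, 100)
    volume_range_cm3: tuple = (5.0, 70.0)
    overdispersion: float | None = None  # Dirichlet concentration; None = pure multinomial

    def __post_init__(self):
        if not 0.0 <= self.empty_fraction < 1.0:
            raise ValueError("empty_fraction must be in [0, 1)")
        lo, hi = self.volume_range_cm3
        if lo < 5.0 or hi > 70.0:
            raise ValueError("volume_range_cm3 must lie within [5, 70]")

    @property
    def n_states(self) -> int:
        return int(max(max(s for s, _ in c.state_runs) for c in self.cores)) + 1


def generate_truth_profiles(n_states: int = 4, n_taxa: int = 97,
                            indicator_fraction: float = 0.57, seed: int = 0,
                            specificity_range: tuple = (0.8, 1.0),
                            fidelity_range: tuple = (0.8, 1.0)) -> TruthProfiles:
    """Draw per-state taxon profiles with a planted indicator structure.

    ``round(indicator_fraction * n_taxa)`` taxa become indicators.  The
    first (least favourable) state receives none; later states receive
    proportionally more, reproducing a rising richness gradient.  Remaining
    taxa get diffuse profiles, with the fraction of taxa active in a state
    also increasing along the state order.
    """
    if not 0.0 <= indicator_fraction <= 1.0:
        raise ValueError("indicator_fraction must be in [0, 1]")
    if n_states < 2:
        raise ValueError("need at least 2 states")
    if n_taxa < n_states:
        raise ValueError("need n_taxa >= n_states")
    rng = np.random.default_rng(seed)

    n_ind = int(round(indicator_fraction * n_taxa))
    # state weights 0, 1, 2, ... : no indicator for the harshest state
    w = np.arange(n_states, dtype=float)
    if n_ind > 0 and n_states > 1:
        per_state = np.floor(w / w.sum() * n_ind).astype(int)
        # distribute the remainder to the most favourable states
        for k in range(n_ind - per_state.sum()):
            per_state[n_states - 1 - (k % (n_states - 1))] += 1
    else:
        per_state = np.zeros(n_states, dtype=int)

    indicator_assignment: list = [None] * n_taxa
    ind_ids = rng.permutation(n_taxa)[:n_ind]
    pos = 0
    for s in range(n_states):
        for _ in range(per_state[s]):
            i = int(ind_ids[pos]); pos += 1
            a = float(rng.uniform(*specificity_range))
            f = float(rng.uniform(*fidelity_range))
            indicator_assignment[i] = (s, a, f)

    # diffuse (non-indicator) taxa keep a state-constant expected share, so
    # they stay near the indicator null; each state's indicator group gets
    # the same total mass, keeping row totals comparable across states
    magnitude = rng.lognormal(mean=0.0, sigma=1.0, size=n_taxa)
    M = np.zeros((n_states, n_taxa))
    group_total = magnitude.mean() * max(n_ind, 1) / max(
        int((per_state > 0).sum()), 1)
    for s in range(n_states):
        ids = [i for i, a in enumerate(indicator_assignment)
               if a is not None and a[0] == s]
        scale = group_total / magnitude[ids].sum() if ids else 1.0
        for i in ids:
            _s, a, _f = indicator_assignment[i]
            share = np.full(n_states, (1.0 - a) / (n_states - 1))
            share[s] = a
            M[:, i] = scale * magnitude[i] * share
    for i in range(n_taxa):
        if indicator_assignment[i] is None:
            M[:, i] = magnitude[i]
    M /= M.sum(axis=1, keepdims=True)

    names = [f"taxon_{i:03d}" for i in range(n_taxa)]
    return TruthProfiles(n_states, n_taxa, M, indicator_assignment, names)


def _sample_counts(rng, profile, total, profiles, state, overdispersion):
    """One multinomial draw with fidelity dropout and optional overdispersion."""
    p = profile.copy()
    for i, assign in enumerate(profiles.indicator_assignment):
        if assign is None:
            continue
        s, _a, f = assign
        if s == state and rng.random() > f:
            p[i] = 0.0
    tot = p.sum()
    if tot <= 0:
        return np.zeros_like(p, dtype=np.int64)
    p /= tot
    if overdispersion is not None:
        nz = p > 0
        alpha = overdispersion * p[nz]
        draw = rng.dirichlet(alpha)
        p = np.zeros_like(p)
        p[nz] = draw
    return rng.multinomial(total, p)


def generate_dataset(profiles: TruthProfiles, layout: CoreLayout, seed: int = 0):
    """Generate one full scenario.

    Returns ``(matrix, sample_table, geochem, truth)``: the integer
    assemblage matrix, the per-sample metadata table, the geochemistry
    table and the truth labels (true state, is_empty).  Reproducible for a
    fixed seed.
    """
    if layout.n_states > profiles.n_states:
        raise ValueError("layout references more states than the profiles define")
    rng = np.random.default_rng(seed)
    lo, hi = layout.total_count_range

    codes, cores, depths, states = [], [], [], []
    for core in layout.cores:
        d = core.depths()
        st = core.states()
        for depth, s in zip(d, st):
            codes.append(f"{core.core_id}-{int(depth)}")
            cores.append(core.core_id)
            depths.append(int(depth))
            states.append(int(s))
    n = len(codes)

    counts = np.zeros((n, profiles.n_taxa), dtype=np.int64)
    for k in range(n):
        total = int(rng.integers(lo, hi + 1))
        counts[k] = _sample_counts(rng, profiles.state_mean_abundance[states[k]],
                                   total, profiles, states[k], layout.overdispersion)
    matrix = pd.DataFrame(counts, index=pd.Index(codes, name="sample_code"),
                          columns=profiles.taxon_names)

    rows = []
    for core in layout.cores:
        d = core.depths().astype(float)
        age = core.age_at_top_AD - (d - core.depth_top_cm) * core.years_per_cm
        age = age + rng.normal(0.0, core.age_noise_sd, size=len(d))
        vol = rng.uniform(*layout.volume_range_cm3, size=len(d))
        for j in range(core.n_samples):
            rows.append((core.core_id, int(d[j]), float(age[j]),
                         core.age_sd_years, float(vol[j])))
    sample = pd.DataFrame(rows, index=matrix.index,
                          columns=["core_id", "depth_cm_bgl", "age_mean_AD",
                                   "age_sd", "volume_cm3"])

    geochem = _draw_geochem(rng, np.asarray(states), profiles.n_states, matrix.index)

    truth = pd.DataFrame({"state": states, "is_empty": False}, index=matrix.index)
    if layout.empty_fraction > 0:
        matrix, truth = inject_empty_samples(matrix, truth, layout.empty_fraction,
                                             seed=int(rng.integers(2**31)))
    return matrix, sample, geochem, truth


# state-conditional geochemistry means, states ordered unfavourable->favourable.
# Na tracks K and Mg tracks Ca (built-in collinearity for the screening step);
# Mn tracks Fe/60 and Zn tracks Cu/0.27 so the classic redox/pollution ratio
# indices sit near their reference means.
_GEO_MEANS = {
    "pH":         ([4.6, 6.6, 7.3, 7.8], 0.7),
    "OM_percent": ([12.0, 59.9, 35.0, 22.0], 14.0),
    "Ca":         ([2.0, 6.0, 14.0, 24.0], 5.0),
    "Pb":         ([120.0, 60.0, 32.0, 15.0], 25.0),
    "Fe":         ([9.0, 14.0, 24.0, 38.0], 8.0),
    "Cu":         ([18.0, 30.0, 48.0, 75.0], 16.0),
    "K":          ([0.3, 0.8, 1.3, 1.9], 0.4),
}


def _draw_geochem(rng, states, n_states, index):
    n = len(states)
    geo = {}
    for col, (means, sd) in _GEO_MEANS.items():
        m = np.asarray(means, dtype=float)
        if n_states != 4:  # interpolate the 4-point gradient onto n_states
            m = np.interp(np.linspace(0, 3, n_states), np.arange(4), m)
        geo[col] = rng.normal(m[states], sd)
    geo["pH"] = np.clip(geo["pH"], 3.0, 10.0)
    geo["OM_percent"] = np.clip(geo["OM_percent"], 0.0, 100.0)
    geo["Na"] = np.maximum(0.12 * geo["K"] + rng.normal(0, 0.012, n), 0.0)
    geo["Mg"] = np.maximum(0.35 * geo["Ca"] + rng.normal(0, 0.4, n), 0.0)
    geo["Mn"] = np.maximum(geo["Fe"] / 60.0 + rng.normal(0, 0.15, n), 1e-3)
    geo["Zn"] = np.maximum(geo["Cu"] / 0.27 + rng.normal(0, 70.0, n), 1.0)
    geo["TOC"] = np.clip(0.5 * geo["OM_percent"] + rng.normal(0, 1.0, n), 0.1, 100.0)
    # telmatic states keep a high (terrestrial-plant) TOC/N, limnetic a low one
    cn = np.where(states >= n_states // 2, 14.0, 26.0) + rng.normal(0, 1.5, n)
    geo["TN"] = geo["TOC"] / np.maximum(cn, 5.0)
    clay = np.clip(rng.normal(2.0 + states.astype(float), 0.8), 0.0, 100.0)
    sand = np.clip(rng.normal(60.0 - 12.0 * states, 6.0), 0.0, 100.0)
    silt = np.clip(100.0 - clay - sand, 0.0, 100.0)
    geo["sand_percent"], geo["silt_percent"], geo["clay_percent"] = sand, silt, clay
    for col in ("Ca", "Pb", "Fe", "Cu", "K"):
        geo[col] = np.maximum(geo[col], 0.0)
    cols = ["OM_percent", "pH", "TOC", "TN", "Na", "K", "Ca", "Mg", "Fe", "Mn",
            "Cu", "Zn", "Pb", "sand_percent", "silt_percent", "clay_percent"]
    return pd.DataFrame({c: geo[c] for c in cols}, index=index)


def inject_empty_samples(matrix: pd.DataFrame, truth: pd.DataFrame,
                         fraction: float, seed: int = 0):
    """Zero out exactly ``floor(fraction * n)`` rows, flagging them as empty."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must be in [0, 1)")
    matrix = matrix.copy()
    truth = truth.copy()
    n_zero = int(np.floor(fraction * matrix.shape[0]))
    if n_zero == 0:
        return matrix, truth
    rng = np.random.default_rng(seed)
    chosen = rng.choice(matrix.shape[0], size=n_zero, replace=False)
    matrix.iloc[chosen] = 0
    truth.iloc[chosen, truth.columns.get_loc("is_empty")] = True
    return matrix, truth


def default_layout(empty_fraction: float = 0.21) -> CoreLayout:
    """The study-scale layout: 4 cores, 100 slices, 21% barren by default."""
    cores = [
        CoreSpec("W2", 30, [(0, 5), (1, 9), (0, 3), (3, 13)],
                 depth_step_cm=2, depth_top_cm=51, age_at_top_AD=1890.0),
        CoreSpec("W4", 25, [(0, 4), (1, 5), (2, 8), (0, 3), (2, 5)],
                 depth_step_cm=2, depth_top_cm=55, age_at_top_AD=1880.0),
        CoreSpec("W1", 25, [(2, 1), (3, 2), (0, 17), (1, 5)],
                 depth_step_cm=2, depth_top_cm=21, age_at_top_AD=1870.0,
                 years_per_cm=10.0),
        CoreSpec("F2", 20, [(0, 20)],
                 depth_step_cm=4, depth_top_cm=39, age_at_top_AD=1930.0),
    ]
    return CoreLayout(cores=cores, empty_fraction=empty_fraction)


def default_scenario(seed: int = 0, empty_fraction: float = 0.21, **profile_kw):
    """Profiles + layout + dataset for the emulated study conditions."""
    profiles = generate_truth_profiles(seed=seed, **profile_kw)
    layout = default_layout(empty_fraction=empty_fraction)
    return profiles, layout, generate_dataset(profiles, layout, seed=seed)


def layout_from_config(cfg: dict) -> CoreLayout:
    """Build a CoreLayout from a plain dict (YAML scenario file)."""
    cores = [CoreSpec(core_id=c["core_id"], n_samples=c["n_samples"],
                      state_runs=[tuple(r) for r in c["state_runs"]],
                      **{k: c[k] for k in ("depth_step_cm", "depth_top_cm",
                                           "age_at_top_AD", "years_per_cm",
                                           "age_noise_sd", "age_sd_years")
                         if k in c})
             for c in cfg["cores"]]
    kw = {k: cfg[k] for k in ("empty_fraction", "overdispersion") if k in cfg}
    if "total_count_range" in cfg:
        kw["total_count_range"] = tuple(cfg["total_count_range"])
    if "volume_range_cm3" in cfg:
        kw["volume_range_cm3"] = tuple(cfg["volume_range_cm3"])
    return CoreLayout(cores=cores, **kw)
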