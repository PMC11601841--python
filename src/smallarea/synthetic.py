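"""Synthetic registry data with known spatial risk structure.

Real registry tables (events and person-years per area x age x year x
sex x race x site x outcome) cannot be shipped, so this module generates
them: a ground-truth risk surface is drawn from the same model family the
sampler fits (log-linear age baseline + intrinsic-CAR spatial effect +
random-walk year effect + additive stratum offsets), person-years are
synthesized with a realistic skewed size distribution, and event counts are
Poisson draws against that surface.  Because the truth is retained,
parameter-recovery and coverage tests downstream are well-posed.

All randomness flows from one integer seed through named substreams
(:func:`stream`), so every fixture is bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geography import AreaGraph

OUTCOMES = ("incidence", "late_stage", "mortality")

REGISTRY_COLUMNS = [
    "area_id",
    "age_group",
    "year",
    "sex",
    "race",
    "site",
    "outcome",
    "events",
    "person_years",
]


def stream(seed: int, *names) -> np.random.Generator:
    """Named substream of the master seed.

    Each name is hashed (CRC-32) into the SeedSequence spawn key, so
    ``stream(seed, "counts", "incidence")`` is a stable, independent stream
    regardless of how many other streams are drawn from.
    """
    key = tuple(zlib.crc32(str(n).encode()) for n in names)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic registry.

    Defaults describe the standard fixture: a 10x10 lattice of 100 areas,
    4 age groups, 2 sexes, 2 race groups, 5 years, with annual baseline
    incidence rising steeply with age (20 to 600 per 100,000 person-years,
    the shape typical of adult solid tumours) and moderate spatial
    heterogeneity (marginal SD 0.3 on the log-rate scale).
    """

    age_groups: tuple[str, ...] = ("0-29", "30-49", "50-69", "70+")
    age_shares: tuple[float, ...] = (0.35, 0.25, 0.25, 0.15)
    age_baseline_per_100k: tuple[float, ...] = (20.0, 60.0, 200.0, 600.0)
    years: tuple[int, ...] = (2015, 2016, 2017, 2018, 2019)
    sexes: tuple[str, ...] = ("male", "female")
    sex_shares: tuple[float, ...] = (0.5, 0.5)
    races: tuple[str, ...] = ("White", "Black")
    race_shares: tuple[float, ...] = (0.85, 0.15)
    site: str = "colorectal"
    spatial_sd: float = 0.3
    temporal_sd: float = 0.05
    # additive log-rate offsets; keys are (sex, race) pairs, missing -> 0
    stratum_offsets: dict = field(
        default_factory=lambda: {
            ("male", "White"): 0.10,
            ("male", "Black"): 0.25,
            ("female", "White"): -0.10,
            ("female", "Black"): 0.05,
        }
    )
    pop_range: tuple[float, float] = (500.0, 50000.0)
    pop_drift: float = 0.0  # multiplicative per-year growth rate
    stage_fraction: float = 0.35  # share of incident cases diagnosed late-stage
    mortality_ratio: float = 0.4  # mortality rate relative to incidence
    overdispersion_sd: float = 0.0  # lognormal multiplier SD (misspecification switch)

    def __post_init__(self) -> None:
        if len(self.age_shares) != len(self.age_groups):
            raise ValueError("age_shares must align with age_groups")
        if abs(sum(self.age_shares) - 1.0) > 1e-9:
            raise ValueError("age_shares must sum to 1 within 1e-9")
        if abs(sum(self.sex_shares) - 1.0) > 1e-9:
            raise ValueError("sex_shares must sum to 1 within 1e-9")
        if abs(sum(self.race_shares) - 1.0) > 1e-9:
            raise ValueError("race_shares must sum to 1 within 1e-9")
        if self.spatial_sd < 0 or self.temporal_sd < 0:
            raise ValueError("spatial_sd and temporal_sd must be >= 0")
        if not (0.0 <= self.stage_fraction <= 1.0):
            raise ValueError("stage_fraction must lie in [0, 1]")

    @property
    def baseline_log_rate(self) -> np.ndarray:
        return np.log(np.asarray(self.age_baseline_per_100k) / 1e5)


# ---------------------------------------------------------------------------
# truth surface


@dataclass
class TruthSurface:
    """Ground-truth latent parameters of the generating process."""

    baseline_log_rate: np.ndarray  # per age group
    spatial_effect: np.ndarray  # per area, sums to 0 within each component
    temporal_effect: np.ndarray  # per year, sums to 0
    stratum_offsets: dict  # (sex, race) -> additive log-rate offset
    seed: int

    def cell_log_rate(self, area: int, age: int, year_idx: int, sex: str, race: str) -> float:
        return (
            float(self.baseline_log_rate[age])
            + float(self.spatial_effect[area])
            + float(self.temporal_effect[year_idx])
            + float(self.stratum_offsets.get((sex, race), 0.0))
        )


def icar_marginal_scale(graph: AreaGraph) -> np.ndarray:
    """Per-area marginal SD of the unit-precision intrinsic CAR, via the
    pseudo-inverse eigen-structure of the graph Laplacian (components with a
    single area get scale 0)."""
    n = graph.n_areas
    lap = np.zeros((n, n))
    for i, j in graph.edges:
        lap[i, i] += 1.0
        lap[j, j] += 1.0
        lap[i, j] -= 1.0
        lap[j, i] -= 1.0
    evals, evecs = np.linalg.eigh(lap)
    pos = evals > 1e-10
    if not pos.any():
        return np.zeros(n)
    var = (evecs[:, pos] ** 2 / evals[pos]).sum(axis=1)
    return np.sqrt(var)


def draw_icar(graph: AreaGraph, sd: float, rng: np.random.Generator) -> np.ndarray:
    """One draw from the intrinsic CAR on ``graph``, centered per component and
    rescaled so the average theoretical marginal SD equals ``sd``."""
    n = graph.n_areas
    if sd == 0.0 or n == 1:
        return np.zeros(n)
    lap = np.zeros((n, n))
    for i, j in graph.edges:
        lap[i, i] += 1.0
        lap[j, j] += 1.0
        lap[i, j] -= 1.0
        lap[j, i] -= 1.0
    evals, evecs = np.linalg.eigh(lap)
    pos = evals > 1e-10
    if not pos.any():
        return np.zeros(n)
    z = rng.standard_normal(int(pos.sum()))
    x = evecs[:, pos] @ (z / np.sqrt(evals[pos]))
    for comp in graph.components:
        x[comp] -= x[comp].mean()
    ref = np.sqrt(np.mean((evecs[:, pos] ** 2 / evals[pos]).sum(axis=1)))
    if ref > 0:
        x *= sd / ref
    return x


def simulate_truth(graph: AreaGraph, config: SimulationConfig, seed: int) -> TruthSurface:
    """Draw a ground-truth surface: ICAR spatial field + centered random-walk
    year effect + the configured age baseline and stratum offsets."""
    if config.spatial_sd < 0 or config.temporal_sd < 0:
        raise ValueError("SDs must be non-negative")
    spatial = draw_icar(graph, config.spatial_sd, stream(seed, "truth", "spatial"))
    t = len(config.years)
    if config.temporal_sd > 0 and t > 1:
        steps = stream(seed, "truth", "temporal").standard_normal(t - 1) * config.temporal_sd
        gamma = np.concatenate([[0.0], np.cumsum(steps)])
        gamma -= gamma.mean()
    else:
        gamma = np.zeros(t)
    return TruthSurface(
        baseline_log_rate=config.baseline_log_rate.copy(),
        spatial_effect=spatial,
        temporal_effect=gamma,
        stratum_offsets=dict(config.stratum_offsets),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# populations and counts


def synthetic_populations(graph: AreaGraph, config: SimulationConfig, seed: int) -> pd.DataFrame:
    """Person-years per (area, age, year, sex, race) cell.

    Per-area annual totals are drawn log-uniformly over ``config.pop_range``
    (registry area sizes are strongly right-skewed), split across age, sex
    and race by the configured shares, and held constant over years unless a
    drift rate is configured.
    """
    lo, hi = config.pop_range
    if lo <= 0 or hi < lo:
        raise ValueError("pop_range must satisfy 0 < lo <= hi")
    rng = stream(seed, "populations")
    totals = np.exp(rng.uniform(np.log(lo), np.log(hi), size=graph.n_areas))
    rows = []
    for i, aid in enumerate(graph.area_ids):
        for ia, age in enumerate(config.age_groups):
            for iy, year in enumerate(config.years):
                growth = (1.0 + config.pop_drift) ** iy
                for isx, sex in enumerate(config.sexes):
                    for ir, race in enumerate(config.races):
                        py = (
                            totals[i]
                            * config.age_shares[ia]
                            * config.sex_shares[isx]
                            * config.race_shares[ir]
                            * growth
                        )
                        rows.append((aid, age, year, sex, race, py))
    return pd.DataFrame(
        rows, columns=["area_id", "age_group", "year", "sex", "race", "person_years"]
    )


@dataclass
class RegistryTable:
    """Registry-style cell counts: events and person-years per
    area x age x year x sex x race x site x outcome."""

    cells: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.cells
        missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"registry table missing columns: {missing}")
        self.cells = df = df[REGISTRY_COLUMNS].reset_index(drop=True)
        if (df["events"] < 0).any():
            raise ValueError("events must be >= 0")
        if (df["person_years"] < 0).any():
            raise ValueError("person_years must be >= 0")
        if ((df["person_years"] == 0) & (df["events"] > 0)).any():
            raise ValueError("events must be 0 wherever person_years is 0")
        keys = df[REGISTRY_COLUMNS[:7]]
        if keys.duplicated().any():
            raise ValueError("duplicate (area, age, year, sex, race, site, outcome) keys")
        wide = df.pivot_table(
            index=["area_id", "age_group", "year", "sex", "race", "site"],
            columns="outcome",
            values="events",
            aggfunc="sum",
        )
        if "late_stage" in wide.columns and "incidence" in wide.columns:
            both = wide.dropna(subset=["late_stage", "incidence"])
            if (both["late_stage"] > both["incidence"]).any():
                raise ValueError("late_stage events exceed incidence events in some cells")

    def query(
        self,
        site: str,
        outcome: str,
        sex: str = "all",
        race: str = "all",
        years=None,
    ) -> pd.DataFrame:
        """Restrict to one (site, outcome, stratum) slice; ``"all"`` strata are
        aggregated by summing events and person-years."""
        df = self.cells
        df = df[(df["site"] == site) & (df["outcome"] == outcome)]
        if sex != "all":
            df = df[df["sex"] == sex]
        if race != "all":
            df = df[df["race"] == race]
        if years is not None:
            df = df[df["year"].isin(list(years))]
        grouped = (
            df.groupby(["area_id", "age_group", "year"], as_index=False)[
                ["events", "person_years"]
            ].sum()
        )
        return grouped


def simulate_counts(
    truth: TruthSurface,
    populations: pd.DataFrame,
    config: SimulationConfig,
    graph: AreaGraph,
    seed: int,
) -> RegistryTable:
    """Poisson event counts against the truth surface, for all three outcomes.

    incidence ~ Poisson(py * rate); late_stage by binomial thinning of
    incidence with ``config.stage_fraction``; mortality ~ Poisson with the
    incidence rate scaled by ``config.mortality_ratio``.  An optional
    lognormal overdispersion multiplier (mean 1) mis-specifies the Poisson
    assumption for robustness tests.
    """
    if (populations["person_years"] < 0).any():
        raise ValueError("person_years must be >= 0")
    area_idx = {a: i for i, a in enumerate(graph.area_ids)}
    age_idx = {a: i for i, a in enumerate(config.age_groups)}
    year_idx = {y: i for i, y in enumerate(config.years)}
    pop = populations
    log_rate = (
        truth.baseline_log_rate[pop["age_group"].map(age_idx).to_numpy()]
        + truth.spatial_effect[pop["area_id"].map(area_idx).to_numpy()]
        + truth.temporal_effect[pop["year"].map(year_idx).to_numpy()]
        + np.array(
            [
                truth.stratum_offsets.get((s, r), 0.0)
                for s, r in zip(pop["sex"], pop["race"])
            ]
        )
    )
    rate = np.exp(log_rate)
    if config.overdispersion_sd > 0:
        od_rng = stream(seed, "counts", "overdispersion")
        mult = np.exp(
            od_rng.standard_normal(len(pop)) * config.overdispersion_sd
            - 0.5 * config.overdispersion_sd**2
        )
        rate = rate * mult
    py = pop["person_years"].to_numpy()
    inc_rng = stream(seed, "counts", "incidence")
    incidence = inc_rng.poisson(py * rate)
    stage_rng = stream(seed, "counts", "late_stage")
    late = stage_rng.binomial(incidence, config.stage_fraction)
    mort_rng = stream(seed, "counts", "mortality")
    mortality = mort_rng.poisson(py * rate * config.mortality_ratio)
    frames = []
    for outcome, events in (
        ("incidence", incidence),
        ("late_stage", late),
        ("mortality", mortality),
    ):
        f = pop[["area_id", "age_group", "year", "sex", "race"]].copy()
        f["site"] = config.site
        f["outcome"] = outcome
        f["events"] = events
        f["person_years"] = py
        frames.append(f)
    return RegistryTable(pd.concat(frames, ignore_index=True))


def simulate_registry(
    graph: AreaGraph, config: SimulationConfig, seed: int
) -> tuple[RegistryTable, TruthSurface, pd.DataFrame]:
    """Convenience: truth + populations + counts in one call."""
    truth = simulate_truth(graph, config, seed)
    pops = synthetic_populations(graph, config, seed)
    table = simulate_counts(truth, pops, config, graph, seed)
    return table, truth, pops


def true_age_adjusted_rates(
    truth: TruthSurface,
    populations: pd.DataFrame,
    config: SimulationConfig,
    graph: AreaGraph,
    std_weights: np.ndarray,
    year: int | None = None,
) -> np.ndarray:
    """Ground-truth age-adjusted rate per 100,000 for each area.

    For the all-strata aggregate, the true age-specific rate of a cell is the
    person-years-weighted mixture of the stratum rates; ``year=None`` sets
    the year effect to zero (the year-collapsed reference).
    """
    age_idx = {a: i for i, a in enumerate(config.age_groups)}
    gamma = 0.0 if year is None else float(truth.temporal_effect[list(config.years).index(year)])
    rates = np.zeros((graph.n_areas, len(config.age_groups)))
    pys = np.zeros_like(rates)
    pop = populations[populations["year"] == (config.years[0] if year is None else year)]
    aidx = {a: i for i, a in enumerate(graph.area_ids)}
    for row in pop.itertuples(index=False):
        i, a = aidx[row.area_id], age_idx[row.age_group]
        r = np.exp(
            truth.baseline_log_rate[a]
            + truth.spatial_effect[i]
            + gamma
            + truth.stratum_offsets.get((row.sex, row.race), 0.0)
        )
        rates[i, a] += row.person_years * r
        pys[i, a] += row.person_years
    with np.errstate(invalid="ignore"):
        agespec = np.where(pys > 0, rates / np.maximum(pys, 1e-300), 0.0)
    return 1e5 * agespec @ np.asarray(std_weights)


# ---------------------------------------------------------------------------
# I/O


def write_registry(table: RegistryTable, path) -> None:
    """Delimited text with the exact column set of the registry schema."""
    table.cells.to_csv(path, index=False, columns=REGISTRY_COLUMNS)


def read_registry(path) -> RegistryTable:
    df = pd.read_csv(path)
    return RegistryTable(df)


def write_truth(truth: TruthSurface, graph: AreaGraph, config: SimulationConfig, path) -> None:
    """Key-value sidecar of the ground-truth surface, for test oracles."""
    with open(path, "w") as fh:
        fh.write(f"seed={truth.seed}\n")
        for age, b in zip(config.age_groups, truth.baseline_log_rate):
            fh.write(f"baseline_log_rate.{age}={b!r}\n")
        for aid, u in zip(graph.area_ids, truth.spatial_effect):
            fh.write(f"spatial_effect.{aid}={u!r}\n")
        for year, g in zip(config.years, truth.temporal_effect):
            fh.write(f"temporal_effect.{year}={g!r}\n")
        for (sex, race), off in sorted(truth.stratum_offsets.items()):
            fh.write(f"stratum_offset.{sex}.{race}={off!r}\n")
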