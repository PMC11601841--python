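"""Published measures derived from the posterior: age-adjusted rates, risk
(exceedance) probabilities, hotspot flags, uncertainty classes, and
suppression-aware raw comparisons.

Rates are directly age-standardized: with standard-population weights
``w_a`` (summing to 1) and age-specific rates ``r_a``, the adjusted rate is
``scale * sum_a w_a r_a`` with ``scale = 100,000`` person-years.  The risk
probability of an area is the posterior probability that its adjusted rate
exceeds the state reference — the person-years-weighted state average of the
same quantity — so a value of 0.95 means a high probability that the area's
cancer burden is greater than the overall state's.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geography import AreaGraph
from .model import PosteriorDraws

logger = logging.getLogger(__name__)

RATE_SCALE = 1e5  # standardized rates are per 100,000 person-years

SUPPRESSION_THRESHOLD = 16  # default minimum event count for a raw rate
HOTSPOT_FRACTION = 0.10  # hotspot = top decile of area rates


def _expand(prefix: str, lo: int, hi: int) -> tuple[str, ...]:
    return tuple(f"{prefix}{k}" for k in range(lo, hi + 1))


#: The eight default cancer categories with their ICD-O-3 topography code
#: lists (WHO 2008 site recode), and the sex each site is restricted to.
SITE_CATEGORIES: dict[str, dict] = {
    "colorectal": {"codes": _expand("C", 180, 189) + ("C260",), "sex": None},
    "breast": {"codes": _expand("C", 500, 509), "sex": "female"},
    "cervical": {"codes": _expand("C", 530, 539), "sex": "female"},
    "liver": {"codes": ("C220",), "sex": None},
    "lung": {"codes": _expand("C", 340, 349), "sex": None},
    "melanoma": {"codes": _expand("C", 440, 449), "sex": None},
    "prostate": {"codes": ("C619",), "sex": "male"},
    "non_hodgkin_lymphoma": {
        "codes": ("C024", "C098", "C099", "C111", "C142", "C379", "C422")
        + _expand("C", 770, 779),
        "sex": None,
    },
}

OUTCOMES = ("incidence", "late_stage", "mortality")


@dataclass(frozen=True)
class StandardPopulation:
    """Fixed age-weight vector for direct standardization."""

    weights: tuple[float, ...]
    name: str = "custom"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if (w < 0).any():
            raise ValueError("standard-population weights must be >= 0")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("standard-population weights must sum to 1 within 1e-9")

    @property
    def w(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


#: Flat fixture default for the 4-age-group synthetic registry.
FLAT_4 = StandardPopulation((0.25, 0.25, 0.25, 0.25), name="flat-4")


@dataclass(frozen=True)
class Query:
    """Normalized (site, outcome, stratum) selection."""

    site: str
    outcome: str
    sex: str = "all"
    race: str = "all"
    years: tuple[int, ...] | None = None  # year-range query (collapses time)


def validate_query(
    site: str,
    sex: str = "all",
    race: str = "all",
    outcome: str = "incidence",
    years=None,
    mode: str = "strict",
) -> Query:
    """Check site/sex compatibility and normalize the stratum.

    Sex-restricted sites (prostate is male-only; breast and cervical are
    female-only) reject an incompatible sex in ``strict`` mode, or coerce the
    sex to the site's only valid group in ``coerce`` mode — mirroring a
    front end that hides the impossible option to avoid displaying null data.
    """
    if site not in SITE_CATEGORIES:
        raise ValueError(
            f"unknown site {site!r}; configured sites: {sorted(SITE_CATEGORIES)}"
        )
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}; one of {OUTCOMES}")
    if mode not in ("strict", "coerce"):
        raise ValueError("mode must be 'strict' or 'coerce'")
    required = SITE_CATEGORIES[site]["sex"]
    if required is not None and sex != required:
        if mode == "strict" and sex != required:
            raise ValueError(
                f"site {site!r} is restricted to sex {required!r}; "
                f"got {sex!r} — the combination would display null data"
            )
        sex = required
    return Query(site=site, outcome=outcome, sex=sex, race=race,
                 years=tuple(years) if years is not None else None)


# ---------------------------------------------------------------------------
# posterior-derived measures


def age_adjusted_rate_draws(
    draws: PosteriorDraws, std: StandardPopulation, year: int | None = None
) -> np.ndarray:
    """Per-draw, per-area age-adjusted rates, shape (n_draws, n_areas).

    ``R_i = scale * sum_a w_a exp(mu + alpha_a + u_i + v_i + gamma_t)`` with
    the year effect at the queried year, or omitted for year-collapsed fits.
    """
    if len(std.weights) != len(draws.spec.age_groups):
        raise ValueError("standard-population weights do not match the model age groups")
    log_rates = draws.log_rate_draws(year=year)  # (draws, areas, ages)
    return RATE_SCALE * np.exp(log_rates) @ std.w


def state_reference_draws(
    draws: PosteriorDraws,
    py_area_age: np.ndarray,
    std: StandardPopulation,
    year: int | None = None,
) -> np.ndarray:
    """Per-draw state reference rate, shape (n_draws,).

    The state age-specific rate is the person-years-weighted mean of the
    area age-specific rates; it is then standardized with the same weights
    and scale, so the reference equals the observable state rate in
    expectation.
    """
    py = np.asarray(py_area_age, dtype=float)
    tot = py.sum(axis=0)  # per age group
    if py.sum() <= 0:
        raise ValueError("zero total person-years: no state reference")
    rates = np.exp(draws.log_rate_draws(year=year))  # (draws, areas, ages)
    with np.errstate(invalid="ignore"):
        state_agespec = np.einsum("dia,ia->da", rates, py) / np.maximum(tot, 1e-300)
    state_agespec[:, tot == 0] = 0.0
    return RATE_SCALE * state_agespec @ std.w


def risk_probability(area_rate_draws: np.ndarray, state_rate_draws: np.ndarray) -> np.ndarray:
    """Fraction of retained draws in which each area's rate strictly exceeds
    the state reference (ties count as not exceeding)."""
    area = np.asarray(area_rate_draws)
    state = np.asarray(state_rate_draws)
    if area.shape[0] == 0:
        raise ValueError("no posterior draws")
    if area.shape[0] != state.shape[0]:
        raise ValueError("area and state draw counts differ")
    return (area > state[:, None]).mean(axis=0)


def hotspot_flags(rates: np.ndarray, fraction: float = HOTSPOT_FRACTION) -> np.ndarray:
    """Flag the top ``fraction`` of areas by rate (default: top 10%).

    The threshold is the ``ceil(fraction * N)``-th largest rate; ties at the
    threshold are all flagged.
    """
    rates = np.asarray(rates, dtype=float)
    n = len(rates)
    if n < 1:
        raise ValueError("need at least one area")
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    k = int(np.ceil(fraction * n))
    threshold = np.sort(rates)[::-1][k - 1]
    return rates >= threshold


def uncertainty_classes(rate_sds: np.ndarray) -> list[str]:
    """Tertile classification of posterior SDs into low / medium / high.

    Breaks at the 1/3 and 2/3 empirical quantiles; an SD equal to a break
    goes to the lower class.  Fewer than 3 areas cannot support a tertile
    split and are all labelled "low" (with a warning).
    """
    sds = np.asarray(rate_sds, dtype=float)
    if (sds < 0).any():
        raise ValueError("rate SDs must be >= 0")
    if len(sds) < 3:
        logger.warning("fewer than 3 areas: uncertainty tertiles degenerate to 'low'")
        return ["low"] * len(sds)
    q1, q2 = np.quantile(sds, [1 / 3, 2 / 3])
    return ["low" if s <= q1 else "medium" if s <= q2 else "high" for s in sds]


def raw_rate_with_suppression(
    events_total: int,
    person_years_total: float,
    std: StandardPopulation,
    age_specific_rates: np.ndarray,
    threshold: int = SUPPRESSION_THRESHOLD,
) -> tuple[float | None, bool]:
    """Direct age-standardized raw rate, or a suppressed marker.

    Returns ``(rate, suppressed)``: the rate is reported when the total
    event count reaches the threshold (boundary inclusive), else ``None``
    with ``suppressed=True`` — the modeled estimate remains available
    alongside, which is the point of the smoothing.
    """
    if threshold < 0:
        raise ValueError("suppression threshold must be >= 0")
    if events_total < threshold:
        return None, True
    rate = float(RATE_SCALE * np.asarray(age_specific_rates, dtype=float) @ std.w)
    return rate, False


# ---------------------------------------------------------------------------
# assembling the estimates table


def build_estimates(
    draws: PosteriorDraws,
    std: StandardPopulation,
    graph: AreaGraph,
    query_df: pd.DataFrame,
    query: Query,
    year: int | None = None,
    hotspot_fraction: float = HOTSPOT_FRACTION,
    suppression_threshold: int = SUPPRESSION_THRESHOLD,
) -> pd.DataFrame:
    """One exportable record per area: modeled rate, SD, 95% interval, risk
    probability, hotspot flag, uncertainty class, suppression-aware raw
    rate, and observed totals.

    ``query_df`` is the same (site, outcome, stratum) slice the model was
    fit to (events and person-years per area x age x year).
    """
    aidx = {a: i for i, a in enumerate(graph.area_ids)}
    gidx = {g: i for i, g in enumerate(draws.spec.age_groups)}
    I, A = graph.n_areas, len(draws.spec.age_groups)
    ev = np.zeros((I, A))
    py = np.zeros((I, A))
    np.add.at(ev, (query_df["area_id"].map(aidx), query_df["age_group"].map(gidx)),
              query_df["events"].to_numpy(dtype=float))
    np.add.at(py, (query_df["area_id"].map(aidx), query_df["age_group"].map(gidx)),
              query_df["person_years"].to_numpy(dtype=float))

    area_rates = age_adjusted_rate_draws(draws, std, year=year)
    state_rates = state_reference_draws(draws, py, std, year=year)
    rate = area_rates.mean(axis=0)
    rate_sd = area_rates.std(axis=0, ddof=1)
    ci_low, ci_high = np.percentile(area_rates, [2.5, 97.5], axis=0)
    risk = risk_probability(area_rates, state_rates)
    hot = hotspot_flags(rate, hotspot_fraction)
    unc = uncertainty_classes(rate_sd)

    with np.errstate(invalid="ignore"):
        raw_agespec = np.where(py > 0, ev / np.maximum(py, 1e-300), 0.0)
    raw_rates, suppressed = [], []
    for i in range(I):
        r, s = raw_rate_with_suppression(
            int(ev[i].sum()), float(py[i].sum()), std, raw_agespec[i], suppression_threshold
        )
        raw_rates.append(r)
        suppressed.append(s)

    return pd.DataFrame(
        {
            "area_id": graph.area_ids,
            "area_name": graph.area_names,
            "site": query.site,
            "outcome": query.outcome,
            "sex": query.sex,
            "race": query.race,
            "year": year if year is not None else "all",
            "rate": rate,
            "rate_sd": rate_sd,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "risk_prob": risk,
            "hotspot": hot,
            "uncertainty": unc,
            "raw_rate": raw_rates,
            "suppressed": suppressed,
            "events_total": ev.sum(axis=1).astype(int),
            "person_years_total": py.sum(axis=1),
        }
    )


# ---------------------------------------------------------------------------
# table filtering

_NUMERIC_FIELDS = ("rate", "risk_prob", "rate_sd", "person_years_total")
_NUM_RE = re.compile(
    r"^(?P<field>[a-z_]+)(?P<op>==|<=|>=|<|>)(?P<value>[-+0-9.eE]+)$"
)

_OPS = {
    "<": np.less,
    "<=": np.less_equal,
    ">": np.greater,
    ">=": np.greater_equal,
    "==": np.equal,
}


def filter_estimates(rows: pd.DataFrame, query: str) -> pd.DataFrame:
    """Subset the estimates table by a conjunction of clauses.

    Whitespace-separated clauses:

    - ``id=<prefix>`` — area id prefix match;
    - ``name=<substring>`` — case-insensitive area-name substring match;
    - ``<field><op><number>`` with field in {rate, risk_prob, rate_sd,
      person_years_total} and op in {<, <=, >, >=, ==}.
    """
    mask = np.ones(len(rows), dtype=bool)
    for clause in query.split():
        m = _NUM_RE.match(clause)
        if m and m.group("field") not in ("id", "name"):
            fld = m.group("field")
            if fld not in _NUMERIC_FIELDS:
                raise ValueError(
                    f"unknown field in clause {clause!r}; numeric fields: {_NUMERIC_FIELDS}"
                )
            try:
                val = float(m.group("value"))
            except ValueError:
                raise ValueError(f"malformed number in clause {clause!r}") from None
            mask &= _OPS[m.group("op")](rows[fld].to_numpy(dtype=float), val)
        elif clause.startswith("id="):
            mask &= rows["area_id"].str.startswith(clause[3:]).to_numpy()
        elif clause.startswith("name="):
            mask &= rows["area_name"].str.contains(clause[5:], case=False, regex=False).to_numpy()
        else:
            raise ValueError(f"malformed clause {clause!r}")
    return rows[mask]
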