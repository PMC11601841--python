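"""Shareable products: estimates CSV, choropleth GeoJSON with styling
metadata, class breaks, and plain-language interpretation text.

The map deliverable is data, not pixels: a GeoJSON FeatureCollection whose
features carry every estimate field plus an assigned class bin, with the
color scheme, break values and source note embedded as top-level members —
enough for any front end to render the choropleth bit-identically.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import mapping

from .geography import AreaGraph
from .estimates import Query

logger = logging.getLogger(__name__)

#: The six color-blind-friendly schemes (ColorBrewer palettes, 5-class hex
#: ramps).  Four sequential, two diverging; color values are config data.
COLOR_SCHEMES: dict[str, list[str]] = {
    "YlGnBu": ["#ffffcc", "#a1dab4", "#41b6c4", "#2c7fb8", "#253494"],
    "YlOrRd": ["#ffffb2", "#fecc5c", "#fd8d3c", "#f03b20", "#bd0026"],
    "GnBu": ["#f0f9e8", "#bae4bc", "#7bccc4", "#43a2ca", "#0868ac"],
    "BuPu": ["#edf8fb", "#b3cde3", "#8c96c6", "#8856a7", "#810f7c"],
    "PuOr": ["#e66101", "#fdb863", "#f7f7f7", "#b2abd2", "#5e3c99"],
    "BrBG": ["#a6611a", "#dfc27d", "#f5f5f5", "#80cdc1", "#018571"],
}

DEFAULT_SOURCE_NOTE = "Produced with the smallarea Bayesian small-area mapping pipeline."

CSV_COLUMNS = [
    "area_id",
    "area_name",
    "site",
    "outcome",
    "sex",
    "race",
    "year",
    "rate",
    "rate_sd",
    "ci_low",
    "ci_high",
    "risk_prob",
    "hotspot",
    "uncertainty",
    "raw_rate",
    "suppressed",
    "events_total",
    "person_years_total",
]

_RATE_FIELDS = ("rate", "rate_sd", "ci_low", "ci_high", "raw_rate", "person_years_total")


@dataclass
class MapStyle:
    """Choropleth styling: scheme, class breaks and labels, attribution.

    ``bins`` are the interior break values (k classes need k-1 breaks,
    strictly increasing); a value equal to a break belongs to the lower
    class.
    """

    scheme_name: str
    bins: list[float]
    bin_labels: list[str] = field(default_factory=list)
    source_note: str = DEFAULT_SOURCE_NOTE

    def __post_init__(self) -> None:
        if self.scheme_name not in COLOR_SCHEMES:
            raise ValueError(
                f"unknown scheme {self.scheme_name!r}; available: {sorted(COLOR_SCHEMES)}"
            )
        b = list(self.bins)
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("bins must be strictly increasing")
        if not self.bin_labels:
            self.bin_labels = _bin_labels(b)

    @property
    def colors(self) -> list[str]:
        return COLOR_SCHEMES[self.scheme_name]


def _bin_labels(breaks: list[float]) -> list[str]:
    if not breaks:
        return ["all values"]
    labels = [f"<= {breaks[0]:g}"]
    labels += [f"{a:g} - {b:g}" for a, b in zip(breaks[:-1], breaks[1:])]
    labels.append(f"> {breaks[-1]:g}")
    return labels


def classify_bins(values, method: str = "quantile", k: int = 5) -> list[float]:
    """Interior class breaks for k classes.

    ``quantile`` puts breaks at the i/k empirical quantiles (linear
    interpolation); ``equal-interval`` splits [min, max] evenly.  With fewer
    distinct values than classes, quantile mode falls back to
    equal-interval with a warning; constant input collapses to a single bin.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    vals = np.asarray(values, dtype=float)
    if len(vals) == 0:
        raise ValueError("no values to classify")
    if method not in ("quantile", "equal-interval"):
        raise ValueError(f"unknown classification method {method!r}")
    distinct = np.unique(vals)
    if len(distinct) == 1:
        return []
    if method == "quantile":
        if len(distinct) < k:
            logger.warning(
                "only %d distinct values for %d quantile classes; "
                "falling back to equal-interval",
                len(distinct),
                k,
            )
            method = "equal-interval"
        else:
            breaks = np.quantile(vals, [i / k for i in range(1, k)])
            return [float(b) for b in breaks]
    lo, hi = float(vals.min()), float(vals.max())
    step = (hi - lo) / k
    return [lo + i * step for i in range(1, k)]


def assign_bins(values, breaks: list[float]) -> np.ndarray:
    """Class index per value; a value equal to a break goes to the lower bin."""
    return np.digitize(np.asarray(values, dtype=float), np.asarray(breaks), right=True)


# ---------------------------------------------------------------------------
# value formatting shared by CSV and GeoJSON (identical written precision)


def _fmt(col: str, val):
    if col in _RATE_FIELDS:
        if val is None or (isinstance(val, float) and np.isnan(val)):
            return ""
        return f"{float(val):.1f}"
    if col == "risk_prob":
        return f"{float(val):.3f}"
    if col in ("hotspot", "suppressed"):
        return "true" if bool(val) else "false"
    if col == "events_total":
        return str(int(val))
    return str(val)


def _json_val(col: str, val):
    if col in _RATE_FIELDS:
        if val is None or (isinstance(val, float) and np.isnan(val)):
            return None
        return round(float(val), 1)
    if col == "risk_prob":
        return round(float(val), 3)
    if col in ("hotspot", "suppressed"):
        return bool(val)
    if col == "events_total":
        return int(val)
    return val


def export_csv(rows: pd.DataFrame, path) -> None:
    """RFC-4180 CSV of the estimates table.

    Header is exactly :data:`CSV_COLUMNS`; rates to 1 decimal, probabilities
    to 3 decimals; a suppressed raw rate is written as an empty field with
    ``suppressed=true``.
    """
    if len(rows) == 0:
        raise ValueError("no rows to export")
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for _, row in rows.iterrows():
            writer.writerow([_fmt(c, row[c]) for c in CSV_COLUMNS])


def export_geojson(
    rows: pd.DataFrame,
    graph: AreaGraph,
    style: MapStyle,
    path,
    value_field: str = "rate",
) -> None:
    """Choropleth GeoJSON: one Feature per estimate row with all table
    fields plus the assigned class bin; style echo and source note are
    embedded as top-level foreign members."""
    if graph.polygons is None:
        raise ValueError("graph has no polygons; cannot export a map layer")
    idx = {a: i for i, a in enumerate(graph.area_ids)}
    for aid in rows["area_id"]:
        if aid not in idx:
            raise ValueError(f"area {aid!r} missing from the geography")
    bins = assign_bins(rows[value_field].to_numpy(dtype=float), style.bins)
    features = []
    for (_, row), b in zip(rows.iterrows(), bins):
        props = {c: _json_val(c, row[c]) for c in CSV_COLUMNS}
        props["bin"] = int(b)
        features.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": mapping(graph.polygons[idx[row["area_id"]]]),
            }
        )
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "style": {
            "scheme_name": style.scheme_name,
            "colors": style.colors,
            "bins": style.bins,
            "bin_labels": style.bin_labels,
            "value_field": value_field,
        },
        "source_note": style.source_note,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def interpretation_text(row, query: Query) -> str:
    """Deterministic plain-language sentence explaining one area's estimate,
    including the high-probability clause when risk_prob >= 0.95."""
    stratum = []
    if query.sex != "all":
        stratum.append(query.sex)
    if query.race != "all":
        stratum.append(query.race)
    stratum_txt = f" among the {' '.join(stratum)} population" if stratum else ""
    year = row["year"]
    year_txt = f" in {year}" if year != "all" else ""
    text = (
        f"In {row['area_name']} ({row['area_id']}), the estimated age-adjusted "
        f"{query.site} {query.outcome.replace('_', '-')} rate{stratum_txt}{year_txt} "
        f"is {float(row['rate']):.1f} per 100,000 person-years "
        f"(95% interval {float(row['ci_low']):.1f} to {float(row['ci_high']):.1f}). "
        f"The risk probability is {float(row['risk_prob']):.3f}: the probability "
        f"that this area's rate exceeds the state average."
    )
    if float(row["risk_prob"]) >= 0.95:
        text += (
            " A value of 0.95 or higher represents a high probability of cancer "
            "burden that is greater than the overall state."
        )
    return text
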