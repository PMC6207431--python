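"""Reading, validation and aggregation of death, population and mapping tables.

Death records arrive as delimited text with one row per death or as
pre-aggregated monthly counts.  Loading maps the ICD underlying-cause code to
one of ten leaf categories, maps the state of residence to one of nine US
climate regions, and aggregates to monthly counts per stratum
(age group x sex x cause x region).

The in-memory containers are plain :class:`pandas.DataFrame` objects with
validated schemas; :class:`StratumKey` identifies one analysis stratum.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .errors import SchemaError, UnmappedCodeError

logger = logging.getLogger(__name__)

#: The ten age bands used throughout the analysis, youngest first.
AGE_GROUPS = (
    "0-4", "5-14", "15-24", "25-34", "35-44",
    "45-54", "55-64", "65-74", "75-84", "85+",
)

SEXES = ("male", "female")

#: Leaf cause-of-death categories; every ICD code maps to exactly one.
LEAF_CATEGORIES = (
    "cancers",
    "cardiovascular",
    "chronic_respiratory",
    "respiratory_infections",
    "injuries_unintentional",
    "injuries_intentional",
    "perinatal",
    "maternal",
    "substance_use",
    "other",
)

#: Derived parent categories, each the union of its leaves.
ROLLUPS = {
    "cardiorespiratory": (
        "cardiovascular", "chronic_respiratory", "respiratory_infections",
    ),
    "injuries": ("injuries_unintentional", "injuries_intentional"),
    "all_cause": LEAF_CATEGORIES,
}

REGIONS = (
    "central", "east_north_central", "northeast", "northwest", "south",
    "southeast", "southwest", "west", "west_north_central",
)

DEATH_COLUMNS = ("year", "month", "region", "age_group", "sex", "cause", "count")
POPULATION_COLUMNS = ("year", "region", "age_group", "sex", "population")


@dataclass(frozen=True)
class StratumKey:
    """One analysis stratum: an age band, sex, cause category and region.

    ``cause`` may be a leaf category, a rollup (``cardiorespiratory``,
    ``injuries``, ``all_cause``), and ``region`` is ``"national"`` or one of
    the nine climate-region ids.
    """

    age_group: str
    sex: str
    cause: str = "all_cause"
    region: str = "national"

    def __post_init__(self):
        if self.age_group not in AGE_GROUPS:
            raise SchemaError(f"unknown age group {self.age_group!r}")
        if self.sex not in SEXES:
            raise SchemaError(f"unknown sex {self.sex!r}")
        if self.cause not in LEAF_CATEGORIES and self.cause not in ROLLUPS:
            raise SchemaError(f"unknown cause category {self.cause!r}")
        if self.region != "national" and self.region not in REGIONS:
            raise SchemaError(f"unknown region {self.region!r}")


def _normalize_code(code: str) -> str:
    """Normalise an ICD code to a comparable 3-character stem.

    Dots are stripped and only the first three characters are kept; purely
    numeric ICD-9 stems are zero-padded so that lexicographic comparison
    agrees with numeric order (e.g. ``"49"`` -> ``"049"``).
    """
    stem = str(code).strip().upper().replace(".", "")[:3]
    if stem.isdigit():
        stem = stem.zfill(3)
    return stem


class CauseMap:
    """Ordered list of (revision, pattern, category) rules; first match wins.

    A pattern is a single stem (``"U04"``) or an inclusive stem range
    (``"C00-C97"``).  Ranges compare lexicographically on normalised stems,
    which matches ICD ordering within a code family.
    """

    def __init__(self, rules: list[tuple[int, str, str]]):
        parsed = []
        for revision, pattern, category in rules:
            if category not in LEAF_CATEGORIES:
                raise SchemaError(f"unknown category {category!r} in cause map")
            if "-" in pattern:
                lo, hi = pattern.split("-", 1)
                lo, hi = _normalize_code(lo), _normalize_code(hi)
            else:
                lo = hi = _normalize_code(pattern)
            if lo > hi:
                raise SchemaError(f"inverted pattern range {pattern!r}")
            parsed.append((int(revision), lo, hi, category))
        self._rules = parsed

    @classmethod
    def from_csv(cls, path) -> "CauseMap":
        df = pd.read_csv(path, dtype={"revision": int, "pattern": str, "category": str})
        missing = {"revision", "pattern", "category"} - set(df.columns)
        if missing:
            raise SchemaError(f"cause map missing columns: {sorted(missing)}")
        return cls(list(df.itertuples(index=False, name=None)))

    @classmethod
    def default(cls) -> "CauseMap":
        """The shipped mapping: GBD-style ICD chapter ranges for the ten leaves."""
        with resources.as_file(
            resources.files("seasmort.data") / "cause_map.csv"
        ) as p:
            return cls.from_csv(p)

    def lookup(self, code: str, revision: int) -> str | None:
        """Leaf category for ``code`` under ICD ``revision``; None if unmapped."""
        stem = _normalize_code(code)
        if not stem:
            return None
        for rev, lo, hi, category in self._rules:
            if rev == revision and lo <= stem <= hi:
                return category
        return None


def map_cause(code: str, revision: int, cause_map: CauseMap | None = None,
              *, strict: bool = True) -> str:
    """Map one ICD code to its leaf category.

    In strict mode an unmapped code raises :class:`UnmappedCodeError`;
    in lenient mode it is routed to ``"other"`` with a log entry.
    """
    cause_map = cause_map or CauseMap.default()
    category = cause_map.lookup(code, revision)
    if category is None:
        if strict:
            raise UnmappedCodeError([str(code)])
        logger.warning("unmapped ICD-%d code %r routed to 'other'", revision, code)
        return "other"
    return category


class RegionMap:
    """State/territory postal code -> climate-region id."""

    def __init__(self, mapping: dict[str, str]):
        bad = set(mapping.values()) - set(REGIONS)
        if bad:
            raise SchemaError(f"unknown regions in region map: {sorted(bad)}")
        self._mapping = {k.upper(): v for k, v in mapping.items()}

    @classmethod
    def default(cls) -> "RegionMap":
        with resources.as_file(
            resources.files("seasmort.data") / "region_map.csv"
        ) as p:
            df = pd.read_csv(p)
        return cls(dict(zip(df["state"], df["region"])))

    def lookup(self, state: str) -> str:
        state = str(state).strip().upper()
        if state in REGIONS or state == "national":
            return state  # already a region id
        if state not in self._mapping:
            raise SchemaError(f"state {state!r} not in region map")
        return self._mapping[state]

    def __contains__(self, state):
        return str(state).strip().upper() in self._mapping


def load_region_info() -> pd.DataFrame:
    """Shipped per-region reference: 2016 population and mean annual temperature."""
    with resources.as_file(
        resources.files("seasmort.data") / "region_info.csv"
    ) as p:
        return pd.read_csv(p).set_index("region")


def load_region_month_temps() -> pd.DataFrame:
    """Shipped published regional monthly mean temperatures (long format)."""
    with resources.as_file(
        resources.files("seasmort.data") / "region_month_temps.csv"
    ) as p:
        return pd.read_csv(p)


def load_published_cause_totals() -> pd.DataFrame:
    """Published US death counts by cause category and sex, 1980-2016.

    Returned in the DeathTable schema (one synthetic year/month cell per
    category) so that share summaries can be computed with the same code path
    as microdata.
    """
    with resources.as_file(
        resources.files("seasmort.data") / "us_deaths_by_cause_sex_1980_2016.csv"
    ) as p:
        wide = pd.read_csv(p)
    long = wide.melt(id_vars="category", var_name="sex", value_name="count")
    long["year"] = 2016
    long["month"] = 1
    long["region"] = "national"
    long["age_group"] = "85+"
    long = long.rename(columns={"category": "cause"})
    return long[list(DEATH_COLUMNS)]


def _require_columns(df: pd.DataFrame, required, what: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} missing column(s): {', '.join(missing)}")


def validate_death_table(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, DEATH_COLUMNS, "death table")
    if ((df["month"] < 1) | (df["month"] > 12)).any():
        bad = df.loc[(df["month"] < 1) | (df["month"] > 12), "month"].unique()
        raise SchemaError(f"month out of range [1, 12]: {sorted(bad)}")
    if (df["count"] < 0).any():
        raise SchemaError("negative death counts")
    return df


def load_deaths(path, cause_map: CauseMap | None = None,
                region_map: RegionMap | None = None,
                *, strict: bool = True) -> pd.DataFrame:
    """Load a delimited deaths file into an aggregated DeathTable.

    Expected columns: ``year, month, state, age_group, sex, cause_code,
    count`` (``icd_revision`` optional; inferred from the year if absent:
    revision 9 through 1998, revision 10 thereafter).  Rows whose month or
    state is missing are dropped with a logged count.  Duplicate
    (year, month, stratum) keys are summed.
    """
    cause_map = cause_map or CauseMap.default()
    region_map = region_map or RegionMap.default()
    df = pd.read_csv(path)
    _require_columns(
        df, ("year", "month", "state", "age_group", "sex", "cause_code", "count"),
        "deaths file",
    )

    n0 = len(df)
    df = df.dropna(subset=["month", "state"])
    if len(df) < n0:
        logger.warning("dropped %d rows with missing month or state", n0 - len(df))

    if "icd_revision" not in df.columns:
        df = df.assign(icd_revision=np.where(df["year"] <= 1998, 9, 10))

    causes, unmapped = [], []
    for code, rev in zip(df["cause_code"], df["icd_revision"]):
        cat = cause_map.lookup(code, int(rev))
        if cat is None:
            unmapped.append(str(code))
            cat = "other"
        causes.append(cat)
    if unmapped:
        if strict:
            raise UnmappedCodeError(unmapped)
        logger.warning(
            "%d unmapped codes routed to 'other': %s",
            len(unmapped), sorted(set(unmapped)),
        )

    out = pd.DataFrame({
        "year": df["year"].astype(int),
        "month": df["month"].astype(int),
        "region": [region_map.lookup(s) for s in df["state"]],
        "age_group": df["age_group"],
        "sex": df["sex"],
        "cause": causes,
        "count": df["count"].astype(int),
    })
    out = validate_death_table(out)
    out = (
        out.groupby(list(DEATH_COLUMNS[:-1]), as_index=False, observed=True)["count"]
        .sum()
    )
    return out


def load_population(path, region_map: RegionMap | None = None) -> pd.DataFrame:
    """Load yearly population counts; states are mapped and summed to regions."""
    region_map = region_map or RegionMap.default()
    df = pd.read_csv(path)
    _require_columns(df, ("year", "state", "age_group", "sex", "population"),
                     "population file")
    if (df["population"] <= 0).any():
        raise SchemaError("non-positive population counts")
    out = pd.DataFrame({
        "year": df["year"].astype(int),
        "region": [region_map.lookup(s) for s in df["state"]],
        "age_group": df["age_group"],
        "sex": df["sex"],
        "population": df["population"].astype(float),
    })
    return (
        out.groupby(list(POPULATION_COLUMNS[:-1]), as_index=False, observed=True)
        ["population"].sum()
    )


def _causes_for(cause: str) -> tuple[str, ...]:
    if cause in ROLLUPS:
        return tuple(ROLLUPS[cause])
    return (cause,)


def aggregate_series(deaths: pd.DataFrame, stratum: StratumKey,
                     window: tuple[int, int]) -> pd.Series:
    """Monthly count series for one stratum over an inclusive year window.

    Rollup causes sum their leaves; ``region="national"`` sums all regions.
    The index is a contiguous monthly :class:`pandas.PeriodIndex`; months with
    no deaths are filled with zero (logged if the stratum is entirely absent).
    """
    y0, y1 = window
    if y1 < y0:
        raise SchemaError(f"empty analysis window {window}")
    validate_death_table(deaths)
    sel = (
        (deaths["age_group"] == stratum.age_group)
        & (deaths["sex"] == stratum.sex)
        & deaths["cause"].isin(_causes_for(stratum.cause))
        & (deaths["year"] >= y0)
        & (deaths["year"] <= y1)
    )
    if stratum.region != "national":
        sel &= deaths["region"] == stratum.region
    sub = deaths.loc[sel]

    index = pd.period_range(f"{y0}-01", f"{y1}-12", freq="M")
    series = pd.Series(0.0, index=index, name="count")
    if sub.empty:
        logger.warning("stratum %s has no deaths in %s-%s", stratum, y0, y1)
        return series
    grouped = sub.groupby(["year", "month"], observed=True)["count"].sum()
    keys = pd.PeriodIndex(
        [pd.Period(freq="M", year=y, month=m) for y, m in grouped.index], freq="M"
    )
    series.loc[keys] = grouped.to_numpy(dtype=float)
    return series


def summarize_cause_shares(deaths: pd.DataFrame) -> pd.DataFrame:
    """Counts and percent of all-cause deaths per category, rollups included.

    Percentages are on the all-cause total and rounded to one decimal.  Leaf
    rows sum to the all-cause count; rollup rows are unions of leaves and are
    flagged in the ``rollup`` column.
    """
    validate_death_table(deaths)
    if deaths.empty:
        raise SchemaError("empty death table")
    leaf = deaths.groupby("cause", observed=True)["count"].sum()
    total = int(leaf.sum())
    rows = [
        {"category": c, "count": int(leaf.get(c, 0)), "rollup": False}
        for c in LEAF_CATEGORIES
    ]
    rows += [
        {
            "category": name,
            "count": int(sum(leaf.get(c, 0) for c in members)),
            "rollup": True,
        }
        for name, members in ROLLUPS.items()
    ]
    out = pd.DataFrame(rows)
    out["percent"] = (100.0 * out["count"] / total).round(1)
    return out
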