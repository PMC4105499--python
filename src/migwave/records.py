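"""Reading, validating and filtering dated bird-encounter records.

An encounter record is one dated, geo-located observation of a ringed bird,
carrying three EURING exchange-code fields: ``age`` (1 = nestling), finding
``condition`` (1 = dead not fresh, 3 = long dead) and ``accuracy`` of the
date (0-2 = known to within 3 days).  The analysis keeps live or freshly
dead birds whose encounter date is accurate, excludes nestlings, restricts
to a seasonal window of whole calendar months, and retains repeated
encounters of the same individual.

Day-of-year uses a fixed 365-day convention (1 January = 1): because years
are pooled, dates on or after 1 March in leap years are shifted to their
non-leap index so that, e.g., 30 May is day 150 in every year; 29 February
maps to day 59 and is flagged.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Season windows (inclusive month ranges) per analysis region.
SEASON_MONTHS = {
    ("british_isles", "spring"): (3, 6),
    ("british_isles", "autumn"): (8, 10),
    ("west_europe_nafrica", "spring"): (2, 6),
    ("west_europe_nafrica", "autumn"): (8, 11),
}

#: EURING codes: excluded age (nestlings), excluded finding conditions
#: (dead, not fresh), and the accepted date-accuracy codes (within 3 days).
NESTLING_AGE_CODE = 1
EXCLUDED_CONDITION_CODES = frozenset({1, 3})
ACCEPTED_ACCURACY_CODES = frozenset({0, 1, 2})

#: Default input column names; override with a column_map.
DEFAULT_COLUMNS = {
    "ring_id": "ring_id",
    "date": "date",
    "lat": "lat",
    "lon": "lon",
    "age_code": "age_code",
    "condition_code": "condition_code",
    "accuracy_code": "accuracy_code",
}


@dataclass(frozen=True)
class EncounterRecord:
    """One dated, geo-located encounter of an individually marked bird."""

    ring_id: str
    date: _dt.date
    day: int
    lat: float
    lon: float
    age_code: int | None
    condition_code: int | None
    accuracy_code: int | None
    year: int

    def __post_init__(self):
        if not (1 <= self.day <= 366):
            raise ValueError(f"day {self.day} outside 1..366")
        if not (-90 <= self.lat <= 90):
            raise ValueError(f"latitude {self.lat} out of range")
        if not (-180 <= self.lon <= 180):
            raise ValueError(f"longitude {self.lon} out of range")


@dataclass(frozen=True)
class SeasonWindow:
    """Inclusive month range defining a migration season for a region."""

    name: str  # "spring" or "autumn"
    months: tuple[int, int]
    region: str

    def contains_month(self, month: int) -> bool:
        lo, hi = self.months
        return lo <= month <= hi

    @property
    def day_range(self) -> tuple[int, int]:
        """First and last day-of-year (365-day convention) in the window."""
        lo, hi = self.months
        first = day_of_year(_dt.date(1981, lo, 1))
        if hi == 12:
            last = 365
        else:
            last = day_of_year(_dt.date(1981, hi + 1, 1) - _dt.timedelta(days=1))
        return first, last


def season_window(region: str, season: str) -> SeasonWindow:
    """Preset window: British Isles spring Mar-Jun / autumn Aug-Oct;
    western Europe & north Africa spring Feb-Jun / autumn Aug-Nov."""
    try:
        months = SEASON_MONTHS[(region, season)]
    except KeyError:
        raise ValueError(
            f"unknown region/season {(region, season)!r}; "
            f"valid: {sorted(SEASON_MONTHS)}"
        ) from None
    return SeasonWindow(name=season, months=months, region=region)


def day_of_year(date: _dt.date, calendar: str = "365-day") -> int:
    """Day-of-year with 1 January = 1.

    Under the default 365-day convention, pooled across years, dates on or
    after 1 March of a leap year take their non-leap index (so 30 May = 150
    always); 29 February maps to day 59 with a log flag.  The "proleptic"
    convention returns the plain ordinal day within the year.
    """
    doy = date.timetuple().tm_yday
    if calendar == "proleptic":
        return doy
    if calendar != "365-day":
        raise ValueError(f"unknown calendar convention {calendar!r}")
    leap = date.year % 4 == 0 and (date.year % 100 != 0 or date.year % 400 == 0)
    if leap and doy >= 60:
        if date.month == 2 and date.day == 29:
            logger.info("29 February %d mapped to day 59 (365-day convention)",
                        date.year)
        doy -= 1
    return doy


@dataclass
class FilterReport:
    """Per-rule exclusion counts, in the order the rules were applied."""

    n_input: int = 0
    excluded_window: int = 0
    excluded_age: int = 0
    excluded_condition: int = 0
    excluded_accuracy: int = 0
    excluded_missing_code: int = 0
    n_output: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _parse_date(value) -> _dt.date:
    if isinstance(value, _dt.datetime):
        return value.date()
    if isinstance(value, _dt.date):
        return value
    ts = pd.Timestamp(str(value))
    return ts.date()


def _opt_int(value) -> int | None:
    if value is None or (isinstance(value, float) and pd.isna(value)) or pd.isna(value):
        return None
    return int(value)


def read_records(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    calendar: str = "365-day",
    sep: str = ",",
) -> tuple[list[EncounterRecord], pd.DataFrame]:
    """Read encounter records from delimited text.

    Parameters
    ----------
    path
        CSV/TSV file with one encounter per row.
    column_map
        Mapping from the field names in :data:`DEFAULT_COLUMNS` to the
        file's column names; unmapped fields use the defaults.
    calendar
        Day-of-year convention (see :func:`day_of_year`).

    Returns
    -------
    (records, rejections)
        Validated records, plus a DataFrame of rejected rows with a
        ``reason`` column — rejections are reported, never silently dropped.

    Raises
    ------
    ValueError
        If a mandatory column is missing from the file.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=sep)
    mandatory = ["date", "lat", "lon"]
    missing = [cols[f] for f in mandatory if cols[f] not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {missing}")

    records: list[EncounterRecord] = []
    rejected: list[dict] = []
    for idx, row in df.iterrows():
        try:
            date = _parse_date(row[cols["date"]])
        except (ValueError, TypeError) as exc:
            rejected.append({"row": idx, "reason": f"unparseable date: {exc}"})
            continue
        lat = float(row[cols["lat"]])
        lon = float(row[cols["lon"]])
        if not -90 <= lat <= 90:
            rejected.append({"row": idx, "reason": "latitude out of range"})
            continue
        if not -180 <= lon <= 180:
            rejected.append({"row": idx, "reason": "longitude out of range"})
            continue
        ring = str(row[cols["ring_id"]]) if cols["ring_id"] in df.columns else f"row{idx}"
        try:
            rec = EncounterRecord(
                ring_id=ring,
                date=date,
                day=day_of_year(date, calendar=calendar),
                lat=lat,
                lon=lon,
                age_code=_opt_int(row.get(cols["age_code"])),
                condition_code=_opt_int(row.get(cols["condition_code"])),
                accuracy_code=_opt_int(row.get(cols["accuracy_code"])),
                year=date.year,
            )
        except (ValueError, TypeError) as exc:
            rejected.append({"row": idx, "reason": str(exc)})
            continue
        records.append(rec)
    rej = pd.DataFrame(rejected, columns=["row", "reason"])
    if len(rej):
        logger.warning("%d row(s) rejected while reading %s", len(rej), path)
    return records, rej


def filter_records(
    records: Iterable[EncounterRecord],
    window: SeasonWindow,
) -> tuple[list[EncounterRecord], FilterReport]:
    """Apply the analysis filters in fixed order: window, age, condition,
    date accuracy.

    Keeps records whose month lies in the window, then drops nestlings
    (age code 1), birds found dead but not fresh (condition 1 or 3), and
    dates known less precisely than 3 days (accuracy outside 0-2).
    Records missing a code needed by a rule are excluded conservatively and
    counted under ``excluded_missing_code``.  Repeated encounters of the
    same individual are retained.
    """
    report = FilterReport()
    out: list[EncounterRecord] = []
    for rec in records:
        report.n_input += 1
        if not window.contains_month(rec.date.month):
            report.excluded_window += 1
            continue
        if rec.age_code is None:
            report.excluded_missing_code += 1
            continue
        if rec.age_code == NESTLING_AGE_CODE:
            report.excluded_age += 1
            continue
        if rec.condition_code is None:
            report.excluded_missing_code += 1
            continue
        if rec.condition_code in EXCLUDED_CONDITION_CODES:
            report.excluded_condition += 1
            continue
        if rec.accuracy_code is None:
            report.excluded_missing_code += 1
            continue
        if rec.accuracy_code not in ACCEPTED_ACCURACY_CODES:
            report.excluded_accuracy += 1
            continue
        out.append(rec)
    report.n_output = len(out)
    if not out:
        logger.warning("filter_records: no records survive the filters")
    return out, report


def annotate_days(df: pd.DataFrame, calendar: str = "365-day") -> pd.DataFrame:
    """Add ``day``, ``month`` and ``year`` columns computed from ``date``.

    Frame-level convenience for data already in memory (e.g. fresh from the
    simulator); uses the same day-of-year convention as the reader.
    """
    out = df.copy()
    dates = pd.to_datetime(out["date"])
    out["day"] = [day_of_year(d.date(), calendar=calendar) for d in dates]
    out["month"] = dates.dt.month
    out["year"] = dates.dt.year
    return out


def filter_frame(df: pd.DataFrame, window: SeasonWindow) -> tuple[pd.DataFrame, FilterReport]:
    """Vectorised version of :func:`filter_records` for DataFrames.

    Applies the identical rules in the identical order (window, age,
    condition, accuracy; missing codes excluded conservatively); the frame
    must carry a ``month`` column (see :func:`annotate_days`).
    """
    report = FilterReport(n_input=len(df))
    lo, hi = window.months
    m = df["month"].between(lo, hi)
    report.excluded_window = int((~m).sum())
    df = df[m]

    age = pd.to_numeric(df["age_code"], errors="coerce")
    miss = age.isna()
    report.excluded_missing_code += int(miss.sum())
    df, age = df[~miss], age[~miss]
    bad = age == NESTLING_AGE_CODE
    report.excluded_age = int(bad.sum())
    df = df[~bad]

    cond = pd.to_numeric(df["condition_code"], errors="coerce")
    miss = cond.isna()
    report.excluded_missing_code += int(miss.sum())
    df, cond = df[~miss], cond[~miss]
    bad = cond.isin(EXCLUDED_CONDITION_CODES)
    report.excluded_condition = int(bad.sum())
    df = df[~bad]

    acc = pd.to_numeric(df["accuracy_code"], errors="coerce")
    miss = acc.isna()
    report.excluded_missing_code += int(miss.sum())
    df, acc = df[~miss], acc[~miss]
    bad = ~acc.isin(ACCEPTED_ACCURACY_CODES)
    report.excluded_accuracy = int(bad.sum())
    df = df[~bad]

    report.n_output = len(df)
    if not len(df):
        logger.warning("filter_frame: no records survive the filters")
    return df.copy(), report


def records_to_frame(records: Sequence[EncounterRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of records (one row per encounter)."""
    return pd.DataFrame(
        {
            "ring_id": [r.ring_id for r in records],
            "date": [r.date.isoformat() for r in records],
            "day": [r.day for r in records],
            "lat": [r.lat for r in records],
            "lon": [r.lon for r in records],
            "age_code": [r.age_code for r in records],
            "condition_code": [r.condition_code for r in records],
            "accuracy_code": [r.accuracy_code for r in records],
            "year": [r.year for r in records],
        }
    )


def write_records(records: Sequence[EncounterRecord], path: str | Path) -> None:
    """Write records as CSV in the same dialect :func:`read_records` reads."""
    records_to_frame(records).to_csv(path, index=False)
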