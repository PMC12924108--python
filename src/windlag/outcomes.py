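"""Classification of underlying-cause-of-death codes and aggregation to panels.

Psychoactive drug-related deaths comprise three underlying-cause groups:
poisoning by and exposure to noxious substances (overdoses), mental and
behavioral disorders due to psychoactive substance use, and alcohol-induced
conditions.  Overdoses are treated as the acute subclass; substance-use
disorders and alcohol-induced organ disease as the chronic subclass.

The default ICD-9/ICD-10 prefix table ships as an editable CSV
(``data/icd_codes.csv``) following the NCHS drug-overdose and
alcohol-induced cause definitions; users with their own code lists load a
replacement table with :func:`load_code_map`.  Codes are compared
prefix-wise after stripping dots and upper-casing (NCHS extracts vary in
dot usage); the first matching rule wins and unmatched codes fall through
to ``("other", "none")``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .timeindex import month_index

CATEGORIES = ("overdose", "mental_behavioral", "alcohol_induced")
AGE_GROUPS = ("<15", "15-29", "30-44", "45-59", ">=60")
SEXES = ("female", "male")

# ICD-10 alcohol-poisoning codes whose grouping (overdose vs alcohol-induced)
# differs between published definitions; placement is a CodeMap option.
_ALCOHOL_POISONING_10 = ("X45", "X65", "Y15")


@dataclass
class CodeMap:
    """Ordered prefix-matching rules mapping ICD codes to cause categories."""

    rules: pd.DataFrame  # columns: version, prefix, category, subclass
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        req = {"version", "prefix", "category", "subclass"}
        if not req <= set(self.rules.columns):
            raise ValueError(f"code map needs columns {sorted(req)}")
        rules = self.rules.copy()
        rules["version"] = rules["version"].astype(int)
        rules["prefix"] = rules["prefix"].astype(str).str.replace(".", "", regex=False).str.upper()
        self.rules = rules
        self._by_version = {
            v: list(zip(g["prefix"], g["category"], g["subclass"]))
            for v, g in rules.groupby("version", sort=False)
        }

    def lookup(self, code: str, version: int) -> tuple[str, str]:
        if version not in (9, 10):
            raise ValueError(f"unknown ICD version {version!r}; expected 9 or 10")
        norm = str(code).replace(".", "").upper().strip()
        if not norm:
            raise ValueError("empty ICD code")
        for prefix, category, subclass in self._by_version.get(version, ()):
            if norm.startswith(prefix):
                return category, subclass
        return "other", "none"


def load_code_map(path) -> CodeMap:
    """Load a prefix rule table from a delimited text file."""
    return CodeMap(pd.read_csv(path, dtype={"prefix": str}))


def default_code_map(alcohol_poisoning: str = "overdose") -> CodeMap:
    """The shipped ICD-9/ICD-10 table.

    ``alcohol_poisoning`` places X45/X65/Y15 under ``"overdose"`` (default)
    or ``"alcohol_induced"``.
    """
    with resources.files("windlag.data").joinpath("icd_codes.csv").open() as fh:
        rules = pd.read_csv(fh, dtype={"prefix": str})
    if alcohol_poisoning == "alcohol_induced":
        mask = rules["prefix"].isin(_ALCOHOL_POISONING_10) & (rules["version"] == 10)
        rules.loc[mask, "category"] = "alcohol_induced"
    elif alcohol_poisoning != "overdose":
        raise ValueError("alcohol_poisoning must be 'overdose' or 'alcohol_induced'")
    return CodeMap(rules, meta={"alcohol_poisoning": alcohol_poisoning})


def classify_icd(code: str, version: int, code_map: CodeMap | None = None) -> tuple[str, str]:
    """Classify one underlying-cause code to (category, subclass)."""
    if code_map is None:
        code_map = default_code_map()
    return code_map.lookup(code, version)


def assign_age_group(age_years) -> str | float:
    """Map an age in years to the analysis age bands."""
    try:
        age = float(age_years)
    except (TypeError, ValueError):
        return np.nan
    if not np.isfinite(age) or age < 0:
        return np.nan
    if age < 15:
        return "<15"
    if age < 30:
        return "15-29"
    if age < 45:
        return "30-44"
    if age < 60:
        return "45-59"
    return ">=60"


_SEX_ALIASES = {"f": "female", "female": "female", "m": "male", "male": "male"}


def aggregate_deaths(
    records: pd.DataFrame,
    code_map: CodeMap | None = None,
    start_year: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Aggregate record-level deaths to a county-month mortality panel.

    ``records`` columns: ``county_id, year, month, age_years, sex,
    icd_version, icd_code``.  Returns ``(panel, report)`` where the panel
    counts deaths by county-month x age group x sex x category x subclass
    (category ``other`` excluded) and the report tallies classified /
    other / dropped records so that they sum to the input count.
    Records with unparseable age or sex are dropped with a warning.
    """
    if code_map is None:
        code_map = default_code_map()
    req = {"county_id", "year", "month", "age_years", "sex", "icd_version", "icd_code"}
    missing = req - set(records.columns)
    if missing:
        raise ValueError(f"death records missing columns: {sorted(missing)}")
    n_input = len(records)
    if n_input == 0:
        empty = pd.DataFrame(
            columns=["county_id", "month_index", "age_group", "sex", "category", "subclass", "deaths"]
        )
        return empty, {"input": 0, "classified": 0, "other": 0, "dropped": 0}

    df = records.copy()
    df["age_group"] = df["age_years"].map(assign_age_group)
    df["sex_norm"] = df["sex"].astype(str).str.strip().str.lower().map(_SEX_ALIASES)
    bad = df["age_group"].isna() | df["sex_norm"].isna()
    n_dropped = int(bad.sum())
    if n_dropped:
        warnings.warn(
            f"dropping {n_dropped} death record(s) with unparseable age or sex",
            stacklevel=2,
        )
        df = df.loc[~bad]

    cats, subs = [], []
    for code, ver in zip(df["icd_code"], df["icd_version"]):
        c, s = code_map.lookup(code, int(ver))
        cats.append(c)
        subs.append(s)
    df["category"] = cats
    df["subclass"] = subs
    n_other = int((df["category"] == "other").sum())
    df = df.loc[df["category"] != "other"]

    if start_year is None:
        start_year = int(records["year"].min())
    df["month_index"] = [
        month_index(int(y), int(m), start_year) for y, m in zip(df["year"], df["month"])
    ]
    panel = (
        df.groupby(
            ["county_id", "month_index", "age_group", "sex_norm", "category", "subclass"],
            sort=True,
        )
        .size()
        .rename("deaths")
        .reset_index()
        .rename(columns={"sex_norm": "sex"})
    )
    report = {
        "input": n_input,
        "classified": int(panel["deaths"].sum()),
        "other": n_other,
        "dropped": n_dropped,
        "start_year": start_year,
    }
    return panel, report


def summarize_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Descriptive totals and percentage shares by sex, age group, and cause.

    Returns a tidy table with columns ``axis, level, deaths, percent``
    (percent of the panel total, rounded to one decimal place).
    """
    if len(panel) == 0 or panel["deaths"].sum() == 0:
        raise ValueError("cannot summarize an empty mortality panel")
    total = int(panel["deaths"].sum())
    rows = [("total", "all", total, 100.0)]
    for axis in ("sex", "age_group", "category", "subclass"):
        if axis not in panel.columns:
            continue
        for level, cnt in panel.groupby(axis, sort=True)["deaths"].sum().items():
            rows.append((axis, level, int(cnt), round(100.0 * cnt / total, 1)))
    return pd.DataFrame(rows, columns=["axis", "level", "deaths", "percent"])
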