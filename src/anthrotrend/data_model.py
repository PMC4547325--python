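"""Typed records and CSV I/O for survey summaries, country metadata and estimates.

The analysis consumes survey *summary statistics* (mean Z, SD, sample size,
optional prevalence below -2), never individual children: micro-data, where
available, are assumed to have been collapsed upstream to design-weighted
per-stratum means and SDs. A survey spanning several calendar years is dated
by its midpoint year.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .growth_reference import SummaryStatistic, REFERENCE_KINDS

YEAR_MIN = 1985
YEAR_MAX = 2011
YEARS = tuple(range(YEAR_MIN, YEAR_MAX + 1))

STRATA = ("rural", "urban", "combined")
COVERAGES = ("national", "subnational")
AGE_COVERAGES = ("full", "partial")
METRIC_CODES = ("haz", "waz")

#: Default seven-region grouping of the low- and middle-income countries.
REGIONS7 = (
    "sub_saharan_africa",
    "central_asia_middle_east_north_africa",
    "south_asia",
    "east_southeast_asia",
    "southern_tropical_latin_america",
    "andean_central_latin_america_caribbean",
    "oceania",
)

COVARIATE_COLUMNS = ("educ_years", "log_gdp", "urban_prop", "health_access")

SOURCES_COLUMNS = (
    "country", "year", "stratum", "coverage", "age_coverage", "metric",
    "mean_z", "sd_z", "n", "se_mean", "prev_below", "reference",
)
META_COLUMNS = ("country", "region", "year", "pop_under5", "urban_fraction") + COVARIATE_COLUMNS
ESTIMATES_COLUMNS = (
    "level", "id", "year", "stratum", "metric",
    "mean", "mean_lo", "mean_hi", "prev", "prev_lo", "prev_hi",
)


class ValidationError(ValueError):
    """One or more rows failed validation; the message lists every failure."""


@dataclass(frozen=True)
class DataSource:
    """One survey summary record for one country-year-stratum."""

    country: str
    year: int
    stratum: str
    coverage: str
    age_coverage: str
    metric: str
    summary: SummaryStatistic
    n: int
    se_mean: float

    def __post_init__(self) -> None:
        if not (YEAR_MIN <= self.year <= YEAR_MAX):
            raise ValueError(f"year {self.year} outside analysis window {YEAR_MIN}-{YEAR_MAX}")
        if self.stratum not in STRATA:
            raise ValueError(f"unknown stratum {self.stratum!r}")
        if self.coverage not in COVERAGES:
            raise ValueError(f"unknown coverage {self.coverage!r}")
        if self.age_coverage not in AGE_COVERAGES:
            raise ValueError(f"unknown age_coverage {self.age_coverage!r}")
        if self.metric not in METRIC_CODES:
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.n < 1:
            raise ValueError(f"sample size must be >= 1, got {self.n}")
        if not (self.se_mean > 0):
            raise ValueError(f"se_mean must be positive, got {self.se_mean}")


@dataclass
class CountryMeta:
    """Region membership plus yearly population and covariate series for one country."""

    country: str
    region: str
    series: pd.DataFrame  # indexed by year, columns pop_under5, urban_fraction, covariates

    def __post_init__(self) -> None:
        missing = [y for y in YEARS if y not in self.series.index]
        if missing:
            raise ValueError(f"{self.country}: missing years {missing}")
        uf = self.series["urban_fraction"]
        if ((uf < 0) | (uf > 1)).any():
            raise ValueError(f"{self.country}: urban_fraction outside [0, 1]")
        if (self.series["pop_under5"] < 0).any():
            raise ValueError(f"{self.country}: negative under-5 population")

    def urban_fraction(self, year: int) -> float:
        return float(self.series.at[year, "urban_fraction"])

    def pop_under5(self, year: int) -> float:
        return float(self.series.at[year, "pop_under5"])

    def covariates(self, columns=COVARIATE_COLUMNS) -> np.ndarray:
        """Covariate matrix over the analysis years, shape (n_years, n_covariates)."""
        return self.series.loc[list(YEARS), list(columns)].to_numpy(dtype=float)


@dataclass(frozen=True)
class EstimateRow:
    """One posterior estimate: mean Z and prevalence with 2.5-97.5 credible bounds."""

    level: str  # country | region | global
    id: str
    year: int
    stratum: str
    metric: str
    mean: float
    mean_lo: float
    mean_hi: float
    prev: float
    prev_lo: float
    prev_hi: float

    def validate(self) -> None:
        if not (self.mean_lo <= self.mean <= self.mean_hi):
            raise ValidationError(
                f"{self.level}/{self.id}/{self.year}/{self.stratum}: "
                f"mean CI ordering violated ({self.mean_lo}, {self.mean}, {self.mean_hi})"
            )
        if not (0 <= self.prev_lo <= self.prev <= self.prev_hi <= 1):
            raise ValidationError(
                f"{self.level}/{self.id}/{self.year}/{self.stratum}: "
                f"prevalence CI invalid ({self.prev_lo}, {self.prev}, {self.prev_hi})"
            )


def _norm_token(value, allowed: tuple[str, ...], column: str, line: int, errors: list[str]):
    token = str(value).strip().lower()
    if token not in allowed:
        errors.append(f"line {line}: unknown {column} {value!r} (allowed: {', '.join(allowed)})")
        return None
    return token


def read_sources(path) -> list[DataSource]:
    """Read and validate a sources CSV; raises ValidationError listing bad lines."""
    df = pd.read_csv(path)
    missing = set(SOURCES_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"sources file missing columns: {sorted(missing)}")
    out: list[DataSource] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        stratum = _norm_token(row["stratum"], STRATA, "stratum", line, errors)
        coverage = _norm_token(row["coverage"], COVERAGES, "coverage", line, errors)
        age_cov = _norm_token(row["age_coverage"], AGE_COVERAGES, "age_coverage", line, errors)
        metric = _norm_token(row["metric"], METRIC_CODES, "metric", line, errors)
        reference = str(row["reference"]).strip()
        if reference not in REFERENCE_KINDS:
            errors.append(f"line {line}: unknown reference {row['reference']!r}")
            reference = None
        if None in (stratum, coverage, age_cov, metric, reference):
            continue
        prev = row["prev_below"]
        prev = None if pd.isna(prev) else float(prev)
        try:
            summary = SummaryStatistic(
                mean_z=float(row["mean_z"]), sd_z=float(row["sd_z"]),
                prev_below=prev, reference=reference,
            )
            out.append(DataSource(
                country=str(row["country"]).strip(),
                year=int(row["year"]),
                stratum=stratum,
                coverage=coverage,
                age_coverage=age_cov,
                metric=metric,
                summary=summary,
                n=int(row["n"]),
                se_mean=float(row["se_mean"]),
            ))
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValidationError("invalid source rows:\n" + "\n".join(errors))
    return out


def read_country_meta(path, regions: tuple[str, ...] = REGIONS7) -> dict[str, CountryMeta]:
    """Read country metadata; every country must cover 1985-2011 completely."""
    df = pd.read_csv(path)
    missing = set(META_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"country-meta file missing columns: {sorted(missing)}")
    out: dict[str, CountryMeta] = {}
    errors: list[str] = []
    for country, grp in df.groupby("country", sort=True):
        country = str(country)
        region_vals = grp["region"].unique()
        if len(region_vals) != 1:
            errors.append(f"{country}: inconsistent region assignment {list(region_vals)}")
            continue
        region = str(region_vals[0])
        if region not in regions:
            errors.append(f"{country}: unknown region {region!r}")
            continue
        series = grp.set_index(grp["year"].astype(int)).drop(columns=["country", "region", "year"])
        gaps = [y for y in YEARS if y not in series.index]
        if gaps:
            errors.append(f"{country}: missing years {gaps}")
            continue
        try:
            out[country] = CountryMeta(country=country, region=region,
                                       series=series.sort_index())
        except ValueError as exc:
            errors.append(str(exc))
    if errors:
        raise ValidationError("invalid country metadata:\n" + "\n".join(errors))
    return out


def write_estimates(path, rows: list[EstimateRow]) -> None:
    """Write estimate rows to CSV; refuses rows with invalid credible intervals."""
    for r in rows:
        r.validate()
    df = pd.DataFrame([r.__dict__ for r in rows], columns=ESTIMATES_COLUMNS)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_estimates(path) -> list[EstimateRow]:
    df = pd.read_csv(path)
    rows = []
    for _, r in df.iterrows():
        rows.append(EstimateRow(
            level=str(r["level"]), id=str(r["id"]), year=int(r["year"]),
            stratum=str(r["stratum"]), metric=str(r["metric"]),
            mean=float(r["mean"]), mean_lo=float(r["mean_lo"]), mean_hi=float(r["mean_hi"]),
            prev=float(r["prev"]), prev_lo=float(r["prev_lo"]), prev_hi=float(r["prev_hi"]),
        ))
    return rows


def write_sources(path, sources: list[DataSource]) -> None:
    """Serialise DataSource records to the sources CSV schema."""
    rows = []
    for s in sources:
        rows.append({
            "country": s.country, "year": s.year, "stratum": s.stratum,
            "coverage": s.coverage, "age_coverage": s.age_coverage, "metric": s.metric,
            "mean_z": s.summary.mean_z, "sd_z": s.summary.sd_z, "n": s.n,
            "se_mean": s.se_mean,
            "prev_below": s.summary.prev_below,
            "reference": s.summary.reference,
        })
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows, columns=SOURCES_COLUMNS).to_csv(path, index=False)


def write_country_meta(path, meta: dict[str, CountryMeta]) -> None:
    frames = []
    for m in meta.values():
        df = m.series.reset_index(names="year")
        df.insert(0, "country", m.country)
        df.insert(1, "region", m.region)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)[list(META_COLUMNS)]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False)


__all__ = [
    "DataSource", "CountryMeta", "EstimateRow", "ValidationError",
    "read_sources", "read_country_meta", "read_estimates",
    "write_sources", "write_country_meta", "write_estimates",
    "YEARS", "YEAR_MIN", "YEAR_MAX", "STRATA", "REGIONS7",
    "COVARIATE_COLUMNS", "METRIC_CODES",
]
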