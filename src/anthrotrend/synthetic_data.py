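"""Synthetic multi-country ground truth and survey summaries.

The generator emulates the statistical structure the analysis assumes: each
country's rural mean-Z trajectory is a hierarchical linear trend (global,
region and country intercepts/slopes) plus a smooth second-order random-walk
deviation and covariate effects; the urban trajectory adds a country-specific
offset with its own linear time slope. Population Z distributions are
left-skewed five-component normal mixtures anchored at those means.

Surveys are drawn at the density of the real evidence base (on average 4.8
sources per country, 84% nationally representative) with mixed stratum
reporting (separate rural/urban rows or a combined row weighted by the urban
fraction), mixed reference populations (a fraction is re-expressed against
the NCHS 1977 reference), and observation noise combining sampling error
with the fixed non-sampling variance terms of the observation model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    CountryMeta, DataSource, COVARIATE_COLUMNS, REGIONS7, YEAR_MIN, YEAR_MAX, YEARS,
)
from .growth_reference import ReferenceTable, SummaryStatistic, map_summary
from .hiermix_model import (
    ModelSpec, combined_stratum_mixture, population_mixture, standardize_covariates,
)

_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass
class SimulationConfig:
    """True hyperparameters and survey-process settings for one simulation.

    Defaults encode the study conditions: source density 4.8 per country,
    84% national sources, a 1985-2011 window, and mildly left-skewed mixture
    population distributions. All Z-scale quantities are in Z units; slopes
    are per year.
    """

    n_regions: int = 2
    countries_per_region: int = 4
    metric: str = "haz"
    global_intercept: float = -1.4
    global_slope: float = 0.02
    sd_region_intercept: float = 0.30
    sd_region_slope: float = 0.008
    sd_country_intercept: float = 0.35
    sd_country_slope: float = 0.010
    rw2_sd: float = 0.012
    covariate_coefs: tuple = (0.15, 0.10, 0.05, 0.08)
    urban_offset_mean: float = 0.45
    urban_offset_region_sd: float = 0.10
    urban_offset_sd: float = 0.15
    urban_offset_slope_sd: float = 0.004
    mixture_weights: tuple = ModelSpec.weights
    mixture_pattern: tuple = ModelSpec.offset_pattern
    mixture_sd_ratios: tuple = ModelSpec.sd_ratios
    lam_rural: float = 0.50
    lam_urban: float = 0.45
    s0: float = 1.10
    tau_national: float = 0.03
    tau_subnational_extra: float = 0.06
    tau_partial_age_extra: float = 0.04
    sources_per_country: float = 4.8
    frac_national: float = 0.84
    frac_combined: float = 0.20
    frac_nchs: float = 0.15
    frac_partial_age: float = 0.10
    frac_with_prev: float = 0.70
    n_log_mean: float = float(np.log(2000.0))
    n_log_sd: float = 0.7
    no_data_countries: tuple = ()

    def __post_init__(self) -> None:
        for name in ("sd_region_intercept", "sd_region_slope", "sd_country_intercept",
                     "sd_country_slope", "rw2_sd", "urban_offset_region_sd",
                     "urban_offset_sd", "urban_offset_slope_sd", "tau_national",
                     "tau_subnational_extra", "tau_partial_age_extra", "s0"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("frac_national", "frac_combined", "frac_nchs",
                     "frac_partial_age", "frac_with_prev"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.metric not in ("haz", "waz"):
            raise ValueError("metric must be 'haz' or 'waz'")
        w = np.asarray(self.mixture_weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if self.sources_per_country < 0:
            raise ValueError("sources_per_country must be >= 0")

    def model_spec(self) -> ModelSpec:
        """ModelSpec sharing this simulation's mixture shape and tau terms."""
        return ModelSpec(
            K=len(self.mixture_weights),
            weights=tuple(self.mixture_weights),
            offset_pattern=tuple(self.mixture_pattern),
            sd_ratios=tuple(self.mixture_sd_ratios),
            tau_national=self.tau_national,
            tau_subnational_extra=self.tau_subnational_extra,
            tau_partial_age_extra=self.tau_partial_age_extra,
        )


@dataclass
class SyntheticTruth:
    """True country-year-stratum distributions and metadata of one simulation."""

    config: SimulationConfig
    countries: tuple
    regions: tuple
    region_of: tuple
    years: np.ndarray
    rural_mean: np.ndarray  # (C, T)
    urban_mean: np.ndarray
    rural_prev: np.ndarray
    urban_prev: np.ndarray
    meta: dict
    effects: dict = field(default_factory=dict)

    def country_index(self, country: str) -> int:
        return self.countries.index(country)

    def true_mean(self, country: str, stratum: str, year: int) -> float:
        c = self.country_index(country)
        ti = year - YEAR_MIN
        if stratum == "rural":
            return float(self.rural_mean[c, ti])
        if stratum == "urban":
            return float(self.urban_mean[c, ti])
        p = self.meta[country].urban_fraction(year)
        return float((1 - p) * self.rural_mean[c, ti] + p * self.urban_mean[c, ti])


def _country_codes(n: int) -> list[str]:
    return ["".join((_LETTERS[i // 676], _LETTERS[(i // 26) % 26], _LETTERS[i % 26]))
            for i in range(n)]


def _region_codes(n: int) -> list[str]:
    if n <= len(REGIONS7):
        return list(REGIONS7[:n])
    return list(REGIONS7) + [f"region_{i:02d}" for i in range(len(REGIONS7), n)]


def _smooth_deviation(rng: np.random.Generator, T: int, sd: float, tc: np.ndarray) -> np.ndarray:
    """RW2 path with its level and linear trend projected out."""
    inc = rng.normal(0.0, sd, size=max(T - 2, 0))
    u = np.zeros(T)
    for t in range(2, T):
        u[t] = 2.0 * u[t - 1] - u[t - 2] + inc[t - 2]
    X = np.column_stack([np.ones(T), tc])
    beta, *_ = np.linalg.lstsq(X, u, rcond=None)
    return u - X @ beta


def _make_meta(rng: np.random.Generator, countries, regions, region_of) -> dict:
    meta = {}
    T = len(YEARS)
    frac = np.arange(T) / (T - 1)
    for i, country in enumerate(countries):
        uf0 = rng.uniform(0.15, 0.55)
        uf = np.clip(uf0 + rng.uniform(0.05, 0.25) * frac, 0.0, 0.9)
        educ = rng.uniform(2.0, 8.0) + rng.uniform(0.05, 0.15) * np.arange(T)
        lgdp = rng.uniform(6.5, 9.0) + rng.uniform(0.005, 0.04) * np.arange(T)
        ha0 = rng.uniform(0.2, 0.5)
        ha = ha0 + rng.uniform(0.2, 0.4) * (1.0 / (1.0 + np.exp(-(np.arange(T) - T / 2) / 8.0)))
        pop = 10 ** rng.uniform(5.3, 7.0) * np.exp(rng.uniform(-0.01, 0.02) * np.arange(T))
        series = pd.DataFrame({
            "pop_under5": pop, "urban_fraction": uf, "educ_years": educ,
            "log_gdp": lgdp, "urban_prop": uf, "health_access": ha,
        }, index=list(YEARS))
        meta[country] = CountryMeta(country=country, region=regions[region_of[i]],
                                    series=series)
    return meta


def generate_truth(config: SimulationConfig, seed: int) -> SyntheticTruth:
    """Draw true trajectories, distributions and metadata; deterministic given seed."""
    rng = np.random.default_rng(seed)
    R, per = config.n_regions, config.countries_per_region
    C = R * per
    regions = tuple(_region_codes(R))
    countries = tuple(_country_codes(C))
    region_of = tuple(i // per for i in range(C))
    years = np.arange(YEAR_MIN, YEAR_MAX + 1)
    T = len(years)
    spec = config.model_spec()
    tc = (years - spec.center_year).astype(float)

    meta = _make_meta(rng, countries, regions, region_of)
    X, _, _ = standardize_covariates(meta, spec.covariates)
    gamma = np.asarray(config.covariate_coefs, dtype=float)

    eff = {
        "b0r": rng.normal(0.0, config.sd_region_intercept, R),
        "b1r": rng.normal(0.0, config.sd_region_slope, R),
        "b0c": rng.normal(0.0, config.sd_country_intercept, C),
        "b1c": rng.normal(0.0, config.sd_country_slope, C),
        "d0r": rng.normal(0.0, config.urban_offset_region_sd, R),
        "d0c": rng.normal(0.0, config.urban_offset_sd, C),
        "d1c": rng.normal(0.0, config.urban_offset_slope_sd, C),
    }
    u = np.stack([_smooth_deviation(rng, T, config.rw2_sd, tc) for _ in range(C)])
    ro = np.asarray(region_of)
    b0 = config.global_intercept + eff["b0r"][ro] + eff["b0c"]
    b1 = config.global_slope + eff["b1r"][ro] + eff["b1c"]
    rural = b0[:, None] + np.outer(b1, tc) + u + X @ gamma
    off = (config.urban_offset_mean + eff["d0r"][ro] + eff["d0c"])[:, None] \
        + np.outer(eff["d1c"], tc)
    urban = rural + off

    shp_r = (config.lam_rural, config.s0)
    shp_u = (config.lam_urban, config.s0)
    rural_prev = np.empty_like(rural)
    urban_prev = np.empty_like(urban)
    for c in range(C):
        for t in range(T):
            rural_prev[c, t] = population_mixture(rural[c, t], spec, shp_r).cdf(spec.threshold)
            urban_prev[c, t] = population_mixture(urban[c, t], spec, shp_u).cdf(spec.threshold)

    return SyntheticTruth(
        config=config, countries=countries, regions=regions, region_of=region_of,
        years=years, rural_mean=rural, urban_mean=urban,
        rural_prev=rural_prev, urban_prev=urban_prev, meta=meta, effects=eff,
    )


def _true_distribution(truth: SyntheticTruth, spec: ModelSpec, country: str,
                       stratum: str, year: int):
    cfg = truth.config
    c = truth.country_index(country)
    ti = year - YEAR_MIN
    mix_r = population_mixture(truth.rural_mean[c, ti], spec, (cfg.lam_rural, cfg.s0))
    mix_u = population_mixture(truth.urban_mean[c, ti], spec, (cfg.lam_urban, cfg.s0))
    if stratum == "rural":
        return mix_r
    if stratum == "urban":
        return mix_u
    return combined_stratum_mixture(mix_r, mix_u, truth.meta[country].urban_fraction(year))


def generate_surveys(truth: SyntheticTruth, config: SimulationConfig, seed: int,
                     who_table: ReferenceTable | None = None,
                     nchs_table: ReferenceTable | None = None) -> list[DataSource]:
    """Draw survey summary records around the true distributions.

    A source that reports rural and urban children separately yields two
    records; a combined source yields one, weighted by the urban fraction.
    NCHS-flagged sources are re-expressed in NCHS Z space by the same
    quantile mapping the pipeline later inverts; these carry means only
    (older summary-statistic sources typically reported no tail prevalence).
    """
    rng = np.random.default_rng(seed)
    spec = config.model_spec()
    metric_name = "height" if config.metric == "haz" else "weight"
    out: list[DataSource] = []
    for country in truth.countries:
        if country in config.no_data_countries:
            continue
        n_src = rng.poisson(config.sources_per_country)
        for _ in range(n_src):
            year = int(rng.integers(YEAR_MIN, YEAR_MAX + 1))
            coverage = "national" if rng.uniform() < config.frac_national else "subnational"
            age_cov = "partial" if rng.uniform() < config.frac_partial_age else "full"
            nchs = rng.uniform() < config.frac_nchs
            combined = rng.uniform() < config.frac_combined
            with_prev = (not nchs) and rng.uniform() < config.frac_with_prev
            strata = ["combined"] if combined else ["rural", "urban"]
            for stratum in strata:
                mix = _true_distribution(truth, spec, country, stratum, year)
                true_mean = mix.mean()
                true_sd = float(np.sqrt(mix.variance()))
                true_prev = mix.cdf(spec.threshold)
                n = int(np.clip(round(np.exp(rng.normal(config.n_log_mean, config.n_log_sd))),
                                100, 1_000_000))
                sd_obs = float(max(true_sd * (1.0 + 0.05 * rng.standard_normal()), 0.3))
                se = sd_obs / np.sqrt(n)
                v = se ** 2 + config.tau_national ** 2
                if coverage == "subnational":
                    v += config.tau_subnational_extra ** 2
                if age_cov == "partial":
                    v += config.tau_partial_age_extra ** 2
                obs_mean = float(true_mean + rng.normal(0.0, np.sqrt(v)))
                prev = None
                if with_prev:
                    prev = float(np.clip(rng.binomial(n, true_prev) / n, 1e-4, 1 - 1e-4))
                reference = "WHO2006"
                if nchs:
                    who_table = who_table or ReferenceTable.packaged("WHO2006")
                    nchs_table = nchs_table or ReferenceTable.packaged("NCHS1977")
                    m_n, sd_n, _ = map_summary(obs_mean, sd_obs, who_table, nchs_table,
                                               (0.0, 60.0), metric_name)
                    obs_mean, sd_obs = m_n, sd_n
                    se = sd_obs / np.sqrt(n)
                    reference = "NCHS1977"
                out.append(DataSource(
                    country=country, year=year, stratum=stratum, coverage=coverage,
                    age_coverage=age_cov, metric=config.metric,
                    summary=SummaryStatistic(mean_z=obs_mean, sd_z=sd_obs,
                                             prev_below=prev, reference=reference),
                    n=n, se_mean=float(se),
                ))
    return out


def write_truth(truth: SyntheticTruth, path) -> None:
    """Serialise the true means and prevalences as a long CSV."""
    rows = []
    for c, country in enumerate(truth.countries):
        for t, year in enumerate(truth.years):
            rows.append((country, int(year), "rural",
                         truth.rural_mean[c, t], truth.rural_prev[c, t]))
            rows.append((country, int(year), "urban",
                         truth.urban_mean[c, t], truth.urban_prev[c, t]))
    df = pd.DataFrame(rows, columns=["country", "year", "stratum", "true_mean", "true_prev"])
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


__all__ = [
    "SimulationConfig", "SyntheticTruth",
    "generate_truth", "generate_surveys", "write_truth",
]
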