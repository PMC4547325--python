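"""Bayesian hierarchical mixture model for rural/urban child growth trends.

The population distribution of height-for-age or weight-for-age Z scores in
country ``c``, year ``t`` and stratum ``s`` (rural or urban) is a K-component
normal mixture whose shape (component weights, offset pattern and SD ratios)
is shared globally per stratum, and whose location is the country-year-stratum
mean

    mu_rural(c, t) = a_c + b_c * t~ + u_{c,t} + x_{c,t}' gamma
    mu_urban(c, t) = mu_rural(c, t) + d_c + e_c * t~

with ``t~`` the year centred at 1998, ``u_c`` a smooth second-order
random-walk deviation, ``x`` standardised covariates (maternal education,
log per-person GDP, urban proportion, health-care access), and nested
hierarchies global -> region -> country on the intercepts ``a_c``, slopes
``b_c`` and the urban offsets ``d_c, e_c``.

Survey summaries are observed with Gaussian error around the model mean:
the variance is the reported sampling variance plus fixed non-sampling
variance terms (all sources), extra terms for subnational and partial-age
coverage, and reference-conversion variance for NCHS-referenced sources.
Reported prevalences below Z = -2 enter on the probit scale with
delta-method variance.

Fitting uses a blocked MCMC: all linear effects are drawn jointly from their
Gaussian full conditional (exactly when no prevalence observations are
present; otherwise through a linearised Gaussian proposal corrected by a
Metropolis-Hastings step), and variance components and mixture-shape
parameters are updated by slice sampling.
"""

from __future__ import annotations

import json
import warnings as _pywarnings
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.special import ndtr, ndtri

from ._samplers import slice_sample
from .data_model import (
    CountryMeta, DataSource, COVARIATE_COLUMNS, YEAR_MIN, YEAR_MAX, YEARS,
)
from .growth_reference import (
    ReferenceTable, SummaryStatistic, convert_summary_nchs_to_who,
)

_LOG2PI = float(np.log(2.0 * np.pi))
_KAPPA = 1.0e6  # penalty pinning the RW2 level and linear trend to zero
_PCLIP = 1.0e-6  # probit clipping for observed/model prevalences


# ---------------------------------------------------------------------------
# Specification and state
# ---------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Structural and prior settings of the hierarchical mixture model.

    The mixture shape is parameterised by fixed component ``weights``, a
    mean-zero ``offset_pattern`` scaled by a nonnegative skewness parameter
    (lambda, one per stratum) and ``sd_ratios`` scaled by a common component
    SD (s0, one per stratum); lambda and s0 are estimated.  The tau terms are
    fixed non-sampling error SDs (Z units).
    """

    K: int = 5
    weights: tuple = (0.1, 0.2, 0.4, 0.2, 0.1)
    offset_pattern: tuple = (-1.55, -0.55, 0.15, 0.55, 0.95)
    sd_ratios: tuple = (1.2, 1.0, 0.9, 0.9, 1.1)
    covariates: tuple = COVARIATE_COLUMNS
    center_year: int = 1998
    threshold: float = -2.0
    tau_national: float = 0.03
    tau_subnational_extra: float = 0.06
    tau_partial_age_extra: float = 0.04
    prior_sd_fixed: float = 10.0
    prior_scale_intercept_sd: float = 0.5
    prior_scale_slope_sd: float = 0.05
    prior_scale_rw2_sd: float = 0.05
    prior_scale_lam: float = 1.0
    prior_scale_s0: float = 2.0
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not (len(self.weights) == len(self.offset_pattern) == len(self.sd_ratios) == self.K):
            raise ValueError("weights, offset_pattern and sd_ratios must have length K")
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must be nonnegative and sum to 1")
        if np.any(np.asarray(self.sd_ratios) <= 0):
            raise ValueError("sd_ratios must be positive")
        for name in ("prior_sd_fixed", "prior_scale_intercept_sd", "prior_scale_slope_sd",
                     "prior_scale_rw2_sd", "prior_scale_lam", "prior_scale_s0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # re-centre the offset pattern so anchoring is exact by construction
        pat = np.asarray(self.offset_pattern, dtype=float)
        self.offset_pattern = tuple(pat - float(w @ pat))

    @property
    def weights_arr(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)

    @property
    def pattern_arr(self) -> np.ndarray:
        return np.asarray(self.offset_pattern, dtype=float)

    @property
    def ratios_arr(self) -> np.ndarray:
        return np.asarray(self.sd_ratios, dtype=float)


@dataclass
class MixtureDistribution:
    """K-component normal mixture for one country-year-stratum Z distribution."""

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if abs(self.weights.sum() - 1.0) > 1e-9 or np.any(self.weights < 0):
            raise ValueError("mixture weights must be nonnegative and sum to 1")
        if np.any(self.sds <= 0):
            raise ValueError("mixture component SDs must be positive")
        if not (len(self.weights) == len(self.means) == len(self.sds)):
            raise ValueError("mixture parameter arrays must share a length")

    def mean(self) -> float:
        return float(self.weights @ self.means)

    def variance(self) -> float:
        m = self.mean()
        return float(self.weights @ ((self.means - m) ** 2 + self.sds ** 2))

    def skewness(self) -> float:
        m = self.mean()
        d = self.means - m
        m3 = float(self.weights @ (d ** 3 + 3.0 * d * self.sds ** 2))
        return m3 / self.variance() ** 1.5

    def cdf(self, x: float) -> float:
        return float(self.weights @ ndtr((x - self.means) / self.sds))


@dataclass
class ModelState:
    """One realisation of every latent quantity of the model."""

    countries: tuple
    regions: tuple
    region_of: tuple  # region index per country
    center_year: int
    covariate_names: tuple
    cov_center: np.ndarray
    cov_scale: np.ndarray
    beta0: float
    beta1: float
    b0r: np.ndarray
    b1r: np.ndarray
    b0c: np.ndarray
    b1c: np.ndarray
    d0: float
    d1: float
    d0r: np.ndarray
    d1r: np.ndarray
    d0c: np.ndarray
    d1c: np.ndarray
    gamma: np.ndarray
    u: np.ndarray  # (C, T) smooth deviations
    sigmas: dict
    lam_rural: float = 0.5
    lam_urban: float = 0.5
    s0_rural: float = 1.0
    s0_urban: float = 1.0

    def shape_for(self, stratum: str) -> tuple[float, float]:
        if stratum == "urban":
            return self.lam_urban, self.s0_urban
        return self.lam_rural, self.s0_rural


@dataclass
class MCMCSettings:
    """Sampler run lengths; retained draws = chains * (iterations - burnin) / thin."""

    chains: int = 2
    iterations: int = 3000
    burnin: int = 500
    thin: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.iterations <= self.burnin:
            raise ValueError("iterations must exceed burnin")
        if self.thin < 1 or self.chains < 1:
            raise ValueError("thin and chains must be >= 1")

    @property
    def draws_per_chain(self) -> int:
        return (self.iterations - self.burnin) // self.thin

    @property
    def total_draws(self) -> int:
        return self.chains * self.draws_per_chain


# ---------------------------------------------------------------------------
# Core model operations
# ---------------------------------------------------------------------------

def population_mixture(mu: float, spec: ModelSpec, shape: tuple[float, float]) -> MixtureDistribution:
    """Mixture with global shape ``(lam, s0)`` anchored so its mean is ``mu``."""
    lam, s0 = shape
    if s0 <= 0:
        raise ValueError("component SD scale s0 must be positive")
    return MixtureDistribution(
        weights=spec.weights_arr,
        means=mu + lam * spec.pattern_arr,
        sds=s0 * spec.ratios_arr,
    )


def combined_stratum_mixture(rural: MixtureDistribution, urban: MixtureDistribution,
                             p_urban: float) -> MixtureDistribution:
    """Population mixture when rural and urban children are reported together."""
    if not (0.0 <= p_urban <= 1.0):
        raise ValueError(f"p_urban must be in [0, 1], got {p_urban}")
    return MixtureDistribution(
        weights=np.concatenate([(1.0 - p_urban) * rural.weights, p_urban * urban.weights]),
        means=np.concatenate([rural.means, urban.means]),
        sds=np.concatenate([rural.sds, urban.sds]),
    )


def mean_z(country: str, stratum: str, year: int, state: ModelState,
           meta: CountryMeta) -> float:
    """Model mean Z for one country-year-stratum under ``state``."""
    if country not in state.countries:
        raise KeyError(f"country {country!r} not in fitted model")
    c = state.countries.index(country)
    r = state.region_of[c]
    t = float(year - state.center_year)
    ti = year - YEAR_MIN
    x_raw = meta.series.loc[year, list(state.covariate_names)].to_numpy(dtype=float)
    x = (x_raw - state.cov_center) / state.cov_scale
    mu_r = (state.beta0 + state.b0r[r] + state.b0c[c]
            + (state.beta1 + state.b1r[r] + state.b1c[c]) * t
            + state.u[c, ti] + float(x @ state.gamma))
    if stratum == "rural":
        return float(mu_r)
    offset = (state.d0 + state.d0r[r] + state.d0c[c]
              + (state.d1 + state.d1r[r] + state.d1c[c]) * t)
    if stratum == "urban":
        return float(mu_r + offset)
    if stratum == "combined":
        p = meta.urban_fraction(year)
        return float(mu_r + p * offset)
    raise ValueError(f"unknown stratum {stratum!r}")


def observation_variance(source: DataSource, spec: ModelSpec,
                         conversion_variance: float = 0.0) -> float:
    """Total error variance (Z^2) of a source's observed mean."""
    if conversion_variance < 0:
        raise ValueError("conversion_variance must be >= 0")
    v = source.se_mean ** 2 + spec.tau_national ** 2 + conversion_variance
    if source.coverage == "subnational":
        v += spec.tau_subnational_extra ** 2
    if source.age_coverage == "partial":
        v += spec.tau_partial_age_extra ** 2
    return float(v)


def _stratum_prevalence(mu, spec: ModelSpec, lam: float, s0: float):
    """P(Z < threshold) of the anchored mixture; vectorised over ``mu``."""
    mu = np.asarray(mu, dtype=float)
    arg = (spec.threshold - mu[..., None] - lam * spec.pattern_arr) / (s0 * spec.ratios_arr)
    return ndtr(arg) @ spec.weights_arr


def _stratum_prevalence_grad(mu, spec: ModelSpec, lam: float, s0: float):
    """d prevalence / d mu (negative)."""
    mu = np.asarray(mu, dtype=float)
    sds = s0 * spec.ratios_arr
    arg = (spec.threshold - mu[..., None] - lam * spec.pattern_arr) / sds
    phi = np.exp(-0.5 * arg ** 2) / np.sqrt(2.0 * np.pi)
    return -(phi / sds) @ spec.weights_arr


def _probit_obs(p_hat: float) -> float:
    return float(ndtri(np.clip(p_hat, _PCLIP, 1.0 - _PCLIP)))


def prevalence_obs_variance(source: DataSource, spec: ModelSpec,
                            conversion_variance: float = 0.0) -> float:
    """Delta-method variance of the probit-transformed observed prevalence."""
    p = float(np.clip(source.summary.prev_below, _PCLIP, 1.0 - _PCLIP))
    var_p = p * (1.0 - p) / source.n
    dens = np.exp(-0.5 * ndtri(p) ** 2) / np.sqrt(2.0 * np.pi)
    w = var_p / dens ** 2 + spec.tau_national ** 2 + conversion_variance
    if source.coverage == "subnational":
        w += spec.tau_subnational_extra ** 2
    if source.age_coverage == "partial":
        w += spec.tau_partial_age_extra ** 2
    return float(max(w, 1e-8))


def _source_prevalence(source: DataSource, state: ModelState, meta: CountryMeta,
                       spec: ModelSpec) -> float:
    """Model prevalence matching a source's stratum composition."""
    if source.stratum == "combined":
        p = meta.urban_fraction(source.year)
        mu_r = mean_z(source.country, "rural", source.year, state, meta)
        mu_u = mean_z(source.country, "urban", source.year, state, meta)
        pr = _stratum_prevalence(mu_r, spec, state.lam_rural, state.s0_rural)
        pu = _stratum_prevalence(mu_u, spec, state.lam_urban, state.s0_urban)
        return float((1.0 - p) * pr + p * pu)
    mu = mean_z(source.country, source.stratum, source.year, state, meta)
    lam, s0 = state.shape_for(source.stratum)
    return float(_stratum_prevalence(mu, spec, lam, s0))


def log_likelihood(state: ModelState, sources: list[DataSource],
                   meta: dict[str, CountryMeta], spec: ModelSpec,
                   conversion_variances=None) -> float:
    """Sum of per-source Gaussian mean terms and probit prevalence terms.

    ``sources`` must already be expressed against the WHO standards;
    ``conversion_variances`` carries the per-source extra variance from any
    NCHS conversion (zeros when absent).
    """
    if conversion_variances is None:
        conversion_variances = np.zeros(len(sources))
    total = 0.0
    for s, cv in zip(sources, conversion_variances):
        m = meta[s.country]
        mu = mean_z(s.country, s.stratum, s.year, state, m)
        if not np.isfinite(mu):
            raise ValueError("non-finite model mean")
        v = observation_variance(s, spec, cv)
        resid = s.summary.mean_z - mu
        total += -0.5 * (_LOG2PI + np.log(v)) - resid ** 2 / (2.0 * v)
        if s.summary.prev_below is not None:
            p_model = float(np.clip(_source_prevalence(s, state, m, spec),
                                    _PCLIP, 1.0 - _PCLIP))
            w = prevalence_obs_variance(s, spec, cv)
            dev = _probit_obs(s.summary.prev_below) - ndtri(p_model)
            total += -0.5 * (_LOG2PI + np.log(w)) - dev ** 2 / (2.0 * w)
    return float(total)


def prepare_sources(sources: list[DataSource], who: ReferenceTable | None = None,
                    nchs: ReferenceTable | None = None,
                    age_range: tuple[float, float] = (0.0, 60.0),
                    ) -> tuple[list[DataSource], np.ndarray]:
    """Convert NCHS-referenced sources to WHO Z space.

    Returns WHO-referenced sources and the per-source conversion variance.
    """
    if any(s.summary.reference == "NCHS1977" for s in sources):
        who = who or ReferenceTable.packaged("WHO2006")
        nchs = nchs or ReferenceTable.packaged("NCHS1977")
    out, cvs = [], []
    for s in sources:
        if s.summary.reference == "NCHS1977":
            metric = "height" if s.metric == "haz" else "weight"
            conv, cv = convert_summary_nchs_to_who(s.summary, age_range, who, nchs, metric)
            scale = conv.sd_z / s.summary.sd_z  # rescale the reported SE too
            out.append(DataSource(
                country=s.country, year=s.year, stratum=s.stratum,
                coverage=s.coverage, age_coverage=s.age_coverage, metric=s.metric,
                summary=conv, n=s.n, se_mean=s.se_mean * scale,
            ))
            cvs.append(cv)
        else:
            out.append(s)
            cvs.append(0.0)
    return out, np.asarray(cvs)


# ---------------------------------------------------------------------------
# Internal fitting machinery
# ---------------------------------------------------------------------------

class _Layout:
    """Positions of the linear-effect blocks inside the parameter vector."""

    def __init__(self, R: int, C: int, T: int, G: int):
        cursor = 0

        def block(n):
            nonlocal cursor
            sl = slice(cursor, cursor + n)
            cursor += n
            return sl

        self.beta0 = block(1)
        self.beta1 = block(1)
        self.b0r = block(R)
        self.b1r = block(R)
        self.b0c = block(C)
        self.b1c = block(C)
        self.d0 = block(1)
        self.d1 = block(1)
        self.d0r = block(R)
        self.d1r = block(R)
        self.d0c = block(C)
        self.d1c = block(C)
        self.gamma = block(G)
        self.u = block(C * T)
        self.p = cursor
        self.R, self.C, self.T, self.G = R, C, T, G

    # blocks whose prior SD is an estimated variance component
    def sigma_blocks(self, spec: ModelSpec):
        i, s = spec.prior_scale_intercept_sd, spec.prior_scale_slope_sd
        return [
            ("b0r", self.b0r, i), ("b1r", self.b1r, s),
            ("b0c", self.b0c, i), ("b1c", self.b1c, s),
            ("d0r", self.d0r, i), ("d1r", self.d1r, s),
            ("d0c", self.d0c, i), ("d1c", self.d1c, s),
        ]


def standardize_covariates(meta: dict[str, CountryMeta], covariates=COVARIATE_COLUMNS):
    """Stack covariates to (C, T, G) and standardise over all country-years."""
    countries = sorted(meta)
    X = np.stack([meta[c].covariates(covariates) for c in countries])
    center = X.reshape(-1, X.shape[-1]).mean(axis=0)
    scale = X.reshape(-1, X.shape[-1]).std(axis=0)
    scale = np.where(scale < 1e-12, 1.0, scale)
    return (X - center) / scale, center, scale


def _rw2_structure(T: int, tc: np.ndarray):
    D2 = np.zeros((T - 2, T))
    for i in range(T - 2):
        D2[i, i], D2[i, i + 1], D2[i, i + 2] = 1.0, -2.0, 1.0
    K = D2.T @ D2
    c1 = np.ones(T) / np.sqrt(T)
    c2 = tc / np.linalg.norm(tc)
    con = _KAPPA * (np.outer(c1, c1) + np.outer(c2, c2))
    return K, con


class _Problem:
    """Vectorised design, likelihood and prior machinery for one fit."""

    def __init__(self, sources: list[DataSource], cvs: np.ndarray,
                 meta: dict[str, CountryMeta], spec: ModelSpec):
        self.spec = spec
        self.countries = tuple(sorted(meta))
        self.regions = tuple(sorted({m.region for m in meta.values()}))
        self.region_of = tuple(self.regions.index(meta[c].region) for c in self.countries)
        self.meta = meta
        missing = {s.country for s in sources} - set(self.countries)
        if missing:
            raise KeyError(f"sources reference countries absent from metadata: {sorted(missing)}")
        self.years = np.arange(YEAR_MIN, YEAR_MAX + 1)
        self.T = len(self.years)
        self.tc = (self.years - spec.center_year).astype(float)
        self.X, self.cov_center, self.cov_scale = standardize_covariates(meta, spec.covariates)
        C, R, G = len(self.countries), len(self.regions), len(spec.covariates)
        self.layout = _Layout(R, C, self.T, G)
        self.K27, self.con = _rw2_structure(self.T, self.tc)

        cidx = {c: i for i, c in enumerate(self.countries)}
        rows, self.y, self.v = [], [], []
        prev_rows_r, prev_rows_u, prev_wr, prev_wu = [], [], [], []
        self.yp, self.wp = [], []
        for s, cv in zip(sources, cvs):
            c = cidx[s.country]
            ti = s.year - YEAR_MIN
            p_urb = meta[s.country].urban_fraction(s.year)
            uw = {"rural": 0.0, "urban": 1.0, "combined": p_urb}[s.stratum]
            rows.append(self._row(c, ti, uw))
            self.y.append(s.summary.mean_z)
            self.v.append(observation_variance(s, spec, cv))
            if s.summary.prev_below is not None:
                prev_rows_r.append(self._row(c, ti, 0.0))
                prev_rows_u.append(self._row(c, ti, 1.0))
                wr, wu = {"rural": (1.0, 0.0), "urban": (0.0, 1.0),
                          "combined": (1.0 - p_urb, p_urb)}[s.stratum]
                prev_wr.append(wr)
                prev_wu.append(wu)
                self.yp.append(_probit_obs(s.summary.prev_below))
                self.wp.append(prevalence_obs_variance(s, spec, cv))
        self.A = np.array(rows) if rows else np.zeros((0, self.layout.p))
        self.y = np.asarray(self.y)
        self.v = np.asarray(self.v)
        self.n_prev = len(self.yp)
        self.Ar_prev = np.array(prev_rows_r) if prev_rows_r else np.zeros((0, self.layout.p))
        self.Au_prev = np.array(prev_rows_u) if prev_rows_u else np.zeros((0, self.layout.p))
        self.prev_wr = np.asarray(prev_wr)
        self.prev_wu = np.asarray(prev_wu)
        self.yp = np.asarray(self.yp)
        self.wp = np.asarray(self.wp)
        # fixed Gaussian-likelihood pieces (observation variances do not move)
        self.M = (self.A.T * (1.0 / self.v)) @ self.A if len(self.y) else np.zeros((self.layout.p,) * 2)
        self.b_mean = self.A.T @ (self.y / self.v) if len(self.y) else np.zeros(self.layout.p)
        self._fixed_prior = np.zeros(self.layout.p)
        for sl in (self.layout.beta0, self.layout.beta1, self.layout.d0,
                   self.layout.d1, self.layout.gamma):
            self._fixed_prior[sl] = 1.0 / spec.prior_sd_fixed ** 2

    def _row(self, c: int, ti: int, uw: float) -> np.ndarray:
        l = self.layout
        a = np.zeros(l.p)
        r = self.region_of[c]
        t = self.tc[ti]
        a[l.beta0] = 1.0
        a[l.b0r.start + r] = 1.0
        a[l.b0c.start + c] = 1.0
        a[l.beta1] = t
        a[l.b1r.start + r] = t
        a[l.b1c.start + c] = t
        a[l.gamma] = self.X[c, ti]
        a[l.u.start + c * self.T + ti] = 1.0
        if uw:
            a[l.d0] = uw
            a[l.d0r.start + r] = uw
            a[l.d0c.start + c] = uw
            a[l.d1] = uw * t
            a[l.d1r.start + r] = uw * t
            a[l.d1c.start + c] = uw * t
        return a

    # -- prior ---------------------------------------------------------------

    def prior_precision(self, sigmas: dict) -> np.ndarray:
        l = self.layout
        P = np.zeros((l.p, l.p))
        d = self._fixed_prior.copy()
        for name, sl, _ in l.sigma_blocks(self.spec):
            d[sl] = 1.0 / sigmas[name] ** 2
        np.fill_diagonal(P, d)
        block = self.K27 / sigmas["u"] ** 2 + self.con
        for c in range(l.C):
            sl = slice(l.u.start + c * self.T, l.u.start + (c + 1) * self.T)
            P[sl, sl] = block
        return P

    # -- mean surfaces -------------------------------------------------------

    def means(self, theta: np.ndarray):
        """Rural and urban mean-Z surfaces (C, T) implied by ``theta``."""
        l = self.layout
        ro = np.asarray(self.region_of)
        b0 = theta[l.beta0] + theta[l.b0r][ro] + theta[l.b0c]
        b1 = theta[l.beta1] + theta[l.b1r][ro] + theta[l.b1c]
        u = theta[l.u].reshape(l.C, self.T)
        cov = self.X @ theta[l.gamma]
        mu_r = b0[:, None] + np.outer(b1, self.tc) + u + cov
        off0 = theta[l.d0] + theta[l.d0r][ro] + theta[l.d0c]
        off1 = theta[l.d1] + theta[l.d1r][ro] + theta[l.d1c]
        mu_u = mu_r + off0[:, None] + np.outer(off1, self.tc)
        return mu_r, mu_u

    # -- likelihood pieces ---------------------------------------------------

    def mean_loglik_quad(self, theta: np.ndarray) -> float:
        if not len(self.y):
            return 0.0
        r = self.y - self.A @ theta
        return float(-0.5 * np.sum(r ** 2 / self.v))

    def prev_eval(self, theta: np.ndarray, lam_r, s0_r, lam_u, s0_u):
        """Probit model prevalence, its Jacobian wrt theta, and the log-likelihood."""
        spec = self.spec
        mu_r = self.Ar_prev @ theta
        mu_u = self.Au_prev @ theta
        fr = _stratum_prevalence(mu_r, spec, lam_r, s0_r)
        fu = _stratum_prevalence(mu_u, spec, lam_u, s0_u)
        p_model = np.clip(self.prev_wr * fr + self.prev_wu * fu, _PCLIP, 1.0 - _PCLIP)
        t = ndtri(p_model)
        dens = np.exp(-0.5 * t ** 2) / np.sqrt(2.0 * np.pi)
        dfr = _stratum_prevalence_grad(mu_r, spec, lam_r, s0_r)
        dfu = _stratum_prevalence_grad(mu_u, spec, lam_u, s0_u)
        J = ((self.prev_wr * dfr / dens)[:, None] * self.Ar_prev
             + (self.prev_wu * dfu / dens)[:, None] * self.Au_prev)
        ll = float(np.sum(-0.5 * (self.yp - t) ** 2 / self.wp))
        return t, J, ll

    def prev_loglik_mu(self, mu_r, mu_u, lam_r, s0_r, lam_u, s0_u) -> float:
        if not self.n_prev:
            return 0.0
        spec = self.spec
        fr = _stratum_prevalence(mu_r, spec, lam_r, s0_r)
        fu = _stratum_prevalence(mu_u, spec, lam_u, s0_u)
        p_model = np.clip(self.prev_wr * fr + self.prev_wu * fu, _PCLIP, 1.0 - _PCLIP)
        return float(np.sum(-0.5 * (self.yp - ndtri(p_model)) ** 2 / self.wp))

    def prev_loglik(self, theta, lam_r, s0_r, lam_u, s0_u) -> float:
        if not self.n_prev:
            return 0.0
        return self.prev_loglik_mu(self.Ar_prev @ theta, self.Au_prev @ theta,
                                   lam_r, s0_r, lam_u, s0_u)


def _gauss_approx(prob: _Problem, P, th, shape, newton_iters: int):
    """Gaussian approximation of the linear-effect conditional.

    Linearises the probit prevalence terms at ``th`` (newton_iters=1: the
    tangent proposal, exact at the current point) or iterates the
    linearisation toward the conditional mode.
    """
    lam_r, s0_r, lam_u, s0_u = shape
    x = th
    for _ in range(newton_iters):
        t0, J, _ = prob.prev_eval(x, lam_r, s0_r, lam_u, s0_u)
        Q = P + prob.M + (J.T * (1.0 / prob.wp)) @ J
        b = prob.b_mean + J.T @ ((prob.yp - t0 + J @ x) / prob.wp)
        L = np.linalg.cholesky(Q)
        x = cho_solve((L, True), b)
    return L, Q, x


def _theta_update(prob: _Problem, theta, sigmas, shape, rng, newton_iters: int = 1):
    """Joint draw of all linear effects.

    Without prevalence data this is the exact Gaussian full conditional.
    With prevalence data the proposal is a Gaussian approximation with the
    probit terms linearised (at the current state, or iterated toward the
    conditional mode), corrected by Metropolis-Hastings; the construction
    is deterministic given the start point, so the reverse proposal
    density is well defined.
    """
    P = prob.prior_precision(sigmas)
    lam_r, s0_r, lam_u, s0_u = shape

    if not prob.n_prev:
        Q = P + prob.M
        L = np.linalg.cholesky(Q)
        m = cho_solve((L, True), prob.b_mean)
        z = rng.standard_normal(prob.layout.p)
        return m + solve_triangular(L.T, z, lower=False), True

    def build(th):
        return _gauss_approx(prob, P, th, shape, newton_iters)

    def logq(L_, Q_, m_, x):
        d = x - m_
        return float(np.sum(np.log(np.diag(L_))) - 0.5 * d @ (Q_ @ d))

    def logtarget(th):
        return (-0.5 * th @ (P @ th) + prob.mean_loglik_quad(th)
                + prob.prev_loglik(th, lam_r, s0_r, lam_u, s0_u))

    L, Q, m = build(theta)
    z = rng.standard_normal(prob.layout.p)
    prop = m + solve_triangular(L.T, z, lower=False)
    L2, Q2, m2 = build(prop)
    log_alpha = (logtarget(prop) - logtarget(theta)
                 + logq(L2, Q2, m2, theta) - logq(L, Q, m, prop))
    if np.log(rng.uniform()) < log_alpha:
        return prop, True
    return theta, False


_LOG_SIGMA_MIN = float(np.log(1e-6))  # keeps 1/sigma^2 finite in float64
_LOG_SIGMA_MAX = float(np.log(50.0))


def _update_sigmas(prob: _Problem, theta, sigmas, rng):
    spec = prob.spec
    l = prob.layout
    for name, sl, scale in l.sigma_blocks(spec):
        vals = theta[sl]
        n, q = len(vals), float(vals @ vals)

        def logpost(log_s, n=n, q=q, scale=scale):
            if not (_LOG_SIGMA_MIN < log_s < _LOG_SIGMA_MAX):
                return -np.inf
            s = np.exp(log_s)
            return -n * log_s - q / (2.0 * s * s) - s * s / (2.0 * scale ** 2) + log_s

        sigmas[name] = float(np.exp(slice_sample(logpost, np.log(sigmas[name]), rng, width=1.0)))
    # RW2 smoothness SD: rank T-2 per country
    u = theta[l.u].reshape(l.C, prob.T)
    q = float(np.einsum("ct,ts,cs->", u, prob.K27, u))
    n = l.C * (prob.T - 2)
    scale = spec.prior_scale_rw2_sd

    def logpost_u(log_s):
        if not (_LOG_SIGMA_MIN < log_s < _LOG_SIGMA_MAX):
            return -np.inf
        s = np.exp(log_s)
        return -n * log_s - q / (2.0 * s * s) - s * s / (2.0 * scale ** 2) + log_s

    sigmas["u"] = float(np.exp(slice_sample(logpost_u, np.log(sigmas["u"]), rng, width=1.0)))
    return sigmas


def _rescale_moves(prob: _Problem, theta, sigmas, shape, rng, step: float = 0.7):
    """Joint multiplicative moves on (sigma_b, theta_b) per hierarchy block.

    The centred Gibbs updates of a variance component given its effects can
    trap both near zero (the funnel's neck). Scaling a block's effects and
    its SD by a common factor moves along the funnel; the acceptance ratio
    carries the scale-group volume correction c^d with d the number of
    scaled coordinates net of the prior's scale-invariant rank.
    """
    l = prob.layout
    lam_r, s0_r, lam_u, s0_u = shape
    blocks = [(name, sl, scale, 1.0) for name, sl, scale in l.sigma_blocks(prob.spec)]
    # RW2 block: prior rank (T-2) per country => net exponent 2C + 1
    blocks.append(("u", l.u, prob.spec.prior_scale_rw2_sd, 2.0 * l.C + 1.0))
    mu_r0 = prob.Ar_prev @ theta if prob.n_prev else None
    mu_u0 = prob.Au_prev @ theta if prob.n_prev else None
    r0 = prob.y - prob.A @ theta if len(prob.y) else None
    for name, sl, scale, d_eff in blocks:
        c = float(np.exp(step * rng.standard_normal()))
        s_new = sigmas[name] * c
        if not (1e-6 < s_new < 50.0):
            continue
        vals = theta[sl]
        log_alpha = d_eff * np.log(c) \
            - (s_new ** 2 - sigmas[name] ** 2) / (2.0 * scale ** 2)
        if r0 is not None:
            col = prob.A[:, sl] @ vals
            r1 = r0 - (c - 1.0) * col
            log_alpha += -0.5 * float(np.sum((r1 ** 2 - r0 ** 2) / prob.v))
        if prob.n_prev:
            dr = (c - 1.0) * (prob.Ar_prev[:, sl] @ vals)
            du = (c - 1.0) * (prob.Au_prev[:, sl] @ vals)
            log_alpha += (prob.prev_loglik_mu(mu_r0 + dr, mu_u0 + du,
                                              lam_r, s0_r, lam_u, s0_u)
                          - prob.prev_loglik_mu(mu_r0, mu_u0,
                                                lam_r, s0_r, lam_u, s0_u))
        if name == "u":
            u = vals.reshape(l.C, prob.T)
            quad_con = float(np.einsum("ct,ts,cs->", u, prob.con, u))
            log_alpha += -0.5 * (c ** 2 - 1.0) * quad_con
        if np.log(rng.uniform()) < log_alpha:
            theta[sl] = vals * c
            sigmas[name] = s_new
            if r0 is not None:
                r0 = r1
            if prob.n_prev:
                mu_r0 = mu_r0 + dr
                mu_u0 = mu_u0 + du
    return theta, sigmas


def _update_shape(prob: _Problem, theta, shape, rng):
    spec = prob.spec
    lam_r, s0_r, lam_u, s0_u = shape

    def ll(lr, sr, lu, su):
        return prob.prev_loglik(theta, lr, sr, lu, su)

    def logpost_lam_r(x):
        if not (0.0 <= x < 20.0):
            return -np.inf
        return ll(x, s0_r, lam_u, s0_u) - x * x / (2.0 * spec.prior_scale_lam ** 2)

    lam_r = slice_sample(logpost_lam_r, lam_r, rng, width=0.3)

    def logpost_s0_r(log_s):
        if not (np.log(1e-3) < log_s < np.log(50.0)):
            return -np.inf
        s = np.exp(log_s)
        return (ll(lam_r, s, lam_u, s0_u)
                - s * s / (2.0 * spec.prior_scale_s0 ** 2) + log_s)

    s0_r = float(np.exp(slice_sample(logpost_s0_r, np.log(s0_r), rng, width=0.3)))

    def logpost_lam_u(x):
        if not (0.0 <= x < 20.0):
            return -np.inf
        return ll(lam_r, s0_r, x, s0_u) - x * x / (2.0 * spec.prior_scale_lam ** 2)

    lam_u = slice_sample(logpost_lam_u, lam_u, rng, width=0.3)

    def logpost_s0_u(log_s):
        if not (np.log(1e-3) < log_s < np.log(50.0)):
            return -np.inf
        s = np.exp(log_s)
        return (ll(lam_r, s0_r, lam_u, s)
                - s * s / (2.0 * spec.prior_scale_s0 ** 2) + log_s)

    s0_u = float(np.exp(slice_sample(logpost_s0_u, np.log(s0_u), rng, width=0.3)))
    return (lam_r, s0_r, lam_u, s0_u)


# ---------------------------------------------------------------------------
# Fit result container
# ---------------------------------------------------------------------------

_SIGMA_NAMES = ("b0r", "b1r", "b0c", "b1c", "d0r", "d1r", "d0c", "d1c", "u")
_SHAPE_NAMES = ("lam_rural", "s0_rural", "lam_urban", "s0_urban")


@dataclass
class FitResult:
    """Posterior draws of the model and the derived mean-Z surfaces.

    Arrays carry an explicit chain dimension: ``rural_mean`` and
    ``urban_mean`` have shape (chains, draws, countries, years), ``theta``
    (chains, draws, p), each hyperparameter (chains, draws).
    """

    countries: tuple
    regions: tuple
    region_of: tuple
    years: np.ndarray
    spec: ModelSpec
    covariate_names: tuple
    cov_center: np.ndarray
    cov_scale: np.ndarray
    rural_mean: np.ndarray
    urban_mean: np.ndarray
    theta: np.ndarray
    hyper: dict
    diagnostics: dict
    accept_rate: float
    layout_blocks: dict

    @property
    def n_draws(self) -> int:
        return self.rural_mean.shape[0] * self.rural_mean.shape[1]

    def _flat(self, arr: np.ndarray) -> np.ndarray:
        return arr.reshape((-1,) + arr.shape[2:])

    def hyper_draws(self, name: str) -> np.ndarray:
        return self._flat(self.hyper[name])

    def mean_draws(self, country: str, stratum: str,
                   meta: dict[str, CountryMeta] | None = None) -> np.ndarray:
        """Posterior draws of mean Z, shape (n_draws, n_years)."""
        c = self.countries.index(country)
        mu_r = self._flat(self.rural_mean)[:, c, :]
        mu_u = self._flat(self.urban_mean)[:, c, :]
        if stratum == "rural":
            return mu_r
        if stratum == "urban":
            return mu_u
        if stratum == "combined":
            if meta is None:
                raise ValueError("combined-stratum draws need country metadata")
            p = np.array([meta[country].urban_fraction(int(y)) for y in self.years])
            return (1.0 - p) * mu_r + p * mu_u
        raise ValueError(f"unknown stratum {stratum!r}")

    def prevalence_draws(self, country: str, stratum: str,
                         meta: dict[str, CountryMeta] | None = None) -> np.ndarray:
        """Posterior draws of P(Z < threshold), shape (n_draws, n_years)."""
        if stratum == "combined":
            if meta is None:
                raise ValueError("combined-stratum draws need country metadata")
            p = np.array([meta[country].urban_fraction(int(y)) for y in self.years])
            return ((1.0 - p) * self.prevalence_draws(country, "rural")
                    + p * self.prevalence_draws(country, "urban"))
        mu = self.mean_draws(country, stratum)
        lam = self.hyper_draws(f"lam_{stratum}")[:, None, None]
        s0 = self.hyper_draws(f"s0_{stratum}")[:, None, None]
        spec = self.spec
        arg = (spec.threshold - mu[..., None] - lam * spec.pattern_arr) / (s0 * spec.ratios_arr)
        return ndtr(arg) @ spec.weights_arr

    def state(self, chain: int, draw: int) -> ModelState:
        """Reconstruct the full ModelState of one retained draw."""
        th = self.theta[chain, draw]
        lb = {k: slice(v[0], v[1]) for k, v in self.layout_blocks.items()}
        C = len(self.countries)
        T = len(self.years)
        sigmas = {k: float(self.hyper[f"sigma_{k}"][chain, draw]) for k in _SIGMA_NAMES}
        return ModelState(
            countries=self.countries, regions=self.regions, region_of=self.region_of,
            center_year=self.spec.center_year, covariate_names=self.covariate_names,
            cov_center=self.cov_center, cov_scale=self.cov_scale,
            beta0=float(th[lb["beta0"]][0]), beta1=float(th[lb["beta1"]][0]),
            b0r=th[lb["b0r"]], b1r=th[lb["b1r"]], b0c=th[lb["b0c"]], b1c=th[lb["b1c"]],
            d0=float(th[lb["d0"]][0]), d1=float(th[lb["d1"]][0]),
            d0r=th[lb["d0r"]], d1r=th[lb["d1r"]], d0c=th[lb["d0c"]], d1c=th[lb["d1c"]],
            gamma=th[lb["gamma"]], u=th[lb["u"]].reshape(C, T), sigmas=sigmas,
            lam_rural=float(self.hyper["lam_rural"][chain, draw]),
            s0_rural=float(self.hyper["s0_rural"][chain, draw]),
            lam_urban=float(self.hyper["lam_urban"][chain, draw]),
            s0_urban=float(self.hyper["s0_urban"][chain, draw]),
        )

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        header = {
            "countries": list(self.countries),
            "regions": list(self.regions),
            "region_of": list(self.region_of),
            "covariate_names": list(self.covariate_names),
            "spec": asdict(self.spec),
            "diagnostics": self.diagnostics,
            "accept_rate": self.accept_rate,
            "layout_blocks": {k: list(v) for k, v in self.layout_blocks.items()},
            "hyper_names": list(self.hyper),
        }
        arrays = {f"hyper_{k}": v for k, v in self.hyper.items()}
        np.savez_compressed(
            path, header=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8),
            years=self.years, cov_center=self.cov_center, cov_scale=self.cov_scale,
            rural_mean=self.rural_mean, urban_mean=self.urban_mean, theta=self.theta,
            **arrays,
        )

    @classmethod
    def load(cls, path) -> "FitResult":
        with np.load(path) as z:
            header = json.loads(bytes(z["header"].tobytes()).decode())
            hyper = {k: z[f"hyper_{k}"] for k in header["hyper_names"]}
            return cls(
                countries=tuple(header["countries"]),
                regions=tuple(header["regions"]),
                region_of=tuple(header["region_of"]),
                years=z["years"],
                spec=ModelSpec(**{k: (tuple(v) if isinstance(v, list) else v)
                                  for k, v in header["spec"].items()}),
                covariate_names=tuple(header["covariate_names"]),
                cov_center=z["cov_center"], cov_scale=z["cov_scale"],
                rural_mean=z["rural_mean"], urban_mean=z["urban_mean"], theta=z["theta"],
                hyper=hyper, diagnostics=header["diagnostics"],
                accept_rate=float(header["accept_rate"]),
                layout_blocks={k: tuple(v) for k, v in header["layout_blocks"].items()},
            )


def _diagnostics(hyper: dict, threshold: float) -> dict:
    """Effective sample sizes and split-chain scale reduction via arviz."""
    import arviz as az
    monitored = {k: v for k, v in hyper.items()}
    idata = az.from_dict(posterior=monitored)
    ess = az.ess(idata)
    out = {"ess": {k: float(ess[k].values) for k in monitored},
           "rhat": {}, "warnings": []}
    if next(iter(monitored.values())).shape[0] >= 2:
        with _pywarnings.catch_warnings():
            _pywarnings.simplefilter("ignore")
            rhat = az.rhat(idata)
        for k in monitored:
            r = float(rhat[k].values)
            out["rhat"][k] = r
            if np.isfinite(r) and r > threshold:
                out["warnings"].append(
                    f"split-chain scale reduction {r:.3f} > {threshold} for {k}"
                )
    return out


def fit(sources: list[DataSource], meta: dict[str, CountryMeta],
        spec: ModelSpec | None = None, mcmc: MCMCSettings | None = None,
        who_table: ReferenceTable | None = None,
        nchs_table: ReferenceTable | None = None) -> FitResult:
    """Fit the hierarchical mixture model by MCMC.

    NCHS-referenced sources are converted to WHO Z space first; their
    conversion variance is added to the observation variance. Draws are
    deterministic given ``mcmc.seed``.
    """
    if not sources:
        raise ValueError("at least one data source is required")
    spec = spec or ModelSpec()
    mcmc = mcmc or MCMCSettings()
    conv_sources, cvs = prepare_sources(sources, who_table, nchs_table)
    prob = _Problem(conv_sources, cvs, meta, spec)
    l = prob.layout
    D = mcmc.draws_per_chain
    theta_out = np.zeros((mcmc.chains, D, l.p))
    rural_out = np.zeros((mcmc.chains, D, l.C, prob.T))
    urban_out = np.zeros((mcmc.chains, D, l.C, prob.T))
    hyper_out = {f"sigma_{k}": np.zeros((mcmc.chains, D)) for k in _SIGMA_NAMES}
    hyper_out.update({k: np.zeros((mcmc.chains, D)) for k in _SHAPE_NAMES})
    for k in ("beta0", "beta1", "d0", "d1"):
        hyper_out[k] = np.zeros((mcmc.chains, D))
    n_accept = n_total = 0

    for chain in range(mcmc.chains):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=mcmc.seed,
                                                           spawn_key=(chain,)))
        theta = np.zeros(l.p)
        sigmas = {name: 0.5 * scale * float(np.exp(0.3 * rng.standard_normal()))
                  for name, _, scale in l.sigma_blocks(spec)}
        sigmas["u"] = 0.5 * spec.prior_scale_rw2_sd * float(np.exp(0.3 * rng.standard_normal()))
        shape = (0.5 * float(np.exp(0.2 * rng.standard_normal())), 1.0,
                 0.5 * float(np.exp(0.2 * rng.standard_normal())), 1.0)
        # start at a draw from the Gaussian approximation at the conditional
        # mode so the first MH steps are not dominated by initialisation
        P0 = prob.prior_precision(sigmas)
        L0, _, m0 = _gauss_approx(prob, P0, theta, shape,
                                  newton_iters=6 if prob.n_prev else 1)
        theta = m0 + solve_triangular(L0.T, rng.standard_normal(l.p), lower=False)
        kept = 0
        for it in range(mcmc.iterations):
            theta, accepted = _theta_update(prob, theta, sigmas, shape, rng,
                                            newton_iters=1 if it % 2 == 0 else 3)
            n_accept += accepted
            n_total += 1
            sigmas = _update_sigmas(prob, theta, sigmas, rng)
            theta, sigmas = _rescale_moves(prob, theta, sigmas, shape, rng)
            shape = _update_shape(prob, theta, shape, rng)
            if it >= mcmc.burnin and (it - mcmc.burnin) % mcmc.thin == 0 and kept < D:
                theta_out[chain, kept] = theta
                mu_r, mu_u = prob.means(theta)
                rural_out[chain, kept] = mu_r
                urban_out[chain, kept] = mu_u
                for name in _SIGMA_NAMES:
                    hyper_out[f"sigma_{name}"][chain, kept] = sigmas[name]
                for name, val in zip(_SHAPE_NAMES, (shape[0], shape[1], shape[2], shape[3])):
                    hyper_out[name][chain, kept] = val
                hyper_out["beta0"][chain, kept] = theta[l.beta0][0]
                hyper_out["beta1"][chain, kept] = theta[l.beta1][0]
                hyper_out["d0"][chain, kept] = theta[l.d0][0]
                hyper_out["d1"][chain, kept] = theta[l.d1][0]
                kept += 1

    diagnostics = _diagnostics(hyper_out, spec.rhat_threshold)
    blocks = {name: (getattr(l, name).start, getattr(l, name).stop)
              for name in ("beta0", "beta1", "b0r", "b1r", "b0c", "b1c",
                           "d0", "d1", "d0r", "d1r", "d0c", "d1c", "gamma", "u")}
    return FitResult(
        countries=prob.countries, regions=prob.regions, region_of=prob.region_of,
        years=prob.years, spec=spec, covariate_names=tuple(spec.covariates),
        cov_center=prob.cov_center, cov_scale=prob.cov_scale,
        rural_mean=rural_out, urban_mean=urban_out, theta=theta_out,
        hyper=hyper_out, diagnostics=diagnostics,
        accept_rate=n_accept / max(n_total, 1), layout_blocks=blocks,
    )


__all__ = [
    "ModelSpec", "MixtureDistribution", "ModelState", "MCMCSettings", "FitResult",
    "population_mixture", "combined_stratum_mixture", "mean_z",
    "observation_variance", "prevalence_obs_variance", "log_likelihood",
    "prepare_sources", "standardize_covariates", "fit",
]
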