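"""Posterior summaries: credible intervals, prevalences, PPs, aggregates, counts.

Credible intervals are percentiles 2.5-97.5 of the posterior draws, using the
linear-interpolation percentile convention. Regional and global quantities
are population-weighted averages of country draws, computed draw-wise; the
weights for rural (urban) quantities are the rural (urban) under-5
populations, so that the combined-stratum aggregate is exactly the
urban-fraction-weighted average of the stratum aggregates.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr

from .data_model import CountryMeta, EstimateRow
from .hiermix_model import FitResult, MixtureDistribution


def summarize(draws) -> tuple[float, float, float]:
    """Posterior mean and 2.5/97.5 percentile credible bounds of a draw vector."""
    draws = np.asarray(draws, dtype=float)
    if draws.ndim != 1 or len(draws) < 2:
        raise ValueError("need a 1-d vector of at least 2 draws")
    if not np.all(np.isfinite(draws)):
        raise ValueError("draws must be finite")
    lo, hi = np.percentile(draws, [2.5, 97.5])
    return float(draws.mean()), float(lo), float(hi)


def prevalence_below(mix: MixtureDistribution, threshold: float = -2.0) -> float:
    """P(Z < threshold) under a normal mixture (stunting/underweight definition)."""
    return float(mix.weights @ ndtr((threshold - mix.means) / mix.sds))


def pp_direction(change_draws) -> float:
    """Posterior probability that a change is truly in the direction estimated.

    0.5 means an increase is indistinguishable from a decrease; draws exactly
    at zero split equally between the directions.
    """
    draws = np.asarray(change_draws, dtype=float)
    if draws.ndim != 1 or len(draws) < 2:
        raise ValueError("need a 1-d vector of at least 2 draws")
    f = float(np.mean(draws > 0) + 0.5 * np.mean(draws == 0))
    return max(f, 1.0 - f)


def aggregate_population_weighted(member_draws, weights) -> np.ndarray:
    """Draw-wise weighted average of member draw vectors; weights are normalised."""
    arrs = [np.asarray(d, dtype=float) for d in member_draws]
    if len({a.shape for a in arrs}) != 1:
        raise ValueError("members must have equal draw counts")
    w = np.asarray(weights, dtype=float)
    if len(w) != len(arrs):
        raise ValueError("one weight per member required")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be nonnegative and not all zero")
    w = w / w.sum()
    return np.tensordot(w, np.stack(arrs), axes=1)


def count_undernourished(prev_rural, prev_urban, pop_under5: float,
                         urban_fraction: float) -> dict[str, np.ndarray]:
    """Draw-wise counts of undernourished children by stratum and in total."""
    pr = np.asarray(prev_rural, dtype=float)
    pu = np.asarray(prev_urban, dtype=float)
    if np.any((pr < 0) | (pr > 1)) or np.any((pu < 0) | (pu > 1)):
        raise ValueError("prevalences must be in [0, 1]")
    if not (0.0 <= urban_fraction <= 1.0):
        raise ValueError("urban_fraction must be in [0, 1]")
    rural = pr * (1.0 - urban_fraction) * pop_under5
    urban = pu * urban_fraction * pop_under5
    return {"rural": rural, "urban": urban, "total": rural + urban}


# ---------------------------------------------------------------------------
# Aggregation across the fitted hierarchy
# ---------------------------------------------------------------------------

def _stratum_weights(meta: dict[str, CountryMeta], countries, year: int, stratum: str):
    w = []
    for c in countries:
        pop = meta[c].pop_under5(year)
        p = meta[c].urban_fraction(year)
        w.append({"rural": (1 - p) * pop, "urban": p * pop, "combined": pop}[stratum])
    return np.asarray(w)


def group_draws(fit: FitResult, meta: dict[str, CountryMeta], countries,
                stratum: str, kind: str = "mean") -> np.ndarray:
    """Population-weighted draws (n_draws, n_years) for a group of countries."""
    fn = fit.mean_draws if kind == "mean" else fit.prevalence_draws
    member = [fn(c, stratum, meta) for c in countries]
    out = np.empty_like(member[0])
    for t, year in enumerate(fit.years):
        w = _stratum_weights(meta, countries, int(year), stratum)
        out[:, t] = aggregate_population_weighted([m[:, t] for m in member], w)
    return out


def estimates_table(fit: FitResult, meta: dict[str, CountryMeta], metric: str,
                    levels=("country", "region", "global")) -> list[EstimateRow]:
    """EstimateRows (mean Z and prevalence with CIs) for every level-year-stratum."""
    groups: list[tuple[str, str, tuple]] = []
    if "country" in levels:
        groups += [("country", c, (c,)) for c in fit.countries]
    if "region" in levels:
        for r_idx, region in enumerate(fit.regions):
            members = tuple(c for c, r in zip(fit.countries, fit.region_of) if r == r_idx)
            groups.append(("region", region, members))
    if "global" in levels:
        groups.append(("global", "all", tuple(fit.countries)))
    rows = []
    for level, gid, members in groups:
        for stratum in ("rural", "urban", "combined"):
            md = group_draws(fit, meta, members, stratum, "mean")
            pd_ = group_draws(fit, meta, members, stratum, "prev")
            for t, year in enumerate(fit.years):
                m, mlo, mhi = summarize(md[:, t])
                p, plo, phi = summarize(pd_[:, t])
                rows.append(EstimateRow(
                    level=level, id=gid, year=int(year), stratum=stratum, metric=metric,
                    mean=m, mean_lo=mlo, mean_hi=mhi,
                    prev=min(max(p, plo), phi), prev_lo=plo, prev_hi=phi,
                ))
    return rows


__all__ = [
    "summarize", "prevalence_below", "pp_direction",
    "aggregate_population_weighted", "count_undernourished",
    "group_draws", "estimates_table",
]
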