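"""Additive decomposition of a change in population mean Z.

The change in a population's mean Z between a start and an end year splits
exactly into three parts: the change among rural children weighted by the
start-year rural share, the change among urban children weighted by the
start-year urban share, and an urbanisation term — the change in the urban
share multiplied by the end-year urban-rural gap:

    total = p0*(zu1 - zu0) + (1 - p0)*(zr1 - zr0) + (p1 - p0)*(zu1 - zr1)

The identity is algebraic: the three components always sum to the total
change. Shares (components divided by the total) sum to 1 whenever the total
is nonzero; any share may be negative or exceed 1 when components oppose
each other. Applied to posterior draws, the decomposition is computed per
draw and the reported shares are means of the per-draw shares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import CountryMeta
from .hiermix_model import FitResult
from .posterior_summaries import group_draws, summarize

COMPONENTS = ("rural", "urban", "urbanisation")


@dataclass(frozen=True)
class DecompositionResult:
    """Rural, urban and urbanisation components of a change in mean Z."""

    total_change: float
    rural_component: float
    urban_component: float
    urbanisation_component: float
    shares: tuple | None  # None when total_change == 0

    @property
    def shares_defined(self) -> bool:
        return self.shares is not None


def decompose_change(z_r_start: float, z_u_start: float, z_r_end: float,
                     z_u_end: float, p_start: float, p_end: float) -> DecompositionResult:
    """Decompose the change in population mean Z between two years."""
    for name, p in (("p_start", p_start), ("p_end", p_end)):
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {p}")
    rural = (1.0 - p_start) * (z_r_end - z_r_start)
    urban = p_start * (z_u_end - z_u_start)
    urbanisation = (p_end - p_start) * (z_u_end - z_r_end)
    total = (p_end * z_u_end + (1.0 - p_end) * z_r_end) \
        - (p_start * z_u_start + (1.0 - p_start) * z_r_start)
    # normalise by the components' own sum (equal to the total in exact
    # arithmetic) so the partition property survives floating cancellation
    comp_sum = rural + urban + urbanisation
    if total == 0.0 or comp_sum == 0.0:
        shares = None
    else:
        shares = (rural / comp_sum, urban / comp_sum, urbanisation / comp_sum)
    return DecompositionResult(
        total_change=float(total), rural_component=float(rural),
        urban_component=float(urban), urbanisation_component=float(urbanisation),
        shares=shares,
    )


def decompose_draws(z_r_start, z_u_start, z_r_end, z_u_end,
                    p_start: float, p_end: float) -> dict:
    """Draw-wise decomposition of posterior draw vectors.

    Shares are computed per draw; draws with exactly zero total change are
    excluded from share averaging and counted in ``n_zero_total``.
    """
    zr0 = np.asarray(z_r_start, dtype=float)
    zu0 = np.asarray(z_u_start, dtype=float)
    zr1 = np.asarray(z_r_end, dtype=float)
    zu1 = np.asarray(z_u_end, dtype=float)
    rural = (1.0 - p_start) * (zr1 - zr0)
    urban = p_start * (zu1 - zu0)
    urbanisation = (p_end - p_start) * (zu1 - zr1)
    total = rural + urban + urbanisation
    ok = total != 0.0
    shares = {}
    for name, comp in zip(COMPONENTS, (rural, urban, urbanisation)):
        shares[name] = comp[ok] / total[ok]
    return {
        "rural": rural, "urban": urban, "urbanisation": urbanisation, "total": total,
        "shares": shares, "n_zero_total": int(np.sum(~ok)),
    }


def decompose_fit(fit: FitResult, meta: dict[str, CountryMeta], metric: str,
                  start: int, end: int,
                  levels=("region", "global")) -> pd.DataFrame:
    """Decomposition shares with credible intervals for fitted groups.

    The group urban fraction is the under-5-population-weighted urban
    fraction of its member countries; stratum means aggregate with
    stratum-specific population weights.
    """
    groups: list[tuple[str, str, tuple]] = []
    if "country" in levels:
        groups += [("country", c, (c,)) for c in fit.countries]
    if "region" in levels:
        for r_idx, region in enumerate(fit.regions):
            members = tuple(c for c, r in zip(fit.countries, fit.region_of) if r == r_idx)
            groups.append(("region", region, members))
    if "global" in levels:
        groups.append(("global", "all", tuple(fit.countries)))
    t0 = int(start - fit.years[0])
    t1 = int(end - fit.years[0])
    if not (0 <= t0 < len(fit.years) and 0 <= t1 < len(fit.years)):
        raise ValueError(f"start/end outside fitted years {fit.years[0]}-{fit.years[-1]}")
    rows = []
    for level, gid, members in groups:
        pops0 = np.array([meta[c].pop_under5(start) for c in members])
        pops1 = np.array([meta[c].pop_under5(end) for c in members])
        uf0 = np.array([meta[c].urban_fraction(start) for c in members])
        uf1 = np.array([meta[c].urban_fraction(end) for c in members])
        p0 = float((pops0 * uf0).sum() / pops0.sum())
        p1 = float((pops1 * uf1).sum() / pops1.sum())
        zr = group_draws(fit, meta, members, "rural", "mean")
        zu = group_draws(fit, meta, members, "urban", "mean")
        d = decompose_draws(zr[:, t0], zu[:, t0], zr[:, t1], zu[:, t1], p0, p1)
        for comp in COMPONENTS:
            mean_share, lo, hi = summarize(d["shares"][comp])
            rows.append({
                "level": level, "id": gid, "metric": metric, "component": comp,
                "share_mean": mean_share, "share_lo": lo, "share_hi": hi,
                "n_zero_total": d["n_zero_total"],
            })
    return pd.DataFrame(rows)


__all__ = ["DecompositionResult", "decompose_change", "decompose_draws",
           "decompose_fit", "COMPONENTS"]
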