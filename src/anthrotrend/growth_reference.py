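"""Z scores against LMS growth references, and reference-to-reference conversion.

An anthropometric reference (the WHO 2006 growth standards, or the older
NCHS 1977 reference) summarises the distribution of height or weight of
well-nourished children at each age and sex by three parameters: a Box-Cox
skewness power ``L``, the median ``M`` and a coefficient of variation ``S``.
A child's measurement ``x`` maps to a Z score by

    Z = ((x / M)**L - 1) / (L * S)     for L != 0
    Z = log(x / M) / S                 for L == 0

This module provides that transform and its inverse, the measurement-unit
equivalent of one Z score at a given age (e.g. one height-for-age Z is about
3.2 cm at age 2 years on the WHO standards), and a deterministic quantile
mapping that re-expresses survey summary statistics reported against the
NCHS reference in WHO-standard Z space.

The packaged reference tables are *synthetic* approximations built from
public growth-chart anchor values (see ``data/who2006_synthetic_lms.csv``);
real WHO/NCHS LMS tables with the same CSV schema are drop-in replacements.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.stats import norm

SEXES = ("male", "female")
METRICS = ("height", "weight")
REFERENCE_KINDS = ("WHO2006", "NCHS1977")

_PACKAGED_TABLES = {
    "WHO2006": "who2006_synthetic_lms.csv",
    "NCHS1977": "nchs1977_synthetic_lms.csv",
}


class GrowthDomainError(ValueError):
    """Measurement or Z score outside the domain of the LMS transform."""


class ReferenceLookupError(KeyError):
    """Requested (age, sex, metric) not covered by a reference table."""


@dataclass(frozen=True)
class LMSRow:
    """LMS parameters at one age/sex/metric cell of a reference table."""

    age: float  # months
    sex: str
    metric: str
    L: float
    M: float  # cm or kg
    S: float

    def __post_init__(self) -> None:
        if self.M <= 0:
            raise ValueError(f"LMS median must be positive, got M={self.M}")
        if self.S <= 0:
            raise ValueError(f"LMS coefficient of variation must be positive, got S={self.S}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")


@dataclass(frozen=True)
class SummaryStatistic:
    """Survey summary of a Z-score population: mean, SD, optional tail prevalence."""

    mean_z: float
    sd_z: float
    prev_below: float | None = None  # P(Z < -2)
    reference: str = "WHO2006"

    def __post_init__(self) -> None:
        if not np.isfinite(self.mean_z):
            raise ValueError("mean_z must be finite")
        if not (self.sd_z > 0):
            raise ValueError(f"sd_z must be positive, got {self.sd_z}")
        if self.prev_below is not None and not (0.0 <= self.prev_below <= 1.0):
            raise ValueError(f"prev_below must be in [0, 1], got {self.prev_below}")
        if self.reference not in REFERENCE_KINDS:
            raise ValueError(f"reference must be one of {REFERENCE_KINDS}")


class ReferenceTable:
    """An LMS reference table with exact grid lookup and linear interpolation.

    Parameters
    ----------
    kind
        ``"WHO2006"`` or ``"NCHS1977"``.
    rows
        DataFrame with columns ``metric, sex, age_months, L, M, S``; each
        sex-by-metric block must cover a contiguous age grid with unique ages.
    """

    def __init__(self, kind: str, rows: pd.DataFrame):
        if kind not in REFERENCE_KINDS:
            raise ValueError(f"kind must be one of {REFERENCE_KINDS}, got {kind!r}")
        required = {"metric", "sex", "age_months", "L", "M", "S"}
        missing = required - set(rows.columns)
        if missing:
            raise ValueError(f"reference table missing columns: {sorted(missing)}")
        self.kind = kind
        self._grids: dict[tuple[str, str], dict[str, np.ndarray]] = {}
        for (metric, sex), grp in rows.groupby(["metric", "sex"], sort=True):
            grp = grp.sort_values("age_months")
            ages = grp["age_months"].to_numpy(dtype=float)
            if len(np.unique(ages)) != len(ages):
                raise ValueError(f"duplicate ages for {metric}/{sex} in {kind} table")
            self._grids[(str(metric), str(sex))] = {
                "age": ages,
                "L": grp["L"].to_numpy(dtype=float),
                "M": grp["M"].to_numpy(dtype=float),
                "S": grp["S"].to_numpy(dtype=float),
            }
        for metric in METRICS:
            for sex in SEXES:
                if (metric, sex) not in self._grids:
                    raise ValueError(f"{kind} table lacks {metric}/{sex} rows")

    @classmethod
    def from_csv(cls, path) -> "ReferenceTable":
        df = pd.read_csv(path)
        kinds = df["kind"].unique()
        if len(kinds) != 1:
            raise ValueError(f"reference CSV must contain a single kind, found {list(kinds)}")
        return cls(str(kinds[0]), df)

    @classmethod
    def packaged(cls, kind: str) -> "ReferenceTable":
        """Load the packaged synthetic table for ``kind``."""
        if kind not in _PACKAGED_TABLES:
            raise ValueError(f"no packaged table for {kind!r}")
        ref = resources.files("anthrotrend.data") / _PACKAGED_TABLES[kind]
        with resources.as_file(ref) as path:
            return cls.from_csv(path)

    def grid(self, sex: str, metric: str) -> np.ndarray:
        """Ages (months) at which the table has exact entries."""
        return self._grids[(metric, sex)]["age"].copy()

    def lookup(self, age: float, sex: str, metric: str) -> LMSRow:
        """LMS parameters at ``age`` months; linear interpolation off the grid."""
        key = (metric, sex)
        if key not in self._grids:
            raise ReferenceLookupError(f"no {metric}/{sex} block in {self.kind} table")
        g = self._grids[key]
        if not (g["age"][0] <= age <= g["age"][-1]):
            raise ReferenceLookupError(
                f"age {age} months outside {self.kind} {metric}/{sex} grid "
                f"[{g['age'][0]}, {g['age'][-1]}]"
            )
        L = float(np.interp(age, g["age"], g["L"]))
        M = float(np.interp(age, g["age"], g["M"]))
        S = float(np.interp(age, g["age"], g["S"]))
        return LMSRow(age=float(age), sex=sex, metric=metric, L=L, M=M, S=S)

    def covers(self, age_range: tuple[float, float], sex: str, metric: str) -> bool:
        g = self._grids[(metric, sex)]["age"]
        return g[0] <= age_range[0] and age_range[1] <= g[-1]


def lms_zscore(x: float, row: LMSRow) -> float:
    """Z score of measurement ``x`` (cm or kg) under the LMS parameters ``row``.

    Evaluated as expm1(L*log(x/M)) / (L*S), which reduces smoothly to the
    L = 0 log form and is stable for L near zero.
    """
    if not (x > 0):
        raise GrowthDomainError(f"measurement must be positive, got {x}")
    logr = np.log(x / row.M)
    if row.L != 0.0:
        return float(np.expm1(row.L * logr) / (row.L * row.S))
    return float(logr / row.S)


def lms_inverse(z: float, row: LMSRow) -> float:
    """Measurement whose Z score is ``z``; inverse of :func:`lms_zscore`."""
    if row.L != 0.0:
        base = 1.0 + row.L * row.S * z
        if base <= 0.0:
            raise GrowthDomainError(
                f"z={z} outside invertible range for L={row.L}, S={row.S}"
            )
        return float(row.M * np.exp(np.log1p(row.L * row.S * z) / row.L))
    return float(row.M * np.exp(row.S * z))


def zscore_unit_equivalent(age: float, metric: str, table: ReferenceTable) -> float:
    """Measurement units (cm or kg) spanned by one Z score at ``age`` months.

    Sex-averaged distance between the reference median (Z=0) and Z=+1;
    ``age`` must be an exact grid age of the table.
    """
    vals = []
    for sex in SEXES:
        grid = table.grid(sex, metric)
        if not np.any(np.isclose(grid, age)):
            raise ReferenceLookupError(
                f"age {age} not on the {table.kind} {metric}/{sex} grid"
            )
        row = table.lookup(age, sex, metric)
        vals.append(lms_inverse(1.0, row) - lms_inverse(0.0, row))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# Reference conversion by quantile mapping
# ---------------------------------------------------------------------------

def _gauss_hermite(n: int = 61) -> tuple[np.ndarray, np.ndarray]:
    nodes, weights = np.polynomial.hermite.hermgauss(n)
    return nodes * np.sqrt(2.0), weights / np.sqrt(np.pi)


def _map_component(mean: float, sd: float, src_row: LMSRow, tgt_row: LMSRow,
                   nodes: np.ndarray, weights: np.ndarray):
    """Moments in target Z space of N(mean, sd^2) in source Z space, one age/sex cell."""
    z_src = mean + sd * nodes
    base = 1.0 + src_row.L * src_row.S * z_src if src_row.L != 0 else None
    if base is not None:
        if np.any(base <= 0):  # clip far-tail nodes that leave the Box-Cox domain
            base = np.clip(base, 1e-12, None)
        x = src_row.M * base ** (1.0 / src_row.L)
    else:
        x = src_row.M * np.exp(src_row.S * z_src)
    if tgt_row.L != 0:
        z_tgt = ((x / tgt_row.M) ** tgt_row.L - 1.0) / (tgt_row.L * tgt_row.S)
    else:
        z_tgt = np.log(x / tgt_row.M) / tgt_row.S
    m1 = float(np.sum(weights * z_tgt))
    m2 = float(np.sum(weights * z_tgt ** 2))
    return m1, m2


def map_summary(mean_z: float, sd_z: float, src: ReferenceTable, tgt: ReferenceTable,
                age_range: tuple[float, float], metric: str,
                components: Iterable[tuple[float, float, float]] | None = None,
                n_nodes: int = 61) -> tuple[float, float, float]:
    """Quantile-map a Z-score population from one reference to another.

    The population is assumed normal ``N(mean_z, sd_z^2)`` in source Z space
    (or the supplied ``(weight, mean, sd)`` mixture components), uniform over
    the target table's grid ages within ``age_range`` and balanced over sex.
    Returns ``(mean, sd, prev_below_-2)`` in target Z space.
    """
    if components is None:
        components = [(1.0, mean_z, sd_z)]
    nodes, weights = _gauss_hermite(n_nodes)
    cells = []
    for sex in SEXES:
        if not (src.covers(age_range, sex, metric) and tgt.covers(age_range, sex, metric)):
            raise ReferenceLookupError(
                f"age range {age_range} not covered for {metric}/{sex}"
            )
        grid = tgt.grid(sex, metric)
        ages = grid[(grid >= age_range[0]) & (grid <= age_range[1])]
        if len(ages) == 0:
            raise ReferenceLookupError(f"no grid ages inside {age_range} for {metric}/{sex}")
        for age in ages:
            cells.append((src.lookup(age, sex, metric), tgt.lookup(age, sex, metric)))
    m1s, m2s, prevs = [], [], []
    for src_row, tgt_row in cells:
        m1 = m2 = prev = 0.0
        # source-space Z value mapping to target Z = -2 in this cell
        t_cell = lms_zscore(lms_inverse(-2.0, tgt_row), src_row)
        for w, cm, cs in components:
            c1, c2 = _map_component(cm, cs, src_row, tgt_row, nodes, weights)
            m1 += w * c1
            m2 += w * c2
            prev += w * float(norm.cdf((t_cell - cm) / cs))
        m1s.append(m1)
        m2s.append(m2)
        prevs.append(prev)
    mean = float(np.mean(m1s))
    second = float(np.mean(m2s))
    sd = float(np.sqrt(max(second - mean ** 2, 1e-12)))
    return mean, sd, float(np.mean(prevs))


def _skewed_components(mean_z: float, sd_z: float) -> list[tuple[float, float, float]]:
    # two-component left-skewed mixture with the same mean and SD
    d = 0.25 * sd_z
    sc = float(np.sqrt(0.8125)) * sd_z
    return [(0.75, mean_z + d, sc), (0.25, mean_z - 3.0 * d, sc)]


def convert_summary_nchs_to_who(
    s: SummaryStatistic,
    age_range: tuple[float, float],
    who: ReferenceTable,
    nchs: ReferenceTable,
    metric: str = "height",
) -> tuple[SummaryStatistic, float]:
    """Re-express an NCHS-referenced summary in WHO-standard Z space.

    Returns the converted summary and a ``conversion_variance`` (Z^2) that the
    observation model adds to the source's error variance. The variance is the
    squared discrepancy between the mapped mean under a normal population
    assumption and under a mildly left-skewed two-component assumption with
    identical mean and SD — a measure of how sensitive the deterministic
    mapping is to the unobserved population shape.
    """
    if s.reference != "NCHS1977":
        raise ValueError("input summary must be NCHS1977-referenced")
    mean_n, sd_n, prev_n = map_summary(s.mean_z, s.sd_z, nchs, who, age_range, metric)
    mean_m, _, _ = map_summary(
        s.mean_z, s.sd_z, nchs, who, age_range, metric,
        components=_skewed_components(s.mean_z, s.sd_z),
    )
    conv_var = float((mean_n - mean_m) ** 2)
    out = SummaryStatistic(
        mean_z=mean_n,
        sd_z=sd_n,
        prev_below=prev_n if s.prev_below is not None else None,
        reference="WHO2006",
    )
    return out, conv_var


__all__ = [
    "LMSRow",
    "ReferenceTable",
    "SummaryStatistic",
    "GrowthDomainError",
    "ReferenceLookupError",
    "lms_zscore",
    "lms_inverse",
    "zscore_unit_equivalent",
    "map_summary",
    "convert_summary_nchs_to_who",
    "SEXES",
    "METRICS",
    "REFERENCE_KINDS",
]
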