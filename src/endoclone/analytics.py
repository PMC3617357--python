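"""Statistical program: clone statistics, tumor heterogeneity tables,
fractional-mass MRCA tables, median-cancer-cell extraction and the
two-sample Kolmogorov-Smirnov comparison of tumor cohorts.

Conventions: medians of even-sized samples are the midpoint of the central
pair; standard deviations use the n-1 denominator; durations are reported
in days (1 month = 30 days); kurtosis is raw (not excess).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .params import Phenotype
from .phylogeny import LineageTree

__all__ = [
    "CdfTable",
    "clone_stats",
    "tumor_cdfs",
    "stem_fraction",
    "mrca_table",
    "median_cell",
    "tumor_median_distribution",
    "ks_two_sample",
    "MRCA_FRACTIONS",
    "D_BREAKPOINTS",
    "K_BREAKPOINTS",
    "ALPHA_BREAKPOINTS",
]

#: mass fractions tabulated for MRCA analyses
MRCA_FRACTIONS = (1.0, 0.999, 0.995, 0.99, 0.95, 0.90, 0.80, 0.70, 0.60, 0.50)

#: default cdf breakpoints for the three heterogeneity variables
D_BREAKPOINTS = (28, 30, 32, 34, 36, 38, 40, 41, 42, 43, 44, 45, 46, 47)
K_BREAKPOINTS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9,
                 1.0, 1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7)
ALPHA_BREAKPOINTS = (-7.5, -5.0, -2.5, 0.0, 2.0, 4.0, 5.0, 6.0, 7.0, 8.0,
                     9.0, 10.0, 11.0, 12.0, 13.0, 14.0, 15.0, 16.0, 17.0, 18.0)


@dataclass
class CdfTable:
    """Empirical cdf of one variable at ordered breakpoints."""

    variable: str
    breakpoints: np.ndarray
    probabilities: np.ndarray
    median: float
    n: int

    def __post_init__(self):
        b = np.asarray(self.breakpoints, dtype=float)
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(np.diff(b) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(np.diff(p) < 0) or np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must be a non-decreasing cdf")
        self.breakpoints, self.probabilities = b, p

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({self.variable: self.breakpoints,
                             "cdf": self.probabilities})


def _order_stats(values: np.ndarray) -> dict:
    v = np.asarray(values, dtype=float)
    return {
        "median": float(np.median(v)),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "min": float(v.min()),
        "max": float(v.max()),
    }


def clone_stats(records) -> pd.DataFrame:
    """Median/SD/min/max of clone peak sizes and lifespans.

    Accepts a ``CohortSummary`` or an iterable of ``CloneRecord``; lifespans
    are in days.
    """
    if hasattr(records, "peaks"):
        peaks = np.asarray(records.peaks, dtype=float)
        lifespans = np.asarray(records.lifespans_days, dtype=float)
    else:
        records = list(records)
        if not records:
            raise ValueError("no clone records")
        peaks = np.array([r.peak for r in records], dtype=float)
        lifespans = np.array([r.lifespan_days for r in records], dtype=float)
    if peaks.size == 0:
        raise ValueError("no clone records")
    return pd.DataFrame(
        [_order_stats(peaks), _order_stats(lifespans)],
        index=["peak_cells", "lifespan_days"],
    )


def _snapshot_column(snapshot, name: str) -> np.ndarray:
    if isinstance(snapshot, pd.DataFrame):
        return snapshot[name].to_numpy(dtype=float)
    return np.asarray(snapshot[name], dtype=float)


def tumor_cdfs(snapshot, breakpoints: dict | None = None) -> dict[str, CdfTable]:
    """Empirical cdfs of d, k and alpha over a detection-time cell snapshot.

    ``snapshot`` is a DataFrame (or mapping) with columns d, k, alpha.
    Returns one :class:`CdfTable` per variable, evaluated at the standard
    breakpoints (overridable per variable via ``breakpoints``).
    """
    defaults = {"d": D_BREAKPOINTS, "k": K_BREAKPOINTS, "alpha": ALPHA_BREAKPOINTS}
    if breakpoints:
        defaults.update(breakpoints)
    out = {}
    for var, bps in defaults.items():
        v = _snapshot_column(snapshot, var)
        if v.size == 0:
            raise ValueError("empty snapshot")
        bps = np.asarray(bps, dtype=float)
        probs = np.searchsorted(np.sort(v), bps, side="right") / v.size
        out[var] = CdfTable(var, bps, probs, median=float(np.median(v)), n=v.size)
    return out


def stem_fraction(snapshot) -> float:
    """Fraction of cells with the differentiation coefficient clamped at
    zero — the cancer-stem-cell portion of the mass."""
    k = _snapshot_column(snapshot, "k")
    if k.size == 0:
        raise ValueError("empty snapshot")
    return float((k == 0.0).mean())


def mrca_table(
    tumors: Iterable[LineageTree],
    x_list: Sequence[float] = MRCA_FRACTIONS,
) -> pd.DataFrame:
    """Order statistics of MRCA(x) phenotypes across tumors.

    For each mass fraction x, collects the MRCA's division depth d and its
    birth phenotype (alpha, k) from every tumor and reports median/SD/
    min/max across tumors — the layout of the fractional-mass ancestor
    tables.  MRCA depth is non-increasing in x (asserted).
    """
    tumors = list(tumors)
    if not tumors:
        raise ValueError("no tumors")
    rows = []
    for x in x_list:
        res = [t.mrca(x) for t in tumors]
        for var, vals in (("d", [r.d for r in res]),
                          ("alpha", [r.alpha for r in res]),
                          ("k", [r.k for r in res])):
            rows.append({"x": x, "variable": var, **_order_stats(np.array(vals))})
    table = pd.DataFrame(rows).set_index(["variable", "x"])
    med_d = table.loc["d"]["median"].sort_index()  # ascending x
    if np.any(np.diff(med_d.to_numpy()) > 1e-12):
        # a larger covered fraction has an equal-or-shallower ancestor
        raise AssertionError("MRCA depth not monotone in x")
    return table


def median_cell(snapshot) -> dict:
    """The median cancer cell (MCC): component-wise medians of (k, alpha)
    and of the depth/generation — a synthetic phenotype, not an actual cell.

    Returns both ``d`` and ``g`` medians (they are nearly identical in this
    model); the ``phenotype`` entry uses g.
    """
    k = _snapshot_column(snapshot, "k")
    if k.size == 0:
        raise ValueError("empty snapshot")
    alpha = _snapshot_column(snapshot, "alpha")
    d = _snapshot_column(snapshot, "d")
    try:
        g = _snapshot_column(snapshot, "g")
    except (KeyError, IndexError):
        g = d
    med_k = float(np.median(k))
    med_a = float(np.median(alpha))
    med_d = float(np.median(d))
    med_g = float(np.median(g))
    return {
        "k": med_k,
        "alpha": med_a,
        "d": med_d,
        "g": med_g,
        "phenotype": Phenotype(k=med_k, alpha=med_a, g=max(1, int(round(med_g)))),
    }


def tumor_median_distribution(tumor_details: pd.DataFrame) -> pd.DataFrame:
    """Distribution of per-tumor median properties across a tumor cohort.

    Input is the per-tumor table produced by the engine (columns
    ``median_k``, ``median_alpha``, ``median_d``); output has one row per
    property with median, mean, SD, skewness and raw (non-excess)
    kurtosis — the layout used to compare cohorts of tumors.
    """
    from scipy.stats import kurtosis, skew

    if len(tumor_details) < 2:
        raise ValueError("need at least 2 tumors")
    rows = {}
    for prop, col in (("k", "median_k"), ("alpha", "median_alpha"), ("d", "median_d")):
        v = tumor_details[col].to_numpy(dtype=float)
        rows[prop] = {
            "median": float(np.median(v)),
            "mean": float(v.mean()),
            "sd": float(v.std(ddof=1)),
            "skewness": float(skew(v)),
            "kurtosis": float(kurtosis(v, fisher=False)),
        }
    return pd.DataFrame(rows).T


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    D is the exact supremum distance between the two empirical cdfs; the
    p-value is the asymptotic (Kolmogorov) two-sided approximation with
    effective size n*m/(n+m).
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    n, m = a.size, b.size
    if n < 2 or m < 2:
        raise ValueError("both samples need at least 2 observations")
    grid = np.concatenate([a, b])
    fa = np.searchsorted(a, grid, side="right") / n
    fb = np.searchsorted(b, grid, side="right") / m
    d = float(np.abs(fa - fb).max())
    en = np.sqrt(n * m / (n + m))
    p = float(special.kolmogorov(en * d))
    return d, min(max(p, 0.0), 1.0)
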