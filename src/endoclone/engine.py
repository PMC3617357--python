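"""Event-driven population simulation.

A clone is the set of descendants of one root cell, simulated cell by cell
on a priority queue of exact division/death times (see
:mod:`endoclone.trajectory` for the per-cell dynamics).  The engine provides
three experiment shapes:

* :func:`simulate_clone` — one progenitor, until extinction, tumor
  detection (living count reaching ``detect_threshold``) or the time
  horizon;
* :func:`simulate_cohort` — many independent progenitors, aggregated into a
  :class:`CohortSummary` with an exact Poisson confidence interval on the
  per-progenitor tumor probability;
* :func:`simulate_from_phenotype` — roots initialized with a
  tumor-initiating phenotype (k, alpha, g), e.g. the typical TICC
  (0.18, 3.66, 17) or its k = 0 stem counterpart.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernel as _k
from .params import ModelParameters, Phenotype
from .phylogeny import LineageTree
from .trajectory import programmed_differentiation

__all__ = [
    "CloneRecord",
    "CohortSummary",
    "simulate_clone",
    "simulate_cohort",
    "simulate_from_phenotype",
    "poisson_exact_ci",
    "incidence_per_100k",
]

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.0

_STATUS = {
    _k.ST_EXTINCT: "extinct",
    _k.ST_DETECTED: "detected",
    _k.ST_CENSORED: "censored",
    _k.ST_MEMCAP: "aborted",
}

#: progenitors per woman implied by the printed incidence conversion
#: (94 per 100,000 women at probability 2.61862e-8 per progenitor);
#: used only for the labeled derived incidence figure.
PROGENITORS_PER_WOMAN = 35_897.0


@dataclass
class CloneRecord:
    """Outcome of one clone simulation."""

    seed: int
    status: str                    # extinct | detected | censored
    peak: int                      # maximum simultaneous living cells
    lifespan_days: float           # progenitor birth to last death (or censor time)
    tumor: bool                    # reached detect_threshold
    time_to_detection_days: Optional[float]
    n_cells_total: int             # cells ever born
    n_censored_cells: int
    tree: Optional[LineageTree] = None
    snapshot: Optional[pd.DataFrame] = None  # phenotypes of living cells at detection
    _events: Optional[tuple] = field(default=None, repr=False)

    def series(self) -> pd.DataFrame:
        """Living-cell count N(t) sampled at every birth/death event."""
        if self._events is None:
            raise ValueError("event series not recorded for this clone")
        _, t_event, code = self._events
        # one net change per fate event: a division replaces the parent with
        # two daughters (+1), a death removes a cell (-1); events ordered the
        # way the simulation processes them, by (time, cell index)
        has_event = code != _k.EV_CAP
        idx = np.nonzero(has_event)[0]
        times = t_event[idx]
        delta = np.where(code[idx] == _k.EV_DIV, 1, -1)
        order = np.lexsort((idx, times))
        times, delta = times[order], delta[order]
        n = 1 + np.cumsum(delta)  # the root is alive from t = 0
        return pd.DataFrame({"t_days": times * DAYS_PER_MONTH, "n_living": n.astype(int)})


@dataclass
class CohortSummary:
    """Aggregate over independent clones."""

    n_progenitors: int
    n_tumors: int
    probability: float
    ci_low: float
    ci_high: float
    peaks: np.ndarray
    lifespans_days: np.ndarray
    n_censored: int
    tumor_details: pd.DataFrame    # one row per tumor: medians, stem fraction, MRCA depth
    phenotype: Optional[Phenotype] = None
    seed: Optional[int] = None

    @property
    def incidence_per_100k(self) -> float:
        """Tumors per 100,000 women under the fixed per-progenitor-to-woman
        mapping — a labeled derived figure, not a model quantity."""
        return incidence_per_100k(self.probability)


def poisson_exact_ci(x: int, n: float, level: float = 0.95) -> tuple[float, float]:
    """Garwood exact Poisson interval for a probability estimated as x/n.

    ``[chi2(a/2, 2x)/2, chi2(1-a/2, 2x+2)/2] / n`` with a zero lower bound
    at x = 0.  This is the construction whose printed bounds the reference
    incidence experiment reproduces to six significant figures.
    """
    if x < 0 or n <= 0:
        raise ValueError("need x >= 0 and n > 0")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    a = 1.0 - level
    low = 0.0 if x == 0 else stats.chi2.ppf(a / 2.0, 2 * x) / 2.0 / n
    high = stats.chi2.ppf(1.0 - a / 2.0, 2 * x + 2) / 2.0 / n
    return float(low), float(high)


def incidence_per_100k(probability: float,
                       progenitors_per_woman: float = PROGENITORS_PER_WOMAN) -> float:
    """Convert a per-progenitor tumor probability to tumors per 100,000
    women (derived figure; see :data:`PROGENITORS_PER_WOMAN`)."""
    return probability * progenitors_per_woman * 1e5


def _clone_seeds(seed: int, n: int) -> np.ndarray:
    """Independent per-clone substreams derived from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF


def _run_kernel(params: ModelParameters, seed: int, phenotype: Optional[Phenotype]):
    P = params.to_array()
    if phenotype is None:
        return P, _k.run_clone(P, int(seed), 0.0, 1, 0.0, False)
    phenotype.validate()
    return P, _k.run_clone(P, int(seed), float(phenotype.alpha),
                           int(phenotype.g), float(phenotype.k), True)


def _build_tree(raw, params: ModelParameters, alive: np.ndarray) -> LineageTree:
    (_, n, _, _, _, _, _, parent, digit, depth, t_birth, a_birth,
     beta, msum, t_event, a_event, code) = raw
    kp = programmed_differentiation(depth.astype(float), params)
    k_birth = np.maximum(params.k_floor, kp + msum)
    return LineageTree(parent, digit, depth, t_birth, t_event,
                       a_birth, a_event, k_birth, alive)


def _detection_snapshot(raw, params: ModelParameters) -> tuple[np.ndarray, pd.DataFrame]:
    P = params.to_array()
    t_det = raw[4]
    depth, t_birth, a_birth, beta, msum, t_event = (
        raw[9], raw[10], raw[11], raw[12], raw[13], raw[14])
    alive, a_now, k_now, g_now, c_now = _k.snapshot_at(
        P, t_det, depth, t_birth, a_birth, beta, msum, t_event)
    df = pd.DataFrame({
        "d": depth[alive],
        "g": g_now[alive].astype(int),
        "alpha": a_now[alive],
        "k": k_now[alive],
        "c": c_now[alive],
        "beta": beta[alive],
    })
    return alive, df


def simulate_clone(
    params: ModelParameters | None = None,
    seed: int = 0,
    phenotype: Optional[Phenotype] = None,
    record: str = "full",
) -> CloneRecord:
    """Simulate one clone from a single root cell.

    ``record`` — "full" keeps the lineage tree, the detection snapshot and
    the N(t) event series; "counts" keeps scalars only.  Full recording is
    refused (RuntimeError) if the simulation would exceed the
    ``params.max_cells`` memory guard.
    """
    params = params or ModelParameters()
    params.validate()
    if record not in ("full", "counts"):
        raise ValueError("record must be 'full' or 'counts'")
    _, raw = _run_kernel(params, seed, phenotype)
    status, n, living, peak, t_det, t_last, n_cens = raw[:7]
    if status == _k.ST_MEMCAP:
        raise RuntimeError(
            f"clone exceeded the max_cells guard ({params.max_cells}); raise "
            "ModelParameters.max_cells or lower detect_threshold")
    tumor = status == _k.ST_DETECTED
    lifespan = (t_det if tumor else t_last) * DAYS_PER_MONTH
    rec = CloneRecord(
        seed=seed,
        status=_STATUS[status],
        peak=int(peak),
        lifespan_days=float(lifespan),
        tumor=tumor,
        time_to_detection_days=float(t_det * DAYS_PER_MONTH) if tumor else None,
        n_cells_total=int(n),
        n_censored_cells=int(n_cens),
    )
    if record == "full":
        if tumor:
            alive, snap = _detection_snapshot(raw, params)
            rec.snapshot = snap
        else:
            alive = raw[14] > params.max_sim_time - 1e-12  # censored cells only
        rec.tree = _build_tree(raw, params, alive)
        rec._events = (raw[10], raw[14], raw[16])
    return rec


def _tumor_detail_row(raw, params: ModelParameters, seed: int) -> dict:
    alive, snap = _detection_snapshot(raw, params)
    tree = _build_tree(raw, params, alive)
    mrca995 = tree.mrca(0.995)
    return {
        "seed": seed,
        "t_detect_days": raw[4] * DAYS_PER_MONTH,
        "n_cells": int(alive.sum()),
        "median_d": float(np.median(snap["d"])),
        "median_k": float(np.median(snap["k"])),
        "median_alpha": float(np.median(snap["alpha"])),
        "stem_fraction": float((snap["k"].to_numpy() == 0.0).mean()),
        "mrca995_d": int(mrca995.d),
    }


_TUMOR_COLUMNS = ["seed", "t_detect_days", "n_cells", "median_d", "median_k",
                  "median_alpha", "stem_fraction", "mrca995_d"]


def simulate_cohort(
    n: int,
    params: ModelParameters | None = None,
    seed: int = 0,
    phenotype: Optional[Phenotype] = None,
    tumor_stats: bool = True,
    max_tumor_stats: Optional[int] = None,
    level: float = 0.95,
    progress_every: int = 10_000,
) -> CohortSummary:
    """Simulate ``n`` independent clones on seeded substreams.

    Results are independent of execution order (each clone consumes only its
    own substream).  For every detected tumor (up to ``max_tumor_stats``) the
    detection snapshot is reduced to median phenotypes, the stem-cell
    fraction and the MRCA(0.995) depth, then discarded.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params = params or ModelParameters()
    params.validate()
    seeds = _clone_seeds(seed, n)
    peaks = np.empty(n, dtype=np.int64)
    lifespans = np.empty(n)
    n_tumors = 0
    n_censored = 0
    rows = []
    for i, s in enumerate(seeds):
        _, raw = _run_kernel(params, int(s), phenotype)
        status, _, _, peak, t_det, t_last, _ = raw[:7]
        if status == _k.ST_MEMCAP:
            raise RuntimeError("clone exceeded the max_cells guard")
        peaks[i] = peak
        tumor = status == _k.ST_DETECTED
        if tumor:
            n_tumors += 1
            lifespans[i] = t_det * DAYS_PER_MONTH
            if tumor_stats and (max_tumor_stats is None or len(rows) < max_tumor_stats):
                rows.append(_tumor_detail_row(raw, params, int(s)))
        else:
            if status == _k.ST_CENSORED:
                n_censored += 1
            lifespans[i] = t_last * DAYS_PER_MONTH
        if progress_every and (i + 1) % progress_every == 0:
            logger.info("cohort progress: %d/%d clones, %d tumors", i + 1, n, n_tumors)
    prob = n_tumors / n
    ci_low, ci_high = poisson_exact_ci(n_tumors, n, level)
    return CohortSummary(
        n_progenitors=n,
        n_tumors=n_tumors,
        probability=prob,
        ci_low=ci_low,
        ci_high=ci_high,
        peaks=peaks,
        lifespans_days=lifespans,
        n_censored=n_censored,
        tumor_details=pd.DataFrame(rows, columns=_TUMOR_COLUMNS),
        phenotype=phenotype,
        seed=seed,
    )


def simulate_from_phenotype(
    phenotype: Phenotype,
    n: int,
    params: ModelParameters | None = None,
    seed: int = 0,
    **kwargs,
) -> CohortSummary:
    """Cohort of root cells initialized with a given (k, alpha, g).

    The root's mutation sum is set to ``k - k_p(g)`` so the differentiation
    equation holds, and it carries its implied ancestry ``d = g``; the run
    then proceeds exactly as a progenitor clone.  The summary's
    ``probability`` is the spawn probability of a detectable tumor.
    """
    phenotype.validate()
    return simulate_cohort(n, params=params, seed=seed, phenotype=phenotype, **kwargs)
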