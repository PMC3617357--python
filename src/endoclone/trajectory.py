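"""Single-cell dynamics: programmed trajectory and exact event propagation.

A cell's life is governed by its cycle status ``c(t)`` (the integral of the
proliferation potential ``alpha`` since birth): ``c = +1`` triggers division,
``c = -1`` apoptosis.  ``alpha`` relaxes toward the programmed proliferation
curve ``alpha_p(g)`` with strength ``k`` (the differentiation coefficient)
under hormonal forcing ``beta``.  The generation number ``g`` advances with
the running maximum of the lineage-cumulative cycle integral, modelling
telomere-style irreversible senescence.

:func:`propagate_cell` is exact (closed-form exponential relaxation on each
constant-``g`` piece, with bracketed Newton root finding for the event time);
it wraps the same compiled kernel the population engine uses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from . import _kernel as _k
from .params import ModelParameters

__all__ = [
    "programmed_proliferation",
    "programmed_differentiation",
    "CellState",
    "PropagationResult",
    "propagate_cell",
]


def _check_generation(g, minimum: int) -> np.ndarray:
    arr = np.asarray(g)
    if not np.issubdtype(arr.dtype, np.number):
        raise TypeError("generation must be numeric")
    if np.any(arr != np.floor(arr)):
        raise ValueError("generation must be an integer")
    if np.any(arr < minimum):
        raise ValueError(f"generation must be >= {minimum}")
    return arr.astype(float)


def programmed_proliferation(g, params: ModelParameters | None = None):
    """Programmed proliferation potential ``alpha_p(g)`` (cycles/month).

    Positive while ``g < g_limit``, zero at the limit, increasingly negative
    past it (the senescence pull), saturating at ``-alpha_p_scale`` under the
    default curve.  Scalar or array ``g``.
    """
    p = params or ModelParameters()
    garr = _check_generation(g, 1)
    gl, s = p.g_limit, p.alpha_p_scale
    if p.alpha_p_form == "linear":
        out = s * (gl - garr) / gl
    elif p.alpha_p_form == "rational":
        out = s * (gl - garr) / garr
    elif p.alpha_p_form == "clipped":
        out = np.maximum(s * (gl - garr) / gl, -s)
    else:  # saturating (default)
        q = math.log(s / p.senescence_onset) / math.log(p.senescence_span)
        x = np.clip((garr - gl) / p.senescence_span, 0.0, 1.0)
        out = np.where(garr <= gl, s * (gl - garr) / gl, -s * x**q)
    return out if isinstance(g, np.ndarray) else float(out)


def programmed_differentiation(g, params: ModelParameters | None = None):
    """Programmed differentiation coefficient
    ``k_p(g) = sat*(1 - exp(-rate*g)) + lin*g`` (1/month).

    Zero at ``g = 0``, increasing, approaching ``sat`` plus a slow linear
    drift; about 4.0 at the default generation limit (the differentiation
    level of a terminally differentiated epithelial cell).
    """
    p = params or ModelParameters()
    garr = _check_generation(g, 0)
    out = p.kp_saturation * (1.0 - np.exp(-p.kp_rate * garr)) + p.kp_linear * garr
    return out if isinstance(g, np.ndarray) else float(out)


@dataclass
class CellState:
    """The live record of one cell.

    ``lineage_code`` is the digit path from the progenitor (root ``"1"``,
    daughters append 1 or 2 — the decimal ID scheme ``10x + i`` kept as a
    digit sequence so depth is unbounded).  ``C`` is the lineage-cumulative
    cycle integral, inherited across divisions; ``C_max`` its running
    maximum; ``g = 1 + floor(C_max)``.
    """

    lineage_code: str = "1"
    birth_time: float = 0.0
    c: float = 0.0
    C: float = 0.0
    C_max: float = 0.0
    alpha: float = 2.95
    mutation_sum: float = 0.0
    beta: float = 5.0
    fate: str = "alive"

    @property
    def d(self) -> int:
        """Division depth: the root progenitor counts as division 1."""
        return len(self.lineage_code)

    @property
    def g(self) -> int:
        return 1 + int(math.floor(self.C_max))

    def k(self, params: ModelParameters | None = None) -> float:
        p = params or ModelParameters()
        kp = programmed_differentiation(self.g, p)
        return max(p.k_floor, kp + self.mutation_sum)

    def validate(self) -> None:
        if not set(self.lineage_code) <= {"1", "2"} or not self.lineage_code.startswith("1"):
            raise ValueError("lineage_code must be '1' followed by digits in {1,2}")
        if not -1.0 < self.c < 1.0:
            raise ValueError("cycle status must be strictly inside (-1, 1) for a live cell")
        if self.C_max < self.C - 1e-12:
            raise ValueError("C_max must be >= C")
        if self.fate != "alive":
            raise ValueError("only live cells can be propagated")


@dataclass
class PropagationResult:
    event: Literal["division", "death", "censored"]
    event_time: float       # absolute, months
    alpha: float            # alpha at the event
    k: float                # k at the event (post any generation increments)
    g: int
    c: float                # +1 division, -1 death, interior value if censored
    C_max: float
    snapshots: list = field(default_factory=list)  # (t, alpha, k, g, c) samples


_EVENT_NAMES = {_k.EV_DIV: "division", _k.EV_DIE: "death", _k.EV_CAP: "censored"}


def _advance_state(state: CellState, p: ModelParameters, horizon: float):
    P = p.to_array()
    Cbirth = state.C - state.c
    return _k._advance(
        state.alpha, state.c, state.mutation_sum, state.beta,
        Cbirth, state.C_max, horizon, P,
    )


def propagate_cell(
    state: CellState,
    params: ModelParameters | None = None,
    sample_times: np.ndarray | None = None,
) -> PropagationResult:
    """Exact propagation of a live cell to its next fate event.

    Integrates ``d(alpha)/dt = k (alpha_p - alpha) + beta`` piecewise in
    closed form, processing generation increments (which update ``k_p``,
    ``alpha_p`` and re-clamp ``k``), and returns the earliest time at which
    ``c`` reaches +1 (division) or -1 (death).  If no event occurs before
    ``max_sim_time`` the outcome is censored — a signal of parameter
    pathology such as ``alpha`` pinned near zero.

    ``sample_times`` (absolute months, within the cell's life) adds
    trajectory snapshots ``(t, alpha, k, g, c)`` to the result.
    """
    p = params or ModelParameters()
    state.validate()
    horizon = p.max_sim_time - state.birth_time
    code, s_end, a_end, g_e, k_e, c_e, cmx = _advance_state(state, p, horizon)
    snaps = []
    if sample_times is not None:
        for t in np.asarray(sample_times, dtype=float):
            rel = t - state.birth_time
            if rel < 0 or rel > s_end:
                continue
            cc, ss, aa, gg, kk, ccv, cm = _advance_state(state, p, rel)
            snaps.append((t, aa, kk, int(gg), ccv))
    return PropagationResult(
        event=_EVENT_NAMES[code],
        event_time=state.birth_time + s_end,
        alpha=a_end,
        k=k_e,
        g=int(g_e),
        c=c_e,
        C_max=cmx,
        snapshots=snaps,
    )
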