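"""Lineage bookkeeping and tree analysis.

Every cell carries a lineage code: the progenitor is ``"1"`` and a daughter
appends the digit 1 or 2 (the decimal scheme that assigns daughter IDs
``10x + i``, kept as a digit sequence because tumor lineages reach ~47
divisions and the literal integer would overflow 64 bits past ~18).

:class:`LineageTree` stores a whole clone's ancestry column-wise (parent
links, times, phenotype snapshots) plus which cells are alive in the final
mass, and supports descendant counts, fractional-mass most recent common
ancestors (MRCA), and Newick export.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernel import descendant_counts_arrays

__all__ = [
    "child_code",
    "LineageTree",
    "MrcaResult",
    "descendant_counts",
    "mrca_fraction",
    "to_newick",
]


def child_code(parent_code: str, which: int) -> str:
    """Lineage code of a daughter: append the digit ``which`` (1 or 2).

    Equivalent to the integer ID ``10x + which`` for codes short enough to
    fit an integer; depth equals the code length.
    """
    if which not in (1, 2):
        raise ValueError("which must be 1 or 2")
    if not parent_code or not set(parent_code) <= {"1", "2"}:
        raise ValueError("invalid lineage code")
    return parent_code + str(which)


@dataclass(frozen=True)
class MrcaResult:
    """MRCA(x): the deepest node covering at least ceil(x * final mass)."""

    index: int
    code: str
    d: int
    g: int
    alpha: float        # phenotype at the node's birth
    k: float
    count: int          # descendants in the final mass
    time_days: float    # birth time


class LineageTree:
    """Compressed clone ancestry with per-node phenotype snapshots.

    Column arrays over nodes (index 0 is the root; children always have a
    larger index than their parent): ``parent`` (-1 for the root), ``digit``
    (1 or 2), ``d`` (division depth; the progenitor's birth counts as
    division 1), birth/event times (months), alpha at birth and at the
    event, the differentiation coefficient at birth, and ``alive`` in the
    final mass.
    """

    def __init__(self, parent, digit, d, t_birth, t_event, alpha_birth,
                 alpha_event, k_birth, alive, root_code: str = "1"):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.digit = np.asarray(digit, dtype=np.int8)
        self.d = np.asarray(d, dtype=np.int32)
        self.t_birth = np.asarray(t_birth, dtype=float)
        self.t_event = np.asarray(t_event, dtype=float)
        self.alpha_birth = np.asarray(alpha_birth, dtype=float)
        self.alpha_event = np.asarray(alpha_event, dtype=float)
        self.k_birth = np.asarray(k_birth, dtype=float)
        self.alive = np.asarray(alive, dtype=bool)
        self.root_code = root_code
        self._counts = None
        self._validate()

    # -- construction -----------------------------------------------------
    @classmethod
    def from_codes(cls, codes, alive, root_code: str = "1", **node_fields):
        """Build a tree from explicit lineage codes (testing / toy trees).

        ``codes`` must contain every ancestor of every code (prefix-closed,
        rooted at ``root_code``); ``alive`` is the subset alive in the final
        mass.  Optional per-node fields (dicts code -> value): t_birth,
        t_event, alpha_birth, alpha_event, k_birth.
        """
        codes = sorted(set(codes), key=lambda s: (len(s), s))
        if not codes or codes[0] != root_code:
            raise ValueError(f"tree must be rooted at {root_code!r}")
        index = {c: i for i, c in enumerate(codes)}
        n = len(codes)
        parent = np.full(n, -1, dtype=np.int64)
        digit = np.ones(n, dtype=np.int8)
        for c, i in index.items():
            if c == root_code:
                continue
            if c[:-1] not in index:
                raise ValueError(f"orphan code {c!r}: parent {c[:-1]!r} missing")
            parent[i] = index[c[:-1]]
            digit[i] = int(c[-1])
        d = np.array([len(c) for c in codes], dtype=np.int32)
        alive_set = set(alive)
        unknown = alive_set - set(codes)
        if unknown:
            raise ValueError(f"alive codes not in tree: {sorted(unknown)}")
        alive_mask = np.array([c in alive_set for c in codes])

        def col(name, default=0.0):
            src = node_fields.get(name)
            if src is None:
                return np.full(n, default)
            return np.array([src.get(c, default) for c in codes])

        return cls(parent, digit, d, col("t_birth"), col("t_event"),
                   col("alpha_birth"), col("alpha_event"), col("k_birth"),
                   alive_mask, root_code=root_code)

    def _validate(self):
        n = len(self.parent)
        if n == 0:
            raise ValueError("empty tree")
        if self.parent[0] != -1 or np.any(self.parent[1:] < 0):
            raise ValueError("node 0 must be the unique root")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise ValueError("children must have larger indices than parents")

    # -- basic properties --------------------------------------------------
    def __len__(self) -> int:
        return len(self.parent)

    @property
    def n_final(self) -> int:
        """Cells alive in the final mass."""
        return int(self.alive.sum())

    def code(self, i: int) -> str:
        """Lineage code of node ``i`` (digit path from the root)."""
        digits = []
        while i > 0:
            digits.append(str(self.digit[i]))
            i = self.parent[i]
        return self.root_code + "".join(reversed(digits))

    def children(self) -> list[list[int]]:
        out: list[list[int]] = [[] for _ in range(len(self))]
        for i in range(1, len(self)):
            out[self.parent[i]].append(i)
        return out

    # -- analyses ----------------------------------------------------------
    def descendant_counts(self) -> np.ndarray:
        """Per-node count of final-mass descendants, the node itself
        included if alive.  Additive: a node's count equals the sum over its
        children plus its own alive flag; the root's count is the final
        mass size."""
        if self._counts is None:
            self._counts = descendant_counts_arrays(self.parent, self.alive)
        return self._counts

    def mrca(self, x: float) -> MrcaResult:
        """MRCA(x): deepest node whose final-mass descendant count covers at
        least ``ceil(x * N)`` of the ``N`` cells alive at the end.

        Ties at equal depth break toward the larger count, then the
        lexicographically smallest lineage code.  MRCA(1) is always the
        root.  Phenotype is reported at the node's birth.
        """
        if not 0.0 < x <= 1.0:
            raise ValueError("x must be in (0, 1]")
        n_final = self.n_final
        if n_final == 0:
            raise ValueError("final mass is empty")
        need = int(np.ceil(x * n_final))
        counts = self.descendant_counts()
        cand = np.nonzero(counts >= need)[0]
        dmax = self.d[cand].max()
        cand = cand[self.d[cand] == dmax]
        cmax = counts[cand].max()
        cand = cand[counts[cand] == cmax]
        if len(cand) > 1:
            best = min((self.code(int(i)), int(i)) for i in cand)[1]
        else:
            best = int(cand[0])
        return MrcaResult(
            index=best, code=self.code(best), d=int(self.d[best]),
            g=int(self.d[best]), alpha=float(self.alpha_birth[best]),
            k=float(self.k_birth[best]), count=int(counts[best]),
            time_days=float(self.t_birth[best] * 30.0),
        )

    def node_table(self) -> pd.DataFrame:
        """Per-node CSV-ready table (code, depth, times in days, phenotype,
        descendant count)."""
        counts = self.descendant_counts()
        return pd.DataFrame({
            "code": [self.code(i) for i in range(len(self))],
            "d": self.d,
            "t_birth_days": self.t_birth * 30.0,
            "t_event_days": self.t_event * 30.0,
            "alpha_birth": self.alpha_birth,
            "alpha_event": self.alpha_event,
            "k_birth": self.k_birth,
            "alive": self.alive,
            "descendants_in_mass": counts,
        })

    def to_newick(self, annotate: bool = False) -> str:
        """Newick serialization: labels are lineage codes, branch lengths
        the node lifespans in days, optional bracketed phenotype comments."""
        kids = self.children()
        pieces: dict[int, str] = {}
        # children have larger indices, so a reverse sweep sees them first
        for i in range(len(self) - 1, -1, -1):
            label = self.code(i)
            if annotate:
                label += (f"[&d={int(self.d[i])},alpha={self.alpha_birth[i]:.4g},"
                          f"k={self.k_birth[i]:.4g}]")
            length = max(self.t_event[i] - self.t_birth[i], 0.0) * 30.0
            me = f"{label}:{length:.6g}"
            if kids[i]:
                me = "(" + ",".join(pieces.pop(j) for j in kids[i]) + ")" + me
            pieces[i] = me
        return pieces[0] + ";"


def descendant_counts(tree: LineageTree) -> np.ndarray:
    """Per-node descendant counts in the final mass (see the method)."""
    return tree.descendant_counts()


def mrca_fraction(tree: LineageTree, x: float) -> MrcaResult:
    """Most recent common ancestor of ``x*100%`` of the final mass."""
    return tree.mrca(x)


def to_newick(tree: LineageTree, annotate: bool = False) -> str:
    """Serialize a lineage tree to Newick text."""
    return tree.to_newick(annotate=annotate)
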