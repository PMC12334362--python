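"""Feedback-loop enumeration and loop-weight analysis.

A loop is a closed chain of k distinct groups traversed through nonzero
community-matrix entries; its weight is the geometric mean of the absolute
values of the entries along the chain,

    w = |α_{i1 i2} · α_{i2 i3} · … · α_{ik i1}|^(1/k).

The maximum loop weight (MLW) over all loops approximates the minimal
diagonal strength needed for stability; in energetically derived webs it
is dominated by three-link omnivorous loops (two top-down effects plus one
bottom-up effect), so MLW defaults to the length-3 maximum.  Two-link
predator–prey loops generate pure negative feedback and are excluded from
MLW by default.

The two traversal directions of a cycle pass through different matrix
entries and are therefore distinct loops with distinct weights; both are
enumerated, and the tabular report keeps the heavier direction per group
set, which is how published loop tables are laid out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd

from .interaction import CommunityMatrix
from .webmodel import FoodWeb

__all__ = [
    "LoopRecord",
    "enumerate_loops",
    "loop_weight",
    "max_loop_weight",
    "loop_table",
    "category_means",
]


@dataclass(frozen=True)
class LoopRecord:
    """One directed loop: node chain, traversed entries, and weight.

    ``nodes = (n1, …, nk)`` traverses effects n1→n2→…→nk→n1, so
    ``entries = (α[n2,n1], α[n3,n2], …, α[n1,nk])``.  The rotation is
    canonical (lexicographically smallest node first); the direction is
    preserved.
    """

    nodes: tuple[str, ...]
    entries: tuple[float, ...]
    weight: float
    sign: int
    start_category: str = ""

    @property
    def k(self) -> int:
        return len(self.nodes)

    @property
    def label(self) -> str:
        return " > ".join(self.nodes)

    @property
    def n_negative(self) -> int:
        return sum(e < 0 for e in self.entries)


def loop_weight(entries) -> float:
    """Geometric mean of the absolute entry values along a loop."""
    entries = np.asarray(entries, dtype=float)
    if np.any(entries == 0.0):
        raise ValueError("loop entries must all be nonzero")
    return float(np.exp(np.mean(np.log(np.abs(entries)))))


def _record(matrix: CommunityMatrix, cycle: list[str]) -> LoopRecord:
    idx = {n: i for i, n in enumerate(matrix.names)}
    start = min(range(len(cycle)), key=lambda i: cycle[i])
    nodes = tuple(cycle[start:] + cycle[:start])
    entries = tuple(
        float(matrix.alpha[idx[nodes[(i + 1) % len(nodes)]], idx[nodes[i]]])
        for i in range(len(nodes))
    )
    sign = 1 if math.prod(1 if e > 0 else -1 for e in entries) > 0 else -1
    return LoopRecord(
        nodes=nodes, entries=entries, weight=loop_weight(entries), sign=sign
    )


def enumerate_loops(matrix: CommunityMatrix, k: int) -> list[LoopRecord]:
    """All simple directed loops of length exactly k in the off-diagonal
    nonzero pattern of α (edge u→v wherever u affects v, α[v,u] ≠ 0)."""
    if k < 2:
        raise ValueError("loop length must be at least 2")
    g = nx.DiGraph()
    g.add_nodes_from(matrix.names)
    off = matrix.off_diagonal()
    idx = {n: i for i, n in enumerate(matrix.names)}
    for u in matrix.names:
        for v in matrix.names:
            if u != v and off[idx[v], idx[u]] != 0.0:
                g.add_edge(u, v)
    records = [
        _record(matrix, cyc)
        for cyc in nx.simple_cycles(g, length_bound=k)
        if len(cyc) == k
    ]
    records.sort(key=lambda r: r.nodes)
    return records


def enumerate_loops_bruteforce(matrix: CommunityMatrix, k: int) -> list[LoopRecord]:
    """Exhaustive permutation search — independent oracle for small webs."""
    if k < 2:
        raise ValueError("loop length must be at least 2")
    off = matrix.off_diagonal()
    idx = {n: i for i, n in enumerate(matrix.names)}
    seen: set[tuple[str, ...]] = set()
    out: list[LoopRecord] = []
    for perm in permutations(matrix.names, k):
        if perm[0] != min(perm):  # canonical rotation only
            continue
        ok = all(
            off[idx[perm[(i + 1) % k]], idx[perm[i]]] != 0.0 for i in range(k)
        )
        if ok and perm not in seen:
            seen.add(perm)
            out.append(_record(matrix, list(perm)))
    out.sort(key=lambda r: r.nodes)
    return out


def max_loop_weight(
    matrix: CommunityMatrix,
    k: int = 3,
    all_lengths: bool = False,
    include_pairs: bool = False,
) -> tuple[float, LoopRecord]:
    """Maximum loop weight and its argmax loop.

    By default only length-3 loops are searched.  ``all_lengths=True``
    scans 2 ≤ k ≤ n, dropping two-link predator–prey loops unless
    ``include_pairs`` is set.  Ties break on lexicographic node order.
    """
    if all_lengths:
        lengths = range(2 if include_pairs else 3, matrix.n + 1)
    else:
        lengths = [k]
    best: LoopRecord | None = None
    for kk in lengths:
        for rec in enumerate_loops(matrix, kk):
            if best is None or rec.weight > best.weight + 0.0 or (
                rec.weight == best.weight and rec.nodes < best.nodes
            ):
                best = rec
    if best is None:
        raise ValueError("the matrix contains no loops")
    return best.weight, best


def _basal_rotation(nodes: tuple[str, ...], basal: set[str]) -> tuple[str, ...]:
    """Rotate a loop so a basal node (detritus/producer) leads, if present."""
    for i, n in enumerate(nodes):
        if n in basal:
            return nodes[i:] + nodes[:i]
    return nodes


def loop_table(
    matrix: CommunityMatrix,
    web: FoodWeb | None = None,
    categories: dict[str, str] | None = None,
    k: int = 3,
) -> pd.DataFrame:
    """Tabular report of k-link loops, one row per group set.

    Of the two traversal directions of each cycle the heavier one is kept
    (its weight, label, and count of negative entries).  Labels start at the
    basal node (detritus, then producers) when the loop has one.
    ``categories`` maps group name → root category (e.g. "phytoplankton",
    "macrophyte", "detritus"); groups without an entry are classified from
    web roles when a web is given, else "other".
    """
    cat = dict(categories or {})
    basal: set[str] = set()
    if web is not None:
        for g in web.groups:
            if g.role == "detritus":
                basal.add(g.name)
                cat.setdefault(g.name, "detritus")
            elif g.role == "producer":
                basal.add(g.name)
                cat.setdefault(g.name, "producer")
    basal |= {n for n, c in cat.items() if c != "other"}

    by_set: dict[frozenset, LoopRecord] = {}
    for rec in enumerate_loops(matrix, k):
        key = frozenset(rec.nodes)
        cur = by_set.get(key)
        if cur is None or rec.weight > cur.weight:
            by_set[key] = rec

    rows = []
    for rec in by_set.values():
        nodes = _basal_rotation(rec.nodes, basal)
        rows.append(
            {
                "loop": " > ".join(nodes),
                "start": nodes[0],
                "category": cat.get(nodes[0], "other"),
                "weight": rec.weight,
                "sign": rec.sign,
                "n_negative": rec.n_negative,
            }
        )
    df = pd.DataFrame(
        rows, columns=["loop", "start", "category", "weight", "sign", "n_negative"]
    )
    return df.sort_values("loop", ignore_index=True)


def category_means(table: pd.DataFrame, value_columns=None) -> pd.Series:
    """Arithmetic mean loop weight per root category, pooling every value
    cell (loops × periods when several period columns are supplied)."""
    if value_columns is None:
        value_columns = [c for c in ("weight",) if c in table.columns] or [
            c for c in table.columns if c not in ("loop", "start", "category",
                                                  "sign", "n_negative")
        ]
    melted = table.melt(
        id_vars=["category"], value_vars=list(value_columns), value_name="w"
    )
    return melted.groupby("category")["w"].mean()
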