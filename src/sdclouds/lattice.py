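"""Wildcard-pattern lattice over SD cores and its CV-guided pruning.

A *pattern* is a 6-character string over ``{A, C, G, T, _}`` where ``_``
marks an unspecified (wildcard) position; its *level* is the number of
fixed positions, so level 0 is the root ``______`` and level 6 the 4096
fully specified cores.  Every pattern is annotated with the mean and the
coefficient of variation (CV = sample std / mean) of the ETRs of the
leaves it matches.  Because a core can be reached from the root along
``6! = 720`` fixing orders, the lattice is pruned to a proper tree by
letting every pattern keep the single candidate parent of minimal CV —
the path of minimal variability — which yields one root-to-leaf path per
core.

The number of distinct patterns with ``k`` fixed positions is
``C(6, k) * 4**k`` (24 at level 1, 15 625 in total).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
import pandas as pd
from sklearn.base import BaseEstimator

from .etr_data import ALPHABET, CORE_LENGTH, EtrMap, WILDCARD

#: Total order on pattern symbols used for every tie-break and traversal:
#: ``_`` sorts before the nucleotides so that unfixing an earlier position
#: wins ties.
SYMBOL_ORDER = {WILDCARD: 0, "A": 1, "C": 2, "G": 3, "T": 4}

PATTERN_ALPHABET = set(ALPHABET) | {WILDCARD}


class PatternError(ValueError):
    """Invalid wildcard pattern."""


def validate_pattern(pattern: str) -> str:
    if len(pattern) != CORE_LENGTH or any(
        c not in PATTERN_ALPHABET for c in pattern
    ):
        raise PatternError(
            f"malformed pattern {pattern!r}: expected {CORE_LENGTH} "
            f"characters over {{A,C,G,T,_}}"
        )
    return pattern


def pattern_level(pattern: str) -> int:
    """Number of fixed (non-wildcard) positions."""
    return CORE_LENGTH - pattern.count(WILDCARD)


def pattern_key(pattern: str) -> tuple[int, ...]:
    """Sort key implementing the ``_ < A < C < G < T`` symbol order."""
    return tuple(SYMBOL_ORDER[c] for c in pattern)


def pattern_matches(pattern: str, core: str) -> bool:
    """True iff ``core`` is a (descendant) leaf of ``pattern``."""
    return all(p == WILDCARD or p == c for p, c in zip(pattern, core))


def pattern_children(pattern: str) -> set[str]:
    """All patterns obtained by fixing one wildcard to one nucleotide.

    A level-``k`` pattern has ``(6 - k) * 4`` children; a fully specified
    core has none.
    """
    validate_pattern(pattern)
    children = set()
    for pos, sym in enumerate(pattern):
        if sym != WILDCARD:
            continue
        for base in ALPHABET:
            children.add(pattern[:pos] + base + pattern[pos + 1:])
    return children


def pattern_parents(pattern: str) -> set[str]:
    """All patterns obtained by unfixing exactly one fixed position.

    A level-``j`` pattern has exactly ``j`` candidate parents; the root
    has none and is rejected.
    """
    validate_pattern(pattern)
    if pattern_level(pattern) == 0:
        raise PatternError("the root pattern has no parents")
    return {
        pattern[:pos] + WILDCARD + pattern[pos + 1:]
        for pos, sym in enumerate(pattern)
        if sym != WILDCARD
    }


@dataclass
class LatticeNode:
    """A pattern annotated with its descendant-leaf ETR statistics."""

    pattern: str
    level: int
    n_leaves: int
    mean_etr: float
    cv: float
    chosen_parent: str | None = None


def _cv(n: int, total: float, total_sq: float) -> tuple[float, float]:
    """(mean, cv) from streaming moments; sample (n-1) std; leaf cv 0."""
    mean = total / n
    if n < 2:
        return mean, 0.0
    var = max(0.0, (total_sq - total * total / n) / (n - 1))
    std = math.sqrt(var)
    if std == 0.0:
        return mean, 0.0
    if mean == 0.0:
        # cannot occur for ETRs in (0, 1] but keep degenerate inputs safe:
        # such a parent must never be preferred.
        return mean, math.inf
    return mean, std / mean


def build_lattice(etr_map: EtrMap) -> dict[str, LatticeNode]:
    """Annotate all 15 625 distinct patterns with mean ETR and CV.

    Requires a complete landscape.  Statistics are over the multiset of
    ETRs of the ``4**(6-level)`` leaves each pattern matches.
    """
    etr_map.require_complete()
    masks = [
        mask
        for k in range(CORE_LENGTH + 1)
        for mask in combinations(range(CORE_LENGTH), k)
    ]
    acc: dict[str, list[float]] = {}
    for core, v in etr_map.items():
        vsq = v * v
        for mask in masks:
            chars = list(core)
            for pos in mask:
                chars[pos] = WILDCARD
            p = "".join(chars)
            rec = acc.get(p)
            if rec is None:
                acc[p] = [1, v, vsq]
            else:
                rec[0] += 1
                rec[1] += v
                rec[2] += vsq
    nodes: dict[str, LatticeNode] = {}
    for p, (n, s, s2) in acc.items():
        mean, cv = _cv(n, s, s2)
        nodes[p] = LatticeNode(p, pattern_level(p), n, mean, cv)
    return nodes


ROOT = WILDCARD * CORE_LENGTH

PATH_COLUMNS = [f"level {k}" for k in range(CORE_LENGTH + 1)]


class PrunedLatticeTree(BaseEstimator):
    """Pruned wildcard-pattern tree over a complete SD-core landscape.

    Fitting builds the full annotated lattice, then resolves the multiple
    ancestries by giving every pattern the candidate parent with minimal
    CV (ties broken by the ``_ < A < C < G < T`` lexicographic order of
    the parent pattern) and discarding patterns that end up on no
    root-to-leaf chain.  The result is an arborescence in which each of
    the 4096 cores appears exactly once as a leaf and consecutive
    patterns along any path differ by fixing a single position.

    Attributes
    ----------
    lattice_ : dict[str, LatticeNode]
        All 15 625 annotated patterns (pre-pruning).
    nodes_ : dict[str, LatticeNode]
        Retained patterns; every non-root node carries ``chosen_parent``.
    children_ : dict[str, list[str]]
        Retained children per retained pattern, in traversal order.
    leaf_paths_ : dict[str, tuple[str, ...]]
        Root-to-leaf pattern path (7 entries) per core.
    path_table_ : pandas.DataFrame
        One row per leaf in depth-first order: columns ``level 0`` ..
        ``level 6``, ``ETR``, ``df_index``.
    """

    def fit(self, etr_map: EtrMap, y=None) -> "PrunedLatticeTree":
        lattice = build_lattice(etr_map)
        choice: dict[str, str] = {}
        for p in lattice:
            if p == ROOT:
                continue
            choice[p] = min(
                pattern_parents(p),
                key=lambda q: (lattice[q].cv, pattern_key(q)),
            )
        leaf_paths: dict[str, tuple[str, ...]] = {}
        retained: set[str] = {ROOT}
        for core in etr_map.cores:
            path = [core]
            while path[-1] != ROOT:
                path.append(choice[path[-1]])
            path.reverse()
            leaf_paths[core] = tuple(path)
            retained.update(path)
        nodes: dict[str, LatticeNode] = {}
        children: dict[str, list[str]] = {p: [] for p in retained}
        for p in retained:
            node = lattice[p]
            nodes[p] = LatticeNode(
                p,
                node.level,
                node.n_leaves,
                node.mean_etr,
                node.cv,
                None if p == ROOT else choice[p],
            )
            if p != ROOT:
                children[choice[p]].append(p)
        for kids in children.values():
            kids.sort(key=pattern_key)
        self.lattice_ = lattice
        self.nodes_ = nodes
        self.children_ = children
        self.leaf_paths_ = leaf_paths
        self.path_table_ = self._make_path_table(etr_map)
        return self

    def _make_path_table(self, etr_map: EtrMap) -> pd.DataFrame:
        rows: list[list] = []
        stack = [ROOT]
        while stack:
            p = stack.pop()
            kids = self.children_[p]
            if not kids:  # leaf
                rows.append(list(self.leaf_paths_[p]) + [etr_map[p]])
            else:
                stack.extend(reversed(kids))
        df = pd.DataFrame(rows, columns=PATH_COLUMNS + ["ETR"])
        df["df_index"] = range(len(df))
        return df

    # -- convenience -----------------------------------------------------
    @property
    def leaves_(self) -> list[str]:
        """Cores in depth-first path-table order."""
        return list(self.path_table_[f"level {CORE_LENGTH}"])

    def export_paths(self, path: str | Path) -> None:
        """Write the depth-first path table as CSV (UTF-8, '.' decimal)."""
        self.path_table_.to_csv(path, index=False, encoding="utf-8")


def prune_lattice(etr_map: EtrMap) -> PrunedLatticeTree:
    """Functional wrapper: fit a :class:`PrunedLatticeTree` on a landscape."""
    return PrunedLatticeTree().fit(etr_map)


def export_paths(
    tree: PrunedLatticeTree, path: str | Path
) -> pd.DataFrame:
    """Write ``tree.path_table_`` to ``path`` and return it."""
    tree.export_paths(path)
    return tree.path_table_
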