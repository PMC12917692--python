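"""Activity-cloud partitioning of SD cores.

Each pruned-tree leaf is embedded in a 230-dimensional binary space:

* 30 sequence bits — one-hot over the 5-symbol alphabet ``A, C, G, T, _``
  per position (the wildcard slot is retained, and constantly zero, for
  fully specified cores);
* 200 ETR bits — a cumulative (thermometer) encoding that turns the
  ETR ``v`` into ``k = round(v, 2) * 200`` leading ones, so that
  differences in expression become exact Hamming distances comparable in
  weight to the sequence bits.

Squared Euclidean distance between two encoded cores therefore equals
``2 * hamming(seq) + |k1 - k2|``.

Density clustering (DBSCAN, Euclidean, ``min_samples = 1`` so that no
point is noise and clusters are exactly the connected components of the
eps-neighborhood graph) is run along an eps sweep — starting at 5.9 and
growing by 0.05 — until at most 400 labels remain.  The resulting
clusters are the *activity clouds*: groups of cores proximal both in
sequence space and in expression, summarized by their mean and sample
standard deviation of member ETRs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import DBSCAN

from .etr_data import EtrMap, SYMBOLS, CORE_LENGTH
from .lattice import PrunedLatticeTree, validate_pattern

N_SEQ_BITS = CORE_LENGTH * len(SYMBOLS)  # 30
N_ETR_BITS = 200

_SYM_INDEX = {s: i for i, s in enumerate(SYMBOLS)}


class CloudError(ValueError):
    """Invalid clustering input or cloud lookup."""


def encode_pattern(pattern: str) -> np.ndarray:
    """One-hot encode a pattern: 6 blocks of 5 bits (A, C, G, T, _)."""
    validate_pattern(pattern)
    bits = np.zeros(N_SEQ_BITS, dtype=np.uint8)
    for pos, sym in enumerate(pattern):
        bits[pos * len(SYMBOLS) + _SYM_INDEX[sym]] = 1
    return bits


def etr_rank(v: float) -> int:
    """Number of leading ones in the cumulative ETR encoding.

    ``k = round(v, 2) * 200`` — the two-decimal rounding happens first,
    so e.g. ``v = 0.50 -> k = 100`` and ``v = 0.1190 -> k = 24``.
    """
    if not 0.0 <= v <= 1.0:
        raise CloudError(f"ETR out of [0, 1]: {v}")
    return int(round(round(float(v), 2) * N_ETR_BITS))


def encode_etr(v: float) -> np.ndarray:
    """Cumulative binary encoding: ``etr_rank(v)`` ones then zeros."""
    k = etr_rank(v)
    bits = np.zeros(N_ETR_BITS, dtype=np.uint8)
    bits[:k] = 1
    return bits


def feature_matrix(
    patterns: Sequence[str], etrs: Sequence[float]
) -> np.ndarray:
    """Stack ``encode_pattern ⊕ encode_etr`` rows into an (n, 230) matrix."""
    if len(patterns) != len(etrs):
        raise CloudError("patterns and etrs must have equal length")
    rows = [
        np.concatenate([encode_pattern(p), encode_etr(v)])
        for p, v in zip(patterns, etrs)
    ]
    return np.asarray(rows, dtype=float)


@dataclass
class SweepConfig:
    """Parameters of the eps sweep (defaults pin the published run)."""

    eps_start: float = 5.9
    eps_step: float = 0.05
    label_cap: int = 400
    min_samples: int = 1

    def __post_init__(self) -> None:
        if self.eps_start <= 0 or self.eps_step <= 0 or self.label_cap < 1:
            raise CloudError(f"invalid sweep configuration: {self}")


def cluster_sweep(
    X: np.ndarray, config: SweepConfig | None = None
) -> tuple[np.ndarray, float, list[tuple[float, int]]]:
    """Run the DBSCAN eps sweep and return ``(labels, final_eps, history)``.

    Starting at ``eps_start``, DBSCAN (Euclidean) is re-run with eps
    incremented by ``eps_step`` until the number of distinct labels
    (clusters plus noise) is at most ``label_cap``.  With
    ``min_samples = 1`` no point is ever labeled noise and the labels are
    the connected components of the eps-neighborhood graph, so the label
    count is non-increasing along the sweep (asserted).
    """
    config = config or SweepConfig()
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise CloudError("feature matrix must be a nonempty 2-D array")
    # Upper bound on the data diameter (bounding-box diagonal): once eps
    # exceeds it everything is one cluster, so failing to meet any cap
    # >= 1 below it signals an internal error.
    diameter_bound = float(
        np.sqrt(np.sum((X.max(axis=0) - X.min(axis=0)) ** 2))
    )
    eps = config.eps_start
    history: list[tuple[float, int]] = []
    prev = None
    while True:
        labels = DBSCAN(
            eps=eps, min_samples=config.min_samples, metric="euclidean"
        ).fit_predict(X)
        n_labels = len(np.unique(labels))
        history.append((eps, n_labels))
        if config.min_samples == 1 and prev is not None and n_labels > prev:
            raise AssertionError(
                "label count increased along the sweep "
                f"({prev} -> {n_labels} at eps={eps:g})"
            )
        prev = n_labels
        if n_labels <= config.label_cap:
            return labels, eps, history
        if eps > diameter_bound + config.eps_step:
            raise RuntimeError(
                "eps sweep exceeded the data diameter without meeting the "
                "label cap"
            )
        eps = round(eps + config.eps_step, 10)


class CloudTable:
    """Activity-cloud partition with per-cloud statistics.

    Holds one record per cloud: integer label, mean ETR ``mu``, sample
    standard deviation ``sigma`` (missing for singletons) and the member
    core list.  Labels are assigned 0, 1, 2, ... by first member
    occurrence in the row order used to build the table (depth-first
    path-table order in the standard pipeline).
    """

    def __init__(
        self,
        members: Mapping[int, Sequence[str]],
        etr_map: EtrMap,
    ) -> None:
        self._members: dict[int, list[str]] = {
            int(k): list(v) for k, v in members.items()
        }
        seen: dict[str, int] = {}
        for label, cores in self._members.items():
            if not cores:
                raise CloudError(f"cloud {label} is empty")
            for c in cores:
                if c in seen:
                    raise CloudError(f"core {c} in clouds {seen[c]} and {label}")
                seen[c] = label
        self._label_of = seen
        recs = []
        for label in sorted(self._members):
            etrs = np.array([etr_map[c] for c in self._members[label]])
            recs.append(
                {
                    "label": label,
                    "mean": float(etrs.mean()),
                    "std": float(etrs.std(ddof=1)) if len(etrs) > 1 else np.nan,
                    "n": len(etrs),
                }
            )
        self.stats = pd.DataFrame(recs)

    # -- construction ----------------------------------------------------
    @classmethod
    def from_labels(
        cls,
        cores: Sequence[str],
        labels: Sequence[int],
        etr_map: EtrMap,
    ) -> "CloudTable":
        """Build a table from raw cluster labels.

        Clouds are relabeled 0, 1, 2, ... by first occurrence in the
        given row order.
        """
        if len(cores) != len(labels):
            raise CloudError("cores and labels must have equal length")
        relabel: dict[int, int] = {}
        members: dict[int, list[str]] = {}
        for core, raw in zip(cores, labels):
            label = relabel.setdefault(int(raw), len(relabel))
            members.setdefault(label, []).append(core)
        return cls(members, etr_map)

    # -- access ----------------------------------------------------------
    @property
    def labels(self) -> list[int]:
        return list(self.stats["label"])

    @property
    def n_clouds(self) -> int:
        return len(self.stats)

    def members(self, label: int) -> list[str]:
        return list(self._members[label])

    def label_of(self, core: str) -> int:
        try:
            return self._label_of[core]
        except KeyError:
            raise CloudError(f"core {core} belongs to no cloud") from None

    def __contains__(self, core: str) -> bool:
        return core in self._label_of

    def mean(self, label: int) -> float:
        return float(self.stats.set_index("label").loc[label, "mean"])

    def core_to_label(self) -> dict[str, int]:
        return dict(self._label_of)

    # -- I/O ---------------------------------------------------------
    CSV_COLUMNS = [
        "CLUSTER",
        "CORE REL EXPR_mean",
        "CORE REL EXPR_std",
        "SEQ_unique",
    ]

    def to_frame(self) -> pd.DataFrame:
        """Publication-style table; singleton std rendered as ``N/A``."""
        df = pd.DataFrame(
            {
                "CLUSTER": self.stats["label"],
                "CORE REL EXPR_mean": self.stats["mean"].round(4),
                "CORE REL EXPR_std": [
                    "N/A" if np.isnan(s) else f"{s:.4f}"
                    for s in self.stats["std"]
                ],
                "SEQ_unique": [
                    ", ".join(self._members[label])
                    for label in self.stats["label"]
                ],
            }
        )
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, encoding="utf-8")

    @classmethod
    def from_csv(cls, path: str | Path, etr_map: EtrMap) -> "CloudTable":
        df = pd.read_csv(path)
        members = {
            int(row["CLUSTER"]): [
                s.strip() for s in str(row["SEQ_unique"]).split(",")
            ]
            for _, row in df.iterrows()
        }
        return cls(members, etr_map)


def summarize_clouds(
    labels: Sequence[int],
    cores: Sequence[str],
    etr_map: EtrMap,
) -> CloudTable:
    """Per-cloud mean/std/members from raw labels (relabeled by first
    occurrence in the given row order)."""
    return CloudTable.from_labels(cores, labels, etr_map)


class ActivityCloudPartitioner(ClusterMixin, BaseEstimator):
    """Eps-sweep density clustering of encoded SD cores.

    scikit-learn style estimator: ``fit(X)`` on the (n, 230) binary
    feature matrix runs the DBSCAN eps sweep and exposes the final
    labels.  Labels are renumbered 0, 1, 2, ... by first occurrence in
    row order, so feeding rows in depth-first path-table order yields the
    canonical cloud numbering.

    Parameters
    ----------
    eps_start, eps_step, label_cap, min_samples :
        See :class:`SweepConfig`; defaults are the published settings
        (5.9, 0.05, 400, 1).

    Attributes
    ----------
    labels_ : ndarray of int
        Final cloud label per row.
    eps_ : float
        The eps at which the sweep terminated.
    sweep_history_ : list of (eps, n_labels)
    n_clouds_ : int
    """

    def __init__(
        self,
        eps_start: float = 5.9,
        eps_step: float = 0.05,
        label_cap: int = 400,
        min_samples: int = 1,
    ) -> None:
        self.eps_start = eps_start
        self.eps_step = eps_step
        self.label_cap = label_cap
        self.min_samples = min_samples

    def fit(self, X, y=None) -> "ActivityCloudPartitioner":
        config = SweepConfig(
            eps_start=self.eps_start,
            eps_step=self.eps_step,
            label_cap=self.label_cap,
            min_samples=self.min_samples,
        )
        raw, eps, history = cluster_sweep(np.asarray(X, dtype=float), config)
        relabel: dict[int, int] = {}
        labels = np.empty(len(raw), dtype=int)
        for i, r in enumerate(raw):
            labels[i] = relabel.setdefault(int(r), len(relabel))
        self.labels_ = labels
        self.eps_ = eps
        self.sweep_history_ = history
        self.n_clouds_ = len(relabel)
        return self

    def fit_tree(
        self, tree: PrunedLatticeTree, etr_map: EtrMap
    ) -> CloudTable:
        """Cluster the pruned tree's leaves and return the cloud table.

        Rows are the 4096 leaves in depth-first order, features are the
        sequence one-hot concatenated with the cumulative ETR encoding.
        """
        leaves = tree.leaves_
        X = feature_matrix(leaves, [etr_map[c] for c in leaves])
        self.fit(X)
        self.cloud_table_ = CloudTable.from_labels(
            leaves, self.labels_, etr_map
        )
        return self.cloud_table_
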