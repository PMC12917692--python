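"""Positional nucleotide influence on ETR.

Quantifies how each nucleotide at each SD-core position contributes to
the effective translation rate by regressing the one-hot encoded
sequence (5 symbols x 6 positions = 30 predictors) on ETR with partial
least squares (PLS).  PLS handles the perfect multicollinearity of
one-hot blocks and its orthogonal components let the overall coefficient
of every (symbol, position) feature be decomposed into per-component
contributions; summing those contributions signed gives the *raw* total
influence, summing their magnitudes the *absolute* total influence.

The module also provides composition summaries: which nucleotide is
newly fixed at a given level of the pruned tree across all 4096 leaf
paths, and the positional nucleotide distribution inside high-ETR
activity clouds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import train_test_split

from .etr_data import ALPHABET, CORE_LENGTH, EtrMap, SYMBOLS
from .clouds import CloudTable, encode_pattern
from .lattice import PrunedLatticeTree, WILDCARD


class InfluenceError(ValueError):
    """Invalid influence-analysis input."""


POSITION_COLUMNS = [f"pos{i + 1}" for i in range(CORE_LENGTH)]


def _to_matrix(per_feature: np.ndarray) -> pd.DataFrame:
    """Reshape a length-30 feature vector to the 5 x 6 symbol-by-position
    layout (rows A, C, G, T, _)."""
    mat = np.empty((len(SYMBOLS), CORE_LENGTH))
    for pos in range(CORE_LENGTH):
        for si in range(len(SYMBOLS)):
            mat[si, pos] = per_feature[pos * len(SYMBOLS) + si]
    return pd.DataFrame(mat, index=list(SYMBOLS), columns=POSITION_COLUMNS)


class PositionalInfluencePLS(BaseEstimator):
    """PLS-based 5 x 6 nucleotide-by-position influence matrices.

    Parameters
    ----------
    n_components : int, default 4
        Number of PLS components.
    train_fraction : float, default 0.8
        Fraction of rows used for fitting; the rest scores the held-out
        R^2.  ``1.0`` fits on everything (R^2 reported as NaN).
    random_state : int, default 0
        Pins the train/test split.

    Attributes
    ----------
    raw_ : DataFrame (5 x 6)
        Signed total influence: per-feature sum of signed per-component
        coefficient contributions (equals the overall PLS regression
        coefficient).
    absolute_ : DataFrame (5 x 6)
        Sum of per-component contribution magnitudes.
    r2_ : float
        Held-out R^2 (NaN when ``train_fraction == 1`` or the response
        is constant).

    Notes
    -----
    Predictors are left unscaled: one-hot columns already share a common
    scale, and the wildcard columns are constant (zero) when fitting on
    fully specified cores — their influence is exactly 0 by construction.
    A constant response yields all-zero influence matrices rather than an
    error, consistent with "no signal".
    """

    def __init__(
        self,
        n_components: int = 4,
        train_fraction: float = 0.8,
        random_state: int = 0,
    ) -> None:
        self.n_components = n_components
        self.train_fraction = train_fraction
        self.random_state = random_state

    def fit(self, X, y) -> "PositionalInfluencePLS":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if self.n_components < 1:
            raise InfluenceError("n_components must be >= 1")
        if X.ndim != 2 or X.shape[1] != len(SYMBOLS) * CORE_LENGTH:
            raise InfluenceError(
                f"X must have {len(SYMBOLS) * CORE_LENGTH} one-hot columns"
            )
        if np.ptp(y) == 0:
            zeros = np.zeros(X.shape[1])
            self.raw_ = _to_matrix(zeros)
            self.absolute_ = _to_matrix(zeros)
            self.r2_ = float("nan")
            self.contributions_ = np.zeros((X.shape[1], self.n_components))
            return self
        if self.train_fraction < 1.0:
            X_tr, X_te, y_tr, y_te = train_test_split(
                X,
                y,
                train_size=self.train_fraction,
                random_state=self.random_state,
            )
        else:
            X_tr, y_tr = X, y
            X_te = y_te = None
        pls = PLSRegression(n_components=self.n_components, scale=False)
        pls.fit(X_tr, y_tr)
        # Coefficient chain: B = x_rotations_ @ y_loadings_.T, so component
        # a contributes x_rotations_[:, a] * y_loadings_[0, a] per feature.
        contrib = pls.x_rotations_ * pls.y_loadings_[0][np.newaxis, :]
        self.contributions_ = contrib
        self.raw_ = _to_matrix(contrib.sum(axis=1))
        self.absolute_ = _to_matrix(np.abs(contrib).sum(axis=1))
        self.r2_ = (
            float(pls.score(X_te, y_te)) if X_te is not None else float("nan")
        )
        self.pls_ = pls
        return self

    def fit_landscape(self, etr_map: EtrMap) -> "PositionalInfluencePLS":
        """Fit on all fully specified cores of a complete landscape."""
        etr_map.require_complete()
        cores = etr_map.cores
        X = np.asarray([encode_pattern(c) for c in cores], dtype=float)
        y = etr_map.etr_array(cores)
        return self.fit(X, y)


def fit_positional_influence(
    etr_map: EtrMap,
    n_components: int = 4,
    train_fraction: float = 0.8,
    seed: int = 0,
) -> PositionalInfluencePLS:
    """Functional wrapper over :class:`PositionalInfluencePLS`."""
    return PositionalInfluencePLS(
        n_components=n_components,
        train_fraction=train_fraction,
        random_state=seed,
    ).fit_landscape(etr_map)


def level_composition(tree: PrunedLatticeTree, level: int) -> pd.DataFrame:
    """Distribution of the nucleotide newly fixed at ``level``.

    Over all 4096 leaf paths, tallies which base the step from
    ``level - 1`` to ``level`` fixes (for level 1 this is the single
    fixed base of the level-1 pattern).  Returns a 4-row table indexed
    A, C, G, T with ``count`` and ``fraction`` columns; counts sum to
    4096.
    """
    if not 1 <= level <= CORE_LENGTH:
        raise InfluenceError(f"level must be in 1..{CORE_LENGTH}, got {level}")
    counts = {b: 0 for b in ALPHABET}
    for path in tree.leaf_paths_.values():
        prev, cur = path[level - 1], path[level]
        for a, b in zip(prev, cur):
            if a == WILDCARD and b != WILDCARD:
                counts[b] += 1
                break
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "count": [counts[b] for b in ALPHABET],
            "fraction": [counts[b] / total for b in ALPHABET],
        },
        index=list(ALPHABET),
    )


def high_etr_cloud_composition(
    cloud_table: CloudTable, threshold: float = 0.75
) -> pd.DataFrame:
    """Positional nucleotide distribution in strong activity clouds.

    Pools the member cores of every cloud with mean ETR strictly above
    ``threshold`` and returns a 4 x 6 table of per-position nucleotide
    fractions (rows A, C, G, T; each column sums to 1).  An empty
    selection returns an empty table.
    """
    members: list[str] = []
    for row in cloud_table.stats.itertuples():
        if row.mean > threshold:
            members.extend(cloud_table.members(int(row.label)))
    if not members:
        return pd.DataFrame(columns=POSITION_COLUMNS)
    counts = np.zeros((len(ALPHABET), CORE_LENGTH))
    idx = {b: i for i, b in enumerate(ALPHABET)}
    for core in members:
        for pos, base in enumerate(core):
            counts[idx[base], pos] += 1
    return pd.DataFrame(
        counts / len(members), index=list(ALPHABET), columns=POSITION_COLUMNS
    )
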