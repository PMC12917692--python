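"""Design queries and external-validation machinery.

The bidirectional workflow over an activity-cloud partition:

* forward — ``core_to_cloud``: which cloud (hence which ETR band) a
  chosen SD core falls in;
* inverse — ``target_to_candidates``: which clouds (hence which member
  cores) best match a target ETR.

For validating against external RBS-activity data sets the module also
calls SD cores in 5'-UTRs (sliding a 6-nt window over the admissible
spacer range and keeping the strongest core), aggregates external
readouts per cloud with 95% confidence intervals, and computes the
Pearson correlation between cloud-mean ETRs and cloud-mean readouts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .etr_data import ALPHABET, CORE_LENGTH, EtrMap, ExternalMeasurement
from .clouds import CloudError, CloudTable

logger = logging.getLogger(__name__)

DEFAULT_SPACER_RANGE = (5, 8)


class QueryError(ValueError):
    """Invalid query input (infeasible UTR geometry, bad target, ...)."""


@dataclass(frozen=True)
class CoreCall:
    """An SD core called inside a 5'-UTR.

    ``spacer_length`` counts the bases strictly between the core's 3' end
    and the start codon's first base; ``window_start`` is the 0-based
    offset of the core in the UTR.
    """

    core: str
    spacer_length: int
    window_start: int


@dataclass(frozen=True)
class CloudHit:
    """A cloud returned by a design query."""

    label: int
    mean: float
    std: float  # NaN for singleton clouds
    members: tuple[str, ...]


def core_to_cloud(core: str, cloud_table: CloudTable) -> CloudHit:
    """Forward query: the unique cloud containing ``core``.

    Raises :class:`~sdclouds.clouds.CloudError` if the core belongs to no
    cloud.
    """
    label = cloud_table.label_of(core)
    row = cloud_table.stats.set_index("label").loc[label]
    return CloudHit(
        label=int(label),
        mean=float(row["mean"]),
        std=float(row["std"]),
        members=tuple(cloud_table.members(label)),
    )


def target_to_candidates(
    target_etr: float,
    cloud_table: CloudTable,
    max_clouds: int | None = None,
) -> list[CloudHit]:
    """Inverse query: clouds ranked by ``|mu_j - target|``.

    Ties are broken by ascending label; the ranking is truncated to
    ``max_clouds`` entries when given.
    """
    if not 0.0 <= target_etr <= 1.0:
        raise QueryError(f"target ETR out of [0, 1]: {target_etr}")
    if cloud_table.n_clouds == 0:
        raise QueryError("empty cloud table")
    order = sorted(
        cloud_table.stats.itertuples(),
        key=lambda r: (abs(r.mean - target_etr), r.label),
    )
    if max_clouds is not None:
        order = order[:max_clouds]
    return [
        CloudHit(
            label=int(r.label),
            mean=float(r.mean),
            std=float(r.std),
            members=tuple(cloud_table.members(int(r.label))),
        )
        for r in order
    ]


def identify_sd_core(
    utr: str,
    start_index: int,
    etr_map: EtrMap,
    spacer_range: tuple[int, int] = DEFAULT_SPACER_RANGE,
) -> CoreCall:
    """Call the SD core in a 5'-UTR by the max-ETR rule.

    For each feasible spacer length ``s`` in ``spacer_range`` (default
    5-8 nt) the candidate window is the 6-mer ending ``s`` bases before
    ``start_index`` (the 0-based position of the start codon's first
    base).  Among feasible windows the one with maximal ETR wins; ties go
    to the smallest spacer.  Windows containing non-ACGT characters, or
    whose 6-mer is absent from the landscape, are skipped.

    Raises
    ------
    QueryError
        If no candidate window fits in the UTR ("UTR too short") or every
        window was skipped.
    """
    utr = utr.upper().replace("U", "T")
    lo, hi = spacer_range
    if lo < 0 or hi < lo:
        raise QueryError(f"invalid spacer range {spacer_range}")
    best: CoreCall | None = None
    best_etr = -np.inf
    any_feasible = False
    for spacer in range(lo, hi + 1):
        ws = start_index - spacer - CORE_LENGTH
        if ws < 0 or start_index - spacer > len(utr):
            continue
        any_feasible = True
        window = utr[ws:ws + CORE_LENGTH]
        if any(c not in ALPHABET for c in window) or window not in etr_map:
            continue
        etr = etr_map[window]
        if etr > best_etr:  # strict: ties keep the smallest spacer
            best_etr = etr
            best = CoreCall(window, spacer, ws)
    if not any_feasible:
        raise QueryError(
            f"UTR too short: no {CORE_LENGTH}-mer window fits with spacers "
            f"{lo}-{hi} before start_index {start_index}"
        )
    if best is None:
        raise QueryError("all candidate windows were skipped")
    return best


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its two-sided p-value."""

    r: float
    p: float
    n: int


def correlate(
    x: Sequence[float], y: Sequence[float]
) -> CorrelationResult:
    """Pearson r and two-sided p under the zero-correlation null."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise QueryError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise QueryError(f"need at least 3 pairs, got {len(x)}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise QueryError("non-finite values in correlation input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise QueryError("zero variance: correlation undefined")
    r, p = _stats.pearsonr(x, y)
    return CorrelationResult(float(r), float(p), len(x))


def aggregate_external_by_cloud(
    measurements: Sequence[ExternalMeasurement],
    calls: Sequence[CoreCall | None],
    cloud_table: CloudTable,
) -> pd.DataFrame:
    """Aggregate external readouts per activity cloud.

    ``calls`` is parallel to ``measurements`` (``None`` marks a failed
    core call).  Measurements whose call is missing or whose core belongs
    to no cloud are skipped with a logged warning.  Returns one row per
    cloud with columns ``label``, ``n``, ``mean``, ``std`` (sample,
    ddof=1; NaN for n < 2) and ``ci95_halfwidth = 1.96 * std / sqrt(n)``.
    """
    if len(measurements) != len(calls):
        raise QueryError("measurements and calls must be parallel")
    rows = []
    skipped = 0
    for m, call in zip(measurements, calls):
        if call is None:
            skipped += 1
            continue
        try:
            label = cloud_table.label_of(call.core)
        except CloudError:
            skipped += 1
            continue
        rows.append({"label": label, "readout": m.readout})
    if skipped:
        logger.warning(
            "aggregate_external_by_cloud: skipped %d of %d measurements "
            "without a resolvable cloud",
            skipped,
            len(measurements),
        )
    if not rows:
        raise QueryError("no measurement could be resolved to a cloud")
    df = pd.DataFrame(rows)
    agg = (
        df.groupby("label")["readout"]
        .agg(n="count", mean="mean", std=lambda s: s.std(ddof=1))
        .reset_index()
    )
    agg["ci95_halfwidth"] = 1.96 * agg["std"] / np.sqrt(agg["n"])
    return agg


def call_cores(
    measurements: Sequence[ExternalMeasurement],
    start_index: int,
    etr_map: EtrMap,
    spacer_range: tuple[int, int] = DEFAULT_SPACER_RANGE,
) -> list[CoreCall | None]:
    """Call the SD core of every measurement; ``None`` where calling fails."""
    calls: list[CoreCall | None] = []
    for m in measurements:
        try:
            calls.append(
                identify_sd_core(
                    m.rbs_sequence, start_index, etr_map, spacer_range
                )
            )
        except QueryError:
            calls.append(None)
    return calls


def validate_against_external(
    measurements: Sequence[ExternalMeasurement],
    start_index: int,
    etr_map: EtrMap,
    cloud_table: CloudTable,
    spacer_range: tuple[int, int] = DEFAULT_SPACER_RANGE,
) -> tuple[pd.DataFrame, CorrelationResult]:
    """End-to-end external validation.

    Calls cores, aggregates readouts per cloud, then correlates cloud
    mean ETR (x) against cloud mean readout (y).  Returns the per-cloud
    aggregate table (with the cloud-mean ETR joined in) and the
    correlation.
    """
    calls = call_cores(measurements, start_index, etr_map, spacer_range)
    agg = aggregate_external_by_cloud(measurements, calls, cloud_table)
    cloud_means = cloud_table.stats.set_index("label")["mean"]
    agg = agg.assign(cloud_mean_etr=agg["label"].map(cloud_means))
    result = correlate(agg["cloud_mean_etr"], agg["mean"])
    return agg, result
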