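"""Loading, validation, conversion and synthesis of SD-core ETR landscapes.

The central object is :class:`EtrMap`, a mapping from six-nucleotide
Shine-Dalgarno (SD) core sequences to an effective translation rate
(ETR), a dimensionless relative expression strength normalized to
``[0, 1]``.  A *complete* map covers all ``4**6 = 4096`` cores and is the
input to every downstream analysis (lattice pruning, activity-cloud
partitioning, positional influence, mutational graphs).

Besides reading/writing the canonical tab-delimited format, this module

* merges a *measured* and a *predicted* table into one landscape,
  preferring measurements and recording per-entry provenance;
* extracts sequence->value dictionaries embedded in upstream Python
  source files (the form in which the EMOPEC measurements are
  distributed) so they can be converted to the canonical format;
* generates synthetic landscapes with additive per-position nucleotide
  effects plus seeded Gaussian noise, and synthetic RBS activity
  measurements correlated with a landscape — the test bed for the whole
  toolkit.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

ALPHABET = "ACGT"
#: Symbol order used by the one-hot encoding (wildcard last).
SYMBOLS = "ACGT_"
WILDCARD = "_"
CORE_LENGTH = 6
N_CORES = 4 ** CORE_LENGTH  # 4096

VALID_SOURCES = frozenset({"measured", "predicted", "synthetic"})


class EtrDataError(ValueError):
    """Malformed or inconsistent landscape/measurement data."""


def all_cores() -> Iterator[str]:
    """Yield all 4096 fully specified cores in lexicographic order."""
    for tup in itertools.product(ALPHABET, repeat=CORE_LENGTH):
        yield "".join(tup)


def validate_core(core: str) -> str:
    """Return ``core`` uppercased, or raise :class:`EtrDataError`."""
    if not isinstance(core, str):
        raise EtrDataError(f"core must be a string, got {type(core).__name__}")
    core = core.upper()
    if len(core) != CORE_LENGTH or any(c not in ALPHABET for c in core):
        raise EtrDataError(
            f"malformed core {core!r}: expected {CORE_LENGTH} characters over "
            f"{{A,C,G,T}}"
        )
    return core


@dataclass
class EtrMap:
    """Mapping core -> ETR with per-entry provenance.

    Parameters
    ----------
    values :
        ``core -> etr`` with every key a 6-mer over ``{A,C,G,T}`` and every
        value in ``[0, 1]``.
    sources :
        ``core -> provenance`` with provenance one of ``measured``,
        ``predicted`` or ``synthetic``.  Must share the key set of
        ``values``.
    """

    values: dict[str, float]
    sources: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, float] = {}
        srcs: dict[str, str] = {}
        for core, v in self.values.items():
            core = validate_core(core)
            v = float(v)
            if not 0.0 <= v <= 1.0:
                raise EtrDataError(f"ETR for {core} out of [0, 1]: {v}")
            clean[core] = v
            src = self.sources.get(core, "measured")
            if src not in VALID_SOURCES:
                raise EtrDataError(f"unknown source {src!r} for {core}")
            srcs[core] = src
        self.values = clean
        self.sources = srcs

    # -- mapping protocol ------------------------------------------------
    def __getitem__(self, core: str) -> float:
        return self.values[validate_core(core)]

    def __contains__(self, core: str) -> bool:
        return core in self.values

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self) -> Iterator[str]:
        return iter(self.values)

    def items(self):
        return self.values.items()

    @property
    def cores(self) -> list[str]:
        """Member cores in lexicographic order."""
        return sorted(self.values)

    def is_complete(self) -> bool:
        """True iff the key set is exactly the 4096 six-mers."""
        return len(self.values) == N_CORES

    def require_complete(self) -> "EtrMap":
        if not self.is_complete():
            raise EtrDataError(
                f"landscape incomplete: {len(self.values)} of {N_CORES} cores"
            )
        return self

    def etr_array(self, cores: Sequence[str] | None = None) -> np.ndarray:
        """ETR values for ``cores`` (default: lexicographic order)."""
        cores = self.cores if cores is None else list(cores)
        return np.array([self.values[c] for c in cores], dtype=float)

    # -- canonical I/O ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        cores = self.cores
        return pd.DataFrame(
            {
                "core": cores,
                "etr": [self.values[c] for c in cores],
                "source": [self.sources[c] for c in cores],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write the canonical headered TSV (core, etr, source), UTF-8.

        Values are written in shortest exact decimal form so that a
        round-trip through the file reproduces them exactly.
        """
        df = self.to_frame()
        df["etr"] = df["etr"].map(repr)
        df.to_csv(path, sep="\t", index=False, encoding="utf-8")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EtrMap":
        df = pd.read_csv(
            path, sep="\t", dtype={"core": str}, float_precision="round_trip"
        )
        missing = {"core", "etr"} - set(df.columns)
        if missing:
            raise EtrDataError(f"ETR table missing column(s): {sorted(missing)}")
        sources = (
            dict(zip(df["core"], df["source"]))
            if "source" in df.columns
            else {}
        )
        return cls(dict(zip(df["core"], df["etr"])), sources)


def load_etr_map(
    measured_table: Mapping[str, float],
    predicted_table: Mapping[str, float],
    cores: Iterable[str] | None = None,
) -> EtrMap:
    """Merge measured and predicted core->ETR tables into one landscape.

    For every requested core the measured value is used when available and
    the predicted one otherwise; per-entry provenance is recorded so that
    the predicted fraction of the landscape stays auditable.

    Parameters
    ----------
    measured_table, predicted_table :
        ``core -> etr`` mappings.  Values outside ``[0, 1]`` are rejected.
    cores :
        The core set the landscape must cover.  Defaults to the union of
        the two tables' keys.

    Raises
    ------
    EtrDataError
        If a requested core is missing from both tables, or a key/value is
        malformed.
    """
    measured = {validate_core(k): float(v) for k, v in measured_table.items()}
    predicted = {validate_core(k): float(v) for k, v in predicted_table.items()}
    if cores is None:
        wanted = sorted(set(measured) | set(predicted))
    else:
        wanted = [validate_core(c) for c in cores]
    values: dict[str, float] = {}
    sources: dict[str, str] = {}
    for core in wanted:
        if core in measured:
            values[core] = measured[core]
            sources[core] = "measured"
        elif core in predicted:
            values[core] = predicted[core]
            sources[core] = "predicted"
        else:
            raise EtrDataError(
                f"incomplete landscape: core {core} absent from both the "
                f"measured and the predicted table"
            )
    return EtrMap(values, sources)


# -- upstream-script conversion -----------------------------------------

_PAIR_RE = re.compile(
    r"['\"]([ACGTacgt]{6})['\"]\s*:\s*([0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?)"
)


def parse_script_table(text: str) -> dict[str, float]:
    """Extract a ``6-mer -> value`` mapping embedded in Python source.

    The upstream EMOPEC distribution ships its measured and
    model-predicted landscapes as dictionary literals inside two scripts;
    this pulls out every ``'SEQUENCE': value`` pair by pattern matching,
    decoupling the toolkit from the upstream packaging.
    """
    pairs = _PAIR_RE.findall(text)
    if not pairs:
        raise EtrDataError("no sequence->value pairs found in script text")
    return {seq.upper(): float(val) for seq, val in pairs}


def convert_upstream_scripts(
    measured_script: str | Path,
    predicted_script: str | Path,
    out_tsv: str | Path | None = None,
) -> EtrMap:
    """Convert the two upstream script-embedded tables to a canonical map.

    Measured values win on key collisions; provenance is recorded per
    entry.  If ``out_tsv`` is given the canonical TSV is written as well.
    """
    measured = parse_script_table(Path(measured_script).read_text())
    predicted = parse_script_table(Path(predicted_script).read_text())
    etr_map = load_etr_map(measured, predicted)
    if out_tsv is not None:
        etr_map.to_tsv(out_tsv)
    return etr_map


# -- synthetic landscape -------------------------------------------------

def _default_effect_table() -> dict[tuple[str, int], float]:
    """Additive per-(nucleotide, position) effects emulating an SD landscape.

    Central guanines carry the dominant positive weight (the anti-SD helix
    prefers G-rich cores, strongest at the middle positions), thymine is
    mildly positive and cytosine mildly detrimental.  Positions are
    0-based.  With the default 0.12 baseline the noise-free range spans
    roughly 0.02 (C-rich) to 0.75 (GGGGGG).
    """
    g = [0.05, 0.10, 0.15, 0.15, 0.10, 0.05]
    t = [0.00, 0.01, 0.02, 0.02, 0.01, 0.00]
    c = [-0.01, -0.02, -0.03, -0.03, -0.02, -0.01]
    table: dict[tuple[str, int], float] = {}
    for pos in range(CORE_LENGTH):
        table[("G", pos)] = g[pos]
        table[("T", pos)] = t[pos]
        table[("C", pos)] = c[pos]
        table[("A", pos)] = 0.0
    return table


@dataclass
class SyntheticLandscapeConfig:
    """Configuration of the additive synthetic SD landscape.

    ``etr(s) = clamp01(baseline + sum_pos effect_table[s[pos], pos] + eps)``
    with ``eps ~ Normal(0, noise_sd)`` drawn once per core from the given
    seed.  Identical seeds yield identical maps.
    """

    baseline: float = 0.12
    effect_table: dict[tuple[str, int], float] = field(
        default_factory=_default_effect_table
    )
    noise_sd: float = 0.02
    seed: int = 42

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise EtrDataError(f"noise_sd must be >= 0, got {self.noise_sd}")


def generate_synthetic_landscape(
    config: SyntheticLandscapeConfig | None = None,
) -> EtrMap:
    """Generate a complete 4096-entry synthetic landscape.

    Deterministic given ``config.seed``; values clamped to ``[0, 1]``;
    every entry carries source ``synthetic``.
    """
    config = config or SyntheticLandscapeConfig()
    rng = np.random.default_rng(config.seed)
    cores = list(all_cores())
    base = np.full(len(cores), config.baseline)
    for i, core in enumerate(cores):
        base[i] += sum(
            config.effect_table.get((sym, pos), 0.0)
            for pos, sym in enumerate(core)
        )
    if config.noise_sd > 0:
        base = base + rng.normal(0.0, config.noise_sd, size=len(cores))
    values = np.clip(base, 0.0, 1.0)
    return EtrMap(
        dict(zip(cores, values)), {c: "synthetic" for c in cores}
    )


# -- external RBS-activity measurements ----------------------------------

@dataclass(frozen=True)
class ExternalMeasurement:
    """One externally measured RBS variant.

    ``readout`` houses an activity proxy such as the normalized integral
    of a recombinase flipping profile over 0-480 min post-induction
    (IFP_0-480min); ``read_count`` is the sequencing support for the row.
    """

    rbs_sequence: str
    readout: float
    read_count: int

    def __post_init__(self) -> None:
        if len(self.rbs_sequence) < CORE_LENGTH:
            raise EtrDataError(
                f"rbs_sequence shorter than {CORE_LENGTH} nt: "
                f"{self.rbs_sequence!r}"
            )
        if self.read_count < 0:
            raise EtrDataError(f"negative read_count: {self.read_count}")
        if self.readout < 0:
            raise EtrDataError(f"negative readout: {self.readout}")


DEFAULT_MIN_READ_COUNT = 500


def load_external_measurements(
    table: pd.DataFrame | str | Path,
    min_read_count: int = DEFAULT_MIN_READ_COUNT,
    sequence_col: str = "sequence",
    readout_col: str = "IFP480",
    read_count_col: str = "Read_Count",
) -> list[ExternalMeasurement]:
    """Load an external RBS-activity table, dropping low-support rows.

    Rows with ``read_count < min_read_count`` are removed (default
    threshold 500); the input row order is preserved.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    missing = {sequence_col, readout_col, read_count_col} - set(table.columns)
    if missing:
        raise EtrDataError(
            f"measurement table missing column(s): {sorted(missing)}"
        )
    out: list[ExternalMeasurement] = []
    for _, row in table.iterrows():
        count = int(row[read_count_col])
        if count < min_read_count:
            continue
        out.append(
            ExternalMeasurement(
                rbs_sequence=str(row[sequence_col]).upper(),
                readout=float(row[readout_col]),
                read_count=count,
            )
        )
    return out


def generate_synthetic_measurements(
    etr_map: EtrMap,
    n: int = 2000,
    seed: int = 42,
    slope: float = 1.0,
    intercept: float = 0.05,
    noise_sd: float = 0.05,
    utr_length: int = 20,
    spacer_range: tuple[int, int] = (5, 8),
    median_read_count: float = 1000.0,
) -> tuple[list[ExternalMeasurement], int]:
    """Simulate an external RBS-activity data set from a landscape.

    Each record embeds a random core at a random spacer (bases strictly
    between core and start codon) within a fixed-length 5'-UTR; the
    readout is ``max(0, slope * etr + intercept + noise)`` and read counts
    are log-normal (sigma 1) around the given median — heavy-tailed like
    real sequencing support, so a realistic fraction of rows falls below
    typical read-count filters.

    Returns
    -------
    (measurements, start_index) :
        ``start_index`` is the 0-based position of the start codon's
        first base, i.e. ``utr_length`` (shared by all records, emulating
        a fixed construct architecture).
    """
    rng = np.random.default_rng(seed)
    lo, hi = spacer_range
    cores = etr_map.cores
    out: list[ExternalMeasurement] = []
    for _ in range(n):
        core = cores[rng.integers(len(cores))]
        spacer = int(rng.integers(lo, hi + 1))
        prefix_len = utr_length - spacer - CORE_LENGTH
        if prefix_len < 0:
            raise EtrDataError(
                f"utr_length {utr_length} too short for spacer {spacer}"
            )
        prefix = "".join(
            ALPHABET[j] for j in rng.integers(0, 4, size=prefix_len)
        )
        spacer_seq = "".join(
            ALPHABET[j] for j in rng.integers(0, 4, size=spacer)
        )
        readout = max(
            0.0,
            slope * etr_map[core] + intercept + rng.normal(0.0, noise_sd),
        )
        count = int(rng.lognormal(np.log(median_read_count), 1.0))
        out.append(
            ExternalMeasurement(prefix + core + spacer_seq, readout, count)
        )
    return out, utr_length


def measurements_to_frame(
    measurements: Iterable[ExternalMeasurement],
    sequence_col: str = "sequence",
    readout_col: str = "IFP480",
    read_count_col: str = "Read_Count",
) -> pd.DataFrame:
    """Tabulate measurements in the external TSV column layout."""
    return pd.DataFrame(
        {
            sequence_col: [m.rbs_sequence for m in measurements],
            readout_col: [m.readout for m in measurements],
            read_count_col: [m.read_count for m in measurements],
        }
    )
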