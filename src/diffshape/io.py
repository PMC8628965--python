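"""Reactivity data model, tabular I/O, replicate filtering and class binning.

SHAPE (selective 2'-hydroxyl acylation analyzed by primer extension)
reactivities report per-nucleotide ribose flexibility: flexible,
single-stranded positions acylate readily (high reactivity) while paired or
constrained positions do not. This module holds the in-memory containers for
per-replicate reactivity tables, the replicate-agreement outlier filter, the
triplicate aggregation, and the three-bin reactivity classification used for
colouring secondary-structure diagrams (low < 0.4 <= moderate <= 0.7 < high).

Files are plain TSV with a ``position``/``base`` header followed by one
column per replicate; ``NA`` marks undetermined entries. The two-column
``index reactivity`` dialect with a ``-999`` missing sentinel (as consumed by
RNAstructure and RNAfold) is supported for export.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "PROBES",
    "SHAPE_SENTINEL",
    "Condition",
    "ReplicateSet",
    "ReactivityProfile",
    "ReactivityClass",
    "ParseError",
    "read_reactivity_table",
    "write_reactivity_table",
    "filter_outliers",
    "aggregate",
    "classify_reactivity",
    "read_shape",
    "write_shape",
]

PROBES = ("1M7", "NMIA", "BzCN")

#: Missing-value sentinel of the RNAstructure .shape dialect.
SHAPE_SENTINEL = -999.0

_VALID_BASES = frozenset("ACGU")


class ParseError(ValueError):
    """Raised when a reactivity table violates the expected format."""


@dataclass(frozen=True)
class Condition:
    """One probing condition: reagent, MgCl2 concentration and temperature.

    Parameters
    ----------
    probe:
        SHAPE acylating reagent, one of ``1M7``, ``NMIA``, ``BzCN``.
    mg_mM:
        MgCl2 concentration in mM (>= 0). 5 mM is the native-like condition;
        0 mM destabilizes the tertiary structure.
    temperature_C:
        Probing temperature in degrees Celsius, within [0, 100].
    label:
        Free-text tag carried through to outputs.
    """

    probe: str = "1M7"
    mg_mM: float = 5.0
    temperature_C: float = 37.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.probe not in PROBES:
            raise ValueError(f"unknown probe {self.probe!r}; expected one of {PROBES}")
        if not 0.0 <= self.temperature_C <= 100.0:
            raise ValueError(f"temperature_C={self.temperature_C} outside [0, 100]")
        if self.mg_mM < 0.0:
            raise ValueError(f"mg_mM={self.mg_mM} must be non-negative")


@dataclass
class ReplicateSet:
    """Per-position replicate reactivities under one condition.

    ``values[i]`` holds the usable replicate measurements for ``positions[i]``
    (possibly fewer than the number of table columns after outlier removal);
    an empty array means the position is undetermined.
    """

    condition: Condition
    positions: np.ndarray  # 1-based, strictly increasing
    bases: np.ndarray  # unicode 'A'/'C'/'G'/'U'
    values: list[np.ndarray]
    n_discarded: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.bases = np.asarray(self.bases, dtype="U1")
        if len(self.positions) != len(self.bases) or len(self.positions) != len(self.values):
            raise ValueError("positions, bases and values must have equal length")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing and unique")
        self.values = [np.asarray(v, dtype=float) for v in self.values]

    @property
    def undetermined(self) -> np.ndarray:
        return np.array([len(v) == 0 for v in self.values], dtype=bool)

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class ReactivityProfile:
    """Aggregated (mean) reactivity profile for one condition."""

    condition: Condition
    positions: np.ndarray
    bases: np.ndarray
    mean: np.ndarray  # NaN where undetermined
    sd: np.ndarray  # sample sd; NaN where n_used < 2
    n_used: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.bases = np.asarray(self.bases, dtype="U1")
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n_used = np.asarray(self.n_used, dtype=int)

    @property
    def undetermined(self) -> np.ndarray:
        return self.n_used == 0

    def __len__(self) -> int:
        return len(self.positions)


class ReactivityClass(enum.Enum):
    """Three-bin reactivity classification used for structure diagrams."""

    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"
    UNDETERMINED = "undetermined"


def read_reactivity_table(path: str | Path, condition: Condition | None = None) -> ReplicateSet:
    """Read a per-replicate reactivity TSV into a :class:`ReplicateSet`.

    The file must carry a header line ``position<TAB>base<TAB>rep1...`` with
    at least one replicate column; ``NA`` marks an undetermined measurement.
    Rows whose replicate entries are all ``NA`` are flagged undetermined.

    Raises
    ------
    ParseError
        Naming the offending 1-based line number on malformed rows,
        duplicate or non-increasing positions, or non-ACGU bases.
    """
    path = Path(path)
    with path.open() as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    if len(header) < 3 or header[0] != "position" or header[1] != "base":
        raise ParseError(f"{path}:1: expected header 'position\\tbase\\trep...', got {header!r}")
    n_rep = len(header) - 2

    positions: list[int] = []
    bases: list[str] = []
    values: list[np.ndarray] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        fields = raw.split("\t")
        if len(fields) != 2 + n_rep:
            raise ParseError(f"{path}:{lineno}: expected {2 + n_rep} columns, got {len(fields)}")
        try:
            pos = int(fields[0])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-integer position {fields[0]!r}") from None
        base = fields[1].strip()
        if base not in _VALID_BASES:
            raise ParseError(f"{path}:{lineno}: invalid base {base!r} (expected A/C/G/U)")
        row: list[float] = []
        for entry in fields[2:]:
            entry = entry.strip()
            if entry in ("NA", ""):
                continue
            try:
                row.append(float(entry))
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric reactivity {entry!r}") from None
        if positions and pos <= positions[-1]:
            kind = "duplicate" if pos == positions[-1] else "non-increasing"
            raise ParseError(f"{path}:{lineno}: {kind} position {pos}")
        positions.append(pos)
        bases.append(base)
        values.append(np.array(row, dtype=float))

    return ReplicateSet(
        condition=condition or Condition(),
        positions=np.array(positions, dtype=int),
        bases=np.array(bases, dtype="U1"),
        values=values,
    )


def write_reactivity_table(reps: ReplicateSet, path: str | Path) -> None:
    """Write a :class:`ReplicateSet` as TSV, padding ragged rows with NA.

    Floats are written with Python's shortest round-trip repr so a
    write/read cycle reproduces values bit-exactly.
    """
    n_rep = max((len(v) for v in reps.values), default=0)
    n_rep = max(n_rep, 1)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("position\tbase\t" + "\t".join(f"rep{i + 1}" for i in range(n_rep)) + "\n")
        for pos, base, vals in zip(reps.positions, reps.bases, reps.values):
            cells = [repr(float(v)) for v in vals] + ["NA"] * (n_rep - len(vals))
            fh.write(f"{pos}\t{base}\t" + "\t".join(cells) + "\n")


def filter_outliers(reps: ReplicateSet, window: float = 0.4) -> ReplicateSet:
    """Discard replicate values far from every other measurement.

    Within each position's replicate group a value is discarded iff its
    absolute distance to *every* other value exceeds ``window`` (default 0.4
    reactivity units) — i.e. it agrees with none of the other measurements.
    Positions where all values are mutually more than ``window`` apart have
    no consistent majority and become undetermined. Groups of fewer than
    three values pass through unchanged (no outlier is identifiable).

    The filter is idempotent: every retained value has a retained neighbour
    within ``window``, so a second pass discards nothing.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    new_values: list[np.ndarray] = []
    n_discarded = reps.n_discarded
    for vals in reps.values:
        if len(vals) < 3:
            new_values.append(vals.copy())
            continue
        dist = np.abs(vals[:, None] - vals[None, :])
        np.fill_diagonal(dist, np.inf)
        keep = (dist <= window).any(axis=1)
        if not keep.any():
            n_discarded += len(vals)
            new_values.append(np.empty(0, dtype=float))
        else:
            n_discarded += int((~keep).sum())
            new_values.append(vals[keep])
    return ReplicateSet(
        condition=reps.condition,
        positions=reps.positions.copy(),
        bases=reps.bases.copy(),
        values=new_values,
        n_discarded=n_discarded,
    )


def aggregate(reps: ReplicateSet) -> ReactivityProfile:
    """Aggregate replicates into per-position mean, sample sd and count."""
    n = len(reps)
    mean = np.full(n, np.nan)
    sd = np.full(n, np.nan)
    n_used = np.zeros(n, dtype=int)
    for i, vals in enumerate(reps.values):
        n_used[i] = len(vals)
        if len(vals) >= 1:
            mean[i] = float(np.mean(vals))
        if len(vals) >= 2:
            sd[i] = float(np.std(vals, ddof=1))
    return ReactivityProfile(
        condition=reps.condition,
        positions=reps.positions.copy(),
        bases=reps.bases.copy(),
        mean=mean,
        sd=sd,
        n_used=n_used,
    )


def classify_reactivity(profile: ReactivityProfile) -> list[ReactivityClass]:
    """Bin mean reactivities into low / moderate / high classes.

    Bins are ``(-inf, 0.4)`` low (negative normalized values clamp to low),
    ``[0.4, 0.7]`` moderate, and ``(0.7, inf)`` high; undetermined positions
    pass through as :attr:`ReactivityClass.UNDETERMINED`.
    """
    classes: list[ReactivityClass] = []
    for r, und in zip(profile.mean, profile.undetermined):
        if und or math.isnan(r):
            classes.append(ReactivityClass.UNDETERMINED)
        elif r < 0.4:
            classes.append(ReactivityClass.LOW)
        elif r <= 0.7:
            classes.append(ReactivityClass.MODERATE)
        else:
            classes.append(ReactivityClass.HIGH)
    return classes


def write_shape(positions: Sequence[int], values: Sequence[float], path: str | Path) -> None:
    """Write a two-column ``index reactivity`` SHAPE file.

    NaN values are written as the ``-999`` missing sentinel; determined
    values are printed with 6 significant digits.
    """
    path = Path(path)
    with path.open("w") as fh:
        for pos, val in zip(positions, values):
            if val is None or (isinstance(val, float) and math.isnan(val)):
                fh.write(f"{int(pos)} {SHAPE_SENTINEL:.0f}\n")
            else:
                fh.write(f"{int(pos)} {float(val):.6g}\n")


def read_shape(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a two-column SHAPE file; ``-999`` entries come back as NaN."""
    positions: list[int] = []
    values: list[float] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.split()
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected two columns")
        positions.append(int(fields[0]))
        val = float(fields[1])
        values.append(np.nan if val == SHAPE_SENTINEL else val)
    return np.array(positions, dtype=int), np.array(values, dtype=float)
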