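"""Constraint/reactivity files for downstream structure prediction.

Thermodynamic folding engines (RNAstructure, RNAfold, IPANEMAP,
ShapeKnots) accept per-nucleotide SHAPE pseudo-energies but cannot, for
the most part, predict pseudoknots. Differential probing between two
conditions — 37 vs 53 degC, or with vs without Mg2+ — highlights exactly
the nucleotides whose pairing partners are tertiary (pseudoknots, kissing
loops), and three constraint strategies exploit that:

``passthrough``
    a profile exported as-is (e.g. the 53 degC reactivities used directly);
``boost10``
    significantly temperature-sensitive positions are assigned reactivity
    10 (forcing them single-stranded for the predictor) while all other
    positions keep their 37 degC value;
``pk_mask``
    significantly varying positions get -0.2 (freely pairable) and every
    other determined position gets 5 (strongly penalized), so the only
    pairings a predictor can form are among the differential positions —
    on temperature-differential data those pairings reconstruct the
    pseudoknot.

A complementarity screen over the masked candidate set is included so the
pseudoknot helix the mask permits can be verified without running any
external predictor; consistent with predictors' behaviour, helices shorter
than ``min_len`` (default 3 bp) are not reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .differential import DifferentialRecord
from .io import ReactivityProfile, read_shape, write_shape

__all__ = [
    "ConstraintSet",
    "HelixCandidate",
    "make_passthrough",
    "make_boost10",
    "make_pk_mask",
    "find_complementary_helices",
    "export_shape",
]

_PAIRS_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_PAIRS_GU = {("G", "U"), ("U", "G")}


@dataclass
class ConstraintSet:
    """Per-position constraint values for one export strategy.

    ``values`` holds reactivity units or the strategy's sentinels; NaN
    marks undetermined positions and is written as -999.
    """

    strategy: str  # passthrough | boost10 | pk_mask
    positions: np.ndarray
    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.positions.shape != self.values.shape:
            raise ValueError("positions and values must align")


@dataclass
class HelixCandidate:
    """A maximal antiparallel complementary stretch (i..i+L-1 : j-L+1..j)."""

    i_start: int
    j_start: int
    length: int
    pairs: list[tuple[int, int]] = field(default_factory=list)


def make_passthrough(profile: ReactivityProfile, provenance: str = "") -> ConstraintSet:
    """Export a profile unchanged (undetermined -> sentinel)."""
    return ConstraintSet(
        strategy="passthrough",
        positions=profile.positions.copy(),
        values=profile.mean.copy(),
        provenance=provenance or f"passthrough {profile.condition.label}",
    )


def make_boost10(
    profile37: ReactivityProfile,
    diff: Sequence[DifferentialRecord],
    boost: float = 10.0,
) -> ConstraintSet:
    """Boost significantly changed positions to a reactivity of 10.

    Significant positions in ``diff`` take the value ``boost``; every other
    determined position keeps its 37 degC reactivity; undetermined
    positions carry the missing sentinel. Differential positions must be a
    subset of the profile's positions.
    """
    pos_set = set(map(int, profile37.positions))
    sig = {r.position for r in diff if r.significant}
    stray = sig - pos_set
    if stray:
        raise ValueError(f"differential positions {sorted(stray)} absent from the 37 degC profile")
    values = profile37.mean.copy()
    for k, pos in enumerate(profile37.positions):
        if int(pos) in sig:
            values[k] = boost
    return ConstraintSet(
        strategy="boost10",
        positions=profile37.positions.copy(),
        values=values,
        provenance=f"boost10({boost:g}) on {len(sig)} significant positions",
    )


def make_pk_mask(
    diff: Sequence[DifferentialRecord],
    low: float = -0.2,
    high: float = 5.0,
    all_positions: Iterable[int] | None = None,
) -> ConstraintSet:
    """Mask everything except the differential positions.

    Significant positions get ``low`` (-0.2: pairing unpenalized), other
    compared positions get ``high`` (5: pairing strongly penalized). When
    ``all_positions`` supplies the full sequence universe, positions absent
    from the differential (undetermined in either condition) get the
    missing sentinel (NaN here, -999 in the file).
    """
    if not diff:
        raise ValueError("empty differential input")
    value_by_pos = {r.position: (low if r.significant else high) for r in diff}
    if all_positions is None:
        positions = np.array(sorted(value_by_pos), dtype=int)
    else:
        positions = np.array(sorted(set(map(int, all_positions)) | set(value_by_pos)), dtype=int)
    values = np.array([value_by_pos.get(int(p), np.nan) for p in positions])
    n_sig = sum(1 for r in diff if r.significant)
    return ConstraintSet(
        strategy="pk_mask",
        positions=positions,
        values=values,
        provenance=f"pk_mask low={low:g} high={high:g}; {n_sig} significant of {len(diff)} compared",
    )


def _can_pair(x: str, y: str, allow_gu: bool) -> bool:
    return (x, y) in _PAIRS_WC or (allow_gu and (x, y) in _PAIRS_GU)


def find_complementary_helices(
    sequence: str,
    candidates: Iterable[int],
    min_len: int = 3,
    allow_gu: bool = True,
) -> list[HelixCandidate]:
    """Maximal antiparallel helices formable among candidate positions.

    Scans all (i, j) pairs of the 1-based ``candidates`` set and extends
    stacks (i, j), (i+1, j-1), ... as long as both positions stay in the
    candidate set and the bases are complementary (Watson-Crick, plus G-U
    wobble unless ``allow_gu`` is false). Only maximal stacks of at least
    ``min_len`` pairs with non-overlapping strands are reported, sorted by
    length (desc) then 5' start.
    """
    seq = sequence.upper().replace("T", "U")
    n = len(seq)
    cand = {int(p) for p in candidates}
    if any(p < 1 or p > n for p in cand):
        raise ValueError("candidate positions outside the sequence")

    def valid(i: int, j: int) -> bool:
        return 1 <= i < j <= n and i in cand and j in cand and _can_pair(seq[i - 1], seq[j - 1], allow_gu)

    helices = []
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            if not valid(i, j) or valid(i - 1, j + 1):
                continue  # not a valid pair, or not the outermost pair of its stack
            length = 0
            while valid(i + length, j - length) and (i + length) < (j - length):
                length += 1
            if length >= min_len:
                pairs = [(i + t, j - t) for t in range(length)]
                helices.append(HelixCandidate(i_start=i, j_start=j, length=length, pairs=pairs))
    helices.sort(key=lambda h: (-h.length, h.i_start))
    return helices


def export_shape(cs: ConstraintSet, path: str | Path) -> None:
    """Write a ConstraintSet in the two-column SHAPE dialect (-999 = missing)."""
    write_shape(cs.positions, cs.values, path)


def import_shape(path: str | Path, strategy: str = "passthrough") -> ConstraintSet:
    """Read a SHAPE file back into a ConstraintSet (sentinel -> NaN)."""
    positions, values = read_shape(path)
    return ConstraintSet(strategy=strategy, positions=positions, values=values, provenance=str(path))
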