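"""Two-condition differential reactivity calling.

Given replicate reactivity measurements of the same RNA under two
conditions (e.g. with and without Mg2+, or at 37 vs 53 degC), each shared
position is scored by

* the absolute difference of mean reactivities, dR = |R1 - R2|,
* the relative change dR / (R1 + R2),
* a two-sided Welch t-test on the per-replicate values.

A position is called significant when all three criteria hold strictly:
dR > 0.2, relative change > 0.2 and p < 0.05. The pairing of an absolute
and a relative criterion suppresses both small shifts between weakly
reactive nucleotides and large-but-uninformative shifts between highly
reactive ones. Positions undetermined in either condition are excluded.

Welch's unequal-variance form is used because triplicate SHAPE
measurements give no grounds for assuming equal variances at n = 3; a
Benjamini-Hochberg adjusted significance column is available but off by
default, matching the per-position character of the published rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import ReplicateSet, aggregate

__all__ = ["DifferentialRecord", "compare_profiles", "records_to_frame", "mg_differential_report"]

#: Structural classes recognized by :func:`mg_differential_report`.
STRUCTURE_CLASSES = ("SS", "HELIX", "STABLE_HELIX", "TERT", "PK5", "PK3", "KL")


@dataclass
class DifferentialRecord:
    """Differential call for one nucleotide between two conditions.

    ``direction`` reports the sign of the change (``up_in_2`` when the mean
    reactivity rises in the second condition) independently of significance;
    ``flag`` marks degenerate cases (too few replicates for a t-test,
    non-positive reactivity sum, or zero variance on both sides).
    """

    position: int
    base: str
    r1: float
    r2: float
    delta_r: float
    rel_change: float
    p_value: float
    significant: bool
    direction: str  # up_in_2 | down_in_2 | none
    flag: str | None = None


def _welch_p(va: np.ndarray, vb: np.ndarray) -> tuple[float, str | None]:
    """Two-sided Welch t-test p-value with degenerate-case handling."""
    if len(va) < 2 or len(vb) < 2:
        return np.nan, "insufficient_replicates"
    if np.ptp(va) == 0.0 and np.ptp(vb) == 0.0:
        # All replicates tied on both sides: the test statistic is undefined.
        return (1.0, "degenerate_variance") if va[0] == vb[0] else (0.0, "degenerate_variance")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
    return p, None


def compare_profiles(
    a: ReplicateSet,
    b: ReplicateSet,
    dr_thresh: float = 0.2,
    rel_thresh: float = 0.2,
    alpha: float = 0.05,
    adjust: str | None = None,
) -> list[DifferentialRecord]:
    """Call differentially reactive positions between two replicate sets.

    Parameters
    ----------
    a, b:
        Replicate sets for the two conditions (outlier filtering, if
        wanted, is applied beforehand). Only positions determined in both
        are compared.
    dr_thresh, rel_thresh, alpha:
        Strict thresholds on |R1-R2|, |R1-R2|/(R1+R2) and the Welch p-value.
    adjust:
        ``"bh"`` applies a Benjamini-Hochberg correction to the p-values
        before the alpha comparison; ``None`` (default) leaves them raw.

    Returns
    -------
    One :class:`DifferentialRecord` per shared determined position, in
    position order. Empty (with a warning) if no position is shared.
    """
    prof_a = aggregate(a)
    prof_b = aggregate(b)
    idx_a = {int(p): i for i, p in enumerate(prof_a.positions)}
    und_a = prof_a.undetermined
    und_b = prof_b.undetermined

    records: list[DifferentialRecord] = []
    raw_p: list[float] = []
    for j, pos in enumerate(prof_b.positions):
        i = idx_a.get(int(pos))
        if i is None or und_a[i] or und_b[j]:
            continue
        r1 = float(prof_a.mean[i])
        r2 = float(prof_b.mean[j])
        delta = abs(r1 - r2)
        p, flag = _welch_p(a.values[i], b.values[j])
        total = r1 + r2
        if total > 0:
            rel = delta / total
        else:
            rel = np.nan
            flag = flag or "nonpositive_sum"
        if r2 > r1:
            direction = "up_in_2"
        elif r2 < r1:
            direction = "down_in_2"
        else:
            direction = "none"
        records.append(
            DifferentialRecord(
                position=int(pos),
                base=str(prof_b.bases[j]),
                r1=r1,
                r2=r2,
                delta_r=delta,
                rel_change=rel,
                p_value=p,
                significant=False,
                direction=direction,
                flag=flag,
            )
        )
        raw_p.append(p)

    if not records:
        warnings.warn("no shared determined positions between the two conditions")
        return records

    p_eff = np.array(raw_p, dtype=float)
    if adjust == "bh":
        p_eff = _benjamini_hochberg(p_eff)
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")

    for rec, p in zip(records, p_eff):
        rec.significant = bool(
            rec.delta_r > dr_thresh
            and np.isfinite(rec.rel_change)
            and rec.rel_change > rel_thresh
            and np.isfinite(p)
            and p < alpha
        )
    return records


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up), NaN-preserving."""
    q = np.full_like(p, np.nan)
    finite = np.isfinite(p)
    pf = p[finite]
    m = len(pf)
    if m == 0:
        return q
    order = np.argsort(pf)
    ranked = pf[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[finite] = out
    return q


def records_to_frame(records: list[DifferentialRecord]) -> pd.DataFrame:
    """Tabulate differential records (one row per position)."""
    return pd.DataFrame(
        {
            "position": [r.position for r in records],
            "base": [r.base for r in records],
            "R1": [r.r1 for r in records],
            "R2": [r.r2 for r in records],
            "deltaR": [r.delta_r for r in records],
            "rel_change": [r.rel_change for r in records],
            "p": [r.p_value for r in records],
            "significant": [r.significant for r in records],
            "direction": [r.direction for r in records],
            "flag": [r.flag or "" for r in records],
        }
    )


def write_differential(records: list[DifferentialRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def mg_differential_report(
    records: list[DifferentialRecord],
    annotation: dict[int, str] | "np.ndarray | list[str]",
) -> pd.DataFrame:
    """Summarize significant calls per structural class and direction.

    ``annotation`` maps 1-based positions to a structural class (``SS``,
    ``HELIX``, ``STABLE_HELIX``, ``TERT``, ``PK5``, ``PK3``, ``KL``); an
    array-like is interpreted positionally (index 0 -> position 1).
    Positions without annotation are tallied under ``unannotated``. The
    ``fraction_significant`` column divides significant calls by compared
    positions within each class.
    """
    if not isinstance(annotation, dict):
        annotation = {i + 1: str(c) for i, c in enumerate(annotation)}
    rows = {
        cls: {"n_compared": 0, "n_significant": 0, "n_up_in_2": 0, "n_down_in_2": 0}
        for cls in STRUCTURE_CLASSES + ("unannotated",)
    }
    for rec in records:
        cls = annotation.get(rec.position, "unannotated")
        if cls not in rows:
            cls = "unannotated"
        rows[cls]["n_compared"] += 1
        if rec.significant:
            rows[cls]["n_significant"] += 1
            if rec.direction == "up_in_2":
                rows[cls]["n_up_in_2"] += 1
            elif rec.direction == "down_in_2":
                rows[cls]["n_down_in_2"] += 1
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "class"
    with np.errstate(invalid="ignore", divide="ignore"):
        frame["fraction_significant"] = np.where(
            frame["n_compared"] > 0, frame["n_significant"] / frame["n_compared"], np.nan
        )
    return frame
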