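"""Sugar-pucker pseudorotation analysis of five-membered ribose rings.

The conformation of a furanose ring is summarized by two pseudorotation
parameters computed from the five ring dihedrals v1 (C1'-C2'-C3'-C4')
through v5 (O4'-C1'-C2'-C3'):

    a   = 0.4 * sum_i v_i * cos(0.8*pi*(i-1))
    b   = -0.4 * sum_i v_i * sin(0.8*pi*(i-1))
    Amp = sqrt(a^2 + b^2)
    Pha = a / Amp            (the cosine of the phase angle)

The amplitude measures how puckered the ring is; the phase says which atom
is most displaced from the mean plane. These relations are exact for the
cosine model v_i = Amp * cos(P + 0.8*pi*(i-1)), under which a = Amp*cos(P)
and b = Amp*sin(P), so the full phase angle P = atan2(b, a) is recovered
alongside the published cosine. Classification uses the full angle: the
cosine alone cannot separate all ten conventional pucker families, which
partition the pseudorotation wheel into 36-degree sectors (C3'-endo
centered at 18 degrees, C2'-endo at 162 degrees, and so on).

Families group into A-like (C3'-endo, C4'-exo, C1'-endo, C2'-exo — the
A-form helix side of the wheel), B-like (C2'-endo, C3'-exo, C1'-exo,
C4'-endo) and "other" for the two O4' families. Persistent C3'-endo means
a rigid A-form ribose (SHAPE-unreactive); C2'-endo excursions and
intermediate phases accompany backbone flexibility and elevated SHAPE
reactivity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FAMILIES",
    "FAMILY_GROUP",
    "PuckerState",
    "ScalarQuantitySummary",
    "pseudorotation",
    "pseudorotation_many",
    "classify_pucker",
    "family_of_phase",
    "dihedrals_from_pucker",
    "trajectory_stats",
    "summarize_quantity",
    "read_dihedral_csv",
]

#: Phase angles 0.8*pi*(i-1) for i = 1..5.
_THETA = 0.8 * np.pi * np.arange(5)

#: Ten pucker families in pseudorotation-wheel order; family j spans
#: phases [36*j, 36*(j+1)) degrees.
FAMILIES = (
    "C3'-endo",
    "C4'-exo",
    "O4'-endo",
    "C1'-exo",
    "C2'-endo",
    "C3'-exo",
    "C4'-endo",
    "O4'-exo",
    "C1'-endo",
    "C2'-exo",
)

FAMILY_GROUP: Mapping[str, str] = {
    "C3'-endo": "A_like",
    "C4'-exo": "A_like",
    "C1'-endo": "A_like",
    "C2'-exo": "A_like",
    "C1'-exo": "B_like",
    "C2'-endo": "B_like",
    "C3'-exo": "B_like",
    "C4'-endo": "B_like",
    "O4'-endo": "other",
    "O4'-exo": "other",
}

GROUPS = ("A_like", "B_like", "other")


@dataclass
class PuckerState:
    """Pseudorotation coordinates (and classification) of one ring."""

    a: float
    b: float
    amp: float
    phase_deg: float  # in [0, 360); meaningless when planar
    pha_cos: float  # a / amp, the published cosine form
    planar: bool
    family: str | None = None
    group: str | None = None


@dataclass
class ScalarQuantitySummary:
    """Mean +/- sample standard deviation of a per-frame scalar."""

    name: str
    mean: float
    sd: float
    n: int


def pseudorotation(v: Sequence[float], planar_tol: float = 1e-6) -> PuckerState:
    """Pseudorotation amplitude and phase from five ring dihedrals (degrees).

    Rings with amplitude below ``planar_tol`` are flagged planar; their
    phase and family are undefined.
    """
    v = np.asarray(v, dtype=float)
    if v.shape != (5,):
        raise ValueError("expected exactly five ring dihedrals v1..v5")
    if not np.all(np.isfinite(v)):
        raise ValueError("ring dihedrals must be finite")
    a = 0.4 * float(np.sum(v * np.cos(_THETA)))
    b = -0.4 * float(np.sum(v * np.sin(_THETA)))
    amp = float(np.hypot(a, b))
    if amp < planar_tol:
        return PuckerState(a=a, b=b, amp=amp, phase_deg=np.nan, pha_cos=np.nan, planar=True)
    phase = float(np.degrees(np.arctan2(b, a)) % 360.0)
    return PuckerState(a=a, b=b, amp=amp, phase_deg=phase, pha_cos=a / amp, planar=False)


def pseudorotation_many(V: np.ndarray, planar_tol: float = 1e-6):
    """Vectorized pseudorotation over an (n, 5) dihedral array.

    Returns ``(amp, phase_deg, planar)`` arrays; phase is NaN where planar.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2 or V.shape[1] != 5:
        raise ValueError("expected an (n, 5) dihedral array")
    a = 0.4 * (V * np.cos(_THETA)).sum(axis=1)
    b = -0.4 * (V * np.sin(_THETA)).sum(axis=1)
    amp = np.hypot(a, b)
    planar = amp < planar_tol
    with np.errstate(invalid="ignore"):
        phase = np.degrees(np.arctan2(b, a)) % 360.0
    phase = np.where(planar, np.nan, phase)
    return amp, phase, planar


def family_of_phase(phase_deg: float) -> str:
    """Pucker family for a phase angle, by 36-degree wheel sectors."""
    return FAMILIES[int(np.floor((phase_deg % 360.0) / 36.0)) % 10]


def classify_pucker(state: PuckerState) -> PuckerState:
    """Attach family and A/B-like group to a non-planar pucker state."""
    if state.planar:
        raise ValueError("planar ring has no defined pucker family")
    state.family = family_of_phase(state.phase_deg)
    state.group = FAMILY_GROUP[state.family]
    return state


def dihedrals_from_pucker(amp: float, phase_deg: float) -> np.ndarray:
    """Ring dihedrals of an ideal pucker: v_i = Amp * cos(P + 0.8*pi*(i-1)).

    Exact inverse of :func:`pseudorotation` for any amplitude and phase.
    """
    return amp * np.cos(np.radians(phase_deg) + _THETA)


def trajectory_stats(
    frames: Mapping[str, np.ndarray], planar_tol: float = 1e-6
) -> pd.DataFrame:
    """Per-nucleotide pucker-family occupancy over a trajectory.

    ``frames`` maps a nucleotide identifier to its (n_frames, 5) dihedral
    array. Returns a DataFrame indexed by nucleotide with percentage
    occupancy of each of the ten families, an ``undefined`` column for
    planar frames, and the A_like/B_like/other group totals. Percentages
    sum to 100 per nucleotide (groups + undefined likewise).
    """
    if not frames:
        raise ValueError("empty trajectory")
    rows = {}
    for nt, V in frames.items():
        V = np.asarray(V, dtype=float)
        if V.size == 0:
            raise ValueError(f"nucleotide {nt!r} has no frames")
        amp, phase, planar = pseudorotation_many(V, planar_tol=planar_tol)
        n = len(amp)
        row = {}
        fam_idx = np.floor(phase[~planar] / 36.0).astype(int) % 10
        counts = np.bincount(fam_idx, minlength=10)
        for j, fam in enumerate(FAMILIES):
            row[fam] = 100.0 * counts[j] / n
        row["undefined"] = 100.0 * float(planar.sum()) / n
        for g in GROUPS:
            row[g] = sum(row[f] for f in FAMILIES if FAMILY_GROUP[f] == g)
        rows[nt] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "nucleotide"
    return frame


def summarize_quantity(name: str, series: Sequence[float]) -> ScalarQuantitySummary:
    """Mean and sample standard deviation of a per-frame scalar quantity."""
    arr = np.asarray(series, dtype=float)
    if arr.size == 0:
        raise ValueError("empty series")
    sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else np.nan
    return ScalarQuantitySummary(name=name, mean=float(np.mean(arr)), sd=sd, n=int(arr.size))


def read_dihedral_csv(path) -> dict[str, np.ndarray]:
    """Read per-frame ring dihedrals from CSV.

    Expected columns: frame, nucleotide, v1..v5 (degrees). Returns the
    mapping consumed by :func:`trajectory_stats`, frames sorted by index.
    """
    frame = pd.read_csv(path)
    required = {"frame", "nucleotide", "v1", "v2", "v3", "v4", "v5"}
    if not required.issubset(frame.columns):
        raise ValueError(f"dihedral CSV needs columns {sorted(required)}")
    out = {}
    for nt, sub in frame.groupby("nucleotide", sort=True):
        sub = sub.sort_values("frame")
        out[str(nt)] = sub[["v1", "v2", "v3", "v4", "v5"]].to_numpy(dtype=float)
    return out
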