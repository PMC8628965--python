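"""Synthetic probing data emulating a ribozyme's multi-condition SHAPE study.

Every analysis stage in this package is testable against planted truth:
this module generates (i) a structure annotation for an RNA carrying the
recurring tertiary motifs of interest — a pseudoknot (5' and 3' strands),
a kissing-loop pair, non-canonical tertiary positions, regular helices and
one exceptionally stable helix; (ii) triplicate reactivity tables whose
class-dependent means follow logistic thermal responses matching the four
unfolding archetypes, with a Mg2+ term reproducing the hallmark pseudoknot
asymmetry (the 3' pseudoknot strand lights up without Mg2+ while the 5'
strand stays unreactive, as it trades the pseudoknot for an alternative
pairing); (iii) melt curves as a dye-decay baseline with sigmoidal
unfolding transitions; and (iv) ring-dihedral trajectories built by
inverse pseudorotation from per-nucleotide pucker-family mixtures.

All outputs are deterministic functions of the configuration (including
its seed). Numeric defaults are generator choices tuned for realism
(normalized SHAPE units, triplicate noise, RT-PCR-grade fluorescence
noise), not measurements.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import Condition, ReplicateSet
from .melt import MeltCurve
from .pucker import FAMILIES, dihedrals_from_pucker

__all__ = [
    "CLASSES",
    "CLASS_ARCHETYPE",
    "StructureAnnotation",
    "GeneratorConfig",
    "make_structure",
    "simulate_reactivities",
    "simulate_melt",
    "simulate_dihedrals",
    "planted_truth",
]

CLASSES = ("SS", "HELIX", "STABLE_HELIX", "TERT", "PK5", "PK3", "KL")

#: Thermal-unfolding archetype each structural class is planted to follow.
CLASS_ARCHETYPE = {
    "SS": "always_reactive",
    "TERT": "tertiary_37_53",
    "PK5": "tertiary_37_53",
    "PK3": "tertiary_37_53",
    "KL": "tertiary_37_53",
    "HELIX": "secondary_65",
    "STABLE_HELIX": "stable_85",
}

_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}


@dataclass
class StructureAnnotation:
    """Planted structure: sequence, per-position class, pairing layout."""

    length: int
    sequence: str
    classes: np.ndarray  # per position, one of CLASSES
    dot_bracket: str  # secondary structure + one pseudoknot layer ([])
    helix_pairs: list[tuple[int, int]]
    pk_pairs: list[tuple[int, int]]
    kl_pairs: list[tuple[int, int]]  # kissing loop; tracked here, not in the string

    def positions_of(self, cls: str) -> np.ndarray:
        return np.flatnonzero(self.classes == cls) + 1


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic study, with study-like defaults.

    ``class_thermal`` maps a structural class to (baseline, amplitude,
    midpoint degC, width degC) of its logistic reactivity-vs-temperature
    response in normalized SHAPE units. ``mg_effect`` is the reactivity
    gained at 0 mM Mg2+ (scaled linearly to zero at ``mg_native_mM``);
    the 5' pseudoknot strand deliberately gets none.
    """

    seed: int = 0
    n_replicates: int = 3
    #: Replicate noise is heteroscedastic, as in capillary-electrophoresis
    #: SHAPE data: sd = noise_sd_floor + noise_sd_rel * |mean|.
    noise_sd_floor: float = 0.02
    noise_sd_rel: float = 0.08
    undetermined_fraction: float = 0.03
    class_thermal: dict = field(
        default_factory=lambda: {
            "SS": (0.92, -0.40, 65.0, 10.0),
            "TERT": (0.50, 0.55, 45.0, 4.0),
            "PK5": (0.12, 0.90, 45.0, 4.0),
            "PK3": (0.12, 0.90, 45.0, 4.0),
            "KL": (0.12, 0.90, 45.0, 4.0),
            "HELIX": (0.10, 0.90, 68.0, 5.0),
            "STABLE_HELIX": (0.06, 0.90, 83.0, 2.0),
        }
    )
    mg_effect: dict = field(
        default_factory=lambda: {
            "SS": 0.0,
            "HELIX": 0.0,
            "STABLE_HELIX": 0.0,
            "TERT": 0.40,
            "KL": 0.45,
            "PK3": 0.50,
            "PK5": 0.0,
        }
    )
    mg_native_mM: float = 5.0
    # Melt-curve model: normalized fluorescence = 1 - decay - sum of
    # sigmoidal drops; -dRFU/dT then peaks at each planted Tm.
    melt_transitions: tuple = ((57.0, 0.25), (80.0, 0.45))
    melt_width_C: float = 1.8
    melt_decay_per_C: float = 0.006
    melt_noise_sd: float = 0.001
    melt_grid: tuple = (37.0, 95.0, 0.2)
    melt_replicates: int = 3
    # Pucker trajectories.
    pucker_amp_mean: float = 38.6
    pucker_amp_sd: float = 2.0
    pucker_phase_jitter_deg: float = 6.0


def _rng(cfg_seed: int, *stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg_seed) % (2**31), *stream]))


def make_structure(seed: int = 0, length: int = 188) -> StructureAnnotation:
    """Deterministic motif layout for an RNA of ``length`` >= 60 nt.

    The layout hosts, 5' to 3': one or two exceptionally stable hairpins
    (mirroring a molecule where several helices resist melting below
    85 degC), a hairpin whose loop carries one kissing-loop strand, a
    hairpin whose loop carries the 5' pseudoknot strand, tertiary-contact
    blocks, a hairpin carrying the second kissing-loop strand, and the 3'
    pseudoknot strand (complementary to the 5' strand and crossing the
    intervening helix — a true pseudoknot), padded with single-stranded
    spacers. Class proportions are chosen so the four thermal archetypes
    form comparably sized groups, as in the reference molecule where each
    archetype cluster collects whole structural elements.
    """
    if length < 60:
        raise ValueError("length must be >= 60 to host the motif set")
    two_stable = length >= 100
    if two_stable:
        stem = max(3, round(length * 0.0425))
        stable_stem = max(4, round(length * 0.064))
        tert = max(2, round(length * 0.09))
    else:  # minimal motif set for short constructs
        stem, stable_stem, tert = 3, 4, 2
    pk_len, kl_len, stable_loop = 5, 4, 4

    # (tag, class, length); spacer rows (length None) absorb the remainder.
    segments = [
        ("sp", "SS", None),
        ("stA5", "STABLE_HELIX", stable_stem),
        ("stALoop", "SS", stable_loop),
        ("stA3", "STABLE_HELIX", stable_stem),
        ("sp", "SS", None),
        ("hA5", "HELIX", stem),
        ("kl1", "KL", kl_len),
        ("hA3", "HELIX", stem),
        ("sp", "SS", None),
        ("hB5", "HELIX", stem),
        ("pk5", "PK5", pk_len),
        ("hB3", "HELIX", stem),
        ("tert1", "TERT", tert),
        ("hC5", "HELIX", stem),
        ("kl2", "KL", kl_len),
        ("hC3", "HELIX", stem),
        ("sp", "SS", None),
        ("pk3", "PK3", pk_len),
        ("tert2", "TERT", tert),
        ("sp", "SS", None),
    ]
    if two_stable:
        segments[5:5] = [
            ("stB5", "STABLE_HELIX", stable_stem),
            ("stBLoop", "SS", stable_loop),
            ("stB3", "STABLE_HELIX", stable_stem),
            ("sp", "SS", None),
        ]
    n_spacers = sum(1 for _, _, ln in segments if ln is None)
    fixed = sum(ln for _, _, ln in segments if ln is not None)
    free = length - fixed
    if free < n_spacers:
        raise ValueError(f"length {length} too small for the motif set (needs >= {fixed + n_spacers})")
    base_sp, extra = divmod(free, n_spacers)
    sp_sizes = [base_sp + (1 if i < extra else 0) for i in range(n_spacers)]

    rng = _rng(seed, 0)
    classes: list[str] = []
    seq: list[str] = []
    spans: dict[str, tuple[int, int]] = {}
    i_sp = 0
    cursor = 0
    for tag, cls, ln in segments:
        if ln is None:
            ln = sp_sizes[i_sp]
            i_sp += 1
        if tag != "sp":
            spans[tag] = (cursor, cursor + ln)
        classes.extend([cls] * ln)
        seq.extend(rng.choice(list("ACGU"), size=ln))
        cursor += ln

    def span(tag: str) -> tuple[int, int]:
        return spans[tag]

    def revcomp_into(src: tuple[int, int], dst: tuple[int, int]) -> list[tuple[int, int]]:
        (a0, a1), (b0, b1) = src, dst
        pairs = []
        for off in range(a1 - a0):
            i = a0 + off
            j = b1 - 1 - off
            seq[j] = _COMPLEMENT[seq[i]]
            pairs.append((i + 1, j + 1))
        return pairs

    helix_pairs = []
    duplexes = [("stA5", "stA3"), ("hA5", "hA3"), ("hB5", "hB3"), ("hC5", "hC3")]
    if two_stable:
        duplexes.insert(1, ("stB5", "stB3"))
    for five, three in duplexes:
        helix_pairs += revcomp_into(span(five), span(three))
    pk_pairs = revcomp_into(span("pk5"), span("pk3"))
    kl_pairs = revcomp_into(span("kl1"), span("kl2"))

    db = ["."] * length
    for i, j in helix_pairs:
        db[i - 1], db[j - 1] = "(", ")"
    for i, j in pk_pairs:
        db[i - 1], db[j - 1] = "[", "]"

    return StructureAnnotation(
        length=length,
        sequence="".join(seq),
        classes=np.array(classes, dtype="U16"),
        dot_bracket="".join(db),
        helix_pairs=helix_pairs,
        pk_pairs=pk_pairs,
        kl_pairs=kl_pairs,
    )


def _logistic(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def class_mean(cls: str, condition: Condition, cfg: GeneratorConfig) -> float:
    """Planted mean reactivity of a structural class under a condition."""
    if cls not in cfg.class_thermal:
        raise ValueError(f"unknown structural class {cls!r}")
    base, amp, mid, width = cfg.class_thermal[cls]
    mean = base + amp * float(_logistic((condition.temperature_C - mid) / width))
    mg_scale = max(0.0, 1.0 - condition.mg_mM / cfg.mg_native_mM)
    mean += cfg.mg_effect.get(cls, 0.0) * mg_scale
    return mean


def simulate_reactivities(
    ann: StructureAnnotation, condition: Condition, cfg: GeneratorConfig | None = None
) -> ReplicateSet:
    """Triplicate reactivity table for one condition (deterministic).

    Per position: mean = class baseline + logistic thermal response + Mg
    term; replicates add Gaussian noise whose sd grows with the signal
    (``noise_sd_floor + noise_sd_rel * |mean|``), as in capillary-sequencer
    SHAPE data; a configured fraction of positions is made undetermined
    (all replicates missing). The random stream is keyed on (seed, probe,
    Mg, temperature) so conditions are independent but reproducible.
    """
    cfg = cfg or GeneratorConfig()
    probe_idx = ("1M7", "NMIA", "BzCN").index(condition.probe)
    rng = _rng(cfg.seed, 1, probe_idx, int(condition.mg_mM * 1000), int(condition.temperature_C * 10))
    n = ann.length
    means = np.array([class_mean(c, condition, cfg) for c in ann.classes])
    sds = cfg.noise_sd_floor + cfg.noise_sd_rel * np.abs(means)
    values: list[np.ndarray] = []
    und = rng.random(n) < cfg.undetermined_fraction
    for i in range(n):
        if und[i]:
            values.append(np.empty(0, dtype=float))
        else:
            values.append(means[i] + sds[i] * rng.standard_normal(cfg.n_replicates))
    return ReplicateSet(
        condition=condition,
        positions=np.arange(1, n + 1),
        bases=np.array(list(ann.sequence), dtype="U1"),
        values=values,
    )


def simulate_melt(
    cfg: GeneratorConfig | None = None,
    transitions: Sequence[tuple[float, float]] | None = None,
    mg_mM: float = 5.0,
) -> list[MeltCurve]:
    """Replicate melt curves: dye-decay baseline plus sigmoidal transitions.

    Fluorescence drops sigmoidally at each planted (Tm, height) as the
    unfolding structure releases the dye, on top of a linear thermal decay,
    so each planted Tm is a maximum of -dRFU/dT. ``transitions=()`` gives
    the pure-decay control; the tertiary-mutant preset is obtained by
    passing only the high-temperature transition.
    """
    cfg = cfg or GeneratorConfig()
    if transitions is None:
        transitions = cfg.melt_transitions
    t0, t1, step = cfg.melt_grid
    temps = np.arange(t0, t1 + step / 2, step)
    rng = _rng(cfg.seed, 2, int(mg_mM * 1000), len(transitions))
    curves = []
    for rep in range(cfg.melt_replicates):
        rfu = 1.0 - cfg.melt_decay_per_C * (temps - temps[0])
        for tm, height in transitions:
            rfu = rfu - height * _logistic((temps - tm) / cfg.melt_width_C)
        rfu = rfu + cfg.melt_noise_sd * rng.standard_normal(len(temps))
        curves.append(MeltCurve(temps.copy(), rfu, replicate_id=rep))
    return curves


def simulate_dihedrals(
    cfg: GeneratorConfig | None = None,
    n_frames: int = 500,
    mixtures: Mapping[str, Sequence[tuple[str, float]]] | None = None,
) -> dict[str, np.ndarray]:
    """Ring-dihedral trajectories from per-nucleotide pucker mixtures.

    Each frame draws a pucker family from the nucleotide's mixture, then
    builds the five dihedrals by inverse pseudorotation at the family's
    center phase (family index * 36 + 18 degrees) with Gaussian jitter on
    amplitude and phase. Default mixtures mimic an MD trajectory with one
    rigid A-form nucleotide, one B-form, and one dynamic nucleotide
    hopping between C3'-endo and C2'-endo.
    """
    cfg = cfg or GeneratorConfig()
    if mixtures is None:
        mixtures = {
            "G10": [("C3'-endo", 1.0)],
            "U83": [("C2'-endo", 0.6), ("C3'-endo", 0.4)],
            "A161": [("C3'-endo", 0.7), ("C2'-exo", 0.3)],
        }
    if n_frames < 1:
        raise ValueError("need at least one frame")
    centers = {fam: 36.0 * i + 18.0 for i, fam in enumerate(FAMILIES)}
    out: dict[str, np.ndarray] = {}
    for k, (nt, mix) in enumerate(sorted(mixtures.items())):
        fams = [f for f, _ in mix]
        weights = np.array([w for _, w in mix], dtype=float)
        if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
            raise ValueError(f"mixture weights for {nt!r} must be non-negative and sum to 1")
        unknown = set(fams) - set(FAMILIES)
        if unknown:
            raise ValueError(f"unknown pucker families {sorted(unknown)}")
        rng = _rng(cfg.seed, 3, k)
        draws = rng.choice(len(fams), size=n_frames, p=weights)
        amps = rng.normal(cfg.pucker_amp_mean, cfg.pucker_amp_sd, size=n_frames)
        phases = np.array([centers[fams[d]] for d in draws])
        phases = phases + rng.normal(0.0, cfg.pucker_phase_jitter_deg, size=n_frames)
        out[nt] = np.vstack([dihedrals_from_pucker(a, p) for a, p in zip(amps, phases)])
    return out


def planted_truth(ann: StructureAnnotation, cfg: GeneratorConfig | None = None) -> dict:
    """Ground truth for test harnesses, serializable as JSON.

    Lists per-position classes and thermal archetypes, the positions
    expected to respond to Mg2+ removal (classes with a non-zero Mg
    effect) and to the 37->53 degC step (the tertiary archetype), the
    planted cluster count and melt transitions, and the pseudoknot pairs.
    """
    cfg = cfg or GeneratorConfig()
    classes = [str(c) for c in ann.classes]
    archetype = [CLASS_ARCHETYPE[c] for c in classes]
    mg_sensitive = [i + 1 for i, c in enumerate(classes) if cfg.mg_effect.get(c, 0.0) > 0]
    temp_sensitive = [i + 1 for i, c in enumerate(classes) if CLASS_ARCHETYPE[c] == "tertiary_37_53"]
    return {
        "length": ann.length,
        "sequence": ann.sequence,
        "classes": classes,
        "archetype": archetype,
        "dot_bracket": ann.dot_bracket,
        "pk_pairs": ann.pk_pairs,
        "kl_pairs": ann.kl_pairs,
        "pk5_positions": [int(p) for p in ann.positions_of("PK5")],
        "pk3_positions": [int(p) for p in ann.positions_of("PK3")],
        "mg_sensitive_positions": mg_sensitive,
        "temp_37_53_sensitive_positions": temp_sensitive,
        "k_true": 4,
        "melt_tms_C": [tm for tm, _ in cfg.melt_transitions],
    }
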