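# diffshape

Differential SHAPE probing analysis for RNA tertiary structure and
pseudoknot detection.

SHAPE chemical probing (with 1M7, NMIA or BzCN) reports per-nucleotide
ribose flexibility, which maps well onto secondary structure: loops are
reactive, helices are not. Pseudoknots, kissing loops and non-canonical
tertiary pairs are the blind spot — their nucleotides are just as
unreactive as ordinary helices, and thermodynamic folding engines
(RNAstructure, RNAfold) cannot predict them anyway. `diffshape` implements
the *differential* strategy around that blind spot: probe the same RNA
under conditions that selectively destabilize the tertiary structure
(removing Mg²⁺, or stepping the temperature from 37 °C through 53, 65, 74
and 85 °C), find the nucleotides whose reactivity changes, and convert
them into constraint files that let standard prediction software recover
the pseudoknot. It is written for structural/computational RNA biologists
processing multi-condition probing experiments.

## What it computes

**Differential reactivity calling.** For mean reactivities R₁, R₂ of a
position under two conditions (each the mean of ~3 replicates, after a
0.4-unit replicate-agreement outlier filter), the call uses the absolute
difference ΔR = |R₁ − R₂| and the relative change ΔR/(R₁ + R₂). A position
is significant iff

    ΔR > 0.2   and   ΔR/(R₁+R₂) > 0.2   and   p < 0.05,

with p from a two-sided Welch t-test on the replicate values. The paired
absolute/relative criteria suppress both small shifts between unreactive
nucleotides and large-but-meaningless shifts between highly reactive ones.

**Thermal-unfolding clustering.** Per-nucleotide reactivity vectors across
the temperature ladder are log₂-transformed (floored at 0.01) and
standardized nucleotide-wise then temperature-wise; k-means (best of 50
restarts) with elbow-based k selection on the within-cluster
sum-of-squared-errors ("distortion") curve for k = 1..10 groups
nucleotides into thermal archetypes: always reactive (single strands),
melting between 37–53 °C (tertiary structure), from ~65 °C (regular
helices), or only above 74 °C (exceptionally stable helices).

**Melting curves.** Fluorescence melt curves are min–max normalized,
differentiated (−dRFU/dT), replicate-averaged and smoothed; local maxima
above a relative prominence threshold are reported as melting transitions
(Tm).

**Sugar pucker.** From the five ring dihedrals ν₁…ν₅, pseudorotation
amplitude and phase are computed as Amp = √(a²+b²), a = 0.4·Σνᵢcos(0.8π(i−1)),
b = −0.4·Σνᵢsin(0.8π(i−1)); phases classify into the ten conventional
pucker families (36° sectors, C3′-endo at 18°) and the A-like/B-like
groups, with per-nucleotide occupancy statistics over MD-derived
trajectories.

**Constraint files.** Three strategies for downstream predictors:
pass a profile through unchanged; *boost10* (significantly
temperature-sensitive positions set to reactivity 10, others keep their
37 °C value); and *pk_mask* (significant positions −0.2, all others 5), which
restricts pairing to the differential positions so that the only helices
a predictor can build are the pseudoknot's. A built-in complementarity
screen verifies what the mask permits without running external software.

A fully deterministic synthetic-data generator (`diffshape.synth`) plants
a 188-nt structure with a pseudoknot, kissing loop, tertiary contacts and
stable helices, and emulates the reactivity, melt and dihedral data of
such a study, including the hallmark Mg²⁺ asymmetry in which the 3′
pseudoknot strand lights up without Mg²⁺ while the 5′ strand stays silent.

## Worked example

```python
from diffshape import *
from diffshape.synth import GeneratorConfig, make_structure, simulate_reactivities, \
    simulate_melt, planted_truth
from diffshape.thermal import build_matrix, ThermalArchetypeKMeans
from diffshape.melt import MeltTransitionDetector

ann = make_structure(seed=0, length=188)
cfg = GeneratorConfig(seed=0)

# +/- Mg differential at 37 degC
a = filter_outliers(simulate_reactivities(ann, Condition(mg_mM=5.0), cfg))
b = filter_outliers(simulate_reactivities(ann, Condition(mg_mM=0.0), cfg))
records = compare_profiles(a, b)
print(sum(r.significant for r in records), "of", len(records),
      "positions differentially reactive without Mg2+")

# thermal clustering across the temperature ladder
profiles = [aggregate(filter_outliers(simulate_reactivities(
    ann, Condition(temperature_C=t), cfg))) for t in (37, 53, 65, 74, 85)]
est = ThermalArchetypeKMeans(n_clusters="auto", random_state=42).fit(build_matrix(profiles))
print("elbow-selected k =", est.k_, "; archetypes:", est.archetypes_)

# melt-curve transitions
det = MeltTransitionDetector().fit(simulate_melt(cfg))
print("transitions:", [f"{t.tm_C:.1f} degC" for t in det.transitions_])
```

prints

```
40 of 177 positions differentially reactive without Mg2+
elbow-selected k = 4 ; archetypes: ['always_reactive', 'secondary_65', 'stable_85', 'tertiary_37_53']
transitions: ['56.6 degC', '80.0 degC']
```

The 40 calls concentrate on the planted tertiary positions: 4 of the 5
3′-pseudoknot nucleotides are called (one is lost to a simulated dropout)
and none of the 5′ strand, reproducing the asymmetry that flags an
alternative fold of the 5′ strand. The four clusters recover the planted
archetypes, and the two derivative maxima sit within 0.4 °C of the planted
tertiary (57 °C) and secondary (80 °C) melting transitions.

The same pipeline is scriptable from the shell:

```sh
diffshape simulate --seed 0 --out-dir data/
diffshape diff --a data/react_1M7_mg5_T37.tsv --b data/react_1M7_mg0_T37.tsv --out diff_mg.tsv
diffshape constrain --a data/react_1M7_mg5_T37.tsv --b data/react_1M7_mg5_T53.tsv \
    --strategy pk_mask --out pk_mask.shape
```

`pk_mask.shape` is a two-column SHAPE file (−999 for missing data) ready
for RNAstructure/RNAfold/IPANEMAP.

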