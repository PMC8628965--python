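# Methods

## Differential reactivity calling

Replicate reactivities are filtered by an agreement rule before any
comparison: within a position's replicate group (applied only when ≥3
values exist), a value is discarded iff its absolute distance to *every*
other value exceeds the window (default 0.4 normalized SHAPE units). This
reading keeps an agreeing pair and drops the straggler; if all values are
mutually further apart than the window there is no consistent majority
and the position becomes undetermined. The filter is idempotent: every
retained value keeps a retained neighbour within the window.

Profiles are the per-position mean of the surviving replicates (sample sd
and count carried along). For two conditions with means R₁, R₂ the caller
computes ΔR = |R₁−R₂| and the relative change ΔR/(R₁+R₂) and requires all
three criteria *strictly*: ΔR > 0.2, rel > 0.2, and p < 0.05 from a
two-sided t-test on the replicate values. Welch's unequal-variance form
is used: with n = 3 per side there is no basis for assuming equal
variances, and at these sample sizes the Welch and pooled tests differ
mostly in pathological cases. Degenerate inputs are flagged rather than
guessed at: fewer than two replicates on a side → p undefined, never
significant; all replicates exactly tied on both sides → p set to 0 when
the tied values differ and 1 when they agree; R₁+R₂ ≤ 0 (possible with
negative normalized reactivities) → relative change undefined, never
significant. No multiple-testing correction is applied by default — the
rule is deliberately per-position, and its absolute/relative thresholds
already suppress most noise calls — but a Benjamini–Hochberg option
(`adjust="bh"`) is available.

## Thermal-unfolding clustering

Nucleotide × temperature matrices keep only positions determined at every
temperature. The transform is: floor at 0.01 (normalized SHAPE values can
be ≤ 0 and the log needs a positive argument; 0.01 is far below any
structurally meaningful reactivity), log₂, standardize each nucleotide
row to mean 0/sd 1, then each temperature column likewise (population sd;
zero-variance rows or columns are centered only). Row standardization
makes clustering sensitive to the *shape* of the thermal response, not
its magnitude; the transform is therefore invariant to uniform rescaling
of the input. The row-then-column order follows the stated convention of
the protocol it automates; the reverse order gives similar but not
identical matrices.

k-means uses the squared-Euclidean objective with k-means++ seeding, 50
restarts (best distortion wins), tolerance 1e-6, fixed seed default 42;
results are bit-reproducible given (seed, restarts). k is chosen from the
distortion curve over k = 1..10 by the maximum perpendicular distance to
the chord joining the curve's endpoints — an automated, deterministic
stand-in for reading the elbow off a graph — and the full curve is always
returned so a user can override k.

Archetype labels are a post-hoc heuristic defined for k = 4: a cluster
whose mean raw 37 °C reactivity exceeds 0.7 (the "high" bin edge) is
`always_reactive`; otherwise the label follows the temperature interval
with the largest raw-centroid rise — 37→53 °C `tertiary_37_53`, 74→85 °C
`stable_85`, anything between `secondary_65`. Ties or k ≠ 4 yield
`unassigned` with a warning. The 0.7 threshold is configurable.

## Melting curves

Replicate fluorescence curves are min–max scaled to [0, 1] (the protocol
says "normalized" without defining it; min–max makes the relative
prominence threshold comparable across runs), differentiated with central
differences (one-sided at the grid ends), averaged pointwise, and
smoothed with a centered moving average spanning a *temperature* window
(default 1.5 °C) so behaviour is independent of the grid step. Transitions
are −dRFU/dT maxima with prominence ≥ 0.05 × (curve max − min); Tm is
reported at the grid point of the maximum (no sub-grid refinement — at
the 0.2 °C default grid this is well inside the ±0.5 °C tolerance the
package tests for). Numerically flat derivative curves (span below 1e-12
of scale) return no transitions.

## Sugar pucker

Pseudorotation components are a = 0.4·Σᵢ νᵢcos(0.8π(i−1)),
b = −0.4·Σᵢ νᵢsin(0.8π(i−1)) over the ring dihedrals ν₁ (C1′-C2′-C3′-C4′)
… ν₅ (O4′-C1′-C2′-C3′); Amp = √(a²+b²). These are exact for the cosine
model νᵢ = Amp·cos(P + 0.8π(i−1)), under which a = Amp·cos P and
b = Amp·sin P — so the package computes the full phase P = atan2(b, a)
(mapped to [0, 360)) alongside the conventional cosine Pha = a/Amp. The
cosine alone cannot separate all ten pucker families; classification uses
the full angle with standard 36° sectors starting at 0° (C3′-endo
centered at 18°, C2′-endo at 162°, …). A-like = {C3′-endo, C4′-exo,
C1′-endo, C2′-exo}; B-like = {C1′-exo, C2′-endo, C3′-exo, C4′-endo}; the
two O4′ families are "other". Rings with Amp below 1e-6° are planar:
phase and family undefined, counted in an `undefined` occupancy bucket.
Scalar per-frame quantities are summarized as mean ± sample sd.

## Synthetic-data generator

The generator defines the study conditions every test runs under. The
planted structure (default 188 nt, deterministic given seed) carries a
5-bp pseudoknot whose brackets cross a regular helix, a 4-bp kissing-loop
pair between two hairpin loops, non-canonical tertiary blocks, three
regular helices and — at default length — two exceptionally stable
hairpins, reflecting molecules in which several helices (not just one)
resist melting below 85 °C. Kissing-loop pairs are tracked in the
annotation but left unpaired in the dot-bracket string, which carries
exactly one pseudoknot layer. For lengths 60–99 a minimal single-stable
layout is used. Class proportions at default length are roughly balanced
across the four thermal archetypes, as in the reference data where each
archetype cluster collects whole structural elements.

Reactivity means follow class-specific logistic thermal responses
(baseline + amplitude·σ((T−midpoint)/width)):

| class | baseline | amplitude | midpoint (°C) | width (°C) | archetype |
|---|---|---|---|---|---|
| SS | 0.92 | −0.40 | 65 | 10 | always_reactive |
| TERT | 0.50 | +0.55 | 45 | 4 | tertiary_37_53 |
| PK5/PK3/KL | 0.12 | +0.90 | 45 | 4 | tertiary_37_53 |
| HELIX | 0.10 | +0.90 | 68 | 5 | secondary_65 |
| STABLE_HELIX | 0.06 | +0.90 | 83 | 2 | stable_85 |

The single-strand decline emulates the normalization-driven fall of
relative reactivity as all nucleotides become reactive at high
temperature. Removing Mg²⁺ adds a class effect scaled linearly from full
at 0 mM to zero at 5 mM: +0.40 (TERT), +0.45 (KL), +0.50 (PK3) and — the
planted asymmetry — nothing for PK5, whose strand is modeled as adopting
an alternative fold without Mg²⁺. Replicate noise is heteroscedastic,
sd = 0.02 + 0.08·|mean|, the error structure typical of
capillary-electrophoresis SHAPE where uncertainty grows with signal; 3%
of positions are undetermined. All draws are keyed on (seed, probe, Mg,
temperature) so every condition is independently reproducible.

Melt curves are modeled as normalized fluorescence
1 − 0.006·(T−37) − Σ h·σ((T−Tm)/1.8) + N(0, 0.001) on a 37–95 °C grid at
0.2 °C: a linear dye-decay baseline with sigmoidal fluorescence drops at
each planted transition (default Tm 57 °C, h = 0.25 and Tm 80 °C,
h = 0.45), so each planted Tm is a −dRFU/dT maximum, matching the
analysis convention. The tertiary-mutant preset passes only the 80 °C
transition. Dihedral trajectories draw a pucker family per frame from a
per-nucleotide mixture and build the five dihedrals by inverse
pseudorotation at the family's center phase, with Gaussian jitter on
amplitude (38.6 ± 2°) and phase (± 6°).

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: sequence-dependent reactivity within a
class, probe-specific chemistry (all three probes share the class model),
correlated replicate error, normalization artifacts beyond the smooth SS
decline, partial dropouts (undetermined positions lose all replicates at
once), and melt-curve shapes beyond decay-plus-sigmoids.

## Design choices and limitations

* Reactivity class bins are half-open: R < 0.4 low (negatives clamp to
  low), 0.4 ≤ R ≤ 0.7 moderate, R > 0.7 high — "high" is strictly above
  0.7.
* The pk_mask strategy assigns −0.2/5 only to positions actually compared;
  positions undetermined in either condition export as −999 rather than
  inheriting the 5.
* The helix screen reports maximal antiparallel stacks of ≥ 3 pairs
  (G-U wobble allowed by default) entirely within the candidate set;
  2-bp interactions are deliberately below the default threshold, as
  prediction engines do not build them either. It ignores loop-size
  constraints and energetics — it is a complementarity check, not a
  folding engine.
* The outlier filter is applied to reactivities as read; whether it should
  precede or follow renormalization is left to the data producer.
* Archetype labels are heuristics over raw centroids; clusters whose
  thermal response is genuinely ambiguous (ties) are left unassigned
  rather than forced.
* Problem sizes in the test and acceptance runs — 188 nt, 5 temperatures,
  triplicates, 20 generator seeds for the clustering checks, 1000 random
  draws for the oracle and round-trip checks — match the scale of the
  emulated study and keep the full suite fast.
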