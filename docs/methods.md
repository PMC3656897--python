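# Methods

## Scope and model

`nrpslip` treats an NRPS system as a co-linear assembly line: an ordered
set of proteins, each a chain of condensation–adenylation–thiolation
(C–A–T) modules, optionally terminated by a thioesterase (TE) tandem on the
last protein. Under the co-linearity assumption, module *i* contributes
residue *i* of the product; the chemistry layer then converts the predicted
residues, the N-linked 3-hydroxy fatty acid and an optional macrolactone
into a molecular formula and monoisotopic masses for comparison with
high-resolution MS. The package makes no attempt at maximum-likelihood
phylogenetics, isotope patterns, MS/MS fragmentation or 3D structure.

## Domain detection

Detection is motif-anchored template matching. Each domain kind ships with
a synthetic consensus template of nominal length (C 450, A 500, T 80,
TE 250 aa) that embeds the canonical core motifs — C: HHxxxDG; A: the A3
"SGTTGxPK"-like and A8 cores; T: xGGxSx with the invariant
phosphopantetheine serine; TE: GxSxG — plus a spread of conserved anchor
columns (~70 for C/A, 24 for T, 70 for TE). A window of template length is
a candidate hit when the fraction of matching anchor columns reaches the
threshold (default **0.6**); overlapping candidates are resolved by score,
then leftmost start, then kind order C < A < T < TE, making output
deterministic. The threshold is far below the ~0.95 expected anchor
identity at the 5%-per-site divergence the generator emulates, and far
above the ~0.05 chance level of unrelated sequence, which is why recall on
synthetic data is complete while the false-positive rate on random
sequence is effectively zero (bound tested: ≤ 1 hit / 10,000 residues).

A pure exact-motif scanner was rejected at design time: a 7-residue motif
survives 5% per-site substitution only ~70% of the time, so single-motif
matching cannot reach full recall; widening to an anchor-column set keeps
the motif information and restores robustness. Boundaries follow the
template extent, so coordinates are meaningful on template-derived
(synthetic) data; for natural sequences, whose boundary conventions vary
between annotation tools, the intended path is importing third-party
domain coordinate tables (`read_domain_table`) — module *counts*, not
coordinates, are the reproducible quantity there. All machine coordinates
are 0-based half-open; human-readable reports are 1-based.

Module building is a greedy left-to-right grammar (C A T)+ (TE){0,2}; hits
that do not fit are reported as diagnostics, never dropped. TE hits on a
non-terminal protein are an error, since protein order is user-declared
biological knowledge.

## Substrate and subtype calling

**Signature extraction.** The A domain is globally aligned to the packaged
anchor (BLOSUM62, affine gaps open 11 / extend 1 — fixed for bit-exact
reproducibility); residues aligned to the 34 signature columns are read
off, and the 10 diagnostic positions are an indexed subset (the index list
ships as data so it can be corrected without code changes). Alignment
coverage below 60% of the anchor raises "signature not extractable".

**Nearest neighbor.** Score is exact identities out of 10 against each
panel signature. All co-optimal labels are reported as ties; confidence is
"none" below a floor of **6/10** (an implementer default, configurable),
"ambiguous" on ties, else "confident". The call is invariant to panel
ordering (references are sorted by id internally).

**Placement.** The query joins the panel in an NJ tree (p-distances on the
pre-aligned sequences); the call is the label of the reference at minimal
patristic distance, ambiguous when a second label lies within **Δ = 0.05**
of the minimum (implementer default). An externally built tree (newick,
query as leaf `@query`) can be supplied instead — the fidelity path when
thresholds were calibrated on ML branch lengths. C-domain typing (starter /
dual C,E / conventional) and TE typing (TE1/TE2) reuse the placement
machinery; module-1 C domains are additionally marked starter candidates
on positional grounds, and a TE call conflicting with its tandem ordinal is
flagged, never silently resolved.

## Phylogenetics

Distances are p-distances over columns where neither row is gapped, with
optional Poisson correction −ln(1−p) (saturated pairs raise an error naming
the pair). Trees come from Saitou–Nei neighbor joining with two
determinism/validity rules: Q-matrix ties break by the lexicographically
smallest representative-label pair, and a negative branch length from the
NJ formulas is clamped to zero with the deficit shifted to the sister
branch, so all output branch lengths are ≥ 0. On additive inputs this
reproduces the generating tree exactly (tested over all three four-taxon
topologies and against an independent NJ implementation). Patristic
distances (summed branch lengths between leaves) are checked against a
graph-shortest-path oracle. Outgroup rooting inserts the root at the
midpoint of the outgroup's pendant edge, which leaves patristic distances
unchanged.

**Grouping rule.** Two domains with patristic distance below a threshold
(default **0.45**) belong to the same specificity group. Because the rule
colors classes rather than pairs, it is interpreted as the single-linkage
transitive closure (connected components of the d < threshold graph); a
`pairwise` mode exposing the raw edge relation is provided for users who
prefer the non-transitive reading. The 0.45 value was calibrated on ML
branch lengths, so reproducing published groupings exactly requires an
imported ML tree; internal NJ trees may shift distances.

## Product prediction and chemistry

Stereochemistry: residue *i*−1 is D iff module *i*'s C domain is dual C/E;
the terminal residue is L; an unassigned subtype yields "unknown". The
vector is emitted with a machine-readable caveat string, because deviations
from the sequence-based rule are documented in this compound family.

Cyclization candidates are enumerated (donor = any internal Ser/Thr/aThr,
ring size n − donor + 1, inclusive) and never auto-selected. Congeners are
the Cartesian product of per-position alternatives and fatty-acid variants,
primary combination first. Glu/Gln ambiguity (Glx) is kept symbolic in the
peptide and only expanded (2 per Glx, 0.984 Da apart) in congener/mass
mode; composing a formula over an unresolved Glx is an error by design.

Formulas: residues enter as amino acid − H₂O; the chain adds one H₂O for
its termini; N-acylation and lactonization each subtract one H₂O; a
3-hydroxy fatty acid with n carbons and d double bonds is CₙH₂ₙ₋₂dO₃.
Monoisotopic atomic masses come from the NIST table shipped with pyteomics
(cross-checked in tests against pyteomics' own mass calculator); protonated
adducts use the proton mass 1.007276 Da — the H-atom mass would be ~0.0005
Da high, visible at the 4-decimal precision used throughout (half-even
rounding, matching the precision of published expected values). The mass-
difference table is restricted to deltas with a defined interpretation for
this compound family (CH₂, C₂H₂, H₂O, Na/H exchange) and is extensible by
passing a custom table.

NMR heuristics: a hydroxyl site is flagged as depsi-bond donor when its
mean H-β deviation from random-coil values exceeds **0.3 ppm** (implementer
default; the published example sits at +0.61 ppm and uninvolved sites near
0). The cis/trans call requires both allylic ¹³C deltas (observed minus
saturated analog) to agree in sign: negative = cis, positive = trans,
mixed = ambiguous.

## Synthetic data

The generator emulates the features the pipeline keys on: module grammar
and coordinates, class-specific signature residues, subtype blocks, TE
tandems, random inter-domain linkers (uniform 10–60 aa, rejection-sampled
against the core-motif patterns), under a seeded per-site substitution
model (each site substituted with probability r to a uniformly chosen
different residue; r ≤ 0.5 enforced; default 0.05 for assembly lines and
panel references, 0.10 for classifier stress queries).

Class structure: each substrate class / subtype descends from its own
ancestor — the kind template with non-anchor scaffold columns diverged at
25% per site and, for A domains, class-specific residues planted at the 10
diagnostic columns. Ancestors are deterministic per (kind, label) and
independent of the per-call seed, so panels and assembly lines generated
separately stay mutually consistent. Fully random ancestors were rejected
because signature extraction and placement require alignability to the
anchor. Planted class signatures are drawn per label from a label-keyed
RNG; the panel generator verifies ≥ 6/10 pairwise differences and refuses
colliding label sets. The default configuration is the 2 + 8 + 4
architecture with the 14-residue substrate plan, starter C at module 1,
dual C/E at 2–11 and 14, conventional C at 12–13, TE tandem and a
C10:0-3OH lipid.

What the generator does **not** emulate: indels (beyond planted test
insertions), rate heterogeneity, realistic substitution matrices,
inter-domain boundary ambiguity, and natural-sequence divergence patterns.
Passing tests therefore demonstrate correctness of the inference logic and
its robustness to point substitution — not detector performance on natural
NRPS sequences, for which profile-HMM coordinates should be imported.

## Problem sizes and determinism

Test and analysis runs use desk-scale sizes chosen as representative:
100-protein recall studies, 200-query accuracy floors (≥ 95% substrate/
subtype, ≥ 90% NN-vs-placement agreement), 50-line stereochemistry checks,
100-tree patristic oracles. Every stochastic stage takes a single explicit
seed (numpy Generator); there is no hidden global RNG, and the pipeline
writes byte-identical report bundles on re-run with equal configuration.

## Known limitations

* Real-sequence domain boundaries (and hence coordinates) are outside the
  validated envelope of the motif-anchored scanner; use imported domain
  tables for natural sequences.
* Substrate calls are only as good as the reference panel; the shipped
  panel is synthetic and exists to exercise the machinery, not to call
  natural domains.
* The C/E stereochemistry rule and the depsi/cis-trans heuristics are
  evidence summaries, not ground truth; they are reported with caveats and
  thresholds exposed.
* NJ branch lengths differ from ML ones; threshold-based groupings ported
  from ML trees should use imported trees.
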