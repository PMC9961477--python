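# Methods

## Mass conventions

All arithmetic is monoisotopic, over a five-element table (C 12 exactly,
H 1.00782503207, N 14.0030740048, O 15.9949146196, S 31.97207100 Da; sulfur
is carried for forward compatibility — no packaged compound uses it).
Nominal masses (integer mass numbers: C 12, H 1, N 14, O 16) are kept
alongside because classic peptaibol ladder bookkeeping is quoted in integer
units (Aib −85 u, Gln −128 u, leucinol −117 u).

Protonation uses the **hydrogen-atom convention**: [M+H]⁺ = M + 1.0078250,
electron mass neglected. The reference measurements this package is
validated against were reduced with instrument software using the same
convention; switching to the proton mass (1.00728) would shift every ppm
comparison by ≈ +0.39 ppm. ppm error is signed,
(observed − theoretical)/theoretical × 10⁶; tests gate on |ppm| only, since
the signs printed in published tables are not always internally consistent.

A peptaibol is modeled as acetyl cap + residue string + C-terminal amino
alcohol; its molecular formula is the acetyl delta (C2H2O) plus residue
formulas (NH-CHR-CO composition) plus the **free** amino-alcohol molecule.
Isobaric residues are never split: Vxx stands for Val/Iva, Lxx for Leu/Ile,
Lxxol for leucinol/isoleucinol. Members of a class share one composition, so
class-level masses are exact.

## Fragmentation model

Only singly charged species are modeled (peptaibols of this size ionize as
monocharged [M+H]⁺; the charge parameter exists but rejects values ≠ 1).
The default ion set is the b series (acylium: acetyl + first *i* residues
+ H, for *i* in 2..n−1) plus the precursor family: [M+H]⁺, the water loss,
and the amino-alcohol loss. The amino-alcohol loss coincides exactly with
b(n−1) — losing the free alcohol from [M+H]⁺ leaves the b(n−1) acylium —
and peak lists merge ions within 1 µDa. y-type ions (suffix + free alcohol
+ H; b_i + y_{n−1−i} = [M+H]⁺ + 1.00783) can be generated for robustness
experiments but are off by default, matching real spectra where they are
rarely informative. No intensity prediction is attempted.

## De novo sequencing

Matching uses a `Tolerance` in Da or ppm; defaults are **0.02 Da** for
fragments (QTOF-class accuracy at m/z 200–1500) and **10 ppm** for the
precursor. Both are free parameters; the published interpretation this
mirrors was manual and quotes no tolerances.

1. *C-terminal anchor.* Each amino alcohol in the alphabet is tested for a
   peak at precursor − neutral loss; hits are ranked by |ppm|. All hits are
   pursued; wrong-alcohol branches die later on the precursor mass check or
   on constraints.
2. *Ladder reading.* A spectrum graph over peaks ≤ anchor: edge when a peak
   difference matches one residue mass (optionally the sum of two —
   "bridging", see below). The reading is the path from the anchor
   maximizing residues explained, tie-broken by fewer bridges, lower
   cumulative |ppm|, then lexicographic labels — fully deterministic.
3. *Prefix completion.* b1/b2 are never required (they are absent from real
   peptaibol spectra); the mass below the last ladder peak, minus acetyl and
   proton, is completed by exhaustive enumeration of residue multisets up to
   k_max = 6 (a hard combinatorial bound). **Exact isobars are a fact of
   this alphabet** (2 Aib + Ala = Gly + Aib + Vxx = 2 Ala + Vxx = Gln + Lxx,
   all C11H19N3O3): completion returns them all, ordered by |ppm| then
   lexicographically, and leaves arbitration to the constraints.
4. *Candidates.* Prefix orderings × bridge-pair orderings are expanded,
   filtered by the precursor tolerance, scored as
   `(matched_b / (n−2)) × exp(−mean|ppm| / 20)` — ladder coverage damped by
   mass accuracy; the functional form is this package's own convention, as
   manual interpretation ranks nothing numerically — then filtered and
   re-ranked by the constraint set. A single survivor from a multi-ordering
   prefix is flagged `module_constraint`; a one-ordering prefix is
   `unique_composition`; remaining ties are `unresolved`.

Two-residue bridge edges (spanning one missing peak) are **off by default**
because they enlarge the candidate space; enabling them is an explicit
choice. A bridged pair is genuinely underdetermined: its internal order, and
cross-isobars such as {Vxx,Vxx} = {Aib,Lxx} or {Ala,Ala} = {Gly,Aib}
(identical compositions), carry no mass signal, so when soft constraints do
not discriminate either, the tie-break is arbitrary-but-deterministic.
Under 10% b-ion dropout this caps recovery of the 21-compound table at
roughly 17–18 of 21 across seeds (two adjacent dropouts additionally defeat
prefix completion when the gap exceeds k_max); the regression test guards
≥ 15/21 at a fixed seed. On noiseless spectra recovery is 21/21.

Gln and Glu (Δ 0.984 Da) are distinguished at the default tolerance;
ambiguity classes are never split.

## Module-collinearity constraints

A constraint set is one allowed-substrate set per module, **hard** (binding;
violations eliminate) or **soft** (advisory; violations demote), in an
INI-style text file. Two presets ship:

- `endophytin_15mod` — only modules 1 ({Aib}, 100% bootstrap) and 2 ({Ala},
  >92%, non-promiscuous) are hard; the promiscuous or weakly supported
  modules are soft, with the "varied" modules 3/7/8 read as
  {Aib, Ala, Vxx, Lxx}. Module 10 encodes both the phylogenetic prediction
  (Ser) and the universally observed residue (Ala) as a soft pair — the
  discrepancy is kept visible rather than resolved.
- `harzianin_14mod` — the Pro modules 5/9/13 are hard (a single monophyletic
  clade indicating high domain specificity); skipping is enabled with runs
  capped at 3, covering the 11-residue products of the same synthetase.

Equal lengths give position-wise set membership. Shorter sequences are
aligned by a dynamic program over monotone injective position→module maps
minimizing (hard violations, skipped runs, soft violations) with the
lexicographically smallest mapping on ties; it is oracle-equivalent to
exhaustive search (tested up to 14 modules). Candidate re-ranking is a
stable sort by soft-violation count, so score order is preserved among ties.

## Molecular networking

Modified cosine: intensities are square-root transformed (GNPS convention;
switchable) and L2-normalized; candidate pairs match directly or after
shifting one spectrum by the precursor difference; a greedy one-to-one
matching (products descending, ties by m/z) accumulates the score. Greedy is
deterministic and, on peaks separated by more than twice the tolerance,
attains the optimal-assignment score (property-tested against
`scipy.optimize.linear_sum_assignment`); matchms' `ModifiedCosine` serves as
an independent cross-check in the tests. Defaults: fragment tolerance
0.5 Da, precursor tolerance 0.05 Da, edges kept at cosine ≥ 0.65 with ≥ 4
matched peaks. No top-K edge pruning or component-size caps are applied.
Edge deltas are annotated against all pairwise residue and amino-alcohol
mass differences within the precursor tolerance; unexplained deltas are
"unassigned".

## Synthetic data

The generator emulates data-dependent positive-mode QTOF product-ion
spectra of singly protonated peptaibols: the b3..b(n−1) ladder (b1/b2
suppressed by default, as in real spectra) plus the precursor family, with

- Gaussian m/z jitter, σ in ppm (default 0);
- independent per-b-ion dropout (default 0; the precursor family is never
  dropped);
- uniform noise peaks in [200, precursor] with intensities in
  (0, 0.3 × max] (default 0);
- invented intensity models — `uniform` (all 1.0) and `triangular` (rising
  toward mid-ladder); correctness of sequencing on noiseless data is
  independent of the model (tested).

All randomness flows from one integer seed through `numpy.random
.default_rng`; identical parameters and seed give identical spectra. What
the generator does **not** emulate: isotope envelopes, chimeric spectra,
collision-energy-dependent intensities, retention time, profile-mode peaks,
calibration drift. Passing tests therefore demonstrate the correctness of
the inference logic under the stated noise model, not instrument-grade
performance on raw LC-MS/MS data; in particular the published 85-node
network and its m/z 1095–1493 range derive from real data that is not
reproducible at desk scale, and networking is validated by properties
(self-similarity, symmetry, thresholds, analog separation) instead.

The packaged endophytin table stores, for each of the 21 compounds, the
printed experimental m/z, ppm and formula **and** the sequence-derived
formula and theoretical m/z, plus flags: 11 rows are fully self-consistent
(printed formula = sequence formula and |ppm| ≤ 5); the rest have printed
formulas and/or m/z inconsistent with their own sequences and are flagged
rather than corrected. The row printed with the bare name "Endophytin"
(compound 11) is stored as A7, the only unused A-series index. Acceptance
checks use only self-consistent rows.

## Problem sizes

The default test run generates all spectra programmatically (21 fixture
peptaibols, 5 random decoys, property tests with up to ~100 examples) and
completes in well under a minute; the acceptance script sequences the 21
noiseless spectra in a few seconds. Prefix enumeration is bounded at k ≤ 6
over the 9-residue alphabet (≈ 5000 multisets), and the skip-alignment DP is
quadratic in module count.

## Known limitations

- Charge states > 1, PTMs beyond N-acetylation, and a-/c-/z-ions are out of
  scope.
- Bridged-gap ambiguity is irreducible without orthogonal information (see
  above); reported sequences are exact only at ambiguity-class level
  (Vxx/Lxx/Lxxol members are indistinguishable by mass).
- The hard/soft split of the 15-module preset beyond modules 1–2 is a
  reading of qualitative phylogeny descriptions, not of a published tree
  file; users can harden any position in their own configs.
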