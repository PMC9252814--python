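# Methods

## Sequence-mode charge model

Every titratable group is treated as an independent two-state acid/base
with a fixed pKa. The mean fractional charge at a given pH is the
Henderson–Hasselbalch logistic: for an acid `−1/(1 + 10^(pKa−pH))`
(ranging over [−1, 0]), for a base `+1/(1 + 10^(pH−pKa))` (over [0, +1]).
Non-ionizable residues are exactly zero. The model deliberately ignores
the structural micro-environment: every Asp titrates at the same pKa. It
is therefore a screening statistic, not a prediction of any individual
residue's behaviour — structure mode exists for that.

Default pKa table (pH units): Asp 3.80, Glu 4.50, His 6.50, Cys 9.00,
Tyr 10.00, Lys 10.50, Arg 12.50; N-terminus 8.00, C-terminus 3.20. These
are the model pKas of the PROPKA3 empirical predictor, chosen so that
sequence mode and structure mode agree exactly in the limit where the
environment perturbs nothing. The table is a value object and fully
overridable.

Terminal groups are included by default (added to the first/last residue's
charge) with a flag to disable; a single-residue sequence carries both.
pH values are accepted on (0, 14] — the closed upper end makes a full
1–14 titration scan expressible.

The overall charge score of a sequence is
`(Σ q(pH_int) − Σ q(pH_ref)) / N`. It equals the plain mean of per-residue
deltas, is antisymmetric under swapping the two pH values, and is
non-positive whenever the pH is raised (deprotonation only removes
positive or adds negative charge). Collection ranking scans consecutive
pairs of a strictly increasing pH grid (default 1, 2, …, 14; lower value
as reference) and ranks by descending |mean per-shift score|; the signed
mean is reported alongside. All per-shift scores on an increasing grid
share a sign, so magnitude ranking is the natural "most responsive first"
order. Ties break on sequence id, which also makes the ranking
permutation-invariant. Ambiguity codes (X/B/Z/U/O) are treated as
non-ionizable with a warning; a strict mode rejects them. Batches are
soft-capped at 10,000 records.

## Structure ingestion

PDB input is parsed with Biopython behind a small immutable model (chains
→ residues → atoms). Only the first MODEL block is used (the analysis
assumes one static structure); HETATM records, waters and nucleic acids
are dropped, with selenomethionine kept as a standard-residue substitute.
Alternate locations resolve to the highest-occupancy conformer, ties
preferring the blank/'A' altloc. Hydrogens present in the input are kept
and used by the hydrogen-bond angle test; their absence degrades
gracefully (below).

Predicted models (AlphaFold convention) store per-atom pLDDT in the
B-factor column; the per-residue value is the mean over atoms. Confidence
trimming removes residues below a threshold (70 is the conventional
low-confidence line) except inside explicit keep ranges — intended for
inter-domain linkers that are flexible rather than wrong. Removed residue
keys are recorded on the model so downstream reports can note the gaps.
Trimming an experimental structure is refused as meaningless.

## pKa providers

Three interchangeable providers fill the same per-group pKa container
(side chains of D/E/C/Y/H/K/R plus one N- and C-terminal entry per
chain):

* the fixed model table (environment-free baseline);
* a parser for the `SUMMARY OF THIS PREDICTION` block of PROPKA `.pka`
  output, so archived predictions are reusable without the executable —
  unmatched lines are skipped with a warning, duplicate lines (alternate
  conformations) keep their first occurrence, and cysteines flagged with
  the 99.99 disulfide sentinel are dropped as non-ionizable;
* a thin wrapper that writes the model as PDB, invokes a discoverable
  PROPKA executable and parses its output, recording the version. A
  missing executable raises an error that names the file-based fallback.

The empirical predictor itself is wrapped, never reimplemented: this
package's contribution is everything downstream of the pKa values.
Ionizable groups absent from a provider's output (e.g. the dropped
disulfide cysteines) take no charge and no state-dependent bond role.

## Protonation states and the shift rule

Structure mode uses discrete states: a group is protonated iff
`pH < pKa`, with the tie pH = pKa counting as deprotonated. Formal charge
follows polarity (protonated acid 0 / deprotonated −1; protonated base +1
/ deprotonated 0). The tie convention is chosen so that the set of groups
whose state differs between two pH values is exactly those with pKa in
the half-open interval `(min pH, max pH]` — the shift report is computed
by comparing the two full assignments and provably equals that interval
rule. Shift detection is symmetric in its two pH arguments.

The state also fixes hydrogen-bond capabilities at the group level (no
tautomer placement): a neutral imidazole nitrogen may donate or accept
(tautomer-agnostic), an imidazolium only donates and its ring counts as a
cation rather than a π system; carboxylates only accept, while a
protonated carboxylic acid can also donate; ammonium/guanidinium donate,
gaining acceptor capability only in their (rare) neutral forms.

## Interaction detection

Detected under a given protonation assignment, with all thresholds
configurable (defaults follow common residue-interaction-network
conventions; reports embed the values used):

* **Salt bridge** — minimum distance between a charged nitrogen
  (Arg NH1/NH2/NE, Lys NZ, protonated His ND1/NE2, protonated N-terminal
  N) and a charged oxygen (deprotonated Asp OD1/OD2, Glu OE1/OE2,
  deprotonated C-terminal O/OXT) ≤ 4.0 Å; one record per residue pair at
  the minimizing atom pair.
* **Hydrogen bond** — capable donor/acceptor heavy atoms ≤ 3.5 Å;
  when the donor carries explicit hydrogens the best D–H···A angle must
  reach 120°, otherwise the distance criterion alone applies so raw PDB
  files remain analyzable. Backbone N–H/C=O participate; atom pairs that
  already qualify as salt bridges are suppressed.
* **π–π** — ring-centroid distance ≤ 7.0 Å between neutral aromatic
  rings (His 5-ring only while neutral; Phe/Tyr 6-ring; Trp's two rings
  tested separately).
* **Cation–π** — cation site (Lys NZ, Arg guanidinium centroid,
  protonated-His ring centroid) to ring centroid ≤ 6.0 Å. A protonated
  His ring acts *only* as a cation, never simultaneously as a π partner,
  so protonating a histidine recategorizes its ring contacts from π–π to
  cation–π.

Intra-residue and sequence-adjacent pairs (same chain, |Δres| ≤ 1) are
excluded as covalently constrained. Records are canonicalized by partner
order and deduplicated; candidate pairs are pruned with a k-d tree, and
the full detection is deterministic. The test suite holds the indexed
detectors equal to brute-force all-pairs references (re-derived tables,
plain loops) on randomized structures.

## Delta view and patches

Two inventories computed on the same structure with identical geometry
parameters are compared on geometry-free record identity (kind, partner
residues, atom/centroid labels — distances are excluded from identity
since hydrogen placement may legitimately differ between states). Records
present only at the pH of interest are *created*, only at the reference pH
*destroyed*; swapping the inputs swaps the two exactly. A recategorized
His ring contact therefore appears as one destroyed π–π plus one created
cation–π. Mismatched geometry parameters are an error, not a warning.

Patches cluster the protonation-shifting residues: nodes are shifting
side chains (terminal-group-only shifts excluded by default), edges join
residues whose minimum side-chain heavy-atom distance is ≤ the radius
(default 8 Å; any-atom and centroid modes available — side-chain minimum
captures "close in space" better than Cα distance for long side chains).
Patches are connected components with ≥ `min_size` members (default 3,
i.e. each member clusters with at least two other shifting residues;
2 available via flag). Components, not cliques: chains of pairwise-near
residues count as one patch. Sub-threshold components are reported as
near-patch residues rather than dropped. Enlarging the radius can only
add edges, so components only merge.

## Synthetic fixtures

Toy structures pose real residues (ideal internal geometry from the
chemical component dictionary shipped with biotite) at exactly controlled
inter-group distances: salt-bridge pair (Arg/Glu, minimum N–O distance),
hydrogen-bond pair (Ser OG ··· His NE2), His ring stack (centroid
distance), Arg/His cation–π pair, and an n-membered His cluster with
ring centroids on a regular polygon of chosen side length. The requested
distance is realized by axial translation with iterative correction and
verified on the emitted structure to 0.01 Å (0.02 Å for clusters);
requests below 1.5 Å are rejected as steric overlap. Fixtures are written
as genuine PDB text and re-read through the public parser, so tests
exercise the real I/O path. Random peptides are seedable with
ionizable-rich/-free composition controls.

What the fixtures do *not* emulate: realistic backbone connectivity,
packing density, solvent exposure, and environment-shifted pKas. Passing
the synthetic suites demonstrates that the charge mathematics, state
logic, detectors and clustering are correct as specified; it does not by
itself validate agreement with any particular empirical predictor's
output on real proteins, which additionally depends on predictor version
and threshold choices.

## Problem sizes and numerical choices

The randomized oracle comparisons use 100 structures of 8 posed residues
(≤ 200 atoms each) — large enough to produce every bond class and
multi-component patch graphs, small enough that the brute-force references
stay exact and fast. The shift interval rule is checked on a 0.1-unit pKa
grid. Distances are reported to 0.001 Å; charge computations are exact to
double precision (validated at 1e−12 against the analytic formula).
Degenerate inputs are errors with actionable messages: empty sequences,
pH outside (0, 14], structures without standard residues, equal pH pairs
for shift detection, mismatched geometry parameters in the delta.

## Known limitations

Single static structure: no pH-dependent conformational dynamics (that
requires constant-pH molecular dynamics). Discrete states cannot express
partial protonation near the pKa; the half-open interval rule makes the
boundary behaviour explicit instead. Group-level donor/acceptor modelling
ignores tautomer choice. No water-mediated bonds, metal coordination or
halogen bonds. mmCIF input is not supported (PDB format only).
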