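# phdelta

pH regulates protein behaviour by changing the protonation state — and
therefore the charge — of individual residues, which can make or break
intramolecular noncovalent bonds and rearrange structure. `phdelta` is a
library and command-line tool for analysing that sensitivity between **two
user-chosen pH values**, at two levels:

* **Sequence mode.** For each residue the fractional side-chain charge at
  pH follows the Henderson–Hasselbalch relation: an acidic group carries
  `q = −1 / (1 + 10^(pKa − pH))` and a basic group
  `q = +1 / (1 + 10^(pH − pKa))`. Profiles at a reference pH and a pH of
  interest give per-residue charge deltas, and a per-protein
  **overall charge score**

  `score = (Σᵢ qᵢ(pH_int) − Σᵢ qᵢ(pH_ref)) / N`

  (summed residue charges at the two pH values, normalized by chain length
  N). Scanning the score over unit pH steps from 1 to 14 and averaging
  ranks whole sequence collections by pH responsiveness.

* **Structure mode.** Per-residue pKas come from a pluggable provider: a
  fixed model-pKa table, an archived output file of the PROPKA empirical
  predictor, or a wrapped run of that predictor (structure-aware pKas
  capture the micro-environment shifts the sequence model cannot). Discrete
  protonation states are assigned at each pH (protonated iff pH < pKa),
  then four classes of noncovalent bonds are detected under each state —
  salt bridges, hydrogen bonds, π–π and cation–π interactions — and
  compared: bonds present at only one pH form the **created/destroyed
  delta**. Residues that change protonation state and lie within a
  clustering radius of one another (default 8 Å, minimum side-chain
  heavy-atom distance) form **pH-sensitive patches**: spatially contiguous
  switchable regions that are stronger functional candidates than isolated
  residues.

Intended users: structural biologists and protein engineers triaging
candidate pH-sensor residues before mutagenesis, and anyone needing
scriptable charge-vs-pH profiling of many sequences.

## Worked example

An arginine/glutamate pair posed at 3.0 Å salt-bridge distance
(`examples/structure_delta.py`):

```text
pH 7: [('salt_bridge', 'A:2', 'A:10')]
pH 2: [('hydrogen_bond', 'A:2', 'A:10'), ('hydrogen_bond', 'A:2', 'A:10')]

destroyed going to pH 2: [('salt_bridge', 'NH1', 'OE1', 3.0)]
created going to pH 2:   [('hydrogen_bond', 'NH1', 'OE1'), ('hydrogen_bond', 'NH1', 'OE2')]
```

At pH 7 both side chains are charged and the guanidinium–carboxylate
bridge is detected; at pH 2 (below the Glu pKa of 4.5) the carboxylate is
neutral, so the ionic bond is gone and only neutral hydrogen-bond contacts
remain between the same atoms. The delta view lists exactly that exchange.

Patch detection on three histidines with ring centroids 6 Å apart
(`examples/patch_detection.py`) reports, for the pH pair 5.5/7.5:

```text
patch 1: size 3, members ['A:2', 'A:10', 'A:18']
```

all three imidazoles titrate between the two pH values (pKa 6.5) and
connect within the 8 Å radius — one pH-sensitive patch of size 3.

Other examples: `charge_profile.py` (per-residue charges),
`ph_scan_ranking.py` (collection ranking), `predictor_pka_file.py`
(archived predictor output changes the verdict).

## Command line

```bash
phdelta seq    --fasta proteins.fasta --ph-ref 7 --ph-int 5 --scan 1:14
phdelta struct --pdb structure.pdb --ph-ref 8 --ph-int 4 --chains A,B \
               --pka-source file --pka-file structure.pka --radius 8
phdelta show-defaults
```

Structure mode writes the shift report, per-pH interaction tables, the
created/destroyed delta, the patch table, JSON mirrors and a PyMOL script
colouring shifting residues yellow, bond-changing residues orange and
patch members green. For predicted models, `--predicted --plddt-trim 70`
removes low-confidence residues (B-factor column read as pLDDT) with
`--keep-range CHAIN:START-END` exemptions.

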