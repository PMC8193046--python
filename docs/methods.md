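# Methods note

This document records the model behind `capa-screen`, the assumptions and
parameters it fixes, and its limitations. Domain background is in the
README; this note is about *how* the methodology is encoded.

## 1. Molecular identity and aromaticity

* Structures are parsed once with RDKit's default sanitization; the
  resulting aromaticity perception is used by every downstream match. Under
  this model 2-pyridone/pyrimidinone rings are aromatic, which is what the
  thienopyrimidinone-containing candidate (compound 18) requires to match
  its scaffold pattern.
* A compound's identity key is its canonical SMILES **after removal of all
  stereo descriptors** (tetrahedral and double-bond). Stereoisomers
  therefore collapse in deduplication; tautomers, salts and protonation
  states do **not** — the method targets neutral, desalted screening
  libraries, and only stereo redundancy is removed before pattern matching.
* Match counts are symmetry-deduplicated distinct atom sets
  (`GetSubstructMatches(uniquify=True)` plus a frozenset pass), so benzene
  contains one phenyl embedding, not twelve. The cascade itself only
  consumes presence/absence.

## 2. SMARTS semantics of the pattern registry

Fragment *names* do not define queries, so the registry fixes one
documented semantics (each entry ships with an exemplar and a
counter-exemplar; `capa registry --validate` checks all 82):

* **Rings** match as rings permitting substitution and fusion; aromatic
  queries require aromatic atoms, saturated queries aliphatic atoms.
  Positional isomers are strict: pyridine never matches pyrimidine,
  isoxazole never matches oxazole, 1,2,4- and 1,3,4-oxadiazole are
  distinct.
* **Terminal groups** require their full terminal-atom complement:
  isopropyl is `[CX4;H1]([CH3])([CH3])[!#1]`, tert-butyl needs all three
  methyls, amino is a genuine primary amine (amides and sulfonamides
  excluded).
* **Methoxyphenyl series** (clear negatives 2-/3-methoxyphenyl,
  2,5-/3,5-dimethoxyphenyl vs clear positive 3,4,5-trimethoxyphenyl):
  unnamed ring positions carry explicit `[cH]`, so a trimethoxyphenyl does
  not trip the dimethoxyphenyl negatives.
* **Cyclohexyl/cyclopropyl** negatives are isolated monosubstituted
  carbocycles (`[CX4;H1;R1]` ring atom + `[CH2;R1]` rest); a
  1,4-disubstituted cyclohexane linker (compound 17) is deliberately not
  excluded. "Anellated" cyclopropyl/cycloheptyl mean carbocycles fused to
  another ring (two shared `R2` atoms).
* Cross-role name collisions are allowed (pyrrolidine and oxazole appear as
  both clear negative and potential positive) but must share one SMARTS;
  within a role names are unique. The default overrule set
  {pyrrolidine, oxazole} suspends exactly those negatives.
* The fused scaffold for compound 18's series is encoded with
  thieno[2,3-d]pyrimidine ring topology (sulfur adjacent to the fusion
  bond, matching the printed candidate SMILES) under the library's
  historical name "thieno[2,3-b]pyrimidine".

## 3. Derivation generators

* Rings are compared as element/aromaticity sequences canonicalized up to
  rotation and reflection (`RingSpec`), so 1,2- and 2,1-placements
  coincide.
* *Fragmentation* uses SSSR rings of each basic scaffold, keeps fully
  aromatic rings with ≥ 1 N/O/S, and discards carbocycles.
* *Heterocyclic hopping* accepts saturated six/seven-ring parents with one
  or two N/O heteroatoms, produces sizes parent ± 1 clipped to [5, 7],
  conserves the heteroatom multiset, and maps 1,4-placement to 1,3 on
  contraction to a five-ring (a 1,4 placement does not exist there).
* *Heteroaromatic hopping* accepts aromatic five-ring parents with three
  heteroatoms and enumerates aromatic five-rings over non-empty
  sub-multisets (size 1–2) in 1,2-/1,3-placement.
* The published target sets are **curated**, not exhaustive: the raw
  enumeration also yields e.g. homo-piperazine (already a secondary
  positive) and isothiazole (never adopted). The generators therefore apply
  the published sets as allowlists by default and expose `raw=True` for the
  unfiltered enumeration.

## 4. Activity classification

* Activity threshold: IC50 **strictly below 10 µM** per target (default,
  configurable). Classes 0–7 encode the inhibited subset; the mapping fixes
  {ABCB1, ABCC1} → 4, {ABCB1, ABCG2} → 5, {ABCC1, ABCG2} → 6.
* Right-censored values ("> X µM"): inactive when X ≥ threshold; X below
  the threshold cannot resolve activity and is a data error, never a silent
  default.
* Missing measurements count as inactive but mark the label *provisional*;
  a record with no measurement at all is unclassifiable.
* Flag rules for curating putative positives (defaults: class-7 fraction
  ≥ 0.5 with pooled other-class fraction < 0.1 → positive; class-7 fraction
  < 0.1 or other-class fraction ≥ 0.5 → rejected) are validated for mutual
  exclusivity; the "other" fraction pools classes 0–6 by compound, not by
  class average.

## 5. Pharmacophore surrogate

The two five-feature models are published without 3D coordinates, so the
package implements a **topological counting surrogate**, not geometry:

* Feature groups: maximal fused aromatic ring systems (all-carbon systems
  are dual-typed {aromatic, hydrophobic}; heteroaromatic systems
  {aromatic}); connected non-ring aliphatic carbon clusters bonded only to
  C/H/halogen, qualifying as hydrophobic at ≥ 3 carbons or with a halogen;
  acceptor atoms (non-aromatic O; pyridine-type aromatic N; aliphatic
  amine N excluding amide/sulfonamide, anilinic, quaternary and cationic
  nitrogens).
* Models as slot lists: multitarget = 4 × {aromatic, hydrophobic} +
  1 × {acceptor}; ABCC1 = 1 × {aromatic} + 2 × {aromatic, hydrophobic} +
  1 × {hydrophobic} + 1 × {acceptor}.
* Coverage = maximum bipartite matching between groups and slots (each
  group fills at most one slot); verified in tests against a brute-force
  assignment oracle.
* A fused system counts as **one** aromatic group; feature *counts* in
  `FeatureProfile` tally each group once under its primary kind (benzene →
  1 aromatic, 0 hydrophobic), while slot coverage uses the full type sets.

## 6. Synthetic fixtures

Seeded libraries are assembled from decoy scaffolds (benzene, pyridazine —
rings matching no screening-relevant pattern) with planted fragments, each
realizing exactly one named pattern. Default parameters (150 records,
28 stereo-duplicate pairs ≈ the original campaign's duplication rate,
negative-violation rate 0.31 ≈ its exclusion rate, ~10 % class-7 profiles)
are fixed study conditions, not tuned values. Every record is self-checked
after assembly: its match set over the positive screen plus clear negatives
must equal the planted set exactly (bounded retries), which is what lets
tests demand *exact* ground-truth recovery of all cascade statistics.

## 7. Limitations

* The original screening deck is not deposited: the published cascade
  counts (1,510 → 1,229 → 846), hit-count histogram and hit rates cannot be
  reproduced and are covered by property-based substitutes only.
* SMARTS semantics beyond the shipped exemplar pairs are this
  implementation's documented choices; the original work used a commercial
  modelling suite whose exact queries are unpublished.
* The pharmacophore surrogate is purely topological: it cannot reject
  compounds whose features exist but cannot be arranged geometrically, and
  the acceptor typing of the original software is unknown.
* Strict positional-isomer matching leaves one published attribution
  unasserted: the pyridine→compound 23 assignment (whose ring is a
  pyrimidine under strict matching) is treated as an open question.
* Tautomers are not canonicalized; patterns match the input tautomer as
  drawn after RDKit sanitization.
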