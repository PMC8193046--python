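# capa-screen

Substructure-pattern virtual screening for multitarget ABC transporter
inhibitors, implementing the **computer-aided pattern analysis (C@PA)**
methodology, revision 1.2.

## Background

The three ATP-binding cassette (ABC) transporters ABCB1 (P-glycoprotein),
ABCC1 (MRP1) and ABCG2 (BCRP) export chemotherapeutics from tumor cells and
jointly cause multidrug resistance. Compounds that inhibit **all three**
transporters ("pan-ABC" or class 7 inhibitors) are rare, and classical
similarity-based virtual screening finds few of them.

C@PA takes a pattern-centric route instead. From a large annotated training
set it distills a library of **named substructure patterns** with roles:

| role | count | meaning |
|---|---|---|
| clear positive | 8 | enriched in pan-inhibitors (e.g. morpholine, isopropyl, 3,4,5-trimethoxyphenyl) |
| clear negative | 32 | depleted in pan-inhibitors; any match excludes a compound (e.g. nitro, tert-butyl, carboxylic acid) |
| secondary positive | 5 | found in the multitarget hits C@PA itself discovered (1,2,4-oxadiazole, 1,3,4-thiadiazole, piperazine, homo-piperazine, piperidine) |
| potential positive | 15 | rings *deduced* from the parents by fragmentation and substructure hopping |
| basic scaffold | 6 | fused ring systems of the most potent known pan-inhibitors; fragmentation inputs |
| rejected putative positive | 16 | present in pan-inhibitors but too ubiquitous elsewhere |

Secondary plus potential positives are the 20 **extended positive hits**;
with the clear positives they form the 28-pattern positive screen.

The 15 potential positives are not hand-picked: they are generated by three
operations on the library itself —

1. **Scaffold fragmentation** — dissect the 6 basic scaffolds into their
   monocyclic heteroaromatic rings → {pyrimidine, pyrrole, pyridine,
   thiophene};
2. **Heterocyclic substructure hopping** — expand/contract saturated
   six/seven-ring parents by one atom, conserving the heteroatom multiset →
   {pyrrolidine, imidazolidine, oxazolidine, homo-piperidine,
   homo-morpholine};
3. **Heteroaromatic substructure hopping** — enumerate aromatic five-rings
   whose heteroatoms are a sub-multiset of a three-heteroatom parent →
   {furan, thiophene, pyrazole, imidazole, oxazole, isoxazole, thiazole};

compiled with deduplication (thiophene arises twice): 4 + 5 + 7 − 1 = **15**.

Two of the deduced rings — **pyrrolidine** and **oxazole** — are
simultaneously clear negatives. C@PA resolves the collision by
**overruling**: their clear-negative status is suspended in the screening
cascade.

### The screening cascade

```
input library
  │  stereoisomer deduplication (stereo-agnostic canonical identity)
  ▼
unique compounds
  │  clear-negative exclusion (32 patterns, minus overrules)
  ▼
survivors
  │  positive hit profiling (28 patterns, distinct named hits per compound)
  ▼
candidates ranked by distinct positive-hit count
```

In the original campaign this cascade reduced a ~1,500-compound preselection
to hundreds of profiled survivors and ultimately ten purchased candidates,
**all ten** of which inhibited at least one transporter in vitro — those ten
compounds ship with this package as a fixture.

Two further components close the loop:

* **Activity classification** — per-target IC50 values (strictly below
  10 µM = active) map each compound to class 0–7 encoding the inhibited
  subset ({} → 0 … {ABCB1, ABCC1, ABCG2} → 7), with right-censored
  ("> X µM") and missing measurements handled explicitly.
  Pattern-per-class occurrence tables and promiscuity flag rules support
  curating putative positives into clear positives or rejects.
* **Pharmacophore surrogate** — a topological stand-in for the two
  five-feature 3D models (the multitarget model and an ABCC1-selective
  model): compounds are decomposed into typed feature groups (aromatic ring
  systems, hydrophobic clusters, acceptor atoms) and checked against a
  model's slots by maximum bipartite matching.

## Worked example

Screen the ten packaged candidate compounds:

```
$ capa fixtures --paper --out cands.csv
wrote 10 candidate rows to cands.csv
$ capa screen cands.csv --out-tsv cands_ranked.tsv
library_version: capa-1.2
n_input: 10
n_unique: 10
n_removed_stereo: 0
n_passed_negative: 10
n_rejected_negative: 0
n_candidates: 10
histogram: {'0': 0, '1': 1, '2': 3, '3': 2, '4': 3, '5': 1}
$ tail -n +2 cands_ranked.tsv
id	hit_count	positive_hits
18	5	homo-piperidine;piperazine;pyrimidine;thieno[2,3-b]pyrimidine;thiophene
19	4	1,3,4-thiadiazole;piperazine;pyrrole;pyrrolidine
21	4	1,3,4-thiadiazole;piperazine;pyrrole;pyrrolidine
24	4	piperidine;pyrazole;pyridine;pyrimidine
22	3	morpholine;pyrazole;pyridine
23	3	imidazole;piperazine;pyrimidine
16	2	isoxazole;pyrrolidine
20	2	morpholine;pyridine
25	2	isoxazole;piperidine
17	1	imidazole
```

All ten pass the negative filter (compounds 16 and 19/21 only because
pyrrolidine is overruled) and every one carries at least one positive hit.

Compound 23 — the candidate followed up with full dose–response
measurements (IC50 4.01 µM ABCB1, 14.8 µM ABCC1, 9.27 µM ABCG2) — classifies
as a dual inhibitor and presents all five features of both pharmacophore
models:

```
$ printf 'id,abcb1_ic50_um,abcc1_ic50_um,abcg2_ic50_um\n23,4.01,14.8,9.27\n' > act.csv
$ capa classify act.csv
23: class 5 {ABCB1, ABCG2}
$ printf 'CC1=NC(N2C=CN=C2)=CC(N3CCN(C(C(C4=CC=CC=C4)C5=CC=CC=C5)=O)CC3)=N1 23\n' > c23.smi
$ capa features c23.smi
23: aromatic=4 hydrophobic=0 acceptor=4 abcc1=5/5 multitarget=5/5
```

The same workflows are available from Python:

```python
from capa import default_library, run_screen, derive_default

lib = default_library()
report = run_screen([("CCN1CCN(CC1)c1ccncc1", "demo")], library=lib)
print(report.candidates[0].positive_hits)   # frozenset({'piperazine', 'pyridine'})
print(sorted(p.name for p in derive_default(lib)))  # the 15 deduced rings
```

Other subcommands: `capa registry --validate` (role counts + exemplar
self-test), `capa derive` (re-run the derivation), `capa fixtures
--synthetic --seed S --n N --out prefix` (seeded library with planted
ground truth for testing).

## Reproduction

* **Test suite** (~3 s, one CPU):

  ```
  python -m pytest -q tests/
  ```

  `tests/test_acceptance.py` pins the externally established numbers: the
  registry cardinalities (8/32/5/15/20/6/16, 28-pattern positive screen),
  the three-generator derivation compiling to exactly the 15 potential
  positives, the ten candidates passing the cascade with the published
  per-compound attributions, the 4.01/14.8/9.27 µM profile classifying as
  class 5 (not 7), and compound 23 filling 5/5 slots of both models. The
  original large-library statistics (1,510 → 1,229 → 846 cascade counts,
  hit-count distribution, hit rates) depend on an undeposited screening
  deck and are **not** reproducible here; they are substituted by
  property-based checks on seeded synthetic libraries whose planted ground
  truth must be recovered exactly.

* **Acceptance targets**:

  ```
  python scripts/acceptance.py --seed 1 --out results/acceptance.json
  ```

  writes `{"t1": {"value": 15, ...}, "t6": {"value": 10, ...}, "t7":
  {"value": 10, ...}}` — the derivation count and the candidate pass/hit
  counts, computed from scratch.

See `docs/methods.md` for the modelling decisions, encoded SMARTS
conventions, and limitations.
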