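"""Deriving potential positive hits by fragmentation and substructure hopping.

Three generators extend the positive pattern fingerprints:

* **Scaffold fragmentation** dissects the fused basic scaffolds into their
  constituent monocyclic aromatic rings and keeps the heteroaromatic ones
  (pure carbocycles such as benzene carry no pattern information and are
  discarded).
* **Heterocyclic substructure hopping** expands or contracts a saturated
  six- or seven-membered parent ring by one atom while conserving its
  heteroatom multiset; parents with 1,4-heteroatom placement contract to the
  1,3-placed five-ring (a 1,4 placement does not exist in a five-ring).
* **Heteroaromatic substructure hopping** derives aromatic five-rings whose
  heteroatom multiset is a non-empty sub-multiset (one or two atoms) of a
  three-heteroatom aromatic parent, in 1,2- or 1,3-placement.

The published derivation is curated rather than exhaustive (for instance
isothiazole is a legitimate enumerant from 1,3,4-thiadiazole but was not
adopted), so each hopping generator runs the raw enumeration and then
applies the curated target set as an allowlist; ``raw=True`` exposes the
unfiltered enumeration for exploratory work.

Rings are compared as :class:`RingSpec` values - element/aromaticity
sequences read around the ring, canonicalized up to rotation and
reflection - so that "1,2-" and "2,1-" placements collapse to one ring.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from rdkit import Chem

from .patterns import (
    ROLE_CLEAR_NEGATIVE,
    ROLE_POTENTIAL_POSITIVE,
    PatternLibrary,
    SubstructurePattern,
    load_example_pairs,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Ring specification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RingSpec:
    """An element/aromaticity sequence read around a simple ring.

    Two specs are equal iff their sequences coincide up to rotation and
    reflection; ``atoms`` is stored in that canonical form.
    """

    atoms: tuple[tuple[str, bool], ...]

    def __post_init__(self):
        if not 3 <= len(self.atoms) <= 8:
            raise ValueError(f"ring size {len(self.atoms)} outside [3, 8]")
        object.__setattr__(self, "atoms", _canonical_cycle(self.atoms))

    @property
    def size(self) -> int:
        return len(self.atoms)

    @property
    def aromatic(self) -> bool:
        return all(arom for _, arom in self.atoms)

    def heteroatom_multiset(self) -> tuple[str, ...]:
        return tuple(sorted(sym for sym, _ in self.atoms if sym != "C"))


def _canonical_cycle(
    atoms: Sequence[tuple[str, bool]],
) -> tuple[tuple[str, bool], ...]:
    seq = tuple(atoms)
    n = len(seq)
    variants = []
    for s in (seq, seq[::-1]):
        for i in range(n):
            variants.append(s[i:] + s[:i])
    return min(variants)


def ring_spec_from_mol_ring(mol: Chem.Mol, ring_atoms: Sequence[int]) -> RingSpec:
    """Build a :class:`RingSpec` from a ring's atom indices (in ring order)."""
    atoms = tuple(
        (mol.GetAtomWithIdx(i).GetSymbol(), mol.GetAtomWithIdx(i).GetIsAromatic())
        for i in ring_atoms
    )
    return RingSpec(atoms)


def _placed_spec(size: int, hetero: Sequence[str], positions: Sequence[int], aromatic: bool) -> RingSpec:
    atoms = [("C", aromatic)] * size
    for sym, pos in zip(hetero, positions):
        atoms[pos] = (sym, aromatic)
    return RingSpec(tuple(atoms))


# ---------------------------------------------------------------------------
# Named monocycles
#
# SMILES give the parent ring (used for structure-based operations and as a
# fixture source); SMARTS give the library matching query (substitution and
# fusion permitted, aromaticity class strict).
# ---------------------------------------------------------------------------

NAMED_RINGS: dict[str, dict[str, str]] = {
    # aromatic six-rings
    "benzene": {"smiles": "c1ccccc1", "smarts": "c1ccccc1"},
    "pyridine": {"smiles": "c1ccncc1", "smarts": "c1ccncc1"},
    "pyridazine": {"smiles": "c1ccnnc1", "smarts": "c1ccnnc1"},
    "pyrimidine": {"smiles": "c1cncnc1", "smarts": "c1cncnc1"},
    "pyrazine": {"smiles": "c1cnccn1", "smarts": "c1cnccn1"},
    # aromatic five-rings
    "pyrrole": {"smiles": "c1cc[nH]c1", "smarts": "c1ccnc1"},
    "furan": {"smiles": "c1ccoc1", "smarts": "c1ccoc1"},
    "thiophene": {"smiles": "c1ccsc1", "smarts": "c1ccsc1"},
    "imidazole": {"smiles": "c1c[nH]cn1", "smarts": "c1ncnc1"},
    "pyrazole": {"smiles": "c1cc[nH]n1", "smarts": "c1ccnn1"},
    "oxazole": {"smiles": "c1ocnc1", "smarts": "o1cncc1"},
    "isoxazole": {"smiles": "c1cnoc1", "smarts": "o1nccc1"},
    "thiazole": {"smiles": "c1cscn1", "smarts": "s1cncc1"},
    "isothiazole": {"smiles": "c1csnc1", "smarts": "s1nccc1"},
    "1,2,4-oxadiazole": {"smiles": "c1nocn1", "smarts": "o1ncnc1"},
    "1,3,4-oxadiazole": {"smiles": "c1nnco1", "smarts": "o1cnnc1"},
    "1,3,4-thiadiazole": {"smiles": "c1nncs1", "smarts": "s1cnnc1"},
    "1,2,4-thiadiazole": {"smiles": "c1nscn1", "smarts": "s1ncnc1"},
    # saturated five-rings
    "pyrrolidine": {"smiles": "C1CCNC1", "smarts": "N1CCCC1"},
    "pyrazolidine": {"smiles": "C1CNNC1", "smarts": "N1NCCC1"},
    "imidazolidine": {"smiles": "C1CNCN1", "smarts": "N1CNCC1"},
    "oxazolidine": {"smiles": "C1CNCO1", "smarts": "O1CNCC1"},
    "isoxazolidine": {"smiles": "C1CNOC1", "smarts": "O1NCCC1"},
    "oxolane": {"smiles": "C1CCOC1", "smarts": "C1CCOC1"},
    # saturated six-rings
    "piperidine": {"smiles": "C1CCNCC1", "smarts": "N1CCCCC1"},
    "piperazine": {"smiles": "C1CNCCN1", "smarts": "N1CCNCC1"},
    "morpholine": {"smiles": "C1COCCN1", "smarts": "O1CCNCC1"},
    "hexahydropyrimidine": {"smiles": "C1CNCNC1", "smarts": "N1CNCCC1"},
    "1,3-oxazinane": {"smiles": "C1CNCOC1", "smarts": "O1CNCCC1"},
    "oxane": {"smiles": "C1CCOCC1", "smarts": "O1CCCCC1"},
    # saturated seven-rings ("homo" ring-expanded variants)
    "homo-piperidine": {"smiles": "C1CCCNCC1", "smarts": "N1CCCCCC1"},
    "homo-piperazine": {"smiles": "C1CNCCNC1", "smarts": "N1CCNCCC1"},
    "homo-morpholine": {"smiles": "C1CNCCOC1", "smarts": "O1CCNCCC1"},
}

_SPEC_TO_NAME: dict[RingSpec, str] = {}


def _ring_spec_of_named(name: str) -> RingSpec:
    mol = Chem.MolFromSmiles(NAMED_RINGS[name]["smiles"])
    ring = mol.GetRingInfo().AtomRings()[0]
    return ring_spec_from_mol_ring(mol, ring)


def ring_name(spec: RingSpec) -> str | None:
    """Common name for a monocycle spec, or None if not in the table."""
    if not _SPEC_TO_NAME:
        for name in NAMED_RINGS:
            _SPEC_TO_NAME[_ring_spec_of_named(name)] = name
    return _SPEC_TO_NAME.get(spec)


def _pattern_for_ring(name: str, provenance: str) -> SubstructurePattern:
    return SubstructurePattern(
        name=name,
        smarts=NAMED_RINGS[name]["smarts"],
        role=ROLE_POTENTIAL_POSITIVE,
        provenance=provenance,
    )


def _unnamed_pattern(spec: RingSpec, provenance: str) -> SubstructurePattern:
    # systematic fall-back for raw enumerants outside the common-name table:
    # the query is the ring written atom-by-atom
    symbols = [
        (sym.lower() if arom else sym.upper()) for sym, arom in spec.atoms
    ]
    smarts = f"{symbols[0]}1" + "".join(symbols[1:]) + "1"
    return SubstructurePattern(
        name=f"ring:{smarts}",
        smarts=smarts,
        role=ROLE_POTENTIAL_POSITIVE,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Structure access for patterns
# ---------------------------------------------------------------------------


def _structure_of(pattern: SubstructurePattern) -> Chem.Mol:
    """A concrete molecule realizing a pattern.

    Ring SMARTS in this registry double as valid SMILES; composite queries
    (e.g. 4-anilinopyrimidine) fall back to the pattern's shipped exemplar.
    """
    mol = Chem.MolFromSmiles(pattern.smarts)
    if mol is not None:
        return mol
    pairs = load_example_pairs()
    if pattern.name in pairs:
        mol = Chem.MolFromSmiles(pairs[pattern.name][0])
        if mol is not None:
            return mol
    raise ValueError(f"no parseable structure for pattern {pattern.name!r}")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

FRAGMENTATION_PROVENANCE = "scaffold fragmentation of the basic scaffolds"
HETEROCYCLIC_PROVENANCE = "heterocyclic substructure hopping"
HETEROAROMATIC_PROVENANCE = "heteroaromatic substructure hopping"

#: curated target set of the heterocyclic hop
HETEROCYCLIC_TARGETS = frozenset(
    {"imidazolidine", "homo-piperidine", "pyrrolidine", "homo-morpholine", "oxazolidine"}
)
#: curated target set of the heteroaromatic hop
HETEROAROMATIC_TARGETS = frozenset(
    {"isoxazole", "oxazole", "imidazole", "furan", "thiazole", "pyrazole", "thiophene"}
)


def fragment_scaffolds(
    scaffolds: Iterable[SubstructurePattern],
) -> set[SubstructurePattern]:
    """Split fused scaffolds into their monocyclic heteroaromatic rings.

    Every simple (SSSR) ring of each scaffold that is fully aromatic and
    contains at least one N/O/S contributes one potential-positive ring
    pattern; exocyclic substituents are stripped and pure carbocycles are
    discarded.  Acyclic inputs contribute nothing (logged).
    """
    out: dict[str, SubstructurePattern] = {}
    for scaffold in scaffolds:
        mol = _structure_of(scaffold)
        rings = mol.GetRingInfo().AtomRings()
        if not rings:
            logger.warning("scaffold %s is acyclic; skipped", scaffold.name)
            continue
        for ring in rings:
            spec = ring_spec_from_mol_ring(mol, ring)
            if not spec.aromatic or not spec.heteroatom_multiset():
                continue
            name = ring_name(spec)
            pattern = (
                _pattern_for_ring(name, FRAGMENTATION_PROVENANCE)
                if name is not None
                else _unnamed_pattern(spec, FRAGMENTATION_PROVENANCE)
            )
            out.setdefault(pattern.name, pattern)
    return set(out.values())


def _parent_monocycle(pattern: SubstructurePattern) -> RingSpec:
    mol = _structure_of(pattern)
    rings = mol.GetRingInfo().AtomRings()
    if len(rings) != 1:
        raise ValueError(f"parent {pattern.name!r} is not a monocycle")
    return ring_spec_from_mol_ring(mol, rings[0])


def hop_heterocycle(
    parents: Iterable[SubstructurePattern], raw: bool = False
) -> set[SubstructurePattern]:
    """Ring expansion/contraction of saturated six/seven-ring parents.

    Candidate rings have size parent +/- 1 clipped to [5, 7] and conserve the
    parent's heteroatom multiset.  Two-heteroatom parents keep their atom
    separation on expansion; on contraction to a five-ring the 1,4 placement
    becomes 1,3.  Unless ``raw``, the result is intersected with the curated
    target set.
    """
    specs: set[RingSpec] = set()
    for parent in parents:
        try:
            spec = _parent_monocycle(parent)
        except ValueError as exc:
            logger.warning("hop_heterocycle: %s; skipped", exc)
            continue
        hetero = spec.heteroatom_multiset()
        if spec.aromatic or spec.size not in (6, 7) or not 1 <= len(hetero) <= 2:
            logger.warning(
                "hop_heterocycle: parent %s outside supported size/composition; skipped",
                parent.name,
            )
            continue
        positions = sorted(
            i for i, (sym, _) in enumerate(spec.atoms) if sym != "C"
        )
        sep = None
        if len(hetero) == 2:
            d = positions[1] - positions[0]
            sep = min(d, spec.size - d)
        for new_size in {spec.size - 1, spec.size + 1} & {5, 6, 7}:
            if len(hetero) == 1:
                specs.add(_placed_spec(new_size, hetero, [0], aromatic=False))
            else:
                new_sep = sep if new_size > spec.size else min(sep, 2)
                specs.add(
                    _placed_spec(new_size, hetero, [0, new_sep], aromatic=False)
                )
    return _named_set(specs, HETEROCYCLIC_PROVENANCE, None if raw else HETEROCYCLIC_TARGETS)


def hop_heteroaromatic(
    parents: Iterable[SubstructurePattern], raw: bool = False
) -> set[SubstructurePattern]:
    """Aromatic five-ring deduction from three-heteroatom aromatic parents.

    Enumerates aromatic five-rings whose heteroatoms form a non-empty
    sub-multiset (size 1-2) of the parent's, placed 1,2 or 1,3.  Unless
    ``raw``, the result is intersected with the curated target set.
    """
    specs: set[RingSpec] = set()
    for parent in parents:
        try:
            spec = _parent_monocycle(parent)
        except ValueError as exc:
            logger.warning("hop_heteroaromatic: %s; skipped", exc)
            continue
        hetero = spec.heteroatom_multiset()
        if not spec.aromatic or spec.size != 5 or len(hetero) != 3:
            logger.warning(
                "hop_heteroaromatic: parent %s outside supported composition; skipped",
                parent.name,
            )
            continue
        singles = sorted(set(hetero))
        pairs = sorted(
            {
                tuple(sorted((a, b)))
                for i, a in enumerate(hetero)
                for b in hetero[i + 1 :]
            }
        )
        for sym in singles:
            specs.add(_placed_spec(5, [sym], [0], aromatic=True))
        for pair in pairs:
            for sep in (1, 2):  # 1,2- and 1,3-placement
                specs.add(_placed_spec(5, pair, [0, sep], aromatic=True))
                if pair[0] != pair[1]:
                    specs.add(_placed_spec(5, pair[::-1], [0, sep], aromatic=True))
    return _named_set(
        specs, HETEROAROMATIC_PROVENANCE, None if raw else HETEROAROMATIC_TARGETS
    )


def _named_set(
    specs: set[RingSpec],
    provenance: str,
    allowlist: frozenset[str] | None,
) -> set[SubstructurePattern]:
    out: dict[str, SubstructurePattern] = {}
    for spec in specs:
        name = ring_name(spec)
        if allowlist is not None and (name is None or name not in allowlist):
            continue
        pattern = (
            _pattern_for_ring(name, provenance)
            if name is not None
            else _unnamed_pattern(spec, provenance)
        )
        out.setdefault(pattern.name, pattern)
    return set(out.values())


def compile_potential_positive(
    frag: set[SubstructurePattern],
    het: set[SubstructurePattern],
    arom: set[SubstructurePattern],
    lib: PatternLibrary,
) -> set[SubstructurePattern]:
    """Union of the three generator outputs, deduplicated by ring name.

    Rings produced by more than one route (thiophene arises from both
    fragmentation and the heteroaromatic hop) appear once.  Members whose
    name collides with a clear negative (pyrrolidine, oxazole) are retained
    and simultaneously registered in ``lib.overrules``.
    """
    out: dict[str, SubstructurePattern] = {}
    for pattern in sorted(frag | het | arom, key=lambda p: p.name):
        out.setdefault(pattern.name, pattern)
    negative_names = lib.names(ROLE_CLEAR_NEGATIVE)
    for name in out:
        if name in negative_names:
            lib.overrules.add(name)
            logger.info("potential positive %s overrules its clear-negative role", name)
    return set(out.values())


def derive_default(lib: PatternLibrary) -> set[SubstructurePattern]:
    """Run the full derivation with the default parents from ``lib``."""
    from .patterns import ROLE_BASIC_SCAFFOLD, ROLE_SECONDARY_POSITIVE

    scaffolds = lib.by_role(ROLE_BASIC_SCAFFOLD)
    secondary = {p.name: p for p in lib.by_role(ROLE_SECONDARY_POSITIVE)}
    clear = {p.name: p for p in lib.by_role("clear_positive")}
    het_parents = [
        secondary["piperazine"],
        secondary["homo-piperazine"],
        secondary["piperidine"],
        clear["morpholine"],
    ]
    arom_parents = [secondary["1,2,4-oxadiazole"], secondary["1,3,4-thiadiazole"]]
    frag = fragment_scaffolds(scaffolds)
    het = hop_heterocycle(het_parents)
    arom = hop_heteroaromatic(arom_parents)
    return compile_potential_positive(frag, het, arom, lib)
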