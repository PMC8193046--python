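"""Topological pharmacophore surrogate for the multitarget feature models.

The 3D pharmacophore models behind the pattern library reduce, in this
package, to a purely topological surrogate: a compound is decomposed into
*feature groups*, and a model is a list of *slots*, each accepting one or
more feature types.  A compound satisfies a slot assignment when a set of
distinct feature groups can be matched one-to-one onto the slots, each
group carrying a type accepted by its slot (maximum bipartite matching).

Feature groups and their types:

* **aromatic ring systems** - maximal fused systems of aromatic rings.  A
  system built entirely of carbon atoms is simultaneously a hydrophobic
  contact surface and carries ``{aromatic, hydrophobic}``; a system with
  ring heteroatoms carries ``{aromatic}`` only.
* **aliphatic clusters** - connected sets of non-ring aliphatic carbons
  bonded only to carbon, hydrogen or halogen; a cluster qualifies as a
  hydrophobic group when it spans at least three carbons or carries a
  halogen, and carries ``{hydrophobic}``.
* **acceptor atoms** - each hydrogen-bond acceptor atom is its own group
  with ``{acceptor}``: any oxygen that is not an aromatic ring member and
  not positively charged; aromatic nitrogens with two ring neighbours and
  no hydrogen (pyridine-type); non-aromatic trivalent nitrogens excluding
  amide/sulfonamide nitrogens, anilinic nitrogens and positively charged
  or quaternary nitrogens.

These rules are deliberately coarse - they are a counting surrogate, not a
geometric model - but they reproduce the feature coverage of the reference
inhibitors the models were validated on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from rdkit import Chem

from .chem import Molecule

AROMATIC = "aromatic"
HYDROPHOBIC = "hydrophobic"
ACCEPTOR = "acceptor"

FEATURE_TYPES = (AROMATIC, HYDROPHOBIC, ACCEPTOR)


@dataclass(frozen=True)
class FeatureGroup:
    """One pharmacophoric group of a compound.

    ``atoms`` are the member atom indices; ``types`` the feature types the
    group can serve as (a group fills at most one model slot).
    """

    kind: str
    atoms: tuple[int, ...]
    types: frozenset[str]

    def __post_init__(self):
        if not self.types <= set(FEATURE_TYPES):
            raise ValueError(f"unknown feature types {self.types - set(FEATURE_TYPES)}")


@dataclass(frozen=True)
class FeatureProfile:
    """Feature groups of a compound plus per-type tallies.

    The count attributes tally groups by *kind* (each group counted once,
    under its primary kind), while ``groups`` retains the full type sets
    used for slot coverage.
    """

    groups: tuple[FeatureGroup, ...]
    n_aromatic: int
    n_hydrophobic: int
    n_acceptor: int


# ---------------------------------------------------------------------------
# Feature perception
# ---------------------------------------------------------------------------

_HALOGENS = {9, 17, 35, 53}


def _aromatic_ring_systems(mol: Chem.Mol) -> list[tuple[int, ...]]:
    """Maximal fused systems of aromatic rings (union-find over shared atoms)."""
    rings = [
        set(r)
        for r in mol.GetRingInfo().AtomRings()
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in r)
    ]
    systems: list[set[int]] = []
    for ring in rings:
        merged = ring
        rest = []
        for sys_ in systems:
            if sys_ & merged:
                merged = merged | sys_
            else:
                rest.append(sys_)
        rest.append(merged)
        systems = rest
    return [tuple(sorted(s)) for s in systems]


def _aliphatic_clusters(mol: Chem.Mol) -> list[tuple[tuple[int, ...], bool]]:
    """Connected non-ring aliphatic carbon clusters; flag = carries halogen."""
    eligible = set()
    for atom in mol.GetAtoms():
        if (
            atom.GetAtomicNum() == 6
            and not atom.GetIsAromatic()
            and not atom.IsInRing()
            and all(
                n.GetAtomicNum() in _HALOGENS or n.GetAtomicNum() in (1, 6)
                for n in atom.GetNeighbors()
            )
        ):
            eligible.add(atom.GetIdx())
    clusters: list[tuple[tuple[int, ...], bool]] = []
    todo = set(eligible)
    while todo:
        seed = todo.pop()
        comp = {seed}
        stack = [seed]
        while stack:
            idx = stack.pop()
            for n in mol.GetAtomWithIdx(idx).GetNeighbors():
                j = n.GetIdx()
                if j in todo:
                    todo.discard(j)
                    comp.add(j)
                    stack.append(j)
        has_halogen = any(
            n.GetAtomicNum() in _HALOGENS
            for i in comp
            for n in mol.GetAtomWithIdx(i).GetNeighbors()
        )
        clusters.append((tuple(sorted(comp)), has_halogen))
    return clusters


def _is_acceptor(atom: Chem.Atom) -> bool:
    z = atom.GetAtomicNum()
    if atom.GetFormalCharge() > 0:
        return False
    if z == 8:
        return not atom.GetIsAromatic()
    if z != 7:
        return False
    if atom.GetIsAromatic():
        # pyridine-type: two ring neighbours, no hydrogen, no exocyclic bond
        return atom.GetDegree() == 2 and atom.GetTotalNumHs() == 0
    if atom.GetDegree() + atom.GetTotalNumHs() > 3:
        return False  # quaternary
    for n in atom.GetNeighbors():
        if n.GetIsAromatic():
            return False  # anilinic: lone pair delocalized into the ring
        if n.GetAtomicNum() == 6 and any(
            b.GetBondType() == Chem.BondType.DOUBLE
            and b.GetOtherAtom(n).GetAtomicNum() in (8, 16)
            for b in n.GetBonds()
        ):
            return False  # amide / thioamide nitrogen
        if n.GetAtomicNum() == 16 and any(
            b.GetBondType() == Chem.BondType.DOUBLE
            and b.GetOtherAtom(n).GetAtomicNum() == 8
            for b in n.GetBonds()
        ):
            return False  # sulfonamide nitrogen
    return True


def feature_profile(mol: Molecule) -> FeatureProfile:
    """Decompose ``mol`` into pharmacophoric feature groups."""
    rdmol = mol.rdmol
    groups: list[FeatureGroup] = []
    n_arom = n_hydro = n_acc = 0
    for system in _aromatic_ring_systems(rdmol):
        all_carbon = all(
            rdmol.GetAtomWithIdx(i).GetAtomicNum() == 6 for i in system
        )
        types = (
            frozenset({AROMATIC, HYDROPHOBIC}) if all_carbon else frozenset({AROMATIC})
        )
        groups.append(FeatureGroup("aromatic_system", system, types))
        n_arom += 1
    for atoms, has_halogen in _aliphatic_clusters(rdmol):
        if len(atoms) >= 3 or has_halogen:
            groups.append(
                FeatureGroup("aliphatic_cluster", atoms, frozenset({HYDROPHOBIC}))
            )
            n_hydro += 1
    for atom in rdmol.GetAtoms():
        if _is_acceptor(atom):
            groups.append(
                FeatureGroup("acceptor_atom", (atom.GetIdx(),), frozenset({ACCEPTOR}))
            )
            n_acc += 1
    return FeatureProfile(
        groups=tuple(groups),
        n_aromatic=n_arom,
        n_hydrophobic=n_hydro,
        n_acceptor=n_acc,
    )


# ---------------------------------------------------------------------------
# Models and coverage
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PharmacophoreModel:
    """A named list of slots, each a frozenset of accepted feature types."""

    name: str
    slots: tuple[frozenset[str], ...]

    def __post_init__(self):
        for slot in self.slots:
            if not slot or not slot <= set(FEATURE_TYPES):
                raise ValueError(f"invalid slot {set(slot)}")

    @property
    def n_slots(self) -> int:
        return len(self.slots)


#: multitarget model: F1-F4 aromatic/hydrophobic, F5 acceptor
MULTITARGET_MODEL = PharmacophoreModel(
    name="multitarget",
    slots=(
        frozenset({AROMATIC, HYDROPHOBIC}),
        frozenset({AROMATIC, HYDROPHOBIC}),
        frozenset({AROMATIC, HYDROPHOBIC}),
        frozenset({AROMATIC, HYDROPHOBIC}),
        frozenset({ACCEPTOR}),
    ),
)

#: ABCC1-selective model: F1 aromatic, F2/F3 aromatic/hydrophobic, F4 hydrophobic, F5 acceptor
ABCC1_MODEL = PharmacophoreModel(
    name="abcc1",
    slots=(
        frozenset({AROMATIC}),
        frozenset({AROMATIC, HYDROPHOBIC}),
        frozenset({AROMATIC, HYDROPHOBIC}),
        frozenset({HYDROPHOBIC}),
        frozenset({ACCEPTOR}),
    ),
)

MODELS = {m.name: m for m in (MULTITARGET_MODEL, ABCC1_MODEL)}


@dataclass(frozen=True)
class CoverageResult:
    """Slot coverage of a compound against one model.

    ``assignment`` maps covered slot indices to the index of the feature
    group (in the profile's ``groups``) filling them.
    """

    model: str
    covered: int
    total: int
    assignment: dict[int, int]

    @property
    def complete(self) -> bool:
        return self.covered == self.total


def coverage_check(
    profile: FeatureProfile, model: PharmacophoreModel
) -> CoverageResult:
    """Maximum number of model slots fillable by distinct feature groups.

    Computed as a maximum bipartite matching between slots and groups,
    where a group may fill a slot iff the slot accepts one of its types.
    """
    groups = profile.groups
    compatible: list[list[int]] = [
        [g for g, group in enumerate(groups) if group.types & slot]
        for slot in model.slots
    ]
    match_of_group: dict[int, int] = {}

    def try_assign(slot: int, seen: set[int]) -> bool:
        for g in compatible[slot]:
            if g in seen:
                continue
            seen.add(g)
            if g not in match_of_group or try_assign(match_of_group[g], seen):
                match_of_group[g] = slot
                return True
        return False

    for slot in range(len(model.slots)):
        try_assign(slot, set())
    assignment = {slot: g for g, slot in match_of_group.items()}
    return CoverageResult(
        model=model.name,
        covered=len(assignment),
        total=model.n_slots,
        assignment=assignment,
    )


def coverage_summary(
    mol: Molecule, models: Sequence[PharmacophoreModel] = (MULTITARGET_MODEL, ABCC1_MODEL)
) -> dict[str, CoverageResult]:
    profile = feature_profile(mol)
    return {m.name: coverage_check(profile, m) for m in models}
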