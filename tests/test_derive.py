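import pytest

from capa.derive import (
    HETEROAROMATIC_TARGETS,
    HETEROCYCLIC_TARGETS,
    NAMED_RINGS,
    RingSpec,
    compile_potential_positive,
    derive_default,
    fragment_scaffolds,
    hop_heteroaromatic,
    hop_heterocycle,
    ring_name,
)
from capa.patterns import (
    ROLE_BASIC_SCAFFOLD,
    ROLE_CLEAR_POSITIVE,
    ROLE_POTENTIAL_POSITIVE,
    ROLE_SECONDARY_POSITIVE,
    SubstructurePattern,
)


def _sec(lib):
    return {p.name: p for p in lib.by_role(ROLE_SECONDARY_POSITIVE)}


def _clear(lib):
    return {p.name: p for p in lib.by_role(ROLE_CLEAR_POSITIVE)}


# ---------------------------------------------------------------------------
# RingSpec
# ---------------------------------------------------------------------------


def test_ringspec_rotation_and_reflection_invariance():
    a = RingSpec((("N", False), ("C", False), ("C", False), ("C", False), ("C", False)))
    b = RingSpec((("C", False), ("C", False), ("N", False), ("C", False), ("C", False)))
    assert a == b
    # 1,2- vs 2,1- placement: mirror images collapse
    c = RingSpec((("O", True), ("N", True), ("C", True), ("C", True), ("C", True)))
    d = RingSpec((("N", True), ("O", True), ("C", True), ("C", True), ("C", True)))
    assert c == d


def test_ringspec_distinguishes_placement_and_aromaticity():
    placed_13 = RingSpec((("N", False), ("C", False), ("N", False), ("C", False), ("C", False)))
    placed_12 = RingSpec((("N", False), ("N", False), ("C", False), ("C", False), ("C", False)))
    assert placed_13 != placed_12
    aromatic = RingSpec((("N", True), ("C", True), ("N", True), ("C", True), ("C", True)))
    assert placed_13 != aromatic


def test_ringspec_size_bounds():
    with pytest.raises(ValueError):
        RingSpec((("C", False), ("C", False)))


def test_ring_name_table():
    assert ring_name(RingSpec(tuple(("C", True) for _ in range(6)))) == "benzene"
    assert (
        ring_name(
            RingSpec((("N", False), ("C", False), ("N", False), ("C", False), ("C", False)))
        )
        == "imidazolidine"
    )


# ---------------------------------------------------------------------------
# Generators against the shipped parents
# ---------------------------------------------------------------------------


def test_fragmentation_of_basic_scaffolds(lib):
    derived = fragment_scaffolds(lib.by_role(ROLE_BASIC_SCAFFOLD))
    assert {p.name for p in derived} == {"pyrimidine", "pyrrole", "pyridine", "thiophene"}
    for p in derived:
        assert p.role == ROLE_POTENTIAL_POSITIVE


def test_fragmentation_discards_pure_carbocycles(lib):
    quinazoline = lib.get("quinazoline", ROLE_BASIC_SCAFFOLD)
    derived = fragment_scaffolds([quinazoline])
    assert {p.name for p in derived} == {"pyrimidine"}  # the benzo ring is dropped


def test_fragmentation_skips_acyclic_parent(caplog):
    acyclic = SubstructurePattern(
        name="ether", smarts="CCOCC", role=ROLE_BASIC_SCAFFOLD, provenance="test"
    )
    assert fragment_scaffolds([acyclic]) == set()


def test_heterocyclic_hop_targets(lib):
    sec, clear = _sec(lib), _clear(lib)
    parents = [sec["piperazine"], sec["homo-piperazine"], sec["piperidine"], clear["morpholine"]]
    derived = hop_heterocycle(parents)
    assert {p.name for p in derived} == set(HETEROCYCLIC_TARGETS)
    assert len(derived) == 5


def test_heterocyclic_hop_conserves_heteroatom_multiset(lib):
    sec, clear = _sec(lib), _clear(lib)
    parents = {
        "piperazine": ("N", "N"),
        "piperidine": ("N",),
        "morpholine": ("N", "O"),
    }
    for parent_name, hetero in parents.items():
        parent = sec.get(parent_name) or clear.get(parent_name)
        for child in hop_heterocycle([parent], raw=True):
            from rdkit import Chem

            mol = Chem.MolFromSmiles(NAMED_RINGS[child.name]["smiles"])
            got = tuple(
                sorted(a.GetSymbol() for a in mol.GetAtoms() if a.GetSymbol() != "C")
            )
            assert got == hetero, (parent_name, child.name)


def test_heterocyclic_hop_raw_superset_includes_curated(lib):
    sec, clear = _sec(lib), _clear(lib)
    parents = [sec["piperazine"], sec["homo-piperazine"], sec["piperidine"], clear["morpholine"]]
    raw = {p.name for p in hop_heterocycle(parents, raw=True)}
    curated = {p.name for p in hop_heterocycle(parents)}
    assert curated <= raw
    assert "homo-piperazine" in raw - curated  # enumerated but not adopted


def test_heterocyclic_hop_14_contracts_to_13(lib):
    morpholine = _clear(lib)["morpholine"]
    names = {p.name for p in hop_heterocycle([morpholine], raw=True)}
    # contraction of the 1,4 N/O six-ring lands on the 1,3 five-ring
    assert "oxazolidine" in names
    assert "isoxazolidine" not in names


def test_heteroaromatic_hop_targets(lib):
    sec = _sec(lib)
    derived = hop_heteroaromatic([sec["1,2,4-oxadiazole"], sec["1,3,4-thiadiazole"]])
    assert {p.name for p in derived} == set(HETEROAROMATIC_TARGETS)
    assert len(derived) == 7


def test_heteroaromatic_hop_sub_multiset_property(lib):
    from rdkit import Chem

    sec = _sec(lib)
    parent_hetero = {"1,2,4-oxadiazole": ("N", "N", "O"), "1,3,4-thiadiazole": ("N", "N", "S")}
    for parent_name, hetero in parent_hetero.items():
        for child in hop_heteroaromatic([sec[parent_name]], raw=True):
            mol = Chem.MolFromSmiles(NAMED_RINGS[child.name]["smiles"])
            got = sorted(a.GetSymbol() for a in mol.GetAtoms() if a.GetSymbol() != "C")
            assert 1 <= len(got) <= 2
            remaining = list(hetero)
            for sym in got:
                assert sym in remaining, (parent_name, child.name)
                remaining.remove(sym)


def test_heteroaromatic_hop_enumerates_unadopted_isothiazole(lib):
    sec = _sec(lib)
    raw = {p.name for p in hop_heteroaromatic([sec["1,3,4-thiadiazole"]], raw=True)}
    assert "isothiazole" in raw
    curated = {p.name for p in hop_heteroaromatic([sec["1,3,4-thiadiazole"]])}
    assert "isothiazole" not in curated


def test_hop_rejects_unsupported_parent(lib):
    benzofuran_like = _sec(lib)["1,2,4-oxadiazole"]
    # aromatic parent into the saturated hop: skipped, empty result
    assert hop_heterocycle([benzofuran_like]) == set()
    saturated = _clear(lib)["morpholine"]
    assert hop_heteroaromatic([saturated]) == set()


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------


def test_compile_dedups_thiophene_and_counts_15(lib):
    derived = derive_default(lib)
    assert len(derived) == 15
    names = {p.name for p in derived}
    assert names == lib.names(ROLE_POTENTIAL_POSITIVE)
    # thiophene reachable via two routes, present once
    assert sum(1 for p in derived if p.name == "thiophene") == 1


def test_compile_registers_overrules(lib):
    fresh = lib.with_overrules(frozenset())
    derive_default(fresh)
    assert fresh.overrules == {"pyrrolidine", "oxazole"}


def test_derived_smarts_agree_with_registry(lib):
    registry = {p.name: p.smarts for p in lib.by_role(ROLE_POTENTIAL_POSITIVE)}
    for p in derive_default(lib):
        assert p.smarts == registry[p.name], p.name
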