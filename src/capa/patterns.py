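"""The named substructure-pattern registry and its matching primitives.

The computer-aided pattern analysis (C@PA) methodology screens compound
libraries against a curated set of named substructures, each carrying a role:

``clear_positive``
    The eight substructures enriched among triple ABCB1/ABCC1/ABCG2
    inhibitors ("class 7" compounds) in the original C@PA training set.
``clear_negative``
    The thirty-two substructures depleted among class 7 compounds; any
    enforced match excludes a molecule from the screen.
``secondary_positive``
    The five substructures observed in the multitarget hits that C@PA itself
    discovered (1,2,4-oxadiazole, 1,3,4-thiadiazole, piperazine,
    homo-piperazine, piperidine).
``potential_positive``
    The fifteen rings deduced from the parents by scaffold fragmentation and
    substructure hopping (see :mod:`capa.derive`).
``basic_scaffold``
    The six fused ring systems underlying the most potent known triple
    inhibitors; inputs to scaffold fragmentation.
``rejected_putative_positive``
    Sixteen substructures that occur in class 7 compounds but are too
    ubiquitous in the other classes to count as clear positives.

Secondary plus potential positives are the twenty "extended positive hits";
together with the clear positives they form the 28-pattern positive screen.

Pattern names follow the common names of the fragments.  A name may appear
under more than one role (pyrrolidine and oxazole are simultaneously clear
negatives and deduced potential positives - the collision that motivates the
overrule mechanism), but within a role names are unique, and entries sharing
a name must share a SMARTS.

SMARTS encoding conventions (the fragment names do not define queries, so
the registry fixes one documented semantics):

* Ring fragments match as rings permitting arbitrary substitution and ring
  fusion; aromatic queries require aromatic target atoms, saturated queries
  aliphatic ones.  Azine/azole positional isomers are strict: pyridine never
  matches pyrimidine, isoxazole never matches oxazole.
* Terminal groups require their full terminal-atom complement: methoxy is
  O-CH3 with a genuine terminal methyl, amino is a primary amine -NH2,
  isopropyl and tert-butyl need all of their methyls.
* Composite phenyl patterns (methoxyphenyl series, hydroquinone, resorcin,
  biphenyl, stilbene, chalcone, ...) encode the exact regiochemistry of the
  named pattern; the methoxyphenyl series requires explicit hydrogens at the
  unnamed ring positions so that e.g. 3,4,5-trimethoxyphenyl (a clear
  positive) does not trip the dimethoxyphenyl negatives.
* "Anellated" cyclopropyl/cycloheptyl mean carbocycles fused to another ring
  (sharing a bond), distinct from the plain substituent patterns.

Match counts are symmetry-deduplicated distinct embeddings; the screening
cascade itself only consumes presence/absence.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from rdkit import Chem

from .chem import Molecule

logger = logging.getLogger(__name__)

ROLE_CLEAR_POSITIVE = "clear_positive"
ROLE_SECONDARY_POSITIVE = "secondary_positive"
ROLE_POTENTIAL_POSITIVE = "potential_positive"
ROLE_CLEAR_NEGATIVE = "clear_negative"
ROLE_BASIC_SCAFFOLD = "basic_scaffold"
ROLE_REJECTED = "rejected_putative_positive"

ROLES = (
    ROLE_CLEAR_POSITIVE,
    ROLE_SECONDARY_POSITIVE,
    ROLE_POTENTIAL_POSITIVE,
    ROLE_CLEAR_NEGATIVE,
    ROLE_BASIC_SCAFFOLD,
    ROLE_REJECTED,
)

#: roles whose union forms the "extended positive" screen
EXTENDED_POSITIVE_ROLES = (ROLE_SECONDARY_POSITIVE, ROLE_POTENTIAL_POSITIVE)
#: roles counted as positive in the default screening cascade
DEFAULT_POSITIVE_ROLES = (
    ROLE_CLEAR_POSITIVE,
    ROLE_SECONDARY_POSITIVE,
    ROLE_POTENTIAL_POSITIVE,
)

#: clear negatives suspended by default so that the deduced pyrrolidine and
#: oxazole chemistry can pass the exclusion filter
DEFAULT_OVERRULES = frozenset({"pyrrolidine", "oxazole"})

DEFAULT_VERSION = "capa-1.2"


class RegistryError(ValueError):
    """The pattern registry is malformed."""


@dataclass(frozen=True)
class SubstructurePattern:
    """A named SMARTS query with a screening role."""

    name: str
    smarts: str
    role: str
    provenance: str = ""
    _query: Chem.Mol = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self):
        if self.role not in ROLES:
            raise RegistryError(f"pattern {self.name!r}: unknown role {self.role!r}")
        query = Chem.MolFromSmarts(self.smarts)
        if query is None:
            raise RegistryError(
                f"pattern {self.name!r}: SMARTS does not compile: {self.smarts!r}"
            )
        object.__setattr__(self, "_query", query)

    @property
    def query(self) -> Chem.Mol:
        return self._query


def matches(pattern: SubstructurePattern, mol: Molecule) -> int:
    """Count distinct, symmetry-deduplicated embeddings of ``pattern`` in ``mol``."""
    hits = mol.rdmol.GetSubstructMatches(pattern.query, uniquify=True)
    # uniquify removes order-permuted duplicates; distinct atom sets remain
    return len({frozenset(h) for h in hits})


class PatternLibrary:
    """Versioned registry of :class:`SubstructurePattern` plus overrule list."""

    def __init__(
        self,
        patterns: Iterable[SubstructurePattern],
        overrules: Iterable[str] = DEFAULT_OVERRULES,
        version: str = DEFAULT_VERSION,
    ):
        self.patterns: tuple[SubstructurePattern, ...] = tuple(patterns)
        self.overrules: set[str] = set(overrules)
        self.version = version
        self._validate()

    # -- registry integrity -------------------------------------------------

    def _validate(self) -> None:
        by_role: dict[str, set[str]] = {}
        by_name: dict[str, str] = {}
        problems: list[str] = []
        for p in self.patterns:
            names = by_role.setdefault(p.role, set())
            if p.name in names:
                problems.append(f"duplicate name {p.name!r} within role {p.role}")
            names.add(p.name)
            if p.name in by_name and by_name[p.name] != p.smarts:
                problems.append(
                    f"name {p.name!r} bound to conflicting SMARTS across roles"
                )
            by_name.setdefault(p.name, p.smarts)
        negative_names = by_role.get(ROLE_CLEAR_NEGATIVE, set())
        for name in self.overrules:
            if name not in negative_names:
                problems.append(f"overrule {name!r} is not a clear negative")
        if problems:
            raise RegistryError("; ".join(problems))

    # -- accessors ----------------------------------------------------------

    def by_role(self, role: str) -> tuple[SubstructurePattern, ...]:
        return tuple(p for p in self.patterns if p.role == role)

    def names(self, role: str) -> set[str]:
        return {p.name for p in self.patterns if p.role == role}

    def get(self, name: str, role: str | None = None) -> SubstructurePattern:
        for p in self.patterns:
            if p.name == name and (role is None or p.role == role):
                return p
        raise KeyError(name)

    def role_counts(self) -> dict[str, int]:
        return {role: len(self.by_role(role)) for role in ROLES}

    def extended_positive_names(self) -> set[str]:
        out: set[str] = set()
        for role in EXTENDED_POSITIVE_ROLES:
            out |= self.names(role)
        return out

    def positive_patterns(
        self, roles: Sequence[str] = DEFAULT_POSITIVE_ROLES
    ) -> tuple[SubstructurePattern, ...]:
        seen: set[str] = set()
        out: list[SubstructurePattern] = []
        for role in roles:
            for p in self.by_role(role):
                if p.name not in seen:
                    seen.add(p.name)
                    out.append(p)
        return tuple(out)

    def with_overrules(self, overrules: Iterable[str]) -> "PatternLibrary":
        return PatternLibrary(self.patterns, overrules, self.version)

    # -- self test ----------------------------------------------------------

    def self_test(
        self, example_pairs: Mapping[str, tuple[str, str]] | None = None
    ) -> list[str]:
        """Check every pattern against its exemplar/counter-exemplar pair.

        Returns a list of failure descriptions (empty when healthy).
        """
        from .chem import parse_structure

        if example_pairs is None:
            example_pairs = load_example_pairs()
        failures: list[str] = []
        for p in self.patterns:
            pair = example_pairs.get(p.name)
            if pair is None:
                failures.append(f"{p.name}: no exemplar pair")
                continue
            exemplar, counter = pair
            if matches(p, parse_structure(exemplar, f"{p.name}-exemplar")) == 0:
                failures.append(f"{p.name}: exemplar {exemplar} not matched")
            if matches(p, parse_structure(counter, f"{p.name}-counter")) > 0:
                failures.append(f"{p.name}: counter-exemplar {counter} matched")
        return failures


# ---------------------------------------------------------------------------
# Screening primitives
# ---------------------------------------------------------------------------


def negative_filter(
    mol: Molecule,
    lib: PatternLibrary,
    overrules: Iterable[str] | None = None,
) -> tuple[bool, list[str]]:
    """Clear-negative exclusion with overrules.

    Returns ``(passed, violations)`` where ``violations`` lists every
    *enforced* clear negative that matches, sorted by name.  A molecule
    passes iff no enforced negative matches.
    """
    enforced_skip = set(lib.overrules if overrules is None else overrules)
    violations = sorted(
        p.name
        for p in lib.by_role(ROLE_CLEAR_NEGATIVE)
        if p.name not in enforced_skip and matches(p, mol) > 0
    )
    return (not violations, violations)


def positive_hit_profile(
    mol: Molecule,
    lib: PatternLibrary,
    roles: Sequence[str] = DEFAULT_POSITIVE_ROLES,
) -> tuple[frozenset[str], int]:
    """Distinct positive patterns present in ``mol`` for the requested roles."""
    unknown = set(roles) - set(ROLES)
    if unknown:
        raise ValueError(f"unknown roles: {sorted(unknown)}")
    hit_names = frozenset(
        p.name for p in lib.positive_patterns(tuple(roles)) if matches(p, mol) > 0
    )
    return hit_names, len(hit_names)


# ---------------------------------------------------------------------------
# Registry file I/O
# ---------------------------------------------------------------------------

_REGISTRY_COLUMNS = ("name", "smarts", "role", "provenance")


def load_registry(path: str | Path) -> list[SubstructurePattern]:
    """Load patterns from a tab-separated registry file."""
    patterns: list[SubstructurePattern] = []
    bad: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not set(_REGISTRY_COLUMNS[:3]) <= set(
            reader.fieldnames
        ):
            raise RegistryError(f"{path}: expected columns {_REGISTRY_COLUMNS}")
        for row in reader:
            try:
                patterns.append(
                    SubstructurePattern(
                        name=row["name"],
                        smarts=row["smarts"],
                        role=row["role"],
                        provenance=row.get("provenance", "") or "",
                    )
                )
            except RegistryError as exc:
                bad.append(str(exc))
    if bad:
        raise RegistryError(f"{path}: " + "; ".join(bad))
    return patterns


def save_registry(
    patterns: Iterable[SubstructurePattern], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(_REGISTRY_COLUMNS)
        for p in patterns:
            writer.writerow([p.name, p.smarts, p.role, p.provenance])


def _data_path(name: str):
    return resources.files("capa.data").joinpath(name)


def load_example_pairs() -> dict[str, tuple[str, str]]:
    """Exemplar/counter-exemplar SMILES pairs shipped with the registry."""
    pairs: dict[str, tuple[str, str]] = {}
    with resources.as_file(_data_path("pattern_examples.tsv")) as path:
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                pairs[row["name"]] = (row["exemplar"], row["counter_exemplar"])
    return pairs


def default_library() -> PatternLibrary:
    """The fully populated default registry under version ``capa-1.2``."""
    with resources.as_file(_data_path("patterns.tsv")) as path:
        patterns = load_registry(path)
    return PatternLibrary(patterns, DEFAULT_OVERRULES, DEFAULT_VERSION)
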