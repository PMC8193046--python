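"""Seeded synthetic screening libraries with planted ground truth.

The generator assembles molecules from a small decoy scaffold pool (rings
that match no screening-relevant pattern on their own) plus planted
substituent fragments, each of which realizes exactly one named registry
pattern.  Because every planted fragment's effect on the match profile is
known and verified record-by-record after generation, the generator's
ground truth predicts the outcome of the entire screening cascade exactly:
stage counts, stereo-duplicate removals, the positive-hit histogram, and -
with sampled per-target IC50 profiles - activity class sizes and
pattern/class occurrence tables.

It also exposes :func:`paper_candidates`, the packaged table of the ten
experimentally validated candidate compounds with vendor identifiers and
measured IC50 values, used read-only by tests and the worked examples.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field

from .chem import Molecule, parse_structure, read_csv_library
from .classify import (
    ActivityProfile,
    Censored,
    Measurement,
    SUBSET_OF_CLASS,
    parse_measurement,
)
from .patterns import (
    DEFAULT_POSITIVE_ROLES,
    ROLE_CLEAR_NEGATIVE,
    PatternLibrary,
    default_library,
    matches,
)

logger = logging.getLogger(__name__)

#: decoy ring systems matching no positive or clear-negative pattern
DECOY_SCAFFOLDS = ("c1ccccc1", "c1ccnnc1")

#: attachable fragment SMILES realizing exactly one positive pattern each;
#: written so that prefixing an aliphatic carbon yields a valid substituent
POSITIVE_FRAGMENTS: dict[str, str] = {
    "piperazine": "N1CCNCC1",
    "morpholine": "N1CCOCC1",
    "piperidine": "N1CCCCC1",
    "pyridine": "c1ccncc1",
    "imidazole": "n1ccnc1",
    "pyrazole": "n1cccn1",
    "thiophene": "c1cccs1",
    "isopropyl": "C(C)C",
}

#: attachable fragments realizing exactly one clear-negative pattern each
NEGATIVE_FRAGMENTS: dict[str, str] = {
    "nitro": "[N+](=O)[O-]",
    "tert-butyl": "C(C)(C)C",
    "dimethylamino": "N(C)C",
    "carboxylic acid": "C(=O)O",
}

PLANTABLE = {**POSITIVE_FRAGMENTS, **NEGATIVE_FRAGMENTS}

DEFAULT_PLANT_RATES: dict[str, float] = {
    "piperazine": 0.25,
    "morpholine": 0.20,
    "piperidine": 0.20,
    "pyridine": 0.25,
    "imidazole": 0.15,
    "pyrazole": 0.15,
    "thiophene": 0.15,
    "isopropyl": 0.10,
}


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class PlantConfig:
    """Generator parameters.

    ``plant_rates`` gives, per positive pattern name, the independent
    probability that a molecule carries that fragment.
    ``negative_violation_rate`` is the probability that a molecule
    additionally carries one random clear-negative fragment.
    ``stereo_pair_count`` molecules are emitted twice, as enantiomeric
    records sharing one stereo-free constitution.  ``class_probs`` weights
    the sampled activity class 0-7; actives draw IC50 log-uniformly from
    ``active_range_um`` (both ends below the 10 uM activity threshold),
    inactives from ``inactive_range_um`` or, with probability
    ``censor_rate``, a right-censored bound from the same range.
    """

    n_molecules: int = 150
    seed: int = 0
    plant_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLANT_RATES)
    )
    stereo_pair_count: int = 28
    negative_violation_rate: float = 0.31
    class_probs: tuple[float, ...] = (
        0.30, 0.12, 0.10, 0.12, 0.10, 0.08, 0.08, 0.10,
    )
    active_range_um: tuple[float, float] = (0.1, 9.5)
    inactive_range_um: tuple[float, float] = (12.0, 500.0)
    censor_rate: float = 0.2

    def __post_init__(self):
        if self.n_molecules < self.stereo_pair_count * 2:
            raise ConfigError("n_molecules must be >= 2 * stereo_pair_count")
        if self.stereo_pair_count < 0:
            raise ConfigError("stereo_pair_count must be >= 0")
        for name, rate in self.plant_rates.items():
            if name not in POSITIVE_FRAGMENTS:
                raise ConfigError(f"unknown plantable pattern {name!r}")
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"plant rate for {name!r} outside [0, 1]")
        if not 0.0 <= self.negative_violation_rate <= 1.0:
            raise ConfigError("negative_violation_rate outside [0, 1]")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ConfigError("censor_rate outside [0, 1]")
        if len(self.class_probs) != 8 or any(p < 0 for p in self.class_probs):
            raise ConfigError("class_probs must be 8 non-negative weights")
        if not math.isclose(sum(self.class_probs), 1.0, abs_tol=1e-9):
            raise ConfigError("class_probs must sum to 1")
        lo, hi = self.active_range_um
        if not 0 < lo <= hi < 10.0:
            raise ConfigError("active_range_um must lie within (0, 10)")
        lo, hi = self.inactive_range_um
        if not 10.0 < lo <= hi:
            raise ConfigError("inactive_range_um must lie above 10")


@dataclass(frozen=True)
class PlantedRecord:
    """One generated record plus everything the generator knows about it."""

    id: str
    smiles: str
    planted_positive: frozenset[str]
    planted_negative: frozenset[str]
    stereo_duplicate_of: str | None
    profile: ActivityProfile
    class_value: int

    @property
    def passes_negative(self) -> bool:
        return not self.planted_negative


@dataclass(frozen=True)
class GeneratedLibrary:
    """Generated records (duplicates after their originals) and summaries."""

    config: PlantConfig
    records: tuple[PlantedRecord, ...]

    def molecules(self) -> list[Molecule]:
        return [parse_structure(r.smiles, r.id) for r in self.records]

    @property
    def originals(self) -> tuple[PlantedRecord, ...]:
        return tuple(r for r in self.records if r.stereo_duplicate_of is None)

    def expected_summary(self) -> dict:
        """Cascade outcome implied by the ground truth."""
        survivors = [r for r in self.originals if r.passes_negative]
        top = max((len(r.planted_positive) for r in survivors), default=0)
        hist = {k: 0 for k in range(top + 1)}
        for r in survivors:
            hist[len(r.planted_positive)] += 1
        class_sizes = [0] * 8
        for r in self.originals:
            class_sizes[r.class_value] += 1
        return {
            "n_input": len(self.records),
            "n_unique": len(self.originals),
            "n_removed_stereo": len(self.records) - len(self.originals),
            "n_passed_negative": len(survivors),
            "n_candidates": sum(1 for r in survivors if r.planted_positive),
            "histogram": hist,
            "class_sizes": class_sizes,
        }


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

_MAX_ASSEMBLY_TRIES = 25


def _assemble(
    scaffold: str, fragments: list[str], tag_length: int, stereo: str | None
) -> str:
    """Linear-backbone SMILES: one chain carbon per fragment, alkyl tag, scaffold.

    ``stereo`` prefixes a CHFCl stereocenter written with the given
    chirality tag ('@' or '@@').
    """
    backbone = "".join(f"C({frag})" for frag in fragments)
    prefix = f"F[C{stereo}H](Cl)" if stereo else ""
    return f"{prefix}C{backbone}{'C' * tag_length}{scaffold}"


def _relevant_patterns(lib: PatternLibrary):
    relevant = {p.name: p for p in lib.positive_patterns(DEFAULT_POSITIVE_ROLES)}
    for p in lib.by_role(ROLE_CLEAR_NEGATIVE):
        relevant.setdefault(p.name, p)
    return list(relevant.values())


def _sample_profile(
    rng: random.Random, config: PlantConfig
) -> tuple[ActivityProfile, int]:
    cls = rng.choices(range(8), weights=config.class_probs)[0]
    inhibited = SUBSET_OF_CLASS[cls]
    values: dict[str, Measurement] = {}
    for target in ("ABCB1", "ABCC1", "ABCG2"):
        if target in inhibited:
            lo, hi = config.active_range_um
            values[target] = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        else:
            lo, hi = config.inactive_range_um
            value = math.exp(rng.uniform(math.log(lo), math.log(hi)))
            values[target] = (
                Censored(round(value, 3)) if rng.random() < config.censor_rate else value
            )
    profile = ActivityProfile(
        abcb1=values["ABCB1"], abcc1=values["ABCC1"], abcg2=values["ABCG2"]
    )
    return profile, cls


def generate_library(
    config: PlantConfig = PlantConfig(), library: PatternLibrary | None = None
) -> GeneratedLibrary:
    """Generate a seeded library; identical config yields identical output.

    Every record is verified after assembly: its match set over the positive
    screen plus the clear negatives must equal the planted set exactly,
    otherwise the record is reassembled (bounded retries).
    """
    if library is None:
        library = default_library()
    relevant = _relevant_patterns(library)
    rng = random.Random(config.seed)
    n_unique = config.n_molecules - config.stereo_pair_count
    seen_keys: set[str] = set()
    records: list[PlantedRecord] = []

    stereo_indices = set(
        rng.sample(range(n_unique), config.stereo_pair_count)
        if config.stereo_pair_count
        else []
    )

    for i in range(n_unique):
        rec_id = f"syn{i + 1:04d}"
        positives = frozenset(
            name for name, rate in sorted(config.plant_rates.items()) if rng.random() < rate
        )
        negatives = frozenset(
            [rng.choice(sorted(NEGATIVE_FRAGMENTS))]
            if rng.random() < config.negative_violation_rate
            else []
        )
        planted = positives | negatives
        stereo = "@" if i in stereo_indices else None
        record = None
        for attempt in range(_MAX_ASSEMBLY_TRIES):
            scaffold = rng.choice(DECOY_SCAFFOLDS)
            tag = rng.randint(1, 8)
            fragments = [PLANTABLE[name] for name in sorted(planted)]
            rng.shuffle(fragments)
            smiles = _assemble(scaffold, fragments, tag, stereo)
            try:
                mol = parse_structure(smiles, rec_id)
            except ValueError:
                logger.warning("assembly %s attempt %d unparsable; retrying", rec_id, attempt)
                continue
            if mol.canonical_key in seen_keys:
                continue
            matched = frozenset(p.name for p in relevant if matches(p, mol) > 0)
            if matched != planted:
                logger.warning(
                    "assembly %s attempt %d: match set %s != planted %s; retrying",
                    rec_id, attempt, sorted(matched), sorted(planted),
                )
                continue
            seen_keys.add(mol.canonical_key)
            profile, cls = _sample_profile(rng, config)
            record = PlantedRecord(
                id=rec_id,
                smiles=smiles,
                planted_positive=positives,
                planted_negative=negatives,
                stereo_duplicate_of=None,
                profile=profile,
                class_value=cls,
            )
            break
        if record is None:
            raise RuntimeError(
                f"could not assemble record {rec_id} in {_MAX_ASSEMBLY_TRIES} tries"
            )
        records.append(record)

    # enantiomeric duplicates, emitted after all originals so the original
    # is always the first-seen (kept) representative
    for i in sorted(stereo_indices):
        orig = records[i]
        records.append(
            PlantedRecord(
                id=f"{orig.id}dup",
                smiles=orig.smiles.replace("[C@H]", "[C@@H]", 1),
                planted_positive=orig.planted_positive,
                planted_negative=orig.planted_negative,
                stereo_duplicate_of=orig.id,
                profile=orig.profile,
                class_value=orig.class_value,
            )
        )

    return GeneratedLibrary(config=config, records=tuple(records))


# ---------------------------------------------------------------------------
# Paper fixtures
# ---------------------------------------------------------------------------


def paper_candidates() -> list[dict]:
    """The ten packaged candidate compounds as row dicts.

    Each row carries the parsed ``molecule``, an ``activity_profile``
    (measurements are missing for all but the followed-up compound), and the
    vendor metadata columns.
    """
    from importlib import resources

    path = resources.files("capa.data") / "paper_candidates.csv"
    with resources.as_file(path) as p:
        rows, errors = read_csv_library(p)
    if errors:
        raise RuntimeError(f"packaged candidate table has parse errors: {errors}")
    for row in rows:
        row["activity_profile"] = ActivityProfile(
            abcb1=parse_measurement(row["abcb1_ic50_um"]),
            abcc1=parse_measurement(row["abcc1_ic50_um"]),
            abcg2=parse_measurement(row["abcg2_ic50_um"]),
        )
    return rows
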