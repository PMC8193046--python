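"""The pattern-based virtual screening cascade.

The cascade applies, in order:

1. **Stereoisomer deduplication** - records that differ only in stereo
   descriptors collapse to one first-seen representative.
2. **Negative pattern filter** - compounds matching any enforced clear
   negative pattern are excluded; a clear negative listed in the library's
   overrule set (a ring simultaneously adopted as a potential positive) is
   suspended and never excludes anything.
3. **Positive hit profiling** - each surviving compound is annotated with
   the set of positive patterns it contains at least once; compounds with at
   least one hit are the candidate output.

The report records counts at every stage, the per-compound hit attributions,
a histogram of compounds per positive-hit count (including the zero bin),
and the library version plus configuration, so a run is reproducible from
its own output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .chem import Molecule, deduplicate_with_provenance, parse_structure
from .patterns import (
    DEFAULT_POSITIVE_ROLES,
    PatternLibrary,
    default_library,
    negative_filter,
    positive_hit_profile,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenConfig:
    """Cascade switches; defaults reproduce the full cascade."""

    deduplicate: bool = True
    apply_negative_filter: bool = True
    positive_roles: tuple[str, ...] = DEFAULT_POSITIVE_ROLES
    min_positive_hits: int = 1

    def __post_init__(self):
        if self.min_positive_hits < 0:
            raise ValueError("min_positive_hits must be >= 0")


@dataclass(frozen=True)
class ScreeningRecord:
    """Per-compound outcome of a screening run."""

    id: str
    canonical_key: str
    passed_negative: bool
    violations: tuple[str, ...]
    positive_hits: frozenset[str]

    @property
    def hit_count(self) -> int:
        return len(self.positive_hits)


@dataclass(frozen=True)
class ScreeningReport:
    """Aggregate outcome of a screening run.

    ``records`` holds every unique compound in input order; ``candidates``
    the subset passing the negative filter with at least
    ``config.min_positive_hits`` positive hits, ranked by descending hit
    count (ties by lexicographic id).
    """

    config: ScreenConfig
    library_version: str
    n_input: int
    n_unique: int
    removed_stereo: dict[str, str]
    records: tuple[ScreeningRecord, ...]

    @property
    def n_removed_stereo(self) -> int:
        return len(self.removed_stereo)

    @property
    def passed_negative(self) -> tuple[ScreeningRecord, ...]:
        return tuple(r for r in self.records if r.passed_negative)

    @property
    def rejected_negative(self) -> tuple[ScreeningRecord, ...]:
        return tuple(r for r in self.records if not r.passed_negative)

    @property
    def candidates(self) -> tuple[ScreeningRecord, ...]:
        eligible = [
            r
            for r in self.passed_negative
            if r.hit_count >= self.config.min_positive_hits
        ]
        return tuple(rank_candidates(eligible))

    def histogram(self) -> dict[int, int]:
        """Compounds passing the negative filter, per positive-hit count.

        Keys run contiguously from 0 to the maximum observed count, so the
        zero bin (survivors carrying no positive pattern) is explicit.
        """
        passed = self.passed_negative
        top = max((r.hit_count for r in passed), default=0)
        hist = {k: 0 for k in range(top + 1)}
        for r in passed:
            hist[r.hit_count] += 1
        return hist

    def summary(self) -> dict:
        return {
            "library_version": self.library_version,
            "n_input": self.n_input,
            "n_unique": self.n_unique,
            "n_removed_stereo": self.n_removed_stereo,
            "n_passed_negative": len(self.passed_negative),
            "n_rejected_negative": len(self.rejected_negative),
            "n_candidates": len(self.candidates),
            "histogram": {str(k): v for k, v in self.histogram().items()},
        }


def rank_candidates(records: Iterable[ScreeningRecord]) -> list[ScreeningRecord]:
    """Order records by descending positive-hit count, ties by id."""
    return sorted(records, key=lambda r: (-r.hit_count, r.id))


def run_screen(
    inputs: Sequence[Molecule] | Sequence[tuple[str, str]],
    library: PatternLibrary | None = None,
    config: ScreenConfig = ScreenConfig(),
) -> ScreeningReport:
    """Run the cascade over parsed molecules or ``(smiles, id)`` pairs."""
    if library is None:
        library = default_library()
    mols: list[Molecule] = []
    for item in inputs:
        if isinstance(item, Molecule):
            mols.append(item)
        else:
            smiles, rec_id = item
            mols.append(parse_structure(smiles, rec_id))
    n_input = len(mols)
    removed: dict[str, str] = {}
    if config.deduplicate:
        mols, removed = deduplicate_with_provenance(mols)
    records: list[ScreeningRecord] = []
    for mol in mols:
        if config.apply_negative_filter:
            passed, violations = negative_filter(mol, library)
        else:
            passed, violations = True, []
        hits: frozenset[str] = frozenset()
        if passed:
            hits, _ = positive_hit_profile(mol, library, roles=config.positive_roles)
        records.append(
            ScreeningRecord(
                id=mol.id,
                canonical_key=mol.canonical_key,
                passed_negative=passed,
                violations=tuple(violations),
                positive_hits=hits,
            )
        )
    report = ScreeningReport(
        config=config,
        library_version=library.version,
        n_input=n_input,
        n_unique=len(mols),
        removed_stereo=removed,
        records=tuple(records),
    )
    logger.info(
        "screen: %d input, %d unique, %d passed negative, %d candidates",
        report.n_input,
        report.n_unique,
        len(report.passed_negative),
        len(report.candidates),
    )
    return report


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def report_to_dict(report: ScreeningReport) -> dict:
    return {
        "summary": report.summary(),
        "config": {
            "deduplicate": report.config.deduplicate,
            "apply_negative_filter": report.config.apply_negative_filter,
            "positive_roles": list(report.config.positive_roles),
            "min_positive_hits": report.config.min_positive_hits,
        },
        "removed_stereo": dict(report.removed_stereo),
        "candidates": [
            {
                "id": r.id,
                "hit_count": r.hit_count,
                "positive_hits": sorted(r.positive_hits),
            }
            for r in report.candidates
        ],
        "rejected": [
            {"id": r.id, "violations": list(r.violations)}
            for r in report.rejected_negative
        ],
    }


def write_report_json(report: ScreeningReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report_to_dict(report), fh, indent=2)
        fh.write("\n")


def write_candidates_tsv(report: ScreeningReport, path: str | Path) -> None:
    """Ranked candidate table: id, hit count, semicolon-joined hit names."""
    with open(path, "w") as fh:
        fh.write("# library_version\t" + report.library_version + "\n")
        fh.write("id\thit_count\tpositive_hits\n")
        for r in report.candidates:
            fh.write(f"{r.id}\t{r.hit_count}\t{';'.join(sorted(r.positive_hits))}\n")
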