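"""Activity classification against ABCB1, ABCC1 and ABCG2.

A compound's per-target half-maximal inhibitory concentrations (IC50, in
micromolar) map to one of eight activity classes, encoding which subset of
the three transporters the compound inhibits:

====== =========================
class  inhibited target subset
====== =========================
0      none
1      {ABCB1}
2      {ABCC1}
3      {ABCG2}
4      {ABCB1, ABCC1}
5      {ABCB1, ABCG2}
6      {ABCC1, ABCG2}
7      {ABCB1, ABCC1, ABCG2}
====== =========================

A target counts as inhibited when its IC50 is *strictly below* the activity
threshold (default 10 uM).  Right-censored measurements (reported as
"> X uM") count as inactive when the censoring bound is at or above the
threshold; a bound below the threshold leaves activity undetermined and is
rejected as a data error.  Missing measurements are treated as inactive for
class assignment but mark the label *provisional*; a compound with no
measurement on any target cannot be classified at all.

Pattern/class co-occurrence tables and the promiscuity flag rules built on
top of them drive the curation of putative positive patterns into clear
positives and rejected patterns.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .chem import Molecule
from .patterns import SubstructurePattern, matches

TARGETS = ("ABCB1", "ABCC1", "ABCG2")

DEFAULT_THRESHOLD_UM = 10.0

#: class index for every inhibited-target subset
CLASS_OF_SUBSET: dict[frozenset[str], int] = {
    frozenset(): 0,
    frozenset({"ABCB1"}): 1,
    frozenset({"ABCC1"}): 2,
    frozenset({"ABCG2"}): 3,
    frozenset({"ABCB1", "ABCC1"}): 4,
    frozenset({"ABCB1", "ABCG2"}): 5,
    frozenset({"ABCC1", "ABCG2"}): 6,
    frozenset({"ABCB1", "ABCC1", "ABCG2"}): 7,
}

SUBSET_OF_CLASS: dict[int, frozenset[str]] = {v: k for k, v in CLASS_OF_SUBSET.items()}

#: classes describing multitarget (two- and three-target) inhibitors
MULTITARGET_CLASSES = frozenset({4, 5, 6, 7})


class ClassificationError(ValueError):
    """A record's measurements do not support a class assignment."""


@dataclass(frozen=True)
class Censored:
    """A right-censored measurement, reported as '> bound uM'."""

    bound: float

    def __post_init__(self):
        if not math.isfinite(self.bound) or self.bound <= 0:
            raise ValueError(f"censoring bound must be finite positive, got {self.bound}")

    def __str__(self) -> str:
        return f">{self.bound:g}"


Measurement = float | Censored | None


@dataclass(frozen=True)
class ActivityProfile:
    """Per-target IC50 measurements (uM) for one compound.

    Each entry is a finite positive float, a :class:`Censored` bound, or
    ``None`` for a missing measurement.
    """

    abcb1: Measurement = None
    abcc1: Measurement = None
    abcg2: Measurement = None

    def __post_init__(self):
        for target, value in self.items():
            if value is None or isinstance(value, Censored):
                continue
            if not isinstance(value, (int, float)) or not math.isfinite(value) or value <= 0:
                raise ValueError(
                    f"{target} IC50 must be finite positive, censored or None, got {value!r}"
                )

    def items(self) -> tuple[tuple[str, Measurement], ...]:
        return (("ABCB1", self.abcb1), ("ABCC1", self.abcc1), ("ABCG2", self.abcg2))


@dataclass(frozen=True)
class ClassLabel:
    """An assigned activity class.

    ``provisional`` is True when one or two targets lack a measurement and
    were assumed inactive; additional data could only move the compound to a
    class whose subset is a superset of ``inhibited``.
    """

    value: int
    inhibited: frozenset[str]
    provisional: bool

    def __post_init__(self):
        if CLASS_OF_SUBSET[self.inhibited] != self.value:
            raise ValueError("class value does not match inhibited subset")

    @property
    def multitarget(self) -> bool:
        return self.value in MULTITARGET_CLASSES


def _is_active(value: Measurement, threshold: float) -> bool | None:
    """True/False for a determined measurement, None for missing."""
    if value is None:
        return None
    if isinstance(value, Censored):
        if value.bound >= threshold:
            return False
        raise ClassificationError(
            f"censored measurement {value} cannot resolve activity at threshold {threshold:g} uM"
        )
    return value < threshold


def assign_class(
    profile: ActivityProfile, threshold: float = DEFAULT_THRESHOLD_UM
) -> ClassLabel:
    """Map an activity profile to its class label.

    Raises :class:`ClassificationError` when every measurement is missing or
    a censored bound lies below the threshold.
    """
    if not math.isfinite(threshold) or threshold <= 0:
        raise ValueError(f"threshold must be finite positive, got {threshold}")
    inhibited: set[str] = set()
    n_missing = 0
    for target, value in profile.items():
        try:
            active = _is_active(value, threshold)
        except ClassificationError as exc:
            raise ClassificationError(f"{target}: {exc}") from None
        if active is None:
            n_missing += 1
        elif active:
            inhibited.add(target)
    if n_missing == len(TARGETS):
        raise ClassificationError("no measurement on any target")
    subset = frozenset(inhibited)
    return ClassLabel(
        value=CLASS_OF_SUBSET[subset], inhibited=subset, provisional=n_missing > 0
    )


# ---------------------------------------------------------------------------
# Pattern/class co-occurrence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OccurrenceTable:
    """Pattern-by-class occurrence counts over a classified compound set.

    ``counts`` has one row per pattern name and one column per class (0-7);
    cell (p, c) is the number of class-c compounds containing pattern p at
    least once.  ``class_sizes`` gives the number of compounds per class.
    """

    counts: pd.DataFrame
    class_sizes: tuple[int, ...]

    def fraction(self, pattern: str, cls: int) -> float:
        """Fraction of class-``cls`` compounds containing ``pattern``."""
        size = self.class_sizes[cls]
        return self.counts.at[pattern, cls] / size if size else 0.0

    def pooled_fraction(self, pattern: str, classes: Iterable[int]) -> float:
        """Fraction of the pooled compounds of ``classes`` containing ``pattern``."""
        classes = list(classes)
        total = sum(self.class_sizes[c] for c in classes)
        if total == 0:
            return 0.0
        hits = sum(int(self.counts.at[pattern, c]) for c in classes)
        return hits / total


def class_distribution(
    records: Sequence[tuple[Molecule, ClassLabel]],
    patterns: Sequence[SubstructurePattern],
) -> OccurrenceTable:
    """Count, per pattern and class, the compounds containing the pattern."""
    names = [p.name for p in patterns]
    counts = pd.DataFrame(0, index=names, columns=list(range(8)))
    sizes = [0] * 8
    for mol, label in records:
        sizes[label.value] += 1
        for pattern in patterns:
            if matches(pattern, mol) > 0:
                counts.at[pattern.name, label.value] += 1
    return OccurrenceTable(counts=counts, class_sizes=tuple(sizes))


@dataclass(frozen=True)
class FlagRules:
    """Thresholds for promoting or rejecting putative positive patterns.

    A pattern is *positive-flagged* when its occurrence fraction within the
    pan-inhibitor class (class 7) reaches ``positive_min_class7`` while its
    pooled fraction over all other classes stays below
    ``positive_max_other``.  It is *promiscuity-flagged* (rejected) when its
    class-7 fraction stays below ``reject_max_class7`` or its pooled
    other-class fraction reaches ``reject_min_other``.  The two rules must
    be mutually exclusive.
    """

    positive_min_class7: float = 0.5
    positive_max_other: float = 0.1
    reject_max_class7: float = 0.1
    reject_min_other: float = 0.5

    def __post_init__(self):
        for name in (
            "positive_min_class7",
            "positive_max_other",
            "reject_max_class7",
            "reject_min_other",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if (
            self.reject_max_class7 > self.positive_min_class7
            or self.reject_min_other < self.positive_max_other
        ):
            raise ValueError("flag rules are not mutually exclusive")


OTHER_CLASSES = tuple(c for c in range(8) if c != 7)


def flag_hits(
    table: OccurrenceTable, rules: FlagRules = FlagRules()
) -> dict[str, str]:
    """Classify each pattern of ``table`` as 'positive', 'rejected' or 'undecided'."""
    out: dict[str, str] = {}
    for name in table.counts.index:
        in7 = table.fraction(name, 7)
        other = table.pooled_fraction(name, OTHER_CLASSES)
        if in7 >= rules.positive_min_class7 and other < rules.positive_max_other:
            out[name] = "positive"
        elif in7 < rules.reject_max_class7 or other >= rules.reject_min_other:
            out[name] = "rejected"
        else:
            out[name] = "undecided"
    return out


# ---------------------------------------------------------------------------
# CSV input
# ---------------------------------------------------------------------------


def parse_measurement(text: str | None) -> Measurement:
    """Parse an IC50 cell: empty -> None, '>X' -> Censored(X), else float."""
    if text is None:
        return None
    text = text.strip()
    if not text or text.lower() in {"na", "nan", "none"}:
        return None
    if text.startswith(">"):
        return Censored(float(text[1:].strip()))
    value = float(text)
    return value


def load_activity_csv(
    path: str | Path,
) -> list[tuple[str, ActivityProfile]]:
    """Read ``id``/per-target IC50 columns from a compound CSV.

    Expects columns ``abcb1_ic50_um``, ``abcc1_ic50_um``, ``abcg2_ic50_um``;
    cells may be blank (missing) or '>X' (censored).
    """
    out: list[tuple[str, ActivityProfile]] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "abcb1_ic50_um", "abcc1_ic50_um", "abcg2_ic50_um"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: CSV must have columns {sorted(required)}")
        for row in reader:
            profile = ActivityProfile(
                abcb1=parse_measurement(row["abcb1_ic50_um"]),
                abcc1=parse_measurement(row["abcc1_ic50_um"]),
                abcg2=parse_measurement(row["abcg2_ic50_um"]),
            )
            out.append((row["id"], profile))
    return out
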