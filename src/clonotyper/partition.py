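"""Genotype-concordance partition of filtered SNVs across clones.

A site where all clones share the same genotype (same category *and* same
allele pair — an A/T het and an A/G het are different genotypes) is a
varietal SNV, unless every clone is homozygous reference, in which case the
site is not a variant at all. A site where exactly one clone deviates from
the genotype shared by all the others is clone-specific, attributed to the
deviating clone with that clone's genotype as the reported category (so a
hom-ref outlier against two variant clones populates the homozygous-reference
clone-specific cells). Sites where the clones disagree without a single
outlier are excluded as discordant.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .core_io import DataError, GenotypeCall, GenotypeCategory


class PartitionKind(str, Enum):
    VARIETAL = "VARIETAL"
    CLONE_SPECIFIC = "CLONE_SPECIFIC"
    EXCLUDED_DISCORDANT = "EXCLUDED_DISCORDANT"
    NOT_A_VARIANT = "NOT_A_VARIANT"


@dataclass(frozen=True)
class PartitionLabel:
    kind: PartitionKind
    outlier_clone: str | None = None
    reported_category: GenotypeCategory | None = None

    def __post_init__(self) -> None:
        if (self.outlier_clone is not None) != (self.kind is PartitionKind.CLONE_SPECIFIC):
            raise DataError("outlier_clone present iff kind is CLONE_SPECIFIC")
        if self.kind is PartitionKind.VARIETAL and self.reported_category is GenotypeCategory.HOM_REF:
            raise DataError("an all-hom-ref site is NOT_A_VARIANT, never VARIETAL")


def _genotype_key(call: GenotypeCall) -> tuple[GenotypeCategory, tuple[str, ...]]:
    return call.category, tuple(sorted(call.alleles))


def classify_site(calls: Mapping[str, GenotypeCall]) -> PartitionLabel:
    """Classify one site from its per-clone genotype calls.

    Defined for any number of clones >= 2 as: all-equal / exactly-one-outlier /
    other; with three clones this is exactly the varietal / clone-specific /
    discordant trichotomy.
    """
    if len(calls) < 2:
        raise DataError("need calls from at least two clones")
    for clone, call in calls.items():
        if call.category in (GenotypeCategory.MISSING, GenotypeCategory.MULTI):
            raise DataError(f"clone {clone}: {call.category.value} calls must be filtered before partitioning")
    keys = {clone: _genotype_key(call) for clone, call in calls.items()}
    tally = Counter(keys.values())
    if len(tally) == 1:
        category = next(iter(tally))[0]
        if category is GenotypeCategory.HOM_REF:
            return PartitionLabel(PartitionKind.NOT_A_VARIANT)
        return PartitionLabel(PartitionKind.VARIETAL, reported_category=category)
    if len(tally) == 2 and len(calls) >= 3:
        (k1, n1), (k2, n2) = tally.most_common()
        if n2 == 1:
            outlier = next(clone for clone, key in keys.items() if key == k2)
            return PartitionLabel(PartitionKind.CLONE_SPECIFIC, outlier_clone=outlier,
                                  reported_category=k2[0])
    return PartitionLabel(PartitionKind.EXCLUDED_DISCORDANT)


_TABLE_ROWS = (GenotypeCategory.HOM_REF, GenotypeCategory.HOM_ALT, GenotypeCategory.HET)


@dataclass
class PartitionSummary:
    """Table-1-shaped tally: genotype-category rows x (per-clone clone-specific,
    varietal, total) columns, plus the discordant-excluded count."""

    clone_names: tuple[str, ...]
    clone_specific: dict[str, Counter] = field(default_factory=dict)
    varietal: Counter = field(default_factory=Counter)
    excluded: int = 0
    not_a_variant: int = 0

    @property
    def varietal_total(self) -> int:
        return sum(self.varietal.values())

    def clone_total(self, clone: str) -> int:
        return sum(self.clone_specific.get(clone, Counter()).values())

    @property
    def clone_specific_total(self) -> int:
        return sum(self.clone_total(c) for c in self.clone_names)

    @property
    def total(self) -> int:
        """All classified variant sites (NOT_A_VARIANT excluded)."""
        return self.varietal_total + self.clone_specific_total + self.excluded

    @property
    def varietal_fraction(self) -> float | None:
        return self.varietal_total / self.total if self.total else None

    def row(self, category: GenotypeCategory) -> dict:
        cells = {c: self.clone_specific.get(c, Counter()).get(category, 0) for c in self.clone_names}
        v = self.varietal.get(category, 0)
        return {**cells, "varietal": v, "total": sum(cells.values()) + v}

    def as_dict(self) -> dict:
        rows = {cat.value: self.row(cat) for cat in _TABLE_ROWS}
        return {
            "clones": list(self.clone_names),
            "rows": rows,
            "excluded": self.excluded,
            "totals": {
                **{c: self.clone_total(c) for c in self.clone_names},
                "varietal": self.varietal_total,
                "total": self.total,
            },
            "clone_specific_total": self.clone_specific_total,
            "varietal_fraction": self.varietal_fraction,
            "not_a_variant": self.not_a_variant,
        }


def tabulate_partition(labels: Iterable[PartitionLabel], clone_names: Sequence[str] | None = None) -> PartitionSummary:
    """Tally partition labels into a Table-1-shaped summary.

    ``clone_names`` fixes column order; by default columns appear in order of
    first appearance among the outlier clones.
    """
    labels = list(labels)
    if clone_names is None:
        seen: list[str] = []
        for lab in labels:
            if lab.outlier_clone is not None and lab.outlier_clone not in seen:
                seen.append(lab.outlier_clone)
        clone_names = seen
    summary = PartitionSummary(clone_names=tuple(clone_names))
    for clone in clone_names:
        summary.clone_specific[clone] = Counter()
    for lab in labels:
        if lab.kind is PartitionKind.VARIETAL:
            summary.varietal[lab.reported_category] += 1
        elif lab.kind is PartitionKind.CLONE_SPECIFIC:
            summary.clone_specific.setdefault(lab.outlier_clone, Counter())[lab.reported_category] += 1
        elif lab.kind is PartitionKind.EXCLUDED_DISCORDANT:
            summary.excluded += 1
        else:
            summary.not_a_variant += 1
    return summary


def labels_from_counts(
    varietal: Mapping[GenotypeCategory, int],
    clone_specific: Mapping[str, Mapping[GenotypeCategory, int]],
    excluded: int = 0,
) -> list[PartitionLabel]:
    """Expand a cell-count table into the equivalent flat list of labels."""
    labels: list[PartitionLabel] = []
    for category, n in varietal.items():
        labels.extend([PartitionLabel(PartitionKind.VARIETAL, reported_category=category)] * n)
    for clone, cells in clone_specific.items():
        for category, n in cells.items():
            labels.extend(
                [PartitionLabel(PartitionKind.CLONE_SPECIFIC, outlier_clone=clone, reported_category=category)] * n
            )
    labels.extend([PartitionLabel(PartitionKind.EXCLUDED_DISCORDANT)] * excluded)
    return labels


def write_labels_tsv(records, labels, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tkind\toutlier\treported_category\n")
        for record, lab in zip(records, labels):
            fh.write(
                f"{record.chrom}\t{record.pos}\t{lab.kind.value}\t"
                f"{lab.outlier_clone or ''}\t{lab.reported_category.value if lab.reported_category else ''}\n"
            )
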