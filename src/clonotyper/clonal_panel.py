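"""Multilocus genotype classes from a marker panel, and minimal
discriminating marker subsets.

State tokens are compared literally: a composite chimeric token such as
``"CC~CT"`` (L2 genotype ~ L1 genotype) is a state of its own, distinct from
``"CC"`` — chimeric states are what distinguish some clonal genotypes.
Rows containing MISSING tokens are excluded from grouping and reported
separately rather than imputed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_io import DataError

MISSING_TOKEN = "MISSING"


@dataclass(frozen=True)
class MarkerPanel:
    markers: tuple[str, ...]
    rows: Mapping[str, tuple[str, ...]]  # accession -> one token per marker

    def __post_init__(self) -> None:
        for accession, tokens in self.rows.items():
            if len(tokens) != len(self.markers):
                raise DataError(f"{accession}: {len(tokens)} tokens for {len(self.markers)} markers")


@dataclass(frozen=True)
class GenotypeClass:
    label: str
    profile: tuple[str, ...]
    members: tuple[str, ...]


@dataclass
class PanelGrouping:
    classes: list[GenotypeClass]
    excluded: list[str] = field(default_factory=list)  # accessions with MISSING tokens


def _letters() -> Iterable[str]:
    for letter in string.ascii_uppercase:
        yield letter
    for a in string.ascii_uppercase:  # beyond 26 classes: AA, AB, ...
        for b in string.ascii_uppercase:
            yield a + b


def read_panel_csv(path) -> MarkerPanel:
    df = pd.read_csv(path, dtype=str).fillna(MISSING_TOKEN)
    markers = tuple(df.columns[1:])
    rows = {row[0]: tuple(row[1:]) for row in df.itertuples(index=False)}
    return MarkerPanel(markers, rows)


def write_panel_csv(panel: MarkerPanel, path) -> None:
    df = pd.DataFrame(
        [(acc, *tokens) for acc, tokens in panel.rows.items()],
        columns=["accession", *panel.markers],
    )
    df.to_csv(path, index=False)


def group_profiles(panel: MarkerPanel, canonical_labels: bool = False) -> PanelGrouping:
    """Group accessions into classes of exact profile equality.

    Labels are assigned A, B, ... in order of first appearance; with
    ``canonical_labels`` they are instead assigned by descending member
    count, ties broken by lexicographic profile order (reproducible across
    row orderings).
    """
    excluded = [acc for acc, tokens in panel.rows.items() if MISSING_TOKEN in tokens]
    groups: dict[tuple[str, ...], list[str]] = {}
    for accession, tokens in panel.rows.items():
        if MISSING_TOKEN in tokens:
            continue
        groups.setdefault(tokens, []).append(accession)
    ordered = list(groups.items())
    if canonical_labels:
        ordered.sort(key=lambda kv: (-len(kv[1]), kv[0]))
    classes = [
        GenotypeClass(label, profile, tuple(members))
        for label, (profile, members) in zip(_letters(), ordered)
    ]
    return PanelGrouping(classes=classes, excluded=excluded)


def _discriminates(profiles: Sequence[tuple[str, ...]], subset: tuple[int, ...]) -> bool:
    seen = set()
    for p in profiles:
        key = tuple(p[i] for i in subset)
        if key in seen:
            return False
        seen.add(key)
    return True


@dataclass
class MinimalSubsets:
    size: int
    subsets: list[tuple[str, ...]]  # every witness of minimal size, by marker name


def minimal_discriminating_subsets(
    classes: Sequence[GenotypeClass],
    markers: Sequence[str],
) -> MinimalSubsets:
    """Exhaustive search for the smallest marker subsets keeping all class
    profiles distinct (all witnesses of the minimal size are returned)."""
    profiles = [c.profile for c in classes]
    if len(set(profiles)) != len(profiles):
        raise DataError("class profiles are not distinct on the full panel")
    if len(profiles) <= 1:
        return MinimalSubsets(size=0, subsets=[()])
    n = len(markers)
    for k in range(1, n + 1):
        witnesses = [
            tuple(markers[i] for i in subset)
            for subset in combinations(range(n), k)
            if _discriminates(profiles, subset)
        ]
        if witnesses:
            return MinimalSubsets(size=k, subsets=witnesses)
    raise DataError("full panel does not discriminate the classes")  # pragma: no cover


def greedy_discriminating_subset(
    classes: Sequence[GenotypeClass],
    markers: Sequence[str],
) -> tuple[str, ...]:
    """Greedy heuristic for large panels: repeatedly add the marker that
    splits the most currently-colliding class pairs."""
    profiles = [c.profile for c in classes]
    chosen: list[int] = []
    while not _discriminates(profiles, tuple(chosen)):
        best, best_gain = None, -1
        for i in range(len(markers)):
            if i in chosen:
                continue
            subset = tuple(chosen) + (i,)
            keys = [tuple(p[j] for j in subset) for p in profiles]
            gain = len(set(keys))
            if gain > best_gain:
                best, best_gain = i, gain
        if best is None:  # pragma: no cover
            raise DataError("full panel does not discriminate the classes")
        chosen.append(best)
    return tuple(markers[i] for i in chosen)
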