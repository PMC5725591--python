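"""Periclinal-chimera inference from tissue-level allelic fractions.

A periclinal chimera carries different genotypes in the meristem cell layers
L1 (epidermal lineage) and L2 (subepidermal lineage). Tissues sample the
layers in different proportions — berry flesh derives from L2 only, berry
skin and leaf from both — so the alternate-allele fraction observed in
tissue ``t`` is the linear mixture

    f_t = alpha_t * s1 + (1 - alpha_t) * s2

where ``alpha_t`` is the L1 cell fraction of the tissue and ``s1``, ``s2``
are the per-layer expected fractions (0, 0.5 or 1 for a diploid layer that
is hom-ref, het or hom-alt; states 0 and 1 are indistinguishable from a
hemizygous layer and are always flagged as such).

Inference is an exhaustive least-squares fit over the nine (s1, s2) pairs;
a chimeric (s1 != s2) solution is called only when it beats the best
non-chimeric solution by at least the decision margin ``tau`` (ties go to
the non-chimeric solution).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from itertools import product
from typing import Iterable, Mapping, Sequence

from .core_io import DataError


class FractionState(str, Enum):
    HOM_REF = "HOM_REF"
    HET = "HET"
    HOM_ALT = "HOM_ALT"
    INTERMEDIATE = "INTERMEDIATE"


DEFAULT_TISSUE_WEIGHTS = {"leaf": 0.5, "skin": 0.5, "flesh": 0.0}


@dataclass(frozen=True)
class LayerAssay:
    locus: str
    tissue: str
    alt_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alt_fraction <= 1.0:
            raise DataError(f"{self.locus}/{self.tissue}: fraction {self.alt_fraction} outside [0, 1]")


@dataclass(frozen=True)
class CallThresholds:
    hom_ref_max: float = 0.15
    het_low: float = 0.35
    het_high: float = 0.65
    hom_alt_min: float = 0.85

    def __post_init__(self) -> None:
        if not (self.hom_ref_max < self.het_low <= self.het_high < self.hom_alt_min):
            raise DataError("threshold bands must be disjoint and ordered")


@dataclass(frozen=True)
class ChimeraModelConfig:
    tissue_weights: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TISSUE_WEIGHTS))
    state_space: tuple[float, ...] = (0.0, 0.5, 1.0)
    thresholds: CallThresholds = field(default_factory=CallThresholds)
    decision_margin: float = 0.01  # tau

    def __post_init__(self) -> None:
        if any(not 0.0 <= a <= 1.0 for a in self.tissue_weights.values()):
            raise DataError("tissue L1 weights must lie in [0, 1]")


@dataclass(frozen=True)
class ChimeraInference:
    locus: str
    l1_state: float
    l2_state: float
    is_chimera: bool
    residual: float
    note: str = ""

    def __post_init__(self) -> None:
        assert self.is_chimera == (self.l1_state != self.l2_state)


def expected_fraction(l1_state: float, l2_state: float, alpha: float) -> float:
    """Mixture fraction alpha*s1 + (1-alpha)*s2 of a tissue with L1 weight alpha."""
    if not all(0.0 <= x <= 1.0 for x in (l1_state, l2_state, alpha)):
        raise DataError("states and alpha must lie in [0, 1]")
    return alpha * l1_state + (1.0 - alpha) * l2_state


def call_state(f: float, thresholds: CallThresholds | None = None) -> FractionState:
    """Banded classification of a single observed fraction."""
    t = thresholds or CallThresholds()
    if not 0.0 <= f <= 1.0:
        raise DataError(f"fraction {f} outside [0, 1]")
    if f <= t.hom_ref_max:
        return FractionState.HOM_REF
    if t.het_low <= f <= t.het_high:
        return FractionState.HET
    if f >= t.hom_alt_min:
        return FractionState.HOM_ALT
    return FractionState.INTERMEDIATE


_HEMIZYGOUS_NOTE = "hom/hemizygous indistinguishable"


def infer_layer_genotypes(
    assays: Sequence[LayerAssay],
    config: ChimeraModelConfig | None = None,
) -> ChimeraInference:
    """Least-squares inference of the (L1, L2) state pair for one locus."""
    config = config or ChimeraModelConfig()
    if not assays:
        raise DataError("no assays supplied")
    loci = {a.locus for a in assays}
    if len(loci) != 1:
        raise DataError(f"assays span multiple loci: {sorted(loci)}")
    locus = loci.pop()
    unknown = sorted({a.tissue for a in assays} - set(config.tissue_weights))
    if unknown:
        raise DataError(f"{locus}: unknown tissue(s) {unknown}")
    if len(assays) < 2:
        raise DataError(f"{locus}: need assays from at least two tissues")
    alphas = {config.tissue_weights[a.tissue] for a in assays}
    if len(alphas) < 2:
        raise DataError(f"{locus}: all tissues have the same L1 weight; layers are not identifiable")

    def sse(s1: float, s2: float) -> float:
        return sum(
            (a.alt_fraction - expected_fraction(s1, s2, config.tissue_weights[a.tissue])) ** 2
            for a in assays
        )

    fits = sorted(
        ((sse(s1, s2), s1, s2) for s1, s2 in product(config.state_space, repeat=2)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    best_nonchim = min((f for f in fits if f[1] == f[2]), key=lambda t: t[0])
    best_chim = min((f for f in fits if f[1] != f[2]), key=lambda t: t[0], default=None)

    if best_chim is not None and best_nonchim[0] - best_chim[0] >= config.decision_margin:
        residual, s1, s2 = best_chim
        is_chimera = True
    else:
        residual, s1, s2 = best_nonchim
        is_chimera = False
    note = _HEMIZYGOUS_NOTE if (s1 in (0.0, 1.0) or s2 in (0.0, 1.0)) else ""
    return ChimeraInference(locus, s1, s2, is_chimera, residual, note)


def infer_all_loci(
    assays: Iterable[LayerAssay],
    config: ChimeraModelConfig | None = None,
) -> list[ChimeraInference]:
    by_locus: dict[str, list[LayerAssay]] = {}
    for a in assays:
        by_locus.setdefault(a.locus, []).append(a)
    return [infer_layer_genotypes(group, config) for _, group in sorted(by_locus.items())]
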