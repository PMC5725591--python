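"""SNV retention cascade for multi-clone cohorts.

Two presets are provided. The default ``recalibrated`` cascade keeps a site
only if, in every clone, depth >= 15, and sitewise FS <= 10, QD >= 10,
|ReadPosRankSum| <= 2, no clone shows a third allele at >= 3 reads, and no
homozygous call carries more than 2 reads of the opposite allele. The
``initial_hard_filter`` preset reproduces the earlier, superseded hard-filter
wiring (QUAL < 100, depth outside [0.5x, 3x] the mean, SB > 0, FS < 1,
ReadPosRankSum outside [-2, 2.5], AF < 0.2); it is kept because its rules are
individually exercisable, not because it is recommended.

All inequalities are strict exactly as configured: FS == 10.0 passes the
FS > 10 rule. Absent annotations never fail their rule (rank-sum statistics
are legitimately absent at sites without heterozygous carriers).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

from .core_io import DataError, GenotypeCategory, RegionMask, VariantRecord


class FilterReason(str, Enum):
    IN_REPEAT = "IN_REPEAT"
    SPURIOUS_ALLELE = "SPURIOUS_ALLELE"
    LOW_COVERAGE = "LOW_COVERAGE"
    HIGH_FS = "HIGH_FS"
    LOW_QD = "LOW_QD"
    BAD_READ_POS = "BAD_READ_POS"
    DISCORDANT_HOM = "DISCORDANT_HOM"
    INADEQUATE_COVERAGE_ANY_CLONE = "INADEQUATE_COVERAGE_ANY_CLONE"
    QUAL_LOW = "QUAL_LOW"
    COVERAGE_BOUNDS = "COVERAGE_BOUNDS"
    STRAND_BIAS = "STRAND_BIAS"
    LOW_AF = "LOW_AF"


@dataclass(frozen=True)
class FilterParams:
    """Thresholds of the retention cascade.

    ``rprs_two_sided=True`` tests |ReadPosRankSum| > threshold; the literal
    one-sided reading (discard only the positive tail) is available by
    setting it to False.
    """

    min_depth: int = 15
    max_fs: float = 10.0
    min_qd: float = 10.0
    max_read_pos_rank_sum: float = 2.0
    rprs_two_sided: bool = True
    max_discordant_reads: int = 2
    allele_detection_min_reads: int = 3
    preset: str = "recalibrated"  # or "initial_hard_filter"
    # initial_hard_filter thresholds
    min_qual: float = 100.0
    mean_depth: float = 30.0
    depth_bounds: tuple[float, float] = (0.5, 3.0)
    min_fs_initial: float = 1.0
    rprs_bounds_initial: tuple[float, float] = (-2.0, 2.5)
    min_af: float = 0.2

    def __post_init__(self) -> None:
        if min(self.min_depth, self.max_fs, self.min_qd, self.max_read_pos_rank_sum,
               self.max_discordant_reads, self.allele_detection_min_reads) < 0:
            raise DataError("filter thresholds must be non-negative")
        if self.preset not in ("recalibrated", "initial_hard_filter"):
            raise DataError(f"unknown preset {self.preset!r}")


@dataclass(frozen=True)
class FilterDecision:
    passed: bool
    reasons: frozenset[FilterReason]

    def __post_init__(self) -> None:
        assert self.passed == (not self.reasons)


@dataclass
class FilterSummary:
    """Per-reason counts (a record may count toward several reasons)."""

    n_input: int = 0
    n_passed: int = 0
    n_rejected: int = 0
    reason_counts: Counter = field(default_factory=Counter)

    def as_dict(self) -> dict:
        return {
            "records_input": self.n_input,
            "records_passed": self.n_passed,
            "records_rejected": self.n_rejected,
            "reasons": {r.value: self.reason_counts.get(r, 0) for r in FilterReason},
        }


def _spurious(record: VariantRecord, params: FilterParams) -> bool:
    for call in record.calls.values():
        if call.category is GenotypeCategory.MULTI:
            return True
        supported = sum(1 for d in call.allele_depths.values() if d >= params.allele_detection_min_reads)
        if supported >= 3:
            return True
    return False


def _discordant_hom(record: VariantRecord, params: FilterParams) -> bool:
    for call in record.calls.values():
        ref_reads = call.allele_depths.get(record.ref, 0)
        alt_reads = sum(d for a, d in call.allele_depths.items() if a != record.ref)
        if call.category is GenotypeCategory.HOM_ALT and ref_reads > params.max_discordant_reads:
            return True
        if call.category is GenotypeCategory.HOM_REF and alt_reads > params.max_discordant_reads:
            return True
    return False


def evaluate_filters(record: VariantRecord, mask: RegionMask, params: FilterParams | None = None) -> FilterDecision:
    """Evaluate every rule of the configured preset; all violations are reported."""
    params = params or FilterParams()
    reasons: set[FilterReason] = set()
    if mask.covers(record.chrom, record.pos):
        reasons.add(FilterReason.IN_REPEAT)
    if _spurious(record, params):
        reasons.add(FilterReason.SPURIOUS_ALLELE)

    if params.preset == "recalibrated":
        for clone, call in record.calls.items():
            if call.depth == 0 and not call.allele_depths:
                raise DataError(f"{record.chrom}:{record.pos}: clone {clone} has no depth data")
        if any(call.depth < params.min_depth for call in record.calls.values()):
            # one threshold realizes both the per-site coverage rule and the
            # "not adequately covered in at least one clone" exclusion; both
            # labels are kept for traceability.
            reasons.add(FilterReason.LOW_COVERAGE)
            reasons.add(FilterReason.INADEQUATE_COVERAGE_ANY_CLONE)
        ann = record.ann
        if ann.fs is not None and ann.fs > params.max_fs:
            reasons.add(FilterReason.HIGH_FS)
        if ann.qd is not None and ann.qd < params.min_qd:
            reasons.add(FilterReason.LOW_QD)
        rprs = ann.read_pos_rank_sum
        if rprs is not None:
            bad = abs(rprs) > params.max_read_pos_rank_sum if params.rprs_two_sided \
                else rprs > params.max_read_pos_rank_sum
            if bad:
                reasons.add(FilterReason.BAD_READ_POS)
        if _discordant_hom(record, params):
            reasons.add(FilterReason.DISCORDANT_HOM)
    else:  # initial_hard_filter
        ann = record.ann
        if ann.qual < params.min_qual:
            reasons.add(FilterReason.QUAL_LOW)
        lo = params.depth_bounds[0] * params.mean_depth
        hi = params.depth_bounds[1] * params.mean_depth
        if any(not (lo <= call.depth <= hi) for call in record.calls.values()):
            reasons.add(FilterReason.COVERAGE_BOUNDS)
        if ann.sb is not None and ann.sb > 0:
            reasons.add(FilterReason.STRAND_BIAS)
        if ann.fs is not None and ann.fs < params.min_fs_initial:
            reasons.add(FilterReason.HIGH_FS)
        if ann.read_pos_rank_sum is not None and not (
            params.rprs_bounds_initial[0] <= ann.read_pos_rank_sum <= params.rprs_bounds_initial[1]
        ):
            reasons.add(FilterReason.BAD_READ_POS)
        if ann.af is not None and ann.af < params.min_af:
            reasons.add(FilterReason.LOW_AF)

    return FilterDecision(passed=not reasons, reasons=frozenset(reasons))


def filter_cohort(
    records: Iterable[VariantRecord],
    mask: RegionMask,
    params: FilterParams | None = None,
) -> tuple[list[VariantRecord], list[tuple[VariantRecord, FilterDecision]], FilterSummary]:
    """Partition records into passing and rejected sets with a per-reason summary."""
    params = params or FilterParams()
    passing: list[VariantRecord] = []
    rejected: list[tuple[VariantRecord, FilterDecision]] = []
    summary = FilterSummary()
    for record in records:
        summary.n_input += 1
        decision = evaluate_filters(record, mask, params)
        if decision.passed:
            passing.append(record)
            summary.n_passed += 1
        else:
            rejected.append((record, decision))
            summary.n_rejected += 1
            summary.reason_counts.update(decision.reasons)
    return passing, rejected, summary


def write_rejected_tsv(rejected: Sequence[tuple[VariantRecord, FilterDecision]], path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\treasons\n")
        for record, decision in rejected:
            reasons = ",".join(sorted(r.value for r in decision.reasons))
            fh.write(f"{record.chrom}\t{record.pos}\t{record.ref}\t{','.join(record.alts)}\t{reasons}\n")
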