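"""In-phase allele counting, exclusion rules, and per-million normalization.

RNA levels are measured as in-phase read counts: a read counts for one
allele of a heterozygous pair only if it perfectly matches that allele's
window-containing reference, overlaps the polymorphic-exon window, and does
not also perfectly match the partner allele.  Homozygous, partially phased
and hemizygous configurations are excluded from comparative datasets
because their reads cannot be divided between alleles.  Counts are
standardized by window target size (reads per base) and scaled so each
sample's selected locus set totals one million.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype import ExactMatcher, GenotypeCall
from .reference import (
    AlleleReference,
    ExonWindow,
    Locus,
    PartialReferenceError,
    ReferenceSet,
    WINDOW_SPECS,
    extract_window,
)

__all__ = [
    "PhaseStatus",
    "LocusSetConfig",
    "locus_set",
    "LOCUS_SETS",
    "classify_phase",
    "assign_in_phase",
    "count_in_phase",
    "count_pair",
    "standardize_by_size",
    "normalize_to_million",
    "quantify_sample",
    "build_dataset",
    "SampleQuant",
    "AllZeroSampleError",
]

MILLION = 1_000_000.0


class AllZeroSampleError(ValueError):
    """All size-standardized counts of a sample are zero."""


class PhaseStatus(str, enum.Enum):
    COMPLETELY_PHASED = "completely_phased"
    PARTIALLY_PHASED = "partially_phased"
    HOMOZYGOUS = "homozygous"
    HEMIZYGOUS = "hemizygous"
    ABSENT = "absent"


@dataclass(frozen=True)
class LocusSetConfig:
    """One of the four comparative locus sets."""

    set_id: int
    loci: frozenset[Locus]
    drb345_included: bool


_CLASS_II_CORE = frozenset(
    {Locus.DPA1, Locus.DPB1, Locus.DQA1, Locus.DQB1, Locus.DRA, Locus.DRB1}
)
_DRB345 = frozenset({Locus.DRB3, Locus.DRB4, Locus.DRB5})

LOCUS_SETS: Mapping[int, LocusSetConfig] = {
    1: LocusSetConfig(1, frozenset(Locus), True),
    2: LocusSetConfig(2, frozenset({Locus.A, Locus.B, Locus.C}), False),
    3: LocusSetConfig(3, _CLASS_II_CORE, False),
    4: LocusSetConfig(4, _CLASS_II_CORE | _DRB345, True),
}


def locus_set(set_id: int) -> LocusSetConfig:
    """Set 1: all 12 loci; set 2: class I; set 3: class II without
    DRB3/4/5; set 4: class II with DRB3/4/5."""
    try:
        return LOCUS_SETS[set_id]
    except KeyError:
        raise ValueError(f"locus set id must be 1-4, got {set_id}") from None


def classify_phase(
    call: GenotypeCall, panel: ReferenceSet, window: ExonWindow | None = None
) -> PhaseStatus:
    """Classify a genotype call for inclusion in comparative datasets.

    A heterozygous pair is completely phased when its window sequences
    differ in *every* window exon (each exon's reads are then assignable);
    differing in only some exons gives partial phasing; identical window
    sequences behave as homozygous.  Partial references (missing a window
    exon) classify as partially phased.
    """
    if call.zygosity == "absent":
        return PhaseStatus.ABSENT
    if call.zygosity == "hemizygous":
        return PhaseStatus.HEMIZYGOUS
    if call.zygosity == "homozygous":
        return PhaseStatus.HOMOZYGOUS
    if window is None:
        window = WINDOW_SPECS[call.locus]
    ref_a, ref_b = (panel[n] for n in call.allele_pair)
    try:
        exons_a = [ref_a.exon_sequence(e) for e in window.exon_ids]
        exons_b = [ref_b.exon_sequence(e) for e in window.exon_ids]
    except PartialReferenceError:
        return PhaseStatus.PARTIALLY_PHASED
    differs = [a != b for a, b in zip(exons_a, exons_b)]
    if all(differs):
        return PhaseStatus.COMPLETELY_PHASED
    if any(differs):
        return PhaseStatus.PARTIALLY_PHASED
    return PhaseStatus.HOMOZYGOUS


def _window_intervals(ref: AlleleReference, window: ExonWindow) -> list[tuple[int, int]]:
    return [ref.exon_interval(e) for e in window.exon_ids]


def assign_in_phase(
    reads: Iterable[tuple[str, str]],
    ref_x: AlleleReference,
    ref_y: AlleleReference,
) -> list[tuple[str, str | None]]:
    """Per-read in-phase assignment for a phased allele pair.

    Each read is labelled ``"x"`` or ``"y"`` when it perfectly matches that
    allele's reference with >=1 base of window overlap and does not
    perfectly match the other allele at all; ``"ambiguous"`` when it
    perfectly matches both (out of phase); ``None`` otherwise.
    """
    win_x = _window_intervals(ref_x, WINDOW_SPECS[ref_x.name.locus])
    win_y = _window_intervals(ref_y, WINDOW_SPECS[ref_y.name.locus])
    matcher = ExactMatcher([ref_x, ref_y])
    key_x = ref_x.name.render()

    out: list[tuple[str, str | None]] = []
    for read_id, seq in reads:
        in_x = win_hit_x = in_y = win_hit_y = False
        for ref, s, e, _ in matcher.match(seq.upper()):
            if ref.name.render() == key_x:
                in_x = True
                win_hit_x = win_hit_x or any(s < we and e > ws for ws, we in win_x)
            else:
                in_y = True
                win_hit_y = win_hit_y or any(s < we and e > ws for ws, we in win_y)
        if in_x and in_y:
            label = "ambiguous" if (win_hit_x or win_hit_y) else None
        elif in_x and win_hit_x:
            label = "x"
        elif in_y and win_hit_y:
            label = "y"
        else:
            label = None
        out.append((read_id, label))
    return out


def count_pair(
    reads: Iterable[tuple[str, str]],
    ref_x: AlleleReference,
    ref_y: AlleleReference,
    split_ambiguous: bool = False,
) -> tuple[float, float, int]:
    """In-phase counts for a phased allele pair (possibly cross-paralog).

    Aggregates :func:`assign_in_phase`: reads matching both alleles are out
    of phase — discarded by default, or split 0.5/0.5 when
    ``split_ambiguous``.  Mates are independent reads here; callers
    deduplicate by read_id if a pair should count once.
    """
    count_x = count_y = 0.0
    n_ambiguous = 0
    for _, label in assign_in_phase(reads, ref_x, ref_y):
        if label == "x":
            count_x += 1
        elif label == "y":
            count_y += 1
        elif label == "ambiguous":
            n_ambiguous += 1
            if split_ambiguous:
                count_x += 0.5
                count_y += 0.5
    return count_x, count_y, n_ambiguous


def count_in_phase(
    reads: Iterable[tuple[str, str]],
    call: GenotypeCall,
    panel: ReferenceSet,
    window: ExonWindow | None = None,
    split_ambiguous: bool = False,
) -> dict[str, float]:
    """Raw in-phase counts per allele of a completely phased locus call."""
    if classify_phase(call, panel, window) is not PhaseStatus.COMPLETELY_PHASED:
        raise ValueError(
            f"{call.locus}: in-phase counting requires a completely phased "
            f"heterozygous call"
        )
    ref_x, ref_y = (panel[n] for n in call.allele_pair)
    cx, cy, _ = count_pair(reads, ref_x, ref_y, split_ambiguous=split_ambiguous)
    return {ref_x.name.render(): cx, ref_y.name.render(): cy}


def standardize_by_size(raw: float, target_size_bp: int) -> float:
    """Reads per base of mapping-window target."""
    if target_size_bp <= 0:
        raise ValueError("target_size_bp must be positive")
    if raw < 0:
        raise ValueError("raw count must be non-negative")
    return raw / target_size_bp


def normalize_to_million(size_standardized: Sequence[float]) -> np.ndarray:
    """Scale a sample's size-standardized counts to sum to one million."""
    values = np.asarray(size_standardized, dtype=float)
    if values.size == 0:
        raise AllZeroSampleError("no values to normalize")
    if (values < 0).any():
        raise ValueError("size-standardized counts must be non-negative")
    total = values.sum()
    if total <= 0:
        raise AllZeroSampleError("all size-standardized counts are zero")
    return values * (MILLION / total)


@dataclass
class AlleleQuant:
    allele: str
    locus: Locus
    raw_reads: float
    target_size_bp: int

    @property
    def size_standardized(self) -> float:
        return standardize_by_size(self.raw_reads, self.target_size_bp)


@dataclass
class SampleQuant:
    """Per-sample quantification state: phase statuses and raw counts."""

    sample_id: str
    locus_status: dict[Locus, PhaseStatus] = field(default_factory=dict)
    drb_group_status: PhaseStatus = PhaseStatus.ABSENT
    counts: list[AlleleQuant] = field(default_factory=list)
    exclusions: dict[str, str] = field(default_factory=dict)

    def qc_record(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "locus_status": {l.value: s.value for l, s in self.locus_status.items()},
            "drb_group_status": self.drb_group_status.value,
            "exclusions": dict(self.exclusions),
        }


def quantify_sample(
    sample_id: str,
    reads: Sequence[tuple[str, str]],
    calls: Mapping[Locus, GenotypeCall],
    panel: ReferenceSet,
    split_ambiguous: bool = False,
) -> SampleQuant:
    """Classify phase and count in-phase reads for every locus of a sample.

    The DRB3/DRB4/DRB5 paralogs are treated as one compound group: a sample
    with two distinguishable group alleles (e.g. DRB3 on one haplotype,
    DRB4 on the other) is completely phased for the group and the two
    alleles are counted against each other; one group allele is hemizygous
    and excluded.
    """
    sq = SampleQuant(sample_id)
    drb_alleles: list[AlleleReference] = []
    for locus, call in calls.items():
        status = classify_phase(call, panel)
        sq.locus_status[locus] = status
        if locus.is_drb_paralog:
            for name in call.allele_pair:
                drb_alleles.append(panel[name])
            continue
        if status is not PhaseStatus.COMPLETELY_PHASED:
            if status is not PhaseStatus.ABSENT:
                sq.exclusions[locus.value] = status.value
            continue
        counts = count_in_phase(reads, call, panel, split_ambiguous=split_ambiguous)
        for allele, raw in counts.items():
            size = len(extract_window(panel[allele], WINDOW_SPECS[locus]))
            sq.counts.append(AlleleQuant(allele, locus, raw, size))

    # DRB3/4/5 compound group
    if len(drb_alleles) == 2:
        wa = extract_window(drb_alleles[0], WINDOW_SPECS[drb_alleles[0].name.locus])
        wb = extract_window(drb_alleles[1], WINDOW_SPECS[drb_alleles[1].name.locus])
        if drb_alleles[0].name.locus is drb_alleles[1].name.locus and wa == wb:
            sq.drb_group_status = PhaseStatus.HOMOZYGOUS
            sq.exclusions["DRB3/4/5"] = "homozygous-by-window"
        else:
            sq.drb_group_status = PhaseStatus.COMPLETELY_PHASED
            cx, cy, _ = count_pair(
                reads, drb_alleles[0], drb_alleles[1], split_ambiguous=split_ambiguous
            )
            for ref, raw in zip(drb_alleles, (cx, cy)):
                size = len(extract_window(ref, WINDOW_SPECS[ref.name.locus]))
                sq.counts.append(
                    AlleleQuant(ref.name.render(), ref.name.locus, raw, size)
                )
    elif len(drb_alleles) == 1:
        sq.drb_group_status = PhaseStatus.HEMIZYGOUS
        sq.exclusions["DRB3/4/5"] = "hemizygous"
    elif len(drb_alleles) > 2:
        sq.drb_group_status = PhaseStatus.PARTIALLY_PHASED
        sq.exclusions["DRB3/4/5"] = f"{len(drb_alleles)} group alleles called"
    return sq


DATASET_COLUMNS = [
    "sample_id",
    "set_id",
    "locus",
    "allele",
    "raw_reads",
    "target_size_bp",
    "size_standardized",
    "normalized_reads",
]


def build_dataset(
    samples: Iterable[SampleQuant], set_config: LocusSetConfig
) -> pd.DataFrame:
    """Long-format normalized count table for one locus set.

    Per sample: keep completely phased loci belonging to the set; for sets
    that include DRB3/4/5 the sample must carry two distinguishable group
    alleles, otherwise it is excluded from the set entirely.  Counts are
    renormalized within the set so each retained sample sums to one
    million.
    """
    rows = []
    for sq in samples:
        if set_config.drb345_included and (
            sq.drb_group_status is not PhaseStatus.COMPLETELY_PHASED
        ):
            continue
        quants = [
            q
            for q in sq.counts
            if q.locus in set_config.loci
            and (set_config.drb345_included or not q.locus.is_drb_paralog)
        ]
        if not quants:
            continue
        std = [q.size_standardized for q in quants]
        try:
            normalized = normalize_to_million(std)
        except AllZeroSampleError:
            continue  # flagged upstream; sample carries no signal in this set
        for q, s, n in zip(quants, std, normalized):
            rows.append(
                (
                    sq.sample_id,
                    set_config.set_id,
                    q.locus.value,
                    q.allele,
                    q.raw_reads,
                    q.target_size_bp,
                    s,
                    n,
                )
            )
    return pd.DataFrame(rows, columns=DATASET_COLUMNS)
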