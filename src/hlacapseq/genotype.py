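"""Perfect-match read assignment and genotype calling.

Reads are assigned to panel alleles only when the full read (or its reverse
complement) occurs as an exact substring of the allele's reference
sequence — the 100%-matched condition that avoids mismapping between the
highly similar HLA loci.  Genotypes are then called per locus by selecting
the allele pair that explains the most reads, scored by unique support
(reads hitting exactly one member of the pair), with a deterministic
lexicographic tie-break.  Reads that fail the perfect-match filter but sit
one substitution away from a called allele are aggregated into
novel-variant candidates.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import pandas as pd

from .reference import (
    AlleleName,
    AlleleReference,
    Locus,
    ReferenceSet,
    WINDOW_SPECS,
)
from .simulate import reverse_complement

__all__ = [
    "ReadHit",
    "GenotypeCall",
    "NovelVariantCandidate",
    "ExactMatcher",
    "match_reads",
    "call_genotype",
    "flag_novel_variants",
]

HIT_COLUMNS = ["read_id", "allele", "start", "end", "orientation"]


@dataclass(frozen=True)
class ReadHit:
    """An exact full-length occurrence of a read on an allele reference."""

    read_id: str
    allele: AlleleName
    start: int
    end: int
    orientation: str  # "+" or "-"


@dataclass
class GenotypeCall:
    """A per-locus diploid call with support and phase/zygosity status."""

    locus: Locus
    allele_pair: tuple[AlleleName, ...]
    zygosity: str  # heterozygous | homozygous | hemizygous | absent
    support: dict[str, int] = field(default_factory=dict)
    ambiguity_note: list[tuple[str, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.zygosity == "heterozygous" and (
            len(self.allele_pair) != 2 or self.allele_pair[0] == self.allele_pair[1]
        ):
            raise ValueError("heterozygous call requires two distinct alleles")
        if self.zygosity == "hemizygous" and not self.locus.is_drb_paralog:
            raise ValueError("hemizygous calls are only valid for DRB3/DRB4/DRB5")
        if any(v < 0 for v in self.support.values()):
            raise ValueError("support counts must be non-negative")


@dataclass(frozen=True)
class NovelVariantCandidate:
    """A single-substitution deviation from a called allele.

    ``position`` is the coordinate within the concatenated mapping-window
    sequence of ``nearest_allele``.
    """

    locus: Locus
    nearest_allele: AlleleName
    position: int
    observed_base: str
    supporting_reads: int


class ExactMatcher:
    """k-mer seeded exact-substring search over a reference panel.

    The contract is exact-substring semantics only: a hit exists iff the
    full read, or its reverse complement, occurs verbatim in an allele
    sequence.  The seed table (first k bases) merely accelerates the scan;
    reads shorter than k fall back to a direct scan.
    """

    def __init__(self, panel: Iterable[AlleleReference], k: int = 24) -> None:
        self.alleles = list(panel)
        if not self.alleles:
            raise ValueError("empty reference panel")
        self.k = k
        self._index: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for ai, ref in enumerate(self.alleles):
            seq = ref.sequence
            for pos in range(len(seq) - k + 1):
                self._index[seq[pos : pos + k]].append((ai, pos))

    def _scan(self, read: str, orientation: str) -> list[tuple[int, int, int, str]]:
        hits = []
        n = len(read)
        if n >= self.k:
            for ai, pos in self._index.get(read[: self.k], ()):
                if self.alleles[ai].sequence[pos : pos + n] == read:
                    hits.append((ai, pos, pos + n, orientation))
        else:
            for ai, ref in enumerate(self.alleles):
                start = ref.sequence.find(read)
                while start != -1:
                    hits.append((ai, start, start + n, orientation))
                    start = ref.sequence.find(read, start + 1)
        return hits

    def match(self, read: str) -> list[tuple[AlleleReference, int, int, str]]:
        """All exact occurrences of ``read`` (forward or reverse-complement)."""
        read = read.upper()
        raw = self._scan(read, "+")
        rc = reverse_complement(read)
        raw += self._scan(rc, "-")
        return [(self.alleles[ai], s, e, o) for ai, s, e, o in raw]


def match_reads(
    reads: Iterable[tuple[str, str]],
    panel: ReferenceSet | Sequence[AlleleReference],
    k: int = 24,
) -> pd.DataFrame:
    """Exact-match every read against every panel allele.

    ``reads`` yields ``(read_id, sequence)``.  N-containing reads never
    match (references are unambiguous A/C/G/T).  Returns a hit table with
    columns ``read_id, allele, start, end, orientation`` listing all hits
    across all alleles.
    """
    matcher = ExactMatcher(list(panel), k=k)
    rows = []
    for read_id, seq in reads:
        for ref, start, end, orientation in matcher.match(seq):
            rows.append((read_id, ref.name.render(), start, end, orientation))
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def _reads_restricted_to_locus(
    hits: pd.DataFrame, locus: Locus
) -> dict[str, frozenset[str]]:
    """Map read_id -> alleles hit at ``locus``, excluding cross-locus reads.

    Reads that also hit alleles of a different locus are dropped entirely
    (they cannot discriminate between loci under perfect-match semantics).
    """
    if hits.empty:
        return {}
    by_read: dict[str, set[str]] = defaultdict(set)
    cross: set[str] = set()
    for read_id, allele in zip(hits["read_id"], hits["allele"]):
        read_locus = allele.split("*", 1)[0]
        if read_locus == locus.value:
            by_read[read_id].add(allele)
        else:
            cross.add(read_id)
    return {
        rid: frozenset(alleles)
        for rid, alleles in by_read.items()
        if rid not in cross
    }


def call_genotype(
    hits: pd.DataFrame,
    locus: Locus,
    min_unique_support: int = 10,
    max_candidates: int = 50,
) -> GenotypeCall:
    """Call the diploid genotype at one locus from the hit table.

    Pair selection maximizes the number of explained reads (reads hitting
    either member), then total unique support (reads hitting exactly one
    member), with remaining ties resolved lexicographically and recorded in
    ``ambiguity_note``.  A single allele explaining all locus reads gives a
    homozygous call (hemizygous at the DRB3/4/5 paralogs, where a
    one-haplotype gene is the common configuration and read data cannot
    distinguish one copy from two identical copies).  A heterozygous
    partner must reach ``min_unique_support`` unique reads, else the call
    collapses to the better-supported allele.
    """
    read_alleles = _reads_restricted_to_locus(hits, locus)
    if not read_alleles:
        return GenotypeCall(locus, (), "absent")

    allele_reads: dict[str, set[str]] = defaultdict(set)
    for rid, alleles in read_alleles.items():
        for a in alleles:
            allele_reads[a].add(rid)
    candidates = sorted(
        allele_reads, key=lambda a: (-len(allele_reads[a]), a)
    )[:max_candidates]
    total_reads = len(read_alleles)

    def pair_score(pair: tuple[str, ...]) -> tuple[int, int]:
        if len(pair) == 1:
            explained = unique = len(allele_reads[pair[0]])
            return explained, unique
        ra, rb = allele_reads[pair[0]], allele_reads[pair[1]]
        explained = len(ra | rb)
        unique = len(ra - rb) + len(rb - ra)
        return explained, unique

    scored: list[tuple[int, int, tuple[str, ...]]] = []
    for a in candidates:
        scored.append((*pair_score((a,)), (a,)))
    for a, b in combinations(candidates, 2):
        pair = tuple(sorted((a, b)))
        scored.append((*pair_score(pair), pair))

    best_explained = max(s[0] for s in scored)
    best = [s for s in scored if s[0] == best_explained]
    # homozygous call when one allele alone explains every locus read
    singles = [s for s in best if len(s[2]) == 1 and s[0] == total_reads]
    if singles:
        best = singles
    best_unique = max(s[1] for s in best)
    best = sorted(s[2] for s in best if s[1] == best_unique)
    winner = best[0]
    ties = [p for p in best[1:]]

    if len(winner) == 2:
        ra, rb = allele_reads[winner[0]], allele_reads[winner[1]]
        ua, ub = len(ra - rb), len(rb - ra)
        weaker = min(ua, ub)
        if weaker < min_unique_support:
            keep = winner[0] if ua >= ub else winner[1]
            winner, ties = (keep,), []
            support = {keep: len(allele_reads[keep])}
        else:
            support = {winner[0]: ua, winner[1]: ub}
    if len(winner) == 1:
        support = {winner[0]: len(allele_reads[winner[0]])}
        zygosity = "hemizygous" if locus.is_drb_paralog else "homozygous"
    else:
        zygosity = "heterozygous"

    from .reference import parse_allele_name

    return GenotypeCall(
        locus,
        tuple(parse_allele_name(a) for a in winner),
        zygosity,
        support,
        [tuple(t) for t in ties],
    )


def _one_mismatch_alignments(read: str, seq: str) -> list[tuple[int, int, str]]:
    """Full-length alignments of ``read`` on ``seq`` with exactly 1 mismatch.

    Returns ``(offset, mismatch_position_on_seq, observed_base)`` triples.
    A single substitution leaves at least one read half intact, so exact
    occurrences of each half anchor the candidate offsets.
    """
    n = len(read)
    half = n // 2
    offsets: set[int] = set()
    for piece, shift in ((read[:half], 0), (read[half:], half)):
        if not piece:
            continue
        start = seq.find(piece)
        while start != -1:
            offsets.add(start - shift)
            start = seq.find(piece, start + 1)
    out = []
    for off in sorted(offsets):
        if off < 0 or off + n > len(seq):
            continue
        mismatches = [
            i for i in range(n) if read[i] != seq[off + i]
        ]
        if len(mismatches) == 1:
            i = mismatches[0]
            out.append((off, off + i, read[i]))
    return out


def flag_novel_variants(
    reads: Iterable[tuple[str, str]],
    call: GenotypeCall,
    panel: ReferenceSet,
    min_support: int = 10,
) -> list[NovelVariantCandidate]:
    """Aggregate single-substitution deviations from the called alleles.

    A read that perfectly matches no panel allele but aligns to a called
    allele's window with exactly one substitution votes for that
    (position, base); positions reaching ``min_support`` distinct reads
    become candidates.  Positions outside the mapping window are ignored.
    """
    if not call.allele_pair:
        return []
    matcher = ExactMatcher(list(panel))
    refs = [panel[name] for name in call.allele_pair]
    windows = {}
    for ref in refs:
        window = WINDOW_SPECS[ref.name.locus]
        # map reference coordinate -> concatenated-window coordinate
        coord_map: dict[int, int] = {}
        offset = 0
        for exon_id in window.exon_ids:
            s, e = ref.exon_interval(exon_id)
            for p in range(s, e):
                coord_map[p] = offset + (p - s)
            offset += e - s
        windows[ref.name.render()] = coord_map

    votes: dict[tuple[str, int, str], set[str]] = defaultdict(set)
    for read_id, seq in reads:
        seq = seq.upper()
        if "N" in seq:
            continue
        if matcher.match(seq):
            continue  # perfectly matched somewhere; not a variant read
        for ref in refs:
            for oriented in (seq, reverse_complement(seq)):
                for _, ref_pos, base in _one_mismatch_alignments(
                    oriented, ref.sequence
                ):
                    win_pos = windows[ref.name.render()].get(ref_pos)
                    if win_pos is not None:
                        votes[(ref.name.render(), win_pos, base)].add(read_id)

    out = []
    for (allele, pos, base), readers in sorted(votes.items()):
        if len(readers) >= min_support:
            from .reference import parse_allele_name

            name = parse_allele_name(allele)
            out.append(
                NovelVariantCandidate(name.locus, name, pos, base, len(readers))
            )
    return out
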