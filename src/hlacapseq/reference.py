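"""HLA loci, allele nomenclature, and allele reference sequences.

The 12 classical HLA loci (class I: A, B, C; class II: DPA1, DPB1, DQA1,
DQB1, DRA, DRB1 and the secondary DR paralogs DRB3/DRB4/DRB5) are modelled
together with allele names in standard colon-delimited nomenclature
(``locus*f1:f2[:f3[:f4]][suffix]``), reference sequences annotated with exon
coordinates, and the fixed polymorphic-exon mapping windows used for
perfect-match read counting: exons 2+3 (546 bp) for class I, exon 2 for
class II (239–270 bp depending on locus).

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Locus",
    "AlleleName",
    "AlleleReference",
    "ReferenceSet",
    "ExonWindow",
    "ProbeSet",
    "AlleleNameError",
    "ReferenceError",
    "PartialReferenceError",
    "parse_allele_name",
    "mapping_window",
    "extract_window",
    "load_reference_set",
    "write_reference_set",
    "WINDOW_SPECS",
]


class AlleleNameError(ValueError):
    """Raised when text does not follow HLA allele nomenclature."""


class ReferenceError(ValueError):
    """Raised when a reference panel fails validation at load time."""


class PartialReferenceError(KeyError):
    """Raised when a reference lacks an exon required by a mapping window."""


class Locus(enum.Enum):
    """One of the 12 classical HLA loci."""

    A = "A"
    B = "B"
    C = "C"
    DPA1 = "DPA1"
    DPB1 = "DPB1"
    DQA1 = "DQA1"
    DQB1 = "DQB1"
    DRA = "DRA"
    DRB1 = "DRB1"
    DRB3 = "DRB3"
    DRB4 = "DRB4"
    DRB5 = "DRB5"

    @property
    def hla_class(self) -> str:
        """``"I"`` for A/B/C, ``"II"`` otherwise."""
        return "I" if self.value in ("A", "B", "C") else "II"

    @property
    def is_drb_paralog(self) -> bool:
        """True for the secondary DR beta paralogs DRB3/DRB4/DRB5.

        At most one of these genes is carried per haplotype, so samples may
        be hemizygous or lack them entirely.
        """
        return self.value in ("DRB3", "DRB4", "DRB5")

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Expression-variant suffixes of the HLA nomenclature (N = null, L = low,
#: S = secreted, Q = questionable, C = cytoplasm, A = aberrant).
EXPRESSION_SUFFIXES = frozenset("NLSQCA")

_LOCUS_ALT = "|".join(sorted((l.value for l in Locus), key=len, reverse=True))
_NAME_RE = re.compile(
    rf"^(?:HLA-)?({_LOCUS_ALT})\*"
    r"(\d{1,4}):(\d{1,4})(?::(\d{1,4}))?(?::(\d{1,4}))?"
    r"([NLSQCA])?$"
)


@dataclass(frozen=True, order=True)
class AlleleName:
    """A structured HLA allele name.

    Fields 1 and 2 are mandatory (allele group / protein); fields 3 and 4
    distinguish synonymous and non-coding variants.  An optional one-letter
    suffix marks expression variants (e.g. ``N`` for null alleles).
    """

    locus: Locus
    field1: int
    field2: int
    field3: int | None = None
    field4: int | None = None
    suffix: str | None = None

    def __post_init__(self) -> None:
        for f in (self.field1, self.field2):
            if f is None or f < 0:
                raise AlleleNameError(f"fields 1 and 2 are required: {self!r}")
        if self.field4 is not None and self.field3 is None:
            raise AlleleNameError(f"field 4 requires field 3: {self!r}")
        if self.suffix is not None and self.suffix not in EXPRESSION_SUFFIXES:
            raise AlleleNameError(
                f"unknown expression suffix {self.suffix!r} (expected one of "
                f"{''.join(sorted(EXPRESSION_SUFFIXES))})"
            )

    @property
    def resolution(self) -> int:
        """Finest field level present (2, 3 or 4)."""
        if self.field4 is not None:
            return 4
        if self.field3 is not None:
            return 3
        return 2

    def at_resolution(self, level: int) -> "AlleleName":
        """Truncate to ``level`` fields (suffix retained)."""
        if not 2 <= level <= 4:
            raise ValueError("resolution level must be 2, 3 or 4")
        return AlleleName(
            self.locus,
            self.field1,
            self.field2,
            self.field3 if level >= 3 else None,
            self.field4 if level >= 4 else None,
            self.suffix,
        )

    def render(self) -> str:
        parts = [f"{self.field1:02d}", f"{self.field2:02d}"]
        if self.field3 is not None:
            parts.append(f"{self.field3:02d}")
        if self.field4 is not None:
            parts.append(f"{self.field4:02d}")
        return f"{self.locus.value}*{':'.join(parts)}{self.suffix or ''}"

    def __str__(self) -> str:
        return self.render()


def parse_allele_name(text: str) -> AlleleName:
    """Parse ``locus*f1:f2[:f3[:f4]][suffix]`` (optionally ``HLA-`` prefixed).

    >>> parse_allele_name("A*02:15N")
    AlleleName(locus=<Locus.A: 'A'>, field1=2, field2=15, field3=None, field4=None, suffix='N')
    """
    if not isinstance(text, str):
        raise AlleleNameError(f"allele name must be a string, got {type(text).__name__}")
    m = _NAME_RE.match(text.strip())
    if m is None:
        # point at the offending token for a usable error message
        head = text.split("*", 1)[0].removeprefix("HLA-")
        if head not in {l.value for l in Locus}:
            raise AlleleNameError(f"unknown locus {head!r} in allele name {text!r}")
        raise AlleleNameError(f"malformed allele fields in {text!r}")
    locus, f1, f2, f3, f4, suffix = m.groups()
    return AlleleName(
        Locus(locus),
        int(f1),
        int(f2),
        int(f3) if f3 is not None else None,
        int(f4) if f4 is not None else None,
        suffix,
    )


@dataclass(frozen=True)
class ExonWindow:
    """The polymorphic-exon mapping window of one locus."""

    locus: Locus
    exon_ids: tuple[int, ...]
    expected_length_bp: int


#: Fixed mapping windows: the highly polymorphic exons used for read
#: counting, with their expected concatenated lengths in bp.
WINDOW_SPECS: Mapping[Locus, ExonWindow] = {
    **{Locus(n): ExonWindow(Locus(n), (2, 3), 546) for n in ("A", "B", "C")},
    Locus.DRA: ExonWindow(Locus.DRA, (2,), 239),
    **{
        Locus(n): ExonWindow(Locus(n), (2,), 270)
        for n in ("DRB1", "DRB3", "DRB4", "DRB5", "DQB1")
    },
    Locus.DQA1: ExonWindow(Locus.DQA1, (2,), 249),
    Locus.DPA1: ExonWindow(Locus.DPA1, (2,), 246),
    Locus.DPB1: ExonWindow(Locus.DPB1, (2,), 264),
}


def mapping_window(locus: Locus) -> ExonWindow:
    """Return the fixed polymorphic-exon window spec for ``locus``."""
    return WINDOW_SPECS[locus]


_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class AlleleReference:
    """An allele reference sequence with its exon annotation.

    ``exon_table`` holds ``(exon_id, start, end)`` rows in 0-based half-open
    coordinates on ``sequence``; intervals must be ordered and disjoint.
    ``full_length_flag`` is False for partial references missing one or more
    mapping-window exons (such alleles can still support genotyping but are
    excluded from quantification).
    """

    name: AlleleName
    sequence: str
    exon_table: tuple[tuple[int, int, int], ...]
    full_length_flag: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ReferenceError(f"{self.name}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise ReferenceError(
                f"{self.name}: ambiguous or invalid bases {sorted(bad)}; "
                "perfect-match semantics require unambiguous A/C/G/T"
            )
        prev_end = 0
        for exon_id, start, end in self.exon_table:
            if not (0 <= start < end <= len(self.sequence)):
                raise ReferenceError(
                    f"{self.name}: exon {exon_id} interval [{start}, {end}) "
                    f"outside sequence of length {len(self.sequence)}"
                )
            if start < prev_end:
                raise ReferenceError(
                    f"{self.name}: exon {exon_id} overlaps or disorders previous exon"
                )
            prev_end = end

    @property
    def exon_ids(self) -> tuple[int, ...]:
        return tuple(e for e, _, _ in self.exon_table)

    def exon_interval(self, exon_id: int) -> tuple[int, int]:
        for e, start, end in self.exon_table:
            if e == exon_id:
                return start, end
        raise PartialReferenceError(
            f"{self.name}: exon {exon_id} not annotated (partial reference)"
        )

    def exon_sequence(self, exon_id: int) -> str:
        start, end = self.exon_interval(exon_id)
        return self.sequence[start:end]


def extract_window(ref: AlleleReference, window: ExonWindow) -> str:
    """Concatenate the window exons' subsequences of ``ref`` in exon order.

    Raises :class:`PartialReferenceError` if any window exon is missing from
    the reference annotation.
    """
    return "".join(ref.exon_sequence(e) for e in window.exon_ids)


def window_target_size(ref: AlleleReference, window: ExonWindow) -> int:
    """Length in bp of the window on this reference (the "target size")."""
    return len(extract_window(ref, window))


class ReferenceSet:
    """A validated collection of allele references keyed by rendered name."""

    def __init__(self, alleles: Iterable[AlleleReference] = ()) -> None:
        self._alleles: dict[str, AlleleReference] = {}
        for ref in alleles:
            self.add(ref)

    def add(self, ref: AlleleReference) -> None:
        key = ref.name.render()
        if key in self._alleles:
            raise ReferenceError(f"duplicate allele name {key}")
        self._alleles[key] = ref

    def __len__(self) -> int:
        return len(self._alleles)

    def __contains__(self, name: AlleleName | str) -> bool:
        key = name.render() if isinstance(name, AlleleName) else name
        return key in self._alleles

    def __getitem__(self, name: AlleleName | str) -> AlleleReference:
        key = name.render() if isinstance(name, AlleleName) else name
        return self._alleles[key]

    def __iter__(self) -> Iterator[AlleleReference]:
        return iter(self._alleles.values())

    @property
    def names(self) -> list[str]:
        return list(self._alleles)

    @property
    def loci(self) -> list[Locus]:
        seen: dict[Locus, None] = {}
        for ref in self:
            seen.setdefault(ref.name.locus)
        return list(seen)

    def by_locus(self, locus: Locus) -> list[AlleleReference]:
        return [r for r in self if r.name.locus is locus]

    def validate(self) -> None:
        """Check cross-allele consistency of exon numbering per locus."""
        for locus in self.loci:
            refs = self.by_locus(locus)
            full = [r for r in refs if r.full_length_flag]
            if not full:
                continue
            canonical = full[0].exon_ids
            for r in full[1:]:
                if r.exon_ids != canonical:
                    raise ReferenceError(
                        f"{locus}: inconsistent exon ids across alleles "
                        f"({full[0].name}: {canonical} vs {r.name}: {r.exon_ids})"
                    )


def _has_window_exons(exon_ids: Iterable[int], locus: Locus) -> bool:
    return set(WINDOW_SPECS[locus].exon_ids) <= set(exon_ids)


def load_reference_set(fasta_path: str | Path, annotation_path: str | Path) -> ReferenceSet:
    """Load a panel from a FASTA file plus exon annotation TSV.

    FASTA headers must be rendered allele names; the annotation file is
    tab-separated with a header row and columns
    ``allele  exon_id  start  end`` (0-based half-open), one row per exon.
    """
    fasta_path, annotation_path = Path(fasta_path), Path(annotation_path)
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        header = record.id
        if header in sequences:
            raise ReferenceError(f"duplicate FASTA header {header}")
        sequences[header] = str(record.seq).upper()

    annotations: dict[str, list[tuple[int, int, int]]] = {}
    with open(annotation_path) as fh:
        header_row = fh.readline().rstrip("\n").split("\t")
        expected = ["allele", "exon_id", "start", "end"]
        if header_row[:4] != expected:
            raise ReferenceError(
                f"annotation header must start with {expected}, got {header_row}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ReferenceError(f"{annotation_path}:{lineno}: expected 4 columns")
            allele, exon_id, start, end = parts[:4]
            annotations.setdefault(allele, []).append(
                (int(exon_id), int(start), int(end))
            )

    missing_ann = sorted(set(sequences) - set(annotations))
    missing_seq = sorted(set(annotations) - set(sequences))
    if missing_ann or missing_seq:
        raise ReferenceError(
            "FASTA/annotation mismatch; "
            f"no annotation for: {missing_ann or 'none'}; "
            f"no sequence for: {missing_seq or 'none'}"
        )

    refs = ReferenceSet()
    for header, seq in sequences.items():
        name = parse_allele_name(header)
        exons = tuple(sorted(annotations[header], key=lambda row: row[1]))
        refs.add(
            AlleleReference(
                name=name,
                sequence=seq,
                exon_table=exons,
                full_length_flag=_has_window_exons((e for e, _, _ in exons), name.locus),
            )
        )
    refs.validate()
    return refs


def write_reference_set(
    refs: ReferenceSet, fasta_path: str | Path, annotation_path: str | Path
) -> None:
    """Write a panel as FASTA + annotation TSV (sorted by allele name)."""
    ordered = sorted(refs, key=lambda r: r.name.render())
    records = [
        SeqRecord(Seq(r.sequence), id=r.name.render(), description="")
        for r in ordered
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    with open(annotation_path, "w") as fh:
        fh.write("allele\texon_id\tstart\tend\n")
        for r in ordered:
            for exon_id, start, end in r.exon_table:
                fh.write(f"{r.name.render()}\t{exon_id}\t{start}\t{end}\n")


@dataclass(frozen=True)
class Probe:
    sequence: str
    source_allele: AlleleName


@dataclass
class ProbeSet:
    """Capture probes (50–100 bases) used only by the capture-bias model."""

    probes: list[Probe] = field(default_factory=list)

    def __post_init__(self) -> None:
        for p in self.probes:
            if not 50 <= len(p.sequence) <= 100:
                raise ReferenceError(
                    f"probe from {p.source_allele} has length {len(p.sequence)}; "
                    "must be in [50, 100]"
                )

    @classmethod
    def load_tsv(cls, path: str | Path) -> "ProbeSet":
        probes = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["sequence", "source_allele"]:
                raise ReferenceError(
                    f"probe file header must be ['sequence', 'source_allele'], got {header}"
                )
            for line in fh:
                if not line.strip():
                    continue
                seq, allele = line.rstrip("\n").split("\t")[:2]
                probes.append(Probe(seq.upper(), parse_allele_name(allele)))
        return cls(probes)
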