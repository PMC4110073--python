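"""Core data model for transcript-aware annotation of truncating variants.

Coordinates are stored 0-based half-open internally; every public function
that accepts or returns a genomic or CDS position uses the 1-based inclusive
convention of GTF/VCF, converted exactly once at the object boundary.

The CDS of a transcript is modelled as an ordered set of genomic intervals.
UTR exons are not represented: all downstream features (truncated fraction,
domain loss, NMD-target region) are computed on coding coordinates, so the
"last exon-exon junction" used by the NMD rule is the junction between the
last two CDS segments.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

#: genomic interval, 0-based half-open
Interval = tuple[int, int]

VARIANT_CLASSES = ("stop_gain", "frameshift", "synonymous", "missense")
TRUNCATING_CLASSES = ("stop_gain", "frameshift")


class ModelValidationError(ValueError):
    """An object violates a structural invariant (e.g. CDS length not a
    multiple of three, overlapping intervals, domain outside the protein)."""


@dataclass(frozen=True)
class TranscriptModel:
    """One coding transcript: an ordered list of CDS intervals on one strand.

    Parameters
    ----------
    cds_intervals
        Genomic intervals (0-based half-open), non-overlapping, sorted by
        start. Use :func:`intervals_from_1based` when building from GTF-style
        1-based inclusive coordinates.
    stop_codon_in_cds
        Whether the natural stop codon is part of the CDS. Under the default
        (CCDS-like) convention the protein length is ``coding_length_nt/3 - 1``.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    cds_intervals: tuple[Interval, ...]
    stop_codon_in_cds: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ModelValidationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.cds_intervals:
            raise ModelValidationError(f"{self.transcript_id}: no CDS intervals")
        prev_end = -1
        for s, e in self.cds_intervals:
            if e <= s:
                raise ModelValidationError(
                    f"{self.transcript_id}: empty or inverted interval ({s}, {e})"
                )
            if s < prev_end:
                raise ModelValidationError(
                    f"{self.transcript_id}: intervals overlap or are unsorted"
                )
            prev_end = e
        if self.coding_length_nt % 3 != 0:
            raise ModelValidationError(
                f"{self.transcript_id}: CDS length {self.coding_length_nt} "
                "not divisible by 3"
            )
        if self.protein_length_aa < 1:
            raise ModelValidationError(f"{self.transcript_id}: empty protein")

    @property
    def coding_length_nt(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    @property
    def protein_length_aa(self) -> int:
        n = self.coding_length_nt // 3
        return n - 1 if self.stop_codon_in_cds else n

    @property
    def n_segments(self) -> int:
        return len(self.cds_intervals)

    def contains(self, gpos: int) -> bool:
        """True if the 1-based genomic position lies in a CDS interval."""
        g0 = gpos - 1
        return any(s <= g0 < e for s, e in self.cds_intervals)

    def span(self) -> Interval:
        return (self.cds_intervals[0][0], self.cds_intervals[-1][1])


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more coding isoforms and (optionally) a principal
    isoform designation (APPRIS-like)."""

    gene_id: str
    transcripts: tuple[TranscriptModel, ...]
    principal_transcript_id: str | None = None

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ModelValidationError(f"{self.gene_id}: gene without transcripts")
        if len({t.gene_id for t in self.transcripts}) != 1:
            raise ModelValidationError(f"{self.gene_id}: mixed gene_ids")
        if self.transcripts[0].gene_id != self.gene_id:
            raise ModelValidationError(f"{self.gene_id}: transcript gene_id mismatch")
        if len({t.chrom for t in self.transcripts}) != 1:
            raise ModelValidationError(f"{self.gene_id}: transcripts on several chromosomes")
        if self.principal_transcript_id is not None and self.principal_transcript_id not in {
            t.transcript_id for t in self.transcripts
        }:
            raise ModelValidationError(
                f"{self.gene_id}: principal isoform {self.principal_transcript_id} "
                "is not a member transcript"
            )

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for t in self.transcripts:
            if t.transcript_id == transcript_id:
                return t
        raise KeyError(transcript_id)

    def span(self) -> Interval:
        starts, ends = zip(*(t.span() for t in self.transcripts))
        return (min(starts), max(ends))


@dataclass(frozen=True)
class DomainAnnotation:
    """A protein domain on one transcript, 1-based inclusive amino-acid
    coordinates (InterPro supermatch style)."""

    transcript_id: str
    domain_id: str
    start_aa: int
    end_aa: int

    def __post_init__(self) -> None:
        if self.start_aa < 1 or self.end_aa < self.start_aa:
            raise ModelValidationError(
                f"{self.domain_id}@{self.transcript_id}: bad bounds "
                f"[{self.start_aa}, {self.end_aa}]"
            )

    @property
    def length_aa(self) -> int:
        return self.end_aa - self.start_aa + 1

    def check_against(self, t: TranscriptModel) -> None:
        if self.end_aa > t.protein_length_aa:
            raise ModelValidationError(
                f"{self.domain_id}@{self.transcript_id}: end {self.end_aa} beyond "
                f"protein length {t.protein_length_aa}"
            )


@dataclass
class VariantRecord:
    """One variant call with population summary information.

    ``pos`` is 1-based genomic. For frameshifts the stored position is the
    (possibly dialect-adjusted) location of the insertion/deletion event.
    """

    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    vclass: str
    maf: float | None = None
    genotype_counts: tuple[int, int, int] | None = None  # (hom_ref, het, hom_alt)
    carriers: tuple[str, ...] | None = None
    dataset: str = ""
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.vclass not in VARIANT_CLASSES:
            raise ModelValidationError(
                f"{self.variant_id}: unknown variant class {self.vclass!r}"
            )
        if self.maf is not None and not (0.0 <= self.maf <= 0.5):
            raise ModelValidationError(
                f"{self.variant_id}: MAF {self.maf} outside [0, 0.5]"
            )
        if self.genotype_counts is not None:
            if any(c < 0 for c in self.genotype_counts):
                raise ModelValidationError(f"{self.variant_id}: negative genotype count")
            if self.maf is not None:
                n = sum(self.genotype_counts)
                if n > 0:
                    af = (self.genotype_counts[1] + 2 * self.genotype_counts[2]) / (2 * n)
                    af = min(af, 1.0 - af)
                    # counts and MAF must agree to within rounding of one allele
                    if abs(af - self.maf) > 0.5 / n + 1e-6:
                        raise ModelValidationError(
                            f"{self.variant_id}: MAF {self.maf} inconsistent with "
                            f"genotype counts {self.genotype_counts}"
                        )

    @property
    def is_truncating(self) -> bool:
        return self.vclass in TRUNCATING_CLASSES

    @property
    def n_carriers(self) -> int | None:
        if self.carriers is not None:
            return len(self.carriers)
        if self.genotype_counts is not None:
            return self.genotype_counts[1] + self.genotype_counts[2]
        return None

    @property
    def is_singleton(self) -> bool | None:
        """Variant seen in exactly one individual."""
        n = self.n_carriers
        return None if n is None else n == 1


@dataclass(frozen=True)
class CdsPosition:
    """A position inside a spliced CDS, 1-based, counted 5'->3'."""

    transcript_id: str
    cds_nt: int
    codon_index: int

    def __post_init__(self) -> None:
        if self.cds_nt < 1:
            raise ModelValidationError("cds_nt must be >= 1")
        if self.codon_index != math.ceil(self.cds_nt / 3):
            raise ModelValidationError("codon_index must equal ceil(cds_nt/3)")


def intervals_from_1based(starts, ends) -> tuple[Interval, ...]:
    """Convert parallel 1-based inclusive start/end lists to sorted internal
    intervals."""
    iv = sorted((int(s) - 1, int(e)) for s, e in zip(starts, ends))
    return tuple(iv)


def genomic_to_cds(t: TranscriptModel, gpos: int) -> CdsPosition | None:
    """Map a 1-based genomic position to its 1-based offset in the spliced CDS.

    Returns None when the position lies outside every CDS interval. On the
    minus strand the CDS is read in reverse-complement order: the base with
    the highest genomic coordinate is cds_nt = 1.
    """
    g0 = gpos - 1
    offset = 0  # bases genomically left of g0 within the CDS
    hit = False
    for s, e in t.cds_intervals:
        if g0 >= e:
            offset += e - s
        elif g0 >= s:
            offset += g0 - s
            hit = True
            break
        else:
            break
    if not hit:
        return None
    if t.strand == "+":
        cds_nt = offset + 1
    else:
        cds_nt = t.coding_length_nt - offset
    return CdsPosition(t.transcript_id, cds_nt, math.ceil(cds_nt / 3))


def cds_to_genomic(t: TranscriptModel, cds_nt: int) -> int:
    """Inverse of :func:`genomic_to_cds`; returns a 1-based genomic position."""
    if not (1 <= cds_nt <= t.coding_length_nt):
        raise ValueError(f"cds_nt {cds_nt} outside 1..{t.coding_length_nt}")
    if t.strand == "+":
        offset = cds_nt - 1
    else:
        offset = t.coding_length_nt - cds_nt
    for s, e in t.cds_intervals:
        if offset < e - s:
            return s + offset + 1
        offset -= e - s
    raise AssertionError("unreachable")


def last_junction_cds(t: TranscriptModel) -> int | None:
    """CDS coordinate (1-based, 5'->3') of the last base of the penultimate
    CDS segment — the 3'-most junction between coding segments. None for
    single-segment transcripts (which escape NMD)."""
    if t.n_segments < 2:
        return None
    if t.strand == "+":
        last_len = t.cds_intervals[-1][1] - t.cds_intervals[-1][0]
    else:
        last_len = t.cds_intervals[0][1] - t.cds_intervals[0][0]
    return t.coding_length_nt - last_len
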