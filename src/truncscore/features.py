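"""Per-variant sequence features of protein-truncating variants.

A truncating variant (stop-gain or frameshift) is reduced to the codon at
which translation of each isoform is disrupted; everything from that codon to
the natural protein end counts as affected. Six features summarize the damage
across the gene's isoforms:

* maximum fraction of protein sequence affected over affected isoforms,
* maximum fraction of any annotated domain truncated,
* number of isoforms and ratio of isoforms affected,
* whether the principal isoform is truncated,
* whether the premature stop lies in the NMD-target region (more than 50 nt
  upstream of the 3'-most junction between coding segments) of at least one
  affected isoform.

Frameshifts are treated as truncating from the indel-containing codon onward;
no downstream re-encoded stop is searched for, since no nucleotide sequence
is modelled and both classes use identical positional features.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

from .models import (
    DomainAnnotation,
    GeneModel,
    TranscriptModel,
    VariantRecord,
    genomic_to_cds,
    last_junction_cds,
)

logger = logging.getLogger(__name__)

#: distance threshold of the NMD 50-nt rule; "more than 50" is strict
NMD_DISTANCE_NT = 50


class NonCodingVariantError(ValueError):
    """The variant position falls in no CDS of any isoform of the gene."""


@dataclass
class FeatureVector:
    """Classifier inputs for one variant, plus analysis-only flags."""

    variant_id: str
    gene_id: str
    fraction_affected_max: float
    domain_truncation_max: float
    n_isoforms: int
    ratio_isoforms_affected: float
    principal_truncated: bool
    nmd_target: bool
    missing_domain: bool = False
    missing_principal: bool = False
    constitutive_position: bool = False
    nmd_scope: str = "none"  # {all, some, none} over affected isoforms

    def __post_init__(self) -> None:
        if not (0.0 < self.fraction_affected_max <= 1.0):
            raise ValueError("fraction_affected_max outside (0, 1]")
        if not (0.0 <= self.domain_truncation_max <= 1.0):
            raise ValueError("domain_truncation_max outside [0, 1]")
        if not (0.0 < self.ratio_isoforms_affected <= 1.0):
            raise ValueError("ratio_isoforms_affected outside (0, 1]")
        if self.nmd_scope not in ("all", "some", "none"):
            raise ValueError(f"bad nmd_scope {self.nmd_scope!r}")


def truncation_point(v: VariantRecord, t: TranscriptModel) -> int | None:
    """1-based index of the codon at which this isoform's translation is
    disrupted; None when the variant position is outside the isoform's CDS.

    For frameshifts this is the codon containing the (dialect-adjusted) indel
    base. The codon index may equal protein_length_aa + 1 when the variant
    hits the natural stop codon; consumers clamp to the last residue.
    """
    cp = genomic_to_cds(t, v.pos)
    return None if cp is None else cp.codon_index


def _clamped_codon(codon: int, t: TranscriptModel) -> int:
    if codon > t.protein_length_aa:
        logger.warning(
            "truncation codon %d beyond protein end %d on %s; clamping",
            codon, t.protein_length_aa, t.transcript_id,
        )
        return t.protein_length_aa
    return codon


def fraction_affected(v: VariantRecord, t: TranscriptModel) -> float:
    """Fraction of protein residues at or downstream of the truncation codon."""
    codon = truncation_point(v, t)
    if codon is None:
        raise ValueError(f"{v.variant_id} does not affect {t.transcript_id}")
    codon = _clamped_codon(codon, t)
    p = t.protein_length_aa
    return (p - codon + 1) / p


def domain_truncation(
    v: VariantRecord, t: TranscriptModel, domains: list[DomainAnnotation]
) -> tuple[float, bool]:
    """Maximal truncated fraction over this isoform's domains.

    Returns ``(max_fraction, any_complete_loss)`` where a domain counts as
    completely lost when every one of its residues lies at or downstream of
    the truncation codon. 0.0 when no domain is annotated on the transcript
    (missingness handled by the classifier's imputation).
    """
    codon = truncation_point(v, t)
    if codon is None:
        raise ValueError(f"{v.variant_id} does not affect {t.transcript_id}")
    codon = _clamped_codon(codon, t)
    max_frac = 0.0
    complete = False
    for d in domains:
        if d.transcript_id != t.transcript_id:
            continue
        d.check_against(t)
        lost = max(0, d.end_aa - max(d.start_aa, codon) + 1)
        frac = lost / d.length_aa
        if frac >= 1.0:
            complete = True
        max_frac = max(max_frac, frac)
    return max_frac, complete


def isoform_summary(
    v: VariantRecord, g: GeneModel
) -> tuple[int, int, float, bool]:
    """``(n_isoforms, n_affected, ratio, constitutive_position)``.

    A position is constitutive when it lies in the CDS of every isoform.
    """
    n = len(g.transcripts)
    n_aff = sum(1 for t in g.transcripts if truncation_point(v, t) is not None)
    if n_aff == 0:
        raise NonCodingVariantError(
            f"{v.variant_id} is non-coding in all isoforms of {g.gene_id}"
        )
    return n, n_aff, n_aff / n, n_aff == n


def principal_transcript(g: GeneModel) -> tuple[TranscriptModel, bool]:
    """The principal isoform, falling back to the longest CDS (ties broken by
    lexicographically smallest transcript_id) when no designation exists.
    Returns ``(transcript, missing_principal)``."""
    if g.principal_transcript_id is not None:
        return g.transcript(g.principal_transcript_id), False
    best = min(g.transcripts, key=lambda t: (-t.coding_length_nt, t.transcript_id))
    if len(g.transcripts) > 1:
        logger.debug(
            "gene %s lacks a principal isoform; using longest CDS %s",
            g.gene_id, best.transcript_id,
        )
    return best, True


def principal_truncated(v: VariantRecord, g: GeneModel) -> tuple[bool, bool]:
    """Whether the (or imputed) principal isoform is truncated by the variant."""
    t, missing = principal_transcript(g)
    return truncation_point(v, t) is not None, missing


def nmd_target(v: VariantRecord, t: TranscriptModel) -> bool:
    """True when the variant's first affected CDS base lies more than 50 nt
    upstream of the last junction between coding segments; single-segment
    transcripts escape NMD."""
    junction = last_junction_cds(t)
    if junction is None:
        return False
    cp = genomic_to_cds(t, v.pos)
    if cp is None:
        raise ValueError(f"{v.variant_id} does not affect {t.transcript_id}")
    return junction - cp.cds_nt > NMD_DISTANCE_NT


def nmd_isoform_scope(v: VariantRecord, g: GeneModel) -> str:
    """Classify NMD-targeting over affected isoforms: all / some / none."""
    flags = [
        nmd_target(v, t)
        for t in g.transcripts
        if truncation_point(v, t) is not None
    ]
    if not flags:
        raise NonCodingVariantError(
            f"{v.variant_id} is non-coding in all isoforms of {g.gene_id}"
        )
    if all(flags):
        return "all"
    return "some" if any(flags) else "none"


def compute_feature_vector(
    v: VariantRecord, g: GeneModel, domains: list[DomainAnnotation]
) -> FeatureVector:
    """Compute all six classifier features for one variant on one gene.

    Maxima are taken over affected isoforms; the classifier-level NMD flag is
    true when at least one affected isoform is an NMD target (the stricter
    all-isoform classification is retained in ``nmd_scope``).
    """
    affected = [t for t in g.transcripts if truncation_point(v, t) is not None]
    if not affected:
        raise NonCodingVariantError(
            f"{v.variant_id} is non-coding in all isoforms of {g.gene_id}"
        )
    n, n_aff, ratio, constitutive = isoform_summary(v, g)

    frac_max = max(fraction_affected(v, t) for t in affected)

    has_domains = any(
        d.transcript_id == t.transcript_id for d in domains for t in affected
    )
    if has_domains:
        dom_max = max(domain_truncation(v, t, domains)[0] for t in affected)
        missing_domain = False
    else:
        dom_max = 0.0  # imputed
        missing_domain = True

    p_trunc, missing_principal = principal_truncated(v, g)
    scope = nmd_isoform_scope(v, g)

    return FeatureVector(
        variant_id=v.variant_id,
        gene_id=g.gene_id,
        fraction_affected_max=frac_max,
        domain_truncation_max=dom_max,
        n_isoforms=n,
        ratio_isoforms_affected=ratio,
        principal_truncated=p_trunc,
        nmd_target=scope in ("all", "some"),
        missing_domain=missing_domain,
        missing_principal=missing_principal,
        constitutive_position=constitutive,
        nmd_scope=scope,
    )


def assign_gene(v: VariantRecord, genes: list[GeneModel]) -> list[GeneModel]:
    """Genes whose CDS span (on the variant's chromosome) contains the
    variant. Variants in several genes are assigned to all of them."""
    hits = []
    for g in genes:
        if g.chrom != v.chrom:
            continue
        lo, hi = g.span()
        if lo <= v.pos - 1 < hi:
            hits.append(g)
    return hits


def annotate_variants(
    variants: list[VariantRecord],
    genes: list[GeneModel],
    domains: list[DomainAnnotation],
) -> list[FeatureVector]:
    """Feature vectors for all truncating variants mapping to a gene CDS.

    Variants coding in no isoform of any overlapping gene are flagged
    ``non-coding-in-all-isoforms`` on the record and skipped. A variant
    overlapping several genes yields one vector per gene.
    """
    out: list[FeatureVector] = []
    for v in variants:
        if not v.is_truncating:
            continue
        hit_any = False
        for g in assign_gene(v, genes):
            try:
                out.append(compute_feature_vector(v, g, domains))
                hit_any = True
            except NonCodingVariantError:
                continue
        if not hit_any:
            v.flags.add("non-coding-in-all-isoforms")
            logger.info("variant %s is coding in no isoform; skipped", v.variant_id)
    return out
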