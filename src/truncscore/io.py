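"""Readers and writers for transcript models, variants, and annotation tables.

Standard formats go through established parsers: GTF via gffutils, VCF via
pysam, tabular inputs via pandas. Internal tables are plain TSV so that every
artifact round-trips as text.
"""
from __future__ import annotations

import logging
import os
from collections import OrderedDict

import gffutils
import pandas as pd
import pysam

from .models import (
    DomainAnnotation,
    GeneModel,
    ModelValidationError,
    TranscriptModel,
    VariantRecord,
    intervals_from_1based,
)

logger = logging.getLogger(__name__)

AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}

VARIANT_TSV_COLUMNS = [
    "variant_id", "chrom", "pos", "ref", "alt", "vclass",
    "maf", "n_hom_ref", "n_het", "n_hom_alt", "carriers", "dataset",
]

DIALECTS = ("generic", "esp_frameshift_plus1")


class ParseError(ValueError):
    """A record could not be parsed; the message names the offending line."""


# ---------------------------------------------------------------------------
# transcripts


def _group_into_genes(
    transcripts: list[TranscriptModel],
) -> list[GeneModel]:
    by_gene: OrderedDict[str, list[TranscriptModel]] = OrderedDict()
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    return [GeneModel(g, tuple(ts)) for g, ts in by_gene.items()]


def read_transcripts(
    path: str,
    fmt: str | None = None,
    autosomes_only: bool = False,
    exclusion_log: list | None = None,
) -> list[GeneModel]:
    """Load gene models from a GTF file or a CCDS-like TSV dump.

    Transcripts violating structural invariants (CDS length not divisible by
    three, overlapping intervals) are excluded, not fatal: each exclusion is
    logged and appended to ``exclusion_log`` as ``(transcript_id, reason)``.
    With ``autosomes_only`` transcripts on chromosomes other than 1..22 /
    chr1..chr22 are dropped silently when the naming is recognizable.

    Raises
    ------
    ParseError
        If a record is unparseable (the message carries the line number).
    ValueError
        If no valid transcript remains.
    """
    if fmt is None:
        fmt = "gtf" if os.path.splitext(path)[1].lower() in (".gtf", ".gff", ".gff3") else "tsv"
    if fmt == "gtf":
        raw = _read_gtf_cds(path)
    elif fmt == "tsv":
        raw = _read_transcript_tsv(path)
    else:
        raise ValueError(f"unknown transcript format {fmt!r}")

    transcripts: list[TranscriptModel] = []
    for tid, (gene_id, chrom, strand, starts, ends) in raw.items():
        if autosomes_only and chrom not in AUTOSOMES and (
            chrom.lstrip("chr").isdigit() or chrom.lstrip("chr") in {"X", "Y", "M", "MT"}
        ):
            continue
        try:
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gene_id,
                    chrom=chrom,
                    strand=strand,
                    cds_intervals=intervals_from_1based(starts, ends),
                )
            )
        except ModelValidationError as err:
            logger.warning("excluding transcript %s: %s", tid, err)
            if exclusion_log is not None:
                exclusion_log.append((tid, str(err)))
    if not transcripts:
        raise ValueError(f"no valid transcripts in {path}")
    return _group_into_genes(transcripts)


def _read_gtf_cds(path: str) -> OrderedDict:
    try:
        db = gffutils.create_db(
            path,
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as err:  # gffutils reports the offending line itself
        raise ParseError(f"cannot parse GTF {path}: {err}") from err
    out: OrderedDict = OrderedDict()
    for f in db.features_of_type("CDS", order_by=("seqid", "start")):
        try:
            tid = f.attributes["transcript_id"][0]
            gid = f.attributes["gene_id"][0]
        except KeyError as err:
            raise ParseError(
                f"{path}: CDS record at {f.seqid}:{f.start} lacks {err} attribute"
            ) from err
        rec = out.setdefault(tid, (gid, f.seqid, f.strand, [], []))
        rec[3].append(f.start)
        rec[4].append(f.end)
    return out


def _read_transcript_tsv(path: str) -> OrderedDict:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "transcript_id", "chrom", "strand", "cds_starts", "cds_ends"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    out: OrderedDict = OrderedDict()
    for i, row in df.iterrows():
        try:
            starts = [int(x) for x in str(row.cds_starts).split(",")]
            ends = [int(x) for x in str(row.cds_ends).split(",")]
        except ValueError as err:
            raise ParseError(f"{path} line {i + 2}: bad interval list") from err
        out[row.transcript_id] = (row.gene_id, row.chrom, row.strand, starts, ends)
    return out


def write_transcripts(genes: list[GeneModel], path: str) -> None:
    """Write gene models to the internal TSV dump (1-based inclusive
    coordinates, comma-separated per segment); read_transcripts round-trips."""
    rows = []
    for g in genes:
        for t in g.transcripts:
            rows.append(
                {
                    "gene_id": t.gene_id,
                    "transcript_id": t.transcript_id,
                    "chrom": t.chrom,
                    "strand": t.strand,
                    "cds_starts": ",".join(str(s + 1) for s, _ in t.cds_intervals),
                    "cds_ends": ",".join(str(e) for _, e in t.cds_intervals),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# variants


def read_variants(
    path: str,
    dialect: str = "generic",
    fmt: str | None = None,
    exclusion_log: list | None = None,
) -> list[VariantRecord]:
    """Load variants from a VCF (with optional per-sample genotypes) or TSV.

    ``dialect`` controls source-specific coordinate conventions:

    * ``generic`` — positions taken as reported;
    * ``esp_frameshift_plus1`` — one base is added to the reported position of
      frameshift variants so that it names the actual indel event location;
      all other classes are untouched.

    Multi-allelic VCF rows are split into one record per alternate allele.
    Records with malformed MAF or genotype fields are rejected with a logged
    reason rather than aborting the load.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if fmt is None:
        fmt = "vcf" if path.lower().endswith((".vcf", ".vcf.gz")) else "tsv"
    if fmt == "vcf":
        records = _read_vcf(path, exclusion_log)
    elif fmt == "tsv":
        records = _read_variant_tsv(path, exclusion_log)
    else:
        raise ValueError(f"unknown variant format {fmt!r}")
    if dialect == "esp_frameshift_plus1":
        for v in records:
            if v.vclass == "frameshift":
                v.pos += 1
    return records


def _info_get(rec, key, default=None):
    # pysam raises on keys absent from the header, not just from the record
    try:
        return rec.info[key]
    except (KeyError, ValueError):
        return default


def _read_vcf(path: str, exclusion_log: list | None) -> list[VariantRecord]:
    out: list[VariantRecord] = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            alts = rec.alts or ()
            for ai, alt in enumerate(alts, start=1):
                vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}>{alt}"
                if len(alts) > 1:
                    vid = f"{vid}_alt{ai}"
                try:
                    vclass = str(_info_get(rec, "VCLASS", "missense"))
                    maf = _info_get(rec, "MAF")
                    maf = None if maf is None else float(maf)
                    counts = None
                    carriers = None
                    if samples:
                        n_hom_ref = n_het = n_hom_alt = 0
                        carrier_ids = []
                        for s in samples:
                            gt = rec.samples[s]["GT"]
                            dose = sum(1 for a in gt if a == ai)
                            if dose == 0:
                                n_hom_ref += 1
                            elif dose == 1:
                                n_het += 1
                                carrier_ids.append(s)
                            else:
                                n_hom_alt += 1
                                carrier_ids.append(s)
                        counts = (n_hom_ref, n_het, n_hom_alt)
                        carriers = tuple(carrier_ids)
                        if maf is None:
                            n = sum(counts)
                            af = (n_het + 2 * n_hom_alt) / (2 * n) if n else 0.0
                            maf = min(af, 1 - af)
                        else:
                            # single-precision INFO floats: re-round
                            maf = round(maf, 6)
                    out.append(
                        VariantRecord(
                            variant_id=vid,
                            chrom=rec.chrom,
                            pos=rec.pos,
                            ref=rec.ref,
                            alt=alt,
                            vclass=vclass,
                            maf=maf,
                            genotype_counts=counts,
                            carriers=carriers,
                            dataset=str(_info_get(rec, "DATASET", "")),
                        )
                    )
                except (ModelValidationError, ValueError, TypeError) as err:
                    logger.warning("rejecting %s: %s", vid, err)
                    if exclusion_log is not None:
                        exclusion_log.append((vid, str(err)))
    return out


def _read_variant_tsv(path: str, exclusion_log: list | None) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"variant_id", "chrom", "pos", "ref", "alt", "vclass"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    out: list[VariantRecord] = []
    for _, row in df.iterrows():
        try:
            maf = float(row["maf"]) if row.get("maf", "") != "" else None
            counts = None
            if row.get("n_het", "") != "":
                counts = (
                    int(row.get("n_hom_ref", 0) or 0),
                    int(row["n_het"]),
                    int(row.get("n_hom_alt", 0) or 0),
                )
            carriers = None
            if "carriers" in df.columns:
                carriers = tuple(c for c in row["carriers"].split(",") if c)
            out.append(
                VariantRecord(
                    variant_id=row["variant_id"],
                    chrom=row["chrom"],
                    pos=int(row["pos"]),
                    ref=row["ref"],
                    alt=row["alt"],
                    vclass=row["vclass"],
                    maf=maf,
                    genotype_counts=counts,
                    carriers=carriers,
                    dataset=row.get("dataset", ""),
                )
            )
        except (ModelValidationError, ValueError) as err:
            logger.warning("rejecting %s: %s", row.get("variant_id", "?"), err)
            if exclusion_log is not None:
                exclusion_log.append((row.get("variant_id", "?"), str(err)))
    return out


def write_variants_tsv(variants: list[VariantRecord], path: str) -> None:
    rows = []
    for v in variants:
        c = v.genotype_counts or ("", "", "")
        rows.append(
            {
                "variant_id": v.variant_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "vclass": v.vclass,
                "maf": "" if v.maf is None else repr(float(v.maf)),
                "n_hom_ref": c[0],
                "n_het": c[1],
                "n_hom_alt": c[2],
                "carriers": "" if v.carriers is None else ",".join(v.carriers),
                "dataset": v.dataset,
            }
        )
    pd.DataFrame(rows, columns=VARIANT_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# annotation tables


def read_domains(path: str) -> list[DomainAnnotation]:
    """TSV with columns transcript_id, domain_id, start_aa, end_aa."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"transcript_id", "domain_id", "start_aa", "end_aa"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    return [
        DomainAnnotation(
            transcript_id=row.transcript_id,
            domain_id=row.domain_id,
            start_aa=int(row.start_aa),
            end_aa=int(row.end_aa),
        )
        for row in df.itertuples()
    ]


def validate_domains(
    domains: list[DomainAnnotation], genes: list[GeneModel]
) -> None:
    """Check every domain against its transcript's protein length; raises on
    out-of-bounds domains, ignores domains on unknown transcripts."""
    by_tid = {t.transcript_id: t for g in genes for t in g.transcripts}
    for d in domains:
        t = by_tid.get(d.transcript_id)
        if t is not None:
            d.check_against(t)


def read_gene_scores(path: str, kind: str = "probability") -> dict[str, float]:
    """TSV with columns gene_id, score. For ``kind='probability'`` scores must
    lie in [0, 1]; ``kind='raw'`` accepts any real (e.g. RVIS). Duplicate
    genes resolve last-wins with a logged warning."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    out: dict[str, float] = {}
    for row in df.itertuples():
        s = float(row.score)
        if kind == "probability" and not (0.0 <= s <= 1.0):
            raise ValueError(
                f"{path}: probability-type score {s} for {row.gene_id} outside [0, 1]"
            )
        if row.gene_id in out:
            logger.warning("duplicate gene score for %s; keeping last", row.gene_id)
        out[row.gene_id] = s
    return out


def read_principal(
    path: str, genes: list[GeneModel] | None = None
) -> dict[str, str]:
    """TSV with columns gene_id, transcript_id mapping each gene to its
    principal isoform. When gene models are supplied, entries naming an
    unknown transcript of the gene are dropped with a warning."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "transcript_id"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing column(s) {sorted(missing)}")
    known = None
    if genes is not None:
        known = {g.gene_id: {t.transcript_id for t in g.transcripts} for g in genes}
    out: dict[str, str] = {}
    for row in df.itertuples():
        if row.gene_id in out:
            logger.warning("duplicate principal entry for %s; keeping last", row.gene_id)
        if known is not None and row.transcript_id not in known.get(row.gene_id, set()):
            logger.warning(
                "principal transcript %s not found in gene %s; entry dropped",
                row.transcript_id, row.gene_id,
            )
            continue
        out[row.gene_id] = row.transcript_id
    return out


def attach_principal(
    genes: list[GeneModel], principal: dict[str, str]
) -> list[GeneModel]:
    """Return gene models with principal_transcript_id filled in where known."""
    out = []
    for g in genes:
        tid = principal.get(g.gene_id)
        if tid is not None:
            out.append(GeneModel(g.gene_id, g.transcripts, tid))
        else:
            out.append(g)
    return out
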