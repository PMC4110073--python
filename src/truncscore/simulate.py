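"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical structure of real truncating-variant
data at desk scale: multi-isoform multi-exon genes with shared and
isoform-specific coding exons, protein domains, class-conditional variant
placement (pathogenic-like variants 5', on the principal isoform, inside the
NMD-target region; benign-like variants 3' and at higher allele frequency),
and an expression matrix in which carriers of NMD-target variants have the
affected gene's expression reduced multiplicatively.

Every variant comes with a ground-truth feature row computed by brute-force
per-residue marking over explicit per-base coordinate lists — an independent
oracle for the interval arithmetic in :mod:`truncscore.features`.

One integer seed drives everything; each stage derives its own stream
deterministically so stages can be regenerated independently.
"""
from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import pysam

from .classifier import FEATURE_KINDS, FEATURE_NAMES, TrainingSet
from .expression import ExpressionMatrix
from .models import GeneModel, TranscriptModel, VariantRecord, intervals_from_1based
from .io import write_transcripts, write_variants_tsv

TRUTH_COLUMNS = [
    "variant_id", "gene_id", "label", "vclass", "maf",
    "fraction_affected_max", "domain_truncation_max", "n_isoforms",
    "ratio_isoforms_affected", "principal_truncated", "nmd_target",
    "missing_domain", "missing_principal", "constitutive_position", "nmd_scope",
]


@dataclass
class ClassPlacement:
    """Where and how often one variant class lands.

    ``rel_lo``/``rel_hi`` bound the relative CDS position of the disruption;
    ``prefer_principal`` targets the principal (or longest) isoform;
    ``nmd`` constrains the resulting classifier-level NMD flag:
    "free" (no constraint), "always", or "never" (bounded resampling).
    """

    rel_lo: float = 0.02
    rel_hi: float = 0.30
    prefer_principal: bool = True
    nmd: str = "free"
    maf_lo: float = 1e-4
    maf_hi: float = 2e-3
    p_singleton: float = 0.5


@dataclass
class ExpressionConfig:
    n_samples: int = 50
    baseline_log: float = 3.0
    baseline_log_sd: float = 0.5
    nmd_effect_size: float = 0.5  # multiplicative reduction on carriers
    noise_sd: float = 0.2  # log-scale noise


@dataclass
class FeatureModel:
    """Direct per-class generative model of the six classifier features
    (four Gaussian, two Bernoulli), used to sample training matrices without
    building transcripts."""

    mu: tuple[float, ...] = (0.75, 0.50, 3.0, 0.85)
    sd: tuple[float, ...] = (0.20, 0.20, 1.5, 0.25)
    theta: tuple[float, ...] = (0.80, 0.70)


@dataclass
class FixtureConfig:
    seed: int = 0
    n_genes: int = 20
    isoform_count_weights: tuple[float, ...] = (0.35, 0.40, 0.25)  # P(1..3 isoforms)
    exons_per_gene: tuple[int, int] = (1, 6)
    exon_length_range: tuple[int, int] = (30, 150)  # nt, multiples of 3 enforced
    intron_length_range: tuple[int, int] = (50, 500)
    domain_density: float = 0.7  # P(a transcript carries >= 1 domain)
    p_principal_annotated: float = 0.8
    n_variants_per_class: int = 100
    pathogenic: ClassPlacement = field(default_factory=ClassPlacement)
    benign: ClassPlacement = field(
        default_factory=lambda: ClassPlacement(
            rel_lo=0.70, rel_hi=0.98, prefer_principal=False, nmd="free",
            maf_lo=0.01, maf_hi=0.20, p_singleton=0.0,
        )
    )
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    class1_model: FeatureModel = field(default_factory=FeatureModel)
    class0_model: FeatureModel = field(
        default_factory=lambda: FeatureModel(
            mu=(0.35, 0.15, 3.0, 0.55), sd=(0.20, 0.20, 1.5, 0.25),
            theta=(0.35, 0.25),
        )
    )

    def __post_init__(self) -> None:
        if self.n_genes < 2 or self.n_variants_per_class < 1:
            raise ValueError("need >= 2 genes and >= 1 variant per class")
        if self.exon_length_range[0] < 3:
            raise ValueError("exon length must be >= 3 nt")
        if not (0.0 < self.expression.nmd_effect_size <= 1.0):
            raise ValueError("nmd_effect_size must be in (0, 1]")

    def rng(self, stage: int) -> np.random.Generator:
        # per-stage stream, derived deterministically from the single seed
        return np.random.default_rng([int(self.seed), stage])


# ---------------------------------------------------------------------------
# gene models


def generate_gene_models(cfg: FixtureConfig):
    """Gene models plus domain and principal-isoform tables.

    The first gene is always single-isoform/single-exon and the second
    single-isoform/multi-exon (edge coverage); the rest draw isoform counts
    and exon compositions at random. Every exon length is a multiple of
    three, so all CDS lengths satisfy the divisibility invariant by
    construction.
    """
    rng = cfg.rng(1)
    genes: list[GeneModel] = []
    domain_rows: list[dict] = []
    principal: dict[str, str] = {}
    cursor: dict[str, int] = {}

    for i in range(cfg.n_genes):
        gid = f"G{i:03d}"
        chrom = str(1 + i % 22)
        start = cursor.get(chrom, 1000)
        if i == 0:
            n_ex, n_iso = 1, 1
        elif i == 1:
            n_ex, n_iso = max(2, cfg.exons_per_gene[0] + 1), 1
        else:
            n_ex = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
            n_iso = 1 + int(
                rng.choice(len(cfg.isoform_count_weights), p=cfg.isoform_count_weights)
            )
        lo3 = max(1, cfg.exon_length_range[0] // 3)
        hi3 = max(lo3 + 1, cfg.exon_length_range[1] // 3)
        lengths = 3 * rng.integers(lo3, hi3 + 1, size=n_ex)
        gaps = rng.integers(*cfg.intron_length_range, size=n_ex)
        exons = []
        pos = start
        for L, gap in zip(lengths, gaps):
            exons.append((pos, pos + int(L)))  # 0-based half-open
            pos += int(L) + int(gap)
        cursor[chrom] = pos + 10_000
        strand = "+" if rng.random() < 0.5 else "-"

        transcripts = []
        for j in range(n_iso):
            tid = f"{gid}.T{j}"
            if n_iso == 1 or j == 0:
                members = list(range(n_ex))  # one isoform always uses all exons
            else:
                members = [0] + [
                    k for k in range(1, n_ex) if rng.random() < 0.75
                ]
                if len(members) == 1 and n_ex > 1:
                    members.append(int(rng.integers(1, n_ex)))
                members = sorted(set(members))
            transcripts.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=gid,
                    chrom=chrom,
                    strand=strand,
                    cds_intervals=tuple(exons[k] for k in members),
                )
            )
        principal_tid = None
        if rng.random() < cfg.p_principal_annotated:
            principal_tid = transcripts[int(rng.integers(n_iso))].transcript_id
            principal[gid] = principal_tid
        genes.append(GeneModel(gid, tuple(transcripts), principal_tid))

        for t in transcripts:
            if rng.random() >= cfg.domain_density:
                continue
            p = t.protein_length_aa
            if p < 20:
                continue
            for d in range(int(rng.integers(1, 3))):
                s = int(rng.integers(1, p - 10))
                e = min(p, s + int(rng.integers(5, 41)) - 1)
                domain_rows.append(
                    {
                        "transcript_id": t.transcript_id,
                        "domain_id": f"D{t.transcript_id}.{d}",
                        "start_aa": s,
                        "end_aa": e,
                    }
                )
    domains = pd.DataFrame(
        domain_rows, columns=["transcript_id", "domain_id", "start_aa", "end_aa"]
    )
    return genes, domains, principal


# ---------------------------------------------------------------------------
# brute-force truth


def _base_list(t: TranscriptModel) -> tuple[list[int], list[int]]:
    """Per-base genomic positions (1-based) of the spliced CDS in transcript
    order, plus the CDS-segment index of each base."""
    bases: list[int] = []
    segs: list[int] = []
    for si, (s, e) in enumerate(t.cds_intervals):
        for g0 in range(s, e):
            bases.append(g0 + 1)
            segs.append(si)
    if t.strand == "-":
        bases.reverse()
        segs.reverse()
    return bases, segs


def _brute_isoform(pos: int, t: TranscriptModel, domain_rows: pd.DataFrame):
    """Brute-force per-residue feature computation for one isoform; None when
    the position is outside the isoform's CDS."""
    bases, segs = _base_list(t)
    if pos not in bases:
        return None
    idx = bases.index(pos)  # 0-based offset in the spliced CDS
    cds_nt = idx + 1
    p = len(bases) // 3 - 1  # natural stop codon included in the CDS
    codon = min(idx // 3 + 1, p)
    affected_residues = set(range(codon, p + 1))
    frac = len(affected_residues) / p

    dom_fracs = []
    sub = domain_rows[domain_rows.transcript_id == t.transcript_id]
    for row in sub.itertuples():
        residues = set(range(int(row.start_aa), int(row.end_aa) + 1))
        dom_fracs.append(len(residues & affected_residues) / len(residues))

    if len(set(segs)) < 2:
        nmd = False
    else:
        last_seg = segs[-1]
        junction_cds = sum(1 for s in segs if s != last_seg)
        nmd = (junction_cds - cds_nt) > 50
    return {"fraction": frac, "dom_fracs": dom_fracs, "nmd": nmd}


def brute_force_truth(
    pos: int, gene: GeneModel, domain_rows: pd.DataFrame
) -> dict | None:
    """Ground-truth feature row for a variant at ``pos`` on ``gene``,
    computed by explicit per-base/per-residue enumeration."""
    per_iso = {
        t.transcript_id: _brute_isoform(pos, t, domain_rows)
        for t in gene.transcripts
    }
    affected = {tid: r for tid, r in per_iso.items() if r is not None}
    if not affected:
        return None
    n = len(gene.transcripts)
    n_aff = len(affected)

    if gene.principal_transcript_id is not None:
        principal_tid, missing_principal = gene.principal_transcript_id, False
    else:
        principal_tid = min(
            gene.transcripts,
            key=lambda t: (-len(_base_list(t)[0]), t.transcript_id),
        ).transcript_id
        missing_principal = True

    all_dom_fracs = [f for r in affected.values() for f in r["dom_fracs"]]
    missing_domain = len(all_dom_fracs) == 0
    nmd_flags = [r["nmd"] for r in affected.values()]
    scope = "all" if all(nmd_flags) else ("some" if any(nmd_flags) else "none")
    return {
        "fraction_affected_max": max(r["fraction"] for r in affected.values()),
        "domain_truncation_max": 0.0 if missing_domain else max(all_dom_fracs),
        "n_isoforms": n,
        "ratio_isoforms_affected": n_aff / n,
        "principal_truncated": principal_tid in affected,
        "nmd_target": scope in ("all", "some"),
        "missing_domain": missing_domain,
        "missing_principal": missing_principal,
        "constitutive_position": n_aff == n,
        "nmd_scope": scope,
    }


# ---------------------------------------------------------------------------
# variants


def _draw_genotypes(
    rng: np.random.Generator, placement: ClassPlacement, n_samples: int
):
    """Allele frequency and HWE-consistent genotype counts for one variant."""
    if placement.p_singleton > 0 and rng.random() < placement.p_singleton:
        n_carrier_alleles = 1
    else:
        maf = rng.uniform(placement.maf_lo, placement.maf_hi)
        n_carrier_alleles = max(1, int(round(maf * 2 * n_samples)))
    n_hom_alt = min(
        n_carrier_alleles // 2,
        int(round(n_samples * (n_carrier_alleles / (2 * n_samples)) ** 2)),
    )
    n_het = n_carrier_alleles - 2 * n_hom_alt
    maf = n_carrier_alleles / (2 * n_samples)
    return round(maf, 6), (n_samples - n_het - n_hom_alt, n_het, n_hom_alt)


def generate_variants(cfg: FixtureConfig, genes: list[GeneModel], domains: pd.DataFrame):
    """Class-conditional variant placement with attached ground truth.

    Returns ``(variants, truth)`` where truth has one row per variant in the
    order generated (pathogenic-like first).
    """
    rng = cfg.rng(2)
    n_samples = cfg.expression.n_samples
    sample_ids = [f"S{k:03d}" for k in range(n_samples)]
    base_lists = {
        t.transcript_id: _base_list(t)[0] for g in genes for t in g.transcripts
    }

    variants: list[VariantRecord] = []
    truth_rows: list[dict] = []
    vid_counter = 0
    for label, placement in ((1, cfg.pathogenic), (0, cfg.benign)):
        for _ in range(cfg.n_variants_per_class):
            for _retry in range(200):
                gene = genes[int(rng.integers(len(genes)))]
                if placement.prefer_principal:
                    if gene.principal_transcript_id is not None:
                        t = gene.transcript(gene.principal_transcript_id)
                    else:
                        t = min(
                            gene.transcripts,
                            key=lambda tr: (-tr.coding_length_nt, tr.transcript_id),
                        )
                else:
                    t = gene.transcripts[int(rng.integers(len(gene.transcripts)))]
                bases = base_lists[t.transcript_id]
                L = len(bases)
                u = rng.uniform(placement.rel_lo, placement.rel_hi)
                cds_nt = min(max(int(u * L) + 1, 1), L - 3)  # avoid the stop codon
                pos = bases[cds_nt - 1]
                truth = brute_force_truth(pos, gene, domains)
                assert truth is not None
                if placement.nmd == "always" and not truth["nmd_target"]:
                    continue
                if placement.nmd == "never" and truth["nmd_target"]:
                    continue
                break
            else:
                raise RuntimeError(
                    f"could not place a class-{label} variant satisfying "
                    f"nmd={placement.nmd!r} after bounded retries"
                )
            vid = f"v{vid_counter:04d}"
            vid_counter += 1
            vclass = "stop_gain" if vid_counter % 2 else "frameshift"
            maf, counts = _draw_genotypes(rng, placement, n_samples)
            n_carriers = counts[1] + counts[2]
            carriers = tuple(
                sorted(rng.choice(sample_ids, size=n_carriers, replace=False))
            )
            ref, alt = ("G", "A") if vclass == "stop_gain" else ("A", "AT")
            variants.append(
                VariantRecord(
                    variant_id=vid,
                    chrom=gene.chrom,
                    pos=pos,
                    ref=ref,
                    alt=alt,
                    vclass=vclass,
                    maf=maf,
                    genotype_counts=counts,
                    carriers=carriers,
                    dataset="sim",
                )
            )
            truth_rows.append(
                {"variant_id": vid, "gene_id": gene.gene_id, "label": label,
                 "vclass": vclass, "maf": maf, **truth}
            )
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return variants, truth


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    cfg: FixtureConfig, genes: list[GeneModel], variants: list[VariantRecord],
    truth: pd.DataFrame,
) -> ExpressionMatrix:
    """Log-normal expression with the planted NMD effect.

    Carriers of variants whose ground-truth NMD flag is set have the affected
    gene's value multiplied by ``1 - nmd_effect_size``; effects of multiple
    NMD variants on the same (gene, carrier) cell compound.
    """
    ex = cfg.expression
    rng = cfg.rng(3)
    sample_ids = [f"S{k:03d}" for k in range(ex.n_samples)]
    gene_ids = [g.gene_id for g in genes]
    baseline = rng.normal(ex.baseline_log, ex.baseline_log_sd, size=len(gene_ids))
    logvals = baseline[:, None] + rng.normal(
        0.0, ex.noise_sd, size=(len(gene_ids), ex.n_samples)
    )
    values = pd.DataFrame(np.exp(logvals), index=gene_ids, columns=sample_ids)

    nmd_of = dict(zip(truth.variant_id, truth.nmd_target.astype(bool)))
    gene_of = dict(zip(truth.variant_id, truth.gene_id))
    for v in variants:
        if not nmd_of.get(v.variant_id, False) or not v.carriers:
            continue
        g = gene_of[v.variant_id]
        values.loc[g, list(v.carriers)] *= 1.0 - ex.nmd_effect_size
    return ExpressionMatrix(values, normalization_label="synthetic-RPKM")


# ---------------------------------------------------------------------------
# direct feature-matrix sampling


def sample_feature_matrix(
    cfg: FixtureConfig, n_per_class: int, seed_stage: int = 4
) -> TrainingSet:
    """Sample rows directly from the per-class Gaussian/Bernoulli models the
    classifier assumes, bypassing transcripts entirely."""
    rng = cfg.rng(seed_stage)
    blocks = []
    labels = []
    for label, model in ((1, cfg.class1_model), (0, cfg.class0_model)):
        cont = rng.normal(model.mu, model.sd, size=(n_per_class, len(model.mu)))
        binm = (rng.random((n_per_class, len(model.theta))) < model.theta).astype(float)
        blocks.append(np.hstack([cont, binm]))
        labels.append(np.full(n_per_class, label))
    order = cfg.rng(seed_stage + 100).permutation(2 * n_per_class)
    X = np.vstack(blocks)[order]
    c = np.concatenate(labels)[order]
    return TrainingSet(X, c, FEATURE_NAMES, FEATURE_KINDS)


def true_log_likelihood_ratio(X: np.ndarray, cfg: FixtureConfig) -> np.ndarray:
    """Log-likelihood ratio of the generating class models (no fitting) —
    the Bayes-optimal score for data from :func:`sample_feature_matrix`."""
    m1, m0 = cfg.class1_model, cfg.class0_model
    X = np.atleast_2d(np.asarray(X, dtype=float))
    k_cont = len(m1.mu)
    llr = np.zeros(X.shape[0])
    for k in range(k_cont):
        for sign, m in ((1.0, m1), (-1.0, m0)):
            d = X[:, k] - m.mu[k]
            llr += sign * (-0.5 * np.log(2 * np.pi * m.sd[k] ** 2) - d**2 / (2 * m.sd[k] ** 2))
    for k in range(len(m1.theta)):
        y = X[:, k_cont + k]
        llr += y * (np.log(m1.theta[k]) - np.log(m0.theta[k]))
        llr += (1 - y) * (np.log(1 - m1.theta[k]) - np.log(1 - m0.theta[k]))
    return llr


def bayes_optimal_auc(cfg: FixtureConfig, n_mc: int = 100_000, seed_stage: int = 5) -> float:
    """Monte-Carlo AUC of the true log-likelihood ratio on fresh samples from
    the generating model — the ceiling any fitted classifier can approach."""
    from .evaluation import auc as mw_auc

    ts = sample_feature_matrix(cfg, n_mc, seed_stage=seed_stage)
    return mw_auc(true_log_likelihood_ratio(ts.X, cfg), ts.c)


# ---------------------------------------------------------------------------
# bundle IO


def _write_gtf(genes: list[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        for g in genes:
            for t in g.transcripts:
                for s, e in t.cds_intervals:
                    fh.write(
                        f"{t.chrom}\ttruncscore_sim\tCDS\t{s + 1}\t{e}\t.\t"
                        f'{t.strand}\t0\tgene_id "{t.gene_id}"; '
                        f'transcript_id "{t.transcript_id}";\n'
                    )


def _write_vcf(variants: list[VariantRecord], genes: list[GeneModel], path: str) -> None:
    header = pysam.VariantHeader()
    chrom_max: dict[str, int] = {}
    for g in genes:
        chrom_max[g.chrom] = max(chrom_max.get(g.chrom, 0), g.span()[1] + 10_000)
    for chrom in sorted(chrom_max, key=lambda c: (len(c), c)):
        header.contigs.add(chrom, length=chrom_max[chrom])
    header.info.add("VCLASS", 1, "String", "variant consequence class")
    header.info.add("MAF", 1, "Float", "minor allele frequency")
    header.info.add("DATASET", 1, "String", "source dataset label")
    header.formats.add("GT", 1, "String", "Genotype")
    sample_ids = sorted({s for v in variants for s in (v.carriers or ())})
    n_samples = sum(variants[0].genotype_counts) if variants else 0
    all_samples = [f"S{k:03d}" for k in range(n_samples)] or sample_ids
    for s in all_samples:
        header.add_sample(s)
    with pysam.VariantFile(path, "w", header=header) as out:
        for v in sorted(variants, key=lambda v: ((len(v.chrom), v.chrom), v.pos)):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt), id=v.variant_id,
            )
            rec.info["VCLASS"] = v.vclass
            rec.info["MAF"] = v.maf
            rec.info["DATASET"] = v.dataset
            hom = set()
            if v.genotype_counts and v.genotype_counts[2] > 0 and v.carriers:
                hom = set(v.carriers[: v.genotype_counts[2]])
            carrier_set = set(v.carriers or ())
            for s in all_samples:
                if s in hom:
                    rec.samples[s]["GT"] = (1, 1)
                elif s in carrier_set:
                    rec.samples[s]["GT"] = (0, 1)
                else:
                    rec.samples[s]["GT"] = (0, 0)
            out.write(rec)


def generate_bundle(cfg: FixtureConfig, outdir: str) -> dict[str, str]:
    """Generate the full fixture bundle into ``outdir`` and return the file
    map. Repeated runs with the same config are byte-identical."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        name: os.path.join(outdir, fname)
        for name, fname in [
            ("gtf", "genes.gtf"), ("transcripts_tsv", "transcripts.tsv"),
            ("domains", "domains.tsv"), ("principal", "principal.tsv"),
            ("vcf", "variants.vcf"), ("variants_tsv", "variants.tsv"),
            ("truth", "truth.tsv"), ("expression", "expression.tsv"),
            ("config", "config.json"),
        ]
    }
    genes, domains, principal = generate_gene_models(cfg)
    variants, truth = generate_variants(cfg, genes, domains)
    em = generate_expression(cfg, genes, variants, truth)

    _write_gtf(genes, paths["gtf"])
    write_transcripts(genes, paths["transcripts_tsv"])
    domains.to_csv(paths["domains"], sep="\t", index=False)
    pd.DataFrame(
        [{"gene_id": g, "transcript_id": t} for g, t in sorted(principal.items())]
    ).to_csv(paths["principal"], sep="\t", index=False)
    _write_vcf(variants, genes, paths["vcf"])
    write_variants_tsv(variants, paths["variants_tsv"])
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.10g")
    em.to_tsv(paths["expression"])
    with open(paths["config"], "w") as fh:
        json.dump(asdict(cfg), fh, indent=2, default=list)
        fh.write("\n")
    return paths
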