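import os

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import truncscore as ts

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")

GOLDEN_DIR = os.path.join(os.path.dirname(__file__), "data", "golden")
GOLDEN_SEED = 20140724


@pytest.fixture(scope="session")
def golden_dir() -> str:
    return GOLDEN_DIR


@pytest.fixture(scope="session")
def golden_cfg() -> ts.FixtureConfig:
    return ts.FixtureConfig(seed=GOLDEN_SEED)


@pytest.fixture(scope="session")
def golden_bundle(golden_cfg):
    """In-memory regeneration of the golden fixture (no file IO)."""
    genes, domains, principal = ts.generate_gene_models(golden_cfg)
    variants, truth = ts.generate_variants(golden_cfg, genes, domains)
    return {
        "cfg": golden_cfg,
        "genes": genes,
        "domains": domains,
        "principal": principal,
        "variants": variants,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def golden_domain_list(golden_bundle):
    return [
        ts.DomainAnnotation(r.transcript_id, r.domain_id, int(r.start_aa), int(r.end_aa))
        for r in golden_bundle["domains"].itertuples()
    ]


def make_transcript(
    intervals_1based, strand="+", tid="T1", gid="G1", chrom="1"
) -> ts.TranscriptModel:
    """Build a transcript from 1-based inclusive (start, end) pairs."""
    return ts.TranscriptModel(
        transcript_id=tid,
        gene_id=gid,
        chrom=chrom,
        strand=strand,
        cds_intervals=tuple(sorted((s - 1, e) for s, e in intervals_1based)),
    )


def make_variant(pos, vclass="stop_gain", chrom="1", vid="v1", **kw) -> ts.VariantRecord:
    return ts.VariantRecord(
        variant_id=vid, chrom=chrom, pos=pos, ref="G", alt="A", vclass=vclass, **kw
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_transcript(rng, max_segments=6, strand=None, chrom="1") -> ts.TranscriptModel:
    """Random valid transcript: 1..max_segments CDS intervals with lengths
    divisible by 3 only in total (per-segment lengths arbitrary)."""
    n_seg = int(rng.integers(1, max_segments + 1))
    lengths = rng.integers(4, 120, size=n_seg)
    total = int(lengths.sum())
    lengths[-1] += (-total) % 3
    if lengths.sum() < 6:
        lengths[-1] += 3
    gaps = rng.integers(1, 300, size=n_seg)
    intervals = []
    pos = int(rng.integers(100, 10_000))
    for L, gap in zip(lengths, gaps):
        intervals.append((pos, pos + int(L)))
        pos += int(L) + int(gap)
    return ts.TranscriptModel(
        transcript_id="Trand",
        gene_id="Grand",
        chrom=chrom,
        strand=strand or ("+" if rng.random() < 0.5 else "-"),
        cds_intervals=tuple(intervals),
    )
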