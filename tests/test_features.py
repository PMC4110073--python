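"""Sequence-feature engine: truncation, domains, isoforms, NMD."""
import numpy as np
import pytest

import truncscore as ts
from truncscore.simulate import _base_list

from conftest import make_transcript, make_variant, random_transcript


def single_exon_transcript(length_nt=303, start=1001, **kw):
    return make_transcript([(start, start + length_nt - 1)], **kw)


class TestTruncationPoint:
    def test_first_codon(self):
        t = single_exon_transcript()
        assert ts.truncation_point(make_variant(1001), t) == 1

    def test_codon_from_cds_offset(self):
        t = single_exon_transcript()
        assert ts.truncation_point(make_variant(1001 + 120), t) == 41  # cds_nt 121

    def test_unaffected_isoform_is_none(self):
        t = single_exon_transcript()
        assert ts.truncation_point(make_variant(50), t) is None


class TestFractionAffected:
    def test_mid_protein(self):
        t = single_exon_transcript(303)  # 100 aa
        v = make_variant(1001 + 40 * 3)  # codon 41
        assert ts.fraction_affected(v, t) == pytest.approx(0.60)

    def test_whole_protein_lost_at_first_codon(self):
        t = single_exon_transcript(303)
        assert ts.fraction_affected(make_variant(1001), t) == 1.0

    def test_last_residue(self):
        t = single_exon_transcript(303)
        v = make_variant(1001 + 99 * 3)  # codon 100 of 100
        assert ts.fraction_affected(v, t) == pytest.approx(0.01)

    def test_natural_stop_codon_clamps(self, caplog):
        t = single_exon_transcript(303)
        v = make_variant(1001 + 302)  # inside the stop codon (codon 101)
        with caplog.at_level("WARNING"):
            assert ts.fraction_affected(v, t) == pytest.approx(0.01)
        assert any("clamping" in r.message for r in caplog.records)


class TestDomainTruncation:
    @pytest.mark.parametrize(
        "codon, expected_frac, expected_complete",
        [(60, 20 / 30, False), (80, 0.0, False), (10, 1.0, True)],
        ids=["partial", "domain-upstream", "complete-loss"],
    )
    def test_domain_50_79(self, codon, expected_frac, expected_complete):
        t = single_exon_transcript(303)
        dom = [ts.DomainAnnotation("T1", "D1", 50, 79)]
        v = make_variant(1001 + (codon - 1) * 3)
        frac, complete = ts.domain_truncation(v, t, dom)
        assert frac == pytest.approx(expected_frac)
        assert complete is expected_complete

    def test_domain_beyond_protein_rejected(self):
        t = single_exon_transcript(303)
        dom = [ts.DomainAnnotation("T1", "D1", 50, 150)]
        with pytest.raises(ts.ModelValidationError, match="beyond"):
            ts.domain_truncation(make_variant(1001), t, dom)

    def test_complete_loss_iff_fraction_one(self, rng):
        """domain_truncation_max == 1.0 exactly when a whole domain is lost."""
        for _ in range(100):
            t = random_transcript(rng)
            p = t.protein_length_aa
            if p < 5:
                continue
            s = int(rng.integers(1, p))
            e = int(rng.integers(s, p + 1))
            dom = [ts.DomainAnnotation("Trand", "D", s, e)]
            cds_nt = int(rng.integers(1, t.coding_length_nt - 2))
            gpos = ts.cds_to_genomic(t, cds_nt)
            frac, complete = ts.domain_truncation(make_variant(gpos), t, dom)
            assert complete == (frac == 1.0)


def two_isoform_gene(shared=True):
    # exon A 1001-1090 (90 nt), exon B 2001-2090 (90 nt)
    t1 = make_transcript([(1001, 1090), (2001, 2090)], tid="T1")
    if shared:
        t2 = make_transcript([(1001, 1090), (2001, 2090)], tid="T2")
    else:
        t2 = make_transcript([(2001, 2090)], tid="T2")
    return ts.GeneModel("G1", (t1, t2))


class TestIsoformSummary:
    def test_partial_sharing(self):
        g = two_isoform_gene(shared=False)
        n, n_aff, ratio, constitutive = ts.isoform_summary(make_variant(1010), g)
        assert (n, n_aff, ratio, constitutive) == (2, 1, 0.5, False)

    def test_shared_exon_is_constitutive(self):
        g = two_isoform_gene(shared=True)
        n, n_aff, ratio, constitutive = ts.isoform_summary(make_variant(1010), g)
        assert (ratio, constitutive) == (1.0, True)

    def test_single_isoform_gene(self):
        g = ts.GeneModel("G1", (single_exon_transcript(),))
        assert ts.isoform_summary(make_variant(1010), g)[2:] == (1.0, True)

    def test_noncoding_everywhere_is_an_error(self):
        g = two_isoform_gene()
        with pytest.raises(ts.NonCodingVariantError):
            ts.isoform_summary(make_variant(5), g)


class TestPrincipalTruncated:
    def test_designated_principal(self):
        g = ts.GeneModel("G1", two_isoform_gene(shared=False).transcripts, "T1")
        hit, missing = ts.principal_truncated(make_variant(1010), g)
        assert (hit, missing) == (True, False)

    def test_fallback_to_longest_isoform(self):
        g = two_isoform_gene(shared=False)  # T1 180 nt, T2 90 nt, no principal
        hit, missing = ts.principal_truncated(make_variant(1010), g)
        assert (hit, missing) == (True, True)
        # variant only in T2's exon: longest isoform T1 also carries that exon
        hit2, _ = ts.principal_truncated(make_variant(2010), g)
        assert hit2 is True

    def test_length_tie_breaks_lexicographically(self):
        t1 = make_transcript([(1001, 1090)], tid="TB")
        t2 = make_transcript([(2001, 2090)], tid="TA", gid="G1")
        g = ts.GeneModel("G1", (t1, t2))
        t, missing = ts.features.principal_transcript(g)
        assert (t.transcript_id, missing) == ("TA", True)


class TestNmdTarget:
    def _transcript_with_junction_at(self, junction_cds=250, total=300):
        # two segments: first of length junction_cds, second the rest
        return make_transcript(
            [(1001, 1000 + junction_cds), (5001, 5000 + total - junction_cds)]
        )

    def test_distance_51_triggers(self):
        t = self._transcript_with_junction_at(250)
        v = make_variant(1001 + 198)  # cds_nt 199, distance 51
        assert ts.nmd_target(v, t) is True

    def test_distance_50_escapes_boundary_is_strict(self):
        t = self._transcript_with_junction_at(250)
        v = make_variant(1001 + 199)  # cds_nt 200, distance 50
        assert ts.nmd_target(v, t) is False

    def test_single_segment_transcript_escapes(self):
        t = single_exon_transcript()
        assert ts.nmd_target(make_variant(1001), t) is False

    @pytest.mark.parametrize(
        "flags, expected",
        [((True, True), "all"), ((True, False), "some"), ((False, False), "none")],
    )
    def test_isoform_scope(self, flags, expected):
        # both isoforms share a long first exon; junction position differs
        t1 = make_transcript([(1001, 1300), (5001, 5060)], tid="T1")  # junction 300
        t2 = make_transcript([(1001, 1300), (5001, 5003), (6001, 6057)], tid="T2")
        g = ts.GeneModel("G1", (t1, t2))
        # choose positions realizing each flag combination on (T1, T2):
        # T2's junction for its last segment is 303
        pos_by_flags = {
            (True, True): 1001,      # cds 1: far from both junctions
            (True, False): 1001 + 251,  # cds 252: 300-252=48<=50? no -> 48 escapes T1
            (False, False): 1001 + 260,
        }
        v = make_variant(pos_by_flags[flags])
        if flags == (True, False):
            # distance to T1 junction (300) is 48 -> escape; T2 junction (303) is 51 -> target
            v = make_variant(1001 + 251)
            assert ts.nmd_target(v, t1) is False
            assert ts.nmd_target(v, t2) is True
            assert ts.nmd_isoform_scope(v, g) == "some"
        elif flags == (True, True):
            assert ts.nmd_isoform_scope(v, g) == "all"
        else:
            assert ts.nmd_isoform_scope(v, g) == "none"


class TestComputeFeatureVector:
    def test_degenerate_single_exon_gene(self):
        g = ts.GeneModel("G1", (single_exon_transcript(),))
        fv = ts.compute_feature_vector(make_variant(1001), g, [])
        assert fv.fraction_affected_max == 1.0
        assert fv.domain_truncation_max == 0.0 and fv.missing_domain
        assert (fv.n_isoforms, fv.ratio_isoforms_affected) == (1, 1.0)
        assert fv.principal_truncated and fv.missing_principal
        assert fv.nmd_target is False and fv.nmd_scope == "none"

    def test_moving_to_last_codon_only_changes_fraction(self):
        t = single_exon_transcript(303)
        g = ts.GeneModel("G1", (t,))
        first = ts.compute_feature_vector(make_variant(1001), g, [])
        last = ts.compute_feature_vector(make_variant(1001 + 99 * 3), g, [])
        assert last.fraction_affected_max == pytest.approx(1 / 100)
        for f in ("domain_truncation_max", "n_isoforms", "ratio_isoforms_affected",
                  "principal_truncated", "nmd_target"):
            assert getattr(first, f) == getattr(last, f)

    def test_monotone_in_position_along_one_isoform(self, rng):
        """Sliding 3' along a transcript never increases the truncated
        fractions and never switches NMD from escape to target."""
        for _ in range(30):
            t = random_transcript(rng)
            p = t.protein_length_aa
            if p < 10:
                continue
            dom = [ts.DomainAnnotation("Trand", "D", max(1, p // 3), max(2, 2 * p // 3))]
            prev = None
            for cds_nt in range(1, t.coding_length_nt - 2, 7):
                v = make_variant(ts.cds_to_genomic(t, cds_nt))
                cur = (
                    ts.fraction_affected(v, t),
                    ts.domain_truncation(v, t, dom)[0],
                    ts.nmd_target(v, t),
                )
                if prev is not None:
                    assert cur[0] <= prev[0] + 1e-12
                    assert cur[1] <= prev[1] + 1e-12
                    assert not (cur[2] and not prev[2])
                prev = cur

    def test_brute_force_per_residue_oracle_on_fixture(self, golden_bundle, golden_domain_list):
        """Marking every residue downstream of the truncation codon one by
        one reproduces the interval-arithmetic features exactly."""
        genes = {g.gene_id: g for g in golden_bundle["genes"]}
        truth = golden_bundle["truth"]
        for v, (_, row) in zip(golden_bundle["variants"], truth.iterrows()):
            fv = ts.compute_feature_vector(v, genes[row.gene_id], golden_domain_list)
            assert fv.fraction_affected_max == pytest.approx(row.fraction_affected_max, abs=1e-12)
            assert fv.domain_truncation_max == pytest.approx(row.domain_truncation_max, abs=1e-12)
            assert fv.nmd_target == bool(row.nmd_target)

    def test_constitutive_implies_full_ratio(self, golden_bundle, golden_domain_list):
        genes = {g.gene_id: g for g in golden_bundle["genes"]}
        for v, (_, row) in zip(golden_bundle["variants"], golden_bundle["truth"].iterrows()):
            fv = ts.compute_feature_vector(v, genes[row.gene_id], golden_domain_list)
            if fv.constitutive_position:
                assert fv.ratio_isoforms_affected == 1.0
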