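"""Population-variant ingestion, overlay, and privacy summaries."""

import pandas as pd
import pytest

from offpop.datasets import variant_for_row
from offpop.errors import (
    DataIntegrityError,
    ParameterError,
    ValidationError,
)
from offpop.guide import CandidateSite
from offpop.variants import (
    EFFECT_NO_CHANGE,
    VariantRecord,
    apply_variant,
    polymorphic_filter,
    population_privacy,
    read_frequencies,
    reevaluate,
)

SPACER = "GCTCTAGGCCGAAGTGTCGC"
PMAP = {"E": "EUR_AF", "LA": "AMR_AF", "A": "AFR_AF", "W": "AF"}

VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=AF,Number=A,Type=Float,Description="AF">
##INFO=<ID=EUR_AF,Number=A,Type=Float,Description="EUR AF">
##INFO=<ID=AMR_AF,Number=A,Type=Float,Description="AMR AF">
##INFO=<ID=AFR_AF,Number=A,Type=Float,Description="AFR AF">
##contig=<ID=chr19,length=100000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _site(id, seq, chrom="chr1", start=100, strand="+", **kw):
    ungapped = seq.replace("-", "")
    return CandidateSite(
        id=id, chrom=chrom, start=start, end=start + len(ungapped),
        strand=strand, observed_seq=seq, **kw
    )


class TestReadFrequencies:
    def test_vcf_population_mapping(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(
            VCF_HEADER
            + "chr19\t8456443\t.\tTAC\tT\t.\tPASS\t"
              "AF=0.070;EUR_AF=0.043;AMR_AF=0.037;AFR_AF=0.113\n"
        )
        (rec,) = read_frequencies(p, PMAP)
        assert rec.af == pytest.approx(
            {"E": 0.043, "LA": 0.037, "A": 0.113, "W": 0.070}
        )
        assert rec.ref == "TAC" and rec.alt == "T"

    def test_multiallelic_split(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(
            VCF_HEADER
            + "chr19\t100\t.\tA\tC,G\t.\tPASS\t"
              "AF=0.1,0.2;EUR_AF=0.01,0.02\n"
        )
        recs = read_frequencies(p, PMAP)
        assert len(recs) == 2
        assert recs[0].alt == "C" and recs[0].af["E"] == pytest.approx(0.01)
        assert recs[1].alt == "G" and recs[1].af["W"] == pytest.approx(0.2)

    def test_absent_population_is_absent_not_zero(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(VCF_HEADER + "chr19\t100\t.\tA\tC\t.\tPASS\tAFR_AF=0.05\n")
        (rec,) = read_frequencies(p, PMAP)
        assert rec.af == pytest.approx({"A": 0.05})
        assert "E" not in rec.af

    def test_unmapped_info_key_is_config_error(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(VCF_HEADER + "chr19\t100\t.\tA\tC\t.\tPASS\tAF=0.1\n")
        with pytest.raises(ValidationError, match="SAS_AF"):
            read_frequencies(p, {"X": "SAS_AF"})

    def test_tsv_single_population(self, tmp_path):
        p = tmp_path / "freqs.tsv"
        p.write_text(
            "chrom\tpos\tref\talt\tpopulation\taf\n"
            "chr1\t500\tG\tA\tLA\t0.021\n"
        )
        (rec,) = read_frequencies(p, PMAP)
        assert rec.af == {"LA": 0.021}

    def test_tsv_unmapped_population_label(self, tmp_path):
        p = tmp_path / "freqs.tsv"
        p.write_text(
            "chrom\tpos\tref\talt\tpopulation\taf\nchr1\t500\tG\tA\tXX\t0.5\n"
        )
        with pytest.raises(ValidationError, match="XX"):
            read_frequencies(p, PMAP)

    def test_empty_population_map(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(VCF_HEADER)
        with pytest.raises(ValidationError):
            read_frequencies(p, {})


class TestPolymorphicFilter:
    def test_single_population_over_threshold(self):
        rec = VariantRecord("chr1", 1, "C", "T",
                            af={"E": 0.0, "LA": 0.006, "A": 0.031, "W": 0.009})
        polymorphic_filter([rec])
        assert rec.polymorphic and rec.populations_over_threshold == {"A"}

    def test_all_populations_over(self):
        rec = VariantRecord("chr1", 1, "C", "T",
                            af={"E": 0.81, "LA": 0.878, "A": 0.629, "W": 0.79})
        polymorphic_filter([rec])
        assert rec.populations_over_threshold == {"E", "LA", "A"}

    def test_below_threshold_everywhere(self):
        rec = VariantRecord("chr1", 1, "C", "T",
                            af={"E": 0.009, "LA": 0.0, "A": 0.0099})
        polymorphic_filter([rec])
        assert not rec.polymorphic

    def test_threshold_is_inclusive(self):
        rec = VariantRecord("chr1", 1, "C", "T", af={"E": 0.01})
        polymorphic_filter([rec])
        assert rec.polymorphic

    def test_worldwide_does_not_trigger(self):
        rec = VariantRecord("chr1", 1, "C", "T", af={"W": 0.5, "E": 0.001})
        polymorphic_filter([rec])
        assert not rec.polymorphic

    def test_parameter_validation(self):
        rec = VariantRecord("chr1", 1, "C", "T", af={})
        with pytest.raises(ParameterError):
            polymorphic_filter([rec], threshold=1.5)
        with pytest.raises(ValidationError):
            polymorphic_filter([rec], populations=set())


class TestApplyVariant:
    def test_snv_forced_decrease(self, guide, tables):
        # mismatch at position 9 (T vs guide C); ALT restores the guide base
        seq = SPACER[:8] + "T" + SPACER[9:] + "AGG"
        site = _site("x", seq)
        v = VariantRecord("chr1", 100 + 9, "T", "C", af={})
        res = reevaluate(site, v, guide, tables)
        assert res.m_i_before[0] - res.m_i_after[0] == 1

    def test_ref_mismatch_is_data_integrity_error(self):
        site = _site("x", SPACER + "AGG")
        v = VariantRecord("chr1", 101, "T", "C", af={})  # actual base is G
        with pytest.raises(DataIntegrityError):
            apply_variant(site, v)

    def test_variant_outside_window_without_flanks(self):
        site = _site("x", SPACER + "AGG")
        v = VariantRecord("chr1", 95, "A", "T", af={})
        with pytest.raises(ValidationError, match="outside"):
            apply_variant(site, v)

    def test_flanks_allow_upstream_variant(self):
        site = _site("x", SPACER + "AGG", flank5="AAAAATTTTT")
        site.start, site.end = 110, 133
        v = VariantRecord("chr1", 106, "T", "G", af={})
        assert apply_variant(site, v) == site.ungapped  # window unchanged

    def test_deletion_variant_shrinks_window(self, guide, tables):
        site = _site("x", SPACER + "AGG")
        # delete spacer bases 5-6 (TA): REF covers an anchor plus two bases
        v = VariantRecord("chr1", 105, "TAG", "T", af={})
        new_seq = apply_variant(site, v)
        assert len(new_seq) == 21
        assert new_seq == SPACER[:5] + SPACER[7:] + "AGG"

    def test_insufficient_flank_for_large_deletion(self):
        site = _site("x", SPACER + "AGG")
        v = VariantRecord("chr1", 101, "GCTCT", "G", af={})  # 23->19 nt
        with pytest.raises(ValidationError, match="flank"):
            apply_variant(site, v)

    def test_minus_strand_substitution(self, guide, tables):
        from Bio.Seq import reverse_complement

        seq = SPACER + "AGG"
        site = _site("x", seq, strand="-")
        # genomic window is revcomp; variant at genomic pos of guide base 1
        v = VariantRecord("chr1", 100 + 23, reverse_complement(SPACER[0]),
                          "A", af={})
        new_seq = apply_variant(site, v)
        assert new_seq == "T" + seq[1:]


class TestReevaluate:
    def test_demo_overlay_rows(self, guide, tables, demo_candidates,
                               demo_site_variants):
        sites, _ = demo_candidates
        by_id = {s.id: s for s in sites}
        for row in demo_site_variants.itertuples(index=False):
            site = by_id[row.site_id]
            res = reevaluate(site, variant_for_row(site, row), guide, tables)
            if pd.notna(row.mi_before):
                assert f"{res.m_i_before[0]}/{res.m_i_before[1]}" == row.mi_before, row
            if pd.notna(row.mi_after):
                assert f"{res.m_i_after[0]}/{res.m_i_after[1]}" == row.mi_after, row
            if pd.notna(row.pam_after):
                assert res.pam_after == row.pam_after, row
            if row.group in {"pam_disrupted", "pam_created"}:
                assert row.group in res.effects, row

    def test_no_change_for_synonymous_window_variant(self, guide, tables):
        site = _site("x", SPACER + "AGG", flank5="TTTTTTTTTT")
        site.start, site.end = 110, 133
        v = VariantRecord("chr1", 103, "T", "C", af={})  # in flank only
        res = reevaluate(site, v, guide, tables)
        assert res.effects == {EFFECT_NO_CHANGE}

    def test_pam_disrupted_and_created_mutually_exclusive(
        self, guide, tables, demo_candidates, demo_site_variants
    ):
        sites, _ = demo_candidates
        by_id = {s.id: s for s in sites}
        for row in demo_site_variants.itertuples(index=False):
            site = by_id[row.site_id]
            res = reevaluate(site, variant_for_row(site, row), guide, tables)
            assert not (
                "pam_disrupted" in res.effects and "pam_created" in res.effects
            )

    def test_inverse_variant_round_trip(self, guide, tables, demo_candidates,
                                        demo_site_variants):
        sites, _ = demo_candidates
        by_id = {s.id: s for s in sites}
        for row in demo_site_variants.itertuples(index=False):
            site = by_id[row.site_id]
            v = variant_for_row(site, row)
            new_seq = apply_variant(site, v)
            mutated = CandidateSite(
                id=site.id + "_mut", chrom=site.chrom, start=site.start,
                end=site.start + len(new_seq), strand=site.strand,
                observed_seq=new_seq,
            )
            inverse = VariantRecord(v.chrom, v.pos, v.alt, v.ref, af={})
            restored = apply_variant(mutated, inverse)
            assert restored == site.ungapped
            res = reevaluate(mutated, inverse, guide, tables)
            before = reevaluate(site, v, guide, tables)
            assert res.m_i_after == before.m_i_before
            # the score round-trips exactly when the stored notation is the
            # aligner's own placement; predictor-declared gaps/markup may
            # realign differently once re-derived from the raw sequence
            if "-" not in site.observed_seq and site.observed_seq.isupper():
                assert res.score_after == before.score_before


class TestPopulationPrivacy:
    def _recs(self, af_list):
        recs = [
            VariantRecord("chr1", i + 1, "A", "C", af=af)
            for i, af in enumerate(af_list)
        ]
        return polymorphic_filter(recs)

    def test_single_population_dataset_all_private(self):
        recs = self._recs([{"A": 0.05}, {"A": 0.02}, {"A": 0.001}])
        out = population_privacy(recs)
        assert out["private"]["A"] == 2
        assert out["shared"] == 0 and out["total"] == 2

    def test_two_population_shared(self):
        recs = self._recs([{"E": 0.02, "LA": 0.03}])
        out = population_privacy(recs)
        assert out["shared"] == 1
        assert all(v == 0 for v in out["private"].values())

    def test_partition_property(self):
        import numpy as np

        rng = np.random.default_rng(42)
        af_list = [
            {p: float(rng.uniform(0, 0.05)) for p in ("E", "LA", "A")}
            for _ in range(200)
        ]
        recs = self._recs(af_list)
        out = population_privacy(recs)
        n_poly = sum(1 for r in recs if r.polymorphic)
        assert sum(out["private"].values()) + out["shared"] == n_poly
        assert out["total"] == n_poly

    def test_demo_frequency_rows(self, demo_candidates, demo_site_variants):
        sites, _ = demo_candidates
        by_id = {s.id: s for s in sites}
        recs = []
        for row in demo_site_variants.itertuples(index=False):
            if pd.notna(row.af_A):
                recs.append(variant_for_row(by_id[row.site_id], row))
        polymorphic_filter(recs)
        out = population_privacy(recs)
        # rows over 1% only in Africa: 75 (x2), 18, 123, 173 -> private to A
        assert out["private"]["A"] == 5
        assert out["private"]["E"] == 0
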