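import numpy as np
import pytest

from genomehub.dataloading import GenomicInterval
from genomehub.model_spec import ArraySchema, DataloaderConfig, ModelDescription
from genomehub.models import LinearModel
from genomehub.registry import Model
from genomehub.variant_effects import (
    RefMismatchError,
    Variant,
    center_on_variant,
    effect_scores,
    inject_allele,
    match_anchored_regions,
    read_vcf_snvs,
    score_variants,
    write_annotated_vcf,
)


def make_wrapped_linear(weights, bias=0.0, link="identity", L=8, name="toy"):
    desc = ModelDescription(
        name=name,
        framework_kind="linear",
        inputs=[ArraySchema("seq", (None, L, 4), special_type="DNASeq")],
        targets=ArraySchema("score", (None, 1), column_labels=["score"]),
        dataloader=DataloaderConfig(sequence_length=L),
    )
    return Model(desc, LinearModel(weights=weights, bias=bias, link=link))


@pytest.fixture()
def constant_model():
    # zero weights: prediction is the same whatever the sequence
    return make_wrapped_linear(np.zeros(32), bias=0.3, link="sigmoid", L=8)


class TestReadVcf:
    def test_non_snv_alleles_counted_not_crashed(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\trs1\tA\tC\t.\t.\t.\n"
            "chr1\t200\trs2\tAT\tA\t.\t.\t.\n"
            "chr1\t300\trs3\tG\tT\t.\t.\t.\n"
        )
        variants, skipped = read_vcf_snvs(p)
        assert len(variants) == 2 and skipped == 1

    def test_multiallelic_expansion(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t150\trs1\tA\tC,G\t.\t.\t.\n"
        )
        variants, skipped = read_vcf_snvs(p)
        assert [(v.ref, v.alt) for v in variants] == [("A", "C"), ("A", "G")]
        assert skipped == 0

    def test_empty_body(self, tmp_path):
        p = tmp_path / "v.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        assert read_vcf_snvs(p) == ([], 0)


class TestWindows:
    @pytest.mark.parametrize(
        "pos,L,start,end,offset",
        [(101, 10, 95, 105, 5), (5, 3, 3, 6, 1), (1, 4, -2, 2, 2)],
    )
    def test_centered_window_geometry(self, pos, L, start, end, offset):
        iv = center_on_variant(Variant("chr1", pos, "A", "C"), L)
        assert (iv.start, iv.end) == (start, end)
        assert (pos - 1) - iv.start == offset

    def test_anchored_overlap_uses_half_open_semantics(self):
        region = GenomicInterval("chr1", 100, 200)
        inside = Variant("chr1", 150, "A", "C")
        boundary = Variant("chr1", 100, "A", "C")  # 0-based 99, outside
        outside = Variant("chr1", 250, "A", "C")
        pairs, unscored = match_anchored_regions([region], [inside, boundary, outside])
        assert [(v.pos) for v, _ in pairs] == [150]
        assert [v.pos for v in unscored] == [100, 250]

    def test_variant_matching_multiple_regions_pairs_each(self):
        regions = [GenomicInterval("chr1", 0, 50), GenomicInterval("chr1", 20, 70)]
        v = Variant("chr1", 30, "A", "C")
        pairs, unscored = match_anchored_regions(regions, [v])
        assert len(pairs) == 2 and unscored == []


class TestInjectAllele:
    iv = GenomicInterval("chr1", 0, 4)

    def test_alt_substituted_at_offset(self):
        ref_seq, alt_seq = inject_allele("AAAA", self.iv, Variant("chr1", 2, "A", "C"))
        assert (ref_seq, alt_seq) == ("AAAA", "ACAA")

    def test_ref_mismatch_raises(self):
        with pytest.raises(RefMismatchError, match="expected REF 'G'"):
            inject_allele("AAAA", self.iv, Variant("chr1", 2, "G", "C"))

    def test_hamming_distance_always_one(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=10))
            pos = int(rng.integers(1, 11))
            ref = seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            r, a = inject_allele(seq, GenomicInterval("chr1", 0, 10), Variant("chr1", pos, ref, alt))
            assert sum(x != y for x, y in zip(r, a)) == 1


class TestScoring:
    def test_logit_closed_form(self):
        scores = effect_scores(0.2, 0.7, ("DIFF", "LOGIT"))
        assert scores["DIFF"] == pytest.approx(0.5)
        assert scores["LOGIT"] == pytest.approx(
            np.log(0.7 / 0.3) - np.log(0.2 / 0.8), abs=1e-9
        )
        assert scores["LOGIT"] == pytest.approx(2.2336, abs=5e-4)

    def test_constant_model_scores_all_zero(self, constant_model, genome_fa, snv_vcf):
        variants, _ = read_vcf_snvs(snv_vcf)
        records = score_variants(
            constant_model, genome_fa, variants, scorings=("DIFF", "LOGIT")
        )
        assert records and all(r.scored for r in records)
        for rec in records:
            assert rec.scores["DIFF"] == 0.0
            assert rec.scores["LOGIT"] == 0.0

    def test_antisymmetry_under_ref_alt_swap(self, tmp_path):
        # score A->C against a genome carrying A, then C->A against the
        # same window carrying C: identical windows, swapped alleles
        model = make_wrapped_linear(
            np.random.default_rng(5).normal(size=32), link="sigmoid", L=8
        )
        fa_ref = tmp_path / "ref.fa"
        fa_ref.write_text(">chr1\nTTTTATTTTTTT\n")
        fa_alt = tmp_path / "alt.fa"
        fa_alt.write_text(">chr1\nTTTTCTTTTTTT\n")
        v_fwd = Variant("chr1", 5, "A", "C")
        v_rev = Variant("chr1", 5, "C", "A")
        (fwd,) = score_variants(model, fa_ref, [v_fwd], scorings=("DIFF", "LOGIT"))
        (rev,) = score_variants(model, fa_alt, [v_rev], scorings=("DIFF", "LOGIT"))
        assert fwd.scores["DIFF"] == pytest.approx(-rev.scores["DIFF"], abs=1e-15)
        assert fwd.scores["LOGIT"] == pytest.approx(-rev.scores["LOGIT"], abs=1e-12)

    def test_pwm_motif_destroying_variant_scores_negative(self, tmp_path):
        from genomehub.models import PWMModel
        from genomehub.model_spec import TestConfig

        probs = np.full((4, 4), 0.01)
        probs[:, 0] = 0.97  # AAAA consensus
        pwm = PWMModel(probs=probs / probs.sum(axis=1, keepdims=True))
        desc = ModelDescription(
            name="pwm_test", framework_kind="pwm",
            inputs=[ArraySchema("seq", (None, 12, 4), special_type="DNASeq")],
            targets=ArraySchema("score", (None, 1)),
            dataloader=DataloaderConfig(sequence_length=12),
        )
        model = Model(desc, pwm)
        fasta = tmp_path / "g.fa"
        fasta.write_text(">chr1\nCGCGAAAACGCG\n")
        v = Variant("chr1", 6, "A", "G")  # breaks the only AAAA match
        (rec,) = score_variants(model, fasta, [v], scorings=("DIFF",))
        assert rec.scored and rec.scores["DIFF"] < 0

    def test_anchored_mode_without_regions_errors(self, constant_model, genome_fa):
        with pytest.raises(ValueError, match="anchored mode requires regions"):
            score_variants(constant_model, genome_fa, [], mode="anchored")

    def test_mode_equivalence_for_centered_region(self, pwm_model, genome_fa, snv_vcf):
        variants, _ = read_vcf_snvs(snv_vcf)
        v = variants[0]
        L = pwm_model.input_length
        region = center_on_variant(v, L)
        centered = score_variants(pwm_model, genome_fa, [v], mode="centered")
        anchored = score_variants(
            pwm_model, genome_fa, [v], mode="anchored", regions=[region]
        )
        assert centered[0].scores == anchored[0].scores

    def test_ref_mismatch_reported_unscored(self, pwm_model, genome_fa, snv_vcf):
        from genomehub.dataloading import fetch_sequence

        variants, _ = read_vcf_snvs(snv_vcf)
        v = variants[0]
        # fabricate a wrong-REF variant at the same position
        genome_base = v.ref
        wrong_ref = next(b for b in "ACGT" if b not in (genome_base, v.alt))
        bad = Variant(v.chrom, v.pos, wrong_ref, v.alt)
        recs = score_variants(pwm_model, genome_fa, [bad])
        assert len(recs) == 1 and not recs[0].scored and recs[0].scores == {}


class TestAnnotatedVcf:
    def test_record_conservation_header_and_roundtrip(
        self, pwm_model, genome_fa, snv_vcf, tmp_path
    ):
        variants, _ = read_vcf_snvs(snv_vcf)
        records = score_variants(
            pwm_model, genome_fa, variants, scorings=("DIFF", "LOGIT")
        )
        out = tmp_path / "annotated.vcf"
        write_annotated_vcf(snv_vcf, records, out)
        in_body = [l for l in open(snv_vcf) if not l.startswith("#")]
        out_lines = open(out).readlines()
        out_body = [l for l in out_lines if not l.startswith("#")]
        assert len(out_body) == len(in_body)
        # non-INFO columns byte-identical, input order preserved
        for a, b in zip(in_body, out_body):
            assert a.split("\t")[:7] == b.split("\t")[:7]
        info_headers = [l for l in out_lines if l.startswith("##INFO")]
        assert len(info_headers) == 2  # one per (model, output, scoring)
        assert all("Number=A,Type=Float" in h for h in info_headers)
        # scores survive the round trip at 6 significant digits
        by_key = {}
        for rec in records:
            by_key[rec.variant.key] = rec.scores["DIFF"]
        for line in out_body:
            f = line.split("\t")
            key = (f[0], int(f[1]), f[3], f[4])
            info = dict(kv.split("=") for kv in f[7].split(";"))
            diff_field = next(v for k, v in info.items() if k.endswith("_DIFF"))
            assert float(diff_field) == pytest.approx(by_key[key], rel=1e-5)

    def test_unscored_variant_gets_dot(self, pwm_model, genome_fa, snv_vcf, tmp_path):
        variants, _ = read_vcf_snvs(snv_vcf)
        region = center_on_variant(variants[0], pwm_model.input_length)
        records = score_variants(
            pwm_model, genome_fa, variants, mode="anchored", regions=[region]
        )
        out = tmp_path / "annotated.vcf"
        write_annotated_vcf(snv_vcf, records, out)
        body = [l for l in open(out) if not l.startswith("#")]
        assert len(body) == len(variants)
        dots = [l for l in body if "=." in l.split("\t")[7]]
        assert len(dots) == len(variants) - 1
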