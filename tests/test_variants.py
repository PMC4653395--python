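"""VCF reading and the class/region/quality/AF/genotype filter cascade."""

import itertools

import pytest

from ontovar.fixtures import FixtureSpec, default_filter_config, make_disease_world, make_vcf
from ontovar.variants import (
    ConsequenceClass as CC,
    FilterConfig,
    Genotype as GT,
    InheritanceMode,
    VariantRecord,
    apply_filters,
    class_filter,
    genotype_filter,
    read_vcf,
    region_qual_af_filter,
    write_filter_report,
    write_vcf_subset,
)

HEADER = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000000>
##INFO=<ID=CSQ,Number=.,Type=String,Description="ALT|GENE|TRANSCRIPT|CLASS">
##INFO=<ID=AF,Number=A,Type=Float,Description="AF">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tAFF\tUNAFF
"""


def write_vcf_text(tmp_path, body, header=HEADER):
    path = tmp_path / "test.vcf"
    path.write_text(header + body)
    return str(path)


def record(gene="G1", classes=(CC.MISSENSE,), gts=None, pos=100, qual=50.0, af=None):
    return VariantRecord(
        chrom="chr1", pos=pos, ref="A", alt="T", qual=qual, gene=gene,
        consequences={(f"tx{i}", c) for i, c in enumerate(classes)},
        genotypes=gts or {"AFF": GT.HOM_ALT, "UNAFF": GT.HET},
        allele_frequency=af,
    )


class TestReadVcf:
    def test_two_sample_genotypes(self, tmp_path):
        path = write_vcf_text(
            tmp_path, "chr1\t100\t.\tA\tT\t50\t.\tCSQ=T|G1|tx1|MISSENSE\tGT\t1/1\t0/1\n"
        )
        data = read_vcf(path)
        (v,) = data.records
        assert v.genotypes == {"AFF": GT.HOM_ALT, "UNAFF": GT.HET}
        assert v.gene == "G1"
        assert v.consequences == {("tx1", CC.MISSENSE)}

    def test_multiallelic_split(self, tmp_path):
        path = write_vcf_text(
            tmp_path,
            "chr1\t100\t.\tG\tA,T\t50\t.\t"
            "CSQ=A|G1|tx1|MISSENSE,T|G1|tx1|NONSENSE;AF=0.01,0.2\tGT\t1/2\t0/1\n",
        )
        data = read_vcf(path)
        assert len(data.records) == 2
        a, t = data.records
        assert (a.alt, t.alt) == ("A", "T")
        assert a.genotypes["AFF"] is GT.HET and t.genotypes["AFF"] is GT.HET
        assert t.genotypes["UNAFF"] is GT.HOM_REF  # '0/1' relative to allele 2
        assert a.allele_frequency == pytest.approx(0.01)
        assert t.allele_frequency == pytest.approx(0.2)
        assert {c for _, c in t.consequences} == {CC.NONSENSE}

    def test_header_only(self, tmp_path):
        assert read_vcf(write_vcf_text(tmp_path, "")).records == []

    def test_missing_genotype_coded(self, tmp_path):
        path = write_vcf_text(
            tmp_path, "chr1\t100\t.\tA\tT\t50\t.\tCSQ=T|G1|tx1|MISSENSE\tGT\t./.\t0/0\n"
        )
        (v,) = read_vcf(path).records
        assert v.genotypes["AFF"] is GT.MISSING

    def test_no_gt_format_is_hard_error(self, tmp_path):
        header = HEADER.replace(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n',
        )
        path = write_vcf_text(tmp_path, "", header=header)
        with pytest.raises(ValueError, match="GT"):
            read_vcf(path)


class TestClassFilter:
    DROP = FilterConfig(drop_classes=frozenset({CC.SYNONYMOUS}))

    def test_all_benign_removed(self):
        assert not class_filter(record(classes=(CC.SYNONYMOUS,)), self.DROP)

    def test_transcript_plurality_survives(self):
        # benign in tx0, damaging in tx1: codon-position plurality keeps it
        assert class_filter(record(classes=(CC.SYNONYMOUS, CC.MISSENSE)), self.DROP)

    def test_empty_drop_classes_keeps_everything(self):
        assert class_filter(record(classes=(CC.SYNONYMOUS,)), FilterConfig())


class TestRegionQualAf:
    def test_region_boundaries_inclusive(self):
        cfg = FilterConfig(regions=[("chr1", 100, 200)])
        assert region_qual_af_filter(record(pos=100), cfg)
        assert region_qual_af_filter(record(pos=200), cfg)
        assert not region_qual_af_filter(record(pos=99), cfg)
        assert not region_qual_af_filter(record(pos=201), cfg)

    def test_low_quality_removed(self):
        assert not region_qual_af_filter(record(qual=10), FilterConfig(min_qual=20))

    def test_absent_af_is_retained(self):
        cfg = FilterConfig(max_af=0.01)
        assert region_qual_af_filter(record(af=None), cfg)
        assert not region_qual_af_filter(record(af=0.5), cfg)

    def test_degenerate_region_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            FilterConfig(regions=[("chr1", 200, 100)])


RECESSIVE = FilterConfig(
    inheritance_mode=InheritanceMode.RECESSIVE, affected=["AFF"], unaffected=["UNAFF"]
)


class TestGenotypeFilter:
    def test_hom_alt_affected_het_unaffected_retained(self):
        v = record(gts={"AFF": GT.HOM_ALT, "UNAFF": GT.HET})
        assert genotype_filter(v, RECESSIVE, {})

    def test_both_hom_alt_removed(self):
        v = record(gts={"AFF": GT.HOM_ALT, "UNAFF": GT.HOM_ALT})
        assert not genotype_filter(v, RECESSIVE, {})

    def test_unknown_sample_is_hard_error(self):
        cfg = FilterConfig(genotype_requirements={"NOPE": {GT.HET}})
        with pytest.raises(ValueError, match="absent from VCF"):
            genotype_filter(record(), cfg, {})

    def test_explicit_requirements(self):
        cfg = FilterConfig(genotype_requirements={"AFF": {GT.HOM_ALT}})
        assert genotype_filter(record(gts={"AFF": GT.HOM_ALT, "UNAFF": GT.HET}), cfg, {})
        assert not genotype_filter(record(gts={"AFF": GT.HET, "UNAFF": GT.HET}), cfg, {})

    def test_missing_satisfies_nothing_unless_allowed(self):
        cfg = FilterConfig(genotype_requirements={"AFF": {GT.HOM_ALT}})
        assert not genotype_filter(record(gts={"AFF": GT.MISSING, "UNAFF": GT.HET}), cfg, {})
        cfg2 = FilterConfig(genotype_requirements={"AFF": {GT.HOM_ALT, GT.MISSING}})
        assert genotype_filter(record(gts={"AFF": GT.MISSING, "UNAFF": GT.HET}), cfg2, {})

    def test_compound_het_matches_bruteforce(self):
        """Two variants in one gene: compare against exhaustive rule evaluation."""
        def rule(gt, n_het):
            return gt is GT.HOM_ALT or (gt is GT.HET and n_het >= 2)

        gts = [GT.HOM_REF, GT.HET, GT.HOM_ALT]
        for aff1, aff2, un1, un2 in itertools.product(gts, repeat=4):
            v1 = record(gts={"AFF": aff1, "UNAFF": un1}, pos=100)
            v2 = record(gts={"AFF": aff2, "UNAFF": un2}, pos=200)
            survivors, _, _ = apply_filters([v1, v2], RECESSIVE)
            for v, gt_a, gt_u in ((v1, aff1, un1), (v2, aff2, un2)):
                n_het_a = sum(g is GT.HET for g in (aff1, aff2))
                n_het_u = sum(g is GT.HET for g in (un1, un2))
                expected = rule(gt_a, n_het_a) and not rule(gt_u, n_het_u)
                assert (v in survivors) == expected, (aff1, aff2, un1, un2)

    def test_compound_het_spec_example(self):
        # affected het at both variants, unaffected het at only one: both retained
        v1 = record(gts={"AFF": GT.HET, "UNAFF": GT.HET}, pos=100)
        v2 = record(gts={"AFF": GT.HET, "UNAFF": GT.HOM_REF}, pos=200)
        survivors, genes, _ = apply_filters([v1, v2], RECESSIVE)
        assert survivors == [v1, v2]
        assert genes == {"G1"}


class TestApplyFilters:
    def six_variant_fixture(self):
        cfg = FilterConfig(
            drop_classes=frozenset({CC.SYNONYMOUS}),
            min_qual=20, max_af=0.01,
            inheritance_mode=InheritanceMode.RECESSIVE,
            affected=["AFF"], unaffected=["UNAFF"],
        )
        variants = [
            record(gene="G1", classes=(CC.SYNONYMOUS,), pos=1),        # class
            record(gene="G2", qual=10, pos=2),                          # quality
            record(gene="G3", af=0.5, pos=3),                           # AF
            record(gene="G4", gts={"AFF": GT.HET, "UNAFF": GT.HOM_REF},
                   pos=4),                                              # lone het
            record(gene="G5", gts={"AFF": GT.HET, "UNAFF": GT.HET}, pos=5),
            record(gene="G5", gts={"AFF": GT.HET, "UNAFF": GT.HOM_REF}, pos=6),
        ]
        return variants, cfg

    def test_hand_counted_six_variant_fixture(self):
        variants, cfg = self.six_variant_fixture()
        survivors, genes, report = apply_filters(variants, cfg)
        assert [v.pos for v in survivors] == [5, 6]
        assert genes == {"G5"}
        assert report.removed_class == 1
        assert report.removed_region_qual_af == 2
        assert report.removed_genotype == 1
        assert report.total_removed() == 4
        assert report.n_survivors == 2

    def test_all_pass_config_keeps_everything(self):
        variants, _ = self.six_variant_fixture()
        survivors, _, report = apply_filters(variants, FilterConfig())
        assert survivors == variants
        assert report.total_removed() == 0

    def test_empty_input(self):
        survivors, genes, report = apply_filters([], FilterConfig())
        assert survivors == [] and genes == set() and report.n_input == 0

    def test_stricter_quality_never_gains_survivors(self):
        variants, cfg = self.six_variant_fixture()
        import dataclasses
        prev = None
        for q in (0, 20, 40, 60):
            c = dataclasses.replace(cfg, min_qual=q)
            n = apply_filters(variants, c)[2].n_survivors
            if prev is not None:
                assert n <= prev
            prev = n

    def test_pure_predicates_order_independent(self):
        variants, cfg = self.six_variant_fixture()
        a = [v for v in variants if class_filter(v, cfg) and region_qual_af_filter(v, cfg)]
        b = [v for v in variants if region_qual_af_filter(v, cfg) and class_filter(v, cfg)]
        assert a == b

    def test_report_and_subset_written(self, tmp_path):
        spec = FixtureSpec(seed=5, n_variants=30)
        world = make_disease_world(spec)
        vcf_path = tmp_path / "sim.vcf"
        truth = make_vcf(spec, world, str(vcf_path))
        data = read_vcf(str(vcf_path))
        cfg = default_filter_config(truth["affected"], truth["unaffected"])
        survivors, genes, report = apply_filters(data.records, cfg)
        assert truth["planted_gene"] in genes
        write_filter_report(report, str(tmp_path / "report.tsv"))
        write_vcf_subset(data, survivors, str(tmp_path / "subset.vcf"))
        sub = read_vcf(str(tmp_path / "subset.vcf"))
        assert len(sub.records) == len(survivors)
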