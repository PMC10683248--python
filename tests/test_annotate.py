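import math

import pytest

from mmis import (
    AnnotationReport,
    VariantKey,
    annotate,
    filter_to_panel,
    read_annotated_table,
    read_vcf,
    select_mane_transcript,
    write_annotated_table,
)
from mmis.annotate import CoercionFailure, SchemaError, coerce_value
from mmis.synth import gen_registry, gen_schema, gen_sources, gen_vcf


class TestVariantKey:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chromosome="chr1", position=0, ref="A", alt="C"),
            dict(chromosome="chr1", position=5, ref="A", alt="A"),
            dict(chromosome="chr1", position=5, ref="", alt="C"),
            dict(chromosome="chr1", position=5, ref="N", alt="C"),
        ],
    )
    def test_invalid_keys_rejected(self, kwargs):
        with pytest.raises(ValueError):
            VariantKey(**kwargs)


class TestFilterToPanel:
    def test_matches_brute_force_interval_scan(self, rng):
        """Panel filtering is equivalent to scanning every gene per variant."""
        registry = gen_registry((2, 3, 4), seed=5)
        keys = []
        for _ in range(100):
            gene = registry.records[rng.integers(0, len(registry))]
            offset = int(rng.integers(-2000, 2000))
            pos = max(1, gene.start + offset)
            keys.append(VariantKey(gene.chromosome, pos, "A", "C"))
        got = list(filter_to_panel(keys, registry))
        # oracle: per-variant scan over every gene, symbol order within a variant
        expected = [
            (k, g.symbol)
            for k in keys
            for g in sorted(registry.records, key=lambda r: r.symbol)
            if g.contains(k.chromosome, k.position)
        ]
        assert got == expected

    def test_boundary_position_retained(self, three_gene_registry):
        key = VariantKey("chr1", 9000, "A", "G")  # NUC1 interval end
        assert list(filter_to_panel([key], three_gene_registry)) == [(key, "NUC1")]

    def test_no_overlap_gives_empty_stream(self, three_gene_registry):
        keys = [VariantKey("chr1", 4999, "A", "G"), VariantKey("chr9", 10, "T", "C")]
        assert list(filter_to_panel(keys, three_gene_registry)) == []

    def test_missense_only_filters_on_consequence(self, three_gene_registry):
        inside = VariantKey("chr1", 6000, "A", "G")
        stream = [(inside, "missense_variant"), (inside, "synonymous_variant"),
                  (inside, None)]
        got = list(filter_to_panel(stream, three_gene_registry, missense_only=True))
        assert got == [(inside, "NUC1")]

    def test_vcf_fraction_in_panel(self, tmp_path):
        registry = gen_registry((1, 2, 2), seed=3)
        path = gen_vcf(10, registry, 0.4, seed=4, path=tmp_path / "t.vcf")
        keys = [k for k, _ in read_vcf(path, consequence_key="CSQ")]
        kept = list(filter_to_panel(keys, registry))
        assert len(kept) == 4
        # input order preserved
        kept_keys = [k for k, _ in kept]
        assert kept_keys == [k for k in keys if k in kept_keys]


class TestReadVcf:
    def test_multiallelic_records_decompose_per_alt(self, tmp_path):
        path = tmp_path / "ma.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=CSQ,Number=1,Type=String,Description="c">\n'
            "##contig=<ID=chr1,length=1000000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\t.\tA\tC,T\t.\tPASS\tCSQ=missense_variant\n"
        )
        keys = [k for k, _ in read_vcf(path)]
        assert keys == [
            VariantKey("chr1", 100, "A", "C"),
            VariantKey("chr1", 100, "A", "T"),
        ]


class TestManeSelection:
    def test_mane_present_is_chosen(self, three_gene_registry):
        gene = three_gene_registry["NUC1"]
        assert select_mane_transcript(gene, ["NUC1.t2", "NUC1.t1"]) == "NUC1.t2"

    def test_empty_observed_defaults_to_mane(self, three_gene_registry):
        gene = three_gene_registry["NUC1"]
        assert select_mane_transcript(gene, []) == "NUC1.t2"

    @pytest.mark.parametrize(
        "observed,expected",
        [
            (["t9", "t3"], "t3"),
            (["zz", "aa", "mm"], "aa"),
            (["only"], "only"),
        ],
    )
    def test_fallback_is_lexicographic_minimum(
        self, three_gene_registry, observed, expected
    ):
        gene = three_gene_registry["MTG1"]  # MANE is MTG1.t1, absent below
        assert select_mane_transcript(gene, observed) == expected


class TestCoercion:
    @pytest.mark.parametrize(
        "raw,dtype,expected",
        [
            ("1", "boolean", True),
            ("0", "boolean", False),
            ("true", "boolean", True),
            ("FALSE", "boolean", False),
            ("NA", "boolean", None),
            (".", "continuous", None),
            ("3", "integer", 3),
            ("3.0", "integer", 3),
            ("-2.5", "continuous", -2.5),
            (None, "integer", None),
            (float("nan"), "continuous", None),
        ],
    )
    def test_coercion_table(self, raw, dtype, expected):
        assert coerce_value(raw, dtype) == expected

    @pytest.mark.parametrize(
        "raw,dtype",
        [("3.5", "integer"), ("maybe", "boolean"), ("abc", "continuous"), ("2", "boolean")],
    )
    def test_unparseable_values_raise_coercion_failure(self, raw, dtype):
        with pytest.raises(CoercionFailure):
            coerce_value(raw, dtype)


class TestAnnotate:
    def test_all_three_levels_joined(
        self, three_gene_registry, tiny_schema, tiny_sources
    ):
        key = VariantKey("chrM", 150, "A", "G")
        [av] = annotate(
            [(key, "MTG1")], tiny_schema, tiny_sources, three_gene_registry
        )
        assert av.values == {"sift_like": 0.93, "expressed": True, "exon_count": 4}
        assert av.transcript == "MTG1.t1"
        assert av.consequence == "missense_variant"

    def test_unmatched_variant_gets_all_missing_from_that_source(
        self, three_gene_registry, tiny_schema, tiny_sources
    ):
        key = VariantKey("chrM", 999, "C", "T")  # not in variant source
        report = AnnotationReport()
        [av] = annotate(
            [(key, "MTG1")], tiny_schema, tiny_sources, three_gene_registry,
            report=report,
        )
        assert av.values["sift_like"] is None
        assert av.values["expressed"] is True  # gene-level still joins
        assert report.missing_counts["sift_like"] == 1

    def test_coercion_failure_is_missing_not_fatal(
        self, three_gene_registry, tiny_schema, tiny_sources
    ):
        tiny_sources.variant.loc[0, "sift_like"] = "broken"
        sources = type(tiny_sources)(
            variant=tiny_sources.variant,
            gene=tiny_sources.gene,
            transcript=tiny_sources.transcript,
        )
        report = AnnotationReport()
        key = VariantKey("chrM", 150, "A", "G")
        [av] = annotate(
            [(key, "MTG1")], tiny_schema, sources, three_gene_registry, report=report
        )
        assert av.values["sift_like"] is None
        assert report.coercion_failures["sift_like"] == 1

    def test_unknown_gene_rejected(self, three_gene_registry, tiny_schema, tiny_sources):
        key = VariantKey("chr5", 1, "A", "G")
        with pytest.raises(SchemaError, match="not in registry"):
            list(annotate([(key, "NOPE")], tiny_schema, tiny_sources,
                          three_gene_registry))


class TestAnnotatedTable:
    def _annotated(self, registry, schema, n=4, seed=11):
        vcf_keys = []
        rngkeys = []
        import numpy as np

        rng = np.random.default_rng(seed)
        for _ in range(n):
            gene = registry.records[rng.integers(0, len(registry))]
            pos = int(rng.integers(gene.start, gene.end + 1))
            vcf_keys.append((VariantKey(gene.chromosome, pos, "A", "G"), gene.symbol))
        sources = gen_sources(
            registry, schema, [k for k, _ in vcf_keys], seed=seed, missing_rate=0.3
        )
        return list(annotate(vcf_keys, schema, sources, registry)), sources

    def test_empty_stream_writes_header_only(self, tmp_path, tiny_schema):
        path = tmp_path / "ann.tsv"
        assert write_annotated_table([], tiny_schema, path) == 0
        assert path.read_text().count("\n") == 1

    def test_column_count_is_seven_plus_schema(self, tmp_path):
        registry = gen_registry((1, 1, 1), seed=2)
        schema = gen_schema(seed=2)
        annotated, _ = self._annotated(registry, schema)
        path = tmp_path / "ann.tsv"
        assert write_annotated_table(annotated, schema, path) == 4
        lines = path.read_text().splitlines()
        assert all(len(l.split("\t")) == 7 + len(schema) for l in lines)

    def test_round_trip_is_value_identical_and_byte_stable(self, tmp_path):
        registry = gen_registry((1, 2, 1), seed=9)
        schema = gen_schema(seed=9)
        annotated, _ = self._annotated(registry, schema, n=6)
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_annotated_table(annotated, schema, p1)
        back = read_annotated_table(p1, schema)
        assert [(a.key, a.gene, a.transcript, a.values) for a in annotated] == [
            (b.key, b.gene, b.transcript, b.values) for b in back
        ]
        write_annotated_table(back, schema, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_annotation_is_idempotent(self, tmp_path):
        """Re-annotating annotated output with the same sources changes nothing."""
        registry = gen_registry((1, 2, 1), seed=13)
        schema = gen_schema(seed=13)
        annotated, sources = self._annotated(registry, schema, n=5, seed=13)
        again = list(
            annotate(
                [(a.key, a.gene, a.consequence) for a in annotated],
                schema,
                sources,
                registry,
            )
        )
        assert [(a.key, a.values) for a in annotated] == [
            (a.key, a.values) for a in again
        ]
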