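"""Parsing, classification, and serialization of annotation dialects."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitodraw import annotation_io as aio
from mitodraw.errors import (
    EmptyAnnotation,
    FeatureOutOfBounds,
    MalformedRecord,
    UnrecognizedFormat,
)
from mitodraw.model import Feature, FeatureClass, GenomeAnnotation, Strand, Topology

MINIMAL_GENBANK = """\
LOCUS       chrM                    1000 bp    DNA     circular UNK 01-JAN-1980
FEATURES             Location/Qualifiers
     tRNA            10..75
                     /product="tRNA-Phe"
ORIGIN
//
"""

GFF3_TEXT = (
    "##gff-version 3\n"
    "##sequence-region chrM 1 16500\n"
    "chrM\ttest\ttRNA\t1\t68\t.\t+\t.\tName=trnF\n"
)

GTF_TEXT = '#length=16500\nchrM\ttest\ttRNA\t1\t68\t.\t+\t.\tgene_id "trnF"; gene_name "trnF";\n'

BED_TEXT = "chrM\t0\t68\ttrnF\t0\t+\n"

TSV_TEXT = "#length=16500\nname\ttype\tstart\tend\tstrand\ntrnM\ttRNA\t1\t68\t+\n"


class TestDetectFormat:
    @pytest.mark.parametrize(
        "text,expected",
        [
            (MINIMAL_GENBANK, aio.Format.genbank),
            (GFF3_TEXT, aio.Format.gff3),
            ("chrM\tx\ttRNA\t1\t68\t.\t+\t.\tName=trnF\n", aio.Format.gff3),
            (GTF_TEXT, aio.Format.gtf),
            (BED_TEXT, aio.Format.bed),
            (TSV_TEXT, aio.Format.tsv),
        ],
    )
    def test_structural_markers(self, text, expected):
        assert aio.detect_format(text) is expected

    def test_each_dialect_detector_fires_uniquely(self, canonical):
        writers = {
            aio.Format.genbank: aio.write_genbank,
            aio.Format.gff3: aio.write_gff3,
            aio.Format.gtf: aio.write_gtf,
            aio.Format.bed: aio.write_bed,
            aio.Format.tsv: aio.write_tsv,
        }
        for fmt, writer in writers.items():
            assert aio.detect_format(writer(canonical)) is fmt

    @pytest.mark.parametrize("text", ["", "   \n", "not an annotation\n", "a\tb\tc\n"])
    def test_unrecognized(self, text):
        with pytest.raises(UnrecognizedFormat):
            aio.detect_format(text)


class TestParseGenbank:
    def test_minimal_record(self):
        ann = aio.parse_genbank(MINIMAL_GENBANK)
        assert ann.genome_length == 1000
        assert ann.topology is Topology.circular
        (f,) = ann.features
        # 1-based inclusive 10..75 -> 0-based start 9, length 66
        assert (f.name, f.feature_class, f.start, f.length, f.strand) == (
            "tRNA-Phe", FeatureClass.tRNA, 9, 66, Strand.forward,
        )

    def test_complement_is_reverse_strand(self):
        text = MINIMAL_GENBANK.replace(
            '     tRNA            10..75\n                     /product="tRNA-Phe"',
            '     CDS             complement(100..200)\n                     /gene="nad1"',
        )
        (f,) = aio.parse_genbank(text).features
        # 1-based inclusive 100..200 covers 101 bases
        assert (f.start, f.length, f.strand) == (99, 101, Strand.reverse)
        assert f.feature_class is FeatureClass.PCG

    def test_empty_feature_table(self):
        text = (
            "LOCUS       chrM                    1000 bp    DNA     circular UNK 01-JAN-1980\n"
            "FEATURES             Location/Qualifiers\nORIGIN\n//\n"
        )
        ann = aio.parse_genbank(text)
        assert ann.genome_length == 1000 and len(ann) == 0

    def test_linear_locus_line(self):
        text = MINIMAL_GENBANK.replace("circular", "linear  ")
        assert aio.parse_genbank(text).topology is Topology.linear

    def test_origin_spanning_join_collapses_to_one_wrapping_feature(self):
        text = MINIMAL_GENBANK.replace(
            '     tRNA            10..75\n                     /product="tRNA-Phe"',
            '     misc_feature    join(950..1000,1..50)\n                     /note="D-loop"',
        )
        (f,) = aio.parse_genbank(text).features
        assert (f.start, f.length) == (949, 101)
        assert f.end > 1000  # stored as a single wrapping record

    def test_gene_cds_pair_collapses_with_gene_name(self):
        text = MINIMAL_GENBANK.replace(
            '     tRNA            10..75\n                     /product="tRNA-Phe"',
            '     gene            100..400\n'
            '                     /gene="nad9"\n'
            '     CDS             100..400\n'
            '                     /product="NADH dehydrogenase"',
        )
        (f,) = aio.parse_genbank(text).features
        assert f.name == "nad9"
        assert f.feature_class is FeatureClass.PCG  # CDS key wins for the class

    def test_unnamed_feature_gets_fallback_name(self):
        text = MINIMAL_GENBANK.replace(
            '     tRNA            10..75\n                     /product="tRNA-Phe"',
            "     misc_feature    10..75",
        )
        (f,) = aio.parse_genbank(text).features
        assert f.name == "feature_1"

    def test_out_of_bounds_raises(self):
        text = MINIMAL_GENBANK.replace("10..75", "10..2000")
        with pytest.raises(FeatureOutOfBounds):
            aio.parse_genbank(text)

    def test_no_locus_length_raises(self):
        with pytest.raises(MalformedRecord):
            aio.parse_genbank("FEATURES             Location/Qualifiers\n//\n")


class TestParseTabular:
    @pytest.mark.parametrize(
        "text,fmt",
        [
            (BED_TEXT, aio.Format.bed),
            (GFF3_TEXT, aio.Format.gff3),
            (GTF_TEXT, aio.Format.gtf),
        ],
    )
    def test_coordinate_conventions_converge(self, text, fmt):
        # BED 0-based half-open [0,68) and GFF/GTF 1-based inclusive 1..68
        # describe the same 68 bp span starting at offset 0
        (f,) = aio.parse_tabular(text, fmt).features
        assert (f.start, f.length, f.strand) == (0, 68, Strand.forward)

    def test_tsv_dialect(self):
        ann = aio.parse_tabular(TSV_TEXT, "tsv")
        assert ann.genome_length == 16500
        (f,) = ann.features
        assert (f.name, f.feature_class, f.start, f.length) == (
            "trnM", FeatureClass.tRNA, 0, 68,
        )

    def test_genome_length_defaults_to_max_end(self):
        text = "chrM\t10\t900\tnad1\t0\t+\nchrM\t0\t68\ttrnF\t0\t+\n"
        ann = aio.parse_tabular(text, "bed")
        assert ann.genome_length == 900
        assert ann.topology is Topology.circular

    def test_wrapping_feature_via_declared_length(self):
        text = "#length=1000\nchrM\t950\t1050\tctrl\t0\t+\n"
        (f,) = aio.parse_tabular(text, "bed").features
        assert (f.start, f.length) == (950, 100)

    def test_wrong_column_count_raises(self):
        with pytest.raises(MalformedRecord):
            aio.parse_tabular("chrM\t0\t68\ttrnF\n", "bed")
        with pytest.raises(MalformedRecord):
            aio.parse_tabular("##gff-version 3\nchrM\tx\ttRNA\t1\t68\t.\t+\n", "gff3")

    def test_empty_annotation_raises(self):
        with pytest.raises(EmptyAnnotation):
            aio.parse_tabular("##gff-version 3\n", "gff3")

    def test_out_of_bounds_raises_never_truncates(self):
        with pytest.raises(FeatureOutOfBounds):
            aio.parse_tabular("#length=100\nchrM\t150\t160\tx\t0\t+\n", "bed")


class TestClassifyFeature:
    @pytest.mark.parametrize(
        "name,source_key,expected",
        [
            ("trnM", None, FeatureClass.tRNA),
            ("tRNA-Phe", None, FeatureClass.tRNA),
            ("rrnS", None, FeatureClass.rRNA),
            ("12S ribosomal RNA", None, FeatureClass.rRNA),
            ("s-rRNA", None, FeatureClass.rRNA),
            ("nad4l", None, FeatureClass.PCG),
            ("ND4L", None, FeatureClass.PCG),
            ("COX1", None, FeatureClass.PCG),
            ("COIII", None, FeatureClass.PCG),
            ("CYTB", None, FeatureClass.PCG),
            ("MT-ATP6", None, FeatureClass.PCG),
            ("D-loop", "D-loop", FeatureClass.other),
            ("mystery", None, FeatureClass.other),
            ("anything", "tRNA", FeatureClass.tRNA),
            ("anything", "rRNA", FeatureClass.rRNA),
            ("anything", "CDS", FeatureClass.PCG),
            ("nad1", "other", FeatureClass.other),  # explicit key beats name rules
        ],
    )
    def test_cascade(self, name, source_key, expected):
        assert aio.classify_feature(name, source_key) is expected


class TestWriteTsv:
    def test_single_feature_row(self):
        ann = GenomeAnnotation(
            genome_length=16500,
            features=(
                Feature("trnF", FeatureClass.tRNA, 0, 68, Strand.forward),
            ),
        )
        lines = aio.write_tsv(ann).splitlines()
        assert lines[1] == aio.TSV_HEADER
        assert lines[2] == "trnF\ttRNA\t1\t68\t+"

    def test_empty_annotation_is_header_only(self):
        ann = GenomeAnnotation(genome_length=100)
        lines = aio.write_tsv(ann).splitlines()
        assert lines == ["#length=100", aio.TSV_HEADER]

    def test_canonical_has_38_rows(self, canonical):
        # 37 transcribed features plus the control region
        lines = aio.write_tsv(canonical).splitlines()
        data_rows = lines[lines.index(aio.TSV_HEADER) + 1 :]
        assert len(data_rows) == 38


# --- round trips and cross-format equivalence ------------------------------

_names = st.text(
    alphabet=st.characters(whitelist_categories=("Lu", "Ll", "Nd"), whitelist_characters="-_"),
    min_size=1,
    max_size=12,
)


@st.composite
def annotations(draw):
    L = draw(st.integers(min_value=100, max_value=5000))
    n = draw(st.integers(min_value=0, max_value=12))
    features = []
    seen = set()
    for _ in range(n):
        name = draw(_names.filter(lambda s: s not in seen))
        seen.add(name)
        start = draw(st.integers(min_value=0, max_value=L - 1))
        length = draw(st.integers(min_value=1, max_value=L))
        features.append(
            Feature(
                name=name,
                feature_class=draw(st.sampled_from(list(FeatureClass))),
                start=start,
                length=length,
                strand=draw(st.sampled_from([Strand.forward, Strand.reverse])),
            )
        )
    topo = draw(st.sampled_from([Topology.circular, Topology.linear]))
    return GenomeAnnotation(genome_length=L, topology=topo, features=tuple(features))


@given(annotations())
@settings(max_examples=60, derandomize=True)
def test_tsv_round_trip_preserves_all_semantic_fields(ann):
    back = aio.parse_tabular(aio.write_tsv(ann), "tsv")
    assert back.semantic_key() == ann.semantic_key()


def test_cross_format_equivalence_on_canonical_fixture(canonical):
    texts = {
        "genbank": aio.write_genbank(canonical),
        "gff3": aio.write_gff3(canonical),
        "gtf": aio.write_gtf(canonical),
        "bed": aio.write_bed(canonical),
        "tsv": aio.write_tsv(canonical),
    }
    keys = {fmt: aio.parse_text(text).semantic_key() for fmt, text in texts.items()}
    reference = canonical.semantic_key()
    assert all(key == reference for key in keys.values())


@given(annotations())
@settings(max_examples=30, derandomize=True)
def test_parsers_never_emit_invariant_violating_features(ann):
    for fmt, writer in [("bed", aio.write_bed), ("gff3", aio.write_gff3)]:
        if not ann.features:
            continue
        parsed = aio.parse_tabular(writer(ann), fmt)
        for f in parsed.features:
            f.validate(parsed.genome_length)  # raises on violation
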