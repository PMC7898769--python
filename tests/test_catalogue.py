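"""Annotation parsing, structure classification, patching and mending."""

import io

import numpy as np
import pytest

from vmscreen.catalogue import (
    MendParams,
    StructureClass,
    classify_structure,
    cpg_density,
    extract_ltr_sequence,
    group_into_elements,
    mend_fragmented,
    parse_rm_annotation,
    patch_500kb_splits,
    summarize_catalogue,
)

from conftest import CF, INT, LTR, make_features, random_catalogue
from oracles import oracle_mend


class TestParse:
    def test_field_mapping(self, registry):
        feats = parse_rm_annotation(
            io.StringIO("chr1\t1000\t1337\t+\tIAPLTR2_Mm\tLTR/ERVK\t7\n"), registry
        )
        assert len(feats) == 1
        f = feats[0]
        assert (f.chrom, f.start, f.end, f.strand) == ("chr1", 1000, 1337, "+")
        assert f.rep_name == "IAPLTR2_Mm" and f.element_id == 7

    def test_iap_only_filter_excludes_line(self, registry):
        stream = io.StringIO(
            "chr1 1000 1337 + IAPLTR2_Mm LTR/ERVK 7\n"
            "chr1 5000 6000 + L1Md_A LINE/L1 8\n"
        )
        feats = parse_rm_annotation(stream, registry, iap_only=True)
        assert [f.rep_name for f in feats] == ["IAPLTR2_Mm"]

    def test_empty_stream(self, registry):
        assert parse_rm_annotation(io.StringIO(""), registry) == []

    def test_ucsc_header_dialect(self, registry):
        stream = io.StringIO(
            "#genoName genoStart genoEnd strand repName repClass repFamily id\n"
            "chr1 100 400 - IAPEz-int LTR ERVK 3\n"
        )
        feats = parse_rm_annotation(stream, registry)
        assert feats[0].rep_class_family == "LTR/ERVK"
        assert feats[0].element_id == 3

    @pytest.mark.parametrize("row", [
        "chr1 1000 1337 * IAPLTR2_Mm LTR/ERVK 7",  # bad strand
        "chr1 xxx 1337 + IAPLTR2_Mm LTR/ERVK 7",  # bad coordinate
        "chr1 1000 1337 +",  # too few columns
    ])
    def test_malformed_row_names_line(self, row, registry):
        with pytest.raises(ValueError, match="line 1"):
            parse_rm_annotation(io.StringIO(row + "\n"), registry)

    def test_output_sorted_by_position(self, registry):
        stream = io.StringIO(
            "chr2 50 100 + IAPLTR2_Mm LTR/ERVK 1\n"
            "chr1 500 900 + IAPLTR2_Mm LTR/ERVK 2\n"
            "chr1 10 40 + IAPLTR2_Mm LTR/ERVK 3\n"
        )
        feats = parse_rm_annotation(stream, registry)
        assert [(f.chrom, f.start) for f in feats] == [
            ("chr1", 10), ("chr1", 500), ("chr2", 50)]


class TestGrouping:
    def test_shared_id_one_element(self, registry):
        feats = make_features([(0, 300, "+", LTR, 7), (300, 1500, "+", INT, 7),
                               (1500, 1800, "+", LTR, 7)])
        els = group_into_elements(feats, registry)
        assert len(els) == 1 and len(els[0].features) == 3

    def test_distinct_ids_two_elements(self, registry):
        feats = make_features([(0, 300, "+", LTR, 7), (5000, 5300, "+", LTR, 8)])
        assert len(group_into_elements(feats, registry)) == 2

    def test_id_reuse_across_chroms_splits_with_warning(self, registry, caplog):
        feats = (make_features([(0, 300, "+", LTR, 7)], chrom="chr1")
                 + make_features([(0, 300, "+", LTR, 7)], chrom="chr2"))
        with caplog.at_level("WARNING"):
            els = group_into_elements(feats, registry)
        assert len(els) == 2
        assert any("element ID 7" in r.message for r in caplog.records)

    def test_huge_intra_id_gap_splits(self, registry):
        feats = make_features([(0, 300, "+", LTR, 7), (200_000, 200_300, "+", LTR, 7)])
        assert len(group_into_elements(feats, registry)) == 2


class TestClassify:
    @pytest.mark.parametrize("pattern,strand,expected", [
        ([LTR, INT, LTR], "+", StructureClass.FULL),
        ([LTR, INT, LTR], "-", StructureClass.FULL),
        ([LTR], "+", StructureClass.SOLO_LTR),
        ([INT], "+", StructureClass.FRAG_INTERNAL_ONLY),
        ([LTR, INT], "+", StructureClass.FRAG_NO3),
        ([INT, LTR], "+", StructureClass.FRAG_NO5),
        ([INT, LTR, INT], "+", StructureClass.FRAG_OTHER),
        ([LTR, LTR], "+", StructureClass.SOLO_LTR),
    ])
    def test_patterns(self, pattern, strand, expected, registry):
        genomic = pattern if strand == "+" else pattern[::-1]
        rows = [(i * 1000, i * 1000 + 500, strand, name, 1)
                for i, name in enumerate(genomic)]
        els = group_into_elements(make_features(rows), registry)
        assert len(els) == 1
        assert els[0].structure is expected

    def test_strand_awareness(self, registry):
        # genomic order [LTR, INT] on minus strand = element order [INT, LTR]
        rows = [(0, 500, "-", LTR, 1), (1000, 1500, "-", INT, 1)]
        els = group_into_elements(make_features(rows), registry)
        assert els[0].structure is StructureClass.FRAG_NO5

    def test_zero_features_is_error(self, registry):
        with pytest.raises(ValueError):
            classify_structure([], registry)


class TestPatch500kb:
    def test_boundary_pair_unified(self, registry):
        feats = make_features([(499_000, 500_000, "+", LTR, 1),
                               (500_000, 500_800, "+", INT, 2),
                               (500_800, 501_200, "+", LTR, 2)])
        els = patch_500kb_splits(group_into_elements(feats, registry),
                                 registry=registry)
        assert len(els) == 1
        assert els[0].structure is StructureClass.FULL
        assert els[0].element_id == 1

    def test_non_boundary_meeting_point_unchanged(self, registry):
        feats = make_features([(498_000, 499_123, "+", LTR, 1),
                               (499_123, 499_800, "+", INT, 2)])
        els = patch_500kb_splits(group_into_elements(feats, registry),
                                 registry=registry)
        assert len(els) == 2

    def test_empty_input(self):
        assert patch_500kb_splits([]) == []


class TestMend:
    def test_step1_no3_plus_no5(self, registry):
        # FRAG_NO3 [LTR,INT] then FRAG_NO5 [INT,LTR] with a 500 bp gap
        feats = make_features([
            (1000, 1300, "+", LTR, 1), (1300, 3000, "+", INT, 1),
            (3500, 5700, "+", INT, 2), (5700, 6000, "+", LTR, 2),
        ])
        els = mend_fragmented(group_into_elements(feats, registry),
                              MendParams(), registry)
        assert len(els) == 1
        assert els[0].structure is StructureClass.FULL
        assert (els[0].span_start, els[0].span_end) == (1000, 6000)

    def test_gap_beyond_2000_not_merged(self, registry):
        feats = make_features([
            (1000, 1300, "+", LTR, 1), (1300, 3000, "+", INT, 1),
            (5100, 5700, "+", INT, 2), (5700, 6000, "+", LTR, 2),
        ])
        els = mend_fragmented(group_into_elements(feats, registry),
                              MendParams(), registry)
        assert len(els) == 2

    def test_step2_solo_ltr_completes_no5(self, registry):
        # solo LTR ending 100 bp upstream of a FRAG_NO5 5' edge
        feats = make_features([
            (500, 900, "+", LTR, 1),
            (1000, 2700, "+", INT, 2), (2700, 3000, "+", LTR, 2),
        ])
        els = mend_fragmented(group_into_elements(feats, registry),
                              MendParams(), registry)
        assert len(els) == 1 and els[0].structure is StructureClass.FULL

    def test_step3_forms_higher_order_element(self, registry):
        # FRAG_NO5 adjacent to a FULL element with no better partner
        feats = make_features([
            (0, 300, "+", LTR, 1), (300, 1500, "+", INT, 1), (1500, 1800, "+", LTR, 1),
            (2000, 3000, "+", INT, 2), (3000, 3300, "+", LTR, 2),
        ])
        els = mend_fragmented(group_into_elements(feats, registry),
                              MendParams(), registry)
        assert len(els) == 1
        # double element: LTR INT LTR INT LTR -> flanked at both ends
        assert els[0].structure is StructureClass.FULL
        assert len(els[0].features) == 5

    def test_internal_only_mended_on_both_edges(self, registry):
        feats = make_features([
            (0, 300, "+", LTR, 1),
            (500, 2000, "+", INT, 2),
            (2200, 2500, "+", LTR, 3),
        ])
        els = mend_fragmented(group_into_elements(feats, registry),
                              MendParams(), registry)
        assert len(els) == 1 and els[0].structure is StructureClass.FULL

    def test_never_crosses_strand(self, registry):
        feats = make_features([
            (1000, 1300, "+", LTR, 1), (1300, 3000, "+", INT, 1),
            (3500, 5700, "-", LTR, 2), (5700, 6000, "-", INT, 2),
        ])
        els = mend_fragmented(group_into_elements(feats, registry),
                              MendParams(), registry)
        assert len(els) == 2


class TestMendProperties:
    """Idempotence, conservation, monotonicity, and oracle equivalence
    over randomised catalogues."""

    @staticmethod
    def _key(elements):
        return sorted(
            (e.chrom, e.span_start, e.span_end, e.strand, e.structure.value,
             tuple(f.identity for f in e.features))
            for e in elements
        )

    @pytest.mark.parametrize("seed", range(60))
    def test_idempotence_conservation_monotonicity(self, seed, registry):
        cat = random_catalogue(np.random.default_rng(seed), registry)
        mended = mend_fragmented(cat, MendParams(), registry)
        again = mend_fragmented(mended, MendParams(), registry)
        assert self._key(mended) == self._key(again)
        assert sorted(f.identity for e in cat for f in e.features) == \
            sorted(f.identity for e in mended for f in e.features)
        before, after = summarize_catalogue(cat), summarize_catalogue(mended)
        assert after.n_elements <= before.n_elements
        # a partial mend (e.g. internal-only + solo LTR) keeps the fragment
        # count flat while shrinking the total, so the monotone quantity is
        # the fragment count, not the fraction
        assert after.n_fragmented <= before.n_fragmented

    @pytest.mark.parametrize("seed", range(60))
    def test_oracle_equivalence(self, seed, registry):
        cat = random_catalogue(np.random.default_rng(1000 + seed), registry,
                               n_max=10, n_chroms=2)
        assert self._key(mend_fragmented(cat, MendParams(), registry)) == \
            self._key(oracle_mend(cat, 2000, registry))

    def test_locality_no_merge_spans_beyond_max_gap(self, registry):
        for seed in range(20):
            cat = random_catalogue(np.random.default_rng(2000 + seed), registry)
            mended = mend_fragmented(cat, MendParams(), registry)
            for e in mended:
                # reconstruct constituent envelopes; facing gaps <= max_gap
                members = []
                for orig in cat:
                    ids = {f.identity for f in orig.features}
                    if ids <= {f.identity for f in e.features}:
                        members.append(orig)
                members.sort(key=lambda m: m.span_start)
                for a, b in zip(members, members[1:]):
                    assert b.span_start - a.span_end <= 2000


class TestSummary:
    def test_counts_and_fraction(self, registry):
        feats = make_features([
            (0, 300, "+", LTR, 1), (300, 1500, "+", INT, 1), (1500, 1800, "+", LTR, 1),
            (5000, 5300, "+", LTR, 2),
            (9000, 9500, "+", INT, 3),
        ])
        s = summarize_catalogue(group_into_elements(feats, registry))
        assert (s.n_elements, s.n_full, s.n_solo_ltr, s.n_fragmented) == (3, 1, 1, 1)
        assert s.fragmented_fraction == pytest.approx(1 / 3)

    def test_empty(self):
        s = summarize_catalogue([])
        assert s.n_elements == 0 and s.fragmented_fraction == 0.0


class TestCpGDensity:
    @pytest.mark.parametrize("seq,expected", [
        ("CGCGCG", 0.5),
        ("AAAA", 0.0),
        ("ACGT", 0.25),
        ("acgt", 0.25),
    ])
    def test_closed_form(self, seq, expected):
        assert cpg_density(seq) == pytest.approx(expected)

    def test_empty_sequence_is_error(self):
        with pytest.raises(ValueError):
            cpg_density("")


class TestExtractLtr:
    GENOME = {"chr1": "A" * 100 + "ACGTACGTAC" + "T" * 100}

    def _element(self, strand, registry):
        pattern = [LTR, INT, LTR] if strand == "+" else [LTR, INT, LTR][::-1]
        rows = [(100, 110, strand, pattern[0], 1),
                (110, 180, strand, pattern[1], 1),
                (180, 200, strand, pattern[2], 1)]
        return group_into_elements(make_features(rows), registry)[0]

    def test_plus_strand_verbatim(self, registry):
        el = self._element("+", registry)
        assert extract_ltr_sequence(el, "5p", self.GENOME, registry) == "ACGTACGTAC"

    def test_minus_strand_reverse_complement(self, registry):
        el = self._element("-", registry)
        # on minus strand the 5' LTR is the genomic-right feature
        seq = extract_ltr_sequence(el, "5p", self.GENOME, registry)
        assert seq == "A" * 20  # revcomp of TTTT... is AAAA...
        seq3 = extract_ltr_sequence(el, "3p", self.GENOME, registry)
        assert seq3 == "GTACGTACGT"

    def test_missing_ltr_is_error(self, registry):
        els = group_into_elements(
            make_features([(100, 200, "+", INT, 1)]), registry)
        with pytest.raises(ValueError):
            extract_ltr_sequence(els[0], "5p", self.GENOME, registry)

    def test_missing_chromosome_is_error(self, registry):
        el = self._element("+", registry)
        with pytest.raises(KeyError):
            extract_ltr_sequence(el, "5p", {"chr9": "ACGT"}, registry)
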