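"""Fragment and alignment IO: coordinate conventions, filters, round-trips."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cffrag.core_io import (
    FormatError,
    Fragment,
    FragmentTableError,
    read_fragment_tsv,
    read_fragments_from_alignment,
    read_long_read_fragments,
    read_sample_sheet,
    write_fragment_tsv,
    write_sample_sheet,
)
from cffrag.synthetic_cohort import (
    CANINE_HEALTHY,
    CANINE_TUMOR,
    SubjectTruth,
    fragments_to_bam,
    sample_fragments,
)

fragments_strategy = st.lists(
    st.tuples(
        st.sampled_from(["chr1", "chr2"]),
        st.integers(min_value=0, max_value=10_000),
        st.integers(min_value=1, max_value=5_000),
    ).map(lambda t: Fragment(t[0], t[1], t[1] + t[2])),
    min_size=0,
    max_size=50,
)


class TestFragment:
    def test_length_is_end_minus_start(self):
        assert Fragment("chr1", 100, 280).length == 180

    @pytest.mark.parametrize("start,end", [(200, 100), (5, 5), (-1, 10)])
    def test_invalid_intervals_rejected(self, start, end):
        with pytest.raises(FragmentTableError):
            Fragment("chr1", start, end).validate()


class TestFragmentTsv:
    @settings(derandomize=True, max_examples=25)
    @given(fragments_strategy)
    def test_write_read_identity(self, tmp_path_factory, frags):
        path = tmp_path_factory.mktemp("tsv") / "f.tsv"
        write_fragment_tsv(frags, path)
        assert list(read_fragment_tsv(path)) == frags

    def test_basic_row_parses(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("chr1\t0\t150\n")
        (frag,) = read_fragment_tsv(p)
        assert frag == Fragment("chr1", 0, 150) and frag.length == 150

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "f.tsv"
        p.write_text("chr1\t0\t150\nchr1\t200\t100\n")
        with pytest.raises(FragmentTableError, match="line 2"):
            list(read_fragment_tsv(p))


def _write_sam(path, records, contigs=(("chr1", 100_000),)):
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": n, "LN": ln} for n, ln in contigs],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            out.write(rec)


def _pair(header, name, start, tlen, mapq=60, duplicate=False, proper=True,
          read_len=50):
    """A coordinate-consistent read pair spanning [start, start + tlen)."""
    reads = []
    for first in (True, False):
        a = pysam.AlignedSegment(header=header)
        a.query_name = name
        a.reference_id = 0
        a.mapping_quality = mapq
        a.is_paired = True
        a.is_proper_pair = proper
        a.is_duplicate = duplicate
        a.set_tag("MQ", mapq)
        a.query_sequence = "A" * read_len
        a.cigarstring = f"{read_len}M"
        a.next_reference_id = 0
        if first:
            a.reference_start = start
            a.next_reference_start = start + tlen - read_len
            a.template_length = tlen
            a.is_read1 = True
        else:
            a.reference_start = start + tlen - read_len
            a.next_reference_start = start
            a.template_length = -tlen
            a.is_read2 = True
            a.is_reverse = True
        reads.append(a)
    return reads


class TestAlignmentReader:
    @pytest.fixture()
    def header(self):
        return pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6", "SO": "coordinate"},
             "SQ": [{"SN": "chr1", "LN": 100_000}]}
        )

    def test_pair_becomes_template_span_fragment(self, tmp_path, header):
        sam = tmp_path / "a.sam"
        _write_sam(sam, _pair(header, "p1", 100, 180))
        assert list(read_fragments_from_alignment(sam)) == [Fragment("chr1", 100, 280)]

    def test_each_pair_emitted_exactly_once(self, tmp_path, header):
        recs = _pair(header, "p1", 100, 180) + _pair(header, "p2", 300, 150)
        recs.sort(key=lambda r: r.reference_start)
        sam = tmp_path / "a.sam"
        _write_sam(sam, recs)
        assert len(list(read_fragments_from_alignment(sam))) == 2

    def test_duplicate_filter(self, tmp_path, header):
        sam = tmp_path / "a.sam"
        _write_sam(sam, _pair(header, "d1", 100, 180, duplicate=True))
        with pytest.warns(UserWarning, match="no read pairs"):
            assert list(read_fragments_from_alignment(sam)) == []
        assert len(list(read_fragments_from_alignment(sam, keep_duplicates=True))) == 1

    def test_mapq_filter_is_monotone(self, tmp_path, header):
        recs = []
        for i, mq in enumerate([10, 20, 40, 60]):
            recs += _pair(header, f"p{i}", 100 + 500 * i, 180, mapq=mq)
        recs.sort(key=lambda r: r.reference_start)
        sam = tmp_path / "a.sam"
        _write_sam(sam, recs)
        counts = [len(list(read_fragments_from_alignment(sam, min_mapq=q)))
                  for q in (0, 15, 30, 50, 70)]
        assert counts == [4, 3, 2, 1, 0]
        assert counts == sorted(counts, reverse=True)

    def test_unsorted_input_rejected(self, tmp_path, header):
        sam = tmp_path / "a.sam"
        hdr = {"HD": {"VN": "1.6", "SO": "unsorted"},
               "SQ": [{"SN": "chr1", "LN": 100_000}]}
        with pysam.AlignmentFile(str(sam), "w", header=hdr) as out:
            for r in _pair(header, "p1", 100, 180):
                out.write(r)
        with pytest.raises(FormatError, match="coordinate-sorted"):
            list(read_fragments_from_alignment(sam))

    def test_synthetic_bam_round_trip_matches_truth(self, tmp_path, toy_genome):
        subj = SubjectTruth("H1", "healthy", 0.0)
        frags, _ = sample_fragments(subj, CANINE_HEALTHY, CANINE_TUMOR, depth=250,
                                    genome=toy_genome, seed=5, apply_end_bias=False)
        frags = frags[:1000]
        bam = fragments_to_bam(frags, toy_genome, tmp_path / "t.bam")
        got = sorted(read_fragments_from_alignment(bam, min_mapq=30))
        assert got == sorted(frags)


class TestLongReadReader:
    def test_reference_span_and_secondary_filter(self, tmp_path):
        header = pysam.AlignmentHeader.from_dict(
            {"HD": {"VN": "1.6", "SO": "coordinate"},
             "SQ": [{"SN": "chr1", "LN": 100_000}]}
        )
        primary = pysam.AlignedSegment(header=header)
        primary.query_name = "r1"
        primary.reference_id = 0
        primary.reference_start = 5_000
        primary.mapping_quality = 60
        primary.query_sequence = "A" * 1_200
        primary.cigarstring = "1200M"
        secondary = pysam.AlignedSegment(header=header)
        secondary.query_name = "r1"
        secondary.reference_id = 0
        secondary.reference_start = 9_000
        secondary.mapping_quality = 60
        secondary.is_secondary = True
        secondary.query_sequence = None
        secondary.cigarstring = "1200M"
        sam = tmp_path / "lr.sam"
        _write_sam(sam, [primary, secondary])
        frags = list(read_long_read_fragments(sam))
        assert frags == [Fragment("chr1", 5_000, 6_200)]
        assert frags[0].length == 1_200


class TestSampleSheet:
    def test_round_trip(self, tmp_path, cohort):
        path = tmp_path / "samples.csv"
        write_sample_sheet(cohort["samples"], path)
        back = read_sample_sheet(path)
        assert back.equals(cohort["samples"])

    def test_duplicate_sample_id_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("sample_id,subject_id,group,timepoint,species\n"
                     "s1,d1,healthy,na,canine\ns1,d2,cancer,pretreatment,canine\n")
        with pytest.raises(FormatError, match="duplicate sample_id"):
            read_sample_sheet(p)

    def test_unknown_group_rejected(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("sample_id,subject_id,group,timepoint,species\n"
                     "s1,d1,sick,na,canine\n")
        with pytest.raises(FormatError, match="unknown group"):
            read_sample_sheet(p)
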