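import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnakit import genome_io as gio

from conftest import make_profile


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")


SEG_HEADER = "Sample\tChromosome\tStart\tEnd\tNum_Probes\tSegment_Mean"


class TestReadSeg:
    def test_one_based_conversion(self, tmp_path):
        path = tmp_path / "a.seg"
        write_lines(path, [SEG_HEADER, "S1\tchr1\t1\t1000\t50\t0.42"])
        (profile,) = gio.read_seg(path, dialect="one_based_inclusive")
        seg = profile.segments[0]
        assert (seg.chrom, seg.start, seg.end) == ("chr1", 0, 1000)
        assert seg.n_probes == 50 and seg.log2 == pytest.approx(0.42)

    def test_zero_based_passthrough(self, tmp_path):
        path = tmp_path / "a.seg"
        write_lines(path, [SEG_HEADER, "S1\tchr1\t0\t1000\t50\t0.42"])
        (profile,) = gio.read_seg(path, dialect="zero_based_half_open")
        assert profile.segments[0].start == 0

    def test_header_only_gives_empty_list(self, tmp_path):
        path = tmp_path / "a.seg"
        write_lines(path, [SEG_HEADER])
        assert gio.read_seg(path) == []

    def test_shuffled_rows_grouped_and_sorted(self, tmp_path):
        rows = [
            "B\tchr2\t1\t10\t1\t0.0",
            "A\tchr1\t21\t30\t1\t0.0",
            "A\tchr1\t1\t10\t1\t0.0",
            "B\tchr1\t1\t10\t1\t0.0",
            "A\tchr1\t11\t20\t1\t0.0",
            "B\tchr1\t11\t20\t1\t0.0",
        ]
        path = tmp_path / "a.seg"
        write_lines(path, [SEG_HEADER, *rows])
        profiles = gio.read_seg(path)
        assert sorted(p.sample_id for p in profiles) == ["A", "B"]
        for p in profiles:
            assert len(p.segments) == 3
            keys = [(s.chrom, s.start) for s in p.segments]
            assert keys == sorted(keys)

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "a.seg"
        write_lines(path, [SEG_HEADER, "S1\tchr1\t1\t1000\t50\t0.42",
                           "S1\tchr1\txx\t2000\t5\t0.1"])
        with pytest.raises(ValueError, match="line 3"):
            gio.read_seg(path)

    def test_overlapping_segments_error(self, tmp_path):
        path = tmp_path / "a.seg"
        write_lines(path, [SEG_HEADER, "S1\tchr1\t1\t1000\t5\t0.1",
                           "S1\tchr1\t500\t2000\t5\t0.2"])
        with pytest.raises(ValueError, match="overlap"):
            gio.read_seg(path)

    def test_unknown_chromosome_error(self, tmp_path, build):
        path = tmp_path / "a.seg"
        write_lines(path, [SEG_HEADER, "S1\tchr9\t1\t1000\t5\t0.1"])
        with pytest.raises(ValueError, match="chr9"):
            gio.read_seg(path, build=build)

    def test_missing_probe_column_defaults_to_one(self, tmp_path):
        path = tmp_path / "a.seg"
        write_lines(path, ["Sample\tChromosome\tStart\tEnd\tSegment_Mean",
                           "S1\tchr1\t1\t1000\t0.42"])
        (profile,) = gio.read_seg(path)
        assert profile.segments[0].n_probes == 1

    def test_bare_chromosome_names_normalized(self, tmp_path):
        path = tmp_path / "a.seg"
        write_lines(path, [SEG_HEADER, "S1\t1\t1\t1000\t5\t0.1"])
        (profile,) = gio.read_seg(path)
        assert profile.segments[0].chrom == "chr1"


class TestWriteSeg:
    def test_round_trip_identity(self, tmp_path):
        profile = make_profile("S1", "chr1",
                               [(0, 1000, 7, 0.31), (1000, 5000, 12, -0.8)])
        path = tmp_path / "a.seg"
        gio.write_seg([profile], path)
        (back,) = gio.read_seg(path)
        assert back.sample_id == profile.sample_id
        for a, b in zip(back.segments, profile.segments):
            assert (a.start, a.end, a.n_probes) == (b.start, b.end, b.n_probes)
            assert a.log2 == pytest.approx(b.log2, abs=1e-9)

    def test_empty_list_writes_header_only(self, tmp_path):
        path = tmp_path / "a.seg"
        gio.write_seg([], path)
        assert path.read_text().strip() == SEG_HEADER

    def test_log2_precision(self, tmp_path):
        profile = make_profile("S1", "chr1", [(0, 10, 1, -1.2345678)])
        path = tmp_path / "a.seg"
        gio.write_seg([profile], path)
        (back,) = gio.read_seg(path)
        assert abs(back.segments[0].log2 - (-1.2345678)) < 1e-6


class TestRegions:
    def test_read_basic(self, tmp_path):
        path = tmp_path / "r.bed"
        write_lines(path, ["chr19\t34997000\t35000000\t19q12\tgain\texternal_peak"])
        (region,) = gio.read_regions(path)
        assert region.chrom == "chr19" and region.aber_type == "gain"
        assert (region.start, region.end) == (34997000, 35000000)

    def test_start_ge_end_error(self, tmp_path):
        path = tmp_path / "r.bed"
        write_lines(path, ["chr1\t100\t100\tx\tgain\ttier"])
        with pytest.raises(ValueError):
            gio.read_regions(path)

    def test_bad_aber_type_error(self, tmp_path):
        path = tmp_path / "r.bed"
        write_lines(path, ["chr1\t1\t100\tx\tamplified\ttier"])
        with pytest.raises(ValueError, match="aber_type"):
            gio.read_regions(path)

    def test_duplicate_labels_suffixed_deterministically(self, tmp_path):
        path = tmp_path / "r.bed"
        write_lines(path, [
            "chr1\t1\t100\tpeak\tgain\ttier",
            "chr2\t1\t100\tpeak\tgain\ttier",
            "chr2\t200\t300\tpeak\tgain\ttier",
        ])
        labels = [r.label for r in gio.read_regions(path)]
        assert labels == ["peak", "peak_2", "peak_3"]

    def test_round_trip(self, tmp_path):
        regions = [
            gio.Region("chr1", 10, 500, "gain", "a", "tier", amplitude=0.6),
            gio.Region("chrX", 5, 9, "loss", "b", "cnp"),
        ]
        path = tmp_path / "r.bed"
        gio.write_regions(regions, path)
        back = gio.read_regions(path)
        assert [(r.chrom, r.start, r.end, r.aber_type, r.label, r.provenance,
                 r.amplitude) for r in back] == [
            (r.chrom, r.start, r.end, r.aber_type, r.label, r.provenance,
             r.amplitude) for r in regions]


ANNOT_HEADER = ("sample_id\tcohort\tsubtype\tgrade\tstage"
                "\tos_time\tos_event\tpfs_time\tpfs_event")


class TestAnnotations:
    def test_read_three_rows(self, tmp_path):
        path = tmp_path / "a.tsv"
        write_lines(path, [
            ANNOT_HEADER,
            "S1\ttest\tserous\t3\tIII\t100\t1\t50\t1",
            "S2\ttest\tserous\t2\tII\t200\t0\tNA\tNA",
            "S3\tvalidation\tendometrioid\tNA\tNA\t300\t1\t120\t0",
        ])
        records = gio.read_annotations(path)
        assert len(records) == 3
        assert records[1].pfs_time is None and records[1].pfs_event is None
        assert records[0].os_event == 1

    def test_bad_event_code_error(self, tmp_path):
        path = tmp_path / "a.tsv"
        write_lines(path, [ANNOT_HEADER, "S1\tt\ts\t1\tI\t10\t2\t5\t0"])
        with pytest.raises(ValueError, match="os_event"):
            gio.read_annotations(path)

    def test_negative_time_error(self, tmp_path):
        path = tmp_path / "a.tsv"
        write_lines(path, [ANNOT_HEADER, "S1\tt\ts\t1\tI\t-1\t1\t5\t0"])
        with pytest.raises(ValueError, match="negative"):
            gio.read_annotations(path)

    def test_duplicate_sample_error(self, tmp_path):
        path = tmp_path / "a.tsv"
        write_lines(path, [ANNOT_HEADER,
                           "S1\tt\ts\t1\tI\t10\t1\t5\t0",
                           "S1\tt\ts\t1\tI\t10\t1\t5\t0"])
        with pytest.raises(ValueError, match="duplicated"):
            gio.read_annotations(path)

    def test_round_trip(self, tmp_path):
        records = [
            gio.SampleAnnotation("S1", cohort="test", os_time=10.0, os_event=1),
            gio.SampleAnnotation("S2", pfs_time=5.5, pfs_event=0),
        ]
        path = tmp_path / "a.tsv"
        gio.write_annotations(records, path)
        back = gio.read_annotations(path)
        assert back == records


coords = st.tuples(
    st.integers(min_value=0, max_value=10**9),
    st.integers(min_value=1, max_value=10**9),
).map(lambda t: (t[0], t[0] + t[1]))


@given(coords)
def test_coordinate_conversion_involution(interval):
    start, end = interval
    assert gio.from_one_based_inclusive(*gio.to_one_based_inclusive(start, end)) \
        == (start, end)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=2**32 - 1), st.booleans())
def test_seg_round_trip_random_profiles(tmp_path_factory, seed, one_based):
    rng = np.random.default_rng(seed)
    from conftest import random_contiguous_profile

    profiles = [
        random_contiguous_profile(rng, f"S{i}", chrom=f"chr{i % 2 + 1}")
        for i in range(3)
    ]
    path = tmp_path_factory.mktemp("seg") / "x.seg"
    dialect = "one_based_inclusive" if one_based else "zero_based_half_open"
    gio.write_seg(profiles, path, dialect=dialect)
    back = {p.sample_id: p for p in gio.read_seg(path, dialect=dialect)}
    for p in profiles:
        q = back[p.sample_id]
        assert [(s.chrom, s.start, s.end, s.n_probes) for s in q.segments] \
            == [(s.chrom, s.start, s.end, s.n_probes) for s in p.segments]
        for a, b in zip(q.segments, p.segments):
            assert a.log2 == pytest.approx(b.log2, abs=1e-7)
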