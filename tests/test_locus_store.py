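"""Locus parsing, store construction, and neighborhood queries."""

import io
import math
from collections import Counter
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import brute_force_query, hit_key
from hervprox.locus_store import (
    GenomicInterval,
    HervLocus,
    LocusStore,
    ParseError,
    QueryParams,
    build_store,
    gap,
    parse_blast_tabular,
    parse_repeatmasker_out,
    read_bed,
)

BLAST_PLUS = "HML2\tchr1\t98.5\t100\t1\t0\t1\t100\t1001\t1100\t1e-50\t180"
BLAST_MINUS = "HML2\tchr1\t98.5\t100\t1\t0\t1\t100\t1100\t1001\t1e-50\t180"

RM_OUT = """\
   SW   perc perc perc  query      position in query           matching       repeat              position in  repeat
score   div. del. ins.  sequence    begin     end    (left)    repeat         class/family         begin  end (left)   ID

  463   1.3  0.6  1.7  chr1        1001    1100  (248954622) +  MER4A          LTR/ERV1                1  100    (5)   1
  239  29.4  1.9  1.0  chr1        2001    2100  (248954522) +  AluSx          SINE/Alu                1  100  (200)   2
  300  10.0  0.0  0.0  chr2         501     700  (99999300)  C  THE1B          LTR/ERVL-MaLR           1  200    (0)   3
"""


class TestParseBlastTabular:
    def test_plus_strand_coordinate_conversion(self):
        (locus,) = parse_blast_tabular(io.StringIO(BLAST_PLUS), max_evalue=1e-10)
        assert locus.interval == GenomicInterval("chr1", 1000, 1100, "+")
        assert locus.evalue == 1e-50
        assert locus.source_id == "HML2"
        assert locus.score == 180.0

    def test_minus_strand_from_coordinate_order(self):
        (locus,) = parse_blast_tabular(io.StringIO(BLAST_MINUS), max_evalue=1e-10)
        assert locus.interval == GenomicInterval("chr1", 1000, 1100, "-")

    def test_evalue_above_ceiling_excluded(self):
        line = BLAST_PLUS.replace("1e-50", "1e-9")
        assert parse_blast_tabular(io.StringIO(line), max_evalue=1e-10) == []

    def test_evalue_ceiling_is_inclusive(self):
        line = BLAST_PLUS.replace("1e-50", "1e-10")
        assert len(parse_blast_tabular(io.StringIO(line), max_evalue=1e-10)) == 1

    def test_equal_subject_coordinates_give_one_bp_locus(self):
        line = "\t".join(BLAST_PLUS.split("\t")[:8] + ["500", "500", "1e-50", "99"])
        (locus,) = parse_blast_tabular(io.StringIO(line))
        assert (locus.interval.start, locus.interval.end) == (499, 500)
        assert locus.interval.length == 1

    def test_comments_and_blank_lines_skipped(self):
        text = f"# a comment\n\n{BLAST_PLUS}\n"
        assert len(parse_blast_tabular(io.StringIO(text))) == 1

    @pytest.mark.parametrize(
        "bad",
        ["only\tthree\tfields", BLAST_PLUS.replace("1001", "one-thousand")],
        ids=["short-line", "non-numeric"],
    )
    def test_malformed_line_rejected_with_line_number(self, bad):
        text = f"{BLAST_PLUS}\n{bad}\n"
        with pytest.raises(ParseError, match="line 2"):
            parse_blast_tabular(io.StringIO(text))


class TestParseRepeatMaskerOut:
    def test_ltr_class_filter_and_conversion(self):
        loci = parse_repeatmasker_out(io.StringIO(RM_OUT), class_filter="LTR")
        assert [l.source_id for l in loci] == ["MER4A", "THE1B"]
        assert loci[0].interval == GenomicInterval("chr1", 1000, 1100, "+")
        assert loci[1].interval == GenomicInterval("chr2", 500, 700, "-")  # "C"

    def test_no_evalue_means_zero(self):
        loci = parse_repeatmasker_out(io.StringIO(RM_OUT))
        assert all(l.evalue == 0.0 for l in loci)

    def test_other_class_excluded(self):
        assert parse_repeatmasker_out(io.StringIO(RM_OUT), class_filter="SINE") == [
            HervLocus(GenomicInterval("chr1", 2000, 2100, "+"), 0.0, "AluSx", 239.0)
        ]

    def test_short_data_line_rejected_with_line_number(self):
        text = RM_OUT + "  100  1.0  0.0  0.0  chr1  10  20\n"
        with pytest.raises(ParseError, match="line 7"):
            parse_repeatmasker_out(io.StringIO(text))


class TestBedAndIntervals:
    def test_bed_taken_as_zero_based(self):
        text = "chr1\t100\t220\tprobeA\t0\t-\nchr2\t5\t10\n"
        regions = read_bed(io.StringIO(text))
        assert regions[0] == ("probeA", GenomicInterval("chr1", 100, 220, "-"))
        assert regions[1][0] == "chr2:5-10"

    @pytest.mark.parametrize(
        "start,end", [(-1, 5), (5, 5), (7, 3)], ids=["neg", "empty", "reversed"]
    )
    def test_degenerate_interval_rejected(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end)

    def test_gap_overlap_abut_and_separation(self):
        a = GenomicInterval("chr1", 100, 200)
        assert gap(a, GenomicInterval("chr1", 150, 250)) == 0  # overlap
        assert gap(a, GenomicInterval("chr1", 200, 250)) == 0  # abutting
        assert gap(a, GenomicInterval("chr1", 300, 400)) == 100
        assert gap(a, GenomicInterval("chr1", 10, 50)) == 50
        with pytest.raises(ValueError):
            gap(a, GenomicInterval("chr2", 300, 400))


class TestStore:
    def test_empty_store_answers_empty(self):
        store = build_store([])
        assert store.count == 0
        region = GenomicInterval("chr1", 0, 100)
        assert store.query(region, QueryParams(max_distance=10**9)) == []

    def test_counts_preserved_per_chromosome(self, toy_store):
        assert toy_store.count == 6
        assert toy_store.chromosome_counts() == {"chr1": 3, "chr2": 3}

    def test_duplicate_loci_retained(self):
        locus = HervLocus(GenomicInterval("chr1", 10, 20), 1e-30, "X")
        store = build_store([locus, locus])
        assert store.count == 2
        hits = store.query(GenomicInterval("chr1", 10, 20), QueryParams())
        assert len(hits) == 2

    def test_gap_threshold_boundary(self, toy_store):
        region = GenomicInterval("chr1", 1200, 1300)
        hits = toy_store.query(region, QueryParams(max_distance=100))
        assert [(h[0].source_id, h[1]) for h in hits] == [("L1", 100)]
        assert toy_store.query(region, QueryParams(max_distance=99)) == []

    def test_overlap_is_distance_zero(self, toy_store):
        hits = toy_store.query(
            GenomicInterval("chr1", 1050, 1060), QueryParams(max_distance=0)
        )
        assert [(h[0].source_id, h[1]) for h in hits] == [("L1", 0)]

    def test_evalue_ceiling_filters(self, toy_store):
        region = GenomicInterval("chr1", 4900, 5300)
        assert toy_store.query(region, QueryParams(0, max_evalue=1e-100)) == []
        hits = toy_store.query(region, QueryParams(0, max_evalue=1e-20))
        assert [h[0].source_id for h in hits] == ["L2"]

    def test_length_bounds(self, toy_store):
        region = GenomicInterval("chr2", 0, 10000)
        params = QueryParams(max_distance=10000)
        all_ids = {h[0].source_id for h in toy_store.query(region, params)}
        assert all_ids == {"L4", "L5", "L6"}
        narrow = replace(params, min_length=50, max_length=100)
        assert {h[0].source_id for h in toy_store.query(region, narrow)} == {"L4"}

    def test_absent_chromosome_gives_empty(self, toy_store):
        assert toy_store.query(GenomicInterval("chrX", 0, 100), QueryParams()) == []

    def test_results_sorted_by_gap_then_start(self, toy_store):
        hits = toy_store.query(
            GenomicInterval("chr1", 2000, 2100), QueryParams(max_distance=10**5)
        )
        gaps = [h[1] for h in hits]
        assert gaps == sorted(gaps)
        assert [h[0].source_id for h in hits] == ["L1", "L2", "L3"]

    def test_tsv_round_trip(self, toy_store):
        buf = io.StringIO()
        assert toy_store.to_tsv(buf) == 6
        again = LocusStore.from_tsv(io.StringIO(buf.getvalue()))
        assert list(again) == list(toy_store)

    def test_parse_build_query_conservation(self):
        # every parsed locus is reachable through a wide query (round trip)
        lines = [BLAST_PLUS, BLAST_MINUS, BLAST_PLUS.replace("chr1", "chr2")]
        loci = parse_blast_tabular(io.StringIO("\n".join(lines)))
        store = build_store(loci)
        touched = []
        for chrom in ("chr1", "chr2"):
            touched += [
                h[0]
                for h in store.query(
                    GenomicInterval(chrom, 0, 1), QueryParams(max_distance=10**9)
                )
            ]
        assert Counter(id(l) for l in touched) == Counter(id(l) for l in loci)


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------

_chrom = st.sampled_from(["chr1", "chr2", "chr3"])
_strand = st.sampled_from(["+", "-", "."])


@st.composite
def _locus(draw):
    start = draw(st.integers(0, 20_000))
    length = draw(st.integers(1, 800))
    evalue = draw(st.sampled_from([0.0, 1e-150, 1e-80, 1e-30, 1e-10, 1e-5]))
    return HervLocus(
        GenomicInterval(draw(_chrom), start, start + length, draw(_strand)),
        evalue,
        draw(st.sampled_from(["A", "B", "C"])),
    )


@st.composite
def _region(draw):
    start = draw(st.integers(0, 20_000))
    return GenomicInterval(draw(_chrom), start, start + draw(st.integers(1, 500)))


@st.composite
def _params(draw):
    min_len = draw(st.one_of(st.none(), st.integers(1, 400)))
    max_len = draw(st.one_of(st.none(), st.integers(400, 1000)))
    return QueryParams(
        max_distance=draw(st.integers(0, 8_000)),
        max_evalue=draw(st.sampled_from([0.0, 1e-100, 1e-40, 1e-10, math.inf])),
        min_length=min_len,
        max_length=max_len,
    )


@settings(max_examples=80, deadline=None, derandomize=True)
@given(loci=st.lists(_locus(), max_size=40), region=_region(), params=_params())
def test_query_equals_brute_force_scan(loci, region, params):
    """The indexed query returns exactly what a linear scan returns."""
    store = build_store(loci)
    got = sorted(store.query(region, params), key=hit_key)
    expected = sorted(brute_force_query(loci, region, params), key=hit_key)
    assert got == expected


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    loci=st.lists(_locus(), max_size=30),
    region=_region(),
    params=_params(),
    d_extra=st.integers(0, 5000),
)
def test_hit_set_monotone_in_distance_and_evalue(loci, region, params, d_extra):
    """Relaxing distance, E-value or length bounds never removes hits."""
    store = build_store(loci)
    tight = {hit_key(h) for h in store.query(region, params)}
    relaxed_params = QueryParams(
        max_distance=params.max_distance + d_extra,
        max_evalue=math.inf,
        min_length=None,
        max_length=None,
    )
    relaxed = {hit_key(h) for h in store.query(region, relaxed_params)}
    assert tight <= relaxed


@settings(max_examples=50, deadline=None, derandomize=True)
@given(loci=st.lists(_locus(), max_size=30), region=_region(), params=_params())
def test_strand_never_affects_gaps(loci, region, params):
    """Mirroring every strand leaves (coordinates, gap) results unchanged."""
    flip = {"+": "-", "-": "+", ".": "."}
    mirrored = [
        HervLocus(
            replace(l.interval, strand=flip[l.interval.strand]),
            l.evalue,
            l.source_id,
            l.score,
        )
        for l in loci
    ]
    key_no_strand = lambda h: (h[1], h[0].interval.start, h[0].interval.end, h[0].evalue)
    got = sorted(build_store(loci).query(region, params), key=key_no_strand)
    mirror = sorted(build_store(mirrored).query(region, params), key=key_no_strand)
    assert [key_no_strand(h) for h in got] == [key_no_strand(h) for h in mirror]


def test_query_oracle_on_large_random_store():
    """10,000 random loci: indexed results match brute force for 100 queries."""
    rng = np.random.default_rng(42)
    loci = []
    for _ in range(10_000):
        chrom = f"chr{rng.integers(1, 4)}"
        start = int(rng.integers(0, 900_000))
        loci.append(
            HervLocus(
                GenomicInterval(chrom, start, start + int(rng.integers(1, 5_000))),
                float(10.0 ** rng.uniform(-150, -5)),
                "R",
            )
        )
    store = build_store(loci)
    for _ in range(100):
        start = int(rng.integers(0, 900_000))
        region = GenomicInterval(f"chr{rng.integers(1, 4)}", start, start + 200)
        params = QueryParams(
            max_distance=int(rng.integers(0, 20_000)),
            max_evalue=float(10.0 ** rng.uniform(-120, -5)),
        )
        got = sorted(store.query(region, params), key=hit_key)
        assert got == sorted(brute_force_query(loci, region, params), key=hit_key)
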