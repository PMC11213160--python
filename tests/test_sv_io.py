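import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ppsv import sv_io
from ppsv.sv_io import (
    BndLine,
    GenomicBreakpoint,
    SVRecord,
    canonicalize,
    format_bnd_alt,
    make_record,
    parse_bnd_alt,
    resolve_bnd_pairs,
    read_sv_vcf,
    sv_length,
    write_sv_vcf,
)


class TestBreakpoint:
    def test_rejects_bad_pos(self):
        with pytest.raises(ValueError):
            GenomicBreakpoint("chr1", 0)

    def test_rejects_bad_orient(self):
        with pytest.raises(ValueError):
            GenomicBreakpoint("chr1", 5, "x")

    def test_rejects_empty_chrom(self):
        with pytest.raises(ValueError):
            GenomicBreakpoint("", 5)


class TestRecordInvariants:
    def test_tra_requires_interchromosomal(self):
        with pytest.raises(ValueError):
            make_record("a", "chr1", 100, "chr1", 200, "TRA")

    def test_intra_type_rejects_different_chroms(self):
        with pytest.raises(ValueError):
            make_record("a", "chr1", 100, "chr2", 200, "DEL")

    def test_unknown_type(self):
        with pytest.raises(ValueError):
            make_record("a", "chr1", 100, "chr1", 200, "CNV")


class TestCanonicalize:
    def test_swaps_reversed_breakpoints(self):
        rec = SVRecord(
            "a",
            GenomicBreakpoint("chr1", 200, "-"),
            GenomicBreakpoint("chr1", 100, "+"),
            "DEL",
        )
        out = canonicalize(rec)
        assert (out.bp1.pos, out.bp2.pos) == (100, 200)
        assert (out.bp1.orient, out.bp2.orient) == ("+", "-")

    def test_idempotent(self):
        rec = make_record("a", "chr1", 100, "chr1", 200, "DEL")
        assert canonicalize(canonicalize(rec)) == canonicalize(rec)

    def test_interchromosomal_order_preserved(self):
        # fusion naming relies on the caller-reported order (chr9 first)
        rec = make_record("a", "chr9", 132876361, "chr6", 56896165, "TRA")
        out = canonicalize(rec)
        assert out.bp1.chrom == "chr9" and out.bp2.chrom == "chr6"


class TestSvLength:
    # printed lengths from the reference candidate table
    @pytest.mark.parametrize(
        "chrom,p1,p2,svtype,expected",
        [
            ("chr15", 28017719, 28020677, "DEL", 2958),
            ("chr18", 62152637, 62157701, "DEL", 5064),
            ("chr2", 44281377, 44281612, "DUP", 235),
            ("chr8", 17418976, 17544122, "DEL", 125146),
        ],
    )
    def test_end_minus_start(self, chrom, p1, p2, svtype, expected):
        assert sv_length(make_record("a", chrom, p1, chrom, p2, svtype)) == expected

    def test_ins_uses_sequence_length(self):
        rec = make_record("a", "chr1", 100, "chr1", 100, "INS", insertion_seq="ACGT" * 20)
        assert sv_length(rec) == 80

    def test_tra_undefined(self):
        rec = make_record("a", "chr1", 100, "chr2", 200, "TRA")
        assert sv_length(rec) is None

    def test_invariant_under_canonicalization(self):
        rec = SVRecord(
            "a",
            GenomicBreakpoint("chr1", 900, "-"),
            GenomicBreakpoint("chr1", 400, "+"),
            "DUP",
        )
        assert sv_length(rec) == sv_length(canonicalize(rec)) == 500


class TestBndAlt:
    @pytest.mark.parametrize(
        "alt,expected",
        [
            ("N[chr2:500[", ("chr2", 500, "+", "-")),
            ("N]chr2:500]", ("chr2", 500, "+", "+")),
            ("[chr2:500[N", ("chr2", 500, "-", "-")),
            ("]chr2:500]N", ("chr2", 500, "-", "+")),
        ],
    )
    def test_all_four_bracket_forms(self, alt, expected):
        assert parse_bnd_alt(alt) == expected

    def test_format_is_inverse_of_parse(self):
        for so in "+-":
            for mo in "+-":
                alt = format_bnd_alt(so, GenomicBreakpoint("chr3", 77, mo))
                assert parse_bnd_alt(alt) == ("chr3", 77, so, mo)

    @pytest.mark.parametrize("alt", ["N", "N[chr2:500]", "[chr2:500[", "<DEL>"])
    def test_malformed(self, alt):
        with pytest.raises(ValueError):
            parse_bnd_alt(alt)


def _bnd_pair(id1, id2, chrom1, pos1, chrom2, pos2, o1, o2):
    return [
        BndLine(id1, chrom1, pos1, chrom2, pos2, o1, o2, mate_id=id2),
        BndLine(id2, chrom2, pos2, chrom1, pos1, o2, o1, mate_id=id1),
    ]


class TestResolveBndPairs:
    # the bracket-orientation -> simple-type mapping, all four forms
    @pytest.mark.parametrize(
        "o1,o2,expected",
        [("+", "-", "DEL"), ("-", "+", "DUP"), ("+", "+", "INV"), ("-", "-", "INV")],
    )
    def test_same_chromosome_mapping(self, o1, o2, expected):
        out = resolve_bnd_pairs(_bnd_pair("a", "b", "chr1", 100, "chr1", 500, o1, o2))
        assert len(out) == 1
        assert out[0].svtype == expected
        assert out[0].bnd_derived

    def test_deletion_example(self):
        # ALT "t[chr1:500[" at pos 100 -> orientations (+,-) -> DEL of 400
        out = resolve_bnd_pairs(_bnd_pair("a", "b", "chr1", 100, "chr1", 500, "+", "-"))
        assert out[0].svtype == "DEL"
        assert sv_length(out[0]) == 400

    def test_cross_chromosome_is_tra(self):
        out = resolve_bnd_pairs(
            _bnd_pair("a", "b", "chr5", 138903881, "chr19", 21614900, "+", "-")
        )
        assert len(out) == 1
        assert out[0].svtype == "TRA"

    def test_orphan_retained_with_warning(self, caplog):
        lines = _bnd_pair("a", "b", "chr1", 100, "chr1", 500, "+", "-")
        lines.append(BndLine("c", "chr2", 50, "chr3", 60, "+", "-", mate_id="zz"))
        with caplog.at_level("WARNING"):
            out = resolve_bnd_pairs(lines)
        assert len(out) == 2
        assert {r.svtype for r in out} == {"DEL", "TRA"}
        assert "orphan" in caplog.text

    def test_inconsistent_mates_raise(self):
        lines = _bnd_pair("a", "b", "chr1", 100, "chr1", 500, "+", "-")
        lines[1].pos = 999  # mate no longer where a's ALT points
        with pytest.raises(sv_io.SVParseError):
            resolve_bnd_pairs(lines)

    def test_output_count_identity(self):
        # (bnd lines - orphans)/2 + orphans
        lines = _bnd_pair("a", "b", "chr1", 100, "chr1", 500, "+", "-")
        lines += _bnd_pair("c", "d", "chr2", 100, "chr2", 900, "-", "+")
        lines.append(BndLine("e", "chr1", 10, "chr2", 20, "+", "-", mate_id=None))
        out = resolve_bnd_pairs(lines)
        assert len(out) == (len(lines) - 1) // 2 + 1


class TestVcfRoundTrip:
    def _records(self):
        return [
            make_record("del1", "chr1", 1000, "chr1", 3000, "DEL"),
            make_record("dup1", "chr1", 5000, "chr1", 9000, "DUP"),
            make_record("ins1", "chr2", 100, "chr2", 100, "INS", insertion_seq="ACGTAC"),
            make_record("inv1", "chr2", 4000, "chr2", 8000, "INV"),
            make_record("tra1", "chr1", 2000, "chr2", 7000, "TRA"),
        ]

    @pytest.mark.parametrize("dialect", ["manta", "gridss"])
    def test_round_trip(self, tmp_path, dialect):
        recs = self._records()
        path = tmp_path / "x.vcf"
        write_sv_vcf(recs, path, dialect)
        back = read_sv_vcf(path, dialect)
        assert sorted(r.key() for r in back) == sorted(r.key() for r in recs)

    def test_empty_vcf(self, tmp_path):
        path = tmp_path / "e.vcf"
        write_sv_vcf([], path, "manta", contigs={"chr1": 1_000_000})
        assert read_sv_vcf(path, "manta") == []

    def test_manta_tra_written_as_bnd_pair(self, tmp_path):
        path = tmp_path / "x.vcf"
        write_sv_vcf(
            [
                make_record("d", "chr1", 100, "chr1", 300, "DEL"),
                make_record("t", "chr1", 100, "chr2", 300, "TRA"),
            ],
            path,
            "manta",
        )
        body = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(body) == 3  # 1 symbolic + 2 BND
        assert sum("MATEID" in l for l in body) == 2

    def test_filter_dot_is_pass(self, tmp_path):
        path = tmp_path / "x.vcf"
        write_sv_vcf([make_record("d", "chr1", 100, "chr1", 300, "DEL")], path, "manta")
        text = path.read_text().replace("\tPASS\t", "\t.\t")
        path.write_text(text)
        (rec,) = read_sv_vcf(path, "manta")
        assert rec.filter_pass

    def test_non_pass_filter_round_trips(self, tmp_path):
        rec = make_record("d", "chr1", 100, "chr1", 300, "DEL", filter_pass=False)
        path = tmp_path / "x.vcf"
        write_sv_vcf([rec], path, "manta")
        (back,) = read_sv_vcf(path, "manta")
        assert not back.filter_pass

    def test_genotyped_round_trip(self, tmp_path):
        recs = [
            make_record("s1", "chr1", 1000, "chr1", 3000, "DEL"),
            make_record("s2", "chr1", 5000, "chr1", 9000, "INV"),
            make_record("s3", "chr1", 2000, "chr2", 7000, "TRA"),
        ]
        payload = sv_io.GenotypePayload(samples=["A", "B"])
        payload.site_info = {"s1": (1.0, True), "s2": (0.7, True), "s3": (0.4, False)}
        payload.calls = {
            "s1": [(0, "PASS", 99), (1, "PASS", 80)],
            "s2": [(2, None, 99), (None, None, 12)],
            "s3": [(1, None, 19), (0, None, 99)],
        }
        path = tmp_path / "g.vcf"
        write_sv_vcf(recs, path, "genotyped", genotypes=payload)
        back, pl = read_sv_vcf(path, "genotyped")
        assert sorted(r.key()[:6] for r in back) == sorted(r.key()[:6] for r in recs)
        # INV/TRA come back as BND-derived (Graphtyper-style), DEL does not
        flags = {r.id: r.bnd_derived for r in back}
        assert flags == {"s1": False, "s2": True, "s3": True}
        assert pl.samples == ["A", "B"]
        assert pl.calls["s1"] == [(0, "PASS", 99), (1, "PASS", 80)]
        assert pl.calls["s2"][0][0] == 2 and pl.calls["s2"][1][0] is None
        assert pl.calls["s3"][0][2] == 19
        assert pl.site_info["s1"][0] == pytest.approx(1.0)
        assert pl.site_info["s3"][1] is False

    def test_malformed_alt_reports_line(self, tmp_path):
        path = tmp_path / "bad.vcf"
        write_sv_vcf([make_record("d", "chr1", 100, "chr1", 300, "DEL")], path, "manta")
        with open(path, "a") as fh:
            fh.write("chr1\t500\tbad\tN\tN[chr1:900\t.\tPASS\tSVTYPE=BND\n")
        with pytest.raises(sv_io.SVParseError, match="line 2"):
            read_sv_vcf(path, "manta")


_svtype = st.sampled_from(["DEL", "DUP", "INS", "INV", "TRA"])


@st.composite
def _record_lists(draw):
    n = draw(st.integers(0, 8))
    out = []
    for i in range(n):
        svtype = draw(_svtype)
        p1 = draw(st.integers(1_000, 500_000))
        if svtype == "TRA":
            chrom1, chrom2 = "chr1", "chr2"
            p2 = draw(st.integers(1_000, 500_000))
        elif svtype == "INS":
            chrom1 = chrom2 = draw(st.sampled_from(["chr1", "chr2"]))
            p2 = p1
        else:
            chrom1 = chrom2 = draw(st.sampled_from(["chr1", "chr2"]))
            p2 = p1 + draw(st.integers(50, 100_000))
        seq = "ACGT" * draw(st.integers(13, 40)) if svtype == "INS" else None
        out.append(
            make_record(
                f"sv{i}", chrom1, p1, chrom2, p2, svtype,
                filter_pass=draw(st.booleans()), insertion_seq=seq,
            )
        )
    return out


@settings(max_examples=25, deadline=None)
@given(recs=_record_lists(), dialect=st.sampled_from(["manta", "gridss"]))
def test_round_trip_property(tmp_path_factory, recs, dialect):
    path = tmp_path_factory.mktemp("rt") / "x.vcf"
    write_sv_vcf(recs, path, dialect, contigs={"chr1": 1_000_000, "chr2": 1_000_000})
    back = read_sv_vcf(path, dialect)
    assert sorted(r.key() for r in back) == sorted(
        canonicalize(r).key() for r in recs
    )
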