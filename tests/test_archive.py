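import numpy as np
import pytest

from oracles import ceil_div, covering_blocks_oracle
from qsarc import synthgen
from qsarc.archive import (
    ArchiveError,
    ArchiveReader,
    build_containers,
    build_index,
    compress_archive,
    covering_blocks,
    decompress_archive,
    extract_range,
    inspect_archive,
)
from qsarc.qio import QualityLine
from qsarc.qmap import EOL, MapperParams, PLACEHOLDER

from conftest import make_lines


def _labelled(strings, labels):
    return list(zip(make_lines(strings), labels))


def test_container_layout_interleaves_placeholders():
    strings = ["FFFF", "GGGG", "FFFH", "GGGH", "GGGG"]
    labels = ["A", "B", "A", "B", "B"]
    c = build_containers(_labelled(strings, labels), MapperParams(70), MapperParams(71))
    # container A: mapped line, placeholder, mapped line, placeholder x2
    a_lines = [
        c.a_symbols[c.a_line_offsets[i]: c.a_line_offsets[i + 1]].tolist()
        for i in range(c.n_lines)
    ]
    assert a_lines[0] == [204, EOL]         # run of 4 F with C=70
    assert a_lines[1] == [PLACEHOLDER]
    assert a_lines[3] == [PLACEHOLDER]
    assert a_lines[4] == [PLACEHOLDER]
    assert a_lines[2][-1] == EOL
    assert c.placeholder_positions.tolist() == [2, 4, 5]
    assert c.n_b_lines == 3                 # placeholders in A == lines in B
    b_lines = [
        c.b_symbols[c.b_line_offsets[i]: c.b_line_offsets[i + 1]].tolist()
        for i in range(c.n_b_lines)
    ]
    assert b_lines[0] == [204, EOL]         # run of 4 G with C=71
    assert all(bl[-1] == EOL for bl in b_lines)


def test_single_class_containers_degenerate():
    c = build_containers(
        _labelled(["FF", "FF"], ["A", "A"]), MapperParams(70), MapperParams(70)
    )
    assert c.n_b_lines == 0 and c.b_symbols.size == 0
    assert c.placeholder_positions.size == 0
    c = build_containers(
        _labelled(["FF", "FF"], ["B", "B"]), MapperParams(70), MapperParams(70)
    )
    assert c.a_symbols.tolist() == [PLACEHOLDER, PLACEHOLDER]
    assert c.n_b_lines == 2


def test_index_entries_alternating_fixture():
    strings = ["FFFF"] * 10
    labels = ["A", "B"] * 5
    c = build_containers(_labelled(strings, labels), MapperParams(70), MapperParams(70))
    a_entries, b_entries = build_index(c, block_size=3)
    assert [e.first_line for e in a_entries] == [1, 4, 7, 10]
    assert [e.cum_placeholders for e in a_entries] == [0, 1, 3, 4]
    assert [(e.first_ordinal, e.last_ordinal) for e in b_entries] == [(1, 3), (4, 5)]
    # index record stays under 64 bytes per block
    from qsarc.archive import _ENTRY_SIZE

    assert _ENTRY_SIZE < 64


def test_single_block_index():
    c = build_containers(_labelled(["FF"], ["A"]), MapperParams(70), MapperParams(70))
    a_entries, b_entries = build_index(c, block_size=100)
    assert len(a_entries) == 1
    assert a_entries[0].first_line == 1 and a_entries[0].cum_placeholders == 0
    assert b_entries == []


def test_covering_blocks_matches_linear_scan(rng):
    for _ in range(50):
        n_blocks = int(rng.integers(1, 12))
        sizes = rng.integers(1, 9, size=n_blocks)
        firsts = np.concatenate([[1], 1 + np.cumsum(sizes)[:-1]]).astype(np.int64)
        n_items = int(np.sum(sizes))
        a = int(rng.integers(1, n_items + 1))
        b = int(rng.integers(a, n_items + 1))
        got = list(covering_blocks(firsts, a, b))
        assert got == covering_blocks_oracle(firsts.tolist(), n_items, a, b)


@pytest.fixture
def alternating_archive(tmp_path):
    """Ten lines whose classes alternate A,B,A,B,...: odd lines are runs
    of F (their 4-mer dominates the sample), even lines are low-repetition
    junk."""
    strings = []
    for i in range(10):
        if i % 2 == 0:
            strings.append("F" * 8)
        else:
            j = i // 2
            strings.append("".join(chr(73 + (3 * j + t) % 31) for t in range(8)))
    lines = make_lines(strings)
    from qsarc.classify import ClassifierParams, classify_stream

    out = classify_stream(lines, ClassifierParams(k=4, M=10, alpha=0.5))
    assert [f.label for _, f in out] == ["A", "B"] * 5
    path = tmp_path / "alt.qsv"
    compress_archive(lines, path, k=4, sample_lines=10, alpha=0.5, block_size=3)
    return path, strings


def test_locate_blocks_oracle_and_bounds(alternating_archive):
    path, strings = alternating_archive
    r = ArchiveReader(path)
    loc = r.locate_blocks(4, 7)
    # lines 4..7 live in A-blocks 2 and 3 (entries 1..2, 0-based); the
    # class-B lines in range are global lines 4 and 6 = ordinals 2 and 3
    assert list(loc.a_blocks) == [1, 2]
    assert loc.b_ordinals == (2, 3)
    assert list(loc.b_blocks) == [0]
    loc_all = r.locate_blocks(1, 10)
    assert list(loc_all.a_blocks) == list(range(len(r.a_index)))
    with pytest.raises(ValueError):
        r.locate_blocks(0, 3)
    with pytest.raises(ValueError):
        r.locate_blocks(3, 11)
    with pytest.raises(ValueError):
        r.locate_blocks(5, 4)


def test_extract_equals_slicing(alternating_archive):
    path, strings = alternating_archive
    for a in range(1, 11):
        for b in range(a, 11):
            got = extract_range(path, a, b)
            assert [ql.scores for ql in got] == strings[a - 1: b]
            assert [ql.line_no for ql in got] == list(range(a, b + 1))


@pytest.mark.parametrize("profile_name", sorted(synthgen.PROFILES))
def test_lossless_roundtrip_all_profiles(tmp_path, profile_name):
    prof = synthgen.profile(profile_name, n_reads=600, seed=3)
    lines = synthgen.generate(prof)
    path = tmp_path / "x.qsv"
    compress_archive(lines, path, block_size=150, sample_lines=200)
    back = decompress_archive(path)
    assert [ql.scores for ql in back] == [ql.scores for ql in lines]
    assert [ql.line_no for ql in back] == [ql.line_no for ql in lines]


def test_random_ranges_match_slicing_and_block_bound(tmp_path, rng):
    prof = synthgen.profile("pacbio_wide", n_reads=2000, seed=9)
    lines = synthgen.generate(prof)
    strings = [ql.scores for ql in lines]
    path = tmp_path / "r.qsv"
    bs = 100
    compress_archive(lines, path, block_size=bs, sample_lines=500)
    r = ArchiveReader(path)
    for _ in range(50):
        a = int(rng.integers(1, 2001))
        b = int(rng.integers(a, 2001))
        r.drop_cache()
        got = r.extract(a, b)
        assert [ql.scores for ql in got] == strings[a - 1: b]
        bound = 2 * (ceil_div(b - a + 1, bs) + 1)
        assert r.stats["blocks_decoded"] <= bound


def test_archive_bytes_deterministic_across_threads(tmp_path):
    lines = synthgen.generate(synthgen.profile("illumina_binned", n_reads=1200, seed=2))
    p1, p2, p3 = (tmp_path / f"{i}.qsv" for i in range(3))
    compress_archive(lines, p1, block_size=100, threads=1)
    compress_archive(lines, p2, block_size=100, threads=8)
    compress_archive(lines, p3, block_size=100, threads=1)
    assert p1.read_bytes() == p2.read_bytes() == p3.read_bytes()


def test_corrupt_block_detected(tmp_path):
    lines = make_lines(["FFFF"] * 20)
    path = tmp_path / "c.qsv"
    compress_archive(lines, path, block_size=5)
    raw = bytearray(path.read_bytes())
    r = ArchiveReader(path)
    off = r.a_index[0].byte_offset
    raw[off] ^= 0xFF
    path.write_bytes(bytes(raw))
    with pytest.raises(ArchiveError):
        ArchiveReader(path)  # file checksum already catches it


def test_not_an_archive_rejected(tmp_path):
    p = tmp_path / "junk.qsv"
    p.write_bytes(b"this is not an archive at all.....")
    with pytest.raises(ArchiveError, match="magic"):
        ArchiveReader(p)


def test_empty_and_degenerate_inputs_roundtrip(tmp_path):
    p = tmp_path / "e.qsv"
    compress_archive([], p)
    assert decompress_archive(p) == []
    # all-empty lines: no k-mer evidence anywhere
    lines = make_lines(["", "", ""])
    compress_archive(lines, p)
    assert [ql.scores for ql in decompress_archive(p)] == ["", "", ""]
    # single line
    compress_archive(make_lines(["IIII"]), p)
    assert [ql.scores for ql in decompress_archive(p)] == ["IIII"]


def test_header_fields_survive_roundtrip(tmp_path):
    lines = synthgen.generate(synthgen.profile("illumina_binned", n_reads=300, seed=4))
    path = tmp_path / "h.qsv"
    hdr = compress_archive(
        lines, path, k=3, sample_lines=128, alpha=0.25, block_size=64, backend="lzma"
    )
    r = ArchiveReader(path)
    assert (r.header.k, r.header.M, r.header.block_size) == (3, 128, 64)
    assert r.header.alpha == pytest.approx(0.25)
    assert r.header.backend == "lzma"
    assert r.header.n_lines == 300
    assert r.header.total_scores == sum(len(ql.scores) for ql in lines)
    assert (r.header.C_A, r.header.C_B) == (hdr.C_A, hdr.C_B)


def test_inspect_accounting(tmp_path):
    lines = synthgen.generate(synthgen.profile("illumina_binned", n_reads=500, seed=6))
    path = tmp_path / "i.qsv"
    compress_archive(lines, path, block_size=100)
    info = inspect_archive(path)
    assert info["n_lines"] == 500
    assert info["total_scores"] == 500 * 100
    assert info["archive_bytes"] == path.stat().st_size
    assert info["bits_per_score"] == pytest.approx(
        8 * info["archive_bytes"] / info["total_scores"]
    )
    assert info["n_a_blocks"] == 5
    assert 0 < info["index_overhead_pct"] < 100


def test_file_roundtrip_fastq_and_lines(tmp_path):
    prof = synthgen.profile("nanopore_long", n_reads=80, seed=8)
    src = tmp_path / "in.fastq"
    synthgen.generate_file(prof, src, "fastq")
    path = tmp_path / "f.qsv"
    compress_archive(src, path, format="fastq", block_size=30)
    back = decompress_archive(path)
    expected = synthgen.generate(prof)
    assert [ql.scores for ql in back] == [ql.scores for ql in expected]
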