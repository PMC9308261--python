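import numpy as np
import pytest

from oracles import classify_oracle, ebar_oracle, kmer_counts_oracle
from qsarc.classify import (
    ClassifierParams,
    classify_arrays,
    classify_stream,
    fit_kmer_model,
    fit_kmer_model_arrays,
    line_feature,
)
from qsarc.qio import QualityLine, lines_to_arrays

from conftest import make_lines


def test_kmer_counts_with_overlaps():
    model = fit_kmer_model(make_lines(["AABB", "ABAB"]), k=2)
    assert model.counts == {"AA": 1, "AB": 3, "BB": 1, "BA": 1}
    assert model.total == 6
    assert model.proportions["AB"] == pytest.approx(0.5)
    assert sum(model.proportions.values()) == pytest.approx(1.0, abs=1e-12)


def test_overlap_counting_single_repeated_line():
    model = fit_kmer_model(make_lines(["AAAA"]), k=2)
    assert model.counts == {"AA": 3}
    assert model.total == 3


def test_sample_with_no_long_enough_line_is_error():
    with pytest.raises(ValueError):
        fit_kmer_model(make_lines(["A"]), k=2)
    with pytest.raises(ValueError):
        fit_kmer_model([], k=2)


def test_line_feature_hand_values():
    # distinct 2-mers of "AABB": AA, AB, BB -> (1 + 3 + 1)/6
    model = fit_kmer_model(make_lines(["AABB", "ABAB"]), k=2)
    f1 = line_feature(QualityLine(1, "AABB"), model, L_m=5 / 6)
    assert f1.e_bar == pytest.approx(5 / 6)
    assert f1.mx == pytest.approx(1.0)
    # "ABAB": AB, BA -> 4/6; mx = (4/6)/(5/6) = 0.8
    f2 = line_feature(QualityLine(2, "ABAB"), model, L_m=5 / 6)
    assert f2.e_bar == pytest.approx(4 / 6)
    assert f2.mx == pytest.approx(0.8)


def test_line_feature_absent_kmers_contribute_zero():
    model = fit_kmer_model(make_lines(["AABB"]), k=2)
    f = line_feature(QualityLine(1, "ZZZZ"), model, L_m=1.0)
    assert f.e_bar == 0.0
    assert f.mx == 0.0
    # shorter than k: no evidence at all
    assert line_feature(QualityLine(1, "Z"), model, L_m=1.0).e_bar == 0.0


def test_classify_stream_worked_example():
    out = classify_stream(
        make_lines(["AABB", "ABAB"]), ClassifierParams(k=2, M=2, alpha=0.9)
    )
    assert [f.label for _, f in out] == ["A", "B"]
    assert out[0][1].mx == pytest.approx(1.0)
    assert out[1][1].mx == pytest.approx(0.8)


def test_identical_lines_all_class_a():
    out = classify_stream(make_lines(["FFFF"] * 5), ClassifierParams(k=2, M=3, alpha=0.99))
    assert all(f.label == "A" and f.mx == pytest.approx(1.0) for _, f in out)


def test_out_of_sample_feature_is_clamped_to_one():
    """A tiling of the dominant 2-mer accumulates the proportions of both
    of its rotations, which never share a sample line, so its raw ratio
    e_bar/L_m exceeds 1 and must be clamped."""
    # one group plants "FG", the other "GF", each padded with junk k-mers
    # unique to the line; every line has 3 windows, e_bar = 12/60
    sample = [chr(48 + i) + chr(58 + i) + "FG" for i in range(10)]
    sample += ["GF" + chr(80 + i) + chr(91 + i) for i in range(10)]
    tail = ["FG" * 20]  # distinct 2-mers {FG, GF}: e_bar = 20/60
    params = ClassifierParams(k=2, M=20, alpha=0.5)
    out = classify_stream(make_lines(sample + tail), params)
    raw = out[-1][1].e_bar / params.L_m
    assert raw == pytest.approx((20 / 60) / (12 / 60))
    assert out[-1][1].mx == 1.0
    assert out[-1][1].label == "A"


def test_in_sample_max_mx_is_exactly_one(small_corpus):
    params = ClassifierParams(k=4, M=100, alpha=0.5)
    out = classify_stream(small_corpus, params)
    mx = [f.mx for _, f in out]
    assert max(mx[:100]) == 1.0
    assert all(0.0 <= m <= 1.0 for m in mx)


def test_labels_depend_only_on_sample_window(small_corpus):
    """Permuting lines beyond the first M leaves the model, and hence each
    line's feature, unchanged."""
    params = ClassifierParams(k=4, M=50, alpha=0.5)
    out1 = {ql.scores: f.mx for ql, f in classify_stream(small_corpus, params)}
    shuffled = small_corpus[:50] + small_corpus[50:][::-1]
    shuffled = [QualityLine(i + 1, ql.scores) for i, ql in enumerate(shuffled)]
    out2 = {ql.scores: f.mx for ql, f in classify_stream(shuffled, ClassifierParams(k=4, M=50, alpha=0.5))}
    assert out1 == out2


def test_agreement_with_bruteforce_oracle(rng):
    """Array path == per-line dict path == naive oracle on random data."""
    alphabet = [chr(c) for c in range(60, 70)]
    strings = [
        "".join(rng.choice(alphabet, size=rng.integers(0, 30)))
        for _ in range(60)
    ]
    strings[0] = "BBBBBB"  # ensure a fit-able sample line
    k, M, alpha = 3, 20, 0.4
    labels_o, mx_o, L_m_o = classify_oracle(strings, k, M, alpha)

    params = ClassifierParams(k=k, M=M, alpha=alpha)
    out = classify_stream(make_lines(strings), params)
    assert params.L_m == pytest.approx(L_m_o)
    assert [f.label for _, f in out] == labels_o
    assert [f.mx for _, f in out] == pytest.approx(mx_o)

    flat, offsets = lines_to_arrays(make_lines(strings))
    labels_arr, feats = classify_arrays(flat, offsets, ClassifierParams(k=k, M=M, alpha=alpha))
    assert ["A" if v else "B" for v in labels_arr] == labels_o
    assert feats["mx"] == pytest.approx(np.array(mx_o))


def test_array_model_matches_dict_model():
    strings = ["FFGH", "GHFF", "HFGF", "FFFF"]
    flat, offsets = lines_to_arrays(make_lines(strings))
    m_arr = fit_kmer_model_arrays(flat, offsets, 2)
    m_dict = fit_kmer_model(make_lines(strings), 2)
    assert m_arr.total == m_dict.total
    assert dict(m_arr.counts.items()) == m_dict.counts


def test_param_validation():
    with pytest.raises(ValueError):
        ClassifierParams(k=0)
    with pytest.raises(ValueError):
        ClassifierParams(alpha=0.0)
    with pytest.raises(ValueError):
        ClassifierParams(alpha=1.5)
    with pytest.raises(ValueError):
        ClassifierParams(M=0)
    with pytest.raises(ValueError):
        classify_stream([], ClassifierParams())
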