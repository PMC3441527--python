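import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import random_pwm
from prc2lnc.features import (
    PWM,
    build_feature_matrix,
    kmer_frequencies,
    lz76_complexity,
    lz76_phrase_count,
    pwm_hit_frequency,
    read_jaspar_pfms,
    reverse_complement,
    write_jaspar_pfms,
)
from prc2lnc.seqio import SequenceRecord, SequenceSet

dna = st.text(alphabet="ACGT", min_size=1, max_size=80)


# ---------------------------------------------------------------- k-words

@pytest.mark.parametrize(
    "seq,k,expected",
    [
        ("AAAA", 2, {"AA": 1.0}),
        ("ACGT", 2, {"AC": 1 / 3, "CG": 1 / 3, "GT": 1 / 3}),
        ("ACGTACGT", 3, {"ACG": 2 / 6, "CGT": 2 / 6, "GTA": 1 / 6, "TAC": 1 / 6}),
    ],
)
def test_kmer_frequencies_examples(seq, k, expected):
    freqs = kmer_frequencies(seq, k)
    assert freqs == pytest.approx(expected)


def test_kmer_windows_with_n_are_skipped():
    # ACNGT at k=2: windows AC, CN, NG, GT -> only AC and GT are valid
    assert kmer_frequencies("ACNGT", 2) == pytest.approx({"AC": 0.5, "GT": 0.5})


def test_kmer_zero_valid_windows_gives_empty_spectrum():
    assert kmer_frequencies("A", 2) == {}
    assert kmer_frequencies("ANANA", 3) == {}


@settings(deadline=None, derandomize=True)
@given(dna, st.integers(min_value=2, max_value=4))
def test_kmer_frequencies_sum_to_one(seq, k):
    freqs = kmer_frequencies(seq, k)
    if freqs:
        assert sum(freqs.values()) == pytest.approx(1.0, abs=1e-9)
        assert all(f > 0 for f in freqs.values())


# ---------------------------------------------------------------- LZ76

@pytest.mark.parametrize(
    "seq,expected",
    [("A", 1), ("AAAAAA", 2), ("ACACACACAC", 3), ("AACGACGA", 4)],
)
def test_lz76_phrase_count_examples(seq, expected):
    # AAAAAA parses A | AAAAA; ACACACACAC parses A | C | ACACACAC
    assert lz76_phrase_count(seq) == expected


def test_lz76_known_binary_parse():
    # classic worked example: 0|001|10|100|1000|101 -> 6 phrases
    assert lz76_phrase_count("0001101001000101") == 6


@settings(deadline=None, derandomize=True)
@given(dna)
def test_lz76_doubling_adds_at_most_one_phrase(seq):
    assert lz76_phrase_count(seq + seq) <= lz76_phrase_count(seq) + 1


def test_lz76_normalized_is_positive_and_strips_n():
    score = lz76_complexity("ACGTNNACGT")
    assert score.length_used == 8
    assert score.normalized > 0
    with pytest.raises(ValueError):
        lz76_complexity("NNN")


def test_periodic_sequence_less_complex_than_random():
    rng = np.random.default_rng(7)
    bases = np.array(list("ACGT"))
    wins = 0
    draws = 40
    for _ in range(draws):
        unit = "".join(bases[rng.integers(0, 4, 10)])
        periodic = (unit * 60)[:600]
        random_seq = "".join(bases[rng.integers(0, 4, 600)])
        if lz76_complexity(periodic).normalized < lz76_complexity(random_seq).normalized:
            wins += 1
    assert wins >= 0.95 * draws


# ---------------------------------------------------------------- PWM

def _consensus_pwm(word: str) -> PWM:
    m = np.zeros((4, len(word)))
    for j, b in enumerate(word):
        m["ACGT".index(b), j] = 10.0
    return PWM(word, m)


def test_pwm_exact_consensus_hits_both_strands():
    # ACGTACGT is its own reverse complement: 2 hits in 5 windows per strand
    assert pwm_hit_frequency("ACGTACGT", _consensus_pwm("ACGT"), 1.0) == pytest.approx(0.4)


def test_pwm_on_too_short_sequence_is_zero():
    assert pwm_hit_frequency("ACG", _consensus_pwm("ACGT"), 0.8) == 0.0


def test_uniform_pwm_threshold_zero_hits_everywhere():
    uniform = PWM("u", np.full((4, 5), 1.0))
    assert pwm_hit_frequency("ACGTACGTAC", uniform, 0.0) == 1.0


@settings(deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=10, max_size=60), st.integers(0, 2**31 - 1))
def test_pwm_hit_frequency_strand_symmetric(seq, pwm_seed):
    pwm = random_pwm(np.random.default_rng(pwm_seed), "p", width=5)
    assert pwm_hit_frequency(seq, pwm, 0.8) == pytest.approx(
        pwm_hit_frequency(reverse_complement(seq), pwm, 0.8), abs=1e-12
    )


def test_jaspar_pfm_roundtrip(tmp_path):
    rng = np.random.default_rng(3)
    pwms = [random_pwm(rng, f"M{i}", width=6) for i in range(3)]
    path = tmp_path / "motifs.pfm"
    write_jaspar_pfms(pwms, path)
    back = read_jaspar_pfms(path)
    assert [p.name for p in back] == ["M0", "M1", "M2"]
    for orig, rec in zip(pwms, back):
        np.testing.assert_allclose(orig.matrix, rec.matrix)


def test_jaspar_bracket_style_parsed(tmp_path):
    path = tmp_path / "m.pfm"
    path.write_text(">MA0001\nA [ 1 2 ]\nC [ 3 4 ]\nG [ 5 6 ]\nT [ 7 8 ]\n")
    (pwm,) = read_jaspar_pfms(path)
    np.testing.assert_allclose(pwm.matrix, [[1, 2], [3, 4], [5, 6], [7, 8]])


# ---------------------------------------------------------------- matrix

def _seqset(seqs, label=None):
    return SequenceSet([SequenceRecord(f"s{i}", s, label) for i, s in enumerate(seqs)])


def test_matrix_dimensions():
    fm = build_feature_matrix(_seqset(["ACGTACGT", "AAAAAAA", "CCCCCGG"]), k=2)
    assert fm.values.shape == (3, 17)  # 16 dinucleotides + kc
    rng = np.random.default_rng(0)
    pwms = [random_pwm(rng, f"M{i}", 4) for i in range(3)]
    fm2 = build_feature_matrix(_seqset(["ACGTACGTAC"] * 2), k=2, pwms=pwms)
    assert fm2.values.shape == (2, 16 + 3 + 1)
    names = fm2.feature_names
    assert names[-1] == "kc" and names[16].startswith("pwm:")


def test_matrix_row_order_follows_set_order():
    seqs = ["ACGTACGT", "AAAATTTT", "CGCGCGCG"]
    fm = build_feature_matrix(_seqset(seqs), k=2)
    reordered = build_feature_matrix(
        SequenceSet(
            [SequenceRecord(f"s{i}", s) for i, s in zip((2, 0, 1), (seqs[2], seqs[0], seqs[1]))]
        ),
        k=2,
    )
    np.testing.assert_allclose(fm.values[[2, 0, 1]], reordered.values)


def test_matrix_kmer_rows_sum_to_one():
    fm = build_feature_matrix(_seqset(["ACGTACGT", "TTTTTTTT"]), k=3)
    kmer_cols = [n for n in fm.feature_names if n.startswith("kmer:")]
    sums = fm.data[kmer_cols].sum(axis=1)
    np.testing.assert_allclose(sums, 1.0, atol=1e-9)


def test_matrix_labels_attached_when_all_labeled():
    fm = build_feature_matrix(_seqset(["ACGT" * 5], "positive"), k=2)
    assert fm.labels.tolist() == [1]
    fm2 = build_feature_matrix(_seqset(["ACGT" * 5]), k=2)
    assert fm2.labels is None


def test_matrix_extension_hook():
    ext = lambda rec: {"ext:gc": (rec.sequence.count("G") + rec.sequence.count("C")) / rec.length}
    fm = build_feature_matrix(_seqset(["GGGG", "AAAA"]), k=2, include_kc=False, extensions=[ext])
    assert fm.data["ext:gc"].tolist() == [1.0, 0.0]


def test_matrix_tsv_roundtrip(tmp_path):
    fm = build_feature_matrix(_seqset(["ACGTACGT", "AATTAATT"], "negative"), k=2)
    path = tmp_path / "fm.tsv"
    fm.to_tsv(path)
    from prc2lnc.features import FeatureMatrix

    back = FeatureMatrix.from_tsv(path)
    assert back.feature_names == fm.feature_names
    np.testing.assert_allclose(back.values, fm.values)
    np.testing.assert_array_equal(back.labels, fm.labels)
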