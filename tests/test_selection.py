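import numpy as np
import pytest
from scipy import stats

from conftest import fm_from_array
from prc2lnc.selection import (
    consensus_iupac,
    enriched_kmer_consensus,
    select_features,
    selected_counts_by_namespace,
    selected_features,
    welch_t_test,
)


# ---------------------------------------------------------------- t-test

def test_welch_identical_samples():
    assert welch_t_test([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)


def test_welch_hand_computed_example():
    # delta = -1, SE = sqrt(5/6), Welch df = 6 -> t = -1.095, p = 0.315
    t, p = welch_t_test([1, 2, 3, 4], [2, 3, 4, 5])
    assert t == pytest.approx(-1.095, abs=1e-3)
    assert p == pytest.approx(0.315, abs=1e-3)


def test_welch_swap_symmetry():
    rng = np.random.default_rng(0)
    for _ in range(100):
        x = rng.normal(size=rng.integers(2, 10))
        y = rng.normal(size=rng.integers(2, 10))
        tx, px = welch_t_test(x, y)
        ty, py = welch_t_test(y, x)
        assert tx == pytest.approx(-ty)
        assert px == pytest.approx(py)


def test_welch_degenerate_cases():
    assert welch_t_test([2, 2, 2], [2, 2]) == (0.0, 1.0)
    t, p = welch_t_test([3, 3], [1, 1, 1])
    assert np.isinf(t) and t > 0 and p == 0.0
    with pytest.raises(ValueError):
        welch_t_test([1], [1, 2])


# ---------------------------------------------------------------- selection

def _labeled_matrix(rng, n_per_class=50, n_features=100, shift_col=None, shift=0.0):
    X = rng.normal(size=(2 * n_per_class, n_features))
    y = np.r_[np.ones(n_per_class, int), np.zeros(n_per_class, int)]
    if shift_col is not None:
        X[: n_per_class, shift_col] += shift
    return fm_from_array(X, y)


def test_tiny_alpha_selects_nothing():
    fm = _labeled_matrix(np.random.default_rng(0))
    table = select_features(fm, alpha=1e-12)
    assert not table["selected"].any()


def test_shifted_column_detected_at_conservative_alpha():
    hits = 0
    for seed in range(20):
        fm = _labeled_matrix(np.random.default_rng(seed), shift_col=3, shift=3.0)
        table = select_features(fm, alpha=0.01)
        if table.iloc[3]["selected"] and table.iloc[3]["enriched_class"] == "positive":
            hits += 1
    assert hits >= 0.99 * 20  # a 3 SD shift at n=50/50 is essentially always found


def test_null_type_one_error_near_alpha():
    fracs = []
    for seed in range(20):
        fm = _labeled_matrix(np.random.default_rng(seed), n_features=1000)
        table = select_features(fm, alpha=0.05)
        fracs.append(table["selected"].mean())
    assert abs(np.mean(fracs) - 0.05) <= 0.02


def test_selection_invariant_to_column_order_and_scaling():
    fm = _labeled_matrix(np.random.default_rng(5), n_features=20, shift_col=0, shift=2.0)
    base = select_features(fm, alpha=0.05)
    shuffled = fm.subset_features(list(reversed(fm.feature_names)))
    perm = select_features(shuffled, alpha=0.05)
    assert perm.loc["f0", "p"] == pytest.approx(base.loc["f0", "p"])
    scaled = fm.data.copy()
    scaled["f0"] = scaled["f0"] * 1000.0
    from prc2lnc.features import FeatureMatrix

    rescored = select_features(FeatureMatrix(scaled, fm.labels), alpha=0.05)
    assert rescored.loc["f0", "t"] == pytest.approx(base.loc["f0", "t"])
    assert rescored.loc["f0", "p"] == pytest.approx(base.loc["f0", "p"])


def test_selection_requires_both_classes():
    fm = fm_from_array(np.random.default_rng(0).normal(size=(6, 3)), [1, 1, 1, 1, 1, 1])
    with pytest.raises(ValueError):
        select_features(fm, alpha=0.05)


def test_zero_variance_features_flagged_not_dropped():
    X = np.random.default_rng(1).normal(size=(10, 3))
    X[:, 2] = 7.0
    fm = fm_from_array(X, [1] * 5 + [0] * 5)
    table = select_features(fm, alpha=0.05)
    assert len(table) == 3
    assert bool(table.iloc[2]["degenerate"])
    assert table.iloc[2]["p"] == 1.0


def test_bh_correction_is_more_conservative():
    fm = _labeled_matrix(np.random.default_rng(9), n_features=500)
    raw = select_features(fm, alpha=0.05)
    bh = select_features(fm, alpha=0.05, bh_correction=True)
    assert bh["selected"].sum() <= raw["selected"].sum()


# ---------------------------------------------------------------- consensus

@pytest.mark.parametrize(
    "words,expected",
    [
        (["AAAA", "TTTT"], "WWWW"),
        (["ACGT"], "ACGT"),
        (["AAAA", "AATT", "ATTT"], "AWWW"),
    ],
)
def test_consensus_examples(words, expected):
    assert consensus_iupac(words).iupac == expected


def test_consensus_min_freq_drops_rare_bases():
    words = ["AAAA"] * 19 + ["CAAA"]  # C at 5% < 10% min_freq
    assert consensus_iupac(words, min_freq=0.1).iupac == "AAAA"


def test_consensus_rejects_mixed_lengths():
    with pytest.raises(ValueError):
        consensus_iupac(["AAA", "AAAA"])


def test_enriched_consensus_from_table():
    rng = np.random.default_rng(2)
    n = 30
    X = rng.normal(size=(2 * n, 3))
    X[:n, 0] += 4.0  # kmer:AATT up in positives
    X[n:, 1] += 4.0  # kmer:GGCC up in negatives
    fm = fm_from_array(
        X, [1] * n + [0] * n, names=["kmer:AATT", "kmer:GGCC", "kc"]
    )
    table = select_features(fm, alpha=0.01)
    pos = enriched_kmer_consensus(table, "positive")
    neg = enriched_kmer_consensus(table, "negative")
    assert pos.iupac == "AATT" and pos.support == 1
    assert neg.iupac == "GGCC"
    counts = selected_counts_by_namespace(table)
    assert counts["kmer"] == 2
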