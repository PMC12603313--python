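import math

import numpy as np
import pandas as pd
import pytest

from auxinmir.expression import (CountMatrix, compact_letter_display, ddct,
                                 fpkm, group_tests, rpm, zscore_rows)


def matrix(data, lengths=None, samples=None):
    df = pd.DataFrame(data)
    if samples:
        df.columns = samples
    lens = pd.Series(lengths) if lengths is not None else None
    return CountMatrix(counts=df, feature_lengths=lens)


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

class TestFpkmRpm:
    def test_fpkm_worked_example(self):
        # 10 fragments on a 2 kb transcript in a 1e6-fragment library -> 5.0
        m = matrix({"s": {"f": 10, "filler": 999990}},
                   lengths={"f": 2000, "filler": 1000})
        assert fpkm(m).loc["f", "s"] == 5.0

    def test_fpkm_invariant_under_uniform_count_scaling(self):
        rng = np.random.default_rng(21)
        counts = pd.DataFrame(rng.integers(1, 100, size=(6, 3)))
        lengths = pd.Series(rng.integers(200, 3000, size=6))
        a = fpkm(CountMatrix(counts, lengths))
        b = fpkm(CountMatrix(counts * 7, lengths))
        assert np.allclose(a.values, b.values)

    def test_formula_oracle_on_random_matrices(self):
        rng = np.random.default_rng(22)
        counts = pd.DataFrame(rng.integers(0, 500, size=(8, 4)))
        counts.iloc[0] += 1          # keep library totals positive
        lengths = pd.Series(rng.integers(100, 5000, size=8))
        got = fpkm(CountMatrix(counts, lengths))
        for f in range(8):
            for s in range(4):
                expected = (counts.iloc[f, s] / (counts.iloc[:, s].sum() / 1e6)
                            / (lengths.iloc[f] / 1e3))
                assert math.isclose(got.iloc[f, s], expected)
        got_rpm = rpm(CountMatrix(counts))
        assert np.allclose(got_rpm.sum(axis=0), 1e6)

    def test_rpm_worked_example(self):
        m = matrix({"s": {"f": 7, "filler": 999993}})
        assert rpm(m).loc["f", "s"] == 7.0

    def test_zero_total_rejected(self):
        m = matrix({"s": {"f": 0}}, lengths={"f": 100})
        with pytest.raises(ValueError, match="zero library total"):
            fpkm(m)
        with pytest.raises(ValueError, match="zero library total"):
            rpm(m)

    def test_feature_permutation_equivariance(self):
        rng = np.random.default_rng(23)
        counts = pd.DataFrame(rng.integers(1, 50, size=(5, 3)),
                              index=list("abcde"))
        lengths = pd.Series(rng.integers(100, 900, size=5), index=list("abcde"))
        base = fpkm(CountMatrix(counts, lengths))
        perm = ["c", "a", "e", "b", "d"]
        shuffled = fpkm(CountMatrix(counts.loc[perm], lengths))
        assert np.allclose(shuffled.loc[perm].values, base.loc[perm].values)


class TestZscore:
    def test_closed_form_row(self):
        z, flagged = zscore_rows(pd.DataFrame([[1.0, 2.0, 3.0]]))
        assert np.allclose(z.values, [[-1.22474487, 0.0, 1.22474487]])
        assert flagged == []

    def test_constant_row_flagged_and_zeroed(self):
        z, flagged = zscore_rows(pd.DataFrame([[5.0, 5.0, 5.0]], index=["r"]))
        assert (z.values == 0).all() and flagged == ["r"]

    def test_rows_standardised(self):
        rng = np.random.default_rng(24)
        x = pd.DataFrame(rng.uniform(0, 100, size=(20, 10)))
        z, _ = zscore_rows(x)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=0), 1, atol=1e-9)


# ---------------------------------------------------------------------------
# qPCR 2^-ddCt
# ---------------------------------------------------------------------------

def qpcr_rows(entries):
    return pd.DataFrame(entries, columns=["gene", "group", "bio_rep",
                                          "tech_rep", "ct"])


class TestDdct:
    def test_worked_example_fold_4(self):
        rows = []
        for rep in (1, 2, 3):
            rows += [("g", "treated", rep, 1, 20.0), ("ref", "treated", rep, 1, 18.0),
                     ("g", "control", rep, 1, 22.0), ("ref", "control", rep, 1, 18.0)]
        (treated,) = [r for r in ddct(qpcr_rows(rows), "ref", "control")
                      if r.group == "treated"]
        assert treated.fold_change == 4.0       # ddCt = -2 exactly

    def test_calibrator_against_itself_is_one(self):
        rows = []
        for rep in (1, 2, 3):
            rows += [("g", "control", rep, 1, 21.0), ("ref", "control", rep, 1, 18.0)]
        (ctrl,) = ddct(qpcr_rows(rows), "ref", "control")
        assert ctrl.fold_change == 1.0

    def test_tech_reps_averaged_on_ct_scale(self):
        rows = [("g", "treated", 1, 1, 19.0), ("g", "treated", 1, 2, 21.0),
                ("ref", "treated", 1, 1, 18.0),
                ("g", "control", 1, 1, 22.0), ("ref", "control", 1, 1, 18.0)]
        (treated,) = [r for r in ddct(qpcr_rows(rows), "ref", "control")
                      if r.group == "treated"]
        assert treated.fold_change == 4.0       # mean Ct 20, not mean fold

    def test_constant_shift_per_sample_cancels(self):
        rows = [("g", "treated", 1, 1, 20.0), ("ref", "treated", 1, 1, 18.0),
                ("g", "control", 1, 1, 22.0), ("ref", "control", 1, 1, 18.0)]
        shifted = [(g, grp, b, t, ct + (3.0 if grp == "treated" else -2.0))
                   for g, grp, b, t, ct in rows]
        a = ddct(qpcr_rows(rows), "ref", "control")
        b = ddct(qpcr_rows(shifted), "ref", "control")
        for x, y in zip(a, b):
            assert math.isclose(x.fold_change, y.fold_change)

    def test_missing_reference_rep_excluded_with_warning(self):
        rows = [("g", "treated", 1, 1, 20.0), ("ref", "treated", 1, 1, 18.0),
                ("g", "treated", 2, 1, 19.0),   # no reference for this rep
                ("g", "control", 1, 1, 22.0), ("ref", "control", 1, 1, 18.0)]
        with pytest.warns(UserWarning, match="no reference-gene Ct"):
            (treated,) = [r for r in ddct(qpcr_rows(rows), "ref", "control")
                          if r.group == "treated"]
        assert treated.n_bio == 1

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(ValueError, match="Ct"):
            ddct(qpcr_rows([("g", "c", 1, 1, -1.0)]), "g", "c")


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

class TestGroupTests:
    def test_identical_groups_share_a_letter(self):
        res = group_tests({"a": [1.0, 1.1, 0.9], "b": [1.0, 1.1, 0.9]})
        assert res.method == "t_test"
        assert res.p_value > 0.9
        assert res.letters["a"] == res.letters["b"]

    def test_separated_groups_get_distinct_letters(self):
        res = group_tests({"lo": [0.0, 0.01, -0.01], "hi": [10.0, 10.01, 9.99]})
        assert res.letters["lo"] != res.letters["hi"]

    def test_three_group_anova_with_tukey_letters(self):
        res = group_tests({"a": [1.0, 1.2, 0.8], "b": [1.1, 0.9, 1.0],
                           "c": [8.0, 8.2, 7.8]})
        assert res.method == "anova_tukey" and res.p_value < 0.01
        assert res.letters["a"] == res.letters["b"] != res.letters["c"]

    def test_degenerate_variance_flagged(self):
        res = group_tests({"a": [2.0, 2.0], "b": [2.0, 2.0]})
        assert res.flagged and res.letters == {}

    def test_cld_insertion_method(self):
        letters = compact_letter_display(
            ["a", "b", "c"], {"a": 3.0, "b": 2.0, "c": 1.0},
            significant={("a", "c")})
        # a and c must not share a letter; b overlaps both
        assert set(letters["a"]) & set(letters["c"]) == set()
        assert set(letters["b"]) & set(letters["a"])
        assert set(letters["b"]) & set(letters["c"])
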