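import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linkedlmm.transforms import (
    COVARIATE_COLUMNS,
    RAW_COLUMNS,
    InvalidPositionError,
    adjust_predictability,
    relative_location,
    scaled_logit,
    select_single_fixations,
    transform_table,
)


class TestRelativeLocation:
    @pytest.mark.parametrize(
        "char, length, expected",
        [
            (3, 5, 0.0),       # middle character of a 5-letter word
            (0, 7, -0.5),      # the space preceding the word
            (2, 3, 0.0),       # 2/4 - 1/2
            (5, 5, 5 / 6 - 0.5),
        ],
    )
    def test_anchor_points(self, char, length, expected):
        assert relative_location(char, length) == pytest.approx(expected)

    def test_out_of_word_raises(self):
        with pytest.raises(InvalidPositionError):
            relative_location(6, 5)
        with pytest.raises(InvalidPositionError):
            relative_location(-1, 5)
        with pytest.raises(InvalidPositionError):
            relative_location(1, 0)

    def test_non_strict_extends_linear_map(self):
        assert relative_location(7, 5, strict=False) == pytest.approx(7 / 6 - 0.5)

    def test_vectorized(self):
        out = relative_location([0, 3, 5], [7, 5, 5])
        assert out == pytest.approx([-0.5, 0.0, 1 / 3])


class TestPredictabilityScale:
    def test_boundary_adjustment(self):
        assert adjust_predictability(0.0, 83) == pytest.approx(1 / 166)
        assert adjust_predictability(1.0, 83) == pytest.approx(165 / 166)
        assert adjust_predictability(0.5, 83) == 0.5

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            adjust_predictability(1.2, 83)
        with pytest.raises(ValueError):
            adjust_predictability(0.5, 0)

    def test_scaled_logit_anchors(self):
        assert scaled_logit(0.5) == 0.0
        # half-logit of the adjusted zero predictability, 0.5*ln(1/165)
        assert scaled_logit(1 / 166) == pytest.approx(0.5 * np.log(1 / 165))
        assert scaled_logit(1 / 166) == pytest.approx(-2.55297, abs=5e-6)

    def test_scaled_logit_rejects_boundaries(self):
        for p in (0.0, 1.0):
            with pytest.raises(ValueError):
                scaled_logit(p)

    @given(st.floats(min_value=1e-6, max_value=1 - 1e-6))
    @settings(deadline=None, max_examples=50)
    def test_antisymmetry(self, p):
        assert scaled_logit(p) + scaled_logit(1 - p) == pytest.approx(0.0, abs=1e-9)


def _raw_frame(n=40, seed=3):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "subject": rng.integers(0, 4, n),
            "sentence": rng.integers(0, 5, n),
            "word": rng.integers(0, 30, n),
            "word_index": rng.integers(2, 6, n),
            "char_index": 0.0,
            "duration_ms": rng.uniform(80, 600, n),
            "launch_chars": rng.uniform(1, 12, n),
            "skip": rng.integers(0, 2, n),
        }
    )
    for suf in ("n", "nm1", "np1"):
        df[f"len_{suf}"] = rng.integers(2, 10, n)
        df[f"freq_{suf}"] = rng.uniform(0, 1000, n)
        df[f"pred_{suf}"] = rng.uniform(0, 1, n)
    df["char_index"] = rng.integers(0, 2, n) + 1.0
    return df


class TestTransformTable:
    def test_reference_transformations(self):
        df = _raw_frame()
        df.loc[0, "duration_ms"] = 1000.0
        df.loc[0, "launch_chars"] = 4.0
        df.loc[0, "freq_n"] = 0.0
        ft = transform_table(df)
        row = ft.data.iloc[0]
        assert row["log_dur"] == pytest.approx(np.log(1000))
        assert row["log2_launch"] == pytest.approx(2.0)
        assert row["log_freq_n"] == 0.0
        assert row["inv_len_n"] == pytest.approx(1 / row["len_n"])

    def test_centering_roundtrip_and_zero_means(self):
        ft = transform_table(_raw_frame())
        for c in COVARIATE_COLUMNS:
            centered = ft.data[f"{c}_c"]
            assert centered.mean() == pytest.approx(0.0, abs=1e-12)
            restored = centered + ft.centering[c]
            np.testing.assert_allclose(restored, ft.data[c], rtol=0, atol=1e-15)

    def test_stored_centering_applies_to_new_data(self):
        train = transform_table(_raw_frame(seed=1))
        new = transform_table(_raw_frame(seed=2), centering=train.centering)
        assert new.centering == train.centering
        # new data centered with *stored* constants need not have mean zero
        c = COVARIATE_COLUMNS[0]
        np.testing.assert_allclose(new.data[f"{c}_c"],
                                   new.data[c] - train.centering[c])

    def test_monotonicity_of_transforms(self):
        # each transformation is strictly monotone on its domain
        d = np.array([50.0, 100.0, 400.0])
        assert np.all(np.diff(np.log(d)) > 0)
        ell = np.array([2.0, 5.0, 9.0])
        assert np.all(np.diff(1.0 / ell) < 0)
        ft1 = transform_table(_raw_frame())
        order = np.argsort(ft1.data["freq_n"].to_numpy())
        assert np.all(np.diff(ft1.data["log_freq_n"].to_numpy()[order]) >= 0)

    def test_row_level_validation(self):
        df = _raw_frame()
        df.loc[5, "duration_ms"] = -3.0
        with pytest.raises(ValueError, match="duration_ms"):
            transform_table(df)

    def test_missing_column_and_dropped_rows(self):
        df = _raw_frame()
        with pytest.raises(ValueError, match="pred_np1"):
            transform_table(df.drop(columns=["pred_np1"]))
        df2 = _raw_frame()
        df2.loc[3, "freq_n"] = np.nan
        ft = transform_table(df2)
        assert ft.n_dropped == 1
        assert len(ft.data) == len(df2) - 1


def brute_force_flags(words):
    """Rule-by-rule literal checker, independent of the implementation."""
    n = len(words)
    qualifies, skip = [], []
    for i in range(n):
        w = words[i]
        # run containing i
        s = i
        while s > 0 and words[s - 1] == w:
            s -= 1
        e = i
        while e + 1 < n and words[e + 1] == w:
            e += 1
        first_pass = all(words[j] < w for j in range(s))
        single = first_pass and (e == s)
        fwd = 0 < i < n - 1 and words[i - 1] < w < words[i + 1]
        qualifies.append(first_pass and single and fwd)
        skip.append(int(fwd and words[i - 1] < w - 1))
    return qualifies, skip


class TestSingleFixationSelection:
    def test_worked_trace(self):
        out = select_single_fixations([1, 2, 2, 4, 5, 3, 6])
        assert out["qualifies"].tolist() == [False, False, False, True,
                                             False, False, False]
        assert out.loc[3, "skip"] == 1  # launched from word 2, skipping word 3

    def test_simple_forward_reading(self):
        out = select_single_fixations([1, 2, 3])
        assert out["qualifies"].tolist() == [False, True, False]
        assert out.loc[1, "skip"] == 0

    def test_skipping_label(self):
        out = select_single_fixations([1, 3, 4])
        assert out["qualifies"].tolist() == [False, True, False]
        assert out.loc[1, "skip"] == 1

    def test_empty_sequence(self):
        out = select_single_fixations([])
        assert len(out) == 0

    def test_trial_boundaries_never_qualify(self):
        out = select_single_fixations([2, 5])
        assert not out["qualifies"].any()

    @given(st.lists(st.integers(min_value=1, max_value=6), min_size=1,
                    max_size=10))
    @settings(deadline=None, max_examples=200)
    def test_agrees_with_brute_force(self, words):
        out = select_single_fixations(words)
        q, s = brute_force_flags(words)
        assert out["qualifies"].tolist() == q
        sel = out["qualifies"].to_numpy()
        assert out.loc[sel, "skip"].tolist() == [s[i] for i in range(len(words))
                                                 if q[i]]
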