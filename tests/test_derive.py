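"""Signature derivation: raw filter, ANOVA, BH adjustment, fold changes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from sigscore.containers import ExpressionMatrix, SampleGroups
from sigscore.derive import (
    bh_adjust,
    derive_signature,
    fold_changes,
    one_way_anova,
    raw_intensity_filter,
)
from sigscore.errors import ValidationError
from sigscore.simulate import simulate_two_group


def _matrix(rows: dict, samples, scale="log2"):
    return ExpressionMatrix(
        pd.DataFrame(rows, index=samples).T, scale=scale, feature_level="gene"
    )


def _groups(n_a, n_b):
    samples = [f"A{i}" for i in range(n_a)] + [f"B{i}" for i in range(n_b)]
    return (
        samples,
        SampleGroups(
            {s: ("A" if s.startswith("A") else "B") for s in samples}, reference_group="A"
        ),
    )


def bh_oracle(p):
    """Literal step-up definition: q_i = min over {j : p_(j) >= p_i} of min(1, m p_(j)/j)."""
    p = list(p)
    m = len(p)
    p_sorted = sorted(p)
    out = []
    for pi in p:
        candidates = [
            min(1.0, m * pj / j) for j, pj in enumerate(p_sorted, start=1) if pj >= pi
        ]
        out.append(min(candidates))
    return out


def anova_oracle(groups_values):
    """Brute-force one-way ANOVA from sums of squares and the F distribution."""
    all_vals = np.concatenate(groups_values)
    grand = all_vals.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups_values)
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups_values)
    dfb = len(groups_values) - 1
    dfw = len(all_vals) - len(groups_values)
    F = (ssb / dfb) / (ssw / dfw)
    return F, stats.f.sf(F, dfb, dfw)


class TestRawFilter:
    def test_feature_below_floor_dropped(self):
        samples, _ = _groups(2, 2)
        m = _matrix({"LOW": [10, 10, 10, 10], "OK": [60, 80, 100, 90]}, samples, "raw_linear")
        out = raw_intensity_filter(m, 50.0, 35272.484)
        assert out.feature_ids == ["OK"]

    def test_max_in_detection_window_retained(self):
        samples, _ = _groups(2, 2)
        m = _matrix({"G": [10, 20, 100, 30]}, samples, "raw_linear")
        assert raw_intensity_filter(m, 50.0, 35272.484).feature_ids == ["G"]

    def test_permissive_bounds_are_identity(self):
        samples, _ = _groups(2, 2)
        m = _matrix({"G": [1, 2, 3, 4], "H": [5, 6, 7, 8]}, samples, "raw_linear")
        assert raw_intensity_filter(m, 0.0, np.inf).feature_ids == ["G", "H"]

    def test_log2_input_rejected(self, tiny_log2_matrix):
        with pytest.raises(ValidationError, match="raw_linear"):
            raw_intensity_filter(tiny_log2_matrix, 50.0, 35272.484)


class TestAnova:
    def test_two_group_example_against_oracle(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        F_exp, p_exp = anova_oracle([a, b])
        samples, groups = _groups(3, 3)
        res = one_way_anova(_matrix({"G": a + b}, samples), groups)
        assert res.loc["G", "F"] == pytest.approx(F_exp, rel=1e-12)
        assert res.loc["G", "p"] == pytest.approx(p_exp, rel=1e-12)
        assert F_exp == pytest.approx(1.5, rel=1e-12)
        assert p_exp == pytest.approx(0.2879, abs=5e-4)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(0)
        samples = [f"A{i}" for i in range(3)] + [f"B{i}" for i in range(4)] + [
            f"C{i}" for i in range(3)
        ]
        groups = SampleGroups({s: s[0] for s in samples}, reference_group="A")
        vals = rng.normal(size=(20, 10))
        m = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"G{i}" for i in range(20)], columns=samples),
            scale="log2",
            feature_level="gene",
        )
        res = one_way_anova(m, groups)
        F_ref, p_ref = stats.f_oneway(vals[:, :3], vals[:, 3:7], vals[:, 7:], axis=1)
        np.testing.assert_allclose(res["F"], F_ref, rtol=1e-10)
        np.testing.assert_allclose(res["p"], p_ref, rtol=1e-10)

    def test_f_equals_t_squared_for_two_groups(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=4), rng.normal(size=5)
        samples, groups = _groups(4, 5)
        res = one_way_anova(_matrix({"G": np.concatenate([a, b])}, samples), groups)
        t, p = stats.ttest_ind(a, b, equal_var=True)
        assert res.loc["G", "F"] == pytest.approx(t**2, rel=1e-12)
        assert res.loc["G", "p"] == pytest.approx(p, abs=1e-12)

    def test_degenerate_conventions(self):
        samples, groups = _groups(3, 3)
        m = _matrix(
            {"SAME": [5.0] * 6, "SHIFT": [1.0, 1.0, 1.0, 2.0, 2.0, 2.0]}, samples
        )
        res = one_way_anova(m, groups)
        assert res.loc["SAME", "p"] == 1.0
        assert res.loc["SHIFT", "p"] == 0.0

    def test_requires_two_per_group(self):
        samples = ["A0", "A1", "B0"]
        groups = SampleGroups({s: s[0] for s in samples}, reference_group="A")
        with pytest.raises(ValidationError):
            one_way_anova(_matrix({"G": [1, 2, 3]}, samples), groups)


class TestBH:
    def test_worked_example_and_oracle(self):
        p = [0.01, 0.02, 0.03, 0.04]
        q = bh_adjust(p)
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)
        np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)

    def test_single_p_is_identity(self):
        np.testing.assert_allclose(bh_adjust([0.05]), [0.05])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_matches_oracle_and_invariants(self, p):
        q = bh_adjust(p)
        np.testing.assert_allclose(q, bh_oracle(p), atol=1e-12)
        assert (q >= np.asarray(p) - 1e-15).all()  # q >= p pointwise
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()  # monotone in p

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestFoldChanges:
    def test_log_mean_examples(self, two_groups):
        samples = list(two_groups.assignment)
        m = _matrix(
            {
                "UP": [4, 4, 4, 6, 6, 6],
                "DOWN": [6, 6, 6, 4, 4, 4],
                "FLAT": [5, 5, 5, 5, 5, 5],
            },
            samples,
        )
        fc = fold_changes(m, two_groups)
        assert fc.loc["UP", "fc_linear"] == pytest.approx(4.0)
        assert fc.loc["UP", "direction"] == "up"
        assert fc.loc["DOWN", "fc_linear"] == pytest.approx(0.25)
        assert fc.loc["DOWN", "direction"] == "down"
        assert fc.loc["FLAT", "fc_linear"] == pytest.approx(1.0)
        assert fc.loc["FLAT", "direction"] == "flat"

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(0.0, 16.0), min_size=3, max_size=3),
        st.lists(st.floats(0.0, 16.0), min_size=3, max_size=3),
    )
    def test_reciprocal_symmetry_under_group_swap(self, a, b):
        samples = [f"A{i}" for i in range(3)] + [f"B{i}" for i in range(3)]
        m = _matrix({"G": a + b}, samples)
        g_ab = SampleGroups({s: s[0] for s in samples}, reference_group="A")
        g_ba = SampleGroups({s: s[0] for s in samples}, reference_group="B")
        fc1 = fold_changes(m, g_ab).loc["G", "fc_linear"]
        fc2 = fold_changes(m, g_ba).loc["G", "fc_linear"]
        assert fc1 * fc2 == pytest.approx(1.0, rel=1e-9)


class TestDeriveSignature:
    def test_recovers_planted_signature(self):
        m, groups, truth = simulate_two_group(
            1000, 3, 50, 50, effect_log2=2.0, noise_sd=0.25, seed=1
        )
        sig, de = derive_signature(m, groups)
        called = set(sig.induced) | set(sig.repressed)
        tp = len(set(sig.induced) & truth.de_up) + len(set(sig.repressed) & truth.de_down)
        assert tp / 100 >= 0.95
        assert (len(called) - tp) / max(len(called), 1) <= 0.10
        # audit table covers every gene and q >= p pointwise
        assert len(de) == 1000
        assert (de["q_bh"] >= de["p_anova"] - 1e-15).all()

    def test_null_simulation_calls_stay_near_nominal(self):
        import warnings

        counts = []
        for seed in range(20):
            m, groups, _ = simulate_two_group(200, 3, 0, 0, 0.0, 0.3, seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)  # empty halves expected
                sig, de = derive_signature(m, groups)
            counts.append(int(de["induced"].sum() + de["repressed"].sum()))
        assert np.mean(counts) <= 0.05 * 200

    def test_infinite_fc_cutoff_empties_signature(self, tiny_log2_matrix, two_groups):
        with pytest.warns(UserWarning):
            sig, _ = derive_signature(tiny_log2_matrix, two_groups, fc_cutoff=np.inf)
        assert sig.induced == [] and sig.repressed == []

    def test_invariant_to_row_and_column_order(self):
        m, groups, _ = simulate_two_group(100, 3, 10, 10, 2.0, 0.25, seed=5)
        sig1, _ = derive_signature(m, groups)
        shuffled = ExpressionMatrix(
            m.values.iloc[::-1][list(reversed(m.sample_ids))],
            scale="log2",
            feature_level="gene",
        )
        sig2, _ = derive_signature(shuffled, groups)
        assert sig1.induced == sig2.induced and sig1.repressed == sig2.repressed

    def test_swapping_groups_swaps_halves(self):
        m, groups, _ = simulate_two_group(100, 3, 10, 10, 2.0, 0.25, seed=5)
        swapped = SampleGroups(dict(groups.assignment), reference_group="TREATED")
        sig1, _ = derive_signature(m, groups)
        sig2, _ = derive_signature(m, swapped)
        assert set(sig1.induced) == set(sig2.repressed)
        assert set(sig1.repressed) == set(sig2.induced)

    @pytest.mark.filterwarnings("ignore::UserWarning")  # strict cutoff may empty a half
    def test_calls_nested_across_cutoffs(self):
        m, groups, _ = simulate_two_group(300, 3, 20, 20, 1.0, 0.4, seed=8)
        strict, _ = derive_signature(m, groups, q_cutoff=0.01)
        loose, _ = derive_signature(m, groups, q_cutoff=0.2)
        assert set(strict.induced) <= set(loose.induced)
        assert set(strict.repressed) <= set(loose.repressed)

    def test_raw_filter_restricts_candidates(self):
        samples = [f"A{i}" for i in range(3)] + [f"B{i}" for i in range(3)]
        groups = SampleGroups({s: s[0] for s in samples}, reference_group="A")
        log2 = _matrix(
            {"KEEP": [4, 4, 4, 8, 8, 8], "DIM": [4, 4, 4, 8, 8, 8]}, samples
        )
        raw = _matrix({"KEEP": [100] * 6, "DIM": [10] * 6}, samples, "raw_linear")
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # one-gene input, halves may be empty
            sig, de = derive_signature(log2, groups, raw=raw)
        assert "DIM" not in de.index and "KEEP" in de.index

    def test_invalid_cutoffs_rejected(self, tiny_log2_matrix, two_groups):
        with pytest.raises(ValidationError):
            derive_signature(tiny_log2_matrix, two_groups, q_cutoff=-1)
        with pytest.raises(ValidationError):
            derive_signature(tiny_log2_matrix, two_groups, fc_cutoff=0.5)
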