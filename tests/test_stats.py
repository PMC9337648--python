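import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from thyrus.stats import (
    bland_altman,
    interobserver_table,
    intraobserver_variability,
    paired_t_test,
    reference_comparison,
    split_groups,
)


class TestIntraobserver:
    def test_identical_repeats_zero_cv(self):
        mean, sd, per = intraobserver_variability({1: [10.0, 10.0, 10.0]})
        assert mean == 0.0 and per[1] == 0.0

    def test_known_cv(self):
        mean, _, per = intraobserver_variability({1: [9.0, 10.0, 11.0]})
        assert per[1] == pytest.approx(10.0)  # sample SD 1.0 on mean 10

    def test_scale_invariance(self):
        base = {1: [8.0, 9.5, 10.0], 2: [4.0, 5.0, 4.4]}
        scaled = {k: [7.3 * x for x in v] for k, v in base.items()}
        m1, s1, _ = intraobserver_variability(base)
        m2, s2, _ = intraobserver_variability(scaled)
        assert m1 == pytest.approx(m2) and s1 == pytest.approx(s2)

    def test_single_repeat_rejected(self):
        with pytest.raises(ValueError):
            intraobserver_variability({1: [10.0]})


class TestBlandAltman:
    def test_identical_series(self):
        r = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.mean_diff == 0.0 and r.sd_diff == 0.0
        assert r.loa_low == 0.0 and r.loa_high == 0.0

    def test_closed_form_two_pairs(self):
        r = bland_altman([1.0, 0.0], [0.0, 1.0])  # diffs {1, −1}
        assert r.mean_diff == pytest.approx(0.0)
        assert r.sd_diff == pytest.approx(np.sqrt(2.0), abs=1e-12)
        assert r.loa_high == pytest.approx(1.96 * np.sqrt(2.0), abs=1e-9)

    def test_loa_width_invariant(self):
        rng = np.random.default_rng(0)
        a, b = rng.random(20), rng.random(20)
        r = bland_altman(a, b)
        assert r.loa_high - r.loa_low == pytest.approx(2 * 1.96 * r.sd_diff, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_antisymmetry_and_textbook_formula(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 30))
        a, b = rng.normal(size=n), rng.normal(size=n)
        r = bland_altman(a, b)
        s = bland_altman(b, a)
        assert r.mean_diff == pytest.approx(-s.mean_diff, abs=1e-9)
        assert r.loa_low == pytest.approx(-s.loa_high, abs=1e-9)
        d = a - b
        assert r.mean_diff == pytest.approx(d.mean(), abs=1e-9)
        assert r.sd_diff == pytest.approx(d.std(ddof=1), abs=1e-9)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])


class TestPairedT:
    def test_closed_form_example(self):
        r = paired_t_test([1.0, 2.0, 3.0], [2.0, 4.0, 6.0])
        assert r.t == pytest.approx(-3.4641, abs=1e-4)
        assert r.df == 2
        assert r.p == pytest.approx(0.0742, abs=2e-4)

    def test_degenerate_constant_offset_flagged(self):
        a = np.arange(30.0)
        r = paired_t_test(a + 0.5, a)
        assert r.degenerate and r.p == 0.0 and not r.significant

    def test_degenerate_identical_series(self):
        a = np.arange(10.0)
        r = paired_t_test(a, a)
        assert r.degenerate and r.p == 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_scipy_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        a = rng.normal(size=n)
        b = rng.normal(size=n)
        r = paired_t_test(a, b)
        ref = sps.ttest_rel(a, b)
        assert r.t == pytest.approx(ref.statistic, abs=1e-9)
        assert r.p == pytest.approx(ref.pvalue, abs=1e-9)
        assert paired_t_test(b, a).p == pytest.approx(r.p, abs=1e-12)

    def test_null_rejection_rate_is_alpha(self):
        """Simulated null (no bias, equal noise): rejection rate ≈ 5%
        within Monte-Carlo error over 2000 replicates."""
        rng = np.random.default_rng(123)
        n, reps = 28, 2000
        rejections = 0
        for _ in range(reps):
            ref = rng.normal(7.4, 3.0, size=n)
            a = ref + rng.normal(0, 0.4, size=n)
            b = ref + rng.normal(0, 0.4, size=n)
            if paired_t_test(a, b).p < 0.05:
                rejections += 1
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3.5 * se


def _toy_study():
    rows = []
    rng = np.random.default_rng(0)
    ref = {v: 6.0 + v for v in range(1, 9)}
    for v in range(1, 9):
        for io, obs in enumerate(["MD1", "MD2", "MD3"]):
            for rep in (1, 2):
                bias = [0.0, -0.1, 1.0][io]
                rows.append({"volunteer": v, "observer": obs, "repeat": rep,
                             "modality": "2D",
                             "volume_ml": ref[v] + bias + rng.normal(0, 0.2),
                             "reference_ml": ref[v]})
    return pd.DataFrame(rows)


class TestTables:
    def test_three_observers_give_three_pairs(self):
        t = interobserver_table(_toy_study(), "2D")
        assert list(t["pair"]) == ["1/2", "1/3", "2/3"]

    def test_identical_observers_zero_differences(self):
        df = _toy_study()
        wide = df[df["observer"] == "MD1"]
        clones = []
        for obs in ("MD1", "MD2", "MD3"):
            c = wide.copy()
            c["observer"] = obs
            clones.append(c)
        t = interobserver_table(pd.concat(clones), "2D")
        assert np.allclose(t["mean_diff_ml"], 0.0)

    def test_biased_observer_pair_has_larger_mean_difference(self):
        t = interobserver_table(_toy_study(), "2D").set_index("pair")
        assert abs(t.loc["2/3", "mean_diff_ml"]) > abs(t.loc["1/2", "mean_diff_ml"])

    def test_reference_comparison_detects_systematic_scaling(self):
        df = _toy_study()
        df["volume_ml"] = df["reference_ml"] * 1.2
        t = reference_comparison(df, "2D")
        assert t["significant"].all()

    def test_reference_comparison_null_mostly_non_significant(self):
        """Estimates = reference + small unbiased noise: non-significant in
        ~95% of seeded replicates (α = 0.05), within Monte-Carlo error."""
        hits = 0
        reps = 200
        for seed in range(reps):
            rng = np.random.default_rng(seed)
            rows = []
            for v in range(1, 29):
                ref = rng.normal(7.4, 3.0)
                rows.append({"volunteer": v, "observer": "MD1", "repeat": 1,
                             "modality": "3D", "volume_ml": ref + rng.normal(0, 0.1),
                             "reference_ml": ref})
            t = reference_comparison(pd.DataFrame(rows), "3D")
            if not t["significant"].iloc[0]:
                hits += 1
        se = np.sqrt(0.05 * 0.95 / reps)
        assert hits / reps >= 0.95 - 3.5 * se

    def test_estimates_equal_reference_degenerate(self):
        df = _toy_study()
        df["volume_ml"] = df["reference_ml"]
        t = reference_comparison(df, "2D")
        assert t["degenerate"].all()
        assert not t["significant"].any()


class TestSplitGroups:
    def test_empty_training_ids(self):
        df = _toy_study()
        g1, g2 = split_groups(df, [])
        assert g1.empty and len(g2) == len(df)

    def test_partition_complete(self):
        df = _toy_study()
        g1, g2 = split_groups(df, [1, 2, 3])
        assert len(g1) + len(g2) == len(df)
        assert set(g1["volunteer"]) == {1, 2, 3}

    def test_clinical_design_split_sizes(self):
        rows = [{"volunteer": v, "observer": "MD1", "repeat": 1, "modality": "3D",
                 "volume_ml": 7.0, "reference_ml": 7.0} for v in range(1, 29)]
        df = pd.DataFrame(rows)
        g1, g2 = split_groups(df, list(range(1, 16)))
        assert g1["volunteer"].nunique() == 15
        assert g2["volunteer"].nunique() == 13

    def test_unknown_id_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            split_groups(_toy_study(), [99])
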