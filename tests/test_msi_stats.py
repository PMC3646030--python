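"""PI/PD index, classification, KS and t tests against independent oracles."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from msiseq import (
    ConfigError,
    MSIResult,
    SampleProfile,
    classify,
    cohort_report,
    group_compare,
    ks_length_test,
    msi_index,
)
from msiseq.msi_stats import INDETERMINATE, MSI, MSS, read_report, write_report


def profile(n_ins=10, ins_ms=4, n_del=20, del_ms=10, sample_id="s"):
    return SampleProfile(
        sample_id=sample_id,
        n_ins_total=n_ins,
        n_ins_ms=ins_ms,
        n_del_total=n_del,
        n_del_ms=del_ms,
        del_lengths_ms=[1] * del_ms,
        ins_lengths_ms=[1] * ins_ms,
    )


class TestIndex:
    def test_ratio_of_proportions(self):
        res = msi_index(profile(n_ins=10, ins_ms=4, n_del=20, del_ms=10))
        assert res.pi == 0.4 and res.pd == 0.5 and res.index == pytest.approx(0.8)

    def test_equal_proportions_give_unit_index(self):
        res = msi_index(profile(n_ins=50, ins_ms=10, n_del=100, del_ms=20))
        assert res.index == pytest.approx(1.0)

    def test_zero_denominators_flagged_not_crashed(self):
        res = msi_index(profile(n_ins=0, ins_ms=0))
        assert res.pi is None and res.index is None
        res = msi_index(profile(n_del=0, del_ms=0))
        assert res.pd is None and res.index is None

    def test_zero_ms_deletions_leaves_index_undefined(self):
        res = classify(msi_index(profile(n_del=30, del_ms=0)), min_ins=5, min_del=5)
        assert res.pd == 0.0 and res.index is None and res.label == INDETERMINATE

    def test_pseudocount_rescues_zero_counts(self):
        res = msi_index(profile(n_ins=0, ins_ms=0), pseudocount=1.0)
        assert res.pi == pytest.approx(1.0)  # (0+1)/(0+1)

    def test_scale_invariance(self):
        base = msi_index(profile(10, 4, 20, 10)).index
        scaled = msi_index(profile(30, 12, 60, 30)).index
        assert scaled == pytest.approx(base)

    def test_monotone_in_ms_deletions(self):
        idx = [
            msi_index(profile(100, 30, 100, d)).index for d in range(10, 90, 10)
        ]
        assert all(a > b for a, b in zip(idx, idx[1:]))


def test_tract_numerators_deduplicate_repeat_hits():
    from msiseq import Microsatellite, annotate, compute_profile
    from msiseq.annotator import TranscriptModel
    from msiseq.indel_model import DELETION, IndelCall

    tract = Microsatellite("T1", 10, 20, "A", 10.0)
    calls = [
        IndelCall("T1", DELETION, (11, 12), "A"),
        IndelCall("T1", DELETION, (12, 13), "A"),
        IndelCall("T1", DELETION, (40, 41), "C"),
    ]
    ann = annotate(calls, [tract], {"T1": TranscriptModel("T1", length=100)})
    prof = compute_profile(ann, "s")
    assert prof.n_del_ms == 2 and prof.n_del_ms_tracts == 1
    assert msi_index(prof).pd == pytest.approx(2 / 3)
    assert msi_index(prof, tract_numerators=True).pd == pytest.approx(1 / 3)


class TestClassify:
    def test_threshold_rule(self):
        res = MSIResult("s", pi=0.4, pd=0.5, index=0.8, n_ins_total=100, n_del_total=100)
        assert classify(res, threshold=0.9).label == MSI
        res = MSIResult("s", pi=0.6, pd=0.5, index=1.2, n_ins_total=100, n_del_total=100)
        assert classify(res, threshold=0.9).label == MSS

    def test_low_counts_indeterminate(self):
        res = MSIResult("s", pi=0.4, pd=0.5, index=0.8, n_ins_total=5, n_del_total=100)
        assert classify(res, min_ins=20).label == INDETERMINATE

    def test_invalid_threshold(self):
        res = MSIResult("s", pi=0.4, pd=0.5, index=0.8)
        with pytest.raises(ConfigError):
            classify(res, threshold=0.0)

    def test_threshold_monotone_never_flips_msi_to_mss(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            idx = float(rng.uniform(0.2, 2.0))
            res = MSIResult("s", pi=idx, pd=1.0, index=idx,
                            n_ins_total=100, n_del_total=100)
            labels = [classify(res, threshold=t).label for t in (0.5, 0.9, 1.0, 1.5)]
            # once MSI under a low threshold, higher thresholds keep it MSI
            first_msi = next((i for i, l in enumerate(labels) if l == MSI), None)
            if first_msi is not None:
                assert all(l == MSI for l in labels[first_msi:])


def ks_oracle(a, b):
    """Max empirical-CDF gap over the union support, by direct enumeration."""
    a, b = sorted(a), sorted(b)
    support = sorted(set(a) | set(b))
    gap = 0.0
    for x in support:
        fa = sum(v <= x for v in a) / len(a)
        fb = sum(v <= x for v in b) / len(b)
        gap = max(gap, abs(fa - fb))
    return gap


class TestKS:
    def test_identical_multisets(self):
        d, p = ks_length_test([1, 1, 2, 5], [1, 1, 2, 5])
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _ = ks_length_test([1] * 100, [5] * 100)
        assert d == 1.0

    def test_statistic_matches_enumeration_oracle(self):
        rng = np.random.default_rng(9)
        cases = [([1, 1, 2, 3], [1, 2, 2, 3])]
        for _ in range(40):
            na, nb = int(rng.integers(1, 50)), int(rng.integers(1, 50))
            cases.append(
                (rng.integers(1, 8, size=na).tolist(), rng.integers(1, 8, size=nb).tolist())
            )
        for a, b in cases:
            d, p = ks_length_test(a, b)
            assert d == pytest.approx(ks_oracle(a, b), abs=1e-12)
            assert 0.0 < p <= 1.0
            d2, _ = ks_length_test(b, a)
            assert d2 == pytest.approx(d)  # symmetry in D

    def test_empty_side_flagged_undefined(self):
        out = ks_length_test([], [1, 2])
        assert math.isnan(out.statistic) and not out.defined


class TestGroupCompare:
    def test_identical_groups(self):
        out = group_compare([1, 2, 3], [1, 2, 3])
        assert out.statistic == 0.0 and out.pvalue == pytest.approx(1.0)

    def test_paired_zero_differences_degenerate(self):
        out = group_compare([1, 2, 3], [1, 2, 3], paired=True)
        assert out.degenerate

    def test_pooled_variance_closed_form(self):
        # textbook hand computation: means 0.5 vs 10.5, pooled s^2 = 1/3,
        # se = sqrt(s2 * (1/4 + 1/4)) = sqrt(1/6), t = -10 / se, df = 6
        a, b = [0, 0, 1, 1], [10, 10, 11, 11]
        t_hand = -10.0 / math.sqrt(1.0 / 6.0)
        p_hand = 2 * sps.t.sf(abs(t_hand), df=6)
        out = group_compare(a, b)
        assert out.statistic == pytest.approx(t_hand)
        assert out.pvalue == pytest.approx(p_hand)

    def test_paired_matches_differences_t(self):
        a, b = [1.0, 2.0, 3.0, 5.0], [0.5, 2.5, 2.0, 4.0]
        d = np.array(a) - np.array(b)
        t_hand = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
        out = group_compare(a, b, paired=True)
        assert out.statistic == pytest.approx(t_hand)

    def test_size_checks(self):
        with pytest.raises(ConfigError):
            group_compare([1], [1, 2])
        with pytest.raises(ConfigError):
            group_compare([1, 2, 3], [1, 2], paired=True)


class TestCohortReport:
    def make_inputs(self):
        profs = {
            "a": profile(100, 30, 100, 40, sample_id="a"),
            "b": profile(100, 25, 100, 30, sample_id="b"),
        }
        results = [
            classify(msi_index(p)) for p in profs.values()
        ]
        return results, profs

    def test_one_row_per_sample_and_round_trip(self, tmp_path):
        results, profs = self.make_inputs()
        controls = [profile(80, 20, 80, 25, sample_id=f"c{i}") for i in range(3)]
        df = cohort_report(results, profs, controls)
        assert list(df["sample_id"]) == ["a", "b"]
        assert df.loc[0, "index"] == pytest.approx(0.75)
        write_report(df, tmp_path / "r.tsv", tmp_path / "r.json")
        back = read_report(tmp_path / "r.tsv")
        for col in ("PI", "PD", "index", "ks_del_p"):
            assert back[col].tolist() == pytest.approx(df[col].tolist(), nan_ok=True)

    def test_without_controls_ks_columns_empty(self):
        results, profs = self.make_inputs()
        df = cohort_report(results, profs, None)
        assert df["ks_del_p"].isna().all() and df["ks_ins_p"].isna().all()
        assert df["PI"].notna().all()
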