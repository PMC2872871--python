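import subprocess
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from congenic.diffexpr import (
    average_regions,
    bh_fdr,
    detection_filter,
    differential_test,
    relative_difference,
    signed_fold_change,
    summarize_counts,
    to_log2,
)
from congenic.errors import ConfigurationError, ValidationError
from congenic.expression import COMBINED

sys.path.insert(0, str(Path(__file__).parent))
from conftest import make_matrix
from oracles import bh_stepup, count_summary_recount, pooled_t_pvalue

GROUPS_4V4 = ["ip"] * 4 + ["inp"] * 4
GROUPS_8V8 = ["ip"] * 8 + ["inp"] * 8


# ----------------------------------------------------------------------
# Detection filter
# ----------------------------------------------------------------------

class TestDetectionFilter:
    def test_fraction_thresholds_8v8(self):
        det = np.zeros((3, 16), dtype=bool)
        det[0, :3] = True          # 3/8 in the iP group only: 0.375 >= 1/3
        det[1, [0, 1, 8, 9]] = True  # 2/8 in each group: 0.25 < 1/3
        det[2, :] = True           # everywhere
        m = make_matrix(np.zeros((3, 16)), GROUPS_8V8, detection=det)
        kept = detection_filter(m, scope="region")
        assert kept == ["ps000", "ps002"]

    def test_exact_boundary_counts(self):
        # 2 of 6 arrays is exactly one third and must be retained
        det = np.zeros((1, 12), dtype=bool)
        det[0, :2] = True
        m = make_matrix(np.zeros((1, 12)), ["ip"] * 6 + ["inp"] * 6, detection=det)
        assert detection_filter(m, scope="region") == ["ps000"]

    def test_combined_scope_any_region_any_group(self, five_regions):
        # present in a single (region, group) cell at 3/8 -> retained combined
        vals = np.zeros((2, 16, 5))
        det = np.zeros((2, 16, 5), dtype=bool)
        det[0, 8:11, 2] = True  # iNP group, one region, 3 of 8 animals
        m = make_matrix(vals, GROUPS_8V8, regions=five_regions, detection=det)
        assert detection_filter(m, scope="combined") == ["ps000"]

    def test_requires_detection(self):
        m = make_matrix(np.zeros((2, 8)), GROUPS_4V4)
        with pytest.raises(ConfigurationError):
            detection_filter(m, scope="region")

    def test_region_scope_rejects_multi_region_matrix(self, five_regions):
        m = make_matrix(
            np.zeros((1, 4, 5)), ["ip", "ip", "inp", "inp"], regions=five_regions,
            detection=np.ones((1, 4, 5), dtype=bool),
        )
        with pytest.raises(ValidationError):
            detection_filter(m, scope="region")


# ----------------------------------------------------------------------
# Region averaging
# ----------------------------------------------------------------------

class TestAverageRegions:
    def test_mean_of_regions(self, five_regions):
        vals = np.zeros((1, 2, 5))
        vals[0, 0] = [1, 2, 3, 4, 5]
        vals[0, 1] = 7.0
        m = make_matrix(vals, ["ip", "inp"], regions=five_regions)
        avg = average_regions(m)
        assert avg.values.shape == (1, 2)
        np.testing.assert_allclose(sorted(avg.values.iloc[0]), [3.0, 7.0])
        assert set(avg.samples["region"]) == {COMBINED}

    def test_shape_contract_16_animals(self, five_regions, rng):
        m = make_matrix(rng.normal(size=(4, 16, 5)), GROUPS_8V8, regions=five_regions)
        avg = average_regions(m)
        assert avg.values.shape == (4, 16)
        assert avg.samples["animal_id"].nunique() == 16

    def test_missing_region_names_animal(self, five_regions):
        m = make_matrix(np.zeros((1, 2, 5)), ["ip", "inp"], regions=five_regions)
        sub_cols = [c for c in m.sample_ids if not c.endswith("hippocampus") or "an00" not in c]
        m2 = make_matrix(np.zeros((1, 2, 5)), ["ip", "inp"], regions=five_regions)
        trimmed = m2.values[sub_cols]
        from congenic.expression import ExpressionMatrix

        m3 = ExpressionMatrix(trimmed, m2.samples.loc[sub_cols])
        with pytest.raises(ValidationError, match="an00.*hippocampus"):
            average_regions(m3)


# ----------------------------------------------------------------------
# Two-group tests
# ----------------------------------------------------------------------

class TestDifferentialTest:
    # fixed values for the brute-force check
    A = [8.1, 8.4, 7.9, 8.6]
    B = [7.2, 7.8, 7.5, 7.1]

    def test_student_matches_brute_force(self):
        m = make_matrix(np.array([self.A + self.B]), GROUPS_4V4)
        res = differential_test(m, method="student")
        t0, df0, p0 = pooled_t_pvalue(self.A, self.B)
        row = res.iloc[0]
        assert row["log2_diff"] == pytest.approx(np.mean(self.A) - np.mean(self.B))
        assert row["t"] == pytest.approx(t0)
        assert row["df"] == df0
        assert row["p"] == pytest.approx(p0, rel=1e-12)

    def test_orientation_is_ip_minus_inp(self):
        m = make_matrix(
            np.array([[2.0, 2.1, 1.9, 2.0, 1.0, 1.1, 0.9, 1.0]]), GROUPS_4V4
        )
        res = differential_test(m, method="welch")
        assert res["log2_diff"].iloc[0] == pytest.approx(1.0)
        assert res["signed_fc"].iloc[0] == pytest.approx(2.0)

    def test_welch_matches_scipy(self, rng):
        vals = rng.normal(8, 1, size=(20, 16))
        m = make_matrix(vals, GROUPS_8V8)
        res = differential_test(m, method="welch")
        t, p = stats.ttest_ind(vals[:, :8], vals[:, 8:], axis=1, equal_var=False)
        np.testing.assert_allclose(res["t"], t)
        np.testing.assert_allclose(res["p"], p)

    def test_equal_means_give_p_near_one(self):
        a = [1.0, 2.0, 3.0, 4.0]
        m = make_matrix(np.array([a + a]), GROUPS_4V4)
        res = differential_test(m, method="student")
        assert res["log2_diff"].iloc[0] == 0
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_degenerate_constant_groups(self):
        m = make_matrix(np.array([[5.0] * 8]), GROUPS_4V4)
        for method in ("student", "welch", "moderated"):
            res = differential_test(m, method=method)
            assert res["p"].iloc[0] == 1.0 and res["t"].iloc[0] == 0.0

    def test_constant_unequal_welch_rejected_student_defined(self):
        m = make_matrix(np.array([[5.0] * 4 + [4.0] * 4]), GROUPS_4V4)
        with pytest.raises(ValidationError):
            differential_test(m, method="welch")
        res = differential_test(m, method="student")
        assert res["p"].iloc[0] == 0.0

    def test_small_group_rejected(self):
        m = make_matrix(np.zeros((1, 3)), ["ip", "inp", "inp"])
        with pytest.raises(ValidationError):
            differential_test(m, method="student")

    def test_moderated_equal_variances_reduces_to_student(self, rng):
        # every probe set has identical sample variance -> no finite prior df
        base = rng.normal(size=8)
        shifts = rng.normal(size=(30, 1))
        m = make_matrix(base[None, :] + shifts, GROUPS_4V4)
        res_mod = differential_test(m, method="moderated")
        res_stu = differential_test(m, method="student")
        np.testing.assert_allclose(res_mod["p"], res_stu["p"])
        np.testing.assert_allclose(res_mod["df"], res_stu["df"])

    def test_moderated_matches_limma_oracle(self, rng, tmp_path):
        """Cross-check shrinkage against the reference empirical-Bayes fit."""
        vals = rng.normal(8, 1, size=(60, 8)) * rng.uniform(0.5, 2.0, size=(60, 1))
        m = make_matrix(vals, GROUPS_4V4)
        res = differential_test(m, method="moderated")
        mat = tmp_path / "m.tsv"
        pd.DataFrame(vals).to_csv(mat, sep="\t")
        rscript = tmp_path / "oracle.R"
        rscript.write_text(
            "suppressMessages(library(limma))\n"
            f"m <- as.matrix(read.delim('{mat}', row.names=1))\n"
            "design <- cbind(intercept=1, diff=c(rep(1,4), rep(0,4)))\n"
            "fit <- eBayes(lmFit(m, design))\n"
            "cat(fit$df.prior, '\\n')\n"
            "cat(fit$p.value[,'diff'], sep='\\n')\n"
        )
        out = subprocess.run(
            ["Rscript", str(rscript)], capture_output=True, text=True, check=True
        )
        lines = out.stdout.strip().splitlines()
        d0 = float(lines[0])
        p_ref = np.array([float(x) for x in lines[1:]])
        assert res["df"].iloc[0] == pytest.approx(d0 + 6, rel=1e-4)
        np.testing.assert_allclose(res["p"], p_ref, rtol=1e-5, atol=1e-12)

    def test_average_then_test_on_identical_regions(self, five_regions, rng):
        vals2d = rng.normal(8, 0.5, size=(10, 16))
        vals = np.repeat(vals2d[:, :, None], 5, axis=2)
        m = make_matrix(vals, GROUPS_8V8, regions=five_regions)
        one = differential_test(m.subset_region("amygdala"), method="student")
        avg = differential_test(average_regions(m), method="student")
        np.testing.assert_allclose(avg["log2_diff"], one["log2_diff"])
        assert (avg["p"] <= one["p"] + 1e-15).all()


# ----------------------------------------------------------------------
# FDR
# ----------------------------------------------------------------------

class TestBhFdr:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.2], [0.2]),
            ([0.07, 0.07, 0.07], [0.07, 0.07, 0.07]),
        ],
    )
    def test_hand_executed_examples(self, p, expected):
        np.testing.assert_allclose(bh_fdr(p), expected)

    def test_against_stepup_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 500))
            p = rng.random(n)
            np.testing.assert_allclose(bh_fdr(p), bh_stepup(p), rtol=1e-12)

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.random(200)
        q = bh_fdr(p)
        assert (q >= p - 1e-15).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_invalid_p_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])
        with pytest.raises(ValidationError):
            bh_fdr([-0.1])


# ----------------------------------------------------------------------
# Ratio conventions
# ----------------------------------------------------------------------

class TestRatioConventions:
    @pytest.mark.parametrize(
        "ld, fc", [(1.0, 2.0), (-1.0, -2.0), (0.0, 1.0), (np.log2(2.22), 2.22)]
    )
    def test_signed_fold_change(self, ld, fc):
        assert signed_fold_change(ld) == pytest.approx(fc)

    def test_published_ratio_round_trip(self):
        # Ptprr, nucleus accumbens: signed ratio 2.22 <-> log2 diff ~ 1.1504
        assert to_log2(2.22) == pytest.approx(1.1506, abs=1e-4)
        assert signed_fold_change(to_log2(2.22)) == pytest.approx(2.22)

    @given(st.floats(min_value=-20, max_value=20, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_round_trip_and_oddness(self, ld):
        s = signed_fold_change(ld)
        assert abs(s) >= 1
        assert to_log2(s) == pytest.approx(ld, abs=1e-9)
        # swapping the groups negates the log2 difference and maps s -> -s
        if ld != 0:
            assert signed_fold_change(-ld) == pytest.approx(-s)

    @pytest.mark.parametrize("s, ld", [(2.0, 1.0), (-2.0, -1.0), (1.0, 0.0)])
    def test_to_log2(self, s, ld):
        assert to_log2(s) == pytest.approx(ld)

    def test_to_log2_rejects_convention_violation(self):
        with pytest.raises(ValidationError):
            to_log2(0.5)

    @pytest.mark.parametrize("a, b, expected", [(3.0, 3.0, 0.0), (2.0, 4.0, 1.0), (4.0, 2.0, -0.5)])
    def test_relative_difference(self, a, b, expected):
        assert relative_difference(a, b) == pytest.approx(expected)

    def test_relative_difference_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            relative_difference(0.0, 1.0)


# ----------------------------------------------------------------------
# Count summary
# ----------------------------------------------------------------------

class TestSummarizeCounts:
    regions = ["r1", "r2", "r3", "r4", "r5"]

    def _random_results(self, rng, n=80):
        rows = []
        for i in range(n):
            for ctx in self.regions + [COMBINED]:
                rows.append({"probe_set_id": f"p{i}", "context": ctx, "q": rng.random()})
        return pd.DataFrame(rows)

    def test_no_significant_gives_zeros(self):
        res = pd.DataFrame(
            {"probe_set_id": ["p1"], "context": ["r1"], "q": [0.9]}
        )
        table = summarize_counts(res, 0.25, self.regions)
        assert (table["count"] == 0).all()

    def test_two_region_probe_counts(self):
        rows = [
            {"probe_set_id": "p1", "context": "r1", "q": 0.1},
            {"probe_set_id": "p1", "context": "r2", "q": 0.1},
            {"probe_set_id": "p1", "context": COMBINED, "q": 0.9},
        ]
        table = summarize_counts(pd.DataFrame(rows), 0.25, self.regions)
        get = lambda s, c: int(table.set_index(["statistic", "context"]).loc[(s, c), "count"])
        assert get("total", "at_least_one_region") == 1
        assert get("total", "multiple_regions") == 1
        assert get("single_region_only", "r1") == 0
        assert get("single_region_only", "r2") == 0

    def test_matches_brute_force_recount(self, rng):
        res = self._random_results(rng)
        table = summarize_counts(res, 0.25, self.regions)
        sig = res[res["q"] <= 0.25]
        by_region = {
            r: set(sig.loc[sig["context"] == r, "probe_set_id"]) for r in self.regions
        }
        combined = set(sig.loc[sig["context"] == COMBINED, "probe_set_id"])
        expected = count_summary_recount(by_region, combined, self.regions)
        for row in table.itertuples(index=False):
            assert row.count == expected[(row.statistic, row.context)]
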