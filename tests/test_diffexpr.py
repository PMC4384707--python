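"""Differential expression: technical-replicate collapse, fold change,
per-probe tests (Welch and moderated), BH adjustment, condition calling."""

import math
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atdose.diffexpr import (
    DesignError,
    ExpressionStudy,
    benjamini_hochberg,
    call_de,
    collapse_technical,
    de_summary,
    fold_change,
    moderated_test,
    probe_test,
)
from atdose.simulate import SimulationDesign, gen_expression


def bh_stepup_oracle(p):
    """Brute-force BH: sort, q_i = p_i * m / i, cumulative min from the top."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        q[i] = min(q[i], q[i + 1])
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def tiny_study(matrix_values, n_tech=1):
    """Two-condition study: 3 control + 3 treated biological replicates."""
    n_probes, _ = matrix_values.shape
    cols, rows = {}, []
    j = 0
    for is_ctrl in (True, False):
        for b in range(1, 4):
            for tech in range(1, n_tech + 1):
                sid = f"{'c' if is_ctrl else 't'}{b}_{tech}"
                cols[sid] = matrix_values[:, j]
                rows.append({"sample_id": sid, "activity_kbq": 0.0 if is_ctrl else 1.7,
                             "time_h": 24.0 if is_ctrl else 1.0, "bio_rep": b,
                             "tech_rep": tech, "is_control": is_ctrl})
                j += 1
    return ExpressionStudy(
        matrix=pd.DataFrame(cols, index=[f"p{i}" for i in range(n_probes)]),
        samples=pd.DataFrame(rows),
    )


class TestCollapseTechnical:
    def make_study(self, values_by_sample):
        cols, rows = {}, []
        for sid, (b, tech, vals) in values_by_sample.items():
            cols[sid] = vals
            rows.append({"sample_id": sid, "activity_kbq": 1.7, "time_h": 1.0,
                         "bio_rep": b, "tech_rep": tech, "is_control": False})
        rows.append({"sample_id": "c", "activity_kbq": 0.0, "time_h": 24.0,
                     "bio_rep": 1, "tech_rep": 1, "is_control": True})
        cols["c"] = vals * 0
        return ExpressionStudy(matrix=pd.DataFrame(cols), samples=pd.DataFrame(rows))

    def test_identical_columns_collapse_to_same(self):
        v = np.array([1.0, 5.0])
        s = self.make_study({"a": (1, 1, v), "b": (1, 2, v), "c2": (1, 3, v)})
        out = collapse_technical(s)
        treated = out.samples.loc[~out.samples.is_control, "sample_id"].iloc[0]
        assert np.allclose(out.matrix[treated], v)

    def test_mean_of_log2_values(self):
        s = self.make_study({"a": (1, 1, np.array([1.0])), "b": (1, 2, np.array([2.0])),
                             "c2": (1, 3, np.array([3.0]))})
        out = collapse_technical(s)
        treated = out.samples.loc[~out.samples.is_control, "sample_id"].iloc[0]
        assert out.matrix[treated].iloc[0] == pytest.approx(2.0)

    def test_idempotent(self, rng):
        study, _ = gen_expression(
            SimulationDesign(seed=3, n_probes=500, n_up_per_condition=8,
                             n_down_per_condition=4, n_biomarkers_per_pattern=1)
        )
        once = collapse_technical(study)
        twice = collapse_technical(once)
        assert np.allclose(once.matrix.to_numpy(), twice.matrix.to_numpy())

    def test_duplicate_tech_rep_annotation_rejected(self):
        v = np.array([1.0])
        with pytest.raises(DesignError, match="duplicate"):
            self.make_study({"a": (1, 1, v), "b": (1, 1, v)})


class TestFoldChange:
    @pytest.mark.parametrize(
        "treated, control, expected",
        [([3, 3], [1, 1], 4.0), ([1, 1], [3, 3], -4.0), ([2, 2], [2, 2], 1.0)],
    )
    def test_signed_convention(self, treated, control, expected):
        assert fold_change(treated, control) == pytest.approx(expected)

    @given(
        a=st.lists(st.floats(-5, 15), min_size=2, max_size=5),
        b=st.lists(st.floats(-5, 15), min_size=2, max_size=5),
    )
    @settings(max_examples=50, deadline=None)
    def test_antisymmetric_for_unequal_means(self, a, b):
        if abs(np.mean(a) - np.mean(b)) < 1e-9:
            return
        assert fold_change(a, b) == pytest.approx(-fold_change(b, a), rel=1e-9)

    def test_abs_fc_at_least_one(self, rng):
        for _ in range(20):
            fc = fold_change(rng.normal(7, 1, 3), rng.normal(7, 1, 3))
            assert abs(fc) >= 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(DesignError):
            fold_change([], [1, 2])


class TestProbeTest:
    def test_identical_groups_give_p_one(self):
        assert probe_test([5.0, 5.0, 5.0], [5.0, 5.0, 5.0]) == 1.0

    def test_separated_tight_groups(self):
        # hand Welch: t = 10 / (0.01*sqrt(2/3)), huge; p far below 1e-4
        a = [10.0, 10.01, 9.99]
        b = [0.0, 0.01, -0.01]
        p = probe_test(a, b)
        # textbook Welch check
        va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
        t = (np.mean(a) - np.mean(b)) / math.sqrt(va / 3 + vb / 3)
        assert t > 100
        assert p < 1e-4

    def test_symmetric_under_label_swap(self, rng):
        a, b = rng.normal(0, 1, 4), rng.normal(1, 1, 4)
        assert probe_test(a, b) == pytest.approx(probe_test(b, a))

    def test_small_group_rejected(self):
        with pytest.raises(DesignError):
            probe_test([1.0], [1.0, 2.0])


class TestModeratedTest:
    def test_matches_limma_ebayes(self, rng, tmp_path):
        """Independent oracle: limma's moderated t on the same matrix."""
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        n = 200
        sd = np.exp(rng.normal(-1.2, 0.4, n))
        a = rng.normal(0, 1, (n, 3)) * sd[:, None]
        b = rng.normal(0, 1, (n, 3)) * sd[:, None]
        a[:15] += 1.5
        pd.DataFrame(np.hstack([a, b])).to_csv(tmp_path / "m.tsv", sep="\t", index=False)
        script = textwrap.dedent(
            """
            suppressMessages(library(limma))
            m <- as.matrix(read.delim("m.tsv"))
            design <- cbind(Intercept=1, Treat=c(1,1,1,0,0,0))
            fit <- eBayes(lmFit(m, design))
            write.csv(data.frame(p=fit$p.value[,"Treat"]), "out.csv", row.names=FALSE)
            """
        )
        (tmp_path / "s.R").write_text(script)
        res = subprocess.run(["Rscript", "s.R"], cwd=tmp_path, capture_output=True)
        if res.returncode != 0:
            pytest.skip(f"limma unavailable: {res.stderr.decode()[:200]}")
        p_limma = pd.read_csv(tmp_path / "out.csv")["p"].to_numpy()
        p_mine = moderated_test(a, b)
        assert np.max(np.abs(p_mine - p_limma)) < 1e-8

    def test_large_effects_reach_far_smaller_p_than_welch(self, rng):
        n = 2000
        a = rng.normal(0, 0.25, (n, 3))
        b = rng.normal(0, 0.25, (n, 3))
        a[:50] += 2.0
        p_mod = moderated_test(a, b)
        assert np.median(p_mod[:50]) < 1e-10
        assert (p_mod[50:] < 0.01).mean() < 0.03  # nulls stay calibrated


class TestBenjaminiHochberg:
    def test_frozen_worked_example(self):
        got = benjamini_hochberg([0.001, 0.008, 0.039, 0.041])
        assert np.allclose(got, [0.004, 0.016, 0.041, 0.041])

    def test_all_equal_unchanged(self):
        assert np.allclose(benjamini_hochberg([0.3] * 5), [0.3] * 5)

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.1, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_matches_stepup_oracle_and_bounds(self, p):
        got = benjamini_hochberg(p)
        assert np.allclose(got, bh_stepup_oracle(p), atol=1e-12)
        assert np.all(got >= np.asarray(p) - 1e-12)
        assert np.all(got <= 1.0)


class TestCallDE:
    def test_planted_counts_recovered(self, default_study, default_calls):
        """50 up / 30 down per condition (|FC|=4, sd 0.25) recovered within
        +/-10%, with the planted biomarker probes on top."""
        study, truth = default_study
        for cond, calls in default_calls.items():
            col = f"log2fc_{cond[0]:g}kbq_{cond[1]:g}h"
            tt = truth.probe_truth.set_index("probe")[col]
            n_up_true = int((tt > 0).sum())
            n_down_true = int((tt < 0).sum())
            n_up, n_down = de_summary(calls)
            assert abs(n_up - n_up_true) <= 0.1 * n_up_true
            assert abs(n_down - n_down_true) <= 0.1 * n_down_true

    def test_recall_and_fdr(self, default_study, default_calls):
        study, truth = default_study
        for cond, calls in default_calls.items():
            col = f"log2fc_{cond[0]:g}kbq_{cond[1]:g}h"
            planted = set(truth.probe_truth.probe[truth.probe_truth[col] != 0])
            sig = set(calls.index[calls.significant])
            recall = len(sig & planted) / len(planted)
            fdr = len(sig - planted) / max(1, len(sig))
            assert recall >= 0.9
            assert fdr <= 0.05

    def test_null_matrix_nearly_no_false_positives(self, rng):
        vals = rng.normal(7, 0.25, (5000, 6))
        study = tiny_study(vals)
        calls = call_de(study, (1.7, 1.0))
        assert calls["significant"].sum() <= 2

    def test_up_only_signal_gives_no_downcalls(self, rng):
        vals = rng.normal(7, 0.25, (1000, 6))
        vals[:20, 3:] += 2.5
        calls = call_de(tiny_study(vals), (1.7, 1.0))
        n_up, n_down = de_summary(calls)
        assert n_down == 0
        assert n_up >= 15

    def test_unknown_condition_lists_available(self, default_study):
        study, _ = default_study
        with pytest.raises(DesignError, match=r"available"):
            call_de(study, (9.9, 9.9))

    def test_probe_order_permutation_invariant(self, rng):
        vals = rng.normal(7, 0.25, (500, 6))
        vals[:10, 3:] += 2.0
        study = tiny_study(vals)
        calls = call_de(study, (1.7, 1.0))
        perm = rng.permutation(study.matrix.index)
        study2 = ExpressionStudy(matrix=study.matrix.loc[perm],
                                 samples=study.samples)
        calls2 = call_de(study2, (1.7, 1.0))
        a = set(calls.index[calls.significant])
        b = set(calls2.index[calls2.significant])
        assert a == b

    def test_welch_method_available(self, rng):
        vals = rng.normal(7, 0.05, (200, 6))
        vals[:5, 3:] += 3.0
        calls = call_de(tiny_study(vals), (1.7, 1.0), method="welch")
        assert set(calls.columns) >= {"fold_change", "p_raw", "p_adj", "significant"}
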