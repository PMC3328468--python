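"""Confusion-table metrics, panel calling/search, group tests, concordance
and the paired pre/post comparison."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from methylpanel.diagnostics import (
    ConfusionTable,
    PanelDefinition,
    call_panel,
    concordance,
    diagnostics,
    group_test,
    paired_prepost,
    round_pct,
    search_panel,
    wilson_ci,
)
from methylpanel.simulate import MatrixSimConfig, simulate_matrix

from conftest import make_matrix


class TestRounding:
    def test_half_away_from_zero(self):
        assert round_pct(0.12195) == 12.20   # 12.195 rounds up, not truncates
        assert round_pct(0.042445) == 4.24
        assert round_pct(142 / 149) == 95.30

    def test_wilson_matches_statsmodels(self, rng):
        from statsmodels.stats.proportion import proportion_confint

        for _ in range(50):
            n = int(rng.integers(1, 400))
            k = int(rng.integers(0, n + 1))
            lo, hi = wilson_ci(k, n)
            slo, shi = proportion_confint(k, n, alpha=0.05, method="wilson")
            assert lo == pytest.approx(slo, abs=2e-4)
            assert hi == pytest.approx(shi, abs=2e-4)


class TestDiagnostics:
    def test_single_marker_predictive_values(self):
        # 90/212 positive cases, 142/149 negative controls
        table = ConfusionTable(tp=90, fn=122, tn=142, fp=7)
        m = diagnostics(table=table).metrics
        assert m.ppv.percent == 92.78
        assert m.npv.percent == 53.79
        assert m.sensitivity.percent == 42.45
        assert m.specificity.percent == 95.30

    def test_five_marker_panel_headline(self):
        table = ConfusionTable(tp=188, fn=24, tn=130, fp=19)
        m = diagnostics(table=table).metrics
        assert m.sensitivity.percent == 88.68
        assert m.specificity.percent == 87.25

    def test_perfect_classifier(self):
        m = diagnostics(table=ConfusionTable(tp=10, fn=0, tn=10, fp=0)).metrics
        for name in ("sensitivity", "specificity", "ppv", "npv", "accuracy"):
            assert getattr(m, name).percent == 100.0
        assert m.auc_binary.value == 1.0

    def test_zero_denominator_flagged_not_nan(self):
        m = diagnostics(table=ConfusionTable(tp=0, fn=0, tn=5, fp=3)).metrics
        assert not m.sensitivity.defined
        assert m.sensitivity.value is None
        assert not m.auc_binary.defined

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        tp=st.integers(0, 500), fp=st.integers(0, 500),
        tn=st.integers(0, 500), fn=st.integers(0, 500),
    )
    def test_metric_identities(self, tp, fp, tn, fn):
        """SN*(TP+FN) = TP, PPV*(TP+FP) = TP, etc., and AUC = (SN+SP)/2."""
        if tp + fp + tn + fn == 0:
            return
        m = diagnostics(table=ConfusionTable(tp=tp, fp=fp, tn=tn, fn=fn)).metrics
        if m.sensitivity.defined:
            assert m.sensitivity.value * (tp + fn) == pytest.approx(tp)
        if m.specificity.defined:
            assert m.specificity.value * (tn + fp) == pytest.approx(tn)
        if m.ppv.defined:
            assert m.ppv.value * (tp + fp) == pytest.approx(tp)
        if m.npv.defined:
            assert m.npv.value * (tn + fn) == pytest.approx(tn)
        if m.auc_binary.defined:
            assert m.auc_binary.value == pytest.approx(
                (m.sensitivity.value + m.specificity.value) / 2
            )
            assert 0 <= m.auc_binary.value <= 1


class TestCallPanel:
    def _random_matrix(self, rng, n=50, k=8):
        groups = ["BC"] * (n // 2) + ["normal_control"] * (n - n // 2)
        calls = {f"G{j}": (rng.random(n) < 0.3).astype(float) for j in range(k)}
        return make_matrix(calls, groups)

    def test_all_negative_matrix_predicts_negative(self):
        m = make_matrix({"A": [0.0] * 4, "B": [0.0] * 4}, ["BC"] * 4)
        pred = call_panel(m, PanelDefinition(("A", "B")))
        assert (pred == 0).all()

    def test_single_positive_member_suffices_at_m1(self):
        calls = {g: [0.0] for g in "ABCDE"}
        calls["C"] = [1.0]
        m = make_matrix(calls, ["BC"])
        pred = call_panel(m, PanelDefinition(tuple("ABCDE"), min_positive=1))
        assert pred.iloc[0] == 1.0

    @pytest.mark.parametrize("m_pos", [1, 2, 3])
    def test_matches_per_sample_hand_count(self, rng, m_pos):
        mat = self._random_matrix(rng)
        members = tuple(f"G{j}" for j in range(5))
        pred = call_panel(mat, PanelDefinition(members, min_positive=m_pos))
        for sample in mat.samples:
            row = mat.calls.loc[sample, list(members)]
            assert pred[sample] == float((row == 1).sum() >= m_pos)

    def test_all_member_calls_missing_gives_missing_prediction(self):
        m = make_matrix({"A": [np.nan], "B": [np.nan]}, ["BC"])
        pred = call_panel(m, PanelDefinition(("A", "B")))
        assert np.isnan(pred.iloc[0])

    def test_unknown_member_errors(self, rng):
        mat = self._random_matrix(rng)
        with pytest.raises(KeyError, match="NOPE"):
            call_panel(mat, PanelDefinition(("G0", "NOPE")))

    def test_adding_a_gene_is_sn_up_sp_down(self, rng):
        """Any-positive monotonicity: a larger panel never loses
        sensitivity and never gains specificity."""
        mat = self._random_matrix(rng, n=120)
        truth = (mat.groups == "BC").astype(float).to_numpy()
        members: list[str] = []
        prev_sn, prev_sp = -1.0, 2.0
        for g in [f"G{j}" for j in range(8)]:
            members.append(g)
            pred = call_panel(mat, PanelDefinition(tuple(members))).to_numpy()
            m = diagnostics(pred, truth).metrics
            assert m.sensitivity.value >= prev_sn
            assert m.specificity.value <= prev_sp
            prev_sn, prev_sp = m.sensitivity.value, m.specificity.value


class TestSearchPanel:
    def _matrix(self, seed=0, n_targets=6):
        rates = {
            "BC": {f"G{j}": 0.15 + 0.08 * j for j in range(n_targets)},
            "normal_control": {f"G{j}": 0.02 + 0.01 * j for j in range(n_targets)},
        }
        cfg = MatrixSimConfig(
            group_sizes={"BC": 60, "normal_control": 50},
            rates=rates, seed=seed,
        )
        return simulate_matrix(cfg)

    def test_single_candidate_returns_singleton(self):
        mat = self._matrix()
        res = search_panel(mat, ["G3"])
        assert res.best.members == ("G3",)

    def test_oracle_gene_wins_with_perfect_auc(self):
        n_bc, n_nc = 20, 20
        truth_col = [1.0] * n_bc + [0.0] * n_nc
        calls = {"ORACLE": truth_col, "NOISE": [0.0, 1.0] * 20}
        mat = make_matrix(calls, ["BC"] * n_bc + ["normal_control"] * n_nc)
        res = search_panel(mat, ["ORACLE", "NOISE"])
        assert res.best.members == ("ORACLE",)
        assert res.score == 1.0

    def test_matches_independent_enumeration(self):
        mat = self._matrix(seed=7)
        candidates = [f"G{j}" for j in range(6)]
        res = search_panel(mat, candidates)
        # independent oracle: plain pandas enumeration of every subset
        truth = mat.groups == "BC"
        best_score, best_members = -1.0, None
        for size in range(1, 7):
            for members in itertools.combinations(sorted(candidates), size):
                pred = (mat.calls[list(members)] == 1).any(axis=1)
                sn = (pred & truth).sum() / truth.sum()
                sp = (~pred & ~truth).sum() / (~truth).sum()
                score = (sn + sp) / 2
                if score > best_score + 1e-12:
                    best_score, best_members = score, members
        assert res.best.members == best_members
        assert res.score == pytest.approx(best_score)
        assert len(res.trace) == 2**6 - 1

    def test_invariant_under_candidate_permutation(self):
        mat = self._matrix(seed=3)
        cand = [f"G{j}" for j in range(5)]
        a = search_panel(mat, cand)
        b = search_panel(mat, cand[::-1])
        assert a.best.members == b.best.members

    def test_no_candidates_errors(self):
        with pytest.raises(ValueError, match="no candidate"):
            search_panel(self._matrix(), [])


class TestGroupTest:
    def test_perfect_separation_is_overwhelming(self):
        calls = {"T": [1.0] * 50 + [0.0] * 50}
        m = make_matrix(calls, ["BC"] * 50 + ["normal_control"] * 50)
        res = group_test(m, "T", "BC", "normal_control")
        assert res.p_value < 1e-15

    def test_independence_gives_chi2_zero(self):
        calls = {"T": [1.0] * 10 + [0.0] * 10 + [1.0] * 10 + [0.0] * 10}
        m = make_matrix(calls, ["BC"] * 20 + ["normal_control"] * 20)
        res = group_test(m, "T", "BC", "normal_control")
        assert res.method == "chi2"
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_small_expected_counts_switch_to_fisher(self):
        calls = {"T": [1.0, 1.0, 0.0, 0.0, 0.0] + [0.0] * 5}
        m = make_matrix(calls, ["BC"] * 5 + ["normal_control"] * 5)
        res = group_test(m, "T", "BC", "normal_control")
        assert res.method == "fisher_exact"

    def test_degenerate_margin_flagged(self):
        calls = {"T": [0.0] * 6}
        m = make_matrix(calls, ["BC"] * 3 + ["normal_control"] * 3)
        res = group_test(m, "T", "BC", "normal_control")
        assert not res.defined and res.p_value is None

    def test_fisher_p_equals_hypergeometric_enumeration(self, rng):
        """Two-sided point-probability rule re-derived from the
        hypergeometric pmf."""
        checked = 0
        while checked < 200:
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            table = np.array([[a, b], [c, d]])
            if table.sum() == 0 or (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
                continue
            _, p = stats.fisher_exact(table)
            n, r1, c1 = table.sum(), a + b, a + c
            lo, hi = max(0, r1 + c1 - n), min(r1, c1)
            pmf = {x: stats.hypergeom.pmf(x, n, r1, c1) for x in range(lo, hi + 1)}
            p_obs = pmf[a]
            p_enum = sum(v for v in pmf.values() if v <= p_obs * (1 + 1e-9))
            assert p == pytest.approx(min(1.0, p_enum), abs=1e-12)
            checked += 1

    def test_reference_counts_are_strongly_separated(self):
        """Marker positive in 90/212 cases vs 7/149 controls: p << 1e-4."""
        calls = {"T": [1.0] * 90 + [0.0] * 122 + [1.0] * 7 + [0.0] * 142}
        m = make_matrix(calls, ["BC"] * 212 + ["normal_control"] * 149)
        res = group_test(m, "T", "BC", "normal_control")
        assert res.method == "chi2"
        assert res.p_value < 1e-4


class TestConcordance:
    def test_cystoscopy_breakdown(self):
        # 32 reference-positive (25 panel-positive), 16 reference-negative
        # (14 panel-negative) -> 39/48 agreement
        ref = [1.0] * 32 + [0.0] * 16
        pred = [1.0] * 25 + [0.0] * 7 + [0.0] * 14 + [1.0] * 2
        res = concordance(pred, ref)
        assert res.agreement == 39 / 48
        assert res.agreement_percent == 81.25
        assert res.both_positive == 25 and res.both_negative == 14

    def test_identical_vectors_agree_fully(self, rng):
        v = (rng.random(30) < 0.5).astype(float)
        assert concordance(v, v).agreement == 1.0

    def test_matches_hand_count(self, rng):
        pred = (rng.random(200) < 0.4).astype(float)
        ref = (rng.random(200) < 0.5).astype(float)
        res = concordance(pred, ref)
        assert res.agreement == np.mean(pred == ref)

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            concordance([1.0], [1.0, 0.0])


class TestPairedPrePost:
    def test_surgery_clears_methylation(self):
        pre = [1.0] * 21
        post = [1.0] * 2 + [0.0] * 19
        res = paired_prepost(pre, post)
        assert round_pct(res.pre_rate, 1) == 100.0
        assert round_pct(res.post_rate, 1) == 9.5
        assert res.p_value < 1e-4

    def test_no_change_gives_p_one(self, rng):
        v = (rng.random(15) < 0.5).astype(float)
        res = paired_prepost(v, v)
        assert res.n_discordant == 0 and res.p_value == 1.0

    def test_matches_statsmodels_exact_mcnemar(self, rng):
        from statsmodels.stats.contingency_tables import mcnemar

        for _ in range(50):
            n = int(rng.integers(2, 60))
            pre = (rng.random(n) < 0.5).astype(float)
            post = (rng.random(n) < 0.5).astype(float)
            res = paired_prepost(pre, post)
            table = [
                [((pre == 1) & (post == 1)).sum(), ((pre == 1) & (post == 0)).sum()],
                [((pre == 0) & (post == 1)).sum(), ((pre == 0) & (post == 0)).sum()],
            ]
            sm = mcnemar(table, exact=True)
            assert res.p_value == pytest.approx(float(sm.pvalue), abs=1e-12)
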