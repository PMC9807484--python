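import itertools
import math

import numpy as np
import pytest

from mirameta.bias import (begg_exact_p, begg_test, bias_summary,
                           default_bias_targets, egger_test, fixed_effect_center,
                           funnel_data, kendall_s, trim_and_fill)
from mirameta.corpus import StudyCorpus
from mirameta.meta import run_meta

from conftest import make_effects, make_record


def brute_force_two_sided_p(s_obs: int, k: int) -> float:
    """Full k! enumeration of the Kendall S permutation null."""
    base = list(range(k))
    hits = total = 0
    for perm in itertools.permutations(base):
        s = kendall_s(base, perm)
        total += 1
        hits += abs(s) >= abs(s_obs)
    return hits / total


class TestBegg:
    @pytest.mark.parametrize("k", [3, 4, 5, 6])
    def test_exact_p_equals_full_enumeration(self, k):
        smax = k * (k - 1) // 2
        for s_obs in range(-smax, smax + 1, 2):
            assert begg_exact_p(s_obs, k) == pytest.approx(
                brute_force_two_sided_p(s_obs, k), abs=1e-12)

    def test_concordant_k4(self):
        # monotone funnel: deviates and variances strictly concordant
        eff = make_effects([0.5, 1.2, 2.0, 3.5], [0.05, 0.2, 0.7, 2.0])
        tau, p, method = begg_test(eff)
        assert method == "exact"
        assert tau == pytest.approx(1.0)
        assert p == pytest.approx(0.0833, abs=1e-4)

    def test_concordant_k6(self):
        vs = [0.05, 0.1, 0.25, 0.6, 1.2, 2.5]
        eff = make_effects([0.3, 0.9, 1.6, 2.5, 3.6, 5.0], vs)
        tau, p, method = begg_test(eff)
        assert (tau, method) == (pytest.approx(1.0), "exact")
        assert p == pytest.approx(0.0028, abs=1e-4)

    def test_concordant_k3(self):
        eff = make_effects([0.5, 1.5, 3.0], [0.1, 0.5, 2.0])
        tau, p, method = begg_test(eff)
        assert p == pytest.approx(1 / 3, abs=1e-6)

    def test_large_k_uses_normal_approx(self):
        rng = np.random.default_rng(3)
        eff = make_effects(rng.normal(size=12), rng.uniform(0.1, 2.0, size=12))
        _, p, method = begg_test(eff)
        assert method == "normal_approx" and 0 <= p <= 1

    def test_single_parent_not_testable(self):
        eff = make_effects([1.0, 2.0, 3.0], [0.1, 0.5, 1.0], parents=["p"] * 3)
        assert begg_test(eff) == (None, None, "not_testable")


class TestEgger:
    def test_symmetric_construction_zero_intercept(self):
        eff = make_effects([1.0, -1.0, 2.0, -2.0], [1.0, 1.0, 4.0, 4.0])
        intercept, z, p, perfect = egger_test(eff)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert not perfect

    def test_closed_form_ols(self):
        # x = 1/se = (1,2,3); t = y/se = (2,3,5) -> intercept 1/3
        se = np.array([1.0, 0.5, 1 / 3])
        t = np.array([2.0, 3.0, 5.0])
        intercept, z, p, _ = egger_test(make_effects(t * se, se ** 2))
        assert intercept == pytest.approx(1 / 3, abs=1e-9)

    def test_perfect_fit_flagged(self):
        x = np.array([1.0, 2.0, 4.0, 8.0])
        t = 1.0 + 2.0 * x
        se = 1.0 / x
        intercept, z, p, perfect = egger_test(make_effects(t * se, se ** 2))
        assert perfect and intercept == pytest.approx(1.0, abs=1e-8)
        assert math.isinf(z)

    def test_degenerate_precision_design(self):
        with pytest.raises(ValueError, match="degenerate"):
            egger_test(make_effects([1.0, 2.0, 3.0], 1.0))


class TestTrimAndFill:
    def test_symmetric_returns_zero_k0(self):
        k0, filled, mu, _ = trim_and_fill(make_effects([-2, -1, 0, 1, 2], 1.0))
        assert k0 == 0 and len(filled) == 5
        assert mu == pytest.approx(0.0, abs=1e-12)

    def test_worked_example_right_side(self):
        eff = make_effects([0.0, 3.0, 3.1, 3.2, 3.3], 1.0)
        k0, filled, mu, p = trim_and_fill(eff, side="right")
        assert k0 == 1
        fills = [e.y for e in filled[5:]]
        assert fills == [pytest.approx(1.35, abs=1e-10)]

    def test_mirrored_fill_preserves_trimmed_center(self):
        eff = make_effects([0.0, 3.0, 3.1, 3.2, 3.3], 1.0)
        k0, filled, _, _ = trim_and_fill(eff, side="right")
        trimmed = sorted(e.y for e in eff)[: len(eff) - k0]
        assert fixed_effect_center(filled) == pytest.approx(np.mean(trimmed), abs=1e-12)

    def test_left_censoring_detected(self):
        """Suppressing the low side of a symmetric funnel yields k0 >= 1
        (imputing on the left) in the clear majority of replicates."""
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(100):
            v = rng.uniform(0.05, 1.5, size=20)
            y = rng.normal(0.5, np.sqrt(v))  # dispersion from sampling variance
            keep = np.argsort(y)[6:]  # censor the lowest 30%
            k0, *_ = trim_and_fill(make_effects(y[keep], v[keep]), side="right")
            hits += k0 >= 1
        assert hits > 50

    def test_mu_moves_toward_suppressed_side(self):
        eff = make_effects([0.0, 3.0, 3.1, 3.2, 3.3], 1.0)
        _, _, mu_adj, _ = trim_and_fill(eff, side="right")
        mu_naive = fixed_effect_center(eff)
        assert mu_adj < mu_naive


class TestBiasSummary:
    def _corpus(self, n_sub, parent_per_sub=True, mirna="miR-126-3p"):
        recs = []
        for i in range(n_sub):
            recs.append(make_record(
                substudy_id=f"s{i}", parent=f"p{i}" if parent_per_sub else "p0",
                mirna=mirna, n_case=10 + 4 * i, n_ctrl=10 + 4 * i,
                events_case=8 + i, events_ctrl=2))
        return StudyCorpus(recs)

    def test_full_report_for_independent_substudies(self):
        corpus = self._corpus(8)
        analysis = run_meta(corpus)
        (rep,) = bias_summary(analysis, corpus)
        assert rep.begg_method in ("exact", "normal_approx")
        assert rep.p_begg is not None and rep.k0 is not None
        assert rep.significant_after_correction is not None

    def test_single_parent_study_not_testable(self):
        corpus = self._corpus(4, parent_per_sub=False)
        analysis = run_meta(corpus)
        (rep,) = bias_summary(analysis, corpus)
        assert rep.begg_method == "not_testable"
        assert rep.p_begg is None and rep.k0 is None

    def test_absent_target_skipped(self):
        corpus = self._corpus(4)
        analysis = run_meta(corpus)
        reports = bias_summary(analysis, corpus, targets=["miR-999-3p"])
        assert reports == []

    def test_default_targets_most_reported(self, two_mirna_corpus):
        analysis = run_meta(two_mirna_corpus)
        targets = default_bias_targets(analysis, n_top=1)
        assert targets[0] in {"miR-10a-5p", "miR-20b-5p"}


def test_funnel_center_is_fixed_effect():
    eff = make_effects([0.5, 1.0, 1.5], [0.1, 0.2, 0.4])
    fd = funnel_data(eff)
    w = 1 / np.array([0.1, 0.2, 0.4])
    assert fd.center == pytest.approx(np.sum(w * [0.5, 1.0, 1.5]) / w.sum())
    assert [p[1] for p in fd.points] == pytest.approx(np.sqrt([0.1, 0.2, 0.4]))
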